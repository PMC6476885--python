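"""DMR annotation: CpG density, length bins, clusters, gene proximity,
and cross-set (generation) overlap.

All coordinates are 0-based half-open.  Gene association follows the
promoter-inclusive convention of measuring the edge-to-edge gap between
the DMR and the gene body, associating when the gap is at most 10 kb
(overlap counts as gap 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .dmr import DmrSet

__all__ = [
    "cpg_annotate",
    "density_histogram",
    "length_histogram",
    "associate_genes",
    "detect_clusters",
    "overlap_sets",
    "OverlapResult",
]


def load_genome(fasta_path):
    """Open an (indexed) FASTA for annotation lookups."""
    import pyfaidx

    return pyfaidx.Fasta(str(fasta_path))


def _get_seq(genome, chrom: str, start: int, end: int) -> str:
    """Fetch a sequence slice from a pyfaidx Fasta, SimGenome, or mapping."""
    if hasattr(genome, "sequences"):  # SimGenome
        seq = genome.sequences[chrom]
    elif isinstance(genome, Mapping):
        seq = genome[chrom]
    else:  # pyfaidx.Fasta-like
        rec = genome[chrom]
        if end > len(rec):
            raise ValueError(f"{chrom}:{start}-{end} beyond chromosome end")
        return str(rec[start:end])
    if end > len(seq):
        raise ValueError(f"{chrom}:{start}-{end} beyond chromosome end")
    return seq[start:end]


def count_cpg(seq: str) -> int:
    """Number of CG dinucleotides in a forward scan of ``seq``."""
    return seq.upper().count("CG")


def cpg_annotate(
    dmr_set: DmrSet, genome, desert_threshold: float = 10.0
) -> pd.DataFrame:
    """Per-DMR CpG count, density per 100 bp, length and desert flag.

    ``desert_threshold`` (CpG per 100 bp) only sets a reporting flag;
    nothing downstream consumes it.
    """
    rows = []
    for i, d in enumerate(dmr_set):
        seq = _get_seq(genome, d.chrom, d.start, d.end)
        n_cpg = count_cpg(seq)
        density = n_cpg * 100.0 / d.length
        rows.append(
            {
                "dmr": i,
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "length": d.length,
                "cpg_count": n_cpg,
                "cpg_density_per_100bp": density,
                "cpg_desert": density < desert_threshold,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["dmr", "chrom", "start", "end", "length", "cpg_count",
                 "cpg_density_per_100bp", "cpg_desert"],
    )


def density_histogram(annotation: pd.DataFrame) -> pd.Series:
    """Counts of DMRs per integer CpG-density bin (floor of density)."""
    bins = np.floor(annotation["cpg_density_per_100bp"]).astype(int)
    return bins.value_counts().sort_index()


def length_histogram(annotation: pd.DataFrame, bin_bp: int = 1000) -> pd.Series:
    """Counts of DMRs per length bin (kb bins by default)."""
    bins = (annotation["length"] // bin_bp).astype(int)
    return bins.value_counts().sort_index()


def _interval_gap(s1: int, e1: int, s2: int, e2: int) -> int:
    """Edge-to-edge gap between half-open intervals; 0 when they overlap."""
    if s1 < e2 and s2 < e1:
        return 0
    return s2 - e1 if s2 >= e1 else s1 - e2


def associate_genes(
    dmr_set: DmrSet, genes: pd.DataFrame, max_dist: int = 10_000
) -> tuple[pd.DataFrame, float]:
    """Gene associations for each DMR within ``max_dist`` bp of a gene body.

    Returns the association table (dmr, gene, distance) and the fraction
    of DMRs with at least one associated gene; the remainder are
    intergenic at this distance.
    """
    rows = []
    associated = set()
    by_chrom = {c: g for c, g in genes.groupby("chrom")}
    for i, d in enumerate(dmr_set):
        g = by_chrom.get(d.chrom)
        if g is None:
            continue
        for _, gene in g.iterrows():
            gap = _interval_gap(d.start, d.end, int(gene["start"]), int(gene["end"]))
            if abs(gap) <= max_dist:
                rows.append({"dmr": i, "gene": gene["name"], "distance": abs(gap)})
                associated.add(i)
    table = pd.DataFrame(rows, columns=["dmr", "gene", "distance"])
    frac = len(associated) / len(dmr_set) if len(dmr_set) else float("nan")
    return table, frac


def detect_clusters(
    dmr_set: DmrSet, cluster_gap: int = 2_000_000, min_size: int = 3
) -> np.ndarray:
    """Cluster id per DMR (-1 for unclustered).

    A cluster is a maximal run of at least ``min_size`` DMRs on one
    chromosome whose consecutive start-to-start gaps are all at most
    ``cluster_gap``.
    """
    dmrs = list(dmr_set)
    ids = np.full(len(dmrs), -1, dtype=int)
    order = sorted(range(len(dmrs)), key=lambda i: (dmrs[i].chrom, dmrs[i].start))
    next_id = 0
    run: list[int] = []
    prev_chrom, prev_start = None, None
    def _flush():
        nonlocal next_id
        if len(run) >= min_size:
            for j in run:
                ids[j] = next_id
            next_id += 1
    for i in order:
        d = dmrs[i]
        if prev_chrom == d.chrom and d.start - prev_start <= cluster_gap:
            run.append(i)
        else:
            _flush()
            run = [i]
        prev_chrom, prev_start = d.chrom, d.start
    _flush()
    return ids


@dataclass(frozen=True)
class OverlapResult:
    """Venn cells over 2-3 named DMR sets.

    ``cells`` maps a sorted '&'-joined membership pattern (e.g. "F1&F3")
    to the number of connected components of the overlap graph with that
    pattern; components are chains of DMRs sharing >= 1 bp.
    """

    cells: dict[str, int]
    set_names: tuple[str, ...]

    @property
    def union_size(self) -> int:
        return sum(self.cells.values())


def overlap_sets(named_sets: dict[str, DmrSet]) -> OverlapResult:
    """Region-level Venn of 2 or 3 DMR sets.

    Two DMRs overlap iff they share at least 1 bp.  The intervals of all
    sets are pooled; each connected component of the overlap graph is
    classified by which sets contribute to it and counts once in that
    Venn cell, so the cells sum to the number of components (the union
    size under region-level counting).
    """
    if not 2 <= len(named_sets) <= 3:
        raise ValueError("overlap supports 2 or 3 sets")
    items = []  # (chrom, start, end, set_name)
    for sname, dset in named_sets.items():
        for d in dset:
            items.append((d.chrom, d.start, d.end, sname))
    items.sort(key=lambda t: (t[0], t[1], t[2]))
    cells: dict[str, int] = {}
    comp_sets: set[str] = set()
    cur_chrom, cur_end = None, -1
    def _close():
        if comp_sets:
            key = "&".join(sorted(comp_sets))
            cells[key] = cells.get(key, 0) + 1
    for chrom, start, end, sname in items:
        if chrom == cur_chrom and start < cur_end:
            comp_sets.add(sname)
            cur_end = max(cur_end, end)
        else:
            _close()
            comp_sets = {sname}
            cur_chrom, cur_end = chrom, end
    _close()
    return OverlapResult(cells=cells, set_names=tuple(named_sets))
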