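"""DMR calling from per-window test results.

A differential methylation region (DMR) starts from any window whose
p-value passes a stringent seed threshold, is extended while any window
with p below a laxer extension threshold lies within a fixed distance of
the region edge (absorbing every window in between, so regions stay
contiguous intervals), and regions that touch or overlap after
extension are merged.  Distance is measured edge-to-edge in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .windows import GenomeWindows

__all__ = [
    "DmrConfig",
    "Dmr",
    "DmrSet",
    "call_dmrs",
    "classify_multiple_window",
    "threshold_table",
]


@dataclass(frozen=True)
class DmrConfig:
    p_seed: float = 1e-6
    p_extend: float = 0.1
    extend_dist: int = 1000
    window_size: int = 100
    threshold_grid: tuple[float, ...] = (1e-5, 1e-6, 1e-7, 1e-8)

    def __post_init__(self) -> None:
        if not 0 < self.p_seed <= self.p_extend <= 1:
            raise ValueError("need 0 < p_seed <= p_extend <= 1")
        if self.extend_dist < self.window_size:
            raise ValueError("extend_dist must be >= window_size")


@dataclass(frozen=True)
class Dmr:
    chrom: str
    start: int
    end: int
    seed_windows: tuple[int, ...]       # global window indices with p < p_seed
    n_significant_windows: int
    min_p: float
    min_q: float
    max_abs_log2_fc: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.n_significant_windows < 1:
            raise ValueError("a DMR must contain at least one seed window")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DmrSet:
    dmrs: list[Dmr]
    config: DmrConfig
    name: str = ""

    def __len__(self) -> int:
        return len(self.dmrs)

    def __iter__(self):
        return iter(self.dmrs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": d.chrom,
                    "start": d.start,
                    "end": d.end,
                    "length": d.length,
                    "n_significant_windows": d.n_significant_windows,
                    "min_p": d.min_p,
                    "min_q": d.min_q,
                    "max_abs_log2_fc": d.max_abs_log2_fc,
                }
                for d in self.dmrs
            ],
            columns=[
                "chrom", "start", "end", "length", "n_significant_windows",
                "min_p", "min_q", "max_abs_log2_fc",
            ],
        )

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, d in enumerate(self.dmrs):
                score = -np.log10(max(d.min_p, 1e-300))
                fh.write(f"{d.chrom}\t{d.start}\t{d.end}\tDMR_{i + 1}\t{score:.3f}\n")

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _expand_seed(
    seed: int,
    starts: np.ndarray,
    ends: np.ndarray,
    cand: np.ndarray,
    extend_dist: int,
) -> tuple[int, int]:
    """Expand one seed (local index) to its fixpoint [a, b] (inclusive).

    ``cand`` is a sorted array of local indices with p < p_extend.
    Absorbing a candidate absorbs every window between it and the region,
    so the region is always a contiguous index range.
    """
    a = b = seed
    while True:
        grew = False
        # left: candidates j < a with gap starts[a] - ends[j] <= extend_dist
        pos = np.searchsorted(cand, a)
        if pos > 0:
            left = cand[:pos]
            ok = starts[a] - ends[left] <= extend_dist
            if ok.any():
                a = int(left[np.argmax(ok)])  # farthest qualifying (first True)
                grew = True
        # right: candidates j > b with gap starts[j] - ends[b] <= extend_dist
        pos = np.searchsorted(cand, b, side="right")
        if pos < len(cand):
            right = cand[pos:]
            ok = starts[right] - ends[b] <= extend_dist
            if ok.any():
                b = int(right[len(ok) - 1 - np.argmax(ok[::-1])])  # last True
                grew = True
        if not grew:
            return a, b


def call_dmrs(
    results: pd.DataFrame,
    genome_windows: GenomeWindows,
    config: DmrConfig | None = None,
    name: str = "",
) -> DmrSet:
    """Call DMRs from per-window test results.

    ``results`` must carry ``window_index``, ``p_value`` and optionally
    ``q_value``/``log2_fc`` columns; windows absent from the frame
    (filtered out upstream) participate with p = 1.
    """
    config = config or DmrConfig()
    n = genome_windows.n_windows
    widx = results["window_index"].to_numpy(dtype=np.int64)
    if len(np.unique(widx)) != len(widx):
        raise ValueError("duplicate window indices in results")
    pv = results["p_value"].to_numpy(dtype=float)
    if (pv <= 0).any() or (pv > 1).any():
        raise ValueError("p-values must lie in (0, 1]")

    p_full = np.ones(n)
    p_full[widx] = pv
    q_full = np.ones(n)
    if "q_value" in results:
        q_full[widx] = results["q_value"].to_numpy(dtype=float)
    lfc_full = np.zeros(n)
    if "log2_fc" in results:
        lfc_full[widx] = results["log2_fc"].to_numpy(dtype=float)

    offs = genome_windows.offsets
    dmrs: list[Dmr] = []
    for c, cname in enumerate(genome_windows.chrom_names):
        lo, hi = int(offs[c]), int(offs[c + 1])
        p = p_full[lo:hi]
        seeds = np.flatnonzero(p < config.p_seed)
        if seeds.size == 0:
            continue
        cand = np.flatnonzero(p < config.p_extend)
        _, starts, ends = genome_windows.coords(np.arange(lo, hi))
        intervals = []
        for s in seeds:
            a, b = _expand_seed(int(s), starts, ends, cand, config.extend_dist)
            intervals.append((a, b))
        # merge regions that touch or overlap (inclusive index ranges)
        intervals.sort()
        merged: list[list[int]] = []
        for a, b in intervals:
            if merged and starts[a] <= ends[merged[-1][1]]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        for a, b in merged:
            span = slice(a, b + 1)
            in_span = np.arange(a, b + 1)
            seed_local = in_span[p[span] < config.p_seed]
            dmrs.append(
                Dmr(
                    chrom=cname,
                    start=int(starts[a]),
                    end=int(ends[b]),
                    seed_windows=tuple(int(x) + lo for x in seed_local),
                    n_significant_windows=int(seed_local.size),
                    min_p=float(p[span].min()),
                    min_q=float(q_full[lo:hi][span].min()),
                    max_abs_log2_fc=float(np.abs(lfc_full[lo:hi][span]).max()),
                )
            )
    return DmrSet(dmrs=dmrs, config=config, name=name)


def classify_multiple_window(dmr_set: DmrSet) -> tuple[int, int, dict[int, int]]:
    """Count all DMRs, multiple-window DMRs (>= 2 seed windows), and the
    histogram of significant-window counts."""
    hist: dict[int, int] = {}
    for d in dmr_set:
        hist[d.n_significant_windows] = hist.get(d.n_significant_windows, 0) + 1
    total = len(dmr_set)
    multiple = sum(v for k, v in hist.items() if k >= 2)
    return total, multiple, hist


def threshold_table(
    results: pd.DataFrame,
    genome_windows: GenomeWindows,
    config: DmrConfig | None = None,
) -> pd.DataFrame:
    """DMR counts at each seed threshold of the grid (extension fixed)."""
    config = config or DmrConfig()
    rows = []
    for thr in sorted(config.threshold_grid, reverse=True):
        dset = call_dmrs(results, genome_windows, replace(config, p_seed=thr))
        total, multiple, _ = classify_multiple_window(dset)
        rows.append({"p_seed": thr, "n_dmrs": total, "n_multiple_window": multiple})
    return pd.DataFrame(rows)
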