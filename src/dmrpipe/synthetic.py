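"""Synthetic data generators with known ground truth.

Two arms are emulated, at desk scale:

* the epigenomic arm — a small multi-chromosome genome with spatially
  varying CpG density, pooled methylation-enrichment sequencing counts
  over 100-bp windows (6 pools per lineage, negative-binomial noise,
  enrichment increasing with window CpG content) with spiked
  differential regions recorded in a truth table, and per-pool BED read
  files whose re-binning reproduces the count matrix exactly;

* the pathology arm — cohorts of animals with per-tissue abnormality
  counts scored by three observers (overdispersed Poisson with an
  animal-level effect), body measures, adipocyte areas, and breeding
  outcomes, with per-animal truth labels.

Every generator is deterministic for a fixed integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .windows import GenomeWindows, WindowCountMatrix

__all__ = [
    "SimGenome",
    "CountSimConfig",
    "TruthTable",
    "CohortSimConfig",
    "generate_genome",
    "generate_gene_annotation",
    "simulate_window_counts",
    "emit_reads",
    "simulate_cohort",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimGenome:
    """A small synthetic genome with known CpG positions."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    sequences: dict[str, str]
    cpg_positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        for name, pos in self.cpg_positions.items():
            if len(pos) and (np.diff(pos) <= 0).any():
                raise ValueError(f"{name}: cpg_positions must be strictly increasing")

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def windows(self, window_size: int = 100) -> GenomeWindows:
        return GenomeWindows(window_size, self.chrom_names, self.chrom_lengths)

    def write_fasta(self, path: str | Path, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self.chrom_names:
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")


def generate_genome(
    chrom_lengths: dict[str, int],
    seed: int,
    density_levels: tuple[float, ...] = (1.0, 4.0, 10.0),
    density_weights: tuple[float, ...] | None = None,
    block_size: int = 5000,
) -> SimGenome:
    """Random genome with blockwise-varying CpG density.

    CpG density is controlled exactly: a CG-free background sequence is
    drawn first, then per ``block_size`` block a density level (expected
    CpG dinucleotides per 100 bp) is chosen and CG pairs are planted at
    binomially sampled non-overlapping even slots.  Low levels produce
    "CpG desert" stretches, high levels CpG-dense stretches.
    """
    if any(l <= 0 for l in chrom_lengths.values()):
        raise ValueError("zero- or negative-length chromosome rejected")
    if density_weights is None:
        density_weights = tuple([1.0 / len(density_levels)] * len(density_levels))
    levels = np.asarray(density_levels, dtype=float)
    weights = np.asarray(density_weights, dtype=float)
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)

    names = tuple(chrom_lengths)
    seqs: dict[str, str] = {}
    cpgs: dict[str, np.ndarray] = {}
    for name in names:
        length = chrom_lengths[name]
        arr = rng.choice(_BASES, size=length)
        # remove accidental CG dinucleotides (G -> A never creates a new CG)
        is_cg = (arr[:-1] == b"C") & (arr[1:] == b"G")
        arr[1:][is_cg] = b"A"
        # plant CG pairs at even slots, blockwise binomial counts
        planted: list[np.ndarray] = []
        for b0 in range(0, length, block_size):
            b1 = min(b0 + block_size, length)
            slots = np.arange(b0 + (b0 % 2), b1 - 1, 2)
            if slots.size == 0:
                continue
            dens = float(rng.choice(levels, p=weights))
            p_slot = min(dens / 50.0, 1.0)  # 50 slots per 100 bp
            k = rng.binomial(slots.size, p_slot)
            if k:
                chosen = rng.choice(slots, size=k, replace=False)
                arr[chosen] = b"C"
                arr[chosen + 1] = b"G"
                planted.append(chosen)
        pos = np.sort(np.concatenate(planted)) if planted else np.array([], dtype=int)
        seqs[name] = arr.tobytes().decode("ascii")
        cpgs[name] = pos.astype(np.int64)
    return SimGenome(names, tuple(chrom_lengths.values()), seqs, cpgs)


def generate_gene_annotation(
    genome: SimGenome,
    n_genes: int,
    seed: int,
    length_range: tuple[int, int] = (2000, 20000),
    max_tries: int = 10000,
) -> pd.DataFrame:
    """Non-overlapping gene intervals, uniform over the genome.

    Returns a frame with chrom/start/end/name sorted by coordinate.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    lo, hi = length_range
    if lo > min(genome.chrom_lengths):
        raise ValueError("gene longer than the shortest chromosome")
    rng = np.random.default_rng(seed)
    lens = np.asarray(genome.chrom_lengths, dtype=float)
    probs = lens / lens.sum()
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in genome.chrom_names}
    rows = []
    tries = 0
    while len(rows) < n_genes:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place all genes without overlap")
        c = int(rng.choice(len(lens), p=probs))
        name = genome.chrom_names[c]
        glen = int(rng.integers(lo, hi + 1))
        if glen > genome.chrom_lengths[c]:
            continue
        start = int(rng.integers(0, genome.chrom_lengths[c] - glen + 1))
        end = start + glen
        if any(start < e and s < end for s, e in placed[name]):
            continue
        placed[name].append((start, end))
        rows.append({"chrom": name, "start": start, "end": end,
                     "name": f"gene_{len(rows) + 1}"})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return df.sort_values(["chrom", "start"], ignore_index=True)


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    genes[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", index=False, header=False
    )


@dataclass(frozen=True)
class CountSimConfig:
    """Parameters of the pooled window-count simulation.

    Defaults mirror the study design (6 DNA pools per lineage, 100-bp
    windows, ~50-bp reads) at desk scale: the per-pool depth stands in
    for the study's ~20 million reads per pool.
    """

    n_control_pools: int = 6
    n_exposed_pools: int = 6
    window_size: int = 100
    mean_library_size: int = 200_000
    library_size_cv: float = 0.2
    dispersion: float = 0.1
    n_true_dmrs: int = 50
    dmr_span_windows: tuple[int, int] = (1, 5)
    fold_change: float = 4.0
    cpg_enrichment_slope: float = 0.15
    enrichment_cap: float = 3.0
    min_dmr_separation: int = 2000
    generation: str = "F3"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control_pools, self.n_exposed_pools) < 2:
            raise ValueError("need >= 2 pools per group")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if self.n_true_dmrs > 0 and self.fold_change == 1.0:
            raise ValueError("spiked regions need fold_change != 1")


@dataclass(frozen=True)
class TruthTable:
    """Spiked differential regions and per-window truth flags."""

    regions: pd.DataFrame  # chrom, start, end, direction, fold_change
    window_is_dmr: np.ndarray  # bool per genome window

    def __post_init__(self) -> None:
        r = self.regions.sort_values(["chrom", "start"])
        for _, g in r.groupby("chrom"):
            if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                raise ValueError("truth regions must be non-overlapping")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, phi) via gamma-Poisson mixture; Poisson when phi == 0."""
    if phi == 0.0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mean)
    return rng.poisson(lam)


def simulate_window_counts(
    genome: SimGenome, config: CountSimConfig
) -> tuple[WindowCountMatrix, TruthTable]:
    """Simulate pooled enrichment counts over genome windows.

    Window attraction is monotone in CpG content, lambda_w proportional
    to exp(slope * cpg_w) capped; counts are NB(libsize * lambda_w *
    FC_w, phi) with FC_w = the configured fold change on truth windows
    of exposed pools (inverted for "down" regions) and 1 elsewhere.
    """
    rng = np.random.default_rng(config.seed)
    gw = genome.windows(config.window_size)
    n = gw.n_windows

    idx = np.arange(n)
    ci, starts, ends = gw.coords(idx)
    cpg = np.zeros(n)
    for c, name in enumerate(gw.chrom_names):
        mask = ci == c
        pos = genome.cpg_positions[name]
        cpg[mask] = np.searchsorted(pos, ends[mask]) - np.searchsorted(pos, starts[mask])
    lam = np.exp(np.minimum(config.cpg_enrichment_slope * cpg, config.enrichment_cap))
    lam /= lam.sum()

    # spike truth regions on window boundaries, well separated
    is_dmr = np.zeros(n, dtype=bool)
    fc_w = np.ones(n)
    rows = []
    if config.n_true_dmrs > 0:
        span_lo, span_hi = config.dmr_span_windows
        sep_w = -(-config.min_dmr_separation // config.window_size)
        order = rng.permutation(n)
        taken: dict[int, list[tuple[int, int]]] = {}
        for w0 in order:
            if len(rows) >= config.n_true_dmrs:
                break
            span = int(rng.integers(span_lo, span_hi + 1))
            c = int(ci[w0])
            w1 = w0 + span - 1
            if w1 >= n or int(ci[w1]) != c:
                continue
            clash = any(
                w0 <= b + sep_w and a <= w1 + sep_w for a, b in taken.get(c, [])
            )
            if clash:
                continue
            taken.setdefault(c, []).append((int(w0), int(w1)))
            direction = "up" if rng.random() < 0.5 else "down"
            fc = config.fold_change if direction == "up" else 1.0 / config.fold_change
            is_dmr[w0 : w1 + 1] = True
            fc_w[w0 : w1 + 1] = fc
            rows.append(
                {
                    "chrom": gw.chrom_names[c],
                    "start": int(starts[w0]),
                    "end": int(ends[w1]),
                    "direction": direction,
                    "fold_change": fc,
                }
            )
        if len(rows) < config.n_true_dmrs:
            raise RuntimeError("genome too small to place the requested truth regions")

    n_pools = config.n_control_pools + config.n_exposed_pools
    sigma2 = np.log1p(config.library_size_cv**2)
    lib = rng.lognormal(
        mean=np.log(config.mean_library_size) - sigma2 / 2,
        sigma=np.sqrt(sigma2),
        size=n_pools,
    )
    groups = ["control"] * config.n_control_pools + ["exposed"] * config.n_exposed_pools
    samples = [
        f"{g}_{config.generation}_{i + 1}"
        for g, i in zip(
            groups,
            list(range(config.n_control_pools)) + list(range(config.n_exposed_pools)),
        )
    ]
    means = np.empty((n, n_pools))
    for j, g in enumerate(groups):
        fc_col = fc_w if g == "exposed" else 1.0
        means[:, j] = lib[j] * lam * fc_col
    counts = _nb_draw(rng, means, config.dispersion)

    matrix = WindowCountMatrix(
        counts=counts.astype(np.int64),
        samples=samples,
        groups=groups,
        windows=gw,
        library_sizes=counts.sum(axis=0),
        generation=config.generation,
    )
    regions = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "direction", "fold_change"]
    ).sort_values(["chrom", "start"], ignore_index=True)
    return matrix, TruthTable(regions=regions, window_is_dmr=is_dmr)


def emit_reads(
    matrix: WindowCountMatrix,
    out_dir: str | Path,
    seed: int,
    read_length: int = 50,
) -> dict[str, Path]:
    """Write one BED6 file per pool; re-binning reproduces the matrix.

    Each window/pool cell emits exactly its count of reads with 5'
    starts uniform inside the window (read ends clipped at the
    chromosome end).
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gw = matrix.windows
    ci, w_starts, w_ends = gw.coords(matrix.window_index)
    chrom_names = np.asarray(gw.chrom_names, dtype=object)[ci]
    chrom_lens = np.asarray(gw.chrom_lengths, dtype=np.int64)[ci]
    paths: dict[str, Path] = {}
    for j, sample in enumerate(matrix.samples):
        col = matrix.counts[:, j]
        nz = np.flatnonzero(col)
        reps = col[nz]
        lo = np.repeat(w_starts[nz], reps)
        width = np.repeat(w_ends[nz] - w_starts[nz], reps)
        starts = lo + (rng.integers(0, width) if lo.size else np.array([], dtype=np.int64))
        ends = np.minimum(starts + read_length, np.repeat(chrom_lens[nz], reps))
        chroms = np.repeat(chrom_names[nz], reps)
        path = out_dir / f"{sample}.bed"
        df = pd.DataFrame(
            {
                "chrom": chroms,
                "start": starts,
                "end": ends,
                "name": ".",
                "score": 0,
                "strand": "+",
            }
        )
        df.to_csv(path, sep="\t", index=False, header=False)
        paths[sample] = path
    return paths


@dataclass(frozen=True)
class CohortSimConfig:
    """Parameters of the pathology-cohort simulation.

    Per-tissue abnormality counts are overdispersed Poisson: each
    animal x tissue draws a gamma multiplier (mean 1, variance
    ``observer_noise``) shared across its three observers.  Affected
    exposed animals have their rate multiplied by ``disease_effect``.
    """

    n_per_group: int = 30
    tissues: tuple[str, ...] = ("testis", "prostate", "kidney", "ovary")
    male_tissues: tuple[str, ...] = ("testis", "prostate", "kidney")
    female_tissues: tuple[str, ...] = ("ovary", "kidney")
    lambda_control: float = 3.0
    disease_effect: float = 5.0
    affected_fraction: float = 0.3
    n_observers: int = 3
    observer_noise: float = 0.05
    bmi_mean: float = 0.65
    bmi_sd: float = 0.05
    length_mean_cm: float = 25.0
    length_sd_cm: float = 1.0
    adipocyte_shape: float = 4.0
    adipocyte_scale: float = 1250.0
    adiposity_mean: float = 2.0
    adiposity_sd: float = 0.8
    obese_fraction: float = 0.4
    obese_shift_sd: float = 2.5
    puberty_mean_days: float = 42.0
    puberty_sd_days: float = 3.0
    weaning_weight_mean_g: float = 55.0
    weaning_weight_sd_g: float = 6.0
    n_images: int = 5
    cells_per_image: int = 30
    breedings_per_dam: int = 1
    pregnancy_prob: float = 0.9
    parturition_abnormality_prob_control: float = 0.03
    parturition_abnormality_prob_exposed: float = 0.35
    generation: str = "F3"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.affected_fraction,
            self.obese_fraction,
            self.pregnancy_prob,
            self.parturition_abnormality_prob_control,
            self.parturition_abnormality_prob_exposed,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.lambda_control <= 0:
            raise ValueError("lambda_control must be > 0")
        if self.observer_noise < 0:
            raise ValueError("observer_noise must be >= 0")


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one generation's cohort.

    Returns (observations, measures, adipocytes, breeding, truth):

    * observations — one row per animal x tissue x observer with the
      abnormality count;
    * measures — one row per animal: weight, length, adiposity score,
      puberty age, weaning weight;
    * adipocytes — one row per animal x image x cell with the area;
    * breeding — one row per dam;
    * truth — per-animal affected/obese flags.
    """
    rng = np.random.default_rng(config.seed)
    obs_rows, meas_rows, adi_rows, breed_rows, truth_rows = [], [], [], [], []
    for lineage in ("control", "exposed"):
        for i in range(config.n_per_group):
            sex = "male" if i % 2 == 0 else "female"
            aid = f"{lineage}_{config.generation}_{i + 1:03d}"
            tissues = (
                config.male_tissues if sex == "male" else config.female_tissues
            )
            affected_tissues = []
            for tissue in tissues:
                affected = (
                    lineage == "exposed" and rng.random() < config.affected_fraction
                )
                lam = config.lambda_control * (
                    config.disease_effect if affected else 1.0
                )
                if config.observer_noise > 0:
                    u = rng.gamma(
                        1.0 / config.observer_noise, config.observer_noise
                    )
                else:
                    u = 1.0
                counts = rng.poisson(lam * u, size=config.n_observers)
                for o, cnt in enumerate(counts, start=1):
                    obs_rows.append(
                        {
                            "animal_id": aid,
                            "sex": sex,
                            "generation": config.generation,
                            "lineage": lineage,
                            "tissue": tissue,
                            "observer": o,
                            "count": int(cnt),
                        }
                    )
                if affected:
                    affected_tissues.append(tissue)

            obese = lineage == "exposed" and rng.random() < config.obese_fraction
            shift = config.obese_shift_sd if obese else 0.0
            length = rng.normal(config.length_mean_cm, config.length_sd_cm)
            bmi_val = rng.normal(config.bmi_mean + shift * config.bmi_sd, config.bmi_sd)
            weight = bmi_val * length**2
            adiposity = rng.normal(
                config.adiposity_mean + shift * config.adiposity_sd, config.adiposity_sd
            )
            scale = config.adipocyte_scale * (1.0 + 0.4 * shift if obese else 1.0)
            for img in range(1, config.n_images + 1):
                areas = rng.gamma(
                    config.adipocyte_shape, scale, size=config.cells_per_image
                )
                for cell, area in enumerate(areas, start=1):
                    adi_rows.append(
                        {
                            "animal_id": aid,
                            "image": img,
                            "cell": cell,
                            "area_um2": float(area),
                        }
                    )
            meas_rows.append(
                {
                    "animal_id": aid,
                    "sex": sex,
                    "generation": config.generation,
                    "lineage": lineage,
                    "weight_g": float(weight),
                    "length_cm": float(length),
                    "adiposity_score": float(adiposity),
                    "puberty_age_days": float(
                        rng.normal(config.puberty_mean_days, config.puberty_sd_days)
                    ),
                    "weaning_weight_g": float(
                        rng.normal(
                            config.weaning_weight_mean_g, config.weaning_weight_sd_g
                        )
                    ),
                }
            )
            if sex == "female":
                n_b = config.breedings_per_dam
                n_p = int(rng.binomial(n_b, config.pregnancy_prob))
                p_ab = (
                    config.parturition_abnormality_prob_exposed
                    if lineage == "exposed"
                    else config.parturition_abnormality_prob_control
                )
                n_ab = int(rng.binomial(n_p, p_ab))
                breed_rows.append(
                    {
                        "dam_id": aid,
                        "generation": config.generation,
                        "lineage": lineage,
                        "n_breedings": n_b,
                        "n_pregnancies": n_p,
                        "n_abnormal_parturitions": n_ab,
                    }
                )
            truth_rows.append(
                {
                    "animal_id": aid,
                    "sex": sex,
                    "lineage": lineage,
                    "affected_tissues": ";".join(affected_tissues),
                    "obese": obese,
                }
            )
    return (
        pd.DataFrame(obs_rows),
        pd.DataFrame(meas_rows),
        pd.DataFrame(adi_rows),
        pd.DataFrame(breed_rows),
        pd.DataFrame(truth_rows),
    )
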