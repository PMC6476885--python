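"""Permutation null for DMR counts and DMR-restricted sample PCA.

The permutation reruns the *identical* analysis entry point (dispersion
estimation, exact test, region calling) for each relabeling of the
samples that preserves group sizes, and records the resulting DMR
count.  The empirical p-value uses the +1 correction so it can never be
zero.  Under the exhaustive scheme all C(n, n1) labelings are
enumerated; the two labelings equal to the observed partition (the
identity and its complement, which yields the same two-sided result)
are excluded from the null counts so that an observed count larger than
every null count reaches exactly 1 / (n_permutations + 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .difftest import NormalizationFactors, estimate_common_dispersion, normalize, test_windows
from .dmr import DmrConfig, DmrSet, call_dmrs
from .windows import WindowCountMatrix

__all__ = ["PermutationNull", "PcaResult", "analyze_labeling", "permutation_null", "dmr_pca"]


@dataclass(frozen=True)
class PermutationNull:
    null_counts: np.ndarray
    observed_count: int
    n_permutations: int
    n_labelings: int  # size of the full labeling space (e.g. C(12,6) = 924)
    empirical_p: float
    scheme: str  # "exhaustive" | "sampled"

    def __post_init__(self) -> None:
        if not 0 < self.empirical_p <= 1:
            raise ValueError("empirical_p must lie in (0, 1]")
        if len(self.null_counts) != self.n_permutations:
            raise ValueError("null_counts length must equal n_permutations")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dmr_count": self.null_counts})


@dataclass(frozen=True)
class PcaResult:
    scores: np.ndarray  # samples x k
    explained_variance_ratio: np.ndarray
    samples: tuple[str, ...]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        evr = np.asarray(self.explained_variance_ratio)
        if (evr < -1e-12).any() or evr.sum() > 1 + 1e-9:
            raise ValueError("explained-variance fractions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            columns=[f"PC{i + 1}" for i in range(self.scores.shape[1])],
        )
        df.insert(0, "sample", self.samples)
        df.insert(1, "group", self.groups)
        return df


def analyze_labeling(
    matrix: WindowCountMatrix,
    group_labels: list[str],
    factors: NormalizationFactors,
    config: DmrConfig,
    reestimate_dispersion: bool = True,
    phi: float | None = None,
) -> DmrSet:
    """One full analysis pass under an arbitrary sample labeling.

    This is the single code path used for both the observed analysis and
    every permutation (no drift between the two).
    """
    relabeled = WindowCountMatrix(
        counts=matrix.counts,
        samples=matrix.samples,
        groups=list(group_labels),
        windows=matrix.windows,
        library_sizes=matrix.library_sizes,
        window_index=matrix.window_index,
        generation=matrix.generation,
    )
    if reestimate_dispersion or phi is None:
        phi = estimate_common_dispersion(relabeled, factors).phi
    results = test_windows(relabeled, factors, phi=phi)
    return call_dmrs(results, matrix.windows, config)


def permutation_null(
    matrix: WindowCountMatrix,
    config: DmrConfig | None = None,
    factors: NormalizationFactors | None = None,
    scheme: str = "auto",
    max_perms: int = 1000,
    seed: int = 0,
    reestimate_dispersion: bool = True,
) -> PermutationNull:
    """DMR-count null distribution under group-label shuffling."""
    if max_perms < 1:
        raise ValueError("max_perms must be >= 1")
    config = config or DmrConfig()
    if factors is None:
        factors = normalize(matrix, "total")
    group_names = sorted(set(matrix.groups))
    if len(group_names) != 2:
        raise ValueError("permutation requires exactly two groups")
    g1 = group_names[0]
    n = matrix.n_samples
    n1 = sum(g == g1 for g in matrix.groups)
    observed_idx = frozenset(i for i, g in enumerate(matrix.groups) if g == g1)

    observed_set = analyze_labeling(
        matrix, list(matrix.groups), factors, config, reestimate_dispersion
    )
    observed = len(observed_set)

    n_labelings = comb(n, n1)
    if scheme == "auto":
        scheme = "exhaustive" if n_labelings <= max_perms else "sampled"
    if scheme not in ("exhaustive", "sampled"):
        raise ValueError(f"unknown scheme {scheme!r}")

    complement_idx = frozenset(range(n)) - observed_idx
    labelings: list[frozenset[int]] = []
    if scheme == "exhaustive":
        for combo in itertools.combinations(range(n), n1):
            s = frozenset(combo)
            if s == observed_idx or s == complement_idx:
                continue  # the observed partition is not part of the null
            labelings.append(s)
    else:
        rng = np.random.default_rng(seed)
        seen = set()
        target = min(max_perms, n_labelings - 2)
        while len(labelings) < target:
            s = frozenset(rng.choice(n, size=n1, replace=False).tolist())
            # both orientations of the observed partition are the observed
            # statistic itself (the test is two-sided), so neither is null
            if s == observed_idx or s == complement_idx or s in seen:
                continue
            seen.add(s)
            labelings.append(s)

    null_counts = np.empty(len(labelings), dtype=np.int64)
    for k, s in enumerate(labelings):
        # analyze with the two permuted groups standing in for control/exposed
        dset = analyze_labeling(
            matrix,
            ["control" if i in s else "exposed" for i in range(n)],
            factors,
            config,
            reestimate_dispersion,
        )
        null_counts[k] = len(dset)

    n_perms = len(null_counts)
    emp_p = (1 + int((null_counts >= observed).sum())) / (1 + n_perms)
    return PermutationNull(
        null_counts=null_counts,
        observed_count=observed,
        n_permutations=n_perms,
        n_labelings=n_labelings,
        empirical_p=emp_p,
        scheme=scheme,
    )


def dmr_pca(
    matrix: WindowCountMatrix,
    dmr_set: DmrSet,
    factors: NormalizationFactors | None = None,
    k: int = 2,
) -> PcaResult:
    """PCA of samples on log2(CPM + 1) over DMR windows only.

    Windows are centered (the features), samples are the observations.
    """
    if factors is None:
        factors = normalize(matrix, "total")
    if len(dmr_set) == 0:
        raise ValueError(
            "no DMRs to restrict to; rerun on all windows (whole-genome PCA) instead"
        )
    if matrix.n_samples < 3:
        raise ValueError("PCA needs >= 3 samples")
    ci, starts, ends = matrix.windows.coords(matrix.window_index)
    names = np.asarray(matrix.windows.chrom_names, dtype=object)[ci]
    in_dmr = np.zeros(matrix.n_windows, dtype=bool)
    for d in dmr_set:
        in_dmr |= (names == d.chrom) & (starts < d.end) & (ends > d.start)
    if in_dmr.sum() < 2:
        raise ValueError("need >= 2 DMR windows for PCA")
    cpm = matrix.counts[in_dmr] / factors.effective_lib_sizes * 1e6
    x = np.log2(cpm + 1.0)
    x = x - x.mean(axis=1, keepdims=True)  # center each window
    k = min(k, matrix.n_samples - 1, int(in_dmr.sum()))
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x.T)
    return PcaResult(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        samples=tuple(matrix.samples),
        groups=tuple(matrix.groups),
    )
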