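"""Per-window two-group differential count testing.

The model is a negative binomial with a single common dispersion phi
(variance = mu + phi * mu^2; phi = 0 recovers the Poisson).  Counts are
first scaled to a common effective library size (the geometric mean of
the per-sample effective sizes) with deterministic half-even rounding,
so that an exact conditional test can be run on integer pseudo-counts:
conditioning on the grand total of a window, the probability of every
split of that total between the two group sums is enumerated, and the
two-sided p-value sums the probabilities of all splits no more probable
than the observed one (minimum-likelihood convention).

A key property used throughout: the sum of n i.i.d. NB(mu, phi) counts
is NB(n * mu, phi / n), so group sums are sufficient under equalized
library sizes and a common dispersion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .windows import WindowCountMatrix

__all__ = [
    "NormalizationFactors",
    "DispersionEstimate",
    "normalize",
    "estimate_common_dispersion",
    "exact_nb_test",
    "test_windows",
    "adjust_fdr",
]

_TIE_REL = 1 + 1e-12  # relative tolerance when comparing split probabilities


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-sample effective library sizes (reads) and the method used."""

    effective_lib_sizes: np.ndarray
    method: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "effective_lib_sizes", np.asarray(self.effective_lib_sizes, float)
        )
        if (self.effective_lib_sizes <= 0).any():
            raise ValueError("effective library sizes must be positive")


@dataclass(frozen=True)
class DispersionEstimate:
    phi: float
    n_windows_used: int
    method: str = "common-conditional-ml"

    def __post_init__(self) -> None:
        if not np.isfinite(self.phi) or self.phi < 0:
            raise ValueError("phi must be finite and >= 0")


def normalize(matrix: WindowCountMatrix, method: str = "total") -> NormalizationFactors:
    """Effective library sizes by total-count or trimmed-mean (TMM-style).

    ``total``: column sums.  ``trimmed-mean``: column sums scaled by a
    doubly trimmed mean of per-window log2 count ratios against a
    reference sample (30% trim on the log-ratios, 5% on abundance).
    """
    counts = np.asarray(matrix.counts, dtype=float)
    colsums = counts.sum(axis=0)
    if (colsums == 0).any():
        bad = [s for s, t in zip(matrix.samples, colsums) if t == 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    if method in ("total", "total-count"):
        return NormalizationFactors(colsums, "total-count")
    if method not in ("tmm", "trimmed-mean"):
        raise ValueError(f"unknown normalization method {method!r}")

    # reference: sample whose upper-quartile count fraction is closest to the mean
    uq = np.array([np.quantile(counts[:, j] / colsums[j], 0.75)
                   for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(counts.shape[1])
    p_ref = counts[:, ref] / colsums[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        p_j = counts[:, j] / colsums[j]
        ok = (p_j > 0) & (p_ref > 0)
        if not ok.any():
            continue
        m = np.log2(p_j[ok] / p_ref[ok])        # log-ratio
        a = 0.5 * np.log2(p_j[ok] * p_ref[ok])  # abundance
        keep = _double_trim_mask(m, a, trim_m=0.30, trim_a=0.05)
        factors[j] = 2.0 ** np.mean(m[keep]) if keep.any() else 1.0
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return NormalizationFactors(colsums * factors, "trimmed-mean")


def _double_trim_mask(m: np.ndarray, a: np.ndarray, trim_m: float, trim_a: float):
    lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
    return (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)


def equalize_counts(counts: np.ndarray, eff_lib_sizes: np.ndarray) -> np.ndarray:
    """Scale counts to the geometric-mean effective depth, half-even rounded."""
    eff = np.asarray(eff_lib_sizes, dtype=float)
    target = np.exp(np.mean(np.log(eff)))
    scaled = np.asarray(counts, dtype=float) * (target / eff)
    return np.round(scaled).astype(np.int64)  # numpy rounds half to even


def _cond_loglik(phi: float, pseudo: np.ndarray, masks: list[np.ndarray]) -> float:
    """Pooled conditional log-likelihood of phi given per-group window sums."""
    total = 0.0
    for mask in masks:
        y = pseudo[:, mask]
        n_g = int(mask.sum())
        s = y.sum(axis=1)
        if phi < 1e-10:
            # Poisson limit: counts | sum ~ multinomial with equal cell probs
            total += float(
                np.sum(gammaln(s + 1) - gammaln(y + 1).sum(axis=1) - s * np.log(n_g))
            )
        else:
            r = 1.0 / phi
            total += float(
                np.sum(
                    gammaln(y + r).sum(axis=1)
                    - n_g * gammaln(r)
                    - gammaln(y + 1).sum(axis=1)
                    - (gammaln(s + n_g * r) - gammaln(n_g * r) - gammaln(s + 1))
                )
            )
    return total


def estimate_common_dispersion(
    matrix: WindowCountMatrix,
    factors: NormalizationFactors | None = None,
    max_phi: float = 10.0,
    tol: float = 1e-4,
) -> DispersionEstimate:
    """Common NB dispersion maximizing the pooled conditional likelihood.

    Works on library-size-equalized pseudo-counts; the conditional
    likelihood (given each group's window sum) is free of the window
    means, so a single bracketed 1-D search over phi suffices.
    """
    groups = set(matrix.groups)
    if len(groups) < 2:
        raise ValueError("need two groups")
    masks = [matrix.group_mask(g) for g in sorted(groups)]
    if any(m.sum() < 2 for m in masks):
        raise ValueError("need >= 2 samples per group")
    if factors is None:
        factors = normalize(matrix, "total")
    pseudo = equalize_counts(matrix.counts, factors.effective_lib_sizes)
    used = pseudo.sum(axis=1) > 0
    pseudo = pseudo[used]
    if pseudo.size == 0 or np.all(pseudo == pseudo[:, :1]):
        warnings.warn("degenerate data: no overdispersion evidence, phi = 0",
                      stacklevel=2)
        return DispersionEstimate(0.0, int(used.sum()))

    res = minimize_scalar(
        lambda phi: -_cond_loglik(phi, pseudo, masks),
        bounds=(0.0, max_phi),
        method="bounded",
        options={"xatol": tol},
    )
    phi = float(res.x)
    if _cond_loglik(0.0, pseudo, masks) >= -res.fun:
        phi = 0.0  # Poisson boundary at least as likely
    return DispersionEstimate(phi, pseudo.shape[0])


def _log_nb_pmf(y: np.ndarray, mean: float, disp: float) -> np.ndarray:
    """log pmf of NB(mean, dispersion); Poisson when disp == 0."""
    y = np.asarray(y, dtype=float)
    if disp == 0.0:
        return y * np.log(mean) - mean - gammaln(y + 1)
    r = 1.0 / disp
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1)
        + r * np.log(r / (r + mean))
        + y * np.log(mean / (r + mean))
    )


def _split_pvalues(total: int, n1: int, n2: int, phi: float) -> np.ndarray:
    """Two-sided exact p-value for every split s1 = 0..total of the total.

    Conditional on the grand total T of equalized counts, S1 ~ NB(n1*mu,
    phi/n1) and S2 = T - S1 ~ NB(n2*mu, phi/n2) with mu = T/(n1+n2); the
    p-value of split k sums the normalized probabilities of all splits
    whose probability is <= that of k (ties included).
    """
    mu = total / (n1 + n2)
    k = np.arange(total + 1)
    logp = _log_nb_pmf(k, n1 * mu, phi / n1) + _log_nb_pmf(total - k, n2 * mu, phi / n2)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    order = np.argsort(p, kind="stable")
    csum = np.cumsum(p[order])
    csum /= csum[-1]  # the least extreme split gets p exactly 1
    # for each split, the largest sorted position whose prob is <= its prob*(1+eps)
    sorted_p = p[order]
    pos = np.searchsorted(sorted_p, p * _TIE_REL, side="right") - 1
    pvals = np.empty(total + 1)
    pvals[:] = csum[pos]
    return np.minimum(pvals, 1.0)


def exact_nb_test(
    window_counts: np.ndarray,
    groups: np.ndarray,
    eff_lib_sizes: np.ndarray,
    phi: float,
    group_order: tuple[str, str] = ("control", "exposed"),
) -> tuple[float, float]:
    """Exact conditional NB test for one window.

    Returns (two-sided p-value, log2 fold change exposed vs control).
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    counts = np.asarray(window_counts)
    groups = np.asarray(groups)
    g_ctl, g_exp = group_order
    m1 = groups == g_ctl
    m2 = groups == g_exp
    if not (m1.any() and m2.any()):
        raise ValueError("both groups must be present")
    pseudo = equalize_counts(counts[None, :], eff_lib_sizes)[0]
    s1 = int(pseudo[m1].sum())
    s2 = int(pseudo[m2].sum())
    total = s1 + s2
    if total == 0:
        raise ValueError("window has zero total count; pre-filter such windows")
    pvals = _split_pvalues(total, int(m1.sum()), int(m2.sum()), phi)
    p = float(pvals[s1])

    target = np.exp(np.mean(np.log(np.asarray(eff_lib_sizes, float))))
    norm = counts / np.asarray(eff_lib_sizes, float) * target
    lfc = float(np.log2((norm[m2].mean() + 0.5) / (norm[m1].mean() + 0.5)))
    return p, lfc


def test_windows(
    matrix: WindowCountMatrix,
    factors: NormalizationFactors | None = None,
    phi: float | None = None,
    group_order: tuple[str, str] = ("control", "exposed"),
) -> pd.DataFrame:
    """Run the exact NB test on every window of a matrix.

    Returns a frame with chrom/start/end, per-group normalized means,
    log2_fc (exposed vs control), p_value and BH q_value; the per-window
    conditional split distributions are cached by grand total, which is
    what makes genome-wide testing cheap.
    """
    if factors is None:
        factors = normalize(matrix, "total")
    eff = factors.effective_lib_sizes
    if phi is None:
        phi = estimate_common_dispersion(matrix, factors).phi
    if phi < 0:
        raise ValueError("phi must be >= 0")
    g_ctl, g_exp = group_order
    m1 = matrix.group_mask(g_ctl)
    m2 = matrix.group_mask(g_exp)
    if not (m1.any() and m2.any()):
        raise ValueError(f"groups {group_order} not both present")

    pseudo = equalize_counts(matrix.counts, eff)
    s1 = pseudo[:, m1].sum(axis=1)
    totals = s1 + pseudo[:, m2].sum(axis=1)
    n1, n2 = int(m1.sum()), int(m2.sum())

    p = np.ones(matrix.n_windows)
    nonzero = totals > 0
    cache: dict[int, np.ndarray] = {}
    for t in np.unique(totals[nonzero]):
        cache[int(t)] = _split_pvalues(int(t), n1, n2, phi)
    idx = np.flatnonzero(nonzero)
    for i in idx:
        p[i] = cache[int(totals[i])][s1[i]]

    target = np.exp(np.mean(np.log(eff)))
    norm = matrix.counts / eff * target
    mean_ctl = norm[:, m1].mean(axis=1)
    mean_exp = norm[:, m2].mean(axis=1)
    lfc = np.log2((mean_exp + 0.5) / (mean_ctl + 0.5))

    ci, starts, ends = matrix.windows.coords(matrix.window_index)
    out = pd.DataFrame(
        {
            "chrom": np.asarray(matrix.windows.chrom_names, dtype=object)[ci],
            "start": starts,
            "end": ends,
            "window_index": matrix.window_index,
            "mean_control": mean_ctl,
            "mean_exposed": mean_exp,
            "log2_fc": lfc,
            "p_value": p,
        }
    )
    out["q_value"] = adjust_fdr(out["p_value"].to_numpy())
    out.attrs["phi"] = float(phi)
    out.attrs["normalization"] = factors.method
    return out


def adjust_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
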