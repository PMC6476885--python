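"""Blinded-observer disease classification and cohort statistics.

Each tissue section is scored for histological abnormalities by three
observers blinded to lineage.  Per observer, an animal's tissue is
flagged when its abnormality count strictly exceeds that observer's
cutoff of control mean + 2 sample SD; the tissue is called diseased
when at least two of the three observers flag it.  Obesity combines
BMI (weight g / length cm^2), mean adipocyte area of the largest cells,
and an abdominal adiposity score against control mean +/- 1.5 SD.
Disease frequencies are compared with two-sided Fisher exact tests,
continuous measures with pooled-variance t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiseaseThresholds",
    "GroupComparison",
    "compute_thresholds",
    "call_tissue_disease",
    "call_diseases",
    "bmi",
    "adipocyte_metric",
    "obesity_classify",
    "frequency_test",
    "continuous_test",
    "fertility_rate",
    "disease_burden",
]


@dataclass(frozen=True)
class DiseaseThresholds:
    """Per-observer cutoffs (control mean + 2 sample SD) for one tissue."""

    tissue: str
    cutoffs: dict[int, float]  # observer -> cutoff

    def __post_init__(self) -> None:
        if not self.cutoffs:
            raise ValueError("no observer cutoffs")


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    test: str  # "fisher" | "t"
    table: tuple[tuple[int, int], tuple[int, int]] | None = None
    degenerate: bool = False


def compute_thresholds(
    observations: pd.DataFrame, tissue: str, control_lineage: str = "control"
) -> DiseaseThresholds:
    """Cutoff = control mean + 2 sample SD (n-1), per observer.

    ``observations`` is long-form with columns animal_id, lineage,
    tissue, observer, count.
    """
    ctl = observations[
        (observations["lineage"] == control_lineage)
        & (observations["tissue"] == tissue)
    ]
    if ctl.empty:
        raise ValueError(f"no control observations for tissue {tissue!r}")
    cutoffs: dict[int, float] = {}
    for obs, g in ctl.groupby("observer"):
        counts = g["count"].to_numpy(dtype=float)
        if counts.size < 2:
            raise ValueError(
                f"need >= 2 control animals for tissue {tissue!r}, observer {obs}"
            )
        cutoffs[int(obs)] = float(counts.mean() + 2.0 * counts.std(ddof=1))
    return DiseaseThresholds(tissue=tissue, cutoffs=cutoffs)


def call_tissue_disease(
    counts_by_observer: dict[int, int], thresholds: DiseaseThresholds
) -> tuple[bool, dict[int, bool]]:
    """2-of-3 consensus call for one animal and tissue.

    An observer flags the tissue when the count strictly exceeds that
    observer's cutoff (ties are healthy).  Missing observers are an
    error — no imputation.
    """
    flags: dict[int, bool] = {}
    for obs, cutoff in thresholds.cutoffs.items():
        if obs not in counts_by_observer:
            raise ValueError(f"missing count for observer {obs}")
        flags[obs] = counts_by_observer[obs] > cutoff
    diseased = sum(flags.values()) >= 2
    return diseased, flags


def call_diseases(
    observations: pd.DataFrame, control_lineage: str = "control"
) -> pd.DataFrame:
    """Disease calls for every animal x tissue in a long-form table.

    Thresholds are computed from the control lineage of the same table
    (callers should pass one generation and, where relevant, one sex at
    a time).  Returns one row per animal x tissue with the consensus
    call.
    """
    rows = []
    for tissue, sub in observations.groupby("tissue"):
        thr = compute_thresholds(observations, tissue, control_lineage)
        for (aid,), g in sub.groupby(["animal_id"]):
            counts = dict(zip(g["observer"].astype(int), g["count"].astype(int)))
            diseased, flags = call_tissue_disease(counts, thr)
            rows.append(
                {
                    "animal_id": aid,
                    "lineage": g["lineage"].iloc[0],
                    "tissue": tissue,
                    "diseased": diseased,
                    "n_observers_flagged": sum(flags.values()),
                }
            )
    return pd.DataFrame(rows)


def bmi(weight_g: float, length_cm: float) -> float:
    """Body mass index, weight (g) / length (cm)^2."""
    if length_cm <= 0:
        raise ValueError("length must be positive")
    return weight_g / length_cm**2


def adipocyte_metric(areas_per_image: list[np.ndarray], top_n: int = 20) -> float:
    """Mean area of the ``top_n`` largest adipocytes per image, pooled.

    With the default five images this averages 100 cell areas; the
    largest (hypertrophic) cells are the metabolically relevant ones.
    """
    pooled = []
    for i, areas in enumerate(areas_per_image, start=1):
        a = np.asarray(areas, dtype=float)
        if a.size < top_n:
            raise ValueError(f"image {i}: needs >= {top_n} measured cells, got {a.size}")
        pooled.append(np.sort(a)[-top_n:])
    return float(np.concatenate(pooled).mean())


def obesity_classify(
    measures: np.ndarray | dict[str, float],
    control_stats: dict[str, tuple[float, float]],
    sd_mult: float = 1.5,
    quorum: int = 2,
) -> str:
    """Classify one animal as obese / lean / normal.

    ``measures`` maps measure name (e.g. bmi, adipocyte_area,
    adiposity) to the animal's value; ``control_stats`` maps the same
    names to (control mean, control SD), computed per sex.  A measure
    above mean + sd_mult*SD votes "high", below mean - sd_mult*SD votes
    "low"; ``quorum`` matching votes make the call.
    """
    high = low = 0
    for name, value in measures.items():
        mean, sd = control_stats[name]
        if value > mean + sd_mult * sd:
            high += 1
        elif value < mean - sd_mult * sd:
            low += 1
    obese = high >= quorum
    lean = low >= quorum
    assert not (obese and lean), "quorum satisfied in both directions"
    if obese:
        return "obese"
    if lean:
        return "lean"
    return "normal"


def frequency_test(
    affected_a: int, total_a: int, affected_b: int, total_b: int
) -> GroupComparison:
    """Two-sided Fisher exact test on an affected/total 2x2 table."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("group totals must be positive")
    if not (0 <= affected_a <= total_a and 0 <= affected_b <= total_b):
        raise ValueError("affected counts must lie in [0, total]")
    table = [[affected_a, total_a - affected_a], [affected_b, total_b - affected_b]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return GroupComparison(
        statistic=float(odds),
        p_value=float(p),
        test="fisher",
        table=((table[0][0], table[0][1]), (table[1][0], table[1][1])),
    )


def continuous_test(samples_a, samples_b) -> GroupComparison:
    """Pooled-variance two-sided Student t-test."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    if var_a == 0 and var_b == 0:
        if a.mean() == b.mean():
            return GroupComparison(0.0, 1.0, "t")
        return GroupComparison(float("inf"), 0.0, "t", degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(statistic=float(t), p_value=float(p), test="t")


def fertility_rate(breeding: pd.DataFrame) -> pd.Series:
    """Pregnancies / breedings per lineage."""
    grouped = breeding.groupby("lineage")[["n_pregnancies", "n_breedings"]].sum()
    if (grouped["n_breedings"] <= 0).any():
        raise ValueError("zero breedings in a group")
    if (grouped["n_pregnancies"] > grouped["n_breedings"]).any():
        raise ValueError("pregnancies cannot exceed breedings")
    return grouped["n_pregnancies"] / grouped["n_breedings"]


def disease_burden(
    calls: pd.DataFrame, control_lineage: str = "control"
) -> pd.DataFrame:
    """Per-lineage frequency of >= 1 and >= 2 distinct diseases.

    ``calls`` is the output of :func:`call_diseases`, optionally with
    extra rows for tumor or obesity flags (tissue column holding the
    flag name).  Fisher comparisons are against the control lineage.
    """
    per_animal = (
        calls.groupby(["animal_id", "lineage"])["diseased"].sum().reset_index()
    )
    rows = []
    counts = {}
    for lineage, g in per_animal.groupby("lineage"):
        n = len(g)
        ge1 = int((g["diseased"] >= 1).sum())
        ge2 = int((g["diseased"] >= 2).sum())
        counts[lineage] = (ge1, ge2, n)
    if control_lineage not in counts:
        raise ValueError(f"control lineage {control_lineage!r} absent")
    c1, c2, cn = counts[control_lineage]
    for lineage, (ge1, ge2, n) in counts.items():
        p1 = p2 = float("nan")
        if lineage != control_lineage:
            p1 = frequency_test(ge1, n, c1, cn).p_value
            p2 = frequency_test(ge2, n, c2, cn).p_value
        rows.append(
            {
                "lineage": lineage,
                "n_animals": n,
                "n_ge1_disease": ge1,
                "freq_ge1": ge1 / n,
                "fisher_p_ge1": p1,
                "n_ge2_disease": ge2,
                "freq_ge2": ge2 / n,
                "fisher_p_ge2": p2,
            }
        )
    return pd.DataFrame(rows)
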