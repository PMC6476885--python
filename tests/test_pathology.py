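"""Disease thresholds, consensus calls, obesity and cohort statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from dmrpipe.pathology import (
    DiseaseThresholds,
    adipocyte_metric,
    bmi,
    call_tissue_disease,
    compute_thresholds,
    continuous_test,
    disease_burden,
    fertility_rate,
    frequency_test,
    obesity_classify,
)


def obs_frame(control_counts, tissue="testis", observer=1):
    rows = [
        {"animal_id": f"c{i}", "lineage": "control", "tissue": tissue,
         "observer": observer, "count": c}
        for i, c in enumerate(control_counts)
    ]
    return pd.DataFrame(rows)


def fisher_enumeration_oracle(a, b, c, d):
    """Full hypergeometric enumeration for a 2x2 table [[a,b],[c,d]]."""
    r1, n1 = a + b, a + c
    n = a + b + c + d
    denom = comb(n, n1, exact=True)
    probs = []
    for x in range(max(0, n1 - (n - r1)), min(r1, n1) + 1):
        probs.append(comb(r1, x, exact=True) * comb(n - r1, n1 - x, exact=True))
    p_obs = comb(r1, a, exact=True) * comb(n - r1, n1 - a, exact=True)
    return sum(p for p in probs if p <= p_obs) / denom


class TestThresholds:
    def test_hand_computed_cutoff(self):
        # mean 1.0, sample SD sqrt(0.8): cutoff = 1 + 2*0.894 = 2.789
        thr = compute_thresholds(obs_frame([1, 2, 1, 0, 2, 0]), "testis")
        assert thr.cutoffs[1] == pytest.approx(1.0 + 2 * math.sqrt(0.8), abs=1e-3)
        assert thr.cutoffs[1] == pytest.approx(2.789, abs=1e-3)

    def test_all_zero_controls_cutoff_zero(self):
        thr = compute_thresholds(obs_frame([0, 0, 0, 0]), "testis")
        assert thr.cutoffs[1] == 0.0

    def test_constant_controls_cutoff_equals_constant(self):
        thr = compute_thresholds(obs_frame([3, 3, 3]), "testis")
        assert thr.cutoffs[1] == 3.0

    def test_single_control_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            compute_thresholds(obs_frame([1]), "testis")


class TestConsensusCall:
    THR = DiseaseThresholds("testis", {1: 2.789, 2: 2.789, 3: 2.789})

    def test_two_of_three_flags_is_diseased(self):
        diseased, flags = call_tissue_disease({1: 3, 2: 4, 3: 1}, self.THR)
        assert diseased and flags == {1: True, 2: True, 3: False}

    def test_one_of_three_is_healthy(self):
        diseased, _ = call_tissue_disease({1: 3, 2: 1, 3: 1}, self.THR)
        assert not diseased

    def test_tie_at_cutoff_is_healthy(self):
        thr = DiseaseThresholds("testis", {1: 3.0, 2: 3.0, 3: 3.0})
        diseased, flags = call_tissue_disease({1: 3, 2: 3, 3: 3}, thr)
        assert not any(flags.values()) and not diseased

    def test_missing_observer_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            call_tissue_disease({1: 3, 2: 4}, self.THR)

    def test_monotone_in_counts(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            counts = {o: int(c) for o, c in zip((1, 2, 3), rng.integers(0, 6, 3))}
            base, _ = call_tissue_disease(counts, self.THR)
            bumped = dict(counts)
            bumped[int(rng.integers(1, 4))] += 1
            more, _ = call_tissue_disease(bumped, self.THR)
            assert more or not base  # raising a count never un-flags


class TestBodyMeasures:
    def test_bmi_formula(self):
        assert bmi(400, 20) == 1.0
        assert bmi(0, 20) == 0.0
        assert bmi(800, 20) == 2 * bmi(400, 20)
        with pytest.raises(ValueError):
            bmi(400, 0)

    def test_adipocyte_metric_constant(self):
        areas = [np.full(20, 50.0)] * 5
        assert adipocyte_metric(areas) == 50.0

    def test_smallest_cells_do_not_affect_metric(self):
        rng = np.random.default_rng(3)
        base = [rng.uniform(100, 200, size=20) for _ in range(5)]
        padded = [np.concatenate([a, np.full(5, 1.0)]) for a in base]
        assert adipocyte_metric(padded) == pytest.approx(adipocyte_metric(base))

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        imgs = [rng.uniform(10, 300, size=25) for _ in range(5)]
        shuffled = [rng.permutation(a) for a in imgs]
        assert adipocyte_metric(shuffled) == pytest.approx(adipocyte_metric(imgs))

    def test_too_few_cells_names_image(self):
        areas = [np.full(20, 50.0)] * 4 + [np.full(10, 50.0)]
        with pytest.raises(ValueError, match="image 5"):
            adipocyte_metric(areas)


class TestObesityClassify:
    STATS = {"bmi": (0.60, 0.05), "adipocyte_area": (5000, 500),
             "adiposity": (2.0, 0.5)}

    def test_all_at_mean_is_normal(self):
        m = {"bmi": 0.60, "adipocyte_area": 5000, "adiposity": 2.0}
        assert obesity_classify(m, self.STATS) == "normal"

    def test_two_high_votes_is_obese(self):
        m = {"bmi": 0.70, "adipocyte_area": 6000, "adiposity": 2.0}
        assert obesity_classify(m, self.STATS) == "obese"

    def test_hand_cutoff_arithmetic(self):
        # control BMI mean 0.60 SD 0.05 -> high cutoff 0.675; 0.70 votes high
        m = {"bmi": 0.70, "adipocyte_area": 5000, "adiposity": 2.0}
        assert obesity_classify(m, self.STATS) == "normal"  # one vote only
        m["adiposity"] = 3.0
        assert obesity_classify(m, self.STATS) == "obese"

    def test_two_low_votes_is_lean(self):
        m = {"bmi": 0.50, "adipocyte_area": 3000, "adiposity": 2.0}
        assert obesity_classify(m, self.STATS) == "lean"


class TestFrequencyTest:
    def test_identical_proportions_give_p_one(self):
        assert frequency_test(5, 10, 5, 10).p_value == 1.0

    def test_hand_enumerated_table(self):
        # [[3,7],[0,10]]: p = (C(3,3)C(17,7) + C(3,0)C(17,10)) / C(20,10)
        res = frequency_test(3, 10, 0, 10)
        assert res.p_value == pytest.approx(2 * 19448 / 184756, rel=1e-9)
        assert res.p_value == pytest.approx(0.2105, abs=2e-4)

    def test_group_order_symmetry(self):
        p1 = frequency_test(3, 12, 8, 15).p_value
        p2 = frequency_test(8, 15, 3, 12).p_value
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(6)
        for _ in range(60):
            n1 = int(rng.integers(2, 20))
            n2 = int(rng.integers(2, 20))
            a = int(rng.integers(0, n1 + 1))
            c = int(rng.integers(0, n2 + 1))
            got = frequency_test(a, n1, c, n2).p_value
            want = fisher_enumeration_oracle(a, n1 - a, c, n2 - c)
            assert got == pytest.approx(want, rel=1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            frequency_test(0, 0, 1, 10)


class TestContinuousTest:
    def test_identical_samples(self):
        res = continuous_test([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == 1.0

    def test_textbook_pooled_t(self):
        res = continuous_test([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.225, abs=1e-3)
        assert res.p_value == pytest.approx(0.288, abs=2e-3)

    def test_zero_variance_degenerate(self):
        res = continuous_test([0, 0], [1, 1])
        assert res.degenerate and res.p_value == 0.0
        res2 = continuous_test([1, 1], [1, 1])
        assert res2.p_value == 1.0 and not res2.degenerate


class TestFertilityAndBurden:
    def test_fertility_rate(self):
        breeding = pd.DataFrame(
            {"lineage": ["control"] * 2 + ["exposed"] * 2,
             "n_breedings": [5, 5, 6, 4],
             "n_pregnancies": [3, 2, 0, 0]}
        )
        rates = fertility_rate(breeding)
        assert rates["control"] == 0.5
        assert rates["exposed"] == 0.0

    def test_zero_breedings_rejected(self):
        breeding = pd.DataFrame(
            {"lineage": ["control"], "n_breedings": [0], "n_pregnancies": [0]}
        )
        with pytest.raises(ValueError):
            fertility_rate(breeding)

    def test_burden_counts_and_invariant(self):
        calls = pd.DataFrame(
            {
                "animal_id": ["a1", "a1", "a2", "a3", "b1", "b2"],
                "lineage": ["exposed"] * 4 + ["control"] * 2,
                "tissue": ["testis", "kidney", "testis", "kidney", "testis", "kidney"],
                "diseased": [True, True, True, False, False, False],
            }
        )
        burden = disease_burden(calls)
        exp = burden[burden["lineage"] == "exposed"].iloc[0]
        assert exp["n_ge1_disease"] == 2      # a1 (two diseases) and a2
        assert exp["n_ge2_disease"] == 1      # a1 only
        ctl = burden[burden["lineage"] == "control"].iloc[0]
        assert ctl["n_ge1_disease"] == 0 and ctl["n_ge2_disease"] == 0
        assert (burden["freq_ge2"] <= burden["freq_ge1"]).all()
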