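"""Normalization, dispersion estimation, exact NB test and FDR."""

import numpy as np
import pytest
from scipy.stats import binom

from dmrpipe.difftest import (
    adjust_fdr,
    equalize_counts,
    estimate_common_dispersion,
    exact_nb_test,
    normalize,
    test_windows as run_window_tests,
)
from dmrpipe.synthetic import CountSimConfig, generate_genome, simulate_window_counts
from dmrpipe.windows import WindowCountMatrix, filter_windows

GROUPS_6V6 = np.array(["control"] * 6 + ["exposed"] * 6)
EQUAL_LIBS = np.full(12, 10_000.0)


def conditional_binomial_p(s1: int, s2: int, n1: int, n2: int) -> float:
    """Independent oracle: Poisson counts conditioned on the total are
    binomial; two-sided p sums outcomes no more probable than observed."""
    total = s1 + s2
    pmf = binom.pmf(np.arange(total + 1), total, n1 / (n1 + n2))
    return float(pmf[pmf <= pmf[s1] * (1 + 1e-12)].sum())


def _matrix(counts, groups, libs=None):
    counts = np.asarray(counts)
    gw_len = counts.shape[0] * 100
    from dmrpipe.windows import GenomeWindows

    gw = GenomeWindows(100, ("chr1",), (gw_len,))
    return WindowCountMatrix(
        counts, [f"s{i}" for i in range(counts.shape[1])], list(groups), gw,
        libs if libs is not None else counts.sum(axis=0),
    )


class TestNormalize:
    def test_identical_samples_equal_factors(self):
        m = _matrix(np.tile([[5], [7], [9]], (1, 4)), ["control"] * 2 + ["exposed"] * 2)
        for method in ("total", "trimmed-mean"):
            f = normalize(m, method)
            assert np.allclose(f.effective_lib_sizes, f.effective_lib_sizes[0])

    def test_doubled_sample_doubles_total_factor(self):
        a = np.array([3, 5, 9, 2, 8])
        m = _matrix(np.stack([a, 2 * a], axis=1), ["control", "exposed"])
        f = normalize(m, "total")
        assert f.effective_lib_sizes[1] / f.effective_lib_sizes[0] == pytest.approx(2.0)

    def test_trimmed_mean_matches_total_on_proportional_samples(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(50, size=200) + 1
        scales = np.array([1.0, 2.0, 0.5, 1.5])
        counts = np.round(base[:, None] * scales[None, :]).astype(int)
        m = _matrix(counts, ["control"] * 2 + ["exposed"] * 2)
        tot = normalize(m, "total").effective_lib_sizes
        tmm = normalize(m, "trimmed-mean").effective_lib_sizes
        ratio = tmm / tot
        assert np.allclose(ratio, ratio[0], rtol=1e-2)

    def test_all_zero_sample_rejected(self):
        counts = np.array([[1, 0], [2, 0]])
        m = _matrix(counts, ["control", "exposed"], libs=np.array([3, 1]))
        with pytest.raises(ValueError, match="all-zero"):
            normalize(m)


class TestDispersion:
    @pytest.mark.parametrize("true_phi,tol", [(0.0, 0.02), (0.2, 0.2)])
    def test_parameter_recovery(self, true_phi, tol):
        genome = generate_genome({"chr1": 400_000}, seed=3)
        cfg = CountSimConfig(
            mean_library_size=100_000, dispersion=true_phi, n_true_dmrs=0, seed=4
        )
        matrix, _ = simulate_window_counts(genome, cfg)
        est = estimate_common_dispersion(filter_windows(matrix, 10))
        if true_phi == 0.0:
            assert est.phi < tol
        else:
            assert est.phi == pytest.approx(true_phi, rel=tol)

    def test_constant_counts_give_zero_phi(self):
        counts = np.full((5, 12), 7)
        m = _matrix(counts, GROUPS_6V6, libs=np.full(12, 35))
        with pytest.warns(UserWarning, match="degenerate"):
            est = estimate_common_dispersion(m)
        assert est.phi == 0.0


class TestExactNbTest:
    def test_identical_counts_give_p_one(self):
        counts = np.full(12, 9)
        for phi in (0.0, 0.1, 0.5):
            p, lfc = exact_nb_test(counts, GROUPS_6V6, EQUAL_LIBS, phi)
            assert p == 1.0
            assert lfc == pytest.approx(0.0)

    def test_ten_vs_zero_matches_binomial_enumeration(self):
        # group sums 10 vs 0 under phi=0 and equal sizes: conditional
        # Binomial(10, 1/2), p = P(0) + P(10) = 2/1024
        counts = np.array([2, 2, 2, 2, 1, 1] + [0] * 6)
        p, _ = exact_nb_test(counts, GROUPS_6V6, EQUAL_LIBS, 0.0)
        assert p == pytest.approx(2 / 1024, rel=1e-12)

    def test_label_swap_symmetry(self):
        counts = np.array([5, 1, 3, 2, 8, 1, 9, 12, 4, 7, 11, 6])
        swapped = np.where(GROUPS_6V6 == "control", "exposed", "control")
        for phi in (0.0, 0.15):
            p1, lfc1 = exact_nb_test(counts, GROUPS_6V6, EQUAL_LIBS, phi)
            p2, lfc2 = exact_nb_test(counts, swapped, EQUAL_LIBS, phi)
            assert p1 == pytest.approx(p2, rel=1e-12)
            assert lfc1 == pytest.approx(-lfc2, rel=1e-9)

    def test_poisson_limit_equals_conditional_binomial(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            counts = rng.poisson(6.0, size=12)
            if counts.sum() == 0:
                continue
            p, _ = exact_nb_test(counts, GROUPS_6V6, EQUAL_LIBS, 0.0)
            s1 = counts[:6].sum()
            s2 = counts[6:].sum()
            assert p == pytest.approx(conditional_binomial_p(s1, s2, 6, 6), rel=1e-12)

    def test_unbalanced_design_poisson_limit(self):
        groups = np.array(["control"] * 4 + ["exposed"] * 8)
        libs = np.full(12, 5000.0)
        counts = np.array([3, 1, 2, 0, 5, 6, 4, 8, 7, 5, 6, 3])
        p, _ = exact_nb_test(counts, groups, libs, 0.0)
        oracle = conditional_binomial_p(counts[:4].sum(), counts[4:].sum(), 4, 8)
        assert p == pytest.approx(oracle, rel=1e-12)

    def test_matches_reference_exact_test(self):
        # Oracle: Bioconductor edgeR 4.0.16 exactTest with
        # rejection.region="smallp", equal library sizes of 1e4,
        # dispersion fixed; values computed once and frozen.
        counts = np.array(
            [
                [5, 7, 3, 6, 9, 4, 12, 15, 20, 9, 14, 18],
                [10] * 12,
                [0, 1, 0, 2, 1, 0, 8, 6, 9, 5, 7, 10],
                [30, 25, 28, 33, 27, 29, 12, 10, 15, 9, 13, 11],
                [2, 0, 1, 1, 0, 2, 0, 1, 0, 0, 1, 0],
            ]
        )
        expected = {
            0.1: [0.000518278536283162, 1.0, 1.15358020443204e-07,
                  0.000116491606890451, 0.305004293330498],
            0.4: [0.0275911148217785, 1.0, 5.28732290871264e-05,
                  0.0257739642490695, 0.347863993025283],
        }
        for phi, exp in expected.items():
            got = [exact_nb_test(row, GROUPS_6V6, EQUAL_LIBS, phi)[0]
                   for row in counts]
            assert got == pytest.approx(exp, rel=1e-9)

    def test_scaling_counts_does_not_increase_p_on_signal(self):
        counts = np.array([4, 5, 3, 6, 4, 5, 12, 14, 9, 13, 12, 15])
        for phi in (0.0, 0.1):
            p1, _ = exact_nb_test(counts, GROUPS_6V6, EQUAL_LIBS, phi)
            p2, _ = exact_nb_test(counts * 3, GROUPS_6V6, EQUAL_LIBS * 3, phi)
            assert p2 <= p1

    def test_negative_phi_rejected(self):
        with pytest.raises(ValueError):
            exact_nb_test(np.ones(12), GROUPS_6V6, EQUAL_LIBS, -0.1)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            exact_nb_test(np.zeros(12), GROUPS_6V6, EQUAL_LIBS, 0.1)


class TestEqualization:
    def test_equal_sizes_are_identity(self):
        counts = np.arange(24).reshape(2, 12)
        assert (equalize_counts(counts, EQUAL_LIBS) == counts).all()

    def test_scaling_to_geometric_mean(self):
        counts = np.array([[100, 100]])
        libs = np.array([1000.0, 4000.0])  # geometric mean 2000
        pseudo = equalize_counts(counts, libs)
        assert list(pseudo[0]) == [200, 50]


class TestTestWindows:
    def test_matches_single_window_path(self, small_matrix):
        matrix, _ = small_matrix
        filtered = filter_windows(matrix, 10)
        factors = normalize(filtered)
        res = run_window_tests(filtered, factors, phi=0.1)
        rng = np.random.default_rng(0)
        groups = np.asarray(filtered.groups)
        for i in rng.choice(len(res), size=20, replace=False):
            p, lfc = exact_nb_test(
                filtered.counts[i], groups, factors.effective_lib_sizes, 0.1
            )
            assert res["p_value"].iloc[i] == pytest.approx(p, rel=1e-12)
            assert res["log2_fc"].iloc[i] == pytest.approx(lfc, rel=1e-9)


class TestAdjustFdr:
    def test_hand_computed_bh(self):
        q = adjust_fdr(np.array([0.01, 0.02, 0.03]))
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert adjust_fdr(np.array([0.2])) == pytest.approx([0.2])

    def test_empty_input(self):
        assert adjust_fdr(np.array([])).size == 0

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1, size=100)
        q = adjust_fdr(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr(np.array([0.0, 0.5]))
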