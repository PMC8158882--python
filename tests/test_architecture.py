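"""Dominance deviation and pairwise epistasis tests."""

import itertools

import numpy as np
import pytest
from scipy import stats

from pheoscan.architecture import epistasis_frame, epistasis_scan, estimate_dominance


class TestDominance:
    def _from_class_means(self, means, n_per=50, sd=0.0, rng=None):
        """Phenotype/dosage vectors with the three genotype-class means."""
        y, g = [], []
        for k, m in enumerate(means):
            y.extend([m] * n_per)
            g.extend([k] * n_per)
        return np.array(y, dtype=float), np.array(g, dtype=float)

    def test_perfect_additivity_d_zero(self):
        y, g = self._from_class_means([0.0, 0.5, 1.0])
        est = estimate_dominance(y, g, standardize=False)
        assert est.d == pytest.approx(0.0, abs=1e-12)

    def test_complete_dominance_d_half(self):
        y, g = self._from_class_means([0.0, 1.0, 1.0])
        est = estimate_dominance(y, g, standardize=False)
        assert est.d == pytest.approx(0.5, abs=1e-12)

    def test_hand_computed_small_classes(self):
        """Classes {1,1,2 | 2,3 | 3,3,4}: m = 7/3, het mean 2.5, d = 1/6,
        CI from the two-observation het class via t with 1 df."""
        y = np.array([1, 1, 2, 2, 3, 3, 3, 4], dtype=float)
        g = np.array([0, 0, 0, 1, 1, 2, 2, 2], dtype=float)
        est = estimate_dominance(y, g, standardize=False)
        assert est.midpoint == pytest.approx(7 / 3)
        assert est.mean_het == pytest.approx(2.5)
        assert est.d == pytest.approx(1 / 6)
        se = np.std([2, 3], ddof=1) / np.sqrt(2)
        tq = stats.t.ppf(0.975, 1)
        assert est.het_ci[0] == pytest.approx(2.5 - tq * se)
        assert est.het_ci[1] == pytest.approx(2.5 + tq * se)
        assert est.significant is False  # wide 1-df CI contains the midpoint

    def test_affine_rescaling_rescales_d(self, rng):
        g = rng.binomial(2, 0.5, 200).astype(float)
        y = 2.0 + g + rng.normal(0, 0.5, 200)
        a = estimate_dominance(y, g, standardize=False)
        b = estimate_dominance(3.0 * y - 5.0, g, standardize=False)
        assert b.d == pytest.approx(3.0 * a.d, rel=1e-9)
        # and the standardized-scale d is invariant to affine rescaling
        az = estimate_dominance(y, g)
        bz = estimate_dominance(3.0 * y - 5.0, g)
        assert bz.d == pytest.approx(az.d, rel=1e-9)

    def test_empty_class_error_names_class(self):
        y = np.array([1.0, 2.0, 3.0])
        g = np.array([0.0, 0.0, 2.0])
        with pytest.raises(ValueError, match="class 1"):
            estimate_dominance(y, g, standardize=False)

    def test_single_het_gives_d_without_significance(self):
        y = np.array([1.0, 1.5, 2.0, 3.0, 3.5])
        g = np.array([0.0, 0.0, 1.0, 2.0, 2.0])
        est = estimate_dominance(y, g, standardize=False)
        assert est.het_ci is None and est.significant is None
        assert est.d == pytest.approx(2.0 - (1.25 + 3.25) / 2)

    def test_detects_planted_dominance(self, rng):
        g = rng.binomial(2, 0.5, 2000).astype(float)
        means = {0: 0.0, 1: 0.9, 2: 1.0}  # red allele nearly dominant
        y = np.vectorize(means.get)(g) + rng.normal(0, 0.3, 2000)
        est = estimate_dominance(y, g)
        assert est.d > 0 and est.significant is True


class TestEpistasis:
    def _balanced_cells(self):
        """All 9 genotype cells, equally replicated."""
        cells = list(itertools.product([0.0, 1.0, 2.0], repeat=2))
        ga = np.repeat([c[0] for c in cells], 10)
        gb = np.repeat([c[1] for c in cells], 10)
        return ga, gb

    def test_additive_null_beta3_zero(self):
        ga, gb = self._balanced_cells()
        y = ga + gb
        res = epistasis_scan(y, {"A": ga, "B": gb})[0]
        assert res.beta3 == pytest.approx(0.0, abs=1e-12)

    def test_planted_interaction_recovered_exactly(self):
        ga, gb = self._balanced_cells()
        y = 1.0 + 0.3 * ga + 0.2 * gb + 0.5 * ga * gb
        res = epistasis_scan(y, {"A": ga, "B": gb})[0]
        assert res.beta3 == pytest.approx(0.5, abs=1e-12)
        # normal-equations oracle
        X = np.column_stack([np.ones(ga.size), ga, gb, ga * gb])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        for got, want in zip((res.beta0, res.beta1, res.beta2, res.beta3), beta):
            assert got == pytest.approx(want, abs=1e-12)

    def test_noisy_interaction_matches_oracle(self, rng):
        ga = rng.binomial(2, 0.5, 500).astype(float)
        gb = rng.binomial(2, 0.4, 500).astype(float)
        y = 1.0 + 0.4 * ga + 0.1 * ga * gb + rng.normal(0, 0.8, 500)
        res = epistasis_scan(y, {"A": ga, "B": gb})[0]
        X = np.column_stack([np.ones(500), ga, gb, ga * gb])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (500 - 4)
        se3 = np.sqrt(np.linalg.inv(X.T @ X)[3, 3] * sigma2)
        assert res.beta3 == pytest.approx(beta[3], abs=1e-10)
        assert res.stat == pytest.approx((beta[3] / se3) ** 2, abs=1e-8)
        assert res.p_value == pytest.approx(
            stats.chi2.sf((beta[3] / se3) ** 2, 1), abs=1e-12
        )

    def test_five_loci_give_ten_pairs(self, rng):
        dosages = {
            f"L{k}": rng.binomial(2, 0.5, 200).astype(float) for k in range(5)
        }
        y = rng.normal(3, 1, 200)
        results = epistasis_scan(y, dosages)
        assert len(results) == 10
        frame = epistasis_frame(results)
        assert list(frame.columns[:4]) == ["interaction", "beta3", "stat", "p_value"]

    def test_locus_label_swap_leaves_beta3_and_p(self, rng):
        ga = rng.binomial(2, 0.5, 300).astype(float)
        gb = rng.binomial(2, 0.3, 300).astype(float)
        y = 1.0 + 0.2 * ga * gb + rng.normal(0, 0.5, 300)
        ab = epistasis_scan(y, {"A": ga, "B": gb})[0]
        ba = epistasis_scan(y, {"B": gb, "A": ga})[0]
        assert ba.beta3 == pytest.approx(ab.beta3, abs=1e-12)
        assert ba.p_value == pytest.approx(ab.p_value, abs=1e-12)

    def test_collinear_loci_rejected(self, rng):
        g = rng.binomial(2, 0.5, 100).astype(float)
        with pytest.raises(ValueError, match="collinear"):
            epistasis_scan(rng.normal(size=100), {"A": g, "B": g.copy()})

    def test_monomorphic_locus_rejected(self, rng):
        g = rng.binomial(2, 0.5, 100).astype(float)
        with pytest.raises(ValueError, match="monomorphic"):
            epistasis_scan(rng.normal(size=100), {"A": g, "B": np.zeros(100)})

    def test_stat_to_p_mapping_is_chi2_1df(self):
        """The published statistic/p pairs follow the chi-square(1) tail:
        stat 41.835 -> ~9.98e-11, stat 15.652 -> ~7.62e-5."""
        assert stats.chi2.sf(41.835, 1) == pytest.approx(9.98e-11, rel=5e-3)
        assert stats.chi2.sf(15.652, 1) == pytest.approx(7.62e-5, rel=5e-3)

    def test_bonferroni_flag_tightens_significance(self, rng):
        ga = rng.binomial(2, 0.5, 400).astype(float)
        gb = rng.binomial(2, 0.5, 400).astype(float)
        y = 0.1 * ga * gb + rng.normal(0, 1, 400)
        plain = epistasis_scan(y, {"A": ga, "B": gb}, alpha=0.05)[0]
        tight = epistasis_scan(
            y, {"A": ga, "B": gb}, alpha=0.05, bonferroni=True
        )[0]
        assert tight.p_value == plain.p_value  # only the flag differs
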