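"""Encodings, OLS fitting with PRE, enumeration, selection, pruning, LRT."""

import numpy as np
import pytest

from pheoscan.model_search import (
    ADDITIVE,
    HET_HOM_SPLIT,
    RED_DOMINANT,
    RED_RECESSIVE,
    ModelSpec,
    encode_genotype,
    enumerate_model_space,
    fit_from_dict,
    fit_model,
    fit_to_dict,
    infer_best_encoding,
    likelihood_ratio_test,
    prune_by_pre,
    select_best,
)


class TestEncodeGenotype:
    @pytest.mark.parametrize(
        "dosage,encoding,expected",
        [
            (0, RED_RECESSIVE, 0.0),
            (1, RED_RECESSIVE, 0.0),
            (2, RED_RECESSIVE, 1.0),
            (0, RED_DOMINANT, 0.0),
            (1, RED_DOMINANT, 1.0),
            (2, RED_DOMINANT, 1.0),
            (0, ADDITIVE, 0.0),
            (1, ADDITIVE, 1.0),
            (2, ADDITIVE, 2.0),
        ],
    )
    def test_single_term_encodings(self, dosage, encoding, expected):
        assert encode_genotype(float(dosage), encoding) == expected

    def test_het_hom_split_two_indicators(self):
        het, hom = encode_genotype(np.array([0.0, 1.0, 2.0]), HET_HOM_SPLIT)
        np.testing.assert_array_equal(het, [0, 1, 0])
        np.testing.assert_array_equal(hom, [0, 0, 1])

    def test_missing_propagates(self):
        out = encode_genotype(np.array([np.nan, 2.0]), RED_DOMINANT)
        assert np.isnan(out[0]) and out[1] == 1.0

    def test_invalid_dosage_rejected(self):
        with pytest.raises(ValueError):
            encode_genotype(3.0, ADDITIVE)


def _dosages(rng, n, loci, freqs=None):
    freqs = freqs or [0.5] * len(loci)
    return {
        l: rng.binomial(2, p, n).astype(float) for l, p in zip(loci, freqs)
    }


class TestFitModel:
    def test_intercept_only_fit(self, rng):
        spec = ModelSpec(loci=(), encodings=())
        y = rng.normal(3, 1, 100)
        fit = fit_model(y, {}, spec)
        assert fit.adj_r2 == pytest.approx(0.0, abs=1e-12)
        assert fit.pre == {}
        assert fit.intercept == pytest.approx(y.mean())

    def test_noiseless_recovery_is_exact(self, rng):
        loci = ("A", "B", "C")
        spec = ModelSpec(
            loci=loci,
            encodings=(ADDITIVE, RED_RECESSIVE, RED_DOMINANT),
            interactions=(("A", "B"),),
            intercept=1.2,
            coefficients={"A": 0.9, "B_2": 0.3, "C_red_dom": -0.4, "A x B_2": 0.25},
        )
        dos = _dosages(rng, 600, loci)
        y = spec.latent_values(dos)
        fit = fit_model(y, dos, spec)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.2, abs=1e-10)
        for term, beta in spec.coefficients.items():
            assert fit.coef[term] == pytest.approx(beta, abs=1e-10)

    def test_matches_brute_force_normal_equations(self, rng):
        """12-sample fit against an explicit normal-equations + refit-per-
        term oracle, cross-checked with statsmodels."""
        import statsmodels.api as sm

        loci = ("A", "B")
        spec = ModelSpec(loci=loci, encodings=(ADDITIVE, RED_DOMINANT))
        dos = {
            "A": np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 1, 1, 0], dtype=float),
            "B": np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 0, 2, 1], dtype=float),
        }
        y = np.array([1.0, 2, 4, 2, 3.5, 5, 1.5, 3, 6, 2, 4, 2.5])
        fit = fit_model(y, dos, spec)
        X = np.column_stack(
            [np.ones(12), dos["A"], (dos["B"] >= 1).astype(float)]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        sse = float(np.sum((y - X @ beta) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.coef["A"] == pytest.approx(beta[1], abs=1e-10)
        assert fit.coef["B_red_dom"] == pytest.approx(beta[2], abs=1e-10)
        r2 = 1 - sse / sst
        assert fit.adj_r2 == pytest.approx(1 - (1 - r2) * 11 / 9, abs=1e-10)
        assert fit.loglik == pytest.approx(
            -6.0 * (np.log(2 * np.pi * sse / 12) + 1), abs=1e-10
        )
        # PRE oracle: refit without each column
        for j, term in enumerate(["A", "B_red_dom"]):
            Xr = np.delete(X, j + 1, axis=1)
            br = np.linalg.solve(Xr.T @ Xr, Xr.T @ y)
            sse_r = float(np.sum((y - Xr @ br) ** 2))
            assert fit.pre[term] == pytest.approx((sse_r - sse) / sst, abs=1e-10)
        # independent cross-check of coefficients/se via statsmodels
        smf = sm.OLS(y, X).fit()
        assert fit.se["A"] == pytest.approx(smf.bse[1], abs=1e-10)
        assert fit.pvalues["B_red_dom"] == pytest.approx(smf.pvalues[2], abs=1e-10)

    def test_rank_deficiency_reported(self, rng):
        dos = {"A": rng.binomial(2, 0.5, 50).astype(float)}
        dos["B"] = dos["A"].copy()  # perfectly collinear
        spec = ModelSpec(loci=("A", "B"), encodings=(ADDITIVE, ADDITIVE))
        with pytest.raises(ValueError, match="collinear|rank"):
            fit_model(rng.normal(size=50), dos, spec)


class TestEnumeration:
    ALTS = {
        "CFA2": (ADDITIVE, RED_RECESSIVE),
        "CFA15": (ADDITIVE, RED_RECESSIVE),
        "CFA18": (ADDITIVE, RED_DOMINANT),
        "CFA20": (ADDITIVE, RED_DOMINANT),
        "CFA21": (ADDITIVE, RED_DOMINANT),
    }
    LOCI = tuple(ALTS)
    PAIRS = (
        ("CFA15", "CFA20"),
        ("CFA18", "CFA20"),
        ("CFA2", "CFA15"),
        ("CFA18", "CFA21"),
        ("CFA2", "CFA18"),
        ("CFA2", "CFA21"),
        ("CFA15", "CFA21"),
    )

    def test_five_locus_toggles_give_31_models(self):
        specs = enumerate_model_space(self.LOCI, self.ALTS, include_base=False)
        assert len(specs) == 31

    def test_with_seven_interactions_4095_models(self):
        specs = enumerate_model_space(
            self.LOCI, self.ALTS, self.PAIRS, include_base=False
        )
        assert len(specs) == 4095
        assert len({s.key() for s in specs}) == 4095  # all distinct

    def test_single_locus_single_model(self):
        specs = enumerate_model_space(
            ("L",), {"L": (ADDITIVE, RED_DOMINANT)}, include_base=False
        )
        assert len(specs) == 1

    def test_include_base_adds_one(self):
        specs = enumerate_model_space(self.LOCI, self.ALTS, include_base=True)
        assert len(specs) == 32


class TestSelection:
    def test_single_candidate_is_itself(self, rng):
        spec = ModelSpec(loci=("A",), encodings=(ADDITIVE,))
        dos = _dosages(rng, 50, ("A",))
        fit = fit_model(rng.normal(size=50), dos, spec)
        assert select_best([fit])[0] is fit

    def test_identical_r2_prefers_smaller_model(self, rng):
        dos = _dosages(rng, 200, ("A", "B"))
        y = 1.0 + dos["A"] * 0.5
        small = fit_model(y, dos, ModelSpec(loci=("A",), encodings=(ADDITIVE,)))
        big = fit_model(
            y, dos, ModelSpec(loci=("A", "B"), encodings=(ADDITIVE, ADDITIVE))
        )
        # both are perfect fits (R^2 = 1): the smaller must rank first
        ranked = select_best([big, small])
        assert ranked[0] is small

    def test_generative_spec_wins_at_large_n(self, rng):
        loci = ("A", "B")
        truth = ModelSpec(
            loci=loci,
            encodings=(ADDITIVE, RED_DOMINANT),
            intercept=1.0,
            coefficients={"A": 0.8, "B_red_dom": 0.9},
        )
        dos = _dosages(rng, 5000, loci)
        y = truth.latent_values(dos) + rng.normal(0, 0.3, 5000)
        alts = {"A": (ADDITIVE, RED_RECESSIVE), "B": (ADDITIVE, RED_DOMINANT)}
        fits = [
            fit_model(y, dos, s)
            for s in enumerate_model_space(loci, alts, include_base=True)
        ]
        assert select_best(fits)[0].spec.encodings == truth.encodings


class TestInferBestEncoding:
    @pytest.mark.parametrize(
        "b1,b2,expected",
        [(0.5, 1.0, ADDITIVE), (0.05, 1.0, RED_RECESSIVE), (0.95, 1.0, RED_DOMINANT)],
    )
    def test_ratio_rule(self, rng, b1, b2, expected):
        dos = _dosages(rng, 4000, ("L",))
        spec = ModelSpec(
            loci=("L",),
            encodings=(HET_HOM_SPLIT,),
            intercept=0.0,
            coefficients={"L_1": b1, "L_2": b2},
        )
        y = spec.latent_values(dos)
        fit = fit_model(y, dos, spec)
        assert infer_best_encoding(fit, "L") == expected


class TestPruneAndLRT:
    def _fits(self, rng, null_beta=0.0, n=3000):
        loci = ("A", "B")
        truth = ModelSpec(
            loci=loci,
            encodings=(ADDITIVE, ADDITIVE),
            intercept=1.0,
            coefficients={"A": 0.8, "B": null_beta},
        )
        dos = _dosages(rng, n, loci)
        y = truth.latent_values(dos) + rng.normal(0, 0.5, n)
        full = fit_model(y, dos, ModelSpec(loci=loci, encodings=(ADDITIVE, ADDITIVE)))
        return y, dos, full

    def test_strong_terms_survive(self, rng):
        y, dos, full = self._fits(rng, null_beta=0.6)
        pruned = prune_by_pre(full, y, dos, threshold=1e-3)
        assert pruned.terms == full.terms

    def test_null_term_pruned(self, rng):
        y, dos, full = self._fits(rng, null_beta=0.0)
        pruned = prune_by_pre(full, y, dos, threshold=1e-3)
        assert pruned.terms == ("A",)

    def test_pruning_never_increases_loglik(self, rng):
        y, dos, full = self._fits(rng, null_beta=0.1)
        pruned = prune_by_pre(full, y, dos, threshold=0.05)
        assert pruned.loglik <= full.loglik + 1e-10

    def test_pre_nonnegative_and_zero_pre_term_is_free(self, rng):
        y, dos, full = self._fits(rng, null_beta=0.3)
        assert all(v >= -1e-12 for v in full.pre.values())

    def test_identical_models_p_one(self, rng):
        y, dos, full = self._fits(rng)
        assert likelihood_ratio_test(full, full) == 1.0

    def test_non_nested_rejected(self, rng):
        y, dos, _ = self._fits(rng)
        fa = fit_model(y, dos, ModelSpec(loci=("A",), encodings=(RED_DOMINANT,)))
        fb = fit_model(y, dos, ModelSpec(loci=("B",), encodings=(ADDITIVE,)))
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(fa, fb)

    def test_nested_reduction_detected(self, rng):
        y, dos, full = self._fits(rng, null_beta=0.5)
        red = fit_model(
            y,
            dos,
            ModelSpec(
                loci=("A", "B"),
                encodings=(ADDITIVE, ADDITIVE),
                excluded_terms=frozenset({"B"}),
            ),
        )
        p = likelihood_ratio_test(red, full)
        assert p < 1e-6  # B truly matters here


class TestSerialization:
    def test_fit_round_trips_through_json_dict(self, rng):
        import json

        loci = ("A", "B")
        spec = ModelSpec(
            loci=loci,
            encodings=(ADDITIVE, RED_DOMINANT),
            interactions=(("A", "B"),),
        )
        dos = _dosages(rng, 300, loci)
        y = 1.0 + 0.5 * dos["A"] + rng.normal(0, 0.4, 300)
        fit = fit_model(y, dos, spec)
        blob = json.dumps(fit_to_dict(fit))
        back = fit_from_dict(json.loads(blob))
        np.testing.assert_allclose(back.predict(dos), fit.predict(dos), atol=1e-12)
        assert back.terms == fit.terms
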