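"""MR estimators: exact identities, published worked rows, harmonization."""

import numpy as np
import pandas as pd
import pytest

from methmr import mr
from methmr.simdata import SimulationConfig, simulate_scenario


class TestWaldRatio:
    def test_adiponectin_worked_row(self):
        b, se, p = mr.wald_ratio(0.982, 0.103, -0.629, 0.143)
        assert b == pytest.approx(-0.641, abs=1e-3)
        assert se == pytest.approx(0.160, abs=1e-3)
        assert p < 1e-4

    def test_expression_worked_row(self):
        b, se, _ = mr.wald_ratio(-0.980, 0.037, -1.240, 0.105)
        assert b == pytest.approx(1.265, abs=1e-3)
        assert se == pytest.approx(0.117, abs=1e-3)

    def test_unit_denominator_identity(self):
        b, se, _ = mr.wald_ratio(1.0, 0.0, 0.42, 0.07)
        assert (b, se) == (0.42, 0.07)

    def test_second_delta_term_matters(self):
        """Dropping the exposure-uncertainty term understates the SE
        (0.146 instead of 0.160 for the adiponectin row)."""
        _, se_full, _ = mr.wald_ratio(0.982, 0.103, -0.629, 0.143)
        se_first = 0.143 / 0.982
        assert se_first == pytest.approx(0.146, abs=1e-3)
        assert se_full > se_first

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ValueError):
            mr.wald_ratio(0.0, 0.1, 0.2, 0.1)


class TestTwoStageLeastSquares:
    def test_single_instrument_equals_reduced_form_ratio(self,
                                                         small_iv_data):
        g, x, y, covs = small_iv_data

        def slope(target):
            X = np.column_stack([np.ones_like(g), g, covs])
            return np.linalg.lstsq(X, target, rcond=None)[0][1]

        res = mr.two_stage_least_squares(g, x, y, covs)
        assert res.beta == pytest.approx(slope(y) / slope(x), abs=1e-10)
        assert res.method == "2SLS"

    def test_matches_statsmodels_iv2sls(self, small_iv_data):
        """Independent cross-check against the statsmodels sandbox
        IV2SLS implementation (point estimate and SE)."""
        from statsmodels.sandbox.regression.gmm import IV2SLS

        g, x, y, covs = small_iv_data
        exog = np.column_stack([np.ones_like(x), x, covs])
        instr = np.column_stack([np.ones_like(g), g, covs])
        fit = IV2SLS(y, exog, instrument=instr).fit()
        res = mr.two_stage_least_squares(g, x, y, covs)
        assert res.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert res.se == pytest.approx(fit.bse[1], rel=1e-6)

    def test_recovers_mediation_effect(self):
        """2SLS mean estimate over seeds recovers the generative
        methylation->trait effect (small replicate of the full
        parameter-recovery run)."""
        ests = []
        for seed in range(25):
            s = simulate_scenario(SimulationConfig(
                scenario="mediation", a=0.9, b=0.3, n_samples=5000,
                n_variants_region=3, seed=seed))
            res = mr.two_stage_least_squares(
                s.genotypes.column(s.truth["sentinel_id"]),
                s.methylation, s.trait,
                s.covariates.to_numpy(float))
            ests.append(res.beta)
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.3) < 3 * mc_se

    def test_pleiotropy_indistinguishable_from_mediation(self):
        """2SLS returns the same nonzero estimate under pure horizontal
        pleiotropy (b=0): one instrument cannot separate the two."""
        s = simulate_scenario(SimulationConfig(
            scenario="pleiotropy", a=0.9, d=0.27, n_samples=5000,
            n_variants_region=3, seed=5))
        res = mr.two_stage_least_squares(
            s.genotypes.column(s.truth["sentinel_id"]),
            s.methylation, s.trait, s.covariates.to_numpy(float))
        assert res.beta == pytest.approx(0.3, abs=0.08)
        assert res.p < 1e-6

    def test_null_first_stage_raises(self, rng):
        n = 100
        g = np.zeros(n)
        with pytest.raises(ValueError, match="rank deficient|instrument"):
            mr.two_stage_least_squares(g, rng.normal(size=n),
                                       rng.normal(size=n))

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError, match=">= 50"):
            mr.two_stage_least_squares(rng.binomial(2, 0.3, 20),
                                       rng.normal(size=20),
                                       rng.normal(size=20))


class TestMultivariable2sls:
    def _study(self, seed, n=4000):
        r = np.random.default_rng(seed)
        g1 = r.binomial(2, 0.3, n).astype(float)
        g2 = r.binomial(2, 0.4, n).astype(float)
        x = 0.5 * g1 + 0.4 * g2 + r.normal(size=n)
        y = 0.4 * x + r.normal(size=n)
        return g1, g2, x, y

    def test_two_instruments_tighter_than_one(self):
        betas = []
        for seed in range(20):
            g1, g2, x, y = self._study(seed)
            both = mr.multivariable_2sls(g1, g2, x, y)
            single = mr.two_stage_least_squares(g1, x, y)
            assert both.se < single.se
            assert both.method == "MV2SLS"
            betas.append(both.beta)
        mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas) - 0.4) < 3 * mc_se

    def test_irrelevant_second_instrument(self):
        g1, _, x, y = self._study(3)
        r = np.random.default_rng(30)
        null_g = r.binomial(2, 0.3, len(x)).astype(float)
        both = mr.multivariable_2sls(g1, null_g, x, y)
        single = mr.two_stage_least_squares(g1, x, y)
        assert both.beta == pytest.approx(single.beta, abs=0.02)

    def test_duplicated_instrument_raises(self):
        g1, _, x, y = self._study(4)
        with pytest.raises(ValueError, match="rank deficient|collinear"):
            mr.multivariable_2sls(g1, g1, x, y)


def _stats(rows):
    return pd.DataFrame(rows, columns=["snp_id", "effect_allele",
                                       "other_allele", "eaf", "beta", "se"])


class TestHarmonize:
    def test_allele_swap_flips_sign(self):
        exp = _stats([("rs1", "A", "G", 0.3, 0.5, 0.05)])
        out = _stats([("rs1", "G", "A", 0.7, -0.2, 0.04)])
        pairs = mr.harmonize(exp, out)
        assert pairs[0].beta_out == pytest.approx(0.2)

    def test_palindromic_ambiguous_dropped(self):
        exp = _stats([("rs1", "A", "T", 0.49, 0.5, 0.05)])
        out = _stats([("rs1", "A", "T", 0.49, 0.2, 0.04)])
        assert mr.harmonize(exp, out) == []

    def test_palindromic_with_informative_maf_kept(self):
        exp = _stats([("rs1", "C", "G", 0.10, 0.5, 0.05)])
        out = _stats([("rs1", "C", "G", 0.10, 0.2, 0.04)])
        pairs = mr.harmonize(exp, out)
        assert len(pairs) == 1 and pairs[0].palindromic

    def test_proxy_substitution_records_r2(self):
        exp = _stats([("rs1", "A", "G", 0.3, 0.5, 0.05)])
        out = _stats([("rs_proxy", "A", "G", 0.3, 0.3, 0.04)])
        ld = pd.DataFrame({"snp_id": ["rs1"], "proxy_id": ["rs_proxy"],
                           "r2": [0.85]})
        pairs = mr.harmonize(exp, out, ld)
        assert pairs[0].proxy_r2 == 0.85

    def test_no_proxy_above_threshold_omitted(self):
        exp = _stats([("rs1", "A", "G", 0.3, 0.5, 0.05)])
        out = _stats([("rs_other", "A", "G", 0.3, 0.3, 0.04)])
        ld = pd.DataFrame({"snp_id": ["rs1"], "proxy_id": ["rs_other"],
                           "r2": [0.5]})
        assert mr.harmonize(exp, out, ld) == []


class TestIvw:
    def _pair(self, snp, bx, sx, by, sy):
        return mr.HarmonizedPair(snp, bx, sx, by, sy, "A")

    def test_single_pair_identity(self):
        res = mr.ivw([self._pair("rs1", 1.0, 1e-12, 0.5, 0.1)])
        assert res.method == "WALD"
        assert (res.beta, res.se) == (pytest.approx(0.5),
                                      pytest.approx(0.1))

    def test_equal_ratios_pool_as_inverse_root_two(self):
        pairs = [self._pair(f"rs{i}", 1.0, 1e-12, 0.5, 0.1)
                 for i in range(2)]
        res = mr.ivw(pairs)
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1 / np.sqrt(2), abs=1e-6)

    def test_hand_computed_weights(self):
        # ratios 0.4 (se 0.1) and 0.8 (se 0.2): weights 100 and 25
        pairs = [self._pair("a", 1.0, 1e-12, 0.4, 0.1),
                 self._pair("b", 1.0, 1e-12, 0.8, 0.2)]
        res = mr.ivw(pairs)
        assert res.beta == pytest.approx(0.48, abs=1e-10)
        assert res.se == pytest.approx(1 / np.sqrt(125), abs=1e-6)

    def test_order_invariance_and_scaling(self):
        pairs = [self._pair("a", 0.9, 0.02, 0.4, 0.1),
                 self._pair("b", 1.1, 0.03, 0.8, 0.2),
                 self._pair("c", 0.7, 0.01, -0.1, 0.15)]
        fwd = mr.ivw(pairs)
        rev = mr.ivw(pairs[::-1])
        assert fwd.beta == pytest.approx(rev.beta, abs=1e-12)
        scaled = [mr.HarmonizedPair(p.snp_id, 2 * p.beta_exp,
                                    2 * p.se_exp, p.beta_out, p.se_out, "A")
                  for p in pairs]
        assert mr.ivw(scaled).beta == pytest.approx(fwd.beta / 2, rel=1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mr.ivw([])


class TestReverseMr:
    def test_detects_reverse_causation(self):
        s = simulate_scenario(SimulationConfig(
            scenario="reverse", c=0.4, n_samples=5000, seed=2))
        outcome = _instrument_scan(s)
        res, verdict = mr.reverse_mr(s.gwas_stats, outcome)
        assert res.p < 0.05
        assert verdict == "reverse causation indicated"
        assert res.beta == pytest.approx(0.4, abs=0.15)

    def test_null_under_mediation(self):
        hits = 0
        for seed in range(20):
            s = simulate_scenario(SimulationConfig(
                scenario="mediation", n_samples=2000, seed=seed))
            res, verdict = mr.reverse_mr(s.gwas_stats, _instrument_scan(s))
            hits += verdict == "reverse causation unlikely"
        assert hits >= 17  # ~95% nominal

    def test_no_instruments_is_inconclusive(self):
        empty = pd.DataFrame(columns=["snp_id", "effect_allele",
                                      "other_allele", "eaf", "beta", "se"])
        res, verdict = mr.reverse_mr(empty, empty)
        assert res is None and verdict == "inconclusive"


def _instrument_scan(study):
    """Per-instrument effects on methylation from the study sample."""
    mask = (study.genotypes.variants["role"] == "trait_instrument"
            ).to_numpy()
    rows = []
    meta = study.genotypes.variants[mask]
    for j, (_, v) in zip(np.where(mask)[0], meta.iterrows()):
        g = study.genotypes.dosages[:, j]
        gc = g - g.mean()
        beta = float(gc @ study.methylation / (gc @ gc))
        resid = study.methylation - beta * gc
        se = float(np.sqrt(resid @ resid / (len(g) - 2) / (gc @ gc)))
        rows.append((v["variant_id"], v["alt"], v["ref"], v["maf"],
                     beta, se))
    return _stats(rows)
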