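"""Bayes factors, posteriors over causal configurations, concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import multivariate_normal, norm

from methmr import finemap as fm


def abf_by_quadrature(beta, se, w):
    """Independent oracle: numerically integrate the Gaussian prior times
    the Gaussian likelihood over the effect grid."""
    like = lambda b: norm.pdf(beta, loc=b, scale=se) * norm.pdf(
        b, loc=0.0, scale=np.sqrt(w))
    num, _ = integrate.quad(like, -20 * np.sqrt(w), 20 * np.sqrt(w),
                            limit=200)
    return np.log(num) - norm.logpdf(beta, loc=0.0, scale=se)


class TestAbf:
    def test_hand_evaluated_value(self):
        # 0.5*log(0.0025/0.0425) + 0.5*36*(0.04/0.0425)
        assert fm.abf(0.3, 0.05, 0.04) == pytest.approx(15.524, abs=2e-3)

    def test_null_data_favors_h0(self):
        lb = fm.abf(0.0, 0.1, 0.04)
        assert lb == pytest.approx(0.5 * np.log(0.01 / 0.05), abs=1e-12)
        assert lb < 0

    def test_degenerate_prior_limit(self):
        assert fm.abf(0.5, 0.1, 1e-12) == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_abs_z(self):
        lbs = [fm.abf(b, 0.05, 0.04) for b in (0.0, 0.1, -0.2, 0.3)]
        assert lbs == sorted(lbs)

    def test_matches_numerical_integration(self, rng):
        for _ in range(20):
            beta = rng.normal(scale=0.5)
            se = rng.uniform(0.02, 0.3)
            w = rng.uniform(0.005, 0.2)
            assert fm.abf(beta, se, w) == pytest.approx(
                abf_by_quadrature(beta, se, w), abs=1e-6)

    @pytest.mark.parametrize("se,w", [(0.0, 0.04), (-0.1, 0.04),
                                      (0.1, 0.0)])
    def test_domain_errors(self, se, w):
        with pytest.raises(ValueError):
            fm.abf(0.3, se, w)


class TestSingleVariantPosteriors:
    def test_uniform_when_equal(self):
        post = fm.single_variant_posteriors([2.0] * 5)
        np.testing.assert_allclose(post, 0.2)

    def test_dominating_bf(self):
        post = fm.single_variant_posteriors([0.0, 25.0, 0.0])
        assert post[1] > 0.999

    def test_single_variant(self):
        assert fm.single_variant_posteriors([3.0]) == pytest.approx([1.0])

    def test_permutation_equivariance(self, rng):
        lb = rng.normal(size=8)
        perm = rng.permutation(8)
        np.testing.assert_allclose(
            fm.single_variant_posteriors(lb)[perm],
            fm.single_variant_posteriors(lb[perm]), atol=1e-12)

    def test_sums_to_one_and_empty_raises(self, rng):
        assert fm.single_variant_posteriors(
            rng.normal(size=30) * 10).sum() == pytest.approx(1.0, abs=1e-9)
        with pytest.raises(ValueError):
            fm.single_variant_posteriors([])


class TestBuildRegion:
    def _row(self):
        return pd.Series({"s": 1.0, "a": 0.95, "b": 0.8, "c": 0.5,
                          "d": 0.79})

    def test_boundary_inclusive(self):
        got = fm.build_region("s", self._row())
        assert got == ["s", "a", "b"]  # r2 == 0.8 included

    def test_isolated_sentinel(self):
        row = pd.Series({"s": 1.0, "a": 0.1})
        assert fm.build_region("s", row) == ["s"]

    def test_missing_sentinel_raises(self):
        with pytest.raises(ValueError):
            fm.build_region("nope", self._row())


class TestKCausalPosterior:
    def test_matches_direct_mvn_densities(self, rng):
        """Closed-form set Bayes factors equal brute-force multivariate
        normal density ratios."""
        m = 6
        R = np.corrcoef(rng.standard_normal((300, m)), rowvar=False)
        z = rng.normal(size=m) * 4
        v = 40.0
        lbf1, lbf2 = fm._log_bf_sets(z, R, v)

        def direct(S):
            U = R[:, S]
            cov = R + v * U @ U.T
            return (multivariate_normal.logpdf(z, cov=cov)
                    - multivariate_normal.logpdf(z, cov=R))

        for i in range(m):
            assert lbf1[i] == pytest.approx(direct([i]), abs=1e-9)
        iu, ju = np.triu_indices(m, 1)
        for k, (i, j) in enumerate(zip(iu, ju)):
            assert lbf2[k] == pytest.approx(direct([i, j]), abs=1e-9)

    def test_two_separated_causals(self, rng):
        z = rng.normal(size=10)
        z[2] += 9.0
        z[7] -= 9.0
        post = fm.k_causal_posterior(z, np.eye(10), nc_var=80.0)
        assert post[2] > 0.9

    def test_single_strong_causal(self):
        z = np.zeros(10)
        z[4] = 8.0
        post = fm.k_causal_posterior(z, np.eye(10), nc_var=63.0)
        assert post[1] > 0.7

    def test_no_information_weak_prior_limit(self):
        post = fm.k_causal_posterior(np.zeros(10), np.eye(10),
                                     priors={1: 0.3, 2: 0.7},
                                     nc_var=1e-3)
        assert post[1] == pytest.approx(0.3, abs=0.01)
        assert post[2] == pytest.approx(0.7, abs=0.01)

    def test_region_size_cap(self):
        with pytest.raises(ValueError):
            fm.k_causal_posterior(np.zeros(501), np.eye(501))


def _region_fm(z_meth, z_trait, ids=None, pos=None):
    m = len(z_meth)
    ids = ids or [f"v{i}" for i in range(m)]
    pos = pos if pos is not None else np.arange(m)
    se = 0.05
    lbf_m = np.array([fm.abf(z * se, se) for z in z_meth])
    lbf_t = np.array([fm.abf(z * se, se) for z in z_trait])
    return fm.RegionFineMap(
        sentinel_id=ids[0], variant_ids=ids, pos=np.asarray(pos),
        z_meth=np.asarray(z_meth, float), z_trait=np.asarray(z_trait, float),
        log_bf_meth=lbf_m, log_bf_trait=lbf_t,
        posterior_meth=fm.single_variant_posteriors(lbf_m),
        posterior_trait=fm.single_variant_posteriors(lbf_t),
    )


class TestConcordance:
    def test_same_top_large_region_concordant(self):
        z = np.ones(60)
        z[10] = 9.0
        res = fm.concordance(_region_fm(z, z * 0.5))
        assert res.rank_of_top_meth_in_trait_ranking == 1
        assert res.concordance_rate == pytest.approx(1 / 60)
        assert res.verdict == "concordant"

    def test_rate_exactly_alpha_is_discordant(self):
        """Rank 3 of 60 gives 0.05 exactly: strict inequality fails."""
        zm = np.ones(60)
        zm[10] = 9.0
        zt = np.ones(60)
        zt[3], zt[5], zt[10] = 9.0, 8.0, 7.0
        res = fm.concordance(_region_fm(zm, zt))
        assert res.rank_of_top_meth_in_trait_ranking == 3
        assert res.concordance_rate == pytest.approx(0.05)
        assert res.verdict == "discordant"

    def test_small_region_cannot_be_concordant(self):
        z = np.ones(10)
        z[4] = 9.0
        res = fm.concordance(_region_fm(z, z))
        assert res.rank_of_top_meth_in_trait_ranking == 1
        assert res.concordance_rate == pytest.approx(0.1)
        assert res.verdict == "discordant"

    def test_tie_break_is_deterministic(self):
        zm = np.array([5.0, 5.0, 1.0])
        zt = np.array([5.0, 5.0, 1.0])
        a = fm.concordance(_region_fm(zm, zt))
        b = fm.concordance(_region_fm(zm, zt))
        assert a == b
        assert a.top_meth_variant == "v0"  # tie -> smaller position

    def test_scenario_separation(self):
        """Distinct causal variants produce discordant rankings; a shared
        causal variant produces rank 1 (smaller replicate of the
        simulation-based contract)."""
        from methmr.simdata import SimulationConfig, simulate_scenario
        rates_ld, rates_med = [], []
        for seed in range(10):
            for scen, sink in (("ld_confounded", rates_ld),
                               ("mediation", rates_med)):
                s = simulate_scenario(SimulationConfig(
                    scenario=scen, n_samples=3000, seed=seed))
                reg = (s.genotypes.variants["role"] == "region").to_numpy()
                G = s.genotypes.dosages[:, reg]
                ids = s.genotypes.variants.loc[reg, "variant_id"].tolist()
                ld = pd.DataFrame(np.corrcoef(G, rowvar=False) ** 2,
                                  index=ids, columns=ids)
                sent = s.truth["sentinel_id"]
                region = fm.build_region(sent, ld.loc[sent])
                idx = [ids.index(v) for v in region]

                def scan(y):
                    betas, ses = [], []
                    for j in idx:
                        gc = G[:, j] - G[:, j].mean()
                        b = float(gc @ y / (gc @ gc))
                        r = y - b * gc
                        ses.append(np.sqrt(
                            r @ r / (len(y) - 2) / (gc @ gc)))
                        betas.append(b)
                    return np.array(betas), np.array(ses)

                bm, sm = scan(s.methylation)
                bt, st_ = scan(s.trait)
                rfm = fm.fine_map_region(
                    sent, region,
                    s.genotypes.variants.loc[reg, "pos"].to_numpy()[idx],
                    bm, sm, bt, st_, ld)
                sink.append(fm.concordance(rfm).concordance_rate)
        assert np.median(rates_ld) > 0.05
        assert np.median(rates_med) <= 2 / 20


class TestRegionFineMapInvariants:
    def test_posteriors_sum_to_one(self):
        r = _region_fm(np.arange(5.0), np.arange(5.0)[::-1])
        assert r.posterior_meth.sum() == pytest.approx(1.0, abs=1e-9)
        assert r.posterior_trait.sum() == pytest.approx(1.0, abs=1e-9)

    def test_sentinel_must_be_in_region(self):
        with pytest.raises(ValueError, match="sentinel"):
            fm.RegionFineMap(
                sentinel_id="zz", variant_ids=["a", "b"],
                pos=np.arange(2), z_meth=np.ones(2), z_trait=np.ones(2),
                log_bf_meth=np.ones(2), log_bf_trait=np.ones(2),
                posterior_meth=np.array([0.5, 0.5]),
                posterior_trait=np.array([0.5, 0.5]))
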