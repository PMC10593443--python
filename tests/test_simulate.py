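"""Synthetic-cohort generator: determinism, calibration closed forms and
round trips, the Poisson-binomial oracle, and dependence behaviour.

Monte-Carlo assertions use the sample sizes the calibration machinery is
specified at (200k draws where a prevalence is checked against 3 binomial
SEs); these complete in seconds.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from metscreen import (
    CohortConfig,
    MarginalSpec,
    STUDY_TARGETS,
    calibrate_compound_bp,
    calibrate_dependence,
    calibrate_marginal,
    classify_components_df,
    default_cohort_config,
    load_config,
    mets_prob_poisson_binomial,
    sample_cohort,
    save_config,
)
from metscreen.simulate import replace_config


class TestMarginalSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            MarginalSpec("x", "normal", 0, -1)
        with pytest.raises(ValueError):
            MarginalSpec("x", "weibull", 0, 1)
        with pytest.raises(ValueError):
            MarginalSpec("x", "normal", 0, 1, target=(1.0, 1.5, "high"))
        with pytest.raises(ValueError):
            MarginalSpec("x", "normal", 0, 1, bounds=(2.0, 1.0))

    def test_lognormal_quantile(self):
        spec = MarginalSpec("tg", "lognormal", 0.0, 1.0)
        assert spec.quantile(0.5) == pytest.approx(1.0)
        assert spec.from_latent(np.array([0.0, 1.0]))[1] == pytest.approx(math.e)


class TestCalibrateMarginal:
    def test_closed_form_wc(self):
        """sd 11, threshold 90, exceedance 0.739 -> mean 97.04."""
        spec = MarginalSpec("wc", "normal", 95, 11, target=(90, 0.739, "high"))
        res = calibrate_marginal(spec)
        assert res.value == pytest.approx(97.043, abs=0.002)
        assert res.converged and res.achieved == pytest.approx(0.739, abs=1e-12)

    def test_median_target_is_threshold(self):
        spec = MarginalSpec("x", "normal", 0, 5, target=(42.0, 0.5, "high"))
        assert calibrate_marginal(spec).value == pytest.approx(42.0)

    def test_deficit_mirror(self):
        spec = MarginalSpec("hdl", "normal", 1, 0.25, target=(1.03, 0.499, "low"))
        res = calibrate_marginal(spec)
        # P(X < 1.03) = 0.499 => mean just above the threshold
        assert res.value == pytest.approx(1.03 - 0.25 * sps.norm.ppf(0.499), rel=1e-12)
        assert res.achieved == pytest.approx(0.499, abs=1e-12)

    def test_no_target_error(self):
        with pytest.raises(ValueError):
            calibrate_marginal(MarginalSpec("x", "normal", 0, 1))

    def test_sampling_round_trip(self, rng):
        """Thresholding 200k draws from the calibrated marginal recovers the
        target within 3 binomial SEs."""
        spec = MarginalSpec("fbg", "lognormal", math.log(90), 0.2,
                            target=(100.0, 0.195, "high"))
        mu = calibrate_marginal(spec).value
        x = np.exp(mu + 0.2 * rng.standard_normal(200_000))
        q = (x >= 100).mean()
        se = math.sqrt(0.195 * 0.805 / 200_000)
        assert abs(q - 0.195) < 3 * se


class TestCompoundBP:
    sbp = MarginalSpec("sbp", "normal", 122, 15)
    dbp = MarginalSpec("dbp", "normal", 80, 10)

    def test_inclusion_exclusion_oracle_at_zero_corr(self):
        """Independent SBP/DBP: achieved == p1 + p2 - p1*p2 for the means
        the bisection lands on."""
        res = calibrate_compound_bp(self.sbp, self.dbp, target=0.511, latent_corr=0.0)
        assert res.converged
        p1 = sps.norm.sf((130 - res.value) / 15)
        p2 = sps.norm.sf((85 - 80) / 10)
        assert res.achieved == pytest.approx(p1 + p2 - p1 * p2, abs=1e-9)
        assert res.achieved == pytest.approx(0.511, abs=0.002)

    def test_dbp_dominant_boundary(self):
        """DBP exceedance already above the target: SBP driven to the
        bracket floor, achieved >= target reported honestly."""
        dbp_hot = MarginalSpec("dbp", "normal", 95, 10)  # P(dbp>=85) ~ 0.84
        res = calibrate_compound_bp(self.sbp, dbp_hot, target=0.511)
        assert res.achieved >= 0.511
        assert not res.converged or res.achieved == pytest.approx(0.511, abs=0.002)
        assert "floor" in res.note

    def test_monte_carlo_round_trip(self):
        """The calibrated SBP mean reproduces the compound prevalence on a
        fresh 200k cohort within 3 binomial SEs."""
        cfg = default_cohort_config(n=200_000, seed=31)
        cohort = sample_cohort(cfg)
        bp = classify_components_df(cohort)["elevated_bp"].mean()
        se = math.sqrt(0.511 * 0.489 / 200_000)
        assert abs(bp - 0.511) < 3 * se

    def test_target_validation(self):
        with pytest.raises(ValueError):
            calibrate_compound_bp(self.sbp, self.dbp, target=1.5)


class TestPoissonBinomial:
    def test_study_probabilities(self):
        """The 5-step DP on the printed component prevalences."""
        p = mets_prob_poisson_binomial([0.739, 0.511, 0.499, 0.196, 0.195])
        assert p == pytest.approx(0.35418, abs=5e-6)

    def test_degenerate_and_symmetry(self):
        assert mets_prob_poisson_binomial([1, 1, 1, 1, 1]) == 1.0
        assert mets_prob_poisson_binomial([0, 0, 0, 0, 0]) == 0.0
        probs = [0.1, 0.5, 0.9, 0.3, 0.7]
        base = mets_prob_poisson_binomial(probs)
        assert mets_prob_poisson_binomial(probs[::-1]) == pytest.approx(base, abs=1e-15)

    def test_matches_exhaustive_enumeration(self):
        """Brute-force over all 2^5 outcomes."""
        import itertools

        probs = [0.739, 0.511, 0.499, 0.196, 0.195]
        total = 0.0
        for bits in itertools.product([0, 1], repeat=5):
            if sum(bits) >= 3:
                pr = 1.0
                for b, p in zip(bits, probs):
                    pr *= p if b else 1 - p
                total += pr
        assert mets_prob_poisson_binomial(probs) == pytest.approx(total, abs=1e-14)

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            mets_prob_poisson_binomial([0.5, 1.2])


class TestSampleCohort:
    def test_determinism(self):
        cfg = default_cohort_config(n=2000, seed=5)
        a = sample_cohort(cfg)
        b = sample_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_seed_changes_draw(self):
        cfg = default_cohort_config(n=500, seed=5)
        a, b = sample_cohort(cfg), sample_cohort(cfg, seed=6)
        assert not a["wc"].equals(b["wc"])

    def test_invalid_rho_names_eigenvalue(self):
        marg = default_cohort_config(n=10).marginals
        with pytest.raises(ValueError, match="eigenvalue"):
            CohortConfig(n=10, p_male=0.5, marginals=marg, rho=-0.3)

    def test_zero_rho_cross_correlations_vanish(self):
        """At rho = 0 the cross-component correlations are ~0 (|r| < 0.01
        at n = 200k) while SBP-DBP keeps its fixed within-block 0.6."""
        cfg = default_cohort_config(n=200_000, seed=17)
        cohort = sample_cohort(cfg)
        male = cohort[cohort.sex == "male"]
        for a, b in [("wc", "tg"), ("wc", "fbg"), ("tg", "hdl"), ("fbg", "sbp")]:
            r = np.corrcoef(male[a], male[b])[0, 1]
            assert abs(r) < 0.01, (a, b, r)
        r_bp = np.corrcoef(male["sbp"], male["dbp"])[0, 1]
        assert r_bp == pytest.approx(0.6, abs=0.02)
        # adiposity cluster keeps its loading
        assert np.corrcoef(male["wc"], male["weight"])[0, 1] == pytest.approx(0.5, abs=0.02)

    def test_default_demographics(self):
        """Sex mix and age moments reproduce the study description at 200k."""
        cfg = default_cohort_config(n=200_000, seed=23)
        cohort = sample_cohort(cfg)
        p_male = (cohort.sex == "male").mean()
        assert abs(p_male - 0.626) < 3 * math.sqrt(0.626 * 0.374 / 200_000)
        age_se = 12.18 / math.sqrt(200_000)
        assert abs(cohort.age.mean() - 42.66) < 3 * age_se
        assert cohort.age.std() == pytest.approx(12.18, rel=0.02)

    def test_tg_right_skewed(self):
        cohort = sample_cohort(default_cohort_config(n=50_000, seed=29))
        assert sps.skew(cohort.tg) > 0.5

    def test_bounds_respected(self):
        cfg = default_cohort_config(n=20_000, seed=37)
        cohort = sample_cohort(cfg)
        for var in ["height", "weight", "hdl", "tg", "fbg"]:
            lo, hi = cfg.marginals["male"][var].bounds
            assert cohort[var].between(lo, hi).all()
        assert (cohort.sbp > cohort.dbp).all()


class TestDependenceCalibration:
    def test_independence_target_recovers_zero_rho(self):
        """Targeting the Poisson-binomial value itself should solve to
        rho ~ 0 (the independence oracle)."""
        cfg = default_cohort_config(n=1065, seed=0)
        target = mets_prob_poisson_binomial(
            [STUDY_TARGETS[c] for c in
             ("elevated_wc", "elevated_bp", "reduced_hdl", "elevated_tg", "elevated_fbg")]
        )
        res = calibrate_dependence(cfg, target=target, eval_n=100_000, eval_seed=404,
                                   tol=0.003)
        assert res.converged
        assert abs(res.value) < 0.06

    def test_unreachable_target(self):
        cfg = default_cohort_config(n=1065, seed=0)
        res = calibrate_dependence(cfg, target=0.999, eval_n=20_000, eval_seed=405)
        assert not res.converged
        assert "range" in res.note

    def test_prevalence_increases_with_rho(self):
        """MetS prevalence is empirically monotone over the search range."""
        from metscreen.simulate import _simulated_mets_prevalence

        cfg = default_cohort_config(n=1065, seed=0)
        vals = [_simulated_mets_prevalence(cfg, r, 100_000, 406)
                for r in (-0.2, 0.0, 0.3, 0.7)]
        assert vals == sorted(vals)


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        cfg = default_cohort_config(n=1234, seed=9, rho=0.1)
        path = tmp_path / "config.yaml"
        save_config(cfg, path)
        back = load_config(path)
        assert back.n == 1234 and back.seed == 9 and back.rho == 0.1
        assert back.p_male == cfg.p_male
        for sex in ("male", "female"):
            for name, spec in cfg.marginals[sex].items():
                b = back.marginals[sex][name]
                assert b.family == spec.family
                assert b.mean == pytest.approx(spec.mean, rel=1e-12)
                assert b.target == spec.target
        # a config round trip preserves the draw exactly
        pd.testing.assert_frame_equal(sample_cohort(cfg), sample_cohort(back))

    def test_replace_config(self):
        cfg = default_cohort_config(n=10, seed=1)
        cfg2 = replace_config(cfg, n=20, rho=0.2)
        assert cfg2.n == 20 and cfg2.rho == 0.2 and cfg2.seed == cfg.seed
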