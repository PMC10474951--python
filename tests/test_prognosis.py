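import numpy as np
import pandas as pd
import pytest
from scipy.stats import beta as beta_dist

from mirimpact.prognosis import (
    SurvivalEndpoint,
    beta_p,
    cges_permutation_p,
    cges_statistic,
    composite_score,
    cox_per_feature,
    cox_univariate,
)


def simulate_survival(rng, score, baseline=1e-3, log_hr=0.0, censor_scale=2000.0):
    n = score.size
    t = rng.exponential(1.0 / (baseline * np.exp(log_hr * score)))
    c = rng.exponential(censor_scale, n)
    return SurvivalEndpoint("OS", np.minimum(t, c), (t <= c).astype(float))


class TestCoxUnivariate:
    def test_agrees_with_lifelines(self, rng):
        from lifelines import CoxPHFitter

        x = rng.normal(0, 1, 150)
        ep = simulate_survival(rng, x, log_hr=0.6)
        fit = cox_univariate(x[None, :], ep.time, ep.event)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"T": ep.time, "E": ep.event, "x": x}), "T", "E"
        )
        assert fit["beta"][0] == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit["ll1"][0] == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_handles_ties_like_r_survival_breslow(self, rng, tmp_path):
        import subprocess

        x = rng.normal(0, 1, 80)
        ep = simulate_survival(rng, x, log_hr=0.5)
        time = np.round(ep.time / 100) * 100 + 1  # force heavy ties
        fit = cox_univariate(x[None, :], time, ep.event)
        data = tmp_path / "surv.tsv"
        pd.DataFrame({"T": time, "E": ep.event, "x": x}).to_csv(
            data, sep="\t", index=False
        )
        script = tmp_path / "cox.R"
        script.write_text(
            f"""suppressMessages(library(survival))
d <- read.delim("{data}")
fit <- coxph(Surv(T, E) ~ x, data=d, ties="breslow")
cat(sprintf("%.10f", coef(fit)))
"""
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        assert fit["beta"][0] == pytest.approx(float(proc.stdout), abs=1e-6)


class TestCoxPerFeature:
    def test_null_pvalues_calibrated(self, rng):
        n = 150
        expr = rng.normal(0, 1, (2000, n))
        ep = simulate_survival(rng, np.zeros(n))
        out = cox_per_feature(expr, ep)
        frac = np.mean(out["cox_p"] < 0.05)
        assert 0.03 <= frac <= 0.07

    def test_log_hr_recovery(self, rng):
        betas = []
        for _ in range(30):
            x = rng.normal(0, 1, 300)
            ep = simulate_survival(rng, x, log_hr=0.5)
            betas.append(cox_per_feature(x[None, :], ep)["log_hr"][0])
        assert 0.35 <= np.median(betas) <= 0.65

    def test_constant_feature_missing_not_spurious(self, rng):
        n = 60
        expr = np.vstack([np.full(n, 3.0), rng.normal(0, 1, n)])
        ep = simulate_survival(rng, np.zeros(n))
        out = cox_per_feature(expr, ep)
        assert np.isnan(out.loc[0, "hazard_ratio"])
        assert np.isfinite(out.loc[1, "cox_p"])

    def test_too_few_events_all_missing(self, rng):
        expr = rng.normal(0, 1, (3, 20))
        ep = SurvivalEndpoint(
            "OS", np.full(20, 100.0), np.r_[1.0, np.zeros(19)]
        )
        out = cox_per_feature(expr, ep)
        assert out["cox_p"].isna().all()

    def test_missing_endpoint_patients_dropped(self, rng):
        n = 100
        x = rng.normal(0, 1, n)
        ep_full = simulate_survival(rng, x, log_hr=0.8)
        time = ep_full.time.copy()
        time[:20] = np.nan
        ep_missing = SurvivalEndpoint("DSS", time, ep_full.event)
        assert ep_missing.observed.sum() == 80
        out = cox_per_feature(x[None, :], ep_missing)
        assert np.isfinite(out["cox_p"][0])


class TestCompositeScore:
    def test_singleton_identity(self, rng):
        x = rng.normal(2, 3, (1, 40))
        z = (x[0] - x[0].mean()) / x[0].std()
        assert composite_score(x, [1.0]) == pytest.approx(z)

    def test_direction_flip_negates(self, rng):
        x = rng.normal(0, 1, (5, 40))
        d = np.array([1, -1, 1, 1, -1.0])
        assert composite_score(x, -d) == pytest.approx(-composite_score(x, d))

    def test_zero_variance_feature_excluded(self, rng):
        x = rng.normal(0, 1, (3, 40))
        x[1] = 5.0
        s = composite_score(x, np.ones(3))
        expected = composite_score(x[[0, 2]], np.ones(2))
        assert s == pytest.approx(expected)

    def test_aggregation_beats_single_features(self, rng):
        """When hazard rides on the set mean, the composite outperforms
        the median per-feature Cox p."""
        wins = 0
        for _ in range(25):
            expr = rng.normal(0, 1, (10, 200))
            sc = expr.mean(axis=0)
            sc = (sc - sc.mean()) / sc.std()
            ep = simulate_survival(rng, sc, log_hr=0.4)
            s, _ = cges_statistic(expr, ep)
            per_feature = cox_per_feature(expr, ep)["cox_p"].median()
            wins += s < per_feature
        assert wins / 25 >= 0.8


class TestCGESStatistic:
    def test_in_unit_interval_and_uniform_for_singleton(self, rng):
        svals = []
        for _ in range(200):
            x = rng.normal(0, 1, (1, 60))
            ep = simulate_survival(rng, np.zeros(60))
            s, _ = cges_statistic(x, ep)
            svals.append(s)
        svals = np.array(svals)
        assert np.all((svals >= 0) & (svals <= 1))
        assert 0.01 <= np.mean(svals < 0.05) <= 0.10

    def test_power_for_strong_composite_effect(self, rng):
        hits = 0
        for _ in range(20):
            expr = rng.normal(0, 1, (10, 300))
            sc = expr.mean(axis=0)
            sc = (sc - sc.mean()) / sc.std()
            ep = simulate_survival(rng, sc, log_hr=0.8)
            s, _ = cges_statistic(expr, ep)
            hits += s < 0.001
        assert hits / 20 >= 0.9


class TestCGESPermutation:
    def test_floor_when_observed_beats_all(self, rng):
        expr = rng.normal(0, 1, (8, 120))
        sc = expr.mean(axis=0)
        sc = (sc - sc.mean()) / sc.std()
        ep = simulate_survival(rng, sc, log_hr=1.2)
        p, stats, s_obs = cges_permutation_p(expr, ep, B=150, seed=5)
        if np.all(stats > s_obs):
            assert p == pytest.approx(1 / 151)
        assert p >= 1 / 151

    def test_B_resolution_agreement(self, rng):
        expr = rng.normal(0, 1, (6, 100))
        sc = expr.mean(axis=0)
        ep = simulate_survival(rng, (sc - sc.mean()) / sc.std(), log_hr=0.45)
        p_small, _, _ = cges_permutation_p(expr, ep, B=100, seed=9)
        p_big, _, _ = cges_permutation_p(expr, ep, B=1000, seed=10)
        tol = 2 * np.sqrt(p_big * (1 - p_big) / 100) + 2 / 101
        assert abs(p_small - p_big) <= tol

    def test_selection_bias_controlled(self, rng):
        """With directions chosen on observed data under null survival, the
        naive composite Cox p is anti-conservative while the permutation P
        (re-selecting directions in the null) stays calibrated."""
        naive_hits, perm_hits, reps = 0, 0, 120
        for _ in range(reps):
            expr = rng.normal(0, 1, (15, 80))
            ep = simulate_survival(rng, np.zeros(80))
            s, _ = cges_statistic(expr, ep)
            naive_hits += s < 0.05
            p, _, _ = cges_permutation_p(expr, ep, B=100, seed=int(rng.integers(2**31)))
            perm_hits += p < 0.05
        assert naive_hits / reps > 0.12        # visibly inflated
        assert 0.01 <= perm_hits / reps <= 0.11  # calibrated
        assert naive_hits > 2 * perm_hits

    def test_rejects_tiny_B(self, rng):
        expr = rng.normal(0, 1, (3, 50))
        ep = simulate_survival(rng, np.zeros(50))
        with pytest.raises(ValueError):
            cges_permutation_p(expr, ep, B=50, seed=1)


class TestBetaP:
    def test_uniform_stats_give_flat_beta(self, rng):
        stats = rng.random(1000)
        fit = beta_p(0.3, stats)
        assert fit.alpha == pytest.approx(1.0, abs=0.15)
        assert fit.beta == pytest.approx(1.0, abs=0.15)
        assert fit.p_beta == pytest.approx(0.3, abs=0.05)

    def test_beta_parameters_recovered(self, rng):
        stats = rng.beta(2, 5, 1000)
        fit = beta_p(0.1, stats)
        assert abs(fit.alpha - 2) / 2 < 0.3
        assert abs(fit.beta - 5) / 5 < 0.3

    def test_strictly_increasing_in_statistic(self, rng):
        stats = rng.beta(2, 5, 1000)
        grid = np.linspace(0.01, 0.9, 40)
        p = [beta_p(float(s), stats).p_beta for s in grid]
        assert np.all(np.diff(p) > 0)

    def test_degenerate_variance_falls_back(self):
        stats = np.array([0.0, 1.0] * 100)  # variance at the Bernoulli bound
        fit = beta_p(0.4, stats)
        assert fit.fallback
        assert 0 < fit.p_beta <= 1

    def test_out_of_range_stats_rejected(self):
        with pytest.raises(ValueError):
            beta_p(0.5, np.array([0.2, 1.4]))


class TestEndpointSeparation:
    def test_os_and_dss_use_distinct_event_vectors(self, rng):
        n = 50
        clinical = pd.DataFrame(
            {
                "os_time": rng.exponential(1000, n),
                "os_event": (rng.random(n) < 0.6).astype(float),
                "dss_time": rng.exponential(1000, n),
                "dss_event": (rng.random(n) < 0.4).astype(float),
            }
        )
        clinical.loc[:9, ["dss_time", "dss_event"]] = np.nan
        os_ep = SurvivalEndpoint.from_clinical(clinical, "OS")
        dss_ep = SurvivalEndpoint.from_clinical(clinical, "DSS")
        assert os_ep.observed.sum() == n
        assert dss_ep.observed.sum() == n - 10
        assert not np.array_equal(os_ep.event, dss_ep.event)
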