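import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import splicestem as st
from splicestem.survival import (
    backward_select_aic,
    sase_survival_screen,
    time_dependent_auc,
    univariate_screen,
)


def _clin(times, events, index=None):
    idx = index or [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"os_time": times, "os_event": events},
                        index=pd.Index(idx, name="sample_id"))


def _sim_surv(rng, n, beta=0.0, x=None):
    x = rng.uniform(0, 1, n) if x is None else x
    t = rng.exponential(np.exp(-beta * x))
    c = rng.uniform(0.2, 2.5, n)
    return _clin(np.maximum(np.minimum(t, c), 1e-3), (t <= c).astype(int)), \
        pd.Series(x, index=[f"s{i}" for i in range(n)], name="x")


class TestDichotomize:
    def test_even_split(self):
        labels = st.dichotomize_by_median(
            pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd")))
        assert set(labels[labels == "low"].index) == {"a", "b"}
        assert set(labels[labels == "high"].index) == {"c", "d"}

    def test_median_value_labeled_low(self):
        labels = st.dichotomize_by_median(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        assert labels["b"] == "low"

    def test_missing_excluded(self):
        labels = st.dichotomize_by_median(
            pd.Series([0.1, np.nan, 0.9], index=list("abc")))
        assert "b" not in labels.index

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            st.dichotomize_by_median(pd.Series([0.5, 0.5, 0.5]))


def _partial_likelihood_oracle(times, events, x):
    """Closed-form Cox partial log-likelihood (no ties) maximised by Brent."""
    times, events, x = map(np.asarray, (times, events, x))

    def npl(beta):
        ll = 0.0
        for i in np.where(events == 1)[0]:
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return -ll

    return optimize.minimize_scalar(npl, bounds=(-10, 10), method="bounded",
                                    options={"xatol": 1e-10}).x


class TestCoxUnivariate:
    def test_matches_partial_likelihood_oracle_on_six_subjects(self):
        times = [1.0, 2.5, 3.1, 4.7, 6.2, 8.9]
        events = [1, 1, 0, 1, 1, 0]
        x = [0.9, 0.4, 0.7, 0.2, 0.1, 0.3]
        res = st.cox_univariate(_clin(times, events),
                                pd.Series(x, index=[f"s{i}" for i in range(6)]))
        oracle = _partial_likelihood_oracle(times, events, x)
        assert res.coef == pytest.approx(oracle, abs=1e-4)

    def test_negated_covariate_gives_reciprocal_hr(self):
        rng = np.random.default_rng(0)
        clin, x = _sim_surv(rng, 60, beta=0.8)
        r1 = st.cox_univariate(clin, x)
        r2 = st.cox_univariate(clin, -x)
        assert np.log(r1.hr) == pytest.approx(-np.log(r2.hr), abs=1e-6)

    def test_constant_covariate_rejected(self):
        clin, x = _sim_surv(np.random.default_rng(1), 20)
        with pytest.raises(ValueError, match="constant"):
            st.cox_univariate(clin, pd.Series(1.0, index=x.index))

    def test_planted_log_hr_recovered(self):
        ests = []
        for seed in range(8):
            _, _, clinical, truth = st.simulate_tumor_cohort(
                st.SimulationConfig(seed=seed))
            tum = clinical[clinical["tissue_type"] == "tumor"]
            res = st.cox_univariate(tum, truth.latent_stemness)
            ests.append(res.coef)
        assert np.mean(ests) == pytest.approx(1.0, abs=0.3)

    def test_univariate_screen_bh_monotone(self):
        rng = np.random.default_rng(2)
        clin, _ = _sim_surv(rng, 80)
        cov = pd.DataFrame(rng.normal(0, 1, (80, 6)), index=clin.index,
                           columns=[f"c{i}" for i in range(6)])
        screen = univariate_screen(clin, cov)
        s = screen.sort_values("p")
        assert s["fdr"].is_monotonic_increasing
        assert (s["fdr"] >= s["p"] - 1e-12).all()


class TestCoxMultivariate:
    def test_single_covariate_equals_univariate(self):
        rng = np.random.default_rng(3)
        clin, x = _sim_surv(rng, 50, beta=1.0)
        uni = st.cox_univariate(clin, x)
        multi = st.cox_multivariate(clin, x.to_frame())
        assert multi.coefficients["x"] == pytest.approx(uni.coef, abs=1e-8)

    def test_noise_covariate_barely_moves_signal_coefficient(self):
        rng = np.random.default_rng(4)
        clin, x = _sim_surv(rng, 400, beta=1.0)
        noise = pd.Series(rng.normal(0, 1, 400), index=x.index, name="noise")
        alone = st.cox_multivariate(clin, x.to_frame()).coefficients["x"]
        joint = st.cox_multivariate(
            clin, pd.concat([x, noise], axis=1)).coefficients["x"]
        assert abs(alone - joint) < 0.1

    def test_protective_covariate_has_hr_below_one(self):
        rng = np.random.default_rng(5)
        clin, x = _sim_surv(rng, 150, beta=-1.5)  # higher x -> longer survival
        res = st.cox_multivariate(clin, x.to_frame())
        assert res.hazard_ratios.loc["x", "exp(coef)"] < 1

    def test_collinear_pair_named(self):
        rng = np.random.default_rng(6)
        clin, x = _sim_surv(rng, 50)
        cov = pd.concat([x.rename("a"), (2 * x + 1).rename("b")], axis=1)
        with pytest.raises(ValueError, match="'a' and 'b'"):
            st.cox_multivariate(clin, cov)

    def test_sample_guard(self):
        rng = np.random.default_rng(7)
        clin, x = _sim_surv(rng, 20)
        cov = pd.DataFrame(rng.normal(0, 1, (20, 5)), index=clin.index,
                           columns=list("abcde"))
        with pytest.raises(ValueError, match="insufficient"):
            st.cox_multivariate(clin, cov)

    def test_backward_aic_drops_pure_noise(self):
        rng = np.random.default_rng(8)
        clin, x = _sim_surv(rng, 300, beta=1.5)
        cov = pd.concat([x.rename("signal")]
                        + [pd.Series(rng.normal(0, 1, 300), index=clin.index,
                                     name=f"noise{i}") for i in range(3)], axis=1)
        selected = backward_select_aic(clin, cov)
        assert "signal" in selected and len(selected) < 4


class TestKaplanMeierLogrank:
    def test_identical_groups_p_one(self):
        times = [1.0, 2.0, 3.0, 4.0] * 2
        events = [1, 1, 0, 1] * 2
        idx = [f"s{i}" for i in range(8)]
        clin = _clin(times, events, idx)
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=idx)
        _, p = st.kaplan_meier_logrank(clin, groups)
        assert p == pytest.approx(1.0)

    def test_hand_computed_logrank_table(self):
        # deaths at t=1,2 in A and t=3,4 in B, no censoring:
        # O_A=2, E_A = 1/2 + 1/3 = 5/6, V = 1/4 + 2/9; chi2 = (2-5/6)^2 / V
        idx = list("abcd")
        clin = _clin([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], idx)
        groups = pd.Series(["A", "A", "B", "B"], index=idx)
        _, p = st.kaplan_meier_logrank(clin, groups)
        from scipy.stats import chi2
        v = 2 * 2 * 1 * 3 / (16 * 3) + 1 * 2 * 1 * 2 / (9 * 2)
        expected_p = chi2.sf((2 - 5 / 6) ** 2 / v, df=1)
        assert p == pytest.approx(expected_p, rel=1e-6)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(1, 40)
        idx = [f"s{i}" for i in range(40)]
        clin = _clin(times, [1] * 40, idx)
        groups = pd.Series(["A"] * 20 + ["B"] * 20, index=idx)
        curves, _ = st.kaplan_meier_logrank(clin, groups)
        a = curves[curves.group == "A"]
        ta = np.sort(times[:20])
        for t, s in zip(a.time, a.survival):
            if t > 0:
                assert s == pytest.approx((ta > t).mean(), abs=1e-12)

    def test_plateau_beyond_last_event_with_censoring(self):
        idx = [f"s{i}" for i in range(6)]
        clin = _clin([1.0, 2.0, 3.0, 10.0, 1.5, 2.5], [1, 1, 0, 0, 1, 1], idx)
        groups = pd.Series(["A", "A", "A", "A", "B", "B"], index=idx)
        curves, _ = st.kaplan_meier_logrank(clin, groups)
        a = curves[curves.group == "A"].sort_values("time")
        # S(1)=0.75, S(2)=0.5, then censoring only: plateau at 0.5
        assert a.survival.iloc[-1] == pytest.approx(0.5)
        assert a.time.iloc[-1] == pytest.approx(10.0)

    def test_single_group_rejected(self):
        clin = _clin([1.0, 2.0], [1, 1], ["a", "b"])
        with pytest.raises(ValueError, match="groups"):
            st.kaplan_meier_logrank(clin, pd.Series(["A", "A"], index=["a", "b"]))


class TestConcordance:
    def test_perfect_ordering(self):
        c = st.concordance_index([4, 3, 2, 1], [1, 1, 1, 1], [1, 2, 3, 4])
        assert c == 1.0

    def test_random_risk_near_half(self):
        rng = np.random.default_rng(10)
        c = st.concordance_index(rng.exponential(1, 300), np.ones(300),
                                 rng.normal(0, 1, 300))
        assert c == pytest.approx(0.5, abs=0.07)

    def test_mixed_censoring_fixture_matches_brute_force(self):
        times = [2.0, 4.0, 4.5, 6.0, 7.0]
        events = [1, 0, 1, 1, 0]
        risk = [3.0, 1.0, 2.0, 2.0, 0.5]
        # independent exhaustive oracle over ordered pairs
        conc = usable = 0.0
        for i in range(5):
            for j in range(5):
                if i == j or events[i] != 1:
                    continue
                if times[j] > times[i] or (times[j] == times[i] and events[j] == 0):
                    usable += 1
                    conc += 1.0 if risk[i] > risk[j] else (0.5 if risk[i] == risk[j] else 0)
        expected = conc / usable
        assert st.concordance_index(times, events, risk) == pytest.approx(expected)
        from lifelines.utils import concordance_index as ll_ci
        assert ll_ci(times, -np.asarray(risk), events) == pytest.approx(expected)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            st.concordance_index([1.0, 2.0], [0, 0], [1.0, 2.0])


class TestTimeDependentAuc:
    def test_no_censoring_reduces_to_binary_auc(self):
        rng = np.random.default_rng(11)
        times = rng.exponential(1, 60)
        risk = -times + rng.normal(0, 0.3, 60)
        clin_t, horizon = times, float(np.median(times))
        auc = st.time_dependent_auc(clin_t, np.ones(60), risk, [horizon])[horizon]
        binary = st.evaluate_separation(risk, times <= horizon)
        assert auc == pytest.approx(binary, abs=1e-12)

    def test_perfect_risk_ordering(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        risk = -times
        aucs = st.time_dependent_auc(times, np.ones(6), risk, [2.5, 4.5])
        assert all(a == 1.0 for a in aucs.values())

    def test_agrees_with_sksurv_under_censoring(self):
        from sksurv.metrics import cumulative_dynamic_auc
        rng = np.random.default_rng(12)
        n = 120
        x = rng.normal(0, 1, n)
        t = rng.exponential(np.exp(-x))
        c = rng.uniform(0.3, 3.0, n)
        times = np.minimum(t, c)
        events = t <= c
        y = np.array(list(zip(events, times)),
                     dtype=[("event", "?"), ("time", "<f8")])
        horizons = [float(np.quantile(times, q)) for q in (0.3, 0.5)]
        ours = st.time_dependent_auc(times, events.astype(int), x, horizons)
        ref, _ = cumulative_dynamic_auc(y, y, x, horizons)
        for h, r in zip(horizons, ref):
            assert ours[h] == pytest.approx(r, abs=0.02)

    def test_inadmissible_horizon_warns_nan(self):
        with pytest.warns(UserWarning, match="no cases"):
            out = st.time_dependent_auc([1.0, 2.0, 3.0], [1, 1, 1], [3, 2, 1], [0.5])
        assert np.isnan(out[0.5])


class TestSaseScreen:
    def test_screen_recovers_stemness_events_as_prognostic(self, default_run):
        truth = default_run["truth"]
        psi = default_run["filtered"].subset_samples(default_run["tumor_ids"]).psi
        sase_ids = sorted(truth.true_sase_ids)[:20]
        clin = default_run["clinical"].loc[default_run["tumor_ids"]]
        screen = sase_survival_screen(clin, psi.loc[sase_ids])
        # each event carries an attenuated share of the latent hazard signal,
        # so well above the 5% null rate but far from full power
        assert (screen["p"] < 0.05).mean() > 0.2
        assert {"hr", "ci_low", "ci_high", "fdr", "logrank_p"} <= set(screen.columns)
        assert ((screen["ci_low"] <= screen["hr"] + 1e-12)
                & (screen["hr"] <= screen["ci_high"] + 1e-12)).all()
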