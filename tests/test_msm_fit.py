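import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from msmimpute.msm_fit import (
    TransitionDataset,
    fit_cox,
    fit_weibull_ph,
    markov_test,
    to_transition_datasets,
)
from msmimpute.simulator import DGMConfig, simulate_cohort


def make_td(entry, exit_, status, X, transition="01", names=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(exit_):
        X = X.T
    names = names or tuple(f"x{j}" for j in range(X.shape[1]))
    frame = pd.DataFrame({"id": np.arange(len(exit_)), "entry": entry, "exit": exit_,
                          "status": status})
    for j, nm in enumerate(names):
        frame[nm] = X[:, j]
    return TransitionDataset(frame, transition, tuple(names))


class TestTransitionDatasets:
    def test_definitional_rows(self):
        c = pd.DataFrame(
            {
                "id": [0, 1],
                "z1": [1, 0],
                "z2": [0, 1],
                "aghd_status": [1, 0],
                "aghd_time": [30.0, 400.0],
                "rd_status": [1, 0],
                "rd_time": [90.0, 400.0],
                "true_aghd_time": [30.0, 400.0],
                "true_rd_time": [90.0, 400.0],
                "aghd_time_missing": [False, False],
                "rd_time_missing": [False, False],
            }
        )
        tds = to_transition_datasets(c)
        assert tds["01"].frame.loc[0, ["entry", "exit", "status"]].tolist() == [0.0, 30.0, 1]
        assert tds["02"].frame.loc[0, ["entry", "exit", "status"]].tolist() == [0.0, 30.0, 0]
        assert tds["12"].frame.iloc[0][["entry", "exit", "status"]].tolist() == [30.0, 90.0, 1]
        # censored patient: no 1->2 row, both 0-state rows censored at 400
        assert tds["01"].frame.loc[1, ["exit", "status"]].tolist() == [400.0, 0]
        assert tds["02"].frame.loc[1, ["exit", "status"]].tolist() == [400.0, 0]
        assert len(tds["12"].frame) == 1

    def test_risk_set_partition(self, cohort500):
        tds = to_transition_datasets(cohort500)
        assert len(tds["12"].frame) == int((cohort500.aghd_status == 1).sum())
        assert len(tds["01"].frame) == len(cohort500)

    def test_ordering_violation_policies(self, tiny_cohort):
        bad = tiny_cohort.copy()
        bad.loc[0, "rd_time"] = 10.0  # before its aGvHD at 30
        with pytest.raises(ValueError):
            to_transition_datasets(bad)
        dropped = to_transition_datasets(bad, on_violation="drop")
        assert 0 not in dropped["12"].frame["id"].tolist()
        clipped = to_transition_datasets(bad, on_violation="clip")
        row = clipped["12"].frame.set_index("id").loc[0]
        assert row["exit"] == pytest.approx(30.0001)


class TestCox:
    def test_four_subject_brute_force_oracle(self):
        """Newton solution equals the grid/Brent root of the 4-term
        partial-likelihood score."""
        entry = np.zeros(4)
        exit_ = np.array([1.0, 2.0, 3.0, 4.0])
        status = np.array([1, 1, 0, 1])
        z = np.array([1.0, 0.0, 1.0, 0.0])

        def neg_pl(b):
            # risk sets: t=1 {all}, t=2 {2,3,4}, t=4 {4}
            ll = b * 1 - np.log(np.exp(b) * 2 + 2)
            ll += 0 - np.log(np.exp(b) + 2)
            ll += 0 - np.log(1.0)
            return -ll

        brute = optimize.minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded").x
        fit = fit_cox(make_td(entry, exit_, status, z))
        assert fit.beta[0] == pytest.approx(brute, abs=1e-6)

    def test_agrees_with_lifelines(self, cohort500):
        lifelines = pytest.importorskip("lifelines")
        tds = to_transition_datasets(cohort500)
        for key, td in tds.items():
            ours = fit_cox(td)
            cph = lifelines.CoxPHFitter()
            cph.fit(
                td.frame[["entry", "exit", "status", *td.covariates]],
                duration_col="exit",
                event_col="status",
                entry_col="entry",
            )
            # continuous times: no ties, so Efron and Breslow coincide
            assert np.allclose(ours.beta, cph.params_.to_numpy(), atol=5e-5), key

    def test_constant_covariate_rejected(self):
        td = make_td(np.zeros(4), [1.0, 2, 3, 4], [1, 1, 1, 0], np.ones(4))
        with pytest.raises(ValueError, match="constant"):
            fit_cox(td)

    def test_time_rescaling_invariance(self, cohort500):
        tds = to_transition_datasets(cohort500)
        td = tds["12"]
        base = fit_cox(td)
        scaled_frame = td.frame.copy()
        scaled_frame[["entry", "exit"]] *= 3.7
        scaled = fit_cox(TransitionDataset(scaled_frame, "12", td.covariates))
        assert np.allclose(base.beta, scaled.beta, atol=1e-8)

    def test_left_truncation_respected(self, cohort500):
        """A 1->2 row entering after every exit time never joins a risk
        set; removing it leaves the fit unchanged."""
        td = to_transition_datasets(cohort500)["12"]
        frame = td.frame.copy()
        extra = frame.iloc[[0]].copy()
        extra["id"] = 99999
        extra["entry"] = frame["exit"].max() + 1.0
        extra["exit"] = frame["exit"].max() + 2.0
        extra["status"] = 0
        aug = fit_cox(TransitionDataset(pd.concat([frame, extra], ignore_index=True), "12",
                                        td.covariates))
        base = fit_cox(td)
        assert np.allclose(base.beta, aug.beta, atol=1e-10)

    def test_null_breslow_baseline_identity(self):
        """At beta=0 the cumulative Breslow baseline at the last event
        time equals sum over events of 1 / (number at risk)."""
        rng = np.random.default_rng(8)
        n = 60
        exit_ = rng.exponential(10.0, n)
        status = (rng.random(n) < 0.7).astype(int)
        z = rng.integers(0, 2, n).astype(float)
        td = make_td(np.zeros(n), exit_, status, z)
        fit = fit_cox(td, max_iter=0)  # stay at the beta=0 start
        expected = sum(
            1.0 / np.sum(exit_ >= t) for t in np.sort(exit_[status == 1])
        )
        assert fit.baseline["increment"].sum() == pytest.approx(expected, rel=1e-10)

    def test_score_zero_at_optimum(self, cohort500):
        from msmimpute.msm_fit import _cox_quantities

        td = to_transition_datasets(cohort500)["01"]
        fit = fit_cox(td)
        entry, exit_, status, X = td.arrays()
        ev = status == 1
        event_times, inv = np.unique(exit_[ev], return_inverse=True)
        d_k = np.bincount(inv).astype(float)
        s_k = np.zeros((len(event_times), X.shape[1]))
        np.add.at(s_k, inv, X[ev])
        at_risk = (entry[None, :] < event_times[:, None]) & (exit_[None, :] >= event_times[:, None])
        _, score, _, _ = _cox_quantities(fit.beta, X, d_k, s_k, at_risk)
        assert np.max(np.abs(score)) < 1e-6 * max(1.0, abs(fit.loglik))


class TestWeibull:
    def test_intercept_only_matches_classical_mle(self):
        """No censoring, no truncation: (shape, scale) equal the standard
        Weibull MLE, cross-checked against scipy's generic fitter."""
        rng = np.random.default_rng(9)
        x = stats.weibull_min.rvs(1.4, scale=50.0, size=400, random_state=rng)
        z = np.concatenate([np.zeros(200), np.ones(200)])  # needs a covariate
        td = make_td(np.zeros(400), x, np.ones(400, int), z)
        ours = fit_weibull_ph(td)
        assert ours.converged
        # scipy fits the plain Weibull; with beta ~ 0 the PH scale matches
        c_hat, _, s_hat = stats.weibull_min.fit(x, floc=0)
        assert ours.shape == pytest.approx(c_hat, rel=5e-2)
        assert ours.scale == pytest.approx(s_hat, rel=5e-2)

    def test_recovers_dgm_parameters_with_left_truncation(self):
        c = simulate_cohort(DGMConfig(n_patients=5000, seed=12))
        td = to_transition_datasets(c)["12"]
        fit = fit_weibull_ph(td)
        assert fit.converged
        se = np.sqrt(np.diag(fit.vcov))
        assert abs(np.log(fit.shape) - np.log(0.8)) < 3 * se[0]
        assert abs(np.log(fit.scale) - np.log(160.0)) < 3 * se[1]
        assert abs(fit.beta[0] - 1.2) < 3 * se[2]
        assert abs(fit.beta[1] - (-1.0)) < 3 * se[3]

    def test_single_event_flagged(self):
        td = make_td(np.zeros(3), [1.0, 2.0, 3.0], [1, 0, 0], [0.0, 1.0, 0.0])
        fit = fit_weibull_ph(td)
        assert not fit.converged

    def test_time_rescaling_transforms_scale_only(self, cohort500):
        td = to_transition_datasets(cohort500)["12"]
        base = fit_weibull_ph(td)
        frame = td.frame.copy()
        frame[["entry", "exit"]] *= 2.0
        scaled = fit_weibull_ph(TransitionDataset(frame, "12", td.covariates))
        assert scaled.shape == pytest.approx(base.shape, rel=1e-4)
        assert scaled.scale == pytest.approx(2.0 * base.scale, rel=1e-4)
        assert np.allclose(scaled.beta, base.beta, atol=1e-4)


class TestMarkovTest:
    def test_gamma_near_zero_on_complete_data(self, cohort500):
        mk = markov_test(cohort500, model="cox")
        assert abs(mk.gamma) < 4 * mk.se
        assert mk.ci[0] < mk.ci[1]

    def test_constant_entry_time_rejected(self, tiny_cohort):
        c = tiny_cohort.copy()
        c.loc[c.aghd_status == 1, "aghd_time"] = 25.0
        with pytest.raises(ValueError):
            markov_test(c, model="cox")
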