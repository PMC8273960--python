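"""Compositional Cox fitting, diagnostics, and rotation invariance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import movecox as mc
from movecox.model import _check_collinearity


class TestFitBasics:
    def test_summary_shape_and_order(self, small_cohort):
        res = mc.CompositionalCoxPH(small_cohort, covariates="model-1").fit()
        summ = res.summary()
        assert list(summ.index[:2]) == ["z1", "z2"]
        assert {"coef", "se", "hr", "hr_low", "hr_high", "p"} <= set(summ.columns)
        assert res.n_events == int(small_cohort.event.sum())

    def test_wald_ci_brackets_estimate_and_cov_psd(self, small_cohort):
        res = mc.CompositionalCoxPH(small_cohort, covariates="model-1").fit()
        summ = res.summary()
        assert (summ.hr_low <= summ.hr).all() and (summ.hr <= summ.hr_high).all()
        eig = np.linalg.eigvalsh(res.cov_params.to_numpy())
        assert eig.min() > -1e-10

    def test_matches_independent_cox_implementation(self, small_cohort):
        """statsmodels PHReg (Efron ties) as the independent oracle."""
        sm = pytest.importorskip("statsmodels.duration.hazard_regression")
        res = mc.CompositionalCoxPH(small_cohort, covariates="model-1").fit()
        frame = res._frame
        X = frame.drop(columns=["followup_years", "event"])
        phreg = sm.PHReg(
            frame["followup_years"], X, status=frame["event"], ties="efron"
        ).fit()
        np.testing.assert_allclose(
            res.params.to_numpy(), phreg.params, rtol=1e-4, atol=1e-6
        )
        np.testing.assert_allclose(
            np.sqrt(np.diag(res.cov_params)), phreg.bse, rtol=1e-3
        )

    def test_rotation_invariance_of_likelihood_and_lp(self, fitted_by_rotation):
        fits = list(fitted_by_rotation.values())
        lls = [f.log_likelihood for f in fits]
        assert max(lls) - min(lls) < 1e-6
        lp0 = fits[0].linear_predictor()
        for f in fits[1:]:
            np.testing.assert_allclose(f.linear_predictor(), lp0, atol=1e-6)

    def test_rotated_coefficients_differ_but_norm_is_preserved(
        self, fitted_by_rotation
    ):
        betas = {r: f.beta_z for r, f in fitted_by_rotation.items()}
        # orthogonal reparameterisation: same Euclidean norm
        norms = [np.linalg.norm(b) for b in betas.values()]
        assert max(norms) - min(norms) < 1e-6
        assert not np.allclose(
            betas[mc.Rotation.SB_FIRST], betas[mc.Rotation.MVPA_FIRST]
        )

    def test_adjustment_set_resolution(self, small_cohort):
        with pytest.raises(KeyError, match="unknown adjustment set"):
            mc.CompositionalCoxPH(small_cohort, covariates="model-9")
        with pytest.raises(KeyError, match="not in cohort"):
            mc.CompositionalCoxPH(small_cohort, covariates=["no_such_column"])

    def test_input_validation(self, small_cohort):
        bad = small_cohort.copy()
        bad.loc[0, "mvpa_min"] = 0.0
        with pytest.raises(ValueError, match="imputation"):
            mc.CompositionalCoxPH(bad)
        few = small_cohort.copy()
        few["event"] = 0
        few.loc[0, "event"] = 1
        with pytest.raises(ValueError, match="2 events"):
            mc.CompositionalCoxPH(few)

    def test_collinear_covariates_named(self, small_cohort):
        df = small_cohort.copy()
        df["age_twice"] = 2 * df["age"]
        model = mc.CompositionalCoxPH(df, covariates=["age", "age_twice"])
        with pytest.raises(ValueError, match="age"):
            model.fit()
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            _check_collinearity(X)

    def test_waking_duration_covariate_enters_model(self, small_cohort):
        df = small_cohort.copy()
        rng = np.random.default_rng(0)
        df["waking_min"] = rng.normal(960, 30, len(df))
        res = mc.CompositionalCoxPH(
            df, covariates="model-1", include_waking_duration=True
        ).fit()
        assert "waking_min" in res.params.index


class TestCoefficientRecovery:
    def test_null_coefficients_recovered(self):
        """beta_z = 0: estimates centred on zero across replicates."""
        est = []
        for s in range(30):
            cfg = mc.SimulationConfig(
                n_subjects=2000, seed=300 + s, zero_rate_mvpa=0.0,
                beta_z=(0.0, 0.0),
            )
            df = mc.simulate_cohort(cfg)
            est.append(mc.CompositionalCoxPH(df, covariates="model-1").fit().beta_z)
        est = np.array(est)
        se_of_mean = est.std(axis=0) / np.sqrt(len(est))
        assert np.all(np.abs(est.mean(axis=0)) < 3.5 * se_of_mean + 0.01)

    def test_orthogonal_covariates_leave_beta_z_alone(self):
        cfg = mc.SimulationConfig(
            n_subjects=20000, seed=77, zero_rate_mvpa=0.0, beta_z=(0.3, 0.15)
        )
        df = mc.simulate_cohort(cfg)
        b_un = mc.CompositionalCoxPH(df, covariates="unadjusted").fit().beta_z
        b_adj = mc.CompositionalCoxPH(df, covariates="model-2").fit().beta_z
        # covariates are generated independently of the composition, and the
        # log-hazard scale is collapsible over independent covariates only up
        # to the small noncollapsibility of proportional hazards
        assert np.all(np.abs(b_un - b_adj) < 0.08)


class TestPHCheck:
    def test_matches_brute_force_score_test(self, small_cohort):
        """Recompute the time-varying-coefficient score test by explicit
        per-event-time loops over risk sets and compare exactly."""
        res = mc.CompositionalCoxPH(small_cohort, covariates="model-1").fit()
        ph = res.ph_test("identity")

        frame = res._frame
        names = list(res.params.index)
        X = frame[names].to_numpy(float)
        t = frame["followup_years"].to_numpy(float)
        e = frame["event"].to_numpy(int)
        w = np.exp(res.linear_predictor())
        p = len(names)
        gbar = t[e == 1].mean()
        U = np.zeros(p)
        A = np.zeros((p, p))
        B = np.zeros((p, p))
        C = np.zeros((p, p))
        for tk in np.unique(t[e == 1]):
            risk = t >= tk
            sw = w[risk].sum()
            xbar = (w[risk, None] * X[risk]).sum(0) / sw
            Xc = X[risk] - xbar
            Vk = (w[risk, None] * Xc).T @ Xc / sw
            dead = (t == tk) & (e == 1)
            dk = dead.sum()
            gc = tk - gbar
            U += gc * (X[dead].sum(0) - dk * xbar)
            A += dk * Vk
            B += dk * gc * Vk
            C += dk * gc * gc * Vk
        W = C - B @ np.linalg.solve(A, B)
        global_stat = U @ np.linalg.solve(W, U)
        assert ph.global_stat == pytest.approx(global_stat, rel=1e-8)
        np.testing.assert_allclose(
            ph.per_term["chi2"].to_numpy(), U**2 / np.diag(W), rtol=1e-8
        )

    def test_global_p_in_unit_interval_and_df(self, fitted_by_rotation):
        res = next(iter(fitted_by_rotation.values()))
        ph = res.ph_test()
        assert 0.0 <= ph.global_p <= 1.0
        assert (ph.per_term["p"].between(0, 1)).all()

    def test_null_level(self):
        """Under proportional hazards the global test keeps its level."""
        rej = 0
        n_rep = 60
        for s in range(n_rep):
            cfg = mc.SimulationConfig(
                n_subjects=1200, seed=800 + s, zero_rate_mvpa=0.0,
                beta_z=(0.0, 0.0),
            )
            df = mc.simulate_cohort(cfg)
            res = mc.CompositionalCoxPH(df, covariates="unadjusted").fit()
            rej += res.ph_test("rank").global_p < 0.05
        # 3-SE binomial band around 5% at 60 reps
        assert rej / n_rep < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_detects_time_varying_effect(self):
        """Effect reversal mid-follow-up must be flagged (power > 50%)."""
        rej = 0
        n_rep = 30
        for s in range(n_rep):
            df = _time_varying_cohort(3000 + s, n=3000)
            res = mc.CompositionalCoxPH(df, covariates="unadjusted").fit()
            rej += res.ph_test("rank").per_term.loc["z1", "p"] < 0.05
        assert rej / n_rep > 0.5

    def test_transform_options(self, small_cohort):
        res = mc.CompositionalCoxPH(small_cohort, covariates="unadjusted").fit()
        stats_ = {
            tr: res.ph_test(tr).global_stat
            for tr in ("rank", "identity", "log", "km")
        }
        assert all(s >= 0 for s in stats_.values())
        with pytest.raises(ValueError, match="transform"):
            res.ph_test("bogus")


def _time_varying_cohort(seed, n=3000):
    """Cohort whose z1 log-hazard effect flips sign after 3 years."""
    cfg = mc.SimulationConfig(
        n_subjects=n, seed=seed, zero_rate_mvpa=0.0, beta_z=(0.0, 0.0)
    )
    df = mc.simulate_cohort(cfg)
    rng = np.random.default_rng(seed + 1)
    z = mc.ilr_matrix(
        df[["sb_min", "lipa_min", "mvpa_min"]].to_numpy(), mc.Rotation.SB_FIRST
    )
    x = z[:, 0] - z[:, 0].mean()
    lam, b1, b2, t0 = 1 / 78.0, 0.8, -0.8, 3.0
    T1 = rng.exponential(1 / (lam * np.exp(b1 * x)))
    T = np.where(T1 < t0, T1, t0 + rng.exponential(1 / (lam * np.exp(b2 * x))))
    C = rng.uniform(6.0, 7.5, n)
    df["followup_years"] = np.maximum(np.round(np.minimum(T, C) * 365.25), 1) / 365.25
    df["event"] = (T <= C).astype(int)
    return df


class TestInteraction:
    def test_p_value_contract(self, small_cohort):
        df = small_cohort.copy()
        res = mc.CompositionalCoxPH(df, covariates="model-1").fit()
        out = res.interaction_test("female")
        assert 0.0 <= out.p_value <= 1.0
        assert out.df == 2
        assert len(out.per_term) == 2

    def test_constant_modifier_rejected(self, small_cohort):
        df = small_cohort.copy()
        df["flag"] = 1.0
        res = mc.CompositionalCoxPH(df, covariates="model-1").fit()
        with pytest.raises(ValueError, match="constant"):
            res.interaction_test("flag")

    def test_nonbinary_modifier_rejected(self, small_cohort):
        res = mc.CompositionalCoxPH(small_cohort, covariates="model-1").fit()
        with pytest.raises(ValueError, match="binary"):
            res.interaction_test("age")

    def test_power_against_injected_modification(self):
        """A strong stratum shift in beta_z1 is detected most of the time."""
        rej = 0
        n_rep = 25
        for s in range(n_rep):
            df = _interaction_cohort(9000 + s, delta=0.8)
            res = mc.CompositionalCoxPH(df, covariates="model-2").fit()
            rej += res.interaction_test("modifier").p_value < 0.05
        assert rej / n_rep > 0.5


def _interaction_cohort(seed, delta):
    halves = []
    for i, b1 in enumerate((0.10, 0.10 + delta)):
        cfg = mc.SimulationConfig(
            n_subjects=1660, seed=seed + 50000 * i, zero_rate_mvpa=0.0,
            beta_z=(b1, 0.15),
        )
        d = mc.simulate_cohort(cfg)
        d["modifier"] = float(i)
        halves.append(d)
    return pd.concat(halves, ignore_index=True)


class TestRotationReport:
    def test_table_shape_and_labels(self, small_cohort):
        table = mc.rotation_report(small_cohort, covariate_sets=("model-1",))
        assert len(table) == 6  # 3 rotations x 2 coordinates
        mvpa_row = table[
            (table.rotation == "MVPA_FIRST") & (table.coordinate == "z1")
        ].iloc[0]
        assert "MVPA increase relative to" in mvpa_row.interpretation
        sb_lipa = table[
            (table.rotation == "MVPA_FIRST") & (table.coordinate == "z2")
        ].iloc[0]
        assert sb_lipa.interpretation == "SB increase relative to LIPA"
        # one shared maximum of the partial likelihood
        assert table.log_likelihood.std() < 1e-6
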