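"""Compositional Cox proportional-hazards model and its results object.

:class:`CompositionalCoxPH` is built from a cohort table (one row per
subject: behaviour minutes, covariates, follow-up time, event indicator).
The three-part waking-day composition enters the hazard through its two
pivot ilr coordinates under a chosen rotation, alongside ordinary
covariates:

    h(t | z, x) = h0(t) * exp(beta_z1 z1 + beta_z2 z2 + gamma' x)

``fit()`` maximises the Cox partial likelihood (Efron tie handling,
delegated to lifelines) and returns a :class:`CompositionalCoxResults`
carrying coefficients, covariance, Wald intervals and diagnostics:
the Grambsch-Therneau proportional-hazards test on scaled Schoenfeld
residuals, 2-df Wald effect-modification tests, and the reallocation
hazard-ratio machinery (tables and ternary surfaces).

The rotations are orthogonal reparameterisations: the log partial
likelihood, linear predictors and every reallocation HR are identical
across rotations; only (beta_z1, beta_z2) rotate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .composition import Rotation, ilr_matrix
from . import reallocation as _realloc

__all__ = [
    "ADJUSTMENT_SETS",
    "CompositionalCoxPH",
    "CompositionalCoxResults",
    "PHTestResult",
    "InteractionTestResult",
    "rotation_report",
]

#: Named covariate-adjustment sets.  "model-1" is sociodemographic +
#: lifestyle; "model-2" adds cardiometabolic risk factors and the
#: multimorbidity index.  Resolved against the cohort's columns at fit
#: time so renamed cohorts can supply their own lists instead.
ADJUSTMENT_SETS: dict[str, tuple[str, ...]] = {
    "unadjusted": (),
    "model-1": (
        "age",
        "female",
        "nonwhite",
        "married",
        "higher_educ",
        "low_occup",
        "alcohol_moderate",
        "current_smoker",
        "fruit_veg_daily",
    ),
    "model-2": (
        "age",
        "female",
        "nonwhite",
        "married",
        "higher_educ",
        "low_occup",
        "alcohol_moderate",
        "current_smoker",
        "fruit_veg_daily",
        "bmi_overweight",
        "bmi_obese",
        "diabetes",
        "hypertension",
        "hyperlipidaemia",
        "multimorbidity",
    ),
}

_PART_COLS = ("sb_min", "lipa_min", "mvpa_min")


def _resolve_covariates(cohort: pd.DataFrame, covariates) -> list[str]:
    if covariates is None:
        return []
    if isinstance(covariates, str):
        if covariates not in ADJUSTMENT_SETS:
            raise KeyError(
                f"unknown adjustment set {covariates!r}; "
                f"known: {sorted(ADJUSTMENT_SETS)}"
            )
        covariates = ADJUSTMENT_SETS[covariates]
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise KeyError(f"covariates not in cohort table: {missing}")
    return list(covariates)


def _check_collinearity(X: pd.DataFrame) -> None:
    """Raise naming the offending terms if the design is rank-deficient."""
    A = X.to_numpy(dtype=float)
    A = A - A.mean(axis=0)
    norms = np.linalg.norm(A, axis=0)
    if np.any(norms == 0):
        const = list(X.columns[norms == 0])
        raise ValueError(f"constant covariate column(s): {const}")
    A = A / norms
    _, s, vt = np.linalg.svd(A, full_matrices=False)
    if s[-1] < 1e-8 * s[0]:
        involved = list(X.columns[np.abs(vt[-1]) > 1e-3])
        raise ValueError(f"collinear covariates: {involved}")


class CompositionalCoxPH:
    """Cox model for a 3-part waking-day composition plus covariates.

    Parameters
    ----------
    cohort
        Subject-level table with behaviour-minute columns, covariates,
        follow-up duration and event indicator.
    rotation
        Which behaviour occupies the ilr pivot; default
        ``Rotation.SB_FIRST``.
    covariates
        Either an explicit list of column names or the name of an
        adjustment set from :data:`ADJUSTMENT_SETS`.
    include_waking_duration
        Add the raw waking-day duration as a covariate — the
        "non-normalised" sensitivity analysis (the ilr coordinates are
        scale-invariant, so only this extra term distinguishes it).
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        rotation: Rotation = Rotation.SB_FIRST,
        covariates="unadjusted",
        duration_col: str = "followup_years",
        event_col: str = "event",
        parts_cols: tuple[str, str, str] = _PART_COLS,
        include_waking_duration: bool = False,
        waking_col: str = "waking_min",
    ) -> None:
        self.cohort = cohort.reset_index(drop=True)
        self.rotation = rotation
        self.covariate_label = (
            covariates if isinstance(covariates, str) else "custom"
        )
        self.covariates = _resolve_covariates(cohort, covariates)
        self.duration_col = duration_col
        self.event_col = event_col
        self.parts_cols = tuple(parts_cols)
        self.include_waking_duration = include_waking_duration
        self.waking_col = waking_col

        parts = self.cohort[list(self.parts_cols)].to_numpy(dtype=float)
        if np.any(parts <= 0):
            raise ValueError(
                "compositions must be strictly positive; run zero "
                "imputation before fitting"
            )
        if np.any(self.cohort[duration_col] <= 0):
            raise ValueError("follow-up durations must be positive")
        ev = self.cohort[event_col]
        if not set(np.unique(ev)) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")
        if ev.sum() < 2:
            raise ValueError("need at least 2 events to fit")
        self._parts = parts

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame, **kwargs) -> "CompositionalCoxPH":
        return cls(cohort, **kwargs)

    def design(self, extra: pd.DataFrame | None = None) -> pd.DataFrame:
        """Regression frame: z1, z2, covariates, duration and event."""
        z = ilr_matrix(self._parts, self.rotation)
        df = pd.DataFrame({"z1": z[:, 0], "z2": z[:, 1]})
        for c in self.covariates:
            df[c] = self.cohort[c].to_numpy(dtype=float)
        if self.include_waking_duration:
            df[self.waking_col] = self.cohort[self.waking_col].to_numpy(
                dtype=float
            )
        if extra is not None:
            for c in extra.columns:
                df[c] = extra[c].to_numpy(dtype=float)
        df[self.duration_col] = self.cohort[self.duration_col].to_numpy(
            dtype=float
        )
        df[self.event_col] = self.cohort[self.event_col].to_numpy(dtype=int)
        return df

    def fit(self, ties: str = "efron") -> "CompositionalCoxResults":
        """Maximise the Cox partial likelihood; Efron ties by default."""
        df = self.design()
        _check_collinearity(
            df.drop(columns=[self.duration_col, self.event_col])
        )
        cph = self._fit_frame(df, ties)
        return CompositionalCoxResults(self, cph, df)

    def _fit_frame(self, df: pd.DataFrame, ties: str = "efron") -> CoxPHFitter:
        if ties != "efron":
            raise ValueError("only the Efron tie approximation is supported")
        cph = CoxPHFitter()
        try:
            cph.fit(
                df,
                duration_col=self.duration_col,
                event_col=self.event_col,
            )
        except Exception as exc:  # lifelines raises ConvergenceError
            raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
        return cph


@dataclass
class PHTestResult:
    """Grambsch-Therneau proportional-hazards diagnostics."""

    per_term: pd.DataFrame  # index: coefficient; columns: chi2, p
    global_stat: float
    global_p: float
    time_transform: str

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PHTestResult(global chi2={self.global_stat:.3f}, "
            f"p={self.global_p:.4f}, transform={self.time_transform!r})"
        )


@dataclass
class InteractionTestResult:
    """Joint 2-df Wald test of modifier x (z1, z2) interaction terms."""

    modifier: str
    stat: float
    df: int
    p_value: float
    per_term: pd.DataFrame = field(repr=False)


class CompositionalCoxResults:
    """Fitted compositional Cox model: estimates, diagnostics, contrasts."""

    def __init__(
        self, model: CompositionalCoxPH, cph: CoxPHFitter, frame: pd.DataFrame
    ) -> None:
        self.model = model
        self._cph = cph
        self._frame = frame

    # -- estimates -----------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return self._cph.params_

    @property
    def cov_params(self) -> pd.DataFrame:
        return self._cph.variance_matrix_

    @property
    def beta_z(self) -> np.ndarray:
        return self.params[["z1", "z2"]].to_numpy()

    @property
    def cov_z(self) -> np.ndarray:
        return self.cov_params.loc[["z1", "z2"], ["z1", "z2"]].to_numpy()

    @property
    def log_likelihood(self) -> float:
        return float(self._cph.log_likelihood_)

    @property
    def n_events(self) -> int:
        return int(self._frame[self.model.event_col].sum())

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.norm.ppf(1 - alpha / 2)
        se = np.sqrt(np.diag(self.cov_params))
        lo = np.exp(self.params - q * se)
        hi = np.exp(self.params + q * se)
        return pd.DataFrame(
            {"hr_low": lo, "hr_high": hi}, index=self.params.index
        )

    def linear_predictor(self) -> np.ndarray:
        """Centered linear predictor x'beta per subject."""
        return self._cph.predict_log_partial_hazard(self._frame).to_numpy()

    def summary(self) -> pd.DataFrame:
        """Coefficient table: log HR, se, HR with 95% CI, Wald p."""
        se = pd.Series(
            np.sqrt(np.diag(self.cov_params)), index=self.params.index
        )
        z = self.params / se
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": se,
                "hr": self.hazard_ratios,
                "hr_low": ci["hr_low"],
                "hr_high": ci["hr_high"],
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )

    # -- diagnostics ---------------------------------------------------
    def ph_test(self, time_transform: str = "rank") -> PHTestResult:
        """Grambsch-Therneau proportional-hazards test.

        Score test for a time-varying coefficient ``beta_j(t) = beta_j +
        theta_j g(t)``: with Schoenfeld residual sums ``S_k`` and
        risk-set information contributions ``d_k V_k`` at each event
        time,

            U = sum_k (g_k - gbar) S_k
            W = sum gc^2 d_k V_k - [sum gc d_k V_k] [sum d_k V_k]^-1
                                    [sum gc d_k V_k]
            T = U' W^-1 U  ~  chi2(p)

        with per-term 1-df versions ``U_j^2 / W_jj``.  The risk-set
        variances (rather than the averaged-information approximation)
        keep the test calibrated under tied event times.
        """
        if self.n_events == 0:
            raise ValueError("no events: proportional-hazards test undefined")
        names = list(self.params.index)
        X = self._frame[names].to_numpy(dtype=float)
        t = self._frame[self.model.duration_col].to_numpy(dtype=float)
        e = self._frame[self.model.event_col].to_numpy(dtype=int)
        w = np.exp(self.linear_predictor())

        order = np.argsort(-t, kind="stable")  # descending: cumulative risk sets
        Xs, ts, es, ws = X[order], t[order], e[order], w[order]
        cw = np.cumsum(ws)
        cwx = np.cumsum(ws[:, None] * Xs, axis=0)
        cwxx = np.cumsum(
            ws[:, None, None] * Xs[:, :, None] * Xs[:, None, :], axis=0
        )

        event_times = np.unique(ts[es == 1])[::-1]
        p = len(names)
        S_list, V_list, d_list, g_times = [], [], [], []
        for tk in event_times:
            at_risk = np.searchsorted(-ts, -tk, side="right") - 1
            sw = cw[at_risk]
            xbar = cwx[at_risk] / sw
            Vk = cwxx[at_risk] / sw - np.outer(xbar, xbar)
            dead = (ts == tk) & (es == 1)
            dk = int(dead.sum())
            S_list.append(Xs[dead].sum(axis=0) - dk * xbar)
            V_list.append(Vk)
            d_list.append(dk)
            g_times.append(tk)
        S = np.array(S_list)
        Vks = np.array(V_list)
        dks = np.array(d_list, dtype=float)
        g_times = np.array(g_times)

        # transform applied to every follow-up time (censored included),
        # centred at the mean over events — as in standard survival tooling
        if time_transform == "rank":
            g_all = stats.rankdata(t, method="average")
        elif time_transform == "identity":
            g_all = t.copy()
        elif time_transform == "log":
            g_all = np.log(t)
        elif time_transform == "km":
            g_all = _km_transform(t, e, t)
        else:
            raise ValueError(f"unknown time transform {time_transform!r}")
        gbar = float(g_all[e == 1].mean())
        g_of = dict(zip(t, g_all))
        gc = np.array([g_of[tk] for tk in g_times]) - gbar

        U = (gc[:, None] * S).sum(axis=0)
        A = (dks[:, None, None] * Vks).sum(axis=0)
        B = ((dks * gc)[:, None, None] * Vks).sum(axis=0)
        C = ((dks * gc * gc)[:, None, None] * Vks).sum(axis=0)
        W = C - B @ np.linalg.solve(A, B)
        global_stat = float(U @ np.linalg.solve(W, U))
        global_p = float(stats.chi2.sf(global_stat, p))
        per_chi2 = U**2 / np.diag(W)
        per_term = pd.DataFrame(
            {"chi2": per_chi2, "p": stats.chi2.sf(per_chi2, 1)}, index=names
        )
        return PHTestResult(per_term, global_stat, global_p, time_transform)

    def interaction_test(self, modifier: str) -> InteractionTestResult:
        """Effect modification: add modifier*z1 and modifier*z2, Wald 2-df.

        The modifier must be a binary column of the cohort table.  The
        joint test is reported with the per-term Wald tests alongside.
        """
        m = self.model.cohort[modifier].to_numpy(dtype=float)
        levels = np.unique(m)
        if levels.size < 2:
            raise ValueError(f"modifier {modifier!r} is constant")
        if not set(levels) <= {0.0, 1.0}:
            raise ValueError(f"modifier {modifier!r} must be binary 0/1")
        z = ilr_matrix(self.model._parts, self.model.rotation)
        extra = pd.DataFrame(
            {
                f"{modifier}:z1": m * z[:, 0],
                f"{modifier}:z2": m * z[:, 1],
            }
        )
        if modifier not in ["z1", "z2", *self.model.covariates]:
            extra.insert(0, modifier, m)
        df = self.model.design(extra=extra)
        cph = self.model._fit_frame(df)
        names = [f"{modifier}:z1", f"{modifier}:z2"]
        b = cph.params_[names].to_numpy()
        Vb = cph.variance_matrix_.loc[names, names].to_numpy()
        stat = float(b @ np.linalg.solve(Vb, b))
        se = np.sqrt(np.diag(Vb))
        per = pd.DataFrame(
            {
                "coef": b,
                "se": se,
                "p": 2 * stats.norm.sf(np.abs(b / se)),
            },
            index=names,
        )
        return InteractionTestResult(
            modifier, stat, 2, float(stats.chi2.sf(stat, 2)), per
        )

    # -- reallocation contrasts ---------------------------------------
    def reallocation_hr(
        self, ref, from_behaviour: str, to_behaviour: str, delta_min: float
    ) -> _realloc.ReallocationEstimate:
        return _realloc.reallocation_hr(
            self.beta_z,
            self.cov_z,
            self.model.rotation,
            ref,
            from_behaviour,
            to_behaviour,
            delta_min,
        )

    def reallocation_table(
        self, references, deltas=(10.0, 20.0, 30.0)
    ) -> pd.DataFrame:
        return _realloc.reallocation_table(
            self.beta_z, self.cov_z, self.model.rotation, references, deltas
        )

    def hr_surface(
        self,
        ref,
        grid_step: float = 5.0,
        ranges: dict[str, tuple[float, float]] | None = "observed",
    ) -> pd.DataFrame:
        """HR surface over the simplex; ranges default to observed data."""
        if ranges == "observed":
            parts = self.model._parts
            total = ref.composition.total_min
            closed = parts * (total / parts.sum(axis=1, keepdims=True))
            ranges = {
                b: (closed[:, i].min(), closed[:, i].max())
                for i, b in enumerate(("SB", "LIPA", "MVPA"))
            }
        return _realloc.hr_surface(
            self.beta_z,
            self.cov_z,
            self.model.rotation,
            ref,
            grid_step,
            ranges,
        )


def _km_transform(durations, events, event_times) -> np.ndarray:
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter().fit(durations, events)
    s = km.survival_function_at_times(event_times).to_numpy()
    return 1.0 - s


def rotation_report(
    cohort: pd.DataFrame,
    covariate_sets=("model-1", "model-2"),
    rotations=tuple(Rotation),
    **model_kwargs,
) -> pd.DataFrame:
    """Relative-importance table: three rotations x adjustment sets.

    For each rotation the z1 row reads as "<pivot> increase relative to
    the other two behaviours" and z2 as the contrast of the remaining
    pair; entries are HR (95% CI) and Wald p.
    """
    rows = []
    for rot in rotations:
        for cs in covariate_sets:
            res = CompositionalCoxPH(
                cohort, rotation=rot, covariates=cs, **model_kwargs
            ).fit()
            summ = res.summary()
            order = rot.pivot_order
            labels = {
                "z1": f"{order[0]} increase relative to {order[1]} and {order[2]}",
                "z2": f"{order[1]} increase relative to {order[2]}",
            }
            for coord in ("z1", "z2"):
                r = summ.loc[coord]
                rows.append(
                    {
                        "rotation": rot.name,
                        "coordinate": coord,
                        "interpretation": labels[coord],
                        "adjustment": cs,
                        "hr": r["hr"],
                        "hr_low": r["hr_low"],
                        "hr_high": r["hr_high"],
                        "p": r["p"],
                        "log_likelihood": res.log_likelihood,
                    }
                )
    return pd.DataFrame(rows)
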