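"""Log-ratio EM imputation of zero behaviour durations.

Accelerometer-derived daily durations can contain structural-looking zeros
(typically zero MVPA) that are really values below the measurement
resolution of one 60-s epoch.  Log-ratio methods require strictly positive
parts, so zeros are treated as left-censored below a detection limit and
replaced by their expected values under a censored additive-log-ratio
(alr) normal model, fitted by Expectation-Maximization — the lrEM approach
for compositional data.

Model: with reference part r (a behaviour observed in every subject),
``y_ij = ln(x_ij / x_ir)`` follows a multivariate normal across subjects.
A zero cell ``x_ij = 0`` contributes a censoring constraint
``y_ij < ln(DL_j / x_ir)``.  EM alternates truncated-normal conditional
moments (E-step) with normal MLEs on the completed data (M-step); imputed
cells are the conditional truncated means at convergence, guaranteed to
fall in ``(0, DL)``.  Rows are re-closed to their original totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["LrEMResult", "LrEMError", "impute_zeros_lrem"]


class LrEMError(RuntimeError):
    """EM failure, carrying iteration diagnostics."""

    def __init__(self, message: str, n_iter: int = 0, loglik_path=None):
        super().__init__(message)
        self.n_iter = n_iter
        self.loglik_path = list(loglik_path or [])


@dataclass
class LrEMResult:
    """Imputed composition matrix plus EM diagnostics."""

    parts: np.ndarray
    n_imputed: int
    n_iter: int
    converged: bool
    loglik_path: list[float] = field(default_factory=list)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"LrEMResult(n_imputed={self.n_imputed}, n_iter={self.n_iter}, "
            f"converged={self.converged})"
        )


def _truncated_upper_moments(m, s, c):
    """Mean and second moment of N(m, s^2) truncated to (-inf, c)."""
    alpha = (c - m) / s
    # log-space Mills ratio keeps far-tail censoring stable
    lam = np.exp(stats.norm.logpdf(alpha) - stats.norm.logcdf(alpha))
    mean = m - s * lam
    var = s * s * (1.0 - lam * (lam + alpha))
    return mean, var + mean * mean


def impute_zeros_lrem(
    parts,
    detection_limit: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> LrEMResult:
    """Replace zero cells in an (n, 3) minutes matrix with lrEM estimates.

    Parameters
    ----------
    parts
        Array-like of shape (n, 3), canonical (SB, LIPA, MVPA) order,
        nonnegative minutes per day; rows need not be closed.
    detection_limit
        Minutes below which a duration registers as zero.  Default 1 min,
        the resolution of one 60-s epoch.  Scalar or length-3 per part.
    tol
        Convergence tolerance on the largest absolute change of any alr
        mean/covariance parameter between iterations.
    max_iter
        Iteration cap; exceeding it raises :class:`LrEMError`.

    Returns
    -------
    LrEMResult with ``parts`` strictly positive, rows summing to the
    original row totals, zero cells replaced by values in
    ``(0, detection_limit)`` and positive cells preserved up to re-closure.
    """
    X = np.asarray(parts, dtype=float).copy()
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("expected an (n, 3) matrix of SB/LIPA/MVPA minutes")
    if np.any(X < 0):
        raise ValueError("negative durations are not compositions")
    dl = np.broadcast_to(np.asarray(detection_limit, dtype=float), (3,)).copy()
    if np.any(dl <= 0):
        raise ValueError("detection limit must be positive")

    zero_mask = X == 0.0
    n_pos = (~zero_mask).sum(axis=1)
    if np.any(n_pos < 2):
        bad = int(np.flatnonzero(n_pos < 2)[0])
        raise ValueError(
            f"row {bad} has fewer than 2 positive parts; cannot impute"
        )
    n_imputed = int(zero_mask.sum())
    if n_imputed == 0:
        return LrEMResult(X, 0, 0, True)

    totals = X.sum(axis=1)
    col_zeros = zero_mask.sum(axis=0)
    candidates = np.flatnonzero(col_zeros == 0)
    if candidates.size == 0:
        raise LrEMError(
            "every behaviour has zeros somewhere; no alr reference available"
        )
    ref = int(candidates[0])  # SB in practice: it is never zero in a worn day
    others = [j for j in range(3) if j != ref]

    # alr coordinates; censored cells get a placeholder, replaced in E-steps
    with np.errstate(divide="ignore"):
        Y = np.log(X[:, others] / X[:, [ref]])
    cens = zero_mask[:, others]  # at most one True per row (>=2 positives)
    thresh = np.log(dl[others] / X[:, [ref]])  # per-row censor bounds

    # multiplicative-replacement initialisation: zeros at 0.65 * DL
    Y0 = Y.copy()
    for k in range(2):
        Y0[cens[:, k], k] = np.log(0.65 * dl[others[k]] / X[cens[:, k], ref])
    mu = Y0.mean(axis=0)
    Sigma = np.cov(Y0, rowvar=False, bias=True)
    Sigma += np.eye(2) * 1e-10

    loglik_path: list[float] = []
    converged = False
    n_iter = 0
    Yc = Y0
    for n_iter in range(1, max_iter + 1):
        Yc = Y.copy()
        Y2sum = np.zeros((2, 2))
        # rows fully observed contribute y y^T directly
        full = ~cens.any(axis=1)
        Yf = Yc[full]
        Y2sum += Yf.T @ Yf
        ll = 0.0
        if full.any():
            ll += stats.multivariate_normal.logpdf(Yf, mu, Sigma).sum()
        for k in range(2):  # coordinate k censored, other observed
            rows = cens[:, k]
            if not rows.any():
                continue
            ko = 1 - k
            yo = Y[rows, ko]
            c = thresh[rows, k]
            s2 = Sigma[k, k] - Sigma[k, ko] ** 2 / Sigma[ko, ko]
            s2 = max(s2, 1e-12)
            m = mu[k] + Sigma[k, ko] / Sigma[ko, ko] * (yo - mu[ko])
            ey, ey2 = _truncated_upper_moments(m, np.sqrt(s2), c)
            Yc[rows, k] = ey
            n_r = rows.sum()
            M = np.zeros((2, 2))
            M[ko, ko] = np.sum(yo * yo)
            M[k, ko] = M[ko, k] = np.sum(ey * yo)
            M[k, k] = np.sum(ey2)
            Y2sum += M
            # observed-data likelihood: marginal of observed coord x Phi
            ll += stats.norm.logpdf(
                yo, mu[ko], np.sqrt(Sigma[ko, ko])
            ).sum()
            ll += stats.norm.logcdf((c - m) / np.sqrt(s2 + 0.0)).sum()
            del n_r
        loglik_path.append(float(ll))

        n = X.shape[0]
        mu_new = Yc.mean(axis=0)
        Sigma_new = Y2sum / n - np.outer(mu_new, mu_new)
        Sigma_new += np.eye(2) * 1e-12
        delta = max(
            np.max(np.abs(mu_new - mu)), np.max(np.abs(Sigma_new - Sigma))
        )
        mu, Sigma = mu_new, Sigma_new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise LrEMError(
            f"lrEM did not converge in {max_iter} iterations",
            n_iter=n_iter,
            loglik_path=loglik_path,
        )

    # impute on the minutes scale and re-close rows to their original totals
    out = X.copy()
    for k in range(2):
        rows = cens[:, k]
        if rows.any():
            out[rows, others[k]] = X[rows, ref] * np.exp(Yc[rows, k])
    out *= (totals / out.sum(axis=1))[:, None]
    return LrEMResult(out, n_imputed, n_iter, True, loglik_path)
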