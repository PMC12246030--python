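"""Competing-risks estimation: Aalen–Johansen CIFs and Fine–Gray regression.

Discontinuation and reinitiation are analysed under a competing risk of
death: a naive Kaplan–Meier of the event of interest would overstate its
cumulative incidence because dead patients can never experience it.  This
module provides

* :func:`aalen_johansen` — the nonparametric cumulative incidence function
  (CIF) estimator for each cause, with pointwise variances and
  complementary-log-log confidence intervals;
* :func:`censoring_km` — the Kaplan–Meier estimator of the censoring
  distribution G, needed for inverse-probability-of-censoring weights;
* :func:`fine_gray_fit` — the Fine–Gray sub-distribution hazard model fitted
  by Newton–Raphson on the IPCW-weighted partial likelihood, in which
  subjects who fail from the competing cause remain in later risk sets with
  weight G(t-)/G(T_i-).

Event coding throughout: 0 = censored, 1 = event of interest, 2 = competing
event (death).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous step function with left-limit evaluation."""

    times: np.ndarray
    values: np.ndarray
    initial: float = 1.0

    def __call__(self, t) -> np.ndarray | float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self._pick(idx)

    def left(self, t) -> np.ndarray | float:
        """Left limit: the value just before ``t``."""
        idx = np.searchsorted(self.times, t, side="left") - 1
        return self._pick(idx)

    def _pick(self, idx):
        vals = np.concatenate(([self.initial], self.values))
        return vals[np.asarray(idx) + 1]


def _validate(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape or time.ndim != 1:
        raise ValueError("time and event must be 1-d arrays of equal length")
    if np.any(time <= 0):
        raise ValueError("all times must be positive")
    if not np.isin(event, (0, 1, 2)).all():
        raise ValueError("event codes must be 0 (censored), 1 (event) or 2 (death)")
    return time, event


@dataclass(frozen=True)
class CIFEstimate:
    """Aalen–Johansen cumulative incidence for one cause.

    ``times`` holds the distinct event times of *any* cause; all step
    functions are right-continuous.  ``survival`` is the all-cause
    Kaplan–Meier, so at every jump ``cif_1 + cif_2 + survival = 1``.
    """

    cause: int
    times: np.ndarray
    cif: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int
    alpha: float = 0.05

    def cif_at(self, t: float) -> tuple[float, float, float]:
        """Step-function evaluation ``(value, ci_low, ci_high)`` at ``t``.

        Right-continuous: evaluation at a jump time returns the post-jump
        value; before the first jump the CIF is 0.
        """
        if t < 0:
            raise ValueError("t must be non-negative")
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        if idx < 0:
            return 0.0, 0.0, 0.0
        return (
            float(self.cif[idx]),
            float(self.ci_low[idx]),
            float(self.ci_high[idx]),
        )


def cif_at(estimate: CIFEstimate, t: float) -> tuple[float, float, float]:
    """Module-level alias for :meth:`CIFEstimate.cif_at`."""
    return estimate.cif_at(t)


def format_cif(estimate: CIFEstimate, t: float) -> str:
    """Percentage with 95% CI to one decimal, e.g. ``'23.6% (95% CI 23.2, 23.9)'``."""
    v, lo, hi = estimate.cif_at(t)
    return f"{100 * v:.1f}% (95% CI {100 * lo:.1f}, {100 * hi:.1f})"


def _cloglog_ci(cif, var, alpha):
    """Pointwise CI on the log(-log F) scale, clipped to [0, 1]."""
    z = stats.norm.ppf(1 - alpha / 2)
    lo = np.zeros_like(cif)
    hi = np.zeros_like(cif)
    interior = (cif > 0) & (cif < 1)
    f = cif[interior]
    se = np.sqrt(np.maximum(var[interior], 0.0))
    rel = se / np.abs(f * np.log(f))
    lo[interior] = f ** np.exp(z * rel)
    hi[interior] = f ** np.exp(-z * rel)
    lo[cif >= 1] = hi[cif >= 1] = 1.0
    return np.clip(lo, 0, 1), np.clip(hi, 0, 1)


def aalen_johansen(time, event, cause: int = 1, alpha: float = 0.05) -> CIFEstimate:
    """Nonparametric cumulative incidence of ``cause`` under competing risks.

    At each distinct event time ``t_j`` with ``n_j`` subjects at risk,
    ``d_j`` all-cause events and ``d_kj`` events of cause ``k``, the CIF
    accumulates ``S(t_{j-1}) * d_kj / n_j`` where ``S`` is the all-cause
    Kaplan–Meier.  Pointwise variance uses the standard counting-process
    (delta-method) estimator; confidence limits are formed on the
    complementary log-log scale.
    """
    time, event = _validate(time, event)
    if cause not in (1, 2):
        raise ValueError("cause must be 1 or 2")
    n = len(time)
    if n == 0:
        raise ValueError("no observations")
    etimes = np.unique(time[event > 0])
    if etimes.size == 0:
        warnings.warn("all observations censored; CIF is identically zero")
        empty = np.array([])
        return CIFEstimate(cause, empty, empty, empty, empty, empty, empty, n, alpha)

    n_at_risk = np.array([(time >= t).sum() for t in etimes], dtype=float)
    d_all = np.array([((time == t) & (event > 0)).sum() for t in etimes], dtype=float)
    d_cause = np.array(
        [((time == t) & (event == cause)).sum() for t in etimes], dtype=float
    )

    surv = np.cumprod(1.0 - d_all / n_at_risk)
    surv_prev = np.concatenate(([1.0], surv[:-1]))
    inc = surv_prev * d_cause / n_at_risk
    cif = np.cumsum(inc)

    # delta-method variance (Aalen / Marubini–Valsecchi form), vectorised via
    # cumulative sums: var(F_j) = F_j^2 A_j - 2 F_j B_j + C_j + D_j - 2(F_j E_j - H_j)
    with np.errstate(divide="ignore", invalid="ignore"):
        km_term = np.where(
            n_at_risk > d_all, d_all / (n_at_risk * (n_at_risk - d_all)), 0.0
        )
    a = np.cumsum(km_term)
    b = np.cumsum(cif * km_term)
    c = np.cumsum(cif**2 * km_term)
    inc_term = surv_prev**2 * (n_at_risk - d_cause) / n_at_risk * d_cause / n_at_risk**2
    d_ = np.cumsum(inc_term)
    e = np.cumsum(surv_prev * d_cause / n_at_risk**2)
    h = np.cumsum(cif * surv_prev * d_cause / n_at_risk**2)
    var = cif**2 * a - 2 * cif * b + c + d_ - 2 * (cif * e - h)
    var = np.maximum(var, 0.0)

    lo, hi = _cloglog_ci(cif, var, alpha)
    return CIFEstimate(cause, etimes, cif, surv, var, lo, hi, n, alpha)


def censoring_km(time, event) -> StepFunction:
    """Kaplan–Meier estimate of the censoring survival function G.

    Censorings (event code 0) are treated as the event; failures of any
    cause are treated as censored.  At tied times, failures are taken to
    precede censorings, so a censored subject does not count itself in the
    denominator reduction of the same instant's failures.
    """
    time, event = _validate(time, event)
    ctimes = np.unique(time[event == 0])
    if ctimes.size == 0:
        return StepFunction(np.array([]), np.array([]), 1.0)
    n_at_risk = np.array([(time >= t).sum() for t in ctimes], dtype=float)
    d_c = np.array([((time == t) & (event == 0)).sum() for t in ctimes], dtype=float)
    g = np.cumprod(1.0 - d_c / n_at_risk)
    return StepFunction(ctimes, g, 1.0)


@dataclass(frozen=True)
class FGFit:
    """Fitted Fine–Gray sub-distribution hazard model."""

    names: tuple[str, ...]
    coef: np.ndarray
    cov: np.ndarray
    loglik_trace: tuple[float, ...]
    converged: bool
    n_iter: int
    n: int
    n_events: int
    alpha: float = 0.05

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def sdhr(self) -> np.ndarray:
        """Sub-distribution hazard ratios, exp(beta)."""
        return np.exp(self.coef)

    def confint(self) -> tuple[np.ndarray, np.ndarray]:
        """CI for the sdHRs, symmetric on the log scale."""
        z = stats.norm.ppf(1 - self.alpha / 2)
        return np.exp(self.coef - z * self.se), np.exp(self.coef + z * self.se)

    def summary(self) -> dict:
        lo, hi = self.confint()
        return {
            "n": self.n,
            "events": self.n_events,
            "iterations": self.n_iter,
            "converged": self.converged,
            "coef": {k: float(v) for k, v in zip(self.names, self.coef)},
            "se": {k: float(v) for k, v in zip(self.names, self.se)},
            "sdHR": {k: float(v) for k, v in zip(self.names, self.sdhr)},
            "ci": {k: [float(a), float(b)] for k, a, b in zip(self.names, lo, hi)},
        }


def _check_full_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pinpoint offending columns through the QR decomposition
        r = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = [names[i] for i in np.where(r < 1e-10 * max(r.max(), 1.0))[0]]
        raise ValueError(f"design matrix is singular; collinear columns: {bad}")


def fine_gray_fit(
    time,
    event,
    X,
    names: tuple[str, ...] | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
    alpha: float = 0.05,
) -> FGFit:
    """Fine–Gray sub-distribution hazard regression via IPCW weights.

    Subjects who experience the competing event remain in the risk set of
    every later event time ``t`` with weight ``G(t-) / G(T_i-)``, where G is
    the Kaplan–Meier estimate of the censoring distribution.  The weighted
    partial likelihood (Breslow tie handling) is maximised by Newton–Raphson
    with step-halving; the covariance is the inverse of the observed
    information, treating the estimated weights as fixed.
    """
    time, event = _validate(time, event)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n != len(time):
        raise ValueError("X and time must have matching length")
    if n <= p:
        raise ValueError("need more observations than covariates")
    if names is None:
        names = tuple(f"x{i}" for i in range(p))
    _check_full_rank(X, names)
    if not (event == 1).any():
        raise ValueError("no events of interest; nothing to fit")

    G = censoring_km(time, event)
    etimes = np.unique(time[event == 1])
    m = len(etimes)
    # weight matrix W[j, i]: contribution of subject i to the risk set at etimes[j]
    W = np.zeros((m, n))
    at_risk = time[None, :] >= etimes[:, None]
    W[at_risk] = 1.0
    prior_competing = (event == 2)[None, :] & (time[None, :] < etimes[:, None])
    if prior_competing.any():
        g_t = np.asarray(G.left(etimes), dtype=float)  # G(t_j-)
        g_Ti = np.asarray(G.left(time), dtype=float)  # G(T_i-)
        jj, ii = np.where(prior_competing)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(g_Ti[ii] > 0, g_t[jj] / g_Ti[ii], 0.0)
        W[jj, ii] = w

    d = np.array([((time == t) & (event == 1)).sum() for t in etimes], dtype=float)
    s = np.vstack([X[(time == t) & (event == 1)].sum(axis=0) for t in etimes])

    def loglik_score_info(beta):
        r = np.exp(X @ beta)
        wr = W * r[None, :]
        A = wr.sum(axis=1)  # (m,)
        B = wr @ X  # (m, p)
        C = np.einsum("ji,ik,il->jkl", wr, X, X)  # (m, p, p)
        ll = float((s * beta).sum() - (d * np.log(A)).sum())
        mean = B / A[:, None]
        score = (s - d[:, None] * mean).sum(axis=0)
        info = (
            d[:, None, None] * (C / A[:, None, None] - mean[:, :, None] * mean[:, None, :])
        ).sum(axis=0)
        return ll, score, info

    beta = np.zeros(p)
    ll, score, info = loglik_score_info(beta)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular information matrix: {exc}") from exc
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, score_new, info_new = loglik_score_info(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll_old, ll, score, info = cand, ll, ll_new, score_new, info_new
        trace.append(ll)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1e-10):
            converged = True
            break
    if not converged:
        log.warning("Fine-Gray fit did not converge in %d iterations", max_iter)
    cov = np.linalg.inv(info)
    cov = (cov + cov.T) / 2.0
    return FGFit(
        names=tuple(names),
        coef=beta,
        cov=cov,
        loglik_trace=tuple(trace),
        converged=converged,
        n_iter=it,
        n=n,
        n_events=int((event == 1).sum()),
        alpha=alpha,
    )
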