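"""Cox proportional-hazards machinery for conception-time analysis.

Everything downstream of the image models reduces to a scalar per-patient
log-hazard (the linear predictor ``beta^T x`` in the classical model, or a
network output in the deep model).  This module holds the shared survival
mathematics: the Breslow-tie negative log partial likelihood and its
regularized per-event form used as the deep model's training loss, a
Newton--Raphson maximizer for the linear model (the analytic oracle and the
hazard-ratio engine), the Breslow cumulative baseline-hazard estimator that
converts log-hazards into time-resolved conception probabilities, and the
Kaplan--Meier product-limit estimator.

Conventions: time is measured in months from adhesiolysis; ``event == 1``
means ongoing pregnancy (fetal heartbeat beyond 12 weeks of gestation);
higher log-hazard means earlier expected conception.  Tied event times are
handled with the Breslow approximation throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

__all__ = [
    "SurvivalRecord",
    "CohortTable",
    "RiskScore",
    "LinearCoxModel",
    "BaselineHazardCurve",
    "StepFunction",
    "NoEventsError",
    "InvalidScoreError",
    "ConvergenceError",
    "negative_log_partial_likelihood",
    "deepsurv_loss",
    "fit_linear_cox",
    "breslow_cumulative_hazard",
    "predicted_event_probability",
    "kaplan_meier",
]


class NoEventsError(ValueError):
    """Raised when a computation requires at least one observed event ("no-events")."""


class InvalidScoreError(ValueError):
    """Raised on NaN or infinite log-hazard scores ("invalid-score")."""


class ConvergenceError(RuntimeError):
    """Newton--Raphson failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: Optional[List[float]] = None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SurvivalRecord:
    """One patient's follow-up: time in months, event flag, ART flag, covariates."""

    patient_id: str
    time: float
    event: int
    art: int = 0
    covariates: np.ndarray = field(default_factory=lambda: np.zeros(0))
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValueError(f"time must be a positive real, got {self.time!r}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event!r}")
        if self.art not in (0, 1):
            raise ValueError(f"art must be 0 or 1, got {self.art!r}")
        self.covariates = np.asarray(self.covariates, dtype=float)


@dataclass
class CohortTable:
    """Ordered patient records plus the patient-id -> image-paths index.

    Risk sets and event counts are always derived on the fly from ``records``;
    they are never stored.
    """

    records: List[SurvivalRecord]
    image_index: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate patient_id in cohort")
        lens = {r.covariates.size for r in self.records}
        if len(lens) > 1:
            raise ValueError("covariate length differs across cohort")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def patient_ids(self) -> List[str]:
        return [r.patient_id for r in self.records]

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records], dtype=float)

    @property
    def events(self) -> np.ndarray:
        return np.array([r.event for r in self.records], dtype=int)

    @property
    def art(self) -> np.ndarray:
        return np.array([r.art for r in self.records], dtype=int)

    @property
    def covariate_matrix(self) -> np.ndarray:
        return np.vstack([r.covariates for r in self.records])

    def subset(self, patient_ids: Sequence[str]) -> "CohortTable":
        keep = set(patient_ids)
        recs = [r for r in self.records if r.patient_id in keep]
        idx = {k: v for k, v in self.image_index.items() if k in keep}
        return CohortTable(records=recs, image_index=idx)


@dataclass
class RiskScore:
    """Scalar log-hazard for one patient; shifts by a constant are irrelevant."""

    patient_id: str
    log_hazard: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_hazard):
            raise InvalidScoreError(
                f"invalid-score: non-finite log_hazard for {self.patient_id}"
            )


@dataclass
class LinearCoxModel:
    beta: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: float
    n_iterations: int = 0

    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def confidence_intervals(self, z: float = 1.959963984540054) -> np.ndarray:
        """Wald CIs for the hazard ratios, shape (p, 2)."""
        lo = np.exp(self.beta - z * self.standard_errors)
        hi = np.exp(self.beta + z * self.standard_errors)
        return np.column_stack([lo, hi])

    def p_values(self) -> np.ndarray:
        from scipy import stats

        z = self.beta / self.standard_errors
        return 2.0 * stats.norm.sf(np.abs(z))


class StepFunction:
    """Right-continuous step function, constant at ``initial`` before the first knot."""

    def __init__(self, times: np.ndarray, values: np.ndarray, initial: float):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.initial = float(initial)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            out = np.full(t.shape, self.initial)
            return float(self.initial) if t.ndim == 0 else out
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], self.initial)
        return float(out) if out.ndim == 0 else out


@dataclass
class BaselineHazardCurve:
    """Breslow cumulative baseline hazard H0(t): a non-decreasing step function.

    Evaluation is right-continuous and returns 0 before the first event time.
    """

    times: np.ndarray
    cumulative_hazard: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative_hazard = np.asarray(self.cumulative_hazard, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.cumulative_hazard < 0) or np.any(
            np.diff(self.cumulative_hazard) < 0
        ):
            raise ValueError("cumulative_hazard must be non-negative, non-decreasing")

    def __call__(self, t):
        return StepFunction(self.times, self.cumulative_hazard, 0.0)(t)


# ---------------------------------------------------------------------------
# Validation helpers
# ---------------------------------------------------------------------------


def _validate_triplet(scores, times, events):
    scores = np.asarray(scores, dtype=float).ravel()
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events, dtype=int).ravel()
    if not (scores.size == times.size == events.size):
        raise ValueError("scores, times, events must have equal length")
    if scores.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(scores)):
        raise InvalidScoreError("invalid-score: NaN or infinite log-hazard")
    if np.any(times <= 0) or not np.all(np.isfinite(times)):
        raise ValueError("times must be positive finite reals")
    if not np.all((events == 0) | (events == 1)):
        raise ValueError("events must be binary")
    if events.sum() == 0:
        raise NoEventsError("no-events: at least one observed event is required")
    return scores, times, events


# ---------------------------------------------------------------------------
# Partial likelihood and training loss
# ---------------------------------------------------------------------------


def negative_log_partial_likelihood(scores, times, events) -> float:
    """Breslow-tie negative log Cox partial likelihood.

    -log L = - sum_{i: E_i=1} [ s_i - log sum_{j: T_j >= T_i} exp(s_j) ].
    Invariant under adding a constant to all scores.
    """
    scores, times, events = _validate_triplet(scores, times, events)
    # Stabilize exp(); the result is shift-invariant anyway.
    s = scores - scores.max()
    order = np.argsort(-times, kind="stable")
    s_sorted = s[order]
    t_sorted = times[order]
    e_sorted = events[order]
    # cumulative log-sum-exp over the descending-time prefix = log of the
    # risk-set mass for each time
    cum_lse = np.logaddexp.accumulate(s_sorted)
    # Breslow: tied event times share the full tied risk set -> use the last
    # index of each tie group.
    n = t_sorted.size
    last_of_group = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_sorted[j + 1] == t_sorted[i]:
            j += 1
        last_of_group[i : j + 1] = j
        i = j + 1
    ev = e_sorted == 1
    log_denoms = cum_lse[last_of_group[ev]]
    return float(np.sum(log_denoms - s_sorted[ev]))


def deepsurv_loss(
    scores, times, events, weight_sq_norm: float = 0.0, lam: float = 0.0
) -> float:
    """Per-event negative log partial likelihood plus L2 weight penalty.

    loss = (1 / N_events) * (-log L) + lam * ||theta||^2
    """
    if lam < 0 or weight_sq_norm < 0:
        raise ValueError("lam and weight_sq_norm must be non-negative")
    scores, times, events = _validate_triplet(scores, times, events)
    n_events = int(events.sum())
    nll = negative_log_partial_likelihood(scores, times, events)
    return nll / n_events + lam * weight_sq_norm


def cox_loss_and_score_gradient(scores, times, events):
    """Per-event Cox loss and its gradient with respect to the scores.

    Used by minibatch training; returns ``(loss, dloss/dscores)`` where the
    loss is the Breslow negative log partial likelihood divided by the number
    of events in the batch.
    """
    scores, times, events = _validate_triplet(scores, times, events)
    n = scores.size
    n_events = int(events.sum())
    smax = scores.max()
    w = np.exp(scores - smax)
    order = np.argsort(-times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    w_sorted = w[order]
    cum_w = np.cumsum(w_sorted)
    # tie groups on the descending-time axis
    last_of_group = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_sorted[j + 1] == t_sorted[i]:
            j += 1
        last_of_group[i : j + 1] = j
        i = j + 1
    denom = cum_w[last_of_group]  # risk-set mass for each sorted subject's time
    ev = e_sorted == 1
    s_sorted = scores[order]
    loss = float(np.sum(np.log(denom[ev]) + smax - s_sorted[ev])) / n_events
    # gradient: d(-logL)/ds_k = -E_k + sum over events i with k in R(T_i) of
    # w_k / denom_i ; subject k (sorted position q) is in R(T_i) iff the
    # event's group-end index >= q, i.e. events at sorted positions <= q
    # (descending time) with group extending to q.  Because denom uses
    # last_of_group, subject q belongs to risk sets of all events at
    # positions p with last_of_group[p] >= q; with descending sort that is
    # all p <= last position where group end >= q -> prefix structure.
    inv_denom_ev = np.where(ev, 1.0 / denom, 0.0)
    # cumulative sum of event 1/denom terms whose risk set includes position q:
    # event at position p includes q iff q <= last_of_group[p].  Build an
    # array adding 1/denom at position 0..last_of_group[p] -> difference trick.
    add = np.zeros(n + 1)
    np.add.at(add, 0, 0.0)
    for p in np.nonzero(ev)[0]:
        add[0] += inv_denom_ev[p]
        add[last_of_group[p] + 1] -= inv_denom_ev[p]
    coef = np.cumsum(add[:n])
    grad_sorted = w_sorted * coef - e_sorted
    grad = np.empty(n)
    grad[order] = grad_sorted
    return loss, grad / n_events


# ---------------------------------------------------------------------------
# Linear Cox fitting (Newton-Raphson)
# ---------------------------------------------------------------------------


def _breslow_loglik_grad_info(beta, X, times, events, entry=None):
    """Log partial likelihood, gradient and observed information at beta.

    ``entry`` enables left truncation: subject j is at risk at t iff
    entry_j < t <= time_j (counting-process risk sets).
    """
    eta = X @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    p = X.shape[1]
    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    event_times = np.unique(times[events == 1])
    for t in event_times:
        if entry is None:
            at_risk = times >= t
        else:
            at_risk = (times >= t) & (entry < t)
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        Xr = X[at_risk]
        wr = w[at_risk]
        s0 = wr.sum()
        s1 = Xr.T @ wr
        s2 = (Xr * wr[:, None]).T @ Xr
        xbar = s1 / s0
        loglik += float((X[dead] @ beta).sum()) - d * np.log(s0)
        grad += X[dead].sum(axis=0) - d * xbar
        info += d * (s2 / s0 - np.outer(xbar, xbar))
    # the eta shift inflated every log-denominator by -shift; restore it
    shift = (X @ beta).max()
    loglik -= int(events.sum()) * shift
    return loglik, grad, info


def fit_linear_cox(
    covariate_matrix,
    times,
    events,
    entry=None,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> LinearCoxModel:
    """Maximize the Breslow log partial likelihood by Newton--Raphson.

    Convergence when the log-likelihood change falls below ``tol``; the step
    is halved whenever it would decrease the likelihood.  Standard errors come
    from the inverse observed information.  Monotone likelihoods (complete
    separation) are detected by runaway coefficients and reported as
    "divergent-beta".
    """
    X = np.atleast_2d(np.asarray(covariate_matrix, dtype=float))
    if X.shape[0] == 1 and np.asarray(times).size > 1:
        X = X.T
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events, dtype=int).ravel()
    if entry is not None:
        entry = np.asarray(entry, dtype=float).ravel()
    if events.sum() == 0:
        raise NoEventsError("no-events: cannot fit Cox model without events")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant covariate column")

    p = X.shape[1]
    beta = np.zeros(p)
    loglik, grad, info = _breslow_loglik_grad_info(beta, X, times, events, entry)
    trace = [loglik]
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving on likelihood decrease
        factor = 1.0
        for _ in range(30):
            new_beta = beta + factor * step
            new_loglik, new_grad, new_info = _breslow_loglik_grad_info(
                new_beta, X, times, events, entry
            )
            if new_loglik >= loglik - 1e-14:
                break
            factor *= 0.5
        else:
            raise ConvergenceError(
                f"step-halving failed at iteration {it}", trace=trace
            )
        delta = new_loglik - loglik
        beta, loglik, grad, info = new_beta, new_loglik, new_grad, new_info
        trace.append(loglik)
        if np.any(np.abs(beta) > 50):
            raise ConvergenceError(
                "divergent-beta: monotone likelihood (complete separation?)",
                trace=trace,
            )
        if abs(delta) < tol:
            break
    else:
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations; trace={trace}", trace=trace
        )
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return LinearCoxModel(
        beta=beta, standard_errors=se, log_likelihood=loglik, n_iterations=it
    )


# ---------------------------------------------------------------------------
# Baseline hazard, survival conversion, Kaplan-Meier
# ---------------------------------------------------------------------------


def breslow_cumulative_hazard(scores, times, events) -> BaselineHazardCurve:
    """Breslow estimator: dH0(t) = d_t / sum_{j in R(t)} exp(score_j)."""
    scores, times, events = _validate_triplet(scores, times, events)
    w = np.exp(scores)
    event_times = np.unique(times[events == 1])
    increments = np.empty(event_times.size)
    for k, t in enumerate(event_times):
        d = int(((times == t) & (events == 1)).sum())
        increments[k] = d / w[times >= t].sum()
    return BaselineHazardCurve(
        times=event_times, cumulative_hazard=np.cumsum(increments)
    )


def predicted_event_probability(
    log_hazard: float, curve: BaselineHazardCurve, horizon: float
):
    """P(conception by ``horizon``) = 1 - exp(-H0(horizon) * exp(log_hazard)).

    Accepts a scalar or vector of log-hazards; monotone in both arguments and
    bounded in [0, 1].
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    H = curve(horizon)
    lh = np.asarray(log_hazard, dtype=float)
    out = 1.0 - np.exp(-H * np.exp(lh))
    return float(out) if out.ndim == 0 else out


def kaplan_meier(times, events) -> StepFunction:
    """Product-limit survival estimator; right-continuous, starts at 1."""
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events, dtype=int).ravel()
    if times.size == 0:
        raise ValueError("empty input")
    uniq = np.unique(times[events == 1])
    surv = np.empty(uniq.size)
    s = 1.0
    for k, t in enumerate(uniq):
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_at_risk
        surv[k] = s
    return StepFunction(uniq, surv, 1.0)


def censoring_kaplan_meier(times, events) -> StepFunction:
    """KM estimate of the censoring survival G(t) (censorings as 'events').

    Used for inverse-probability-of-censoring weights; ties between an event
    and a censoring at the same time are resolved with the standard
    convention that events precede censorings.
    """
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events, dtype=int).ravel()
    cens = 1 - events
    uniq = np.unique(times[cens == 1])
    surv = np.empty(uniq.size)
    g = 1.0
    for k, t in enumerate(uniq):
        # events at t leave the risk set before the censorings at t
        n_at_risk = int((times >= t).sum()) - int(((times == t) & (events == 1)).sum())
        c = int(((times == t) & (cens == 1)).sum())
        if n_at_risk > 0:
            g *= 1.0 - c / n_at_risk
        else:
            g = 0.0
        surv[k] = g
    return StepFunction(uniq, surv, 1.0)
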