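"""Time-to-event performance metrics and between-model comparisons.

Discrimination is measured two ways: Harrell's concordance index over usable
patient pairs, and the Uno-style cumulative-case / dynamic-control AUC at a
horizon with inverse-probability-of-censoring weights (IPCW) derived from the
Kaplan--Meier estimate of the censoring distribution.  Calibration compares
quantile-binned predicted conception probabilities with the Kaplan--Meier
observed event frequency in each bin.  All confidence intervals and model
comparisons use seeded patient-level bootstrap resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence
import warnings

import numpy as np
from scipy import stats

from .survival_core import (
    NoEventsError,
    censoring_kaplan_meier,
    kaplan_meier,
)

__all__ = [
    "ConcordanceResult",
    "TimeAUCPoint",
    "CalibrationBin",
    "EvaluationReport",
    "harrell_cindex",
    "ipcw_time_auc",
    "time_auc_curve",
    "calibration_table",
    "compare_cindex",
    "compare_time_auc",
]


@dataclass
class ConcordanceResult:
    c_index: float
    ci_low: float
    ci_high: float
    n_concordant: int
    n_discordant: int
    n_tied_score: int


@dataclass
class TimeAUCPoint:
    horizon: float
    auc: float
    ci_low: float
    ci_high: float


@dataclass
class CalibrationBin:
    bin_index: int
    mean_predicted: float
    observed: Optional[float]
    n: int
    observed_ci_low: Optional[float] = None
    observed_ci_high: Optional[float] = None


@dataclass
class EvaluationReport:
    """Bundle of metrics for one model, serializable to JSON via cli_io."""

    model_id: str
    c_index: Optional[ConcordanceResult] = None
    auc: List[TimeAUCPoint] = field(default_factory=list)
    calibration: dict = field(default_factory=dict)  # horizon -> [CalibrationBin]
    comparisons: List[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------


def _concordance_counts(scores, times, events):
    """Vectorized pair counting.

    A pair is usable when the earlier time belongs to an event, including the
    tie case (event at t vs censoring at the same t).  Pairs of two events at
    the same time are not usable.  Higher score must go with the earlier
    event (higher conception hazard = earlier conception).
    """
    s = np.asarray(scores, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    ev = e == 1
    # i ranges over events; usable j: t_j > t_i, or t_j == t_i and e_j == 0
    ti = t[ev][:, None]
    si = s[ev][:, None]
    later = (t[None, :] > ti) | ((t[None, :] == ti) & (e[None, :] == 0))
    conc = int(np.sum(later & (si > s[None, :])))
    disc = int(np.sum(later & (si < s[None, :])))
    tied = int(np.sum(later & (si == s[None, :])))
    return conc, disc, tied


def harrell_cindex(
    scores,
    times,
    events,
    n_bootstrap: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ConcordanceResult:
    """Harrell's c-index with a patient-level bootstrap percentile CI."""
    s = np.asarray(scores, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    conc, disc, tied = _concordance_counts(s, t, e)
    total = conc + disc + tied
    if total == 0:
        raise ValueError("no usable pairs for concordance")
    c = (conc + 0.5 * tied) / total

    lo = hi = c
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = s.size
        boot = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            bc, bd, bt = _concordance_counts(s[idx], t[idx], e[idx])
            tot = bc + bd + bt
            if tot > 0:
                boot.append((bc + 0.5 * bt) / tot)
        lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return ConcordanceResult(
        c_index=float(c),
        ci_low=float(min(lo, c)),
        ci_high=float(max(hi, c)),
        n_concordant=conc,
        n_discordant=disc,
        n_tied_score=tied,
    )


# ---------------------------------------------------------------------------
# IPCW time-dependent AUC
# ---------------------------------------------------------------------------


def _ipcw_auc_point(scores, times, events, horizon) -> float:
    s = np.asarray(scores, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    cases = (t <= horizon) & (e == 1)
    controls = t > horizon
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError("degenerate-horizon: need at least one case and one control")
    G = censoring_kaplan_meier(t, e)
    # weight for a case with event at T_i: 1 / G(T_i-); controls: 1 / G(t)
    eps = 1e-12
    g_case = np.maximum(G(t[cases] - 1e-9), eps)
    g_ctrl = max(G(horizon), eps)
    w_case = 1.0 / g_case
    w_ctrl = np.full(int(controls.sum()), 1.0 / g_ctrl)
    sc = s[cases]
    sk = s[controls]
    # weighted Mann-Whitney with 0.5 credit for score ties
    gt = (sc[:, None] > sk[None, :]).astype(float)
    gt += 0.5 * (sc[:, None] == sk[None, :])
    wmat = w_case[:, None] * w_ctrl[None, :]
    return float(np.sum(gt * wmat) / np.sum(wmat))


def ipcw_time_auc(
    scores,
    times,
    events,
    horizon: float,
    n_bootstrap: int = 0,
    seed: int = 0,
    alpha: float = 0.05,
) -> TimeAUCPoint:
    """Cumulative/dynamic AUC at ``horizon`` with KM censoring weights.

    With no censoring before the horizon every weight is equal and the
    estimator reduces exactly to the Mann--Whitney AUC of the binary label
    ``time <= horizon``.
    """
    auc = _ipcw_auc_point(scores, times, events, horizon)
    lo = hi = auc
    if n_bootstrap > 0:
        s = np.asarray(scores, float)
        t = np.asarray(times, float)
        e = np.asarray(events, int)
        rng = np.random.default_rng(seed)
        boot = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, s.size, s.size)
            try:
                boot.append(_ipcw_auc_point(s[idx], t[idx], e[idx], horizon))
            except ValueError:
                continue
        if boot:
            lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return TimeAUCPoint(
        horizon=float(horizon),
        auc=auc,
        ci_low=float(min(lo, auc)),
        ci_high=float(max(hi, auc)),
    )


def time_auc_curve(
    scores,
    times,
    events,
    horizons: Sequence[float],
    n_bootstrap: int = 200,
    seed: int = 0,
) -> List[TimeAUCPoint]:
    """Per-horizon IPCW AUC; degenerate horizons are skipped with a warning."""
    out = []
    for h in horizons:
        try:
            out.append(
                ipcw_time_auc(scores, times, events, h, n_bootstrap=n_bootstrap, seed=seed)
            )
        except (ValueError, NoEventsError) as exc:
            warnings.warn(f"horizon {h}: {exc}; point skipped")
    return out


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def calibration_table(
    predicted_probs,
    times,
    events,
    horizon: float,
    n_bins: int = 5,
) -> List[CalibrationBin]:
    """Quantile-bin predictions; observed = 1 - KM survival at horizon per bin."""
    p = np.asarray(predicted_probs, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:  # all predictions identical -> single bin
        assignment = np.zeros(p.size, dtype=int)
        n_eff = 1
    else:
        assignment = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, edges.size - 2)
        n_eff = edges.size - 1
    bins: List[CalibrationBin] = []
    for b in range(n_eff):
        mask = assignment == b
        n = int(mask.sum())
        if n == 0:
            continue
        mean_pred = float(p[mask].mean())
        tb, eb = t[mask], e[mask]
        has_info = (eb == 1).any() or (tb >= horizon).any()
        if not has_info:
            bins.append(CalibrationBin(b, mean_pred, None, n))
            continue
        km = kaplan_meier(tb, eb) if (eb == 1).any() else None
        surv = km(horizon) if km is not None else 1.0
        obs = 1.0 - float(surv)
        # Greenwood-free binomial-style CI on the observed frequency
        se = np.sqrt(max(obs * (1 - obs), 1e-12) / n)
        bins.append(
            CalibrationBin(
                b,
                mean_pred,
                obs,
                n,
                observed_ci_low=float(max(0.0, obs - 1.96 * se)),
                observed_ci_high=float(min(1.0, obs + 1.96 * se)),
            )
        )
    return bins


# ---------------------------------------------------------------------------
# Paired bootstrap comparisons
# ---------------------------------------------------------------------------


def _paired_bootstrap_p(stat_fn, n, B, seed) -> float:
    """Two-sided normal-approximation p for a paired bootstrap difference."""
    d0 = stat_fn(np.arange(n))
    rng = np.random.default_rng(seed)
    diffs = []
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            diffs.append(stat_fn(idx))
        except ValueError:
            continue
    diffs = np.asarray(diffs)
    sd = diffs.std(ddof=1) if diffs.size > 1 else 0.0
    if sd == 0:
        return 1.0 if d0 == 0 else 0.0
    z = d0 / sd
    return float(2.0 * stats.norm.sf(abs(z)))


def compare_cindex(scores_a, scores_b, times, events, B: int = 1000, seed: int = 0) -> float:
    """Paired patient-level bootstrap test of the c-index difference."""
    sa = np.asarray(scores_a, float)
    sb = np.asarray(scores_b, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if not (sa.size == sb.size == t.size):
        raise ValueError("paired comparison requires the same patients")

    def stat(idx):
        ca = _concordance_counts(sa[idx], t[idx], e[idx])
        cb = _concordance_counts(sb[idx], t[idx], e[idx])
        ta_, tb_ = sum(ca), sum(cb)
        if ta_ == 0 or tb_ == 0:
            raise ValueError("no usable pairs in resample")
        return (ca[0] + 0.5 * ca[2]) / ta_ - (cb[0] + 0.5 * cb[2]) / tb_

    return _paired_bootstrap_p(stat, sa.size, B, seed)


def compare_time_auc(
    scores_a, scores_b, times, events, horizon: float, B: int = 1000, seed: int = 0
) -> float:
    """Paired patient-level bootstrap test of the IPCW AUC difference."""
    sa = np.asarray(scores_a, float)
    sb = np.asarray(scores_b, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if not (sa.size == sb.size == t.size):
        raise ValueError("paired comparison requires the same patients")

    def stat(idx):
        return _ipcw_auc_point(sa[idx], t[idx], e[idx], horizon) - _ipcw_auc_point(
            sb[idx], t[idx], e[idx], horizon
        )

    return _paired_bootstrap_p(stat, sa.size, B, seed)
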