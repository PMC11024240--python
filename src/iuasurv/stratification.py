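"""Risk-group stratification and ART-benefit hazard ratios.

Patients are split on their predicted 1-year natural-conception probability
(threshold 0.5 by default; the boundary value goes to the low-probability
group) and, within each stratum, the benefit of assisted reproduction (ART)
is quantified as the Cox hazard ratio of conception for ART users versus
non-users.  The same machinery runs the clinical comparator stratifications:
AFS score (>= 5 vs < 5), CSGE score (>= 18 vs < 18) and endometrial
thickness (>= 7 mm vs < 7 mm).

By default ART enters as a baseline binary covariate with time measured
from surgery.  Because ART typically starts months after surgery, a
time-dependent option delays the ART arm's risk-set entry to the ART start
month (left truncation), avoiding immortal-time bias; neither convention is
privileged, both are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence

import numpy as np

from .survival_core import (
    CohortTable,
    ConvergenceError,
    fit_linear_cox,
)

__all__ = [
    "StratumReport",
    "assign_risk_groups",
    "art_benefit_hr",
    "stratification_table",
    "CLINICAL_CUTOFFS",
]

# canonical order of the optional clinical covariates in the cohort CSV
COVARIATE_NAMES = ("age", "afs", "csge", "emt_mm")

# comparator stratifiers: covariate name -> (cutoff, high-label, low-label)
CLINICAL_CUTOFFS = {
    "afs": (5.0, "AFS >=5", "AFS <5"),
    "csge": (18.0, "CSGE >=18", "CSGE <18"),
    "emt_mm": (7.0, "EMT >=7 mm", "EMT <7 mm"),
}


@dataclass
class StratumReport:
    stratifier: str
    stratum_label: str
    hr: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p: Optional[float]
    n: int
    n_events: int
    note: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def assign_risk_groups(
    probabilities_1yr: Sequence[float], threshold: float = 0.5
) -> np.ndarray:
    """Label each patient 'low' or 'high' natural-conception probability.

    The boundary value (probability exactly at the threshold) is assigned to
    the low-probability group.
    """
    p = np.asarray(probabilities_1yr, dtype=float)
    if p.size == 0:
        raise ValueError("empty probability vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return np.where(p > threshold, "high", "low")


def art_benefit_hr(
    times,
    events,
    art,
    stratifier: str = "model",
    stratum_label: str = "",
    time_dependent: bool = False,
    art_start_month: float = 12.0,
) -> StratumReport:
    """Cox hazard ratio of conception for ART users vs non-users in a stratum.

    HR = exp(beta) with Wald 95% CI and two-sided p.  With
    ``time_dependent=True`` the ART arm enters the risk set only at
    ``art_start_month`` (left truncation), the immortal-time-safe reading.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    a = np.asarray(art, dtype=int)
    n = t.size
    n_events = int(e.sum())
    if a.sum() == 0 or a.sum() == n:
        raise ValueError("no-contrast: stratum lacks an ART or a non-ART arm")
    if n_events == 0:
        raise ValueError("no-events: stratum has no observed conceptions")
    entry = None
    if time_dependent:
        entry = np.where(a == 1, float(art_start_month), 0.0)
        # the event/censoring must postdate entry for left truncation
        keep = t > entry
        t, e, a, entry = t[keep], e[keep], a[keep], entry[keep]
    try:
        fit = fit_linear_cox(a.reshape(-1, 1).astype(float), t, e, entry=entry)
    except ConvergenceError as exc:
        return StratumReport(
            stratifier, stratum_label, None, None, None, None, n, n_events,
            note=f"separation-flagged: {exc}",
        )
    hr = float(np.exp(fit.beta[0]))
    ci = fit.confidence_intervals()[0]
    p = float(fit.p_values()[0])
    return StratumReport(
        stratifier, stratum_label, hr, float(ci[0]), float(ci[1]), p, n, n_events
    )


def stratification_table(
    cohort: CohortTable,
    probabilities_1yr: Sequence[float],
    threshold: float = 0.5,
    stratifiers: Sequence[str] = ("model", "afs", "csge", "emt_mm"),
    time_dependent: bool = False,
    art_start_month: float = 12.0,
) -> List[StratumReport]:
    """ART-benefit hazard ratios per stratum for each requested stratifier.

    ``probabilities_1yr`` are the model's predicted 1-year conception
    probabilities in cohort record order.  Strata without both arms
    propagate as rows with a 'no-contrast' note rather than aborting the
    whole table.
    """
    t = cohort.times
    e = cohort.events
    a = cohort.art
    p = np.asarray(probabilities_1yr, dtype=float)
    if p.size != len(cohort):
        raise ValueError("probabilities must match cohort size")

    covs: Dict[str, np.ndarray] = {}
    if cohort.records and cohort.records[0].covariates.size == len(COVARIATE_NAMES):
        X = cohort.covariate_matrix
        covs = {name: X[:, j] for j, name in enumerate(COVARIATE_NAMES)}

    out: List[StratumReport] = []
    for strat in stratifiers:
        if strat == "model":
            groups = assign_risk_groups(p, threshold)
            masks = [
                (groups == "low", f"Conception probability <{threshold:g}"),
                (groups == "high", f"Conception probability >{threshold:g}"),
            ]
            name = "PH AI application"
        else:
            if strat not in CLINICAL_CUTOFFS:
                raise ValueError(f"unknown stratifier {strat!r}")
            if strat not in covs:
                raise ValueError(
                    f"cohort lacks the clinical covariate {strat!r} "
                    f"(expected covariate order {COVARIATE_NAMES})"
                )
            cut, hi_label, lo_label = CLINICAL_CUTOFFS[strat]
            v = covs[strat]
            masks = [(v >= cut, hi_label), (v < cut, lo_label)]
            name = strat
        for mask, label in masks:
            n = int(mask.sum())
            n_events = int(e[mask].sum())
            try:
                out.append(
                    art_benefit_hr(
                        t[mask], e[mask], a[mask],
                        stratifier=name, stratum_label=label,
                        time_dependent=time_dependent,
                        art_start_month=art_start_month,
                    )
                )
            except ValueError as exc:
                out.append(
                    StratumReport(
                        name, label, None, None, None, None, n, n_events,
                        note=str(exc),
                    )
                )
    return out
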