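"""Synthetic hysteroscopy-like cohorts with a known conception-hazard law.

The generator renders schematic second-look hysteroscopy views -- a pale
uterine-cavity silhouette on a dark background, occluded by adhesion-like
dark bands whose number and thickness grow with a latent severity in [0, 1],
plus two cornua views with a proportionally occluded ostium disc -- and
draws conception times from an exponential proportional-hazards model:

    h_i = baseline_rate * exp(beta_severity * (severity_i - 0.5))

with administrative censoring, optional exponential loss to follow-up, and
an optional ART treatment that multiplies the hazard from ``art_start_month``
onward by a stratum-specific hazard ratio.  Severity is centered at 0.5 so
``baseline_rate`` is the median patient's hazard.  Everything is
deterministic given the seed, so every other module can be tested against
ground truth with no data download.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from PIL import Image

from .survival_core import CohortTable, SurvivalRecord

__all__ = [
    "GeneratorConfig",
    "render_image",
    "generate_cohort",
    "make_splits",
    "image_seed",
]


def image_seed(config: "GeneratorConfig", patient_index: int) -> int:
    """Seed used to render patient ``patient_index``'s views; public so
    ground-truth masks can be re-rendered reproducibly."""
    return config.seed * 100003 + patient_index

VIEWS = ("cavity", "left_cornu", "right_cornu")


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults emulate the clinical setting: ~4 years of follow-up in months,
    a median natural-conception hazard giving roughly two-thirds of patients
    an event, worse adhesions lowering the conception hazard
    (``beta_severity`` = -1.2 on the centered severity), ART becoming
    available one year after surgery, and an ART benefit concentrated in the
    poor-prognosis stratum.
    """

    n_patients: int = 200
    images_per_patient: int = 3  # cavity + two cornua views
    image_size: int = 64
    beta_severity: float = -1.2
    baseline_rate: float = 0.05  # events per month for the median patient
    weibull_shape: float = 1.0  # 1 = exponential
    admin_censor_months: float = 48.0
    loss_to_followup_rate: float = 0.005
    art_enabled: bool = False
    art_start_month: float = 12.0
    art_probability: float = 0.5
    art_hr_low_stratum: float = 3.0  # benefit where natural prognosis is poor
    art_hr_high_stratum: float = 1.0
    noise_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_rate", "admin_censor_months", "art_hr_low_stratum",
                     "art_hr_high_stratum", "weibull_shape"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.loss_to_followup_rate < 0:
            raise ValueError("loss_to_followup_rate must be non-negative")
        if self.seed is None:
            raise ValueError("seed is mandatory")


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------


def _cavity_silhouette(size: int) -> np.ndarray:
    """Boolean mask of an inverted-triangle-ish ellipse, the cavity lumen."""
    y, x = np.mgrid[0:size, 0:size]
    cy, cx = size * 0.52, size * 0.5
    ry, rx = size * 0.38, size * 0.30
    ell = ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0
    # taper the lower pole to hint at the cervical canal
    taper = (y > cy) & (np.abs(x - cx) > rx * (1.0 - 0.55 * (y - cy) / ry))
    return ell & ~taper


def render_image(
    severity: float,
    view: str = "cavity",
    config: Optional[GeneratorConfig] = None,
    seed: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render one schematic view; returns (uint8 RGB image, band-pixel mask).

    The number and thickness of dark occluding bands increase monotonically
    with ``severity``; severity 0 renders an unoccluded cavity.  Cornua views
    show an ostium disc occluded in proportion to severity.  Deterministic
    for a fixed (severity, view, seed).
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    if view not in VIEWS:
        raise ValueError(f"view must be one of {VIEWS}")
    config = config or GeneratorConfig()
    size = config.image_size
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) * 7919 + hash(view) % 104729
    )

    img = np.empty((size, size, 3))
    img[..., 0] = 0.18  # dark red-brown background (out-of-cavity tissue)
    img[..., 1] = 0.08
    img[..., 2] = 0.08
    mask = np.zeros((size, size), dtype=bool)
    y, x = np.mgrid[0:size, 0:size]

    if view == "cavity":
        lumen = _cavity_silhouette(size)
        pale = np.array([0.92, 0.75, 0.70])  # pale endometrium
        img[lumen] = pale
        n_bands = int(np.ceil(severity * 4))
        thick = max(1, int(round(size * (0.02 + 0.09 * severity))))
        rows = rng.permutation(np.arange(int(size * 0.25), int(size * 0.75)))
        for b in range(n_bands):
            r0 = rows[b]
            band = (y >= r0) & (y < r0 + thick) & lumen
            # adhesion bands: dark fibrotic strands crossing the cavity
            img[band] = np.array([0.35, 0.15, 0.15]) + rng.normal(0, 0.02, 3)
            mask |= band
    else:
        # ostium disc in the upper cavity corner
        cx = size * (0.35 if view == "left_cornu" else 0.65)
        cy = size * 0.45
        r_ost = size * 0.22
        disc = (y - cy) ** 2 + (x - cx) ** 2 <= r_ost**2
        img[disc] = np.array([0.90, 0.72, 0.68])
        if severity > 0:
            r_occ = r_ost * np.sqrt(severity)
            occ = (y - cy) ** 2 + (x - cx) ** 2 <= r_occ**2
            img[occ] = np.array([0.38, 0.16, 0.16])
            mask |= occ

    # illumination gradient (endoscope light falls off toward the periphery)
    cy0, cx0 = size * 0.45, size * 0.5
    dist = np.sqrt((y - cy0) ** 2 + (x - cx0) ** 2) / size
    img *= (1.1 - 0.5 * dist)[..., None]
    img += rng.normal(0.0, config.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return (img * 255).astype(np.uint8), mask


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _draw_event_time(rng, hazard: float, shape: float) -> float:
    """Weibull PH sampler; shape 1 reduces to the exponential."""
    u = rng.uniform()
    # S(t) = exp(-hazard * t^shape)  =>  t = (-log u / hazard)^(1/shape)
    return float((-np.log(u) / hazard) ** (1.0 / shape))


def generate_cohort(
    config: GeneratorConfig,
    out_dir: Optional[str] = None,
    render: bool = True,
) -> Tuple[CohortTable, pd.DataFrame, Dict[str, List[np.ndarray]]]:
    """Simulate a cohort; returns (cohort, truth table, in-memory images).

    ``truth`` records per patient: latent severity, true log-hazard, the
    natural (counterfactual, ART-free) conception time, ART assignment and
    the observed follow-up.  When ``out_dir`` is given the cohort CSV,
    truth.csv and an ``images/<patient_id>/<view>.png`` tree are written.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    severities = rng.uniform(0.0, 1.0, n)
    log_h = np.log(config.baseline_rate) + config.beta_severity * (severities - 0.5)
    hazards = np.exp(log_h)

    records: List[SurvivalRecord] = []
    rows = []
    images: Dict[str, List[np.ndarray]] = {}
    image_index: Dict[str, List[str]] = {}

    for i in range(n):
        pid = f"P{i:04d}"
        h = hazards[i]
        t_nat = _draw_event_time(rng, h, config.weibull_shape)
        art = 0
        t_event = t_nat
        if config.art_enabled and t_nat > config.art_start_month:
            if rng.uniform() < config.art_probability:
                art = 1
                # the generating truth: poor natural 1-year prognosis benefits
                p1yr = 1.0 - np.exp(-h * 12.0**config.weibull_shape)
                hr = (
                    config.art_hr_low_stratum
                    if p1yr < 0.5
                    else config.art_hr_high_stratum
                )
                resid = _draw_event_time(rng, h * hr, config.weibull_shape)
                t_event = config.art_start_month + resid
        c_admin = config.admin_censor_months
        c_ltf = (
            rng.exponential(1.0 / config.loss_to_followup_rate)
            if config.loss_to_followup_rate > 0
            else np.inf
        )
        c = min(c_admin, c_ltf)
        time = min(t_event, c)
        event = int(t_event <= c)
        time = max(time, 1e-6)

        # clinical comparator covariates: noisy monotone proxies of severity
        age = float(np.clip(rng.normal(31.0, 4.0), 20, 45))
        afs = int(np.clip(round(1 + 10 * severities[i] + rng.normal(0, 1.5)), 1, 12))
        csge = int(np.clip(round(4 + 28 * severities[i] + rng.normal(0, 4.0)), 0, 40))
        emt = float(np.clip(10.5 - 5.0 * severities[i] + rng.normal(0, 1.0), 2, 15))

        rec = SurvivalRecord(
            patient_id=pid,
            time=time,
            event=event,
            art=art,
            covariates=np.array([age, afs, csge, emt]),
        )
        records.append(rec)
        rows.append(
            dict(
                patient_id=pid,
                severity=severities[i],
                true_log_hazard=log_h[i],
                natural_time=t_nat,
                event_time=t_event,
                censor_time=c,
                time=time,
                event=event,
                art=art,
                age=age,
                afs=afs,
                csge=csge,
                emt_mm=emt,
            )
        )
        if render:
            views = VIEWS[: config.images_per_patient]
            imgs = []
            for v in views:
                im, _ = render_image(severities[i], v, config, seed=image_seed(config, i))
                imgs.append(im)
            images[pid] = imgs
            image_index[pid] = [f"{pid}/{v}.png" for v in views]

    cohort = CohortTable(records=records, image_index=image_index)
    truth = pd.DataFrame(rows)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        csv_rows = []
        for r, tr in zip(records, rows):
            csv_rows.append(
                dict(
                    patient_id=r.patient_id,
                    time_months=r.time,
                    event=r.event,
                    art=r.art,
                    age=tr["age"],
                    afs=tr["afs"],
                    csge=tr["csge"],
                    emt_mm=tr["emt_mm"],
                    image_dir=r.patient_id,
                )
            )
        pd.DataFrame(csv_rows).to_csv(os.path.join(out_dir, "cohort.csv"), index=False)
        truth.to_csv(os.path.join(out_dir, "truth.csv"), index=False)
        if render:
            img_root = os.path.join(out_dir, "images")
            for pid, imgs in images.items():
                pdir = os.path.join(img_root, pid)
                os.makedirs(pdir, exist_ok=True)
                for v, im in zip(VIEWS, imgs):
                    Image.fromarray(im).save(os.path.join(pdir, f"{v}.png"))
    return cohort, truth, images


def make_splits(
    cohort: CohortTable,
    seed: int = 0,
    test_fraction: float = 0.25,
    val_fraction_of_modeling: float = 0.2,
) -> Dict[str, List[str]]:
    """Patient-level train/validation/test split (3:1 then 8:2 by default).

    Splits are disjoint by patient, never by image, so no image of a patient
    can leak across sets.
    """
    ids = list(cohort.patient_ids)
    n = len(ids)
    n_test = int(round(n * test_fraction))
    n_modeling = n - n_test
    n_val = int(round(n_modeling * val_fraction_of_modeling))
    n_train = n_modeling - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"cohort of {n} too small for non-empty splits")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    shuffled = [ids[i] for i in perm]
    return {
        "train": sorted(shuffled[:n_train]),
        "validation": sorted(shuffled[n_train : n_train + n_val]),
        "test": sorted(shuffled[n_train + n_val :]),
    }
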