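"""Synthetic pulmonary trees, inflow waveforms and patient cohorts.

The generators stand in for data that cannot be shared (MRI-derived
anatomies and flow curves of a nine-patient valve-implantation cohort).
They emulate the features the analysis depends on: a two-branch
pulmonary tree with ~10 outlets per side, a pulsatile MPA inflow with a
regurgitant diastolic phase before valve implantation (regurgitation
fraction ~44%) and a nearly competent one afterwards (~15%), and
clinical covariates with configurable effect sizes for exercising the
regression machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import PATree, VesselSegment
from .waveform import FlowWaveform

__all__ = [
    "generate_pa_tree",
    "generate_inflow_waveform",
    "generate_cohort",
    "PatientRecord",
    "CohortTable",
]

# Study-condition defaults: pre/post regurgitation-fraction means are the
# cohort means reported for the clinical population this generator
# emulates; dispersions are chosen so individual patients stay within the
# physiological ranges seen in repaired Tetralogy of Fallot.
PRE_PR_MEAN = 0.442
POST_PR_MEAN = 0.145
PRE_PR_SD = 0.06
POST_PR_SD = 0.04


def generate_pa_tree(
    n_outlets_per_side: int = 10,
    mpa_radius: float = 1.3,
    radius_dispersion: float = 0.3,
    seed: int = 0,
    *,
    rpa_radius_ratio: float = 0.76,
    lpa_radius_ratio: float = 0.70,
    mpa_length: float | None = None,
    principal_length: float = 3.0,
    outlet_length: float = 1.0,
    outlet_area_ratio: float = 1.5,
) -> PATree:
    """Generate a two-level synthetic pulmonary-artery tree.

    The tree has one MPA root, RPA and LPA principal segments, and
    ``n_outlets_per_side`` outlet branches hanging off each principal
    segment.  Outlet radii are log-normally dispersed around a base value
    chosen so that the summed outlet area on each side is
    ``outlet_area_ratio`` times the principal-branch area (the peripheral
    bed widens distally, keeping outlet velocities physiological).

    Parameters
    ----------
    n_outlets_per_side : int
        Number of outlet branches per side (>= 1).
    mpa_radius : float
        Root radius in cm.
    radius_dispersion : float
        Log-normal sigma of the outlet radii (0 gives identical outlets).
    seed : int
        Seed for the outlet-radius draw; identical inputs give
        byte-identical trees.
    """
    if n_outlets_per_side < 1:
        raise ValueError("n_outlets_per_side must be >= 1")
    if mpa_radius <= 0:
        raise ValueError("mpa_radius must be > 0")
    if radius_dispersion < 0:
        raise ValueError("radius_dispersion must be >= 0")
    if not (0 < rpa_radius_ratio <= 1 and 0 < lpa_radius_ratio <= 1):
        raise ValueError("principal radius ratios must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    if mpa_length is None:
        mpa_length = 2.5 * mpa_radius

    segments = [VesselSegment("MPA", None, mpa_radius, mpa_length)]
    for side, ratio in (("RPA", rpa_radius_ratio), ("LPA", lpa_radius_ratio)):
        r_side = ratio * mpa_radius
        segments.append(VesselSegment(side, "MPA", r_side, principal_length))
        # base outlet radius: n * pi r_out^2 = outlet_area_ratio * pi r_side^2
        r_base = r_side * np.sqrt(outlet_area_ratio / n_outlets_per_side)
        z = rng.standard_normal(n_outlets_per_side)
        radii = r_base * np.exp(radius_dispersion * z - 0.5 * radius_dispersion**2)
        for k, r_out in enumerate(radii):
            segments.append(
                VesselSegment(f"{side}_out{k:02d}", side, float(r_out), outlet_length)
            )
    return PATree(segments)


def generate_inflow_waveform(
    stroke_volume: float = 75.0,
    period: float = 0.9,
    pr_target: float = 0.44,
    systolic_fraction: float = 0.35,
    n_samples: int = 256,
    seed: int = 0,
    *,
    noise_sd: float = 0.0,
) -> FlowWaveform:
    """Generate an MPA inflow waveform with a controlled regurgitant phase.

    The canonical shape is a forward half-sine ejection lobe over systole
    (volume = ``stroke_volume``) followed by a backward half-sine lobe
    over diastole (volume = ``pr_target * stroke_volume``), so the
    regurgitation fraction of the constructed waveform equals
    ``pr_target`` up to quadrature error.  ``noise_sd`` adds optional
    zero-mean Gaussian jitter (mL/s) drawn from ``seed``; the default is
    a noise-free deterministic shape.
    """
    if stroke_volume <= 0:
        raise ValueError("stroke_volume must be > 0")
    if not 0 <= pr_target < 1:
        raise ValueError("pr_target must lie in [0, 1); net-zero or reversed mean flow is unsupported")
    if not 0 < systolic_fraction < 1:
        raise ValueError("systolic_fraction must lie in (0, 1)")
    if n_samples < 64:
        raise ValueError("n_samples must be >= 64")

    t = np.arange(n_samples) * (period / n_samples)
    t_sys = systolic_fraction * period
    t_dia = period - t_sys
    q_sys = np.pi * stroke_volume / (2.0 * t_sys)
    q_dia = np.pi * pr_target * stroke_volume / (2.0 * t_dia)

    flow = np.where(
        t < t_sys,
        q_sys * np.sin(np.pi * t / t_sys),
        -q_dia * np.sin(np.pi * (t - t_sys) / t_dia),
    )
    if noise_sd > 0:
        flow = flow + np.random.default_rng(seed).normal(0.0, noise_sd, n_samples)
    return FlowWaveform(period=period, flow=flow)


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient: anatomy plus pre/post inflow."""

    patient_id: int
    tree: PATree
    pre_waveform: FlowWaveform
    post_waveform: FlowWaveform
    pr_pre: float
    pr_post: float
    stroke_volume: float
    period: float


@dataclass
class CohortTable:
    """A synthetic cohort with clinical covariates.

    ``covariates`` holds one row per patient (indexed by patient id) with
    demographic columns, any effect covariates, and — when an effect
    configuration is supplied — a ``response`` column generated from the
    requested linear model.
    """

    patients: list[PatientRecord]
    covariates: pd.DataFrame
    seed: int
    effect_config: dict | None = field(default=None)

    def __post_init__(self) -> None:
        for p in self.patients:
            if not p.pr_pre > p.pr_post:
                raise ValueError(f"patient {p.patient_id}: pre PR must exceed post PR")

    @property
    def n_patients(self) -> int:
        return len(self.patients)


def generate_cohort(
    n_patients: int = 9,
    seed: int = 0,
    effect_config: dict | None = None,
    *,
    n_outlets_per_side: int = 10,
    radius_dispersion: float = 0.3,
    n_samples: int = 256,
) -> CohortTable:
    """Generate a synthetic patient cohort.

    Per patient: a PA tree (radius mildly varied around 1.3 cm MPA), a
    pre-implantation inflow with regurgitation fraction drawn around
    44.2% and a post-implantation inflow drawn around 14.5%, with the
    post value forced strictly below the pre value; and clinical
    covariates (ages at corrective surgery and at valve implantation).

    ``effect_config`` adds standard-normal covariates and a linear
    response for regression-recovery experiments::

        {"betas": [2.0, -1.5], "noise_sd": 0.0, "intercept": 0.0}

    Everything is reproducible from ``seed``.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2 (downstream summaries need at least two)")
    rng = np.random.default_rng(seed)

    patients: list[PatientRecord] = []
    rows = []
    for i in range(n_patients):
        mpa_radius = float(np.clip(rng.normal(1.3, 0.1), 1.0, 1.6))
        stroke_volume = float(np.clip(rng.normal(75.0, 10.0), 45.0, 110.0))
        period = float(np.clip(rng.normal(0.9, 0.05), 0.7, 1.1))
        pr_pre = float(np.clip(rng.normal(PRE_PR_MEAN, PRE_PR_SD), 0.25, 0.65))
        pr_post = float(np.clip(rng.normal(POST_PR_MEAN, POST_PR_SD), 0.02, 0.30))
        pr_post = min(pr_post, pr_pre - 0.05)
        tree_seed = int(rng.integers(0, 2**31 - 1))
        tree = generate_pa_tree(
            n_outlets_per_side=n_outlets_per_side,
            mpa_radius=mpa_radius,
            radius_dispersion=radius_dispersion,
            seed=tree_seed,
        )
        pre_wf = generate_inflow_waveform(stroke_volume, period, pr_pre, n_samples=n_samples)
        post_wf = generate_inflow_waveform(stroke_volume, period, pr_post, n_samples=n_samples)
        patients.append(
            PatientRecord(i + 1, tree, pre_wf, post_wf, pr_pre, pr_post, stroke_volume, period)
        )
        rows.append(
            {
                "patient": i + 1,
                "age_at_repair_months": float(np.exp(rng.normal(np.log(10.0), 0.8))),
                "age_at_ppvi_years": float(np.clip(rng.normal(23.0, 3.0), 12.0, 40.0)),
                "pr_pre": pr_pre,
                "pr_post": pr_post,
            }
        )
    covariates = pd.DataFrame(rows).set_index("patient")

    if effect_config is not None:
        betas = np.asarray(effect_config["betas"], dtype=float)
        noise_sd = float(effect_config.get("noise_sd", 0.0))
        intercept = float(effect_config.get("intercept", 0.0))
        x = rng.standard_normal((n_patients, betas.size))
        for j in range(betas.size):
            covariates[f"x{j + 1}"] = x[:, j]
        y = intercept + x @ betas
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, n_patients)
        covariates["response"] = y

    return CohortTable(patients, covariates, seed, effect_config)
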