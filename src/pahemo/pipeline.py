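"""End-to-end analysis pipeline.

Composes the stages in study order: synthetic cohort generation,
boundary-condition construction and flow-split calibration per patient
and state, the six-cycle pulsatile network solution, index computation
at the measurement sites, cohort mean/SD summaries, and paired pre/post
comparisons.  The run is fully deterministic given its configuration.

Also provides the loader for the packaged reference table of published
per-patient indices (nine patients, pre/post), which the summary and
test machinery reproduce.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .indices import compute_indices, summarize_indices
from .network import solve_network
from .stats import wilcoxon_signed_rank
from .synthetic import generate_cohort
from .units import FluidProperties, mmhg_to_cgs
from .waveform import FlowWaveform
from .windkessel import (
    build_resistance_budget,
    calibrate_flow_split,
    rcr_set_from_budget,
    total_pa_resistance,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_reference_indices"]

REFERENCE_SHA256 = "dc401289bec7fbb2fdb943abf8b1563c4410cb40b0d421851232b8325dab200e"
REFERENCE_COLUMNS = [
    "patient", "state",
    "mpa_re", "mpa_wo", "mpa_vo",
    "rpa_re", "rpa_wo", "rpa_vo",
    "lpa_re", "lpa_wo", "lpa_vo",
    "ed",
]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; defaults are the study conditions."""

    n_patients: int = 9
    seed: int = 1
    # cohort / inflow
    pre_pr_rpa_split: float = 0.614  # measured pre-implantation RPA flow share
    post_pr_rpa_split: float = 0.594
    mean_pap_mmhg: float = 13.0  # mean pulmonary-artery pressure driving R_total
    n_outlets_per_side: int = 10
    radius_dispersion: float = 0.3
    waveform_samples: int = 256
    # fluid
    density: float = 1.06
    viscosity: float = 0.04
    # boundary conditions
    murray_exponent: float = 2.3
    proximal_fraction: float = 0.1
    time_constant: float = 1.0
    distal_pressure: float = 0.0
    split_tolerance: float = 0.10
    calibration_max_iter: int = 20
    # solver
    n_cycles: int = 6
    steps_per_cycle: int = 256
    # indices
    n_harmonics: int = 32
    # statistics
    alpha: float = 0.05
    test_method: str = "exact"

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0 < self.pre_pr_rpa_split < 1 or not 0 < self.post_pr_rpa_split < 1:
            raise ValueError("RPA flow splits must lie in (0, 1)")
        if self.mean_pap_mmhg <= 0:
            raise ValueError("mean PA pressure must be > 0")
        if self.test_method not in ("exact", "normal_approx"):
            raise ValueError("test_method must be 'exact' or 'normal_approx'")
        FluidProperties(self.density, self.viscosity)  # validates

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(**data)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class RunReport:
    """All numeric outputs of one pipeline run."""

    indices: pd.DataFrame  # one row per (patient, state)
    summary: dict[str, pd.DataFrame]  # state -> mean/sd table
    comparisons: pd.DataFrame  # per index: W, p for pre vs post
    calibration: dict[str, dict]  # "patient/state" -> report dict
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "indices": self.indices.round(10).to_dict(orient="list"),
            "summary": {k: v.round(10).to_dict(orient="index") for k, v in self.summary.items()},
            "comparisons": self.comparisons.round(10).to_dict(orient="list"),
            "calibration": self.calibration,
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.indices.to_csv(out / "indices.csv", index=False)
        for state, table in self.summary.items():
            table.to_csv(out / f"summary_{state}.csv")
        self.comparisons.to_csv(out / "comparisons.csv", index=False)
        (out / "report.json").write_text(self.to_json())


def _solve_patient_state(patient, waveform: FlowWaveform, rpa_split: float,
                         config: PipelineConfig, fluid: FluidProperties):
    mean_flow = max(waveform.mean_flow(), 1e-6)
    r_total = total_pa_resistance(
        mmhg_to_cgs(config.mean_pap_mmhg), mean_flow, config.distal_pressure
    )
    budget = build_resistance_budget(patient.tree, r_total, rpa_split, config.murray_exponent)
    budget, cal = calibrate_flow_split(
        patient.tree, budget, waveform, rpa_split,
        tolerance=config.split_tolerance, max_iter=config.calibration_max_iter,
        fluid=fluid, proximal_fraction=config.proximal_fraction,
        time_constant=config.time_constant, distal_pressure=config.distal_pressure,
        n_cycles=config.n_cycles, steps_per_cycle=config.steps_per_cycle,
    )
    rcrs = rcr_set_from_budget(budget, config.proximal_fraction,
                               config.time_constant, config.distal_pressure)
    solution = solve_network(patient.tree, rcrs, waveform, fluid,
                             n_cycles=config.n_cycles, steps_per_cycle=config.steps_per_cycle)
    return solution, cal


def run_pipeline(config: PipelineConfig | None = None) -> RunReport:
    """Run the full analysis on a synthetic cohort.

    For every patient and state (pre/post valve implantation): build the
    resistance budget from mean pressure and flow, calibrate the flow
    split, solve six cardiac cycles, and compute the index set; then
    summarize the cohort and compare pre vs post per index with the
    configured Wilcoxon method.  Calibration non-convergence flags the
    patient in the report but does not abort the run.
    """
    if config is None:
        config = PipelineConfig()
    fluid = FluidProperties(config.density, config.viscosity)
    cohort = generate_cohort(
        config.n_patients, config.seed,
        n_outlets_per_side=config.n_outlets_per_side,
        radius_dispersion=config.radius_dispersion,
        n_samples=config.waveform_samples,
    )

    rows = []
    calibration: dict[str, dict] = {}
    for patient in cohort.patients:
        for state, waveform, split in (
            ("pre", patient.pre_waveform, config.pre_pr_rpa_split),
            ("post", patient.post_waveform, config.post_pr_rpa_split),
        ):
            solution, cal = _solve_patient_state(patient, waveform, split, config, fluid)
            row = {"patient": patient.patient_id, "state": state}
            row.update(compute_indices(patient.tree, solution, fluid,
                                       n_harmonics=config.n_harmonics))
            rows.append(row)
            calibration[f"{patient.patient_id}/{state}"] = {
                "converged": cal.converged,
                "iterations": cal.iterations,
                "final_relative_error": cal.final_relative_error,
            }
    indices = pd.DataFrame(rows)

    summary = {
        state: summarize_indices(indices[indices["state"] == state].drop(columns=["patient", "state"]))
        for state in ("pre", "post")
    }

    metric_cols = [c for c in indices.columns if c not in ("patient", "state")]
    pre = indices[indices["state"] == "pre"].set_index("patient")
    post = indices[indices["state"] == "post"].set_index("patient")
    comp_rows = []
    for col in metric_cols:
        res = wilcoxon_signed_rank(pre[col].to_numpy(), post[col].to_numpy(),
                                   method=config.test_method)
        comp_rows.append({"index": col, "statistic": res.statistic,
                          "pvalue": res.pvalue, "method": res.method})
    comparisons = pd.DataFrame(comp_rows)

    provenance = {
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "seed": config.seed,
    }
    return RunReport(indices, summary, comparisons, calibration, provenance)


def load_reference_indices(path=None) -> pd.DataFrame:
    """Load the packaged published per-patient index table.

    Returns a tidy DataFrame with 18 rows (9 patients x pre/post) and
    per-branch Re/Wo/Vo columns plus whole-bed ED.  The packaged copy is
    integrity-checked against a SHA-256 recorded at packaging time; a
    divergent or truncated file raises.
    """
    if path is None:
        text = resources.files("pahemo.data").joinpath("reference_indices.csv").read_text()
    else:
        text = Path(path).read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != REFERENCE_SHA256:
        raise ValueError(
            "reference index table failed its integrity check "
            f"(sha256 {digest[:12]}..., expected {REFERENCE_SHA256[:12]}...)"
        )
    from io import StringIO

    df = pd.read_csv(StringIO(text), comment="#")
    if list(df.columns) != REFERENCE_COLUMNS or len(df) != 18:
        raise ValueError("reference index table has an unexpected schema")
    return df
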