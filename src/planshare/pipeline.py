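"""End-to-end orchestration: simulate -> build-cohort -> infer-plans ->
fit-hurdle -> report, with one config, one master seed and a provenance
manifest (stage order, input/output hashes, timings).

All intermediate artifacts are plain CSV/JSON so a run can be audited with
a text editor.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CodeConfig, build_cohort, compute_annual_oopc
from .design import OUTCOMES, DesignSpec
from .errors import InvalidConfigError
from .hurdle import effects_frame, fit_hurdle, marginal_effects
from .mechanism import classify_plans
from .reporting import (
    cohort_table,
    oopc_by_type_table,
    plan_distribution_table,
    render_table,
    utilization_table,
)
from .synthetic import OutcomeParams, StudyConfig, simulate_study

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("simulate", "build-cohort", "infer-plans", "fit-hurdle", "report")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "runs/demo"
    seed: int = 0
    n_plans: int = 2000
    mixture: tuple[float, float, float, float] = (0.207, 0.583, 0.082, 0.127)
    separation: float = 2.0
    mean_enrollees_per_plan: float = 30.0
    mean_claims_per_enrollee_year: float = 12.0
    screening_rate: float = 0.85
    index_year: int = 2016
    study_start: str = "2015-01-01"
    study_end: str = "2017-12-31"
    n_regions: int = 5
    orientation: str = "as_printed"
    pin_origin: bool = False
    kmeans_restarts: int = 1
    outcomes: tuple[str, ...] = ("all_imaging",)
    apply_smearing: bool = True
    codes: dict = field(default_factory=dict)  # CodeConfig field overrides

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in RunConfig.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        if "mixture" in raw:
            raw["mixture"] = tuple(raw["mixture"])
        if "outcomes" in raw:
            raw["outcomes"] = tuple(raw["outcomes"])
        return RunConfig(**raw)

    def validate(self) -> None:
        if abs(sum(self.mixture) - 1.0) > 1e-2:
            raise InvalidConfigError("mixture must sum to 1")
        for o in self.outcomes:
            if o not in OUTCOMES:
                raise InvalidConfigError(f"unknown outcome {o!r}")
        if self.orientation not in ("as_printed", "standard"):
            raise InvalidConfigError(f"unknown orientation {self.orientation!r}")
        Path(self.outdir).mkdir(parents=True, exist_ok=True)

    def code_config(self) -> CodeConfig:
        if not self.codes:
            return CodeConfig()
        kwargs = {k: frozenset(v) for k, v in self.codes.items()}
        return CodeConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: RunConfig):
        self.entries: list[dict] = []
        self.config = config

    def record(self, stage: str, outputs: list[Path], t0: float) -> None:
        self.entries.append(
            {
                "stage": stage,
                "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
                "seconds": round(time.time() - t0, 3),
            }
        )

    def write(self, outdir: Path) -> Path:
        payload = {
            "package_version": __version__,
            "seed": self.config.seed,
            "config": asdict(self.config),
            "stages": self.entries,
        }
        path = outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)
        return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute all five stages in order and return the manifest dict.

    Any stage failure propagates with the stage name attached, leaving the
    outputs of completed stages in place.
    """
    config.validate()
    outdir = Path(config.outdir)
    manifest = _Manifest(config)
    state: dict = {}
    for stage in STAGES:
        t0 = time.time()
        log.info("stage %s starting", stage)
        try:
            outputs = _STAGE_FNS[stage](config, outdir, state)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, outputs, t0)
    path = manifest.write(outdir)
    with open(path) as fh:
        return json.load(fh)


def _stage_simulate(config: RunConfig, outdir: Path, state: dict) -> list[Path]:
    study = simulate_study(
        StudyConfig(
            n_plans=config.n_plans,
            mixture=config.mixture,
            separation=config.separation,
            mean_enrollees_per_plan=config.mean_enrollees_per_plan,
            mean_claims_per_enrollee_year=config.mean_claims_per_enrollee_year,
            screening_rate=config.screening_rate,
            index_year=config.index_year,
            study_start=config.study_start,
            study_end=config.study_end,
            n_regions=config.n_regions,
            seed=config.seed,
        )
    )
    study.write(outdir)
    state["claims"] = study.claims
    state["enrollment"] = study.enrollment
    state["truth"] = study.truth
    return [outdir / "claims.csv", outdir / "enrollment.csv", outdir / "ground_truth.json"]


def _load_inputs(config: RunConfig, outdir: Path, state: dict) -> None:
    if "claims" not in state:
        claims_path = outdir / "claims.csv"
        if not claims_path.exists():
            raise InvalidConfigError(f"claims file missing: {claims_path}")
        state["claims"] = pd.read_csv(claims_path, parse_dates=["service_date"],
                                      dtype={"cpt_code": str}, keep_default_na=False,
                                      na_values=[])
        state["enrollment"] = pd.read_csv(outdir / "enrollment.csv",
                                          na_values=[""], keep_default_na=False)
        state["enrollment"]["death_date"] = pd.to_datetime(
            state["enrollment"]["death_date"], errors="coerce"
        )


def _stage_build_cohort(config: RunConfig, outdir: Path, state: dict) -> list[Path]:
    _load_inputs(config, outdir, state)
    codes = config.code_config()
    cohort, episodes, exclusions = build_cohort(
        state["claims"], state["enrollment"], codes,
        index_year=config.index_year,
        study_start=config.study_start, study_end=config.study_end,
    )
    state.update(cohort=cohort, episodes=episodes, codes=codes)
    paths = []
    for name, df in (("cohort", cohort), ("episodes", episodes), ("exclusions", exclusions)):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    return paths


def _stage_infer_plans(config: RunConfig, outdir: Path, state: dict) -> list[Path]:
    _load_inputs(config, outdir, state)
    codes = state.get("codes") or config.code_config()
    oopc = compute_annual_oopc(state["claims"], config.index_year, codes)
    oopc = oopc.merge(
        state["enrollment"][["enrollee_id", "plan_id"]], on="enrollee_id", how="left"
    )
    assignments, model, type_stats = classify_plans(
        state["claims"], oopc, seed=config.seed,
        orientation=config.orientation, pin_origin=config.pin_origin,
        n_restarts=config.kmeans_restarts,
    )
    state.update(assignments=assignments, type_stats=type_stats)
    from .mechanism import compute_plan_triplets

    triplets = compute_plan_triplets(state["claims"])
    p1 = outdir / "plan_triplets.csv"
    triplets.to_csv(p1, index=False)
    p2 = outdir / "plan_assignments.csv"
    assignments.to_csv(p2, index=False)
    p3 = outdir / "cluster_model.json"
    with open(p3, "w") as fh:
        json.dump(
            {
                "centers": model.centers.tolist(),
                "seed": model.seed,
                "n_iterations": model.n_iterations,
                "sse": model.sse,
                "orientation": config.orientation,
                "type_stats": type_stats.to_dict(orient="records"),
            },
            fh,
            indent=1,
        )
    return [p1, p2, p3]


def _stage_fit_hurdle(config: RunConfig, outdir: Path, state: dict) -> list[Path]:
    for key in ("cohort", "episodes", "assignments", "type_stats"):
        if key not in state:
            raise InvalidConfigError(f"stage fit-hurdle needs {key}; run earlier stages")
    data = _model_frame(state)
    ref = state["type_stats"].sort_values("oopc_rank")["plan_type"].iloc[0]
    paths = []
    state["fits"] = {}
    for outcome in config.outcomes:
        spec = DesignSpec(outcome=outcome, plan_ref=ref)
        fit = fit_hurdle(data, spec)
        effects = marginal_effects(fit, data, apply_smearing=config.apply_smearing)
        state["fits"][outcome] = (fit, effects)
        p1 = outdir / f"fit_summary_{outcome}.csv"
        fit.summary_frame().to_csv(p1, index=False)
        p2 = outdir / f"marginal_effects_{outcome}.csv"
        effects_frame(effects).to_csv(p2, index=False)
        p3 = outdir / f"fit_meta_{outcome}.json"
        with open(p3, "w") as fh:
            json.dump(
                {
                    "outcome": outcome,
                    "reference_type": ref,
                    "loglik_part1": fit.loglik_part1,
                    "loglik_part2": fit.loglik_part2,
                    "alpha": fit.alpha,
                    "n_obs_part1": fit.n_obs_part1,
                    "n_obs_part2": fit.n_obs_part2,
                    "smearing_factor": fit.smearing_factor,
                    "seed": config.seed,
                },
                fh,
                indent=1,
            )
        paths += [p1, p2, p3]
    return paths


def _model_frame(state: dict) -> pd.DataFrame:
    data = state["cohort"].merge(
        state["episodes"][
            ["patient_id", "n_services", "n_diagnostic_mammo", "n_ultrasound",
             "n_mri", "n_biopsy", "any_subsequent"]
        ],
        on="patient_id",
    )
    return data.merge(
        state["assignments"][["plan_id", "plan_type"]], on="plan_id", how="left"
    )


def _stage_report(config: RunConfig, outdir: Path, state: dict) -> list[Path]:
    for key in ("cohort", "episodes", "assignments", "type_stats"):
        if key not in state:
            raise InvalidConfigError(f"stage report needs {key}; run earlier stages")
    order = state["type_stats"].sort_values("oopc_rank")["plan_type"].tolist()
    tables = {
        "table1_cohort": cohort_table(state["cohort"], state["episodes"]),
        "table2_plans": plan_distribution_table(
            state["assignments"], state["episodes"], order
        ),
        "table3_oopc": oopc_by_type_table(state["episodes"], state["assignments"], order),
        "table4_utilization": utilization_table(
            state["episodes"], state["assignments"], state["type_stats"]
        ),
    }
    paths = []
    for name, tab in tables.items():
        p = outdir / f"{name}.csv"
        tab.to_csv(p, index=False)
        paths.append(p)
        pt = outdir / f"{name}.txt"
        pt.write_text(render_table(tab) + "\n")
        paths.append(pt)
    state["tables"] = tables
    return paths


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "build-cohort": _stage_build_cohort,
    "infer-plans": _stage_infer_plans,
    "fit-hurdle": _stage_fit_hurdle,
    "report": _stage_report,
}
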