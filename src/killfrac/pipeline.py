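"""End-to-end workflow: simulate/load -> extract parameters -> calibrate ->
predict -> sensitivity -> report.

The pipeline reads (or synthesizes) the three input tables, summarizes the
histology markers, estimates the physiological parameters, rescales the
drug-resistant kill data by the in-vitro ratio, fits the kill model, emits a
predicted kill-vs-BVF curve and a sensitivity ranking, and writes a manifest
(config echo, seed, versions, input checksums) that suffices to reproduce
the run.  All outputs are diff-able text (CSV/JSON).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    fit_kill_model,
    read_kill_data,
    rescale_resistant,
)
from .histology import (
    estimate_bvf,
    estimate_vessel_radius,
    read_sections,
    read_vessels,
    summaries_to_frame,
    summarize_markers,
)
from .model import ModelParams, predict_curve
from .sensitivity import (
    DEFAULT_DELTAS,
    sensitivity_coefficient,
    sensitivity_ranking,
)
from .synthetic import SyntheticConfig, generate_kill_dataset, generate_sections

__all__ = [
    "RunConfig",
    "PipelineStageError",
    "ValidationReport",
    "run_pipeline",
    "simulate_inputs",
    "validate_inputs",
]

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run (YAML-mappable field for field)."""

    out_dir: str = "results"
    synthetic: bool = True
    sections_csv: str | None = None
    vessels_csv: str | None = None
    killdata_csv: str | None = None
    convention: str = "fraction"
    rescale_factor: float = 3.5
    fit_init: tuple[float, float] | None = None
    fit_bounds: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0, 1e-3),
        (1.0, 2.0),
    )
    multistart: int = 10
    seed: int = 0
    sensitivity_deltas: tuple[float, ...] = DEFAULT_DELTAS
    reference_rb_um: float = 5.0
    reference_L_um: float = 40.0
    curve_bvf_min: float = 0.005
    curve_bvf_max: float = 0.2
    curve_points: int = 50
    synthetic_config: SyntheticConfig = field(default_factory=SyntheticConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic_config", None)
        kwargs = dict(raw)
        if syn is not None:
            if "marker_stats" in syn:
                syn["marker_stats"] = {
                    tuple(k.split("|")[:2]) + (bool(int(k.split("|")[2])),): tuple(v)
                    for k, v in syn["marker_stats"].items()
                }
            if "bvf_support" in syn:
                syn["bvf_support"] = tuple(syn["bvf_support"])
            kwargs["synthetic_config"] = SyntheticConfig(**syn)
        for key in ("fit_init", "sensitivity_deltas"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if "fit_bounds" in kwargs:
            kwargs["fit_bounds"] = tuple(tuple(b) for b in kwargs["fit_bounds"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic_config"] = self.synthetic_config.to_dict()
        return d


@dataclass(frozen=True)
class ValidationReport:
    errors: tuple[str, ...]
    warnings: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.errors


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def simulate_inputs(config: SyntheticConfig, out_dir) -> dict[str, Path]:
    """Write synthetic sections/vessels/killdata CSVs plus ground truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sections, vessels, truth_s = generate_sections(config)
    kill, truth_k = generate_kill_dataset(config)
    paths = {
        "sections": out / "sections.csv",
        "vessels": out / "vessels.csv",
        "killdata": out / "killdata.csv",
        "ground_truth": out / "ground_truth.json",
    }
    sections.to_csv(paths["sections"], index=False)
    vessels.to_csv(paths["vessels"], index=False)
    pd.DataFrame(
        {
            "line": [p.line for p in kill.points],
            "section_index": [p.section_index for p in kill.points],
            "bvf": [p.bvf for p in kill.points],
            "dead_fraction": [p.dead_fraction for p in kill.points],
        }
    ).to_csv(paths["killdata"], index=False)
    _write_json(paths["ground_truth"], {"sections": truth_s, "kill": truth_k})
    return paths


def validate_inputs(
    paths: dict[str, str | Path], convention: str = "fraction"
) -> ValidationReport:
    """Schema and invariant checks on the input tables.

    Distinguishes hard errors (malformed schema, impossible values) from
    warnings (probable percent-vs-fraction convention mismatch: under the
    fraction convention, any bvf or dead_fraction above 1.5 is flagged).
    """
    errors: list[str] = []
    warnings: list[str] = []
    sections = paths.get("sections")
    if sections is not None:
        try:
            frame = pd.read_csv(sections)
            need = {"line", "treated", "section_index", "roi_index", "marker",
                    "stained_area", "total_area"}
            missing = need - set(frame.columns)
            if missing:
                errors.append(f"sections: missing columns {sorted(missing)}")
            else:
                bad = frame[frame["stained_area"] > frame["total_area"]]
                for idx in bad.index:
                    errors.append(
                        f"sections row {idx}: stained_area exceeds total_area"
                    )
                if (frame["total_area"] <= 0).any():
                    errors.append("sections: non-positive total_area present")
        except Exception as exc:
            errors.append(f"sections: parse error: {exc}")
    kill = paths.get("killdata")
    if kill is not None:
        try:
            frame = pd.read_csv(kill)
            need = {"line", "section_index", "bvf", "dead_fraction"}
            missing = need - set(frame.columns)
            if missing:
                errors.append(f"killdata: missing columns {sorted(missing)}")
            else:
                if convention == "fraction" and (
                    (frame["bvf"] > 1.5).any()
                    or (frame["dead_fraction"] > 1.5).any()
                ):
                    warnings.append(
                        "killdata: values above 1.5 under the fraction "
                        "convention; inputs may be percentages"
                    )
                if ((frame["bvf"] <= 0) | (frame["bvf"] >= 100)).any():
                    errors.append("killdata: bvf outside any valid convention")
        except Exception as exc:
            errors.append(f"killdata: parse error: {exc}")
    vessels = paths.get("vessels")
    if vessels is not None:
        try:
            frame = pd.read_csv(vessels)
            if {"extent1_um", "extent2_um"} <= set(frame.columns):
                if ((frame["extent1_um"] <= 0) | (frame["extent2_um"] <= 0)).any():
                    errors.append("vessels: non-positive extents present")
            else:
                errors.append("vessels: missing extent columns")
        except Exception as exc:
            errors.append(f"vessels: parse error: {exc}")
    return ValidationReport(tuple(errors), tuple(warnings))


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow; returns a report dict and writes all outputs.

    Any stage failure raises :class:`PipelineStageError` naming the stage,
    after persisting the manifest and whatever outputs completed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "killfrac": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {},
        "stages_completed": [],
    }
    report: dict = {}

    def finish_stage(name: str) -> None:
        manifest["stages_completed"].append(name)
        _write_json(out / "manifest.json", manifest)

    def fail(stage: str, exc: Exception):
        _write_json(out / "manifest.json", manifest)
        raise PipelineStageError(stage, exc)

    # --- inputs
    try:
        if config.synthetic:
            syn = dataclasses.replace(config.synthetic_config, seed=config.seed)
            paths = simulate_inputs(syn, out / "inputs")
        else:
            paths = {
                "sections": Path(config.sections_csv),
                "vessels": Path(config.vessels_csv),
                "killdata": Path(config.killdata_csv),
            }
        for name, p in paths.items():
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(Path(p))}
    except Exception as exc:
        fail("inputs", exc)
    finish_stage("inputs")

    # --- histology summaries and physiological parameters
    try:
        rows = read_sections(paths["sections"])
        summaries = summarize_markers(rows)
        frame = summaries_to_frame(summaries)
        frame.to_csv(out / "marker_summaries.csv", index=False)
        vessels = read_vessels(paths["vessels"])
        rb = estimate_vessel_radius(vessels)
        cd31 = {
            (s.line, s.treated): s.mean_fraction
            for s in summaries
            if s.marker == "cd31"
        }
        params_block = {
            "rb_um": {"mean": rb.mean, "sd": rb.sd, "n": rb.n},
            "L_um": {"mean": config.reference_L_um, "sd": None, "n": None},
            "bvf_by_group": {
                f"{line}|{'treated' if treated else 'untreated'}": estimate_bvf(v)
                for (line, treated), v in sorted(cd31.items())
            },
        }
        _write_json(out / "parameters.json", params_block)
        report["parameters"] = params_block
    except Exception as exc:
        fail("histology", exc)
    finish_stage("histology")

    # --- calibration
    try:
        data = read_kill_data(paths["killdata"], config.convention)
        rescaled = rescale_resistant(data, config.rescale_factor)
        result = fit_kill_model(
            rescaled,
            init=config.fit_init,
            bounds=config.fit_bounds,
            multistart=config.multistart,
            seed=config.seed,
        )
        calib = result.to_dict()
        calib["rescale_factor"] = config.rescale_factor
        _write_json(out / "calibration.json", calib)
        report["calibration"] = calib
    except Exception as exc:
        fail("calibration", exc)
    finish_stage("calibration")

    # --- predicted curve
    try:
        grid = np.linspace(config.curve_bvf_min, config.curve_bvf_max,
                           config.curve_points)
        curve = predict_curve(result.fkill_m_hat, result.rb_over_L_hat, grid)
        pd.DataFrame({"bvf": grid, "f_kill": curve}).to_csv(
            out / "predicted_curve.csv", index=False
        )
    except Exception as exc:
        fail("predict", exc)
    finish_stage("predict")

    # --- sensitivity at the calibrated/measured reference
    try:
        bvf_ref = float(np.median(rescaled.bvf))
        fm_ref = result.fkill_m_hat if result.converged else 0.25
        # upward perturbations must keep fkill_m within [0, 1] and bvf < 1
        max_up = max((d for d in config.sensitivity_deltas if d > 0), default=0.0)
        fm_ref = min(fm_ref, (1.0 - 1e-9) / (1.0 + max_up))
        bvf_ref = min(bvf_ref, (1.0 - 1e-9) / (1.0 + max_up))
        reference = ModelParams(
            bvf=bvf_ref,
            rb_um=config.reference_rb_um,
            L_um=config.reference_L_um,
            fkill_m=fm_ref,
        )
        rows = []
        for p in ("bvf", "rb_um", "L_um", "fkill_m"):
            for d in config.sensitivity_deltas:
                rows.append(
                    {
                        "parameter": p,
                        "delta": d,
                        "S": sensitivity_coefficient(reference, p, d).S,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "sensitivity.csv", index=False)
        ranking = sensitivity_ranking(
            reference,
            ("bvf", "rb_um", "L_um", "fkill_m"),
            config.sensitivity_deltas,
        )
        ranking_block = {
            "reference": {
                "bvf": reference.bvf,
                "rb_um": reference.rb_um,
                "L_um": reference.L_um,
                "fkill_m": reference.fkill_m,
            },
            "ranking": [{"parameter": p, "mean_abs_S": s} for p, s in ranking],
        }
        _write_json(out / "sensitivity_ranking.json", ranking_block)
        report["sensitivity"] = ranking_block
    except Exception as exc:
        fail("sensitivity", exc)
    finish_stage("sensitivity")

    _write_json(out / "manifest.json", manifest)
    report["manifest"] = manifest
    return report
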