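"""Synthetic data emulating the murine lymphoma study's measurement structure.

No raw histology data are deposited for this study design, so every input
the pipeline consumes can be generated here with the statistical structure
the analysis assumes:

* per-ROI stained/total areas whose group means and SDs follow the study's
  published marker table (5 section sets for the drug-sensitive line, 6 for
  the drug-resistant line, 3 ROIs each);
* vessel cross-sections drawn ~90% capillary (about 10 um diameter) and
  ~10% vein (about 20 um);
* per-section (BVF, dead fraction) kill data generated from the closed-form
  model at reference parameters fkill_m = 0.25 and r_b/L = 0.068, with the
  resistant line's kill divided by the in-vitro ratio (default 3.5) and
  additive Gaussian measurement noise;
* 9-point 3x dilution dose-response series from 10 uM per line with
  four-parameter-logistic viability at IC50s of 3.5 nM (sensitive) and
  46.2 nM (resistant).

Everything is deterministic under a fixed seed, and each generator returns a
ground-truth record sufficient to recompute the expected downstream result.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .calibration import KillDataset, KillPoint
from .invitro import DoseResponseCurve
from .model import kill_fraction_scaled

__all__ = [
    "SyntheticConfig",
    "TABLE_MARKER_STATS",
    "generate_sections",
    "generate_kill_dataset",
    "generate_dose_response",
]

#: (marker, line, treated) -> (mean fraction, SD) for ROI stain fractions,
#: following the study's published per-group averages.
TABLE_MARKER_STATS: dict[tuple[str, str, bool], tuple[float, float]] = {
    ("necrosis", "sensitive", True): (0.121, 0.05),
    ("necrosis", "resistant", True): (0.047, 0.03),
    ("necrosis", "sensitive", False): (0.005, 0.00),
    ("necrosis", "resistant", False): (0.008, 0.01),
    ("apoptosis", "sensitive", True): (0.038, 0.02),
    ("apoptosis", "resistant", True): (0.051, 0.03),
    ("apoptosis", "sensitive", False): (0.048, 0.02),
    ("apoptosis", "resistant", False): (0.207, 0.12),
    ("cd31", "sensitive", True): (0.031, 0.02),
    ("cd31", "resistant", True): (0.045, 0.03),
    ("cd31", "sensitive", False): (0.018, 0.01),
    ("cd31", "resistant", False): (0.028, 0.02),
    ("hif1a", "sensitive", True): (0.133, 0.08),
    ("hif1a", "resistant", True): (0.134, 0.06),
    ("hif1a", "sensitive", False): (0.017, 0.01),
    ("hif1a", "resistant", False): (0.034, 0.04),
    ("ki67", "sensitive", True): (0.736, 0.13),
    ("ki67", "resistant", True): (0.870, 0.06),
    ("ki67", "sensitive", False): (0.772, 0.18),
    ("ki67", "resistant", False): (0.753, 0.14),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults reproduce the study's design."""

    seed: int = 0
    sections_sensitive: int = 5
    sections_resistant: int = 6
    rois_per_section: int = 3
    marker_stats: dict = field(default_factory=lambda: dict(TABLE_MARKER_STATS))
    roi_total_area_px: int = 1_000_000
    vessels_per_section: int = 20
    capillary_fraction: float = 0.9
    capillary_diameter_um: float = 10.0
    vein_diameter_um: float = 20.0
    vessel_extent_cv: float = 0.1
    # kill-data generation
    true_fkill_m: float = 0.25
    true_rb_over_L: float = 0.068
    kill_ratio: float = 3.5
    dead_noise_sd: float = 0.02
    bvf_mean: float = 0.038
    bvf_sd: float = 0.015
    bvf_support: tuple[float, float] = (0.003, 0.2)
    # dose-response generation
    ic50_sensitive_nM: float = 3.5
    ic50_resistant_nM: float = 46.2
    hill_slope: float = 1.0
    top_concentration_nM: float = 10_000.0
    dilution_factor: float = 3.0
    n_dilutions: int = 9
    dose_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sections_sensitive < 1 or self.sections_resistant < 1:
            raise ValueError("section counts must be >= 1")
        if self.rois_per_section < 1:
            raise ValueError("rois_per_section must be >= 1")
        for key, (mean, sd) in self.marker_stats.items():
            if not 0 <= mean <= 1 or sd < 0:
                raise ValueError(f"invalid marker stats for {key}: {(mean, sd)}")
        if self.dead_noise_sd < 0 or self.dose_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        lo, hi = self.bvf_support
        if not 0 < lo < hi < 1:
            raise ValueError("bvf_support must lie inside (0, 1)")
        if not 0 < self.true_fkill_m <= 1 or self.true_rb_over_L <= 0:
            raise ValueError("true model parameters out of range")
        if self.kill_ratio <= 0:
            raise ValueError("kill_ratio must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["marker_stats"] = {
            f"{m}|{line}|{int(treated)}": list(v)
            for (m, line, treated), v in self.marker_stats.items()
        }
        return d


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Truncated normal on [lo, hi] whose mean EQUALS ``mean``.

    Truncation shifts the mean of a plainly truncated normal away from its
    location parameter (noticeably so for groups near a boundary), so the
    location is moment-matched by root finding.  Degenerate SD returns the
    mean exactly.
    """
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))

    def mean_gap(loc):
        a, b = (lo - loc) / sd, (np.clip(hi, None, 1e12) - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    lo_loc, hi_loc = mean - 10 * sd, mean + 10 * sd
    try:
        loc = brentq(mean_gap, lo_loc, hi_loc, xtol=1e-12)
    except ValueError:  # target mean unreachable within bracket; fall back
        loc = mean
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def generate_sections(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate per-ROI stain tables and vessel cross-sections.

    Returns ``(sections, vessels, ground_truth)`` where the frames use the
    same CSV schemas the histology readers consume and the ground truth
    echoes the configured group means/SDs.
    """
    rng = np.random.default_rng(config.seed)
    n_sections = {
        "sensitive": config.sections_sensitive,
        "resistant": config.sections_resistant,
    }
    rows = []
    for (marker, line, treated), (mean, sd) in sorted(
        config.marker_stats.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
    ):
        for section in range(1, n_sections[line] + 1):
            fracs = _truncated_normal(
                rng, mean, sd, 0.0, 1.0, config.rois_per_section
            )
            for roi, frac in enumerate(fracs, start=1):
                stained = round(frac * config.roi_total_area_px)
                rows.append(
                    {
                        "line": line,
                        "treated": treated,
                        "section_index": section,
                        "roi_index": roi,
                        "marker": marker,
                        "stained_area": stained,
                        "total_area": config.roi_total_area_px,
                    }
                )
    sections = pd.DataFrame(rows)

    vrows = []
    for line in ("sensitive", "resistant"):
        for section in range(1, n_sections[line] + 1):
            classes = np.where(
                rng.random(config.vessels_per_section) < config.capillary_fraction,
                "capillary",
                "vein",
            )
            for vid, vclass in enumerate(classes, start=1):
                diam = (
                    config.capillary_diameter_um
                    if vclass == "capillary"
                    else config.vein_diameter_um
                )
                sd = diam * config.vessel_extent_cv
                e1, e2 = _truncated_normal(rng, diam, sd, 0.5, np.inf, 2)
                vrows.append(
                    {
                        "line": line,
                        "section_index": section,
                        "vessel_id": vid,
                        "extent1_um": float(e1),
                        "extent2_um": float(e2),
                        "vessel_class": vclass,
                    }
                )
    vessels = pd.DataFrame(vrows)

    truth = {
        "config": config.to_dict(),
        "marker_means": {
            f"{m}|{line}|{int(treated)}": mean
            for (m, line, treated), (mean, _) in config.marker_stats.items()
        },
    }
    return sections, vessels, truth


def generate_kill_dataset(config: SyntheticConfig) -> tuple[KillDataset, dict]:
    """Generate the 11-point (BVF, dead fraction) kill dataset, pre-rescaling.

    Sensitive sections carry the model's kill fraction at the true
    parameters plus noise; resistant sections carry the model value divided
    by the in-vitro kill ratio (their cells die less per delivered drug),
    plus noise.  Values are clipped to [0, 1].
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bvf_support
    points = []
    truth_rows = []
    for line, n, scale in (
        ("sensitive", config.sections_sensitive, 1.0),
        ("resistant", config.sections_resistant, 1.0 / config.kill_ratio),
    ):
        bvfs = _truncated_normal(rng, config.bvf_mean, config.bvf_sd, lo, hi, n)
        noiseless = (
            config.true_fkill_m
            * kill_fraction_scaled(bvfs, config.true_rb_over_L)
            * scale
        )
        noise = (
            rng.normal(0.0, config.dead_noise_sd, n)
            if config.dead_noise_sd > 0
            else np.zeros(n)
        )
        dead = np.clip(noiseless + noise, 0.0, 1.0)
        for i, (b, d, nl) in enumerate(zip(bvfs, dead, noiseless), start=1):
            points.append(
                KillPoint(
                    line=line, section_index=i, bvf=float(b), dead_fraction=float(d)
                )
            )
            truth_rows.append(
                {
                    "line": line,
                    "section_index": i,
                    "bvf": float(b),
                    "noiseless_dead_fraction": float(nl),
                }
            )
    truth = {
        "true_fkill_m": config.true_fkill_m,
        "true_rb_over_L": config.true_rb_over_L,
        "kill_ratio": config.kill_ratio,
        "points": truth_rows,
    }
    return KillDataset(tuple(points)), truth


def generate_dose_response(
    config: SyntheticConfig,
) -> tuple[dict[str, DoseResponseCurve], dict]:
    """Generate a 3x serial-dilution viability curve per line (ascending)."""
    rng = np.random.default_rng(config.seed)
    conc = config.top_concentration_nM / config.dilution_factor ** np.arange(
        config.n_dilutions
    )
    conc = np.sort(conc)
    curves = {}
    truth = {"concentrations_nM": conc.tolist(), "ic50_nM": {}}
    for line, ic50 in (
        ("sensitive", config.ic50_sensitive_nM),
        ("resistant", config.ic50_resistant_nM),
    ):
        viability = 1.0 / (1.0 + (conc / ic50) ** config.hill_slope)
        if config.dose_noise_sd > 0:
            viability = viability + rng.normal(
                0.0, config.dose_noise_sd, conc.size
            )
        curves[line] = DoseResponseCurve(
            concentrations_nM=conc,
            viability=np.clip(viability, 0.0, 1.0),
            line=line,
        )
        truth["ic50_nM"][line] = ic50
    return curves, truth
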