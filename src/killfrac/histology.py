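"""Histology-derived model parameters and marker summaries.

Starting point is tabulated immunohistochemistry (IHC) measurements: per
region-of-interest (ROI) stained vs total tissue area for each marker
(necrosis by H&E, apoptosis by Caspase-3, vessels by CD31, hypoxia by HIF-1a,
proliferation by Ki-67), plus vessel cross-section extents in micrometres.
From these the module computes stain fractions, per-group marker summaries
(mean +/- sample SD), treated/untreated fold changes, and the three
physiological model parameters: blood volume fraction (from CD31), vessel
radius r_b (from orthogonal cross-section extents) and the drug penetration
distance L (from vessel-to-hypoxia-onset distances, halved relative to the
oxygen penetration distance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MARKERS",
    "RoiStainMeasurement",
    "VesselCrossSection",
    "MarkerSummary",
    "ParameterEstimate",
    "stain_fraction",
    "summarize_markers",
    "marker_ratio",
    "estimate_bvf",
    "estimate_vessel_radius",
    "estimate_penetration_distance",
    "read_sections",
    "read_vessels",
    "summaries_to_frame",
]

logger = logging.getLogger(__name__)

MARKERS = ("necrosis", "apoptosis", "cd31", "hif1a", "ki67")
LINES = ("sensitive", "resistant")
#: study design: drug-sensitive tumors shrink under treatment and yield one
#: fewer section set than drug-resistant tumors
MAX_SECTIONS = {"sensitive": 5, "resistant": 6}


@dataclass(frozen=True)
class RoiStainMeasurement:
    """Stained vs total area for one marker in one ROI of one section."""

    line: str
    treated: bool
    section_index: int
    roi_index: int
    marker: str
    stained_area: float
    total_area: float

    def __post_init__(self) -> None:
        if self.line not in LINES:
            raise ValueError(f"unknown line {self.line!r}")
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")
        if self.total_area <= 0:
            raise ValueError("total_area must be positive")
        if self.stained_area < 0 or self.stained_area > self.total_area:
            raise ValueError("stained_area must lie in [0, total_area]")
        if self.section_index > MAX_SECTIONS[self.line]:
            logger.warning(
                "section_index %d exceeds the study design's %d sections for "
                "the %s line",
                self.section_index,
                MAX_SECTIONS[self.line],
                self.line,
            )


@dataclass(frozen=True)
class VesselCrossSection:
    """Two orthogonal extent measurements of one vessel cross-section (um)."""

    extent_1: float
    extent_2: float
    vessel_class: str = "capillary"

    def __post_init__(self) -> None:
        if self.extent_1 <= 0 or self.extent_2 <= 0:
            raise ValueError("vessel extents must be positive")
        if self.vessel_class not in ("capillary", "vein"):
            raise ValueError(f"unknown vessel_class {self.vessel_class!r}")


@dataclass(frozen=True)
class MarkerSummary:
    """Mean +/- sample SD of per-ROI stain fractions for one group."""

    marker: str
    line: str
    treated: bool
    mean_fraction: float
    sd_fraction: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_fraction <= 1.0:
            raise ValueError("mean_fraction must lie in [0, 1]")
        if self.sd_fraction < 0:
            raise ValueError("sd_fraction must be non-negative")


class ParameterEstimate(NamedTuple):
    """A mean +/- sample-SD estimate over n measurements."""

    mean: float
    sd: float
    n: int


def stain_fraction(m: RoiStainMeasurement) -> float:
    """Ratio of stained to total (stained + unstained) tissue area."""
    return m.stained_area / m.total_area


def summarize_markers(rows: Iterable[RoiStainMeasurement]) -> list[MarkerSummary]:
    """Group ROIs by (marker, line, treated) and report mean, sample SD, n.

    Sample (n-1) standard deviation; a single-ROI group reports SD 0.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("no measurements to summarize")
    frame = pd.DataFrame(
        {
            "marker": [r.marker for r in rows],
            "line": [r.line for r in rows],
            "treated": [r.treated for r in rows],
            "fraction": [stain_fraction(r) for r in rows],
        }
    )
    out: list[MarkerSummary] = []
    for (marker, line, treated), grp in frame.groupby(
        ["marker", "line", "treated"], sort=True
    ):
        vals = grp["fraction"].to_numpy()
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out.append(
            MarkerSummary(
                marker=marker,
                line=line,
                treated=bool(treated),
                mean_fraction=float(vals.mean()),
                sd_fraction=sd,
                n=int(vals.size),
            )
        )
    return out


def marker_ratio(a: MarkerSummary, b: MarkerSummary) -> float:
    """Fold change of group ``a`` over group ``b`` for the same marker."""
    if a.marker != b.marker:
        raise ValueError(
            f"cannot compare different markers: {a.marker!r} vs {b.marker!r}"
        )
    if b.mean_fraction <= 0:
        raise ZeroDivisionError(
            "denominator group mean is zero; apply a floor or exclude the group"
        )
    return a.mean_fraction / b.mean_fraction


def estimate_bvf(cd31_fraction: float, correction: float = 1.0) -> float:
    """Blood volume fraction from the CD31 stained-area fraction.

    BVF is taken proportional to vascular density; the default correction of
    1 maps the CD31 fraction to BVF directly.  A different factor can express
    a lumen-vs-endothelium correction.  Results above 1 are clamped.
    """
    if not 0.0 <= cd31_fraction <= 1.0:
        raise ValueError("cd31_fraction must lie in [0, 1]")
    if correction <= 0:
        raise ValueError("correction must be positive")
    bvf = cd31_fraction * correction
    if bvf > 1.0:
        logger.warning("estimated BVF %.3f exceeds 1; clamping", bvf)
        return 1.0
    return bvf


def estimate_vessel_radius(
    vessels: Sequence[VesselCrossSection],
) -> ParameterEstimate:
    """Mean vessel radius r_b (um) from orthogonal cross-section extents.

    The extents are diameters; each vessel's radius is the mean of the two
    orthogonal extents divided by 2, i.e. ``(e1 + e2) / 4``.
    """
    if not vessels:
        raise ValueError("no vessel cross-sections provided")
    radii = np.array([(v.extent_1 + v.extent_2) / 4.0 for v in vessels])
    sd = float(np.std(radii, ddof=1)) if radii.size > 1 else 0.0
    return ParameterEstimate(float(radii.mean()), sd, int(radii.size))


def estimate_penetration_distance(
    hypoxia_distances_um: Sequence[float], o2_halving: float = 0.5
) -> ParameterEstimate:
    """Drug penetration distance L (um) from vessel-to-hypoxia-onset distances.

    The hypoxia-onset distance measures how far oxygen penetrates; the drug,
    being a larger molecule, is assumed in the best case to penetrate at most
    a fraction ``o2_halving`` (default one half) of that distance.
    """
    d = np.asarray(hypoxia_distances_um, dtype=float)
    if d.size == 0:
        raise ValueError("no hypoxia-onset distances provided")
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return ParameterEstimate(o2_halving * float(d.mean()), o2_halving * sd, int(d.size))


# ---------------------------------------------------------------------------
# CSV interfaces


def read_sections(path) -> list[RoiStainMeasurement]:
    """Read a sections table (line, treated, section_index, roi_index, marker,
    stained_area, total_area) into validated measurements."""
    frame = pd.read_csv(path)
    required = {
        "line",
        "treated",
        "section_index",
        "roi_index",
        "marker",
        "stained_area",
        "total_area",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"sections table missing columns: {sorted(missing)}")
    return [
        RoiStainMeasurement(
            line=row.line,
            treated=bool(row.treated),
            section_index=int(row.section_index),
            roi_index=int(row.roi_index),
            marker=row.marker,
            stained_area=float(row.stained_area),
            total_area=float(row.total_area),
        )
        for row in frame.itertuples()
    ]


def read_vessels(path) -> list[VesselCrossSection]:
    """Read a vessels table (extent1_um, extent2_um, vessel_class, ...)."""
    frame = pd.read_csv(path)
    required = {"extent1_um", "extent2_um", "vessel_class"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"vessels table missing columns: {sorted(missing)}")
    return [
        VesselCrossSection(
            extent_1=float(row.extent1_um),
            extent_2=float(row.extent2_um),
            vessel_class=row.vessel_class,
        )
        for row in frame.itertuples()
    ]


def summaries_to_frame(summaries: Sequence[MarkerSummary]) -> pd.DataFrame:
    """Marker summaries as a tidy DataFrame (one row per marker x group)."""
    return pd.DataFrame(
        {
            "marker": [s.marker for s in summaries],
            "line": [s.line for s in summaries],
            "treated": [s.treated for s in summaries],
            "mean_fraction": [s.mean_fraction for s in summaries],
            "sd_fraction": [s.sd_fraction for s in summaries],
            "n": [s.n for s in summaries],
        }
    )
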