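"""Histology: stain fractions, marker summaries, fold changes, parameters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from killfrac import (
    MarkerSummary,
    RoiStainMeasurement,
    SyntheticConfig,
    VesselCrossSection,
    estimate_bvf,
    estimate_penetration_distance,
    estimate_vessel_radius,
    generate_sections,
    marker_ratio,
    stain_fraction,
    summarize_markers,
)


def roi(marker="necrosis", line="sensitive", treated=True, section=1, roi_i=1,
        stained=121, total=1000):
    return RoiStainMeasurement(
        line=line, treated=treated, section_index=section, roi_index=roi_i,
        marker=marker, stained_area=stained, total_area=total,
    )


class TestStainFraction:
    @pytest.mark.parametrize(
        "stained,total,expected",
        [(0, 1000, 0.0), (500, 1000, 0.5), (121, 1000, 0.121)],
    )
    def test_ratio_of_stained_to_total(self, stained, total, expected):
        assert stain_fraction(roi(stained=stained, total=total)) == pytest.approx(
            expected
        )

    @settings(max_examples=50, derandomize=True)
    @given(
        stained=st.integers(0, 10**6),
        total=st.integers(1, 10**6),
        k=st.floats(0.01, 1e4),
    )
    def test_scale_invariance(self, stained, total, k):
        stained = min(stained, total)
        f1 = stain_fraction(roi(stained=stained, total=total))
        f2 = stain_fraction(roi(stained=stained * k, total=total * k))
        assert f2 == pytest.approx(f1, rel=1e-12)

    def test_zero_total_area_rejected(self):
        with pytest.raises(ValueError):
            roi(stained=0, total=0)

    def test_stained_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            roi(stained=1001, total=1000)


class TestSummarizeMarkers:
    def test_single_row_group(self):
        (s,) = summarize_markers([roi()])
        assert s.mean_fraction == pytest.approx(0.121)
        assert s.sd_fraction == 0.0
        assert s.n == 1

    def test_two_row_sample_sd(self):
        rows = [roi(stained=100, roi_i=1), roi(stained=300, roi_i=2)]
        (s,) = summarize_markers(rows)
        assert s.mean_fraction == pytest.approx(0.2)
        assert s.sd_fraction == pytest.approx(0.1414, abs=1e-4)

    def test_groups_are_marker_line_treated(self):
        rows = [
            roi(marker="necrosis"),
            roi(marker="cd31"),
            roi(marker="necrosis", treated=False),
            roi(marker="necrosis", line="resistant"),
        ]
        summaries = summarize_markers(rows)
        keys = {(s.marker, s.line, s.treated) for s in summaries}
        assert len(summaries) == 4 and len(keys) == 4

    def test_recovers_generator_group_means(self):
        """Sampling check: many ROIs recover the configured group mean."""
        cfg = SyntheticConfig(seed=7, rois_per_section=120)
        sections, _, _ = generate_sections(cfg)
        rows = [
            RoiStainMeasurement(
                line=r.line, treated=bool(r.treated),
                section_index=int(r.section_index), roi_index=int(r.roi_index),
                marker=r.marker, stained_area=float(r.stained_area),
                total_area=float(r.total_area),
            )
            for r in sections.itertuples()
        ]
        summaries = {
            (s.marker, s.line, s.treated): s for s in summarize_markers(rows)
        }
        for key, (mean, sd) in cfg.marker_stats.items():
            s = summaries[key]
            tol = max(3 * sd / np.sqrt(s.n), 1e-9)
            assert abs(s.mean_fraction - mean) < tol, key


class TestMarkerRatio:
    def make(self, mean, treated=True, marker="necrosis", line="sensitive"):
        return MarkerSummary(marker, line, treated, mean, 0.01, 15)

    def test_treated_over_untreated_necrosis_fold(self):
        ratio = marker_ratio(self.make(0.121), self.make(0.005, treated=False))
        assert ratio == pytest.approx(24.2)
        assert round(ratio) == 24

    def test_untreated_over_treated_apoptosis_fold(self):
        a = self.make(0.207, treated=False, marker="apoptosis", line="resistant")
        b = self.make(0.051, treated=True, marker="apoptosis", line="resistant")
        ratio = marker_ratio(a, b)
        assert ratio == pytest.approx(4.0588, abs=1e-3)
        assert round(ratio) == 4

    def test_equal_means_give_unity(self):
        assert marker_ratio(self.make(0.1), self.make(0.1, False)) == 1.0

    def test_reciprocal_pairs_multiply_to_one(self):
        a, b = self.make(0.3), self.make(0.07, treated=False)
        assert marker_ratio(a, b) * marker_ratio(b, a) == pytest.approx(1.0)

    def test_marker_mismatch_rejected(self):
        with pytest.raises(ValueError, match="marker"):
            marker_ratio(self.make(0.1), self.make(0.1, marker="cd31"))

    def test_zero_denominator_advises(self):
        with pytest.raises(ZeroDivisionError, match="floor"):
            marker_ratio(self.make(0.1), self.make(0.0, treated=False))


class TestParameterEstimates:
    def test_bvf_identity_mapping(self):
        assert estimate_bvf(0.031) == pytest.approx(0.031)
        assert estimate_bvf(0.0, 5.0) == 0.0

    def test_bvf_correction_factor(self):
        assert estimate_bvf(0.045, 1.5) == pytest.approx(0.0675)

    def test_bvf_clamped_at_one(self):
        assert estimate_bvf(0.9, 2.0) == 1.0

    @pytest.mark.parametrize(
        "e1,e2,expected",
        [(10, 10, 5.0), (20, 20, 10.0), (8, 12, 5.0)],
    )
    def test_radius_from_orthogonal_diameters(self, e1, e2, expected):
        est = estimate_vessel_radius([VesselCrossSection(e1, e2)])
        assert est.mean == pytest.approx(expected)
        assert est.sd == 0.0

    def test_radius_mean_and_sd_over_vessels(self):
        vessels = [VesselCrossSection(10, 10), VesselCrossSection(20, 20, "vein")]
        est = estimate_vessel_radius(vessels)
        assert est.mean == pytest.approx(7.5)
        assert est.sd == pytest.approx(np.std([5.0, 10.0], ddof=1))

    def test_penetration_distance_halves_hypoxia_onset(self):
        est = estimate_penetration_distance([80.0, 80.0, 80.0])
        assert est.mean == pytest.approx(40.0)

    def test_penetration_identity_factor(self):
        est = estimate_penetration_distance([80.0], o2_halving=1.0)
        assert est.mean == pytest.approx(80.0)

    def test_penetration_sd_scaled_identically(self):
        est = estimate_penetration_distance([60.0, 100.0])
        assert est.mean == pytest.approx(40.0)
        assert est.sd == pytest.approx(0.5 * np.std([60, 100], ddof=1))

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_vessel_radius([])
        with pytest.raises(ValueError):
            estimate_penetration_distance([])
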