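"""Model core: concentration profile, closed-form kill fraction, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_bvp
from scipy.special import k0

from killfrac import (
    ModelParams,
    TissueGeometry,
    concentration_profile,
    kill_fraction,
    kill_fraction_oracle,
    kill_fraction_scaled,
    predict_curve,
    scaled_concentration,
)


class TestModelParams:
    def test_rb_over_L_is_ratio_of_lengths(self):
        p = ModelParams(bvf=0.038, rb_um=5.0, L_um=40.0, fkill_m=0.25)
        assert p.rb_over_L == pytest.approx(0.125)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(bvf=0.0, rb_um=5, L_um=40, fkill_m=0.25),
            dict(bvf=1.0, rb_um=5, L_um=40, fkill_m=0.25),
            dict(bvf=0.04, rb_um=-1, L_um=40, fkill_m=0.25),
            dict(bvf=0.04, rb_um=5, L_um=0, fkill_m=0.25),
            dict(bvf=0.04, rb_um=5, L_um=40, fkill_m=1.2),
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_diffusivity_uptake_consistency_enforced(self):
        # L = sqrt(D / lambda): 40 = sqrt(160/0.1)
        ModelParams(0.04, 5, 40, 0.25, D_um2_s=160.0, lambda_per_s=0.1)
        with pytest.raises(ValueError, match="inconsistent"):
            ModelParams(0.04, 5, 40, 0.25, D_um2_s=160.0, lambda_per_s=0.2)

    def test_tissue_geometry_from_bvf(self):
        p = ModelParams(bvf=0.04, rb_um=5, L_um=40, fkill_m=0.25)
        geom = TissueGeometry.from_params(p)
        assert geom.rt_scaled == pytest.approx(p.rb_over_L / 0.2)
        assert geom.rt_scaled > geom.rb_scaled


class TestScaledConcentration:
    def test_equals_one_at_vessel_wall(self):
        assert scaled_concentration(0.068, 0.068) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_decreasing_with_radius(self):
        r = np.linspace(0.068, 10.0, 500)
        c = scaled_concentration(r, 0.068)
        assert np.all(np.diff(c) < 0)
        assert np.all((c > 0) & (c <= 1))

    def test_matches_boundary_value_ode_solve(self):
        """Independent oracle: solve (1/r)(r sigma')' = sigma on [rb, 20]."""
        rb = 0.068

        def odes(r, y):
            return np.vstack([y[1], y[0] - y[1] / r])

        def bc(ya, yb):
            return np.array([ya[0] - 1.0, yb[0] - k0(20.0) / k0(rb)])

        r = np.linspace(rb, 20.0, 2000)
        guess = np.vstack([np.exp(-(r - rb)), -np.exp(-(r - rb))])
        sol = solve_bvp(odes, bc, r, guess, tol=1e-8, max_nodes=100000)
        assert sol.status == 0
        bvp_value = float(sol.sol(0.3)[0])
        assert scaled_concentration(0.3, rb) == pytest.approx(bvp_value, rel=1e-6)
        # frozen value from the same oracle, guarding against silent drift
        assert bvp_value == pytest.approx(0.4886672127, rel=1e-6)

    def test_domain_errors_name_offender(self):
        with pytest.raises(ValueError, match="r_scaled"):
            scaled_concentration(0.05, 0.068)
        with pytest.raises(ValueError, match="rb_over_L"):
            scaled_concentration(0.3, -1.0)

    def test_profile_container_validates(self):
        prof = concentration_profile(0.068)
        assert prof.normalized_concentration[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(prof.normalized_concentration) < 0)


class TestKillFraction:
    def test_zero_invitro_kill_gives_zero(self):
        p = ModelParams(bvf=0.04, rb_um=5, L_um=40, fkill_m=0.0)
        assert kill_fraction(p) == 0.0

    def test_full_vascularization_limit(self):
        p = ModelParams(bvf=1 - 1e-9, rb_um=0.068, L_um=1.0, fkill_m=0.25)
        assert kill_fraction(p) == pytest.approx(0.25, abs=1e-6)

    def test_matches_quadrature_at_study_parameters(self):
        p = ModelParams(bvf=0.04, rb_um=0.068, L_um=1.0, fkill_m=0.25)
        oracle = kill_fraction_oracle(p, tol=1e-10)
        assert kill_fraction(p) == pytest.approx(oracle, rel=1e-6)
        # frozen quadrature value for the same point
        assert oracle == pytest.approx(0.1481701741, rel=1e-8)

    def test_oracle_equivalence_over_grid(self, bvf_grid, rb_grid):
        """Central equivalence: closed form vs adaptive quadrature, 24 points."""
        for bvf in bvf_grid:
            for rb in rb_grid:
                p = ModelParams(bvf=bvf, rb_um=rb, L_um=1.0, fkill_m=0.25)
                closed = kill_fraction(p)
                oracle = kill_fraction_oracle(p, tol=1e-10)
                assert abs(closed - oracle) / oracle <= 1e-6, (bvf, rb)

    def test_oracle_trivial_limits(self):
        assert kill_fraction_oracle(
            ModelParams(0.04, 0.068, 1.0, 0.0)
        ) == pytest.approx(0.0, abs=1e-15)
        assert kill_fraction_oracle(
            ModelParams(1 - 1e-9, 0.068, 1.0, 0.25)
        ) == pytest.approx(0.25, abs=1e-6)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        bvf=st.floats(0.001, 0.999),
        rb=st.floats(0.001, 5.0),
        fm=st.floats(0.0, 1.0),
    )
    def test_bounded_by_invitro_kill(self, bvf, rb, fm):
        p = ModelParams(bvf=bvf, rb_um=rb, L_um=1.0, fkill_m=fm)
        f = kill_fraction(p)
        assert 0.0 <= f <= fm + 1e-12

    def test_monotone_increasing_in_bvf(self):
        bvfs = np.linspace(0.005, 0.9, 100)
        f = kill_fraction_scaled(bvfs, 0.068)
        assert np.all(np.diff(f) > 0)

    def test_monotone_decreasing_in_rb(self):
        rbs = np.linspace(0.01, 3.0, 100)
        f = kill_fraction_scaled(0.04, rbs)
        assert np.all(np.diff(f) < 0)

    def test_monotone_increasing_in_L(self):
        Ls = np.linspace(10.0, 100.0, 50)
        f = [
            kill_fraction(ModelParams(bvf=0.04, rb_um=5, L_um=L, fkill_m=0.25))
            for L in Ls
        ]
        assert np.all(np.diff(f) > 0)

    def test_limits_small_and_large_vessel_radius(self):
        # rb/L -> 0 at fixed bvf: whole annulus saturates toward fkill_m.
        # Convergence is logarithmic (K0 ~ -ln rb), so assert the monotone
        # approach over decades rather than proximity at a finite rb.
        vals = [
            kill_fraction(ModelParams(0.04, rb, 1.0, 0.25))
            for rb in (1e-2, 1e-4, 1e-6, 1e-8, 1e-12)
        ]
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] < 0.25 and vals[-1] > 0.93 * 0.25
        # rb/L -> inf: no penetration; decays ~ 2*bvf/((1-bvf)*rb), no NaN
        far = [
            kill_fraction(ModelParams(0.04, rb, 1.0, 0.25))
            for rb in (200.0, 2e3, 2e5)
        ]
        assert np.all(np.diff(far) < 0)
        assert 0.0 <= far[-1] < 1e-6

    def test_exactly_linear_in_fkill_m(self):
        base = kill_fraction(ModelParams(0.04, 0.068, 1.0, 0.5))
        half = kill_fraction(ModelParams(0.04, 0.068, 1.0, 0.25))
        assert half == 0.5 * base  # bitwise: same factor, scaled


class TestPredictCurve:
    def test_strictly_increasing_and_bounded(self):
        grid = np.linspace(0.01, 0.5, 40)
        f = predict_curve(0.25, 0.068, grid)
        assert np.all(np.diff(f) > 0)
        assert np.all(f <= 0.25)

    def test_zero_invitro_kill_gives_zeros(self):
        assert np.all(predict_curve(0.0, 0.068, np.linspace(0.01, 0.5, 10)) == 0)

    def test_elementwise_equals_oracle(self):
        grid = np.array([0.01, 0.05, 0.2])
        f = predict_curve(0.25, 0.068, grid)
        for fi, bvf in zip(f, grid):
            oracle = kill_fraction_oracle(ModelParams(bvf, 0.068, 1.0, 0.25))
            assert fi == pytest.approx(oracle, rel=1e-6)

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            predict_curve(0.25, 0.068, [0.2, 0.1])
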