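"""Forward-model physics: quadrature accuracy, limits, and analyses."""

import numpy as np
import pytest
from scipy import special

from fibrilscape.saxs_model import (
    SAXSModelParams,
    SAXSProfile,
    cross_section_guinier,
    cylinder_form_factor,
    distance_from_q,
    find_correlation_peak,
    lognormal_weights,
    model_intensity,
    powerlaw_slope,
    prism_structure_factor,
)


def _form_factor_oracle(q, r, L, n=10_000):
    """Brute-force trapezoid orientation average, independent of the
    Gauss-Legendre path under test."""
    a = np.linspace(1e-9, np.pi / 2, n)
    qr = q * r * np.sin(a)
    fcs = np.where(qr == 0, 1.0, 2 * special.j1(qr) / np.where(qr == 0, 1, qr))
    fl = np.sinc(0.5 * q * L * np.cos(a) / np.pi)
    return np.trapezoid((fcs * fl) ** 2 * np.sin(a), a)


class TestCylinderFormFactor:
    def test_q_to_zero_limit_is_one(self):
        assert cylinder_form_factor(1e-6, 4.0, 1000.0) == pytest.approx(1.0, abs=1e-4)

    def test_bounded_in_unit_interval(self):
        q = np.geomspace(1e-4, 3.0, 60)
        p = cylinder_form_factor(q, 5.0, 1000.0)
        assert np.all(p > 0) and np.all(p <= 1.0 + 1e-12)

    @pytest.mark.parametrize("q", [0.02, 0.1, 0.3, 1.0, 2.0])
    @pytest.mark.parametrize("r", [2.0, 4.0, 8.0])
    def test_agrees_with_trapezoid_oracle(self, q, r):
        got = cylinder_form_factor(q, r, 1000.0)
        want = _form_factor_oracle(q, r, 1000.0)
        assert got == pytest.approx(want, rel=1e-4)

    def test_rod_scaling_regime_has_unit_exponent(self):
        """A thin long rod scatters as q^-1 between 2pi/L and 1/(2r)."""
        r, L = 4.0, 1000.0
        q = np.geomspace(3 * 2 * np.pi / L, 1 / (2 * r), 40)
        p = cylinder_form_factor(q, r, L)
        fit = powerlaw_slope(SAXSProfile(q, p), q[0], q[-1])
        assert fit.alpha == pytest.approx(1.0, abs=0.15)

    def test_thin_rod_guard(self):
        with pytest.raises(ValueError, match="L >= 20 r"):
            cylinder_form_factor(0.1, 10.0, 100.0)

    def test_rejects_nonpositive_q(self):
        with pytest.raises(ValueError):
            cylinder_form_factor(0.0, 4.0, 1000.0)


class TestLognormalWeights:
    def test_weights_normalized(self):
        grid = np.geomspace(1.0, 40.0, 41)
        w = lognormal_weights(6.0, 0.25, grid)
        assert abs(w.sum() - 1.0) < 1e-9

    def test_weighted_median_tracks_r_median(self):
        grid = np.geomspace(2.0, 18.0, 81)
        w = lognormal_weights(6.0, 0.25, grid)
        med = grid[np.searchsorted(np.cumsum(w), 0.5)]
        step = grid[1] / grid[0]
        assert med / step <= 6.0 <= med * step

    def test_delta_limit_concentrates_on_nearest_point(self):
        grid = np.geomspace(3.0, 12.0, 41)
        w = lognormal_weights(6.0, 1e-7, grid)
        k = np.argmax(w)
        assert w[k] == pytest.approx(1.0)
        assert abs(np.log(grid[k] / 6.0)) == np.min(np.abs(np.log(grid / 6.0)))

    def test_rejects_grid_not_covering_mass(self):
        with pytest.raises(ValueError, match="4 sigma"):
            lognormal_weights(6.0, 0.5, np.geomspace(5.0, 7.0, 11))


class TestPrismStructureFactor:
    def test_no_interaction_gives_unity(self):
        q = np.geomspace(0.01, 2, 50)
        assert np.allclose(prism_structure_factor(q, 24.0, 0.0), 1.0)

    def test_high_q_limit(self):
        s = prism_structure_factor(200.0 / 24.0, 24.0, 1.0)
        assert abs(s - 1.0) < 0.01

    def test_suppressed_at_low_q_for_repulsive_nu(self):
        assert prism_structure_factor(1e-4, 24.0, 1.5) < 1.0

    def test_peak_lands_at_2pi_over_d(self):
        """Calibration contract: argmax of S is 2pi/d within 2% for any
        physical (nu, d)."""
        q = np.geomspace(0.01, 2.0, 4000)
        for nu in (0.5, 1.0, 3.0):
            for d in (10.0, 24.0, 40.0):
                s = prism_structure_factor(q, d, nu)
                q_max = q[np.argmax(s)]
                assert abs(2 * np.pi / q_max - d) / d <= 0.02

    def test_peak_near_reported_position_for_no_inhibitor_distance(self):
        """d = 24 nm puts the correlation peak at ~0.25 nm^-1."""
        q = np.geomspace(0.12, 0.4, 800)
        s = prism_structure_factor(q, 24.0, 1.0)
        q_max = q[np.argmax(s)]
        assert q_max == pytest.approx(0.25, rel=0.10)

    def test_rejects_attractive_and_unstable_nu(self):
        with pytest.raises(ValueError):
            prism_structure_factor(0.1, 24.0, -0.5)
        with pytest.raises(ValueError):
            prism_structure_factor(0.1, 24.0, 5.0)


class TestModelIntensity:
    def test_reduces_to_bare_form_factor(self, q_grid):
        p = SAXSModelParams(A=2.5, r=5.0, sigma_r=0.0, d=24.0, nu=0.0,
                            B=0.0, n_exp=0.0, C=0.0)
        got = model_intensity(q_grid, p)
        want = 2.5 * cylinder_form_factor(q_grid, 5.0, 1000.0)
        assert np.allclose(got, want, rtol=1e-3)

    def test_background_only_when_scale_zero(self, q_grid):
        p = SAXSModelParams(A=0.0, r=5.0, sigma_r=0.1, d=24.0, nu=1.0,
                            B=0.02, n_exp=1.7, C=3e-4)
        got = model_intensity(q_grid, p)
        assert np.allclose(got, 0.02 * q_grid ** -1.7 + 3e-4, rtol=1e-12)

    def test_radius_grid_refinement(self, q_grid, truth_params):
        """41-point polydispersity grid within 0.5% of a 2001-point one."""
        coarse = model_intensity(q_grid, truth_params)
        fine = model_intensity(q_grid, truth_params, _n_radii=2001)
        assert np.max(np.abs(coarse - fine) / fine) <= 5e-3

    def test_strictly_positive(self, q_grid, truth_params):
        assert np.all(model_intensity(q_grid, truth_params) > 0)

    def test_oracle_equivalence_with_polydispersity(self, truth_params):
        """Model values match a brute-force trapezoid quadrature over
        orientation at each radius of the polydispersity grid."""
        from fibrilscape.saxs_model import default_radius_grid
        q_pts = np.geomspace(0.05, 2.0, 12)
        radii = default_radius_grid(truth_params.r, truth_params.sigma_r)
        w = lognormal_weights(truth_params.r, truth_params.sigma_r, radii)
        p = truth_params
        for q in q_pts:
            poly = sum(wi * _form_factor_oracle(q, ri, p.L)
                       for ri, wi in zip(radii, w))
            want = (p.A * poly * prism_structure_factor(q, p.d, p.nu)
                    + p.B * q ** -p.n_exp + p.C)
            got = model_intensity(np.array([q]), p)[0]
            assert got == pytest.approx(want, rel=5e-3)

    def test_porod_regime_slope(self, truth_params):
        """High-q decay of the polydisperse form-factor term falls in
        [3, 4.3] (cross-section Porod region)."""
        q = np.geomspace(0.8, 2.5, 80)
        p = truth_params.replace(nu=0.0, B=0.0, C=0.0)
        fit = powerlaw_slope(SAXSProfile(q, model_intensity(q, p)), q[0], q[-1])
        assert 3.0 <= fit.alpha <= 4.3


class TestPowerLawSlope:
    def test_exact_power_laws(self, q_grid):
        for alpha in (1.0, 4.0):
            prof = SAXSProfile(q_grid, 2.0 * q_grid ** -alpha)
            fit = powerlaw_slope(prof, 0.06, 0.9)
            assert fit.alpha == pytest.approx(alpha, abs=1e-9)
            assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_dilute_long_cylinder_has_unit_exponent(self):
        q = np.geomspace(0.015, 0.12, 80)
        prof = SAXSProfile(q, cylinder_form_factor(q, 4.0, 1000.0))
        fit = powerlaw_slope(prof, 0.02, 0.1)
        assert fit.alpha == pytest.approx(1.0, abs=0.15)

    def test_needs_five_points(self, q_grid):
        prof = SAXSProfile(q_grid, q_grid ** -1.0)
        with pytest.raises(ValueError, match="5 points"):
            powerlaw_slope(prof, 0.05, 0.053)


class TestCorrelationPeak:
    def test_pure_structure_factor_round_trip(self, q_grid):
        for d in (20.0, 24.0):
            s = prism_structure_factor(q_grid, d, 1.0)
            pk = find_correlation_peak(np.column_stack([q_grid, s]),
                                       (0.12, 0.45))
            assert pk is not None
            assert pk.d_eff == pytest.approx(d, rel=0.02)

    def test_monotone_profile_yields_no_peak(self, q_grid, truth_params):
        p = truth_params.replace(nu=0.0)
        prof = SAXSProfile(q_grid, model_intensity(q_grid, p))
        assert find_correlation_peak(prof, (0.12, 0.4)) is None

    def test_shoulder_on_full_profile_detected(self, noiseless_profile):
        pk = find_correlation_peak(noiseless_profile, (0.12, 0.4))
        assert pk is not None

    def test_d_eff_is_2pi_over_qmax(self):
        assert distance_from_q(0.25) == pytest.approx(25.13, abs=0.01)


class TestCrossSectionGuinier:
    @pytest.mark.parametrize("r", [4.0, 6.0])
    def test_implied_radius_matches_cylinder(self, r):
        """For a homogeneous cylinder R_c = r/sqrt(2), so the implied
        radius equals the true radius."""
        q = np.geomspace(0.05, 0.8, 150)
        prof = SAXSProfile(q, cylinder_form_factor(q, r, 1000.0))
        fit = cross_section_guinier(prof, (0.1, 0.6))
        assert fit.implied_radius == pytest.approx(r, rel=0.05)
        assert fit.q_range[1] * fit.R_c <= 1.3 + 1e-9

    def test_flat_profile_rejected(self, q_grid):
        prof = SAXSProfile(q_grid, np.ones_like(q_grid))
        with pytest.raises(ValueError):
            cross_section_guinier(prof, (0.1, 0.5))


class TestProfileContainer:
    def test_rejects_disordered_q(self):
        with pytest.raises(ValueError):
            SAXSProfile(np.array([0.2, 0.1, 0.3]), np.ones(3))

    def test_rejects_nonpositive_q(self):
        with pytest.raises(ValueError):
            SAXSProfile(np.array([0.0, 0.1, 0.3]), np.ones(3))

    def test_params_invariants(self):
        with pytest.raises(ValueError):
            SAXSModelParams(r=-1.0)
        with pytest.raises(ValueError):
            SAXSModelParams(r=60.0, L=1000.0)  # violates L >= 20 r
        with pytest.raises(ValueError):
            SAXSModelParams(d=-5.0)
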