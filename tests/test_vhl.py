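"""Vortex-loop construction, orientation, area, branch distance, axes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vamkit import (
    VortexLoop,
    build_vortex_loop,
    compute_delta_r,
    compute_i,
    compute_vhl_parameters,
    compute_vips,
    compute_vti,
    estimate_baseline,
    fit_gamma_variate,
    loop_orientation,
    principal_axes,
    simulate_voxel,
)
from vamkit.relaxometry import GammaVariateFit, gamma_scale_from_peak, gamma_variate


def _fit_pair(truth, acq):
    ge, se = simulate_voxel(truth, acq)
    dr2s = compute_delta_r(ge, estimate_baseline(ge, acq.n_baseline), acq.te_ge)
    dr2 = compute_delta_r(se, estimate_baseline(se, acq.n_baseline), acq.te_se)
    return (fit_gamma_variate(dr2, acq.times),
            fit_gamma_variate(dr2s, acq.times))


def _circle(radius=1.0, center=(0.0, 0.0), clockwise=True, n=1000, closed=True):
    t = np.linspace(0, 2 * np.pi, n, endpoint=closed is False)
    t = -t if clockwise else t
    return np.column_stack([center[0] + radius * np.cos(t),
                            center[1] + radius * np.sin(t)])


def _ellipse(a, b, clockwise=True, n=10_000):
    t = np.linspace(0, 2 * np.pi, n)
    t = -t if clockwise else t
    return np.column_stack([a * np.cos(t), b * np.sin(t)])


class TestOrientation:
    def test_clockwise_circle_positive(self):
        assert loop_orientation(_circle(clockwise=True)) == +1

    def test_counterclockwise_circle_negative(self):
        assert loop_orientation(_circle(clockwise=False)) == -1

    def test_collinear_points_degenerate(self):
        pts = np.column_stack([np.linspace(0, 1, 50), np.linspace(0, 2, 50)])
        assert loop_orientation(pts) == 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            loop_orientation(np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_se_leading_ge_gives_counterclockwise(self, clean_truth, acq):
        # spin echo peaks 0.4 s before gradient echo in the default truth
        fit_se, fit_ge = _fit_pair(clean_truth, acq)
        loop = build_vortex_loop(fit_se, fit_ge)
        assert loop.orientation == -1

    def test_time_reversal_flips_orientation(self, clean_truth, acq):
        fit_se, fit_ge = _fit_pair(clean_truth, acq)
        loop = build_vortex_loop(fit_se, fit_ge)
        rev = VortexLoop.from_points(loop.points[::-1])
        assert rev.orientation == -loop.orientation


class TestLoopConstruction:
    def test_identical_fits_collapse_to_diagonal(self, acq):
        times = acq.times
        a = gamma_scale_from_peak(10.0, 3.0, 2.0)
        curve = gamma_variate(times, a, 16.0, 3.0, 2.0)
        fit = fit_gamma_variate(curve, times)
        loop = build_vortex_loop(fit, fit)
        assert loop.orientation == 0
        assert compute_vti(loop) == 0.0
        assert compute_i(loop) == 0.0

    def test_invalid_fit_yields_no_loop(self, acq):
        good = fit_gamma_variate(
            gamma_variate(acq.times, 1.0, 16.0, 3.0, 2.0), acq.times)
        bad = GammaVariateFit.invalid(acq.times)
        assert build_vortex_loop(good, bad) is None
        params = compute_vhl_parameters(good, bad)
        assert all(np.isnan(v) for v in vars(params).values())

    def test_loop_is_dense_and_closed(self, clean_truth, acq):
        fit_se, fit_ge = _fit_pair(clean_truth, acq)
        loop = build_vortex_loop(fit_se, fit_ge)
        assert len(loop.points) >= 200
        assert np.allclose(loop.points[-1], [0.0, 0.0])
        assert np.hypot(*loop.points[0]) < 1e-6


class TestVTI:
    def test_ellipse_area_matches_pi_ab(self):
        loop = VortexLoop.from_points(_ellipse(3.0, 1.0, clockwise=True))
        vti = compute_vti(loop)
        assert vti > 0
        assert vti == pytest.approx(3 * np.pi, rel=1e-3)

    def test_counterclockwise_ellipse_negative(self):
        loop = VortexLoop.from_points(_ellipse(3.0, 1.0, clockwise=False))
        assert compute_vti(loop) == pytest.approx(-3 * np.pi, rel=1e-3)

    def test_matches_greens_theorem_integration(self, clean_truth, acq):
        """|area| from the shoelace sum equals the contour integral of x dy."""
        fit_se, fit_ge = _fit_pair(clean_truth, acq)
        loop = build_vortex_loop(fit_se, fit_ge,
                                 grid=np.linspace(fit_se.t0, acq.duration, 2000))
        x, y = loop.points[:, 0], loop.points[:, 1]
        greens = abs(np.sum(0.5 * (x[1:] + x[:-1]) * np.diff(y)))
        assert abs(compute_vti(loop)) == pytest.approx(greens, rel=1e-3)

    def test_healthy_tissue_voxel_negative(self, clean_truth, acq):
        fit_se, fit_ge = _fit_pair(clean_truth, acq)
        assert compute_vti(build_vortex_loop(fit_se, fit_ge)) < 0


class TestDistanceMapI:
    def test_circle_branch_distance_is_diameter(self):
        # circle through the origin: split lands at the far point, the
        # branches are the upper and lower semicircles
        t = -np.linspace(0, 2 * np.pi, 1000)  # clockwise, starting at origin
        pts = np.column_stack([1.0 + np.cos(np.pi + t), np.sin(np.pi + t)])
        loop = VortexLoop.from_points(pts)
        assert abs(compute_i(loop)) == pytest.approx(2.0, rel=1e-3)
        assert compute_i(loop) > 0  # clockwise loop -> positive sign

    def test_monotone_in_echo_lag(self, clean_truth, acq):
        """|I| grows with the SE-GE peak-time lag, all else equal."""
        lags = [0.2, 0.6, 1.2]
        magnitudes = []
        for lag in lags:
            truth = clean_truth.replace(ttp_se=clean_truth.ttp_ge - lag)
            fit_se, fit_ge = _fit_pair(truth, acq)
            magnitudes.append(abs(compute_i(build_vortex_loop(fit_se, fit_ge))))
        assert magnitudes[0] < magnitudes[1] < magnitudes[2]


class TestPrincipalAxes:
    def test_collinear_segment(self):
        # segment of length 5 with slope 2
        t = np.linspace(0, 1, 101)
        seg = np.column_stack([t * 5 / np.sqrt(5), t * 10 / np.sqrt(5)])
        loop = VortexLoop(points=seg, orientation=0, peak_split_index=50)
        bvf, cgi, cbi = principal_axes(loop)
        assert bvf == pytest.approx(5.0, rel=1e-9)
        assert cgi == pytest.approx(2.0, abs=1e-9)
        assert cbi == pytest.approx(0.0, abs=1e-9)

    def test_axis_aligned_ellipse(self):
        loop = VortexLoop.from_points(_ellipse(3.0, 1.0))
        bvf, cgi, cbi = principal_axes(loop)
        assert bvf == pytest.approx(6.0, rel=1e-6)
        assert cbi == pytest.approx(2.0, rel=1e-6)
        assert cgi == pytest.approx(0.0, abs=1e-9)

    def test_rotation_leaves_axis_lengths_invariant(self):
        pts = _ellipse(3.0, 1.0)
        loop = VortexLoop.from_points(pts)
        bvf0, _, cbi0 = principal_axes(loop)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        loop_r = VortexLoop.from_points(pts @ rot.T)
        bvf1, _, cbi1 = principal_axes(loop_r)
        assert abs(bvf1 - bvf0) < 1e-9
        assert abs(cbi1 - cbi0) < 1e-9


class TestVIPS:
    def test_identical_fits_zero(self, acq):
        fit = fit_gamma_variate(
            gamma_variate(acq.times, 1.0, 16.0, 3.0, 2.0), acq.times)
        assert compute_vips(fit, fit) == 0.0

    def test_definition(self, acq):
        def _mk(ttp):
            a = gamma_scale_from_peak(10.0, 3.0, 2.0)
            return fit_gamma_variate(
                gamma_variate(acq.times, a, ttp - 6.0, 3.0, 2.0), acq.times)
        fit_se, fit_ge = _mk(30.0), _mk(31.5)
        assert compute_vips(fit_se, fit_ge) == pytest.approx(-1.5, abs=1e-6)


class TestSignCoherence:
    @pytest.mark.parametrize("lag,expected", [(-0.4, -1), (+0.4, +1)])
    def test_all_signed_parameters_agree_with_orientation(
            self, clean_truth, acq, lag, expected):
        """SE leading (negative lag) makes orientation, I, VTI, VIPS all
        negative simultaneously; GE leading flips all three."""
        truth = clean_truth.replace(ttp_se=clean_truth.ttp_ge + lag)
        fit_se, fit_ge = _fit_pair(truth, acq)
        loop = build_vortex_loop(fit_se, fit_ge)
        assert loop.orientation == expected
        assert np.sign(compute_vti(loop)) == expected
        assert np.sign(compute_i(loop)) == expected
        assert np.sign(compute_vips(fit_se, fit_ge)) == expected

    @given(st.floats(0.2, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, c):
        """Scaling both curves by c scales I, BVF, CBI by c and VTI by c^2,
        and leaves CGI unchanged."""
        pts = _ellipse(3.0, 1.0, n=2000) + np.array([4.0, 5.0])
        loop = VortexLoop.from_points(pts)
        loop_c = VortexLoop.from_points(pts * c)
        assert compute_vti(loop_c) == pytest.approx(c**2 * compute_vti(loop),
                                                    rel=1e-9)
        assert compute_i(loop_c) == pytest.approx(c * compute_i(loop), rel=1e-6)
        bvf, cgi, cbi = principal_axes(loop)
        bvf_c, cgi_c, cbi_c = principal_axes(loop_c)
        assert bvf_c == pytest.approx(c * bvf, rel=1e-9)
        assert cbi_c == pytest.approx(c * cbi, rel=1e-9)
        assert cgi_c == pytest.approx(cgi, rel=1e-9)
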