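"""Forward projection model and the three inverse height solvers."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hairbundle.geometry import (
    Bundle,
    GeometryError,
    ImageView,
    StereociliumGeometry,
    find_parallel_angle,
    reconstruct_bundle,
    render_projection,
    solve_height_known_parallel,
    solve_height_two_view,
    solve_row_height_front_view,
)
from hairbundle.synthetic import NoiseSpec, render_experiment, standard_views


def _single(h=2.4, alpha=10.0, d=0.4):
    s = StereociliumGeometry("s1", 1, h)
    return s, Bundle("b1", insertion_tilt_alpha=alpha, row_spacing_d=d,
                     stereocilia=[s])


class TestRenderProjection:
    @pytest.mark.parametrize("h,tau,expected", [
        (1.0, 90.0, 1.0),       # perpendicular view: p = h
        (2.4, 30.0, 1.2),       # p = h sin(tau)
        (1.7, 0.0, 0.0),        # beam parallel to the stereocilium
    ])
    def test_full_length_values(self, h, tau, expected):
        s, b = _single(h=h)
        view = ImageView(b.insertion_tilt_alpha + tau, "medial",
                         b.insertion_tilt_alpha)
        assert render_projection(s, b, view) == pytest.approx(expected, abs=1e-12)

    def test_step_requires_row1_reference(self):
        s2 = StereociliumGeometry("s2", 2, 1.4, base_offset=-0.4)
        b = Bundle("lonely", insertion_tilt_alpha=10, stereocilia=[s2])
        view = ImageView(50, "medial", 10)
        with pytest.raises(GeometryError, match="lonely"):
            render_projection(s2, b, view, "step_1_to_2")

    @given(tau=st.floats(1.0, 89.0), h=st.floats(0.1, 5.0))
    @settings(derandomize=True, max_examples=50)
    def test_full_length_monotone_in_tau_and_h(self, tau, h):
        s, b = _single(h=h)
        alpha = b.insertion_tilt_alpha

        def p(t):
            return render_projection(s, b, ImageView(alpha + t, "medial", alpha))

        assert p(tau) < p(min(tau + 0.5, 90.0)) or tau + 0.5 > 90.0
        s_tall, b_tall = _single(h=h + 0.1)
        assert render_projection(
            s_tall, b_tall, ImageView(alpha + tau, "medial", alpha)) > p(tau)


class TestTwoViewSolver:
    def test_forward_model_round_trip(self):
        p1 = 2.4 * math.sin(math.radians(10))
        p2 = 2.4 * math.sin(math.radians(30))
        h, alpha = solve_height_two_view(p1, p2, 20.0)
        assert h == pytest.approx(2.4, abs=1e-12)
        assert alpha == pytest.approx(10.0, abs=1e-10)

    def test_equal_projections_force_symmetric_tilt(self):
        # sin(a) = sin(a + tau) forces a = 90 - tau/2
        h, alpha = solve_height_two_view(1.0, 1.0, 20.0)
        assert alpha == pytest.approx(80.0, abs=1e-10)
        assert h == pytest.approx(1.0 / math.sin(math.radians(80)), rel=1e-12)

    def test_degenerate_zero_projections(self):
        with pytest.raises(GeometryError):
            solve_height_two_view(0.0, 0.0, 20.0)

    def test_noisy_numeric_route_matches_closed_form(self):
        p1 = 1.9 * math.sin(math.radians(25))
        p2 = 1.9 * math.sin(math.radians(55))
        exact = solve_height_two_view(p1, p2, 30.0)
        numeric = solve_height_two_view(p1, p2, 30.0, noisy=True)
        assert numeric[0] == pytest.approx(exact[0], rel=1e-8)
        assert numeric[1] == pytest.approx(exact[1], abs=1e-7)

    @given(h=st.floats(0.3, 3.0), a=st.floats(2.0, 55.0),
           sep=st.floats(5.0, 34.0))
    @settings(derandomize=True, max_examples=100)
    def test_consistency_with_one_view_solver(self, h, a, sep):
        """Two-view h equals the known-parallel h at the recovered tilt."""
        p1 = h * math.sin(math.radians(a))
        p2 = h * math.sin(math.radians(a + sep))
        h_hat, a_hat = solve_height_two_view(p1, p2, sep)
        h_one = solve_height_known_parallel(p2, a_hat + sep)
        assert h_hat == pytest.approx(h, rel=1e-9)
        assert h_one == pytest.approx(h_hat, rel=1e-9)


class TestKnownParallelSolver:
    @pytest.mark.parametrize("p,tau,expected", [
        (1.2, 30.0, 2.4),
        (0.5, 90.0, 0.5),
        (0.7, -45.0, 0.7 / math.sin(math.radians(45))),
    ])
    def test_values(self, p, tau, expected):
        assert solve_height_known_parallel(p, tau) == pytest.approx(expected)

    def test_parallel_view_rejected(self):
        with pytest.raises(GeometryError):
            solve_height_known_parallel(1.0, 0.0)

    def test_subdegree_view_rejected(self):
        with pytest.raises(GeometryError):
            solve_height_known_parallel(1.0, 0.5)


class TestFindParallelAngle:
    def test_noise_free_fit(self):
        thetas = [-20.0, -10.0, 0.0, 10.0, 20.0]
        series = [(t, 2.4 * abs(math.sin(math.radians(t - 5.0)))) for t in thetas]
        assert find_parallel_angle(series) == pytest.approx(5.0, abs=0.1)

    def test_exact_zero_pins_angle(self):
        series = [(-10.0, 0.4), (5.0, 0.0), (20.0, 0.6)]
        assert find_parallel_angle(series) == 5.0

    def test_monotone_series_flags_extrapolation(self):
        series = [(t, 0.1 + 0.02 * t) for t in (0.0, 13.0, 26.0, 39.0, 52.0)]
        with pytest.raises(GeometryError, match="extrapolat"):
            find_parallel_angle(series)

    def test_needs_three_distinct_tilts(self):
        with pytest.raises(GeometryError):
            find_parallel_angle([(0.0, 1.0), (10.0, 0.5)])


class TestFrontViewStepSolver:
    def test_perpendicular_no_spacing_equals_height_difference(self):
        assert solve_row_height_front_view(1.0, 90.0, 2.4, 0.0, 0.0, 2) == \
            pytest.approx(1.4)

    def test_zero_step_returns_row1_height(self):
        s1 = StereociliumGeometry("a", 1, 2.4)
        s2 = StereociliumGeometry("b", 2, 2.4, base_offset=-0.4)
        b = Bundle("b", insertion_tilt_alpha=10, row_spacing_d=0.4,
                   stereocilia=[s1, s2])
        view = ImageView(50, "medial", 10)
        p = render_projection(s2, b, view, "step_1_to_2")
        assert solve_row_height_front_view(p, 40.0, 2.4, 0.4, 10.0, 2) == \
            pytest.approx(2.4, abs=1e-12)

    @pytest.mark.parametrize("row,h_row,tau", [
        (2, 1.4, 40.0), (3, 0.7, 40.0), (2, 1.4, -40.0), (3, 0.7, -25.0),
        (2, 2.2, 15.0), (3, 0.31, 70.0),
    ])
    def test_round_trip_against_numeric_forward_model(self, row, h_row, tau):
        """Closed form must invert the vector forward model on both sides."""
        alpha, d, h1 = 10.0, 0.4, 2.4
        s1 = StereociliumGeometry("a", 1, h1)
        s = StereociliumGeometry("b", row, h_row, base_offset=-(row - 1) * d)
        b = Bundle("b", insertion_tilt_alpha=alpha, row_spacing_d=d,
                   stereocilia=[s1, s])
        view = ImageView(alpha + tau, "medial" if tau > 0 else "lateral", alpha)
        p = render_projection(s, b, view, f"step_1_to_{row}")
        assert solve_row_height_front_view(p, tau, h1, d, alpha, row) == \
            pytest.approx(h_row, abs=1e-10)

    def test_inconsistent_measurement_flagged(self):
        with pytest.raises(GeometryError, match="inconsistent"):
            solve_row_height_front_view(5.0, 40.0, 2.4, 0.4, 10.0, 2)


class TestReconstructBundle:
    def test_noise_free_round_trip(self, small_bundle, views, noise_free):
        meas = render_experiment([small_bundle], views, noise_free)
        proj = meas[meas["kind"].isin(
            ["full_length", "step_1_to_2", "step_1_to_3"])]
        recon = reconstruct_bundle(proj)
        truth = {s.id: s.height_h for s in small_bundle.stereocilia}
        assert len(recon) == len(truth)
        for _, r in recon.iterrows():
            assert r["height_um"] == pytest.approx(
                truth[r["stereocilium_id"]], abs=1e-6)

    def test_two_view_and_parallel_methods_identical(self, small_bundle, views,
                                                     noise_free):
        """Both height-measurement techniques give identical results."""
        meas = render_experiment([small_bundle], views, noise_free)
        full = meas[meas["kind"] == "full_length"]
        with_theta0 = reconstruct_bundle(full)
        masked = full.copy()
        masked["parallel_angle_deg"] = np.nan
        two_view = reconstruct_bundle(masked)
        merged = with_theta0.merge(two_view, on="stereocilium_id",
                                   suffixes=("_a", "_b"))
        assert (merged["method_a"] == "parallel_angle").all()
        assert (merged["method_b"] == "two_view").all()
        assert np.allclose(merged["height_um_a"], merged["height_um_b"],
                           atol=1e-6)

    def test_single_view_no_parallel_angle_is_unresolved(self):
        meas = pd.DataFrame([dict(
            bundle_id="b", cell_type="OHC", stereocilium_id="s1", row=1,
            kind="full_length", side="lateral", stage_tilt_deg=-30.0,
            parallel_angle_deg=np.nan, value_um=1.5)])
        recon = reconstruct_bundle(meas)
        assert recon["method"].tolist() == ["unresolved"]
        assert recon["height_um"].isna().all()

    def test_single_measurement_delegates_to_known_parallel(self):
        meas = pd.DataFrame([dict(
            bundle_id="b", cell_type="OHC", stereocilium_id="s1", row=1,
            kind="full_length", side="lateral", stage_tilt_deg=-30.0,
            parallel_angle_deg=10.0, value_um=1.5)])
        recon = reconstruct_bundle(meas)
        expected = solve_height_known_parallel(1.5, -40.0)
        assert recon["height_um"].iloc[0] == pytest.approx(expected, rel=1e-12)
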