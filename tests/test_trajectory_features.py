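import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vte_kit.core_io import PositionTrace
from vte_kit.synthetic import DEFAULT_CHOICE_REGION, SimConfig, simulate_trajectory
from vte_kit.trajectory_features import (
    DegenerateTrajectoryError,
    choice_duration,
    compute_heading,
    compute_idphi,
    extract_trajectory_features,
    fourier_coef_count,
    poly_fit_r2,
    position_sds,
    zidphi_threshold_classifier,
    zscore_by_session,
)


def _trace(x, y, dt=1 / 35):
    x = np.asarray(x, float)
    return PositionTrace(t=np.arange(len(x)) * dt, x=x, y=np.asarray(y, float))


def _idphi_bruteforce(x, y):
    """Independent loop-based sum of shortest-arc heading changes."""
    phis = []
    for i in range(1, len(x)):
        dx, dy = x[i] - x[i - 1], y[i] - y[i - 1]
        if dx or dy:
            phis.append(np.arctan2(dy, dx))
        elif phis:
            phis.append(phis[-1])
    total = 0.0
    for a, b in zip(phis[:-1], phis[1:]):
        d = abs(b - a) % (2 * np.pi)
        total += min(d, 2 * np.pi - d)
    return total


class TestHeadingAndIdPhi:
    def test_straight_walks_have_constant_heading(self):
        right = _trace(np.arange(10), np.zeros(10))
        up = _trace(np.zeros(10), np.arange(10))
        assert np.allclose(compute_heading(right).phi, 0.0)
        assert np.allclose(compute_heading(up).phi, np.pi / 2)
        assert compute_idphi(compute_heading(right)) == 0.0

    def test_quarter_circle_sweeps_half_pi(self):
        theta = np.linspace(0, np.pi / 2, 200)
        h = compute_heading(_trace(np.cos(theta), np.sin(theta)))
        assert compute_idphi(h) == pytest.approx(np.pi / 2, rel=0.02)
        assert np.all(np.diff(h.phi) > 0)  # monotone re-orientation

    def test_out_and_back_reversal_costs_at_least_pi(self):
        x = np.concatenate([np.arange(10), np.arange(10)[::-2]])
        tr = _trace(x, np.zeros(len(x)))
        assert compute_idphi(compute_heading(tr)) >= np.pi

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_walks(self, seed):
        rng = np.random.default_rng(seed)
        x = np.cumsum(rng.normal(size=60))
        y = np.cumsum(rng.normal(size=60))
        got = compute_idphi(compute_heading(_trace(x, y)))
        assert got == pytest.approx(_idphi_bruteforce(x, y), abs=1e-10)

    def test_all_coincident_is_degenerate(self):
        with pytest.raises(DegenerateTrajectoryError):
            compute_heading(_trace(np.ones(5), np.ones(5)))

    @given(
        angle=st.floats(-np.pi, np.pi),
        shift_x=st.floats(-100, 100),
        shift_y=st.floats(-100, 100),
    )
    @settings(max_examples=25, deadline=None)
    def test_idphi_rigid_motion_invariance(self, angle, shift_x, shift_y):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.normal(size=40))
        y = np.cumsum(rng.normal(size=40))
        base = compute_idphi(compute_heading(_trace(x, y)))
        c, s = np.cos(angle), np.sin(angle)
        xr = c * x - s * y + shift_x
        yr = s * x + c * y + shift_y
        moved = compute_idphi(compute_heading(_trace(xr, yr)))
        assert moved == pytest.approx(base, abs=1e-8)

    def test_inserted_sweep_never_decreases_idphi(self):
        # noise-free limit: a head sweep is pure extra re-orientation
        cfg = SimConfig(position_noise_sd=0.0, run_speed_cv=0.0)
        non = [
            compute_idphi(compute_heading(
                simulate_trajectory("nonVTE", cfg, np.random.default_rng(s))
            ))
            for s in range(8)
        ]
        vte = [
            compute_idphi(compute_heading(
                simulate_trajectory("VTE", cfg, np.random.default_rng(s))
            ))
            for s in range(8)
        ]
        assert min(vte) > max(non)


class TestZScore:
    def test_closed_form(self):
        assert np.allclose(
            zscore_by_session([1, 2, 3]), [-1.2247448, 0.0, 1.2247448], atol=1e-6
        )
        assert np.allclose(zscore_by_session([-4.0, 4.0]), [-1.0, 1.0])

    def test_constant_session_errors(self):
        with pytest.raises(ValueError):
            zscore_by_session([2.0, 2.0, 2.0])

    @given(scale=st.floats(0.01, 100), shift=st.floats(-50, 50))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, scale, shift):
        v = np.array([0.3, 1.7, -2.2, 0.9])
        assert np.allclose(
            zscore_by_session(v), zscore_by_session(scale * v + shift), atol=1e-8
        )


class TestGeometryFeatures:
    def test_position_sds_closed_forms(self):
        assert position_sds(_trace([0, 2], [5, 5])) == (1.0, 0.0)
        theta = np.linspace(0, 2 * np.pi, 5000, endpoint=False)
        r = 3.0
        x_sd, y_sd = position_sds(_trace(r * np.cos(theta), r * np.sin(theta)))
        assert x_sd == pytest.approx(r / np.sqrt(2), rel=1e-3)
        assert y_sd == pytest.approx(r / np.sqrt(2), rel=1e-3)

    def test_choice_duration_inside_outside_and_half(self):
        region = np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]])
        inside = _trace(np.zeros(71), np.zeros(71), dt=2.0 / 70)
        assert choice_duration(inside, region) == pytest.approx(2.0, abs=1e-9)
        outside = _trace(np.full(10, 5.0), np.zeros(10))
        with pytest.warns(UserWarning):
            assert choice_duration(outside, region) == 0.0
        # first half of frames inside at uniform rate
        x = np.concatenate([np.zeros(50), np.full(50, 5.0)])
        half = _trace(x, np.zeros(100), dt=0.02)
        span = 99 * 0.02
        assert choice_duration(half, region) == pytest.approx(span / 2, rel=0.03)

    def test_poly_fit_exact_for_low_degree(self):
        x = np.linspace(-2, 2, 50)
        assert poly_fit_r2(_trace(x, x**2)).r2 == pytest.approx(1.0, abs=1e-9)
        y6 = 0.5 * x**6 - x**3 + 2 * x - 1
        assert poly_fit_r2(_trace(x, y6)).r2 == pytest.approx(1.0, abs=1e-6)

    def test_poly_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = np.sort(rng.uniform(-3, 3, 60))
            y = rng.normal(size=60) + np.sin(2 * x) * 3  # zig-zag, poor fit
            fit = poly_fit_r2(_trace(x, y))
            V = np.vander(x, 7)
            beta = np.linalg.solve(V.T @ V, V.T @ y)  # direct normal equations
            sse = float(np.sum((y - V @ beta) ** 2))
            sst = float(np.sum((y - y.mean()) ** 2))
            assert fit.r2 == pytest.approx(1 - sse / sst, abs=1e-6)

    def test_zero_y_spread_undefined_r2(self):
        x = np.linspace(0, 1, 20)
        with pytest.raises(ValueError):
            poly_fit_r2(_trace(x, np.ones(20)))


class TestFourierCoefCount:
    def test_constant_curve_needs_zero(self):
        x = np.linspace(0, 1, 32)
        fit = poly_fit_r2(_trace(x, x))  # then overwrite the estimate
        fit.y_hat = np.full(32, 3.3)
        assert fourier_coef_count(fit) == 0

    def test_single_and_double_sinusoids(self):
        n = 64
        t = np.arange(n)
        fit = poly_fit_r2(_trace(np.linspace(0, 1, n), np.linspace(0, 1, n)))
        fit.y_hat = np.sin(2 * np.pi * 3 * t / n)
        assert fourier_coef_count(fit) == 1
        fit.y_hat = np.sin(2 * np.pi * 3 * t / n) + np.sin(2 * np.pi * 7 * t / n)
        assert fourier_coef_count(fit) == 2


class TestSessionExtraction:
    def test_session_zidphi_is_standardized(self):
        cfg = SimConfig()
        rng = np.random.default_rng(2)
        traces = [
            simulate_trajectory("VTE" if i % 5 == 0 else "nonVTE", cfg, rng)
            for i in range(40)
        ]
        values, names = extract_trajectory_features(traces, DEFAULT_CHOICE_REGION)
        z = values[:, names.index("zidphi")]
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std() == pytest.approx(1.0, abs=1e-9)
        assert values.shape == (40, 7)

    def test_straight_trajectory_trivial_features(self):
        x = np.linspace(-50, 50, 40)
        straight = PositionTrace(np.arange(40) / 35, x, 0.1 * x)
        curved = PositionTrace(
            np.arange(40) / 35, x, 0.01 * x**2 + 0.1 * x
        )
        values, names = extract_trajectory_features(
            [straight, curved], DEFAULT_CHOICE_REGION
        )
        row = dict(zip(names, values[0]))
        assert row["idphi"] == pytest.approx(0.0, abs=1e-9)
        assert row["r2"] == pytest.approx(1.0, abs=1e-9)

    def test_oscillatory_fit_needs_more_coefficients_than_smooth(self):
        x = np.linspace(-60, 60, 80)
        smooth = PositionTrace(np.arange(80) / 35, x, 0.01 * x**2)
        wiggly = PositionTrace(
            np.arange(80) / 35, x, 30 * np.sin(2 * np.pi * 3 * np.arange(80) / 80)
        )
        n_smooth = fourier_coef_count(poly_fit_r2(smooth))
        n_wiggly_fit = poly_fit_r2(wiggly)
        assert fourier_coef_count(n_wiggly_fit) >= 1
        assert n_smooth >= 1  # leakage: smooth non-periodic curve still costs bins


class TestZidphiThreshold:
    def test_separable_case_is_perfect(self):
        z = np.concatenate([np.zeros(40), np.ones(10)])
        labels = np.array(["nonVTE"] * 40 + ["VTE"] * 10, object)
        thr, pred, area = zidphi_threshold_classifier(z, labels)
        assert area == 1.0
        assert np.array_equal(pred, labels)

    def test_random_labels_give_chance_area(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=4000)
        labels = np.where(rng.random(4000) < 0.2, "VTE", "nonVTE").astype(object)
        _, _, area = zidphi_threshold_classifier(z, labels)
        # selection over 31 thresholds inflates chance slightly above 0.5
        assert abs(area - 0.5) < 0.04

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            zidphi_threshold_classifier(
                np.arange(5.0), np.array(["VTE"] * 5, object)
            )
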