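"""Switching functions, CVs, hills, FES reconstruction, path finding."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snnkit.metad import (
    CVDefinition,
    FESGrid,
    Hill,
    MetadError,
    SwitchingParams,
    WallBias,
    bias_potential,
    detect_transition,
    evaluate_cv,
    min_free_energy_path,
    minimax_barrier_threshold,
    read_hills,
    reconstruct_fes,
    switching,
    wall_energy,
    write_hills,
)


class TestSwitching:
    def test_limits(self):
        p = SwitchingParams(r0=1.34)
        assert switching(0.0, p) == pytest.approx(1.0)
        assert switching(100.0, p) == pytest.approx(0.0, abs=1e-10)

    def test_removable_singularity_value(self):
        # at r = r0 the rational form evaluates to nn/mm (L'Hôpital)
        p = SwitchingParams(r0=1.0, nn=6, mm=12)
        assert switching(1.0, p) == pytest.approx(0.5)
        p2 = SwitchingParams(r0=2.5, nn=4, mm=10)
        assert switching(2.5, p2) == pytest.approx(0.4)

    def test_continuity_at_r0(self):
        p = SwitchingParams(r0=1.34)
        eps = 1e-7
        left = switching(1.34 - eps, p)
        right = switching(1.34 + eps, p)
        assert left == pytest.approx(0.5, abs=1e-5)
        assert right == pytest.approx(0.5, abs=1e-5)

    def test_direct_formula_away_from_r0(self):
        p = SwitchingParams(r0=1.0, nn=6, mm=12)
        r = 2.0
        expected = (1 - 2.0**6) / (1 - 2.0**12)  # independent arithmetic
        assert switching(r, p) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0.01, 5.0), st.floats(0.01, 5.0))
    def test_strictly_decreasing(self, a, b):
        p = SwitchingParams(r0=1.34)
        lo, hi = min(a, b), max(a, b)
        if hi - lo > 1e-9:
            assert switching(lo, p) > switching(hi, p)

    def test_invalid_params(self):
        with pytest.raises(MetadError):
            SwitchingParams(r0=-1.0)
        with pytest.raises(MetadError):
            SwitchingParams(r0=1.0, nn=12, mm=6)


def _cvdef():
    return CVDefinition(
        name="CV_1",
        pair_formed=(0, 1),
        params_formed=SwitchingParams(r0=1.34),
        pair_broken=(1, 2),
        params_broken=SwitchingParams(r0=1.34),
    )


class TestEvaluateCV:
    def test_reactant_like_endpoint(self):
        # formed contact absent (far), broken contact present (close) → −0.5
        coords = np.array([[0, 0, 0], [10, 0, 0], [10.3, 0, 0]])
        assert evaluate_cv(coords, _cvdef()) == pytest.approx(-0.5, abs=1e-3)

    def test_product_like_endpoint(self):
        coords = np.array([[0, 0, 0], [0.3, 0, 0], [10, 0, 0]])
        assert evaluate_cv(coords, _cvdef()) == pytest.approx(0.5, abs=1e-3)

    def test_symmetric_point_is_zero(self):
        coords = np.array([[0, 0, 0], [1.34, 0, 0], [1.34 + 1.34, 0, 0]])
        assert evaluate_cv(coords, _cvdef()) == pytest.approx(0.0, abs=1e-12)

    def test_bounded_by_coefficients(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            coords = rng.uniform(0, 5, size=(3, 3))
            v = evaluate_cv(coords, _cvdef())
            assert -0.5 - 1e-9 <= v <= 0.5 + 1e-9

    def test_missing_atom_rejected(self):
        with pytest.raises(MetadError):
            evaluate_cv(np.zeros((2, 3)), _cvdef())


class TestWall:
    @pytest.mark.parametrize("d,expected", [(5.5, 0.0), (5.0, 0.0), (6.5, 200.0)])
    def test_upper_wall_energy(self, d, expected):
        assert wall_energy(d, WallBias()) == pytest.approx(expected)

    def test_quadratic_growth(self):
        w = WallBias(location=5.5, force_constant=200.0, exponent=2)
        assert wall_energy(7.5, w) == pytest.approx(200.0 * 4.0)


class TestBiasPotential:
    def test_single_hill_at_center(self):
        h = Hill(0.1, [0.0, 0.0], [0.005, 0.006], 0.59)
        assert bias_potential([0.0, 0.0], [h]) == pytest.approx(0.59)

    def test_far_point_negligible(self):
        h = Hill(0.1, [0.0, 0.0], [0.005, 0.006], 0.59)
        assert bias_potential([0.1, 0.1], [h]) < 1e-10

    def test_matches_term_by_term_summation(self, rng):
        hills = [
            Hill(0.1 * k, rng.uniform(-0.5, 0.5, 2), [0.05, 0.06], rng.uniform(0.1, 1.0))
            for k in range(100)
        ]
        point = np.array([0.1, -0.2])
        # independent brute-force summation
        expected = 0.0
        for h in hills:
            z = (point - h.center) / h.sigma
            expected += h.height * math.exp(-0.5 * (z[0] ** 2 + z[1] ** 2))
        assert bias_potential(point, hills) == pytest.approx(expected, abs=1e-12)

    def test_linearity_in_hills(self, rng):
        hills = [
            Hill(0.1 * k, rng.uniform(-0.5, 0.5, 2), [0.05, 0.06], 0.3) for k in range(40)
        ]
        point = [0.05, 0.05]
        whole = bias_potential(point, hills)
        parts = bias_potential(point, hills[:17]) + bias_potential(point, hills[17:])
        assert whole == pytest.approx(parts, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        h = Hill(0.1, [0.0, 0.0], [0.01, 0.01], 0.5)
        with pytest.raises(MetadError):
            bias_potential([0.0], [h])


class TestHillsIO:
    def test_round_trip(self, tmp_path, rng):
        hills = [
            Hill(0.1 * (k + 1), rng.uniform(-0.5, 0.5, 2), [0.005, 0.006], 0.59)
            for k in range(1000)
        ]
        path = tmp_path / "HILLS"
        write_hills(hills, path, comment="synthetic stream")
        back = read_hills(path)
        assert len(back) == len(hills)
        # functional equality of the bias before and after the round-trip
        for point in ([0.0, 0.0], [0.3, -0.2], [-0.45, 0.45]):
            assert bias_potential(point, back) == pytest.approx(
                bias_potential(point, hills), rel=1e-9
            )

    def test_header_comment_and_rows(self, tmp_path):
        path = tmp_path / "HILLS"
        path.write_text(
            "# metadynamics hills\n"
            "0.1 -0.40 -0.40 0.005 0.006 0.59\n"
            "0.2 -0.39 -0.41 0.005 0.006 0.59\n"
            "0.3 -0.41 -0.38 0.005 0.006 0.59\n"
        )
        hills = read_hills(path)
        assert len(hills) == 3
        assert hills[0].center.tolist() == [-0.40, -0.40]

    def test_biasf_column_tolerated(self, tmp_path):
        path = tmp_path / "HILLS"
        path.write_text("0.1 -0.40 -0.40 0.005 0.006 0.59 1.0\n")
        hills = read_hills(path)
        assert len(hills) == 1
        assert hills[0].height == pytest.approx(0.59)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "HILLS"
        path.write_text("0.1 -0.40 -0.40 0.005 0.006 0.59\nnot numbers here\n")
        with pytest.raises(MetadError, match=":2"):
            read_hills(path)


class TestReconstruct:
    def test_empty_hills_flat_zero(self):
        fes = reconstruct_fes([], ((-0.5, 0.5, 0.1), (-0.5, 0.5, 0.1)))
        assert np.all(fes.values == 0.0)
        assert fes.values.shape == (11, 11)

    def test_min_shifted_to_zero(self, rng):
        hills = [
            Hill(0.1 * k, rng.uniform(-0.3, 0.3, 2), [0.05, 0.05], 0.5) for k in range(50)
        ]
        fes = reconstruct_fes(hills, ((-0.5, 0.5, 0.02), (-0.5, 0.5, 0.02)))
        assert fes.values.min() == pytest.approx(0.0)
        assert fes.values.max() > 0

    def test_deposition_lowers_negated_bias_pointwise(self, rng):
        hills = [
            Hill(0.1 * k, rng.uniform(-0.3, 0.3, 2), [0.05, 0.05], 0.5) for k in range(20)
        ]
        grid = ((-0.5, 0.5, 0.05), (-0.5, 0.5, 0.05))
        # before re-shifting, −V is pointwise non-increasing as hills are added
        for n in range(1, 20):
            a = reconstruct_fes(hills[:n], grid)
            b = reconstruct_fes(hills[: n + 1], grid)
            raw_a = a.values - a.values.max()
            raw_b = b.values - b.values.max()
            # compare unshifted −V: recover via max-alignment of the flat corner
            va = a.values - a.values[0, 0]
            vb = b.values - b.values[0, 0]
            assert np.all(vb - va <= 1e-9) or np.all(raw_b - raw_a <= 1e-9)


class TestPath:
    def test_flat_surface_straight_line(self):
        grid = FESGrid(
            (np.linspace(-0.5, 0.5, 11), np.linspace(-0.5, 0.5, 11)),
            np.zeros((11, 11)),
        )
        res = min_free_energy_path(grid, (-0.5, -0.5), (0.5, 0.5))
        assert res.barrier == pytest.approx(0.0)
        # 8-connected straight diagonal: 11 nodes
        assert len(res.nodes) == 11
        for (i1, j1), (i2, j2) in zip(res.nodes, res.nodes[1:]):
            assert max(abs(i1 - i2), abs(j1 - j2)) == 1

    def test_constructed_saddle_height_recovered(self):
        ax = np.linspace(-1, 1, 41)
        xx, yy = np.meshgrid(ax, ax, indexing="ij")
        # two wells at (±0.5, 0) separated by a ridge of height H at x=0
        h_saddle = 3.0
        values = 5.0 * np.exp(-((np.abs(xx) - 0.5) ** 2) / 0.02) * 0 + np.where(
            np.abs(xx) < 0.025, h_saddle + 2.0 * yy**2, 0.0
        )
        grid = FESGrid((ax, ax), values)
        res = min_free_energy_path(grid, (-0.5, 0.0), (0.5, 0.0))
        assert res.barrier == pytest.approx(h_saddle, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(4, 12), st.integers(4, 12))
    def test_minimax_equals_threshold_oracle_on_random_grids(self, seed, n1, n2):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 10, size=(n1, n2))
        values -= values.min()
        grid = FESGrid((np.arange(n1, dtype=float), np.arange(n2, dtype=float)), values)
        start = (0.0, 0.0)
        end = (float(n1 - 1), float(n2 - 1))
        res = min_free_energy_path(grid, start, end)
        level = minimax_barrier_threshold(grid, start, end)
        assert max(res.free_energy_profile) == pytest.approx(level, abs=1e-12)

    def test_integrated_mode_prefers_short_cheap_path(self):
        values = np.zeros((5, 5))
        values[2, :] = 1.0  # a uniform ridge; integrated mode should cross once
        grid = FESGrid((np.arange(5.0), np.arange(5.0)), values)
        res = min_free_energy_path(grid, (0.0, 0.0), (4.0, 4.0), mode="integrated")
        crossings = sum(1 for i, _ in res.nodes if i == 2)
        assert crossings == 1

    def test_outside_grid_rejected(self):
        grid = FESGrid((np.arange(5.0), np.arange(5.0)), np.zeros((5, 5)))
        with pytest.raises(MetadError):
            min_free_energy_path(grid, (-1.0, 0.0), (4.0, 4.0))


class TestTransitions:
    def test_step_crossing_detected(self):
        times = np.arange(0, 60, 0.05)
        cv1 = np.where(times >= 40.9, 0.5, -0.5)
        cv2 = np.where(times >= 40.9, 0.5, -0.5)
        assert detect_transition(times, [cv1, cv2]) == pytest.approx(40.9)

    def test_monotone_series_never_crossing(self):
        times = np.arange(0, 10, 0.1)
        cv = -1.0 + 0.05 * times  # stays below 0
        assert detect_transition(times, [cv, cv]) is None

    def test_requires_both_series_above(self):
        times = np.arange(0, 10, 0.1)
        cv1 = np.where(times >= 5.0, 0.5, -0.5)
        cv2 = np.full_like(times, -0.5)
        assert detect_transition(times, [cv1, cv2]) is None

    def test_short_blip_ignored_by_dwell(self):
        times = np.arange(0, 10, 0.05)
        cv = np.full_like(times, -0.5)
        blip = (times >= 3.0) & (times < 3.1)  # 0.1 ps < 0.2 ps dwell
        cv[blip] = 0.5
        cv[times >= 8.0] = 0.5
        assert detect_transition(times, [cv]) == pytest.approx(8.0)

    def test_noisy_injected_crossing_recovered(self, rng):
        times = np.arange(0, 57, 0.01)
        noise = rng.normal(scale=0.05, size=times.size)
        cv1 = np.where(times >= 40.9, 0.5, -0.5) + noise
        cv2 = np.where(times >= 40.9, 0.5, -0.5) + rng.normal(scale=0.05, size=times.size)
        found = detect_transition(times, [cv1, cv2], dwell=0.2)
        assert found == pytest.approx(40.9, abs=0.2)

    def test_empty_series_rejected(self):
        with pytest.raises(MetadError):
            detect_transition(np.array([]), [np.array([])])
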