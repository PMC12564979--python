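"""Heatmap construction and entropy against analytic and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gazentropy import (
    Fixation,
    HeatmapParams,
    build_heatmap,
    compute_trial_entropy,
    entropy,
    fixation_kernel,
)
from gazentropy.errors import DomainError, TrialInvalidError, ValidationError
from gazentropy.io import GazeStream


def fix(x, y, dur=1.0, t0=0.0):
    return Fixation(x=x, y=y, t_start=t0, t_end=t0 + dur, n_samples=2)


def brute_force_entropy(fixations, params):
    """Untruncated from-definition oracle: full Gaussian per fixation over
    every cell, duration weights, renormalise, direct -sum p log2 p."""
    xs, ys = np.meshgrid(np.arange(params.grid_w), np.arange(params.grid_h))
    durs = np.array([f.duration for f in fixations])
    w = durs / durs.sum()
    field = np.zeros((params.grid_h, params.grid_w))
    for wi, f in zip(w, fixations):
        g = np.exp(-((xs - f.x) ** 2 + (ys - f.y) ** 2) / (2 * params.sigma_px**2))
        field += wi * g / g.sum()
    field /= field.sum()
    p = field[field > 0]
    return float(-(p * np.log2(p)).sum())


class TestKernel:
    def test_normalised_with_argmax_at_centre(self):
        params = HeatmapParams()
        k = fixation_kernel(640, 512, params)
        assert k.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.unravel_index(k.argmax(), k.shape) == (512, 640)

    def test_reflection_symmetry_for_integer_centre(self, small_heatmap_params):
        k = fixation_kernel(32, 32, small_heatmap_params)
        row = k[32, :]
        np.testing.assert_allclose(row[32 - 10 : 32], row[32 + 10 : 32 : -1])
        np.testing.assert_allclose(k, k.T)

    def test_one_sigma_falloff(self):
        params = HeatmapParams()
        k = fixation_kernel(640, 512, params)
        ratio = k[512, 640 + 30] / k[512, 640]
        assert ratio == pytest.approx(math.exp(-0.5), rel=1e-9)

    def test_out_of_grid_centre_rejected(self):
        with pytest.raises(DomainError):
            fixation_kernel(2000, 512, HeatmapParams())


class TestBuildHeatmap:
    def test_single_fixation_equals_its_kernel(self, small_heatmap_params):
        field = build_heatmap([fix(20, 30)], small_heatmap_params)
        np.testing.assert_allclose(
            field.values, fixation_kernel(20, 30, small_heatmap_params), atol=1e-12
        )

    def test_coincident_fixations_collapse(self, small_heatmap_params):
        one = build_heatmap([fix(30, 30)], small_heatmap_params)
        two = build_heatmap([fix(30, 30), fix(30, 30, t0=1.0)], small_heatmap_params)
        np.testing.assert_allclose(one.values, two.values, atol=1e-12)

    def test_equal_durations_split_mass_evenly(self):
        params = HeatmapParams(sigma_px=10, grid_w=400, grid_h=100)
        field = build_heatmap([fix(80, 50), fix(320, 50, t0=1.0)], params)
        left = field.values[:, :200].sum()
        assert left == pytest.approx(0.5, abs=1e-6)

    def test_order_invariance(self, small_heatmap_params):
        f1, f2, f3 = fix(10, 10, 0.5), fix(40, 40, 1.5, t0=1), fix(25, 50, 1.0, t0=3)
        a = build_heatmap([f1, f2, f3], small_heatmap_params)
        b = build_heatmap([f3, f1, f2], small_heatmap_params)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_empty_fixations_rejected(self, small_heatmap_params):
        with pytest.raises(TrialInvalidError):
            build_heatmap([], small_heatmap_params)

    def test_field_always_sums_to_one(self, small_heatmap_params, rng):
        # including kernels clipped by the grid edge
        fxs = [
            fix(float(rng.uniform(0, 63)), float(rng.uniform(0, 63)), float(rng.uniform(0.1, 2)), t0=i * 3)
            for i in range(6)
        ]
        field = build_heatmap(fxs, small_heatmap_params)
        assert field.values.sum() == pytest.approx(1.0, abs=1e-9)


class TestEntropy:
    def test_point_mass_is_zero(self):
        params = HeatmapParams(grid_w=16, grid_h=16, sigma_px=1)
        field = np.zeros((16, 16))
        field[3, 4] = 1.0
        assert entropy(field, params).H == 0.0

    @pytest.mark.parametrize("n_cells", [1, 4, 64])
    def test_uniform_over_n_cells(self, n_cells):
        params = HeatmapParams(grid_w=16, grid_h=16, sigma_px=1)
        field = np.zeros((16, 16))
        field.flat[:n_cells] = 1.0 / n_cells
        assert entropy(field, params).H == pytest.approx(math.log2(n_cells), abs=1e-12)

    def test_unnormalised_field_rejected(self):
        params = HeatmapParams(grid_w=8, grid_h=8, sigma_px=1)
        with pytest.raises(ValidationError):
            entropy(np.full((8, 8), 0.5), params)

    def test_single_gaussian_matches_differential_entropy(self):
        # discrete sum over the full grid ~ log2(2 pi e sigma^2) for sigma >> 1 px
        params = HeatmapParams()
        h = entropy(fixation_kernel(640, 512, params), params).H
        assert h == pytest.approx(math.log2(2 * math.pi * math.e * 30**2), abs=0.01)

    def test_disjoint_equal_mixture_adds_one_bit(self):
        params = HeatmapParams(sigma_px=8, grid_w=512, grid_h=128)
        h1 = entropy(build_heatmap([fix(100, 64)], params), params).H
        h2 = entropy(
            build_heatmap([fix(100, 64), fix(412, 64, t0=2)], params), params
        ).H
        assert h2 == pytest.approx(h1 + 1.0, abs=1e-3)
        assert h2 == pytest.approx(brute_force_entropy([fix(100, 64), fix(412, 64, t0=2)], params), abs=1e-4)

    @pytest.mark.parametrize("seed", range(4))
    def test_truncated_accumulation_matches_brute_force(self, seed, small_heatmap_params):
        rng = np.random.default_rng(seed)
        fxs = [
            fix(float(rng.uniform(5, 58)), float(rng.uniform(5, 58)), float(rng.uniform(0.2, 2)), t0=i * 3)
            for i in range(int(rng.integers(1, 6)))
        ]
        h_fast = entropy(build_heatmap(fxs, small_heatmap_params), small_heatmap_params).H
        assert h_fast == pytest.approx(brute_force_entropy(fxs, small_heatmap_params), abs=1e-4)

    @given(st.integers(0, 10**6))
    def test_entropy_bounded_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        params = HeatmapParams(grid_w=32, grid_h=32, sigma_px=2)
        vals = rng.dirichlet(np.ones(32 * 32) * 0.05).reshape(32, 32)
        h = entropy(vals, params).H
        assert 0 <= h <= params.max_entropy + 1e-9
        shuffled = vals.flatten()
        rng.shuffle(shuffled)
        assert entropy(shuffled.reshape(32, 32), params).H == pytest.approx(h, abs=1e-9)

    def test_translation_invariance_of_entropy(self):
        params = HeatmapParams(sigma_px=5, grid_w=256, grid_h=256)
        fxs = [fix(80, 80), fix(120, 140, t0=2)]
        moved = [fix(110, 60, 1.0), fix(150, 120, 1.0, t0=2)]
        h0 = entropy(build_heatmap(fxs, params), params).H
        h1 = entropy(build_heatmap(moved, params), params).H
        assert h1 == pytest.approx(h0, abs=1e-6)


class TestComputeTrialEntropy:
    def test_stationary_stream_matches_single_gaussian(self):
        params = HeatmapParams()
        stream = GazeStream(
            t=np.arange(60) / 100.0, x=np.full(60, 640.0), y=np.full(60, 512.0)
        )
        h = compute_trial_entropy(stream, params=params).H
        assert h == pytest.approx(math.log2(2 * math.pi * math.e * 900), abs=0.01)

    def test_more_clusters_strictly_increase_entropy(self):
        params = HeatmapParams(sigma_px=10, grid_w=1280, grid_h=256)
        prev = -1.0
        for k in (1, 2, 4, 8):
            xs = np.concatenate([np.full(30, 100.0 + 150.0 * i) for i in range(k)])
            ys = np.full(30 * k, 128.0)
            stream = GazeStream(t=np.arange(30 * k) / 100.0, x=xs, y=ys)
            h = compute_trial_entropy(stream, params=params).H
            assert h > prev
            prev = h

    def test_no_fixations_marks_trial_invalid(self):
        stream = GazeStream(
            t=np.arange(50) / 100.0, x=np.arange(50) * 60.0, y=np.zeros(50)
        )
        with pytest.raises(TrialInvalidError):
            compute_trial_entropy(stream)

    def test_deterministic_on_identical_input(self):
        stream = GazeStream(
            t=np.arange(80) / 100.0,
            x=np.tile(np.array([300.0, 301.0]), 40),
            y=np.full(80, 200.0),
        )
        params = HeatmapParams(grid_w=640, grid_h=512)
        assert compute_trial_entropy(stream, params=params) == compute_trial_entropy(
            stream, params=params
        )
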