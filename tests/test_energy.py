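"""Energy-decrement and energy-tune algorithms against brute-force oracles."""

import numpy as np
import pytest

from pancseg.energy import (
    StandardLine,
    distance_to_line,
    distance_to_mask,
    energy_decrement,
    energy_tune_auto,
    energy_tune_line,
    source_energy,
)


def brute_distance_to_pixels(pixels, shape):
    """Min Euclidean distance of every grid pixel to a pixel set."""
    pts = np.asarray(pixels, dtype=float)
    rr, cc = np.indices(shape)
    d = np.full(shape, np.inf)
    for r0, c0 in pts:
        d = np.minimum(d, np.hypot(rr - r0, cc - c0))
    return d


def brute_source_energy(r0, g, sigma):
    out = np.zeros_like(g, dtype=float)
    src = np.argwhere(r0)
    for i in range(g.shape[0]):
        for j in range(g.shape[1]):
            for i0, j0 in src:
                d = np.hypot(i - i0, j - j0)
                out[i, j] += np.exp(-d / sigma) * g[i0, j0]
    return out


class TestStandardLine:
    def test_needs_two_vertices(self):
        with pytest.raises(ValueError):
            StandardLine([(1, 1)])

    def test_vertex_outside_image_rejected(self):
        line = StandardLine([(0, 0), (9, 0)])
        with pytest.raises(ValueError, match="outside"):
            line.rasterize((5, 5))

    def test_rasterization_connects_vertices(self):
        mask = StandardLine([(0, 0), (4, 4)]).rasterize((5, 5))
        assert mask[0, 0] and mask[4, 4] and mask.sum() == 5  # main diagonal


class TestDistanceToLine:
    def test_zero_on_line_pixels(self):
        line = StandardLine([(0, 2), (4, 2)])
        d = distance_to_line(line, (5, 5))
        assert np.all(d[:, 2] == 0)

    def test_vertical_line_distances(self):
        line = StandardLine([(0, 2), (4, 2)])
        d = distance_to_line(line, (5, 5))
        assert d[0, 4] == pytest.approx(2.0)

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            verts = [(int(rng.integers(8)), int(rng.integers(8))) for _ in range(3)]
            if len({tuple(v) for v in verts}) < 2:
                continue
            line = StandardLine(verts)
            mask = line.rasterize((8, 8))
            d = distance_to_line(line, (8, 8))
            assert np.allclose(d, brute_distance_to_pixels(np.argwhere(mask), (8, 8)))

    def test_lipschitz_between_neighbors(self):
        d = distance_to_line(StandardLine([(0, 0), (7, 3)]), (8, 8))
        assert np.all(np.abs(np.diff(d, axis=0)) <= 1.0 + 1e-12)
        assert np.all(np.abs(np.diff(d, axis=1)) <= 1.0 + 1e-12)


class TestDistanceToMask:
    def test_zero_exactly_on_mask(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[2:4, 2:4] = True
        d = distance_to_mask(mask)
        assert np.all(d[mask] == 0) and np.all(d[~mask] > 0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            distance_to_mask(np.zeros((4, 4), dtype=bool))


class TestEnergyDecrement:
    def test_zero_threshold_is_identity(self):
        speed = np.random.default_rng(0).uniform(0.1, 1, (6, 6))
        d = distance_to_line(StandardLine([(0, 3), (5, 3)]), (6, 6))
        assert np.array_equal(energy_decrement(speed, d, t_d=0.0), speed)

    def test_on_line_pixel_gets_minimum(self):
        speed = np.full((5, 5), 0.8)
        speed[0, 0] = 0.0
        d = distance_to_line(StandardLine([(0, 2), (4, 2)]), (5, 5))
        out = energy_decrement(speed, d, t_d=1.0)
        assert np.all(out[:, 2] == 0.0)

    def test_band_membership_against_brute_force(self):
        """5x5 uniform 0.8 with one zero corner; vertical line; t_d = 1.5."""
        speed = np.full((5, 5), 0.8)
        speed[0, 0] = 0.0
        line = StandardLine([(0, 2), (4, 2)])
        d = distance_to_line(line, (5, 5))
        out = energy_decrement(speed, d, t_d=1.5)
        brute = brute_distance_to_pixels([(r, 2) for r in range(5)], (5, 5))
        expected = np.where(brute < 1.5, 0.0, speed)
        assert np.array_equal(out, expected)
        # exactly columns 1..3 are inside the band
        assert np.all(out[:, 1:4] == 0.0)
        assert np.all(out[:, 0][1:] == 0.8) and np.all(out[:, 4] == 0.8)

    def test_only_lowers_values_inside_band(self, rng):
        speed = rng.uniform(0.2, 1.0, (7, 7))
        d = distance_to_line(StandardLine([(0, 0), (6, 6)]), (7, 7))
        out = energy_decrement(speed, d, t_d=2.0)
        band = d < 2.0
        assert np.all(out[band] <= speed[band])
        assert np.array_equal(out[~band], speed[~band])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            energy_decrement(np.zeros((4, 4)), np.zeros((5, 5)), 1.0)


class TestSourceEnergy:
    def test_single_pixel_source_self_energy(self):
        r0 = np.zeros((5, 5), dtype=bool)
        r0[2, 3] = True
        g = np.random.default_rng(3).uniform(0.1, 1, (5, 5))
        e = source_energy(r0, g, sigma=2.0)
        assert e[2, 3] == pytest.approx(g[2, 3])

    def test_decreases_with_distance_from_point_source(self):
        r0 = np.zeros((9, 9), dtype=bool)
        r0[4, 4] = True
        e = source_energy(r0, np.ones((9, 9)), sigma=3.0)
        row = e[4]
        assert np.all(np.diff(row[4:]) < 0) and np.all(np.diff(row[:5]) > 0)

    def test_two_pixel_source_closed_form(self):
        r0 = np.zeros((3, 3), dtype=bool)
        r0[0, 0] = r0[0, 1] = True
        e = source_energy(r0, np.ones((3, 3)), sigma=1.0)
        expected = np.exp(-np.sqrt(8)) + np.exp(-np.sqrt(5))
        assert e[2, 2] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.165984, abs=5e-6)

    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(3):
            shape = (int(rng.integers(4, 16)), int(rng.integers(4, 16)))
            r0 = rng.random(shape) < 0.2
            if not r0.any():
                r0[0, 0] = True
            g = rng.uniform(0.05, 1.0, shape)
            sigma = float(rng.uniform(1, 12))
            assert np.allclose(
                source_energy(r0, g, sigma), brute_source_energy(r0, g, sigma), atol=1e-9
            )

    def test_strictly_positive_everywhere(self, rng):
        r0 = np.zeros((8, 8), dtype=bool)
        r0[1, 1] = True
        assert np.all(source_energy(r0, rng.uniform(0.1, 1, (8, 8)), 5.0) > 0)

    def test_empty_source_rejected(self):
        with pytest.raises(ValueError):
            source_energy(np.zeros((4, 4), dtype=bool), np.ones((4, 4)), 1.0)

    def test_chunking_does_not_change_result(self, rng):
        r0 = rng.random((12, 12)) < 0.3
        r0[0, 0] = True
        g = rng.uniform(0.1, 1, (12, 12))
        full = source_energy(r0, g, 4.0, chunk_pixels=10_000)
        tiny = source_energy(r0, g, 4.0, chunk_pixels=7)
        assert np.allclose(full, tiny, atol=1e-12)


def tune_line_reference(g, e, r0, d_line, d_src, a, b):
    """Per-pixel branch-by-branch enumeration of the line-based tune."""
    n = r0.sum()
    out = np.empty_like(g)
    for i in range(g.shape[0]):
        for j in range(g.shape[1]):
            if r0[i, j]:
                out[i, j] = min(1.0, (a / n) * e[i, j] + g[i, j])
            elif d_line[i, j] <= d_src[i, j]:
                if d_line[i, j] == 0:
                    out[i, j] = 0.0 if e[i, j] > 0 else g[i, j]
                else:
                    out[i, j] = max(0.0, g[i, j] - b * e[i, j] / d_line[i, j])
            else:
                out[i, j] = g[i, j]
    return np.clip(out, 0, 1)


def tune_auto_reference(g, e, r0, d_src, d_t, a, b):
    """Per-pixel enumeration of the automatic tune (d_src = d_t attenuates)."""
    n = r0.sum()
    out = np.empty_like(g)
    for i in range(g.shape[0]):
        for j in range(g.shape[1]):
            if r0[i, j]:
                out[i, j] = min(1.0, g[i, j] + (a / n) * e[i, j])
            elif d_src[i, j] > d_t:
                out[i, j] = max(0.0, g[i, j] - b * e[i, j] / (d_src[i, j] - d_t))
            elif d_src[i, j] > 0:
                out[i, j] = g[i, j] / (1.0 + d_src[i, j] / d_t)
            else:
                out[i, j] = g[i, j]
    return np.clip(out, 0, 1)


class TestEnergyTuneLine:
    def setup_method(self):
        self.r0 = np.zeros((5, 5), dtype=bool)
        self.r0[1:3, 0:2] = True
        self.line = StandardLine([(0, 3), (4, 3)])
        self.d_line = distance_to_line(self.line, (5, 5))
        self.d_src = distance_to_mask(self.r0)

    def test_matches_branch_enumeration(self, rng):
        g = rng.uniform(0, 1, (5, 5))
        e = rng.uniform(0, 3, (5, 5))
        out = energy_tune_line(g, e, self.r0, self.d_line, self.d_src, 1.0, 1.0)
        ref = tune_line_reference(g, e, self.r0, self.d_line, self.d_src, 1.0, 1.0)
        assert np.allclose(out, ref, atol=1e-12)

    def test_upper_clamp_inside_source(self):
        g = np.full((5, 5), 0.9)
        e = np.full((5, 5), 100.0)
        out = energy_tune_line(g, e, self.r0, self.d_line, self.d_src, 1.0, 1.0)
        assert np.all(out[self.r0] == 1.0)

    def test_lower_clamp_in_decay_branch(self):
        g = np.full((5, 5), 0.2)
        e = np.full((5, 5), 50.0)
        out = energy_tune_line(g, e, self.r0, self.d_line, self.d_src, 1.0, 1.0)
        decay = ~self.r0 & (self.d_line <= self.d_src)
        assert np.all(out[decay] == 0.0)

    def test_on_line_conventions(self):
        g = np.full((5, 5), 0.7)
        e = np.zeros((5, 5))
        e[0, 3] = 1.0  # on-line pixel with positive energy
        out = energy_tune_line(g, e, self.r0, self.d_line, self.d_src, 1.0, 1.0)
        assert out[0, 3] == 0.0  # limit of the decay branch
        assert out[1, 3] == g[1, 3]  # on line, zero energy: g preserved

    def test_far_pixels_unchanged(self, rng):
        g = rng.uniform(0, 1, (5, 5))
        e = rng.uniform(0, 2, (5, 5))
        out = energy_tune_line(g, e, self.r0, self.d_line, self.d_src, 1.0, 1.0)
        far = ~self.r0 & (self.d_line > self.d_src)
        assert np.array_equal(out[far], g[far])

    def test_enhancement_and_decay_directions(self, rng):
        g = rng.uniform(0.1, 0.9, (5, 5))
        e = rng.uniform(0.01, 1.0, (5, 5))
        out = energy_tune_line(g, e, self.r0, self.d_line, self.d_src, 1.0, 1.0)
        assert np.all(out[self.r0] >= g[self.r0])
        decay = ~self.r0 & (self.d_line <= self.d_src)
        assert np.all(out[decay] <= g[decay])

    def test_output_in_unit_interval(self, rng):
        g = rng.uniform(0, 1, (5, 5))
        e = rng.uniform(0, 10, (5, 5))
        out = energy_tune_line(g, e, self.r0, self.d_line, self.d_src, -3.0, 2.0)
        assert np.all((out >= 0) & (out <= 1))

    def test_empty_source_rejected(self):
        with pytest.raises(ValueError):
            energy_tune_line(
                np.ones((5, 5)), np.ones((5, 5)), np.zeros((5, 5), dtype=bool),
                self.d_line, self.d_src,
            )


class TestEnergyTuneAuto:
    def setup_method(self):
        self.r0 = np.zeros((5, 5), dtype=bool)
        self.r0[0:2, 0:2] = True
        self.d_src = distance_to_mask(self.r0)

    def test_matches_branch_enumeration(self, rng):
        g = rng.uniform(0, 1, (5, 5))
        e = rng.uniform(0, 3, (5, 5))
        out = energy_tune_auto(g, e, self.r0, self.d_src, 2.0, 1.0, 1.0)
        ref = tune_auto_reference(g, e, self.r0, self.d_src, 2.0, 1.0, 1.0)
        assert np.allclose(out, ref, atol=1e-12)

    def test_attenuation_branch_boundary_halves(self):
        """d_src exactly d_t lies in the attenuation branch: g/(1+1)."""
        g = np.full((5, 5), 0.8)
        e = np.zeros((5, 5))
        d_t = 2.0
        out = energy_tune_auto(g, e, self.r0, self.d_src, d_t, 1.0, 1.0)
        at_boundary = ~self.r0 & (self.d_src == d_t)
        assert at_boundary.any()
        assert np.allclose(out[at_boundary], 0.4)

    def test_far_lower_clamp(self):
        g = np.full((5, 5), 0.3)
        e = np.full((5, 5), 40.0)
        out = energy_tune_auto(g, e, self.r0, self.d_src, 1.0, 1.0, 1.0)
        far = ~self.r0 & (self.d_src > 1.0)
        assert np.all(out[far] == 0.0)

    def test_zero_energy_in_source_leaves_g(self):
        g = np.random.default_rng(7).uniform(0.1, 0.9, (5, 5))
        e = np.zeros((5, 5))
        out = energy_tune_auto(g, e, self.r0, self.d_src, 2.0, 1.0, 1.0)
        assert np.array_equal(out[self.r0], g[self.r0])

    def test_output_in_unit_interval(self, rng):
        g = rng.uniform(0, 1, (5, 5))
        e = rng.uniform(0, 10, (5, 5))
        out = energy_tune_auto(g, e, self.r0, self.d_src, 3.0, -2.0, 5.0)
        assert np.all((out >= 0) & (out <= 1))

    def test_rejects_nonpositive_threshold(self):
        with pytest.raises(ValueError):
            energy_tune_auto(np.ones((5, 5)), np.ones((5, 5)), self.r0, self.d_src, 0.0)
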