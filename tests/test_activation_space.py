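"""Hypercube combinatorics, conservation, two-stage harmonization, density
masking, and ASOS vs. brute-force occlusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asosmap.activation_space import (
    ActivationSpace,
    asos_sensitivities,
    build_space,
    compute_density_mask,
    cube_count,
    cube_index,
    harmonize_attributions,
    load_table,
    save_table,
)


class TestCubeIndex:
    def test_lower_corner(self):
        assert cube_index(np.array([-0.999, -0.999, -0.999]), 0.1).tolist() == [0, 0, 0]

    def test_direct_arithmetic(self):
        assert cube_index(np.array([0.05, -0.95, 0.999]), 0.1).tolist() == [10, 0, 19]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="strictly inside"):
            cube_index(np.array([1.0, 0.0, 0.0]), 0.1)

    @given(st.lists(st.floats(-0.999, 0.999), min_size=3, max_size=3),
           st.sampled_from([0.1, 0.2, 0.5]))
    @settings(deadline=None, max_examples=80, derandomize=True)
    def test_partition_every_vector_in_exactly_one_cube(self, v, l_h):
        """cube_index is constant inside a cube's half-open volume and
        changes across bin edges."""
        v = np.array(v)
        idx = cube_index(v, l_h)
        n = int(round(2 / l_h))
        assert np.all((idx >= 0) & (idx < n))
        # a perturbation much smaller than the distance to the nearest edge
        # never changes the cube
        off = (v + 1.0) / l_h - idx
        margin = np.minimum(off, 1.0 - off) * l_h
        delta = np.where(margin > 1e-6, margin / 100.0, 0.0)
        assert np.array_equal(cube_index(v + delta * 0.5, l_h), idx)


class TestCubeCount:
    @pytest.mark.parametrize("l_h,c_act,expected", [
        (0.1, 3, 8000),
        (0.5, 3, 64),
        (2.0, 3, 1),
        (0.1, 2, 400),
    ])
    def test_counts(self, l_h, c_act, expected):
        assert cube_count(l_h, c_act) == expected

    def test_non_integral_rejected_with_suggestion(self):
        with pytest.raises(ValueError, match="nearest valid"):
            cube_count(0.3, 3)


def _random_activation_map(rng, c=3, h=8, w=8):
    return rng.uniform(-0.95, 0.95, (c, h, w))


class TestSpace:
    def test_density_conservation(self):
        rng = np.random.default_rng(0)
        space = ActivationSpace(l_h=0.5, c_act=3)
        for _ in range(10):
            space.add_map(_random_activation_map(rng))
        assert space.total_density() == 10 * 64

    def test_duplicate_image_doubles_density(self):
        rng = np.random.default_rng(1)
        m = _random_activation_map(rng)
        s1 = ActivationSpace(l_h=0.5, c_act=3)
        s1.add_map(m)
        s2 = ActivationSpace(l_h=0.5, c_act=3)
        s2.add_map(m)
        s2.add_map(m)
        assert np.array_equal(s2.density, 2 * s1.density)

    def test_out_of_range_clamped_with_counter(self):
        space = ActivationSpace(l_h=0.5, c_act=1)
        m = np.array([[[-1.0, 0.5], [1.0, 0.0]]])  # exact +-1 from saturation
        space.add_map(m)
        assert space.n_clamped == 2
        assert space.total_density() == 4


def brute_force_two_stage_mean(images):
    """Oracle: explicit per-image grouping; images = [(flat_idx, attr), ...]."""
    per_cube = {}
    for flat, attr in images:
        means = {}
        for i, a in zip(flat, attr):
            means.setdefault(i, []).append(a)
        for cube, vals in means.items():
            per_cube.setdefault(cube, []).append(np.mean(vals))
    return {c: np.mean(v) for c, v in per_cube.items()}


class TestHarmonize:
    def _space_from_indices(self, idx_lists, l_h=2.0, c_act=1):
        """Build a space whose images hit prescribed flat cubes."""
        space = ActivationSpace(l_h=l_h, c_act=c_act)
        n = space.n_per_dim
        for flat in idx_lists:
            flat = np.asarray(flat)
            # centers of the requested cubes as 1-D activation values
            v = (flat + 0.5) * l_h - 1.0
            m = v.reshape(1, 1, -1)
            space.add_map(m)
        return space

    def test_constant_attribution_single_image(self):
        rng = np.random.default_rng(2)
        space = ActivationSpace(l_h=0.5, c_act=3)
        m = _random_activation_map(rng)
        space.add_map(m)
        table = harmonize_attributions(space, [np.full((8, 8), 2.5)])
        occ = table.occupied
        assert np.allclose(table.values[occ], 2.5)
        assert np.isnan(table.values[~occ]).all()

    def test_two_stage_mean_worked_example(self):
        """Image A gives {1,1,4} in a cube (mean 2), image B gives {4}:
        harmonized value is 3.0, not the pixel-weighted 2.5."""
        space = self._space_from_indices([[0, 0, 0], [0]], l_h=1.0)
        attrs = [np.array([[[1.0, 1.0, 4.0]]]).reshape(1, 3),
                 np.array([[4.0]])]
        table = harmonize_attributions(space, attrs)
        assert table.values[0] == pytest.approx(3.0)

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(3)
        space = ActivationSpace(l_h=0.5, c_act=2)
        images = []
        attrs = []
        for _ in range(6):
            m = rng.uniform(-0.95, 0.95, (2, 5, 5))
            flat = space.add_map(m)
            a = rng.standard_normal((5, 5))
            images.append((flat, a.ravel()))
            attrs.append(a)
        table = harmonize_attributions(space, attrs)
        oracle = brute_force_two_stage_mean(images)
        for cube, val in oracle.items():
            assert table.values[cube] == pytest.approx(val, abs=1e-12)
        assert table.occupied.sum() == len(oracle)

    def test_scaling_linearity(self):
        rng = np.random.default_rng(4)
        space = ActivationSpace(l_h=0.5, c_act=2)
        maps = [rng.uniform(-0.9, 0.9, (2, 4, 4)) for _ in range(3)]
        for m in maps:
            space.add_map(m)
        attrs = [rng.standard_normal((4, 4)) for _ in range(3)]
        t1 = harmonize_attributions(space, attrs)
        t2 = harmonize_attributions(space, [2 * a for a in attrs])
        occ = t1.occupied
        assert np.allclose(t2.values[occ], 2 * t1.values[occ])

    def test_misaligned_shapes_rejected(self):
        space = ActivationSpace(l_h=0.5, c_act=2)
        space.add_map(np.zeros((2, 4, 4)) + 0.1)
        with pytest.raises(ValueError, match="misaligned"):
            harmonize_attributions(space, [np.zeros((3, 3))])


class TestDensityMask:
    def _table(self, density):
        from asosmap.activation_space import HarmonizationTable
        density = np.asarray(density, dtype=np.int64)
        values = np.where(density > 0, 1.0, np.nan)
        return HarmonizationTable(
            l_h=2.0, c_act=1, values=values, density=density,
            n_images_per_cube=(density > 0).astype(np.int64),
        )

    def test_uniform_occupancy_nothing_masked(self):
        t = self._table([10])
        assert compute_density_mask(t, 0.5).tolist() == [True]

    def test_worked_arithmetic(self):
        """Counts {10, 2}: average 6, threshold 3, the 2-count cube masks."""
        from asosmap.activation_space import HarmonizationTable
        density = np.array([10, 2], dtype=np.int64)
        t = HarmonizationTable(l_h=1.0, c_act=1, values=np.ones(2),
                               density=density, n_images_per_cube=np.ones(2, dtype=np.int64))
        kept = compute_density_mask(t, 0.5)
        assert kept.tolist() == [True, False]

    def test_factor_zero_keeps_all_occupied(self):
        t = self._table([5, 0, 1])
        kept = compute_density_mask(t, 0.0)
        assert kept.tolist() == [True, False, True]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        t = self._table(rng.integers(0, 50, 32))
        prev = compute_density_mask(t, 0.0)
        for factor in (0.25, 0.5, 1.0, 2.0):
            cur = compute_density_mask(t, factor)
            assert np.all(prev | ~cur)  # raising never unmasks
            prev = cur

    def test_empty_table_rejected(self):
        t = self._table([0, 0])
        with pytest.raises(ValueError, match="no occupied"):
            compute_density_mask(t)


class StubNetwork:
    """Deterministic stand-in network with a nonlinear head, used as the
    target for the brute-force ASOS oracle."""

    class _Spec:
        c_act = 2
        c_in = 2

    unet_spec = _Spec()

    def __init__(self, seed=0):
        rng = np.random.default_rng(seed)
        self.w1 = rng.standard_normal(2)
        self.w2 = rng.standard_normal(2)

    def forward_activation(self, x):
        # fixed pointwise mixing of the input channels into (-1, 1)
        mixed = np.stack([
            np.tanh(1.7 * x[:, 0] - 0.9 * x[:, 1]),
            np.tanh(0.6 * x[:, 0] + 1.1 * x[:, 1] - 0.4),
        ], axis=1)
        return mixed

    def forward_score(self, a):
        s = np.tensordot(a.mean(axis=(2, 3)), self.w1, axes=(1, 0))
        q = np.tensordot((a ** 2).mean(axis=(2, 3)), self.w2, axes=(1, 0))
        return 1.0 / (1.0 + np.exp(-(2.0 * s + 1.5 * q)))


class TestASOS:
    def _setup(self, n_images=2, size=8, l_h=0.5, seed=6):
        rng = np.random.default_rng(seed)
        net = StubNetwork()
        samples = [rng.uniform(0, 1, (size, size, 2)).astype(np.float32)
                   for _ in range(n_images)]
        space = build_space(net, samples, l_h=l_h)
        return net, samples, space

    def test_matches_brute_force_per_cube_occlusion(self):
        """Independent oracle: enumerate cubes, zero the member pixels,
        re-run the head, average deltas over contributing images."""
        net, samples, space = self._setup()
        table = asos_sensitivities(net, samples, space)
        sums = {}
        counts = {}
        for pixels, flat in zip(samples, space.image_indices):
            x = pixels.transpose(2, 0, 1)[None]
            a = net.forward_activation(x)[0]
            y0 = float(net.forward_score(a[None])[0])
            for cube in np.unique(flat):
                occ = a.copy()
                occ_flat = occ.reshape(2, -1)
                occ_flat[:, flat == cube] = 0.0
                delta = y0 - float(net.forward_score(occ[None])[0])
                sums[cube] = sums.get(cube, 0.0) + delta
                counts[cube] = counts.get(cube, 0) + 1
        for cube, total in sums.items():
            assert table.values[cube] == pytest.approx(total / counts[cube], abs=1e-10)
        assert np.isnan(table.values[[c for c in range(space.n_cubes)
                                      if c not in sums]]).all()

    def test_linear_head_closed_form(self):
        """With a linear mean head, delta for cube c in image i is
        sum_k w_k * sum_{p in S_ic} A_k(p) / (hw)."""

        class LinearNet(StubNetwork):
            def forward_score(self, a):
                return np.tensordot(a.mean(axis=(2, 3)), self.w1, axes=(1, 0))

        rng = np.random.default_rng(7)
        net = LinearNet()
        samples = [rng.uniform(0, 1, (4, 4, 2)).astype(np.float32)]
        space = build_space(net, samples, l_h=1.0)
        table = asos_sensitivities(net, samples, space)
        a = net.forward_activation(samples[0].transpose(2, 0, 1)[None])[0]
        flat = space.image_indices[0]
        for cube in np.unique(flat):
            sel = flat == cube
            expected = np.tensordot(
                net.w1, a.reshape(2, -1)[:, sel].sum(axis=1), axes=(0, 0)) / 16.0
            assert table.values[cube] == pytest.approx(expected, abs=1e-8)

    def test_untouched_cube_contributes_nothing(self):
        net, samples, space = self._setup()
        table = asos_sensitivities(net, samples, space)
        untouched = ~space.occupied
        assert np.isnan(table.values[untouched]).all()
        assert np.all(table.n_images_per_cube[untouched] == 0)


def test_scatter_export_samples_aligned_rows(tmp_path):
    rng = np.random.default_rng(9)
    maps = [rng.uniform(-0.9, 0.9, (3, 20, 20)) for _ in range(3)]
    attrs = [rng.standard_normal((20, 20)) for _ in range(3)]
    from asosmap.activation_space import export_scatter_csv

    path = tmp_path / "scatter.csv"
    n = export_scatter_csv(maps, attrs, path, rate=0.2, seed=0)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "act_0,act_1,act_2,attribution"
    assert len(lines) == n + 1
    # sampling rate is honored in expectation (1200 pixels, rate 0.2)
    assert 150 < n < 330
    row = [float(v) for v in lines[1].split(",")]
    assert all(-1 < v < 1 for v in row[:3])


def test_table_hdf5_roundtrip(tmp_path):
    rng = np.random.default_rng(8)
    space = ActivationSpace(l_h=0.5, c_act=2)
    maps = [rng.uniform(-0.9, 0.9, (2, 6, 6)) for _ in range(4)]
    for m in maps:
        space.add_map(m)
    table = harmonize_attributions(
        space, [rng.standard_normal((6, 6)) for _ in range(4)],
        method="gradcam", provenance={"run": "test"})
    path = tmp_path / "table.h5"
    save_table(table, path)
    back = load_table(path)
    assert back.l_h == table.l_h and back.c_act == table.c_act
    occ = table.occupied
    assert np.allclose(back.values[occ], table.values[occ])
    assert np.isnan(back.values[~occ]).all()
    assert np.array_equal(back.density, table.density)
    assert back.method == "gradcam"
    assert back.provenance == {"run": "test"}
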