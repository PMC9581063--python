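"""MRC I/O, resampling, envelope extraction, normalisation and padding."""

import gemmi
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryosse import volio
from cryosse.volio import (
    DensityMap,
    EmptyComponentError,
    MRCFormatError,
    PadSpec,
    SizeLimitError,
    extract_component,
    normalize,
    pad_for_network,
    read_mrc,
    resample_to_unit,
    unpad,
    write_mrc,
)


class TestMRCRoundTrip:
    def test_write_read_identity(self, random_map, tmp_path):
        path = tmp_path / "m.mrc"
        write_mrc(random_map, path)
        back = read_mrc(path)
        np.testing.assert_array_equal(back.data, random_map.data)
        np.testing.assert_allclose(back.origin, random_map.origin, atol=1e-6)
        np.testing.assert_allclose(back.voxel_size, random_map.voxel_size, atol=1e-6)

    def test_anisotropic_voxel_size_preserved(self, tmp_path, rng):
        m = DensityMap(rng.random((4, 5, 6)).astype(np.float32),
                       origin=(0.5, 0, -1), voxel_size=(0.8, 1.2, 2.0))
        write_mrc(m, tmp_path / "a.mrc")
        back = read_mrc(tmp_path / "a.mrc")
        np.testing.assert_allclose(back.voxel_size, m.voxel_size, rtol=1e-6)

    def test_constant_grid_header_min_max(self, tmp_path):
        m = DensityMap(np.full((3, 3, 3), 7.5, dtype=np.float32))
        write_mrc(m, tmp_path / "c.mrc")
        raw = gemmi.read_ccp4_map(str(tmp_path / "c.mrc"))
        assert raw.header_float(20) == raw.header_float(21) == 7.5  # DMIN, DMAX

    def test_unit_voxels_give_cell_equal_to_dims(self, tmp_path):
        m = DensityMap(np.zeros((5, 6, 7), dtype=np.float32), voxel_size=(1, 1, 1))
        write_mrc(m, tmp_path / "u.mrc")
        cell = gemmi.read_ccp4_map(str(tmp_path / "u.mrc")).grid.unit_cell
        assert (cell.a, cell.b, cell.c) == (5.0, 6.0, 7.0)

    def test_permuted_axis_order_reads_same_world_content(self, tmp_path, rng):
        arr = rng.random((3, 4, 5)).astype(np.float32)
        # store with axes (z, x, y): columns (fastest) = Z, rows = X, sections = Y
        perm = np.ascontiguousarray(np.transpose(arr, (2, 0, 1)))
        grid = gemmi.FloatGrid(perm)
        grid.unit_cell = gemmi.UnitCell(3, 4, 5, 90, 90, 90)
        m = gemmi.Ccp4Map()
        m.grid = grid
        m.update_ccp4_header()
        m.set_header_i32(17, 3)
        m.set_header_i32(18, 1)
        m.set_header_i32(19, 2)
        for word, v in zip((8, 9, 10), (3, 4, 5)):
            m.set_header_i32(word, v)
        for word, v in zip((11, 12, 13), (3.0, 4.0, 5.0)):
            m.set_header_float(word, v)
        m.write_ccp4_map(str(tmp_path / "perm.mrc"))
        back = read_mrc(tmp_path / "perm.mrc")
        # brute-force comparison at identical world coordinates
        assert back.shape == arr.shape
        for i in range(3):
            for j in range(4):
                for k in range(5):
                    assert back.data[i, j, k] == pytest.approx(arr[i, j, k])

    def test_garbage_bytes_raise_format_error(self, tmp_path):
        path = tmp_path / "junk.mrc"
        path.write_bytes(b"\x01\x02garbage!")
        with pytest.raises(MRCFormatError):
            read_mrc(path)

    def test_unwritable_path_raises(self, random_map):
        with pytest.raises(OSError):
            write_mrc(random_map, "/nonexistent-dir/deep/m.mrc")


class TestResample:
    def test_already_unit_is_bitwise_identity(self, random_map):
        out = resample_to_unit(random_map)
        assert out.data is random_map.data

    def test_constant_map_stays_constant(self):
        m = DensityMap(np.full((6, 6, 6), 3.25, dtype=np.float32), voxel_size=(0.5, 0.5, 0.5))
        out = resample_to_unit(m)
        np.testing.assert_allclose(out.data, 3.25, rtol=1e-6)
        np.testing.assert_allclose(out.voxel_size, 1.0)

    def test_linear_ramp_reproduced_at_integer_lattice(self):
        # f(x) = x sampled at 0.5 Å; trilinear interpolation is exact on a
        # linear function, so values at the new lattice are the integers 0..n
        i = np.arange(11, dtype=np.float32)
        data = np.broadcast_to(0.5 * i[:, None, None], (11, 5, 5)).copy()
        m = DensityMap(data, voxel_size=(0.5, 0.5, 0.5))
        out = resample_to_unit(m)
        expected = np.arange(out.shape[0], dtype=np.float32)
        np.testing.assert_allclose(out.data[:, 0, 0], expected, atol=1e-6)

    def test_world_extent_preserved_within_one_voxel(self):
        m = DensityMap(np.zeros((9, 9, 9), dtype=np.float32), voxel_size=(0.7, 0.7, 0.7))
        out = resample_to_unit(m)
        extent_in = 8 * 0.7
        extent_out = np.array(out.shape) - 1
        assert np.all(np.abs(extent_out - extent_in) <= 1.0)

    def test_nonpositive_voxel_size_rejected(self):
        m = DensityMap(np.zeros((3, 3, 3), dtype=np.float32))
        m.voxel_size = np.array([0.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            resample_to_unit(m)


class TestExtractComponent:
    def test_single_atom_radius5_retains_515_voxels(self):
        # oracle: integer lattice points within Euclidean distance 5 of a point
        expected = sum(
            1
            for i in range(-5, 6) for j in range(-5, 6) for k in range(-5, 6)
            if i * i + j * j + k * k <= 25
        )
        assert expected == 515
        m = DensityMap(np.ones((21, 21, 21), dtype=np.float32))
        out = extract_component(m, [(10.0, 10.0, 10.0)], radius=5.0)
        assert int((out.data != 0).sum()) == 515

    def test_huge_radius_is_identity(self, random_map):
        atom = random_map.world_coord((6, 5, 7))
        out = extract_component(random_map, [atom], radius=100.0)
        np.testing.assert_array_equal(out.data, random_map.data)
        np.testing.assert_allclose(out.origin, random_map.origin)

    def test_far_atom_raises_empty_component(self, random_map):
        far = random_map.origin - 50.0
        with pytest.raises(EmptyComponentError):
            extract_component(random_map, [far], radius=5.0)

    def test_matches_brute_force_scan(self, rng):
        for _ in range(5):
            shape = tuple(rng.integers(5, 15, 3))
            m = DensityMap(rng.random(shape).astype(np.float32), origin=rng.normal(size=3))
            atoms = m.origin + rng.uniform(0, max(shape), (3, 3))
            radius = float(rng.uniform(2, 6))
            mask = np.zeros(shape, dtype=bool)
            for i in range(shape[0]):
                for j in range(shape[1]):
                    for k in range(shape[2]):
                        c = m.world_coord((i, j, k))
                        if min(np.linalg.norm(c - a) for a in atoms) <= radius:
                            mask[i, j, k] = True
            if not mask.any():
                continue
            out = extract_component(m, atoms, radius)
            kept = np.where(mask)
            lo = [int(x.min()) for x in kept]
            hi = [int(x.max()) + 1 for x in kept]
            expected = np.where(mask, m.data, 0)[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            np.testing.assert_array_equal(out.data, expected)

    def test_origin_shift_keeps_world_coordinates(self, random_map):
        atom = random_map.world_coord((8, 3, 9))
        out = extract_component(random_map, [atom], radius=2.0)
        # the voxel at the atom's position must still map to the same world coord
        idx = np.round((atom - out.origin) / out.voxel_size).astype(int)
        np.testing.assert_allclose(out.world_coord(idx), atom, atol=1e-9)


class TestNormalize:
    def test_min_max_scaling(self):
        m = DensityMap(np.array([[[2.0, 4.0, 6.0]]], dtype=np.float32))
        np.testing.assert_allclose(normalize(m).data, [[[0.0, 0.5, 1.0]]])

    def test_constant_map_becomes_zero(self):
        m = DensityMap(np.full((4, 4, 4), 9.0, dtype=np.float32))
        assert not normalize(m).data.any()

    def test_unit_range_map_unchanged(self, rng):
        data = rng.random((5, 5, 5)).astype(np.float32)
        data.flat[0], data.flat[-1] = 0.0, 1.0
        m = DensityMap(data)
        np.testing.assert_allclose(normalize(m).data, data, atol=1e-7)


class TestPadding:
    def test_table_dims_pad_to_next_multiple_of_4(self):
        m = DensityMap(np.ones((57, 47, 42), dtype=np.float32))
        padded, spec = pad_for_network(m, divisor=4)
        assert padded.shape == (60, 48, 44)
        assert unpad(padded, spec).shape == (57, 47, 42)

    def test_multiples_get_zero_padding(self):
        m = DensityMap(np.ones((8, 12, 16), dtype=np.float32))
        padded, spec = pad_for_network(m, divisor=4)
        assert padded.shape == m.shape
        assert spec.pad_before == spec.pad_after == (0, 0, 0)

    def test_boundary_at_100_voxels(self):
        ok = DensityMap(np.zeros((100, 100, 100), dtype=np.float32))
        padded, _ = pad_for_network(ok, divisor=4)
        assert padded.shape == (100, 100, 100)
        # 99 pads to 100, which is still inside the envelope
        just_ok = DensityMap(np.zeros((99, 99, 99), dtype=np.float32))
        assert pad_for_network(just_ok, divisor=4)[0].shape == (100, 100, 100)
        too_big = DensityMap(np.zeros((101, 10, 10), dtype=np.float32))
        with pytest.raises(SizeLimitError):
            pad_for_network(too_big, divisor=4)

    def test_negative_padspec_rejected(self):
        with pytest.raises(ValueError):
            PadSpec((-1, 0, 0), (0, 0, 0))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(dims=st.tuples(*[st.integers(1, 40)] * 3), divisor=st.integers(1, 8))
    def test_unpad_inverts_pad_exactly(self, dims, divisor):
        data = np.arange(np.prod(dims), dtype=np.float32).reshape(dims)
        m = DensityMap(data, origin=(1.0, -2.0, 0.5))
        padded, spec = pad_for_network(m, divisor=divisor)
        back = unpad(padded, spec)
        np.testing.assert_array_equal(back.data, m.data)
        np.testing.assert_allclose(back.origin, m.origin)
        assert all(n % divisor == 0 for n in padded.shape)


def test_world_coordinate_round_trip(random_map):
    idx = (3, 7, 2)
    world = random_map.world_coord(idx)
    back = (world - random_map.origin) / random_map.voxel_size
    np.testing.assert_allclose(back, idx)
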