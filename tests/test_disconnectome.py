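"""Streamline voxelization and disconnection matrices vs brute force."""

import numpy as np
import pytest

from msnets import (
    ConnMatrix,
    GridMismatchError,
    LesionMask,
    StreamlineAtlas,
    disconnection_matrix,
    disconnection_probability_map,
    lesion_probability_map,
    log1p_tlv,
    node_strength,
    system_block_means,
    total_lesion_volume,
    voxelize_streamline,
)
from msnets.core import DomainError

GRID = (10, 12, 10)


def dense_voxels(polyline, grid, step=0.01):
    """Brute-force traversal oracle: sample every segment densely."""
    out = set()
    pts = np.asarray(polyline, float)
    out.add(tuple(np.floor(pts[0]).astype(int)))
    for p0, p1 in zip(pts[:-1], pts[1:]):
        n = max(2, int(np.linalg.norm(p1 - p0) / step))
        for t in np.linspace(0, 1, n):
            out.add(tuple(np.floor(p0 + t * (p1 - p0)).astype(int)))
    return out


def toy_atlas(streamlines, grid=GRID):
    return StreamlineAtlas(streamlines, grid, (2.0, 2.0, 2.0), space_tag="toy")


def toy_mask(data, grid=GRID):
    m = np.zeros(grid, dtype=np.uint8)
    for v in data:
        m[v] = 1
    return LesionMask(m, (2.0, 2.0, 2.0), space_tag="toy")


class TestVoxelize:
    def test_single_point(self):
        assert voxelize_streamline(np.array([[3.2, 4.9, 5.0]]), GRID) == [(3, 4, 5)]

    def test_axis_aligned_segment_hits_five_voxels(self):
        line = np.array([[1.5, 2.5, 2.5], [5.5, 2.5, 2.5]])
        got = voxelize_streamline(line, GRID)
        assert got == [(k, 2, 2) for k in range(1, 6)]

    def test_reversal_gives_same_voxel_set(self, rng):
        for _ in range(20):
            pts = rng.uniform(0.2, 9.0, size=(5, 3))
            a = set(voxelize_streamline(pts, GRID))
            b = set(voxelize_streamline(pts[::-1], GRID))
            assert a == b

    def test_matches_dense_sampling_oracle(self, rng):
        for _ in range(30):
            pts = rng.uniform(0.2, 9.5, size=(rng.integers(2, 6), 3))
            got = set(voxelize_streamline(pts, GRID))
            oracle = dense_voxels(pts, GRID)
            assert got >= oracle
            # traversal may legitimately include corner-grazing voxels the
            # sampler missed; anything extra must hug the sampled path
            extras = got - dense_voxels(pts, GRID, step=0.002)
            for v in extras:
                assert min(max(abs(a - b) for a, b in zip(v, o)) for o in oracle) <= 1
            assert len(extras) <= 2

    def test_out_of_bounds_point_rejected(self):
        with pytest.raises(ValueError):
            voxelize_streamline(np.array([[11.0, 1.0, 1.0]]), GRID)


class TestDisconnectionMatrix:
    def _random_instance(self, rng):
        n_nodes = int(rng.integers(3, 8))
        streamlines = []
        for _ in range(int(rng.integers(5, 40))):
            i, j = sorted(rng.choice(np.arange(1, n_nodes + 1), 2, replace=False))
            pts = rng.uniform(0.3, 9.5, size=(int(rng.integers(2, 5)), 3))
            streamlines.append(((int(i), int(j)), pts))
        atlas = toy_atlas(streamlines)
        mask = np.zeros(GRID, dtype=np.uint8)
        mask[rng.random(GRID) < 0.1] = 1
        return atlas, LesionMask(mask, (2., 2., 2.), space_tag="toy"), n_nodes

    def test_matches_per_streamline_brute_force(self, rng):
        for _ in range(15):
            atlas, mask, n_nodes = self._random_instance(rng)
            m = disconnection_matrix(mask, atlas, node_ids=np.arange(1, n_nodes + 1))
            hits, counts = {}, {}
            for pair, pts in atlas.streamlines:
                vox = dense_voxels(pts, GRID, step=0.005)
                hit = any(mask.data[v] for v in vox)
                counts[pair] = counts.get(pair, 0) + 1
                hits[pair] = hits.get(pair, 0) + int(hit)
            for pair, c in counts.items():
                a, b = pair[0] - 1, pair[1] - 1
                assert m.values[a, b] == pytest.approx(hits[pair] / c)

    def test_empty_mask_all_zero(self):
        atlas = toy_atlas([((1, 2), np.array([[1.5, 1.5, 1.5], [5.5, 5.5, 5.5]]))])
        m = disconnection_matrix(toy_mask([]), atlas)
        assert (m.values == 0).all()

    def test_full_mask_gives_one_everywhere_connected(self):
        atlas = toy_atlas([((1, 2), np.array([[1.5, 1.5, 1.5], [5.5, 5.5, 5.5]]))])
        full = LesionMask(np.ones(GRID, np.uint8), (2., 2., 2.), space_tag="toy")
        m = disconnection_matrix(full, atlas)
        assert m.values[0, 1] == 1.0
        assert m.structural_mask[0, 1]

    def test_half_transected_pair(self):
        lines = [((1, 2), np.array([[1.5, 1.5, z], [8.5, 1.5, z]])) for z in (1.5, 3.5, 5.5, 7.5)]
        atlas = toy_atlas(lines)
        mask = toy_mask([(4, 1, 1), (4, 1, 3)])     # cuts the z=1.5 and z=3.5 lines
        m = disconnection_matrix(mask, atlas)
        assert m.values[0, 1] == pytest.approx(0.5)

    def test_monotone_in_lesion_voxels(self, rng):
        atlas, mask, n_nodes = self._random_instance(rng)
        m1 = disconnection_matrix(mask, atlas, node_ids=np.arange(1, n_nodes + 1))
        grown = mask.data.copy()
        grown[rng.random(GRID) < 0.2] = 1
        m2 = disconnection_matrix(LesionMask(grown, (2., 2., 2.), space_tag="toy"),
                                  atlas, node_ids=np.arange(1, n_nodes + 1))
        assert (m2.values >= m1.values - 1e-12).all()

    def test_grid_mismatch_rejected(self):
        atlas = toy_atlas([((1, 2), np.array([[1.5, 1.5, 1.5], [5.5, 5.5, 5.5]]))])
        bad = LesionMask(np.zeros((4, 4, 4), np.uint8), (2., 2., 2.), space_tag="toy")
        with pytest.raises(GridMismatchError):
            disconnection_matrix(bad, atlas)


class TestProbabilityMaps:
    def test_identical_masks_idempotent(self):
        m = toy_mask([(1, 1, 1), (2, 2, 2)])
        np.testing.assert_array_equal(lesion_probability_map([m, m, m]), m.data)

    def test_two_disjoint_masks_average(self):
        a, b = toy_mask([(1, 1, 1)]), toy_mask([(5, 5, 5)])
        p = lesion_probability_map([a, b])
        assert p[1, 1, 1] == 0.5 and p[5, 5, 5] == 0.5 and p.sum() == 1.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            lesion_probability_map([])

    def test_single_transected_streamline_traces_itself(self):
        pts = np.array([[1.5, 1.5, 1.5], [7.5, 1.5, 1.5]])
        atlas = toy_atlas([((1, 2), pts)])
        mask = toy_mask([(3, 1, 1)])
        dmap = disconnection_probability_map([mask], atlas)
        vox = voxelize_streamline(pts, GRID)
        for v in vox:
            assert dmap[v] == 1.0
        assert dmap.sum() == len(vox)

    def test_map_bounded(self, rng):
        atlas = toy_atlas([((1, 2), rng.uniform(1, 9, (3, 3))) for _ in range(5)])
        masks = [toy_mask([(int(a), int(b), int(c))])
                 for a, b, c in rng.integers(0, 9, (4, 3))]
        dmap = disconnection_probability_map(masks, atlas)
        assert dmap.min() >= 0 and dmap.max() <= 1


class TestNodeSummaries:
    def _matrix(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = 0.5
        vals[0, 2] = vals[2, 0] = 0.25
        mask = vals > 0
        return ConnMatrix(vals, np.array([1, 2, 3]), "disconnection",
                          system_labels=np.array(["VIS", "VIS", "SM"]),
                          structural_mask=mask)

    def test_node_strength_hand_example(self):
        s = node_strength(self._matrix())
        np.testing.assert_allclose(s, [0.75, 0.5, 0.25])

    def test_handshake_identity(self, rng):
        v = rng.random((6, 6))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        m = ConnMatrix(v / v.max(), np.arange(6), "disconnection")
        assert node_strength(m).sum() == pytest.approx(2 * np.triu(m.values).sum())

    def test_block_means_hand_example(self):
        blocks, order = system_block_means(self._matrix())
        assert order == ["VIS", "SM"]
        assert blocks[0, 0] == pytest.approx(0.5)       # within VIS: edge (1,2)
        assert blocks[0, 1] == pytest.approx(0.125)     # VIS-SM: edges (1,3), (2,3)
        np.testing.assert_allclose(blocks, blocks.T)

    def test_constant_matrix_gives_constant_blocks(self):
        v = np.full((4, 4), 0.3)
        np.fill_diagonal(v, 0)
        m = ConnMatrix(v, np.arange(4), "similarity",
                       system_labels=np.array(["VIS", "VIS", "SM", "SM"]))
        blocks, _ = system_block_means(m)
        np.testing.assert_allclose(blocks, 0.3)

    def test_unknown_system_rejected(self):
        m = self._matrix()
        m.system_labels = np.array(["VIS", "XXX", "SM"])
        with pytest.raises(ValueError):
            system_block_means(m)


class TestLesionVolume:
    def test_volume_arithmetic(self):
        assert total_lesion_volume(toy_mask([])) == 0.0
        ten = toy_mask([(i, 0, 0) for i in range(10)])
        assert total_lesion_volume(ten) == pytest.approx(10 * 8.0)

    def test_log1p(self):
        assert log1p_tlv(0.0) == 0.0
        assert log1p_tlv(1.0) < log1p_tlv(2.0)
        with pytest.raises(DomainError):
            log1p_tlv(-1.0)
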