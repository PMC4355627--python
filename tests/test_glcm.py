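import numpy as np
import pytest

from voxtex import (
    QuantizedVolume,
    offsets_3d,
    offsets_plane,
    plane_disk,
    roi_glcm,
    spherical_neighborhood,
    vglcm3d_map,
    vglcm_top3d_map,
)
from voxtex.glcm import PLANE_NAMES

from oracle import oracle_vglcm_counts


class TestOffsets:
    @pytest.mark.parametrize("d, expected", [(1, 26), (2, 124), (3, 342)])
    def test_3d_cardinality(self, d, expected):
        assert len(offsets_3d(d)) == expected == (2 * d + 1) ** 3 - 1

    @pytest.mark.parametrize("d, expected", [(1, 8), (2, 24)])
    @pytest.mark.parametrize("plane", PLANE_NAMES)
    def test_plane_cardinality(self, d, expected, plane):
        offs = offsets_plane(d, plane)
        assert len(offs) == expected == (2 * d + 1) ** 2 - 1
        # out-of-plane component is zero
        fixed = {"axial": 2, "sagittal": 1, "coronal": 0}[plane]
        assert np.all(offs[:, fixed] == 0)

    @pytest.mark.parametrize("d, total", [(1, 24), (2, 72)])
    def test_total_offsets_over_planes(self, d, total):
        # offsets are counted once per plane they are computed in
        assert sum(len(offsets_plane(d, p)) for p in PLANE_NAMES) == total

    def test_negation_closure(self):
        for offs in (offsets_3d(2), offsets_plane(2, "coronal")):
            s = {tuple(o) for o in offs}
            assert {tuple(-o) for o in offs} == s
        with pytest.raises(ValueError):
            offsets_3d(0)
        with pytest.raises(ValueError):
            offsets_plane(0, "axial")


class TestNeighborhoods:
    def test_sphere_sizes(self):
        # lattice-ball cardinalities: R=1 -> 7 (center + 6 faces), R=2 -> 33
        assert len(spherical_neighborhood((3, 3, 3), 1, (7, 7, 7))) == 7
        assert len(spherical_neighborhood((3, 3, 3), 2, (7, 7, 7))) == 33
        # corner clipping
        assert len(spherical_neighborhood((0, 0, 0), 1, (7, 7, 7))) == 4

    def test_contains_center_and_bounds(self):
        n = spherical_neighborhood((1, 2, 3), 2, (6, 6, 6))
        assert (n == [1, 2, 3]).all(axis=1).any()
        assert n.min() >= 0 and n.max() < 6
        with pytest.raises(ValueError):
            spherical_neighborhood((9, 0, 0), 1, (5, 5, 5))

    def test_plane_disk_is_planar(self):
        d = plane_disk((3, 3, 3), 2, (7, 7, 7), "sagittal")
        assert len(d) == 13  # in-plane lattice disk of radius 2
        assert np.all(d[:, 1] == 3)  # x fixed on the sagittal plane


class TestRoiGLCM:
    def test_constant_region_point_mass(self):
        q = QuantizedVolume(np.full((3, 3, 3), 2), Ng=4, Qg=4)
        region = spherical_neighborhood((1, 1, 1), 1, (3, 3, 3))
        g = roi_glcm(q, region, offsets_3d(1))
        assert g.p[1, 1] == 1.0 and g.p.sum() == 1.0

    def test_single_voxel_region_degenerate(self):
        q = QuantizedVolume(np.full((3, 3, 3), 1), Ng=2, Qg=2)
        g = roi_glcm(q, np.array([[1, 1, 1]]), offsets_3d(1))
        assert g.degenerate and g.n_pairs == 0 and g.p.sum() == 0

    def test_2x2_checker_region(self):
        # 2x2x1 region [[1,2],[1,2]]: by hand, 4 horizontal ordered pairs
        # (1,2)/(2,1), 2 vertical (1,1), 2 vertical (2,2), 4 diagonal.
        data = np.ones((2, 2, 1), dtype=int)
        data[:, 1, 0] = 2
        q = QuantizedVolume(data, Ng=2, Qg=2)
        region = np.argwhere(np.ones((2, 2, 1), dtype=bool))
        g = roi_glcm(q, region, offsets_3d(1))
        assert g.n_pairs == 12
        np.testing.assert_array_equal(g.counts, [[2, 4], [4, 2]])


def _random_case(rng, case):
    """Small random volume + parameters; occasionally adds a mask."""
    n = int(rng.integers(3, 7))
    ng = int(rng.integers(2, 5))
    data = rng.integers(1, ng + 1, size=(n, n, n))
    R = int(rng.integers(1, 3))
    d = int(rng.integers(1, 3))
    mask = None
    if case % 5 == 0:
        mask = rng.random((n, n, n)) > 0.2
        mask[n // 2, n // 2, n // 2] = True
    return QuantizedVolume(data, Ng=ng, Qg=ng), R, d, mask


@pytest.mark.parametrize("case", range(12))
def test_vglcm3d_matches_bruteforce(case):
    """Vectorized spherical-neighborhood maps equal the exhaustive
    pair-enumeration reference at every voxel and entry."""
    rng = np.random.default_rng(1000 + case)
    qv, R, d, mask = _random_case(rng, case)
    gm = vglcm3d_map(qv, R=R, d=d, mask=mask)
    ref = oracle_vglcm_counts(qv.data, qv.Ng, R, d, "full3d", mask=mask)
    for vox, counts in ref.items():
        np.testing.assert_array_equal(gm.counts[vox], counts, err_msg=f"voxel {vox}")


@pytest.mark.parametrize("case", range(12))
def test_vglcm_top3d_matches_bruteforce(case):
    """Per-plane disk maps equal the per-plane exhaustive reference."""
    rng = np.random.default_rng(2000 + case)
    qv, R, d, mask = _random_case(rng, case)
    gms = vglcm_top3d_map(qv, R=R, d=d, mask=mask)
    ref = oracle_vglcm_counts(qv.data, qv.Ng, R, d, "top3d", mask=mask)
    for vox, planes in ref.items():
        for plane in PLANE_NAMES:
            np.testing.assert_array_equal(
                gms[plane].counts[vox], planes[plane], err_msg=f"{vox} {plane}"
            )


class TestMapInvariants:
    def test_normalization_and_symmetry(self, small_qvol):
        gm = vglcm3d_map(small_qvol, R=2, d=1)
        p = gm.probabilities()
        sums = p[gm.valid].sum(axis=(-2, -1))
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        # integer counts: symmetry is exact
        np.testing.assert_array_equal(gm.counts, gm.counts.swapaxes(-2, -1))

    def test_constant_volume_point_mass_everywhere(self):
        qv = QuantizedVolume(np.full((4, 4, 4), 3), Ng=4, Qg=4)
        gm = vglcm3d_map(qv, R=1, d=1)
        assert gm.valid.all()
        p = gm.probabilities()
        np.testing.assert_allclose(p[..., 2, 2], 1.0)
        for planes in vglcm_top3d_map(qv, R=1, d=1).values():
            np.testing.assert_allclose(planes.probabilities()[..., 2, 2], 1.0)

    def test_translation_equivariance(self, rng):
        data = rng.integers(1, 4, size=(6, 6, 6))
        qa = QuantizedVolume(data, Ng=3, Qg=3)
        qb = QuantizedVolume(np.roll(data, (1, 1, 1), axis=(0, 1, 2)), Ng=3, Qg=3)
        ga = vglcm3d_map(qa, R=1, d=1)
        gb = vglcm3d_map(qb, R=1, d=1)
        # compare interior voxels (distance > R + 1 from every face)
        s = slice(2, 4)
        np.testing.assert_array_equal(
            ga.counts[s, s, s], gb.counts[3:5, 3:5, 3:5]
        )

    def test_gray_level_permutation_equivariance(self, rng):
        data = rng.integers(1, 5, size=(5, 5, 5))
        perm = rng.permutation(4) + 1
        qa = QuantizedVolume(data, Ng=4, Qg=4)
        qb = QuantizedVolume(perm[data - 1], Ng=4, Qg=4)
        ga = vglcm3d_map(qa, R=1, d=1)
        gb = vglcm3d_map(qb, R=1, d=1)
        # entry (i, j) of the original equals entry (perm(i), perm(j)) after
        np.testing.assert_array_equal(
            ga.counts, gb.counts[..., perm - 1, :][..., :, perm - 1]
        )

    def test_z_ramp_axial_plane_is_single_level(self):
        """A volume varying only along z is constant within each axial
        plane, so axial GLCMs put all mass on the diagonal."""
        z = np.arange(1, 6)
        data = np.broadcast_to(z, (5, 5, 5)).copy()  # varies along last axis
        qv = QuantizedVolume(data, Ng=5, Qg=5)
        gms = vglcm_top3d_map(qv, R=2, d=1)
        p_axial = gms["axial"].probabilities()
        diag = np.einsum("...ii->...i", p_axial).sum(axis=-1)
        np.testing.assert_allclose(diag[gms["axial"].valid], 1.0)
        # sagittal/coronal planes see the gradient: off-diagonal mass exists
        p_sag = gms["sagittal"].probabilities()
        off = 1.0 - np.einsum("...ii->...i", p_sag).sum(axis=-1)
        assert off[gms["sagittal"].valid].max() > 0.1
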