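"""CT segmentation: region growing, closing, level set, isosurface."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest
import trimesh
from scipy import ndimage

from auriclometry.errors import ArgumentError
from auriclometry.segmentation import (
    CTVolume,
    SegmentationConfig,
    close_cavities,
    extract_isosurface,
    levelset_refine,
    reconstruct_head_surface,
    region_grow_threshold,
    segment_head,
)
from auriclometry.synthetic import ScanSpec, voxelize_to_ct


def bfs_flood_fill(above: np.ndarray, seed) -> np.ndarray:
    """Independent 26-connected BFS flood fill."""
    out = np.zeros_like(above)
    if not above[seed]:
        return out
    q = deque([seed])
    out[seed] = True
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    shape = above.shape
    while q:
        c = q.popleft()
        for o in offsets:
            n = (c[0] + o[0], c[1] + o[1], c[2] + o[2])
            if all(0 <= n[d] < shape[d] for d in range(3)) and above[n] and not out[n]:
                out[n] = True
                q.append(n)
    return out


def _ball_mask(shape, center, radius):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    return sum((g - c) ** 2 for g, c in zip(grids, center)) <= radius**2


def _vol(data, spacing=(1.0, 1.0, 1.0)):
    return CTVolume(np.asarray(data, dtype=np.float32), spacing)


class TestRegionGrow:
    def test_single_sphere_component(self):
        data = np.full((40, 40, 40), -1000.0)
        sphere = _ball_mask(data.shape, (20, 20, 20), 10)
        data[sphere] = 1200.0
        mask = region_grow_threshold(_vol(data), (20, 20, 20), 500.0)
        assert np.array_equal(mask, sphere)

    def test_disjoint_blob_not_included(self):
        data = np.full((40, 40, 40), -1000.0)
        a = _ball_mask(data.shape, (10, 10, 10), 5)
        b = _ball_mask(data.shape, (30, 30, 30), 5)
        data[a | b] = 900.0
        mask = region_grow_threshold(_vol(data), (10, 10, 10), 500.0)
        assert np.array_equal(mask, a)

    def test_matches_bfs_oracle_on_random_volume(self, rng):
        data = rng.normal(0, 600, size=(18, 18, 18)).astype(np.float32)
        above = data > 500.0
        seeds = np.argwhere(above)
        seed = tuple(seeds[0])
        mask = region_grow_threshold(_vol(data), seed, 500.0)
        assert np.array_equal(mask, bfs_flood_fill(above, seed))

    def test_seed_below_threshold_raises(self):
        data = np.full((5, 5, 5), -1000.0)
        with pytest.raises(ArgumentError):
            region_grow_threshold(_vol(data), (2, 2, 2), 500.0)


class TestCloseCavities:
    def test_hollow_shell_interior_filled(self):
        shape = (40, 40, 40)
        shell = _ball_mask(shape, (20, 20, 20), 12) & ~_ball_mask(shape, (20, 20, 20), 9)
        closed = close_cavities(shell, 3.0, (1, 1, 1))
        assert closed[20, 20, 20]
        assert closed[_ball_mask(shape, (20, 20, 20), 8)].all()

    def test_solid_block_unchanged(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[5:15, 5:15, 5:15] = True
        closed = close_cavities(mask, 2.0, (1, 1, 1))
        assert np.array_equal(closed, mask)

    def test_small_perforation_sealed_large_opening_not(self):
        shape = (48, 48, 48)
        c = (24, 24, 24)
        base = _ball_mask(shape, c, 14) & ~_ball_mask(shape, c, 11)

        def punch(mask, half_width):
            out = mask.copy()
            out[
                38 - 20 : 48,
                24 - half_width : 24 + half_width + 1,
                24 - half_width : 24 + half_width + 1,
            ] = False
            return out

        small_hole = punch(base, 1)  # ~3 voxel opening vs radius 4 element
        big_hole = punch(base, 8)  # ~17 voxel opening
        closed_small = close_cavities(small_hole, 4.0, (1, 1, 1))
        closed_big = close_cavities(big_hole, 4.0, (1, 1, 1))
        assert closed_small[c]
        assert not closed_big[c]

    def test_radius_below_voxel_raises(self):
        with pytest.raises(ArgumentError):
            close_cavities(np.ones((4, 4, 4), bool), 0.2, (1, 1, 1))


class TestSegmentHead:
    @staticmethod
    def _layered_phantom():
        shape = (60, 60, 60)
        c = (30, 30, 30)
        data = np.full(shape, -1000.0, dtype=np.float32)
        soft = _ball_mask(shape, c, 22)
        bone = _ball_mask(shape, c, 12) & ~_ball_mask(shape, c, 6)  # cavity inside
        data[soft] = 40.0
        data[bone] = 1200.0
        # thin 1-voxel notch in the soft-tissue surface
        data[30, 30, 51] = -1000.0
        return data, soft, bone, c

    def test_cavity_filled_notch_preserved(self):
        data, soft, bone, c = self._layered_phantom()
        cfg = SegmentationConfig(closing_radius_mm=8.0)
        mask = segment_head(_vol(data), cfg, bone_seed=(30, 30, 40), soft_seed=c)
        assert mask[c]  # bone cavity filled by the closing
        assert not mask[30, 30, 51]  # surface notch survives (no soft closing)
        assert mask[soft & (data > -500)].all()

    def test_missing_bone_raises(self):
        data = np.full((20, 20, 20), -1000.0, dtype=np.float32)
        data[_ball_mask(data.shape, (10, 10, 10), 6)] = 40.0
        with pytest.raises(ArgumentError):
            segment_head(_vol(data), SegmentationConfig(), (10, 10, 10), (10, 10, 10))

    def test_soft_flap_included(self, small_head):
        mesh, _ = small_head
        vol = voxelize_to_ct(mesh, ScanSpec(voxel_mm=(0.7, 0.7, 0.7), noise_sd_hu=0.0, seed=0))
        seed = np.unravel_index(int(np.argmax(vol.intensities)), vol.shape)
        mask = segment_head(vol, SegmentationConfig(), seed, seed)
        soft_voxels = vol.intensities > -500
        # every soft-tissue voxel (head + flap + stem) is reached
        assert (mask & soft_voxels).sum() / soft_voxels.sum() > 0.999

    def test_sandwich_property(self):
        data, *_ = self._layered_phantom()
        cfg = SegmentationConfig(closing_radius_mm=8.0)
        vol = _vol(data)
        mask = segment_head(vol, cfg, (30, 30, 40), (30, 30, 30))
        raw_soft = region_grow_threshold(vol, (30, 30, 30), cfg.soft_threshold_hu)
        assert (raw_soft <= mask).all()
        assert (mask <= close_cavities(raw_soft, cfg.closing_radius_mm, (1, 1, 1))).all()


class TestLevelSet:
    @staticmethod
    def _sphere_volume(noise=0.0, seed=0, spacing=0.5, radius=12.0):
        n = int(2 * (radius + 6) / spacing)
        grids = np.ogrid[:n, :n, :n]
        c = (n - 1) / 2
        r = np.sqrt(sum(((g - c) * spacing) ** 2 for g in grids))
        data = np.where(r <= radius, 40.0, -1000.0).astype(np.float32)
        if noise:
            data += np.random.default_rng(seed).normal(0, noise, data.shape).astype(np.float32)
        return CTVolume(data, (spacing,) * 3), r <= radius, radius, c, spacing

    def test_zero_iterations_is_signed_distance(self):
        vol, mask, *_ = self._sphere_volume()
        cfg = SegmentationConfig(levelset_iterations=0)
        phi = levelset_refine(vol, mask, cfg)
        expected = ndimage.distance_transform_edt(
            ~mask, sampling=vol.voxel_spacing
        ) - ndimage.distance_transform_edt(mask, sampling=vol.voxel_spacing)
        np.testing.assert_allclose(phi, expected, atol=1e-5)

    def test_noiseless_sphere_stays_on_edge(self):
        vol, mask, radius, c, spacing = self._sphere_volume()
        phi = levelset_refine(vol, mask, SegmentationConfig())
        mesh = extract_isosurface(-phi, 0.0, vol.voxel_spacing)
        r = np.linalg.norm(mesh.vertices - np.array([c * spacing] * 3), axis=1)
        assert np.abs(r - radius).max() <= spacing  # within one voxel

    def test_zero_level_confined_to_band(self):
        vol, mask, *_ = self._sphere_volume(noise=60.0, seed=4)
        cfg = SegmentationConfig(band_mm=2.0, levelset_iterations=40)
        phi0 = levelset_refine(vol, mask, SegmentationConfig(levelset_iterations=0))
        phi = levelset_refine(vol, mask, cfg)
        changed_sign = (phi < 0) != (phi0 < 0)
        assert np.abs(phi0[changed_sign]).max() <= cfg.band_mm + max(vol.voxel_spacing)

    def test_refinement_beats_binary_mask_under_noise(self):
        vol, _, radius, c, spacing = self._sphere_volume(noise=30.0, seed=7)
        cfg = SegmentationConfig()
        seed_idx = tuple(int(round(c)) for _ in range(3))
        mask = region_grow_threshold(vol, seed_idx, cfg.soft_threshold_hu)
        center = np.array([c * spacing] * 3)

        def rms_radial(m):
            r = np.linalg.norm(m.vertices - center, axis=1)
            return float(np.sqrt(np.mean((r - radius) ** 2)))

        phi = levelset_refine(vol, mask, cfg)
        refined = rms_radial(extract_isosurface(-phi, 0.0, vol.voxel_spacing))
        phi0 = levelset_refine(vol, mask, SegmentationConfig(levelset_iterations=0))
        binary = rms_radial(extract_isosurface(-phi0, 0.0, vol.voxel_spacing))
        assert refined <= binary

    def test_empty_mask_raises(self):
        vol, *_ = self._sphere_volume()
        with pytest.raises(ArgumentError):
            levelset_refine(vol, np.zeros(vol.shape, bool), SegmentationConfig())


class TestIsosurface:
    def test_sphere_distance_field(self):
        n = 101
        grids = np.ogrid[:n, :n, :n]
        c = (n - 1) / 2
        phi = np.sqrt(sum(((g - c) * 0.5) ** 2 for g in grids)) - 20.0
        mesh = extract_isosurface(phi.astype(np.float32), 0.0, (0.5, 0.5, 0.5))
        r = np.linalg.norm(mesh.vertices - c * 0.5, axis=1)
        assert np.abs(r - 20.0).max() <= np.linalg.norm([0.5, 0.5, 0.5])
        assert mesh.euler_number == 2
        assert abs(abs(mesh.volume) / (4 / 3 * np.pi * 20**3) - 1) < 0.01

    def test_torus_topology(self):
        n = 81
        grids = np.mgrid[:n, :n, :n].astype(float)
        c = (n - 1) / 2
        x, y, z = [(g - c) * 0.5 for g in grids]
        phi = (np.sqrt(x**2 + y**2) - 12.0) ** 2 + z**2 - 5.0**2
        mesh = extract_isosurface(phi.astype(np.float32), 0.0, (0.5, 0.5, 0.5))
        assert mesh.euler_number == 0

    def test_level_outside_range_raises(self):
        with pytest.raises(ArgumentError):
            extract_isosurface(np.ones((4, 4, 4)), 5.0)


class TestFullPipeline:
    def test_resolution_doubling_reduces_error(self):
        sphere = trimesh.creation.icosphere(4, radius=20.0)
        errors = {}
        for spacing in (1.0, 0.5):
            vol = voxelize_to_ct(
                sphere, ScanSpec(voxel_mm=(spacing,) * 3, noise_sd_hu=0.0, seed=1)
            )
            seed = np.unravel_index(int(np.argmax(vol.intensities)), vol.shape)
            mesh = reconstruct_head_surface(vol, None, bone_seed=seed, soft_seed=seed)
            r = np.linalg.norm(mesh.vertices - mesh.vertices.mean(axis=0), axis=1)
            errors[spacing] = float(np.sqrt(np.mean((r - 20.0) ** 2)))
        assert errors[0.5] < errors[1.0]
        assert errors[0.5] <= 0.5  # RMS within the voxel size
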