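"""Preprocessing, descriptor extraction and superpixel decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histograph import (
    DescriptorConfig,
    ImageRecord,
    denoise_anisotropic,
    extract_descriptors,
    extract_patches,
    segment_superpixels,
    to_grayscale,
)
from histograph.errors import InvalidInputError, InvalidParameterError
from histograph.imaging import load_descriptors, save_descriptors


def _record(pixels, id="img"):
    return ImageRecord(id=id, pixels=pixels)


# ---------------------------------------------------------------------------
# grayscale


class TestToGrayscale:
    def test_all_white_rgb_maps_to_ones(self):
        rec = _record(np.ones((32, 32, 3)))
        out = to_grayscale(rec)
        assert out.pixels.shape == (32, 32)
        np.testing.assert_allclose(out.pixels, 1.0)

    def test_grayscale_input_is_returned_unchanged(self):
        rec = _record(np.full((32, 32), 0.3))
        assert to_grayscale(rec) is rec

    def test_pure_red_gives_bt601_red_weight(self):
        rgb = np.zeros((32, 32, 3))
        rgb[:, :, 0] = 1.0
        out = to_grayscale(_record(rgb))
        np.testing.assert_allclose(out.pixels, 0.299)

    def test_luma_weights_applied_channelwise(self, rng):
        rgb = rng.uniform(size=(20, 24, 3))
        out = to_grayscale(_record(rgb))
        expected = 0.299 * rgb[:, :, 0] + 0.587 * rgb[:, :, 1] + 0.114 * rgb[:, :, 2]
        np.testing.assert_allclose(out.pixels, expected)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(InvalidInputError):
            ImageRecord(id="bad", pixels=np.ones((32, 32, 2)))


# ---------------------------------------------------------------------------
# anisotropic diffusion


def _diffusion_oracle(u, n_iter, kappa, gamma):
    """Direct per-pixel loop over the explicit Perona-Malik update."""
    u = u.copy()
    h, w = u.shape
    for _ in range(n_iter):
        nxt = u.copy()
        for r in range(h):
            for c in range(w):
                flux = 0.0
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w:
                        d = u[rr, cc] - u[r, c]
                        flux += np.exp(-((d / kappa) ** 2)) * d
                nxt[r, c] = u[r, c] + gamma * flux
        u = nxt
    return u


class TestDenoiseAnisotropic:
    def test_uniform_image_is_a_fixed_point(self):
        rec = _record(np.full((32, 32), 0.4))
        out = denoise_anisotropic(rec, n_iter=10, kappa=0.1, gamma=0.2)
        np.testing.assert_allclose(out.pixels, 0.4)

    def test_zero_iterations_returns_input_verbatim(self):
        rec = _record(np.random.default_rng(0).uniform(size=(32, 32)))
        assert denoise_anisotropic(rec, n_iter=0) is rec

    @pytest.mark.parametrize("gamma", [0.0, -0.1, 0.3, 1.0])
    def test_unstable_gamma_rejected(self, gamma):
        rec = _record(np.full((32, 32), 0.5))
        with pytest.raises(InvalidParameterError):
            denoise_anisotropic(rec, n_iter=1, gamma=gamma)

    def test_matches_direct_loop_oracle(self, rng):
        px = rng.uniform(0.2, 0.8, size=(18, 20))
        rec = _record(px)
        out = denoise_anisotropic(rec, n_iter=3, kappa=0.1, gamma=0.2)
        oracle = _diffusion_oracle(px, 3, 0.1, 0.2)
        np.testing.assert_allclose(out.pixels, np.clip(oracle, 0, 1), atol=1e-12)

    def test_mean_preserved_each_iteration(self, rng):
        px = rng.uniform(0.1, 0.9, size=(40, 40))
        prev = px.mean()
        rec = _record(px)
        for _ in range(5):
            rec = denoise_anisotropic(rec, n_iter=1, kappa=0.1, gamma=0.2)
            assert abs(rec.pixels.mean() - prev) < 1e-6
            prev = rec.pixels.mean()

    def test_preserves_edges_better_than_equal_variance_gaussian(self, rng):
        from scipy.ndimage import gaussian_filter

        # noisy step edge
        px = np.where(np.arange(64)[None, :] < 32, 0.25, 0.75) * np.ones((64, 1))
        px = np.clip(px + rng.normal(0, 0.05, size=px.shape), 0, 1)
        rec = _record(px)
        out = denoise_anisotropic(rec, n_iter=10, kappa=0.1, gamma=0.2).pixels

        flat = (slice(8, 56), slice(4, 24))
        var_pm = out[flat].var()
        assert var_pm <= 0.5 * px[flat].var()

        # match the flat-region variance with a Gaussian blur, then
        # compare the gradient magnitude across the true edge
        sigmas = np.linspace(0.3, 5, 60)
        blurs = [gaussian_filter(px, s) for s in sigmas]
        match = np.argmin([abs(b[flat].var() - var_pm) for b in blurs])
        gau = blurs[match]
        edge_grad = lambda im: np.abs(np.gradient(im, axis=1))[8:56, 30:34].max()
        assert edge_grad(out) > edge_grad(gau)


# ---------------------------------------------------------------------------
# descriptors


def _descriptor_oracle(px, starts, cfg):
    """Per-pixel loop: hard orientation binning, Gaussian weighting,
    cell pooling and the normalise/clip/renormalise/clip finish."""
    gy, gx = np.gradient(px)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), 2 * np.pi)
    p = cfg.patch_size
    cs = p // cfg.n_cells_per_side
    sigma = p / 2.0
    coords = np.arange(p) - (p - 1) / 2.0
    g1 = np.exp(-(coords**2) / (2 * sigma**2))
    out = []
    for r0, c0 in starts:
        desc = np.zeros((cfg.n_cells_per_side, cfg.n_cells_per_side, cfg.n_orientations))
        for i in range(p):
            for j in range(p):
                r, c = r0 + i, c0 + j
                b = min(
                    int(ang[r, c] / (2 * np.pi / cfg.n_orientations)),
                    cfg.n_orientations - 1,
                )
                desc[i // cs, j // cs, b] += mag[r, c] * g1[i] * g1[j]
        v = desc.ravel()
        n = np.linalg.norm(v)
        if n > 1e-12:
            v = np.minimum(v / n, cfg.clip_threshold)
            v = np.minimum(v / np.linalg.norm(v), cfg.clip_threshold)
        out.append(v)
    return np.array(out)


class TestExtractDescriptors:
    def test_standard_config_gives_128_dimensions(self, blob_image):
        dset = extract_descriptors(blob_image, DescriptorConfig())
        assert dset.d == 128
        assert dset.n_desc >= 1

    def test_constant_image_yields_zero_descriptors(self):
        dset = extract_descriptors(_record(np.full((48, 48), 0.5)))
        assert dset.n_desc > 0
        np.testing.assert_array_equal(dset.descriptors, 0.0)

    def test_too_small_image_rejected(self):
        rec = _record(np.random.default_rng(1).uniform(size=(16, 16)))
        cfg = DescriptorConfig(patch_size=32, n_cells_per_side=4)
        with pytest.raises(InvalidInputError):
            extract_descriptors(rec, cfg)

    def test_vertical_edge_concentrates_orientation_mass(self):
        # vertical stripes -> horizontal gradients -> bins at 0 and pi
        x = np.arange(64)
        px = np.clip(0.5 + 0.4 * np.sin(2 * np.pi * np.tile(x, (64, 1)) / 8), 0, 1)
        dset = extract_descriptors(_record(px), DescriptorConfig())
        cells = dset.descriptors.reshape(dset.n_desc, 16, 8)
        mass = cells.sum(axis=(0, 1))
        # bins 0 (angle ~0) and 4 (angle ~pi) carry the horizontal gradients
        assert (mass[0] + mass[4]) / mass.sum() > 0.95

    def test_matches_per_pixel_oracle(self, rng):
        px = rng.uniform(size=(40, 40))
        cfg = DescriptorConfig(grid_step=12)
        dset = extract_descriptors(_record(px), cfg)
        starts = (dset.locations - (cfg.patch_size - 1) / 2.0).astype(int)
        oracle = _descriptor_oracle(px, starts, cfg)
        np.testing.assert_allclose(dset.descriptors, oracle, atol=1e-10)

    def test_norm_and_clip_bounds(self, rng):
        px = rng.uniform(size=(64, 64))
        cfg = DescriptorConfig()
        dset = extract_descriptors(_record(px), cfg)
        norms = np.linalg.norm(dset.descriptors, axis=1)
        assert np.all(norms <= 1 + 1e-6)
        assert dset.descriptors.max() <= cfg.clip_threshold + 1e-6

    def test_rotating_image_permutes_orientation_bins(self):
        # a periodic grating: rotating the image by 90 deg rotates the
        # cell grid and shifts orientation bins by a quarter turn
        x = np.arange(64)
        px = np.clip(0.5 + 0.4 * np.sin(2 * np.pi * np.tile(x, (64, 1)) / 8), 0, 1)
        rot = np.rot90(px).copy()
        cfg = DescriptorConfig()
        d = extract_descriptors(_record(px), cfg).descriptors.mean(axis=0)
        dr = extract_descriptors(_record(rot), cfg).descriptors.mean(axis=0)
        cells = d.reshape(4, 4, 8)
        permuted = np.roll(np.rot90(cells, 1, axes=(0, 1)), -2, axis=2)
        np.testing.assert_allclose(permuted.ravel(), dr, atol=1e-8)

    @settings(max_examples=25, deadline=None)
    @given(
        n_orient=st.integers(2, 12),
        n_cells=st.integers(1, 4),
        cell_px=st.integers(2, 6),
    )
    def test_dimension_formula_holds_for_any_config(self, n_orient, n_cells, cell_px):
        cfg = DescriptorConfig(
            n_orientations=n_orient,
            n_cells_per_side=n_cells,
            patch_size=n_cells * cell_px,
            grid_step=7,
        )
        px = np.random.default_rng(0).uniform(size=(32, 32))
        dset = extract_descriptors(_record(px), cfg)
        assert dset.d == n_cells**2 * n_orient

    def test_interest_point_mode_returns_descriptors(self, blob_image):
        cfg = DescriptorConfig(sampling="interest_points")
        dset = extract_descriptors(blob_image, cfg)
        assert dset.n_desc >= 1
        assert dset.d == 128

    def test_descriptor_roundtrip(self, tmp_path, blob_image):
        dset = extract_descriptors(blob_image, DescriptorConfig(grid_step=32))
        save_descriptors(dset, tmp_path / "d.txt")
        back = load_descriptors(tmp_path / "d.txt")
        np.testing.assert_allclose(back.descriptors, dset.descriptors)
        np.testing.assert_allclose(back.locations, dset.locations)
        assert back.config == dset.config


# ---------------------------------------------------------------------------
# superpixels


class TestSuperpixels:
    def test_single_segment_covers_everything(self, blob_image):
        seg = segment_superpixels(blob_image, n_segments=1)
        assert seg.n_segments_actual == 1
        np.testing.assert_array_equal(seg.label_map, 0)

    def test_quadrant_image_recovers_quadrants(self, quadrant_image):
        rec, truth = quadrant_image
        seg = segment_superpixels(rec, n_segments=4)
        agree = 0
        for s in range(seg.n_segments_actual):
            _, counts = np.unique(truth[seg.label_map == s], return_counts=True)
            agree += counts.max()
        assert agree / truth.size >= 0.95

    def test_output_is_a_partition(self, fibre_image):
        seg = segment_superpixels(fibre_image, n_segments=20)
        ids, counts = np.unique(seg.label_map, return_counts=True)
        np.testing.assert_array_equal(ids, np.arange(seg.n_segments_actual))
        assert counts.sum() == fibre_image.pixels.size
        assert counts.min() >= 1

    def test_deterministic(self, blob_image):
        a = segment_superpixels(blob_image, 12, seed=3)
        b = segment_superpixels(blob_image, 12, seed=3)
        np.testing.assert_array_equal(a.label_map, b.label_map)

    def test_too_many_segments_rejected(self, blob_image):
        with pytest.raises(InvalidParameterError):
            segment_superpixels(blob_image, n_segments=10**7)


class TestExtractPatches:
    def test_single_segment_patch_equals_image(self, blob_image):
        seg = segment_superpixels(blob_image, n_segments=1)
        patches = extract_patches(blob_image, seg)
        assert len(patches) == 1
        np.testing.assert_array_equal(patches[0].pixels, blob_image.pixels)
        assert patches[0].id == f"{blob_image.id}#0"

    def test_quadrant_patches_have_quadrant_boxes(self, quadrant_image):
        rec, truth = quadrant_image
        seg = segment_superpixels(rec, n_segments=4)
        patches = extract_patches(rec, seg)
        assert len(patches) == seg.n_segments_actual
        for p in patches:
            h, w = p.pixels.shape
            assert 16 <= h <= 40 and 16 <= w <= 40

    def test_mismatched_segmentation_rejected(self, blob_image, fibre_image):
        seg = segment_superpixels(blob_image, n_segments=4)
        other = ImageRecord(id="o", pixels=np.full((64, 64), 0.5))
        with pytest.raises(InvalidInputError):
            extract_patches(other, seg)
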