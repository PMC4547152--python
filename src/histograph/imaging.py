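"""Image loading, preprocessing, local descriptors and superpixel patches.

The preprocessing chain mirrors common practice for H&E histology fields
of view: convert to grayscale, then smooth with edge-preserving
Perona-Malik anisotropic diffusion.  Local appearance is summarised by
SIFT-style descriptors: gradient-orientation histograms pooled over a
square grid of cells, Gaussian-weighted, normalised and clipped.  With
the conventional configuration (8 orientation bins, a 4x4 cell grid)
each descriptor has 4*4*8 = 128 dimensions.  Images can additionally be
decomposed into approximately homogeneous superpixel patches (SLIC) so
that heterogeneous tissue slides can be analysed patch by patch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "ImageRecord",
    "DescriptorConfig",
    "DescriptorSet",
    "SuperpixelSegmentation",
    "load_image",
    "to_grayscale",
    "denoise_anisotropic",
    "extract_descriptors",
    "segment_superpixels",
    "extract_patches",
    "save_descriptors",
    "load_descriptors",
]

# ITU-R BT.601 luma weights.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class ImageRecord:
    """One image of the collection.

    ``pixels`` holds intensities in [0, 1]; shape (H, W) once converted
    to grayscale, or (H, W, 3) for an RGB image fresh off disk.
    ``label`` carries an optional class name or ordinal annotation.
    """

    id: str
    pixels: np.ndarray
    source: str = "synthetic"
    label: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim not in (2, 3):
            raise InvalidInputError(
                f"image {self.id!r}: expected 2-D or 3-channel pixels, "
                f"got shape {self.pixels.shape}"
            )
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise InvalidInputError(
                f"image {self.id!r}: third axis must have 3 channels, "
                f"got {self.pixels.shape[2]}"
            )
        h, w = self.pixels.shape[:2]
        if h < 16 or w < 16:
            raise InvalidInputError(
                f"image {self.id!r}: minimum size is 16x16, got {h}x{w}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidInputError(f"image {self.id!r}: non-finite intensities")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise InvalidInputError(
                f"image {self.id!r}: intensities must lie in [0, 1]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class DescriptorConfig:
    """Configuration of the gradient-orientation descriptor extractor.

    ``n_orientations`` orientation bins over ``n_cells_per_side``^2
    spatial cells give descriptors of dimension
    ``n_cells_per_side**2 * n_orientations`` (128 for the 8 / 4x4
    default).  ``patch_size`` is the side of the square support window
    in pixels and must be divisible by ``n_cells_per_side``; in dense
    mode windows are placed every ``grid_step`` pixels.
    """

    n_orientations: int = 8
    n_cells_per_side: int = 4
    sampling: str = "dense_grid"
    grid_step: int = 8
    patch_size: int = 16
    clip_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.n_orientations < 1 or self.n_cells_per_side < 1:
            raise InvalidParameterError("orientation and cell counts must be >= 1")
        if self.sampling not in ("dense_grid", "interest_points"):
            raise InvalidParameterError(f"unknown sampling mode {self.sampling!r}")
        if self.grid_step < 1:
            raise InvalidParameterError("grid_step must be >= 1")
        if self.patch_size < self.n_cells_per_side:
            raise InvalidParameterError("patch_size smaller than the cell grid")
        if self.patch_size % self.n_cells_per_side:
            raise InvalidParameterError(
                "patch_size must be divisible by n_cells_per_side"
            )
        if not 0 < self.clip_threshold <= 1:
            raise InvalidParameterError("clip_threshold must lie in (0, 1]")

    @property
    def dim(self) -> int:
        return self.n_cells_per_side**2 * self.n_orientations


@dataclass
class DescriptorSet:
    """Local descriptors of one image: an ``n_desc x d`` matrix plus the
    (row, col) centre of each support window."""

    image_id: str
    descriptors: np.ndarray
    locations: np.ndarray
    config: DescriptorConfig | None = None

    @property
    def n_desc(self) -> int:
        return self.descriptors.shape[0]

    @property
    def d(self) -> int:
        return self.descriptors.shape[1]


@dataclass
class SuperpixelSegmentation:
    """A full partition of an image into superpixel segments.

    ``label_map`` assigns every pixel a segment id in
    ``0..n_segments_actual-1``; ``patches`` lists, per segment, its id,
    bounding box (r0, r1, c0, c1) as half-open pixel ranges, and the
    binary mask cropped to that box.
    """

    image_id: str
    label_map: np.ndarray
    n_segments_actual: int
    patches: list[tuple[int, tuple[int, int, int, int], np.ndarray]] = field(
        default_factory=list
    )


# ---------------------------------------------------------------------------
# loading / preprocessing


def load_image(path: str | Path, id: str | None = None) -> ImageRecord:
    """Read a PNG/TIFF/JPEG image and normalise intensities to [0, 1].

    8- and 16-bit integer images and float images are supported;
    grayscale stays single channel, RGB(A) is reduced to 3 channels.
    """
    import imageio.v3 as iio

    path = Path(path)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = np.clip(arr.astype(np.float64), 0.0, 1.0)
    return ImageRecord(id=id or path.stem, pixels=arr, source=str(path))


def to_grayscale(image: ImageRecord) -> ImageRecord:
    """Convert an RGB record to single-channel luminance (BT.601 weights
    0.299/0.587/0.114).  A record that is already single channel is
    returned unchanged."""
    if image.pixels.ndim == 2:
        return image
    if image.pixels.ndim != 3 or image.pixels.shape[2] != 3:
        raise InvalidInputError("to_grayscale expects 1 or 3 channels")
    gray = np.clip(image.pixels @ _LUMA, 0.0, 1.0)
    return replace(image, pixels=gray)


def denoise_anisotropic(
    image: ImageRecord,
    n_iter: int = 10,
    kappa: float = 0.1,
    gamma: float = 0.2,
) -> ImageRecord:
    """Perona-Malik anisotropic diffusion with exponential conduction.

    Explicit 4-neighbour scheme with Neumann (reflecting) boundaries:

        I <- I + gamma * sum_d g(|grad_d I|) * grad_d I,
        g(s) = exp(-(s / kappa)^2)

    ``gamma`` must lie in (0, 0.25] for stability of the explicit
    update.  ``n_iter = 0`` returns the input unchanged.  The scheme
    conserves total intensity, so flat regions are smoothed while
    strong edges (gradients well above ``kappa``) are preserved.
    """
    if n_iter < 0:
        raise InvalidParameterError("n_iter must be >= 0")
    if kappa <= 0:
        raise InvalidParameterError("kappa must be positive")
    if not 0 < gamma <= 0.25:
        raise InvalidParameterError("gamma must lie in (0, 0.25]")
    if image.pixels.ndim != 2:
        raise InvalidInputError("denoise_anisotropic expects a grayscale image")
    if n_iter == 0:
        return image

    u = image.pixels.copy()
    for _ in range(n_iter):
        # Neumann boundaries: zero flux across the border.
        dn = np.zeros_like(u)
        ds = np.zeros_like(u)
        de = np.zeros_like(u)
        dw = np.zeros_like(u)
        dn[1:, :] = u[:-1, :] - u[1:, :]
        ds[:-1, :] = u[1:, :] - u[:-1, :]
        de[:, :-1] = u[:, 1:] - u[:, :-1]
        dw[:, 1:] = u[:, :-1] - u[:, 1:]
        flux = sum(np.exp(-((d / kappa) ** 2)) * d for d in (dn, ds, de, dw))
        u = u + gamma * flux
    return replace(image, pixels=np.clip(u, 0.0, 1.0))


# ---------------------------------------------------------------------------
# descriptors


def _orientation_maps(pixels: np.ndarray, n_orientations: int):
    """Per-pixel gradient magnitude scattered into hard orientation bins.

    Returns an (n_orientations, H, W) stack; each pixel contributes its
    magnitude to exactly one bin (no interpolation across bins).
    """
    gy, gx = np.gradient(pixels)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), 2 * np.pi)
    bins = np.minimum(
        (ang / (2 * np.pi / n_orientations)).astype(np.intp), n_orientations - 1
    )
    h, w = pixels.shape
    omap = np.zeros((n_orientations, h * w))
    omap[bins.ravel(), np.arange(h * w)] = mag.ravel()
    return omap.reshape(n_orientations, h, w)


def _gaussian_window(patch_size: int) -> np.ndarray:
    """Isotropic Gaussian weight over the support window, sigma = half
    the window side (the usual SIFT choice)."""
    sigma = patch_size / 2.0
    r = np.arange(patch_size) - (patch_size - 1) / 2.0
    g = np.exp(-(r**2) / (2 * sigma**2))
    return np.outer(g, g)


def _finalize_descriptors(desc: np.ndarray, clip: float) -> np.ndarray:
    """Normalise raw cell histograms for illumination robustness.

    L2-normalise, clip every bin at ``clip``, renormalise, then clip
    once more.  The trailing clip keeps every bin below the threshold at
    the cost of a final norm slightly below one; zero-gradient windows
    stay exact zero vectors.
    """
    norms = np.linalg.norm(desc, axis=1, keepdims=True)
    nz = norms[:, 0] > 1e-12
    out = np.zeros_like(desc)
    out[nz] = desc[nz] / norms[nz]
    np.minimum(out, clip, out=out)
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    out[nz] = out[nz] / norms[nz]
    np.minimum(out, clip, out=out)
    return out


def _dense_starts(extent: int, patch: int, step: int) -> np.ndarray:
    return np.arange(0, extent - patch + 1, step)


def extract_descriptors(image: ImageRecord, config: DescriptorConfig | None = None) -> DescriptorSet:
    """Extract SIFT-style descriptors from a grayscale image.

    Each support window of ``patch_size`` pixels is divided into an
    ``n_cells_per_side`` x ``n_cells_per_side`` grid; per cell a
    histogram of gradient orientations (``n_orientations`` bins,
    magnitude- and Gaussian-weighted) is accumulated, and the cell
    histograms are concatenated (cell row-major, orientation fastest),
    normalised and clipped.  Dense mode tiles the image with windows
    every ``grid_step`` pixels; interest-point mode centres windows on
    DoG keypoints.
    """
    config = config or DescriptorConfig()
    px = image.pixels
    if px.ndim != 2:
        raise InvalidInputError("extract_descriptors expects a grayscale image")
    h, w = px.shape
    p = config.patch_size
    if h < p or w < p:
        raise InvalidInputError(
            f"image {image.id!r} ({h}x{w}) smaller than patch_size {p}"
        )

    if config.sampling == "dense_grid":
        r0s = _dense_starts(h, p, config.grid_step)
        c0s = _dense_starts(w, p, config.grid_step)
        starts = np.stack(
            [np.repeat(r0s, len(c0s)), np.tile(c0s, len(r0s))], axis=1
        )
    else:
        starts = _interest_point_starts(px, p)

    omap = _orientation_maps(px, config.n_orientations)
    gauss = _gaussian_window(p)
    ncell = config.n_cells_per_side
    cs = p // ncell

    # Strided window view over all valid window origins, then pick the
    # sampled ones; cells are pooled by a reshape-sum.
    win = sliding_window_view(omap, (p, p), axis=(1, 2))
    sel = win[:, starts[:, 0], starts[:, 1]]  # (n_orient, n_win, p, p)
    weighted = sel * gauss
    cells = weighted.reshape(
        config.n_orientations, len(starts), ncell, cs, ncell, cs
    ).sum(axis=(3, 5))
    # -> (n_win, cell_row, cell_col, orientation) flattened row-major
    desc = cells.transpose(1, 2, 3, 0).reshape(len(starts), config.dim)
    desc = _finalize_descriptors(desc, config.clip_threshold)
    centers = starts + (p - 1) / 2.0
    return DescriptorSet(
        image_id=image.id, descriptors=desc, locations=centers, config=config
    )


def _interest_point_starts(px: np.ndarray, patch: int) -> np.ndarray:
    """Window origins centred on DoG keypoints; falls back to a single
    centred window when detection finds nothing (e.g. flat images)."""
    from skimage.feature import SIFT

    h, w = px.shape
    try:
        det = SIFT()
        det.detect(px)
        kp = det.keypoints
    except (RuntimeError, ValueError):
        kp = np.empty((0, 2))
    if len(kp) == 0:
        kp = np.array([[h / 2.0, w / 2.0]])
    starts = np.round(kp - (patch - 1) / 2.0).astype(np.intp)
    starts[:, 0] = np.clip(starts[:, 0], 0, h - patch)
    starts[:, 1] = np.clip(starts[:, 1], 0, w - patch)
    return np.unique(starts, axis=0)


# ---------------------------------------------------------------------------
# superpixels


def segment_superpixels(
    image: ImageRecord,
    n_segments: int = 50,
    compactness: float = 0.5,
    seed: int = 0,
) -> SuperpixelSegmentation:
    """Partition an image into approximately homogeneous superpixels.

    SLIC (k-means in joint intensity-position space, initialised on a
    regular grid) on the grayscale intensities.  Orphan regions smaller
    than 5% of the mean segment size are merged into their largest
    neighbour, and labels are compacted to ``0..n_actual-1``.  The
    result is deterministic; ``seed`` is accepted for interface
    stability.  The achieved segment count can deviate from
    ``n_segments`` (by design up to ~25%).
    """
    from skimage.segmentation import slic

    px = image.pixels
    if px.ndim != 2:
        raise InvalidInputError("segment_superpixels expects a grayscale image")
    h, w = px.shape
    if n_segments < 1:
        raise InvalidParameterError("n_segments must be >= 1")
    if n_segments > h * w:
        raise InvalidParameterError("n_segments exceeds the pixel count")

    if n_segments == 1:
        labels = np.zeros((h, w), dtype=np.intp)
    else:
        labels = slic(
            px,
            n_segments=n_segments,
            compactness=compactness,
            start_label=0,
            channel_axis=None,
            enforce_connectivity=True,
        ).astype(np.intp)
        labels = _merge_orphans(labels)

    ids, labels = np.unique(labels, return_inverse=True)
    labels = labels.reshape(h, w)
    n_actual = len(ids)
    patches = []
    for seg in range(n_actual):
        rows, cols = np.nonzero(labels == seg)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        mask = labels[r0:r1, c0:c1] == seg
        patches.append((seg, (int(r0), int(r1), int(c0), int(c1)), mask))
    return SuperpixelSegmentation(
        image_id=image.id,
        label_map=labels,
        n_segments_actual=n_actual,
        patches=patches,
    )


def _merge_orphans(labels: np.ndarray) -> np.ndarray:
    """Fold segments smaller than 5% of the mean segment size into their
    most frequent neighbouring segment."""
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels, return_counts=True)
        threshold = 0.05 * counts.mean()
        small = ids[counts < threshold]
        if len(small) == 0 or len(ids) == 1:
            return labels
        merged_any = False
        for seg in small:
            mask = labels == seg
            # neighbours: pixels adjacent to the segment border
            from scipy.ndimage import binary_dilation

            ring = binary_dilation(mask) & ~mask
            neigh = labels[ring]
            neigh = neigh[neigh != seg]
            if len(neigh) == 0:
                continue
            vals, vc = np.unique(neigh, return_counts=True)
            labels[mask] = vals[np.argmax(vc)]
            merged_any = True
        if not merged_any:
            return labels


def extract_patches(
    image: ImageRecord, seg: SuperpixelSegmentation
) -> list[ImageRecord]:
    """Cut one patch record per superpixel segment.

    Each patch is the bounding-box crop of its segment; pixels outside
    the segment mask are filled with the patch mean intensity so that
    superpixel borders do not introduce artificial edges.  Patch ids are
    ``<image_id>#<segment_id>``.  Patches smaller than 16 px a side are
    padded with their mean to the minimum record size.
    """
    if image.pixels.ndim != 2:
        raise InvalidInputError("extract_patches expects a grayscale image")
    if seg.label_map.shape != image.pixels.shape:
        raise InvalidInputError("segmentation does not match the image shape")
    out = []
    for seg_id, (r0, r1, c0, c1), mask in seg.patches:
        crop = image.pixels[r0:r1, c0:c1]
        mean = crop[mask].mean()
        filled = np.where(mask, crop, mean)
        h, w = filled.shape
        if h < 16 or w < 16:
            padded = np.full((max(h, 16), max(w, 16)), mean)
            padded[:h, :w] = filled
            filled = padded
        out.append(
            ImageRecord(
                id=f"{image.id}#{seg_id}",
                pixels=filled,
                source=image.source,
                label=image.label,
            )
        )
    return out


# ---------------------------------------------------------------------------
# persistence


def save_descriptors(dset: DescriptorSet, path: str | Path) -> None:
    """Write descriptors as a whitespace-delimited matrix with a JSON
    sidecar (``<path>.json``) holding the extractor configuration."""
    path = Path(path)
    mat = np.hstack([dset.locations, dset.descriptors])
    np.savetxt(path, mat)
    meta = {
        "image_id": dset.image_id,
        "config": None
        if dset.config is None
        else {
            "n_orientations": dset.config.n_orientations,
            "n_cells_per_side": dset.config.n_cells_per_side,
            "sampling": dset.config.sampling,
            "grid_step": dset.config.grid_step,
            "patch_size": dset.config.patch_size,
            "clip_threshold": dset.config.clip_threshold,
        },
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def load_descriptors(path: str | Path) -> DescriptorSet:
    path = Path(path)
    mat = np.atleast_2d(np.loadtxt(path))
    meta = json.loads(Path(str(path) + ".json").read_text())
    config = DescriptorConfig(**meta["config"]) if meta["config"] else None
    return DescriptorSet(
        image_id=meta["image_id"],
        descriptors=mat[:, 2:],
        locations=mat[:, :2],
        config=config,
    )
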