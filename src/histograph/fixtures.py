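"""Synthetic textured image collections with known class structure.

Real histology fields of view are not required to exercise the
pipeline: two visually distinct texture families stand in for the
canonical tissue compartments.  "Blob" textures scatter dark ellipses
(nucleus-like profiles) on a light background, emulating epithelium-rich
fields; "fibre" textures are oriented quasi-periodic streak patterns
emulating stroma.  Class separation is controlled by contrast and
additive Gaussian noise, and every image is reproducible from its seed.
``neighbor_purity`` turns a labelled similarity graph into a single
separation score: the mean fraction of each node's neighbours that
share its class.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .imaging import ImageRecord
from .simgraph import SimilarityGraph

__all__ = [
    "TextureSpec",
    "SyntheticCollection",
    "default_specs",
    "generate_texture_image",
    "generate_collection",
    "neighbor_purity",
    "derive_seed",
]


@dataclass(frozen=True)
class TextureSpec:
    """Recipe for one texture class.

    density is expressed as motifs per 10^4 pixels; motif_scale is the
    characteristic motif size in pixels (ellipse semi-axis for blobs,
    fibre half-period for fibres); contrast in (0, 1] is the intensity
    depth of the motifs; orientation (degrees) applies to fibres.
    """

    class_name: str
    motif: str = "blobs"
    density: float = 2.5
    motif_scale: float = 8.0
    orientation: float = 0.0
    contrast: float = 0.8
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motif not in ("blobs", "fibres", "mixture"):
            raise InvalidParameterError(f"unknown motif {self.motif!r}")
        if self.density <= 0:
            raise InvalidParameterError("density must be positive")
        if not 0 < self.contrast <= 1:
            raise InvalidParameterError("contrast must lie in (0, 1]")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.motif_scale <= 0:
            raise InvalidParameterError("motif_scale must be positive")


@dataclass
class SyntheticCollection:
    images: list[ImageRecord]
    truth: dict[str, str]
    specs: list[TextureSpec]
    master_seed: int


def default_specs(
    contrast: float = 0.8, noise_sd: float = 0.05
) -> list[TextureSpec]:
    """The standard two-class study condition: blob-dominated
    epithelium-like fields vs fibre-dominated stroma-like fields."""
    return [
        TextureSpec(
            class_name="blobs",
            motif="blobs",
            density=2.5,
            motif_scale=8.0,
            contrast=contrast,
            noise_sd=noise_sd,
        ),
        TextureSpec(
            class_name="fibres",
            motif="fibres",
            density=2.5,
            motif_scale=6.0,
            orientation=30.0,
            contrast=contrast,
            noise_sd=noise_sd,
        ),
    ]


def derive_seed(master_seed: int, class_name: str, index: int) -> int:
    """Stable per-image seed: SHA-256 of (master_seed, class_name,
    index), folded to a non-negative 31-bit integer."""
    key = f"{master_seed}|{class_name}|{index}".encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _blob_field(
    rng: np.random.Generator, h: int, w: int, spec: TextureSpec
) -> np.ndarray:
    from skimage.draw import ellipse

    img = np.ones((h, w))
    n_blobs = max(1, round(spec.density * h * w / 1e4))
    low = 1.0 - spec.contrast
    for _ in range(n_blobs):
        r = rng.uniform(0, h)
        c = rng.uniform(0, w)
        a = spec.motif_scale * rng.uniform(0.6, 1.4)
        b = spec.motif_scale * rng.uniform(0.6, 1.4)
        angle = rng.uniform(0, np.pi)
        value = low + 0.1 * spec.contrast * rng.uniform(-1, 1)
        rr, cc = ellipse(r, c, a, b, shape=(h, w), rotation=angle)
        img[rr, cc] = np.minimum(img[rr, cc], np.clip(value, 0.0, 1.0))
    return img


def _fibre_field(
    rng: np.random.Generator, h: int, w: int, spec: TextureSpec
) -> np.ndarray:
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    theta = np.deg2rad(spec.orientation)
    # fibres run along (cos t, sin t) in (col, row); intensity varies
    # along the normal
    u = -np.sin(theta) * cols + np.cos(theta) * rows
    v = np.cos(theta) * cols + np.sin(theta) * rows
    wavelength = 2.0 * spec.motif_scale
    phase = rng.uniform(0, 2 * np.pi)
    stripes = 0.5 + 0.5 * np.sin(2 * np.pi * u / wavelength + phase)
    # mild along-fibre modulation so fibres look broken, not a pure grating
    mod = 0.85 + 0.15 * np.sin(
        2 * np.pi * v / (wavelength * 3.7) + rng.uniform(0, 2 * np.pi)
    )
    return 1.0 - spec.contrast * stripes * mod


def generate_texture_image(
    spec: TextureSpec, height: int = 256, width: int = 256
) -> ImageRecord:
    """Render one seeded texture image in [0, 1].

    blobs: random dark ellipses on a light background; fibres: an
    oriented quasi-periodic streak pattern; mixture: blobs on the left
    half, fibres on the right.  Gaussian noise of sd ``noise_sd`` is
    added and the result clipped to [0, 1].
    """
    if height < 32 or width < 32:
        raise InvalidParameterError("textures need height, width >= 32")
    rng = np.random.default_rng(spec.seed)
    if spec.motif == "blobs":
        img = _blob_field(rng, height, width, spec)
    elif spec.motif == "fibres":
        img = _fibre_field(rng, height, width, spec)
    else:  # mixture: half-and-half composite
        left = _blob_field(rng, height, width, spec)
        right = _fibre_field(rng, height, width, spec)
        img = np.hstack([left[:, : width // 2], right[:, width // 2 :]])
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return ImageRecord(
        id=f"{spec.class_name}_{spec.seed}",
        pixels=img,
        source="synthetic",
        label=spec.class_name,
    )


def generate_collection(
    n_per_class: int,
    specs: list[TextureSpec] | None = None,
    master_seed: int = 0,
    height: int = 256,
    width: int = 256,
) -> SyntheticCollection:
    """Generate ``n_per_class`` images for each texture class.

    Per-image seeds are derived deterministically from
    (master_seed, class_name, index), so regeneration with the same
    arguments is bitwise identical.
    """
    specs = specs if specs is not None else default_specs()
    if n_per_class < 1:
        raise InvalidParameterError("n_per_class must be >= 1")
    names = [s.class_name for s in specs]
    if len(set(names)) != len(names):
        raise InvalidInputError("duplicate class names in specs")
    if len(specs) < 2:
        raise InvalidInputError("need at least 2 texture classes")

    images: list[ImageRecord] = []
    truth: dict[str, str] = {}
    for spec in specs:
        for i in range(n_per_class):
            seed_i = derive_seed(master_seed, spec.class_name, i)
            img = generate_texture_image(
                replace(spec, seed=seed_i), height=height, width=width
            )
            img.id = f"{spec.class_name}_{i:03d}"
            images.append(img)
            truth[img.id] = spec.class_name
    return SyntheticCollection(
        images=images, truth=truth, specs=list(specs), master_seed=master_seed
    )


def neighbor_purity(g: SimilarityGraph, truth: dict[str, str]) -> float:
    """Mean over (non-isolated) nodes of the fraction of graph
    neighbours sharing the node's class; 1.0 means the graph separates
    the classes perfectly."""
    missing = [v for v in g.graph.nodes if v not in truth]
    if missing:
        raise InvalidInputError(f"nodes without truth label: {missing[:5]}")
    if g.graph.number_of_edges() == 0:
        raise InvalidInputError("graph has no edges")
    fracs = []
    for v in g.graph.nodes:
        neigh = list(g.graph.neighbors(v))
        if not neigh:
            continue
        same = sum(truth[u] == truth[v] for u in neigh)
        fracs.append(same / len(neigh))
    return float(np.mean(fracs))
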