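"""Visual codebook training and bag-of-features encoding.

A codebook is a set of k cluster centroids ("visual words") learned by
k-means over local descriptors sampled from the collection.  An image is
then represented as the L1-normalised histogram of nearest-word
assignments of its descriptors — its bag-of-features (BoFs) vector.
Euclidean geometry is used throughout so the histograms feed directly
into the similarity graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

from .errors import EmptyTrainingSetError, InvalidInputError, InvalidParameterError
from .imaging import DescriptorSet

__all__ = [
    "Codebook",
    "BoFsHistogram",
    "sample_training_descriptors",
    "train_codebook",
    "assign_words",
    "encode_bofs",
    "encode_collection",
    "save_codebook",
    "load_codebook",
    "save_histograms",
    "load_histograms",
]


@dataclass
class Codebook:
    """k_words x d matrix of descriptor-space centroids.

    ``inertia`` is the final within-cluster sum of squared distances;
    ``inertia_history`` records it per Lloyd iteration (non-increasing).
    """

    centers: np.ndarray
    seed: int
    inertia: float
    n_training: int
    inertia_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.centers.ndim != 2:
            raise InvalidInputError("codebook centers must be a 2-D matrix")
        if not np.all(np.isfinite(self.centers)):
            raise InvalidInputError("codebook centers must be finite")
        if len(np.unique(self.centers, axis=0)) != len(self.centers):
            raise InvalidInputError("codebook contains duplicate centers")

    @property
    def k_words(self) -> int:
        return self.centers.shape[0]

    @property
    def d(self) -> int:
        return self.centers.shape[1]


@dataclass
class BoFsHistogram:
    """Per-image word-frequency vector (sums to 1 when any descriptor
    was observed; all-zero for a descriptor-free image)."""

    image_id: str
    freqs: np.ndarray
    n_descriptors: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.freqs.ndim != 1 or np.any(self.freqs < -1e-12):
            raise InvalidInputError("freqs must be a non-negative vector")
        if self.n_descriptors > 0 and abs(self.freqs.sum() - 1.0) > 1e-9:
            raise InvalidInputError("non-empty histogram must sum to 1")

    @property
    def k_words(self) -> int:
        return len(self.freqs)


def sample_training_descriptors(
    descriptor_sets: list[DescriptorSet],
    per_image_cap: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Draw up to ``per_image_cap`` descriptors per image, uniformly
    without replacement, preserving image order.  Deterministic for a
    fixed seed.  Capping keeps densely sampled large images from
    dominating the codebook."""
    if per_image_cap < 1:
        raise InvalidParameterError("per_image_cap must be >= 1")
    if not descriptor_sets or all(ds.n_desc == 0 for ds in descriptor_sets):
        raise EmptyTrainingSetError("no descriptors available for training")
    rng = np.random.default_rng(seed)
    rows = []
    for ds in descriptor_sets:
        if ds.n_desc == 0:
            continue
        take = min(per_image_cap, ds.n_desc)
        idx = rng.choice(ds.n_desc, size=take, replace=False)
        rows.append(ds.descriptors[idx])
    return np.vstack(rows)


def train_codebook(
    descriptors: np.ndarray,
    k_words: int = 25,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> Codebook:
    """Lloyd's k-means with k-means++ initialisation.

    Iterates assignment / centroid-update steps until the largest
    centroid shift falls below ``tol`` or ``max_iter`` is reached.
    Clusters that empty out are reseeded to the point currently farthest
    from its assigned centre.  Inertia is recorded per iteration and is
    guaranteed non-increasing.
    """
    X = np.asarray(descriptors, dtype=np.float64)
    if X.ndim != 2:
        raise InvalidInputError("descriptors must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("descriptors must be finite")
    if k_words < 1:
        raise InvalidParameterError("k_words must be >= 1")
    if X.shape[0] < k_words:
        raise InvalidParameterError(
            f"need at least k_words={k_words} descriptors, got {X.shape[0]}"
        )

    rng = np.random.RandomState(seed)
    centers, _ = kmeans_plusplus(X, n_clusters=k_words, random_state=rng)
    history: list[float] = []
    for _ in range(max_iter):
        d2 = cdist(X, centers, "sqeuclidean")
        assign = np.argmin(d2, axis=1)
        inertia = float(d2[np.arange(len(X)), assign].sum())
        if history and inertia > history[-1] + 1e-9:  # Lloyd guarantee
            raise AssertionError("k-means inertia increased")
        history.append(inertia)

        new_centers = centers.copy()
        point_d2 = d2[np.arange(len(X)), assign]
        for j in range(k_words):
            members = assign == j
            if members.any():
                new_centers[j] = X[members].mean(axis=0)
            else:
                new_centers[j] = X[np.argmax(point_d2)]
                point_d2 = point_d2.copy()
                point_d2[np.argmax(point_d2)] = 0.0
        shift = np.max(np.linalg.norm(new_centers - centers, axis=1))
        centers = new_centers
        if shift < tol:
            break

    d2 = cdist(X, centers, "sqeuclidean")
    final_inertia = float(d2[np.arange(len(X)), np.argmin(d2, axis=1)].sum())
    if history and final_inertia > history[-1] + 1e-9:
        raise AssertionError("k-means inertia increased")
    history.append(final_inertia)
    return Codebook(
        centers=centers,
        seed=seed,
        inertia=final_inertia,
        n_training=len(X),
        inertia_history=history,
    )


def assign_words(dset: DescriptorSet, cb: Codebook) -> np.ndarray:
    """Nearest codebook centre (Euclidean) for every descriptor; ties go
    to the lowest word index."""
    if dset.d != cb.d:
        raise InvalidInputError(
            f"descriptor dimension {dset.d} != codebook dimension {cb.d}"
        )
    if dset.n_desc == 0:
        return np.empty(0, dtype=np.intp)
    d2 = cdist(dset.descriptors, cb.centers, "sqeuclidean")
    return np.argmin(d2, axis=1)


def encode_bofs(dset: DescriptorSet, cb: Codebook) -> BoFsHistogram:
    """Bag-of-features histogram: word-assignment counts divided by the
    descriptor count (relative frequencies).  An image with no
    descriptors encodes to the all-zero vector."""
    words = assign_words(dset, cb)
    counts = np.bincount(words, minlength=cb.k_words).astype(np.float64)
    n = dset.n_desc
    freqs = counts / n if n > 0 else counts
    return BoFsHistogram(image_id=dset.image_id, freqs=freqs, n_descriptors=n)


def encode_collection(
    descriptor_sets: list[DescriptorSet], cb: Codebook
) -> list[BoFsHistogram]:
    return [encode_bofs(ds, cb) for ds in descriptor_sets]


# ---------------------------------------------------------------------------
# persistence


def save_codebook(cb: Codebook, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, cb.centers)
    meta = {
        "k_words": cb.k_words,
        "d": cb.d,
        "seed": cb.seed,
        "inertia": cb.inertia,
        "n_training": cb.n_training,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def load_codebook(path: str | Path) -> Codebook:
    path = Path(path)
    centers = np.atleast_2d(np.loadtxt(path))
    meta = json.loads(Path(str(path) + ".json").read_text())
    return Codebook(
        centers=centers,
        seed=meta["seed"],
        inertia=meta["inertia"],
        n_training=meta["n_training"],
    )


def save_histograms(histograms: list[BoFsHistogram], path: str | Path) -> None:
    """CSV with an image_id column, an n_descriptors column and one
    ``w<j>`` frequency column per visual word."""
    if not histograms:
        raise InvalidInputError("no histograms to save")
    k = histograms[0].k_words
    df = pd.DataFrame(
        [h.freqs for h in histograms], columns=[f"w{j}" for j in range(k)]
    )
    df.insert(0, "n_descriptors", [h.n_descriptors for h in histograms])
    df.insert(0, "image_id", [h.image_id for h in histograms])
    df.to_csv(path, index=False, float_format="%.17g")


def load_histograms(path: str | Path) -> list[BoFsHistogram]:
    df = pd.read_csv(path)
    word_cols = [c for c in df.columns if c.startswith("w")]
    return [
        BoFsHistogram(
            image_id=str(row["image_id"]),
            freqs=row[word_cols].to_numpy(dtype=np.float64),
            n_descriptors=int(row["n_descriptors"]),
        )
        for _, row in df.iterrows()
    ]
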