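"""End-to-end orchestration: images -> BoFs histograms -> k-NN graph.

``run_pipeline`` chains the stages — grayscale conversion, anisotropic
diffusion, dense descriptor extraction, codebook training (or reuse),
BoFs encoding, pairwise distances, k-NN graph construction and
force-directed layout — logging one structured line per stage.  The
same configuration and inputs always produce identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import codebook as cb_mod
from . import imaging, simgraph
from .codebook import BoFsHistogram, Codebook
from .errors import InvalidInputError
from .imaging import DescriptorConfig, ImageRecord
from .simgraph import SimilarityGraph

logger = logging.getLogger("histograph")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_image_dir"]


@dataclass
class PipelineConfig:
    """Every tunable of the standard pipeline in one place.

    Defaults follow the conventional configuration: 128-D descriptors
    (8 orientations, 4x4 cells) sampled densely every 8 px, 10
    diffusion iterations, a 25-word codebook, a k = 3 neighbour graph
    and a 300-iteration seeded force-directed layout.
    """

    descriptor: DescriptorConfig = field(default_factory=DescriptorConfig)
    diffusion_n_iter: int = 10
    diffusion_kappa: float = 0.1
    diffusion_gamma: float = 0.2
    k_words: int = 25
    codebook_seed: int = 0
    per_image_cap: int = 500
    sampling_seed: int = 0
    k_nn: int = 3
    layout_seed: int = 7
    layout_n_iter: int = 300
    word_subset: list[int] | None = None

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["descriptor"] = DescriptorConfig(**d["descriptor"])
        return cls(**d)


@dataclass
class PipelineResult:
    histograms: list[BoFsHistogram]
    graph: SimilarityGraph
    coords: dict[str, tuple[float, float]]
    codebook: Codebook
    log: list[str] = field(default_factory=list)


def load_image_dir(image_dir: str | Path) -> list[ImageRecord]:
    """Read every PNG/TIFF/JPEG in a directory (sorted by name);
    unreadable files are skipped with a warning."""
    image_dir = Path(image_dir)
    exts = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
    records = []
    for path in sorted(image_dir.iterdir()):
        if path.suffix.lower() not in exts:
            continue
        try:
            records.append(imaging.load_image(path))
        except Exception as exc:  # unreadable file: warn and move on
            logger.warning("skipping unreadable image %s: %s", path, exc)
    return records


def run_pipeline(
    images: list[ImageRecord],
    config: PipelineConfig | None = None,
    codebook: Codebook | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full representation + graph pipeline over a collection.

    When ``codebook`` is given it is reused; otherwise one is trained
    from descriptors sampled across the collection.  If ``out_dir`` is
    set, histograms (CSV), the graph with layout (GraphML) and the
    stage log are written there.
    """
    config = config or PipelineConfig()
    if len(images) < 2:
        raise InvalidInputError("pipeline needs at least 2 images")
    log: list[str] = []

    def stage(name: str, t0: float, **info) -> None:
        line = f"stage={name} " + " ".join(f"{k}={v}" for k, v in info.items())
        line += f" wall_s={time.perf_counter() - t0:.2f}"
        logger.info(line)
        log.append(line)

    t0 = time.perf_counter()
    gray = [imaging.to_grayscale(im) for im in images]
    smooth = [
        imaging.denoise_anisotropic(
            im,
            n_iter=config.diffusion_n_iter,
            kappa=config.diffusion_kappa,
            gamma=config.diffusion_gamma,
        )
        for im in gray
    ]
    stage("preprocess", t0, n_images=len(smooth), n_iter=config.diffusion_n_iter)

    t0 = time.perf_counter()
    dsets = [imaging.extract_descriptors(im, config.descriptor) for im in smooth]
    stage(
        "extract",
        t0,
        n_images=len(dsets),
        n_descriptors=sum(ds.n_desc for ds in dsets),
        dim=config.descriptor.dim,
    )

    if codebook is None:
        t0 = time.perf_counter()
        training = cb_mod.sample_training_descriptors(
            dsets, per_image_cap=config.per_image_cap, seed=config.sampling_seed
        )
        codebook = cb_mod.train_codebook(
            training, k_words=config.k_words, seed=config.codebook_seed
        )
        stage(
            "codebook",
            t0,
            k_words=codebook.k_words,
            n_training=codebook.n_training,
            inertia=f"{codebook.inertia:.4f}",
        )

    t0 = time.perf_counter()
    histograms = cb_mod.encode_collection(dsets, codebook)
    stage("encode", t0, n_histograms=len(histograms), k_words=codebook.k_words)

    t0 = time.perf_counter()
    if config.word_subset is not None:
        from .feature_select import subset_and_rebuild

        graph = subset_and_rebuild(
            histograms, config.word_subset, k_nn=config.k_nn
        )
    else:
        D = simgraph.pairwise_distances(histograms)
        graph = simgraph.build_knn_graph(D, k_nn=config.k_nn)
    stage(
        "graph",
        t0,
        n_nodes=graph.graph.number_of_nodes(),
        n_edges=graph.graph.number_of_edges(),
        k_nn=config.k_nn,
    )

    t0 = time.perf_counter()
    coords = simgraph.layout_force_directed(
        graph, seed=config.layout_seed, n_iter=config.layout_n_iter
    )
    graph.coords = coords
    stage("layout", t0, n_iter=config.layout_n_iter, seed=config.layout_seed)

    result = PipelineResult(
        histograms=histograms,
        graph=graph,
        coords=coords,
        codebook=codebook,
        log=log,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cb_mod.save_histograms(histograms, out_dir / "histograms.csv")
        cb_mod.save_codebook(codebook, out_dir / "codebook.txt")
        simgraph.export_graph(graph, out_dir / "graph.graphml", format="graphml")
        (out_dir / "pipeline.log").write_text("\n".join(log) + "\n")
        (out_dir / "config.json").write_text(config.to_json())
    return result
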