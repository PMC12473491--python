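"""End-to-end orchestration: preprocess -> semantic -> instances -> traits.

Each stage writes its artifact (cleaned PLY, labelled TXT, instance TXT,
trait CSV) plus a manifest JSON recording parameters and per-stage point
counts, so any stage can be re-run from the previous stage's output.

The semantic stage normally runs a trained segmentation model. A purely
geometric fallback classifier (stem by distance to the plant axis, petiole
by local linearity, leaf otherwise) is provided so the downstream stages
can be exercised without trained weights; it is a test harness, not a
replacement for the learned segmenter.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import LEAF, PETIOLE, STEM, LabeledCloud, PointCloud, TraitReport
from .io import read_ply, write_labeled_txt, write_ply, write_trait_report
from .leaf_instance import ClusterParams, segment_leaves
from .network import CAVFPointNetSegmenter, predict_semantics
from .preprocess import PointCloudPreprocessor, PreprocessParams, cube_edge_length, scale_factor
from .traits import extract_all_traits


class GeometricOrganClassifier:
    """Heuristic stem/petiole/leaf labelling from geometry alone.

    Stem: points radially close to the plant's principal axis. Petiole:
    remaining points whose local neighborhood is strongly linear. Leaf:
    everything else. Useful as a stand-in semantic stage when no trained
    model is available; noticeably cruder than the learned segmenter.
    """

    def __init__(self, stem_radius_quantile: float = 0.9,
                 linearity_threshold: float = 0.75, k: int = 15):
        self.stem_radius_quantile = stem_radius_quantile
        self.linearity_threshold = linearity_threshold
        self.k = k

    def fit_predict(self, cloud: PointCloud) -> np.ndarray:
        from sklearn.neighbors import NearestNeighbors

        coords = cloud.coords
        centroid = coords.mean(axis=0)
        centered = coords - centroid
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        axial = centered @ axis
        radial = np.linalg.norm(centered - np.outer(axial, axis), axis=1)
        # estimate the stem radius from the base of the plant, which is
        # almost pure stem in an upright reconstruction; the PCA axis sign
        # is arbitrary, so take whichever end is radially tighter
        lo = axial <= np.quantile(axial, 0.05)
        hi = axial >= np.quantile(axial, 0.95)
        q_lo = np.quantile(radial[lo], self.stem_radius_quantile)
        q_hi = np.quantile(radial[hi], self.stem_radius_quantile)
        r_thresh = 1.5 * min(q_lo, q_hi)
        labels = np.full(coords.shape[0], LEAF, dtype=np.int64)
        labels[radial <= r_thresh] = STEM
        rest = np.flatnonzero(labels != STEM)
        if rest.size > self.k:
            nn = NearestNeighbors(n_neighbors=self.k + 1).fit(coords[rest])
            _, idx = nn.kneighbors(coords[rest])
            neigh = coords[rest][idx[:, 1:]]
            centered_n = neigh - neigh.mean(axis=1, keepdims=True)
            cov = np.einsum("nki,nkj->nij", centered_n, centered_n)
            eig = np.linalg.eigvalsh(cov)[:, ::-1]
            with np.errstate(invalid="ignore", divide="ignore"):
                linearity = (eig[:, 0] - eig[:, 1]) / eig[:, 0]
            labels[rest[linearity > self.linearity_threshold]] = PETIOLE
        return labels


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`."""

    input_ply: str | Path | None = None
    labeled_txt: str | Path | None = None      # start after the semantic stage
    output_dir: str | Path = "pipeline_out"
    run_preprocess: bool = True
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    semantic: str = "geometric"                # "network" | "geometric" | "skip"
    model: CAVFPointNetSegmenter | None = None
    cluster: ClusterParams = field(default_factory=ClusterParams)
    scale_r: float | None = None
    cube_ply: str | Path | None = None
    cube_real_edge_cm: float = 2.0
    slice_height_cm: float = 2.0
    slab_cm: float = 0.4
    width_mode: str = "leaf-frame"
    min_leaf_points: int = 30
    seed: int = 0


def run_pipeline(cfg: PipelineConfig) -> tuple[TraitReport, dict]:
    """Execute the enabled stages in order and write per-stage artifacts.

    Returns the trait report and a manifest with parameters and per-stage
    point counts. A stage failure raises with the stage name attached;
    artifacts of completed stages stay on disk.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": cfg.seed}
    t0 = time.time()

    def record(stage: str, n_points: int, **extra) -> None:
        manifest["stages"].append({"stage": stage, "points": int(n_points), **extra})

    try:
        if cfg.labeled_txt is not None:
            from .io import read_labeled_txt

            labeled = read_labeled_txt(cfg.labeled_txt)
            record("load_labeled", len(labeled))
        else:
            if cfg.input_ply is None:
                raise ValueError("need input_ply or labeled_txt")
            cloud = read_ply(cfg.input_ply)
            record("load", len(cloud))
            if cfg.run_preprocess:
                pre = PointCloudPreprocessor.from_params(cfg.preprocess)
                cloud = pre.transform(cloud)
                for stage, count in pre.stage_counts_[1:]:
                    record(f"preprocess/{stage}", count)
                write_ply(cloud, out / "clean.ply")
            if cfg.semantic == "network":
                if cfg.model is None:
                    raise ValueError("semantic='network' needs a trained model")
                labeled = predict_semantics(cloud, cfg.model)
            elif cfg.semantic == "geometric":
                labels = GeometricOrganClassifier().fit_predict(cloud)
                labeled = LabeledCloud(cloud, labels)
            else:
                raise ValueError(
                    "semantic must be 'network' or 'geometric' when starting from PLY"
                )
            record("semantic", len(labeled), classes={
                "stem": int((labeled.semantic == STEM).sum()),
                "petiole": int((labeled.semantic == PETIOLE).sum()),
                "leaf": int((labeled.semantic == LEAF).sum()),
            })
            write_labeled_txt(labeled, out / "labeled.txt")

        # leaf instances
        leaf_mask = labeled.semantic == LEAF
        if not leaf_mask.any():
            raise ValueError("no leaf points after the semantic stage")
        instances = segment_leaves(labeled.cloud.select(leaf_mask), cfg.cluster)
        all_instances = np.full(len(labeled), -1, dtype=np.int64)
        all_instances[np.flatnonzero(leaf_mask)] = instances.instance
        labeled = LabeledCloud(labeled.cloud, labeled.semantic, all_instances)
        n_instances = int(instances.instance.max()) + 1 if instances.instance.size else 0
        record("instances", len(labeled), n_instances=n_instances,
               noise=int((instances.instance < 0).sum()))
        write_labeled_txt(labeled, out / "instances.txt", include_instance=True)

        # scale
        if cfg.scale_r is not None:
            r = cfg.scale_r
        elif cfg.cube_ply is not None:
            edge = cube_edge_length(read_ply(cfg.cube_ply))
            r = scale_factor(cfg.cube_real_edge_cm, edge)
        else:
            r = 1.0
        manifest["scale_factor"] = r

        report = extract_all_traits(
            labeled, None, r,
            min_leaf_points=cfg.min_leaf_points,
            slice_height=cfg.slice_height_cm,
            slab=cfg.slab_cm,
            width_mode=cfg.width_mode,
        )
        record("traits", len(labeled), leaves=len(report.leaves),
               skipped=len(report.skipped))
        write_trait_report(report, out / "traits.csv")
    except Exception as err:
        manifest["error"] = str(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    manifest["wall_time_s"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report, manifest
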