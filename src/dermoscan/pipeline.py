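"""End-to-end orchestration, evaluation metrics and the experiment runner.

``analyze_image`` chains the five stages — key-point detection,
background/palette/shape filtering, cluster extraction, histogram
screening, CNN classification — and produces an ``AnalysisReport`` whose
``alert`` flag is true iff at least one cluster was classified
suspicious.  ``evaluate`` computes the confusion counts and the nine
derived quality measures (accuracy, precision, sensitivity, specificity,
fall-out, false-negative rate, negative predictive rate, false-discovery
rate, F-measure).  ``run_experiment`` trains the classifier on a labeled
cluster dataset with a stratified split and reports those measures.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from . import cnn as cnn_mod
from . import imgio
from .clusterer import Cluster, ClusterParams, clusters_from_image
from .cnn import CnnClassifier, CnnModel
from .kpfilter import (BackgroundReference, SkinPalette, DEFAULT_SKIN_PALETTE,
                       filter_background, filter_elongated, filter_palette)
from .scalespace import SiftParams, detect_keypoints
from .screening import NevusDatabase, blur_cluster, screen_cluster

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "ConfusionCounts",
    "Metrics",
    "analyze_image",
    "evaluate",
    "run_experiment",
    "load_ph2",
    "dataset_to_arrays",
    "default_nevus_database",
]


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end analysis in one place."""

    sift: SiftParams = field(default_factory=SiftParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    palette: SkinPalette = field(default_factory=lambda: DEFAULT_SKIN_PALETTE)
    pos_tol: int = 2
    color_tol: int = 20
    aspect_limit: float = 5.0
    screen_margin: float = 1.0
    suspicious_threshold: float = 0.5
    results_store: str | None = None  # path of the local JSON results store


@dataclass
class AnalysisReport:
    image_id: str
    records: list[dict]
    stage_counts: dict[str, int]
    alert: bool
    error: str | None = None
    timestamp: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


@dataclass(frozen=True)
class Metrics:
    """The nine derived quality measures; undefined ratios are NaN."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    fall_out: float
    false_negative_rate: float
    negative_predictive_rate: float
    false_discovery_rate: float
    f_measure: float

    @classmethod
    def from_counts(cls, c: ConfusionCounts) -> "Metrics":
        if c.total < 1:
            raise ValueError("need at least one prediction")
        precision = _ratio(c.TP, c.TP + c.FP)
        sensitivity = _ratio(c.TP, c.TP + c.FN)
        if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
            f_measure = math.nan
        else:
            f_measure = 2.0 * precision * sensitivity / (precision + sensitivity)
        return cls(
            accuracy=_ratio(c.TP + c.TN, c.total),
            precision=precision,
            sensitivity=sensitivity,
            specificity=_ratio(c.TN, c.TN + c.FP),
            fall_out=_ratio(c.FP, c.FP + c.TN),
            false_negative_rate=_ratio(c.FN, c.FN + c.TP),
            negative_predictive_rate=_ratio(c.TN, c.TN + c.FN),
            false_discovery_rate=_ratio(c.FP, c.FP + c.TP),
            f_measure=f_measure,
        )


def f_measure(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity."""
    if precision + sensitivity == 0:
        return math.nan
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def evaluate(predictions: list, truth: list, positive_class="suspicious") -> tuple[ConfusionCounts, Metrics]:
    """Confusion counts and quality measures for one decision class.

    Positive means "the classifier assigned *positive_class*"; TP/TN/FP/FN
    follow the usual one-vs-rest definitions.
    """
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must have equal length")
    if not predictions:
        raise ValueError("need at least one prediction")
    tp = tn = fp = fn = 0
    for p, t in zip(predictions, truth):
        if t == positive_class:
            if p == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:
                tn += 1
    counts = ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)
    return counts, Metrics.from_counts(counts)


def _as_model(model) -> CnnModel:
    return model.model_ if isinstance(model, CnnClassifier) else model


def analyze_image(
    img: np.ndarray,
    model: CnnModel | CnnClassifier,
    ref: BackgroundReference | None,
    db: NevusDatabase,
    config: PipelineConfig | None = None,
    image_id: str = "image",
) -> AnalysisReport:
    """Run the full pipeline on one photo.

    Stage order: detect key points on the grayscale image, drop
    background/off-palette/elongated points, extract clusters, screen by
    histogram, blur and classify the forwarded clusters.  Survivor counts
    per stage are recorded; any stage failure yields a report with an
    error status and no alert.
    """
    config = config or PipelineConfig()
    counts: dict[str, int] = {}
    records: list[dict] = []
    try:
        net = _as_model(model)
        img = np.asarray(img)
        gray = imgio.to_gray(img)
        kps = detect_keypoints(gray, config.sift, descriptors=False)
        counts["keypoints"] = len(kps)
        if ref is not None:
            kps = filter_background(kps, img, ref, config.pos_tol, config.color_tol)
        counts["after_background"] = len(kps)
        kps = filter_palette(kps, img, config.palette)
        counts["after_palette"] = len(kps)
        kps = filter_elongated(kps, img, config.aspect_limit, config.cluster.color_tol)
        counts["after_elongated"] = len(kps)
        clusters = clusters_from_image(img, kps, config.cluster)
        counts["clusters"] = len(clusters)
        forwarded = 0
        for cluster in clusters:
            decision = screen_cluster(cluster, db, config.screen_margin)
            record = {
                "keypoint": {"x": cluster.source_keypoint.x,
                             "y": cluster.source_keypoint.y,
                             "sigma": cluster.source_keypoint.sigma},
                "bbox": list(cluster.bbox),
                "region_size": cluster.region_size,
                "forwarded": decision.forward,
                "similarity_nevus": decision.best_similarity_nevus,
                "similarity_skin": decision.best_similarity_skin,
                "label": None,
                "score": None,
            }
            if decision.forward:
                forwarded += 1
                blur_cluster(cluster)
                label, score = cnn_mod.predict(net, cluster)
                if score >= config.suspicious_threshold:
                    label = "suspicious"
                record["label"] = label
                record["score"] = score
            records.append(record)
        counts["forwarded"] = forwarded
        alert = any(r["label"] == "suspicious" for r in records)
        report = AnalysisReport(
            image_id=image_id, records=records, stage_counts=counts,
            alert=alert, timestamp=_dt.datetime.now().isoformat())
    except Exception as exc:  # a stage failure must not raise a partial alert
        report = AnalysisReport(
            image_id=image_id, records=records, stage_counts=counts,
            alert=False, error=f"{type(exc).__name__}: {exc}",
            timestamp=_dt.datetime.now().isoformat())
    if config.results_store:
        _append_report(report, config.results_store)
    return report


def _append_report(report: AnalysisReport, store: str | Path) -> None:
    store = Path(store)
    existing = json.loads(store.read_text()) if store.exists() else []
    existing.append(report.to_dict())
    store.parent.mkdir(parents=True, exist_ok=True)
    store.write_text(json.dumps(existing, indent=2))


def dataset_to_arrays(dataset: list[tuple[Cluster, str]]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a labeled cluster list into (X images, y labels) arrays."""
    x = np.stack([c.image for c, _ in dataset])
    y = np.array([label for _, label in dataset])
    return x, y


def default_nevus_database(n_exemplars: int = 30, seed: int = 0,
                           dim: tuple[int, int] = (64, 64)) -> NevusDatabase:
    """Screening database seeded from the generator's labeled clusters."""
    from . import synthgen  # local import: synthgen does not depend on pipeline

    nevi = synthgen.make_cluster_dataset(n_exemplars // 2 or 1, dim, seed)
    skin = synthgen.make_skin_patches(n_exemplars, dim, seed + 1)
    images = [c.image for c, _ in nevi] + skin
    labels = ["nevus"] * len(nevi) + ["skin"] * len(skin)
    return NevusDatabase.from_images(images, labels)


def run_experiment(
    dataset: list[tuple[Cluster, str]] | None = None,
    n_per_class: int = 100,
    split: float = 0.7,
    seed: int = 0,
    cnn_params: dict | None = None,
    out_dir: str | Path | None = None,
) -> tuple[Metrics, ConfusionCounts]:
    """Train/test experiment on a labeled cluster dataset.

    Without an explicit dataset, a synthetic one with ``n_per_class``
    clusters per label is generated from *seed*.  The split is stratified
    70/30 by default; training goes through ``CnnClassifier``.  When
    ``out_dir`` is given, a metrics CSV and a confusion-matrix JSON are
    written there.
    """
    from . import synthgen

    if dataset is None:
        dataset = synthgen.make_cluster_dataset(n_per_class, seed=seed)
    x, y = dataset_to_arrays(dataset)
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, train_size=split, stratify=y, random_state=seed)
    params = dict(random_state=seed)
    params.update(cnn_params or {})
    clf = CnnClassifier(**params)
    clf.fit(x_tr, y_tr)
    preds = clf.predict(x_te)
    counts, metrics = evaluate(list(preds), list(y_te), positive_class="suspicious")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = asdict(metrics)
        with open(out_dir / "metrics.csv", "w") as fh:
            fh.write(",".join(rows) + "\n")
            fh.write(",".join(f"{v:.6f}" for v in rows.values()) + "\n")
        (out_dir / "confusion.json").write_text(json.dumps(asdict(counts), indent=2))
    return metrics, counts


# ---------------------------------------------------------------------------
# PH2 loader
# ---------------------------------------------------------------------------

_PH2_DIAGNOSIS = {0: "benign", 1: "benign", 2: "suspicious"}  # common/atypical/melanoma


def load_ph2(directory: str | Path,
             target_dim: tuple[int, int] = (64, 64)) -> list[tuple[Cluster, str]]:
    """Load a PH2-layout dermoscopy directory as a labeled cluster list.

    Expected layout: an index file ``PH2_dataset.txt`` whose rows carry a
    lesion name (IMDxxx) and a clinical diagnosis code in pipe-separated
    columns (0 = common nevus, 1 = atypical nevus, 2 = melanoma), plus
    one folder per lesion containing the dermoscopic image.  Common and
    atypical nevi map to ``benign``, melanoma to ``suspicious``.
    """
    directory = Path(directory)
    index = directory / "PH2_dataset.txt"
    if not index.exists():
        raise ValueError(f"missing PH2 index file {index}")
    entries: list[tuple[str, int]] = []
    for line in index.read_text().splitlines():
        m = re.search(r"(IMD\w*\d+)", line)
        if not m:
            continue
        name = m.group(1).strip()
        cols = [c.strip() for c in line.split("|") if c.strip()]
        code = next((int(c) for c in cols if c in ("0", "1", "2")), None)
        if code is None:
            continue
        entries.append((name, code))
    if not entries:
        raise ValueError("PH2 index file contains no parsable entries")

    missing: list[str] = []
    out: list[tuple[Cluster, str]] = []
    for name, code in entries:
        folder = directory / name
        candidates = sorted(folder.rglob(f"{name}.*")) if folder.exists() else []
        candidates = [p for p in candidates if p.suffix.lower() in (".bmp", ".png", ".jpg", ".jpeg")]
        if not candidates:
            missing.append(name)
            continue
        img = imgio.load_image(candidates[0])
        resized = imgio.resize(img, target_dim[0], target_dim[1])
        cluster = Cluster(image=resized, source_keypoint=None,
                          region_size=resized.shape[0] * resized.shape[1], state="raw")
        out.append((cluster, _PH2_DIAGNOSIS[code]))
    if missing:
        raise ValueError(f"PH2 layout is missing images for: {', '.join(missing)}")
    return out
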