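"""Histogram triage of clusters before classification.

Each cluster's gray and R/G/B histograms are compared against exemplars
stored in a nevus database.  A cluster more similar to the stored nevus
exemplars than to the plain-skin exemplars is forwarded (after a mild
Gaussian blur) to the CNN; a cluster that looks like plain skin is
skipped.  Similarity is histogram intersection on unit-mass histograms,
averaged over the four channels, so it is symmetric and bounded in
[0, 1] with 1 iff the normalized histogram sets coincide.

``HistogramScreener`` wraps the database in a scikit-learn compatible
estimator (fit on labeled cluster images, predict forward decisions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import imgio
from .clusterer import Cluster
from .cnn import BLUR_KERNEL
from .scalespace import convolve

__all__ = [
    "BLUR_KERNEL",
    "NevusDatabase",
    "ScreenDecision",
    "histogram_similarity",
    "screen_cluster",
    "blur_cluster",
    "HistogramScreener",
]

CHANNELS = ("gray", "R", "G", "B")


def _normalized_set(img: np.ndarray) -> dict[str, np.ndarray]:
    return {h.channel: h.normalized() for h in imgio.histograms(img)}


@dataclass
class NevusDatabase:
    """Normalized histogram exemplars labeled ``nevus`` or ``skin``."""

    entries: list[tuple[dict[str, np.ndarray], str]]
    version: str = "1"

    def __post_init__(self) -> None:
        for hists, label in self.entries:
            if label not in ("nevus", "skin"):
                raise ValueError(f"unknown label {label!r}")
            if set(hists) != set(CHANNELS):
                raise ValueError("entry must carry gray, R, G, B histograms")

    @property
    def operational(self) -> bool:
        """At least one exemplar; a missing label scores similarity 0."""
        return bool(self.entries)

    @classmethod
    def from_images(cls, images: list[np.ndarray], labels: list[str]) -> "NevusDatabase":
        """Build a database from exemplar RGB images (e.g. generator output)."""
        if len(images) != len(labels):
            raise ValueError("images and labels must align")
        return cls(entries=[(_normalized_set(np.asarray(img)), lab)
                            for img, lab in zip(images, labels)])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "entries": [
                {"label": label, "histograms": {ch: hists[ch].tolist() for ch in CHANNELS}}
                for hists, label in self.entries
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NevusDatabase":
        payload = json.loads(Path(path).read_text())
        entries = [
            ({ch: np.asarray(e["histograms"][ch], dtype=float) for ch in CHANNELS},
             e["label"])
            for e in payload["entries"]
        ]
        return cls(entries=entries, version=str(payload.get("version", "1")))


@dataclass(frozen=True)
class ScreenDecision:
    forward: bool
    best_similarity_nevus: float
    best_similarity_skin: float


def histogram_similarity(
    a: dict[str, np.ndarray],
    b: dict[str, np.ndarray],
) -> float:
    """Mean histogram intersection over the gray, R, G, B channels."""
    for ch in CHANNELS:
        if ch not in a or ch not in b:
            raise ValueError(f"missing channel {ch!r}")
    total = 0.0
    for ch in CHANNELS:
        ha = np.asarray(a[ch], dtype=float)
        hb = np.asarray(b[ch], dtype=float)
        total += float(np.minimum(ha, hb).sum())
    return total / len(CHANNELS)


def screen_cluster(
    c: Cluster,
    db: NevusDatabase,
    margin: float = 1.0,
    undecided_band: float = 0.02,
) -> ScreenDecision:
    """Compare a cluster against the database and decide forwarding.

    Forward iff best nevus similarity >= margin * best skin similarity;
    near-ties (absolute gap below ``undecided_band``) are forwarded, since
    the system errs on the side of alerting.  The cluster's state becomes
    ``screened`` and the decision is recorded on it.
    """
    if not db.operational:
        raise ValueError("nevus database is empty")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    hists = _normalized_set(c.image)
    best = {"nevus": 0.0, "skin": 0.0}
    for entry, label in db.entries:
        sim = histogram_similarity(hists, entry)
        if sim > best[label]:
            best[label] = sim
    forward = best["nevus"] >= margin * best["skin"]
    if abs(best["nevus"] - best["skin"]) < undecided_band:
        forward = True
    decision = ScreenDecision(forward=forward,
                              best_similarity_nevus=best["nevus"],
                              best_similarity_skin=best["skin"])
    c.state = "screened"
    c.screen = decision
    return decision


def blur_cluster(c: Cluster) -> Cluster:
    """Gaussian 3x3 blur of a forwarded cluster (state screened -> blurred)."""
    if c.state != "screened" or c.screen is None or not c.screen.forward:
        raise ValueError("only screened, forwarded clusters may be blurred")
    img = np.asarray(c.image, dtype=float)
    out = np.empty_like(img)
    for ch in range(img.shape[2]):
        out[..., ch] = convolve(img[..., ch], BLUR_KERNEL)
    c.image = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    c.state = "blurred"
    return c


class HistogramScreener(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style wrapper around the histogram triage.

    fit(X, y): X is a sequence of RGB cluster images (or an (n, h, w, 3)
    array), y the labels ``nevus``/``skin`` (anything truthy vs falsy maps
    onto nevus/skin for convenience).  predict returns 1 where the
    cluster would be forwarded.
    """

    def __init__(self, margin: float = 1.0, undecided_band: float = 0.02):
        self.margin = margin
        self.undecided_band = undecided_band

    def fit(self, X, y):
        labels = ["nevus" if str(lab) in ("1", "True", "nevus", "suspicious") else "skin"
                  for lab in y]
        self.database_ = NevusDatabase.from_images(list(X), labels)
        self.classes_ = np.array([0, 1])
        return self

    def decision_for(self, img: np.ndarray) -> ScreenDecision:
        check_is_fitted(self, "database_")
        shim = Cluster(image=np.asarray(img, dtype=np.uint8),
                       source_keypoint=None, region_size=0)
        return screen_cluster(shim, self.database_, self.margin, self.undecided_band)

    def predict(self, X):
        return np.array([1 if self.decision_for(img).forward else 0 for img in X])
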