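"""Exemplar-region mining: score maps, representative patches, pattern clusters.

The trained scorer assigns each patch a digital-CMS score in [0, 1].  For
interpretation, the patches most confidently scored toward a patient's own
molecular subtype are selected (lowest scores for C1 patients, highest for
C2), pooled per subtype group, and clustered with k-means on their deep
features into a small number of recurring histological patterns; the exemplar
of each cluster is its medoid, i.e. a real patch.  Score maps render the
per-patch scores back onto slide coordinates as a diverging blue (C1) to red
(C2) heatmap centred at the stratification threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from matplotlib.colors import TwoSlopeNorm
from sklearn.cluster import KMeans

from .tripletmil import Bag, TrainedScorer, score_patches

__all__ = [
    "SelectedPatches",
    "ScoreMap",
    "select_representative_patches",
    "cluster_exemplars",
    "render_score_map",
]


@dataclass
class SelectedPatches:
    """Representative patches of one patient: indices into the bag's rows."""

    patient_id: str
    label: int
    indices: np.ndarray
    scores: np.ndarray
    coords: np.ndarray | None
    truncated: bool  # True when the bag held fewer than k patches


@dataclass
class ScoreMap:
    """Per-patch digital-CMS scores of one slide, ready for rendering."""

    slide_id: str
    coords: np.ndarray  # (K, 4) x, y, w, h
    scores: np.ndarray  # (K,) in [0, 1]
    center: float = 0.5  # diverging-map centre (the stratification threshold)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.coords) != len(self.scores):
            raise ValueError("one score per patch required")
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise ValueError("scores must lie in [0, 1]")


def select_representative_patches(
    bags: list[Bag],
    scorer: TrainedScorer,
    k: int = 20,
) -> dict[str, SelectedPatches]:
    """Per patient, the k patches scored most toward the patient's own class.

    C1 patients contribute their k lowest-scoring patches, C2 patients their k
    highest.  Unlabelled patients are skipped with a warning; bags with fewer
    than k patches return all patches flagged ``truncated``.
    """
    out: dict[str, SelectedPatches] = {}
    for bag in bags:
        if bag.label is None:
            warnings.warn(f"patient {bag.patient_id!r} has no CMS label; skipped", stacklevel=2)
            continue
        scores = score_patches(scorer, bag)
        order = np.argsort(scores, kind="stable")
        take = order[:k] if bag.label == 0 else order[::-1][:k]
        out[bag.patient_id] = SelectedPatches(
            patient_id=bag.patient_id,
            label=bag.label,
            indices=take,
            scores=scores[take],
            coords=None if bag.coords is None else np.asarray(bag.coords)[take],
            truncated=bag.n_patches < k,
        )
    return out


def cluster_exemplars(
    features: np.ndarray,
    n_clusters: int = 9,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """k-means partition of selected-patch features into histological patterns.

    Returns ``(assignments, medoid_indices)``; the medoid of a cluster is the
    member patch closest to its centroid, so every exemplar is a real patch.
    k-means++ initialisation with ``n_init`` restarts, deterministic under the
    seed; re-run with fresh seeds in the (rare) event of an empty cluster.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if len(X) < n_clusters:
        raise ValueError(f"{len(X)} patches cannot form {n_clusters} clusters")
    for attempt in range(5):
        km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed + attempt)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) == n_clusters:
            break
    else:  # pragma: no cover - k-means++ essentially never leaves clusters empty
        raise RuntimeError("k-means repeatedly produced empty clusters")
    medoids = np.empty(n_clusters, dtype=np.int64)
    for c in range(n_clusters):
        members = np.flatnonzero(labels == c)
        d = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
        medoids[c] = members[np.argmin(d)]
    return labels, medoids


def render_score_map(
    score_map: ScoreMap,
    downsample: int = 16,
    cmap: str = "coolwarm",
) -> np.ndarray:
    """Rasterise a score map as an RGBA array (float in [0, 1]).

    Patch rectangles are filled with a diverging blue-red colormap centred at
    the stratification threshold; background pixels are fully transparent.
    Patches must not overlap (the tiling grid is non-overlapping by
    construction).
    """
    coords = score_map.coords
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    x0, y0 = coords[:, 0] // downsample, coords[:, 1] // downsample
    x1 = (coords[:, 0] + coords[:, 2] + downsample - 1) // downsample
    y1 = (coords[:, 1] + coords[:, 3] + downsample - 1) // downsample
    width, height = int(x1.max()), int(y1.max())
    center = min(max(score_map.center, 1e-9), 1 - 1e-9)
    norm = TwoSlopeNorm(vmin=0.0, vcenter=center, vmax=1.0)
    colors = colormaps[cmap](norm(score_map.scores))  # (K, 4)
    raster = np.zeros((height, width, 4), dtype=float)
    occupied = np.zeros((height, width), dtype=bool)
    for (xa, ya, xb, yb), rgba in zip(zip(x0, y0, x1, y1), colors):
        if occupied[ya:yb, xa:xb].any():
            raise ValueError("overlapping patches in score map")
        occupied[ya:yb, xa:xb] = True
        raster[ya:yb, xa:xb, :3] = rgba[:3]
        raster[ya:yb, xa:xb, 3] = 1.0
    return raster
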