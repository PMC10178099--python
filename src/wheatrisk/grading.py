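"""Data-driven risk-level grading of indicator points.

The (NIPI, THQ, TCR) triples are min-max normalized per dimension, clustered
with a K-Means variant whose initialization picks the first center uniformly
at random and every further center as the point farthest from its nearest
chosen center (deterministic farthest-point seeding; canonical D^2 sampling
is available behind a switch), and the number of clusters is chosen by the
mean silhouette coefficient over K = 2..6.  Clusters are then ordered into
risk levels by the Euclidean distance of their centers from the origin: for
K = 3 the labels are Low, Medium and High.

New (e.g., forecasted) indicator triples are graded by normalizing with the
stored training extremes — without clipping, since nearest-center assignment
is well defined outside [0, 1] — and taking the label of the nearest center.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

MAX_LLOYD_ITERATIONS = 300


@dataclass(frozen=True)
class NormalizationParams:
    """Per-dimension extremes of the fitting dataset (min-max rule)."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "minimum", np.asarray(self.minimum, dtype=float))
        object.__setattr__(self, "maximum", np.asarray(self.maximum, dtype=float))
        if (self.maximum < self.minimum).any():
            raise ValueError("maximum must be >= minimum per dimension")


def minmax_fit(points: np.ndarray) -> NormalizationParams:
    """Record per-dimension extremes; errors on fewer than 2 points or a constant dimension."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("minmax_fit needs at least two points")
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    degenerate = np.flatnonzero(hi == lo)
    if degenerate.size:
        raise ValueError(f"degenerate (constant) dimensions {degenerate.tolist()}: max == min")
    return NormalizationParams(lo, hi)


def minmax_apply(points: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """(x - min) / (max - min) per dimension; out-of-range inputs are not clipped."""
    pts = np.asarray(points, dtype=float)
    return (pts - params.minimum) / (params.maximum - params.minimum)


def kmeanspp_seed_centers(
    points: np.ndarray, k: int, seed: int, d2_sampling: bool = False
) -> np.ndarray:
    """Initial centers: first uniform at random, then farthest-point.

    The default follows the deterministic rule "take the point with the
    largest distance to its nearest chosen center"; ``d2_sampling=True``
    switches to canonical K-Means++ sampling proportional to the squared
    distance.
    """
    pts = np.asarray(points, dtype=float)
    n_distinct = np.unique(pts, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the number of distinct points ({n_distinct})")
    rng = np.random.default_rng(seed)
    chosen = [int(rng.integers(len(pts)))]
    d2 = ((pts - pts[chosen[0]]) ** 2).sum(axis=1)
    while len(chosen) < k:
        if d2_sampling:
            idx = int(rng.choice(len(pts), p=d2 / d2.sum()))
        else:
            idx = int(np.argmax(d2))
        chosen.append(idx)
        d2 = np.minimum(d2, ((pts - pts[idx]) ** 2).sum(axis=1))
    return pts[chosen].copy()


def kmeans_fit(
    points: np.ndarray,
    k: int,
    seed: int,
    d2_sampling: bool = False,
    inertia_trace: list[float] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd iterations from the seeded centers until the assignment fixpoint.

    Returns (centers, assignments, inertia).  An empty cluster is re-seeded
    at the point farthest from its nearest center (logged).  If
    ``inertia_trace`` is given, the objective after each full Lloyd step is
    appended to it (non-increasing while no re-seeding occurs).
    """
    pts = np.asarray(points, dtype=float)
    centers = kmeanspp_seed_centers(pts, k, seed, d2_sampling=d2_sampling)
    assignments = np.full(len(pts), -1, dtype=np.int64)
    for _ in range(MAX_LLOYD_ITERATIONS):
        d2 = cdist(pts, centers, metric="sqeuclidean")
        new_assignments = d2.argmin(axis=1)
        for j in range(k):
            members = new_assignments == j
            if members.any():
                centers[j] = pts[members].mean(axis=0)
            else:
                farthest = int(d2.min(axis=1).argmax())
                logger.warning("empty cluster %d re-seeded at farthest point %d", j, farthest)
                centers[j] = pts[farthest]
                new_assignments[farthest] = j
        if inertia_trace is not None:
            inertia_trace.append(float(((pts - centers[new_assignments]) ** 2).sum()))
        if (new_assignments == assignments).all():
            break
        assignments = new_assignments
    inertia = float(((pts - centers[assignments]) ** 2).sum())
    return centers, assignments, inertia


def silhouette_mean(points: np.ndarray, assignments: np.ndarray) -> float:
    """Mean silhouette coefficient (b - a) / max(a, b); singleton clusters score 0."""
    assignments = np.asarray(assignments)
    if np.unique(assignments).size < 2:
        raise ValueError("silhouette requires at least two clusters")
    return float(silhouette_score(np.asarray(points, dtype=float), assignments))


def order_levels(centers: np.ndarray) -> list[int]:
    """Cluster indices sorted by ascending Euclidean center-to-origin distance.

    An exact distance tie is broken by the first coordinate (with a warning),
    then by remaining coordinates.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.shape[0] < 2:
        raise ValueError("order_levels needs at least two centers")
    dist = np.sqrt((centers**2).sum(axis=1))
    _, counts = np.unique(dist, return_counts=True)
    if (counts > 1).any():
        logger.warning("exact center-to-origin distance tie; breaking by first dimension")
    keys = np.lexsort(tuple(centers[:, d] for d in reversed(range(centers.shape[1]))) + (dist,))
    return [int(i) for i in keys]


def level_names(k: int) -> list[str]:
    if k == 2:
        return ["Low", "High"]
    if k == 3:
        return ["Low", "Medium", "High"]
    return [f"Level {i + 1}" for i in range(k)]


@dataclass(frozen=True)
class GradingModel:
    """Fitted grading model: normalization, centers and ordered level labels.

    ``centers`` are stored in normalized space in ascending distance-from-
    origin order, so ``level_labels[i]`` names the risk level of
    ``centers[i]``.
    """

    k: int
    centers: np.ndarray  # (k, 3), normalized space, ordered low -> high risk
    level_labels: tuple[str, ...]
    norm: NormalizationParams
    silhouette_by_k: dict[int, float]
    seed: int
    inertia: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))
        if self.centers.shape[0] != self.k or len(self.level_labels) != self.k:
            raise ValueError("centers and level_labels must both have length k")

    def assignments_to_labels(self, assignments: np.ndarray) -> np.ndarray:
        return np.asarray(self.level_labels, dtype=object)[assignments]


def fit_grading(
    points: np.ndarray, k: int, seed: int, d2_sampling: bool = False
) -> GradingModel:
    """Normalize, cluster with a fixed K and order the clusters into levels."""
    norm = minmax_fit(points)
    normalized = minmax_apply(points, norm)
    centers, assignments, inertia = kmeans_fit(normalized, k, seed, d2_sampling=d2_sampling)
    order = order_levels(centers) if k >= 2 else [0]
    sil = {k: silhouette_mean(normalized, assignments)} if k >= 2 else {}
    return GradingModel(
        k=k,
        centers=centers[order],
        level_labels=tuple(level_names(k)),
        norm=norm,
        silhouette_by_k=sil,
        seed=seed,
        inertia=inertia,
    )


def select_k(
    points: np.ndarray,
    kmin: int = 2,
    kmax: int = 6,
    seed: int = 0,
    d2_sampling: bool = False,
) -> GradingModel:
    """Fit K-Means for each K in [kmin, kmax], pick the silhouette argmax.

    Ties are broken toward the smaller K.  Returns the grading model refit at
    the selected K with levels ordered by center-to-origin distance.
    """
    norm = minmax_fit(points)
    normalized = minmax_apply(points, norm)
    silhouettes: dict[int, float] = {}
    fits: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    for k in range(kmin, kmax + 1):
        centers, assignments, inertia = kmeans_fit(normalized, k, seed, d2_sampling=d2_sampling)
        fits[k] = (centers, assignments, inertia)
        silhouettes[k] = silhouette_mean(normalized, assignments)
    best_k = max(sorted(silhouettes), key=lambda k: silhouettes[k])
    centers, _, inertia = fits[best_k]
    order = order_levels(centers)
    return GradingModel(
        k=best_k,
        centers=centers[order],
        level_labels=tuple(level_names(best_k)),
        norm=norm,
        silhouette_by_k=silhouettes,
        seed=seed,
        inertia=inertia,
    )


def assign_level(points: np.ndarray, model: GradingModel) -> np.ndarray:
    """Label each raw indicator triple with the risk level of its nearest center.

    Points are normalized with the model's stored extremes (no clipping); an
    exact distance tie goes to the lower-risk level.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    normalized = minmax_apply(pts, model.norm)
    d2 = cdist(normalized, model.centers, metric="sqeuclidean")
    nearest = d2.argmin(axis=1)  # argmin takes the first (lower-risk) index on ties
    return model.assignments_to_labels(nearest)


def save_grading_model(model: GradingModel, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "k": model.k,
        "centers": model.centers.tolist(),
        "level_labels": list(model.level_labels),
        "norm": {"minimum": model.norm.minimum.tolist(), "maximum": model.norm.maximum.tolist()},
        "silhouette_by_k": {str(k): v for k, v in model.silhouette_by_k.items()},
        "seed": model.seed,
        "inertia": model.inertia,
    }
    path.write_text(json.dumps(doc, indent=2))
    return path


def load_grading_model(path: str | Path) -> GradingModel:
    doc = json.loads(Path(path).read_text())
    return GradingModel(
        k=int(doc["k"]),
        centers=np.asarray(doc["centers"], dtype=float),
        level_labels=tuple(doc["level_labels"]),
        norm=NormalizationParams(
            np.asarray(doc["norm"]["minimum"]), np.asarray(doc["norm"]["maximum"])
        ),
        silhouette_by_k={int(k): float(v) for k, v in doc["silhouette_by_k"].items()},
        seed=int(doc["seed"]),
        inertia=float(doc["inertia"]),
    )


__all__ = [
    "GradingModel",
    "NormalizationParams",
    "assign_level",
    "fit_grading",
    "kmeans_fit",
    "kmeanspp_seed_centers",
    "level_names",
    "load_grading_model",
    "minmax_apply",
    "minmax_fit",
    "order_levels",
    "save_grading_model",
    "select_k",
    "silhouette_mean",
]
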