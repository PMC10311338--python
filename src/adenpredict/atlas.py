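"""Unsupervised atlas of A-domain signature space.

Large genome-mining runs yield hundreds of thousands of A-domains with no
known substrate. K-means clustering of their encoded signatures (euclidean
distance, K chosen by the elbow method) groups domains with similar binding
pockets; a t-SNE embedding gives a 2D map. Clusters among the largest that
contain no domain with a known substrate are flagged as candidates for
novel amino-acid chemistry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans, MiniBatchKMeans
from sklearn.manifold import TSNE


@dataclass(frozen=True)
class ClusterConfig:
    """K-means settings. ``K`` defaults to the atlas-scale choice of 200;
    desk-scale analyses should sweep ``k_sweep`` and use :func:`elbow_select`."""

    K: int = 200
    k_sweep: tuple[int, ...] = ()
    seed: int = 0
    n_init: int = 10
    minibatch: bool = False

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.k_sweep and list(self.k_sweep) != sorted(set(self.k_sweep)):
            raise ValueError("k_sweep must be strictly increasing")


@dataclass
class ClusteringResult:
    assignment: np.ndarray  # cluster index per input
    centroids: np.ndarray  # (K, D)
    inertia: float  # within-cluster sum of squared distances
    cluster_sizes: dict[int, int]

    def recompute_inertia(self, X: np.ndarray) -> float:
        X = np.asarray(X, dtype=float)
        return float(
            ((X - self.centroids[self.assignment]) ** 2).sum()
        )


def cluster(X: np.ndarray, cfg: ClusterConfig) -> ClusteringResult:
    """K-means (k-means++ init, euclidean distance), deterministic per seed."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if len(X) < cfg.K:
        raise ValueError(f"{len(X)} points cannot form K={cfg.K} clusters")
    cls = MiniBatchKMeans if cfg.minibatch else KMeans
    km = cls(n_clusters=cfg.K, n_init=cfg.n_init, random_state=cfg.seed)
    assignment = km.fit_predict(X)
    sizes = {int(c): int(n) for c, n in zip(*np.unique(assignment, return_counts=True))}
    result = ClusteringResult(
        assignment=assignment,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        cluster_sizes=sizes,
    )
    # sklearn's reported inertia can drift from the final assignment by
    # floating error only; store the recomputed value for the exact contract
    result.inertia = result.recompute_inertia(X)
    return result


#: Normalized knee strength below which an inertia curve is considered to
#: have no pronounced elbow (e.g. a single isotropic blob in signature-
#: encoding dimension, whose curve is nearly linear in K).
ELBOW_STRENGTH_THRESHOLD = 0.2


@dataclass(frozen=True)
class ElbowResult:
    chosen_k: int
    k_values: tuple[int, ...]
    inertias: tuple[float, ...]
    knee_strength: float  # max normalized distance of the curve below its chord
    pronounced: bool  # False when the curve has no clear elbow

    def to_dict(self) -> dict:
        return {
            "chosen_k": self.chosen_k,
            "k_values": list(self.k_values),
            "inertias": list(self.inertias),
            "knee_strength": self.knee_strength,
            "pronounced": self.pronounced,
        }


def elbow_select(X: np.ndarray, cfg: ClusterConfig) -> ElbowResult:
    """Sweep K and pick the elbow of the inertia curve, kneedle-style.

    The curve is normalized to the unit square; the chosen K maximizes the
    vertical distance by which the curve dips below the chord joining its
    endpoints (the point of maximum discrete curvature of a convex
    decreasing curve). The full curve is always returned so a human can
    override; when the maximum dip is below
    :data:`ELBOW_STRENGTH_THRESHOLD` the result is flagged as having no
    pronounced elbow.
    """
    if len(cfg.k_sweep) < 3:
        raise ValueError("k_sweep needs at least 3 values for an elbow")
    X = np.asarray(X, dtype=float)
    inertias = []
    for k in cfg.k_sweep:
        res = cluster(X, ClusterConfig(K=k, seed=cfg.seed, n_init=cfg.n_init,
                                       minibatch=cfg.minibatch))
        inertias.append(res.inertia)

    y = np.asarray(inertias, dtype=float)
    x = np.asarray(cfg.k_sweep, dtype=float)
    span = y.max() - y.min()
    if span == 0:  # flat curve: no structure at all
        return ElbowResult(int(cfg.k_sweep[0]), tuple(cfg.k_sweep),
                           tuple(float(v) for v in y), 0.0, False)
    yn = (y - y.min()) / span
    xn = (x - x.min()) / (x.max() - x.min())
    chord = yn[0] + xn * (yn[-1] - yn[0])
    dip = chord - yn
    best = int(np.argmax(dip))
    strength = float(dip.max())
    return ElbowResult(
        chosen_k=int(cfg.k_sweep[best]),
        k_values=tuple(cfg.k_sweep),
        inertias=tuple(float(v) for v in y),
        knee_strength=strength,
        pronounced=strength >= ELBOW_STRENGTH_THRESHOLD,
    )


def embed_2d(
    X: np.ndarray,
    seed: int = 0,
    perplexity: float = 30.0,
    n_iter: int = 1000,
) -> np.ndarray:
    """t-SNE embedding to 2D, deterministic per seed.

    Perplexity is clipped below the sample count as t-SNE requires; PCA
    initialization keeps the embedding reproducible.
    """
    X = np.asarray(X, dtype=float)
    if len(X) < 5:
        raise ValueError("need at least 5 points to embed")
    perplexity = min(perplexity, (len(X) - 1) / 3)
    tsne = TSNE(
        n_components=2,
        random_state=seed,
        perplexity=perplexity,
        max_iter=n_iter,
        init="pca",
    )
    return tsne.fit_transform(X)


@dataclass
class NoveltyReport:
    """Which of the largest clusters contain no labeled member."""

    top_n: int
    ranked_clusters: list[int]  # top_n cluster indices by size (ties by index)
    unlabeled_clusters: list[int]
    composition: dict[int, dict[str, int]]  # cluster -> label -> count

    def to_dict(self) -> dict:
        return {
            "top_n": self.top_n,
            "ranked_clusters": self.ranked_clusters,
            "unlabeled_clusters": self.unlabeled_clusters,
            "composition": {
                str(c): dict(sorted(self.composition[c].items()))
                for c in sorted(self.composition)
            },
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def novelty_report(
    result: ClusteringResult,
    labels: Mapping[int, str],
    top_n: int = 50,
) -> NoveltyReport:
    """Flag the top-``top_n`` largest clusters that hold zero labeled members.

    ``labels`` is a partial mapping from input index to substrate label;
    unmapped inputs are treated as unlabeled. Clusters are ranked by size,
    ties broken by cluster index.
    """
    if top_n > len(result.cluster_sizes):
        raise ValueError(
            f"top_n={top_n} exceeds the number of clusters "
            f"({len(result.cluster_sizes)})"
        )
    ranked = sorted(result.cluster_sizes, key=lambda c: (-result.cluster_sizes[c], c))
    top = ranked[:top_n]

    composition: dict[int, dict[str, int]] = {c: {} for c in top}
    for idx, label in labels.items():
        c = int(result.assignment[idx])
        if c in composition:
            composition[c][label] = composition[c].get(label, 0) + 1

    unlabeled = [c for c in top if not composition[c]]
    return NoveltyReport(
        top_n=top_n,
        ranked_clusters=[int(c) for c in top],
        unlabeled_clusters=[int(c) for c in unlabeled],
        composition=composition,
    )
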