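"""Spatial partitioning of a slide by clustering scaled tile features.

Tiles are agglomerated with Ward's method on Euclidean distances between
scaled feature rows and the tree is cut to exactly ``k`` clusters (default 9
for single-slide maps, 7 per slide in multislide mode).  Labels are
renumbered 1..k by descending cluster size (ties broken by the smallest
member tile index) so outputs are reproducible byte-for-byte.  The full
linkage record is retained, which makes any coarser cut k' <= k recoverable
without re-clustering and keeps cuts nested.

A partition can be refined further with a stepwise k-means subdivision of one
region, and candidate k values can be compared with mean silhouette scores —
an advisory diagnostic only: cluster-validity indices are known to be
unreliable for picking the number of histologic patterns, which is why a
fixed default k is used instead of an automatic selector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .features import FeatureMatrix
from .slide_io import TileGrid

__all__ = [
    "PartitionMap",
    "Embedding2D",
    "WardPartitioner",
    "partition_tiles",
    "subdivide_partition",
    "evaluate_k",
    "embed_tiles",
    "render_partition_map",
    "DEFAULT_K",
    "DEFAULT_K_MULTISLIDE",
]

DEFAULT_K = 9
DEFAULT_K_MULTISLIDE = 7

NON_TISSUE_GRAY = (200, 200, 200)


def relabel_by_size(raw: np.ndarray) -> np.ndarray:
    """Map arbitrary integer labels to 1..k by descending cluster size.

    Ties in size are broken by the smallest member index, so the result is a
    pure, deterministic relabeling of the partition structure.
    """
    raw = np.asarray(raw)
    uniq = np.unique(raw)
    order = sorted(
        uniq,
        key=lambda u: (-int(np.sum(raw == u)), int(np.argmax(raw == u))),
    )
    lut = {u: i + 1 for i, u in enumerate(order)}
    return np.array([lut[u] for u in raw], dtype=int)


def make_palette(labels: list[int]) -> dict[int, tuple[int, int, int]]:
    """Stable label -> RGB palette from an ordered qualitative colormap."""
    import matplotlib

    colors = matplotlib.colormaps["tab20"].colors
    pal = {}
    for lab in sorted(set(labels)):
        r, g, b = colors[(lab - 1) % len(colors)][:3]
        pal[lab] = (int(r * 255), int(g * 255), int(b * 255))
    return pal


@dataclass
class PartitionMap:
    """Assignment of every tissue tile of one slide to one of k clusters."""

    slide_id: str
    k: int
    labels: dict[str, int]
    linkage: np.ndarray | None = field(repr=False, default=None)
    method: str = "ward"
    palette: dict[int, tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labs = sorted(set(self.labels.values()))
        if labs and (labs[0] < 1 or labs[-1] > self.k):
            raise ValueError("labels must lie in 1..k")
        if not self.palette:
            self.palette = make_palette(list(self.labels.values()))

    def labels_for(self, tile_ids: list[str]) -> np.ndarray:
        return np.array([self.labels[t] for t in tile_ids], dtype=int)

    def members(self, label: int) -> list[str]:
        return [t for t, lab in self.labels.items() if lab == label]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"tile_id": list(self.labels), "label": list(self.labels.values())}
        )


@dataclass
class Embedding2D:
    tile_ids: list[str]
    coordinates: np.ndarray
    method: str
    seed: int


class WardPartitioner(BaseEstimator, ClusterMixin):
    """Agglomerative Ward clustering with a retained linkage tree.

    Parameters
    ----------
    n_clusters : int
        Number of clusters the tree is cut to (``labels_`` after ``fit``).

    Attributes
    ----------
    linkage_ : ndarray
        SciPy linkage record of all n-1 merges (children, height, size).
    labels_ : ndarray of int
        Cluster labels 1..k, renumbered by descending cluster size.
    """

    def __init__(self, n_clusters: int = DEFAULT_K):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        n = X.shape[0]
        if not 1 <= self.n_clusters <= n:
            raise ValueError(f"n_clusters must be in [1, {n}], got {self.n_clusters}")
        self.linkage_ = linkage(X, method="ward") if n > 1 else np.empty((0, 4))
        self.labels_ = self.cut(self.n_clusters)
        return self

    def cut(self, k: int) -> np.ndarray:
        """Cut the stored tree to exactly k clusters (size-renumbered labels)."""
        n = self.linkage_.shape[0] + 1
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        if k == n:
            raw = np.arange(n)
        else:
            raw = cut_tree(self.linkage_, n_clusters=k).ravel()
        return relabel_by_size(raw)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _require_scaled(fm: FeatureMatrix) -> None:
    if not fm.scaled:
        raise RuntimeError("feature matrix must be scaled before clustering")


def partition_tiles(fm: FeatureMatrix, k: int = DEFAULT_K) -> PartitionMap:
    """Ward-cluster scaled tile features into k spatial partitions."""
    _require_scaled(fm)
    if not 2 <= k <= fm.n_tiles:
        raise ValueError(f"k must be in [2, {fm.n_tiles}], got {k}")
    model = WardPartitioner(n_clusters=k).fit(fm.values)
    labels = dict(zip(fm.tile_ids, (int(v) for v in model.labels_)))
    return PartitionMap(slide_id=fm.slide_id, k=k, labels=labels,
                        linkage=model.linkage_, method="ward")


def subdivide_partition(
    fm: FeatureMatrix,
    pm: PartitionMap,
    region_label: int,
    k2: int,
    seed: int = 0,
) -> PartitionMap:
    """Split one region into k2 sub-regions with seeded k-means.

    Sub-cluster labels are appended after the existing ones: the largest
    sub-cluster keeps ``region_label``, the rest become k+1 .. k+k2-1.
    """
    _require_scaled(fm)
    member_idx = [i for i, t in enumerate(fm.tile_ids) if pm.labels.get(t) == region_label]
    if not member_idx:
        raise ValueError(f"region {region_label} is empty")
    if not 2 <= k2 <= len(member_idx):
        raise ValueError(f"k2 must be in [2, {len(member_idx)}], got {k2}")
    km = KMeans(n_clusters=k2, n_init=10, random_state=seed).fit(
        fm.values[member_idx]
    )
    sub = relabel_by_size(km.labels_)
    new_labels = dict(pm.labels)
    for idx, s in zip(member_idx, sub):
        tid = fm.tile_ids[idx]
        new_labels[tid] = region_label if s == 1 else pm.k + (s - 1)
    return PartitionMap(
        slide_id=pm.slide_id,
        k=pm.k + k2 - 1,
        labels=new_labels,
        linkage=pm.linkage,
        method="kmeans_subdivide",
    )


def evaluate_k(
    fm: FeatureMatrix, k_min: int = 2, k_max: int = 10
) -> tuple[dict[int, float], int]:
    """Mean silhouette score of the Ward cut at each k in [k_min, k_max].

    Advisory only; returns ``(scores, best_k)`` where best_k is the argmax
    (smallest k on ties).  Degenerate inputs with all-zero pairwise
    distances get a score of 0 and a warning.
    """
    _require_scaled(fm)
    if not 2 <= k_min <= k_max <= fm.n_tiles - 1:
        raise ValueError(
            f"need 2 <= k_min <= k_max <= n_tiles-1; got [{k_min}, {k_max}] "
            f"with {fm.n_tiles} tiles"
        )
    model = WardPartitioner(n_clusters=k_min).fit(fm.values)
    degenerate = bool(np.allclose(fm.values, fm.values[0]))
    scores: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        if degenerate:
            scores[k] = 0.0
            continue
        labels = model.cut(k)
        if len(np.unique(labels)) < 2:
            scores[k] = 0.0
            continue
        scores[k] = float(silhouette_score(fm.values, labels, metric="euclidean"))
    if degenerate:
        warnings.warn("all tiles identical; silhouette undefined, reporting 0",
                      stacklevel=2)
    best_k = max(scores, key=lambda k: (scores[k], -k))
    return scores, best_k


def embed_tiles(fm: FeatureMatrix, method: str = "tsne", seed: int = 0) -> Embedding2D:
    """Seeded 2-D embedding of tile features for visual exploration."""
    if fm.n_tiles < 5:
        raise ValueError("need at least 5 tiles to embed")
    if method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, (fm.n_tiles - 1) / 3.0)
        coords = TSNE(
            n_components=2, random_state=seed, perplexity=perplexity, init="pca"
        ).fit_transform(fm.values)
    elif method == "umap":
        import umap

        coords = umap.UMAP(n_components=2, random_state=seed).fit_transform(fm.values)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return Embedding2D(list(fm.tile_ids), np.asarray(coords, dtype=np.float64),
                       method, seed)


def render_partition_map(
    pm: PartitionMap,
    grid: TileGrid,
    downsample: int = 1,
    out_png: str | None = None,
) -> np.ndarray:
    """Paint each tile its cluster color; non-tissue tiles neutral gray.

    Returns an RGB uint8 raster with one ``tile_size/downsample`` block per
    tile.  When ``out_png`` is given, the raster and a ``<out>.legend.json``
    sidecar (label -> color, tile count) are written.
    """
    if pm.slide_id != grid.slide.slide_id:
        raise ValueError(
            f"partition is for slide {pm.slide_id!r}, grid for {grid.slide.slide_id!r}"
        )
    block = max(1, grid.tile_size_px // max(1, downsample))
    raster = np.zeros((grid.n_rows * block, grid.n_cols * block, 3), dtype=np.uint8)
    for tile in grid.tiles:
        color = (
            pm.palette[pm.labels[tile.tile_id]]
            if tile.is_tissue and tile.tile_id in pm.labels
            else NON_TISSUE_GRAY
        )
        r0, c0 = tile.row * block, tile.col * block
        raster[r0 : r0 + block, c0 : c0 + block] = color
    if out_png is not None:
        import json
        from pathlib import Path

        from PIL import Image

        Image.fromarray(raster).save(out_png)
        counts: dict[int, int] = {}
        for lab in pm.labels.values():
            counts[lab] = counts.get(lab, 0) + 1
        legend = {
            str(lab): {"color": list(pm.palette[lab]), "n_tiles": counts.get(lab, 0)}
            for lab in sorted(pm.palette)
        }
        Path(str(out_png) + ".legend.json").write_text(json.dumps(legend, indent=2))
    return raster
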