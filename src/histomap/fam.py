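"""Interpretability: enriched features, extreme tiles, activation maps.

A partition is interpreted by asking which individual feature channels are
over- or under-represented inside it.  Per feature, in-region tiles are
compared with all other tissue tiles by a two-sample Mann-Whitney U test
(robust to the heavy-tailed activations typical of rectified features; a
t-test is available as a switch), with Benjamini-Hochberg correction across
the d features.  The morphology a feature tracks is surfaced two ways: by
exporting the tiles at the extremes of its value range, and by rendering a
feature activation map (FAM) — the feature's scaled per-tile value, min-max
normalized and painted over the tile grid.  A PCA variance map summarizes
how many components are needed to reach a target share of total variance and
where the leading components activate spatially.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu, ttest_ind
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .features import FeatureMatrix
from .partition import PartitionMap
from .slide_io import TileGrid

__all__ = [
    "FeatureRanking",
    "FAMRaster",
    "PCAVarianceMap",
    "rank_region_features",
    "extreme_tiles",
    "render_fam",
    "pca_variance_map",
]


@dataclass
class RankedFeature:
    feature_idx: int
    effect: float  # in-region mean minus out-region mean (scaled units)
    statistic: float
    p_value: float
    p_adjusted: float


@dataclass
class FeatureRanking:
    region_id: tuple[str, int]
    entries: list[RankedFeature]
    excluded_constant: list[int] = field(default_factory=list)

    def top(self, n: int = 10) -> list[RankedFeature]:
        return self.entries[:n]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "feature_idx": e.feature_idx,
                    "effect": e.effect,
                    "statistic": e.statistic,
                    "p": e.p_value,
                    "p_bh": e.p_adjusted,
                }
                for e in self.entries
            ]
        )


@dataclass
class FAMRaster:
    feature_idx: int
    tile_ids: list[str]
    activation: np.ndarray = field(repr=False)  # per tissue tile, fm order
    normalization: tuple[float, float] = (0.0, 1.0)  # (vmin, vmax) used
    raster: np.ndarray = field(repr=False, default=None)  # (rows, cols, 4) RGBA


@dataclass
class PCAVarianceMap:
    explained_variance_ratio: np.ndarray
    n_components_for_target: int
    variance_target: float
    scores: np.ndarray = field(repr=False, default=None)  # tiles x n_pcs
    rasters: list[np.ndarray] = field(default_factory=list)  # top-PC score maps


def rank_region_features(
    fm: FeatureMatrix,
    pm: PartitionMap,
    region_label: int,
    test: str = "mannwhitney",
) -> FeatureRanking:
    """Rank features by enrichment in one region versus the rest of the slide.

    Returns entries sorted by BH-adjusted p, then by decreasing absolute
    effect size.  Features constant across all tiles carry no contrast and
    are excluded (listed in ``excluded_constant``).
    """
    labels = pm.labels_for(fm.tile_ids)
    in_mask = labels == region_label
    n_in = int(in_mask.sum())
    if n_in == 0:
        raise ValueError(f"region {region_label} is empty")
    if n_in == fm.n_tiles:
        raise ValueError("region covers the whole slide; no contrast group")
    X_in, X_out = fm.values[in_mask], fm.values[~in_mask]

    excluded, idxs, stats, ps, effects = [], [], [], [], []
    for j in range(fm.dim):
        col = fm.values[:, j]
        if col.std() == 0.0:
            excluded.append(j)
            continue
        a, b = X_in[:, j], X_out[:, j]
        if test == "mannwhitney":
            res = mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        elif test == "ttest":
            res = ttest_ind(a, b, equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        idxs.append(j)
        stats.append(stat)
        ps.append(p)
        effects.append(float(a.mean() - b.mean()))
    if not idxs:
        return FeatureRanking((fm.slide_id, region_label), [], excluded)
    p_adj = multipletests(ps, method="fdr_bh")[1]
    entries = [
        RankedFeature(j, e, s, p, pa)
        for j, e, s, p, pa in zip(idxs, effects, stats, ps, p_adj)
    ]
    entries.sort(key=lambda e: (e.p_adjusted, -abs(e.effect), e.feature_idx))
    return FeatureRanking((fm.slide_id, region_label), entries, excluded)


def extreme_tiles(
    fm: FeatureMatrix, feature_idx: int, n: int
) -> tuple[list[str], list[str], bool]:
    """Tile ids at the top and bottom of one feature's value range.

    Returns ``(top_n, bottom_n, tied)`` where ``tied`` flags ties at either
    boundary.  Ties are broken by tile index (stable sort), so on an all-tied
    feature the bottom tiles are the first n and the top tiles the last n by
    tile order.
    """
    if not 0 <= feature_idx < fm.dim:
        raise ValueError(f"feature index {feature_idx} out of range [0, {fm.dim})")
    if not 1 <= n <= fm.n_tiles // 2:
        raise ValueError(f"n must be in [1, {fm.n_tiles // 2}]")
    vals = fm.values[:, feature_idx]
    order = np.argsort(vals, kind="stable")
    bottom = [fm.tile_ids[i] for i in order[:n]]
    top = [fm.tile_ids[i] for i in order[-n:][::-1]]
    sorted_vals = vals[order]
    tied = bool(
        (fm.n_tiles > n and sorted_vals[n - 1] == sorted_vals[n])
        or (fm.n_tiles > n and sorted_vals[-n] == sorted_vals[-n - 1])
    )
    return top, bottom, tied


def render_fam(
    fm: FeatureMatrix,
    grid: TileGrid,
    feature_idx: int,
    cmap: str = "inferno",
) -> FAMRaster:
    """Feature activation map: one feature's value painted over the grid.

    Values are min-max normalized to [0, 1] over tissue tiles and mapped
    through ``cmap``; non-tissue tiles are transparent.  The raster has one
    pixel per grid cell (RGBA uint8).  A constant feature renders as a
    uniform-zero map with a warning.
    """
    if grid.slide.slide_id != fm.slide_id:
        raise ValueError("grid and feature matrix refer to different slides")
    if not 0 <= feature_idx < fm.dim:
        raise ValueError(f"feature index {feature_idx} out of range [0, {fm.dim})")
    vals = fm.values[:, feature_idx]
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmin == vmax:
        warnings.warn(f"feature {feature_idx} is constant; uniform-zero FAM",
                      stacklevel=2)
        act = np.zeros_like(vals)
        vmax = vmin + 1.0
    else:
        act = (vals - vmin) / (vmax - vmin)

    import matplotlib

    colormap = matplotlib.colormaps[cmap]
    raster = np.zeros((grid.n_rows, grid.n_cols, 4), dtype=np.uint8)
    act_by_tile = dict(zip(fm.tile_ids, act))
    for tile in grid.tiles:
        if tile.is_tissue and tile.tile_id in act_by_tile:
            rgba = colormap(float(act_by_tile[tile.tile_id]))
            raster[tile.row, tile.col] = [int(c * 255) for c in rgba]
    return FAMRaster(
        feature_idx=feature_idx,
        tile_ids=list(fm.tile_ids),
        activation=act,
        normalization=(vmin, vmax),
        raster=raster,
    )


def pca_variance_map(
    fm: FeatureMatrix,
    variance_target: float = 0.8,
    grid: TileGrid | None = None,
    n_top_rasters: int = 5,
) -> PCAVarianceMap:
    """Principal components of the scaled matrix and their spatial score maps.

    Reports per-component explained-variance fractions, the smallest number
    of components whose cumulative fraction reaches ``variance_target``, and
    (when a grid is given) per-tile score rasters for the leading components.
    """
    if not fm.scaled:
        raise RuntimeError("feature matrix must be scaled")
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must lie in (0, 1]")
    n_comp = min(fm.n_tiles - 1, fm.dim)
    pca = PCA(n_components=n_comp, svd_solver="full").fit(fm.values)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    n_for_target = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    scores = pca.transform(fm.values)
    rasters: list[np.ndarray] = []
    if grid is not None:
        for pc in range(min(n_top_rasters, n_comp)):
            m = np.full((grid.n_rows, grid.n_cols), np.nan)
            by_tile = dict(zip(fm.tile_ids, scores[:, pc]))
            for tile in grid.tiles:
                if tile.tile_id in by_tile:
                    m[tile.row, tile.col] = by_tile[tile.tile_id]
            rasters.append(m)
    return PCAVarianceMap(
        explained_variance_ratio=evr,
        n_components_for_target=n_for_target,
        variance_target=variance_target,
        scores=scores,
        rasters=rasters,
    )
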