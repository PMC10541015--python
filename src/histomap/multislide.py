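"""Specimen-level organization of regions from many slides.

Slides of one specimen are first partitioned independently (default 7
regions per slide, the point at which discernible histologic patterns
saturate); the resulting region profiles are then merged in a second step by
hierarchically clustering their pairwise Pearson correlation matrix — for a
12-slide specimen at 7 regions each, an 84 x 84 matrix.  Regions are
agglomerated on the correlation distance 1 - r with average linkage (the
standard heatmap convention; the linkage is configurable) and the tree is
cut at a user-chosen K.  Annotation enrichment within specimen-clusters is
tested per cluster with a one-vs-rest chi-square, falling back to a seeded
permutation test when expected counts are small; a global K x L test is also
reported.

The alternative "tile-level global analysis" — pooling every tile of every
slide and clustering once — is provided by :func:`global_tile_clustering`;
on well-separated cohorts the two strategies give equivalent groupings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency
from sklearn.base import BaseEstimator, ClusterMixin
from statsmodels.stats.multitest import multipletests

from .features import FeatureMatrix, scale_features
from .heterogeneity import HeterogeneityMatrix, RegionProfile, pairwise_r
from .partition import DEFAULT_K_MULTISLIDE, PartitionMap, WardPartitioner, relabel_by_size

__all__ = [
    "SpecimenClustering",
    "EnrichmentResult",
    "RegionMerger",
    "merge_regions",
    "enrichment_test",
    "global_tile_clustering",
]


@dataclass
class SpecimenClustering:
    region_ids: list[tuple[str, int]]
    matrix: HeterogeneityMatrix
    dendrogram: np.ndarray = field(repr=False)
    cut_K: int = 2
    assignment: dict[tuple[str, int], int] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "slide_id": [s for s, _ in self.region_ids],
                "label": [lab for _, lab in self.region_ids],
                "specimen_cluster": [self.assignment[r] for r in self.region_ids],
            }
        )


@dataclass
class EnrichmentResult:
    clusters: list[int]
    annotation_labels: list[str]
    contingency: np.ndarray  # K x L counts
    statistics: list[float]  # per-cluster one-vs-rest chi-square
    dof: list[int]
    p_values: list[float]
    p_adjusted: list[float]
    methods: list[str]  # 'chisq' or 'permutation' per cluster
    global_statistic: float = float("nan")
    global_p: float = float("nan")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "specimen_cluster": self.clusters,
                "chi2": self.statistics,
                "dof": self.dof,
                "p": self.p_values,
                "p_bh": self.p_adjusted,
                "method": self.methods,
            }
        )


class RegionMerger(BaseEstimator, ClusterMixin):
    """Hierarchical clustering of region profiles on correlation distance.

    ``fit(X)`` takes the (m, d) matrix of region mean vectors, builds the
    pairwise Pearson matrix, agglomerates on ``1 - r`` with the configured
    linkage and cuts at ``n_clusters``.  ``labels_`` are 1..K renumbered by
    descending cluster size.
    """

    def __init__(self, n_clusters: int = 2, linkage_method: str = "average"):
        self.n_clusters = n_clusters
        self.linkage_method = linkage_method

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        m = X.shape[0]
        if not 2 <= self.n_clusters <= m:
            raise ValueError(f"n_clusters must be in [2, {m}]")
        r = np.corrcoef(X)
        if not np.all(np.isfinite(r)):
            raise ValueError("constant region profile: correlation undefined")
        D = 1.0 - r
        np.fill_diagonal(D, 0.0)
        D = (D + D.T) / 2.0  # enforce exact symmetry before condensing
        self.correlation_ = r
        self.linkage_ = linkage(squareform(np.clip(D, 0.0, None), checks=False),
                                method=self.linkage_method)
        raw = (
            np.arange(m)
            if self.n_clusters == m
            else cut_tree(self.linkage_, n_clusters=self.n_clusters).ravel()
        )
        self.labels_ = relabel_by_size(raw)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def merge_regions(
    profile_sets: list[list[RegionProfile]],
    K: int,
    linkage_method: str = "average",
) -> SpecimenClustering:
    """Merge per-slide region profiles into K specimen-level clusters."""
    if len(profile_sets) < 2:
        raise ValueError("need profiles from at least 2 slides")
    profiles = [p for ps in profile_sets for p in ps]
    dims = {p.mean_vector.shape[0] for p in profiles}
    if len(dims) != 1:
        raise ValueError(
            f"region profiles have mismatched feature dimensions {sorted(dims)}; "
            "slides must use the same extractor"
        )
    matrix = pairwise_r(profiles)
    merger = RegionMerger(n_clusters=K, linkage_method=linkage_method).fit(
        np.vstack([p.mean_vector for p in profiles])
    )
    assignment = {
        p.region_id: int(lab) for p, lab in zip(profiles, merger.labels_)
    }
    return SpecimenClustering(
        region_ids=[p.region_id for p in profiles],
        matrix=matrix,
        dendrogram=merger.linkage_,
        cut_K=K,
        assignment=assignment,
    )


def _chi2_stat(table: np.ndarray) -> tuple[float, int, np.ndarray]:
    stat, _, dof, expected = chi2_contingency(table, correction=False)
    return float(stat), int(dof), expected


def enrichment_test(
    clustering: SpecimenClustering,
    annotations: dict[tuple[str, int], str],
    seed: int = 0,
    n_permutations: int = 10_000,
    min_expected: float = 5.0,
) -> EnrichmentResult:
    """Test each specimen-cluster for enrichment of annotation labels.

    Per cluster, a one-vs-rest 2 x L chi-square on the label distribution;
    when any expected count falls below ``min_expected`` (Cochran's rule),
    the asymptotic p is replaced by a seeded permutation p (label shuffles,
    same statistic) and the per-cluster method flag records it.  Raw p-values
    get Benjamini-Hochberg companions across the K clusters, and a global
    K x L chi-square is reported alongside.
    """
    missing = [r for r in clustering.region_ids if r not in annotations]
    if missing:
        raise ValueError(f"unannotated region(s): {missing}")
    region_labels = [annotations[r] for r in clustering.region_ids]
    ann_labels = sorted(set(region_labels))
    clusters = sorted(set(clustering.assignment.values()))
    if len(ann_labels) < 2 or len(clusters) < 2:
        raise ValueError("need at least 2 specimen-clusters and 2 annotation labels")

    assign = np.array([clustering.assignment[r] for r in clustering.region_ids])
    ann_idx = np.array([ann_labels.index(a) for a in region_labels])
    K, L = len(clusters), len(ann_labels)
    contingency = np.zeros((K, L), dtype=int)
    for ci, c in enumerate(clusters):
        for li in range(L):
            contingency[ci, li] = int(np.sum((assign == c) & (ann_idx == li)))

    rng = np.random.default_rng(seed)
    stats, dofs, ps, methods = [], [], [], []
    col_totals = contingency.sum(axis=0)
    for ci, c in enumerate(clusters):
        in_row = contingency[ci]
        out_row = col_totals - in_row
        table = np.vstack([in_row, out_row])
        # drop labels absent from the whole specimen (zero column)
        table = table[:, table.sum(axis=0) > 0]
        stat, dof, expected = _chi2_stat(table)
        if expected.min() < min_expected:
            in_cluster = assign == c
            n_ge = 0
            for _ in range(n_permutations):
                perm = rng.permutation(ann_idx)
                t_in = np.bincount(perm[in_cluster], minlength=L)
                t_out = np.bincount(perm[~in_cluster], minlength=L)
                t = np.vstack([t_in, t_out])
                t = t[:, t.sum(axis=0) > 0]
                s, _, _ = _chi2_stat(t)
                if s >= stat - 1e-12:
                    n_ge += 1
            p = (1 + n_ge) / (1 + n_permutations)
            methods.append("permutation")
        else:
            from scipy.stats import chi2

            p = float(chi2.sf(stat, dof)) if stat > 0 else 1.0
            methods.append("chisq")
        stats.append(stat)
        dofs.append(dof)
        ps.append(float(p))
    p_adj = multipletests(ps, method="fdr_bh")[1].tolist()
    g_stat, g_dof, _ = _chi2_stat(contingency)
    from scipy.stats import chi2

    g_p = float(chi2.sf(g_stat, g_dof)) if g_stat > 0 else 1.0
    return EnrichmentResult(
        clusters=clusters,
        annotation_labels=ann_labels,
        contingency=contingency,
        statistics=stats,
        dof=dofs,
        p_values=ps,
        p_adjusted=p_adj,
        methods=methods,
        global_statistic=g_stat,
        global_p=g_p,
    )


def global_tile_clustering(
    fms: list[FeatureMatrix], k_total: int = DEFAULT_K_MULTISLIDE
) -> dict[str, PartitionMap]:
    """Pool all tiles of all slides and Ward-cluster once (tile-level global
    analysis); labels are shared across slides.

    Unscaled inputs are pooled raw and scaled jointly; pre-scaled inputs are
    pooled as-is (so a single pre-scaled slide reduces exactly to
    :func:`histomap.partition.partition_tiles`).
    """
    if not fms:
        raise ValueError("no feature matrices given")
    dims = {fm.dim for fm in fms}
    if len(dims) != 1:
        raise ValueError(f"mismatched feature dimensions {sorted(dims)}")
    scaled_flags = {fm.scaled for fm in fms}
    if len(scaled_flags) != 1:
        raise ValueError("mix of scaled and unscaled feature matrices")
    pooled = np.vstack([fm.values for fm in fms])
    if not scaled_flags.pop():
        from .features import FeatureMatrix as FM

        pooled_fm = FM(
            slide_id="<pooled>",
            tile_ids=[t for fm in fms for t in fm.tile_ids],
            values=pooled,
            extractor=fms[0].extractor,
        )
        pooled = scale_features(pooled_fm).values
    n_total = pooled.shape[0]
    if not 2 <= k_total <= n_total:
        raise ValueError(f"k_total must be in [2, {n_total}]")
    labels = WardPartitioner(n_clusters=k_total).fit(pooled).labels_
    from .partition import make_palette

    palette = make_palette(list(np.unique(labels)))
    out: dict[str, PartitionMap] = {}
    offset = 0
    for fm in fms:
        sl = labels[offset : offset + fm.n_tiles]
        offset += fm.n_tiles
        out[fm.slide_id] = PartitionMap(
            slide_id=fm.slide_id,
            k=k_total,
            labels=dict(zip(fm.tile_ids, (int(v) for v in sl))),
            linkage=None,
            method="global_tile",
            palette=palette,
        )
    return out
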