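"""Ward partitioning against a naive agglomerative oracle, subdivision,
silhouette k-selection, embeddings, and map rendering."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from histomap import (
    evaluate_k,
    partition_tiles,
    embed_tiles,
    render_partition_map,
    scale_features,
    subdivide_partition,
)
from histomap.partition import NON_TISSUE_GRAY, WardPartitioner, relabel_by_size

from conftest import make_fm


# ---------------------------------------------------------------------------
# independent oracles


def ward_oracle(X):
    """Naive O(n^3) agglomerative Ward via the Lance-Williams update.

    Returns {k: set of frozensets of member indices} for every k in 1..n.
    Entirely independent of scipy's linkage implementation.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    clusters = {i: frozenset([i]) for i in range(n)}
    dist = {
        frozenset((i, j)): float(np.sum((X[i] - X[j]) ** 2))
        for i, j in combinations(range(n), 2)
    }
    partitions = {n: set(clusters.values())}
    next_id = n
    while len(clusters) > 1:
        key, dmin = min(dist.items(), key=lambda kv: kv[1])
        a, b = sorted(key)
        na, nb = len(clusters[a]), len(clusters[b])
        merged = clusters[a] | clusters[b]
        del dist[key]
        for k in list(clusters):
            if k in (a, b):
                continue
            nk = len(clusters[k])
            dka = dist.pop(frozenset((k, a)))
            dkb = dist.pop(frozenset((k, b)))
            dist[frozenset((k, next_id))] = (
                (na + nk) * dka + (nb + nk) * dkb - nk * dmin
            ) / (na + nb + nk)
        del clusters[a], clusters[b]
        clusters[next_id] = merged
        next_id += 1
        partitions[len(clusters)] = set(clusters.values())
    return partitions


def as_partition(labels):
    """Label vector -> set of frozensets of member indices."""
    return {
        frozenset(np.flatnonzero(np.asarray(labels) == lab))
        for lab in np.unique(labels)
    }


def ward_objective(X, assignment):
    return sum(
        float(((X[list(c)] - X[list(c)].mean(axis=0)) ** 2).sum())
        for c in assignment
    )


def two_blobs(rng, n_per=3, d=8, sep=100.0):
    a = rng.normal(0, 1, size=(n_per, d))
    b = rng.normal(0, 1, size=(n_per, d)) + sep
    return np.vstack([a, b])


# ---------------------------------------------------------------------------


class TestWardPartitioner:
    def test_matches_lance_williams_oracle(self):
        """Exact partition agreement with the naive oracle for all k, on 100
        seeded random instances of up to 12 points."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 13))
            X = rng.normal(size=(n, int(rng.integers(2, 7))))
            expected = ward_oracle(X)
            model = WardPartitioner(n_clusters=2).fit(X)
            for k in range(1, n + 1):
                assert as_partition(model.cut(k)) == expected[k], (seed, k)

    def test_two_blobs_and_exhaustive_minimizer(self, rng):
        """k=2 on 6 points in 2 far blobs equals blob membership, which is
        also the exhaustive minimizer of the Ward objective."""
        X = two_blobs(rng)
        labels = WardPartitioner(n_clusters=2).fit_predict(X)
        assert as_partition(labels) == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}
        best = min(
            (
                {frozenset(s), frozenset(set(range(6)) - set(s))}
                for r in range(1, 6)
                for s in combinations(range(6), r)
            ),
            key=lambda p: ward_objective(X, p),
        )
        assert as_partition(labels) == best

    def test_full_cut_singletons(self, rng):
        X = rng.normal(size=(7, 8))
        fm = make_fm(X)
        pm = partition_tiles(fm, k=7)
        assert sorted(pm.labels.values()) == list(range(1, 8))

    def test_cuts_are_nested(self, rng):
        X = rng.normal(size=(15, 6))
        model = WardPartitioner(n_clusters=2).fit(X)
        for k in range(3, 16):
            fine = as_partition(model.cut(k))
            coarse = as_partition(model.cut(k - 1))
            for c in coarse:
                parts = [f for f in fine if f <= c]
                assert frozenset().union(*parts) == c

    def test_renumbering_by_size_then_min_index(self, rng):
        X = two_blobs(rng, n_per=4)
        X = np.vstack([X, X[:2] + 200.0])  # third blob of size 2
        labels = WardPartitioner(n_clusters=3).fit_predict(X)
        sizes = [np.sum(labels == lab) for lab in (1, 2, 3)]
        assert sizes == sorted(sizes, reverse=True)
        # equal-size tie: label 1 must contain the smallest member index
        assert labels[0] == 1

    def test_precondition_errors(self, rng):
        fm = make_fm(rng.normal(size=(5, 8)))
        with pytest.raises(ValueError):
            partition_tiles(fm, k=6)
        raw = make_fm(rng.normal(size=(5, 8)), scaled=False)
        with pytest.raises(RuntimeError, match="scaled"):
            partition_tiles(raw, k=2)


class TestSubdivide:
    def test_blob_region_split(self, rng):
        X = np.vstack([two_blobs(rng), rng.normal(500, 1, size=(4, 8))])
        fm = make_fm(X)
        pm = partition_tiles(fm, k=2)
        region_of_blobs = pm.labels[fm.tile_ids[0]]
        pm2 = subdivide_partition(fm, pm, region_of_blobs, k2=2, seed=0)
        assert pm2.k == 3 and pm2.method == "kmeans_subdivide"
        sub = pm2.labels_for(fm.tile_ids[:6])
        assert as_partition(sub) == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_full_split_and_determinism(self, rng):
        fm = make_fm(rng.normal(size=(8, 8)))
        pm = partition_tiles(fm, k=2)
        size1 = len(pm.members(1))
        pm_a = subdivide_partition(fm, pm, 1, k2=size1, seed=3)
        assert len(set(pm_a.labels_for(pm.members(1)))) == size1
        pm_b = subdivide_partition(fm, pm, 1, k2=size1, seed=3)
        assert pm_a.labels == pm_b.labels

    def test_k2_bounds(self, rng):
        fm = make_fm(rng.normal(size=(8, 8)))
        pm = partition_tiles(fm, k=2)
        with pytest.raises(ValueError):
            subdivide_partition(fm, pm, 1, k2=len(pm.members(1)) + 1)


class TestEvaluateK:
    def test_blobs_argmax_at_two_with_silhouette_oracle(self, rng):
        X = two_blobs(rng, n_per=5)
        fm = make_fm(X)
        scores, best = evaluate_k(fm, 2, 4)
        assert best == 2

        # independent pairwise-distance silhouette oracle at k=2
        def sil(i, labels):
            d = np.linalg.norm(X - X[i], axis=1)
            own = labels == labels[i]
            a = d[own & (np.arange(len(X)) != i)].mean()
            b = min(d[labels == lab].mean() for lab in set(labels) if lab != labels[i])
            return (b - a) / max(a, b)

        labels = WardPartitioner(n_clusters=2).fit_predict(X)
        expected = np.mean([sil(i, labels) for i in range(len(X))])
        assert scores[2] == pytest.approx(expected, rel=1e-9)

    def test_degenerate_identical_rows(self):
        fm = make_fm(np.ones((6, 8)))
        with pytest.warns(UserWarning, match="silhouette undefined"):
            scores, _ = evaluate_k(fm, 2, 3)
        assert all(s == 0.0 for s in scores.values())

    def test_invalid_range(self, rng):
        fm = make_fm(rng.normal(size=(6, 8)))
        with pytest.raises(ValueError):
            evaluate_k(fm, 4, 2)
        with pytest.raises(ValueError):
            evaluate_k(fm, 2, 6)

    def test_scores_bounded(self, rng):
        fm = make_fm(rng.normal(size=(9, 8)) * 10)
        scores, _ = evaluate_k(fm, 2, 5)
        assert all(-1.0 <= s <= 1.0 for s in scores.values())


class TestEmbedTiles:
    def test_seeded_determinism_and_blob_separation(self, rng):
        X = two_blobs(rng, n_per=6)
        fm = make_fm(X)
        e1 = embed_tiles(fm, "tsne", seed=4)
        e2 = embed_tiles(fm, "tsne", seed=4)
        np.testing.assert_array_equal(e1.coordinates, e2.coordinates)
        c = e1.coordinates
        within = np.linalg.norm(c[:6] - c[:6].mean(0), axis=1).mean()
        between = np.linalg.norm(c[:6].mean(0) - c[6:].mean(0))
        assert between > within

    def test_too_few_tiles(self, rng):
        with pytest.raises(ValueError, match="5"):
            embed_tiles(make_fm(rng.normal(size=(4, 8))), "tsne", seed=0)


class TestRenderPartitionMap:
    def test_two_by_two_block_raster(self, three_region):
        slide, grid, fm = three_region
        pm = partition_tiles(fm, k=2)
        raster = render_partition_map(pm, grid, downsample=64)
        assert raster.shape == (grid.n_rows, grid.n_cols, 3)
        colors = {tuple(raster[t.row, t.col]) for t in grid.tiles}
        assert colors == {pm.palette[1], pm.palette[2]}

    def test_non_tissue_gray_and_legend(self, three_region, tmp_path):
        import json

        slide, _, fm = three_region
        from histomap import tile_slide

        grid = tile_slide(slide.as_handle("syn1"), 64)
        grid.tiles[0].is_tissue = False
        pm = partition_tiles(fm, k=3)
        out = tmp_path / "map.png"
        raster = render_partition_map(pm, grid, downsample=64, out_png=str(out))
        assert tuple(raster[0, 0]) == NON_TISSUE_GRAY
        legend = json.loads((out.parent / "map.png.legend.json").read_text())
        assert set(legend) == {"1", "2", "3"}

    def test_slide_mismatch(self, three_region, rng):
        _, grid, _ = three_region
        fm = make_fm(rng.normal(size=(6, 8)), slide_id="other")
        pm = partition_tiles(fm, k=2)
        with pytest.raises(ValueError, match="slide"):
            render_partition_map(pm, grid)


def test_relabel_is_pure_relabeling(rng):
    raw = rng.integers(0, 5, size=40)
    out = relabel_by_size(raw)
    assert as_partition(raw) == as_partition(out)
    assert set(out) == set(range(1, len(np.unique(raw)) + 1))
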