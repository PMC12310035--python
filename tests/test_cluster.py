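"""UPGMA clustering, subcluster cutting, reordering, embedding, alignment."""

import numpy as np
import pandas as pd
import pytest

from regulonkit.cluster import (
    align_by_centroids,
    correlation_distance,
    correlation_distance_matrix,
    cut_subclusters,
    embed_joint,
    hcluster,
    reorder_by_reference,
)


def naive_upgma(df):
    """O(n^3) oracle: recompute average linkage from the leaf distance matrix
    at every step, with the same member-id tie-break."""
    ids = [str(i) for i in df.index]
    D = correlation_distance_matrix(df.to_numpy())
    clusters = {i: [i] for i in range(len(ids))}
    merges = []
    next_node = len(ids)
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([[D[x, y] for y in clusters[b]] for x in clusters[a]])
                ka = tuple(sorted(ids[x] for x in clusters[a]))
                kb = tuple(sorted(ids[x] for x in clusters[b]))
                key = (d, min(ka, kb), max(ka, kb))
                if best is None or (d < best[0][0] - 1e-12) or (
                    abs(d - best[0][0]) <= 1e-12 and key[1:] < best[0][1:]
                ):
                    best = (key, a, b)
        (d, _, _), a, b = best
        merges.append((a, b, d))
        clusters[next_node] = clusters.pop(a) + clusters.pop(b)
        next_node += 1
    return merges


class TestCorrelationDistance:
    def test_self_distance_zero(self):
        assert correlation_distance([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_anticorrelated_distance_two(self):
        assert correlation_distance([1, 2, 3], [-1, -2, -3]) == pytest.approx(2.0)

    def test_closed_form_value(self):
        assert correlation_distance([1, 2, 3], [1, 2, 4]) == pytest.approx(
            1 - 0.9819805, abs=1e-6
        )

    def test_constant_vector_distance_one(self):
        assert correlation_distance([1, 1, 1], [1, 2, 3]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            correlation_distance([1, 2], [1, 2, 3])


class TestHcluster:
    def test_identical_rows_merge_first_at_height_zero(self):
        df = pd.DataFrame(
            [[1, 2, 3, 4], [0, 5, 1, 9], [1, 2, 3, 4], [9, 1, 1, 0]],
            index=["w", "x", "y", "z"],
        )
        dend = hcluster(df)
        l, r, h = dend.merges[0]
        assert {dend.ids[l], dend.ids[r]} == {"w", "y"}
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_hand_upgma_on_four_vectors(self):
        # distances hand-computed from Pearson correlations
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 4.0], [3.0, 2.0, 1.0], [4.0, 2.5, 1.0]],
            index=["a", "b", "c", "d"],
        )
        dend = hcluster(df)
        oracle = naive_upgma(df)
        assert [(m[0], m[1]) for m in dend.merges] == [(m[0], m[1]) for m in oracle]
        for (_, _, h1), (_, _, h2) in zip(dend.merges, oracle):
            assert h1 == pytest.approx(h2, abs=1e-12)

    def test_row_permutation_invariance_up_to_ids(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(6, 5)), index=list("abcdef"))
        d1 = hcluster(df)
        perm = df.sample(frac=1, random_state=1)
        d2 = hcluster(perm)
        assert d1.leaf_order == d2.leaf_order
        h1 = [m[2] for m in d1.merges]
        h2 = [m[2] for m in d2.merges]
        np.testing.assert_allclose(h1, h2, atol=1e-12)

    def test_columns_axis_clusters_transpose(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("wxyz"))
        assert hcluster(df, axis="columns").leaf_order == hcluster(df.T).leaf_order


class TestCutSubclusters:
    @pytest.fixture()
    def dend(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(2, 6))
        rows = np.vstack([base[0] + rng.normal(scale=0.1, size=(3, 6)),
                          base[1] + rng.normal(scale=0.1, size=(3, 6))])
        return hcluster(pd.DataFrame(rows, index=list("abcdef")))

    def test_k_equals_n_gives_singletons(self, dend):
        labels = cut_subclusters(dend, 6)
        assert labels.nunique() == 6

    def test_k_one_gives_single_cluster(self, dend):
        assert cut_subclusters(dend, 1).nunique() == 1

    def test_two_planted_groups_recovered_at_k2(self, dend):
        labels = cut_subclusters(dend, 2)
        assert set(labels[list("abc")]) != set(labels[list("def")])
        assert labels[list("abc")].nunique() == 1
        assert labels[list("def")].nunique() == 1

    def test_k_out_of_range_rejected(self, dend):
        with pytest.raises(ValueError):
            cut_subclusters(dend, 7)

    def test_silhouette_suggestion_finds_planted_group_count(self):
        from regulonkit.cluster import suggest_k

        rng = np.random.default_rng(12)
        centers = rng.normal(size=(3, 8)) * 2
        rows = np.vstack([c + rng.normal(scale=0.1, size=(10, 8)) for c in centers])
        df = pd.DataFrame(rows, index=[f"r{i:02d}" for i in range(30)])
        assert suggest_k(df, 2, 6) == 3

    def test_labels_numbered_by_leaf_order(self, dend):
        labels = cut_subclusters(dend, 3)
        first_seen = []
        for cid in dend.leaf_order:
            if labels[cid] not in first_seen:
                first_seen.append(labels[cid])
        assert first_seen == sorted(first_seen)


class TestScipyCrossCheck:
    def test_matches_scipy_average_linkage_on_tie_free_data(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(8)
        for _ in range(5):
            df = pd.DataFrame(rng.normal(size=(8, 10)))
            dend = hcluster(df)
            D = correlation_distance_matrix(df.to_numpy())
            Z = linkage(squareform(D, checks=False), method="average")
            np.testing.assert_allclose(
                sorted(m[2] for m in dend.merges), sorted(Z[:, 2]), atol=1e-10
            )


class TestReorder:
    def test_own_order_identity(self):
        df = pd.DataFrame(np.arange(6).reshape(2, 3), columns=list("abc"))
        pd.testing.assert_frame_equal(reorder_by_reference(df, list("abc")), df)

    def test_reversed_reference(self):
        df = pd.DataFrame(np.arange(6).reshape(2, 3), columns=list("abc"))
        out = reorder_by_reference(df, list("cba"))
        assert list(out.columns) == ["c", "b", "a"]

    def test_extra_columns_appended_in_original_order(self):
        df = pd.DataFrame(np.arange(8).reshape(2, 4), columns=list("abcd"))
        out = reorder_by_reference(df, ["c", "a"])
        assert list(out.columns) == ["c", "a", "b", "d"]

    def test_values_follow_inverse_permutation(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(3, 4)), columns=list("abcd"))
        out = reorder_by_reference(df, list("dcba"))
        pd.testing.assert_frame_equal(out[list("abcd")], df)

    def test_empty_intersection_rejected(self):
        df = pd.DataFrame(np.zeros((2, 2)), columns=list("ab"))
        with pytest.raises(ValueError):
            reorder_by_reference(df, ["z"])


@pytest.fixture(scope="module")
def separated_embedding():
    # two well-separated activity profiles per condition + one extra in A
    rng = np.random.default_rng(9)
    cols = [f"T{i}" for i in range(8)]

    def block(center, n, prefix):
        X = center + rng.normal(scale=0.05, size=(n, 8))
        return pd.DataFrame(X, columns=cols,
                            index=[f"{prefix}_{i}" for i in range(n)])

    c1, c2, c3 = np.zeros(8), np.ones(8) * 0.5, np.linspace(0, 1, 8)
    auc_a = pd.concat([block(c1, 40, "a1"), block(c2, 40, "a2"), block(c3, 40, "a3")])
    auc_b = pd.concat([block(c1, 40, "b1"), block(c2, 40, "b2")])
    emb = embed_joint(auc_a, auc_b, n_pcs=5, n_neighbors=10, min_dist=0.3, seed=4)
    labels_a = pd.Series(
        {c: ("1" if c.startswith("a1") else "2" if c.startswith("a2") else "3")
         for c in auc_a.index}
    )
    labels_b = pd.Series({c: ("1" if c.startswith("b1") else "2") for c in auc_b.index})
    return emb, labels_a, labels_b


class TestEmbedAndAlign:

    def test_embedding_deterministic_given_seed(self, separated_embedding):
        rng = np.random.default_rng(2)
        auc_a = pd.DataFrame(rng.random((30, 6)), columns=list("abcdef"))
        auc_b = pd.DataFrame(rng.random((25, 6)), columns=list("abcdef"))
        auc_a.index = [f"x{i}" for i in range(30)]
        auc_b.index = [f"y{i}" for i in range(25)]
        e1 = embed_joint(auc_a, auc_b, n_pcs=4, n_neighbors=8, seed=7)
        e2 = embed_joint(auc_a, auc_b, n_pcs=4, n_neighbors=8, seed=7)
        pd.testing.assert_frame_equal(e1, e2)

    def test_duplicated_cell_gets_identical_coordinates(self):
        rng = np.random.default_rng(6)
        auc_a = pd.DataFrame(rng.random((20, 5)), columns=list("abcde"),
                             index=[f"x{i}" for i in range(20)])
        auc_a.iloc[1] = auc_a.iloc[0]
        auc_b = pd.DataFrame(rng.random((15, 5)), columns=list("abcde"),
                             index=[f"y{i}" for i in range(15)])
        emb = embed_joint(auc_a, auc_b, n_pcs=3, n_neighbors=6, seed=3)
        np.testing.assert_array_equal(emb.iloc[0].to_numpy(), emb.iloc[1].to_numpy())

    def test_separated_subclusters_have_distant_centroids(self, separated_embedding):
        emb, labels_a, _ = separated_embedding
        for lab in "123":
            cells = labels_a.index[labels_a == lab]
            centroid = emb.loc[cells].mean()
            within = np.linalg.norm(emb.loc[cells] - centroid, axis=1)
            others = [l for l in "123" if l != lab]
            for o in others:
                oc = emb.loc[labels_a.index[labels_a == o]].mean()
                assert np.linalg.norm(centroid - oc) > np.quantile(within, 0.95)

    def test_alignment_recovers_matches_and_unique(self, separated_embedding):
        emb, labels_a, labels_b = separated_embedding
        res = align_by_centroids(emb, labels_a, labels_b)
        assert ("1", "1") in res.matches and ("2", "2") in res.matches
        assert res.unique_a == ["3"]
        assert res.unique_b == []

    def test_identical_conditions_all_matched_distance_zero(self):
        rng = np.random.default_rng(10)
        emb = pd.DataFrame(rng.normal(size=(40, 2)), columns=["umap_1", "umap_2"],
                           index=[f"c{i}" for i in range(40)])
        labels = pd.Series(["1"] * 20 + ["2"] * 20, index=emb.index)
        res = align_by_centroids(emb, labels, labels)
        assert set(res.matches) == {("1", "1"), ("2", "2")}
        assert res.unique_a == [] and res.unique_b == []
        assert np.trace(res.distance_matrix.to_numpy()) == pytest.approx(0.0)
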