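import itertools

import numpy as np
import pytest

from synmarker.exceptions import MissingGeneError
from synmarker.gene_statistics import GeneClassModel, fit_class_models, llr_vector
from synmarker.io_network import ExpressionDataset
from synmarker.marker_pipeline import (
    SubnetworkMarker,
    identify_markers,
    infer_activity,
    kmeans_1d,
    marker_set_stats,
    postprocess_cluster,
    score_and_rank,
)


def _exhaustive_1d_kmeans_sse(values, k):
    """Oracle: best SSE over all contiguous partitions of the sorted values."""
    x = np.sort(values)
    n = len(x)
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        sse = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = x[a:b]
            sse += ((seg - seg.mean()) ** 2).sum()
        best = min(best, sse)
    return best


def _labels_sse(values, labels):
    sse = 0.0
    for g in np.unique(labels):
        seg = values[labels == g]
        sse += ((seg - seg.mean()) ** 2).sum()
    return sse


class TestKMeans1D:
    @pytest.mark.parametrize("n,k", [(5, 2), (8, 3), (12, 4), (20, 5)])
    def test_dp_matches_exhaustive_partition_search(self, n, k):
        rng = np.random.default_rng(n * 10 + k)
        values = rng.normal(size=n)
        labels = kmeans_1d(values, k)
        assert _labels_sse(values, labels) == pytest.approx(
            _exhaustive_1d_kmeans_sse(values, k)
        )

    def test_trivial_cases(self):
        assert list(kmeans_1d([3.0, 1.0], 1)) == [0, 0]
        assert len(set(kmeans_1d([3.0, 1.0, 2.0], 3))) == 3


class TestPostprocessCluster:
    def test_removes_low_score_group(self):
        scores = {"a": 5.0, "b": 5.1, "c": 4.9, "d": 1.0, "e": 1.1}
        members = ["a", "b", "c", "d", "e"]
        survivors = postprocess_cluster(members, scores)
        assert sorted(survivors) == ["a", "b", "c"]
        before = np.mean([scores[g] for g in members])
        after = np.mean([scores[g] for g in survivors])
        assert before == pytest.approx(3.42)
        assert after == pytest.approx(5.0)

    def test_tied_scores_left_unchanged(self):
        scores = {g: 2.0 for g in "abcd"}
        assert postprocess_cluster(list("abcd"), scores) == list("abcd")

    def test_two_members_forces_k1(self):
        scores = {"a": 9.0, "b": 0.1}
        assert postprocess_cluster(["a", "b"], scores) == ["a", "b"]

    def test_contract_on_random_clusters(self):
        """Never empties, never enlarges, never lowers the mean score."""
        rng = np.random.default_rng(31)
        for _ in range(300):
            n = int(rng.integers(1, 40))
            members = [f"g{j}" for j in range(n)]
            scores = {g: float(rng.gamma(2.0)) for g in members}
            out = postprocess_cluster(members, scores, seed=0)
            assert 0 < len(out) <= n
            assert set(out) <= set(members)
            mean_before = np.mean([scores[g] for g in members])
            mean_after = np.mean([scores[g] for g in out])
            assert mean_after >= mean_before - 1e-12


class TestActivityInference:
    def _two_gene_dataset(self):
        return ExpressionDataset(
            gene_ids=["g1", "g2"],
            values=np.array([[0.0, 1.0, 2.0, 0.5], [1.0, -1.0, 0.0, 2.0]]),
            sample_ids=["S1", "S2", "S3", "S4"],
            labels=np.array([True, True, False, False]),
        )

    def test_single_member_equals_gene_llr(self):
        ds = self._two_gene_dataset()
        model = GeneClassModel("g1", 1.0, 1.0, 0.0, 1.0)
        marker = SubnetworkMarker("g1", ["g1"], [model])
        prof = infer_activity(marker, ds)
        np.testing.assert_allclose(prof.activities, llr_vector(model, ds.row("g1")))

    def test_identical_class_models_zero_activity(self):
        ds = self._two_gene_dataset()
        models = [GeneClassModel(g, 0.3, 1.1, 0.3, 1.1) for g in ["g1", "g2"]]
        marker = SubnetworkMarker("g1", ["g1", "g2"], models)
        np.testing.assert_array_equal(infer_activity(marker, ds).activities, 0.0)

    def test_two_member_hand_sum(self):
        ds = self._two_gene_dataset()
        m1 = GeneClassModel("g1", 1.0, 1.0, 0.0, 1.0)
        m2 = GeneClassModel("g2", -1.0, 2.0, 1.0, 1.0)
        marker = SubnetworkMarker("g1", ["g1", "g2"], [m1, m2])
        expected = llr_vector(m1, ds.row("g1")) + llr_vector(m2, ds.row("g2"))
        np.testing.assert_allclose(infer_activity(marker, ds).activities, expected)

    def test_activity_additivity_on_random_markers(self):
        rng = np.random.default_rng(41)
        n_genes, n_samples = 12, 30
        ds = ExpressionDataset(
            gene_ids=[f"g{j}" for j in range(n_genes)],
            values=rng.standard_normal((n_genes, n_samples)),
            sample_ids=[f"S{j}" for j in range(n_samples)],
            labels=np.array([True] * 10 + [False] * 20),
        )
        models = {m.gene_id: m for m in fit_class_models(ds)}
        for _ in range(20):
            size = int(rng.integers(1, n_genes + 1))
            members = list(rng.choice(ds.gene_ids, size=size, replace=False))
            marker = SubnetworkMarker(members[0], members, [models[g] for g in members])
            total = infer_activity(marker, ds).activities
            parts = sum(
                infer_activity(
                    SubnetworkMarker(g, [g], [models[g]]), ds
                ).activities
                for g in members
            )
            np.testing.assert_allclose(total, parts, atol=1e-12)

    def test_missing_gene_is_named(self):
        ds = self._two_gene_dataset()
        marker = SubnetworkMarker(
            "gX", ["gX"], [GeneClassModel("gX", 0, 1, 0, 1)]
        )
        with pytest.raises(MissingGeneError, match="gX"):
            infer_activity(marker, ds)


class TestScoreAndRank:
    def _dataset_and_markers(self):
        rng = np.random.default_rng(13)
        genes = [f"g{j}" for j in range(6)]
        values = rng.standard_normal((6, 40))
        labels = np.array([True] * 15 + [False] * 25)
        values[0, labels] += 3.0
        values[1, labels] += 2.0
        values[2, labels] += 1.0
        ds = ExpressionDataset(genes, values, [f"S{j}" for j in range(40)], labels)
        models = {m.gene_id: m for m in fit_class_models(ds)}
        markers = [
            SubnetworkMarker(g, [g], [models[g]]) for g in genes[:4]
        ]
        return ds, markers

    def test_rank_order_and_top_k(self):
        ds, markers = self._dataset_and_markers()
        top2 = score_and_rank(markers, ds, top_k=2)
        all_ranked = score_and_rank(markers, ds, top_k=None)
        assert [m.exemplar for m in top2] == [m.exemplar for m in all_ranked[:2]]
        mags = [abs(m.activity_t) for m in all_ranked]
        assert mags == sorted(mags, reverse=True)
        assert all_ranked[0].exemplar == "g0"

    def test_top_k_larger_than_marker_count(self):
        ds, markers = self._dataset_and_markers()
        assert len(score_and_rank(markers, ds, top_k=99)) == len(markers)

    def test_rerun_is_bit_identical(self):
        ds, markers = self._dataset_and_markers()
        first = [(m.exemplar, m.activity_t) for m in score_and_rank(markers, ds, None)]
        second = [(m.exemplar, m.activity_t) for m in score_and_rank(markers, ds, None)]
        assert first == second


class TestMarkerSetStats:
    def _marker(self, *genes):
        return SubnetworkMarker(genes[0], list(genes))

    def test_half_overlap(self):
        stats = marker_set_stats(
            [self._marker("a", "b", "c")], [self._marker("b", "c", "d")]
        )
        assert stats.overlap == pytest.approx(0.5)
        assert stats.unique_genes_a == 3 and stats.unique_genes_b == 3

    def test_identical_and_disjoint(self):
        a = [self._marker("a", "b")]
        assert marker_set_stats(a, a).overlap == 1.0
        assert marker_set_stats(a, [self._marker("x", "y")]).overlap == 0.0
        assert marker_set_stats(a, a).avg_size_a == 2.0


class TestIdentifyMarkers:
    def test_markers_are_gene_disjoint_and_planted_modules_lead(self, small_synthetic):
        spec, network, truth, datasets = small_synthetic
        markers, solution = identify_markers(datasets[0], network, alpha=0.5, top_k=None)
        seen = set()
        for m in markers:
            assert not (seen & set(m.members))
            seen |= set(m.members)
        planted = truth.planted_genes
        top5 = markers[:5]
        assert sum(1 for m in top5 if set(m.members) & planted) >= 4
        # every marker's activity was scored and ranking is by magnitude
        mags = [abs(m.activity_t) for m in markers]
        assert mags == sorted(mags, reverse=True)
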