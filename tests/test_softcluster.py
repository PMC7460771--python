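import numpy as np
import pytest

from hemescreen.softcluster import (
    ProfileMatrix,
    assign_members,
    classify_cluster_pattern,
    estimate_fuzzifier,
    fuzzy_cmeans,
    profile_matrix,
    select_cluster_count,
)
from hemescreen.simulate import SimConfig, generate_experiment

from conftest import make_count_matrix

TRI = ["normal_serum", "heme_deficient", "heme_excess"]


def _planted_profiles(seed=0, n_per=40, noise=0.15):
    """Three well-separated profile shapes plus their gene indices."""
    rng = np.random.default_rng(seed)
    shapes = np.array(
        [
            [0.0, 1.0, -1.0],  # import-like
            [0.0, -1.0, 1.0],  # export-like
            [1.0, -0.5, -0.5],  # serum response
        ]
    )
    rows, labels = [], []
    for k, s in enumerate(shapes):
        for _ in range(n_per):
            rows.append(s + rng.normal(0, noise, 3))
            labels.append(k)
    x = np.array(rows)
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    return (
        ProfileMatrix(
            gene_ids=[f"g{i}" for i in range(len(rows))],
            profiles=x,
            treatments=TRI,
        ),
        np.array(labels),
    )


class TestProfileMatrix:
    def test_rows_standardized(self, small_experiment):
        _, cm, _, _ = small_experiment
        prof = profile_matrix(cm)
        np.testing.assert_allclose(prof.profiles.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(prof.profiles.std(axis=1), 1, atol=1e-9)

    def test_constant_gene_dropped(self):
        counts = np.array([[10, 10, 10], [5, 50, 500]])
        cm = make_count_matrix(counts, TRI)
        # equalize library sizes so gene 0 has identical CPM everywhere
        counts = np.array([[10, 10, 10], [20, 20, 20]])
        cm = make_count_matrix(counts, TRI)
        prof = profile_matrix(cm)
        assert prof.gene_ids == []
        assert set(prof.dropped) == {"g0", "g1"}

    def test_standardization_matches_direct_computation(self, small_experiment):
        _, cm, _, _ = small_experiment
        prof = profile_matrix(cm)
        log_cpm = np.log2(cm.counts / cm.counts.sum(axis=0) * 1e6 + 0.5)
        idx = {g: i for i, g in enumerate(cm.gene_ids)}
        for g in prof.gene_ids[:20]:
            means = np.array(
                [
                    log_cpm[
                        idx[g], [i for i, s in enumerate(cm.samples) if s.treatment == t]
                    ].mean()
                    for t in prof.treatments
                ]
            )
            want = (means - means.mean()) / means.std()
            got = prof.profiles[prof.gene_ids.index(g)]
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_single_treatment_rejected(self):
        cm = make_count_matrix(np.array([[1, 2]]), ["heme_excess", "heme_excess"])
        with pytest.raises(ValueError, match="two treatments"):
            profile_matrix(cm)


class TestEstimateFuzzifier:
    def test_always_above_one(self):
        for n, d in [(2, 2), (100, 3), (10_000, 3), (500, 20)]:
            assert estimate_fuzzifier(n, d) > 1.0

    def test_decreases_with_gene_count(self):
        assert estimate_fuzzifier(100, 3) > estimate_fuzzifier(10_000, 3)

    def test_decreases_with_dimensionality(self):
        assert estimate_fuzzifier(1000, 3) > estimate_fuzzifier(1000, 30)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            estimate_fuzzifier(1, 3)


class TestFuzzyCMeans:
    def test_single_cluster_is_mean_profile(self):
        prof, _ = _planted_profiles()
        model = fuzzy_cmeans(prof, c=1, m=1.5)
        np.testing.assert_allclose(model.memberships, 1.0)
        np.testing.assert_allclose(
            model.centroids[0], prof.profiles.mean(axis=0), atol=1e-12
        )

    def test_membership_rows_sum_to_one(self):
        prof, _ = _planted_profiles(seed=3)
        model = fuzzy_cmeans(prof, c=4, m=1.8, seed=2)
        np.testing.assert_allclose(model.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(model.memberships >= 0) and np.all(model.memberships <= 1)

    def test_coincident_point_gets_full_membership(self):
        x = np.array([[0.0, 1.0, -1.0], [0.0, -1.0, 1.0], [1.0, 0.0, -1.0]])
        prof = ProfileMatrix(["a", "b", "c"], x, TRI)
        model = fuzzy_cmeans(prof, c=3, m=2.0, seed=0, n_restarts=1, max_iter=0)
        # with max_iter=0 the centroids stay at their data-point seeds, so
        # each seeded point must have membership exactly 1 somewhere
        assert np.isclose(model.memberships.max(axis=1), 1.0).sum() >= 3

    def test_near_hard_limit_matches_kmeans_partition(self):
        from scipy.cluster.vq import kmeans2

        prof, labels = _planted_profiles(seed=5, noise=0.08)
        model = fuzzy_cmeans(prof, c=3, m=1.01, seed=4, n_restarts=10)
        hard = model.memberships.argmax(axis=1)
        # brute-force/k-means oracle on the same data
        _, km = kmeans2(prof.profiles, 3, minit="++", seed=7)
        # compare partitions up to label permutation via pair-confusion
        same_fcm = hard[:, None] == hard[None, :]
        same_km = km[:, None] == km[None, :]
        assert (same_fcm == same_km).mean() > 0.98

    def test_determinism_given_seed(self):
        prof, _ = _planted_profiles(seed=6)
        a = fuzzy_cmeans(prof, c=3, m=1.5, seed=9)
        b = fuzzy_cmeans(prof, c=3, m=1.5, seed=9)
        np.testing.assert_array_equal(a.memberships, b.memberships)

    def test_invalid_params_rejected(self):
        prof, _ = _planted_profiles()
        with pytest.raises(ValueError):
            fuzzy_cmeans(prof, c=0, m=1.5)
        with pytest.raises(ValueError):
            fuzzy_cmeans(prof, c=2, m=1.0)


class TestSelectClusterCount:
    def test_recovers_three_planted_shapes(self):
        prof, _ = _planted_profiles(seed=8, n_per=60, noise=0.1)
        c = select_cluster_count(prof, range(2, 7), seed=1, m=1.5)
        assert c == 3

    def test_zero_threshold_returns_max(self):
        prof, _ = _planted_profiles(seed=9)
        c = select_cluster_count(
            prof, range(2, 6), seed=1, m=1.5, min_centroid_distance=0.0
        )
        assert c == 5

    def test_empty_range_rejected(self):
        prof, _ = _planted_profiles()
        with pytest.raises(ValueError, match="empty"):
            select_cluster_count(prof, [], seed=1)

    def test_deterministic(self):
        prof, _ = _planted_profiles(seed=10)
        assert select_cluster_count(prof, range(2, 6), seed=3) == select_cluster_count(
            prof, range(2, 6), seed=3
        )


class TestAssignMembers:
    def test_boundary_membership_excluded(self):
        prof, _ = _planted_profiles()
        model = fuzzy_cmeans(prof, c=2, m=1.5, seed=0)
        model.memberships = np.full((4, 2), 0.5)
        model.gene_ids = ["a", "b", "c", "d"]
        assert len(assign_members(model, threshold=0.5)) == 0

    def test_zero_threshold_assigns_everyone(self):
        prof, _ = _planted_profiles(seed=11)
        model = fuzzy_cmeans(prof, c=3, m=2.0, seed=0)
        assert len(assign_members(model, threshold=0.0)) == len(prof.gene_ids)

    def test_counts_match_brute_force_scan(self):
        prof, _ = _planted_profiles(seed=12)
        model = fuzzy_cmeans(prof, c=3, m=1.6, seed=0)
        table = assign_members(model, threshold=0.5)
        want = sum(
            1
            for row in model.memberships
            if row.max() > 0.5
        )
        assert len(table) == want


class TestClassifyClusterPattern:
    @pytest.mark.parametrize(
        "centroid,expected",
        [
            ((0, 1, -1), "import_like"),
            ((0, -1, 1), "export_like"),
            ((1, -0.5, -0.5), "serum_response"),
            ((-1, 0.5, 0.5), "serum_response"),
            ((0, 0, 0), "other"),
            ((1, 1, -2), "other"),  # tie between serum and deficient
        ],
    )
    def test_three_group_rules(self, centroid, expected):
        assert classify_cluster_pattern(np.array(centroid), TRI) == expected

    def test_two_group_rules(self):
        order = ["normal_serum", "heme_excess"]
        assert classify_cluster_pattern(np.array([1.0, -1.0]), order) == "import_like"
        assert classify_cluster_pattern(np.array([-1.0, 1.0]), order) == "export_like"
        assert classify_cluster_pattern(np.array([0.0, 0.0]), order) == "other"

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown treatment"):
            classify_cluster_pattern(np.zeros(3), ["normal_serum", "x", "heme_excess"])

    def test_negation_swaps_import_export_labels(self):
        rng = np.random.default_rng(15)
        for _ in range(200):
            c = rng.normal(0, 1, 3)
            lab = classify_cluster_pattern(c, TRI)
            neg = classify_cluster_pattern(-c, TRI)
            swap = {"import_like": "export_like", "export_like": "import_like"}
            if lab in swap:
                assert neg == swap[lab]
            else:
                assert neg == lab


class TestPlantedRecovery:
    def test_importers_recovered_in_import_like_clusters(self):
        """Planted importers land in import-labelled clusters at
        membership > 0.5 (median over seeds)."""
        rates = []
        for seed in range(5):
            cfg = SimConfig(
                n_genes=800,
                n_import=50,
                n_export=50,
                n_serum=50,
                dispersion=0.1,
                seed=seed,
            )
            matrices, _, truth = generate_experiment(cfg)
            prof = profile_matrix(matrices[0])
            model = fuzzy_cmeans(prof, c=6, m=1.5, seed=seed)
            table = assign_members(model, threshold=0.5)
            lab = dict(zip(table["gene_id"], table["pattern"]))
            imp = truth.genes_of_class("import")
            rates.append(
                sum(1 for g in imp if lab.get(g) == "import_like") / len(imp)
            )
        assert np.median(rates) >= 0.8
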