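import math

import numpy as np
import pytest
import scipy.stats
from statsmodels.stats.multitest import multipletests

from hemescreen.diffexpr import (
    bh_adjust,
    cpm,
    equalize_libraries,
    estimate_common_dispersion,
    exact_test_gene,
    filter_expressed,
    run_de,
    tmm_factors,
)
from hemescreen.simulate import SimConfig, generate_experiment, nb_draw

from conftest import make_count_matrix


# ---------------------------------------------------------------------------
# independent oracles


def oracle_exact_test(counts_a, counts_b, phi):
    """Brute-force conditional exact test, written from the definition.

    Uses plain Python loops and math.lgamma / math.comb, independent of the
    vectorized implementation.
    """
    sa, sb = sum(counts_a), sum(counts_b)
    na, nb = len(counts_a), len(counts_b)
    s = sa + sb
    if s == 0:
        return 1.0

    def log_pmf_sum(total, n):
        if phi == 0.0:
            return None  # handled by binomial branch
        mu = s / (na + nb)
        mean = n * mu
        r = n / phi
        p = r / (r + mean)
        return (
            math.lgamma(total + r)
            - math.lgamma(r)
            - math.lgamma(total + 1)
            + r * math.log(p)
            + total * math.log(1 - p)
        )

    probs = []
    if phi == 0.0:
        p = na / (na + nb)
        for a in range(s + 1):
            probs.append(math.comb(s, a) * p**a * (1 - p) ** (s - a))
    else:
        logs = [log_pmf_sum(a, na) + log_pmf_sum(s - a, nb) for a in range(s + 1)]
        mx = max(logs)
        probs = [math.exp(v - mx) for v in logs]
    total = sum(probs)
    obs = probs[sa]
    acc = sum(pr for pr in probs if pr <= obs * (1 + 1e-12))
    return min(acc / total, 1.0)


def oracle_tmm(counts, trim_m=0.30, trim_a=0.05):
    """Straight-from-definition TMM, coded with explicit loops and sorting."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    q75 = [np.percentile(counts[:, j] / lib[j], 75) for j in range(counts.shape[1])]
    ref = int(np.argmin(np.abs(np.array(q75) - np.mean(q75))))

    logf = []
    for j in range(counts.shape[1]):
        if j == ref:
            logf.append(0.0)
            continue
        o, r = counts[:, j], counts[:, ref]
        keep = (o > 0) & (r > 0)
        o, r = o[keep], r[keep]
        m = np.log2((o / lib[j]) / (r / lib[ref]))
        a = 0.5 * np.log2((o / lib[j]) * (r / lib[ref]))
        w = (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
        if np.max(np.abs(m)) < 1e-6:
            logf.append(0.0)
            continue
        n = len(m)
        lo_m = int(np.floor(n * trim_m)) + 1
        hi_m = n + 1 - lo_m
        lo_a = int(np.floor(n * trim_a)) + 1
        hi_a = n + 1 - lo_a
        # average ranks for ties, the same convention the trimming rule uses
        order_m = scipy.stats.rankdata(m)
        order_a = scipy.stats.rankdata(a)
        keep2 = (
            (order_m >= lo_m) & (order_m <= hi_m) & (order_a >= lo_a) & (order_a <= hi_a)
        )
        logf.append(np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2]))
    f = 2.0 ** np.array(logf)
    return f / np.exp(np.mean(np.log(f)))


# ---------------------------------------------------------------------------
# exact test


class TestExactTest:
    def test_symmetric_split_gives_p_one(self):
        assert exact_test_gene([5, 5], [5, 5], 0.1) == pytest.approx(1.0)

    def test_binomial_limit_closed_form(self):
        # phi=0, 1 vs 1 sample, counts 0 and 4: Binomial(4, 1/2) tails
        assert exact_test_gene([0], [4], 0.0) == pytest.approx(0.125, abs=1e-12)

    def test_zero_total_returns_one(self):
        assert exact_test_gene([0, 0], [0, 0], 0.2) == 1.0

    def test_group_swap_invariance_equal_n(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 12, 3)
            b = rng.integers(0, 12, 3)
            phi = rng.choice([0.0, 0.1, 0.5])
            assert exact_test_gene(a, b, phi) == pytest.approx(
                exact_test_gene(b, a, phi), abs=1e-12
            )

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    def test_matches_enumeration_oracle(self, phi):
        rng = np.random.default_rng(1)
        for _ in range(60):
            na, nb = rng.integers(1, 5, 2)
            a = rng.integers(0, 50 // (na + nb) + 1, na)
            b = rng.integers(0, 50 // (na + nb) + 1, nb)
            if a.sum() + b.sum() > 50:
                continue
            got = exact_test_gene(a, b, phi)
            want = oracle_exact_test(list(a), list(b), phi)
            assert got == pytest.approx(want, abs=1e-10)


# ---------------------------------------------------------------------------
# BH


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    def test_matches_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.uniform(1e-12, 1.0, rng.integers(1, 40))
            q = bh_adjust(p)
            want = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(q, want, atol=1e-12)
            # monotone in sorted-p order and >= p at each rank
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-15)
            assert np.all(q >= p - 1e-15)
            assert np.all(q <= 1.0)


# ---------------------------------------------------------------------------
# normalization


class TestTMM:
    def test_identical_columns_all_factors_one(self):
        counts = np.tile(np.arange(1, 101)[:, None], (1, 4))
        np.testing.assert_allclose(tmm_factors(counts), 1.0)

    def test_pure_depth_difference_factors_one(self):
        base = np.arange(1, 201)
        counts = np.column_stack([base, 10 * base])
        np.testing.assert_allclose(tmm_factors(counts), 1.0)

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError, match="positive sum"):
            tmm_factors(np.array([[0, 1], [0, 2]]))

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(50, (500, 5))
        f = tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_composition_bias_matches_definition_oracle(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(100, (1000, 4))
        counts[:50, 0] *= 8  # 5% of genes 8-fold up in sample 0
        np.testing.assert_allclose(tmm_factors(counts), oracle_tmm(counts), atol=1e-8)


class TestEqualizeLibraries:
    def test_equal_effective_sizes_identity(self):
        cm = make_count_matrix(
            np.full((50, 2), 20), ["heme_deficient", "heme_excess"]
        )
        pseudo, common = equalize_libraries(cm, np.ones(2))
        assert common == pytest.approx(1000)
        np.testing.assert_array_equal(pseudo, cm.counts)

    def test_column_sums_near_common_size(self):
        rng = np.random.default_rng(11)
        counts = rng.poisson(rng.uniform(20, 120, 4), (400, 4))
        cm = make_count_matrix(counts, ["heme_deficient"] * 2 + ["heme_excess"] * 2)
        # unit factors: pure depth equalization, so column sums must land on
        # the common size up to per-cell rounding
        pseudo, common = equalize_libraries(cm, np.ones(4))
        assert np.all(np.abs(pseudo.sum(axis=0) - common) <= 0.5 * counts.shape[0])

    def test_unscaling_recovers_originals_within_half(self):
        rng = np.random.default_rng(13)
        counts = rng.poisson(60, (300, 3))
        cm = make_count_matrix(
            counts, ["heme_deficient", "heme_deficient", "heme_excess"]
        )
        f = tmm_factors(cm)
        pseudo, common = equalize_libraries(cm, f)
        eff = cm.library_sizes * f
        back = pseudo * (eff / common)
        assert np.all(np.abs(back - counts) <= 0.5 * np.maximum(eff / common, 1) + 1e-9)


class TestFilterExpressed:
    def test_all_zero_gene_removed(self):
        counts = np.array([[0, 0, 0], [5, 5, 5]])
        cm = make_count_matrix(counts, ["heme_deficient", "heme_excess", "heme_excess"])
        out = filter_expressed(cm, min_cpm=1, min_samples=1)
        assert out.gene_ids == ["g1"]

    def test_zero_threshold_identity(self, small_experiment):
        _, cm, _, _ = small_experiment
        out = filter_expressed(cm, min_cpm=0, min_samples=1)
        assert out.gene_ids == cm.gene_ids

    def test_matches_direct_cpm_oracle(self, small_experiment):
        _, cm, _, _ = small_experiment
        out = filter_expressed(cm, min_cpm=5, min_samples=3)
        c = cm.counts / cm.counts.sum(axis=0) * 1e6
        want = [g for g, row in zip(cm.gene_ids, c) if (row >= 5).sum() >= 3]
        assert out.gene_ids == want


# ---------------------------------------------------------------------------
# dispersion


def _simulate_two_group(n_genes, n_per_group, phi, seed, mean_low=20, mean_high=200):
    rng = np.random.default_rng(seed)
    mu = rng.uniform(mean_low, mean_high, n_genes)[:, None]
    counts = nb_draw(rng, np.tile(mu, (1, 2 * n_per_group)), phi)
    groups = [list(range(n_per_group)), list(range(n_per_group, 2 * n_per_group))]
    return counts, groups


class TestCommonDispersion:
    def test_identical_replicates_hit_lower_bound(self):
        pseudo = np.tile(np.arange(10, 60, 5)[:, None], (1, 6))
        est = estimate_common_dispersion(pseudo, [[0, 1, 2], [3, 4, 5]])
        assert est.dispersion < 1e-4

    def test_poisson_boundary_recovery(self):
        counts, groups = _simulate_two_group(1500, 4, 0.0, seed=21)
        est = estimate_common_dispersion(counts, groups)
        assert est.dispersion < 0.02

    def test_parameter_recovery(self):
        counts, groups = _simulate_two_group(2000, 4, 0.2, seed=23)
        est = estimate_common_dispersion(counts, groups)
        assert 0.17 <= est.dispersion <= 0.23

    def test_singleton_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            estimate_common_dispersion(np.ones((5, 2), dtype=int), [[0], [1]])

    def test_bias_shrinks_with_gene_count(self):
        errs = {}
        for n_genes in (500, 5000):
            ests = []
            for seed in range(3):
                counts, groups = _simulate_two_group(n_genes, 4, 0.15, seed=100 + seed)
                ests.append(estimate_common_dispersion(counts, groups).dispersion)
            errs[n_genes] = abs(np.mean(ests) - 0.15)
        assert errs[5000] < errs[500] + 0.01


# ---------------------------------------------------------------------------
# full DE driver


class TestRunDE:
    def test_contrast_swap_negates_log2fc(self, small_experiment):
        _, cm, _, _ = small_experiment
        fwd = run_de(cm, contrast=("heme_deficient", "heme_excess"))
        rev = run_de(cm, contrast=("heme_excess", "heme_deficient"))
        merged = fwd.table.merge(rev.table, on="gene_id")
        np.testing.assert_allclose(merged["logFC_x"], -merged["logFC_y"], atol=1e-12)

    def test_unknown_treatment_rejected(self, small_experiment):
        _, cm, _, _ = small_experiment
        with pytest.raises(ValueError, match="not present"):
            run_de(cm, contrast=("heme_deficient", "no_such_arm"))

    def test_null_simulation_calibration(self):
        """With no planted effects, raw p-values reject at ~alpha and BH
        adjustment brings discoveries to ~0."""
        cfg = SimConfig(n_genes=3000, effect_log2=0.0, dispersion=0.1, seed=31)
        matrices, _, _ = generate_experiment(cfg)
        cm = matrices[0]
        de = run_de(cm, contrast=("heme_deficient", "heme_excess"))
        m = len(de.table)
        for alpha in (0.01, 0.05):
            frac = (de.table["PValue"] < alpha).mean()
            bound = 2.58 * np.sqrt(alpha * (1 - alpha) / m)
            assert abs(frac - alpha) < bound + 0.005  # small slack for discreteness
        assert (de.table["FDR"] < 0.05).mean() < 0.01

    def test_planted_genes_detected(self, small_experiment):
        _, cm, _, truth = small_experiment
        de = run_de(cm, contrast=("heme_deficient", "heme_excess"))
        sig = set(de.significant(0.05)["gene_id"])
        imp = set(truth.genes_of_class("import"))
        exp = set(truth.genes_of_class("export"))
        # Delta=1 on each arm gives a 2-unit contrast; most planted genes hit
        assert len((imp | exp) & sig) / len(imp | exp) > 0.7
        # planted importers go down in excess (negative logFC)
        t = de.table.set_index("gene_id")
        signs = np.sign(t.loc[sorted(imp & sig), "logFC"])
        assert (signs < 0).mean() > 0.95
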