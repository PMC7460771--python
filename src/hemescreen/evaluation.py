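"""Self-contained evaluation studies: parameter recovery, power and
calibration of the screen's statistical machinery on synthetic data.

Each study generates its own data from a seed, runs the relevant pipeline
stage, and returns summary numbers.  Problem sizes are chosen to finish in
seconds on a laptop while leaving the conclusions stable across seeds:
dispersion recovery at 2,000 genes with 4 replicates per group, DE power
and cluster recovery over 10 simulation seeds, and enrichment calibration
over 10,000 replicate tests.
"""

from __future__ import annotations

import numpy as np

from .diffexpr import run_de, estimate_common_dispersion
from .simulate import SimConfig, generate_experiment, nb_draw
from .softcluster import assign_members, fuzzy_cmeans, profile_matrix
from .tm_enrichment import (
    EnrichmentResult,
    hypergeom_moments,
    resample_null,
    ztest_enrichment,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def dispersion_recovery_study(
    seed: int, true_phi: float = 0.2, n_genes: int = 2000, n_per_group: int = 4
) -> float:
    """Estimate the common NB dispersion from data simulated at a known one."""
    rng = np.random.default_rng(seed)
    mu = rng.uniform(20, 200, n_genes)[:, None]
    counts = nb_draw(rng, np.tile(mu, (1, 2 * n_per_group)), true_phi)
    groups = [list(range(n_per_group)), list(range(n_per_group, 2 * n_per_group))]
    return estimate_common_dispersion(counts, groups).dispersion


def de_power_study(
    seed: int,
    n_seeds: int = 10,
    n_genes: int = 2000,
    n_planted: int = 100,
    effect_log2: float = 1.0,
    dispersion: float = 0.1,
    reps: int = 3,
    alpha: float = 0.05,
) -> float:
    """Median fraction of planted responders detected at q < alpha.

    Planted importers/exporters carry +/-``effect_log2`` on each heme arm,
    i.e. a 2x``effect_log2``-unit contrast between heme excess and
    deficiency.
    """
    rates = []
    for s in _child_seeds(seed, n_seeds):
        cfg = SimConfig(
            n_genes=n_genes,
            n_import=n_planted // 2,
            n_export=n_planted - n_planted // 2,
            reps_per_group=reps,
            dispersion=dispersion,
            effect_log2=effect_log2,
            seed=s,
        )
        matrices, _, truth = generate_experiment(cfg)
        de = run_de(matrices[0], contrast=("heme_deficient", "heme_excess"))
        sig = set(de.significant(alpha)["gene_id"])
        planted = set(truth.genes_of_class("import")) | set(
            truth.genes_of_class("export")
        )
        tested = planted & set(de.table["gene_id"])
        rates.append(len(sig & tested) / len(tested))
    return float(np.median(rates))


def cluster_recovery_study(
    seed: int,
    n_seeds: int = 10,
    n_genes: int = 800,
    n_per_class: int = 50,
    dispersion: float = 0.1,
    fuzzifier: float = 1.5,
    n_clusters: int = 6,
    threshold: float = 0.5,
) -> float:
    """Median fraction of planted importers assigned (membership > threshold)
    to clusters labelled import_like."""
    rates = []
    for s in _child_seeds(seed, n_seeds):
        cfg = SimConfig(
            n_genes=n_genes,
            n_import=n_per_class,
            n_export=n_per_class,
            n_serum=n_per_class,
            dispersion=dispersion,
            effect_log2=1.0,
            seed=s,
        )
        matrices, _, truth = generate_experiment(cfg)
        prof = profile_matrix(matrices[0])
        model = fuzzy_cmeans(prof, c=n_clusters, m=fuzzifier, seed=s)
        table = assign_members(model, threshold=threshold)
        lab = dict(zip(table["gene_id"], table["pattern"]))
        imp = truth.genes_of_class("import")
        rates.append(sum(1 for g in imp if lab.get(g) == "import_like") / len(imp))
    return float(np.median(rates))


def _random_tm_universe(rng, g: int, tm_fraction: float) -> np.ndarray:
    return rng.random(g) < tm_fraction


def enrichment_calibration_study(
    seed: int,
    n_replicates: int = 10_000,
    universe_size: int = 2000,
    tm_fraction: float = 0.32,
    query_size: int = 150,
    n_draws: int = 30,
    alpha: float = 0.05,
) -> float:
    """Null rejection rate of the resampling z-test.

    Both the query and the null subsets are drawn from the same universe, so
    the rate should sit near alpha; with only 30 draws the normal
    approximation is thin and some miscalibration is expected.
    """
    rng = np.random.default_rng(seed)
    tm_flag = _random_tm_universe(rng, universe_size, tm_fraction)
    rejections = 0
    for _ in range(n_replicates):
        query_idx = rng.choice(universe_size, query_size, replace=False)
        observed = int(tm_flag[query_idx].sum())
        keys = rng.random((n_draws, universe_size))
        idx = np.argpartition(keys, query_size - 1, axis=1)[:, :query_size]
        draws = tm_flag[idx].sum(axis=1)
        mean = draws.mean()
        sd = draws.std(ddof=1)
        if sd == 0:
            continue
        z = (observed - mean) / sd
        from scipy.stats import norm

        if 2 * norm.sf(abs(z)) < alpha:
            rejections += 1
    return rejections / n_replicates


def enrichment_power_study(
    seed: int,
    n_seeds: int = 100,
    universe_size: int = 8000,
    tm_fraction: float = 0.32,
    query_tm_fraction: float = 0.45,
    query_size: int = 587,
    n_draws: int = 30,
) -> float:
    """Fraction of seeds where an enriched query (elevated TM share) yields
    p < 0.001 with a positive z."""
    hits = 0
    from .io_formats import GeneAnnotation
    import pandas as pd

    for s in _child_seeds(seed, n_seeds):
        # separate streams for the universe and the null draws
        s_universe, s_draws = _child_seeds(s, 2)
        rng = np.random.default_rng(s_universe)
        tm_flag = _random_tm_universe(rng, universe_size, tm_fraction)
        ann = GeneAnnotation(
            pd.DataFrame(
                {
                    "gene_id": [f"u{i}" for i in range(universe_size)],
                    "tm_count": tm_flag.astype(int),
                    "function_class": "other",
                    "is_mitochondrial": False,
                }
            )
        )
        n_tm = int(round(query_tm_fraction * query_size))
        observed = n_tm
        draws = resample_null(ann, n=query_size, n_draws=n_draws, seed=s_draws)
        res = ztest_enrichment(
            observed,
            draws,
            universe_size=universe_size,
            tm_in_universe=int(tm_flag.sum()),
            n=query_size,
        )
        if res.z > 0 and res.p_two_tailed < 0.001:
            hits += 1
    return hits / n_seeds


def published_enrichment_test(
    seed: int,
    observed: int = 251,
    n_deg: int = 587,
    universe_size: int = 8644,
    expected: float = 185.0,
    n_draws: int = 30,
) -> EnrichmentResult:
    """Replay the cultured-cell TM-enrichment comparison from its printed
    inputs: 251 of 587 differentially expressed genes carried >= 1 TM
    segment against an expectation of 185 among the 8,644 expressed genes.

    The genome background is reconstructed so that the expected TM count of
    a 587-gene draw equals the printed expectation (K = round(G*185/587)),
    then the resampling z-test is run exactly as in the screen.
    """
    import pandas as pd
    from .io_formats import GeneAnnotation

    k = int(round(universe_size * expected / n_deg))
    tm = np.zeros(universe_size, dtype=int)
    tm[:k] = 1
    ann = GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": [f"u{i}" for i in range(universe_size)],
                "tm_count": tm,
                "function_class": "other",
                "is_mitochondrial": False,
            }
        )
    )
    draws = resample_null(ann, n=n_deg, n_draws=n_draws, seed=seed)
    return ztest_enrichment(
        observed, draws, universe_size=universe_size, tm_in_universe=k, n=n_deg
    )


def resampling_moment_check(
    seed: int,
    universe_size: int = 800,
    tm_fraction: float = 0.32,
    query_size: int = 150,
    n_draws: int = 10_000,
) -> dict:
    """Empirical vs hypergeometric moments of the resampled null, with the
    standard errors needed to judge agreement."""
    import pandas as pd
    from .io_formats import GeneAnnotation

    rng = np.random.default_rng(seed)
    tm_flag = _random_tm_universe(rng, universe_size, tm_fraction)
    ann = GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": [f"u{i}" for i in range(universe_size)],
                "tm_count": tm_flag.astype(int),
                "function_class": "other",
                "is_mitochondrial": False,
            }
        )
    )
    k = int(tm_flag.sum())
    draws = resample_null(ann, n=query_size, n_draws=n_draws, seed=seed + 1)
    mean, var = hypergeom_moments(universe_size, k, query_size)
    m4 = float(np.mean((draws - draws.mean()) ** 4))
    return {
        "empirical_mean": float(draws.mean()),
        "empirical_var": float(draws.var(ddof=1)),
        "hypergeom_mean": mean,
        "hypergeom_var": var,
        "se_mean": float(np.sqrt(var / n_draws)),
        "se_var": float(np.sqrt(max(m4 - var**2, 0.0) / n_draws)),
    }
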