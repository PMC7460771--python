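"""Transmembrane-domain enrichment of a gene set against a resampled null.

The question: do differentially expressed genes carry membrane-spanning
segments more often than a random draw of the same size from the genome?
The null is built exactly the way the screen does it — ``n_draws`` random
subsets of the universe, each of the query's size, counting TM genes in
each — followed by a two-tailed z-test of the observed count against the
draw mean and sample standard deviation.

Because each draw samples without replacement, the draw counts are exactly
hypergeometric; the closed-form hypergeometric mean and variance are
reported alongside every test as an analytic cross-check on the thin
(default 30-draw) resampled null.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .io_formats import GeneAnnotation

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    observed: int
    n: int
    n_draws: int
    mean: float
    sd: float
    z: float
    p_two_tailed: float
    universe_size: int
    tm_in_universe: int
    hypergeom_mean: float
    hypergeom_var: float
    degenerate_sd: bool = False
    seed: int | None = None

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)


def count_tm_genes(
    gene_set: Iterable[str], annotation: GeneAnnotation, min_tm: int = 1
) -> int:
    """Number of set members with at least ``min_tm`` TM segments."""
    if min_tm < 1:
        raise ValueError("min_tm must be >= 1")
    return int(sum(annotation.tm_count(g) >= min_tm for g in gene_set))


def resample_null(
    universe: GeneAnnotation | Sequence[str],
    n: int,
    n_draws: int = 30,
    seed: int | None = None,
    min_tm: int = 1,
    annotation: GeneAnnotation | None = None,
) -> np.ndarray:
    """TM-gene counts in ``n_draws`` random size-``n`` subsets of the universe.

    Each draw samples genes without replacement; draws are mutually
    independent and reproducible from the seed.
    """
    if isinstance(universe, GeneAnnotation):
        ann = universe
        genes = ann.gene_ids
    else:
        genes = list(universe)
        ann = annotation
        if ann is None:
            raise ValueError("annotation required when universe is a gene list")
    g = len(genes)
    if n > g:
        raise ValueError(f"subset size {n} exceeds universe size {g}")
    if n_draws < 2:
        raise ValueError("need at least 2 draws")
    tm_flag = np.array([ann.tm_count(gid) >= min_tm for gid in genes])

    rng = np.random.default_rng(seed)
    # n smallest of iid uniform keys per row = a uniform size-n subset
    draws = np.empty(n_draws, dtype=np.int64)
    block = max(1, min(n_draws, int(2e7) // max(g, 1)))
    done = 0
    while done < n_draws:
        k = min(block, n_draws - done)
        keys = rng.random((k, g))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        draws[done : done + k] = tm_flag[idx].sum(axis=1)
        done += k
    return draws


def hypergeom_moments(g: int, k: int, n: int) -> tuple[float, float]:
    """Mean and variance of the TM count in a size-``n`` draw without
    replacement from ``g`` genes of which ``k`` are TM genes."""
    if not (0 <= k <= g) or not (0 <= n <= g):
        raise ValueError("require 0 <= K <= G and 0 <= n <= G")
    if n == 0 or g == 0:
        return 0.0, 0.0
    frac = k / g
    mean = n * frac
    if g == 1:
        return mean, 0.0
    var = n * frac * (1 - frac) * (g - n) / (g - 1)
    return mean, var


def ztest_enrichment(
    observed: int,
    draws: np.ndarray,
    universe_size: int,
    tm_in_universe: int,
    n: int,
    seed: int | None = None,
) -> EnrichmentResult:
    """Two-tailed z-test of the observed TM count against the resampled null.

    Uses the sample standard deviation (n-1 denominator).  A degenerate
    null (sd = 0) yields p = 1 when the observation matches the mean and
    p = 0 otherwise, with a warning flag set.
    """
    draws = np.asarray(draws)
    if draws.size < 2:
        raise ValueError("need at least 2 draws")
    mean = float(draws.mean())
    sd = float(draws.std(ddof=1))
    h_mean, h_var = hypergeom_moments(universe_size, tm_in_universe, n)
    degenerate = sd == 0.0
    if degenerate:
        logger.warning("degenerate resampled null (sd = 0)")
        z = 0.0 if observed == mean else np.inf * np.sign(observed - mean)
        p = 1.0 if observed == mean else 0.0
    else:
        z = (observed - mean) / sd
        p = float(2.0 * norm.sf(abs(z)))
    return EnrichmentResult(
        observed=int(observed),
        n=int(n),
        n_draws=int(draws.size),
        mean=mean,
        sd=sd,
        z=float(z),
        p_two_tailed=p,
        universe_size=int(universe_size),
        tm_in_universe=int(tm_in_universe),
        hypergeom_mean=h_mean,
        hypergeom_var=h_var,
        degenerate_sd=degenerate,
        seed=seed,
    )


def enrich_gene_set(
    gene_set: Iterable[str],
    universe: GeneAnnotation,
    n_draws: int = 30,
    seed: int | None = None,
    min_tm: int = 1,
) -> EnrichmentResult:
    """End-to-end enrichment test of a gene set against an annotation universe."""
    genes = list(gene_set)
    observed = count_tm_genes(genes, universe, min_tm=min_tm)
    draws = resample_null(universe, n=len(genes), n_draws=n_draws, seed=seed, min_tm=min_tm)
    k = count_tm_genes(universe.gene_ids, universe, min_tm=min_tm)
    return ztest_enrichment(
        observed,
        draws,
        universe_size=len(universe.gene_ids),
        tm_in_universe=k,
        n=len(genes),
        seed=seed,
    )
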