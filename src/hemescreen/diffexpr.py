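"""Two-group differential expression for negative-binomial counts.

The model is the classic exact-test workflow for small-replicate RNA-seq:

1. filter weakly expressed genes on a CPM threshold;
2. TMM normalization (trimmed, precision-weighted mean of per-gene log
   ratios against a reference sample) to correct composition bias;
3. equalization of effective library sizes so group sums are comparable;
4. a single common NB dispersion, estimated by maximizing the conditional
   log-likelihood given per-group totals (quantile-free, closed-form
   likelihood in the equal-library-size case);
5. a conditional exact test per gene: given the total count ``s`` of the two
   group sums, sum the probabilities of all splits no more likely than the
   observed one;
6. Benjamini-Hochberg step-up adjustment.

The project-wide contrast convention is *second group over first*; the
screen always calls it with (heme_deficient, heme_excess), so a negative
log2FC means "down in heme excess" — the import-consistent sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

from .io_formats import CountMatrix

_TIE_REL_TOL = 1e-12  # relative slack on the exact-test inequality


@dataclass
class DispersionEstimate:
    """Common NB dispersion and the conditional log-likelihood at optimum."""

    dispersion: float
    log_likelihood: float


@dataclass
class DETable:
    """Per-gene differential-expression results for a named contrast."""

    table: pd.DataFrame  # gene_id, logFC, logCPM, PValue, FDR
    contrast: tuple[str, str]
    dispersion: float

    def significant(self, alpha: float) -> pd.DataFrame:
        return self.table.loc[self.table["FDR"] < alpha].reset_index(drop=True)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                f"# contrast: {self.contrast[1]} over {self.contrast[0]}; "
                f"common dispersion {self.dispersion:.6g}\n"
            )
            self.table.to_csv(fh, sep="\t", index=False)


def cpm(counts: np.ndarray, lib_sizes: np.ndarray | None = None) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    return counts / lib_sizes * 1e6


def filter_expressed(
    cm: CountMatrix, min_cpm: float = 1.0, min_samples: int = 1
) -> CountMatrix:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_samples`` samples."""
    if min_cpm < 0:
        raise ValueError("min_cpm must be >= 0")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if min_cpm == 0:
        return cm
    ok = (cpm(cm.counts) >= min_cpm).sum(axis=1) >= min_samples
    return cm.subset_genes(np.flatnonzero(ok))


# ---------------------------------------------------------------------------
# TMM


def tmm_factors(
    cm: CountMatrix | np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    lib_sizes: np.ndarray | None = None,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The factor carries only composition bias; sequencing depth stays in the
    library size.  The reference sample is the one whose 75th CPM percentile
    is closest to the across-sample mean of that percentile.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else np.asarray(cm)
    counts = counts.astype(float)
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    if np.any(lib_sizes <= 0):
        raise ValueError("every column must have a positive sum")

    q75 = np.array(
        [np.percentile(counts[:, j] / lib_sizes[j], 75) for j in range(counts.shape[1])]
    )
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        log_factors[j] = _tmm_pair(
            counts[:, j], counts[:, ref], lib_sizes[j], lib_sizes[ref], trim_m, trim_a
        )
    factors = 2.0**log_factors
    return factors / np.exp(np.mean(np.log(factors)))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """log2 TMM factor of ``obs`` against ``ref``."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic delta-method variance of M
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    if np.max(np.abs(m)) < 1e-6:  # columns proportional: no composition bias
        return 0.0

    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def equalize_libraries(
    cm: CountMatrix, factors: np.ndarray
) -> tuple[np.ndarray, float]:
    """Scale counts to a common effective library size.

    Returns the integer pseudo-count matrix (round half to even) and the
    common size: the geometric mean of effective library sizes
    (library size x TMM factor).
    """
    lib = cm.library_sizes.astype(float)
    eff = lib * np.asarray(factors, dtype=float)
    common = float(np.exp(np.mean(np.log(eff))))
    pseudo = np.rint(cm.counts * (common / eff)).astype(np.int64)
    return pseudo, common


# ---------------------------------------------------------------------------
# dispersion


def _conditional_loglik(pseudo: np.ndarray, group_slices: list[np.ndarray], phi: float) -> float:
    """Summed per-gene, per-group NB conditional log-likelihood at dispersion phi."""
    r = 1.0 / phi
    total = 0.0
    for cols in group_slices:
        y = pseudo[:, cols]
        n = y.shape[1]
        z = y.sum(axis=1)
        ll = (
            gammaln(y + r).sum(axis=1)
            - n * gammaln(r)
            + gammaln(n * r)
            - gammaln(z + n * r)
        )
        total += float(ll.sum())
    return total


def estimate_common_dispersion(
    pseudo: np.ndarray, groups: list[np.ndarray] | list[list[int]]
) -> DispersionEstimate:
    """Conditional-ML common dispersion given per-group totals.

    Maximizes over delta = phi/(1+phi) in [1e-6, 0.999].  Groups with a
    single sample carry no conditional information and are ignored.
    """
    slices = [np.asarray(g) for g in groups if len(g) >= 2]
    if not slices:
        raise ValueError("dispersion estimation needs a group with >= 2 samples")
    pseudo = np.asarray(pseudo)

    def neg_ll(delta: float) -> float:
        phi = delta / (1.0 - delta)
        return -_conditional_loglik(pseudo, slices, phi)

    res = minimize_scalar(
        neg_ll, bounds=(1e-6, 0.999), method="bounded", options={"xatol": 1e-8}
    )
    delta = float(res.x)
    phi = delta / (1.0 - delta)
    return DispersionEstimate(dispersion=phi, log_likelihood=-float(res.fun))


# ---------------------------------------------------------------------------
# exact test


def _nb_sum_logpmf(a: np.ndarray, n: int, mu_per_sample: float, phi: float) -> np.ndarray:
    """log pmf of the sum of ``n`` iid NB(mu, phi) counts, evaluated at ``a``.

    The sum is NB with mean ``n*mu`` and dispersion ``phi/n``, i.e. size
    r = n/phi.
    """
    mean = n * mu_per_sample
    r = n / phi
    p = r / (r + mean)
    return (
        gammaln(a + r) - gammaln(r) - gammaln(a + 1) + r * np.log(p) + a * np.log1p(-p)
    )


def exact_test_gene(
    counts_a: np.ndarray | list[int],
    counts_b: np.ndarray | list[int],
    phi: float,
) -> float:
    """Conditional exact test for a difference between two NB group sums.

    Conditions on ``s = sum(A) + sum(B)`` and accumulates the probability of
    every split at most as likely as the observed one (with a tiny relative
    tie tolerance so float ordering is reproducible).  ``phi = 0`` is the
    Poisson limit, where the conditional law is binomial.
    """
    a_obs = int(np.sum(counts_a))
    b_obs = int(np.sum(counts_b))
    n_a, n_b = len(counts_a), len(counts_b)
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    s = a_obs + b_obs
    if s == 0:
        return 1.0

    a = np.arange(s + 1)
    if phi == 0.0:
        # Poisson limit: SA | s ~ Binomial(s, nA/(nA+nB))
        p = n_a / (n_a + n_b)
        log_joint = (
            gammaln(s + 1)
            - gammaln(a + 1)
            - gammaln(s - a + 1)
            + a * np.log(p)
            + (s - a) * np.log1p(-p)
        )
    else:
        mu = s / (n_a + n_b)
        log_joint = _nb_sum_logpmf(a, n_a, mu, phi) + _nb_sum_logpmf(
            s - a, n_b, mu, phi
        )

    log_obs = log_joint[a_obs]
    mask = log_joint <= log_obs + np.log1p(_TIE_REL_TOL)
    p_value = float(np.exp(logsumexp(log_joint[mask]) - logsumexp(log_joint)))
    return min(p_value, 1.0)


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, in input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# driver


def run_de(
    cm: CountMatrix,
    dataset: str | None = None,
    contrast: tuple[str, str] = ("heme_deficient", "heme_excess"),
    alpha: float = 0.0001,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
    log2fc_offset: float = 0.5,
) -> DETable:
    """Full exact-test DE for one two-group contrast within one dataset.

    log2FC is second group over first on normalized (pseudo-count) group
    means with a +``log2fc_offset`` stabilizer.
    """
    if dataset is not None:
        cm = cm.dataset(dataset)
    group_a, group_b = contrast
    treatments = {s.treatment for s in cm.samples}
    for g in (group_a, group_b):
        if g not in treatments:
            raise ValueError(f"treatment {g!r} not present in dataset")
    keep = [
        i for i, s in enumerate(cm.samples) if s.treatment in (group_a, group_b)
    ]
    cm = cm.subset_samples(keep)

    idx_a = [i for i, s in enumerate(cm.samples) if s.treatment == group_a]
    idx_b = [i for i, s in enumerate(cm.samples) if s.treatment == group_b]
    if min_samples is None:
        min_samples = min(len(idx_a), len(idx_b))
    cm = filter_expressed(cm, min_cpm=min_cpm, min_samples=min_samples)

    factors = tmm_factors(cm)
    pseudo, common = equalize_libraries(cm, factors)
    disp = estimate_common_dispersion(pseudo, [idx_a, idx_b])

    ya, yb = pseudo[:, idx_a], pseudo[:, idx_b]
    p_values = np.array(
        [
            exact_test_gene(ya[g], yb[g], disp.dispersion)
            for g in range(pseudo.shape[0])
        ]
    )
    q_values = bh_adjust(p_values)

    mean_a = ya.mean(axis=1)
    mean_b = yb.mean(axis=1)
    log2fc = np.log2(mean_b + log2fc_offset) - np.log2(mean_a + log2fc_offset)
    log_cpm = np.log2((pseudo.mean(axis=1) + 0.5) / common * 1e6)

    table = pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "logFC": log2fc,
            "logCPM": log_cpm,
            "PValue": p_values,
            "FDR": q_values,
        }
    )
    return DETable(table=table, contrast=contrast, dispersion=disp.dispersion)
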