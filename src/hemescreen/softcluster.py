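"""Soft clustering of per-gene treatment expression profiles.

Each gene's profile is its replicate-averaged log2 CPM per treatment,
z-standardized across treatments, so clustering sees only the *shape* of
the response.  Fuzzy c-means then yields graded cluster memberships, and
each cluster centroid is classified by shape:

* ``import_like``   — maximal under heme deficiency and minimal under heme
  excess, the signature expected of a transcriptionally regulated importer;
* ``export_like``   — the mirrored shape;
* ``serum_response``— driven by serum presence rather than heme (the normal
  growth medium is the only serum-containing condition);
* ``other``         — anything else, including flat or tied centroids.

Only genes whose top membership exceeds a threshold (default 0.5) are
assigned to a cluster.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CountMatrix
from .diffexpr import cpm

logger = logging.getLogger(__name__)

PATTERNS = ("import_like", "export_like", "serum_response", "other")


@dataclass
class ProfileMatrix:
    """Standardized per-gene treatment profiles (rows: mean 0, sd 1)."""

    gene_ids: list[str]
    profiles: np.ndarray  # (n_genes, n_treatments)
    treatments: list[str]
    dropped: list[str] = field(default_factory=list)  # constant-profile genes


@dataclass
class ClusterModel:
    centroids: np.ndarray  # (c, n_treatments)
    memberships: np.ndarray  # (n_genes, c), rows sum to 1
    fuzzifier: float
    objective: float
    treatments: list[str]
    gene_ids: list[str]
    seed: int | None = None

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def pattern_labels(self) -> list[str]:
        return [
            classify_cluster_pattern(c, self.treatments) for c in self.centroids
        ]


def profile_matrix(cm: CountMatrix, dataset: str | None = None) -> ProfileMatrix:
    """Replicate-averaged log2 CPM per treatment, z-standardized per gene."""
    if dataset is not None:
        cm = cm.dataset(dataset)
    treatments: list[str] = []
    for s in cm.samples:
        if s.treatment not in treatments:
            treatments.append(s.treatment)
    if len(treatments) < 2:
        raise ValueError("profiles need at least two treatments")

    log_cpm = np.log2(cpm(cm.counts) + 0.5)
    means = np.column_stack(
        [
            log_cpm[:, [i for i, s in enumerate(cm.samples) if s.treatment == t]].mean(
                axis=1
            )
            for t in treatments
        ]
    )
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] < 1e-12
    if constant.any():
        dropped = [g for g, c in zip(cm.gene_ids, constant) if c]
        logger.info("dropping %d constant-profile gene(s)", len(dropped))
    else:
        dropped = []
    keep = ~constant
    z = (means[keep] - mu[keep]) / sd[keep]
    return ProfileMatrix(
        gene_ids=[g for g, k in zip(cm.gene_ids, keep) if k],
        profiles=z,
        treatments=treatments,
        dropped=dropped,
    )


def estimate_fuzzifier(n_genes: int, n_dims: int) -> float:
    """Data-size-adapted fuzzifier for expression profiles.

    Uses the minimum-hypersphere heuristic of Schwammle & Jensen (2010) —
    the estimator behind the standard soft-clustering tooling for expression
    profiles: m shrinks toward 1 as dimensionality and gene count grow, so
    that random (structureless) data cannot produce compact clusters.
    """
    if n_genes < 2 or n_dims < 2:
        raise ValueError("need at least 2 genes and 2 dimensions")
    n, d = float(n_genes), float(n_dims)
    return 1.0 + (1418.0 / n + 22.05) * d**-2.0 + (12.33 / n + 0.243) * d ** (
        -0.0406 * math.log(n) - 0.1134
    )


def _fcm_memberships(x: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    """Membership update u_ik = 1 / sum_j (d_ik/d_ij)^(2/(m-1)).

    A profile coincident with a centroid gets membership 1 there (limit
    convention), split equally if coincident with several.
    """
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    zero = d2 <= 1e-300
    u = np.zeros_like(d2)
    any_zero = zero.any(axis=1)
    if any_zero.any():
        z = zero[any_zero]
        u[any_zero] = z / z.sum(axis=1, keepdims=True)
    rest = ~any_zero
    if rest.any():
        # scale by the per-row minimum distance so the powers stay in [0, 1]
        # even for fuzzifiers very close to 1
        d2r = d2[rest]
        ratio = d2r / d2r.min(axis=1, keepdims=True)
        inv = ratio ** (-1.0 / (m - 1.0))
        u[rest] = inv / inv.sum(axis=1, keepdims=True)
    return u


def _fcm_objective(x: np.ndarray, centroids: np.ndarray, u: np.ndarray, m: float) -> float:
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return float((u**m * d2).sum())


def fuzzy_cmeans(
    profiles: ProfileMatrix | np.ndarray,
    c: int,
    m: float,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int | None = 0,
    n_restarts: int = 5,
) -> ClusterModel:
    """Fuzzy c-means by alternating membership/centroid updates.

    Runs ``n_restarts`` random initializations and keeps the solution with
    the lowest objective sum(u^m d^2).
    """
    if isinstance(profiles, ProfileMatrix):
        x = profiles.profiles
        gene_ids = profiles.gene_ids
        treatments = profiles.treatments
    else:
        x = np.asarray(profiles, dtype=float)
        gene_ids = [f"g{i}" for i in range(x.shape[0])]
        treatments = [f"dim{i}" for i in range(x.shape[1])]
    if c < 1:
        raise ValueError("c must be >= 1")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if c == 1:
        centroid = x.mean(axis=0, keepdims=True)
        u = np.ones((x.shape[0], 1))
        return ClusterModel(
            centroids=centroid,
            memberships=u,
            fuzzifier=m,
            objective=_fcm_objective(x, centroid, u, m),
            treatments=treatments,
            gene_ids=gene_ids,
            seed=seed,
        )

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_restarts):
        # initialize centroids at distinct data points
        init = rng.choice(x.shape[0], size=min(c, x.shape[0]), replace=False)
        centroids = x[init].copy()
        if centroids.shape[0] < c:  # fewer points than clusters: jitter extras
            extra = centroids[
                rng.integers(0, centroids.shape[0], c - centroids.shape[0])
            ] + rng.normal(0, 1e-3, (c - centroids.shape[0], x.shape[1]))
            centroids = np.vstack([centroids, extra])
        u = _fcm_memberships(x, centroids, m)
        prev_obj = np.inf
        for _it in range(max_iter):
            um = u**m
            centroids = (um.T @ x) / um.sum(axis=0)[:, None]
            u_new = _fcm_memberships(x, centroids, m)
            obj = _fcm_objective(x, centroids, u_new, m)
            # objective is non-increasing for alternating FCM updates
            assert obj <= prev_obj * (1 + 1e-9) + 1e-12
            delta = np.max(np.abs(u_new - u))
            u = u_new
            prev_obj = obj
            if delta < tol:
                break
        if best is None or prev_obj < best[0]:
            best = (prev_obj, centroids.copy(), u.copy())

    obj, centroids, u = best
    return ClusterModel(
        centroids=centroids,
        memberships=u,
        fuzzifier=m,
        objective=obj,
        treatments=treatments,
        gene_ids=gene_ids,
        seed=seed,
    )


def select_cluster_count(
    profiles: ProfileMatrix,
    c_range: range | list[int],
    seed: int | None = 0,
    m: float | None = None,
    min_centroid_distance: float = 0.5,
    **fcm_kwargs,
) -> int:
    """Largest cluster count before centroids start duplicating.

    Clusters the profiles for each c in ``c_range`` and returns the largest
    c whose minimum pairwise centroid distance stays above
    ``min_centroid_distance`` (in standardized-profile units).
    """
    cs = sorted(set(int(c) for c in c_range))
    if not cs:
        raise ValueError("empty cluster-count range")
    if any(c < 2 or c > len(profiles.gene_ids) - 1 for c in cs):
        raise ValueError("cluster counts must lie in [2, n_genes - 1]")
    if m is None:
        m = estimate_fuzzifier(len(profiles.gene_ids), len(profiles.treatments))
    selected = cs[0]
    for c in cs:
        model = fuzzy_cmeans(profiles, c=c, m=m, seed=seed, **fcm_kwargs)
        dists = [
            float(np.linalg.norm(model.centroids[i] - model.centroids[j]))
            for i in range(c)
            for j in range(i + 1, c)
        ]
        if min(dists) > min_centroid_distance:
            selected = c
    return selected


def assign_members(model: ClusterModel, threshold: float = 0.5) -> pd.DataFrame:
    """Assign genes to their argmax cluster when membership strictly exceeds
    ``threshold``.

    Returns a table (gene_id, cluster, membership, pattern).
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    labels = model.pattern_labels()
    top = model.memberships.argmax(axis=1)
    top_u = model.memberships[np.arange(len(top)), top]
    keep = top_u > threshold
    return pd.DataFrame(
        {
            "gene_id": [g for g, k in zip(model.gene_ids, keep) if k],
            "cluster": top[keep],
            "membership": top_u[keep],
            "pattern": [labels[c] for c in top[keep]],
        }
    )


def classify_cluster_pattern(centroid: np.ndarray, treatment_order: list[str]) -> str:
    """Classify a centroid shape over the treatment axis.

    Three-group design (normal_serum, heme_deficient, heme_excess):
    import_like iff the heme-deficient coordinate is the strict maximum and
    heme-excess the strict minimum; export_like iff reversed; serum_response
    iff normal_serum is the strict extremum with both serum-free coordinates
    on the same side; otherwise other.  Two-group heme designs compare the
    heme coordinate against the normal one.  Ties are conservative: other.
    """
    centroid = np.asarray(centroid, dtype=float)
    known = {"normal_serum", "heme_deficient", "heme_excess"}
    unknown = set(treatment_order) - known
    if unknown:
        raise ValueError(f"unknown treatment label(s): {sorted(unknown)}")
    coord = dict(zip(treatment_order, centroid))

    if "heme_deficient" in coord and "heme_excess" in coord and "normal_serum" in coord:
        ns, hd, he = coord["normal_serum"], coord["heme_deficient"], coord["heme_excess"]
        if hd > max(ns, he) and he < min(ns, hd):
            return "import_like"
        if he > max(ns, hd) and hd < min(ns, he):
            return "export_like"
        if ns > max(hd, he) or ns < min(hd, he):
            # strict serum extremum; both serum-free coordinates sit on the
            # same (opposite) side by construction
            return "serum_response"
        return "other"

    # two-group design: one heme treatment against the serum-free or normal
    # baseline; "heme" is whichever of the heme arms is present
    heme_label = (
        "heme_excess" if "heme_excess" in coord else "heme_deficient"
    )
    base_label = next(t for t in treatment_order if t != heme_label)
    if heme_label not in coord or len(treatment_order) != 2:
        return "other"
    heme, base = coord[heme_label], coord[base_label]
    if heme < base:
        return "import_like"
    if heme > base:
        return "export_like"
    return "other"
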