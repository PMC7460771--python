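"""Candidate heme-transporter prioritization and cross-dataset set logic.

The contrast convention is pinned project-wide as heme_excess over
heme_deficient, so a *negative* log2FC (down in heme excess) is the
import-consistent direction and a positive one export-consistent.

The midgut filter chain mirrors the screen: significance at q < alpha,
>= 2 predicted TM segments (the multipass-transporter proxy), exclusion of
mitochondrially encoded genes, and a function-class whitelist standing in
for the manual curation that removed enzymes and ROS-response genes.  The
cultured-cell filter additionally requires a concordant soft-cluster
pattern (strict mode) or reports the DE/cluster union.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import DETable
from .io_formats import GeneAnnotation

CONTRAST_NOTE = "log2FC is heme_excess over heme_deficient"

DEFAULT_ALLOWED_FUNCTIONS = frozenset({"transport", "unknown"})


@dataclass
class CandidateTable:
    """Prioritized candidates with direction labels and filter provenance."""

    table: pd.DataFrame
    # columns: gene_id, direction, log2fc, q_value, tm_count,
    #          pass_tm, pass_fold, pass_function, pass_mito, pass_cluster

    def __len__(self) -> int:
        return len(self.table)

    @property
    def import_like(self) -> pd.DataFrame:
        return self.table.loc[self.table["direction"] == "import_like"]

    @property
    def export_like(self) -> pd.DataFrame:
        return self.table.loc[self.table["direction"] == "export_like"]

    def gene_set(self, direction: str | None = None) -> set[str]:
        t = self.table
        if direction is not None:
            t = t.loc[t["direction"] == direction]
        return set(t["gene_id"])

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# {CONTRAST_NOTE}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def direction_label(log2fc: float) -> str:
    """import_like for negative log2FC, export_like for positive.

    Zero fold change is refused: a gene with no change should never survive
    the significance filter, so reaching here with 0 indicates a bug.
    """
    if log2fc < 0:
        return "import_like"
    if log2fc > 0:
        return "export_like"
    raise ValueError("log2FC of exactly 0 has no direction")


def filter_midgut_candidates(
    de: DETable | pd.DataFrame,
    annotation: GeneAnnotation,
    alpha: float = 0.05,
    min_tm: int = 2,
    allowed_functions: frozenset[str] | set[str] = DEFAULT_ALLOWED_FUNCTIONS,
    exclude_mito: bool = True,
) -> CandidateTable:
    """The midgut prioritization chain: q < alpha, >= ``min_tm`` TM segments,
    transport-plausible function class, non-mitochondrial."""
    table = de.table if isinstance(de, DETable) else de
    gene_col = "gene_id"
    fc_col = "logFC" if "logFC" in table.columns else "log2fc"
    q_col = "FDR" if "FDR" in table.columns else "q_value"

    rows = []
    for row in table.itertuples(index=False):
        d = row._asdict()
        gene = d[gene_col]
        q = float(d[q_col])
        fc = float(d[fc_col])
        tm = annotation.tm_count(gene)
        ok_q = q < alpha
        ok_tm = tm >= min_tm
        ok_func = annotation.function_class(gene) in allowed_functions
        ok_mito = not (exclude_mito and annotation.is_mitochondrial(gene))
        if ok_q and ok_tm and ok_func and ok_mito:
            rows.append(
                {
                    "gene_id": gene,
                    "direction": direction_label(fc),
                    "log2fc": fc,
                    "q_value": q,
                    "tm_count": tm,
                    "pass_tm": True,
                    "pass_fold": True,  # no fold filter at this stage
                    "pass_function": True,
                    "pass_mito": True,
                    "pass_cluster": pd.NA,
                }
            )
    cols = [
        "gene_id",
        "direction",
        "log2fc",
        "q_value",
        "tm_count",
        "pass_tm",
        "pass_fold",
        "pass_function",
        "pass_mito",
        "pass_cluster",
    ]
    return CandidateTable(pd.DataFrame(rows, columns=cols))


def highly_regulated(
    candidates: CandidateTable, min_abs_log2fc: float = 1.0
) -> CandidateTable:
    """Subset with at least a 2^``min_abs_log2fc``-fold change (inclusive)."""
    t = candidates.table
    keep = t["log2fc"].abs() >= min_abs_log2fc
    return CandidateTable(t.loc[keep].reset_index(drop=True))


def filter_cell_candidates(
    de: DETable,
    cluster_assignments: pd.DataFrame,
    annotation: GeneAnnotation,
    alpha: float = 0.0001,
    min_tm: int = 2,
    min_abs_log2fc: float = 1.0,
    mode: str = "strict",
) -> CandidateTable:
    """Cultured-cell candidates combining DE, fold, TM and cluster evidence.

    strict mode: DE-significant with |log2FC| >= threshold, >= ``min_tm`` TM
    segments, AND assigned to a cluster whose pattern matches the DE
    direction.  union mode: DE evidence (fold+TM filtered) OR a matching
    import/export-like cluster assignment for a >= ``min_tm``-TM gene.
    """
    if mode not in ("strict", "union"):
        raise ValueError("mode must be 'strict' or 'union'")
    det = de.table
    cluster_pattern = dict(
        zip(cluster_assignments.get("gene_id", []), cluster_assignments.get("pattern", []))
    )
    fc_by_gene = dict(zip(det["gene_id"], det["logFC"]))
    q_by_gene = dict(zip(det["gene_id"], det["FDR"]))

    rows = []
    seen = set()
    for gene, fc, q in zip(det["gene_id"], det["logFC"], det["FDR"]):
        tm = annotation.tm_count(gene)
        de_ok = q < alpha and abs(fc) >= min_abs_log2fc and tm >= min_tm
        if not de_ok:
            continue
        direction = direction_label(fc)
        in_matching_cluster = cluster_pattern.get(gene) == direction
        if mode == "strict" and not in_matching_cluster:
            continue
        rows.append(
            {
                "gene_id": gene,
                "direction": direction,
                "log2fc": fc,
                "q_value": q,
                "tm_count": tm,
                "pass_tm": True,
                "pass_fold": True,
                "pass_function": pd.NA,
                "pass_mito": pd.NA,
                "pass_cluster": bool(in_matching_cluster),
            }
        )
        seen.add(gene)

    if mode == "union":
        for gene, pattern in cluster_pattern.items():
            if gene in seen or pattern not in ("import_like", "export_like"):
                continue
            if annotation.tm_count(gene) < min_tm:
                continue
            fc = float(fc_by_gene.get(gene, np.nan))
            rows.append(
                {
                    "gene_id": gene,
                    "direction": pattern,
                    "log2fc": fc,
                    "q_value": float(q_by_gene.get(gene, np.nan)),
                    "tm_count": annotation.tm_count(gene),
                    "pass_tm": True,
                    "pass_fold": False,
                    "pass_function": pd.NA,
                    "pass_mito": pd.NA,
                    "pass_cluster": True,
                }
            )
    cols = [
        "gene_id",
        "direction",
        "log2fc",
        "q_value",
        "tm_count",
        "pass_tm",
        "pass_fold",
        "pass_function",
        "pass_mito",
        "pass_cluster",
    ]
    return CandidateTable(pd.DataFrame(rows, columns=cols))


def cross_dataset_tally(
    candidate_sets: list[set[str]],
) -> tuple[dict[int, int], dict[str, int]]:
    """Per-gene dataset-overlap degree and its histogram.

    ``degree`` = number of datasets whose candidate set contains the gene;
    the histogram covers degrees 1..len(candidate_sets).
    """
    if not 1 <= len(candidate_sets) <= 4:
        raise ValueError("expected between 1 and 4 candidate sets")
    degree: dict[str, int] = {}
    for s in candidate_sets:
        for gene in s:
            degree[gene] = degree.get(gene, 0) + 1
    histogram = {d: 0 for d in range(1, len(candidate_sets) + 1)}
    for d in degree.values():
        histogram[d] += 1
    return histogram, degree


def compare_gene_lists(set_a: set[str], set_b: set[str]) -> dict:
    """Overlap report between two gene sets, stably ordered."""
    inter = sorted(set_a & set_b)
    return {
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_overlap": len(inter),
        "fraction_a_in_b": (len(inter) / len(set_a)) if set_a else 0.0,
        "overlap": inter,
    }
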