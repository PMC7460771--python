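"""Bundled published candidate tables for the replay and verification mode.

Two small tables from the midgut arm of the screen are packaged verbatim:

* ``midgut_candidates.tsv`` — the 40 multipass-TM differentially expressed
  genes with transport-consistent expression patterns (gene, log2FC on the
  heme_excess-over-heme_deficient contrast, BH q-value, TM-segment count);
* ``midgut_cell_overlap.tsv`` — the subset of those candidates that recur in
  one or more of the four cultured-cell datasets, with the number of cell
  datasets each was found in.

They serve as frozen worked examples: re-running the prioritization filters
on them must reproduce the published split counts exactly.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io_formats import GeneAnnotation


def load_midgut_candidate_table() -> pd.DataFrame:
    """The 40-row published midgut candidate table.

    Columns: ``gene_id``, ``log2fc``, ``q_value``, ``tm_count``.
    """
    ref = resources.files("hemescreen") / "data" / "midgut_candidates.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def load_midgut_cell_overlap_table() -> pd.DataFrame:
    """Published midgut candidates shared with cultured-cell datasets.

    Columns: ``gene_id``, ``direction`` (import_like/export_like),
    ``overlap_degree`` (number of cell datasets, 1-4).
    """
    ref = resources.files("hemescreen") / "data" / "midgut_cell_overlap.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def midgut_candidate_annotation() -> GeneAnnotation:
    """Annotation view of the candidate table.

    The published table is already curated down to transport-plausible,
    non-mitochondrial genes, so every row is annotated as transport-class and
    non-mitochondrial with its printed TM count.
    """
    t = load_midgut_candidate_table()
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": t["gene_id"],
                "tm_count": t["tm_count"].astype(int),
                "function_class": "transport",
                "is_mitochondrial": False,
            }
        )
    )


def overlap_gene_sets() -> dict[str, list[set[str]]]:
    """Reconstruct per-cell-dataset candidate gene sets from overlap degrees.

    The published table records only how many of the 4 cultured-cell
    datasets each midgut candidate recurred in, not which ones; for set
    arithmetic a canonical reconstruction assigns a degree-``d`` gene to the
    first ``d`` datasets.  Overlap-degree tallies are invariant to this
    choice.
    """
    table = load_midgut_cell_overlap_table()
    out: dict[str, list[set[str]]] = {}
    for direction, sub in table.groupby("direction"):
        sets = [set() for _ in range(4)]
        for row in sub.itertuples():
            for d in range(int(row.overlap_degree)):
                sets[d].add(row.gene_id)
        out[str(direction)] = sets
    return out
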