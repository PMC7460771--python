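#!/usr/bin/env python
"""Prioritize transporter candidates and tally them across datasets.

Combines DE (q, fold change), TM-segment counts and concordant cluster
patterns into strict-mode candidate tables per dataset, tests the DEG sets
for TM enrichment against the simulated genome, and tallies candidate
overlap across datasets.  Writes tables under results/candidates/.
"""

import json
from pathlib import Path

import pandas as pd

from hemescreen.candidates import cross_dataset_tally, filter_cell_candidates
from hemescreen.diffexpr import DETable
from hemescreen.io_formats import read_count_matrix, read_gene_annotation
from hemescreen.tm_enrichment import enrich_gene_set

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "candidates"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ann = read_gene_annotation(BASE / "synthetic" / "annotation.tsv")
    sets = {"import_like": [], "export_like": []}
    for de_path in sorted((BASE / "de").glob("de_*.tsv")):
        ds = de_path.stem.split("_", 1)[1]
        det = pd.read_csv(de_path, sep="\t", comment="#")
        de = DETable(det, contrast=("heme_deficient", "heme_excess"), dispersion=0.0)
        clusters = pd.read_csv(BASE / "clusters" / f"clusters_{ds}.tsv", sep="\t")
        cands = filter_cell_candidates(
            de, clusters, ann, alpha=0.05, min_tm=2, min_abs_log2fc=1.0
        )
        cands.write(OUT / f"candidates_{ds}.tsv")

        deg = list(de.significant(0.0001)["gene_id"])
        enr = enrich_gene_set(deg, ann, n_draws=30, seed=22)
        enr.to_json(OUT / f"enrichment_{ds}.json")
        print(
            f"{ds}: {len(cands)} strict candidates "
            f"({len(cands.import_like)} import-like, {len(cands.export_like)} export-like); "
            f"DEG TM enrichment obs {enr.observed} vs exp {enr.mean:.0f} "
            f"(z={enr.z:.1f}, p={enr.p_two_tailed:.2g})"
        )
        for d in sets:
            sets[d].append(cands.gene_set(d))

    tallies = {}
    for d, s in sets.items():
        hist, degree = cross_dataset_tally(s)
        tallies[d] = {"histogram": hist, "n_union": len(degree)}
        print(f"{d}: overlap-degree histogram {hist}")
    with open(OUT / "cross_dataset_tally.json", "w", encoding="utf-8") as fh:
        json.dump(tallies, fh, indent=2)


if __name__ == "__main__":
    main()
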