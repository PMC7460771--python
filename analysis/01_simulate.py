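#!/usr/bin/env python
"""Generate the synthetic multi-dataset heme-exposure experiment.

Emulates the study design: three media conditions (normal serum, heme
deficient, heme excess), three biological replicates each, across two
cultured-cell-like datasets, with planted import-like, export-like and
serum-response genes and a genome where roughly a third of genes carry a
transmembrane segment.  Writes count matrices, sample sheets, the gene
annotation and the ground truth under results/synthetic/.
"""

from pathlib import Path

from hemescreen.io_formats import write_count_matrix, write_gene_annotation
from hemescreen.simulate import SimConfig, generate_experiment

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(
        n_genes=8000,
        n_datasets=2,
        n_import=100,
        n_export=100,
        n_serum=150,
        n_mito=20,
        dispersion=0.1,
        effect_log2=1.0,
        seed=20,
    )
    matrices, annotation, truth = generate_experiment(cfg)
    for cm in matrices:
        ds = cm.samples[0].dataset_id
        write_count_matrix(cm, OUT / f"counts_{ds}.tsv", OUT / f"samples_{ds}.tsv")
        print(
            f"{ds}: {cm.n_genes} genes x {cm.n_samples} samples, "
            f"median library {int(sorted(cm.library_sizes)[cm.n_samples // 2]):,} reads"
        )
    write_gene_annotation(annotation, OUT / "annotation.tsv")
    truth.write(OUT / "ground_truth.tsv")
    cfg.to_yaml(OUT / "sim_config.yaml")
    tm_frac = (annotation.table["tm_count"] >= 1).mean()
    print(f"annotation: {len(annotation)} genes, {tm_frac:.1%} with >= 1 TM segment")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
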