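"""Configuration-driven orchestration of the full transporter screen.

``run_all`` drives a complete pass — simulate (or load) count matrices,
per-dataset differential expression, soft clustering, TM-domain enrichment,
candidate filtering and the cross-dataset tally — writing every artifact
plus a summary JSON.  All randomness flows from one root seed via named
substreams, so re-running any stage in isolation reproduces the full run.

``replay_published_tables`` re-executes the prioritization filters and overlap
tally on the bundled published candidate tables and checks the printed
split counts; it is the package's built-in verification mode.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .candidates import (
    CandidateTable,
    cross_dataset_tally,
    filter_cell_candidates,
    filter_midgut_candidates,
    highly_regulated,
)
from .diffexpr import run_de
from .io_formats import (
    CountMatrix,
    GeneAnnotation,
    read_count_matrix,
    read_gene_annotation,
    write_count_matrix,
    write_gene_annotation,
)
from .published_tables import (
    load_midgut_candidate_table,
    midgut_candidate_annotation,
    overlap_gene_sets,
)
from .simulate import GroundTruth, SimConfig, generate_experiment
from .softcluster import (
    assign_members,
    estimate_fuzzifier,
    fuzzy_cmeans,
    profile_matrix,
    select_cluster_count,
)
from .tm_enrichment import enrich_gene_set

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full screen run needs.

    Either ``sim`` is set (synthetic mode) or ``counts_path`` /
    ``sample_sheet_path`` / ``annotation_path`` point at real inputs.
    """

    out_dir: str = "results/run"
    seed: int = 0
    sim: SimConfig | None = None
    counts_path: str | None = None
    sample_sheet_path: str | None = None
    annotation_path: str | None = None
    de_alpha: float = 0.0001
    candidate_alpha: float = 0.05
    min_tm: int = 2
    min_abs_log2fc: float = 1.0
    membership_threshold: float = 0.5
    fuzzifier: float | None = None  # None -> estimate from data
    cluster_counts: tuple[int, int] = (2, 12)  # c range searched
    enrichment_draws: int = 30
    contrast: tuple[str, str] = ("heme_deficient", "heme_excess")

    def config_hash(self) -> str:
        # fingerprint of the scientific settings; output location excluded
        d = asdict(self)
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if d.get("sim"):
            d["sim"] = SimConfig(**d["sim"])
        if "cluster_counts" in d:
            d["cluster_counts"] = tuple(d["cluster_counts"])
        if "contrast" in d:
            d["contrast"] = tuple(d["contrast"])
        return cls(**d)


def _provenance(config: RunConfig) -> dict:
    return {
        "software_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


def run_all(config: RunConfig) -> dict:
    """Execute the whole screen; returns (and writes) the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    sub = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("simulation", "clustering", "resampling"), root.spawn(3)
        )
    }

    truth: GroundTruth | None = None
    if config.sim is not None:
        sim_cfg = SimConfig(**{**asdict(config.sim), "seed": sub["simulation"]})
        matrices, annotation, truth = generate_experiment(sim_cfg)
        for m in matrices:
            ds = m.samples[0].dataset_id
            write_count_matrix(m, out / f"counts_{ds}.tsv", out / f"samples_{ds}.tsv")
        write_gene_annotation(annotation, out / "annotation.tsv")
        truth.write(out / "ground_truth.tsv")
    elif config.counts_path:
        cm = read_count_matrix(config.counts_path, config.sample_sheet_path)
        matrices = [cm.dataset(d) for d in cm.dataset_ids]
        annotation = read_gene_annotation(config.annotation_path)
    else:
        raise ValueError("config must provide a simulation or input paths")

    summary: dict = {"provenance": _provenance(config), "datasets": {}}
    per_dataset_sets: dict[str, dict[str, set[str]]] = {}

    for stage_no, cm in enumerate(matrices):
        ds = cm.samples[0].dataset_id
        try:
            ds_summary = _run_dataset(cm, annotation, config, sub, out, ds)
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            fingerprint = hashlib.sha256(cm.counts.tobytes()).hexdigest()[:12]
            raise RuntimeError(
                f"stage 'dataset:{ds}' failed (input fingerprint {fingerprint})"
            ) from exc
        summary["datasets"][ds] = ds_summary["summary"]
        per_dataset_sets[ds] = ds_summary["candidate_sets"]

    for direction in ("import_like", "export_like"):
        sets = [per_dataset_sets[ds][direction] for ds in per_dataset_sets]
        hist, degree = cross_dataset_tally(sets)
        summary[f"overlap_{direction}"] = {
            "histogram": {str(k): v for k, v in hist.items()},
            "n_union": len(degree),
        }

    if truth is not None:
        summary["recovery"] = _recovery_metrics(per_dataset_sets, truth)

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _write_report(summary, out / "report.txt")
    return summary


def _run_dataset(
    cm: CountMatrix,
    annotation: GeneAnnotation,
    config: RunConfig,
    sub: dict[str, int],
    out: Path,
    ds: str,
) -> dict:
    treatments = {s.treatment for s in cm.samples}
    if set(config.contrast) <= treatments:
        contrast = config.contrast
    else:  # two-group designs fall back to normal vs the heme arm present
        present = sorted(treatments)
        contrast = (present[0], present[1])

    de = run_de(cm, contrast=contrast, alpha=config.de_alpha)
    de.write(out / f"de_{ds}.tsv")

    profiles = profile_matrix(cm)
    m = config.fuzzifier or estimate_fuzzifier(
        len(profiles.gene_ids), len(profiles.treatments)
    )
    c_lo, c_hi = config.cluster_counts
    c = select_cluster_count(
        profiles, range(c_lo, c_hi + 1), seed=sub["clustering"], m=m
    )
    model = fuzzy_cmeans(profiles, c=c, m=m, seed=sub["clustering"])
    assignments = assign_members(model, threshold=config.membership_threshold)
    assignments.to_csv(out / f"clusters_{ds}.tsv", sep="\t", index=False)
    with open(out / f"cluster_model_{ds}.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "c": model.n_clusters,
                "m": model.fuzzifier,
                "objective": model.objective,
                "seed": sub["clustering"],
                "treatments": model.treatments,
                "centroids": model.centroids.tolist(),
                "patterns": model.pattern_labels(),
            },
            fh,
            indent=2,
        )

    deg = set(de.significant(config.de_alpha)["gene_id"])
    universe = GeneAnnotation(
        annotation.table.loc[annotation.table["gene_id"].isin(cm.gene_ids)]
    ) if len(annotation) else annotation
    enrichment = None
    if deg:
        enrichment = enrich_gene_set(
            deg, universe, n_draws=config.enrichment_draws, seed=sub["resampling"]
        )
        enrichment.to_json(out / f"enrichment_{ds}.json")

    cands = filter_cell_candidates(
        de,
        assignments,
        annotation,
        alpha=config.candidate_alpha,
        min_tm=config.min_tm,
        min_abs_log2fc=config.min_abs_log2fc,
        mode="strict",
    )
    cands.write(out / f"candidates_{ds}.tsv")
    union = filter_cell_candidates(
        de,
        assignments,
        annotation,
        alpha=config.candidate_alpha,
        min_tm=config.min_tm,
        min_abs_log2fc=config.min_abs_log2fc,
        mode="union",
    )
    union.write(out / f"candidates_union_{ds}.tsv")

    return {
        "summary": {
            "contrast": list(contrast),
            "n_genes_tested": len(de.table),
            "n_significant": len(deg),
            "dispersion": de.dispersion,
            "n_clusters": model.n_clusters,
            "fuzzifier": model.fuzzifier,
            "cluster_patterns": model.pattern_labels(),
            "n_candidates_strict": len(cands),
            "n_candidates_union": len(union),
            "enrichment_z": enrichment.z if enrichment else None,
            "enrichment_p": enrichment.p_two_tailed if enrichment else None,
        },
        "candidate_sets": {
            "import_like": cands.gene_set("import_like"),
            "export_like": cands.gene_set("export_like"),
        },
    }


def _recovery_metrics(
    per_dataset_sets: dict[str, dict[str, set[str]]], truth: GroundTruth
) -> dict:
    metrics: dict = {}
    for direction, cls in (("import_like", "import"), ("export_like", "export")):
        planted = set(truth.genes_of_class(cls))
        found = set().union(
            *(per_dataset_sets[ds][direction] for ds in per_dataset_sets)
        )
        tp = len(planted & found)
        metrics[direction] = {
            "n_planted": len(planted),
            "n_called": len(found),
            "recall": tp / len(planted) if planted else None,
            "precision": tp / len(found) if found else None,
        }
    return metrics


def _write_report(summary: dict, path: Path) -> None:
    lines = [
        "Heme-transporter screen report",
        f"version {summary['provenance']['software_version']}  "
        f"seed {summary['provenance']['seed']}  "
        f"config {summary['provenance']['config_hash']}",
        "",
    ]
    for ds, s in summary.get("datasets", {}).items():
        lines.append(
            f"[{ds}] {s['n_significant']}/{s['n_genes_tested']} DE genes "
            f"(phi={s['dispersion']:.3f}); {s['n_clusters']} clusters; "
            f"{s['n_candidates_strict']} strict candidates"
        )
    for direction in ("import_like", "export_like"):
        key = f"overlap_{direction}"
        if key in summary:
            lines.append(f"{direction} overlap histogram: {summary[key]['histogram']}")
    if "recovery" in summary:
        for d, m in summary["recovery"].items():
            rec = m["recall"]
            prec = m["precision"]
            lines.append(
                f"recovery {d}: recall="
                + (f"{rec:.2f}" if rec is not None else "n/a")
                + " precision="
                + (f"{prec:.2f}" if prec is not None else "n/a")
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# replay of the published tables


def replay_published_tables() -> dict:
    """Re-run the prioritization filters on the bundled published tables.

    Returns a report dict with an ``ok`` flag; every re-derived count is
    checked against the published one.
    """
    table4 = load_midgut_candidate_table()
    ann = midgut_candidate_annotation()
    de_like = pd.DataFrame(
        {
            "gene_id": table4["gene_id"],
            "logFC": table4["log2fc"],
            "FDR": table4["q_value"],
        }
    )
    cands = filter_midgut_candidates(de_like, ann, alpha=0.05, min_tm=2)
    high = highly_regulated(cands, min_abs_log2fc=1.0)

    sets = overlap_gene_sets()
    imp_hist, _ = cross_dataset_tally(sets["import_like"])
    exp_hist, exp_deg = cross_dataset_tally(sets["export_like"])
    imp_union = sum(imp_hist.values())
    exp_union = len(exp_deg)

    report = {
        "n_candidates": len(cands),
        "n_import": len(cands.import_like),
        "n_export": len(cands.export_like),
        "n_high_import": len(high.import_like),
        "n_high_export": len(high.export_like),
        "n_high_total": len(high),
        "import_overlap_histogram": {str(k): v for k, v in imp_hist.items()},
        "n_import_shared": imp_union,
        "n_export_shared": exp_union,
        "n_shared_total": imp_union + exp_union,
    }
    expected = {
        "n_candidates": 40,
        "n_import": 28,
        "n_export": 12,
        "n_high_import": 6,
        "n_high_export": 5,
        "n_high_total": 11,
        "import_overlap_histogram": {"1": 8, "2": 1, "3": 2, "4": 0},
        "n_import_shared": 11,
        "n_export_shared": 4,
        "n_shared_total": 15,
    }
    mismatches = {
        k: {"expected": v, "got": report[k]}
        for k, v in expected.items()
        if report[k] != v
    }
    report["ok"] = not mismatches
    report["mismatches"] = mismatches
    return report
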