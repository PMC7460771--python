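"""Synthetic multi-dataset RNA-seq experiments with planted heme responses.

The generator emulates the structure of the study's treatment design:
each dataset is a cultured-cell or midgut experiment with up to three media
conditions (``normal_serum``, ``heme_deficient``, ``heme_excess``) and a few
biological replicates per condition.  Counts are negative-binomial with a
single common dispersion, matching the model assumed by the exact-test
differential-expression stage.

Planted response classes
------------------------
import-like   up in heme deficiency, down in heme excess (the signature of a
              transcriptionally regulated heme importer)
export-like   the mirrored signature
serum         responds to serum presence only (a nutrient artifact of the
              media design, not a heme response)
mito          up under heme excess (mitochondrial proliferation)
null          no treatment effect

The annotation gives a configurable fraction of planted importers/exporters
>= 2 TM segments and a genome-wide background where roughly a third of all
genes carry at least one TM segment, mirroring the *Ae. aegypti* baseline
the enrichment test resamples from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import CountMatrix, GeneAnnotation, SampleMeta, TREATMENTS

THREE_GROUP = ("normal_serum", "heme_deficient", "heme_excess")
TWO_GROUP = ("normal_serum", "heme_excess")


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment.

    Defaults are sized to the study: ~8,000 expressed genes per dataset,
    3 replicates per media condition, library sizes around 5x10^5 reads, a
    common NB dispersion of 0.1 and 2-fold planted effects (the screen's
    "highly differentially regulated" threshold).
    """

    n_genes: int = 8000
    n_datasets: int = 1
    reps_per_group: int = 3
    design: tuple[str, ...] = THREE_GROUP  # treatments present in each dataset
    baseline_log2_mean: float = 5.0  # log2 CPM scale
    baseline_log2_sd: float = 2.0
    dispersion: float = 0.1  # common NB dispersion phi0
    lib_size_base: float = 5e5
    lib_size_range: tuple[float, float] = (0.8, 1.2)
    n_import: int = 0
    n_export: int = 0
    n_serum: int = 0
    n_mito: int = 0
    effect_log2: float = 1.0  # Delta, log2 units
    p_tm_background: float = 0.32
    tm_transporter_fraction: float = 1.0  # planted import/export genes with >=2 TM
    transporter_tm_low: int = 2
    transporter_tm_high: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.n_import + self.n_export + self.n_serum + self.n_mito
        if planted > self.n_genes:
            raise ValueError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes})"
            )
        if self.effect_log2 < 0:
            raise ValueError("effect_log2 must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 1 <= self.n_datasets <= 4:
            raise ValueError("n_datasets must be in 1..4")
        unknown = set(self.design) - set(TREATMENTS)
        if unknown:
            raise ValueError(f"unknown treatments in design: {sorted(unknown)}")
        if len(self.design) < 2:
            raise ValueError("design needs at least two treatments")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["design"] = list(self.design)
        d["lib_size_range"] = list(self.lib_size_range)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        d["design"] = tuple(d["design"])
        d["lib_size_range"] = tuple(d["lib_size_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-gene planted class and true per-treatment log2 effects."""

    table: pd.DataFrame  # gene_id, true_class, effect_<treatment>...

    def genes_of_class(self, cls: str) -> list[str]:
        t = self.table
        return list(t.loc[t["true_class"] == cls, "gene_id"])

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruth":
        return cls(pd.read_csv(path, sep="\t", comment="#"))


# effect(class, treatment) in log2 units, in multiples of Delta
_CLASS_EFFECTS = {
    "import": {"normal_serum": 0.0, "heme_deficient": +1.0, "heme_excess": -1.0},
    "export": {"normal_serum": 0.0, "heme_deficient": -1.0, "heme_excess": +1.0},
    "serum": {"normal_serum": +1.0, "heme_deficient": 0.0, "heme_excess": 0.0},
    "mito": {"normal_serum": 0.0, "heme_deficient": 0.0, "heme_excess": +1.0},
    "null": {"normal_serum": 0.0, "heme_deficient": 0.0, "heme_excess": 0.0},
}


def _assign_classes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    classes = np.array(["null"] * cfg.n_genes, dtype=object)
    planted = cfg.n_import + cfg.n_export + cfg.n_serum + cfg.n_mito
    idx = rng.choice(cfg.n_genes, size=planted, replace=False)
    pos = 0
    for cls, n in (
        ("import", cfg.n_import),
        ("export", cfg.n_export),
        ("serum", cfg.n_serum),
        ("mito", cfg.n_mito),
    ):
        classes[idx[pos : pos + n]] = cls
        pos += n
    return classes


def nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts with mean ``mean`` and Var = mean + phi*mean^2.

    ``dispersion == 0`` degenerates to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0.0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    # gamma-Poisson mixture keeps the draw exact for non-integer r
    lam = rng.gamma(shape=r, scale=mean / r)
    return rng.poisson(lam)


def generate_experiment(
    cfg: SimConfig,
) -> tuple[list[CountMatrix], GeneAnnotation, GroundTruth]:
    """Simulate count matrices, an annotation and ground truth from a config.

    The same genes (and hence the same planted classes and annotation) are
    shared across datasets; each dataset gets an independent random stream
    derived from the root seed, so adding a dataset never perturbs the
    counts of earlier ones.
    """
    root = np.random.SeedSequence(cfg.seed)
    # fixed-role children: 0 = gene-level randomness, 1..n = per-dataset streams
    children = root.spawn(1 + cfg.n_datasets)
    gene_rng = np.random.default_rng(children[0])

    gene_ids = [f"G{i:06d}" for i in range(cfg.n_genes)]
    classes = _assign_classes(cfg, gene_rng)
    base_log2 = gene_rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
    base_cpm = 2.0**base_log2

    effects = {
        t: cfg.effect_log2
        * np.array([_CLASS_EFFECTS[c][t] for c in classes], dtype=float)
        for t in TREATMENTS
    }

    truth = GroundTruth(
        pd.DataFrame(
            {
                "gene_id": gene_ids,
                "true_class": classes,
                **{f"effect_{t}": effects[t] for t in TREATMENTS},
            }
        )
    )

    annotation = _make_annotation(cfg, gene_rng, gene_ids, classes)

    matrices: list[CountMatrix] = []
    for d in range(cfg.n_datasets):
        ds_rng = np.random.default_rng(children[1 + d])
        dataset_id = f"ds{d + 1}"
        samples: list[SampleMeta] = []
        cols: list[np.ndarray] = []
        for treatment in cfg.design:
            for rep in range(1, cfg.reps_per_group + 1):
                s_factor = ds_rng.uniform(*cfg.lib_size_range)
                lib = cfg.lib_size_base * s_factor
                mu = base_cpm * 2.0 ** effects[treatment]
                mu = mu / mu.sum() * lib  # CPM-scale baselines -> expected counts
                cols.append(nb_draw(ds_rng, mu, cfg.dispersion))
                samples.append(
                    SampleMeta(
                        sample_id=f"{dataset_id}_{treatment}_r{rep}",
                        dataset_id=dataset_id,
                        treatment=treatment,
                        replicate=rep,
                    )
                )
        matrices.append(
            CountMatrix(
                gene_ids=list(gene_ids),
                counts=np.column_stack(cols).astype(np.int64),
                samples=samples,
            )
        )
    return matrices, annotation, truth


def _make_annotation(
    cfg: SimConfig,
    rng: np.random.Generator,
    gene_ids: list[str],
    classes: np.ndarray,
) -> GeneAnnotation:
    n = len(gene_ids)
    tm = np.zeros(n, dtype=np.int64)
    has_tm = rng.random(n) < cfg.p_tm_background
    # background TM genes: mostly 1-2 segments, geometric tail
    tm[has_tm] = np.minimum(rng.geometric(0.55, size=int(has_tm.sum())), 17)

    func = np.array(["other"] * n, dtype=object)
    func[rng.random(n) < 0.15] = "enzyme"
    func[rng.random(n) < 0.05] = "ros_response"
    func[rng.random(n) < 0.10] = "unknown"
    mito = np.zeros(n, dtype=bool)

    transporterish = np.isin(classes, ["import", "export"])
    idx = np.where(transporterish)[0]
    if idx.size:
        chosen = rng.random(idx.size) < cfg.tm_transporter_fraction
        multi = idx[chosen]
        tm[multi] = rng.integers(
            cfg.transporter_tm_low, cfg.transporter_tm_high + 1, size=multi.size
        )
        func[idx] = "transport"
    mito[classes == "mito"] = True
    func[classes == "mito"] = "other"

    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": gene_ids,
                "tm_count": tm,
                "function_class": func,
                "is_mitochondrial": mito,
            }
        )
    )
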