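"""On-disk formats for the heme-transporter screen.

All tabular inputs and outputs are plain TSV: tab-separated, UTF-8, lines
starting with ``#`` ignored, no quoting.  The three formats are

* a count matrix (``gene_id`` column followed by one integer column per
  sample),
* a sample sheet (``sample_id``, ``dataset_id``, ``treatment``,
  ``replicate``), and
* a gene annotation table (``gene_id``, ``tm_count`` *or* ``topology``,
  ``function_class``, ``is_mitochondrial``).

Membrane topology strings use the consensus alphabet ``{i, o, M, S}``
(inside / outside / membrane / signal peptide); the number of predicted
transmembrane segments of a protein is the number of maximal runs of ``M``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREATMENTS = ("normal_serum", "heme_deficient", "heme_excess")

FUNCTION_CLASSES = ("transport", "unknown", "enzyme", "ros_response", "other")

_TOPOLOGY_ALPHABET = frozenset("ioMS")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequencing library (one count-matrix column)."""

    sample_id: str
    dataset_id: str
    treatment: str
    replicate: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"unknown treatment {self.treatment!r} for sample "
                f"{self.sample_id!r}; expected one of {TREATMENTS}"
            )
        if self.replicate < 1:
            raise ValueError(f"replicate index must be >= 1, got {self.replicate}")


@dataclass
class CountMatrix:
    """Integer gene x sample read counts with per-sample metadata."""

    gene_ids: list[str]
    counts: np.ndarray  # (n_genes, n_samples), integer, >= 0
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValueError("gene_ids length does not match count rows")
        if len(self.samples) != self.counts.shape[1]:
            raise ValueError("one SampleMeta required per count column")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        keys = [(s.dataset_id, s.treatment, s.replicate) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("(dataset_id, treatment, replicate) must be unique")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def subset_samples(self, keep: Sequence[int]) -> "CountMatrix":
        keep = list(keep)
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            counts=self.counts[:, keep].copy(),
            samples=[self.samples[i] for i in keep],
        )

    def subset_genes(self, keep: Sequence[int]) -> "CountMatrix":
        keep = list(keep)
        return CountMatrix(
            gene_ids=[self.gene_ids[i] for i in keep],
            counts=self.counts[keep, :].copy(),
            samples=list(self.samples),
        )

    def dataset(self, dataset_id: str) -> "CountMatrix":
        """Columns belonging to one dataset, sample-sheet order preserved."""
        keep = [i for i, s in enumerate(self.samples) if s.dataset_id == dataset_id]
        if not keep:
            raise ValueError(f"no samples for dataset {dataset_id!r}")
        return self.subset_samples(keep)

    @property
    def dataset_ids(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.dataset_id not in seen:
                seen.append(s.dataset_id)
        return seen


@dataclass
class GeneAnnotation:
    """Per-gene transmembrane-segment counts, curated function class and
    mitochondrial flag.

    Defines the sampling universe for the TM-enrichment resampling test and
    the filter inputs for candidate prioritization.  Genes asked about but
    absent from the table fall back to conservative defaults
    (``tm_count=0``, ``function_class='other'``, not mitochondrial).
    """

    table: pd.DataFrame = field(default_factory=lambda: _empty_annotation())

    def __post_init__(self) -> None:
        required = {"gene_id", "tm_count", "function_class", "is_mitochondrial"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if self.table["gene_id"].duplicated().any():
            dups = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene_id in annotation: {list(dups)[:5]}")
        if (self.table["tm_count"] < 0).any():
            raise ValueError("tm_count must be >= 0")
        self.table = self.table.reset_index(drop=True)
        self._index = {g: i for i, g in enumerate(self.table["gene_id"])}

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    def tm_count(self, gene_id: str) -> int:
        i = self._index.get(gene_id)
        if i is None:
            return 0
        return int(self.table["tm_count"].iloc[i])

    def function_class(self, gene_id: str) -> str:
        i = self._index.get(gene_id)
        if i is None:
            return "other"
        return str(self.table["function_class"].iloc[i])

    def is_mitochondrial(self, gene_id: str) -> bool:
        i = self._index.get(gene_id)
        if i is None:
            return False
        return bool(self.table["is_mitochondrial"].iloc[i])

    def tm_counts_for(self, gene_ids: Sequence[str]) -> np.ndarray:
        missing = [g for g in gene_ids if g not in self._index]
        if missing:
            logger.warning(
                "%d gene(s) absent from annotation treated as 0-TM (e.g. %s)",
                len(missing),
                missing[0],
            )
        return np.array([self.tm_count(g) for g in gene_ids], dtype=np.int64)


def _empty_annotation() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": pd.Series(dtype=str),
            "tm_count": pd.Series(dtype=np.int64),
            "function_class": pd.Series(dtype=str),
            "is_mitochondrial": pd.Series(dtype=bool),
        }
    )


# ---------------------------------------------------------------------------
# topology strings


def count_tm_segments(topology: str) -> int:
    """Number of membrane-spanning segments in a consensus topology string.

    A segment is a maximal run of ``'M'``; ``i``/``o`` are the cytosolic and
    extracellular loops and ``S`` a signal peptide.

    >>> count_tm_segments("iiMMMMMMMMooMMMMMMMMii")
    2
    """
    if not topology:
        raise ValueError("topology string must be non-empty")
    for pos, ch in enumerate(topology):
        if ch not in _TOPOLOGY_ALPHABET:
            raise ValueError(
                f"unknown topology symbol {ch!r} at position {pos} "
                "(alphabet is {i, o, M, S})"
            )
    return len(re.findall(r"M+", topology))


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_count_matrix(path: str | Path, sample_sheet: str | Path) -> CountMatrix:
    """Read a count matrix TSV together with its sample sheet.

    Columns are reordered to sample-sheet order.  Every matrix column must be
    described by the sheet and vice versa.
    """
    df = _read_tsv(path, dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ValueError(f"first column must be 'gene_id', got {df.columns[0]!r}")
    sheet = _read_tsv(sample_sheet, dtype={"sample_id": str, "dataset_id": str})

    matrix_samples = list(df.columns[1:])
    sheet_samples = list(sheet["sample_id"])
    orphans = [s for s in matrix_samples if s not in sheet_samples]
    if orphans:
        raise ValueError(f"sample sheet missing metadata for column(s): {orphans}")
    absent = [s for s in sheet_samples if s not in matrix_samples]
    if absent:
        raise ValueError(f"sample sheet lists sample(s) not in matrix: {absent}")

    gene_ids = list(df["gene_id"])
    if len(set(gene_ids)) != len(gene_ids):
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"]
        raise ValueError(f"duplicate gene_id: {list(dupes)[:5]}")

    values = df[sheet_samples].to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if np.any(values != np.round(values)) or np.any(~np.isfinite(values)):
            raise ValueError("count matrix contains non-integer cells")
        values = values.astype(np.int64)
    if np.any(values < 0):
        raise ValueError("count matrix contains negative cells")

    samples = [
        SampleMeta(
            sample_id=str(row.sample_id),
            dataset_id=str(row.dataset_id),
            treatment=str(row.treatment),
            replicate=int(row.replicate),
        )
        for row in sheet.itertuples()
    ]
    return CountMatrix(gene_ids=gene_ids, counts=values, samples=samples)


def write_count_matrix(
    cm: CountMatrix, path: str | Path, sample_sheet: str | Path
) -> None:
    df = pd.DataFrame(cm.counts, columns=cm.sample_ids)
    df.insert(0, "gene_id", cm.gene_ids)
    df.to_csv(path, sep="\t", index=False)
    sheet = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in cm.samples],
            "dataset_id": [s.dataset_id for s in cm.samples],
            "treatment": [s.treatment for s in cm.samples],
            "replicate": [s.replicate for s in cm.samples],
        }
    )
    sheet.to_csv(sample_sheet, sep="\t", index=False)


_BOOL_MAP = {
    "true": True,
    "false": False,
    "1": True,
    "0": False,
    "yes": True,
    "no": False,
}


def _parse_bool(value, line_no: int):
    s = str(value).strip().lower()
    if s not in _BOOL_MAP:
        raise ValueError(f"malformed is_mitochondrial value {value!r} on line {line_no}")
    return _BOOL_MAP[s]


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Read a gene annotation TSV.

    The second column may be either an integer ``tm_count`` or a ``topology``
    string, in which case the TM count is derived with
    :func:`count_tm_segments`.
    """
    df = _read_tsv(path, dtype=str)
    if df.empty and "gene_id" not in df.columns:
        logger.warning("empty annotation file %s", path)
        return GeneAnnotation()
    if "gene_id" not in df.columns:
        raise ValueError("annotation must have a gene_id column")
    if "tm_count" not in df.columns and "topology" not in df.columns:
        raise ValueError("annotation needs a tm_count or topology column")

    records = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        gene = d["gene_id"]
        if "tm_count" in d and not pd.isna(d["tm_count"]):
            try:
                tm = int(d["tm_count"])
            except ValueError as exc:
                raise ValueError(
                    f"malformed tm_count {d['tm_count']!r} on line {line_no}"
                ) from exc
        elif "topology" in d and not pd.isna(d["topology"]):
            tm = count_tm_segments(str(d["topology"]))
        else:
            raise ValueError(f"no tm_count or topology on line {line_no}")
        func = str(d.get("function_class", "other"))
        if pd.isna(d.get("function_class")):
            func = "other"
        if func not in FUNCTION_CLASSES:
            raise ValueError(
                f"unknown function_class {func!r} on line {line_no}; "
                f"expected one of {FUNCTION_CLASSES}"
            )
        mito = d.get("is_mitochondrial", "false")
        if pd.isna(mito):
            mito = "false"
        records.append(
            {
                "gene_id": gene,
                "tm_count": tm,
                "function_class": func,
                "is_mitochondrial": _parse_bool(mito, line_no),
            }
        )
    if not records:
        logger.warning("annotation file %s has a header but no rows", path)
        return GeneAnnotation()
    return GeneAnnotation(pd.DataFrame.from_records(records))


def write_gene_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    out = ann.table.copy()
    out["is_mitochondrial"] = out["is_mitochondrial"].map(
        {True: "true", False: "false"}
    )
    out.to_csv(path, sep="\t", index=False)


def read_topology_file(path: str | Path) -> dict[str, int]:
    """Read a two-column ``gene_id<TAB>topology`` file into per-gene TM counts.

    A gene with several entries (e.g. multiple protein isoforms) gets the
    maximum segment count across them.
    """
    counts: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed topology row on line {line_no}")
            gene, topo = parts
            tm = count_tm_segments(topo)
            counts[gene] = max(tm, counts.get(gene, 0))
    return counts
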