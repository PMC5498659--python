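"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices and BPS matrices are tab-separated (genes/processes as
rows, samples as columns), gene sets use the Broad GMT dialect
(``name<TAB>description<TAB>gene...``), and clinical tables are TSV with
required columns ``sample``, ``time``, ``status``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class PipelineError(RuntimeError):
    """A pipeline stage cannot proceed (e.g. every gene was filtered out)."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a tumor/reference label per sample.

    ``is_reference`` marks the normal (non-tumor) samples used as the
    normalization baseline and curve origin.
    """

    values: np.ndarray  # (n_genes, n_samples) float
    gene_ids: List[str]
    sample_ids: List[str]
    is_reference: np.ndarray  # (n_samples,) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.is_reference = np.asarray(self.is_reference, dtype=bool)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.is_reference.shape != (len(self.sample_ids),):
            raise ValueError("is_reference length does not match sample count")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def reference_ids(self) -> List[str]:
        return [s for s, r in zip(self.sample_ids, self.is_reference) if r]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset preserving the requested gene order; unknown genes error."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in genes]
        return ExpressionMatrix(
            self.values[rows], list(genes), self.sample_ids, self.is_reference
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSetCollection:
    """Ordered, named gene sets: name -> (description, genes)."""

    sets: Dict[str, Tuple[str, List[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> List[str]:
        return list(self.sets)

    def genes(self, name: str) -> List[str]:
        return list(self.sets[name][1])

    def description(self, name: str) -> str:
        return self.sets[name][0]


@dataclass
class ClinicalTable:
    """Per-sample survival time, event status and optional categorical covariates."""

    frame: pd.DataFrame  # columns: sample, time, status, covariates...

    def __post_init__(self) -> None:
        required = {"sample", "time", "status"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"clinical table missing columns: {sorted(missing)}")
        self.frame = self.frame.reset_index(drop=True)
        if self.frame["sample"].duplicated().any():
            raise FormatError("duplicate sample ids in clinical table")
        if (self.frame["time"] <= 0).any():
            raise FormatError("survival times must be positive")
        if not self.frame["status"].isin([0, 1]).all():
            raise FormatError("status must be 0 or 1")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.frame["sample"])

    @property
    def time(self) -> np.ndarray:
        return self.frame["time"].to_numpy(dtype=float)

    @property
    def status(self) -> np.ndarray:
        return self.frame["status"].to_numpy(dtype=int)

    @property
    def covariates(self) -> List[str]:
        return [c for c in self.frame.columns if c not in ("sample", "time", "status")]


@dataclass
class BPSMatrix:
    """Processes x samples Biological Process Scores in [0, 1].

    ``metadata`` carries per-process fit details (k, number of curve centers,
    stop reason, genes used); ``skipped`` maps process name -> reason for
    processes that could not be scored.
    """

    values: np.ndarray  # (n_processes, n_samples)
    process_names: List[str]
    sample_ids: List[str]
    metadata: Dict[str, dict] = field(default_factory=dict)
    skipped: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and self.values.shape != (
            len(self.process_names),
            len(self.sample_ids),
        ):
            raise ValueError("BPS shape does not match name lists")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.reshape(len(self.process_names), len(self.sample_ids)),
            index=self.process_names,
            columns=self.sample_ids,
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name TAB description TAB genes...``.

    Duplicate genes within a set are de-duplicated preserving first occurrence.
    Duplicate set names or lines with fewer than 3 fields raise FormatError
    naming the offending line.
    """
    sets: Dict[str, Tuple[str, List[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = (description, genes)
    return GeneSetCollection(sets)


def write_gmt(genesets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in genesets.names:
            fh.write(
                "\t".join([name, genesets.description(name)] + genesets.genes(name))
                + "\n"
            )


def read_expression(path, reference_ids: Sequence[str] = ()) -> ExpressionMatrix:
    """Load a genes x samples TSV; ``reference_ids`` mark the normal samples.

    Genes with any missing value are dropped (the downstream method is
    variance-sensitive; imputation would silently distort it) and the count is
    logged.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene ids in {path}: {dups[:5]}")
    missing_refs = set(reference_ids) - set(df.columns)
    if missing_refs:
        raise ValueError(
            f"reference ids absent from expression header: {sorted(missing_refs)}"
        )
    n_before = len(df)
    df = df.dropna(axis=0, how="any")
    dropped = n_before - len(df)
    if dropped:
        logger.warning("dropped %d genes with missing values", dropped)
    ref = np.array([c in set(reference_ids) for c in df.columns], dtype=bool)
    return ExpressionMatrix(
        df.to_numpy(dtype=float), list(df.index.astype(str)),
        list(df.columns.astype(str)), ref,
    )


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t")
    df.columns = [str(c) for c in df.columns]
    if "sample" in df.columns:
        df["sample"] = df["sample"].astype(str)
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.frame.to_csv(path, sep="\t", index=False)


def write_bps(bps: BPSMatrix, path) -> None:
    """Write a BPS matrix as TSV with 6 decimal places."""
    if bps.values.size and not np.all(np.isfinite(bps.values)):
        raise ValueError("BPS matrix contains non-finite values")
    bps.to_frame().to_csv(path, sep="\t", float_format="%.6f")


def read_bps(path) -> BPSMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return BPSMatrix(
        df.to_numpy(dtype=float),
        list(df.index.astype(str)),
        list(df.columns.astype(str)),
    )
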