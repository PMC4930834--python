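"""Gene x attribute association matrices.

The universal dataset abstraction: a numeric grid with genes labeling the
rows and biological entities (tissues, diseases, pathways, phenotypes,
chemicals, ...) labeling the columns.  Entries quantify evidence of
association; ``NaN`` marks an unobserved gene-entity pair.  A matrix moves
through the harmonization pipeline by changing its ``value_kind``::

    raw_continuous --ecdf--> standardized_{unsigned,signed} --top-f--> {binary,ternary}

Binary matrices hold {0,1}; ternary matrices hold {-1,0,+1} encoding strong
negative / no / strong positive association.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

UNOBSERVED = np.nan

VALUE_KINDS = (
    "raw_continuous",
    "raw_discrete",
    "standardized_unsigned",
    "standardized_signed",
    "binary",
    "ternary",
)


class ValueKind(str, Enum):
    raw_continuous = "raw_continuous"
    raw_discrete = "raw_discrete"
    standardized_unsigned = "standardized_unsigned"
    standardized_signed = "standardized_signed"
    binary = "binary"
    ternary = "ternary"


def _as_kind(kind: "str | ValueKind") -> ValueKind:
    return ValueKind(kind)


@dataclass
class GeneAttributeMatrix:
    """Genes x attributes grid with provenance metadata.

    Parameters
    ----------
    gene_ids
        Row labels (canonical gene symbols or ids), unique.
    attribute_ids
        Column labels, unique.
    values
        2-D float array; ``NaN`` = unobserved.
    value_kind
        One of :data:`VALUE_KINDS`.
    metadata
        Free-form dataset descriptors (``name``, ``measurement``,
        ``sign_allowed`` ...).  The key ``provenance`` accumulates an
        auditable log of processing steps.
    """

    gene_ids: list
    attribute_ids: list
    values: np.ndarray
    value_kind: ValueKind = ValueKind.raw_continuous
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.attribute_ids = list(self.attribute_ids)
        self.value_kind = _as_kind(self.value_kind)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D grid")
        if self.values.shape != (len(self.gene_ids), len(self.attribute_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene labels x "
                f"{len(self.attribute_ids)} attribute labels"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids contain duplicates")
        if len(set(self.attribute_ids)) != len(self.attribute_ids):
            raise ValueError("attribute_ids contain duplicates")
        self._check_value_domain()

    # -- validation ----------------------------------------------------

    def _check_value_domain(self) -> None:
        obs = self.observed_values()
        if obs.size == 0:
            return
        kind = self.value_kind
        if kind is ValueKind.standardized_unsigned:
            if obs.min() < 0 or obs.max() > 1:
                raise ValueError("standardized_unsigned values must lie in [0, 1]")
        elif kind is ValueKind.standardized_signed:
            if obs.min() < -1 or obs.max() > 1:
                raise ValueError("standardized_signed values must lie in [-1, 1]")
        elif kind is ValueKind.binary:
            if not np.isin(obs, (0.0, 1.0)).all():
                raise ValueError("binary values must be 0 or 1")
        elif kind is ValueKind.ternary:
            if not np.isin(obs, (-1.0, 0.0, 1.0)).all():
                raise ValueError("ternary values must be -1, 0 or +1")

    # -- convenience ---------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def observed_values(self) -> np.ndarray:
        return self.values[self.observed_mask()]

    @property
    def is_thresholded(self) -> bool:
        return self.value_kind in (ValueKind.binary, ValueKind.ternary)

    def materialized(self) -> np.ndarray:
        """Dense values with unobserved entries as 0 (no association)."""
        return np.nan_to_num(self.values, nan=0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.attribute_ids
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        value_kind: "str | ValueKind" = "raw_continuous",
        metadata: "Mapping | None" = None,
    ) -> "GeneAttributeMatrix":
        return cls(
            gene_ids=list(frame.index),
            attribute_ids=list(frame.columns),
            values=frame.to_numpy(dtype=float),
            value_kind=value_kind,
            metadata=dict(metadata or {}),
        )

    def copy_with(
        self,
        values: "np.ndarray | None" = None,
        value_kind: "str | ValueKind | None" = None,
        gene_ids: "Sequence | None" = None,
        attribute_ids: "Sequence | None" = None,
    ) -> "GeneAttributeMatrix":
        return GeneAttributeMatrix(
            gene_ids=list(self.gene_ids if gene_ids is None else gene_ids),
            attribute_ids=list(
                self.attribute_ids if attribute_ids is None else attribute_ids
            ),
            values=np.array(self.values if values is None else values, dtype=float),
            value_kind=self.value_kind if value_kind is None else value_kind,
            metadata={k: (list(v) if isinstance(v, list) else v) for k, v in self.metadata.items()},
        )

    def log_step(self, step: str, **params) -> None:
        """Append one processing step to the provenance log."""
        entry = {"step": step, **params}
        self.metadata.setdefault("provenance", []).append(entry)

    # -- TSV interface -------------------------------------------------

    def to_tsv(self, path_or_buf, unobserved_as_zero: "bool | None" = None) -> None:
        """Write the matrix as UTF-8 tab-delimited text.

        Thresholded matrices write unobserved entries as 0 (semantically
        "no association"); continuous matrices write them as ``NA``.
        """
        if unobserved_as_zero is None:
            unobserved_as_zero = self.is_thresholded
        frame = self.to_frame()
        if unobserved_as_zero:
            frame = frame.fillna(0.0)
        frame.index.name = "gene"
        frame.to_csv(path_or_buf, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(
        cls,
        path_or_buf,
        value_kind: "str | ValueKind" = "raw_continuous",
        zero_is_unobserved: bool = False,
    ) -> "GeneAttributeMatrix":
        """Read a matrix TSV: first row attribute labels, first column gene
        symbols, optional numeric gene-id second column (auto-detected);
        ``NA`` or empty cells are unobserved."""
        frame = pd.read_csv(
            path_or_buf, sep="\t", index_col=0, na_values=["NA", ""], dtype=str
        )
        # auto-detect an all-integer second column of gene ids
        gene_id_col = None
        if frame.shape[1] > 1:
            first = frame.iloc[:, 0].dropna()
            if len(first) and first.str.fullmatch(r"-?\d+").all():
                gene_id_col = frame.columns[0]
        numeric_ids = None
        if gene_id_col is not None:
            numeric_ids = frame[gene_id_col].tolist()
            frame = frame.drop(columns=[gene_id_col])
        try:
            values = frame.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"non-numeric cell value in matrix TSV: {exc}") from exc
        if zero_is_unobserved:
            values = np.where(values == 0.0, np.nan, values)
        mat = cls(
            gene_ids=list(frame.index.astype(str)),
            attribute_ids=list(frame.columns.astype(str)),
            values=values,
            value_kind=value_kind,
        )
        if numeric_ids is not None:
            mat.metadata["numeric_gene_ids"] = numeric_ids
        return mat


def write_provenance(matrix: GeneAttributeMatrix, path_or_buf) -> None:
    """Serialize the provenance log as key/value lines (sidecar text file)."""
    lines = []
    for entry in matrix.metadata.get("provenance", []):
        params = "\t".join(
            f"{k}={v}" for k, v in entry.items() if k != "step"
        )
        lines.append(f"{entry['step']}\t{params}".rstrip())
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w", encoding="utf-8") as fh:
            fh.write(text)
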