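"""Serialization formats for harmonized datasets.

Four interchangeable views of a thresholded gene-attribute matrix:

* matrix TSV (genes x attributes grid; see :mod:`harmonet.matrix`),
* gene-set library — one named set of genes per attribute (GMT dialect),
* attribute-set library — the transpose: one set of attributes per gene,
* bipartite triplets — (gene, attribute, value) edge rows.

Signed (ternary) matrices split each attribute's set into ``_up`` / ``_down``
pairs so the GMT files stay compatible with downstream enrichment tools.
All round-trips are lossless on the nonzero entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import GeneAttributeMatrix, ValueKind

UP_SUFFIX = "_up"
DOWN_SUFFIX = "_down"


@dataclass
class GeneSet:
    term_label: str
    description: str = ""
    members: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.term_label!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.term_label!r} has duplicate members")


@dataclass
class GeneSetLibrary:
    sets: list
    direction_split: bool = False
    n_omitted_empty: int = 0

    def __post_init__(self) -> None:
        labels = [s.term_label for s in self.sets]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate term labels in library")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def get(self, label: str) -> "GeneSet | None":
        for s in self.sets:
            if s.term_label == label:
                return s
        return None


def _require_thresholded(matrix: GeneAttributeMatrix) -> None:
    if not matrix.is_thresholded:
        raise ValueError(
            "set libraries are defined for thresholded (binary/ternary) "
            f"matrices, got {matrix.value_kind.value}"
        )


def _sets_from_grid(values, axis_labels, member_labels, signed, direction_split):
    sets = []
    n_empty = 0
    for j, label in enumerate(axis_labels):
        col = values[:, j]
        if signed and direction_split:
            up = [member_labels[i] for i in np.flatnonzero(col == 1)]
            down = [member_labels[i] for i in np.flatnonzero(col == -1)]
            if not up and not down:
                n_empty += 1
                continue
            if up:
                sets.append(GeneSet(f"{label}{UP_SUFFIX}", "", up))
            if down:
                sets.append(GeneSet(f"{label}{DOWN_SUFFIX}", "", down))
        else:
            members = [member_labels[i] for i in np.flatnonzero(col != 0)]
            if not members:
                n_empty += 1
                continue
            sets.append(GeneSet(str(label), "", members))
    return sets, n_empty


def to_gene_set_library(
    matrix: GeneAttributeMatrix, direction_split: bool = True
) -> GeneSetLibrary:
    """One gene set per attribute (genes with nonzero association).

    Ternary matrices emit ``_up``/``_down`` set pairs when
    ``direction_split``; all-zero attributes are omitted and counted.
    """
    _require_thresholded(matrix)
    signed = matrix.value_kind is ValueKind.ternary
    sets, n_empty = _sets_from_grid(
        matrix.materialized(), matrix.attribute_ids, matrix.gene_ids,
        signed, direction_split,
    )
    return GeneSetLibrary(sets, direction_split=signed and direction_split, n_omitted_empty=n_empty)


def to_attribute_set_library(
    matrix: GeneAttributeMatrix, direction_split: bool = True
) -> GeneSetLibrary:
    """The transpose view: one set of attributes per gene."""
    _require_thresholded(matrix)
    signed = matrix.value_kind is ValueKind.ternary
    sets, n_empty = _sets_from_grid(
        matrix.materialized().T, matrix.gene_ids, matrix.attribute_ids,
        signed, direction_split,
    )
    return GeneSetLibrary(sets, direction_split=signed and direction_split, n_omitted_empty=n_empty)


# ---------------------------------------------------------------------------
# triplets (bipartite graph format)


@dataclass
class TripletList:
    """Bipartite (gene, attribute, value) rows; duplicate pairs forbidden."""

    rows: list  # (gene, attribute, value)

    def __post_init__(self) -> None:
        pairs = [(g, a) for g, a, _ in self.rows]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (gene, attribute) pair in triplet list")

    def __len__(self) -> int:
        return len(self.rows)

    def to_tsv(self, path_or_buf) -> None:
        frame = pd.DataFrame(self.rows, columns=["gene", "attribute", "value"])
        frame.to_csv(path_or_buf, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "TripletList":
        frame = pd.read_csv(path_or_buf, sep="\t", dtype={"gene": str, "attribute": str})
        seen = set()
        for lineno, (g, a) in enumerate(zip(frame["gene"], frame["attribute"]), start=2):
            if (g, a) in seen:
                raise ValueError(f"duplicate (gene, attribute) pair at line {lineno}: ({g}, {a})")
            seen.add((g, a))
        return cls(rows=list(frame.itertuples(index=False, name=None)))


def to_triplets(matrix: GeneAttributeMatrix) -> TripletList:
    """Export observed/nonzero entries as (gene, attribute, value) rows.

    Thresholded matrices list only nonzero entries; continuous matrices
    list every observed entry.
    """
    if matrix.is_thresholded:
        grid = matrix.materialized()
        keep = grid != 0
    else:
        grid = matrix.values
        keep = matrix.observed_mask()
    rows = []
    gi, aj = np.nonzero(keep)
    for i, j in zip(gi, aj):
        rows.append((matrix.gene_ids[i], matrix.attribute_ids[j], float(grid[i, j])))
    return TripletList(rows)


def from_triplets(
    triplets: TripletList,
    value_kind: "str | ValueKind | None" = None,
    gene_ids=None,
    attribute_ids=None,
) -> GeneAttributeMatrix:
    """Reconstruct the sparse matrix from a triplet list.

    Labels default to first-appearance order of the triplets; pass
    ``gene_ids``/``attribute_ids`` to fix the full axes (entries absent
    from the list are unobserved, materialized as 0).
    """
    if gene_ids is None:
        gene_ids = list(dict.fromkeys(g for g, _, _ in triplets.rows))
    if attribute_ids is None:
        attribute_ids = list(dict.fromkeys(a for _, a, _ in triplets.rows))
    values = np.asarray([v for _, _, v in triplets.rows], dtype=float)
    if value_kind is None:
        if np.isin(values, (-1.0, 1.0)).all():
            value_kind = "ternary" if (values == -1.0).any() else "binary"
        else:
            value_kind = "raw_continuous"
    gpos = {g: i for i, g in enumerate(gene_ids)}
    apos = {a: j for j, a in enumerate(attribute_ids)}
    kind = ValueKind(value_kind)
    fill = 0.0 if kind in (ValueKind.binary, ValueKind.ternary) else np.nan
    grid = np.full((len(gene_ids), len(attribute_ids)), fill)
    for g, a, v in triplets.rows:
        grid[gpos[g], apos[a]] = v
    return GeneAttributeMatrix(gene_ids, attribute_ids, grid, kind)


# ---------------------------------------------------------------------------
# GMT


def write_gmt(library: GeneSetLibrary, path_or_buf) -> None:
    """Write a library as GMT: one set per line, tab-separated
    name, description, members...  UTF-8, Unix newlines."""
    lines = [
        "\t".join([s.term_label, s.description, *map(str, s.members)])
        for s in library.sets
    ]
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)


def read_gmt(path_or_buf) -> GeneSetLibrary:
    """Read a GMT file; each line needs at least name, description and one
    member (an empty description field is tolerated)."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf, encoding="utf-8") as fh:
            text = fh.read()
    sets = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line {lineno} has fewer than 3 fields")
        sets.append(GeneSet(parts[0], parts[1], [m for m in parts[2:] if m != ""]))
    lib = GeneSetLibrary(sets)
    lib.direction_split = any(
        s.term_label.endswith((UP_SUFFIX, DOWN_SUFFIX)) for s in sets
    )
    return lib


def library_to_matrix(library: GeneSetLibrary, gene_ids=None) -> GeneAttributeMatrix:
    """Invert a gene-set library back to a thresholded matrix.

    ``_up``/``_down`` set pairs recombine into signed ternary columns.
    """
    columns: dict = {}
    signed = False
    for s in library.sets:
        label, sign = s.term_label, 1.0
        if label.endswith(UP_SUFFIX):
            label, sign, signed = label[: -len(UP_SUFFIX)], 1.0, True
        elif label.endswith(DOWN_SUFFIX):
            label, sign, signed = label[: -len(DOWN_SUFFIX)], -1.0, True
        col = columns.setdefault(label, {})
        for m in s.members:
            col[m] = sign
    attribute_ids = list(columns)
    if gene_ids is None:
        gene_ids = list(dict.fromkeys(m for col in columns.values() for m in col))
    grid = np.zeros((len(gene_ids), len(attribute_ids)))
    gpos = {g: i for i, g in enumerate(gene_ids)}
    for j, label in enumerate(attribute_ids):
        for m, sign in columns[label].items():
            grid[gpos[m], j] = sign
    return GeneAttributeMatrix(
        gene_ids, attribute_ids, grid, "ternary" if signed else "binary"
    )
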