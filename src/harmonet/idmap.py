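"""Identifier mapping to canonical gene ids and symbols.

Heterogeneous datasets label genes with symbols (current, retired or
synonymous), Ensembl gene ids, UniProt accessions, genomic coordinates or
microarray probeset ids.  Everything is converted to a canonical
(gene_id, symbol) pair through mapping tables.  Two filters keep symbol
tables unambiguous: synonyms that map to more than one gene id are dropped,
and synonyms identical to an official symbol are dropped (the official
symbol already claims that string).  Chained id spaces (probeset ->
ensembl -> gene id) are handled by relational composition with the
ambiguity filter re-applied after the join.  Every application of a table
to a matrix emits a report with the unmapped fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import GeneAttributeMatrix

ID_SPACES = (
    "symbol",
    "gene_id",
    "ensembl_gene",
    "uniprot_acc",
    "genomic_coordinate",
    "probeset",
)


@dataclass
class MappingEntry:
    source_identifier: str
    target_gene_id: "int | str"
    target_symbol: str
    source_authority: str = ""


@dataclass
class MappingTable:
    """Finalized identifier -> (gene id, symbol) mapping.

    A finalized table is functional: no source identifier maps to more than
    one target gene id, and in symbol space no source identifier collides
    with an official symbol.
    """

    entries: list
    id_space: str = "symbol"
    n_dropped_ambiguous: int = 0
    n_dropped_official_collision: int = 0

    def __post_init__(self) -> None:
        if self.id_space not in ID_SPACES:
            raise ValueError(f"unknown id space {self.id_space!r}")
        sources = [e.source_identifier for e in self.entries]
        if len(set(sources)) != len(sources):
            raise ValueError("finalized table has a multiply-mapped source identifier")
        self._index = {e.source_identifier: e for e in self.entries}
        self._index_ci = {}
        for e in self.entries:
            self._index_ci.setdefault(str(e.source_identifier).casefold(), e)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, source_id: str) -> bool:
        return source_id in self._index

    def lookup(self, source_id: str, case_insensitive_fallback: bool = True):
        """Resolve one identifier; exact case first, then (for symbol-space
        tables) a case-insensitive fallback.  Returns None if unmapped."""
        hit = self._index.get(source_id)
        if hit is None and case_insensitive_fallback and self.id_space == "symbol":
            hit = self._index_ci.get(str(source_id).casefold())
        return hit

    @classmethod
    def from_tsv(cls, path_or_buf, id_space: str = "symbol") -> "MappingTable":
        """Read a tab-delimited table with header line and columns
        (source_id, target_gene_id, target_symbol[, authority])."""
        frame = pd.read_csv(path_or_buf, sep="\t", dtype=str).fillna("")
        entries = []
        for _, row in frame.iterrows():
            vals = row.tolist()
            entries.append(
                MappingEntry(
                    source_identifier=str(vals[0]),
                    target_gene_id=_coerce_gene_id(vals[1]),
                    target_symbol=str(vals[2]) if len(vals) > 2 else "",
                    source_authority=str(vals[3]) if len(vals) > 3 else "",
                )
            )
        return cls(entries=entries, id_space=id_space)

    def to_tsv(self, path_or_buf) -> None:
        frame = pd.DataFrame(
            [
                (e.source_identifier, e.target_gene_id, e.target_symbol, e.source_authority)
                for e in self.entries
            ],
            columns=["source_id", "target_gene_id", "target_symbol", "authority"],
        )
        frame.to_csv(path_or_buf, sep="\t", index=False)


def _coerce_gene_id(value):
    try:
        return int(value)
    except (TypeError, ValueError):
        return str(value)


@dataclass
class MappingReport:
    """Accounting for one mapping pass: n_mapped + n_unmapped = n_input."""

    n_input: int = 0
    n_mapped: int = 0
    n_dropped_ambiguous: int = 0
    n_unmapped: int = 0
    unmapped_examples: list = field(default_factory=list)

    @property
    def unmapped_fraction(self) -> float:
        return self.n_unmapped / self.n_input if self.n_input else 0.0

    def validate(self) -> None:
        if self.n_mapped + self.n_unmapped != self.n_input:
            raise AssertionError("mapping report does not conserve identifiers")

    def to_text(self) -> str:
        return (
            f"n_input\t{self.n_input}\n"
            f"n_mapped\t{self.n_mapped}\n"
            f"n_dropped_ambiguous\t{self.n_dropped_ambiguous}\n"
            f"n_unmapped\t{self.n_unmapped}\n"
            f"unmapped_fraction\t{self.unmapped_fraction:.6g}\n"
            f"unmapped_examples\t{','.join(self.unmapped_examples[:20])}\n"
        )


def parse_synonym_source(text_or_lines, authority: str = ""):
    """Parse a raw synonym list from two-/three-column tab-delimited text:
    (synonym, gene_id[, official_symbol]) per line."""
    if isinstance(text_or_lines, str):
        lines = text_or_lines.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in text_or_lines]
    rows = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed synonym line {lineno}: {line!r}")
        synonym = parts[0].strip()
        try:
            gene_id = int(parts[1])
        except ValueError as exc:
            raise ValueError(f"malformed gene id on line {lineno}: {parts[1]!r}") from exc
        official = parts[2].strip() if len(parts) > 2 else ""
        rows.append((synonym, gene_id, official, authority))
    return rows


def build_symbol_table(sources) -> MappingTable:
    """Build a finalized symbol -> (gene id, official symbol) table.

    ``sources`` is a list of synonym row lists, each row
    (synonym, gene_id, official_symbol[, authority]).  The union is
    filtered: synonyms mapping to more than one distinct gene id are
    removed as ambiguous, and synonyms identical (case-sensitive) to any
    official symbol are removed — the official symbols themselves are then
    added as identity entries so current symbols still resolve.
    """
    by_synonym: dict = {}
    official_by_id: dict = {}
    official_symbols: set = set()
    n_rows = 0
    for source in sources:
        for row in source:
            synonym, gene_id, official = row[0], row[1], row[2]
            authority = row[3] if len(row) > 3 else ""
            n_rows += 1
            by_synonym.setdefault(synonym, {})[gene_id] = authority
            if official:
                official_symbols.add(official)
                official_by_id.setdefault(gene_id, official)
    if n_rows == 0:
        raise ValueError("empty synonym source union")

    entries = []
    n_ambiguous = 0
    n_collisions = 0
    for synonym in by_synonym:
        targets = by_synonym[synonym]
        if len(targets) > 1:
            n_ambiguous += 1
            continue
        if synonym in official_symbols:
            n_collisions += 1
            continue
        (gene_id, authority), = targets.items()
        entries.append(
            MappingEntry(
                source_identifier=synonym,
                target_gene_id=gene_id,
                target_symbol=official_by_id.get(gene_id, ""),
                source_authority=authority,
            )
        )
    # official symbols map to themselves (identity route)
    for gene_id, official in official_by_id.items():
        if all(e.source_identifier != official for e in entries):
            entries.append(
                MappingEntry(official, gene_id, official, "official")
            )
    return MappingTable(
        entries=entries,
        id_space="symbol",
        n_dropped_ambiguous=n_ambiguous,
        n_dropped_official_collision=n_collisions,
    )


def compose_tables(a: MappingTable, b: MappingTable, id_space: "str | None" = None) -> MappingTable:
    """Relational join: a maps X -> Y, b maps Y -> gene id; result maps
    X -> gene id.  Sources whose join paths reach more than one final gene
    id are dropped and counted; dangling intermediates leave the source
    unmapped (absent from the result)."""
    entries = []
    n_ambiguous = 0
    for e in a.entries:
        hit = b._index.get(str(e.target_gene_id)) or b._index.get(e.target_gene_id)
        if hit is None:
            # intermediate key may be stored as int or str
            hit = b._index.get(_coerce_gene_id(e.target_gene_id))
        if hit is None:
            continue
        entries.append(
            MappingEntry(
                source_identifier=e.source_identifier,
                target_gene_id=hit.target_gene_id,
                target_symbol=hit.target_symbol,
                source_authority=e.source_authority or hit.source_authority,
            )
        )
    # re-apply the ambiguity filter post-join
    seen: dict = {}
    for e in entries:
        seen.setdefault(e.source_identifier, set()).add(e.target_gene_id)
    final = [e for e in entries if len(seen[e.source_identifier]) == 1]
    # deduplicate identical rows
    uniq: dict = {}
    for e in final:
        uniq.setdefault(e.source_identifier, e)
    n_ambiguous = len([s for s, t in seen.items() if len(t) > 1])
    return MappingTable(
        entries=list(uniq.values()),
        id_space=id_space or a.id_space,
        n_dropped_ambiguous=n_ambiguous,
    )


def compose_multimap(a_pairs, b: MappingTable, id_space: str) -> MappingTable:
    """Compose a multi-valued first leg (e.g. a probeset annotation listing
    several intermediate ids per probe) with a finalized second leg.

    ``a_pairs`` is an iterable of (source_id, intermediate_id).  A source
    whose surviving paths reach more than one final gene id is dropped as
    ambiguous."""
    reach: dict = {}
    for src, mid in a_pairs:
        hit = b._index.get(mid, b._index.get(_coerce_gene_id(mid)))
        if hit is not None:
            reach.setdefault(src, {})[hit.target_gene_id] = hit
    entries = []
    n_ambiguous = 0
    for src, hits in reach.items():
        if len(hits) > 1:
            n_ambiguous += 1
            continue
        (gid, hit), = hits.items()
        entries.append(MappingEntry(src, gid, hit.target_symbol))
    return MappingTable(entries=entries, id_space=id_space, n_dropped_ambiguous=n_ambiguous)


def _apply_table(matrix, resolve, collapse="average"):
    """Shared row-relabeling logic: translate, drop unmapped, collapse dups."""
    from .harmonize import _collapse_duplicates

    if matrix.n_genes == 0:
        raise ValueError("cannot map an empty matrix")
    report = MappingReport(n_input=matrix.n_genes)
    new_labels = []
    keep_rows = []
    for i, gene in enumerate(matrix.gene_ids):
        target = resolve(gene)
        if target is None:
            report.n_unmapped += 1
            if len(report.unmapped_examples) < 20:
                report.unmapped_examples.append(str(gene))
            continue
        report.n_mapped += 1
        new_labels.append(target)
        keep_rows.append(i)
    report.validate()
    if not keep_rows:
        out = matrix.copy_with(values=matrix.values[:0], gene_ids=[])
        return out, report
    values = matrix.values[keep_rows]
    labels, collapsed = _collapse_duplicates(
        new_labels, values, axis=0, how=collapse
    )
    out = GeneAttributeMatrix(
        labels, matrix.attribute_ids, collapsed, matrix.value_kind, dict(matrix.metadata)
    )
    out.log_step(
        "map_identifiers",
        n_input=report.n_input,
        n_mapped=report.n_mapped,
        n_unmapped=report.n_unmapped,
        collapse=collapse,
    )
    return out, report


def map_matrix_identifiers(
    matrix: GeneAttributeMatrix,
    table: MappingTable,
    collapse: str = "average",
    target: str = "symbol",
):
    """Translate matrix row labels through a finalized mapping table.

    Unmapped rows are discarded (and reported); rows landing on the same
    canonical label are collapsed by ``average`` (nan-mean) or ``max_abs``
    (largest-magnitude value wins).  ``target`` picks whether rows are
    relabeled with canonical symbols or gene ids.
    """
    if collapse not in ("average", "max_abs"):
        raise ValueError(f"unknown collapse policy {collapse!r}")

    def resolve(gene):
        hit = table.lookup(gene)
        if hit is None:
            return None
        return hit.target_symbol if target == "symbol" else hit.target_gene_id

    return _apply_table(matrix, resolve, collapse)


def map_homologs(matrix: GeneAttributeMatrix, homolog_table: MappingTable):
    """Convert row gene ids across species via a homolog table (gene_id ->
    gene_id).  Rows without a homolog are dropped and counted; many-to-one
    collapses resolve by averaging rows."""
    if homolog_table.id_space != "gene_id":
        raise ValueError("homolog table must be in gene_id space")

    def resolve(gene):
        hit = homolog_table.lookup(gene, case_insensitive_fallback=False)
        if hit is None:
            hit = homolog_table._index.get(_coerce_gene_id(gene))
        return None if hit is None else hit.target_gene_id

    return _apply_table(matrix, resolve, collapse="average")
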