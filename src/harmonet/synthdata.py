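"""Seeded synthetic fixtures with the structure the toolkit assumes.

Three generators make the whole pipeline testable without downloading any
real dataset:

* :func:`make_planted_matrix` — block-structured gene x attribute matrices
  with planted gene modules and attribute clusters plus Gaussian noise,
  emulating the clustered-heat-map phenomenology of real association data;
* :func:`make_mapping_fixture` — synonym tables with injected ambiguous
  symbols and official-symbol collisions, together with the finalized
  table the filters should produce;
* :func:`make_gba_fixture` — a guilt-by-association task whose positive
  class (and a hidden fraction of the "unknown" class) shares elevated
  attribute signatures across several datasets.

Every generator is a pure function of its parameters and seed: reruns are
bit-identical, and the planted ground truth is returned alongside the data
so downstream tests are self-validating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .idmap import MappingEntry, MappingTable, build_symbol_table
from .matrix import GeneAttributeMatrix


@dataclass
class FixtureSpec:
    """Parameters of a planted block-structure matrix.

    within_module_signal is the mean of in-module cells; noise_sd the
    Gaussian noise standard deviation; sparsity the fraction of cells set
    unobserved.
    """

    n_genes: int = 60
    n_attributes: int = 40
    n_modules: int = 3
    within_module_signal: float = 3.0
    noise_sd: float = 1.0
    sparsity: float = 0.0
    signed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_attributes, self.n_modules) <= 0:
            raise ValueError("counts must be positive")
        if not (0 <= self.sparsity <= 1):
            raise ValueError("sparsity must lie in [0, 1]")
        if self.n_modules > min(self.n_genes, self.n_attributes):
            raise ValueError("more modules than genes or attributes")


def make_planted_matrix(spec: FixtureSpec):
    """Generate a module-structured continuous matrix plus ground truth.

    Genes and attributes are partitioned into ``n_modules`` groups; cells
    whose gene and attribute share a module get mean ``within_module_signal``
    (sign alternating by module when ``signed``), all others mean 0.

    Returns ``(matrix, truth)`` where ``truth`` maps ``"gene_modules"`` and
    ``"attribute_modules"`` to per-label module indices.
    """
    rng = np.random.default_rng(spec.seed)
    gene_modules = np.arange(spec.n_genes) % spec.n_modules
    attr_modules = np.arange(spec.n_attributes) % spec.n_modules
    # interleaved assignment, then labels sorted by module for readability
    gene_modules = np.sort(gene_modules)
    attr_modules = np.sort(attr_modules)

    mean = np.zeros((spec.n_genes, spec.n_attributes))
    for m in range(spec.n_modules):
        sign = -1.0 if (spec.signed and m % 2 == 1) else 1.0
        block = np.outer(gene_modules == m, attr_modules == m)
        mean += sign * spec.within_module_signal * block
    values = mean + rng.normal(0.0, spec.noise_sd, mean.shape) if spec.noise_sd > 0 else mean.copy()

    if spec.sparsity > 0:
        drop = rng.random(values.shape) < spec.sparsity
        values[drop] = np.nan

    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    attrs = [f"A{j:04d}" for j in range(spec.n_attributes)]
    matrix = GeneAttributeMatrix(
        genes, attrs, values, "raw_continuous",
        metadata={"name": f"planted_seed{spec.seed}", "sign_allowed": spec.signed},
    )
    truth = {
        "gene_modules": dict(zip(genes, gene_modules.tolist())),
        "attribute_modules": dict(zip(attrs, attr_modules.tolist())),
    }
    return matrix, truth


def make_mapping_fixture(
    n_genes: int = 50,
    n_synonyms: int = 100,
    n_ambiguous: int = 5,
    n_official_collisions: int = 3,
    seed: int = 0,
):
    """Synonym sources with injected pathologies plus the expected table.

    Exactly ``n_ambiguous`` synonyms map to two distinct gene ids and
    exactly ``n_official_collisions`` synonyms equal another gene's
    official symbol; the expected finalized table excludes precisely those.

    Returns ``(sources, expected_table, truth)`` where ``truth`` lists the
    injected identifiers.
    """
    if n_ambiguous + n_official_collisions > n_synonyms:
        raise ValueError("more pathological synonyms than synonyms")
    if n_official_collisions > n_genes - 1:
        raise ValueError("collisions need distinct owner genes")
    rng = np.random.default_rng(seed)
    gene_ids = list(range(1001, 1001 + n_genes))
    officials = {gid: f"GENE{gid}" for gid in gene_ids}

    # one retired-symbol anchor per gene so every official symbol is known
    anchor_rows = [(f"RET{gid}", gid, officials[gid]) for gid in gene_ids]
    expected_entries = [MappingEntry(s, g, o) for s, g, o in anchor_rows]

    clean_rows = []
    n_clean = n_synonyms - n_ambiguous - n_official_collisions
    for k in range(n_clean):
        gid = gene_ids[int(rng.integers(n_genes))]
        syn = f"SYN{k:04d}"
        clean_rows.append((syn, gid, officials[gid]))
        expected_entries.append(MappingEntry(syn, gid, officials[gid]))

    ambiguous_rows = []
    ambiguous_syns = []
    for k in range(n_ambiguous):
        g1, g2 = rng.choice(gene_ids, size=2, replace=False)
        syn = f"AMB{k:04d}"
        ambiguous_syns.append(syn)
        ambiguous_rows.append((syn, int(g1), officials[int(g1)]))
        ambiguous_rows.append((syn, int(g2), officials[int(g2)]))

    # each collision borrows a distinct owner's official symbol as a
    # synonym for some other (victim) gene
    owners = rng.choice(gene_ids, size=n_official_collisions, replace=False)
    collision_rows = []
    collision_syns = []
    for owner in owners:
        victim = int(rng.choice([g for g in gene_ids if g != owner]))
        syn = officials[int(owner)]
        collision_syns.append(syn)
        collision_rows.append((syn, victim, officials[victim]))

    # official symbols resolve to themselves in the finalized table
    for gid in gene_ids:
        expected_entries.append(MappingEntry(officials[gid], gid, officials[gid], "official"))

    sources = [anchor_rows + clean_rows, ambiguous_rows + collision_rows]
    expected = MappingTable(
        entries=expected_entries,
        id_space="symbol",
        n_dropped_ambiguous=n_ambiguous,
        n_dropped_official_collision=n_official_collisions,
    )
    truth = {"ambiguous": ambiguous_syns, "collisions": collision_syns}
    return sources, expected, truth


def make_gba_fixture(
    n_pos: int = 100,
    n_neg: int = 100,
    n_unknown: int = 100,
    n_datasets: int = 3,
    n_attributes: int = 30,
    informative_per_dataset: int = 5,
    effect_size: float = 3.0,
    hidden_positive_fraction: float = 0.2,
    seed: int = 0,
):
    """A planted guilt-by-association task.

    Positive genes — and a hidden ``hidden_positive_fraction`` of the
    unknown genes — receive a mean shift of ``effect_size`` noise-sd units
    on ``informative_per_dataset`` attributes in each dataset; negatives
    and the remaining unknowns are pure noise.

    Returns ``(datasets, labels, hidden_positives)``: the per-dataset
    matrices, a gene -> {positive, negative, unknown} dict and the set of
    unknown genes that secretly carry the positive signature.
    """
    if informative_per_dataset > n_attributes:
        raise ValueError("more informative attributes than attributes")
    rng = np.random.default_rng(seed)
    genes = (
        [f"POS{i:04d}" for i in range(n_pos)]
        + [f"NEG{i:04d}" for i in range(n_neg)]
        + [f"UNK{i:04d}" for i in range(n_unknown)]
    )
    labels = {g: "positive" for g in genes[:n_pos]}
    labels.update({g: "negative" for g in genes[n_pos : n_pos + n_neg]})
    labels.update({g: "unknown" for g in genes[n_pos + n_neg :]})

    n_hidden = int(round(hidden_positive_fraction * n_unknown))
    unknown_genes = genes[n_pos + n_neg :]
    hidden = set(
        rng.choice(unknown_genes, size=n_hidden, replace=False).tolist()
    ) if n_hidden else set()
    carries_signal = np.array(
        [labels[g] == "positive" or g in hidden for g in genes]
    )

    datasets = []
    for d in range(n_datasets):
        informative = rng.choice(n_attributes, size=informative_per_dataset, replace=False)
        values = rng.normal(0.0, 1.0, (len(genes), n_attributes))
        shift = np.zeros((1, n_attributes))
        shift[0, informative] = effect_size
        values = values + carries_signal[:, None] * shift
        attrs = [f"D{d}_A{j:03d}" for j in range(n_attributes)]
        datasets.append(
            GeneAttributeMatrix(
                list(genes), attrs, values, "raw_continuous",
                metadata={"name": f"gba_dataset_{d}",
                          "informative_attributes": [attrs[j] for j in informative]},
            )
        )
    return datasets, labels, hidden


def make_mapping_table_fixture_files(sources, out_dir):
    """Write raw synonym sources as two-/three-column TSV files."""
    import os

    paths = []
    for i, rows in enumerate(sources):
        path = os.path.join(out_dir, f"synonyms_{i}.tsv")
        with open(path, "w", encoding="utf-8") as fh:
            for syn, gid, official in rows:
                fh.write(f"{syn}\t{gid}\t{official}\n")
        paths.append(path)
    return paths
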