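"""Build a symbol-mapping table with ambiguity filters and apply it.

Synonym lists often contain symbols that point at two different genes, or
reuse another gene's official symbol; both are dropped before mapping.
"""

import numpy as np

import harmonet as hn

sources, expected, truth = hn.make_mapping_fixture(
    n_genes=30, n_synonyms=60, n_ambiguous=4, n_official_collisions=2, seed=1
)
table = hn.build_symbol_table(sources)
print(f"finalized table: {len(table)} entries; dropped "
      f"{table.n_dropped_ambiguous} ambiguous synonyms "
      f"({', '.join(truth['ambiguous'])}) and "
      f"{table.n_dropped_official_collision} official-symbol collisions")

rng = np.random.default_rng(1)
genes = [e.source_identifier for e in table.entries[:12]] + ["NOT_A_GENE"]
matrix = hn.GeneAttributeMatrix(
    genes, ["tissue_a", "tissue_b"], rng.random((13, 2)), "raw_continuous"
)
mapped, report = hn.map_matrix_identifiers(matrix, table)
print(f"mapped {report.n_mapped}/{report.n_input} row identifiers "
      f"({100 * report.unmapped_fraction:.1f}% unmapped: "
      f"{report.unmapped_examples}); rows landing on the same canonical "
      f"symbol were averaged, leaving {mapped.n_genes} rows")
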