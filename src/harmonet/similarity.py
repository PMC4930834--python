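"""Cosine-similarity matrices and deterministic clustering orders.

Functional similarity between genes (or between attributes) is measured as
the cosine of their association profiles: S(i, j) = <vi, vj> / (|vi||vj|).
On thresholded matrices this reduces to a normalized overlap of association
sets; on ternary matrices same-sign overlaps add and opposite-sign overlaps
subtract.  Cross-dataset matrices compare attributes of one dataset to
attributes of another on the intersection of their gene universes.
Hierarchical clustering (average linkage on 1 - similarity) supplies the
leaf orderings used to render the block structure in heat maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform


@dataclass
class SimilarityMatrix:
    """Square or rectangular cosine-similarity grid with labels."""

    row_labels: list
    col_labels: list
    values: np.ndarray
    axis_kind: str = "gene_gene"  # gene_gene | attribute_attribute | cross_dataset
    row_order: "list | None" = None
    col_order: "list | None" = None
    zero_norm_rows: list = field(default_factory=list)
    zero_norm_cols: list = field(default_factory=list)
    n_shared_genes: "int | None" = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("similarity grid shape does not match labels")

    @property
    def is_square(self) -> bool:
        return self.axis_kind in ("gene_gene", "attribute_attribute")

    def to_frame(self, clustered: bool = False) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)
        if clustered and self.row_order is not None:
            frame = frame.iloc[self.row_order, :]
        if clustered and self.col_order is not None:
            frame = frame.iloc[:, self.col_order]
        return frame

    def to_tsv(self, path_or_buf, clustered: bool = False) -> None:
        self.to_frame(clustered=clustered).to_csv(path_or_buf, sep="\t")

    def to_edge_list(self, min_abs_similarity: float = 0.0) -> pd.DataFrame:
        """Pairwise (label_i, label_j, similarity) rows with |s| >= cutoff.

        For square matrices only the upper triangle (i < j) is emitted.
        """
        rows = []
        n_r, n_c = self.values.shape
        for i in range(n_r):
            start = i + 1 if self.is_square else 0
            for j in range(start, n_c):
                s = self.values[i, j]
                if abs(s) >= min_abs_similarity:
                    rows.append((self.row_labels[i], self.col_labels[j], s))
        return pd.DataFrame(rows, columns=["label_a", "label_b", "similarity"])


def _cosine(vectors: np.ndarray, other: "np.ndarray | None" = None):
    """Cosine similarity between rows of ``vectors`` (and ``other``);
    zero-norm rows get similarity 0 with every partner."""
    a = np.nan_to_num(np.asarray(vectors, dtype=float), nan=0.0)
    b = a if other is None else np.nan_to_num(np.asarray(other, dtype=float), nan=0.0)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    safe_a = np.where(na == 0, 1.0, na)
    safe_b = np.where(nb == 0, 1.0, nb)
    sims = (a @ b.T) / np.outer(safe_a, safe_b)
    sims[na == 0, :] = 0.0
    sims[:, nb == 0] = 0.0
    np.clip(sims, -1.0, 1.0, out=sims)
    return sims, na == 0, nb == 0


def cosine_similarity_matrix(matrix, axis: str = "rows") -> SimilarityMatrix:
    """Gene-gene (axis="rows") or attribute-attribute (axis="columns")
    cosine-similarity matrix of a standardized or thresholded dataset."""
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    if axis == "rows":
        vectors = matrix.materialized()
        labels = list(matrix.gene_ids)
        kind = "gene_gene"
    else:
        vectors = matrix.materialized().T
        labels = list(matrix.attribute_ids)
        kind = "attribute_attribute"
    if vectors.shape[0] < 2:
        raise ValueError(f"need at least 2 {axis} to compare")
    sims, zero_r, _ = _cosine(vectors)
    # exact symmetry and exact unit diagonal for nonzero vectors
    sims = (sims + sims.T) / 2.0
    idx = np.flatnonzero(~zero_r)
    sims[idx, idx] = 1.0
    flagged = [labels[i] for i in np.flatnonzero(zero_r)]
    return SimilarityMatrix(labels, labels, sims, kind, zero_norm_rows=flagged, zero_norm_cols=flagged)


def cross_dataset_similarity(a, b, min_shared_genes: int = 10) -> SimilarityMatrix:
    """Compare attributes of dataset ``a`` to attributes of dataset ``b``
    by the cosine of their gene-association vectors, restricted to the
    intersection of the two gene universes."""
    shared = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"gene intersection has {len(shared)} genes; "
            f"need at least {min_shared_genes}"
        )
    fa = a.to_frame().loc[shared]
    fb = b.to_frame().loc[shared]
    va = np.nan_to_num(fa.to_numpy(), nan=0.0).T  # attributes x shared genes
    vb = np.nan_to_num(fb.to_numpy(), nan=0.0).T
    sims, zero_r, zero_c = _cosine(va, vb)
    return SimilarityMatrix(
        list(a.attribute_ids),
        list(b.attribute_ids),
        sims,
        "cross_dataset",
        zero_norm_rows=[a.attribute_ids[i] for i in np.flatnonzero(zero_r)],
        zero_norm_cols=[b.attribute_ids[i] for i in np.flatnonzero(zero_c)],
        n_shared_genes=len(shared),
    )


def _leaf_order(square_sims: np.ndarray, labels) -> list:
    """Average-linkage leaf order on distance 1 - similarity.

    Determinism: rows are first put in label-sorted order so identical
    inputs (up to label permutation) produce identical leaf sequences.
    """
    n = len(labels)
    if n == 1:
        return [0]
    rank = sorted(range(n), key=lambda i: str(labels[i]))
    sims = square_sims[np.ix_(rank, rank)]
    dist = 1.0 - sims
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    condensed = squareform(dist, checks=False)
    order_in_sorted = leaves_list(linkage(condensed, method="average"))
    return [rank[i] for i in order_in_sorted]


def hierarchical_order(sim: SimilarityMatrix):
    """Deterministic agglomerative-clustering leaf orderings for heat maps.

    Returns (row_order, col_order) permutations and stores them on ``sim``.
    Square matrices get one ordering applied to both axes; rectangular
    matrices are clustered on each axis via the cosine similarity of their
    own similarity profiles.
    """
    if not np.isfinite(sim.values).all():
        raise ValueError("similarity matrix contains non-finite values")
    if sim.is_square:
        order = _leaf_order(sim.values, sim.row_labels)
        sim.row_order = list(order)
        sim.col_order = list(order)
    else:
        row_profile, _, _ = _cosine(sim.values)
        col_profile, _, _ = _cosine(sim.values.T)
        sim.row_order = _leaf_order(row_profile, sim.row_labels)
        sim.col_order = _leaf_order(col_profile, sim.col_labels)
    return sim.row_order, sim.col_order
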