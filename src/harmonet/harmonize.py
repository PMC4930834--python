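"""Standardization and thresholding of gene-attribute matrices.

Continuous-valued datasets arrive on arbitrary scales.  The harmonization
strategy maps every dataset onto a common score scale by replacing each
observed value with its empirical cumulative probability,

    p(v) = #{observed x : x <= v} / #observed,

pooled either over the whole matrix or gene-by-gene: if the per-gene medians
differ, each gene's row is standardized against its own distribution,
otherwise all values are pooled at once.  For datasets where sign is
meaningful (e.g. up-/down-regulation) the probabilities are mapped to
``2p - 1`` so scores range over [-1, 1] with 0 meaning no association.
Finally a threshold retains only the strongest fraction (default 10%) of
observed associations, yielding a binary {0,1} or ternary {-1,0,+1} matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .matrix import GeneAttributeMatrix, ValueKind


@dataclass
class StandardizationConfig:
    """Controls the ECDF standardization step.

    sign_allowed : map probabilities to [-1, 1] via ``2p - 1``.
    mode : ``auto`` (median rule decides), ``global`` or ``per_gene``.
    median_tolerance : relative tolerance when comparing per-gene medians.
    zero_is_unobserved : treat stored zeros as unobserved entries.
    """

    sign_allowed: bool = False
    mode: str = "auto"
    median_tolerance: float = 1e-9
    zero_is_unobserved: bool = False

    def __post_init__(self) -> None:
        if self.median_tolerance < 0:
            raise ValueError("median_tolerance must be nonnegative")
        if self.mode not in ("auto", "global", "per_gene"):
            raise ValueError(f"unknown standardization mode {self.mode!r}")


@dataclass
class ThresholdConfig:
    """Controls how the strongest associations are retained.

    retain_fraction : fraction of observed entries kept (default 0.10).
    ranking : ``absolute_value`` ranks by |s| (so strong negative
        associations survive); ``value`` ranks by the signed score.
    tie_policy : ``stable_index`` breaks boundary ties by row-major
        position (exactly ``floor(f * N)`` entries retained);
        ``keep_all_tied`` also keeps every entry tied with the cutoff.
    """

    retain_fraction: float = 0.10
    ranking: str = "absolute_value"
    tie_policy: str = "stable_index"

    def __post_init__(self) -> None:
        if not (0 < self.retain_fraction <= 1):
            raise ValueError("retain_fraction must lie in (0, 1]")
        if self.ranking not in ("absolute_value", "value"):
            raise ValueError(f"unknown ranking {self.ranking!r}")
        if self.tie_policy not in ("stable_index", "keep_all_tied"):
            raise ValueError(f"unknown tie_policy {self.tie_policy!r}")


def _working_values(matrix: GeneAttributeMatrix, config: StandardizationConfig) -> np.ndarray:
    vals = np.array(matrix.values, dtype=float)
    if config.zero_is_unobserved:
        vals[vals == 0.0] = np.nan
    return vals


def select_standardization_mode(
    matrix: GeneAttributeMatrix,
    config: StandardizationConfig,
    report: "dict | None" = None,
) -> str:
    """Resolve the pooling mode for ECDF standardization.

    With ``config.mode == "auto"`` the median rule applies: if any two
    rows' medians of observed values differ by more than the tolerance the
    probabilities are computed gene-by-gene, otherwise globally.  Rows with
    no observed values are excluded from the comparison and flagged in
    ``report`` (key ``"rows_without_observations"``).
    """
    if config.mode != "auto":
        return config.mode
    vals = _working_values(matrix, config)
    if np.isnan(vals).all():
        raise ValueError("no observed values")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        medians = np.nanmedian(vals, axis=1)
    empty_rows = [matrix.gene_ids[i] for i in np.flatnonzero(np.isnan(medians))]
    if report is not None:
        report["rows_without_observations"] = empty_rows
    medians = medians[~np.isnan(medians)]
    if medians.size <= 1:
        return "global"
    lo, hi = medians.min(), medians.max()
    scale = max(abs(lo), abs(hi), 1.0)
    return "per_gene" if (hi - lo) > config.median_tolerance * scale else "global"


def _ecdf(pool: np.ndarray) -> np.ndarray:
    """Right-continuous ECDF values p = #(x <= v)/n for each v in pool."""
    return rankdata(pool, method="max") / pool.size


def ecdf_standardize(
    matrix: GeneAttributeMatrix, config: "StandardizationConfig | None" = None
) -> GeneAttributeMatrix:
    """Replace observed values by empirical cumulative probabilities.

    The counting pool is the whole matrix (``global``) or each value's row
    (``per_gene``), resolved by :func:`select_standardization_mode`.
    Unobserved entries stay unobserved.  With ``sign_allowed`` the
    probabilities are doubled and shifted to [-1, 1].  The maximum observed
    output is exactly 1 in either case.
    """
    config = config or StandardizationConfig()
    if matrix.value_kind is ValueKind.raw_discrete:
        raise ValueError(
            "raw_discrete matrices are not ECDF-standardized; pass them to "
            "threshold_associations directly or keep them as-is"
        )
    if matrix.value_kind is not ValueKind.raw_continuous:
        raise ValueError(f"expected raw_continuous input, got {matrix.value_kind.value}")

    vals = _working_values(matrix, config)
    mask = ~np.isnan(vals)
    if not mask.any():
        raise ValueError("no observed values")
    mode = select_standardization_mode(matrix, config)

    out = np.full(vals.shape, np.nan)
    if mode == "global":
        out[mask] = _ecdf(vals[mask])
    else:
        for i in range(vals.shape[0]):
            row_mask = mask[i]
            if row_mask.any():
                out[i, row_mask] = _ecdf(vals[i, row_mask])

    if config.sign_allowed:
        out = np.where(np.isnan(out), np.nan, 2.0 * out - 1.0)
        kind = ValueKind.standardized_signed
    else:
        kind = ValueKind.standardized_unsigned

    result = matrix.copy_with(values=out, value_kind=kind)
    result.log_step(
        "ecdf_standardize", mode=mode, sign_allowed=config.sign_allowed
    )
    return result


def threshold_associations(
    matrix: GeneAttributeMatrix, config: "ThresholdConfig | None" = None
) -> GeneAttributeMatrix:
    """Retain only the strongest fraction of observed associations.

    Observed entries are ranked (by |s| under ``absolute_value`` ranking)
    and the top ``floor(retain_fraction * N_observed)`` become 1 (unsigned
    input -> binary) or keep their sign as +/-1 (signed input -> ternary);
    everything else becomes 0.
    """
    config = config or ThresholdConfig()
    if matrix.is_thresholded:
        raise ValueError("matrix is already thresholded")
    if matrix.value_kind not in (
        ValueKind.standardized_unsigned,
        ValueKind.standardized_signed,
    ):
        raise ValueError(
            f"expected a standardized matrix, got {matrix.value_kind.value}"
        )

    vals = matrix.values
    mask = ~np.isnan(vals)
    flat_idx = np.flatnonzero(mask.ravel())  # row-major positions of observed
    obs = vals.ravel()[flat_idx]
    n_obs = obs.size
    n_keep = math.floor(config.retain_fraction * n_obs)

    key = np.abs(obs) if config.ranking == "absolute_value" else obs
    # stable sort on -key keeps row-major order among ties
    order = np.argsort(-key, kind="stable")
    keep = order[:n_keep]
    if config.tie_policy == "keep_all_tied" and n_keep > 0:
        cutoff = key[order[n_keep - 1]]
        keep = order[key[order] >= cutoff]

    out = np.zeros(vals.size)
    signed = matrix.value_kind is ValueKind.standardized_signed
    kept_positions = flat_idx[keep]
    if signed:
        out[kept_positions] = np.where(obs[keep] >= 0, 1.0, -1.0)
        kind = ValueKind.ternary
    else:
        out[kept_positions] = 1.0
        kind = ValueKind.binary
    out = out.reshape(vals.shape)

    result = matrix.copy_with(values=out, value_kind=kind)
    result.log_step(
        "threshold_associations",
        retain_fraction=config.retain_fraction,
        ranking=config.ranking,
        tie_policy=config.tie_policy,
        n_retained=int(kept_positions.size),
    )
    return result


# ---------------------------------------------------------------------------
# preprocessing steps


def _step_filter_rows(mat, min_observed=1, min_value=None):
    obs = mat.observed_mask().sum(axis=1)
    keep = obs >= min_observed
    if min_value is not None:
        with np.errstate(all="ignore"):
            keep &= np.nan_to_num(np.nanmax(np.abs(mat.values), axis=1), nan=-np.inf) >= min_value
    dropped = [g for g, k in zip(mat.gene_ids, keep) if not k]
    out = mat.copy_with(
        values=mat.values[keep],
        gene_ids=[g for g, k in zip(mat.gene_ids, keep) if k],
    )
    return out, {"n_dropped": len(dropped), "dropped": dropped[:20]}


def _step_filter_columns(mat, min_observed=1, min_value=None):
    obs = mat.observed_mask().sum(axis=0)
    keep = obs >= min_observed
    if min_value is not None:
        with np.errstate(all="ignore"):
            keep &= np.nan_to_num(np.nanmax(np.abs(mat.values), axis=0), nan=-np.inf) >= min_value
    dropped = [a for a, k in zip(mat.attribute_ids, keep) if not k]
    out = mat.copy_with(
        values=mat.values[:, keep],
        attribute_ids=[a for a, k in zip(mat.attribute_ids, keep) if k],
    )
    return out, {"n_dropped": len(dropped), "dropped": dropped[:20]}


def _collapse_duplicates(labels, values, axis, how="average"):
    """Collapse duplicate labels along an axis by nan-mean or max-|v|."""
    frame_vals = values if axis == 0 else values.T
    seen: dict = {}
    order = []
    for i, lab in enumerate(labels):
        seen.setdefault(lab, []).append(i)
        if len(seen[lab]) == 1:
            order.append(lab)
    rows = []
    for lab in order:
        block = frame_vals[seen[lab]]
        if how == "average":
            with np.errstate(all="ignore"):
                row = np.nanmean(block, axis=0)
        else:  # max_abs
            filled = np.nan_to_num(block, nan=0.0)
            pick = np.argmax(np.abs(filled), axis=0)
            row = filled[pick, np.arange(block.shape[1])]
            row[np.isnan(block).all(axis=0)] = np.nan
        rows.append(row)
    collapsed = np.array(rows)
    return order, (collapsed if axis == 0 else collapsed.T)


def _step_average_rows(mat, **_):
    labels, vals = _collapse_duplicates(mat.gene_ids, mat.values, axis=0)
    out = GeneAttributeMatrix(
        labels, mat.attribute_ids, vals, mat.value_kind, dict(mat.metadata)
    )
    return out, {"n_rows": len(labels)}


def _step_average_columns(mat, **_):
    labels, vals = _collapse_duplicates(mat.attribute_ids, mat.values, axis=1)
    out = GeneAttributeMatrix(
        mat.gene_ids, labels, vals, mat.value_kind, dict(mat.metadata)
    )
    return out, {"n_columns": len(labels)}


def _step_impute(mat, strategy="row_mean", **_):
    vals = np.array(mat.values)
    fully_missing = np.isnan(vals).all(axis=1)
    if fully_missing.any():
        row = mat.gene_ids[int(np.flatnonzero(fully_missing)[0])]
        raise ValueError(f"cannot impute fully-unobserved row {row!r}")
    with np.errstate(all="ignore"):
        if strategy == "row_mean":
            fill = np.nanmean(vals, axis=1, keepdims=True)
        elif strategy == "column_mean":
            fill = np.nanmean(vals, axis=0, keepdims=True)
        else:
            raise ValueError(f"unknown impute strategy {strategy!r}")
    vals = np.where(np.isnan(vals), np.broadcast_to(fill, vals.shape), vals)
    return mat.copy_with(values=vals), {"strategy": strategy}


def _step_log_transform(mat, base=2.0, offset=1.0, **_):
    vals = np.log(mat.values + offset) / np.log(base)
    return mat.copy_with(values=vals), {"base": base, "offset": offset}


def _step_zscore_scale(mat, axis="rows", **_):
    vals = np.array(mat.values)
    ax = 1 if axis == "rows" else 0
    with np.errstate(all="ignore"):
        mu = np.nanmean(vals, axis=ax, keepdims=True)
        sd = np.nanstd(vals, axis=ax, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return mat.copy_with(values=(vals - mu) / sd), {"axis": axis}


def _step_quantile_normalize(mat, **_):
    """Force every column's sorted values onto the mean sorted profile.

    Requires fully observed columns of equal length (the standard form of
    the transform); NaNs are not supported here.
    """
    vals = np.array(mat.values)
    if np.isnan(vals).any():
        raise ValueError("quantile_normalize requires fully observed values; impute first")
    order = np.argsort(vals, axis=0, kind="stable")
    ranks = np.empty_like(order)
    n = vals.shape[0]
    ranks[order, np.arange(vals.shape[1])] = np.arange(n)[:, None]
    mean_profile = np.sort(vals, axis=0).mean(axis=1)
    return mat.copy_with(values=mean_profile[ranks]), {}


_STEPS = {
    "filter_rows": _step_filter_rows,
    "filter_columns": _step_filter_columns,
    "average_rows": _step_average_rows,
    "average_columns": _step_average_columns,
    "impute": _step_impute,
    "log_transform": _step_log_transform,
    "zscore_scale": _step_zscore_scale,
    "quantile_normalize": _step_quantile_normalize,
}


def preprocess(matrix: GeneAttributeMatrix, steps) -> GeneAttributeMatrix:
    """Apply an ordered list of preprocessing steps.

    ``steps`` is a sequence of step names or ``(name, params)`` pairs drawn
    from: filter_rows, filter_columns, average_rows, average_columns,
    impute, log_transform, zscore_scale, quantile_normalize.  Each applied
    step is recorded in the provenance log, mirroring the per-dataset
    processing scripts a curated resource would publish.
    """
    mat = matrix
    for step in steps:
        if isinstance(step, str):
            name, params = step, {}
        else:
            name, params = step
        if name not in _STEPS:
            raise ValueError(f"unknown preprocessing step {name!r}")
        mat, info = _STEPS[name](mat, **params)
        mat.log_step(name, **params, **{k: v for k, v in info.items() if k != "dropped"})
    return mat


def coverage_summary(matrices, dataset_names=None):
    """Gene x dataset grid of relative association counts.

    For each thresholded dataset, a gene's cell is its nonzero-association
    count divided by the dataset's maximum such count, so values lie in
    [0, 1] (0 for genes absent from the dataset).  This is the coverage
    summary grid that reveals knowledge gaps across datasets.
    """
    import pandas as pd

    names = dataset_names or [
        m.metadata.get("name", f"dataset_{i}") for i, m in enumerate(matrices)
    ]
    for m in matrices:
        if not m.is_thresholded:
            raise ValueError("coverage_summary requires thresholded matrices")
    universe = sorted(set().union(*(m.gene_ids for m in matrices)))
    grid = pd.DataFrame(0.0, index=universe, columns=names)
    for name, m in zip(names, matrices):
        counts = (m.materialized() != 0).sum(axis=1).astype(float)
        peak = counts.max()
        if peak > 0:
            counts = counts / peak
        grid.loc[list(m.gene_ids), name] = counts
    return grid
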