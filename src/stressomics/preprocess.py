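"""Data-cleaning chain for longitudinal omics matrices.

Stages, in their usual execution order: k-nearest-neighbour imputation of
missing values, per-variable transforms (log10 / sqrt), batch-median
alignment, within-group (within-animal or within-array) normalization, and
probe filtering against negative-control levels.  Every stage can append to a
:class:`ProvenanceLog` so a run is fully reconstructible from its log.

Functions accept either a :class:`~stressomics.containers.LongitudinalMatrix`
or a bare :class:`pandas.DataFrame` (samples in rows, features in columns)
and return the same kind of object.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import LongitudinalMatrix

__all__ = [
    "ProvenanceLog",
    "TransformSpec",
    "ImputationError",
    "TransformError",
    "AlignmentError",
    "impute_knn",
    "apply_transforms",
    "align_batch_medians",
    "quantile_normalize_within_group",
    "filter_probes",
]


class ImputationError(ValueError):
    pass


class TransformError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


@dataclass
class ProvenanceLog:
    """Ordered machine-readable record of preprocessing operations."""

    entries: list[dict] = field(default_factory=list)

    def record(self, operation: str, **params) -> None:
        self.entries.append({"operation": operation, "params": params})

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for entry in self.entries:
                fh.write(json.dumps(entry) + "\n")


def _unwrap(matrix):
    if isinstance(matrix, LongitudinalMatrix):
        return matrix.values, matrix
    return matrix, None


def _rewrap(values: pd.DataFrame, parent):
    if parent is None:
        return values
    return parent.copy(values=values)


# --------------------------------------------------------------------------- #
# Outlier masking
# --------------------------------------------------------------------------- #
def mask_outliers(matrix, z_threshold: float = 4.0, log: ProvenanceLog | None = None):
    """Set extreme observations to missing, to be handled by imputation.

    A cell is masked when its robust z-score within its variable x time-point
    group (|x - median| / (1.4826 * MAD)) exceeds ``z_threshold``.  Grouping
    by time point keeps genuine kinetic shifts from being flagged.
    """
    values, parent = _unwrap(matrix)
    if parent is None:
        raise ValueError("mask_outliers needs time annotations (LongitudinalMatrix)")
    out = values.copy()
    n_masked = 0
    for _t, idx in values.groupby(parent.time.values).groups.items():
        block = values.loc[idx]
        med = block.median(axis=0, skipna=True)
        mad = (block - med).abs().median(axis=0, skipna=True) * 1.4826
        mad = mad.replace(0.0, np.nan)
        z = ((block - med) / mad).abs()
        flag = z > z_threshold
        n_masked += int(flag.values.sum())
        out.loc[idx] = block.mask(flag)
    if log is not None:
        log.record("mask_outliers", z_threshold=z_threshold, n_masked=n_masked)
    return _rewrap(out, parent)


# --------------------------------------------------------------------------- #
# Imputation
# --------------------------------------------------------------------------- #
def impute_knn(
    matrix,
    k: int = 5,
    weighting: str = "uniform",
    log: ProvenanceLog | None = None,
):
    """k-nearest-neighbour imputation of missing cells.

    Distances between rows are Euclidean on columns standardized to unit
    variance, averaged over the columns observed in both rows.  An imputed
    cell is the plain mean (``weighting='uniform'``, default) or the
    inverse-distance-weighted mean (``weighting='distance'``) of that column's
    values in the ``k`` nearest rows that observe it.  Observed cells are
    never altered.
    """
    if weighting not in ("uniform", "distance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    values, parent = _unwrap(matrix)
    missing = values.isna()
    if not missing.values.any():
        if log is not None:
            log.record("impute_knn", k=k, weighting=weighting, n_imputed=0)
        return _rewrap(values.copy(), parent)

    all_missing = missing.all(axis=0)
    if all_missing.any():
        col = values.columns[all_missing][0]
        raise ImputationError(f"column {col!r} is entirely missing; cannot impute")
    if missing.all(axis=1).any():
        row = values.index[missing.all(axis=1)][0]
        raise ImputationError(f"row {row!r} has no observed value")

    sd = values.std(axis=0, ddof=1).replace(0.0, 1.0).fillna(1.0)
    Z = (values / sd).values  # scale only; centring cancels in differences
    mask = ~missing.values
    n, p = Z.shape

    out = values.copy().values
    for i in range(n):
        miss_cols = np.where(~mask[i])[0]
        if miss_cols.size == 0:
            continue
        # mean squared difference over shared observed columns
        shared = mask & mask[i]
        diff = np.where(shared, Z - Z[i], 0.0)
        n_shared = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt((diff**2).sum(axis=1) / n_shared)
        dist[i] = np.inf
        dist[n_shared == 0] = np.inf
        for j in miss_cols:
            candidates = np.where(mask[:, j] & np.isfinite(dist))[0]
            if candidates.size == 0:
                raise ImputationError(
                    f"no neighbour observes column {values.columns[j]!r} "
                    f"for row {values.index[i]!r}"
                )
            order = candidates[np.argsort(dist[candidates], kind="stable")]
            nearest = order[: min(k, order.size)]
            vals = values.values[nearest, j]
            if weighting == "distance":
                w = 1.0 / np.maximum(dist[nearest], 1e-12)
                out[i, j] = np.average(vals, weights=w)
            else:
                out[i, j] = vals.mean()

    result = pd.DataFrame(out, index=values.index, columns=values.columns)
    if log is not None:
        log.record(
            "impute_knn", k=k, weighting=weighting, n_imputed=int(missing.values.sum())
        )
    return _rewrap(result, parent)


# --------------------------------------------------------------------------- #
# Transforms
# --------------------------------------------------------------------------- #
@dataclass
class TransformSpec:
    """Variable -> transform map; transforms are 'log10', 'sqrt' or 'identity'."""

    transforms: Mapping[str, str] = field(default_factory=dict)

    _VALID = ("log10", "sqrt", "identity")

    def __post_init__(self) -> None:
        for var, tr in self.transforms.items():
            if tr not in self._VALID:
                raise ValueError(f"unknown transform {tr!r} for variable {var!r}")

    @classmethod
    def acth_default(cls) -> "TransformSpec":
        """Default profile: cortisol, platelets and white-cell count on log10;
        free fatty acids on square-root; everything else untouched."""
        return cls(
            {
                "cortisol": "log10",
                "platelets": "log10",
                "white_cells": "log10",
                "ffa": "sqrt",
            }
        )


def apply_transforms(matrix, spec: TransformSpec, log: ProvenanceLog | None = None):
    """Apply per-variable transforms in place of the original columns."""
    values, parent = _unwrap(matrix)
    out = values.copy()
    applied = {}
    for var, tr in spec.transforms.items():
        if var not in out.columns or tr == "identity":
            continue
        col = out[var]
        if tr == "log10":
            bad = col <= 0
            if bad.any():
                cell = (bad[bad].index[0], var)
                raise TransformError(f"log10 of non-positive value at {cell}")
            out[var] = np.log10(col)
        elif tr == "sqrt":
            bad = col < 0
            if bad.any():
                cell = (bad[bad].index[0], var)
                raise TransformError(f"sqrt of negative value at {cell}")
            out[var] = np.sqrt(col)
        applied[var] = tr
    if log is not None:
        log.record("apply_transforms", transforms=applied)
    return _rewrap(out, parent)


# --------------------------------------------------------------------------- #
# Batch alignment
# --------------------------------------------------------------------------- #
def align_batch_medians(matrix, batch=None, log: ProvenanceLog | None = None):
    """Shift every batch so its per-column median matches the pooled median.

    The alignment target is the overall (pre-alignment) median of each
    column, so the global location of the data is preserved; within-batch
    rank order is unchanged because the correction is a pure location shift.
    """
    values, parent = _unwrap(matrix)
    if batch is None:
        if parent is None:
            raise ValueError("batch labels required for a bare DataFrame")
        batch = parent.batch
    batch = pd.Series(np.asarray(batch), index=values.index)

    pooled = values.median(axis=0, skipna=True)
    out = values.copy()
    for b, idx in values.groupby(batch).groups.items():
        block = values.loc[idx]
        med = block.median(axis=0, skipna=True)
        if block.notna().sum(axis=0).eq(0).any():
            col = block.columns[block.notna().sum(axis=0).eq(0)][0]
            raise AlignmentError(f"batch {b!r} has column {col!r} entirely missing")
        out.loc[idx] = block + (pooled - med)
    if log is not None:
        log.record("align_batch_medians", n_batches=int(batch.nunique()))
    return _rewrap(out, parent)


# --------------------------------------------------------------------------- #
# Within-group normalization
# --------------------------------------------------------------------------- #
def quantile_normalize_within_group(
    matrix, group=None, mode: str = "quantile", log: ProvenanceLog | None = None
):
    """Normalize samples within each group (e.g. the 4 arrays of one animal).

    mode='quantile' (default): within each group, every sample's sorted value
    vector is replaced by the per-rank mean over the group's samples, so all
    samples of a group share an identical distribution.  mode='median' is the
    degenerate single-statistic variant (within-array median alignment): each
    sample is shifted so group medians coincide at their mean.

    Groups of a single sample are left untouched with a warning.
    """
    if mode not in ("quantile", "median"):
        raise ValueError(f"unknown mode {mode!r}")
    values, parent = _unwrap(matrix)
    if group is None:
        if parent is None:
            raise ValueError("group labels required for a bare DataFrame")
        group = parent.animal
    group = pd.Series(np.asarray(group), index=values.index)

    out = values.copy()
    for g, idx in values.groupby(group).groups.items():
        block = values.loc[idx].values
        if block.shape[0] < 2:
            warnings.warn(f"group {g!r} has a single sample; left unchanged")
            continue
        if mode == "median":
            meds = np.nanmedian(block, axis=1)
            out.loc[idx] = block + (meds.mean() - meds)[:, None]
        else:
            order = np.argsort(block, axis=1, kind="stable")
            ranks = np.empty_like(order)
            rows = np.arange(block.shape[0])[:, None]
            ranks[rows, order] = np.arange(block.shape[1])
            sorted_vals = np.take_along_axis(block, order, axis=1)
            rank_means = sorted_vals.mean(axis=0)
            out.loc[idx] = rank_means[ranks]
    if log is not None:
        log.record(
            "quantile_normalize_within_group", mode=mode, n_groups=int(group.nunique())
        )
    return _rewrap(out, parent)


# --------------------------------------------------------------------------- #
# Probe filtering
# --------------------------------------------------------------------------- #
def filter_probes(
    expression: pd.DataFrame,
    probe_map: pd.DataFrame,
    threshold_mode: str = "control",
    n_control_sd: float = 2.0,
    min_expressed_fraction: float = 0.5,
    log: ProvenanceLog | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Remove control probes and probes indistinguishable from background.

    A probe is kept if its signal exceeds the negative-control threshold
    (control mean + ``n_control_sd`` control SDs) in at least
    ``min_expressed_fraction`` of samples.  ``threshold_mode='none'`` skips
    the background test and removes only control probes.

    Parameters
    ----------
    expression : DataFrame, probes x samples.
    probe_map : DataFrame indexed by probe with a boolean 'is_control' column.

    Returns the filtered matrix and a report dict with per-rule removal counts.
    """
    controls = probe_map.loc[expression.index, "is_control"].astype(bool)
    report = {"n_input": int(len(expression)), "n_controls_removed": int(controls.sum())}
    kept = expression.loc[~controls.values]

    if threshold_mode == "none":
        report["n_below_threshold"] = 0
    elif threshold_mode == "control":
        ctrl_values = expression.loc[controls.values].values
        if ctrl_values.size == 0:
            raise ValueError(
                "threshold_mode='control' requires flagged negative-control probes"
            )
        threshold = float(ctrl_values.mean() + n_control_sd * ctrl_values.std(ddof=1))
        expressed_frac = (kept.values > threshold).mean(axis=1)
        pass_mask = expressed_frac >= min_expressed_fraction
        report["threshold"] = threshold
        report["n_below_threshold"] = int((~pass_mask).sum())
        kept = kept.loc[pass_mask]
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")

    report["n_kept"] = int(len(kept))
    if log is not None:
        log.record("filter_probes", threshold_mode=threshold_mode, **report)
    return kept.copy(), report
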