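"""Steady-state (total-pool) metabolomics preprocessing.

Total metabolite abundances from independent LC-MS experiments are put on a
common scale by dividing every sample by the first-acquired sample of its
batch, variance-stabilised with a generalised log transform, mean-centred
per metabolite, and — for dose-series designs — batch-corrected so that the
no-drug control samples of every batch centre at zero.  The glog

    glog(x) = log2((x + sqrt(x^2 + lambda^2)) / 2)

is defined at 0 and approaches log2(x) for x >> lambda; lambda defaults to
the smallest positive value of the matrix (a data-driven pseudo-count),
either globally or per metabolite.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "normalize_to_reference",
    "glog",
    "transform_and_centre",
    "batch_correct_to_control",
    "top_k_by_score",
]


def _batch_groups(metadata: pd.DataFrame) -> pd.Series:
    if "batch" not in metadata.columns:
        raise ValueError("metadata must carry a 'batch' column")
    return metadata.set_index("sample_id")["batch"]


def normalize_to_reference(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    order_col: str = "acquisition_order",
) -> pd.DataFrame:
    """Divide each batch by its first-acquired (reference) sample.

    ``matrix`` is samples x metabolites; ``metadata`` must declare the
    acquisition order explicitly (never inferred from row order).  The
    reference row becomes all ones.  Metabolites with a zero reference
    value are set to NaN for that batch with a warning.
    """
    meta = metadata.set_index("sample_id")
    if order_col not in meta.columns:
        raise ValueError(f"metadata must carry an explicit {order_col!r} column")
    batches = _batch_groups(metadata)
    out = matrix.astype(float).copy()
    for batch, samples in batches.groupby(batches):
        ids = samples.index
        ref_id = meta.loc[ids, order_col].idxmin()
        ref = matrix.loc[ref_id]
        zero_cols = ref.index[ref == 0]
        if len(zero_cols):
            warnings.warn(
                f"batch {batch!r}: reference sample {ref_id!r} has zero for "
                f"{list(zero_cols)}; excluded for this batch",
                stacklevel=2,
            )
        out.loc[ids] = matrix.loc[ids] / ref.replace(0, np.nan)
    return out


def glog(x, lam) -> np.ndarray:
    """Generalised log2 transform, defined at 0 (glog(0) = log2(lambda/2))."""
    x = np.asarray(x, dtype=float)
    return np.log2((x + np.sqrt(x * x + lam * lam)) / 2.0)


def transform_and_centre(
    matrix: pd.DataFrame, lambda_mode: str = "global"
) -> tuple[pd.DataFrame, float | pd.Series]:
    """glog-transform then mean-centre each metabolite column.

    lambda is the minimum positive value of the whole matrix
    (``lambda_mode='global'``, the default) or of each metabolite column
    (``'feature'``).  Returns the transformed matrix and the lambda used
    (recorded in run logs for reproducibility).
    """
    vals = matrix.to_numpy(dtype=float)
    pos = vals[np.isfinite(vals) & (vals > 0)]
    if pos.size == 0:
        raise ValueError("matrix has no positive values")
    if lambda_mode == "global":
        lam: float | pd.Series = float(pos.min())
        transformed = pd.DataFrame(
            glog(vals, lam), index=matrix.index, columns=matrix.columns
        )
    elif lambda_mode == "feature":
        lams = {}
        cols = {}
        for col in matrix.columns:
            v = matrix[col].to_numpy(dtype=float)
            p = v[np.isfinite(v) & (v > 0)]
            lams[col] = float(p.min()) if p.size else float(pos.min())
            cols[col] = glog(v, lams[col])
        lam = pd.Series(lams)
        transformed = pd.DataFrame(cols, index=matrix.index)[matrix.columns]
    else:
        raise ValueError(f"unknown lambda_mode {lambda_mode!r}")
    centred = transformed - transformed.mean(axis=0, skipna=True)
    return centred, lam


def batch_correct_to_control(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    control_condition: str = "control",
) -> pd.DataFrame:
    """Centre every batch on its own no-drug control samples.

    Subtracts, per batch x metabolite, the mean of that batch's control
    samples (post-transform scale), so controls sit at 0 in every batch and
    additive batch offsets cancel exactly.  A batch without a control
    sample is an error naming the batch.
    """
    meta = metadata.set_index("sample_id")
    batches = _batch_groups(metadata)
    out = matrix.astype(float).copy()
    for batch, samples in batches.groupby(batches):
        ids = samples.index
        ctl_ids = [s for s in ids if meta.loc[s, "condition"] == control_condition]
        if not ctl_ids:
            raise ValueError(
                f"batch {batch!r} has no {control_condition!r} sample"
            )
        out.loc[ids] = matrix.loc[ids] - matrix.loc[ctl_ids].mean(axis=0)
    return out


def top_k_by_score(
    records: pd.DataFrame, k: int = 25, name_col: str = "metabolite"
) -> list[str]:
    """The k best-scoring metabolites for heatmap display (default top 25).

    Ranked by smallest q-value, ties broken by larger |log10 fold change|,
    then name.  Fewer than k records returns all of them with a note.
    """
    if len(records) < k:
        warnings.warn(
            f"only {len(records)} scored metabolites (< k={k}); returning all",
            stacklevel=2,
        )
    ranked = records.assign(_abs_fc=records["log10_fc"].abs()).sort_values(
        ["q_value", "_abs_fc", name_col], ascending=[True, False, True],
        kind="stable",
    )
    return ranked[name_col].head(k).tolist()
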