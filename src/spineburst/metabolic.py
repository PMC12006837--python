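"""35S-Met/Cys incorporation rates and their normalization chain.

Each slice yields triplicate scintillation counts (CPM) and a protein
amount; the incorporation rate is the triplicate mean per mg protein.
Inter-experimental variation is removed by dividing each rate by the
activity of the labeling-mix aliquot (dose) and by the mean of all slices
in the batch, so batch means are 100% by construction. The two divisions
commute, so their order is immaterial.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

CPM_COLUMNS = ("cpm1", "cpm2", "cpm3")


def incorporation_rate(cpm_triplicate, protein_mg: float) -> float:
    """Mean of the triplicate CPM per mg protein."""
    cpm = np.asarray(cpm_triplicate, dtype=float)
    if cpm.size != 3:
        raise ValueError("expected a CPM triplicate")
    if np.any(cpm < 0):
        raise ValueError("CPM values must be non-negative")
    if protein_mg <= 0:
        raise ValueError("protein amount must be positive")
    return float(cpm.mean() / protein_mg)


def normalize_batch(samples: pd.DataFrame, anchor: str | None = None) -> pd.DataFrame:
    """Normalize incorporation rates within each batch.

    Expects columns ``cpm1..cpm3``, ``protein_mg``, ``dose_cpm`` and
    ``batch_id``. Adds ``rate_cpm_per_mg``, ``cpm_sd`` (triplicate SD, kept
    for QC) and ``normalized_percent`` = (rate / dose) as percent of the
    batch mean of (rate / dose). With ``anchor`` set to a group label (and
    a ``group`` column present), the anchor group's mean is used as the
    100% reference instead of the all-slice mean.
    """
    df = samples.copy()
    cpm = df.loc[:, list(CPM_COLUMNS)].to_numpy(dtype=float)
    df["rate_cpm_per_mg"] = cpm.mean(axis=1) / df["protein_mg"].to_numpy(dtype=float)
    df["cpm_sd"] = cpm.std(axis=1, ddof=1)
    rel = df["rate_cpm_per_mg"] / df["dose_cpm"].to_numpy(dtype=float)
    out = np.empty(len(df))
    for batch, idx in df.groupby("batch_id").groups.items():
        if len(idx) < 2:
            warnings.warn(f"batch {batch!r} has a single sample; its normalized value is trivially 100%",
                          RuntimeWarning, stacklevel=2)
        r = rel.loc[idx]
        if anchor is not None:
            ref = r[df.loc[idx, "group"] == anchor].mean()
            if not np.isfinite(ref) or ref <= 0:
                raise ValueError(f"anchor group {anchor!r} missing or degenerate in batch {batch!r}")
        else:
            ref = r.mean()
        out[df.index.get_indexer(idx)] = r / ref * 100.0
    df["normalized_percent"] = out
    return df


__all__ = ["incorporation_rate", "normalize_batch", "CPM_COLUMNS"]
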