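"""Channel normalization and per-feature log2(KO/Control) effects.

All quantification happens in log2 space.  Reporter intensities of exactly 0
are treated as missing (not observed), never imputed.  The group effect is the
difference of group means of log2 intensities, written log2(KO/Ctrl)
throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables_io import SampleDesign


class NormalizationError(ValueError):
    """A channel cannot be normalized (e.g. no finite values)."""


def log2_intensities(table: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """log2-transform the design's channel columns; zeros become NaN."""
    out = table[design.channels].astype(float).copy()
    out[out <= 0] = np.nan
    return np.log2(out)


def normalize_channels(table: pd.DataFrame, design: SampleDesign,
                       method: str = "median") -> pd.DataFrame:
    """Return log2 intensities for the design channels, optionally
    median-centered per channel.

    ``method="median"`` shifts each channel so its median equals the grand
    median of all channel medians, removing loading differences between TMT
    channels.  ``method="none"`` returns the plain log2 transform.  Missing
    entries (zero intensity) stay missing.
    """
    log2 = log2_intensities(table, design)
    if method == "none":
        return log2
    if method != "median":
        raise ValueError(f"unknown normalization method {method!r}")
    medians = log2.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = sorted(medians.index[medians.isna()])
        raise NormalizationError(f"channel(s) with no finite values: {bad}")
    return log2 - (medians - medians.median())


def compute_ratios(log2_table: pd.DataFrame, design: SampleDesign,
                   min_per_group: int = 2) -> pd.DataFrame:
    """Per-feature group means and log2(KO/Ctrl) effect.

    Features with fewer than ``min_per_group`` finite values in either group
    are kept in the output but flagged ``insufficient_replicates=True`` and
    should be excluded from statistics downstream.
    """
    if min_per_group < 2:
        raise ValueError("min_per_group must be >= 2 (t-test needs two values)")
    ko = log2_table[design.ko_channels]
    ctrl = log2_table[design.ctrl_channels]
    n_ko = ko.notna().sum(axis=1)
    n_ctrl = ctrl.notna().sum(axis=1)
    mean_ko = ko.mean(axis=1, skipna=True)
    mean_ctrl = ctrl.mean(axis=1, skipna=True)
    return pd.DataFrame({
        "mean_ko": mean_ko,
        "mean_ctrl": mean_ctrl,
        "log2_effect": mean_ko - mean_ctrl,
        "n_ko": n_ko.astype(int),
        "n_ctrl": n_ctrl.astype(int),
        "insufficient_replicates": (n_ko < min_per_group) | (n_ctrl < min_per_group),
    }, index=log2_table.index)
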