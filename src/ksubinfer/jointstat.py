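"""The joint significance statistic p_joint and volcano-style classification.

For each quantified feature with log2 effect e, p_joint combines two
independent lines of evidence:

* ``p_t`` — the two-sided p-value of an unpaired two-sample t-test on the
  per-channel log2 intensities (pooled variance by default, Welch optional);
* the standard-normal upper tail 1 - Phi(|Z|) of the globally standardized
  effect Z = e / sigma_global, where sigma_global is the sample SD of the
  log2 effects across all tested features in the experiment.

p_joint = p_t x (1 - Phi(|Z|)).  A feature must therefore be both precisely
measured (small p_t) and an outlier relative to the experiment-wide effect
distribution (large |Z|) to score well; the product of two probabilities is
deliberately conservative.  No multiple-testing correction is applied; a
stringent raw threshold (default 0.0005) is used instead.

Phosphosites on proteins whose total abundance itself changes significantly
are excluded from the phospho classification, so protein-level expression
shifts are not mistaken for phosphorylation regulation.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import SampleDesign

logger = logging.getLogger(__name__)

ALPHA_JOINT_DEFAULT = 0.0005

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "not_significant"
STATUS_EXCLUDED = "excluded_protein_change"
STATUS_INSUFFICIENT = "insufficient_replicates"


class StatisticError(ValueError):
    """The statistic is undefined for the given input (e.g. sigma over <2 features)."""


def t_test_two_sample(a, b, equal_var: bool = True) -> float:
    """Two-sided unpaired t-test p-value on two samples of log2 intensities.

    Degenerate inputs follow the conventions: zero variance in both groups
    with equal means gives p = 1; zero variance with unequal means gives the
    p -> 0 limit.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-test needs at least 2 finite values per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 1.0
        logger.warning("zero variance in both groups with unequal means; p -> 0")
        return 0.0
    p = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
    return float(p)


def gaussian_upper_tail(z: float) -> float:
    """Area under the standard normal density from |z| to +infinity.

    Equals 0.5 at z = 0 and is computed via the complementary error function,
    so it stays accurate far into the tail (|z| of 30 and beyond).
    """
    if not np.isfinite(z):
        raise ValueError(f"z must be finite, got {z!r}")
    return float(stats.norm.sf(abs(z)))


def compute_p_joint(ratios: pd.DataFrame, log2_table: pd.DataFrame,
                    design: SampleDesign, equal_var: bool = True,
                    sigma_global: float | None = None) -> pd.DataFrame:
    """Per-feature t-test, standardized effect, Gaussian tail and p_joint.

    ``ratios`` comes from :func:`ksubinfer.quant.compute_ratios`; features
    flagged ``insufficient_replicates`` are skipped.  ``sigma_global`` is the
    sample SD of log2 effects over the tested features; pass a value to reuse
    a sigma computed on a different feature set (e.g. before an exclusion).

    The returned frame carries ``sigma_global`` in ``DataFrame.attrs``.
    """
    tested = ratios[~ratios["insufficient_replicates"]]
    if len(tested) < 2:
        raise StatisticError("sigma_global undefined: fewer than 2 tested features")
    if sigma_global is None:
        sigma_global = float(tested["log2_effect"].std(ddof=1))
    if not (sigma_global > 0):
        raise StatisticError(f"sigma_global must be positive, got {sigma_global}")

    ko = log2_table.loc[tested.index, design.ko_channels].to_numpy(float)
    ctrl = log2_table.loc[tested.index, design.ctrl_channels].to_numpy(float)
    with np.errstate(invalid="ignore"):
        p_t = stats.ttest_ind(ko, ctrl, axis=1, equal_var=equal_var,
                              nan_policy="omit").pvalue
    p_t = np.asarray(p_t, dtype=float)

    # degenerate rows (zero variance in both groups) by convention
    degenerate = ~np.isfinite(p_t)
    if degenerate.any():
        mean_diff = np.nanmean(ko[degenerate], axis=1) - np.nanmean(ctrl[degenerate], axis=1)
        p_t[degenerate] = np.where(mean_diff == 0.0, 1.0, 0.0)
        if (mean_diff != 0.0).any():
            logger.warning("%d feature(s) with zero variance in both groups "
                           "and unequal means; p_t -> 0", int((mean_diff != 0).sum()))

    effect = tested["log2_effect"].to_numpy(float)
    z = effect / sigma_global
    tail = stats.norm.sf(np.abs(z))
    out = pd.DataFrame({
        "log2_effect": effect, "p_t": p_t, "Z": z,
        "gaussian_tail": tail, "p_joint": p_t * tail,
    }, index=tested.index.rename("feature"))
    out.attrs["sigma_global"] = sigma_global
    return out


def classify_sites(phospho_results: pd.DataFrame,
                   protein_results: pd.DataFrame | None,
                   site_accessions: pd.Series | None = None,
                   ratios: pd.DataFrame | None = None,
                   alpha_joint: float = ALPHA_JOINT_DEFAULT) -> pd.DataFrame:
    """Volcano classification of phosphosites with the protein-change exclusion.

    A site whose parent protein (via ``site_accessions``, site id -> accession)
    is itself significant in ``protein_results`` (protein-level p_joint <
    ``alpha_joint``) is marked ``excluded_protein_change`` regardless of its
    own statistic.  Remaining sites are ``up`` / ``down`` /
    ``not_significant`` by the joint threshold and the sign of the effect.
    Sites present in ``ratios`` but absent from ``phospho_results`` (too few
    replicates) are reported as ``insufficient_replicates``, so the statuses
    always partition the input sites.
    """
    excluded_acc: set[str] = set()
    if protein_results is not None and len(protein_results):
        sig = protein_results["p_joint"] < alpha_joint
        excluded_acc = set(protein_results.index[sig])

    records = []
    for fid, row in phospho_results.iterrows():
        acc = None
        if site_accessions is not None:
            try:
                acc = site_accessions[fid]
            except KeyError:
                logger.info("site %s has no protein match; not excluded", fid)
        if acc is not None and acc in excluded_acc:
            status = STATUS_EXCLUDED
        elif row["p_joint"] < alpha_joint:
            status = STATUS_UP if row["log2_effect"] > 0 else STATUS_DOWN
        else:
            status = STATUS_NS
        records.append((fid, acc, row["log2_effect"], row["p_joint"], status))

    if ratios is not None:
        skipped = ratios.index[ratios["insufficient_replicates"]]
        for fid in skipped:
            acc = site_accessions.get(fid) if site_accessions is not None else None
            records.append((fid, acc, math.nan, math.nan, STATUS_INSUFFICIENT))

    out = pd.DataFrame(records, columns=["feature", "accession", "log2_effect",
                                         "p_joint", "status"]).set_index("feature")
    out.attrs["status_counts"] = out["status"].value_counts().to_dict()
    out.attrs["alpha_joint"] = alpha_joint
    return out
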