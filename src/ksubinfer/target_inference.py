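"""Direct-substrate calling and downstream characterization.

A phosphosite is called a *direct* substrate of the deleted kinase when it
satisfies all of:

* joint significance: p_joint below the threshold (default 0.0005);
* effect size and direction: log2(KO/Ctrl) below -effect_threshold
  (default magnitude 0.3) — losing the kinase must reduce the phosphorylation;
* consensus motif: the 13-mer centralized sequence matches the kinase motif.

Sites on proteins whose total abundance changed are ineligible.  Two
comparison modes are provided: ``strict`` applies ``p_joint < alpha`` and
``effect < -threshold`` to full-precision values; ``table_replication``
applies ``p_joint <= alpha`` and ``|effect| > threshold``, which is the
correct reading of published tables whose p-values are rounded to four
decimals (a printed 0.0005 may be any value below the threshold).

The module also characterizes indirect (up-regulated) sites by position
enrichment, intersects changed sites with user-supplied annotation
categories (kinases, phosphatases, ...), runs generic one-sided Fisher-exact
term enrichment, and computes phospho-occupancy ratios with a one-way ANOVA
across dose groups for in vitro validation experiments.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .jointstat import ALPHA_JOINT_DEFAULT, STATUS_EXCLUDED, STATUS_INSUFFICIENT
from .motif import MotifSpec, motif_match, position_enrichment

EFFECT_THRESHOLD_DEFAULT = 0.3

MODE_STRICT = "strict"
MODE_TABLE = "table_replication"


def call_direct_targets(results: pd.DataFrame, spec: MotifSpec,
                        alpha_joint: float = ALPHA_JOINT_DEFAULT,
                        effect_threshold: float = EFFECT_THRESHOLD_DEFAULT,
                        mode: str = MODE_STRICT,
                        statuses: pd.Series | None = None) -> pd.DataFrame:
    """Apply the dual statistical criteria plus motif filter per site.

    ``results`` needs columns ``log2_effect``, ``p_joint`` and ``sequence_13``
    (any extra identifier columns are carried through).  ``statuses``, if
    given, marks sites that are ineligible (``excluded_protein_change`` /
    ``insufficient_replicates``).  Returns the input rows with boolean columns
    ``passes_significance``, ``passes_motif``, ``is_direct``, sorted by
    p_joint then effect.
    """
    if mode not in (MODE_STRICT, MODE_TABLE):
        raise ValueError(f"unknown comparison mode {mode!r}")
    out = results.copy()
    effect = out["log2_effect"].astype(float)
    p = out["p_joint"].astype(float)
    if mode == MODE_STRICT:
        sig = (p < alpha_joint) & (effect < -effect_threshold)
    else:
        sig = (p <= alpha_joint) & (effect < 0) & (effect.abs() > effect_threshold)

    eligible = pd.Series(True, index=out.index)
    if statuses is not None:
        ineligible = statuses.reindex(out.index).isin([STATUS_EXCLUDED,
                                                       STATUS_INSUFFICIENT])
        eligible &= ~ineligible.fillna(False)

    has_seq = out["sequence_13"].notna() & (out["sequence_13"].astype(str).str.len() == 13)
    motif = pd.Series(
        [motif_match(s, spec) if ok else False
         for s, ok in zip(out["sequence_13"].astype(str), has_seq)],
        index=out.index)

    out["passes_significance"] = sig & eligible
    out["passes_motif"] = motif.where(has_seq, other=pd.NA)
    out["is_direct"] = (sig & eligible & motif & has_seq).astype(bool)
    return out.sort_values(["p_joint", "log2_effect"])


def characterize_indirect(up_sequences: Sequence[str],
                          background: Sequence[str] | Mapping[str, float],
                          p_threshold: float = 0.001) -> tuple[pd.DataFrame, dict]:
    """Position enrichment of the up-regulated set; summarizes whether the
    proline-directed signature (P at +1) is flagged.

    An empty up-set yields an empty table and a summary with
    ``proline_plus1_enriched = False``.
    """
    if len(up_sequences) == 0:
        empty = pd.DataFrame(columns=["position", "residue", "fg_count", "fg_total",
                                      "bg_count", "bg_total", "fg_freq", "bg_freq",
                                      "chi_square", "p_value", "log2_enrichment",
                                      "enriched"])
        return empty, {"n_up": 0, "proline_plus1_enriched": False}
    table = position_enrichment(up_sequences, background, p_threshold=p_threshold)
    hit = table[(table["position"] == 1) & (table["residue"] == "P")]
    flagged = bool(hit["enriched"].any())
    return table, {"n_up": len(up_sequences), "proline_plus1_enriched": flagged}


def subset_report(calls: pd.DataFrame, annotation: Mapping[str, str],
                  gene_column: str = "gene") -> pd.DataFrame:
    """Intersect called sites with user-supplied gene categories.

    ``annotation`` maps gene symbol -> category (e.g. kinase, phosphatase).
    Returns the matching rows of ``calls`` (from :func:`call_direct_targets`)
    with a ``category`` column, sorted by category then gene.  No gene
    database is bundled; the annotation is always an input.
    """
    if not annotation or calls.empty:
        return calls.head(0).assign(category=pd.Series(dtype=str))
    cat = calls[gene_column].map(annotation)
    out = calls[cat.notna()].assign(category=cat[cat.notna()])
    return out.sort_values(["category", gene_column])


def fisher_enrichment(query: Iterable[str], annotation: Mapping[str, Iterable[str]],
                      background: Iterable[str],
                      p_threshold: float = 0.05) -> pd.DataFrame:
    """One-sided Fisher-exact term enrichment of a query gene set.

    For each term the 2x2 table (in query / not, in term / not) over the
    background is tested for over-representation (alternative="greater").
    Fold enrichment is (hits / |query|) / (term size / |background|).
    """
    query = set(query)
    background = set(background)
    stray = sorted(query - background)
    if stray:
        raise ValueError(f"query genes absent from background: {stray}")
    n_query, n_bg = len(query), len(background)
    rows = []
    for term, genes in annotation.items():
        term_genes = set(genes) & background
        hits = len(term_genes & query)
        term_size = len(term_genes)
        if term_size == 0:
            continue
        table = [[hits, n_query - hits],
                 [term_size - hits, n_bg - n_query - (term_size - hits)]]
        _, p = stats.fisher_exact(table, alternative="greater")
        fold = (hits / n_query) / (term_size / n_bg) if n_query else np.nan
        rows.append((term, term_size, hits, fold, float(p),
                     bool(p < p_threshold and hits > 0)))
    out = pd.DataFrame(rows, columns=["term", "term_size", "hits",
                                      "fold_enrichment", "p_value", "significant"])
    return out.sort_values("p_value").reset_index(drop=True)


def invitro_phospho_ratio(table: pd.DataFrame,
                          phospho_column: str = "phospho_intensity",
                          total_column: str = "total_intensity",
                          group_column: str = "dose") -> tuple[pd.DataFrame, float]:
    """Per-replicate phospho/total occupancy ratios and a one-way ANOVA p
    across dose groups.

    Rows with zero or missing total intensity get an undefined ratio and a
    ``flagged`` mark; they are dropped from the ANOVA.  Requires at least two
    dose groups with at least two valid replicates each.
    """
    out = table.copy()
    total = out[total_column].astype(float)
    phospho = out[phospho_column].astype(float)
    valid = total > 0
    out["ratio"] = np.where(valid, phospho / total.where(valid), np.nan)
    out["flagged"] = ~valid
    groups = [g["ratio"].dropna().to_numpy()
              for _, g in out.groupby(group_column, sort=True)]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs >= 2 dose groups with >= 2 "
                         "valid replicates each")
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(np.concatenate(groups)) == 0:
        p = 1.0  # all ratios identical: no evidence of a dose effect
    else:
        p = float(stats.f_oneway(*groups).pvalue)
    return out, p
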