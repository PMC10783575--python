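"""End-to-end orchestration: tables in, direct-target calls out.

``run_pipeline`` chains normalization, ratio computation, the joint
statistic on both the phosphosite and the protein-group tables, the
protein-change exclusion, classification, and direct-target calling.  Each
stage remains usable on its own; this module only wires the default data
flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import jointstat, quant
from .jointstat import ALPHA_JOINT_DEFAULT
from .motif import CAMK2_MOTIF, MotifSpec
from .tables_io import SampleDesign
from .target_inference import (EFFECT_THRESHOLD_DEFAULT, MODE_STRICT,
                               call_direct_targets)


@dataclass
class PipelineResult:
    """Bundle of every stage's output table."""

    phospho_ratios: pd.DataFrame
    protein_ratios: pd.DataFrame
    phospho_joint: pd.DataFrame
    protein_joint: pd.DataFrame
    classification: pd.DataFrame
    direct_calls: pd.DataFrame

    @property
    def status_counts(self) -> dict:
        return self.classification.attrs["status_counts"]

    @property
    def direct_sites(self) -> pd.Index:
        return self.direct_calls.index[self.direct_calls["is_direct"]]


def run_pipeline(phospho: pd.DataFrame, proteins: pd.DataFrame,
                 design: SampleDesign,
                 motif: MotifSpec = CAMK2_MOTIF,
                 normalization: str = "median",
                 min_per_group: int = 2,
                 alpha_joint: float = ALPHA_JOINT_DEFAULT,
                 effect_threshold: float = EFFECT_THRESHOLD_DEFAULT,
                 mode: str = MODE_STRICT,
                 equal_var: bool = True,
                 exclude_before_sigma: bool = False) -> PipelineResult:
    """Run the full substrate-inference analysis on one experiment.

    ``phospho`` must carry the identifier columns (``accession``,
    ``sequence_13``) and one intensity column per design channel, indexed by
    site id; ``proteins`` likewise, indexed by accession.  With
    ``exclude_before_sigma`` the global effect SD is computed only over sites
    surviving the protein-change exclusion; the default computes it over all
    tested sites and applies the exclusion to classification only.
    """
    prot = proteins.set_index("accession", drop=False) \
        if proteins.index.name != "accession" else proteins

    phospho_log2 = quant.normalize_channels(phospho, design, method=normalization)
    protein_log2 = quant.normalize_channels(prot, design, method=normalization)

    phospho_ratios = quant.compute_ratios(phospho_log2, design, min_per_group)
    protein_ratios = quant.compute_ratios(protein_log2, design, min_per_group)

    protein_joint = jointstat.compute_p_joint(protein_ratios, protein_log2,
                                              design, equal_var=equal_var)

    sigma = None
    if exclude_before_sigma:
        sig_prot = set(protein_joint.index[protein_joint["p_joint"] < alpha_joint])
        keep = ~phospho["accession"].reindex(phospho_ratios.index).isin(sig_prot)
        kept = phospho_ratios[keep & ~phospho_ratios["insufficient_replicates"]]
        sigma = float(kept["log2_effect"].std(ddof=1))

    phospho_joint = jointstat.compute_p_joint(phospho_ratios, phospho_log2,
                                              design, equal_var=equal_var,
                                              sigma_global=sigma)

    classification = jointstat.classify_sites(
        phospho_joint, protein_joint,
        site_accessions=phospho["accession"],
        ratios=phospho_ratios, alpha_joint=alpha_joint)

    calls_input = phospho_joint.join(phospho["sequence_13"]) \
        .join(phospho[["accession", "gene"]], how="left")
    direct_calls = call_direct_targets(
        calls_input, motif, alpha_joint=alpha_joint,
        effect_threshold=effect_threshold, mode=mode,
        statuses=classification["status"])

    return PipelineResult(phospho_ratios, protein_ratios, phospho_joint,
                          protein_joint, classification, direct_calls)
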