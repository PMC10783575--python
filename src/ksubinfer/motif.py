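"""Centralized-sequence handling and position-specific motif analysis.

A phosphosite is represented by its 13-residue *centralized sequence*: the
window from six residues upstream to six residues downstream of the
phosphorylated S/T/Y, padded with ``_`` where the window runs past a protein
terminus.  Consensus motifs such as the CAMK2 preference
(R/K)-X-X-p(S/T)-X-(D/E) are encoded as per-position allowed-residue sets and
matched against these windows.  Position-specific residue enrichment between a
foreground set (e.g. down-regulated sites) and a background set (e.g. all
quantified sites) is assessed with per-(position, residue) chi-square tests,
the statistic behind sequence-logo style displays.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "_"
WINDOW = 13
HALF_WIDTH = 6

_SEQ_RE = re.compile(r"^_*[ACDEFGHIKLMNPQRSTVWY]+_*$")


def is_valid_centralized(sequence: str) -> bool:
    """True iff ``sequence`` is a valid 13-mer: amino-acid letters with ``_``
    only as a contiguous prefix and/or suffix, and a non-pad center."""
    if len(sequence) != WINDOW:
        return False
    if sequence[HALF_WIDTH] == PAD:
        return False
    return bool(_SEQ_RE.match(sequence))


@dataclass(frozen=True)
class MotifSpec:
    """Position-specific residue constraints on a centralized sequence.

    ``constraints`` maps a relative position in [-6, +6] (0 = the phosphosite)
    to the set of residues allowed there.  Unconstrained positions accept any
    residue.  The center constraint, if present, must be a subset of {S, T, Y};
    the pad character is never an allowed residue.
    """

    constraints: Mapping[int, frozenset[str]]
    name: str = "motif"

    def __post_init__(self) -> None:
        frozen = {int(p): frozenset(r) for p, r in self.constraints.items()}
        for pos, residues in frozen.items():
            if not -HALF_WIDTH <= pos <= HALF_WIDTH:
                raise ValueError(f"motif position {pos} outside [-6, +6]")
            if not residues:
                raise ValueError(f"motif position {pos} has an empty residue set")
            bad = residues - set(AMINO_ACIDS)
            if bad:
                raise ValueError(f"invalid residues {sorted(bad)} at position {pos}")
            if pos == 0 and not residues <= {"S", "T", "Y"}:
                raise ValueError("center (position 0) must be a subset of {S, T, Y}")
        object.__setattr__(self, "constraints", frozen)

    @classmethod
    def from_string(cls, text: str, name: str | None = None) -> "MotifSpec":
        """Parse a compact motif string such as ``"-3:RK,0:ST,+2:DE"``."""
        constraints: dict[int, frozenset[str]] = {}
        for token in text.split(","):
            token = token.strip()
            if not token:
                continue
            pos_s, _, res = token.partition(":")
            if not res:
                raise ValueError(f"malformed motif token {token!r}")
            constraints[int(pos_s)] = frozenset(res.upper())
        return cls(constraints, name=name or text)


#: The CAMK2 consensus (R/K)-X-X-p(S/T)-X-(D/E).
CAMK2_MOTIF = MotifSpec({-3: frozenset("RK"), 0: frozenset("ST"), 2: frozenset("DE")},
                        name="(R/K)-X-X-p(S/T)-X-(D/E)")

#: Proline-directed sites (P immediately C-terminal to the phosphosite).
PROLINE_PLUS1_MOTIF = MotifSpec({0: frozenset("ST"), 1: frozenset("P")},
                                name="p(S/T)-P")


def centralize_sequence(protein_sequence: str, position: int,
                        half_width: int = HALF_WIDTH) -> str:
    """Extract the +/- ``half_width`` window around a 1-based site position.

    Pads with ``_`` where the window extends past either terminus.  The site
    residue must be S, T or Y.
    """
    n = len(protein_sequence)
    if not 1 <= position <= n:
        raise ValueError(f"site position {position} outside protein of length {n}")
    residue = protein_sequence[position - 1]
    if residue not in "STY":
        raise ValueError(f"residue at position {position} is {residue!r}, not S/T/Y")
    i = position - 1
    left = protein_sequence[max(0, i - half_width):i]
    right = protein_sequence[i + 1:i + 1 + half_width]
    return (PAD * (half_width - len(left)) + left + residue
            + right + PAD * (half_width - len(right)))


def motif_match(sequence: str, spec: MotifSpec) -> bool:
    """True iff every constrained position's residue is in the allowed set.

    A pad character at a constrained position fails the match (the motif
    requires a real residue there).
    """
    if len(sequence) != WINDOW:
        raise ValueError(f"centralized sequence must have length {WINDOW}, "
                         f"got {len(sequence)}")
    for pos, allowed in spec.constraints.items():
        if sequence[HALF_WIDTH + pos] not in allowed:
            return False
    return True


def _position_counts(sequences: Iterable[str]) -> tuple[dict[int, Counter], dict[int, int]]:
    """Per relative position: residue counts and the number of sequences with
    a real (non-pad) residue there."""
    counts: dict[int, Counter] = {p: Counter() for p in range(-HALF_WIDTH, HALF_WIDTH + 1)}
    totals: dict[int, int] = {p: 0 for p in counts}
    for seq in sequences:
        if len(seq) != WINDOW:
            raise ValueError(f"sequence {seq!r} is not a {WINDOW}-mer")
        for pos in counts:
            aa = seq[HALF_WIDTH + pos]
            if aa != PAD:
                counts[pos][aa] += 1
                totals[pos] += 1
    return counts, totals


def _group_counts(counter: Counter, members: frozenset[str]) -> int:
    return sum(counter[aa] for aa in members)


def position_enrichment(foreground: Sequence[str],
                        background: Sequence[str] | Mapping[str, float],
                        p_threshold: float = 0.001,
                        residue_groups: Sequence[frozenset[str] | str] | None = None,
                        ) -> pd.DataFrame:
    """Position-specific residue enrichment of foreground vs background.

    For every (relative position, residue) cell a 2x2 chi-square test (1 df,
    no continuity correction) compares the residue's frequency at that
    position between the foreground sequences and the background.  The
    background is either a second sequence set or a residue-frequency model
    (mapping residue -> probability), in which case a one-sample goodness-of-
    fit chi-square against the model frequency is used.  Pad positions
    contribute to neither set.

    ``residue_groups`` optionally adds pooled residue classes (e.g. ``{"R","K"}``)
    tested the same way, reported with a joined label such as ``"RK"``.

    Returns a tidy table with columns ``position, residue, fg_count, fg_total,
    bg_count, bg_total, fg_freq, bg_freq, chi_square, p_value, log2_enrichment,
    enriched`` where ``enriched`` requires both p < ``p_threshold`` and a
    foreground frequency above background.
    """
    foreground = list(foreground)
    if not foreground:
        raise ValueError("foreground sequence set is empty")

    fg_counts, fg_totals = _position_counts(foreground)

    freq_model: Mapping[str, float] | None = None
    if isinstance(background, Mapping):
        total_w = float(sum(background.values()))
        if total_w <= 0:
            raise ValueError("background frequency model sums to zero")
        freq_model = {aa: background.get(aa, 0.0) / total_w for aa in AMINO_ACIDS}
        bg_counts, bg_totals = {}, {}
    else:
        background = list(background)
        bg_counts, bg_totals = _position_counts(background)

    units: list[tuple[str, frozenset[str]]] = [(aa, frozenset(aa)) for aa in AMINO_ACIDS]
    for grp in residue_groups or ():
        members = frozenset(grp)
        units.append(("".join(sorted(members)), members))

    rows = []
    for pos in range(-HALF_WIDTH, HALF_WIDTH + 1):
        fg_total = fg_totals[pos]
        if fg_total == 0:
            continue
        for label, members in units:
            fg_hit = _group_counts(fg_counts[pos], members)
            if freq_model is not None:
                p0 = sum(freq_model[aa] for aa in members)
                bg_hit = math.nan
                bg_total = math.nan
                bg_freq = p0
                chi2, p = _goodness_of_fit_chi2(fg_hit, fg_total, p0)
            else:
                bg_total = bg_totals[pos]
                bg_hit = _group_counts(bg_counts[pos], members)
                bg_freq = bg_hit / bg_total if bg_total else math.nan
                chi2, p = _contingency_chi2(fg_hit, fg_total, bg_hit, bg_total)
            fg_freq = fg_hit / fg_total
            ratio = np.nan
            if fg_freq > 0 and bg_freq and bg_freq > 0:
                ratio = math.log2(fg_freq / bg_freq)
            elif fg_freq > 0 and bg_freq == 0:
                ratio = math.inf
            enriched = bool(p < p_threshold and (np.isnan(bg_freq) or fg_freq > bg_freq))
            rows.append((pos, label, fg_hit, fg_total, bg_hit, bg_total,
                         fg_freq, bg_freq, chi2, p, ratio, enriched))

    return pd.DataFrame(rows, columns=[
        "position", "residue", "fg_count", "fg_total", "bg_count", "bg_total",
        "fg_freq", "bg_freq", "chi_square", "p_value", "log2_enrichment",
        "enriched"])


def _contingency_chi2(fg_hit: int, fg_total: int, bg_hit: int, bg_total: int
                      ) -> tuple[float, float]:
    if bg_total == 0:
        return math.nan, math.nan
    table = np.array([[fg_hit, fg_total - fg_hit],
                      [bg_hit, bg_total - bg_hit]], dtype=float)
    # degenerate margins (residue absent or universal in both sets) carry no signal
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def _goodness_of_fit_chi2(fg_hit: int, fg_total: int, p0: float) -> tuple[float, float]:
    if p0 <= 0.0:
        return (math.inf, 0.0) if fg_hit > 0 else (0.0, 1.0)
    if p0 >= 1.0:
        return (math.inf, 0.0) if fg_hit < fg_total else (0.0, 1.0)
    expected = np.array([fg_total * p0, fg_total * (1 - p0)])
    observed = np.array([fg_hit, fg_total - fg_hit])
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def logo_matrix(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Positions x residues matrix of signed log2 fold enrichment for cells
    flagged as enriched (zero elsewhere), ready for external logo plotting."""
    single = enrichment[enrichment["residue"].str.len() == 1]
    mat = pd.DataFrame(0.0, index=sorted(single["position"].unique()),
                       columns=list(AMINO_ACIDS))
    for _, row in single.iterrows():
        if row["enriched"] and np.isfinite(row["log2_enrichment"]):
            mat.loc[row["position"], row["residue"]] = row["log2_enrichment"]
    mat.index.name = "position"
    return mat
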