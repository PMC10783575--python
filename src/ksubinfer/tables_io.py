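"""Reading, validating and writing the pipeline's tab-separated tables.

Native dialect: plain TSV with explicit column names.  The phosphosite table
has one row per monophosphosite (``accession, gene, residue, position,
sequence_13`` plus one intensity column per TMT channel); the protein-group
table has ``accession, gene`` plus the channel columns; the sample design maps
``channel`` to ``group`` (KO or Control) and ``replicate``.  An import adapter
maps MaxQuant "Phospho (STY)Sites.txt" style column names onto this schema.

Intensities of exactly 0 are kept at read time; downstream quantification
treats them as missing (a TMT zero means "not observed", not "abundance
zero").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .motif import is_valid_centralized, HALF_WIDTH

logger = logging.getLogger(__name__)

GROUP_KO = "KO"
GROUP_CTRL = "Control"

_GROUP_ALIASES = {
    "ko": GROUP_KO, "knockout": GROUP_KO, "null": GROUP_KO,
    "control": GROUP_CTRL, "ctrl": GROUP_CTRL, "intact": GROUP_CTRL,
    "wt": GROUP_CTRL,
}

ID_COLUMNS = ["accession", "gene", "residue", "position", "sequence_13"]
PROTEIN_ID_COLUMNS = ["accession", "gene"]


class SchemaError(ValueError):
    """A required column is missing or an identifier constraint is violated."""


class DesignError(ValueError):
    """The sample design does not satisfy the replicate requirements."""


@dataclass(frozen=True)
class SampleDesign:
    """Channel-to-group assignment for one TMT experiment."""

    table: pd.DataFrame  # columns: channel, group, replicate

    @property
    def channels(self) -> list[str]:
        return list(self.table["channel"])

    def group_channels(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "channel"])

    @property
    def ko_channels(self) -> list[str]:
        return self.group_channels(GROUP_KO)

    @property
    def ctrl_channels(self) -> list[str]:
        return self.group_channels(GROUP_CTRL)

    @property
    def n_ko(self) -> int:
        return len(self.ko_channels)

    @property
    def n_ctrl(self) -> int:
        return len(self.ctrl_channels)


def make_design(n_ko: int, n_ctrl: int) -> SampleDesign:
    """Build a canonical design with channels KO_1..KO_n and Ctrl_1..Ctrl_m."""
    rows = [(f"KO_{i + 1}", GROUP_KO, i + 1) for i in range(n_ko)]
    rows += [(f"Ctrl_{i + 1}", GROUP_CTRL, i + 1) for i in range(n_ctrl)]
    return _validate_design(pd.DataFrame(rows, columns=["channel", "group", "replicate"]))


def _validate_design(df: pd.DataFrame) -> SampleDesign:
    missing = {"channel", "group", "replicate"} - set(df.columns)
    if missing:
        raise SchemaError(f"design is missing columns: {sorted(missing)}")
    groups = []
    for i, raw in enumerate(df["group"]):
        key = str(raw).strip().lower()
        if key not in _GROUP_ALIASES:
            raise SchemaError(f"design row {i}: unknown group label {raw!r} "
                              f"(expected KO or Control)")
        groups.append(_GROUP_ALIASES[key])
    df = df.assign(group=groups, channel=df["channel"].astype(str))
    if df["channel"].duplicated().any():
        dupes = sorted(df.loc[df["channel"].duplicated(), "channel"])
        raise SchemaError(f"duplicated channel labels in design: {dupes}")
    for group in (GROUP_KO, GROUP_CTRL):
        n = int((df["group"] == group).sum())
        if n < 2:
            raise DesignError(f"group {group} has {n} channel(s); "
                              f"at least 2 replicates per group are required")
    return SampleDesign(df.reset_index(drop=True))


def read_design(path: str | Path) -> SampleDesign:
    """Read and validate a TSV sample design (columns channel, group, replicate)."""
    return _validate_design(pd.read_csv(path, sep="\t"))


def write_design(design: SampleDesign, path: str | Path) -> Path:
    path = Path(path)
    design.table.to_csv(path, sep="\t", index=False)
    return path


def _check_channels(df: pd.DataFrame, design: SampleDesign, what: str) -> None:
    missing = [c for c in design.channels if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table lacks intensity columns for design "
                          f"channel(s): {missing}")


def _coerce_intensities(df: pd.DataFrame, channels: list[str]) -> pd.DataFrame:
    df = df.copy()
    for ch in channels:
        df[ch] = pd.to_numeric(df[ch], errors="coerce")
    return df


def read_phosphosite_table(path: str | Path, design: SampleDesign,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a phosphosite TSV, keeping only rows that satisfy the
    monophosphosite record invariants.

    Returns ``(accepted, rejected)`` where ``rejected`` carries a ``reason``
    column; accepted + rejected rows partition the input.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"sequence_13": str},
                      float_precision="round_trip")
    missing = [c for c in ID_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"phosphosite table is missing columns: {missing}")
    _check_channels(raw, design, "phosphosite")
    raw = _coerce_intensities(raw, design.channels)

    reasons = pd.Series("", index=raw.index, dtype=str)

    def flag(mask: pd.Series, reason: str) -> None:
        add = mask & (reasons == "")
        reasons[add] = reason

    seq = raw["sequence_13"].fillna("")
    flag(seq.map(len) != 13, "sequence length != 13")
    flag(~seq.map(is_valid_centralized), "invalid centralized sequence")
    center_ok = seq.str.len().eq(13) & (seq.str[HALF_WIDTH] == raw["residue"])
    flag(~center_ok, "center residue does not match residue column")
    flag(~raw["residue"].isin(["S", "T", "Y"]), "residue not S/T/Y")
    pos = pd.to_numeric(raw["position"], errors="coerce")
    flag(pos.isna() | (pos < 1) | (pos != pos.round()), "invalid site position")
    for ch in design.channels:
        flag(raw[ch].isna() | (raw[ch] < 0), f"non-numeric or negative intensity in {ch}")

    rejected = raw[reasons != ""].assign(reason=reasons[reasons != ""])
    accepted = raw[reasons == ""].copy()
    accepted["position"] = accepted["position"].astype(int)
    if len(rejected):
        for _, row in rejected.iterrows():
            logger.warning("rejected phosphosite row %s/%s: %s",
                           row.get("accession"), row.get("position"), row["reason"])
    return accepted.reset_index(drop=True), rejected.reset_index(drop=True)


def read_protein_table(path: str | Path, design: SampleDesign) -> pd.DataFrame:
    """Read a protein-group TSV; accessions must be unique."""
    raw = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in PROTEIN_ID_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"protein table is missing columns: {missing}")
    _check_channels(raw, design, "protein")
    if raw["accession"].duplicated().any():
        dupes = sorted(raw.loc[raw["accession"].duplicated(), "accession"].unique())
        raise SchemaError(f"duplicate protein accessions: {dupes}")
    raw = _coerce_intensities(raw, design.channels)
    bad = raw[design.channels].isna().any(axis=1) | (raw[design.channels] < 0).any(axis=1)
    if bad.any():
        raise SchemaError(f"{int(bad.sum())} protein rows with non-numeric or "
                          f"negative intensities")
    return raw.reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a results table as TSV.

    Floats are written in pandas' shortest round-trip representation, so a
    read restores them bit-for-bit.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# MaxQuant import adapter

MAXQUANT_COLUMN_MAP = {
    "Protein": "accession",
    "Proteins": "accession",
    "Gene names": "gene",
    "Amino acid": "residue",
    "Position": "position",
    "Sequence window": "sequence_13",
}


def adapt_maxquant_sites(df: pd.DataFrame, design: SampleDesign,
                         intensity_prefix: str = "Reporter intensity corrected",
                         site_multiplicity: str = "___1") -> pd.DataFrame:
    """Map a MaxQuant Phospho(STY)Sites-style frame onto the native schema.

    Reporter columns are matched as ``{intensity_prefix} {i}`` in design-channel
    order; the multiplicity-specific intensity columns (``...___1``) select
    the monophosphorylated form.  Sequence windows longer than 13 are trimmed
    symmetrically around the center.
    """
    out = pd.DataFrame()
    for mq, native in MAXQUANT_COLUMN_MAP.items():
        if mq in df.columns and native not in out.columns:
            out[native] = df[mq]
    missing = [c for c in ID_COLUMNS if c not in out.columns and c != "sequence_13"]
    if missing:
        raise SchemaError(f"MaxQuant input lacks mappable columns for: {missing}")
    if "sequence_13" not in out.columns:
        raise SchemaError("MaxQuant input lacks a 'Sequence window' column")
    out["accession"] = out["accession"].astype(str).str.split(";").str[0]
    out["gene"] = out["gene"].astype(str).str.split(";").str[0]

    def trim(window: str) -> str:
        window = str(window).split(";")[0]
        if len(window) > 13:
            mid = len(window) // 2
            window = window[mid - 6:mid + 7]
        return window

    out["sequence_13"] = out["sequence_13"].map(trim)

    for i, channel in enumerate(design.channels, start=1):
        for candidate in (f"{intensity_prefix} {i}{site_multiplicity}",
                          f"{intensity_prefix} {i}"):
            if candidate in df.columns:
                out[channel] = df[candidate]
                break
        else:
            raise SchemaError(f"no reporter intensity column found for design "
                              f"channel {channel} (index {i})")
    return out
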