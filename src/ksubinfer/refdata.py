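"""Published CAMK2D phosphosite catalogs used for validation.

These small tables come from a CRISPR *Camk2d*-knockout TMT phosphoproteomics
experiment in mouse mpkCCD collecting-duct cells, the study system this
package's statistics were built for.  Each row carries the printed
(4-decimal-rounded) log2(KO/Intact) effect and p_joint, so they should be
evaluated in ``table_replication`` comparison mode.

* ``camk2d_direct_targets()`` — the 35 inferred direct CAMK2D substrates, all
  matching the (R/K)-X-X-p(S/T)-X-(D/E) consensus;
* ``camk2d_kinase_sites()`` — the 19 regulated phosphosites on downstream
  protein kinases;
* ``camk2d_phosphatase_sites()`` — the 4 regulated phosphosites on protein
  phosphatases and phosphatase regulators.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = ["accession", "gene", "site", "sequence_13", "log2_effect", "p_joint"]

_DIRECT_TARGETS = [
    ("E9Q616", "Ahnak", "S2000", "GELKGPSVDVEVP", -0.39, 0.0001),
    ("A1IGU4", "Arhgef37", "S15", "ASSKSESPEQEDQ", -0.38, 0.0003),
    ("O88379", "Baz1a", "S1412", "RGRKRQSTESSPV", -0.42, 0.0001),
    ("Q9D219", "Bcl9", "S104", "KRERSISADSFDQ", -0.33, 0.0001),
    ("Q6EDY6", "Carmil1", "S1328", "SSPRSFSQEASRR", -0.31, 0.0001),
    ("Q9JLQ0", "Cd2ap", "S233", "LRTRTSSSETEEK", -0.52, 0.0000),
    ("Q04899", "Cdk18", "S66", "QNQRRFSMEDLNK", -0.33, 0.0005),
    ("Q09XV5", "Chd8", "S2040", "ARSRLTSQDYEVR", -0.41, 0.0005),
    ("Q8CJ61", "Cmtm4", "S194", "IRARTESRDVDSR", -0.53, 0.0000),
    ("Q80XI3", "Eif4g3", "S1151", "TFLRGSSKDLLDN", -0.69, 0.0000),
    ("Q05D44", "Eif5b", "S108", "QKGKKTSFDENDS", -0.43, 0.0000),
    ("P18608", "Hmgn1", "S7", "MPKRKVSADGAAK", -0.52, 0.0000),
    ("Q6ZPV2", "Ino80", "S470", "HQARTRSFDEDAK", -0.43, 0.0000),
    ("P15066", "Jund", "S100", "GLLKLASPELERL", -0.68, 0.0000),
    ("Q5SVQ0", "Kat7", "S228", "CKVRAQSRDKQIE", -0.46, 0.0001),
    ("B1AVY7", "Kif16b", "S838", "QLVKLASLEKDLV", -0.47, 0.0003),
    ("P57016", "Lad1", "T19", "SLARQRTLEDEEE", -0.79, 0.0000),
    ("Q3UH68", "Limch1", "S379", "SRRRSASQDLIKK", -0.58, 0.0000),
    ("Q9Z2D1", "Mtmr2", "S6", "_MEKSSSCESLGA", -0.33, 0.0004),
    ("Q5HZI1", "Mtus1", "S1143", "AISRQLSTEQAAL", -0.45, 0.0001),
    ("Q78HU3", "Mvb12a", "S168", "QDMRGLSLDPPKE", -0.74, 0.0000),
    ("Q9CX66", "Nopchap1", "S125", "EMSRSDSKEEDSP", -0.46, 0.0002),
    ("Q9DBS9", "Osbpl3", "S33", "QGSRQDSWEVVEG", -0.40, 0.0000),
    ("Q62048", "Pea15", "S116", "DIIRQPSEEEIIK", -0.78, 0.0000),
    ("Q9DBC7", "Prkar1a", "S77", "TGIRTDSREDEIS", -0.36, 0.0003),
    ("Q6GYP7", "Ralgapa1", "T753", "SIVRQKTVDIDDA", -0.39, 0.0002),
    ("Q8BU14", "Sec62", "S309", "KQQKSDSEEKSDS", -0.40, 0.0003),
    ("Q9CY58", "Serbp1", "S329", "VLHKSKSEEAHAE", -0.94, 0.0000),
    ("Q6ZWQ0", "Syne2", "T6489", "LLLRQGTDDSKEG", -0.65, 0.0000),
    ("Q8CC35", "Synpo", "S258", "HLEKVASEEEEVP", -0.54, 0.0000),
    ("P39447", "Tjp1", "S1051", "YIEKQASRDLEQP", -0.63, 0.0000),
    ("Q9Z0U1", "Tjp2", "S988", "SQNREDSFDYSKS", -1.10, 0.0000),
    ("P20065", "Tmsb4x", "T29", "KLKKTETQEKNPL", -0.64, 0.0000),
    ("Q99PP7", "Trim33", "S1134", "RRKRLKSDERPVH", -0.37, 0.0003),
    ("Q8BJ05", "Zc3h14", "S309", "VKVKRFSHDGEEE", -0.38, 0.0004),
]

_KINASE_SITES = [
    ("Q9Z277", "Baz1b", "S325", "KKPKRDSSSLSSP", -0.124, 0.0002),
    ("P11440", "Cdk1", "T14", "EKIGEGTYGVVYK", 0.525, 0.0000),
    ("P11440", "Cdk1", "Y15", "KIGEGTYGVVYKG", 0.461, 0.0000),
    ("Q04899", "Cdk18", "S66", "QNQRRFSMEDLNK", -0.332, 0.0005),
    ("O08796", "Eef2k", "S444", "GDSGYPSEKRSDL", -1.136, 0.0000),
    ("P70424", "Erbb2", "Y878", "DIDETEYHADGGK", -0.190, 0.0001),
    ("Q9ESL4", "Map3k20", "S567", "PGSRSDSSADCQW", 0.371, 0.0002),
    ("Q9ESL4", "Map3k20", "S638", "NPSRSSSPTQYGL", 0.432, 0.0000),
    ("Q8BPM2", "Map4k5", "S433", "QVLRRQSSPSCVP", -0.450, 0.0000),
    ("Q3U214", "Mast3", "S702", "RYRHLGSEDDETN", 0.434, 0.0001),
    ("Q6P9R2", "Oxsr1", "S359", "AISQLRSPRVKDS", 0.450, 0.0000),
    ("Q8CIN4", "Pak2", "T143", "QKYLSFTPPEKDG", -0.462, 0.0004),
    ("Q8CEE6", "Pask", "S852", "ILHRQTSDILVDR", 0.519, 0.0000),
    ("Q5EG47", "Prkaa1", "S508", "SCQRSDSDAEAQG", -0.306, 0.0004),
    ("Q5EG47", "Prkaa1", "T490", "AKSGTATPQRSGS", 0.366, 0.0000),
    ("P97313", "Prkdc", "S3215", "VDEDEESIDREVY", 0.291, 0.0001),
    ("O54988", "Slk", "S779", "KDSGSVSLQETRR", 0.511, 0.0000),
    ("O55098", "Stk10", "S13", "RRILRLSTFEKRK", 0.469, 0.0001),
    ("Q9WTK7", "Stk11", "S31", "FIHRIDSTEVIYQ", -0.275, 0.0004),
]

_PHOSPHATASE_SITES = [
    ("Q9DBR7", "Ppp1r12a", "S445", "GLRKTGSYGALAE", 0.305, 0.0000),
    ("Q9DBR7", "Ppp1r12a", "T669", "RRRSYLTPVRDEE", 0.318, 0.0002),
    ("Q9DCL8", "Ppp1r2", "S90", "EDAYSDSEGNEVM", -0.446, 0.0001),
    ("Q76I79", "Ssh1", "T981", "GSLNFSTEDLSSE", 0.305, 0.0004),
]


def _frame(rows: list[tuple]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.index = df["gene"] + "_" + df["site"]
    df.index.name = "site_id"
    return df


def camk2d_direct_targets() -> pd.DataFrame:
    """The 35 inferred direct CAMK2D substrate phosphosites."""
    return _frame(_DIRECT_TARGETS)


def camk2d_kinase_sites() -> pd.DataFrame:
    """The 19 regulated phosphosites found on downstream protein kinases."""
    return _frame(_KINASE_SITES)


def camk2d_phosphatase_sites() -> pd.DataFrame:
    """The 4 regulated phosphosites on phosphatases and their regulators."""
    return _frame(_PHOSPHATASE_SITES)
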