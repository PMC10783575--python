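"""Synthetic knockout-vs-control TMT phosphoproteomics with known ground truth.

The generator emulates an 11-plex-style reporter design: a handful of
knockout clones against control clones (5 vs 3 by default), log-normal
measurement noise (additive Gaussian in log2 space), a minority of
phosphosites planted as *direct* kinase substrates — negative log2 effects on
sequences carrying the (R/K)-X-X-p(S/T)-X-(D/E) consensus — a minority of
*indirect* up-sites carrying P at +1, and a subset of proteins with a planted
total-abundance shift that propagates into every phosphosite they host (the
confounder the protein-level exclusion rule exists to catch).

Background sequences are uniform over the 20 amino acids (configurable via
``residue_frequencies``); the center residue is S or T at 4:1.  A single root
seed is split deterministically per table, so the same seed and config give
byte-identical outputs and adding channels does not reshuffle the sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .motif import AMINO_ACIDS, HALF_WIDTH, WINDOW
from .tables_io import SampleDesign, make_design, write_design, write_table

CLASS_DIRECT = "direct"
CLASS_INDIRECT_UP = "indirect_up"
CLASS_NULL = "null"


class ConfigError(ValueError):
    """A SyntheticConfig field violates its constraints."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one simulated knockout experiment.

    Defaults mirror the study design the generator emulates: 5 KO vs 3
    control biological replicates, ~2% of sites truly regulated in either
    direction, log2 effects of +/-0.8, reporter noise of 0.25 log2 units, and
    ~3% of proteins with a 0.5-log2 total-abundance shift.
    """

    n_proteins: int = 200
    sites_per_protein: int = 5
    n_ko_replicates: int = 5
    n_ctrl_replicates: int = 3
    frac_direct: float = 0.01
    frac_indirect_up: float = 0.02
    direct_effect_log2: float = -0.8
    indirect_effect_log2: float = 0.8
    noise_sd_log2: float = 0.25
    frac_protein_shift: float = 0.03
    protein_effect_log2: float = 0.5
    base_intensity_log2: float = 20.0
    frac_st_center: float = 0.8  # P(S) vs P(T) at the phosphosite
    residue_frequencies: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        def positive(name: str) -> None:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")

        positive("n_proteins")
        positive("sites_per_protein")
        if self.noise_sd_log2 < 0:
            raise ConfigError(f"noise_sd_log2 must be >= 0, got {self.noise_sd_log2}")
        for name in ("n_ko_replicates", "n_ctrl_replicates"):
            if getattr(self, name) < 2:
                raise ConfigError(f"{name} must be >= 2 (t-test needs 2 per group), "
                                  f"got {getattr(self, name)}")
        for name in ("frac_direct", "frac_indirect_up", "frac_protein_shift"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.frac_direct + self.frac_indirect_up > 1.0:
            raise ConfigError("frac_direct + frac_indirect_up must be <= 1")
        if self.direct_effect_log2 > 0:
            raise ConfigError("direct_effect_log2 must be <= 0 (knockout removes "
                              "the kinase, so direct sites go down)")
        if self.indirect_effect_log2 < 0:
            raise ConfigError("indirect_effect_log2 must be >= 0")

    @property
    def n_sites(self) -> int:
        return self.n_proteins * self.sites_per_protein

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "SyntheticConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)  # type: ignore[arg-type]


def _residue_sampler(config: SyntheticConfig):
    if config.residue_frequencies is None:
        letters = np.array(list(AMINO_ACIDS))
        probs = np.full(len(letters), 1.0 / len(letters))
    else:
        letters = np.array(list(config.residue_frequencies))
        probs = np.array([config.residue_frequencies[aa] for aa in letters], float)
        if (probs < 0).any() or probs.sum() <= 0:
            raise ConfigError("residue_frequencies must be non-negative and sum > 0")
        probs = probs / probs.sum()
    return letters, probs


def _make_sequences(classes: np.ndarray, config: SyntheticConfig,
                    rng: np.random.Generator) -> list[str]:
    n = len(classes)
    letters, probs = _residue_sampler(config)
    seqs = rng.choice(letters, size=(n, WINDOW), p=probs)
    center = rng.choice(np.array(["S", "T"]),
                        size=n, p=[config.frac_st_center, 1 - config.frac_st_center])
    seqs[:, HALF_WIDTH] = center
    direct = classes == CLASS_DIRECT
    seqs[direct, HALF_WIDTH - 3] = rng.choice(np.array(["R", "K"]), size=int(direct.sum()))
    seqs[direct, HALF_WIDTH + 2] = rng.choice(np.array(["D", "E"]), size=int(direct.sum()))
    indirect = classes == CLASS_INDIRECT_UP
    seqs[indirect, HALF_WIDTH + 1] = "P"
    return ["".join(row) for row in seqs]


def generate_experiment(config: SyntheticConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame, SampleDesign, pd.DataFrame]:
    """Simulate one experiment.

    Returns ``(phosphosites, proteins, design, truth)``.  Reporter intensities
    are ``2 ** (base + protein_shift*[KO] + site_effect*[KO] + N(0, noise_sd))``
    per channel; the protein table aggregates the protein shift with
    independent noise.  ``truth`` lists every site's class, planted effect and
    whether its parent protein carries an abundance shift.

    The root seed is split deterministically into independent streams for
    class assignment, sequences, site noise and protein noise.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_assign, rng_seq, rng_site, rng_prot = map(np.random.default_rng, ss.spawn(4))

    n_sites = config.n_sites
    n_direct = int(round(config.frac_direct * n_sites))
    n_indirect = int(round(config.frac_indirect_up * n_sites))

    accessions = np.repeat([f"SYN{i:04d}" for i in range(config.n_proteins)],
                           config.sites_per_protein)
    genes = np.repeat([f"GENE{i:04d}" for i in range(config.n_proteins)],
                      config.sites_per_protein)

    order = rng_assign.permutation(n_sites)
    classes = np.full(n_sites, CLASS_NULL, dtype=object)
    classes[order[:n_direct]] = CLASS_DIRECT
    classes[order[n_direct:n_direct + n_indirect]] = CLASS_INDIRECT_UP

    # protein-level shifts land on proteins hosting no planted site, so the
    # ground-truth classes keep a single unambiguous meaning
    n_shift = int(round(config.frac_protein_shift * config.n_proteins))
    protein_ids = np.array([f"SYN{i:04d}" for i in range(config.n_proteins)])
    hosts_planted = pd.Series(classes != CLASS_NULL).groupby(accessions).any()
    eligible = protein_ids[~hosts_planted.reindex(protein_ids).fillna(False).to_numpy()]
    n_shift = min(n_shift, len(eligible))
    shifted = set(rng_assign.choice(eligible, size=n_shift, replace=False)) if n_shift else set()

    sequences = _make_sequences(classes, config, rng_seq)
    positions = 7 + 10 * np.arange(n_sites) % 990  # synthetic 1-based positions
    residues = [s[HALF_WIDTH] for s in sequences]
    site_ids = [f"{g}_{r}{p}" for g, r, p in zip(genes, residues, positions)]

    effects = np.where(classes == CLASS_DIRECT, config.direct_effect_log2,
                       np.where(classes == CLASS_INDIRECT_UP,
                                config.indirect_effect_log2, 0.0))
    protein_shift = np.array([config.protein_effect_log2 if a in shifted else 0.0
                              for a in accessions])

    design = make_design(config.n_ko_replicates, config.n_ctrl_replicates)
    is_ko = np.array([1.0 if ch.startswith("KO") else 0.0 for ch in design.channels])
    n_ch = len(design.channels)

    noise = rng_site.normal(0.0, config.noise_sd_log2, size=(n_sites, n_ch))
    log2_site = (config.base_intensity_log2
                 + np.outer(protein_shift + effects, is_ko) + noise)
    phospho = pd.DataFrame({
        "accession": accessions, "gene": genes, "residue": residues,
        "position": positions, "sequence_13": sequences,
    })
    phospho[design.channels] = 2.0 ** log2_site
    phospho.index = pd.Index(site_ids, name="site_id")
    phospho.insert(0, "site_id", site_ids)

    prot_shift_vec = np.array([config.protein_effect_log2 if a in shifted else 0.0
                               for a in protein_ids])
    prot_noise = rng_prot.normal(0.0, config.noise_sd_log2,
                                 size=(config.n_proteins, n_ch))
    log2_prot = config.base_intensity_log2 + np.outer(prot_shift_vec, is_ko) + prot_noise
    proteins = pd.DataFrame({
        "accession": protein_ids,
        "gene": [f"GENE{i:04d}" for i in range(config.n_proteins)],
    })
    proteins[design.channels] = 2.0 ** log2_prot

    truth = pd.DataFrame({
        "site_id": site_ids,
        "accession": accessions,
        "sequence_13": sequences,
        "class": classes,
        "planted_effect_log2": effects,
        "protein_shifted": protein_shift != 0.0,
    }).set_index("site_id", drop=False)

    return phospho, proteins, design, truth


def write_fixture(tables: tuple[pd.DataFrame, pd.DataFrame, SampleDesign, pd.DataFrame],
                  directory: str | Path) -> dict[str, Path]:
    """Write phosphosites.tsv, proteins.tsv, design.tsv and truth.tsv.

    Values round-trip through :mod:`ksubinfer.tables_io` at full precision.
    """
    phospho, proteins, design, truth = tables
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "phosphosites": write_table(phospho, directory / "phosphosites.tsv"),
        "proteins": write_table(proteins, directory / "proteins.tsv"),
        "design": write_design(design, directory / "design.tsv"),
        "truth": write_table(truth.reset_index(drop=True), directory / "truth.tsv"),
    }
    return paths
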