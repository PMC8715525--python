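"""Synthetic benchmark data with the statistical structure the silk screen assumes.

The generator emulates, at desk scale, the inputs of a tube-dwelling
crustacean silk-proteomics study:

* long repetitive silk proteins built from motif grammars — a
  GAGAGS-type (silkworm-fibroin-like) family, three serine-rich
  SX-repeat paralogs sharing a conserved N-terminal flank
  (caddisworm-fibroin-like), a GPX-type (collagen-like) family and a
  cysteine-rich (keratin-associated-protein-like) family;
* globular decoy proteins forming both the background proteome and the
  known-protein database for the novelty filter;
* replicate tryptic peptide feature-area tables with log-normal
  intensity noise, per-replicate detection dropout and flagged
  contaminant proteins;
* multi-species transcriptome assemblies with planted ortholog
  presence/absence and TPM expression tables.

Every planted object carries ground-truth metadata in the benchmark
manifest so downstream recovery can be scored exactly.  All randomness
flows from a single seed through `numpy.random.SeedSequence` child
spawns, so partial re-runs of individual components are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quant import TranscriptRecord, compute_tpm

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Observable tryptic peptide length window (fully tryptic, 0 missed
#: cleavages) used both for simulated detection and for the iBAQ
#: theoretical peptide count.
DETECTABLE_MIN = 6
DETECTABLE_MAX = 30

#: Average globular-protein residue frequencies (rounded SwissProt-like
#: composition) used as the default decoy composition.
GLOBULAR_COMPOSITION = {
    "A": 0.0826, "C": 0.0139, "D": 0.0546, "E": 0.0672, "F": 0.0387,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0475, "Q": 0.0393, "R": 0.0553,
    "S": 0.0665, "T": 0.0536, "V": 0.0686, "W": 0.0110, "Y": 0.0291,
}

#: Canonical one-codon-per-residue back-translation table, used when no
#: generator is supplied.
BACK_TRANSLATION = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    "X": "NNN", "*": "TAA",
}

#: All standard-code codons per residue.  Planted transcripts sample
#: synonymous codons (seed-deterministically): with a single fixed codon
#: per residue the CDS of a repeat protein is periodic DNA whose *other*
#: reading frames are again periodic low-complexity proteins, which is
#: not how real transcripts behave; codon variety scatters stop codons
#: through the off-frames and fragments them, as in real data.
SYNONYMOUS_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("CTG", "CTT", "CTC", "CTA", "TTA", "TTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
    "X": ("NNN",),
    "*": ("TAA",),
}

#: Synonymous-codon sampling weights.  Non-uniform for a few residues so
#: that off-frame products of repeat-rich coding sequence are dense in
#: stop codons (TCA reads TGA on the reverse strand; TTA/CTA likewise)
#: — mimicking the stop-fragmented off-frames of real transcripts, which
#: a translated homology search never chains across.
SYNONYMOUS_WEIGHTS = {
    "S": (0.02, 0.02, 0.50, 0.06, 0.30, 0.10),  # favor TCA (reverse reads TGA), then AGT (TAA/TGA junctions)
    "L": (0.1, 0.1, 0.1, 0.2, 0.3, 0.2),  # favor TTA/CTA
    "P": (0.60, 0.05, 0.10, 0.25),        # favor CCT (T|GA stops); avoid CCC (reverse reads Gly)
    "V": (0.05, 0.15, 0.60, 0.20),        # favor GTA (TAG/TAA stops in the +2 off-frame)
    "E": (0.25, 0.75),                    # favor GAG (reverse reads Leu, not Phe)
    "A": (0.55, 0.02, 0.35, 0.08),        # avoid GCC (CCA junctions read back as Trp) and GCG (rc Pro)
    "Y": (0.7, 0.3),                      # favor TAT (TTA across junctions)
    "T": (0.80, 0.08, 0.06, 0.06),        # favor ACT (CTA junctions before A-starts)
    "G": (0.30, 0.45, 0.25, 0.0),         # never GGG (reverse would read Pro)
    "R": (0.1, 0.1, 0.1, 0.1, 0.2, 0.4),  # favor AGG (reverse reads CCT)
}

#: Context rules (residue, next residue) -> codon weights, overriding the
#: marginal weights above.  Junction dinucleotides decide whether an
#: off-frame reads a stop (wanted) or tryptophan/low-complexity filler
#: (unwanted, since Trp-rich off-frames cross-match repeat queries), and
#: the right choice depends on what follows:  e.g. Ala before Gly must
#: avoid GCT (GCT|GGN contains TGG = Trp) while Ala before Ser wants
#: exactly GCT (GCT|AGN contains CTA, a reverse-strand stop).
CONTEXT_WEIGHTS = {
    ("A", "G"): (0.05, 0.02, 0.90, 0.03),   # GCA: no TGG at the A|G junction
    ("A", "S"): (0.95, 0.01, 0.03, 0.01),   # GCT|AGx -> CTA (reverse stop)
    ("G", "G"): (0.05, 0.65, 0.30, 0.0),    # avoid GGT|GGx -> TGG
    ("G", "A"): (0.05, 0.65, 0.30, 0.0),
    ("G", "S"): (0.85, 0.10, 0.05, 0.0),    # GGT|AGx -> TAG (forward stop)
    ("G", "Y"): (0.50, 0.50, 0.0, 0.0),     # GG[TC]|TAT -> TTA/CTA (reverse stops)
    ("T", "G"): (0.05, 0.60, 0.30, 0.05),   # avoid ACT|GGx -> TGG
    ("T", "Y"): (0.95, 0.02, 0.02, 0.01),   # ACT|TAT -> TTA
    ("Y", "G"): (0.10, 0.90),               # avoid TAT|GGx -> TGG
    ("C", "Y"): (0.95, 0.05),               # TGT|TAT -> TTA
    ("P", "D"): (0.95, 0.01, 0.03, 0.01),   # CCT|GAx -> TGA (forward stop)
    ("P", "E"): (0.95, 0.01, 0.03, 0.01),
    ("P", "Q"): (0.95, 0.01, 0.03, 0.01),   # CCT|CAx -> TCA (reverse stop)
    ("P", "T"): (0.95, 0.01, 0.03, 0.01),   # CCT|ACx -> CTA (reverse stop)
    ("P", "S"): (0.95, 0.01, 0.03, 0.01),
    ("V", "G"): (0.02, 0.08, 0.70, 0.20),   # GTA|GGx -> TAG
    ("V", "S"): (0.02, 0.08, 0.70, 0.20),   # GT[AG]|AGx -> TAA/TGA
    ("S", "G"): (0.10, 0.02, 0.80, 0.04, 0.02, 0.02),  # avoid AGT|GGx -> TGG; TCA stops
}


class ConfigurationError(ValueError):
    """Raised for degenerate generator configurations."""


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid record, optionally tied to a transcript and species."""

    id: str
    seq: str
    species_id: str | None = None
    transcript_id: str | None = None
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MotifGrammar:
    """A weighted repeat-unit grammar for one silk family.

    ``core_units`` are the dominant repeat units (e.g. GAGAGS for a
    silkworm-fibroin-like family); ``linker_units`` are rarer spacer
    motifs interleaved among them.  ``unit_weights`` are sampling
    probabilities over core + linker units (in that order) and must sum
    to 1.  ``mutation_rate`` is the per-residue substitution probability
    applied independently to every sampled unit, yielding imperfect
    tandem repeats.
    """

    name: str
    core_units: tuple[str, ...]
    linker_units: tuple[str, ...] = ()
    unit_weights: tuple[float, ...] | None = None
    mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        units = self.all_units
        if not units:
            raise ConfigurationError("grammar must define at least one unit")
        for u in units:
            if not u or set(u) - set(AMINO_ACIDS):
                raise ConfigurationError(f"invalid repeat unit {u!r}")
        if self.unit_weights is not None:
            if len(self.unit_weights) != len(units):
                raise ConfigurationError("unit_weights must cover core + linker units")
            if abs(sum(self.unit_weights) - 1.0) > 1e-9:
                raise ConfigurationError("unit_weights must sum to 1")
            if any(w < 0 for w in self.unit_weights):
                raise ConfigurationError("unit_weights must be non-negative")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ConfigurationError("mutation_rate must be in [0, 1]")

    @property
    def all_units(self) -> tuple[str, ...]:
        return tuple(self.core_units) + tuple(self.linker_units)

    @property
    def weights(self) -> np.ndarray:
        if self.unit_weights is not None:
            return np.asarray(self.unit_weights, dtype=float)
        n = len(self.all_units)
        return np.full(n, 1.0 / n)


@dataclass(frozen=True)
class SilkFamilySpec:
    """Study conditions for one planted silk family."""

    family_id: str
    motif_class: str
    grammar: MotifGrammar
    n_units: int
    n_flank: str
    c_flank: str
    base_abundance: float
    isoform_fractions: tuple[float, ...] = (1.0,)
    flank_mutation: float = 0.0  # per-paralog divergence of a shared flank
    homology_group: str | None = None  # families in one group cross-detect

    @property
    def group(self) -> str:
        return self.homology_group or self.family_id


# Fixed, designed terminal flanks.  Synthetic sequences: non-repetitive,
# with tryptic cleavage sites every 7-13 residues so that every planted
# protein yields several observable peptides.
N_FLANK_GA = "YMVFTIQWDYKYTVVYVFCGRFGLNWFAFYVRQMHTVHCQATLYKTWWHAGGFGKVDCGLNIKFMTYMFAERMWYECFCLK"
N_FLANK_SX = "WLLTLFNKDTDDCAINDTKQMWFTMTIHMFNKAATQGHGMIGQRGDFILHCDICVKWFEEWHFERMINQQWACETADRDYCTCICFK"
N_FLANK_GPX = "VVYVIHWNFTKFNFDCMFLVLQTKTASESNQMKLALICTNQDTKHMMVEALWGMKWVYQVCSSGALRANSQNYADKTHQFQDFK"
N_FLANK_CC = "GNNAGHFFACHKWSVDQGTFWLDKHMVCWATRTFTDYSDEAGKAMGYMSAINYGMKYFIGCMNCRSWFQEVQKCYTTVWSFEK"
C_FLANK_GA = "YGESVLMYRYQWTFLSGGR"
C_FLANK_SX = "QYMGELMMMKHCSNTFFATHK"
C_FLANK_GPX = "GWGGWMCECRVIVHDIYCYNMK"
C_FLANK_CC = "SDINDWTHWYKYNFQADVISFR"

DEFAULT_FAMILIES: tuple[SilkFamilySpec, ...] = (
    SilkFamilySpec(
        family_id="famGA",
        motif_class="silkworm-fibroin-like",
        grammar=MotifGrammar(
            name="GAGAGS",
            core_units=("GAGAGS", "GAGA", "GAGVGY", "GAAS", "GAGAVS"),
            linker_units=("SGRVQQTYTSSF",),
            unit_weights=(0.40, 0.05, 0.15, 0.15, 0.15, 0.10),
            mutation_rate=0.02,
        ),
        n_units=240,
        n_flank=N_FLANK_GA,
        c_flank=C_FLANK_GA,
        base_abundance=1000.0,
        isoform_fractions=(1.0, 0.97, 0.95, 0.93, 0.98, 0.96),
    ),
    SilkFamilySpec(
        family_id="famS1",
        motif_class="caddisworm-fibroin-like",
        grammar=MotifGrammar(
            name="SX-a",
            core_units=("SVSWSY",),
            unit_weights=(1.0,),
            mutation_rate=0.03,
        ),
        n_units=180,
        n_flank=N_FLANK_SX,
        c_flank=C_FLANK_SX,
        base_abundance=300.0,
        isoform_fractions=(1.0, 0.96, 0.93, 0.98),
        flank_mutation=0.03,
        homology_group="caddis",
    ),
    SilkFamilySpec(
        family_id="famS2",
        motif_class="caddisworm-fibroin-like",
        grammar=MotifGrammar(
            name="SX-b",
            core_units=("SFSYSV",),
            unit_weights=(1.0,),
            mutation_rate=0.03,
        ),
        n_units=165,
        n_flank=N_FLANK_SX,
        c_flank=C_FLANK_SX,
        base_abundance=200.0,
        isoform_fractions=(1.0, 0.95, 0.97, 0.93),
        flank_mutation=0.03,
        homology_group="caddis",
    ),
    SilkFamilySpec(
        family_id="famS3",
        motif_class="caddisworm-fibroin-like",
        grammar=MotifGrammar(
            name="SX-c",
            core_units=("SWSFSV",),
            unit_weights=(1.0,),
            mutation_rate=0.03,
        ),
        n_units=150,
        n_flank=N_FLANK_SX,
        c_flank=C_FLANK_SX,
        base_abundance=150.0,
        isoform_fractions=(1.0, 0.96),
        flank_mutation=0.03,
        homology_group="caddis",
    ),
    SilkFamilySpec(
        family_id="famGPX",
        motif_class="collagen-like",
        grammar=MotifGrammar(
            name="GPX",
            core_units=("GPD", "GPE", "GPT", "GPS", "GPQ", "GPV"),
            linker_units=("GPDGEK",),
            unit_weights=(0.12, 0.16, 0.16, 0.12, 0.20, 0.14, 0.10),
            mutation_rate=0.02,
        ),
        n_units=280,
        n_flank=N_FLANK_GPX,
        c_flank=C_FLANK_GPX,
        base_abundance=100.0,
        isoform_fractions=(1.0, 0.94, 0.97),
    ),
    SilkFamilySpec(
        family_id="famCC",
        motif_class="KAP-like",
        grammar=MotifGrammar(
            name="CC",
            core_units=("CCYPSC", "CCVSSC"),
            linker_units=("YCTKCC",),
            unit_weights=(0.70, 0.15, 0.15),
            mutation_rate=0.02,
        ),
        n_units=120,
        n_flank=N_FLANK_CC,
        c_flank=C_FLANK_CC,
        base_abundance=80.0,
        isoform_fractions=(1.0, 0.95),
    ),
)

#: Abundance of each successive isoform relative to the family base.
ISOFORM_ABUNDANCE_FACTORS = (1.0, 0.45, 0.30, 0.22, 0.15, 0.10)


def _default_presence(n_silk: int, n_species: int) -> np.ndarray:
    """Default ortholog presence: mostly conserved, with the GA family
    absent from the two last species and the whole S-rich paralog group
    absent from the second-to-last (echoing lineages lacking parts of
    the silk repertoire).  Absences are consistent within a homology
    group: members of one group legitimately detect each other's
    transcripts, so a group is either present or absent per species."""
    presence = np.ones((n_silk, n_species), dtype=bool)
    absences = [
        (0, n_species - 2),
        (0, n_species - 1),
        (1, n_species - 2),
        (2, n_species - 2),
        (3, n_species - 2),
    ]
    for i, j in absences:
        if 0 <= i < n_silk and 0 <= j < n_species:
            presence[i, j] = False
    return presence


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic benchmark instance."""

    seed: int = 0
    n_species: int = 8
    n_silk: int = 6
    n_decoys: int = 500
    n_replicates: int = 5
    detection_prob: float = 0.9
    intensity_cv: float = 0.3
    contaminant_count: int = 10
    ortholog_presence: tuple[tuple[bool, ...], ...] | None = None
    divergence: float = 0.05
    decoy_length_range: tuple[int, int] = (120, 500)
    decoy_transcripts_per_species: int = 30
    families: tuple[SilkFamilySpec, ...] = DEFAULT_FAMILIES

    def __post_init__(self) -> None:
        for name in ("n_species", "n_silk", "n_decoys", "contaminant_count"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2 (CV undefined otherwise)")
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ConfigurationError("detection_prob must be in [0, 1]")
        if self.intensity_cv < 0:
            raise ConfigurationError("intensity_cv must be non-negative")
        if self.divergence < 0:
            raise ConfigurationError("divergence must be non-negative")

    @property
    def family_specs(self) -> tuple[SilkFamilySpec, ...]:
        """The first ``n_silk`` family templates (cycled if necessary)."""
        if self.n_silk <= len(self.families):
            return self.families[: self.n_silk]
        reps = [
            replace(self.families[i % len(self.families)],
                    family_id=f"{self.families[i % len(self.families)].family_id}x{i}")
            for i in range(self.n_silk)
        ]
        return tuple(reps)

    @property
    def presence_matrix(self) -> np.ndarray:
        if self.ortholog_presence is not None:
            mat = np.asarray(self.ortholog_presence, dtype=bool)
            if mat.shape != (self.n_silk, self.n_species):
                raise ConfigurationError(
                    "ortholog_presence must have shape (n_silk, n_species)"
                )
            return mat
        return _default_presence(self.n_silk, self.n_species)

    def child_rng(self, *key: int) -> np.random.Generator:
        """Per-component generator spawned from the global seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=tuple(key)))


# --- elementary generators --------------------------------------------------

def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Point-substitute each residue with probability ``rate`` (to one of
    the 19 other residues, uniformly)."""
    if rate <= 0 or not seq:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_silk_protein(
    grammar: MotifGrammar,
    n_units: int,
    termini: tuple[str, str] = ("", ""),
    rng_seed: int | np.random.Generator = 0,
    protein_id: str = "silk",
) -> ProteinSequence:
    """Sample a repetitive silk-like protein from a motif grammar.

    The sequence is N-flank + concatenation of ``n_units`` units (each
    sampled by weight and independently point-mutated at the grammar's
    mutation rate) + C-flank.  Deterministic for a fixed seed.
    """
    if n_units < 1:
        raise ConfigurationError("n_units must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    units = grammar.all_units
    idx = rng.choice(len(units), size=n_units, p=grammar.weights)
    body = "".join(mutate_sequence(units[i], grammar.mutation_rate, rng) for i in idx)
    n_flank, c_flank = termini
    return ProteinSequence(id=protein_id, seq=n_flank + body + c_flank)


def generate_decoy_proteome(
    n: int,
    length_range: tuple[int, int] = (120, 500),
    composition: Mapping[str, float] | Sequence[float] | None = None,
    rng_seed: int | np.random.Generator = 0,
    id_prefix: str = "decoy",
) -> list[ProteinSequence]:
    """Sample ``n`` i.i.d. globular decoy proteins.

    Lengths are uniform over ``length_range`` (inclusive) and residues
    i.i.d. from ``composition`` (default: average globular-protein
    frequencies).
    """
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    if composition is None:
        comp = np.array([GLOBULAR_COMPOSITION[a] for a in AMINO_ACIDS])
    elif isinstance(composition, Mapping):
        comp = np.array([float(composition.get(a, 0.0)) for a in AMINO_ACIDS])
    else:
        comp = np.asarray(composition, dtype=float)
        if comp.shape != (20,):
            raise ConfigurationError("composition must be a 20-vector")
    total = comp.sum()
    if total <= 0:
        raise ConfigurationError("composition is degenerate (all zero)")
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError("composition must sum to 1")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ConfigurationError("invalid length range")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    aa = np.array(list(AMINO_ACIDS))
    out = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(aa[rng.choice(20, size=length, p=comp / total)])
        out.append(ProteinSequence(id=f"{id_prefix}{i:04d}", seq=seq))
    return out


# --- in-silico digestion ----------------------------------------------------

def cleavage_sites(seq: str) -> list[int]:
    """Tryptic cleavage positions (Keil rule): after K or R, not before P."""
    return [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]


def in_silico_digest(protein: ProteinSequence | str, missed_cleavages: int = 2) -> list[str]:
    """All tryptic peptides with up to ``missed_cleavages`` internal
    uncleaved sites, in order of start position then length."""
    seq = protein.seq if isinstance(protein, ProteinSequence) else protein
    if missed_cleavages < 0:
        raise ConfigurationError("missed_cleavages must be >= 0")
    if not seq:
        return []
    bounds = [0] + cleavage_sites(seq) + [len(seq)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(bounds))):
            peptides.append(seq[bounds[i] : bounds[j]])
    return peptides


def detectable_peptides(
    protein: ProteinSequence | str,
    min_len: int = DETECTABLE_MIN,
    max_len: int = DETECTABLE_MAX,
) -> list[str]:
    """Fully tryptic peptides (0 missed cleavages) within the observable
    length window; the universe both for simulated detection and for the
    iBAQ theoretical peptide count."""
    return [p for p in in_silico_digest(protein, 0) if min_len <= len(p) <= max_len]


# --- peptide-level evidence -------------------------------------------------

def simulate_peptide_evidence(
    proteins: Sequence[ProteinSequence],
    config: SynthConfig,
    abundances: Mapping[str, float] | None = None,
    contaminants: Sequence[ProteinSequence] | None = None,
) -> pd.DataFrame:
    """Replicate peptide feature-area table for a set of proteins.

    Every observable peptide of every protein is detected in each
    replicate with probability ``detection_prob``; detected areas are
    log-normal with mean equal to the protein's base abundance and
    coefficient of variation ``intensity_cv`` (cv=0 gives the exact base
    abundance).  Contaminant proteins (generated from the decoy grammar
    unless supplied) are appended with ``contam`` ids.  Base abundances
    not supplied in ``abundances`` are drawn log-normally.

    The contaminant records used are attached as ``df.attrs["contaminants"]``.
    """
    rng = config.child_rng(3)
    if contaminants is None:
        contaminants = generate_decoy_proteome(
            config.contaminant_count,
            config.decoy_length_range,
            rng_seed=config.child_rng(3, 1),
            id_prefix="contam",
        )
    abundances = dict(abundances or {})
    replicates = [f"r{i + 1}" for i in range(config.n_replicates)]
    cv = config.intensity_cv
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    rows_id, rows_pep, rows_rep, rows_area = [], [], [], []
    for prot in list(proteins) + list(contaminants):
        peps = detectable_peptides(prot)
        if not peps:
            continue
        base = abundances.get(prot.id)
        if base is None:
            # Contaminant / background abundance distribution is a free
            # parameter of the benchmark; mid-range log-normal.
            base = float(rng.lognormal(mean=np.log(20.0), sigma=1.0))
            abundances[prot.id] = base
        detected = rng.random((len(peps), config.n_replicates)) < config.detection_prob
        if cv > 0:
            areas = rng.lognormal(
                mean=np.log(base) - sigma2 / 2.0,
                sigma=sigma,
                size=(len(peps), config.n_replicates),
            )
        else:
            areas = np.full((len(peps), config.n_replicates), base, dtype=float)
        for pi, pep in enumerate(peps):
            for ri, rep in enumerate(replicates):
                if detected[pi, ri]:
                    rows_id.append(prot.id)
                    rows_pep.append(pep)
                    rows_rep.append(rep)
                    rows_area.append(areas[pi, ri])
    df = pd.DataFrame(
        {
            "protein_id": rows_id,
            "peptide": rows_pep,
            "replicate_id": rows_rep,
            "feature_area": rows_area,
        }
    )
    df.attrs["contaminants"] = list(contaminants)
    df.attrs["abundances"] = abundances
    return df


# --- transcriptomes ---------------------------------------------------------

def back_translate(aa_seq: str, rng: np.random.Generator | None = None) -> str:
    """Back-translate a protein to a coding sequence.

    Without ``rng`` the fixed one-codon-per-residue table is used
    (byte-deterministic).  With ``rng``, synonymous codons are sampled
    uniformly — deterministic for a fixed seed — which keeps the +1
    frame an exact encoding while making the other five reading frames
    stop-fragmented, as in real transcripts.
    """
    if rng is None:
        return "".join(BACK_TRANSLATION[a] for a in aa_seq)
    out = []
    for i, a in enumerate(aa_seq):
        codons = SYNONYMOUS_CODONS[a]
        nxt = aa_seq[i + 1] if i + 1 < len(aa_seq) else None
        weights = CONTEXT_WEIGHTS.get((a, nxt), SYNONYMOUS_WEIGHTS.get(a))
        if weights is None:
            out.append(codons[int(rng.integers(len(codons)))])
        else:
            out.append(codons[int(rng.choice(len(codons), p=weights))])
    return "".join(out)


def simulate_transcriptomes(
    silk_families: Sequence[ProteinSequence],
    config: SynthConfig,
) -> tuple[dict[str, list[TranscriptRecord]], dict[str, pd.DataFrame], dict]:
    """Per-species transcript FASTA + TPM tables with planted orthologs.

    Where the presence matrix is true, the species' assembly contains a
    back-translated copy of the family protein, point-mutated at the
    configured per-site divergence, embedded among random decoy
    transcripts; about a quarter of present cells receive a second,
    lower-expressed copy so the maximum-TPM reporting rule is exercised.
    Planted transcripts carry random UTRs and a random strand.  TPM
    sums to 1e6 per species.

    Returns (assemblies, tpm_tables, truth) where ``truth`` records the
    planted presence matrix and, per (family, species), the planted
    transcript ids with their realized TPM.
    """
    if config.divergence >= 0.5:
        import warnings

        warnings.warn(
            "ortholog divergence >= 0.5: conservation is no longer detectable by design",
            stacklevel=2,
        )
    presence = config.presence_matrix
    if presence.shape[0] != len(silk_families):
        raise ConfigurationError("ortholog_presence rows must match silk family count")
    species_ids = [f"sp{j:02d}" for j in range(config.n_species)]
    assemblies: dict[str, list[TranscriptRecord]] = {}
    tpm_tables: dict[str, pd.DataFrame] = {}
    planted: dict[str, dict[str, list[dict]]] = {f.id: {} for f in silk_families}
    nt = np.array(list("ACGT"))
    for j, sp in enumerate(species_ids):
        rng = config.child_rng(4, j)
        entries: list[tuple[str | None, str, float]] = []  # (family or None, nt, weight)
        for i, fam in enumerate(silk_families):
            if not presence[i, j]:
                continue
            n_copies = 1 + int(rng.random() < 0.25)
            for c in range(n_copies):
                aa = mutate_sequence(fam.seq, config.divergence, rng)
                cds = back_translate(aa, rng)
                utr5 = "".join(nt[rng.integers(0, 4, size=int(rng.integers(20, 61)))])
                utr3 = "".join(nt[rng.integers(0, 4, size=int(rng.integers(20, 61)))])
                tx = utr5 + cds + utr3
                if rng.random() < 0.5:
                    tx = _revcomp(tx)
                weight = float(rng.lognormal(np.log(300.0 if c == 0 else 40.0), 0.6))
                entries.append((fam.id, tx, weight))
        for _ in range(config.decoy_transcripts_per_species):
            length = int(rng.integers(400, 1201))
            tx = "".join(nt[rng.integers(0, 4, size=length)])
            entries.append((None, tx, float(rng.lognormal(np.log(10.0), 1.2))))
        order = rng.permutation(len(entries))
        records: list[TranscriptRecord] = []
        weights = []
        fam_of: list[str | None] = []
        for rank, k in enumerate(order, start=1):
            fam_id, tx, weight = entries[k]
            records.append(
                TranscriptRecord(
                    transcript_id=f"comp{rank}",
                    sequence=tx,
                    species_id=sp,
                    id_rank=rank,
                )
            )
            weights.append(weight)
            fam_of.append(fam_id)
        lengths = np.array([len(r.sequence) for r in records], dtype=float)
        # Interpret the expression weights as expected read counts.
        tpm = compute_tpm(np.asarray(weights) * lengths, lengths)
        for rec, value, fam_id in zip(records, tpm, fam_of):
            rec.tpm = float(value)
            if fam_id is not None:
                planted[fam_id].setdefault(sp, []).append(
                    {"transcript_id": rec.transcript_id, "tpm": rec.tpm}
                )
        assemblies[sp] = records
        tpm_tables[sp] = pd.DataFrame(
            {
                "transcript_id": [r.transcript_id for r in records],
                "tpm": [r.tpm for r in records],
            }
        )
    truth = {
        "species": species_ids,
        "presence": presence.tolist(),
        "family_ids": [f.id for f in silk_families],
        "planted_transcripts": planted,
    }
    return assemblies, tpm_tables, truth


def _revcomp(nt: str) -> str:
    return nt.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# --- full benchmark ---------------------------------------------------------

@dataclass
class SilkBenchmark:
    """One synthetic study: proteome, evidence, assemblies and ground truth."""

    config: SynthConfig
    silk_proteins: list[ProteinSequence]
    representatives: list[ProteinSequence]
    decoys: list[ProteinSequence]
    contaminants: list[ProteinSequence]
    features: pd.DataFrame
    assemblies: dict[str, list[TranscriptRecord]]
    tpm_tables: dict[str, pd.DataFrame]
    truth: dict

    @property
    def proteins(self) -> list[ProteinSequence]:
        """Every protein in the simulated proteome (silks first)."""
        return self.silk_proteins + self.decoys + self.contaminants

    @property
    def known_db(self) -> list[ProteinSequence]:
        """The known-protein reference database for the novelty filter:
        all decoys and contaminants, none of the planted silks."""
        return self.decoys + self.contaminants


def generate_dataset(config: SynthConfig) -> SilkBenchmark:
    """Generate one complete benchmark instance from a single seed."""
    specs = config.family_specs
    silk_proteins: list[ProteinSequence] = []
    representatives: list[ProteinSequence] = []
    abundances: dict[str, float] = {}
    family_truth = []
    for i, spec in enumerate(specs):
        rng = config.child_rng(1, i)
        n_flank = mutate_sequence(spec.n_flank, spec.flank_mutation, rng)
        full = generate_silk_protein(
            spec.grammar,
            spec.n_units,
            termini=(n_flank, spec.c_flank),
            rng_seed=rng,
            protein_id=f"{spec.family_id}_iso1",
        )
        members = []
        for k, frac in enumerate(spec.isoform_fractions):
            pid = f"{spec.family_id}_iso{k + 1}"
            seq = full.seq[: max(1, round(frac * len(full.seq)))]
            silk_proteins.append(ProteinSequence(id=pid, seq=seq))
            factor = ISOFORM_ABUNDANCE_FACTORS[min(k, len(ISOFORM_ABUNDANCE_FACTORS) - 1)]
            abundances[pid] = spec.base_abundance * factor
            members.append(pid)
        representatives.append(ProteinSequence(id=spec.family_id, seq=full.seq))
        family_truth.append(
            {
                "family_id": spec.family_id,
                "motif_class": spec.motif_class,
                "base_abundance": spec.base_abundance,
                "members": members,
                "representative": f"{spec.family_id}_iso1",
            }
        )
    groups: dict[str, list[str]] = {}
    for spec in specs:
        groups.setdefault(spec.group, []).append(spec.family_id)
    decoys = generate_decoy_proteome(
        config.n_decoys,
        config.decoy_length_range,
        rng_seed=config.child_rng(2),
    )
    features = simulate_peptide_evidence(silk_proteins + decoys, config, abundances)
    contaminants = features.attrs["contaminants"]
    assemblies, tpm_tables, tx_truth = simulate_transcriptomes(representatives, config)
    truth = {
        "seed": config.seed,
        "families": family_truth,
        "silk_ids": [p.id for p in silk_proteins],
        "decoy_ids": [p.id for p in decoys],
        "contaminant_ids": [p.id for p in contaminants],
        "abundances": features.attrs["abundances"],
        "homology_groups": groups,
        **tx_truth,
    }
    return SilkBenchmark(
        config=config,
        silk_proteins=silk_proteins,
        representatives=representatives,
        decoys=decoys,
        contaminants=contaminants,
        features=features,
        assemblies=assemblies,
        tpm_tables=tpm_tables,
        truth=truth,
    )


def expected_conservation(truth: Mapping) -> pd.DataFrame:
    """Ground-truth conservation/expression cells implied by a benchmark.

    A (family, species) cell is expected conserved iff any member of the
    family's homology group has a planted transcript in that species
    (paralogs sharing a conserved N-terminal flank detect each other's
    transcripts, exactly as orthologous silk genes do in a real
    translated search); the expected expression is the maximum planted
    TPM over those group transcripts.
    """
    groups: Mapping[str, Sequence[str]] = truth.get(
        "homology_groups", {f: [f] for f in truth["family_ids"]}
    )
    group_of = {fam: g for g, fams in groups.items() for fam in fams}
    planted = truth["planted_transcripts"]
    rows = []
    for fam in truth["family_ids"]:
        siblings = groups[group_of.get(fam, fam)]
        for sp in truth["species"]:
            tpms = [
                entry["tpm"]
                for sib in siblings
                for entry in planted.get(sib, {}).get(sp, [])
            ]
            rows.append(
                {
                    "family_id": fam,
                    "species_id": sp,
                    "conserved": bool(tpms),
                    "expression_tpm": max(tpms) if tpms else float("nan"),
                }
            )
    return pd.DataFrame(rows)


# --- serialization ----------------------------------------------------------

def write_fasta(path: Path, records: Sequence[ProteinSequence | TranscriptRecord]) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seq_records = []
    for rec in records:
        if isinstance(rec, TranscriptRecord):
            seq_records.append(SeqRecord(Seq(rec.sequence), id=rec.transcript_id, description=""))
        else:
            seq_records.append(SeqRecord(Seq(rec.seq), id=rec.id, description=rec.description))
    with open(path, "w") as fh:
        seqio_write(seq_records, fh, "fasta")


def write_dataset(bench: SilkBenchmark, outdir: str | Path) -> None:
    """Serialize a benchmark to disk: FASTA proteome and known DB,
    peptides.tsv, per-species transcript FASTA + tpm_<species>.tsv, and a
    JSON ground-truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "proteins.faa", bench.proteins)
    write_fasta(outdir / "known_db.faa", bench.known_db)
    bench.features.to_csv(outdir / "peptides.tsv", sep="\t", index=False)
    for sp, records in bench.assemblies.items():
        write_fasta(outdir / f"transcripts_{sp}.fasta", records)
        bench.tpm_tables[sp].to_csv(outdir / f"tpm_{sp}.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(bench.truth, fh, indent=1)
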