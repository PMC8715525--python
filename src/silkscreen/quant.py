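"""Label-free quantification and assembly-level filtering.

Turns peptide-level feature areas (the integrated LC-MS signal of each
identified peptide ion, per replicate) into per-protein iBAQ values and
a replicate-consistency statistic, and applies the transcriptome
contamination filter (minimum TPM, maximum assembler ID rank).

iBAQ (intensity-based absolute quantification) divides the summed
feature areas of a protein in one replicate by the number of
theoretically observable tryptic peptides, making abundances comparable
across proteins of different length.  The consistency statistic is the
coefficient of variation (sd / mean) of the per-replicate
total-normalized intensities; proteins detected erratically across
replicates get a large value and are excluded by the screen's Z < 1
criterion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class TranscriptRecord:
    """One assembled transcript with expression and assembler rank."""

    transcript_id: str
    sequence: str
    species_id: str
    tpm: float = 0.0
    id_rank: int = 0

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValueError("tpm must be non-negative")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"transcript sequence contains non-nucleotide symbols: {bad}")


def compute_ibaq(
    features: pd.DataFrame,
    theoretical_peptides: Mapping[str, int],
    replicates: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-replicate iBAQ from a peptide feature-area table.

    ``features`` has columns ``protein_id``, ``peptide``, ``replicate_id``
    and ``feature_area``.  For each protein and replicate,
    iBAQ = (sum of feature areas) / (theoretical peptide count); a
    protein with no features in a replicate gets 0 there.  Rows whose
    ``protein_id`` is absent from ``theoretical_peptides`` are skipped
    with a log entry.

    Returns a frame indexed by ``protein_id`` with one ``ibaq_<rep>``
    column per replicate plus ``peptide_count`` (distinct peptides
    observed across all replicates).
    """
    required = {"protein_id", "peptide", "replicate_id", "feature_area"}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"feature table lacks columns: {sorted(missing)}")
    known = features["protein_id"].isin(theoretical_peptides.keys())
    if not known.all():
        unknown = sorted(features.loc[~known, "protein_id"].unique())
        logger.warning(
            "skipping %d feature rows for %d unknown proteins (e.g. %s)",
            int((~known).sum()),
            len(unknown),
            unknown[:3],
        )
        features = features.loc[known]
    if replicates is None:
        replicates = sorted(features["replicate_id"].unique())
    totals = (
        features.pivot_table(
            index="protein_id",
            columns="replicate_id",
            values="feature_area",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=replicates, fill_value=0.0)
    )
    counts = features.groupby("protein_id")["peptide"].nunique()
    out = pd.DataFrame(index=totals.index)
    for rep in replicates:
        theo = totals.index.map(theoretical_peptides)
        if (theo < 1).any():
            raise ValueError("theoretical peptide count must be >= 1 for quantified proteins")
        out[f"ibaq_{rep}"] = totals[rep].to_numpy() / theo.to_numpy(dtype=float)
    out["peptide_count"] = counts.reindex(out.index).astype(int)
    out.index.name = "protein_id"
    return out


def ibaq_columns(quants: pd.DataFrame) -> list[str]:
    return [c for c in quants.columns if c.startswith("ibaq_")]


def normalize_and_consistency(
    quants: pd.DataFrame, normalize: bool = True, statistic="cv"
) -> pd.DataFrame:
    """Fill ``mean_norm_intensity`` and ``consistency_z``.

    Each replicate's iBAQ column is divided by that replicate's total
    (so the statistic is invariant to per-replicate rescaling of the raw
    areas), then ``consistency_z`` is the coefficient of variation
    sd / mean (sample sd, ddof=1) of the normalized intensities across
    replicates.  Proteins with zero mean get ``inf`` as a sentinel.

    ``normalize=False`` skips the per-replicate total normalization;
    ``statistic`` may be a callable mapping the (proteins x replicates)
    normalized matrix to a per-protein vector, replacing the CV.
    """
    cols = ibaq_columns(quants)
    if len(cols) < 2:
        raise ValueError("consistency statistic requires at least two replicates")
    mat = quants[cols].to_numpy(dtype=float)
    if normalize:
        col_tot = mat.sum(axis=0)
        # A replicate with zero total contributes zeros after normalization.
        norm = mat / np.where(col_tot > 0, col_tot, 1.0)
    else:
        norm = mat
    if callable(statistic):
        out = quants.copy()
        out["mean_norm_intensity"] = norm.mean(axis=1)
        out["consistency_z"] = statistic(norm)
        return out
    if statistic != "cv":
        raise ValueError("statistic must be 'cv' or a callable")
    mean = norm.mean(axis=1)
    sd = norm.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.inf)
    out = quants.copy()
    out["mean_norm_intensity"] = mean
    out["consistency_z"] = cv
    return out


def filter_assembly(
    transcripts: pd.DataFrame, tpm_min: float = 1.0, max_id_rank: int = 30000
) -> pd.DataFrame:
    """Assembly-level cross-contamination filter.

    Keeps transcripts with ``tpm >= tpm_min`` and ``id_rank <=
    max_id_rank`` (defaults: TPM at least 1, assembler ID rank at most
    30,000), preserving input order.  Idempotent by construction.
    """
    keep = (transcripts["tpm"] >= tpm_min) & (transcripts["id_rank"] <= max_id_rank)
    return transcripts.loc[keep]


def compute_tpm(counts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Transcripts-per-million from read counts and transcript lengths.

    tpm_i = (counts_i / lengths_i) / sum_j(counts_j / lengths_j) * 1e6,
    so the vector sums to 1e6.  All-zero counts yield all-zero TPM with
    a warning.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("transcript lengths must be positive")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        warnings.warn("all-zero counts: TPM undefined, returning zeros", stacklevel=2)
        return np.zeros_like(rate)
    return rate / total * 1e6
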