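"""Hydropathy profiling and amino-acid composition of silk candidates.

Marine silks are spun under water and tend to be markedly more
hydrophilic than their terrestrial analogs.  This module computes
Kyte-Doolittle sliding-window hydropathy profiles (over the N-terminal
1,000 residues by convention), the GRAVY score (grand average of
hydropathy; negative = hydrophilic) and residue composition for such
comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .synthgen import AMINO_ACIDS


@dataclass(frozen=True)
class AAComposition:
    """Canonical residue fractions (sum to 1) plus the fraction of the
    full sequence made of ambiguous symbols."""

    fractions: dict[str, float]
    ambiguous: dict[str, float]


@dataclass(frozen=True)
class HydropathyProfile:
    protein_id: str
    window: int
    positions: tuple[int, ...]  # window-center residue indices (0-based)
    scores: tuple[float, ...]
    gravy: float
    span_limit: int
    truncated_window: bool = False  # sequence shorter than one window


def _kd_values(seq: str) -> np.ndarray:
    """Per-residue scale values; NaN for ambiguous symbols ('X', '*', ...)."""
    return np.array([KYTE_DOOLITTLE.get(a, math.nan) for a in seq], dtype=float)


def kyte_doolittle_profile(
    seq: str,
    window: int = 9,
    span_limit: int = 1000,
    protein_id: str = "protein",
) -> HydropathyProfile:
    """Sliding unweighted-mean Kyte-Doolittle profile.

    Only the first ``span_limit`` residues are analyzed (appending
    residues beyond the span never changes the profile).  Windows have
    no partial edges: the profile has ``span - window + 1`` points and
    positions are the window centers.  Ambiguous residues are excluded
    from window means with a reduced denominator.  A sequence shorter
    than one window yields the single full-span mean, flagged via
    ``truncated_window``.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if not seq:
        raise ValueError("empty sequence")
    span = seq[:span_limit].upper()
    vals = _kd_values(span)
    if len(span) < window:
        mean = float(np.nanmean(vals)) if not np.isnan(vals).all() else math.nan
        return HydropathyProfile(
            protein_id=protein_id,
            window=window,
            positions=(len(span) // 2,),
            scores=(mean,),
            gravy=mean,
            span_limit=span_limit,
            truncated_window=True,
        )
    filled = np.nan_to_num(vals, nan=0.0)
    valid = (~np.isnan(vals)).astype(float)
    kernel = np.ones(window)
    sums = np.convolve(filled, kernel, mode="valid")
    counts = np.convolve(valid, kernel, mode="valid")
    with np.errstate(invalid="ignore"):
        scores = np.where(counts > 0, sums / np.where(counts > 0, counts, 1.0), math.nan)
    half = window // 2
    positions = tuple(range(half, len(span) - half))
    return HydropathyProfile(
        protein_id=protein_id,
        window=window,
        positions=positions,
        scores=tuple(float(s) for s in scores),
        gravy=gravy(seq, span_limit),
        span_limit=span_limit,
    )


def gravy(seq: str, span_limit: int = 1000) -> float:
    """Grand average of hydropathy over the analyzed span.

    Ambiguous residues are excluded; an all-ambiguous sequence returns
    NaN as an undefined sentinel.
    """
    if not seq:
        raise ValueError("empty sequence")
    vals = _kd_values(seq[:span_limit].upper())
    if np.isnan(vals).all():
        return math.nan
    return float(np.nanmean(vals))


def aa_composition(seq: str) -> AAComposition:
    """Residue fractions over the 20 canonical amino acids.

    Canonical fractions sum to 1 (denominator = canonical residue
    count); ambiguous symbols are reported separately as fractions of
    the full sequence length.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    canonical = [a for a in seq if a in AMINO_ACIDS]
    n_canon = len(canonical)
    fractions = {
        a: (canonical.count(a) / n_canon if n_canon else 0.0) for a in AMINO_ACIDS
    }
    ambiguous: dict[str, float] = {}
    for a in seq:
        if a not in AMINO_ACIDS:
            ambiguous[a] = ambiguous.get(a, 0.0) + 1.0 / len(seq)
    return AAComposition(fractions=fractions, ambiguous=ambiguous)
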