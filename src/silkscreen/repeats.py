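"""Imperfect tandem-repeat detection and motif classification in proteins.

The silk screen's fourth criterion requires that repetitive units cover
at least 10% of a candidate sequence.  This module provides a
seed-and-extend detector for approximate fixed-period tandem repeats
(substitutions only, no indels): exact self-matches at lag ``p`` seed a
region that is extended residue-by-residue while the divergence from the
running per-column consensus stays within a bound.  Overlapping calls
across periods are resolved by a deterministic maximal-coverage greedy
(larger region wins; ties to the smaller period, then the smaller
start), yielding a disjoint set of regions and a repeat coverage
fraction.

Consensus units are the per-column majority residues (ties broken by
the earliest copy), and a small rule set classifies them against the
classic silk motif families: GA-alternating silkworm-fibroin-like
units, serine-alternating caddisworm-fibroin-like units, GPX
collagen-like triplets and cysteine-rich keratin-associated-protein-like
units.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class RepeatRegion:
    """One approximate tandem-repeat region (0-based, half-open)."""

    start: int
    end: int
    period: int
    copies: float
    consensus: str
    identity: float

    def __post_init__(self) -> None:
        if self.period < 1 or self.end <= self.start:
            raise ValueError("degenerate repeat region")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatProfile:
    """Disjoint repeat regions of one protein plus total coverage."""

    protein_id: str
    regions: tuple[RepeatRegion, ...]
    repeat_fraction: float

    def __post_init__(self) -> None:
        prev_end = -1
        for r in sorted(self.regions, key=lambda r: r.start):
            if r.start < prev_end:
                raise ValueError("repeat regions must be disjoint")
            prev_end = r.end


def _consensus_and_identity(seq: str, start: int, end: int, period: int) -> tuple[str, float]:
    """Majority consensus unit (read in the phase of ``start``) and the
    fraction of region residues matching it.  Column ties are broken by
    the earliest copy's residue."""
    columns: list[Counter] = [Counter() for _ in range(period)]
    first_seen: list[str | None] = [None] * period
    for pos in range(start, end):
        c = (pos - start) % period
        res = seq[pos]
        columns[c][res] += 1
        if first_seen[c] is None:
            first_seen[c] = res
    unit = []
    for c in range(period):
        if not columns[c]:
            unit.append("X")
            continue
        best = max(columns[c].values())
        tied = {r for r, k in columns[c].items() if k == best}
        unit.append(first_seen[c] if first_seen[c] in tied else min(tied))
    unit_s = "".join(unit)
    matches = sum(
        1 for pos in range(start, end) if seq[pos] == unit_s[(pos - start) % period]
    )
    return unit_s, matches / (end - start)


class _RegionBuilder:
    """Incrementally extended region with per-column residue counts.

    Columns are indexed by absolute position mod period, so left and
    right extension share one bookkeeping scheme.
    """

    __slots__ = ("seq", "period", "start", "end", "columns", "mismatches")

    def __init__(self, seq: str, period: int, start: int, end: int):
        self.seq = seq
        self.period = period
        self.start = start
        self.end = end
        self.columns: list[Counter] = [Counter() for _ in range(period)]
        self.mismatches = 0
        for pos in range(start, end):
            self._add(pos)

    def _add(self, pos: int) -> None:
        col = self.columns[pos % self.period]
        before = max(col.values()) if col else 0
        size_before = sum(col.values())
        col[self.seq[pos]] += 1
        after = max(col.values())
        # mismatches in this column = size - max_count
        self.mismatches += (size_before + 1 - after) - (size_before - before)

    def _remove(self, pos: int) -> None:
        col = self.columns[pos % self.period]
        before = max(col.values())
        size_before = sum(col.values())
        col[self.seq[pos]] -= 1
        if col[self.seq[pos]] == 0:
            del col[self.seq[pos]]
        after = max(col.values()) if col else 0
        self.mismatches += (size_before - 1 - after) - (size_before - before)

    def try_extend(self, pos: int, max_divergence: float) -> bool:
        """Add ``pos`` if the region divergence stays within bound."""
        self._add(pos)
        length = self.end - self.start + 1
        if self.mismatches / length <= max_divergence:
            if pos == self.end:
                self.end += 1
            else:
                self.start -= 1
            return True
        self._remove(pos)
        return False


def detect_tandem_repeats(
    seq: str,
    min_period: int = 1,
    max_period: int = 60,
    min_copies: float = 2.0,
    max_divergence: float = 0.3,
    protein_id: str = "protein",
) -> RepeatProfile:
    """Detect disjoint approximate tandem repeats in a protein sequence.

    For every candidate period, runs of exact self-matches at that lag
    seed regions that are greedily extended right, then left, while the
    fraction of residues disagreeing with the running per-column
    consensus stays at or below ``max_divergence``.  Candidates with
    fewer than ``min_copies`` (possibly fractional) unit copies are
    dropped; survivors are made disjoint by maximal-coverage greedy
    selection (ties: smaller period, then smaller start).

    A sequence shorter than ``2 * min_period`` yields an empty profile.
    """
    n = len(seq)
    if min_period < 1 or min_period > max_period:
        raise ValueError("require 1 <= min_period <= max_period")
    if not 0.0 <= max_divergence < 0.5:
        raise ValueError("max_divergence must be in [0, 0.5)")
    if min_copies < 1.0:
        raise ValueError("min_copies must be >= 1")
    hi = min(max_period, n // 2)
    candidates: list[tuple[int, int, int]] = []  # (start, end, period)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for p in range(min_period, hi + 1):
        match = arr[p:] == arr[:-p]
        if not match.any():
            continue
        # maximal runs of True in match; run [a, b) in match-index space
        # corresponds to sequence region [a, b + p).
        edges = np.flatnonzero(np.diff(np.concatenate(([0], match.view(np.int8), [0]))))
        runs = edges.reshape(-1, 2)
        min_seed = min(p, 3)
        found: list[tuple[int, int]] = []
        for a, b in runs:
            if b - a < min_seed:
                continue
            s, e = int(a), int(b) + p
            if any(fs <= s and e <= fe for fs, fe in found):
                continue
            if max_divergence > 0:
                builder = _RegionBuilder(seq, p, s, e)
                while builder.end < n and builder.try_extend(builder.end, max_divergence):
                    pass
                while builder.start > 0 and builder.try_extend(
                    builder.start - 1, max_divergence
                ):
                    pass
                s, e = builder.start, builder.end
                # trim edges that mismatch the consensus: a region must not
                # start or end on an absorbed flank residue
                unit, _ = _consensus_and_identity(seq, s, e, p)
                while e - s > p and seq[e - 1] != unit[(e - 1 - s) % p]:
                    e -= 1
                while e - s > p and seq[s] != unit[0]:
                    s += 1
                    unit = unit[1:] + unit[0]
            found.append((s, e))
            if (e - s) / p >= min_copies:
                candidates.append((s, e, p))
    # deterministic maximal-coverage greedy across all periods
    candidates = sorted(set(candidates), key=lambda t: (-(t[1] - t[0]), t[2], t[0]))
    chosen: list[tuple[int, int, int]] = []
    for s, e, p in candidates:
        if all(e <= cs or s >= ce for cs, ce, _ in chosen):
            chosen.append((s, e, p))
    regions = []
    for s, e, p in sorted(chosen):
        unit, identity = _consensus_and_identity(seq, s, e, p)
        regions.append(
            RepeatRegion(
                start=s, end=e, period=p, copies=(e - s) / p, consensus=unit, identity=identity
            )
        )
    covered = sum(len(r) for r in regions)
    return RepeatProfile(
        protein_id=protein_id,
        regions=tuple(regions),
        repeat_fraction=covered / n if n else 0.0,
    )


def repeat_fraction_criterion(profile: RepeatProfile, threshold: float = 0.10) -> bool:
    """True iff repeat coverage reaches the threshold (inclusive:
    'at least 10% of the sequence')."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return profile.repeat_fraction >= threshold


def consensus_motif(region: RepeatRegion, seq: str) -> str:
    """Column-wise majority unit of a repeat region (ties broken by the
    earliest copy's residue)."""
    unit, _ = _consensus_and_identity(seq, region.start, region.end, region.period)
    return unit


def classify_motif(
    consensus: str,
    composition_of_regions: dict[str, float] | None = None,
    ga_min: float = 0.6,
    ser_min: float = 0.3,
    cys_min: float = 0.2,
) -> str:
    """Rule-based classification of a consensus repeat unit.

    Returns one of ``silkworm-fibroin-like`` (GA-alternating, G+A-rich),
    ``caddisworm-fibroin-like`` (SXSX-alternating, Ser-rich),
    ``collagen-like`` (GPX triplets with glycine every third residue),
    ``KAP-like`` (cysteine-rich) or ``other``.  Composition defaults to
    the consensus unit's own composition; thresholds are configurable.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    if composition_of_regions is None:
        comp = {a: consensus.count(a) / len(consensus) for a in set(consensus)}
    else:
        comp = composition_of_regions
    unit = consensus
    n = len(unit)
    # Cyclic dinucleotide-style alternation (the unit tiles the region).
    pairs = [(unit[i], unit[(i + 1) % n]) for i in range(n)] if n > 1 else []
    ga_pairs = sum(1 for a, b in pairs if {a, b} == {"G", "A"})
    if comp.get("G", 0) + comp.get("A", 0) >= ga_min and pairs and ga_pairs / len(pairs) >= 0.5:
        return "silkworm-fibroin-like"
    if comp.get("S", 0) >= ser_min and n > 1:
        phase_s = max(
            sum(1 for i in range(ph, n, 2) if unit[i] == "S") / len(range(ph, n, 2))
            for ph in (0, 1)
        )
        if phase_s >= 0.6:
            return "caddisworm-fibroin-like"
    if n % 3 == 0:
        for ph in range(3):
            col = [unit[i] for i in range(ph, n, 3)]
            if all(r == "G" for r in col):
                return "collagen-like"
    if comp.get("C", 0) >= cys_min:
        return "KAP-like"
    return "other"
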