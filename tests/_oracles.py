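"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and self-contained: exhaustive
enumeration over candidate structures, with no code shared with the
implementation under test.
"""

from __future__ import annotations

import itertools

# Frozen copy of the published Kyte-Doolittle hydropathy scale.
KD_SCALE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Frozen BLOSUM62 entries for the {A, G, S} test alphabet.
BLOSUM62_AGS = {
    ("A", "A"): 4, ("G", "G"): 6, ("S", "S"): 4,
    ("A", "G"): 0, ("G", "A"): 0,
    ("A", "S"): 1, ("S", "A"): 1,
    ("G", "S"): 0, ("S", "G"): 0,
}


def perfect_repeat_coverage(
    seq: str, min_period: int = 1, max_period: int | None = None, min_copies: float = 2.0
) -> tuple[list[tuple[int, int, int]], int]:
    """Exhaustive perfect-tandem-repeat caller.

    Tests every (start, period) pair, extends to the maximal run of exact
    copies, keeps candidates with at least ``min_copies`` copies, and
    resolves overlaps with the deterministic maximal-coverage greedy
    (larger region first; ties to smaller period, then smaller start).
    Returns (chosen regions as (start, end, period), covered residues).
    """
    n = len(seq)
    if max_period is None:
        max_period = n // 2
    candidates = set()
    for p in range(min_period, min(max_period, n // 2) + 1):
        for s in range(n - p):
            if s > 0 and seq[s - 1] == seq[s - 1 + p]:
                continue  # not maximal on the left
            e = s + p
            while e < n and seq[e] == seq[e - p]:
                e += 1
            if e == s + p:
                continue  # single copy, no tandem
            if (e - s) / p >= min_copies:
                candidates.add((s, e, p))
    chosen: list[tuple[int, int, int]] = []
    for s, e, p in sorted(candidates, key=lambda t: (-(t[1] - t[0]), t[2], t[0])):
        if all(e <= cs or s >= ce for cs, ce, _ in chosen):
            chosen.append((s, e, p))
    chosen.sort()
    return chosen, sum(e - s for s, e, _ in chosen)


def brute_force_local_score(
    a: str,
    b: str,
    matrix=None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> int:
    """Optimal local alignment score by exhaustive path enumeration.

    Recursively enumerates alignment paths (match/mismatch, gap-in-a,
    gap-in-b, with affine gap state), starting at every residue pair and
    allowing the alignment to end anywhere.  A gap of length L costs
    gap_open + L * gap_extend.  The only pruning is an admissible bound
    (best possible remaining score), which cannot exclude an optimum.
    No dynamic-programming tables are used.
    """
    if matrix is None:
        matrix = BLOSUM62_AGS
    if not a or not b:
        return 0
    max_pair = max(matrix.values())
    best = 0

    def rec(i: int, j: int, score: int, state: str) -> None:
        nonlocal best
        if score > best:
            best = score
        bound = max_pair * min(len(a) - i, len(b) - j)
        if bound <= 0 or score + bound <= best:
            return
        # match/mismatch
        rec(i + 1, j + 1, score + matrix[(a[i], b[j])], "M")
        # gap in b (consume a residue of a)
        cost = gap_extend if state == "A" else gap_open + gap_extend
        if i + 1 < len(a):  # a trailing gap can never help
            rec(i + 1, j, score - cost, "A")
        cost = gap_extend if state == "B" else gap_open + gap_extend
        if j + 1 < len(b):
            rec(i, j + 1, score - cost, "B")

    for i in range(len(a)):
        for j in range(len(b)):
            rec(i, j, 0, "M")
    return best


def tryptic_peptides_by_enumeration(seq: str, missed_cleavages: int) -> set[str]:
    """All tryptic peptides with <= ``missed_cleavages`` internal sites,
    by direct enumeration over cleavage-boundary pairs."""
    sites = [
        i + 1 for i in range(len(seq) - 1) if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    bounds = [0] + sites + [len(seq)]
    out = set()
    for i, j in itertools.combinations(range(len(bounds)), 2):
        if j - i - 1 <= missed_cleavages:
            out.add(seq[bounds[i] : bounds[j]])
    return out


def sliding_window_mean(values: list[float], window: int) -> list[float]:
    """Plain sliding mean with no partial windows (None values excluded
    from numerator and denominator)."""
    out = []
    for i in range(len(values) - window + 1):
        chunk = [v for v in values[i : i + window] if v is not None]
        out.append(sum(chunk) / len(chunk) if chunk else float("nan"))
    return out
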