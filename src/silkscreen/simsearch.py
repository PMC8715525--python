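"""Local-alignment similarity search with Karlin-Altschul E-value statistics.

This module powers two stages of the silk screen:

* the *novelty filter* — a BlastP-like scan of each candidate protein
  against a database of known proteins, where a candidate is "novel" iff
  no database subject aligns with E-value below the cut-off; and
* the *conservation screen* — a TBlastN-like translated search of each
  silk-family representative against per-species transcriptome
  assemblies, recording for every (family, species) cell whether a
  conserved transcript exists and the highest expression (TPM) among the
  qualifying transcripts.

Alignments are full Smith-Waterman with affine gaps (no heuristic
banding); at desk scale this is affordable and avoids the approximations
of seeded aligners.  No low-complexity masking is applied anywhere:
silk repeats are inherently low-complexity and masking them would defeat
the screen.

An optional exact k-mer prefilter orders database subjects by shared
k-mer count and skips subjects sharing none; it exists purely for speed
and must not change any decision at the E-value cut-off (verified in the
test suite on planted fixtures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .synthgen import ProteinSequence

# Conventional ungapped BLOSUM62 Karlin-Altschul parameters.  The gapped
# values differ slightly; since the E-values here only need to separate
# strong homology from chance similarity by many orders of magnitude,
# the ungapped constants are used throughout and are configurable.
KA_LAMBDA = 0.3176
KA_K = 0.134

#: Default affine gap model: a gap of length L costs GAP_OPEN + L * GAP_EXTEND.
GAP_OPEN = 11
GAP_EXTEND = 1

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

# Local alignments must never productively cross a stop codon: a
# translated-search hit is confined to one ORF segment of its reading
# frame.  BLOSUM62's mild -4 for '*' would let long repeat alignments
# absorb stops, so the default matrix makes stops prohibitive.
_STOP_BLOCKED = _BLOSUM62.copy()
for _aa in _STOP_BLOCKED.alphabet:
    _STOP_BLOCKED["*", _aa] = -1000.0
    _STOP_BLOCKED[_aa, "*"] = -1000.0


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a query and a subject sequence.

    ``frame`` is 0 for protein subjects and +-1..3 for translated
    nucleotide subjects.  Coordinates are 0-based half-open on the
    untranslated query/subject as given to the aligner.
    """

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    frame: int = 0


def make_aligner(
    matrix=None,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
    mode: str = "local",
) -> PairwiseAligner:
    """Build an affine-gap aligner.

    ``gap_open``/``gap_extend`` follow the BLAST convention: a gap of
    length L costs ``gap_open + L * gap_extend``.
    """
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = matrix if matrix is not None else _STOP_BLOCKED
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def sw_score(
    query: str,
    subject: str,
    matrix=None,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
    _aligner: PairwiseAligner | None = None,
) -> int:
    """Optimal Smith-Waterman score (score-only fast path); 0 if no
    positively scoring local alignment exists."""
    if not query or not subject:
        return 0
    aligner = _aligner if _aligner is not None else make_aligner(matrix, gap_open, gap_extend)
    return int(aligner.score(query, subject))


def smith_waterman(
    query: str,
    subject: str,
    matrix=None,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
    query_id: str = "query",
    subject_id: str = "subject",
    db_residues: int | None = None,
    frame: int = 0,
) -> AlignmentHit | None:
    """Optimal local alignment of ``query`` vs ``subject`` under affine gaps.

    Returns ``None`` (no-hit sentinel) for empty input or when the best
    local alignment does not score positively.  Among co-optimal
    tracebacks the aligner's deterministic first path is reported; the
    score, E-value and novelty/conservation decisions do not depend on
    this choice.
    """
    if not query or not subject:
        return None
    aligner = make_aligner(matrix, gap_open, gap_extend)
    score = aligner.score(query, subject)
    if score <= 0:
        return None
    alignment = aligner.align(query, subject)[0]
    blocks_q, blocks_s = alignment.aligned
    q_start, q_end = int(blocks_q[0][0]), int(blocks_q[-1][1])
    s_start, s_end = int(blocks_s[0][0]), int(blocks_s[-1][1])
    n = db_residues if db_residues is not None else len(subject)
    raw = int(score)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=raw,
        bit_score=bit_score(raw),
        evalue=evalue(raw, len(query), n),
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        frame=frame,
    )


def evalue(raw_score: float, m: int, n: int, K: float = KA_K, lam: float = KA_LAMBDA) -> float:
    """Karlin-Altschul expected hit count: E = K * m * n * exp(-lambda * S).

    ``m`` is the query length and ``n`` the database residue count.
    """
    if m <= 0 or n <= 0:
        raise ValueError("query length and database size must be positive")
    if K <= 0 or lam <= 0:
        raise ValueError("Karlin-Altschul parameters must be positive")
    return K * m * n * math.exp(-lam * raw_score)


def bit_score(raw_score: float, K: float = KA_K, lam: float = KA_LAMBDA) -> float:
    """Normalized score in bits: (lambda * S - ln K) / ln 2."""
    return (lam * raw_score - math.log(K)) / math.log(2.0)


# --- six-frame translation -------------------------------------------------

def six_frame_translate(nt: str) -> list[str]:
    """Translate a nucleotide sequence in all six reading frames.

    Returns the frames in the order [+1, +2, +3, -1, -2, -3].  Stop
    codons are emitted as ``*`` and codons containing N as ``X``.
    Frame -k is defined on the reverse complement, so frame -1 of ``s``
    equals frame +1 of ``revcomp(s)``.
    """
    seq = Seq(nt.upper())
    rc = seq.reverse_complement()
    frames = []
    for src in (seq, rc):
        for off in range(3):
            sub = src[off : off + 3 * ((len(src) - off) // 3)]
            frames.append(str(sub.translate(table=1)))
    return frames


# --- k-mer prefilter -------------------------------------------------------

def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def rank_subjects_by_kmers(
    query: str, subjects: Sequence[tuple[str, str]], k: int = 5
) -> list[tuple[str, str, int]]:
    """Order (id, seq) subjects by shared exact k-mer count, descending.

    Ties broken by subject id so that decisions are independent of input
    order.  Used as a speed prefilter: subjects sharing no k-mer with the
    query are extremely unlikely to reach the stringent E-value cut-off.
    """
    qk = _kmer_set(query, k)
    ranked = []
    for sid, sseq in subjects:
        shared = sum(1 for i in range(len(sseq) - k + 1) if sseq[i : i + k] in qk) if qk else 0
        ranked.append((sid, sseq, shared))
    ranked.sort(key=lambda t: (-t[2], t[0]))
    return ranked


# --- novelty filter --------------------------------------------------------

def novelty_filter(
    query: ProteinSequence | str,
    known_db: Sequence[ProteinSequence] | Mapping[str, str],
    evalue_max: float = 1e-15,
    prefilter: bool = True,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
    K: float = KA_K,
    lam: float = KA_LAMBDA,
) -> bool:
    """True iff the query has no database hit with E-value < ``evalue_max``.

    Mirrors the BlastP-vs-known-proteins novelty criterion of the silk
    screen (default cut-off 1e-15, no low-complexity masking).  The
    database size ``n`` for the E-value is the total residue count of
    the database.  With ``prefilter`` the database is scanned in
    decreasing shared-k-mer order with an exact early exit on the first
    qualifying hit; subjects sharing no 5-mer are skipped.
    """
    qseq = query.seq if isinstance(query, ProteinSequence) else query
    if isinstance(known_db, Mapping):
        entries = list(known_db.items())
    else:
        entries = [(p.id, p.seq) for p in known_db]
    if not entries:
        raise ValueError("novelty filter requires a non-empty known-protein database")
    if not qseq:
        return True
    n_db = sum(len(s) for _, s in entries)
    aligner = make_aligner(None, gap_open, gap_extend)
    if prefilter:
        ranked = rank_subjects_by_kmers(qseq, entries)
        candidates: Iterable[tuple[str, str]] = (
            (sid, sseq) for sid, sseq, shared in ranked if shared > 0
        )
    else:
        candidates = entries
    for _, sseq in candidates:
        if not sseq:
            continue
        score = aligner.score(qseq, sseq)
        if evalue(score, len(qseq), n_db, K=K, lam=lam) < evalue_max:
            return False
    return True


# --- cross-species conservation --------------------------------------------

def conservation_matrix(
    families: Sequence[ProteinSequence],
    assemblies: Mapping[str, Sequence],
    tpm_tables: Mapping[str, pd.DataFrame],
    evalue_max: float = 1e-15,
    prefilter: bool = True,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> pd.DataFrame:
    """TBlastN-like conservation/expression matrix of families x species.

    For every (family, species) pair the family representative protein
    is searched against the six-frame translations of all transcripts of
    that species.  A cell is conserved iff the best hit has
    E < ``evalue_max``; its reported expression is the *maximum* TPM
    among transcripts with a qualifying hit.  Best-hit ties are broken
    by lower E-value, then higher bit score, then lexicographic
    transcript id.

    ``assemblies`` maps species id to a sequence of transcript records
    (objects with ``transcript_id`` and ``sequence`` attributes, or
    (id, sequence) pairs).  ``tpm_tables`` maps species id to a frame
    with columns ``transcript_id`` and ``tpm``.  A qualifying transcript
    missing from the TPM table flags the cell instead of silently
    contributing zero.
    """
    rows = []
    aligner = make_aligner(None, gap_open, gap_extend)
    for species, transcripts in assemblies.items():
        if species not in tpm_tables:
            raise ValueError(f"species {species!r} has no TPM table")
        tpm = tpm_tables[species].set_index("transcript_id")["tpm"].to_dict()
        # Pre-translate every transcript once per species.
        # Pre-translate every transcript once per species.  Frames are
        # split at stop codons: a translated-search hit lives within one
        # ORF segment of its reading frame and never chains across a
        # stop (gapping over a stop would be biologically meaningless).
        translated: list[tuple[str, int, str]] = []  # (tid, frame, aa segment)
        frame_labels = (1, 2, 3, -1, -2, -3)
        for rec in transcripts:
            tid, nt = (
                (rec.transcript_id, rec.sequence)
                if hasattr(rec, "transcript_id")
                else (rec[0], rec[1])
            )
            for frame, aa in zip(frame_labels, six_frame_translate(nt)):
                for segment in aa.split("*"):
                    if segment:
                        translated.append((tid, frame, segment))
        n_db = sum(len(aa) for _, _, aa in translated)
        for fam in families:
            best = None  # (evalue, -score, tid, frame)
            qualifying: dict[str, float] = {}
            if prefilter and fam.seq:
                qk = _kmer_set(fam.seq, 5)
                scan = [
                    (tid, frame, aa)
                    for tid, frame, aa in translated
                    if any(aa[i : i + 5] in qk for i in range(len(aa) - 4))
                ]
            else:
                scan = translated
            for tid, frame, aa in scan:
                if not aa or not fam.seq:
                    continue
                score = aligner.score(fam.seq, aa)
                ev = evalue(score, len(fam.seq), max(n_db, 1))
                if ev < evalue_max:
                    prev = qualifying.get(tid)
                    if prev is None or ev < prev:
                        qualifying[tid] = ev
                key = (ev, -score, tid, frame)
                if best is None or key < best[0]:
                    best = (key, int(score))
            conserved = bool(qualifying)
            expr = float("nan")
            tpm_missing = False
            if conserved:
                with_tpm = {t: tpm[t] for t in qualifying if t in tpm}
                tpm_missing = len(with_tpm) < len(qualifying)
                if with_tpm:
                    expr = max(with_tpm.values())
            rows.append(
                {
                    "family_id": fam.id,
                    "species_id": species,
                    "conserved": conserved,
                    "best_subject": best[0][2] if best is not None else None,
                    "best_frame": best[0][3] if best is not None else 0,
                    "best_evalue": best[0][0] if best is not None else float("inf"),
                    "best_score": best[1] if best is not None else 0,
                    "expression_tpm": expr,
                    "tpm_missing": tpm_missing,
                    "n_qualifying": len(qualifying),
                }
            )
    return pd.DataFrame(rows)
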