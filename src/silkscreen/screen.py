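"""The four-criterion silk screen, family clustering and abundance ranking.

A candidate protein passes the screen iff it

1. is *novel* — no hit in the known-protein database below the E-value
   cut-off (default 1e-15);
2. has at least ``min_peptides`` distinct identified peptides (default 2);
3. is *consistently detected* across replicates — normalized standard
   deviation (coefficient of variation of the total-normalized iBAQ)
   below ``z_max`` (default 1); and
4. has repetitive units covering at least ``repeat_min`` of its length
   (default 10%).

Survivors are clustered into protein families by single-linkage on
pairwise global-alignment identity (isoforms of one gene share long
exact stretches), families are further merged into super-groups when
their representatives' N-terminal stretches are conserved (the
signature of orthologous paralogs with divergent repeat regions), and
the final candidates are ranked by mean iBAQ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quant import ibaq_columns
from .repeats import RepeatProfile
from .simsearch import make_aligner
from .synthgen import ProteinSequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenVerdict:
    """Audit record of the four criteria for one protein."""

    protein_id: str
    novel: bool
    peptide_support: int
    consistent: bool
    repeat_fraction: float
    passes: bool
    reasons: tuple[str, ...]


@dataclass(frozen=True)
class FamilyCluster:
    """A single-linkage identity cluster of survivor proteins."""

    cluster_id: str
    member_ids: tuple[str, ...]
    representative_id: str


def screen_candidates(
    quants: pd.DataFrame,
    repeat_profiles: Mapping[str, RepeatProfile],
    novelty: Mapping[str, bool],
    min_peptides: int = 2,
    z_max: float = 1.0,
    repeat_min: float = 0.10,
) -> pd.DataFrame:
    """Evaluate all four criteria for every quantified protein.

    ``quants`` must carry ``peptide_count`` and ``consistency_z``
    columns (see :mod:`silkscreen.quant`).  Every quantified protein
    must have a repeat profile and a novelty flag; silently dropping a
    candidate would corrupt the audit, so missing inputs raise.

    Returns one row per quantified protein with per-criterion flags,
    ``passes`` (the conjunction) and ``reasons`` listing the failed
    criteria.
    """
    rows = []
    counts = {"not_novel": 0, "few_peptides": 0, "inconsistent": 0, "few_repeats": 0}
    for pid, row in quants.iterrows():
        if pid not in repeat_profiles:
            raise ValueError(f"no repeat profile for quantified protein {pid!r}")
        if pid not in novelty:
            raise ValueError(f"no novelty flag for quantified protein {pid!r}")
        novel = bool(novelty[pid])
        support = int(row["peptide_count"])
        consistent = bool(row["consistency_z"] < z_max)
        fraction = repeat_profiles[pid].repeat_fraction
        reasons = []
        if not novel:
            reasons.append("not_novel")
        if support < min_peptides:
            reasons.append("few_peptides")
        if not consistent:
            reasons.append("inconsistent")
        if fraction < repeat_min:
            reasons.append("few_repeats")
        for r in reasons:
            counts[r] += 1
        rows.append(
            {
                "protein_id": pid,
                "novel": novel,
                "peptide_support": support,
                "consistent": consistent,
                "repeat_fraction": fraction,
                "passes": not reasons,
                "reasons": ",".join(reasons),
            }
        )
    logger.info(
        "screen: %d candidates, %d pass; exclusions %s",
        len(rows),
        sum(1 for r in rows if r["passes"]),
        counts,
    )
    return pd.DataFrame(rows).set_index("protein_id")


# --- identity clustering ----------------------------------------------------

def global_identity(a: str, b: str, aligner=None) -> float:
    """Global-alignment identity: matches / alignment columns (end gaps
    count as columns, so a truncation of fraction f has identity ~f)."""
    if not a or not b:
        return 0.0
    if aligner is None:
        aligner = make_aligner(mode="global")
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    total = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / total if total else 0.0


def _single_linkage(ids: list[str], edge: "np.ndarray") -> list[list[int]]:
    n = len(ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if edge[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [sorted(g) for g in groups.values()]


def cluster_by_identity(
    survivors: Sequence[ProteinSequence], identity_min: float = 0.90
) -> list[FamilyCluster]:
    """Single-linkage clustering of survivors at global identity >=
    ``identity_min``.

    Cluster ids are deterministic (``fam_<smallest member id>``); the
    representative is the longest member, ties broken lexicographically.
    """
    if not 0.0 < identity_min <= 1.0:
        raise ValueError("identity_min must be in (0, 1]")
    seqs = list(survivors)
    n = len(seqs)
    aligner = make_aligner(mode="global")
    edge = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if seqs[i].seq == seqs[j].seq:
                edge[i, j] = True
                continue
            # cheap upper bound: identity <= min(len) / max(len)
            lo, hi = sorted((len(seqs[i].seq), len(seqs[j].seq)))
            if hi and lo / hi < identity_min:
                continue
            edge[i, j] = global_identity(seqs[i].seq, seqs[j].seq, aligner) >= identity_min
    clusters = []
    for group in _single_linkage([s.id for s in seqs], edge):
        members = sorted(seqs[i].id for i in group)
        rep = max((seqs[i] for i in group), key=lambda s: (len(s.seq), s.id))
        # ties on length resolve to the lexicographically smallest id
        tied = [seqs[i] for i in group if len(seqs[i].seq) == len(rep.seq)]
        rep = min(tied, key=lambda s: s.id)
        clusters.append(
            FamilyCluster(
                cluster_id=f"cluster_{members[0]}",
                member_ids=tuple(members),
                representative_id=rep.id,
            )
        )
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


def nterminal_homology_groups(
    families: Sequence[FamilyCluster],
    proteins: Mapping[str, ProteinSequence],
    n_residues: int = 100,
    identity_min: float = 0.7,
) -> list[tuple[str, ...]]:
    """Merge clusters whose representatives share conserved N-termini.

    Clusters whose representatives' first ``n_residues`` align at >=
    ``identity_min`` global identity are single-linkage merged into a
    super-group — the signature of paralogous silk genes with divergent
    repeat regions but a common N-terminal domain.  A representative
    shorter than ``n_residues`` is used in full (logged).

    Returns sorted tuples of cluster ids.
    """
    if n_residues < 20:
        raise ValueError("n_residues must be >= 20")
    reps = []
    for fam in families:
        seq = proteins[fam.representative_id].seq
        if len(seq) < n_residues:
            logger.warning(
                "representative %s shorter than %d residues; using full length",
                fam.representative_id,
                n_residues,
            )
        reps.append(seq[:n_residues])
    n = len(families)
    aligner = make_aligner(mode="global")
    edge = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            edge[i, j] = global_identity(reps[i], reps[j], aligner) >= identity_min
    groups = _single_linkage([f.cluster_id for f in families], edge)
    out = [tuple(sorted(families[i].cluster_id for i in g)) for g in groups]
    out.sort()
    return out


def rank_by_abundance(quants: pd.DataFrame, verdicts: pd.DataFrame) -> pd.DataFrame:
    """Survivors ordered by mean iBAQ (descending; ties by protein id).

    Returns the surviving rows of ``quants`` with a ``mean_ibaq`` column,
    most abundant first.
    """
    survivors = verdicts.index[verdicts["passes"]]
    cols = ibaq_columns(quants)
    sub = quants.loc[quants.index.intersection(survivors), cols].copy()
    sub["mean_ibaq"] = sub[cols].mean(axis=1)
    # stable sort after an index sort gives deterministic id tie-breaks
    sub = sub.sort_index().sort_values("mean_ibaq", ascending=False, kind="stable")
    return sub


# --- end-to-end pipeline ----------------------------------------------------

@dataclass
class ScreenResult:
    """All artifacts of one screen run."""

    quants: pd.DataFrame
    verdicts: pd.DataFrame
    clusters: list[FamilyCluster]
    supergroups: list[tuple[str, ...]]
    ranking: pd.DataFrame
    params: dict


def run_screen(
    proteins: Sequence[ProteinSequence],
    features: pd.DataFrame,
    known_db: Sequence[ProteinSequence],
    min_peptides: int = 2,
    z_max: float = 1.0,
    repeat_min: float = 0.10,
    evalue_max: float = 1e-15,
    identity_min: float = 0.90,
    nterm_residues: int = 100,
    nterm_identity: float = 0.7,
    repeat_kwargs: dict | None = None,
) -> ScreenResult:
    """Quantify, screen, cluster, group and rank a candidate proteome.

    ``proteins`` is the candidate proteome (sequences for every protein
    that may appear in ``features``), ``features`` the peptide
    feature-area table and ``known_db`` the known-protein reference for
    the novelty filter.  Defaults are the screen's canonical thresholds
    (novelty at E < 1e-15, >= 2 distinct peptides, consistency Z < 1,
    repeat coverage >= 10%).
    """
    from .quant import compute_ibaq, normalize_and_consistency
    from .repeats import detect_tandem_repeats
    from .simsearch import novelty_filter
    from .synthgen import detectable_peptides

    by_id = {p.id: p for p in proteins}
    theoretical = {
        pid: len(peps)
        for pid, peps in ((p.id, detectable_peptides(p)) for p in proteins)
        if peps
    }
    quants = normalize_and_consistency(compute_ibaq(features, theoretical))
    profiles = {}
    novelty = {}
    for pid in quants.index:
        prot = by_id[pid]
        profiles[pid] = detect_tandem_repeats(
            prot.seq, protein_id=pid, **(repeat_kwargs or {})
        )
        novelty[pid] = novelty_filter(prot, known_db, evalue_max=evalue_max)
    verdicts = screen_candidates(
        quants, profiles, novelty, min_peptides=min_peptides, z_max=z_max, repeat_min=repeat_min
    )
    survivors = [by_id[pid] for pid in verdicts.index[verdicts["passes"]]]
    clusters = cluster_by_identity(survivors, identity_min=identity_min)
    supergroups = nterminal_homology_groups(
        clusters, by_id, n_residues=nterm_residues, identity_min=nterm_identity
    )
    ranking = rank_by_abundance(quants, verdicts)
    return ScreenResult(
        quants=quants,
        verdicts=verdicts,
        clusters=clusters,
        supergroups=supergroups,
        ranking=ranking,
        params={
            "min_peptides": min_peptides,
            "z_max": z_max,
            "repeat_min": repeat_min,
            "evalue_max": evalue_max,
            "identity_min": identity_min,
            "nterm_residues": nterm_residues,
            "nterm_identity": nterm_identity,
        },
    )
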