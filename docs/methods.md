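# Methods

This note documents the models, parameters and numerical choices behind
`silkscreen`, and what the synthetic benchmark does and does not show.

## The screen

Candidates enter the screen as (protein sequence, peptide feature-area
table) pairs. Feature areas are the integrated LC–MS signals of
identified peptide ions, one row per (protein, peptide, replicate).

**iBAQ.** Per replicate, iBAQ = Σ(feature areas) / N_theoretical,
where N_theoretical counts fully tryptic peptides (cleavage after K/R,
not before P; 0 missed cleavages) of length 6–30 — the conventional
window of peptides observable by LC–MS. A protein absent from a
replicate contributes 0 there rather than an imputed value; this is
conservative and matches the intent of a *consistent detection* filter.

**Consistency.** Each replicate's iBAQ vector is divided by that
replicate's total, making the statistic invariant to per-replicate
loading differences; the consistency score Z is the coefficient of
variation (sample sd, ddof = 1, over the mean) of these normalized
intensities. "Normalized standard deviation" admits several readings;
CV of total-normalized iBAQ is the standard one, and both the
normalization and the statistic are pluggable
(`normalize_and_consistency(normalize=..., statistic=...)`). Proteins
with zero mean receive +inf so they can never pass Z < 1.

**Novelty.** Full Smith–Waterman (BLOSUM62; gap of length L costs
11 + L) against the known-protein database, E = K·m·n·e^(−λS) with the
conventional ungapped BLOSUM62 constants λ = 0.3176, K = 0.134, m the
query length and n the total database residue count. A candidate is
novel iff no subject reaches E < 10⁻¹⁵. No SEG/DUST-style masking is
applied anywhere: the candidates of interest are low-complexity by
nature. A k-mer prefilter (shared 5-mers, best-first with exact early
exit) accelerates the scan; it skips only subjects sharing no 5-mer
with the query and is verified in the tests to leave decisions
unchanged.

**Repeats.** The tandem-repeat detector is seed-and-extend with fixed
period and substitutions only (no indels): exact self-matches at lag p
seed a region that grows residue-by-residue while the fraction of
residues disagreeing with the per-column majority consensus stays
≤ max_divergence (default 0.3); regions are then trimmed so they never
start or end on a residue that mismatches the consensus. Defaults
min_period = 1, max_period = 60, min_copies = 2 cover the observed silk
periods (2–12). Overlapping calls across periods are resolved by a
deterministic maximal-coverage greedy: larger region first, ties to the
smaller period, then the smaller start. A consequence worth knowing:
a long imperfect region at a composite period can outrank a chain of
shorter clean calls, so reported units are sometimes higher-order
repeats of the elementary motif. Repeat coverage is the summed length
of the disjoint regions over the sequence length; the screen requires
≥ 10% (inclusive). Consensus units use column majority with ties broken
by the earliest copy; unit classification is rule-based (G+A ≥ 0.6 with
GA alternation → silkworm-fibroin-like; Ser ≥ 0.3 with SX alternation →
caddisworm-fibroin-like; Gly at every third position → collagen-like;
Cys ≥ 0.2 → KAP-like), with configurable thresholds.

**Clustering and grouping.** Survivors are clustered by single-linkage
on global-alignment identity (matches / alignment columns, end gaps
counted), threshold 0.90: isoforms are near-exact truncations of one
another, so they exceed it, while distinct repeat families stay well
below. Representatives are the longest members. Families whose
representatives' first 100 residues align at ≥ 0.7 identity merge into
super-groups — the signature of paralogs with a conserved N-terminal
domain and divergent repeat regions. The 0.7 default reflects
"conserved but not identical" paralog N-termini; both knobs are
exposed. Ranking is by mean iBAQ, descending, ties by protein id.

**Conservation.** Each family representative is searched against the
six-frame translations of every transcript of every species. Frames
are split at stop codons and each ORF segment is aligned separately: a
translated-search hit is confined to one reading-frame segment, and an
alignment that gaps across a stop would be biologically meaningless.
A (family, species) cell is conserved iff any segment reaches
E < 10⁻¹⁵ (n = total translated residues of that species); the reported
expression is the maximum TPM among transcripts with a qualifying hit,
and a qualifying transcript missing from the TPM table flags the cell
instead of contributing zero. Paralogs that share a conserved
N-terminal flank necessarily detect each other's transcripts — they are
orthologous by construction — so conservation ground truth in the
benchmark is defined per homology group (presence OR-ed, expression
maxed within the group), mirroring how such paralogs are reported as
one class in comparative figures.

**Assembly filter.** Cross-contamination control for multi-sample
assemblies: keep transcripts with TPM ≥ 1 and assembler ID rank
≤ 30,000; order-preserving and idempotent. TPM is computed as
(count/length) / Σ(count/length) × 10⁶.

**Hydropathy.** Kyte–Doolittle profiles are unweighted sliding means
(default window 9, the ProtScale convention; window size is exposed)
over the N-terminal 1,000 residues; no partial windows at the edges;
ambiguous residues are excluded with a reduced denominator. GRAVY is
the mean scale value over the analyzed span; negative values indicate
hydrophilicity, the hallmark of underwater-spun silks relative to their
terrestrial analogs.

## The synthetic benchmark

The generator plants six silk families built from motif grammars
(weighted repeat units + rare linkers, per-residue substitution noise):
a GAGAGS/GAGA family with the classic fibroin hexapeptides (including
GAGVGY and GAAS) and an SGRVQQTYTSSF-type linker; three serine-rich
(SX)ₙ paralogs sharing one N-terminal flank (per-paralog flank
divergence 3%); a GPX collagen-like family (X ∈ D/E/T/S/Q/V); and a
cysteine-rich KAP-like family. Full-length proteins are 800–1,500
residues; per family 2–6 C-terminal-truncation isoforms (≥ 92% of full
length) give 21 silk entries, with isoform abundances decaying from the
family base (1000/300/200/150/100/80 arbitrary units, the GAGAGS family
most abundant). The proteome adds 500 globular decoys (SwissProt-like
composition, 120–500 aa) and 10 flagged contaminants; decoys and
contaminants form the known-protein database, so planted silks are
novel by construction. Terminal flanks are fixed, designed sequences
with tryptic sites every 7–13 residues, guaranteeing each planted
protein several observable peptides.

Peptide evidence: every observable peptide of every protein is detected
per replicate with probability 0.9 (five replicates), detected areas
are log-normal with mean equal to the protein's base abundance and
CV 0.3, and the noiseless limits (detection 1, CV 0) reproduce exact
tables. Contaminant and undeclared-protein abundances are log-normal
with median 20 — the real contaminant abundance distribution is
unknown, so this is a free parameter of the benchmark.

Transcriptomes: eight species; where the planted presence matrix is
true the species carries 1–2 copies of the family protein, mutated at
the configured per-site divergence (default 0.05), back-translated,
framed by random UTRs and placed on a random strand among 30 random
decoy transcripts; TPM is assigned from log-normal expression weights
and sums to 10⁶ per species. The default presence matrix is mostly
conserved with group-consistent absences (the GAGAGS family missing
from the last two species, the whole S-paralog group from the
second-to-last).

Back-translation samples synonymous codons seed-deterministically
rather than using one codon per residue. This is deliberate: with a
fixed table the CDS of a repeat protein is periodic DNA whose *other*
reading frames are again periodic low-complexity proteins, a
translated-search artifact real transcripts do not show. Codon
marginals and one-residue-lookahead context rules are chosen so that
junction trinucleotides place stop codons densely in all six off-frames
(e.g. Ala→GCT before Ser yields CTA, a reverse-strand stop) and avoid
products such as off-frame tryptophan runs that would spuriously
cross-match repeat queries. The result: only the true coding frame has
long ORFs, as in real data, and the families' off-frames stay five
orders of magnitude away from the 10⁻¹⁵ cut (worst cross-class segment
score ≈ 94 against a required ≈ 160).

All randomness descends from a single seed via `SeedSequence` spawn
keys, so components can be regenerated independently and identical
configurations are byte-identical.

**What passing tests show — and don't.** The benchmark demonstrates
that the pipeline's logic is correct under its stated statistical
assumptions: planted signal is recovered perfectly and nulls stay null.
It does not emulate peptide-level ionization bias, shared peptides
between isoforms (each isoform's evidence is simulated independently),
FDR at the spectrum-match level, chimeric or fragmented assemblies,
codon usage of any real organism, or homologs at twilight-zone
divergence. Real screens inherit all of those complications, so
perfect recovery here bounds correctness, not field performance.

## Numerical choices and limitations

- E-values use the ungapped BLOSUM62 Karlin–Altschul constants even for
  gapped alignments; at the 10⁻¹⁵ working point decisions are separated
  by many orders of magnitude, so the gapped correction is immaterial,
  and the constants are configurable.
- The repeat detector models substitutions only; an indel shifts the
  register and truncates a region rather than being absorbed. Nested or
  higher-order repeat architectures are reported as single periods.
- Repeat-coverage monotonicity in max_divergence holds for the
  repeat-dominated and random sequences exercised in the tests; the
  greedy overlap resolution does not guarantee it for adversarial
  inputs.
- Single-linkage clustering is exact (all-pairs alignment) and intended
  for survivor sets of tens of sequences, not whole proteomes; a cheap
  length-ratio bound skips hopeless pairs.
- `consistency_z` with fewer than two replicates is undefined and
  raises; degenerate inputs (empty tables, all-zero counts, all-ambiguous
  sequences) return empty/zero/NaN with warnings rather than failing.
- Sizes used by the shipped tests and acceptance script — 500 decoys,
  5 replicates, 8 species, 10 (tests) or 3 (script) seeds — were chosen
  so a complete run finishes in minutes on one CPU while keeping every
  statistical check well-powered.
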