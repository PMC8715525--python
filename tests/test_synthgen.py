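import numpy as np
import pandas as pd
import pytest

from silkscreen import (
    MotifGrammar,
    SynthConfig,
    generate_dataset,
    generate_decoy_proteome,
    generate_silk_protein,
    in_silico_digest,
    simulate_peptide_evidence,
    simulate_transcriptomes,
)
from silkscreen.synthgen import (
    ConfigurationError,
    back_translate,
    detectable_peptides,
    mutate_sequence,
)
from silkscreen.simsearch import six_frame_translate

from _oracles import tryptic_peptides_by_enumeration


class TestMotifGrammar:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            MotifGrammar("g", ("GA",), unit_weights=(0.5, 0.6), linker_units=("GS",))

    def test_empty_grammar_rejected(self):
        with pytest.raises(ConfigurationError):
            MotifGrammar("g", ())

    @pytest.mark.parametrize("unit", ["", "GAX1", "gaga"])
    def test_invalid_units_rejected(self, unit):
        with pytest.raises(ConfigurationError):
            MotifGrammar("g", (unit,))

    def test_mutation_rate_bounds(self):
        with pytest.raises(ConfigurationError):
            MotifGrammar("g", ("GA",), mutation_rate=1.5)


class TestGenerateSilkProtein:
    def test_zero_mutation_is_plain_concatenation(self):
        g = MotifGrammar("g", ("GAGAGS",))
        prot = generate_silk_protein(g, 3, termini=("M", ""), rng_seed=0)
        assert prot.seq == "MGAGAGSGAGAGSGAGAGS"

    def test_length_bookkeeping(self):
        g = MotifGrammar("g", ("GA",))
        prot = generate_silk_protein(g, 100, termini=("MKT", "WR"), rng_seed=0)
        assert len(prot.seq) == 5 + 200

    def test_same_seed_reproduces(self):
        g = MotifGrammar("g", ("GAGAGS", "GAGA"), mutation_rate=0.05)
        a = generate_silk_protein(g, 50, rng_seed=42)
        b = generate_silk_protein(g, 50, rng_seed=42)
        assert a.seq == b.seq

    def test_mutation_rate_produces_divergent_draws(self):
        # Monte-Carlo oracle: two independent draws of a 10-unit protein at
        # mutation 0.05 coincide with probability ~ P(residue equal)^60,
        # P(equal) = (1-r)^2 + r^2/19 ~ 0.9026 -> ~0.2% of pairs identical.
        g = MotifGrammar("g", ("GAGAGS",), mutation_rate=0.05)
        n_pairs, identical = 500, 0
        for k in range(n_pairs):
            a = generate_silk_protein(g, 10, rng_seed=10_000 + 2 * k)
            b = generate_silk_protein(g, 10, rng_seed=10_001 + 2 * k)
            identical += a.seq == b.seq
        assert identical / n_pairs < 0.02

    def test_zero_units_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_silk_protein(MotifGrammar("g", ("GA",)), 0)


class TestDecoyProteome:
    def test_zero_n_gives_empty_list(self):
        assert generate_decoy_proteome(0) == []

    def test_uniform_composition_frequencies(self):
        comp = [1 / 20] * 20
        decoys = generate_decoy_proteome(1000, (100, 100), comp, rng_seed=3)
        residues = "".join(p.seq for p in decoys)
        assert len(residues) == 100_000
        se = np.sqrt(0.05 * 0.95 / len(residues))
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            assert abs(residues.count(aa) / len(residues) - 0.05) < 3 * se + 1e-12

    def test_fixed_seed_reproducible(self):
        a = generate_decoy_proteome(5, rng_seed=9)
        b = generate_decoy_proteome(5, rng_seed=9)
        assert [p.seq for p in a] == [p.seq for p in b]

    def test_degenerate_composition_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_decoy_proteome(1, composition=[0.0] * 20)


class TestDigest:
    @pytest.mark.parametrize(
        "seq,mc,expected",
        [
            ("AAKGGRCC", 0, ["AAK", "GGR", "CC"]),
            ("AAKPGG", 0, ["AAKPGG"]),  # no cleavage before proline
            ("", 2, []),
        ],
    )
    def test_examples(self, seq, mc, expected):
        assert in_silico_digest(seq, mc) == expected

    @pytest.mark.parametrize("seq", ["AKRK", "MKAAKRPKGGRK", "KRKRKR"])
    @pytest.mark.parametrize("mc", [0, 1, 2, 3])
    def test_matches_subset_enumeration_oracle(self, seq, mc):
        assert set(in_silico_digest(seq, mc)) == tryptic_peptides_by_enumeration(seq, mc)

    def test_zero_missed_peptides_tile_the_sequence(self, bench):
        for prot in bench.silk_proteins[:3]:
            assert "".join(in_silico_digest(prot, 0)) == prot.seq

    def test_every_planted_silk_has_observable_peptides(self, bench):
        for prot in bench.silk_proteins:
            assert len(detectable_peptides(prot)) >= 4


class TestPeptideEvidence:
    def test_noiseless_limit_is_exhaustive_and_exact(self):
        cfg = SynthConfig(seed=0, detection_prob=1.0, intensity_cv=0.0,
                          contaminant_count=0, n_replicates=3)
        prot = generate_silk_protein(
            MotifGrammar("g", ("GAGAGS",)), 30, termini=("MTTPHVLKDDWSNQIDTR", ""),
            rng_seed=1, protein_id="p1")
        df = simulate_peptide_evidence([prot], cfg, abundances={"p1": 50.0})
        n_pep = len(detectable_peptides(prot))
        assert len(df) == n_pep * 3
        assert (df["feature_area"] == 50.0).all()

    def test_zero_detection_gives_empty_table(self):
        cfg = SynthConfig(seed=0, detection_prob=0.0, contaminant_count=0)
        prot = generate_silk_protein(MotifGrammar("g", ("GA",)), 5, rng_seed=0)
        assert simulate_peptide_evidence([prot], cfg).empty

    def test_lognormal_cv_matches_target(self):
        # log-normal moment oracle: empirical CV within +-20% of intensity_cv
        cfg = SynthConfig(seed=5, detection_prob=1.0, intensity_cv=0.3,
                          contaminant_count=0, n_replicates=5)
        decoys = generate_decoy_proteome(30, (300, 400), rng_seed=5)
        df = simulate_peptide_evidence(decoys, cfg, {p.id: 100.0 for p in decoys})
        areas = df["feature_area"].to_numpy()
        assert len(areas) > 1000
        cv = areas.std(ddof=1) / areas.mean()
        assert 0.24 < cv < 0.36

    def test_invalid_detection_prob_rejected(self):
        with pytest.raises(ConfigurationError):
            SynthConfig(detection_prob=1.5)

    def test_contaminants_are_flagged_and_attached(self, bench):
        contams = bench.features.attrs["contaminants"]
        assert len(contams) == bench.config.contaminant_count
        assert all(p.id.startswith("contam") for p in contams)


class TestTranscriptomes:
    def test_all_false_presence_gives_only_decoys(self):
        cfg = SynthConfig(
            seed=2, n_species=2, n_silk=1,
            ortholog_presence=((False, False),),
            families=SynthConfig().families[:1],
            decoy_transcripts_per_species=5,
        )
        fams = [generate_silk_protein(MotifGrammar("g", ("GAGAGS",)), 20,
                                      rng_seed=0, protein_id="famGA")]
        assemblies, tpm, truth = simulate_transcriptomes(fams, cfg)
        assert all(len(v) == 5 for v in assemblies.values())
        assert all(not d for d in truth["planted_transcripts"]["famGA"].values())

    def test_tpm_sums_to_one_million_per_species(self, bench):
        for sp, table in bench.tpm_tables.items():
            assert table["tpm"].sum() == pytest.approx(1e6, abs=1e-3)

    def test_planted_cds_translates_back_to_protein(self):
        cfg = SynthConfig(seed=3, n_species=1, divergence=0.0,
                          ortholog_presence=tuple((True,) for _ in range(6)),
                          decoy_transcripts_per_species=2)
        bench = generate_dataset(cfg)
        rep = bench.representatives[0]
        planted = bench.truth["planted_transcripts"][rep.id]["sp00"]
        recs = {r.transcript_id: r for r in bench.assemblies["sp00"]}
        tid = planted[0]["transcript_id"]
        frames = six_frame_translate(recs[tid].sequence)
        assert any(rep.seq in fr for fr in frames)

    def test_high_divergence_warns(self):
        fams = [generate_silk_protein(MotifGrammar("g", ("GA",)), 10,
                                      rng_seed=0, protein_id="f")]
        cfg = SynthConfig(seed=0, n_silk=1, n_species=1, divergence=0.6,
                          ortholog_presence=((True,),),
                          decoy_transcripts_per_species=1)
        with pytest.warns(UserWarning, match="divergence"):
            simulate_transcriptomes(fams, cfg)


class TestBackTranslate:
    def test_fixed_table_round_trip(self):
        aa = "MGAGAGSWKR"
        assert six_frame_translate(back_translate(aa))[0] == aa

    def test_sampled_codons_round_trip_and_differ(self):
        rng = np.random.default_rng(0)
        aa = "GAGAGSGAGAGS" * 10
        nt = back_translate(aa, rng)
        assert six_frame_translate(nt)[0] == aa
        assert nt != back_translate(aa)  # synonymous variety was used


class TestDeterminism:
    def test_identical_config_gives_identical_benchmark(self):
        cfg = dict(seed=11, n_decoys=20, decoy_transcripts_per_species=4, n_species=2)
        a = generate_dataset(SynthConfig(**cfg))
        b = generate_dataset(SynthConfig(**cfg))
        assert [p.seq for p in a.proteins] == [p.seq for p in b.proteins]
        pd.testing.assert_frame_equal(a.features, b.features)
        for sp in a.assemblies:
            assert [r.sequence for r in a.assemblies[sp]] == [
                r.sequence for r in b.assemblies[sp]
            ]

    def test_mutate_sequence_zero_rate_is_identity(self):
        rng = np.random.default_rng(0)
        assert mutate_sequence("GAGAGS", 0.0, rng) == "GAGAGS"


def test_write_dataset_serializes_expected_files(tmp_path, small_bench):
    from silkscreen import write_dataset
    from Bio import SeqIO

    write_dataset(small_bench, tmp_path)
    assert (tmp_path / "peptides.tsv").exists()
    assert (tmp_path / "truth.json").exists()
    proteins = list(SeqIO.parse(tmp_path / "proteins.faa", "fasta"))
    assert len(proteins) == len(small_bench.proteins)
    for sp in small_bench.assemblies:
        assert (tmp_path / f"transcripts_{sp}.fasta").exists()
        assert (tmp_path / f"tpm_{sp}.tsv").exists()
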