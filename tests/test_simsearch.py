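import itertools
import math

import numpy as np
import pandas as pd
import pytest

from silkscreen import (
    SynthConfig,
    bit_score,
    conservation_matrix,
    evalue,
    generate_dataset,
    novelty_filter,
    six_frame_translate,
    smith_waterman,
    sw_score,
)
from silkscreen.simsearch import make_aligner, rank_subjects_by_kmers
from silkscreen.synthgen import AMINO_ACIDS, back_translate

from _oracles import BLOSUM62_AGS, brute_force_local_score


class TestSmithWaterman:
    def test_self_match_score_is_diagonal_sum(self):
        # lookup-sum oracle with frozen BLOSUM62 diagonal values
        assert sw_score("GAGAGS", "GAGAGS") == 6 + 4 + 6 + 4 + 6 + 4

    def test_all_negative_pairs_give_no_hit(self):
        assert sw_score("WWWW", "DDDD") == 0
        assert smith_waterman("WWWW", "DDDD") is None

    def test_empty_sequence_gives_no_hit(self):
        assert smith_waterman("", "GAGA") is None

    def test_score_symmetric_under_symmetric_matrix(self):
        rng = np.random.default_rng(0)
        aa = list(AMINO_ACIDS)
        for _ in range(20):
            a = "".join(rng.choice(aa, size=rng.integers(5, 40)))
            b = "".join(rng.choice(aa, size=rng.integers(5, 40)))
            assert sw_score(a, b) == sw_score(b, a)

    @pytest.mark.parametrize("length", [1, 2, 3])
    def test_matches_enumeration_oracle_exhaustively(self, length):
        strings = ["".join(t) for t in itertools.product("AGS", repeat=length)]
        for a, b in itertools.combinations_with_replacement(strings, 2):
            assert sw_score(a, b) == brute_force_local_score(a, b), (a, b)

    def test_matches_enumeration_oracle_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            a = "".join(rng.choice(list("AGS"), size=rng.integers(4, 7)))
            b = "".join(rng.choice(list("AGS"), size=rng.integers(4, 7)))
            assert sw_score(a, b) == brute_force_local_score(a, b), (a, b)

    def test_hit_coordinates_cover_self_match(self):
        hit = smith_waterman("MGAGAGSW", "MGAGAGSW")
        assert (hit.q_start, hit.q_end) == (0, 8)
        assert (hit.s_start, hit.s_end) == (0, 8)
        assert hit.raw_score == sw_score("MGAGAGSW", "MGAGAGSW")

    def test_invalid_gap_penalties_rejected(self):
        with pytest.raises(ValueError):
            make_aligner(gap_open=0)


class TestEvalue:
    def test_strictly_decreasing_in_score(self):
        scores = [10, 50, 100, 200, 400]
        values = [evalue(s, 100, 10_000) for s in scores]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_linear_in_database_size(self):
        assert evalue(50, 100, 2_000) == pytest.approx(2 * evalue(50, 100, 1_000))

    def test_hand_computed_value(self):
        # calculator oracle: 0.134 * 100 * 1e4 * exp(-0.3176 * 100)
        assert evalue(100, 100, 10_000) == pytest.approx(2.1573e-09, rel=1e-3)

    def test_bit_score_formula(self):
        assert bit_score(100) == pytest.approx((0.3176 * 100 - math.log(0.134)) / math.log(2))

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            evalue(10, 0, 100)


class TestSixFrame:
    def test_simple_codon_table(self):
        assert six_frame_translate("ATGGCT")[0] == "MA"

    def test_stop_and_ambiguity_symbols(self):
        frames = six_frame_translate("TAANNN")
        assert frames[0] == "*X"

    def test_reverse_frames_are_forward_frames_of_revcomp(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            nt = "".join(rng.choice(list("ACGT"), size=rng.integers(9, 40)))
            rc = nt.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            assert six_frame_translate(nt)[3:] == six_frame_translate(rc)[:3]

    def test_back_translated_protein_recovered_in_first_frame(self):
        aa = "MSILKTWNDGAGAGS"
        assert six_frame_translate(back_translate(aa))[0] == aa


class TestNoveltyFilter:
    def test_identical_database_entry_is_not_novel(self, bench):
        decoy = bench.decoys[0]
        assert novelty_filter(decoy, bench.known_db) is False

    def test_planted_silks_are_novel_against_decoy_database(self, bench):
        for prot in bench.silk_proteins[:6]:
            assert novelty_filter(prot, bench.known_db) is True

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            novelty_filter("GAGAGS", [])

    def test_random_queries_almost_always_novel(self):
        rng = np.random.default_rng(11)
        aa = list(AMINO_ACIDS)
        db = {f"d{i}": "".join(rng.choice(aa, size=200)) for i in range(20)}
        novel = sum(
            novelty_filter("".join(rng.choice(aa, size=200)), db) for _ in range(100)
        )
        assert novel >= 99

    def test_prefilter_does_not_change_decisions(self, small_bench):
        db = small_bench.known_db
        queries = small_bench.silk_proteins[:4] + small_bench.decoys[:6]
        for q in queries:
            assert novelty_filter(q, db, prefilter=True) == novelty_filter(
                q, db, prefilter=False
            ), q.id

    def test_decisions_invariant_to_database_order(self, small_bench):
        db = list(small_bench.known_db)
        query = small_bench.decoys[3]
        assert novelty_filter(query, db) == novelty_filter(query, db[::-1])


class TestKmerPrefilter:
    def test_ranking_is_deterministic_and_shared_kmers_first(self):
        subjects = [("b", "WWWWWWWW"), ("a", "GAGAGSGAGAGS")]
        ranked = rank_subjects_by_kmers("GAGAGSGA", subjects)
        assert ranked[0][0] == "a"
        assert ranked[0][2] > 0 and ranked[1][2] == 0


class TestConservationMatrix:
    @pytest.fixture()
    def tiny_setup(self):
        from silkscreen import ProteinSequence

        protein = "MTTPHVLKDDWSNQIDTR" + "GAGAGS" * 30
        family = ProteinSequence(id="fam", seq=protein)
        rng = np.random.default_rng(0)
        cds = back_translate(protein, rng)
        decoy_nt = "".join(np.random.default_rng(1).choice(list("ACGT"), size=600))
        assemblies = {
            "spA": [("t_hi", "ACGTAC" + cds), ("t_lo", cds), ("t_junk", decoy_nt)],
            "spB": [("t_none", decoy_nt)],
        }
        tpm_tables = {
            "spA": pd.DataFrame({"transcript_id": ["t_hi", "t_lo", "t_junk"],
                                 "tpm": [50.0, 5.0, 100.0]}),
            "spB": pd.DataFrame({"transcript_id": ["t_none"], "tpm": [1e6]}),
        }
        return family, assemblies, tpm_tables

    def test_max_tpm_among_qualifying_transcripts(self, tiny_setup):
        family, assemblies, tpm_tables = tiny_setup
        out = conservation_matrix([family], assemblies, tpm_tables)
        cell = out[(out.family_id == "fam") & (out.species_id == "spA")].iloc[0]
        assert cell.conserved
        assert cell.n_qualifying == 2
        assert cell.expression_tpm == pytest.approx(50.0)

    def test_absent_species_not_conserved(self, tiny_setup):
        family, assemblies, tpm_tables = tiny_setup
        out = conservation_matrix([family], assemblies, tpm_tables)
        cell = out[(out.family_id == "fam") & (out.species_id == "spB")].iloc[0]
        assert not cell.conserved
        assert math.isnan(cell.expression_tpm)

    def test_missing_tpm_flags_cell(self, tiny_setup):
        family, assemblies, tpm_tables = tiny_setup
        tpm_tables["spA"] = tpm_tables["spA"][tpm_tables["spA"].transcript_id != "t_hi"]
        out = conservation_matrix([family], assemblies, tpm_tables)
        cell = out[(out.family_id == "fam") & (out.species_id == "spA")].iloc[0]
        assert cell.tpm_missing
        assert cell.expression_tpm == pytest.approx(5.0)

    def test_missing_tpm_table_rejected(self, tiny_setup):
        family, assemblies, _ = tiny_setup
        with pytest.raises(ValueError):
            conservation_matrix([family], assemblies, {})

    def test_recovery_degrades_monotonically_with_divergence(self):
        sens = []
        presence = tuple(tuple(True for _ in range(2)) for _ in range(6))
        for div in (0.0, 0.3, 0.45):
            cfg = SynthConfig(seed=4, n_species=2, divergence=div,
                              ortholog_presence=presence,
                              decoy_transcripts_per_species=5)
            b = generate_dataset(cfg)
            mat = conservation_matrix(b.representatives, b.assemblies, b.tpm_tables)
            sens.append(mat["conserved"].mean())
        assert sens[0] == 1.0
        assert sens[0] >= sens[1] >= sens[2]
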