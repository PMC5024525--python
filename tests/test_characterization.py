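"""Consensus building, logos, genome scanning, digestion, and ladders."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from censatkit.satellite_characterization import (
    BSAAI,
    ECORV,
    DigestProfile,
    RestrictionEnzyme,
    align_monomers,
    build_consensus,
    build_logo,
    digest_in_silico,
    ladder_analysis,
    pairwise_identity_stats,
    scan_genome,
    screen_positive_rate,
)
from censatkit.synthetic_data import mutate_monomer, random_monomer

DNA = st.text(alphabet="ACGT", min_size=1, max_size=400)


class TestAlignAndConsensus:
    def test_identical_monomers_align_gap_free(self, rng):
        mono = random_monomer(60, rng)
        block = align_monomers([mono] * 5)
        assert all(row == mono for row in block)

    def test_single_insertion_opens_one_gap_column(self, rng):
        mono = random_monomer(60, rng)
        with_ins = mono[:30] + "A" + mono[30:]
        block = align_monomers([mono, mono, with_ins, mono])
        assert len(set(map(len, block))) == 1
        assert all(row.count("-") == 1 for i, row in enumerate(block) if i != 2)
        assert block[2].count("-") == 0

    def test_planted_mutation_set_recovers_clean_consensus(self, rng):
        # 45 units at 4% substitutions + occasional single-base indels:
        # the majority consensus equals the generating monomer
        mono = random_monomer(109, rng)
        units = [mutate_monomer(mono, 0.04, 0.01, rng) for _ in range(45)]
        model = build_consensus(align_monomers(units))
        assert model.consensus == mono

    def test_extreme_length_deviation_rejected(self, rng):
        mono = random_monomer(100, rng)
        with pytest.raises(ValueError, match="deviates"):
            align_monomers([mono, mono, mono[:40]])

    def test_consensus_majority_and_tie_break(self):
        block = ["TTT", "TTT", "TTT", "AAA", "AAC"]
        model = build_consensus(block)
        assert model.consensus == "TTT"
        tie = ["AA", "AA", "CC", "CC"]
        assert build_consensus(tie).consensus == "AA"  # ties break A < C < G < T

    def test_gap_majority_columns_dropped(self):
        block = ["A-G", "A-G", "ACG"]
        assert build_consensus(block).consensus == "AG"

    def test_consensus_idempotence(self, rng):
        mono = random_monomer(80, rng)
        model = build_consensus(align_monomers([mono] * 7))
        again = build_consensus(align_monomers([model.consensus] * 3))
        assert again.consensus == model.consensus


class TestLogo:
    def test_monomorphic_column_carries_two_bits(self):
        cols = build_logo(["A", "A", "A", "A"])
        assert cols[0].info_bits == pytest.approx(2.0)

    def test_uniform_column_carries_zero_bits(self):
        cols = build_logo(["A", "C", "G", "T"])
        assert cols[0].info_bits == pytest.approx(0.0)

    def test_hand_computed_entropy_column(self):
        # frequencies (0.7, 0.1, 0.1, 0.1): H = 1.35678, info = 0.64322 bits
        seqs = ["A"] * 7 + ["C", "G", "T"]
        col = build_logo(seqs)[0]
        assert col.info_bits == pytest.approx(0.64322, abs=1e-5)
        assert col.heights["A"] == pytest.approx(0.7 * 0.64322, abs=1e-5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_logo([])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.text(alphabet="ACGT", min_size=8, max_size=8), min_size=1, max_size=12))
    def test_bounds_and_height_decomposition(self, seqs):
        for col in build_logo(seqs):
            assert 0.0 <= col.info_bits <= 2.0 + 1e-12
            assert sum(col.heights.values()) == pytest.approx(col.info_bits)
            monomorphic = max(col.frequencies.values()) == 1.0
            assert (col.info_bits == pytest.approx(2.0)) == monomorphic


class TestScanGenome:
    def test_exact_tandem_copies_each_hit_once(self, rng):
        mono = random_monomer(109, rng)
        summary = scan_genome(mono, {"s": mono * 10})
        assert summary.n_hits == 10
        assert summary.coverage_bp == 1090
        assert summary.modal_length == 109
        assert summary.unique_modal_monomers == [mono]

    def test_insertion_copy_binned_at_longer_length(self, rng):
        mono = random_monomer(109, rng)
        with_ins = mono[:50] + "ACG" + mono[50:]
        seq = mono * 4 + with_ins + mono * 5
        summary = scan_genome(mono, {"s": seq})
        assert summary.length_histogram == {109: 9, 112: 1}
        assert summary.modal_length == 109

    def test_satellite_free_genome_yields_no_hits(self, rng):
        mono = random_monomer(109, rng)
        summary = scan_genome(mono, {"s": random_monomer(3000, rng)})
        assert summary.n_hits == 0

    def test_hit_count_matches_planted_copies_across_strands(self, rng):
        from Bio.Seq import reverse_complement

        mono = random_monomer(109, rng)
        genome = {
            "fwd": random_monomer(400, rng) + mono * 6 + random_monomer(400, rng),
            "rev": reverse_complement(mono * 5),
        }
        summary = scan_genome(mono, genome)
        assert summary.n_hits == 11
        strands = set(summary.hits["strand"])
        assert strands == {"+", "-"}
        # minus-strand hit sequences are reported in consensus orientation
        assert set(summary.unique_modal_monomers) == {mono}


class TestPairwiseIdentity:
    def test_self_comparison_is_hundred_percent(self, rng):
        s = [random_monomer(109, rng)]
        stats = pairwise_identity_stats(s, list(s))
        assert stats.min_percent == stats.max_percent == 100.0
        assert stats.any_identical_pair

    def test_single_base_difference(self, rng):
        a = random_monomer(109, rng)
        b = a[:87] + ("T" if a[87] != "T" else "A") + a[88:]
        stats = pairwise_identity_stats([a], [b])
        assert stats.min_percent == pytest.approx(100 * 108 / 109)
        assert stats.min_hamming == 1
        assert not stats.any_identical_pair

    def test_disjoint_sets_have_no_identical_pair(self, rng):
        a = [random_monomer(50, rng) for _ in range(4)]
        b = [random_monomer(50, rng) for _ in range(4)]
        assert not pairwise_identity_stats(a, b).any_identical_pair

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pairwise_identity_stats([random_monomer(50, rng)], [random_monomer(60, rng)])


class TestDigestion:
    def _monomer_with_site(self, rng, enzyme=ECORV, site="GATATC", at=50):
        mono = random_monomer(109, rng)
        while True:  # background must carry no accidental site
            cand = mono[:at] + site + mono[at + len(site) :]
            if len(digest_in_silico(cand * 2, enzyme).fragment_lengths) == 3:
                return cand
            mono = random_monomer(109, rng)

    def test_perfect_array_gives_monomer_ladder(self, rng):
        m = self._monomer_with_site(rng)
        profile = digest_in_silico(m * 10, ECORV)
        # 9 internal monomer-length fragments plus the two terminal pieces
        assert profile.rung_table[109] == 9
        assert len(profile.fragment_lengths) == 11
        assert sum(profile.fragment_lengths) == 1090

    def test_site_loss_creates_off_ladder_dimer(self, rng):
        m = self._monomer_with_site(rng)
        lost = m[:50] + "GGTATC" + m[56:]
        profile = digest_in_silico(m * 3 + lost + m * 6, ECORV)
        assert profile.rung_table[218] == 1

    def test_no_sites_single_fragment(self):
        profile = digest_in_silico("A" * 500, ECORV)
        assert profile.fragment_lengths == [500]

    def test_degenerate_bsaai_site_recognized(self):
        # YACGTR: both CACGTA and TACGTG must cut
        for site in ("CACGTA", "TACGTG"):
            seq = "GG" + site + "GG"
            assert len(digest_in_silico(seq, BSAAI).fragment_lengths) == 2

    @settings(max_examples=80, deadline=None)
    @given(DNA, st.sampled_from([ECORV, BSAAI, RestrictionEnzyme("AluI", "AGCT", 2)]))
    def test_fragments_partition_input(self, seq, enzyme):
        profile = digest_in_silico(seq, enzyme)
        assert sum(profile.fragment_lengths) == len(seq)
        assert all(f > 0 for f in profile.fragment_lengths)


class TestLadderAnalysis:
    def test_dimer_rung_classified_on_ladder(self):
        profile = DigestProfile([109] * 50 + [218] * 3, {109: 50, 218: 3}, 6104)
        result = ladder_analysis(profile)
        assert result["main_interval"] == 109
        assert [r["multiple"] for r in result["main_rungs"]] == [1, 2]
        assert result["off_ladder_rungs"] == []

    def test_non_multiple_rung_flagged_off_ladder(self):
        profile = DigestProfile([109] * 50 + [150] * 5, {109: 50, 150: 5}, 6200)
        result = ladder_analysis(profile)
        assert result["main_interval"] == 109
        assert [r["length"] for r in result["off_ladder_rungs"]] == [150]

    def test_single_fragment_has_undefined_interval(self):
        profile = DigestProfile([500], {500: 1}, 500)
        result = ladder_analysis(profile)
        assert result["undefined"]
        assert result["main_interval"] is None


class TestScreenPositiveRate:
    @pytest.mark.parametrize(
        "pos,total,expected",
        [(638, 960, 66.5), (0, 100, 0.0), (960, 960, 100.0)],
    )
    def test_rates(self, pos, total, expected):
        assert screen_positive_rate(pos, total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            screen_positive_rate(0, 0)
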