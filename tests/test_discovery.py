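"""Tandem-repeat detection, dimer similarity, clustering, and ranking."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from censatkit.satellite_discovery import (
    DetectionParams,
    Monomer,
    SimilarityParams,
    TandemArray,
    build_similarity_graph,
    cluster_monomers,
    detect_tandem_repeats,
    extract_monomers,
    match_clusters_across_species,
    summarize_and_rank,
    wraparound_align,
)
from censatkit.synthetic_data import (
    GenomeSpec,
    SatelliteSpec,
    generate_genome,
    random_monomer,
)

from conftest import slow_wraparound_score, union_find_components


def _mutate_at(seq: str, positions, shift=1) -> str:
    out = list(seq)
    for pos in positions:
        out[pos] = "ACGT"[("ACGT".index(out[pos]) + shift) % 4]
    return "".join(out)


class TestDetectTandemRepeats:
    def test_planted_exact_array_in_random_background(self):
        # fixed-seed 500 bp background around 10 exact copies of a 109-mer
        rng = np.random.default_rng(9)
        mono = "".join(rng.choice(list("ACGT"), 109))
        bg = "".join(rng.choice(list("ACGT"), 500))
        seq = bg[:250] + mono * 10 + bg[250:]
        arrays = detect_tandem_repeats(seq)
        assert len(arrays) == 1
        a = arrays[0]
        assert (a.start, a.end) == (250, 250 + 1090)
        assert a.period == 109
        assert a.copy_number == 10.0
        assert a.pct_matches == 100.0
        assert a.score == 1090  # all 1090 positions match the consensus

    def test_two_copies_of_40mer_fail_min_score(self, rng):
        # 2 x 40 exact copies can score at most 80 < 200
        mono = random_monomer(40, rng)
        assert detect_tandem_repeats(mono * 2) == []

    def test_four_copies_60mer_with_six_substitutions_scores_228(self, rng):
        # interior copy carries 6 substitutions: 234 matches - 6 mismatches
        mono = random_monomer(60, rng)
        mutated = _mutate_at(mono, [5, 15, 25, 35, 45, 55])
        seq = mono + mutated + mono + mono
        arrays = detect_tandem_repeats(seq)
        assert len(arrays) == 1
        a = arrays[0]
        assert a.period == 60
        assert a.score == 228
        assert a.pct_matches == pytest.approx(100 * 234 / 240)

    def test_empty_sequence_and_bad_alphabet(self):
        assert detect_tandem_repeats("") == []
        with pytest.raises(ValueError):
            detect_tandem_repeats("ACGTXACGT" * 50)

    def test_scores_match_independent_wraparound_oracle(self, rng):
        # every reported array's score equals a naive relaxation-DP oracle
        # applied to the reported interval and consensus
        mono = random_monomer(80, rng)
        copies = [_mutate_at(mono, rng.choice(80, size=3, replace=False)) for _ in range(6)]
        seq = random_monomer(300, rng) + "".join(copies) + random_monomer(300, rng)
        arrays = detect_tandem_repeats(seq)
        assert arrays
        for a in arrays:
            oracle = slow_wraparound_score(seq[a.start : a.end], a.consensus_monomer)
            assert a.score == oracle

    def test_reverse_complement_yields_mirrored_arrays(self, rng):
        mono = random_monomer(109, rng)
        spec = GenomeSpec(
            1, 8000, planted=[(0, 2000, SatelliteSpec(mono, 20, sub_rate=0.02))],
            rng_seed=21,
        )
        records, _ = generate_genome(spec)
        seq = str(records[0].seq)
        fwd = detect_tandem_repeats(seq)
        rev = detect_tandem_repeats(reverse_complement(seq))
        assert len(fwd) == len(rev) == 1
        f, r = fwd[0], rev[0]
        assert (f.start, f.end) == (len(seq) - r.end, len(seq) - r.start)
        assert f.score == r.score
        assert f.period == r.period

    def test_nested_multimer_period_not_double_counted(self, rng):
        # a pure array often also verifies at twice the period; only one
        # array may be reported for the locus, at the fundamental period
        mono = random_monomer(109, rng)
        seq = random_monomer(500, rng) + mono * 12 + random_monomer(500, rng)
        arrays = detect_tandem_repeats(seq)
        assert len(arrays) == 1
        assert arrays[0].period == 109


class TestWraparoundAlign:
    def test_rotation_invariant_score(self, rng):
        mono = random_monomer(60, rng)
        seq = mono * 4
        base = wraparound_align(seq, mono).score
        for shift in (1, 17, 45):
            rotated = mono[shift:] + mono[:shift]
            assert wraparound_align(seq, rotated).score == base

    def test_indel_costs_two(self, rng):
        mono = random_monomer(50, rng)
        with_ins = mono + mono[:20] + "A" + mono[20:] + mono
        aln = wraparound_align(with_ins, mono)
        assert aln.score == 150 - 2
        assert aln.indels == 1


class TestExtractMonomers:
    def _array(self, seq: str, copies: float = 5.0) -> TandemArray:
        return TandemArray(
            seq_id="s", start=0, end=int(len(seq) * copies), period=len(seq),
            copy_number=copies, consensus_monomer=seq, score=500,
            pct_matches=100.0, pct_indels=0.0,
        )

    def test_length_filter_is_strictly_greater_than_50(self, rng):
        short = self._array(random_monomer(50, rng))
        keep = self._array(random_monomer(51, rng))
        monomers = extract_monomers([short, keep])
        assert [len(m.seq) for m in monomers] == [51]

    def test_empty_input(self):
        assert extract_monomers([]) == []

    def test_monomer_weight_is_array_copy_number(self, rng):
        arr = self._array(random_monomer(109, rng), copies=37.5)
        (m,) = extract_monomers([arr])
        assert m.weight == 37.5


class TestSimilarityGraph:
    def test_identical_monomers_link(self, rng):
        mono = random_monomer(109, rng)
        monomers = [Monomer("a", mono, 1), Monomer("b", mono, 1)]
        assert build_similarity_graph(monomers) == [(0, 1)]

    def test_rotation_absorbed_by_dimerization(self, rng):
        mono = random_monomer(109, rng)
        rotated = mono[30:] + mono[:30]
        monomers = [Monomer("a", mono, 1), Monomer("b", rotated, 1)]
        assert build_similarity_graph(monomers) == [(0, 1)]

    def test_reverse_complement_monomer_links(self, rng):
        mono = random_monomer(109, rng)
        monomers = [Monomer("a", mono, 1), Monomer("b", reverse_complement(mono), 1)]
        assert build_similarity_graph(monomers) == [(0, 1)]

    def test_divergent_monomers_do_not_link(self, rng):
        # 30 substitutions spread evenly: 72.5% full-length identity, and no
        # ungapped segment reaches 75% identity at a significant E-value
        mono = random_monomer(109, rng)
        positions = np.round(np.linspace(1, 107, 30)).astype(int)
        far = _mutate_at(mono, positions)
        simparams = SimilarityParams()
        # ungapped oracle: enumerate every diagonal segment of mono vs far+far
        dimer = far + far
        passing = False
        for offset in range(-len(mono) + 1, len(dimer)):
            for start in range(max(0, -offset), len(mono)):
                if start + offset >= len(dimer):
                    break
                run_scores = []
                score = 0
                ident = 0
                length = 0
                for k in range(start, len(mono)):
                    if k + offset >= len(dimer):
                        break
                    same = mono[k] == dimer[k + offset]
                    score += simparams.match if same else simparams.mismatch
                    ident += same
                    length += 1
                    if score > 0 and ident / length >= simparams.min_identity:
                        ev = simparams.evalue(score, len(mono), 2 * len(dimer))
                        if ev <= simparams.evalue_threshold:
                            passing = True
        assert not passing
        monomers = [Monomer("a", mono, 1), Monomer("b", far, 1)]
        assert build_similarity_graph(monomers, simparams) == []


class TestClusterMonomers:
    def _singletons(self, n: int):
        return [Monomer(f"m{i}", "A" * 60, 1) for i in range(n)]

    def test_transitive_linkage_merges_chain(self):
        clusters = cluster_monomers(self._singletons(3), [(0, 1), (1, 2)])
        assert len(clusters) == 1
        assert len(clusters[0].members) == 3

    def test_no_edges_gives_singletons(self):
        clusters = cluster_monomers(self._singletons(2), [])
        assert [len(c.members) for c in clusters] == [1, 1]

    def test_random_graph_matches_union_find_oracle(self, rng):
        n = 50
        edges = sorted(
            {tuple(sorted(rng.choice(n, 2, replace=False))) for _ in range(40)}
        )
        clusters = cluster_monomers(self._singletons(n), [tuple(map(int, e)) for e in edges])
        got = sorted(
            (frozenset(int(m.monomer_id[1:]) for m in c.members) for c in clusters),
            key=min,
        )
        assert got == union_find_components(n, edges)


class TestSummarizeAndRank:
    def test_weighted_modal_length_and_total(self, rng):
        members = [
            Monomer("a", random_monomer(109, rng), 5),
            Monomer("b", random_monomer(110, rng), 2),
        ]
        (cluster,) = summarize_and_rank(cluster_monomers(members, [(0, 1)]))
        assert cluster.total_count == 7
        assert cluster.modal_length == 109
        assert cluster.modal_count == 5

    def test_gc_percent_extremes(self):
        at = cluster_monomers([Monomer("a", "ATAT" * 20, 1)], [])
        gc = cluster_monomers([Monomer("g", "GCGC" * 20, 1)], [])
        assert summarize_and_rank(at)[0].gc_percent == 0.0
        assert summarize_and_rank(gc)[0].gc_percent == 100.0

    def test_rank_order_and_abundance_drop(self, rng):
        # the dominant satellite outnumbering the runner-up ~13-fold
        big = [Monomer("a", random_monomer(109, rng), 13013.0)]
        small = [Monomer("b", random_monomer(139, rng), 1000.0)]
        ranked = summarize_and_rank(cluster_monomers(big, []) + cluster_monomers(small, []))
        assert [c.rank for c in ranked] == [1, 2]
        assert ranked[0].total_count / ranked[1].total_count == pytest.approx(13.013)


class TestCrossSpeciesMatch:
    def _table(self, seqs, rng):
        clusters = []
        for i, s in enumerate(seqs):
            (c,) = summarize_and_rank(cluster_monomers([Monomer(f"m{i}", s, 10 - i)], []))
            c.rank = i + 1
            clusters.append(c)
        return clusters

    def test_identical_tables_fully_shared_with_identical_ranks(self, rng):
        seqs = [random_monomer(100, rng) for _ in range(4)]
        ta, tb = self._table(seqs, rng), self._table(seqs, rng)
        report = match_clusters_across_species(ta, tb)
        assert report["shared"] == 4
        assert report["all_ranks_identical"]

    def test_nine_of_ten_shared(self, rng):
        shared = [random_monomer(100, rng) for _ in range(9)]
        ta = self._table(shared + [random_monomer(100, rng)], rng)
        tb = self._table(shared + [random_monomer(100, rng)], rng)
        assert match_clusters_across_species(ta, tb)["shared"] == 9

    def test_disjoint_tables_share_nothing(self, rng):
        ta = self._table([random_monomer(100, rng) for _ in range(3)], rng)
        tb = self._table([random_monomer(100, rng) for _ in range(3)], rng)
        assert match_clusters_across_species(ta, tb)["shared"] == 0
        assert match_clusters_across_species([], tb)["shared"] == 0


class TestRotationInvariance:
    @pytest.mark.parametrize("shift", [1, 13, 54, 108])
    def test_rotated_monomer_keeps_cluster_assignment(self, rng, shift):
        base = random_monomer(109, rng)
        other = random_monomer(109, rng)
        monomers = [
            Monomer("a", base, 5),
            Monomer("b", base[shift:] + base[:shift], 3),
            Monomer("c", other, 2),
        ]
        clusters = summarize_and_rank(
            cluster_monomers(monomers, build_similarity_graph(monomers))
        )
        by_member = {
            m.monomer_id: c.cluster_id for c in clusters for m in c.members
        }
        assert by_member["a"] == by_member["b"]
        assert by_member["a"] != by_member["c"]


class TestPlantedRecovery:
    def test_dominant_satellite_recovered_as_rank_one(self, rng):
        # 40 copies at 5% divergence plus a weaker 139 bp satellite
        mono = random_monomer(109, rng)
        minor = random_monomer(139, rng)
        spec = GenomeSpec(
            1,
            30_000,
            planted=[
                (0, 5_000, SatelliteSpec(mono, 20, sub_rate=0.05)),
                (0, 12_000, SatelliteSpec(mono, 20, sub_rate=0.05)),
                (0, 20_000, SatelliteSpec(minor, 8, sub_rate=0.05)),
            ],
            rng_seed=77,
        )
        records, _ = generate_genome(spec)
        arrays = detect_tandem_repeats(str(records[0].seq), seq_id="scaffold0")
        monomers = extract_monomers(arrays)
        clusters = summarize_and_rank(
            cluster_monomers(monomers, build_similarity_graph(monomers))
        )
        assert clusters[0].modal_length == 109
        assert abs(clusters[0].total_count - 40) <= 4  # within 10% of planted
        assert clusters[1].modal_length == 139
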