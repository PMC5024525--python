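"""Satellite consensus, sequence logos, genome scanning, and in-silico digestion.

Once a candidate satellite is identified, its characterization follows the
standard workflow: align cloned monomer units (star alignment against the
modal-length unit), derive a majority-rule consensus, scan genomes with the
consensus and bin hits by length, summarize the column-wise information
content of the unique modal-length monomers as a sequence logo (in bits),
and digest sequences in silico with the diagnostic restriction enzymes to
reproduce the ladder / off-ladder fragment pattern of tandem arrays.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import reverse_complement

from .satellite_discovery import SimilarityParams, wraparound_align

__all__ = [
    "ConsensusModel",
    "LogoColumn",
    "RestrictionEnzyme",
    "DigestProfile",
    "ScanSummary",
    "IdentityStats",
    "ECORV",
    "BSAAI",
    "align_monomers",
    "build_consensus",
    "build_logo",
    "scan_genome",
    "pairwise_identity_stats",
    "digest_in_silico",
    "ladder_analysis",
    "screen_positive_rate",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BASE_ORDER = "ACGT"  # also the consensus tie-break order


# ---------------------------------------------------------------------------
# Monomer alignment and consensus
# ---------------------------------------------------------------------------


def _star_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def align_monomers(monomers: list[str]) -> list[str]:
    """Star multiple alignment of near-equal-length monomers.

    The modal-length monomer (ties: lexicographically smallest) is the star
    center; every other monomer is globally aligned to it with affine gaps
    and the pairwise gaps are merged into consistent columns. Monomers whose
    length deviates more than 50 % from the modal length are rejected.
    """
    if not monomers:
        raise ValueError("at least one monomer required")
    monomers = [m.upper() for m in monomers]
    lengths = Counter(len(m) for m in monomers)
    modal_len = min(lengths.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    for m in monomers:
        if abs(len(m) - modal_len) > 0.5 * modal_len:
            raise ValueError(
                f"monomer of length {len(m)} deviates >50% from modal {modal_len}"
            )
    center = min(m for m in monomers if len(m) == modal_len)
    aligner = _star_aligner()

    n_c = len(center)
    # per sequence: chars aligned to each center position, and insertions
    # opening before each center position (index 0..n_c)
    aligned_chars: list[list[str]] = []
    insertions: list[list[str]] = []
    for seq in monomers:
        aln = aligner.align(center, seq)[0]
        chars = ["-"] * n_c
        ins: list[str] = [""] * (n_c + 1)
        c_prev = s_prev = 0
        for (c0, c1), (s0, s1) in zip(*aln.aligned):
            if s0 > s_prev:  # insertion in seq before center position c0
                ins[c0] += seq[s_prev:s0]
            for k in range(c1 - c0):
                chars[c0 + k] = seq[s0 + k]
            c_prev, s_prev = c1, s1
        if s_prev < len(seq):
            ins[n_c] += seq[s_prev:]
        aligned_chars.append(chars)
        insertions.append(ins)

    ins_width = [max(len(ins[j]) for ins in insertions) for j in range(n_c + 1)]
    block = []
    for chars, ins in zip(aligned_chars, insertions):
        row = []
        for j in range(n_c):
            row.append(ins[j].ljust(ins_width[j], "-"))
            row.append(chars[j])
        row.append(ins[n_c].ljust(ins_width[n_c], "-"))
        block.append("".join(row))
    return block


@dataclass
class ConsensusModel:
    """Aligned monomer block with its majority-rule consensus."""

    block: list[str]
    consensus: str
    frequencies: pd.DataFrame  # columns A, C, G, T, gap; rows = kept columns


def build_consensus(block: list[str]) -> ConsensusModel:
    """Per-column majority consensus; gap-majority columns are dropped.

    Base ties break in the fixed order A < C < G < T. Column frequencies are
    reported over A, C, G, T and gap and sum to 1.
    """
    if not block:
        raise ValueError("empty alignment block")
    width = len(block[0])
    if any(len(row) != width for row in block):
        raise ValueError("ragged alignment block")
    cons = []
    freq_rows = []
    n = len(block)
    for j in range(width):
        col = [row[j] for row in block]
        counts = Counter(col)
        gaps = counts.get("-", 0)
        if gaps > n / 2:
            continue  # gap-majority column: not part of the consensus
        base = max(_BASE_ORDER, key=lambda b: (counts.get(b, 0), -_BASE_ORDER.index(b)))
        cons.append(base)
        freq_rows.append(
            {b: counts.get(b, 0) / n for b in _BASE_ORDER} | {"gap": gaps / n}
        )
    freq = pd.DataFrame(freq_rows)
    return ConsensusModel(block=block, consensus="".join(cons), frequencies=freq)


# ---------------------------------------------------------------------------
# Sequence logo
# ---------------------------------------------------------------------------


@dataclass
class LogoColumn:
    position: int
    frequencies: dict[str, float]
    info_bits: float
    heights: dict[str, float]


def build_logo(
    sequences: list[str], small_sample_correction: bool = False
) -> list[LogoColumn]:
    """Column-wise information content of equal-length sequences, in bits.

    info_bits = 2 - H where H is the Shannon entropy (log2) of the column's
    base frequencies; letter heights are frequency x info_bits. The optional
    small-sample correction subtracts e(n) = 3 / (2 ln2 n); it defaults off
    so column values stay analytically checkable.
    """
    if not sequences:
        raise ValueError("empty input")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must have equal length")
    n = len(sequences)
    correction = 3.0 / (2.0 * math.log(2.0) * n) if small_sample_correction else 0.0
    columns = []
    for j in range(length):
        counts = Counter(s[j] for s in sequences)
        freqs = {b: counts.get(b, 0) / n for b in _BASE_ORDER}
        entropy = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        info = max(0.0, 2.0 - entropy - correction)
        columns.append(
            LogoColumn(
                position=j,
                frequencies=freqs,
                info_bits=info,
                heights={b: f * info for b, f in freqs.items()},
            )
        )
    return columns


# ---------------------------------------------------------------------------
# Genome scanning
# ---------------------------------------------------------------------------


@dataclass
class ScanSummary:
    hits: pd.DataFrame  # seq_id, start, end, length, strand, score, evalue, hit_seq
    n_hits: int
    coverage_bp: int
    length_histogram: dict[int, int]
    modal_length: int | None
    unique_modal_monomers: list[str]


def _seed_regions(genome_seq: str, consensus: str, k: int = 11):
    """Merge seed k-mer matches (vs the doubled consensus) into scan regions."""
    dimer = consensus + consensus
    kmers = {dimer[i : i + k] for i in range(len(dimer) - k + 1)}
    hits = [
        i
        for i in range(len(genome_seq) - k + 1)
        if genome_seq[i : i + k] in kmers
    ]
    if not hits:
        return []
    pad = len(consensus)
    merge_gap = 2 * len(consensus)
    regions = []
    start = prev = hits[0]
    for h in hits[1:]:
        if h - prev > merge_gap:
            regions.append((max(0, start - pad), min(len(genome_seq), prev + k + pad)))
            start = h
        prev = h
    regions.append((max(0, start - pad), min(len(genome_seq), prev + k + pad)))
    return regions


def scan_genome(
    consensus: str,
    genome: dict[str, str],
    simparams: SimilarityParams | None = None,
) -> ScanSummary:
    """Scan scaffolds with the consensus monomer and bin hits by length.

    Candidate regions are seeded by exact 11-mer matches against the doubled
    consensus (both strands), then aligned with the wraparound aligner; each
    pass of the alignment through the consensus yields one monomer hit.
    Hits are kept at E-value <= threshold and resolved greedily (descending
    score, then leftmost) so retained hits never overlap. Minus-strand hit
    sequences are reported in consensus orientation.
    """
    simparams = simparams or SimilarityParams()
    consensus = consensus.upper()
    aligner = simparams.aligner()
    total_len = sum(len(s) for s in genome.values())
    rows = []
    for seq_id, seq in genome.items():
        seq = seq.upper()
        for strand, query in (("+", consensus), ("-", reverse_complement(consensus))):
            for rs, re_ in _seed_regions(seq, query, k=11):
                region = seq[rs:re_]
                aln = wraparound_align(region, query)
                if aln.score <= 0:
                    continue
                cuts = [aln.start] + [b for b in aln.boundaries if aln.start < b < aln.end] + [aln.end]
                for a, b in zip(cuts, cuts[1:]):
                    if b <= a:
                        continue
                    hit = region[a:b]
                    score = aligner.score(query, hit)
                    ev = simparams.evalue(score, len(consensus), total_len)
                    if ev > simparams.evalue_threshold:
                        continue
                    hit_seq = hit if strand == "+" else reverse_complement(hit)
                    rows.append(
                        {
                            "seq_id": seq_id,
                            "start": rs + a,
                            "end": rs + b,
                            "length": b - a,
                            "strand": strand,
                            "score": float(score),
                            "evalue": ev,
                            "hit_seq": hit_seq,
                        }
                    )
    # greedy overlap resolution: best score first, then leftmost
    rows.sort(key=lambda r: (-r["score"], r["seq_id"], r["start"]))
    kept = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for r in rows:
        spans = occupied.setdefault(r["seq_id"], [])
        if any(max(s, r["start"]) < min(e, r["end"]) for s, e in spans):
            continue
        spans.append((r["start"], r["end"]))
        kept.append(r)
    kept.sort(key=lambda r: (r["seq_id"], r["start"]))
    hits = pd.DataFrame(
        kept,
        columns=["seq_id", "start", "end", "length", "strand", "score", "evalue", "hit_seq"],
    )
    histogram = Counter(hits["length"]) if len(hits) else Counter()
    modal = min(histogram.items(), key=lambda kv: (-kv[1], kv[0]))[0] if histogram else None
    unique_modal = (
        sorted(set(hits.loc[hits["length"] == modal, "hit_seq"])) if modal else []
    )
    return ScanSummary(
        hits=hits,
        n_hits=len(hits),
        coverage_bp=int(hits["length"].sum()) if len(hits) else 0,
        length_histogram={int(k): int(v) for k, v in sorted(histogram.items())},
        modal_length=int(modal) if modal else None,
        unique_modal_monomers=unique_modal,
    )


# ---------------------------------------------------------------------------
# Pairwise identity
# ---------------------------------------------------------------------------


@dataclass
class IdentityStats:
    min_percent: float
    max_percent: float
    mean_percent: float
    any_identical_pair: bool
    min_hamming: int


def pairwise_identity_stats(set_a: list[str], set_b: list[str]) -> IdentityStats:
    """Hamming identities over all cross pairs of two equal-length monomer sets.

    When both sets are the same collection, within-set pairs (i < j) are
    compared instead. Also reports whether any cross pair is identical and
    the minimum Hamming distance over all compared pairs.
    """
    if not set_a or not set_b:
        raise ValueError("empty monomer set")
    length = len(set_a[0])
    if any(len(s) != length for s in set_a) or any(len(s) != length for s in set_b):
        raise ValueError("all sequences must share one length across both sets")
    arr_a = np.frombuffer("".join(set_a).encode(), dtype=np.uint8).reshape(len(set_a), length)
    same = set_a is set_b or set_a == set_b
    arr_b = arr_a if same else np.frombuffer(
        "".join(set_b).encode(), dtype=np.uint8
    ).reshape(len(set_b), length)
    # pairwise hamming distances in blocks to bound memory
    dists = []
    for i in range(len(set_a)):
        d = (arr_b != arr_a[i]).sum(axis=1)
        if same:
            d = d[i + 1 :]
        dists.append(d)
    nonempty = [d for d in dists if len(d)]
    if not nonempty:
        # a single-sequence set compared with itself: one identical pair
        nonempty = [np.array([0])]
    dist = np.concatenate(nonempty)
    ident = 100.0 * (1.0 - dist / length)
    return IdentityStats(
        min_percent=float(ident.min()),
        max_percent=float(ident.max()),
        mean_percent=float(ident.mean()),
        any_identical_pair=bool((dist == 0).any()),
        min_hamming=int(dist.min()),
    )


# ---------------------------------------------------------------------------
# Restriction digestion and ladder analysis
# ---------------------------------------------------------------------------


@dataclass
class RestrictionEnzyme:
    name: str
    pattern: str  # IUPAC recognition site
    cut_offset: int  # cut position within the site (0..len)

    def __post_init__(self) -> None:
        self.pattern = self.pattern.upper()
        if set(self.pattern) - set(_IUPAC):
            raise ValueError("pattern must use IUPAC codes")
        if not 0 <= self.cut_offset <= len(self.pattern):
            raise ValueError("cut offset must lie within the recognition site")

    @property
    def regex(self) -> str:
        return "".join(f"[{_IUPAC[c]}]" for c in self.pattern)


ECORV = RestrictionEnzyme("EcoRV", "GATATC", 3)
BSAAI = RestrictionEnzyme("BsaAI", "YACGTR", 3)


@dataclass
class DigestProfile:
    fragment_lengths: list[int]
    rung_table: dict[int, int]  # fragment length -> multiplicity
    input_length: int


def digest_in_silico(sequence: str, enzyme: RestrictionEnzyme) -> DigestProfile:
    """Cut a linear sequence at every recognition-site occurrence.

    Degenerate IUPAC codes are expanded; overlapping sites are honored. The
    fragments partition the input, so their lengths always sum to its length
    (a sequence without sites yields a single full-length fragment).
    """
    sequence = sequence.upper()
    cuts = sorted(
        {
            m.start() + enzyme.cut_offset
            for m in re.finditer(f"(?=({enzyme.regex}))", sequence)
            if 0 < m.start() + enzyme.cut_offset < len(sequence)
        }
    )
    edges = [0] + cuts + [len(sequence)]
    fragments = [b - a for a, b in zip(edges, edges[1:])]
    return DigestProfile(
        fragment_lengths=fragments,
        rung_table=dict(sorted(Counter(fragments).items())),
        input_length=len(sequence),
    )


def ladder_analysis(profile: DigestProfile, monomer_len: int | None = None) -> dict:
    """Classify digest rungs into the main ladder and off-ladder fragments.

    The main interval is the modal nearest-neighbor rung spacing (anchored
    at zero and weighted by rung multiplicity). Spacings shorter than 80 %
    of the most abundant rung are ignored as terminal-fragment artifacts:
    on a tandem-array digest the brightest low rung is the monomer itself.
    Rungs within 2 % (or 2 bp) of an integer multiple of the interval are
    "main", others "off-ladder". With fewer than two distinct rungs the
    interval is undefined.
    """
    rungs = sorted(profile.rung_table)
    if len(rungs) < 2:
        return {
            "main_interval": None,
            "main_rungs": [],
            "off_ladder_rungs": list(rungs),
            "undefined": True,
        }
    modal_rung = min(profile.rung_table.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    spacing_weight: Counter = Counter()
    prev = 0
    for r in rungs:
        spacing = r - prev
        if spacing >= 0.8 * modal_rung:
            spacing_weight[spacing] += profile.rung_table[r]
        prev = r
    if not spacing_weight:
        spacing_weight[modal_rung] = profile.rung_table[modal_rung]
    interval = min(spacing_weight.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    if monomer_len is not None and abs(interval - monomer_len) <= max(2, 0.02 * monomer_len):
        interval = monomer_len
    main, off = [], []
    for r in rungs:
        mult = round(r / interval)
        if mult >= 1 and abs(r - mult * interval) <= max(2, 0.02 * r):
            main.append({"length": r, "count": profile.rung_table[r], "multiple": mult})
        else:
            off.append({"length": r, "count": profile.rung_table[r]})
    return {
        "main_interval": interval,
        "main_rungs": main,
        "off_ladder_rungs": off,
        "undefined": False,
    }


def screen_positive_rate(n_positive: int, n_total: int) -> float:
    """Percent of positive clones, rounded to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_positive <= n_total:
        raise ValueError("n_positive must lie in [0, n_total]")
    return round(100.0 * n_positive / n_total, 1)
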