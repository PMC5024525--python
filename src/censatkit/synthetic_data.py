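"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study design end-to-end: genomes with planted
near-identical ~109 bp tandem arrays at species-specific copy numbers,
karyotype intensity profiles with a dimmer constricted region, slot-blot
signal grids with dilution series that saturate at high load, and continuous
characters evolved along a species tree. All randomness flows from a single
:class:`numpy.random.Generator` per call, so fixed seeds give byte-identical
outputs, and every generator returns the truth needed for recovery tests.

Mutation model: per-base substitutions at ``sub_rate`` and single-base
indels at ``indel_rate`` (insertion or deletion with equal probability),
matching the 1-13 bp monomer length variation scale seen in real satellite
monomers (108-122 bp around a 109 bp mode). Restriction-site loss emulates
the polymorphic recognition sites behind off-ladder digestion fragments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ancestral_reconstruction import Phylogeny
from .blot_quantification import BlotGrid
from .karyotype_metrics import ChromosomeProfile

__all__ = [
    "SatelliteSpec",
    "GenomeSpec",
    "KaryotypeSpec",
    "BlotTruth",
    "BrownianModel",
    "JumpModel",
    "mutate_monomer",
    "tandem_array",
    "generate_genome",
    "generate_karyotype",
    "generate_blot_grid",
    "evolve_character_on_tree",
    "random_monomer",
    "write_genome_fasta",
    "write_truth_tsv",
    "read_truth_tsv",
]

_BASES = np.array(list("ACGT"))
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _check_dna(seq: str) -> str:
    seq = seq.upper()
    if not seq or set(seq) - set("ACGT"):
        raise ValueError("sequence must be non-empty and over ACGT")
    return seq


def random_monomer(length: int, rng: np.random.Generator, gc: float = 0.4) -> str:
    """Random monomer with the given GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class SatelliteSpec:
    """A satellite family to plant: consensus, copies per array, mutation rates."""

    consensus_seq: str
    n_copies: int
    sub_rate: float = 0.0
    indel_rate: float = 0.0
    site_loss_rate: float = 0.0
    loss_site: str | None = None  # IUPAC pattern whose site may be ablated

    def __post_init__(self) -> None:
        self.consensus_seq = _check_dna(self.consensus_seq)
        for r in (self.sub_rate, self.indel_rate, self.site_loss_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_copies < 0:
            raise ValueError("n_copies must be >= 0")

    @property
    def monomer_len(self) -> int:
        return len(self.consensus_seq)


@dataclass
class GenomeSpec:
    n_scaffolds: int
    scaffold_len: int
    background_gc: float = 0.4
    planted: list[tuple[int, int, SatelliteSpec]] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background_gc <= 1:
            raise ValueError("background_gc must lie in [0, 1]")
        for scaffold, start, sat in self.planted:
            if not (0 <= scaffold < self.n_scaffolds):
                raise ValueError("planted scaffold index out of range")
            if start < 0 or start + sat.n_copies * sat.monomer_len > self.scaffold_len:
                raise ValueError("planted array does not fit within scaffold")


@dataclass
class KaryotypeSpec:
    """Karyotype profiles: per-chromosome length, constriction, DNA share."""

    n_chromosomes: int
    lengths: list[int]  # profile samples per chromosome
    constriction_fractions: list[float]
    dip_factor: float = 0.6  # intensity inside constriction, relative
    dna_shares: list[float] | None = None
    constriction_centers: list[float] | None = None  # fraction along chromosome
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if len(self.lengths) != self.n_chromosomes:
            raise ValueError("lengths must list one entry per chromosome")
        if len(self.constriction_fractions) != self.n_chromosomes:
            raise ValueError("one constriction fraction per chromosome required")
        if not 0 < self.dip_factor <= 1:
            raise ValueError("dip factor must lie in (0, 1]")
        if self.dna_shares is None:
            self.dna_shares = [1.0 / self.n_chromosomes] * self.n_chromosomes
        if abs(sum(self.dna_shares) - 1.0) > 1e-9:
            raise ValueError("DNA shares must sum to 1")
        if self.constriction_centers is None:
            self.constriction_centers = [0.5] * self.n_chromosomes
        for f, c in zip(self.constriction_fractions, self.constriction_centers):
            if not 0 <= f <= 1:
                raise ValueError("constriction fraction must lie in [0, 1]")
            if not f / 2 <= c <= 1 - f / 2:
                raise ValueError("constriction interval must lie within chromosome")


@dataclass
class BlotTruth:
    """True relative copy numbers and the dilution design of a slot blot."""

    species: list[str]
    folds: list[float]
    dilutions_ng: tuple[float, ...] = (500.0, 50.0, 5.0)
    saturation_level: float = 1000.0
    noise_cv: float = 0.0
    gain: float = 1.0  # signal units per (fold x ng)
    loading_level: float = 100.0

    def __post_init__(self) -> None:
        if len(self.folds) != len(self.species):
            raise ValueError("one fold per species required")
        if any(f < 0 for f in self.folds):
            raise ValueError("folds must be >= 0")
        d = self.dilutions_ng
        if not all(a > b for a, b in zip(d, d[1:])):
            raise ValueError("dilutions must be strictly decreasing")
        if self.saturation_level <= 0:
            raise ValueError("saturation_level must be positive")


# ---------------------------------------------------------------------------
# Sequence generators
# ---------------------------------------------------------------------------


def mutate_monomer(
    consensus: str,
    sub_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> str:
    """One mutated copy of ``consensus``: substitutions plus single-base indels.

    Expected substitutions are ``sub_rate x length``; indels split evenly
    between single-base insertions and deletions, so the expected length
    change is zero.
    """
    consensus = _check_dna(consensus)
    out: list[str] = []
    for base in consensus:
        u = rng.random()
        if u < indel_rate:
            if rng.random() < 0.5:
                out.append(str(rng.choice(_BASES)))  # insertion before base
                out.append(base)
            # else: deletion, emit nothing
            continue
        if rng.random() < sub_rate:
            others = [b for b in "ACGT" if b != base]
            out.append(others[rng.integers(3)])
        else:
            out.append(base)
    return "".join(out)


def _ablate_site(copy: str, pattern: str, rng: np.random.Generator) -> str:
    """Destroy the first restriction-site occurrence by one substitution."""
    regex = "".join(f"[{_IUPAC[c]}]" for c in pattern.upper())
    m = re.search(regex, copy)
    if m is None:
        return copy
    pos = m.start() + int(rng.integers(len(pattern)))
    base = copy[pos]
    others = [b for b in "ACGT" if b != base and b not in _IUPAC[pattern.upper()[pos - m.start()]]]
    if not others:
        others = [b for b in "ACGT" if b != base]
    return copy[:pos] + others[int(rng.integers(len(others)))] + copy[pos + 1 :]


def tandem_array(spec: SatelliteSpec, rng: np.random.Generator) -> str:
    """Head-to-tail array of independently mutated monomer copies."""
    copies = []
    for _ in range(spec.n_copies):
        copy = mutate_monomer(spec.consensus_seq, spec.sub_rate, spec.indel_rate, rng)
        if spec.loss_site and spec.site_loss_rate > 0 and rng.random() < spec.site_loss_rate:
            copy = _ablate_site(copy, spec.loss_site, rng)
        copies.append(copy)
    return "".join(copies)


def generate_genome(spec: GenomeSpec) -> tuple[list[SeqRecord], pd.DataFrame]:
    """FASTA scaffolds with planted arrays plus a 0-based half-open truth table."""
    rng = np.random.default_rng(spec.rng_seed)
    gc = spec.background_gc
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    scaffolds = [
        list(rng.choice(_BASES, size=spec.scaffold_len, p=p))
        for _ in range(spec.n_scaffolds)
    ]
    rows = []
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(spec.n_scaffolds)}
    for scaffold, start, sat in spec.planted:
        array = tandem_array(sat, rng)
        end = start + len(array)
        if end > spec.scaffold_len:
            raise ValueError("mutated array exceeds scaffold length")
        for s, e in occupied[scaffold]:
            if max(s, start) < min(e, end):
                raise ValueError("planted arrays overlap")
        occupied[scaffold].append((start, end))
        scaffolds[scaffold][start:end] = list(array)
        rows.append(
            {
                "scaffold": f"scaffold{scaffold}",
                "start": start,
                "end": end,
                "period": sat.monomer_len,
                "n_copies": sat.n_copies,
                "consensus": sat.consensus_seq,
            }
        )
    records = [
        SeqRecord(Seq("".join(s)), id=f"scaffold{i}", description="")
        for i, s in enumerate(scaffolds)
    ]
    truth = pd.DataFrame(
        rows, columns=["scaffold", "start", "end", "period", "n_copies", "consensus"]
    ).sort_values(["scaffold", "start"], ignore_index=True)
    return records, truth


# ---------------------------------------------------------------------------
# Karyotype, blot, and tree-character generators
# ---------------------------------------------------------------------------


def generate_karyotype(
    spec: KaryotypeSpec, rng: np.random.Generator
) -> list[ChromosomeProfile]:
    """Intensity profiles with a dimmer annotated constriction per chromosome.

    Total intensity per chromosome is proportional to its DNA share; inside
    the constriction the intensity is reduced by the dip factor.
    """
    profiles = []
    for i in range(spec.n_chromosomes):
        n = spec.lengths[i]
        frac = spec.constriction_fractions[i]
        center = spec.constriction_centers[i]
        width = int(round(frac * n))
        start = int(round(center * n - width / 2))
        start = max(0, min(start, n - width))
        base = np.ones(n)
        base[start : start + width] = spec.dip_factor
        scale = spec.dna_shares[i] / base.sum()
        intensity = base * scale
        if spec.noise_cv > 0:
            sigma = np.sqrt(np.log(1 + spec.noise_cv**2))
            intensity = intensity * rng.lognormal(-sigma**2 / 2, sigma, size=n)
        profiles.append(
            ChromosomeProfile(
                chrom_id=f"chr{i + 1}",
                intensity=intensity,
                constriction=(start, start + width),
            )
        )
    return profiles


def generate_blot_grid(truth: BlotTruth, rng: np.random.Generator) -> BlotGrid:
    """Slot-blot grid: signal = min(saturation, gain x fold x ng) x noise."""
    loads = np.asarray(truth.dilutions_ng, dtype=float)
    signals = np.zeros((len(truth.species), len(loads)))
    controls = np.zeros(len(truth.species))
    sigma = np.sqrt(np.log(1 + truth.noise_cv**2)) if truth.noise_cv > 0 else 0.0
    for si, fold in enumerate(truth.folds):
        clean = np.minimum(truth.saturation_level, truth.gain * fold * loads)
        if sigma > 0:
            noise = rng.lognormal(-sigma**2 / 2, sigma, size=len(loads))
        else:
            noise = 1.0
        signals[si] = clean * noise
        cnoise = rng.lognormal(-sigma**2 / 2, sigma) if sigma > 0 else 1.0
        controls[si] = truth.loading_level * cnoise
    return BlotGrid(
        species=list(truth.species),
        dilutions_ng=loads,
        signals=signals,
        loading_control=controls,
    )


@dataclass
class BrownianModel:
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class JumpModel:
    """Deterministic shifts on named branches, plus optional Brownian noise."""

    jumps: dict[str, float]  # child-node label -> shift applied on its branch
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def evolve_character_on_tree(
    tree: Phylogeny,
    root_value: float,
    model: BrownianModel | JumpModel,
    rng: np.random.Generator,
) -> tuple[dict[str, float], dict[str, float]]:
    """Evolve a continuous character root-to-tips; returns (tip, all-node) values.

    Brownian motion adds N(0, sigma^2 x branch_length) per branch; the jump
    model adds fixed shifts on named branches (so only that clade's tips move).
    """
    sigma = model.sigma
    jumps = model.jumps if isinstance(model, JumpModel) else {}
    values = np.zeros(tree.n_nodes)
    for i in reversed(tree.postorder()):  # preorder
        if i == tree.root:
            values[i] = root_value
            continue
        length = tree.edge_length[i]
        if length is None:
            length = 1.0
        step = sigma * np.sqrt(length) * rng.standard_normal() if sigma > 0 else 0.0
        values[i] = values[tree.parent[i]] + step + jumps.get(tree.labels[i], 0.0)
    node_values = {tree.labels[i]: float(values[i]) for i in range(tree.n_nodes)}
    tip_values = {lb: node_values[lb] for lb in tree.tip_labels}
    return tip_values, node_values


# ---------------------------------------------------------------------------
# Interchange
# ---------------------------------------------------------------------------


def write_genome_fasta(records: list[SeqRecord], path) -> None:
    SeqIO.write(records, path, "fasta")


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
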