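"""Centromere metrics from 1-D chromosome intensity profiles.

A :class:`ChromosomeProfile` is an ordered series of DNA-stain intensity
samples along one chromosome with an annotated centromeric (primary
constriction) interval. From a full karyotype of such profiles the module
computes, per chromosome:

* the fraction of chromosome length covered by the constriction;
* the DNA content of the constriction in Mb, apportioning a fixed haploid
  genome size by stain-intensity fractions (the intensity share of each
  chromosome times the within-chromosome fraction inside the interval);
* the centromeric position class (metacentric .. telocentric) from the
  arm ratio, measured from each terminus to the nearer interval edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChromosomeProfile",
    "KaryotypeParams",
    "KaryotypeReport",
    "interval_coverage_percent",
    "interval_dna_mb",
    "classify_centromere_position",
    "karyotype_summary",
    "coverage_ratio",
    "read_profiles_tsv",
    "write_profiles_tsv",
]


@dataclass
class ChromosomeProfile:
    """Intensity samples along one chromosome (0-based half-open intervals)."""

    chrom_id: str
    intensity: np.ndarray
    constriction: tuple[int, int]
    signal_interval: tuple[int, int] | None = None
    note: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1 or len(self.intensity) < 2:
            raise ValueError("profile needs at least 2 ordered intensity samples")
        if (self.intensity < 0).any():
            raise ValueError("intensities must be non-negative")
        s, e = self.constriction
        if not (0 <= s <= e <= len(self.intensity)):
            raise ValueError("constriction interval outside profile")

    def __len__(self) -> int:
        return len(self.intensity)


@dataclass
class KaryotypeParams:
    """Genome size and arm-ratio class boundaries (Levan convention)."""

    genome_size_mb: float = 484.0
    arm_ratio_boundaries: tuple[float, float, float] = (1.7, 3.0, 7.0)
    class_labels: tuple[str, str, str, str] = (
        "metacentric",
        "submetacentric",
        "subtelocentric",
        "telocentric",
    )
    arm_edge: str = "nearer"  # or "midpoint"

    def __post_init__(self) -> None:
        b = self.arm_ratio_boundaries
        if not all(x < y for x, y in zip(b, b[1:])) or b[0] <= 1:
            raise ValueError("boundaries must be strictly increasing and > 1")


@dataclass
class KaryotypeReport:
    per_chromosome: pd.DataFrame
    mean_coverage_percent: float
    min_coverage_percent: float
    max_coverage_percent: float
    total_dna_mb: float
    class_counts: dict[str, int]


def interval_coverage_percent(
    profile: ChromosomeProfile, interval: tuple[int, int] | None = None
) -> float:
    """Percent of chromosome length spanned by the interval (default: constriction)."""
    if len(profile) == 0:
        raise ValueError("empty profile")
    s, e = interval if interval is not None else profile.constriction
    return 100.0 * (e - s) / len(profile)


def interval_dna_mb(
    profiles: list[ChromosomeProfile],
    chrom_id: str,
    interval: tuple[int, int] | None = None,
    params: KaryotypeParams | None = None,
) -> float:
    """DNA Mb inside the interval, apportioned from the whole karyotype.

    Mb = genome_size_mb x (intensity within interval) / (total intensity over
    all chromosomes); this equals the chromosome's genome share times its
    within-chromosome interval fraction.
    """
    params = params or KaryotypeParams()
    total = sum(float(p.intensity.sum()) for p in profiles)
    if total <= 0:
        raise ValueError("zero total karyotype intensity")
    profile = next(p for p in profiles if p.chrom_id == chrom_id)
    s, e = interval if interval is not None else profile.constriction
    inside = float(profile.intensity[s:e].sum())
    return params.genome_size_mb * inside / total


def classify_centromere_position(
    profile: ChromosomeProfile, params: KaryotypeParams | None = None
) -> tuple[str | None, float]:
    """Centromere position class and arm ratio (longer/shorter arm).

    Arms run from each chromosome terminus to the nearer edge of the
    centromeric interval (configurable to the interval midpoint). A zero
    short arm gives an infinite ratio -> terminal (telocentric) class; an
    interval covering the whole chromosome leaves the class undefined.
    """
    params = params or KaryotypeParams()
    s, e = profile.constriction
    n = len(profile)
    if s == 0 and e == n:
        return None, math.nan
    if params.arm_edge == "midpoint":
        mid = (s + e) / 2.0
        left, right = mid, n - mid
    else:
        left, right = float(s), float(n - e)
    short, long_ = sorted((left, right))
    ratio = math.inf if short == 0 else long_ / short
    b = params.arm_ratio_boundaries
    if ratio < b[0]:
        label = params.class_labels[0]
    elif ratio < b[1]:
        label = params.class_labels[1]
    elif ratio < b[2]:
        label = params.class_labels[2]
    else:
        label = params.class_labels[3]
    return label, ratio


def karyotype_summary(
    profiles: list[ChromosomeProfile], params: KaryotypeParams | None = None
) -> KaryotypeReport:
    """Per-chromosome metrics plus genome-wide aggregates."""
    if not profiles:
        raise ValueError("at least one profile required")
    params = params or KaryotypeParams()
    rows = []
    for p in profiles:
        label, ratio = classify_centromere_position(p, params)
        rows.append(
            {
                "chrom_id": p.chrom_id,
                "coverage_percent": interval_coverage_percent(p),
                "dna_mb": interval_dna_mb(profiles, p.chrom_id, params=params),
                "arm_ratio": ratio,
                "position_class": label,
            }
        )
    table = pd.DataFrame(rows)
    counts = table["position_class"].value_counts().to_dict()
    return KaryotypeReport(
        per_chromosome=table,
        mean_coverage_percent=float(table["coverage_percent"].mean()),
        min_coverage_percent=float(table["coverage_percent"].min()),
        max_coverage_percent=float(table["coverage_percent"].max()),
        total_dna_mb=float(table["dna_mb"].sum()),
        class_counts=counts,
    )


def coverage_ratio(report_a: KaryotypeReport, report_b: KaryotypeReport) -> float:
    """Mean constriction coverage of karyotype A over karyotype B."""
    return report_a.mean_coverage_percent / report_b.mean_coverage_percent


# ---------------------------------------------------------------------------
# TSV interchange (chrom, position_index, intensity, interval flags)
# ---------------------------------------------------------------------------


def write_profiles_tsv(profiles: list[ChromosomeProfile], path) -> None:
    rows = []
    for p in profiles:
        s, e = p.constriction
        sig = p.signal_interval
        for i, v in enumerate(p.intensity):
            rows.append(
                {
                    "chrom": p.chrom_id,
                    "position_index": i,
                    "intensity": v,
                    "in_constriction": int(s <= i < e),
                    "in_signal": int(sig is not None and sig[0] <= i < sig[1]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path) -> list[ChromosomeProfile]:
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("position_index")
        flags = grp["in_constriction"].to_numpy().astype(bool)
        idx = np.nonzero(flags)[0]
        constriction = (int(idx[0]), int(idx[-1]) + 1) if len(idx) else (0, 0)
        sig = None
        if "in_signal" in grp and grp["in_signal"].any():
            sidx = np.nonzero(grp["in_signal"].to_numpy().astype(bool))[0]
            sig = (int(sidx[0]), int(sidx[-1]) + 1)
        profiles.append(
            ChromosomeProfile(
                chrom_id=str(chrom),
                intensity=grp["intensity"].to_numpy(),
                constriction=constriction,
                signal_interval=sig,
            )
        )
    return profiles
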