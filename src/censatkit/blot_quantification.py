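"""Relative satellite copy number from slot-blot signal grids.

A slot blot loads a dilution series of genomic DNA per species, hybridizes a
satellite probe, and stains total DNA as a loading control. Because signals
saturate at high load, quantification uses only unsaturated dilutions:

1. normalize each hybridization signal by the species' loading-control
   intensity (taken at the highest load, where staining is reliable);
2. walk the dilution series from the highest load down and drop saturated
   loads (the signal ratio between adjacent dilutions falls short of the
   dilution factor);
3. average the ratio to an intermediate reference species over the selected
   dilutions, then rescale every species so the final reference equals 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BlotGrid",
    "QuantParams",
    "RelativeCopyEstimate",
    "select_unsaturated",
    "relative_copy_number",
    "pairwise_fold_range",
    "read_blot_tsv",
    "write_blot_tsv",
]


@dataclass
class BlotGrid:
    """Species x dilution hybridization signals plus loading controls."""

    species: list[str]
    dilutions_ng: np.ndarray  # strictly decreasing loads
    signals: np.ndarray  # shape (n_species, n_dilutions)
    loading_control: np.ndarray  # per species, at the highest load

    def __post_init__(self) -> None:
        self.dilutions_ng = np.asarray(self.dilutions_ng, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        self.loading_control = np.asarray(self.loading_control, dtype=float)
        if not (np.diff(self.dilutions_ng) < 0).all():
            raise ValueError("dilution loads must be strictly decreasing")
        if self.signals.shape != (len(self.species), len(self.dilutions_ng)):
            raise ValueError("signal matrix shape mismatch")
        if (self.signals < 0).any():
            raise ValueError("signals must be non-negative")
        if (self.loading_control <= 0).any():
            raise ValueError("loading controls must be positive")

    def row(self, species: str) -> np.ndarray:
        return self.signals[self.species.index(species)]

    def control(self, species: str) -> float:
        return float(self.loading_control[self.species.index(species)])


@dataclass
class QuantParams:
    """Saturation rule, averaging depth, and the two-step reference chain."""

    saturation_tolerance: float = 0.3
    n_average: int = 2
    intermediate_ref: str | None = None
    final_ref: str | None = None
    background: float = 0.0  # signal-unit background estimate
    geometric_mean: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.saturation_tolerance < 1):
            raise ValueError("saturation tolerance must be in (0, 1)")

    @property
    def detection_floor(self) -> float:
        return 2.0 * self.background


@dataclass
class RelativeCopyEstimate:
    table: pd.DataFrame  # species, fold, detected, dilutions_used, flags
    intermediate_ref: str
    final_ref: str

    def fold(self, species: str) -> float:
        return float(self.table.set_index("species").loc[species, "fold"])

    def detected(self, species: str) -> bool:
        return bool(self.table.set_index("species").loc[species, "detected"])


def select_unsaturated(
    grid: BlotGrid, params: QuantParams | None = None
) -> dict[str, dict]:
    """Per-species unsaturated dilution choice.

    Walking from the highest load down, a load is saturated when its signal
    ratio to the next dilution is below dilution_factor x (1 - tolerance).
    The lowest load, having no successor, is unsaturated by convention when
    its signal clears the detection floor. Returns for each species the top
    ``n_average`` unsaturated loads, a below-detection flag, and a shortfall
    flag when fewer than requested loads were available.
    """
    params = params or QuantParams()
    loads = grid.dilutions_ng
    if len(loads) < 2:
        raise ValueError("need at least two dilutions")
    out: dict[str, dict] = {}
    for si, sp in enumerate(grid.species):
        sig = grid.signals[si]
        if (sig <= params.detection_floor).all():
            out[sp] = {
                "loads": [],
                "all_unsaturated": [],
                "below_detection": True,
                "short": True,
            }
            continue
        unsat = []
        for i, load in enumerate(loads):
            if sig[i] <= params.detection_floor:
                continue
            if i < len(loads) - 1:
                factor = loads[i] / loads[i + 1]
                nxt = sig[i + 1]
                ratio = math.inf if nxt == 0 else sig[i] / nxt
                if ratio < factor * (1.0 - params.saturation_tolerance):
                    continue  # saturated
            unsat.append(float(load))
        chosen = unsat[: params.n_average]
        out[sp] = {
            "loads": chosen,
            "all_unsaturated": unsat,
            "below_detection": False,
            "short": len(chosen) < params.n_average,
        }
    return out


def relative_copy_number(
    grid: BlotGrid, params: QuantParams | None = None
) -> RelativeCopyEstimate:
    """Loading-normalized fold estimates via two-step reference rescaling.

    Each species' normalized signals are compared to the intermediate
    reference at the same dilutions and averaged; the resulting values are
    then divided by the final reference's value, fixing it at exactly 1.
    Species below the detection floor get fold 0 with ``detected=False``.
    """
    params = params or QuantParams()
    inter = params.intermediate_ref or grid.species[0]
    final = params.final_ref or inter
    for ref in (inter, final):
        if ref not in grid.species:
            raise ValueError(f"reference species {ref!r} not in grid")
    selections = select_unsaturated(grid, params)
    if selections[inter]["below_detection"] or selections[final]["below_detection"]:
        raise ValueError("reference species below detection")

    norm = grid.signals / grid.loading_control[:, None]
    load_index = {float(l): i for i, l in enumerate(grid.dilutions_ng)}
    inter_row = norm[grid.species.index(inter)]

    raw: dict[str, float] = {}
    rows = []
    for si, sp in enumerate(grid.species):
        sel = selections[sp]
        if sel["below_detection"]:
            raw[sp] = 0.0
            rows.append((sp, [], False, sel["short"]))
            continue
        ref_ok = set(selections[inter]["all_unsaturated"])
        usable = [
            l
            for l in sel["loads"]
            if l in ref_ok and inter_row[load_index[l]] > 0
        ]
        if not usable:
            raise ValueError(f"no usable reference dilutions for {sp}")
        ratios = [
            norm[si, load_index[l]] / inter_row[load_index[l]] for l in usable
        ]
        if params.geometric_mean:
            value = float(np.exp(np.mean(np.log(ratios))))
        else:
            value = float(np.mean(ratios))
        raw[sp] = value
        rows.append((sp, usable, True, sel["short"]))

    final_value = raw[final]
    if final_value <= 0:
        raise ValueError("final reference has non-positive estimate")
    table = pd.DataFrame(
        {
            "species": [r[0] for r in rows],
            "fold": [raw[r[0]] / final_value for r in rows],
            "detected": [r[2] for r in rows],
            "dilutions_used": [",".join(f"{l:g}" for l in r[1]) for r in rows],
            "flag_short_selection": [r[3] for r in rows],
        }
    )
    return RelativeCopyEstimate(table=table, intermediate_ref=inter, final_ref=final)


def pairwise_fold_range(
    grid: BlotGrid,
    species_a: str,
    species_b: str,
    params: QuantParams | None = None,
) -> dict:
    """Bracket the fold of A over B by equal-signal load matching.

    For each unsaturated dilution of B, the load of A expected to give the
    same normalized signal is interpolated (log-log linear) within A's
    unsaturated range; the fold is load_B / load_A. Returns the min/max
    bracket over usable dilutions, or an ``undefined`` flag when the linear
    ranges do not overlap.
    """
    params = params or QuantParams()
    selections = select_unsaturated(grid, params)
    sel_a, sel_b = selections[species_a], selections[species_b]
    if sel_a["below_detection"] or sel_b["below_detection"]:
        return {"low": math.nan, "high": math.nan, "undefined": True}
    norm = grid.signals / grid.loading_control[:, None]
    load_index = {float(l): i for i, l in enumerate(grid.dilutions_ng)}
    ia = grid.species.index(species_a)
    ib = grid.species.index(species_b)

    loads_a = np.array(sorted(sel_a["loads"]))
    sig_a = np.array([norm[ia, load_index[l]] for l in loads_a])
    ok = sig_a > 0
    loads_a, sig_a = loads_a[ok], sig_a[ok]
    folds = []
    for lb in sel_b["loads"]:
        sb = norm[ib, load_index[lb]]
        if sb <= 0:
            continue
        if len(loads_a) == 1:
            # single usable point: assume proportionality through it
            la = float(loads_a[0] * sb / sig_a[0])
            if not (0.5 * loads_a[0] <= la <= 2.0 * loads_a[0]):
                continue
        else:
            if not (sig_a.min() <= sb <= sig_a.max()):
                continue  # outside A's observed linear range
            la = float(
                np.exp(np.interp(np.log(sb), np.log(sig_a), np.log(loads_a)))
            )
        folds.append(lb / la)
    if not folds:
        return {"low": math.nan, "high": math.nan, "undefined": True}
    return {"low": min(folds), "high": max(folds), "undefined": False}


# ---------------------------------------------------------------------------
# TSV interchange (species, load_ng, signal, loading_control)
# ---------------------------------------------------------------------------


def write_blot_tsv(grid: BlotGrid, path) -> None:
    rows = []
    for si, sp in enumerate(grid.species):
        for di, load in enumerate(grid.dilutions_ng):
            rows.append(
                {
                    "species": sp,
                    "load_ng": load,
                    "signal": grid.signals[si, di],
                    "loading_control": grid.loading_control[si],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_blot_tsv(path) -> BlotGrid:
    df = pd.read_csv(path, sep="\t")
    species = list(dict.fromkeys(df["species"]))
    loads = np.sort(df["load_ng"].unique())[::-1]
    signals = np.zeros((len(species), len(loads)))
    controls = np.zeros(len(species))
    for si, sp in enumerate(species):
        sub = df[df["species"] == sp].set_index("load_ng")
        signals[si] = [sub.loc[l, "signal"] for l in loads]
        controls[si] = sub["loading_control"].iloc[0]
    return BlotGrid(species, loads, signals, controls)
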