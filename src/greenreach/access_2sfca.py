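"""Huff-adjusted two-step floating catchment area accessibility.

Step 1 gives every park j a supply-demand ratio

    R_j = S_j / Σ_i Prob_ij · P_i · G(t_ij, t0),        (sum over t_ij ≤ t0)

where S_j is the composite attractiveness, P_i the cell population,
G the normalized Gaussian time decay, and Prob_ij the Huff probability that
cell i chooses park j among its reachable alternatives.  Step 2 sums the
ratios back onto cells:

    A_i = Σ_j Prob_ij · R_j · G(t_ij, t0).              (sum over t_ij ≤ t0)

Because the same Prob·G weights appear in both steps, total population-
weighted accessibility conserves supply exactly:
Σ_i P_i·A_i = Σ_{j : demand > 0} S_j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .attractiveness import ParkSupply
from .network_travel import ODTimeMatrix

HUFF_VARIANTS = ("gaussian", "gaussian_over_time", "gaussian_times_time")

#: Floor (minutes) for travel times in the inverse-time Huff variant.
EPS_MINUTES = 0.1


@dataclass
class DecaySpec:
    """Decay threshold and the Huff weight variant.

    ``gaussian`` (default) weights alternatives by S_j·G; the other two
    variants keep an explicit travel-time factor for sensitivity analysis:
    ``gaussian_over_time`` uses S_j/t_ij·G, ``gaussian_times_time``
    S_j·t_ij·G.
    """

    t0_min: float
    huff_variant: str = "gaussian"

    def __post_init__(self) -> None:
        if self.t0_min <= 0:
            raise ValueError("t0 must be > 0")
        if self.huff_variant not in HUFF_VARIANTS:
            raise ValueError(f"unknown Huff variant {self.huff_variant!r}")


@dataclass
class HuffMatrix:
    """Cell x park selection probabilities; rows with at least one
    reachable park sum to 1, rows with none are all zero."""

    prob: np.ndarray
    cell_ids: list[int]
    park_ids: list[int]


@dataclass
class AccessSurface:
    """Per-park ratios R_j, per-cell accessibility A_i, for one mode."""

    A: np.ndarray
    R: np.ndarray
    D: np.ndarray
    cell_ids: list[int]
    park_ids: list[int]
    mode: str


def gaussian_decay(t, t0: float):
    """Normalized Gaussian time decay on [0, t0].

    g(t) = (e^{-(t/t0)²/2} − e^{-1/2}) / (1 − e^{-1/2}) for t ≤ t0, else 0;
    g(0) = 1, g(t0) = 0, strictly decreasing in between.  Accepts scalars
    or arrays; ``inf`` (unreachable) maps to 0.
    """
    if t0 <= 0:
        raise ValueError("t0 must be > 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr[np.isfinite(t_arr)] < 0):
        raise ValueError("negative travel time")
    e_half = np.exp(-0.5)
    with np.errstate(invalid="ignore"):
        core = np.exp(-0.5 * np.square(np.where(np.isfinite(t_arr), t_arr, t0) / t0))
    g = (core - e_half) / (1.0 - e_half)
    g = np.where(np.isfinite(t_arr) & (t_arr <= t0), g, 0.0)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(g)
    return g


def huff_matrix(
    supplies: Sequence[ParkSupply],
    od: ODTimeMatrix,
    spec: DecaySpec,
) -> HuffMatrix:
    """Huff selection probabilities Prob_ij over parks reachable within t0.

    The weight of park j for cell i follows ``spec.huff_variant``; each
    row is normalized over its reachable parks.  A cell whose reachable
    parks all have zero weight (all S_j = 0) keeps an all-zero row with a
    warning.
    """
    S = np.array([p.Sj for p in supplies], dtype=float)
    t = od.minutes
    G = gaussian_decay(t, spec.t0_min)
    reach = np.isfinite(t) & (t <= spec.t0_min)
    if spec.huff_variant == "gaussian":
        w = S[None, :] * G
    elif spec.huff_variant == "gaussian_over_time":
        w = S[None, :] / np.maximum(np.where(reach, t, 1.0), EPS_MINUTES) * G
    else:  # gaussian_times_time
        w = S[None, :] * np.where(reach, t, 0.0) * G
    w = np.where(reach, w, 0.0)
    rowsum = w.sum(axis=1)
    dead = (rowsum == 0) & reach.any(axis=1)
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} cells have reachable parks but all-zero Huff "
            f"weights; rows left at zero",
            stacklevel=2,
        )
    prob = np.divide(w, rowsum[:, None], out=np.zeros_like(w), where=rowsum[:, None] > 0)
    return HuffMatrix(prob=prob, cell_ids=list(od.cell_ids), park_ids=list(od.park_ids))


def supply_demand_ratios(
    supplies: Sequence[ParkSupply],
    populations: Sequence[float],
    huff: HuffMatrix,
    od: ODTimeMatrix,
    spec: DecaySpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Step 1: per-park ratios R_j = S_j / D_j with weighted demand
    D_j = Σ_i Prob_ij·P_i·G(t_ij, t0); parks with no demand get R_j = 0.

    Returns ``(R, D)``.
    """
    P = np.asarray(populations, dtype=float)
    if (P < 0).any():
        raise ValueError("negative population")
    S = np.array([p.Sj for p in supplies], dtype=float)
    G = gaussian_decay(od.minutes, spec.t0_min)
    D = (huff.prob * P[:, None] * G).sum(axis=0)
    R = np.divide(S, D, out=np.zeros_like(S), where=D > 0)
    return R, D


def accessibility_scores(
    huff: HuffMatrix,
    R: np.ndarray,
    od: ODTimeMatrix,
    spec: DecaySpec,
) -> np.ndarray:
    """Step 2: A_i = Σ_j Prob_ij·R_j·G(t_ij, t0) over reachable parks."""
    G = gaussian_decay(od.minutes, spec.t0_min)
    return (huff.prob * R[None, :] * G).sum(axis=1)


def compute_access(
    supplies: Sequence[ParkSupply],
    populations: Sequence[float],
    od: ODTimeMatrix,
    spec: DecaySpec,
) -> AccessSurface:
    """Run both 2SFCA steps and return the full access surface."""
    huff = huff_matrix(supplies, od, spec)
    R, D = supply_demand_ratios(supplies, populations, huff, od, spec)
    A = accessibility_scores(huff, R, od, spec)
    return AccessSurface(A=A, R=R, D=D, cell_ids=list(od.cell_ids),
                         park_ids=list(od.park_ids), mode=od.mode)


def zone_summary(
    A: Sequence[float],
    populations: Sequence[float],
    zones: Sequence[str | None],
) -> pd.DataFrame:
    """Zonal accessibility statistics over populated cells.

    For each zone (and an ``overall`` row): min, max, mean, SD
    (population-unweighted) of A_i over cells with P_i > 0, plus the
    underserved share — the percentage of populated cells with A_i = 0.
    Empty zones yield an all-NA row with a warning.
    """
    df = pd.DataFrame({
        "A": np.asarray(A, dtype=float),
        "P": np.asarray(populations, dtype=float),
        "zone": list(zones),
    })
    pop = df[df["P"] > 0]
    rows = []
    zone_labels = sorted({z for z in df["zone"] if z is not None})
    for label in zone_labels + ["overall"]:
        sub = pop if label == "overall" else pop[pop["zone"] == label]
        if sub.empty:
            warnings.warn(f"zone {label!r}: no populated cells", stacklevel=2)
            rows.append({"zone": label, "min": np.nan, "max": np.nan,
                         "mean": np.nan, "sd": np.nan, "underserved_pct": np.nan,
                         "n_cells": 0})
            continue
        a = sub["A"].to_numpy()
        rows.append({
            "zone": label,
            "min": float(a.min()),
            "max": float(a.max()),
            "mean": float(a.mean()),
            "sd": float(a.std(ddof=0)),
            "underserved_pct": float(100.0 * (a == 0).mean()),
            "n_cells": int(len(a)),
        })
    return pd.DataFrame(rows)
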