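"""Equality index, Lorenz/Gini equity measures, and LISA clustering.

The equality index rescales cell accessibility so its maximum equals the
maximum park supply-demand ratio,

    E_i = a_i · max_j(R_j) / max_i(a_i),

and bins it into six supply classes.  Inequality across the whole city is
quantified by the Lorenz curve of cumulative park-resource share against
cumulative population share and its Gini coefficient (trapezoid rule).
Spatial clustering of the equality score uses the Anselin local Moran's I
with conditional-permutation significance on lattice contiguity weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse

# Table of the six equality classes: (class, upper-exclusive rule handled in
# code, supply status, spatial equality label).
EQUALITY_CLASSES = {
    "I": ("No supply", "Serious inequality"),
    "II": ("Very weak", "Serious inequality"),
    "III": ("Weak", "Relative inequality"),
    "IV": ("Good", "Equality"),
    "V": ("Very good", "Relative equality"),
    "VI": ("Oversupply", "Serious inequality"),
}

GINI_BANDS = (
    (0.2, "Absolute equality"),
    (0.3, "Equality"),
    (0.4, "Relatively equality"),
    (0.5, "Low inequality"),
    (math.inf, "High inequality"),
)


def equality_index(A: Sequence[float], R: Sequence[float]) -> np.ndarray:
    """E_i = a_i · max(R_j) / max(a_i); all zero if max(a_i) = 0."""
    a = np.asarray(A, dtype=float)
    r = np.asarray(R, dtype=float)
    max_a = a.max() if a.size else 0.0
    max_r = r.max() if r.size else 0.0
    if max_a == 0:
        return np.zeros_like(a)
    return a * (max_r / max_a)


def classify_equality(ei: float) -> tuple[str, str, str]:
    """Map an equality-index value to (class, supply status, equality label).

    Classes: E=0 → I; 0<E<0.25 → II; 0.25≤E<0.5 → III; 0.5≤E<0.75 → IV;
    0.75≤E≤1 → V; E>1 → VI (oversupply).
    """
    if ei < 0 or not math.isfinite(ei):
        raise ValueError(f"equality index must be finite and >= 0, got {ei}")
    if ei == 0:
        cls = "I"
    elif ei < 0.25:
        cls = "II"
    elif ei < 0.5:
        cls = "III"
    elif ei < 0.75:
        cls = "IV"
    elif ei <= 1.0:
        cls = "V"
    else:
        cls = "VI"
    status, label = EQUALITY_CLASSES[cls]
    return cls, status, label


# ---------------------------------------------------------------------------
# Lorenz curve and Gini coefficient
# ---------------------------------------------------------------------------

@dataclass
class LorenzGini:
    """Lorenz points (cumulative population share P, resource share Q),
    Gini coefficient, and its equity band."""

    P: np.ndarray
    Q: np.ndarray
    gini: float
    band: str


def lorenz_gini(
    populations: Sequence[float],
    resources: Sequence[float],
    literal_formula: bool = False,
) -> LorenzGini:
    """Lorenz curve and Gini of resource distribution across units.

    Units are sorted ascending by resource per capita; the Gini is the
    trapezoid rule G = 1 − Σ (P_k − P_{k−1})(Q_k + Q_{k−1}), zero for a
    perfectly even per-capita allocation.  ``literal_formula`` switches to
    the rectangle form 1 − Σ ΔP·ΔQ (debugging only; it does not vanish on
    a uniform allocation).
    """
    P = np.asarray(populations, dtype=float)
    X = np.asarray(resources, dtype=float)
    if P.sum() <= 0:
        raise ValueError("total population must be > 0")
    if (X < 0).any():
        raise ValueError("resources must be >= 0")
    if X.sum() == 0:
        raise ValueError("total resource is zero; Gini undefined")
    keep = P > 0
    P, X = P[keep], X[keep]
    percap = X / P
    order = np.argsort(percap, kind="stable")
    P, X = P[order], X[order]
    cumP = np.concatenate([[0.0], np.cumsum(P) / P.sum()])
    cumQ = np.concatenate([[0.0], np.cumsum(X) / X.sum()])
    dP = np.diff(cumP)
    if literal_formula:
        g = 1.0 - float(np.sum(dP * np.diff(cumQ)))
    else:
        g = 1.0 - float(np.sum(dP * (cumQ[1:] + cumQ[:-1])))
    g = max(g, 0.0)
    return LorenzGini(P=cumP, Q=cumQ, gini=g, band=classify_gini(min(g, 1.0)))


def gini_pairwise(populations: Sequence[float], resources: Sequence[float]) -> float:
    """O(n²) mean-absolute-difference Gini for equal-population units
    (independent cross-check of the trapezoid form)."""
    P = np.asarray(populations, dtype=float)
    X = np.asarray(resources, dtype=float)
    x = X / P
    n = len(x)
    mad = np.abs(x[:, None] - x[None, :]).sum() / (n * n)
    return float(mad / (2.0 * x.mean()))


def classify_gini(g: float) -> str:
    """Gini band: <0.2 absolute equality; 0.2–0.3 equality; 0.3–0.4
    relatively equality; 0.4–0.5 low inequality; >0.5 high inequality.
    Boundary values join the lower-Gini band."""
    if not (0.0 <= g <= 1.0):
        raise ValueError(f"Gini must lie in [0, 1], got {g}")
    for upper, label in GINI_BANDS:
        if g <= upper:
            return label
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Spatial weights and local Moran's I
# ---------------------------------------------------------------------------

def build_weights(
    rows: Sequence[int],
    cols: Sequence[int],
    scheme: str = "queen",
    distance_band: float | None = None,
    coords: Sequence[tuple[float, float]] | None = None,
) -> sparse.csr_matrix:
    """Row-standardized contiguity weights on a lattice grid.

    ``queen`` links the 8 surrounding cells, ``rook`` the 4 edge
    neighbours; ``distance_band`` links cells whose coordinates lie within
    the given distance.  Isolated cells keep empty rows.
    """
    n = len(rows)
    idx = {(r, c): i for i, (r, c) in enumerate(zip(rows, cols))}
    data, ii, jj = [], [], []
    if scheme in ("queen", "rook"):
        if scheme == "queen":
            offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                       (0, 1), (1, -1), (1, 0), (1, 1)]
        else:
            offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        for i, (r, c) in enumerate(zip(rows, cols)):
            for dr, dc in offsets:
                j = idx.get((r + dr, c + dc))
                if j is not None:
                    ii.append(i)
                    jj.append(j)
                    data.append(1.0)
    elif scheme == "distance_band":
        if distance_band is None or coords is None:
            raise ValueError("distance_band scheme needs a band and coordinates")
        from scipy.spatial import cKDTree

        tree = cKDTree(np.asarray(coords, dtype=float))
        pairs = tree.query_pairs(distance_band)
        for i, j in pairs:
            ii.extend([i, j])
            jj.extend([j, i])
            data.extend([1.0, 1.0])
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    W = sparse.csr_matrix((data, (ii, jj)), shape=(n, n))
    rowsum = np.asarray(W.sum(axis=1)).ravel()
    inv = np.divide(1.0, rowsum, out=np.zeros_like(rowsum), where=rowsum > 0)
    return sparse.diags(inv) @ W


@dataclass
class LISAResult:
    """Local Moran statistics: I_i, pseudo p-value, and cluster label
    (HH/HL/LH/LL when significant, otherwise not-significant)."""

    I: np.ndarray
    p_sim: np.ndarray
    labels: list[str]
    quadrant: list[str]


def local_moran(
    values: Sequence[float],
    W: sparse.csr_matrix,
    permutations: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> LISAResult:
    """Anselin local Moran's I with conditional-permutation inference.

    I_i = (x_i − x̄)/m₂ · Σ_j w_ij (x_j − x̄), m₂ = Σ_k (x_k − x̄)²/n.
    For each unit, neighbour values are redrawn ``permutations`` times from
    the remaining units (holding x_i fixed); the pseudo p-value is the
    one-sided share of simulated statistics at least as extreme as the
    observed one, on the observed side.  Labels combine significance
    (p ≤ alpha) with the quadrant of (x_i − x̄, spatial lag − x̄).

    Raises on a constant field (zero variance).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    z = x - x.mean()
    m2 = float((z ** 2).sum() / n)
    if m2 == 0:
        raise ValueError("constant field: zero variance, local Moran undefined")
    Wd = W.tocsr()
    lag = Wd @ z
    I_obs = z / m2 * lag

    rng = np.random.default_rng(seed)
    card = np.diff(Wd.indptr)  # neighbours per unit (row-standardized rows)
    kmax = int(card.max()) if n else 0
    # one shared block of without-replacement draws from the n-1 "others",
    # reused across units (standard conditional-randomization shortcut)
    rids = np.empty((permutations, kmax), dtype=np.int64)
    for p in range(permutations):
        rids[p] = rng.permutation(n - 1)[:kmax]

    p_sim = np.ones(n)
    others_idx = np.arange(n)
    for i in range(n):
        k = int(card[i])
        if k == 0:
            continue
        others = z[others_idx != i]
        sims_lag = others[rids[:, :k]].mean(axis=1)  # row-standardized lag
        sims = z[i] / m2 * sims_lag
        if I_obs[i] >= 0:
            larger = int(np.sum(sims >= I_obs[i]))
        else:
            larger = int(np.sum(sims <= I_obs[i]))
        p_sim[i] = (larger + 1.0) / (permutations + 1.0)

    labels, quadrant = [], []
    for i in range(n):
        hi_i, hi_lag = z[i] >= 0, lag[i] >= 0
        quad = ("HH" if hi_lag else "HL") if hi_i else ("LH" if hi_lag else "LL")
        quadrant.append(quad)
        sig = card[i] > 0 and p_sim[i] <= alpha
        labels.append(quad if sig else "not-significant")
    return LISAResult(I=I_obs, p_sim=p_sim, labels=labels, quadrant=quadrant)


def local_moran_bruteforce(values: Sequence[float], W: sparse.csr_matrix) -> np.ndarray:
    """Double-loop reference implementation of the local Moran statistic."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    xbar = x.mean()
    m2 = sum((x[k] - xbar) ** 2 for k in range(n)) / n
    Wd = W.toarray()
    out = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(n):
            s += Wd[i, j] * (x[j] - xbar)
        out[i] = (x[i] - xbar) / m2 * s
    return out
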