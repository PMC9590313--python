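"""Composite park attractiveness from area, green view, and service mix.

Each park j gets three raw component scores — its area S_ja (m²), the mean
street green-view index S_jg within its network service area, and the
Shannon-Wiener diversity S_jd of service-function POIs in that area.  Each
component is divided by its maximum over all parks and the composite
attractiveness is the weighted sum

    S_j = γ_A·S_ja/max(S_ja) + γ_G·S_jg/max(S_jg) + γ_D·S_jd/max(S_jd),

with γ_A + γ_G + γ_D = 1 (equal thirds by default).  S_j is dimensionless
in [0, 1]; a component whose maximum is zero contributes zero everywhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .city_model import GreenViewSample, POIRecord, Park, POI_CATEGORIES
from .network_travel import ServiceArea


@dataclass
class ParkSupply:
    """Per-park component scores and composite attractiveness."""

    park_id: int
    Sja: float = 0.0   # raw area, m²
    Sjg: float = 0.0   # mean green-view index in service area, [0, 1]
    Sjd: float = 0.0   # Shannon diversity of service functions, nats
    Sj: float = 0.0    # composite attractiveness, [0, 1]
    Sja_norm: float = 0.0
    Sjg_norm: float = 0.0
    Sjd_norm: float = 0.0


def shannon_diversity(category_counts: Sequence[int], base: float = math.e) -> float:
    """Shannon-Wiener index H = −Σ p_c log p_c over categories with
    positive counts; an empty neighbourhood scores 0."""
    counts = np.asarray(category_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative category count")
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base != math.e:
        h /= math.log(base)
    return h


def park_service_diversity(
    park: Park,
    pois: Sequence[POIRecord],
    service_area: ServiceArea,
) -> float:
    """Shannon diversity of the 13 POI service-function categories falling
    inside the park's network service area."""
    counts = {c: 0 for c in POI_CATEGORIES}
    for poi in pois:
        if service_area.contains(poi.location):
            counts[poi.category] += 1
    return shannon_diversity([counts[c] for c in POI_CATEGORIES])


def park_green_view(
    park: Park,
    samples: Sequence[GreenViewSample],
    service_area: ServiceArea,
) -> float:
    """Mean green-view index (4-heading average per sample point) over the
    samples inside the park's service area; 0 with a warning if none."""
    inside = [s.green_view_index for s in samples if service_area.contains(s.location)]
    if not inside:
        warnings.warn(
            f"park {park.park_id}: no green-view sample in service area; Sjg = 0",
            stacklevel=2,
        )
        return 0.0
    return float(np.mean(inside))


def composite_attractiveness(
    parks: Sequence[ParkSupply],
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> list[ParkSupply]:
    """Max-normalize each component across parks and combine with weights
    (γ_A, γ_G, γ_D); fills the ``*_norm`` and ``Sj`` fields in place."""
    if not parks:
        raise ValueError("need at least one park")
    ga, gg, gd = weights
    if abs(ga + gg + gd - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {ga + gg + gd}")
    max_a = max(p.Sja for p in parks)
    max_g = max(p.Sjg for p in parks)
    max_d = max(p.Sjd for p in parks)
    for p in parks:
        p.Sja_norm = p.Sja / max_a if max_a > 0 else 0.0
        p.Sjg_norm = p.Sjg / max_g if max_g > 0 else 0.0
        p.Sjd_norm = p.Sjd / max_d if max_d > 0 else 0.0
        p.Sj = ga * p.Sja_norm + gg * p.Sjg_norm + gd * p.Sjd_norm
    return list(parks)


def score_parks(
    parks: Sequence[Park],
    pois: Sequence[POIRecord],
    greenview: Sequence[GreenViewSample],
    service_areas: Sequence[ServiceArea],
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> list[ParkSupply]:
    """Convenience wrapper: raw components then composite attractiveness."""
    supplies = []
    for park, sa in zip(parks, service_areas):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sjg = park_green_view(park, greenview, sa)
        supplies.append(
            ParkSupply(
                park_id=park.park_id,
                Sja=park.area_m2,
                Sjg=sjg,
                Sjd=park_service_diversity(park, pois, sa),
            )
        )
    return composite_attractiveness(supplies, weights)
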