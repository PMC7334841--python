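"""Effective population size from diversity, and isolation by distance.

Ne comes from the neutral-equilibrium identity pi = 4 Ne mu; confidence
bounds on the mutation rate propagate inversely (a high rate implies a low
Ne).  Isolation by distance regresses linearised differentiation
F_ST / (1 - F_ST) on great-circle distance (km) between population
locations, each location being the spherical midpoint of its members'
coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import PopulationMap, ValidationError

logger = logging.getLogger("campina")

#: Mean Earth radius, km (IUGG).
EARTH_RADIUS_KM = 6371.0088


@dataclass
class NeEstimate:
    pi: float
    mu: float
    ne: float
    mu_ci: tuple[float, float] | None = None
    ne_ci: tuple[float, float] | None = None


@dataclass(frozen=True)
class GeoPoint:
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"longitude {self.longitude} out of range")


@dataclass
class IbdResult:
    pairs: pd.DataFrame  # popA, popB, distance_km, fst, linearized_fst
    slope: float
    intercept: float
    r_squared: float


def ne_from_pi(
    pi: float, mu: float, mu_ci: tuple[float, float] | None = None
) -> NeEstimate:
    """Ne = pi / (4 mu); CI bounds from the mutation-rate CI (inverted order)."""
    if mu <= 0:
        raise ValidationError("mutation rate must be positive")
    if pi < 0:
        raise ValidationError("pi must be non-negative")
    ne = pi / (4.0 * mu)
    ne_ci = None
    if mu_ci is not None:
        mu_lo, mu_hi = mu_ci
        if not 0 < mu_lo <= mu_hi:
            raise ValidationError("mutation-rate CI must satisfy 0 < low <= high")
        ne_ci = (pi / (4.0 * mu_hi), pi / (4.0 * mu_lo))
    return NeEstimate(pi=pi, mu=mu, ne=ne, mu_ci=mu_ci, ne_ci=ne_ci)


def geodesic_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle (haversine) distance in km on a sphere of mean Earth radius."""
    la1, lo1, la2, lo2 = map(
        np.radians, (a.latitude, a.longitude, b.latitude, b.longitude)
    )
    h = (
        np.sin((la2 - la1) / 2.0) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2.0) ** 2
    )
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def geographic_midpoint(points: list[GeoPoint]) -> GeoPoint:
    """Spherical midpoint: average of unit 3-vectors, renormalised."""
    if not points:
        raise ValidationError("midpoint of an empty point set")
    vs = []
    for p in points:
        la, lo = np.radians(p.latitude), np.radians(p.longitude)
        vs.append(
            np.array([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)])
        )
    v = np.mean(vs, axis=0)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValidationError("points average to the sphere's centre; midpoint undefined")
    v /= norm
    lat = float(np.degrees(np.arcsin(np.clip(v[2], -1.0, 1.0))))
    lon = float(np.degrees(np.arctan2(v[1], v[0])))
    return GeoPoint(lat, lon)


def population_location(population: str, popmap: PopulationMap) -> GeoPoint:
    """Spherical midpoint of a population's member coordinates."""
    pts = [
        GeoPoint(*popmap.coordinates[s])
        for s in popmap.samples_in(population)
        if s in popmap.coordinates
    ]
    if not pts:
        raise LookupError(f"population {population!r} has no coordinates")
    return geographic_midpoint(pts)


def ibd_regression(
    fst_pairs: list[tuple[str, str, float]],
    popmap: PopulationMap,
) -> IbdResult:
    """OLS of linearised F_ST on pairwise great-circle distance.

    Negative F_ST values are clamped to 0; pairs at F_ST = 1 are excluded
    (infinite linearised value) with a warning.
    """
    rows = []
    for popA, popB, fst in fst_pairs:
        if not np.isfinite(fst):
            continue
        fst = max(fst, 0.0)
        if fst >= 1.0 - 1e-9:
            logger.warning("ibd_regression: dropping pair %s-%s at F_ST ~ 1", popA, popB)
            continue
        dist = geodesic_distance(
            population_location(popA, popmap), population_location(popB, popmap)
        )
        rows.append(
            {
                "popA": popA,
                "popB": popB,
                "distance_km": dist,
                "fst": fst,
                "linearized_fst": fst / (1.0 - fst),
            }
        )
    if len(rows) < 3:
        raise ValidationError("isolation-by-distance regression needs >= 3 usable pairs")
    df = pd.DataFrame(rows)
    x = df["distance_km"].to_numpy()
    y = df["linearized_fst"].to_numpy()
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise ValidationError("all pairwise distances identical; slope undefined")
    slope = float(np.sum((x - xm) * (y - ym))) / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    syy = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / syy if syy > 0 else 1.0
    return IbdResult(pairs=df, slope=slope, intercept=float(intercept), r_squared=r2)


def slope_ratio(result_a: IbdResult, result_b: IbdResult) -> float:
    """Ratio of isolation-by-distance slopes (species A relative to B)."""
    if result_b.slope == 0:
        raise ValidationError("reference slope is zero")
    return result_a.slope / result_b.slope
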