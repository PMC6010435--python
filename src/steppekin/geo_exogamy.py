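"""Spousal dispersal: couple distances, the density-based exogamy threshold,
exogamy rates and distance classes.

Distances are great-circle (haversine, R = 6371.0088 km) between recorded
birthplaces. The exogamy limit is found as the antimode (local minimum) of a
Gaussian kernel density of log10 distances, estimated per population and
averaged across populations; the study-style default bandwidth is 0.2 on the
log10 scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import SurveyRecord

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

#: floor substituted for 0-km couples on the log scale (density estimation
#: only; rates and counts always use the true distances)
ZERO_DISTANCE_FLOOR_KM = 0.1

KDE_GRID = np.linspace(math.log10(ZERO_DISTANCE_FLOOR_KM), math.log10(2000.0), 512)

DISTANCE_CLASSES = ["<4", "4-20", "20-40", ">40"]


def haversine_km(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    la1, lo1 = map(math.radians, p1)
    la2, lo2 = map(math.radians, p2)
    dlat, dlon = la2 - la1, lo2 - lo1
    h = math.sin(dlat / 2) ** 2 + math.cos(la1) * math.cos(la2) * math.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


@dataclass
class CoupleDistance:
    couple_id: str
    population: str
    group: str
    generation: str  # "current" | "parental"
    distance_km: float


@dataclass
class ExogamyProfile:
    population: str
    threshold_km: float
    n_couples: int
    exogamy_rate: float
    median_exogamous_km: float
    kde: Optional[tuple[np.ndarray, np.ndarray]] = None
    distance_classes: dict[str, str] = field(default_factory=dict)


def couple_distances(
    survey: Sequence[SurveyRecord], generation: str = "current"
) -> list[CoupleDistance]:
    """One distance record per couple.

    ``current``: birthplace distance between spouses (deduplicated across the
    two spouses' survey rows). ``parental``: distance between an individual's
    father's and mother's birthplaces (one "parental couple" per respondent).
    Couples with a missing birthplace are skipped and counted in the log.
    """
    out: list[CoupleDistance] = []
    skipped = 0
    if generation == "current":
        by_id = {r.individual_id: r for r in survey}
        seen: set[frozenset] = set()
        for r in survey:
            if r.spouse_id is None or r.spouse_id not in by_id:
                continue
            key = frozenset((r.individual_id, r.spouse_id))
            if key in seen:
                continue
            seen.add(key)
            sp = by_id[r.spouse_id]
            if r.birthplace is None or sp.birthplace is None:
                skipped += 1
                continue
            out.append(
                CoupleDistance(
                    couple_id="|".join(sorted(key)),
                    population=r.population,
                    group=r.group,
                    generation="current",
                    distance_km=haversine_km(r.birthplace, sp.birthplace),
                )
            )
    elif generation == "parental":
        for r in survey:
            if r.father_birthplace is None or r.mother_birthplace is None:
                skipped += 1
                continue
            out.append(
                CoupleDistance(
                    couple_id=f"parents:{r.individual_id}",
                    population=r.population,
                    group=r.group,
                    generation="parental",
                    distance_km=haversine_km(r.father_birthplace, r.mother_birthplace),
                )
            )
    else:
        raise ValueError("generation must be 'current' or 'parental'")
    if skipped:
        logger.info("couple_distances(%s): skipped %d couples with missing birthplaces",
                    generation, skipped)
    return out


def kde_log_distance(
    distances_km: Sequence[float], bandwidth: float = 0.2,
    grid: np.ndarray = KDE_GRID,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE of log10 distance with a fixed (absolute) bandwidth.

    ``bandwidth`` is the kernel SD on the log10 scale (R's ``bw`` semantics).
    Zero distances are floored at 0.1 km so the endogamous mode stays visible
    on the log axis. Returns ``(grid, density)`` with the density normalised
    to integrate to 1 over the grid.
    """
    d = np.asarray(distances_km, dtype=float)
    if np.all(d <= 0):
        raise ValueError("no exogamous component: all distances are zero")
    if (d > 0).sum() < 2:
        raise ValueError("need at least 2 nonzero distances for a density")
    x = np.log10(np.maximum(d, ZERO_DISTANCE_FLOOR_KM))
    z = (grid[:, None] - x[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (len(x) * bandwidth * math.sqrt(2 * math.pi))
    area = np.trapezoid(dens, grid)
    return grid, dens / area


def _local_extrema(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict-neighbourhood local maxima and minima of a gridded curve."""
    maxima = [i for i in range(1, len(y) - 1) if y[i] >= y[i - 1] and y[i] > y[i + 1]]
    minima = [i for i in range(1, len(y) - 1) if y[i] <= y[i - 1] and y[i] < y[i + 1]]
    return np.array(maxima, dtype=int), np.array(minima, dtype=int)


def find_exogamy_threshold(
    densities: Sequence[tuple[np.ndarray, np.ndarray]]
) -> float:
    """Cross-population average of per-population KDE antimodes, in km.

    Per population, the antimode is the lowest local minimum strictly between
    the two highest local maxima of the log10-distance density. Unimodal
    densities are excluded from the average with a warning; if every density
    is unimodal a ValueError is raised.
    """
    antimodes_km: list[float] = []
    for grid, dens in densities:
        maxima, minima = _local_extrema(np.asarray(dens))
        if len(maxima) < 2:
            logger.warning("find_exogamy_threshold: unimodal density excluded")
            continue
        top2 = maxima[np.argsort(dens[maxima])[-2:]]
        lo, hi = sorted(top2)
        cand = minima[(minima > lo) & (minima < hi)]
        if len(cand) == 0:
            logger.warning("find_exogamy_threshold: no antimode between modes")
            continue
        best = cand[np.argmin(dens[cand])]
        antimodes_km.append(10.0 ** grid[best])
    if not antimodes_km:
        raise ValueError("no bimodal density: cannot locate an exogamy threshold")
    return float(np.mean(antimodes_km))


def exogamy_rate(
    distances: Sequence[CoupleDistance],
    threshold_km: float,
    bandwidth: float = 0.2,
) -> dict[str, ExogamyProfile]:
    """Per-population exogamy profiles at a threshold.

    A couple is exogamous when its distance strictly exceeds the threshold
    (a couple *at* the limit counts as endogamous). Also reports the median
    distance restricted to exogamous couples.
    """
    if threshold_km <= 0:
        raise ValueError("threshold must be positive")
    out: dict[str, ExogamyProfile] = {}
    by_pop: dict[str, list[CoupleDistance]] = {}
    for cd in distances:
        by_pop.setdefault(cd.population, []).append(cd)
    for pop, cds in by_pop.items():
        d = np.array([c.distance_km for c in cds])
        exo = d > threshold_km
        try:
            kde = kde_log_distance(d, bandwidth=bandwidth)
        except ValueError:
            kde = None
        out[pop] = ExogamyProfile(
            population=pop,
            threshold_km=threshold_km,
            n_couples=len(d),
            exogamy_rate=float(exo.mean()) if len(d) else 0.0,
            median_exogamous_km=float(np.median(d[exo])) if exo.any() else math.nan,
            kde=kde,
            distance_classes={c.couple_id: distance_class(c.distance_km) for c in cds},
        )
    return out


def distance_class(distance_km: float) -> str:
    """Four-way distance class with boundaries closed on the left class:
    <=4 -> "<4"; (4, 20] -> "4-20"; (20, 40] -> "20-40"; >40 -> ">40"."""
    if distance_km < 0:
        raise ValueError("distance must be >= 0")
    if distance_km <= 4.0:
        return "<4"
    if distance_km <= 20.0:
        return "4-20"
    if distance_km <= 40.0:
        return "20-40"
    return ">40"
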