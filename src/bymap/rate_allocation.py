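"""Allocation of facility-level consultation counts to areas.

Each health service gets a spatial zone (home area plus a graph
neighborhood whose radius depends on service complexity, or the whole
city for high-complexity services). Zone weights are population
proportional; a service's consultations are multiplied by the weights
to yield fractional per-area cases, conserving the total exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point

COMPLEXITY_TIERS = ("primary", "intermediate", "high")

#: graph-distance radius of a zone per tier; None = whole city
DEFAULT_ZONE_RADII = {"primary": 1, "intermediate": 2, "high": None}


@dataclass
class ServiceRecord:
    service_id: str
    location: Point
    complexity: str
    consultations: int = 0
    migrant_exclusive: bool = False

    def __post_init__(self):
        if self.complexity not in COMPLEXITY_TIERS:
            raise ValueError(
                f"service {self.service_id!r}: complexity must be one of "
                f"{COMPLEXITY_TIERS}, got {self.complexity!r}"
            )
        if self.consultations < 0:
            raise ValueError(
                f"service {self.service_id!r}: negative consultations"
            )


@dataclass
class ServiceZone:
    """Population-proportional weights over the areas a service covers."""

    service_id: str
    complexity: str
    member_indices: np.ndarray  # area positions, ascending
    weights: np.ndarray  # aligned with member_indices, sums to 1
    home_index: int = field(default=-1)

    def __post_init__(self):
        self.member_indices = np.asarray(self.member_indices, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.member_indices.size != self.weights.size:
            raise ValueError("weights misaligned with member areas")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("zone weights must sum to 1")

    def member_areas(self, lattice) -> set[str]:
        return {lattice.area_ids[i] for i in self.member_indices}


def locate_service(service: ServiceRecord, lattice) -> int:
    """Index of the area containing the service location.

    A location on a shared boundary goes to the covering area with the
    lexicographically smallest area_id (ids are stored sorted, so the
    first cover wins).
    """
    for i, poly in enumerate(lattice.polygons):
        if poly.covers(service.location):
            return i
    raise ValueError(
        f"service {service.service_id!r} lies outside all areas"
    )


def graph_ball(lattice, center: int, radius: int) -> np.ndarray:
    """Indices within graph distance ``radius`` of ``center`` (BFS)."""
    seen = {center}
    frontier = {center}
    for _ in range(radius):
        nxt = set()
        for i in frontier:
            nxt.update(lattice.neighbors(i).tolist())
        frontier = nxt - seen
        seen |= frontier
    return np.array(sorted(seen), dtype=int)


def build_service_zones(services, lattice, populations,
                        radii: dict | None = None) -> list[ServiceZone]:
    """One zone per service: graph ball of tier-dependent radius around
    the home area (whole city when the radius is None), with population
    proportional weights."""
    radii = dict(DEFAULT_ZONE_RADII if radii is None else radii)
    pops = np.asarray(populations, dtype=float)
    if pops.shape != (lattice.n,):
        raise ValueError("populations misaligned with lattice")
    zones = []
    for s in services:
        home = locate_service(s, lattice)
        r = radii[s.complexity]
        members = (np.arange(lattice.n) if r is None
                   else graph_ball(lattice, home, int(r)))
        w = pops[members]
        zones.append(ServiceZone(s.service_id, s.complexity, members,
                                 w / w.sum(), home_index=home))
    return zones


def allocate_cases(services, zones, n_areas: int) -> np.ndarray:
    """Per-area fractional cases: cases_j = sum_i consultations_i * w_ij.

    The total allocated equals the total consultations exactly (up to
    float accumulation)."""
    by_id = {z.service_id: z for z in zones}
    cases = np.zeros(n_areas)
    for s in services:
        if s.consultations < 0:
            raise ValueError(f"negative consultations for {s.service_id!r}")
        z = by_id.get(s.service_id)
        if z is None:
            raise ValueError(f"no zone for service {s.service_id!r}")
        cases[z.member_indices] += s.consultations * z.weights
    return cases


def build_area_table(lattice, populations, services, zones,
                     covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Area table with population, allocated cases (all services and the
    migrant-exclusive subset) and per-100 rates. Migrant-exclusive
    services contribute to both ``cases`` and ``migrant_cases``."""
    pops = np.asarray(populations)
    cases = allocate_cases(services, zones, lattice.n)
    migrant = [s for s in services if s.migrant_exclusive]
    migrant_cases = allocate_cases(migrant, zones, lattice.n)
    table = pd.DataFrame(
        {
            "population": pops,
            "cases": cases,
            "migrant_cases": migrant_cases,
        },
        index=pd.Index(lattice.area_ids, name="area_id"),
    )
    if covariates is not None:
        table = table.join(covariates)
    return compute_rates(table)


def compute_rates(area_table: pd.DataFrame) -> pd.DataFrame:
    """Add/refresh per-100-person rate columns.

    rate = 100 * cases / population; migrant_rate uses the total area
    population as denominator (no migrant-specific denominator exists).
    """
    table = area_table.copy()
    pops = table["population"].to_numpy(dtype=float)
    if np.any(pops <= 0):
        bad = table.index[pops <= 0][0]
        raise ValueError(f"non-positive population for area {bad!r}")
    table["rate"] = 100.0 * table["cases"] / pops
    if "migrant_cases" in table:
        table["migrant_rate"] = 100.0 * table["migrant_cases"] / pops
    return table


def round_counts(cases: np.ndarray) -> np.ndarray:
    """Fractional allocated cases -> integer counts for the Poisson
    likelihood, rounding half to even (numpy's default)."""
    return np.rint(np.asarray(cases, dtype=float)).astype(np.int64)


def read_services_csv(path) -> list[ServiceRecord]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        out.append(ServiceRecord(
            service_id=str(row.service_id),
            location=Point(float(row.x), float(row.y)),
            complexity=str(row.complexity),
            consultations=int(row.consultations),
            migrant_exclusive=str(row.migrant_exclusive).lower()
            in ("true", "1", "yes"),
        ))
    return out
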