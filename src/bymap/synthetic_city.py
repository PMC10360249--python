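"""Synthetic city generator with recoverable ground truth.

Produces a Voronoi lattice, heterogeneous populations, spatially
autocorrelated covariates, pollutant stations, tiered health services
and facility-level consultation counts generated under the same
Poisson model (unstructured + ICAR random effects) that the inference
stage fits, so every downstream stage can be validated against known
parameters.

All randomness flows from one global integer seed; each stage uses a
child generator derived from it by a fixed offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely import MultiPoint, voronoi_polygons
from shapely.geometry import Point, box

from bymap.spatial_lattice import AreaLattice, build_adjacency
from bymap.rate_allocation import ServiceRecord

# fixed per-stage seed offsets (single-knob reproducibility)
_STAGE_OFFSET = {
    "lattice": 11,
    "population": 23,
    "covariates": 37,
    "icar": 53,
    "unstructured": 67,
    "counts": 83,
    "services": 97,
    "scatter": 113,
}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STAGE_OFFSET[stage], seed])


#: Table-1-like affine target ranges (lo, hi) per default covariate
DEFAULT_COVARIATE_RANGES = {
    "migrant_rate": (0.0, 12.0),
    "pop_under15": (10.0, 30.0),
    "imp": (0.0, 86.0),
    "pea": (35.0, 70.0),
    "pop_over65": (2.0, 25.0),
}

#: default ground-truth relative risks per unit of covariate
DEFAULT_EXP_BETA = {
    "migrant_rate": 1.25,
    "pop_under15": 1.08,
    "imp": 1.04,
    "pea": 1.0,
    "pop_over65": 1.0,
}

DEFAULT_CITYWIDE_RATE = 0.25  # cases per person-year


@dataclass
class CityTruth:
    """Generating parameters of a synthetic city (log scale)."""

    alpha: float
    beta: np.ndarray
    covariate_names: list[str]
    tau_u: float
    tau_st: float
    u: np.ndarray
    st: np.ndarray
    expected_rate: np.ndarray = field(default=None)

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.st = np.asarray(self.st, dtype=float)
        if self.tau_u <= 0 or self.tau_st <= 0:
            raise ValueError("precisions must be positive")
        if abs(self.st.sum()) > 1e-10 * max(1.0, np.abs(self.st).max()):
            raise ValueError("structured effects must sum to zero")


@dataclass
class SyntheticCity:
    lattice: AreaLattice
    populations: np.ndarray
    covariates: "pandas.DataFrame"  # noqa: F821 — per-area, named columns
    stations: list[tuple[float, float, float]]  # (x, y, annual mean pm10)
    services: list[ServiceRecord]
    service_consultations: dict[str, int]
    truth: CityTruth
    cases: np.ndarray  # per-area ground-truth counts


def generate_lattice(n_areas: int, bbox=(0.0, 0.0, 10_000.0, 10_000.0),
                     seed: int = 0) -> AreaLattice:
    """Voronoi tessellation of uniform seed points clipped to ``bbox``.

    Deterministic given ``seed``; polygons partition the box exactly.
    """
    if n_areas < 4:
        raise ValueError("need at least 4 areas")
    x0, y0, x1, y1 = map(float, bbox)
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate bbox")
    rng = _stage_rng(seed, "lattice")
    pts = np.column_stack(
        [rng.uniform(x0, x1, n_areas), rng.uniform(y0, y1, n_areas)]
    )
    frame = box(x0, y0, x1, y1)
    cells = voronoi_polygons(MultiPoint(pts), extend_to=frame, ordered=True)
    polys = [cell.intersection(frame) for cell in cells.geoms]
    width = len(str(n_areas - 1))
    ids = [f"A{i:0{width}d}" for i in range(n_areas)]
    return build_adjacency(ids, polys, "queen", warn_islands=False)


def sample_icar(lattice: AreaLattice, tau_st: float, seed: int = 0,
                size: int | None = None,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw from the intrinsic CAR distribution under sum-to-zero.

    Samples via the eigendecomposition of the graph Laplacian, placing
    zero mass on the constant null eigenvector, so every draw sums to
    zero exactly (up to float drift, which is recentred away).

    Returns shape (n,) or (size, n).
    """
    if tau_st <= 0:
        raise ValueError("tau_st must be positive")
    if lattice.components().max() != 0:
        raise ValueError(
            "lattice is disconnected; sample each component separately "
            "with its own constraint"
        )
    if rng is None:
        rng = _stage_rng(seed, "icar")
    m = 1 if size is None else size
    L = lattice.laplacian().toarray()
    evals, evecs = np.linalg.eigh(L)
    pos = evals > 1e-10 * evals.max()
    scale = 1.0 / np.sqrt(tau_st * evals[pos])
    z = rng.standard_normal((m, int(pos.sum())))
    draws = (z * scale) @ evecs[:, pos].T
    draws -= draws.mean(axis=1, keepdims=True)
    return draws[0] if size is None else draws


def sample_icar_anchored(lattice: AreaLattice, tau_st: float, seed: int = 0,
                         size: int | None = None, anchor: int = 0) -> np.ndarray:
    """Proper ICAR draw with area ``anchor`` pinned to exactly zero.

    The joint of the free areas is Normal with precision
    tau_st * L[-anchor, -anchor]; every non-anchor area's full
    conditional is exactly Normal(mean of neighbors, 1/(tau_st * n_nbrs)),
    which makes this form convenient for verifying the conditional law.
    """
    if tau_st <= 0:
        raise ValueError("tau_st must be positive")
    if lattice.components().max() != 0:
        raise ValueError("lattice is disconnected")
    rng = _stage_rng(seed, "icar")
    n = lattice.n
    m = 1 if size is None else size
    keep = [i for i in range(n) if i != anchor]
    L = lattice.laplacian().toarray()
    Q = tau_st * L[np.ix_(keep, keep)]
    chol = np.linalg.cholesky(Q)
    z = rng.standard_normal((n - 1, m))
    rest = np.linalg.solve(chol.T, z)  # cov = Q^{-1}
    draws = np.zeros((m, n))
    draws[:, keep] = rest.T
    return draws[0] if size is None else draws


def sample_populations(n_areas: int, seed: int = 0, median: float = 1500.0,
                       sigma_log: float = 0.5, floor: int = 50) -> np.ndarray:
    """Lognormal area populations, rounded, with a hard floor."""
    rng = _stage_rng(seed, "population")
    pops = np.round(
        np.exp(np.log(median) + sigma_log * rng.standard_normal(n_areas))
    ).astype(int)
    return np.maximum(pops, floor)


def sample_covariates(lattice: AreaLattice, seed: int = 0,
                      ranges: dict | None = None,
                      spatial_weight: float = 0.8):
    """Spatially autocorrelated covariates mapped to plausible ranges.

    Each column is a scaled ICAR draw plus white noise, affinely mapped
    onto its (lo, hi) target range, so every covariate shows positive
    spatial autocorrelation and nonzero variance.
    """
    import pandas as pd

    ranges = dict(DEFAULT_COVARIATE_RANGES if ranges is None else ranges)
    rng = _stage_rng(seed, "covariates")
    n = lattice.n
    cols = {}
    base = sample_icar(lattice, tau_st=0.2, size=len(ranges), rng=rng)
    for k, (name, (lo, hi)) in enumerate(ranges.items()):
        raw = spatial_weight * base[k] / max(base[k].std(), 1e-12)
        raw = raw + (1 - spatial_weight) * rng.standard_normal(n)
        lo_r, hi_r = raw.min(), raw.max()
        cols[name] = lo + (raw - lo_r) * (hi - lo) / (hi_r - lo_r)
    return pd.DataFrame(cols, index=lattice.area_ids)


def sample_stations(bbox=(0.0, 0.0, 10_000.0, 10_000.0), seed: int = 0,
                    n_stations: int = 3, mean_pm10: float = 45.0,
                    sd_pm10: float = 3.0):
    """Pollutant monitoring stations at dispersed, jittered locations."""
    rng = _stage_rng(seed, "covariates")
    x0, y0, x1, y1 = bbox
    anchors = [(0.25, 0.3), (0.7, 0.7), (0.4, 0.85)]
    out = []
    for k in range(n_stations):
        fx, fy = anchors[k % len(anchors)]
        x = x0 + (fx + 0.08 * rng.uniform(-1, 1)) * (x1 - x0)
        y = y0 + (fy + 0.08 * rng.uniform(-1, 1)) * (y1 - y0)
        out.append((float(x), float(y),
                    float(mean_pm10 + sd_pm10 * rng.standard_normal())))
    return out


def make_truth(lattice: AreaLattice, covariates, seed: int = 0,
               exp_beta: dict | None = None, tau_u: float = 60.0,
               tau_st: float = 20.0,
               citywide_rate: float = DEFAULT_CITYWIDE_RATE,
               include_random_effects: bool = True) -> CityTruth:
    """Ground-truth parameters; the intercept is chosen so the citywide
    expected rate is approximately ``citywide_rate`` cases per person."""
    exp_beta = dict(DEFAULT_EXP_BETA if exp_beta is None else exp_beta)
    names = list(covariates.columns)
    beta = np.array([np.log(exp_beta.get(c, 1.0)) for c in names])
    X = covariates.to_numpy(dtype=float)
    if include_random_effects:
        u = (1.0 / np.sqrt(tau_u)) * _stage_rng(seed, "unstructured") \
            .standard_normal(lattice.n)
        st = sample_icar(lattice, tau_st, seed=seed)
    else:
        u = np.zeros(lattice.n)
        st = np.zeros(lattice.n)
    alpha = float(np.log(citywide_rate) - (X @ beta).mean())
    eta = alpha + X @ beta + u + st
    return CityTruth(alpha, beta, names, tau_u, tau_st, u, st,
                     expected_rate=np.exp(eta))


def simulate_counts(truth: CityTruth, populations, covariates,
                    seed: int = 0) -> np.ndarray:
    """Per-area counts: Poisson(pop_i * exp(alpha + X_i beta + u_i + st_i))."""
    pops = np.asarray(populations, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.shape != (pops.size, truth.beta.size):
        raise ValueError("dimension mismatch between covariates and beta")
    eta = truth.alpha + X @ truth.beta + truth.u + truth.st
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    lam = pops * np.exp(eta)
    return _stage_rng(seed, "counts").poisson(lam)


# most ambulatory consultations happen locally: primary services out-pull
# the citywide high-complexity hospitals for the same zone weight
_TIER_ATTRACTION = {"primary": 25.0, "intermediate": 2.0, "high": 1.0}


def simulate_services(lattice: AreaLattice, populations,
                      n_primary: int | None = None,
                      n_intermediate: int | None = None, n_high: int = 2,
                      seed: int = 0, migrant_fraction: float = 0.15
                      ) -> list[ServiceRecord]:
    """Place tiered health services at representative points of random areas.

    At least one high-complexity service is required so that its
    city-wide zone guarantees every area is covered.
    """
    if n_high < 1:
        raise ValueError("need at least one high-complexity service")
    if n_primary is None:
        n_primary = max(4, lattice.n // 4)
    if n_intermediate is None:
        n_intermediate = max(2, lattice.n // 25)
    rng = _stage_rng(seed, "services")
    tiers = (["primary"] * n_primary + ["intermediate"] * n_intermediate
             + ["high"] * n_high)
    hosts = rng.choice(lattice.n, size=len(tiers),
                       replace=len(tiers) > lattice.n)
    services = []
    for k, (tier, host) in enumerate(zip(tiers, hosts)):
        c = lattice.polygons[host].representative_point()
        services.append(ServiceRecord(
            service_id=f"S{k:03d}",
            location=Point(c.x, c.y),
            complexity=tier,
            consultations=0,
            migrant_exclusive=bool(rng.uniform() < migrant_fraction),
        ))
    return services


def scatter_cases_to_services(counts, zones, seed: int = 0,
                              attraction: dict | None = None) -> dict[str, int]:
    """Multinomially assign each area's cases to the services whose zone
    covers the area; probability proportional to tier attraction times
    the service's zone weight for that area. Conserves totals exactly.
    """
    rng = _stage_rng(seed, "scatter")
    counts = np.asarray(counts)
    n = counts.size
    per_area: list[list[tuple[str, float]]] = [[] for _ in range(n)]
    for z in zones:
        a = _TIER_ATTRACTION[z.complexity] if attraction is None \
            else attraction[z.service_id]
        for idx, w in zip(z.member_indices, z.weights):
            per_area[idx].append((z.service_id, a * max(w, 1e-300)))
    totals: dict[str, int] = {z.service_id: 0 for z in zones}
    for i in range(n):
        if counts[i] == 0:
            continue
        if not per_area[i]:
            raise ValueError(f"area index {i} covered by no service zone")
        sids, weights = zip(*per_area[i])
        p = np.asarray(weights, dtype=float)
        alloc = rng.multinomial(int(counts[i]), p / p.sum())
        for sid, a in zip(sids, alloc):
            totals[sid] += int(a)
    return totals


def generate_city(n_areas: int = 460, seed: int = 0,
                  bbox=(0.0, 0.0, 10_000.0, 10_000.0),
                  exp_beta: dict | None = None, tau_u: float = 60.0,
                  tau_st: float = 20.0, include_random_effects: bool = True,
                  n_primary: int | None = None,
                  n_intermediate: int | None = None,
                  n_high: int = 2) -> SyntheticCity:
    """Full synthetic city: lattice, populations, covariates, stations,
    services with scattered consultation counts, and the generating truth."""
    from bymap.rate_allocation import build_service_zones

    lattice = generate_lattice(n_areas, bbox, seed)
    pops = sample_populations(n_areas, seed)
    covs = sample_covariates(lattice, seed)
    stations = sample_stations(bbox, seed)
    truth = make_truth(lattice, covs, seed, exp_beta, tau_u, tau_st,
                       include_random_effects=include_random_effects)
    cases = simulate_counts(truth, pops, covs.to_numpy(), seed)
    services = simulate_services(lattice, pops, n_primary, n_intermediate,
                                 n_high, seed)
    zones = build_service_zones(services, lattice, pops)
    consult = scatter_cases_to_services(cases, zones, seed)
    for s in services:
        s.consultations = consult[s.service_id]
    return SyntheticCity(lattice, pops, covs, stations, services, consult,
                         truth, cases)


# ---------------------------------------------------------------------------
# plain-text writers (GeoJSON / CSV / JSON)

def write_city(city: SyntheticCity, outdir) -> None:
    import json
    from pathlib import Path

    from bymap.spatial_lattice import write_areas_geojson

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    props = {aid: {"population": int(p)}
             for aid, p in zip(city.lattice.area_ids, city.populations)}
    write_areas_geojson(outdir / "areas.geojson", city.lattice.area_ids,
                        city.lattice.polygons, props)
    city.covariates.rename_axis("area_id").to_csv(outdir / "covariates.csv")
    with open(outdir / "services.csv", "w") as fh:
        fh.write("service_id,x,y,complexity,consultations,migrant_exclusive\n")
        for s in city.services:
            fh.write(f"{s.service_id},{s.location.x},{s.location.y},"
                     f"{s.complexity},{s.consultations},"
                     f"{str(s.migrant_exclusive).lower()}\n")
    with open(outdir / "stations.csv", "w") as fh:
        fh.write("station_id,x,y,pm10\n")
        for k, (x, y, v) in enumerate(city.stations):
            fh.write(f"P{k},{x},{y},{v}\n")
    truth = {
        "alpha": city.truth.alpha,
        "beta": dict(zip(city.truth.covariate_names,
                         city.truth.beta.tolist())),
        "tau_u": city.truth.tau_u,
        "tau_st": city.truth.tau_st,
        "u": city.truth.u.tolist(),
        "st": city.truth.st.tolist(),
        "cases": city.cases.tolist(),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, sort_keys=True)
        fh.write("\n")
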