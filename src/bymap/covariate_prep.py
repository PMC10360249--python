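"""Covariate preparation: IDW pollutant surfaces, quintile codes, VIF."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StationReading:
    x: float
    y: float
    value: float  # annual mean PM10, ug/m3

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("station value must be positive")


@dataclass
class VIFReport:
    names: list[str]
    vif: np.ndarray
    threshold: float = 5.0

    @property
    def flags(self) -> np.ndarray:
        return self.vif >= self.threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"vif": self.vif, "collinear": self.flags}, index=self.names
        )


def _station_arrays(stations):
    pts, vals = [], []
    for s in stations:
        if isinstance(s, StationReading):
            pts.append((s.x, s.y))
            vals.append(s.value)
        else:  # (x, y, value) tuple
            pts.append((s[0], s[1]))
            vals.append(s[2])
    return np.asarray(pts, dtype=float), np.asarray(vals, dtype=float)


def idw_interpolate(stations, points, power: float = 2.0) -> np.ndarray:
    """Inverse-distance-weighted interpolation.

    v(x) = sum_k z_k d_k^-p / sum_k d_k^-p; a point coinciding with a
    station takes that station's value exactly; results always lie in
    [min z, max z].
    """
    if power <= 0:
        raise ValueError("power must be positive")
    spts, vals = _station_arrays(stations)
    if spts.size == 0:
        raise ValueError("no stations")
    q = np.asarray(points, dtype=float).reshape(-1, 2)
    d = np.linalg.norm(q[:, None, :] - spts[None, :, :], axis=-1)
    out = np.empty(len(q))
    hit = d < 1e-12
    exact = hit.any(axis=1)
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[exact] = 0.0
    np.putmask(w, hit, 1.0)
    out = (w * vals).sum(axis=1) / w.sum(axis=1)
    return out


def _polygon_sample_points(poly, n: int) -> np.ndarray:
    """Deterministic interior sample points: the centroid for n=1, else a
    regular grid over the bounding box filtered to the polygon."""
    from shapely.geometry import Point

    if poly.area <= 0:
        raise ValueError("polygon with zero area")
    if n <= 1:
        c = poly.centroid
        if not poly.covers(c):
            c = poly.representative_point()
        return np.array([[c.x, c.y]])
    x0, y0, x1, y1 = poly.bounds
    m = int(np.ceil(np.sqrt(4 * n)))
    xs = np.linspace(x0, x1, m + 2)[1:-1]
    ys = np.linspace(y0, y1, m + 2)[1:-1]
    pts = [(x, y) for x in xs for y in ys if poly.covers(Point(x, y))]
    if not pts:
        c = poly.representative_point()
        pts = [(c.x, c.y)]
    return np.asarray(pts[: max(n, 1)])


def area_pollution(stations, lattice, power: float = 2.0,
                   n_sample_points: int = 1) -> np.ndarray:
    """Per-area pollutant level: mean of the IDW surface over
    deterministic sample points inside each polygon (centroid when
    ``n_sample_points`` is 1)."""
    out = np.empty(lattice.n)
    for i, poly in enumerate(lattice.polygons):
        pts = _polygon_sample_points(poly, n_sample_points)
        out[i] = idw_interpolate(stations, pts, power).mean()
    return out


def quintile_bin(values, n_bins: int = 5) -> np.ndarray:
    """Rank-based bins 1..n_bins with sizes differing by at most one.

    Ties are broken by position (area_id order), making the binning
    deterministic and idempotent under monotone transforms.
    """
    x = np.asarray(values, dtype=float)
    order = np.argsort(x, kind="stable")
    bins = np.empty(x.size, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins), start=1):
        bins[chunk] = b
    return bins


def vif(covariates, threshold: float = 5.0) -> VIFReport:
    """Variance inflation factors: VIF_j = 1/(1 - R^2_j) from regressing
    column j on the remaining columns plus an intercept. Exact linear
    dependence is reported as +inf rather than raised."""
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more rows than columns + 1")
    out = np.empty(p)
    for j in range(p):
        y = X[:, j]
        if np.ptp(y) == 0:
            raise ValueError(f"constant column {names[j]!r}")
        A = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return VIFReport(names, out, threshold)


def read_stations_csv(path) -> list[StationReading]:
    df = pd.read_csv(path)
    return [StationReading(float(r.x), float(r.y), float(r.pm10))
            for r in df.itertuples(index=False)]
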