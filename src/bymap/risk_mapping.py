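"""Per-area relative risks, exceedance probabilities and cluster labels.

Relative risk is taken from the random effects only, RR_i =
exp(u_i + st_i): the area's risk relative to the citywide baseline
after covariate adjustment. A hotspot is an elevated area (RR > 1)
whose neighbors are all elevated; a coldspot is the mirror image.
Perimeter areas are judged over their existing neighbors only, and
islands are never hot- or coldspots.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from bymap.bym_inference import BYMFit
from bymap.spatial_lattice import AreaLattice

DEFAULT_RR_THRESHOLD = 1.5
DEFAULT_PROB_CUTOFF = 0.8


def _rr_draws(fit: BYMFit) -> np.ndarray:
    return np.exp(fit.u + fit.st)


def area_relative_risk(fit: BYMFit) -> pd.DataFrame:
    """Posterior mean and equal-tailed 95% interval of RR_i = exp(u_i + st_i)."""
    rr = _rr_draws(fit)
    lo, hi = np.quantile(rr, [0.025, 0.975], axis=0)
    return pd.DataFrame({
        "rr_mean": rr.mean(axis=0),
        "rr_q2.5": lo,
        "rr_q97.5": hi,
    })


def exceedance_probability(fit: BYMFit, threshold: float = DEFAULT_RR_THRESHOLD
                           ) -> np.ndarray:
    """Pr(RR_i > threshold | data): fraction of posterior draws above."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return (_rr_draws(fit) > threshold).mean(axis=0)


def detect_clusters(rr_mean, lattice: AreaLattice,
                    rule: str = "all", fraction: float = 1.0) -> np.ndarray:
    """Label each area hotspot / coldspot / elevated / none.

    ``rule="all"`` (default) requires every neighbor on the same side of
    1; ``rule="fraction"`` requires at least ``fraction`` of them.
    Areas without neighbors are never hot- or coldspots.
    """
    rr = np.asarray(rr_mean, dtype=float)
    if rr.shape != (lattice.n,):
        raise ValueError("rr_mean misaligned with lattice")
    labels = np.array(["none"] * lattice.n, dtype=object)
    need = (lambda k: k) if rule == "all" else \
        (lambda k: int(np.ceil(fraction * k)))
    for i in range(lattice.n):
        nbrs = lattice.neighbors(i)
        if rr[i] > 1:
            labels[i] = "elevated"
            if nbrs.size and (rr[nbrs] > 1).sum() >= need(nbrs.size):
                labels[i] = "hotspot"
        elif rr[i] < 1:
            if nbrs.size and (rr[nbrs] < 1).sum() >= need(nbrs.size):
                labels[i] = "coldspot"
    return labels


def risk_summary(fit: BYMFit, lattice: AreaLattice,
                 threshold: float = DEFAULT_RR_THRESHOLD,
                 rule: str = "all") -> pd.DataFrame:
    """Full per-area risk table: RR summaries, exceedance probability
    against ``threshold``, and the cluster label."""
    out = area_relative_risk(fit)
    out.index = pd.Index(lattice.area_ids, name="area_id")
    out["prob_exceed"] = exceedance_probability(fit, threshold)
    out["label"] = detect_clusters(out["rr_mean"].to_numpy(), lattice,
                                   rule=rule)
    return out


def write_risk_outputs(summary: pd.DataFrame, lattice: AreaLattice,
                       outdir) -> None:
    """Risk CSV plus a GeoJSON carrying the same values as feature
    properties for choropleth rendering."""
    from pathlib import Path

    from bymap.spatial_lattice import write_areas_geojson

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary.to_csv(outdir / "risk.csv")
    props = {
        aid: {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
              for k, v in row.items()}
        for aid, row in summary.iterrows()
    }
    write_areas_geojson(outdir / "risk.geojson", lattice.area_ids,
                        lattice.polygons, props)
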