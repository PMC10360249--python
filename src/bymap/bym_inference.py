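"""Hierarchical Poisson regression with paired unstructured and ICAR
spatial random effects, fitted by gradient-based MCMC.

Model, for area i:

    y_i ~ Poisson(lambda_i)
    log lambda_i = alpha + X_i beta + log(pop_i) + u_i + st_i
    u_i ~ Normal(0, 1/tau_u)
    st  ~ ICAR(tau_st)   (improper, rank n - n_components, sum-to-zero)
    log tau_u ~ logGamma(0.1, 0.1)      [i.e. tau_u ~ Gamma(0.1, 0.1)]
    log tau_st ~ logGamma(0.001, 0.001)
    alpha, beta_j ~ Normal(0, 1/0.001)

The sum-to-zero constraint is imposed softly during sampling (a tight
Gaussian penalty on the component means of st) and exactly on the
retained draws (per-component recentring, with the removed mean folded
into the intercept).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from bymap._nuts import nuts
from bymap.spatial_lattice import AreaLattice


@dataclass
class BYMModelSpec:
    """Model specification: covariates, priors and options.

    ``prior_u`` / ``prior_st`` are (shape, rate) of the logGamma prior on
    the log precision of the unstructured / structured component, which
    is equivalent to a Gamma(shape, rate) prior on the precision itself.
    """

    covariate_names: list[str] = field(default_factory=list)
    prior_u: tuple[float, float] = (0.1, 0.1)
    prior_st: tuple[float, float] = (0.001, 0.001)
    fixed_effect_precision: float = 0.001
    adjacency_scheme: str = "queen"
    include_u: bool = True
    include_st: bool = True
    soft_sum_zero_sd: float | None = 0.001  # sd multiplier per component
    standardize: bool = False

    def __post_init__(self):
        for a, b in (self.prior_u, self.prior_st):
            if a <= 0 or b <= 0:
                raise ValueError("logGamma shape/rate must be positive")
        if self.fixed_effect_precision <= 0:
            raise ValueError("fixed-effect precision must be positive")


@dataclass
class BYMData:
    """Aligned model inputs in canonical area order."""

    y: np.ndarray  # nonnegative integer counts
    population: np.ndarray
    X: np.ndarray  # (n, p) covariate matrix
    lattice: AreaLattice
    covariate_names: list[str] = field(default_factory=list)

    @classmethod
    def from_area_table(cls, table: pd.DataFrame, lattice: AreaLattice,
                        covariate_names: list[str],
                        count_column: str = "cases") -> "BYMData":
        from bymap.rate_allocation import round_counts

        if list(table.index) != lattice.area_ids:
            table = table.loc[lattice.area_ids]
        y = round_counts(table[count_column].to_numpy())
        return cls(
            y=y,
            population=table["population"].to_numpy(dtype=float),
            X=table[covariate_names].to_numpy(dtype=float),
            lattice=lattice,
            covariate_names=list(covariate_names),
        )

    def __post_init__(self):
        self.y = np.asarray(self.y)
        self.population = np.asarray(self.population, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = self.y.size
        if self.population.shape != (n,) or self.X.shape[0] != n:
            raise ValueError("misaligned inputs")
        if np.any(self.population <= 0):
            raise ValueError("zero or negative population")
        if np.any(self.y < 0) or not np.issubdtype(self.y.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")


@dataclass
class BYMFit:
    """Posterior draws (flattened across chains) and diagnostics."""

    spec: BYMModelSpec
    alpha: np.ndarray  # (total_draws,)
    beta: np.ndarray  # (total_draws, p)
    u: np.ndarray  # (total_draws, n)
    st: np.ndarray  # (total_draws, n)
    tau_u: np.ndarray
    tau_st: np.ndarray
    n_chains: int
    n_draws: int  # per chain
    rhat: dict[str, float]
    n_divergent: int
    covariate_names: list[str] = field(default_factory=list)

    @property
    def total_draws(self) -> int:
        return self.alpha.size

    def linear_predictor(self, data: BYMData) -> np.ndarray:
        """(total_draws, n) matrix of eta draws (including offset)."""
        eta = (self.alpha[:, None] + self.beta @ data.X.T
               + np.log(data.population)[None, :])
        return eta + self.u + self.st


def icar_quadratic(st: np.ndarray, lattice: AreaLattice) -> float:
    """Pairwise roughness sum_{i~j} (st_i - st_j)^2 over unique edges."""
    L = lattice.laplacian()
    return float(st @ (L @ st))


class _Posterior:
    """Packed-vector posterior with analytic gradient.

    Layout: [alpha_c, beta(p), u(n)?, st(n)?, log_tau_u?, log_tau_st?].

    Covariates are centered internally (alpha_c = alpha + mean(X) beta)
    purely as a reparameterisation for sampler geometry; priors and all
    reported draws refer to the original alpha.
    """

    def __init__(self, data: BYMData, spec: BYMModelSpec):
        self.data = data
        self.spec = spec
        self.n = data.y.size
        self.p = data.X.shape[1]
        self.xmean = data.X.mean(axis=0) if self.p else np.zeros(0)
        self.Xc = data.X - self.xmean
        self.log_pop = np.log(data.population)
        self.L = data.lattice.laplacian()
        comp = data.lattice.components()
        self.comp_masks = [comp == c for c in range(comp.max() + 1)]
        self.rank = self.n - len(self.comp_masks)
        self.lgamma_y = gammaln(data.y + 1.0).sum()
        i = 1 + self.p
        self.sl_beta = slice(1, i)
        self.sl_u = slice(i, i + self.n) if spec.include_u else None
        i += self.n if spec.include_u else 0
        self.sl_st = slice(i, i + self.n) if spec.include_st else None
        i += self.n if spec.include_st else 0
        self.i_ltu = i if spec.include_u else None
        i += 1 if spec.include_u else 0
        self.i_lts = i if spec.include_st else None
        i += 1 if spec.include_st else 0
        self.dim = i

    def pack(self, alpha=0.0, beta=None, u=None, st=None,
             log_tau_u=0.0, log_tau_st=0.0) -> np.ndarray:
        """Pack original-scale parameters into the internal layout."""
        z = np.zeros(self.dim)
        if beta is not None:
            z[self.sl_beta] = beta
        z[0] = alpha + float(self.xmean @ z[self.sl_beta])
        if self.sl_u is not None and u is not None:
            z[self.sl_u] = u
        if self.sl_st is not None and st is not None:
            z[self.sl_st] = st
        if self.i_ltu is not None:
            z[self.i_ltu] = log_tau_u
        if self.i_lts is not None:
            z[self.i_lts] = log_tau_st
        return z

    def value_grad(self, z: np.ndarray):
        d, s = self.data, self.spec
        n = self.n
        alpha_c = z[0]
        beta = z[self.sl_beta]
        u = z[self.sl_u] if self.sl_u is not None else 0.0
        st = z[self.sl_st] if self.sl_st is not None else 0.0
        eta = alpha_c + self.Xc @ beta + self.log_pop + u + st
        lam = np.exp(np.clip(eta, -700, 700))
        logp = float(d.y @ eta - lam.sum()) - self.lgamma_y
        grad = np.zeros(self.dim)
        dres = d.y - lam
        prec0 = s.fixed_effect_precision
        alpha = alpha_c - float(self.xmean @ beta)  # original-scale intercept
        grad[0] = dres.sum() - prec0 * alpha
        grad[self.sl_beta] = (self.Xc.T @ dres + prec0 * alpha * self.xmean
                              - prec0 * beta)
        logp -= 0.5 * prec0 * (alpha * alpha + float(beta @ beta))

        if self.sl_u is not None:
            ltu = z[self.i_ltu]
            tau_u = np.exp(ltu)
            ssq = float(u @ u)
            logp += 0.5 * n * ltu - 0.5 * tau_u * ssq
            grad[self.sl_u] = dres - tau_u * u
            a, b = s.prior_u
            logp += a * ltu - b * tau_u
            grad[self.i_ltu] = 0.5 * n - 0.5 * tau_u * ssq + a - b * tau_u

        if self.sl_st is not None:
            lts = z[self.i_lts]
            tau_st = np.exp(lts)
            Lst = self.L @ st
            quad = float(st @ Lst)
            logp += 0.5 * self.rank * lts - 0.5 * tau_st * quad
            gst = dres - tau_st * Lst
            a, b = s.prior_st
            logp += a * lts - b * tau_st
            grad[self.i_lts] = (0.5 * self.rank - 0.5 * tau_st * quad
                                + a - b * tau_st)
            if s.soft_sum_zero_sd is not None:
                for mask in self.comp_masks:
                    nc = int(mask.sum())
                    sd = s.soft_sum_zero_sd * nc
                    tot = float(st[mask].sum())
                    logp -= 0.5 * (tot / sd) ** 2
                    gst = gst - np.where(mask, tot / sd**2, 0.0)
            grad[self.sl_st] = gst
        return logp, grad

    def hess_diag(self, z: np.ndarray) -> np.ndarray:
        """Diagonal of the negative Hessian (for preconditioning)."""
        d, s = self.data, self.spec
        beta = z[self.sl_beta]
        u = z[self.sl_u] if self.sl_u is not None else 0.0
        st = z[self.sl_st] if self.sl_st is not None else 0.0
        eta = z[0] + self.Xc @ beta + self.log_pop + u + st
        lam = np.exp(np.clip(eta, -700, 700))
        h = np.empty(self.dim)
        prec0 = s.fixed_effect_precision
        h[0] = lam.sum() + prec0
        h[self.sl_beta] = lam @ (self.Xc ** 2) + prec0 * (self.xmean**2 + 1)
        if self.sl_u is not None:
            tau_u = np.exp(z[self.i_ltu])
            h[self.sl_u] = lam + tau_u
            a, b = s.prior_u
            h[self.i_ltu] = tau_u * (0.5 * float(u @ u) + b) + 0.25
        if self.sl_st is not None:
            tau_st = np.exp(z[self.i_lts])
            deg = self.L.diagonal()
            h[self.sl_st] = lam + tau_st * deg
            if s.soft_sum_zero_sd is not None:
                for mask in self.comp_masks:
                    sd = s.soft_sum_zero_sd * int(mask.sum())
                    h[self.sl_st] += np.where(mask, 1.0 / sd**2, 0.0)
            a, b = s.prior_st
            quad = float(st @ (self.L @ st))
            h[self.i_lts] = tau_st * (0.5 * quad + b) + 0.25
        return np.clip(h, 1e-12, None)

    def find_mode(self, z0: np.ndarray, maxiter: int = 500) -> np.ndarray:
        from scipy.optimize import minimize

        def neg(zz):
            v, g = self.value_grad(zz)
            return -v, -g

        res = minimize(neg, z0, jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter})
        return res.x


def log_joint(params: dict, data: BYMData, spec: BYMModelSpec) -> float:
    """Log joint density (up to the ICAR normalising constant) at a
    parameter dictionary with keys alpha, beta, u, st, log_tau_u,
    log_tau_st (absent blocks default to zero)."""
    post = _Posterior(data, spec)
    z = post.pack(
        alpha=params.get("alpha", 0.0),
        beta=np.asarray(params.get("beta", np.zeros(post.p)), dtype=float),
        u=params.get("u"),
        st=params.get("st"),
        log_tau_u=params.get("log_tau_u", 0.0),
        log_tau_st=params.get("log_tau_st", 0.0),
    )
    val, _ = post.value_grad(z)
    if not np.isfinite(val):
        raise ValueError("non-finite log joint")
    return val


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat for a (n_chains, n_draws) array."""
    m, n = chains.shape
    half = n // 2
    if half < 2:
        return np.nan
    sub = np.concatenate([chains[:, :half], chains[:, half : 2 * half]])
    k, h = sub.shape
    means = sub.mean(axis=1)
    w = sub.var(axis=1, ddof=1).mean()
    b = h * means.var(ddof=1)
    var_plus = (h - 1) / h * w + b / h
    if w <= 0:
        return 1.0
    return float(np.sqrt(var_plus / w))


def fit(data: BYMData, spec: BYMModelSpec, n_chains: int = 4,
        n_draws: int = 1000, n_warmup: int = 500, seed: int = 0,
        target_accept: float = 0.8, max_depth: int = 10) -> BYMFit:
    """Posterior sampling by NUTS; retained draws have exactly
    sum-to-zero structured effects (per connected component), with the
    removed mean folded into the intercept."""
    post = _Posterior(data, spec)
    rate0 = max(data.y.sum(), 0.5) / data.population.sum()
    z_start = post.pack(alpha=np.log(rate0), log_tau_u=np.log(10.0),
                        log_tau_st=np.log(10.0))
    z_map = post.find_mode(z_start)
    mass_diag = 1.0 / post.hess_diag(z_map)
    chains = []
    divergent = 0
    for c in range(n_chains):
        rng = np.random.default_rng([seed, c])
        z0 = z_map + 0.1 * np.sqrt(mass_diag) * rng.standard_normal(post.dim)
        res = nuts(post.value_grad, z0, n_warmup, n_draws, rng,
                   target_accept=target_accept, max_depth=max_depth,
                   mass_diag_init=mass_diag)
        chains.append(res.draws)
        divergent += res.n_divergent
    if divergent:
        warnings.warn(f"{divergent} divergent transition(s) observed",
                      stacklevel=2)
    Z = np.stack(chains)  # (chains, draws, dim)

    beta = Z[:, :, post.sl_beta].copy()
    alpha = Z[:, :, 0] - beta @ post.xmean  # back to original scale
    n = post.n
    if post.sl_u is not None:
        u = Z[:, :, post.sl_u].copy()
        tau_u = np.exp(Z[:, :, post.i_ltu])
    else:
        u = np.zeros((n_chains, n_draws, n))
        tau_u = np.full((n_chains, n_draws), np.nan)
    if post.sl_st is not None:
        st = Z[:, :, post.sl_st].copy()
        tau_st = np.exp(Z[:, :, post.i_lts])
        # exact recentring: subtract component means, absorb the global
        # area-weighted mean into the intercept so eta is unchanged
        for mask in post.comp_masks:
            cmean = st[:, :, mask].mean(axis=2)
            st[:, :, mask] -= cmean[:, :, None]
            alpha += cmean * (mask.sum() / n)
    else:
        st = np.zeros((n_chains, n_draws, n))
        tau_st = np.full((n_chains, n_draws), np.nan)

    rhat = {"alpha": _split_rhat(alpha)}
    for j, name in enumerate(data.covariate_names
                             or [f"x{j}" for j in range(post.p)]):
        rhat[f"beta[{name}]"] = _split_rhat(beta[:, :, j])
    if post.sl_u is not None:
        rhat["log_tau_u"] = _split_rhat(np.log(tau_u))
    if post.sl_st is not None:
        rhat["log_tau_st"] = _split_rhat(np.log(tau_st))
    bad = {k: v for k, v in rhat.items() if np.isfinite(v) and v > 1.05}
    if bad:
        warnings.warn(f"split-Rhat > 1.05 for {sorted(bad)}", stacklevel=2)

    flat = lambda a: a.reshape(a.shape[0] * a.shape[1], *a.shape[2:])
    return BYMFit(
        spec=spec,
        alpha=flat(alpha),
        beta=flat(beta),
        u=flat(u),
        st=flat(st),
        tau_u=flat(tau_u),
        tau_st=flat(tau_st),
        n_chains=n_chains,
        n_draws=n_draws,
        rhat=rhat,
        n_divergent=divergent,
        covariate_names=list(data.covariate_names),
    )


def summarize_fixed_effects(fit_: BYMFit) -> pd.DataFrame:
    """Exponentiated posterior means with equal-tailed 95% credible
    intervals; ``credible`` is True when the interval excludes 1."""
    rows = {}
    names = ["intercept"] + (fit_.covariate_names
                             or [f"x{j}" for j in range(fit_.beta.shape[1])])
    draws = [fit_.alpha] + [fit_.beta[:, j]
                            for j in range(fit_.beta.shape[1])]
    for name, d in zip(names, draws):
        e = np.exp(d)
        lo, hi = np.quantile(e, [0.025, 0.975])
        rows[name] = {
            "exp_mean": e.mean(),
            "q2.5": lo,
            "q97.5": hi,
            "credible": bool(lo > 1.0 or hi < 1.0),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "parameter"
    return out


def _poisson_deviance(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """-2 * Poisson log likelihood for eta of shape (..., n)."""
    lam = np.exp(eta)
    ll = (y * eta - lam).sum(axis=-1) - gammaln(y + 1.0).sum()
    return -2.0 * ll


def dic(fit_: BYMFit, data: BYMData) -> tuple[float, float]:
    """Deviance information criterion.

    DIC = Dbar + pD, with pD = Dbar - D(eta_hat) and eta_hat the
    posterior mean of the per-area linear predictor. Lower is better;
    differences under 2 are conventionally an equivalent fit.
    """
    eta = fit_.linear_predictor(data)
    d_draws = _poisson_deviance(eta, data.y)
    d_bar = float(d_draws.mean())
    d_hat = float(_poisson_deviance(eta.mean(axis=0), data.y))
    p_d = d_bar - d_hat
    return d_bar + p_d, p_d


def spatial_variance_fraction(fit_: BYMFit) -> float:
    """Share of between-area variance carried by the structured effect:
    Var_areas(mean st) / (Var_areas(mean st) + Var_areas(mean u))."""
    v_st = float(np.var(fit_.st.mean(axis=0)))
    v_u = float(np.var(fit_.u.mean(axis=0)))
    if v_st + v_u == 0:
        return 0.0
    return v_st / (v_st + v_u)


def write_fit_outputs(fit_: BYMFit, data: BYMData, outdir) -> None:
    """Posterior summary CSV, per-area effects CSV, metadata JSON."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    names = ["alpha"] + [f"beta[{c}]" for c in fit_.covariate_names]
    series = [fit_.alpha] + [fit_.beta[:, j]
                             for j in range(fit_.beta.shape[1])]
    if fit_.spec.include_u:
        names.append("tau_u")
        series.append(fit_.tau_u)
    if fit_.spec.include_st:
        names.append("tau_st")
        series.append(fit_.tau_st)
    for name, d in zip(names, series):
        lo, hi = np.quantile(d, [0.025, 0.975])
        rows.append({"parameter": name, "mean": d.mean(), "sd": d.std(ddof=1),
                     "q2.5": lo, "q97.5": hi,
                     "rhat": fit_.rhat.get(name.replace("tau", "log_tau")
                                           if name.startswith("tau") else name,
                                           np.nan)})
    pd.DataFrame(rows).to_csv(outdir / "posterior_summary.csv", index=False)
    pd.DataFrame(
        {"u_mean": fit_.u.mean(axis=0), "st_mean": fit_.st.mean(axis=0)},
        index=pd.Index(data.lattice.area_ids, name="area_id"),
    ).to_csv(outdir / "area_effects.csv")
    d, p_d = dic(fit_, data)
    meta = {
        "dic": d,
        "p_d": p_d,
        "spatial_variance_fraction": spatial_variance_fraction(fit_),
        "rhat": {k: (None if not np.isfinite(v) else v)
                 for k, v in fit_.rhat.items()},
        "n_chains": fit_.n_chains,
        "n_draws": fit_.n_draws,
        "n_divergent": fit_.n_divergent,
    }
    with open(outdir / "fit_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
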