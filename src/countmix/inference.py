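"""Bayesian fitting engine for the three abundance models.

Latent abundance is always marginalized (see :mod:`countmix.likelihoods`);
the engine targets log posterior = marginal log likelihood + random-effect
densities + weakly informative priors, over the full hierarchical parameter
vector (community means, species and site effects, SDs on the log scale,
and NB dispersion on the log scale).

Two modes:

``map``
    Penalized maximum a posteriori by L-BFGS-B with analytic gradients,
    followed by a Laplace (curvature) approximation whose draws stand in
    for posterior samples. Deterministic given the seed; this is the
    desk-scale mode used by the simulation-evaluation grids.
``mcmc``
    Affine-invariant ensemble MCMC (emcee) initialized at the MAP, with
    R-hat and effective-sample-size diagnostics computed by arviz treating
    walkers as chains. Fits failing the diagnostic thresholds are flagged,
    never silently accepted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .likelihoods import (
    KRule,
    binmix_aux,
    binmix_marginal_loglik_arrays,
    compute_latent_bound,
    history_cell_probs,
    multimix_aux,
    multimix_loglik_arrays,
    nb_glmm_loglik_arrays,
)
from .simulate import history_columns

MODEL_KINDS = ("glmm", "binmix", "multimix")

LOG_SIGMA_BOUNDS = (np.log(0.01), np.log(5.0))
LOG_PHI_BOUNDS = (np.log(0.05), np.log(1000.0))


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorSpec:
    """Named prior families per top-level parameter.

    Families: ``("normal", loc, scale)`` for location parameters,
    ``("half_normal", scale)`` for SDs, ``("half_normal_inv_sqrt", scale)``
    (half-normal on 1/sqrt(phi)) or ``("gamma", shape, rate)`` for the NB
    dispersion. Exact hyperparameters are a design default, chosen to be
    weakly informative on the log/logit scales, and can be overridden.
    """

    entries: dict = field(default_factory=dict)

    @classmethod
    def default(cls) -> "PriorSpec":
        e = {}
        for name in ("mu_alpha1", "alpha3", "mu_alpha4", "mu_beta1", "beta3", "mu_beta4"):
            e[name] = ("normal", 0.0, 2.0)
        for name in (
            "sigma_alpha1",
            "sigma_alpha2",
            "sigma_alpha4",
            "sigma_beta1",
            "sigma_beta2",
            "sigma_beta4",
        ):
            e[name] = ("half_normal", 1.0)
        e["phi"] = ("half_normal_inv_sqrt", 1.0)
        return cls(entries=e)

    def override(self, **kwargs) -> "PriorSpec":
        e = dict(self.entries)
        e.update(kwargs)
        return PriorSpec(entries=e)

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        base = cls.default()
        return base.override(**{k: tuple(v) for k, v in d.items()})

    def get(self, name: str) -> tuple:
        spec = self.entries[name]
        if spec[0] in ("normal", "half_normal", "half_normal_inv_sqrt") and spec[-1] <= 0:
            raise ValueError(f"prior scale for {name} must be positive")
        return spec

    def logpdf_grad(self, name: str, coord: float, on_log_scale: bool):
        """Log prior density and d/d(coordinate); ``coord`` is the sampled
        coordinate (log sigma / log phi for scale parameters)."""
        spec = self.get(name)
        fam = spec[0]
        if fam == "normal":
            _, loc, s = spec
            return (
                -0.5 * (coord - loc) ** 2 / s**2,
                -(coord - loc) / s**2,
            )
        if fam == "half_normal":
            (_, s) = spec
            sig = np.exp(coord)  # includes log-scale Jacobian
            return -0.5 * sig**2 / s**2 + coord, -(sig**2) / s**2 + 1.0
        if fam == "half_normal_inv_sqrt":
            (_, s) = spec
            phi = np.exp(coord)
            return -0.5 / (s**2 * phi) - 0.5 * coord, 0.5 / (s**2 * phi) - 0.5
        if fam == "gamma":
            _, shape, rate = spec
            phi = np.exp(coord)
            return shape * coord - rate * phi, shape - rate * phi
        raise ValueError(f"unknown prior family {fam!r}")


@dataclass(frozen=True)
class EngineConfig:
    """Sampler / optimizer settings and diagnostic thresholds."""

    n_iterations: int = 4000
    n_warmup: int = 2000
    n_chains: int = 4
    rhat_threshold: float = 1.05
    ess_ratio_threshold: float = 0.1
    mode: str = "map"
    seed: int = 0
    map_draws: int = 250
    max_opt_iter: int = 1500

    def __post_init__(self):
        if self.n_warmup >= self.n_iterations:
            raise ValueError("n_warmup must be smaller than n_iterations")
        if self.rhat_threshold <= 0 or self.ess_ratio_threshold <= 0:
            raise ValueError("diagnostic thresholds must be positive")
        if self.mode not in ("map", "mcmc"):
            raise ValueError(f"mode must be 'map' or 'mcmc', got {self.mode!r}")


# ---------------------------------------------------------------------------
# parameter layout
# ---------------------------------------------------------------------------


class _Layout:
    def __init__(self):
        self.names: list[tuple[str, int]] = []
        self.offsets: dict[str, slice] = {}
        self.lb: list[float] = []
        self.ub: list[float] = []
        self._n = 0

    def add(self, name, size=1, bounds=(-np.inf, np.inf)):
        self.offsets[name] = slice(self._n, self._n + size)
        self.names.append((name, size))
        self.lb += [bounds[0]] * size
        self.ub += [bounds[1]] * size
        self._n += size

    @property
    def n(self):
        return self._n

    def get(self, x, name):
        v = x[self.offsets[name]]
        return float(v[0]) if v.size == 1 else v

    def flat_names(self, labels: dict[str, list]) -> list[str]:
        out = []
        for name, size in self.names:
            if size == 1:
                out.append(name)
            else:
                lab = labels.get(name, list(range(size)))
                out += [f"{name}[{v}]" for v in lab]
        return out


# ---------------------------------------------------------------------------
# model core: data + objective
# ---------------------------------------------------------------------------


def _require_columns(df, cols, what):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns {missing}")


class _Core:
    """Prepared data, parameter layout and penalized objective for one fit."""

    def __init__(self, kind, data, abundance_dist="nb", priors=None, k_rule=None):
        if kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {kind!r}")
        if abundance_dist not in ("nb", "poisson"):
            raise ValueError("abundance_dist must be 'nb' or 'poisson'")
        self.kind = kind
        self.abundance_dist = abundance_dist
        self.priors = priors or PriorSpec.default()
        self.k_rule = k_rule or KRule()
        self._prepare(data)
        self._build_layout()

    # -- data ---------------------------------------------------------------

    def _prepare(self, data):
        data = pd.DataFrame(data)
        _require_columns(data, ["site", "species", "year", "restored"], "data table")
        if self.kind == "multimix":
            hcols = [
                c
                for c in data.columns
                if c.startswith("h") and set(c[1:]) <= {"0", "1"} and len(c) > 1
            ]
            if not hcols or "n" not in data.columns:
                raise ValueError(
                    "multimix requires a HistoryTable with h<bits> columns and n"
                )
            self.J = len(hcols[0]) - 1
            hcols = history_columns(self.J)
            _require_columns(data, hcols, "HistoryTable")
            units = data[["site", "species", "year", "restored"]].reset_index(drop=True)
            self.T = data[hcols].to_numpy(dtype=np.int64)
            self.n = data["n"].to_numpy(dtype=np.int64)
            if np.any(self.T.sum(axis=1) != self.n):
                raise ValueError("history tallies do not sum to n")
            self.K = compute_latent_bound(self.n, self.k_rule)
            self.aux = multimix_aux(self.T, self.n, self.K, self.J)
        else:
            _require_columns(data, ["survey", "count"], "CountTable")
            if data["count"].min() < 0:
                raise ValueError("counts must be nonnegative")
            if self.kind == "glmm":
                units = data[["site", "species", "year", "restored"]].reset_index(
                    drop=True
                )
                self.y = data["count"].to_numpy(dtype=np.int64)
                self.J = int(data.groupby(["site", "species", "year"])["survey"].count().max())
            else:
                wide = data.pivot_table(
                    index=["site", "species", "year", "restored"],
                    columns="survey",
                    values="count",
                    aggfunc="first",
                )
                if wide.isna().any().any():
                    raise ValueError("unbalanced survey structure in CountTable")
                units = wide.index.to_frame(index=False)
                self.Y = wide.to_numpy(dtype=np.int64)
                self.J = self.Y.shape[1]
                self.lower = self.Y.max(axis=1)
                self.K = compute_latent_bound(self.lower, self.k_rule)
                self.aux = binmix_aux(self.Y, self.lower, self.K)

        self.species_labels, self.sp_idx = np.unique(
            units["species"].to_numpy(), return_inverse=True
        )
        self.site_labels, self.site_idx = np.unique(
            units["site"].to_numpy(), return_inverse=True
        )
        yr = units["year"].to_numpy(dtype=float)
        self.year = yr - yr.min()
        self.restored = units["restored"].to_numpy(dtype=float)
        self.S = len(self.species_labels)
        self.M = len(self.site_labels)
        self.n_rows = len(units)
        self.data_hash = hex(
            int(pd.util.hash_pandas_object(pd.DataFrame(units)).sum())
            & 0xFFFFFFFFFFFF
        )

    # -- layout -------------------------------------------------------------

    def _build_layout(self):
        lay = _Layout()
        lay.add("mu_alpha1")
        lay.add("alpha1_sp", self.S)
        lay.add("log_sigma_alpha1", bounds=LOG_SIGMA_BOUNDS)
        lay.add("alpha2_site", self.M)
        lay.add("log_sigma_alpha2", bounds=LOG_SIGMA_BOUNDS)
        lay.add("alpha3")
        lay.add("mu_alpha4")
        lay.add("alpha4_sp", self.S)
        lay.add("log_sigma_alpha4", bounds=LOG_SIGMA_BOUNDS)
        if self.abundance_dist == "nb":
            lay.add("log_phi", bounds=LOG_PHI_BOUNDS)
        if self.kind != "glmm":
            lay.add("mu_beta1")
            lay.add("beta1_sp", self.S)
            lay.add("log_sigma_beta1", bounds=LOG_SIGMA_BOUNDS)
            lay.add("beta2_site", self.M)
            lay.add("log_sigma_beta2", bounds=LOG_SIGMA_BOUNDS)
            lay.add("beta3")
            lay.add("mu_beta4")
            lay.add("beta4_sp", self.S)
            lay.add("log_sigma_beta4", bounds=LOG_SIGMA_BOUNDS)
        self.layout = lay

    def flat_names(self):
        labels = {
            "alpha1_sp": list(self.species_labels),
            "alpha4_sp": list(self.species_labels),
            "beta1_sp": list(self.species_labels),
            "beta4_sp": list(self.species_labels),
            "alpha2_site": list(self.site_labels),
            "beta2_site": list(self.site_labels),
        }
        return self.layout.flat_names(labels)

    # -- predictors ---------------------------------------------------------

    def predictors(self, x):
        lay = self.layout
        a1 = x[lay.offsets["alpha1_sp"]]
        a2 = x[lay.offsets["alpha2_site"]]
        a4 = x[lay.offsets["alpha4_sp"]]
        log_lam = (
            a1[self.sp_idx]
            + a2[self.site_idx]
            + lay.get(x, "alpha3") * self.year
            + a4[self.sp_idx] * self.restored
        )
        if self.kind == "glmm":
            return log_lam, None
        b1 = x[lay.offsets["beta1_sp"]]
        b2 = x[lay.offsets["beta2_site"]]
        logit_p = (
            b1[self.sp_idx]
            + b2[self.site_idx]
            + lay.get(x, "beta3") * self.year
            + x[lay.offsets["beta4_sp"]][self.sp_idx] * self.restored
        )
        return log_lam, logit_p

    def phi(self, x):
        if self.abundance_dist == "poisson":
            return None
        return float(np.exp(self.layout.get(x, "log_phi")))

    # -- objective ----------------------------------------------------------

    def neg_log_post(self, x, return_grad=True):
        lay = self.layout
        log_lam, logit_p = self.predictors(x)
        phi = self.phi(x)
        try:
            if self.kind == "glmm":
                out = nb_glmm_loglik_arrays(self.y, log_lam, phi, return_grad)
            elif self.kind == "binmix":
                out = binmix_marginal_loglik_arrays(
                    self.Y, log_lam, logit_p, phi, self.lower, self.K,
                    return_grad, aux=self.aux,
                )
            else:
                out = multimix_loglik_arrays(
                    self.T, self.n, log_lam, logit_p, phi, self.K, self.J,
                    return_grad, aux=self.aux,
                )
        except (ValueError, FloatingPointError):
            if return_grad:
                return np.inf, np.zeros(lay.n)
            return np.inf
        if return_grad:
            ll, lg = out
        else:
            ll, lg = out, None
        g = np.zeros(lay.n)
        if lg is not None:
            gl = lg["log_lam"]
            np.add.at(g, lay.offsets["alpha1_sp"].start + self.sp_idx, gl)
            np.add.at(g, lay.offsets["alpha2_site"].start + self.site_idx, gl)
            g[lay.offsets["alpha3"]] += np.dot(gl, self.year)
            np.add.at(
                g, lay.offsets["alpha4_sp"].start + self.sp_idx, gl * self.restored
            )
            if self.abundance_dist == "nb":
                g[lay.offsets["log_phi"]] += lg["log_phi"]
            if self.kind != "glmm":
                gp = lg["logit_p"]
                np.add.at(g, lay.offsets["beta1_sp"].start + self.sp_idx, gp)
                np.add.at(g, lay.offsets["beta2_site"].start + self.site_idx, gp)
                g[lay.offsets["beta3"]] += np.dot(gp, self.year)
                np.add.at(
                    g, lay.offsets["beta4_sp"].start + self.sp_idx, gp * self.restored
                )

        lp, g = self._add_penalties(x, ll, g)
        if not np.isfinite(lp):
            return (np.inf, np.zeros(lay.n)) if return_grad else np.inf
        if return_grad:
            return -lp, -g
        return -lp

    def _add_penalties(self, x, lp, g):
        lay = self.layout
        pri = self.priors

        def hier(values_name, mu_name, ls_name):
            nonlocal lp
            v = x[lay.offsets[values_name]]
            mu = lay.get(x, mu_name)
            ls = lay.get(x, ls_name)
            sig = np.exp(ls)
            r = v - mu
            lp += -v.size * ls - 0.5 * np.sum(r**2) / sig**2
            g[lay.offsets[values_name]] += -r / sig**2
            g[lay.offsets[mu_name]] += np.sum(r) / sig**2
            g[lay.offsets[ls_name]] += -v.size + np.sum(r**2) / sig**2

        def zero_mean(values_name, ls_name):
            nonlocal lp
            v = x[lay.offsets[values_name]]
            ls = lay.get(x, ls_name)
            sig = np.exp(ls)
            lp += -v.size * ls - 0.5 * np.sum(v**2) / sig**2
            g[lay.offsets[values_name]] += -v / sig**2
            g[lay.offsets[ls_name]] += -v.size + np.sum(v**2) / sig**2

        def prior(coord_name, prior_name):
            nonlocal lp
            c = lay.get(x, coord_name)
            val, dv = pri.logpdf_grad(prior_name, c, coord_name.startswith("log_"))
            lp += val
            g[lay.offsets[coord_name]] += dv

        hier("alpha1_sp", "mu_alpha1", "log_sigma_alpha1")
        hier("alpha4_sp", "mu_alpha4", "log_sigma_alpha4")
        zero_mean("alpha2_site", "log_sigma_alpha2")
        prior("mu_alpha1", "mu_alpha1")
        prior("mu_alpha4", "mu_alpha4")
        prior("alpha3", "alpha3")
        prior("log_sigma_alpha1", "sigma_alpha1")
        prior("log_sigma_alpha2", "sigma_alpha2")
        prior("log_sigma_alpha4", "sigma_alpha4")
        if self.abundance_dist == "nb":
            prior("log_phi", "phi")
        if self.kind != "glmm":
            hier("beta1_sp", "mu_beta1", "log_sigma_beta1")
            hier("beta4_sp", "mu_beta4", "log_sigma_beta4")
            zero_mean("beta2_site", "log_sigma_beta2")
            prior("mu_beta1", "mu_beta1")
            prior("mu_beta4", "mu_beta4")
            prior("beta3", "beta3")
            prior("log_sigma_beta1", "sigma_beta1")
            prior("log_sigma_beta2", "sigma_beta2")
            prior("log_sigma_beta4", "sigma_beta4")
        return lp, g

    # -- initialization -----------------------------------------------------

    def init(self):
        lay = self.layout
        x0 = np.zeros(lay.n)
        for name in lay.offsets:
            if name.startswith("log_sigma"):
                x0[lay.offsets[name]] = np.log(0.3)
        if self.abundance_dist == "nb":
            x0[lay.offsets["log_phi"]] = np.log(10.0)

        if self.kind == "glmm":
            sp_mean = np.zeros(self.S)
            np.add.at(sp_mean, self.sp_idx, self.y)
            cnt = np.bincount(self.sp_idx, minlength=self.S)
            sp_mean = np.log(sp_mean / np.maximum(cnt, 1) + 0.05)
            p0 = None
        elif self.kind == "binmix":
            p0 = 0.3
            umax = self.Y.max(axis=1) / p0
            sp_mean = np.zeros(self.S)
            np.add.at(sp_mean, self.sp_idx, umax)
            cnt = np.bincount(self.sp_idx, minlength=self.S)
            sp_mean = np.log(sp_mean / np.maximum(cnt, 1) + 0.05)
        else:
            ones = np.array([c[1:].count("1") for c in history_columns(self.J)])
            D = float((self.T @ ones).sum())
            ntot = float(self.n.sum())
            p0 = self._solve_caps_per_obs(D / max(ntot, 1.0)) if ntot > 0 else 0.3
            q0 = 1.0 - (1.0 - p0) ** self.J
            nhat = self.n / max(q0, 1e-6)
            sp_mean = np.zeros(self.S)
            np.add.at(sp_mean, self.sp_idx, nhat)
            cnt = np.bincount(self.sp_idx, minlength=self.S)
            sp_mean = np.log(sp_mean / np.maximum(cnt, 1) + 0.05)

        x0[lay.offsets["alpha1_sp"]] = sp_mean
        x0[lay.offsets["mu_alpha1"]] = sp_mean.mean()
        if self.kind != "glmm":
            lp0 = float(logit(np.clip(p0, 1e-3, 1 - 1e-3)))
            x0[lay.offsets["mu_beta1"]] = lp0
            x0[lay.offsets["beta1_sp"]] = lp0
        return x0

    def _solve_caps_per_obs(self, captures_per_observed):
        """Moment init for p from mean captures per observed individual:
        E[captures | observed] = J p / (1 - (1-p)^J)."""
        from scipy.optimize import brentq

        J = self.J
        target = float(np.clip(captures_per_observed, 1.0 + 1e-6, J - 1e-6))

        def f(p):
            return J * p / (1.0 - (1.0 - p) ** J) - target

        try:
            return brentq(f, 1e-6, 1 - 1e-9)
        except ValueError:
            return 0.3

    # -- replicate simulation (for posterior predictive checks) -------------

    def simulate_replicate(self, x, rng):
        log_lam, logit_p = self.predictors(x)
        lam = np.exp(np.clip(log_lam, -30, 25))
        phi = self.phi(x)

        def draw_nb(lam_):
            if phi is None:
                return rng.poisson(lam_)
            return rng.poisson(rng.gamma(phi, lam_ / phi))

        if self.kind == "glmm":
            return draw_nb(lam)
        p = expit(logit_p)
        N = draw_nb(lam)
        if self.kind == "binmix":
            return rng.binomial(N[:, None], p[:, None], size=(len(N), self.J))
        cells = np.zeros((len(N), 2**self.J))
        for u in range(len(N)):
            cp = history_cell_probs(float(p[u]), self.J)
            probs = np.append(cp.pi_obs, cp.pi0)
            cells[u] = rng.multinomial(N[u], probs)
        return cells[:, : 2**self.J - 1].astype(np.int64)

    def statistic(self, rep, name):
        if name == "total_count":
            if self.kind == "multimix":
                ones = np.array([c[1:].count("1") for c in history_columns(self.J)])
                return float((rep @ ones).sum())
            return float(np.sum(rep))
        if name == "var_mean":
            v = rep.sum(axis=1) if (self.kind == "multimix" and rep.ndim == 2) else np.ravel(rep)
            m = v.mean()
            return float(v.var(ddof=1) / m) if m > 0 else 0.0
        raise ValueError(f"unknown statistic {name!r}")

    def observed_statistic(self, name):
        obs = {"glmm": lambda: self.y, "binmix": lambda: self.Y, "multimix": lambda: self.T}[
            self.kind
        ]()
        return self.statistic(obs, name)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class PosteriorResult:
    """Draws, diagnostics and metadata for one model fit."""

    model_kind: str
    mode: str
    draws: pd.DataFrame
    diagnostics: pd.DataFrame
    converged: bool
    mixing_ok: bool
    flags: list
    divergences: int
    n_chains: int
    n_iterations: int
    n_warmup: int
    seed: int
    data_hash: str
    map_estimate: dict | None = None
    _core: "_Core | None" = field(default=None, repr=False, compare=False)

    @property
    def ok(self) -> bool:
        return self.converged and self.mixing_ok and self.divergences == 0

    def summary(self, credible_levels=(0.5, 0.9)) -> pd.DataFrame:
        return summarize(self, credible_levels)

    def save(self, prefix) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.draws.to_csv(f"{prefix}_draws.csv", index=False)
        payload = {
            "model_kind": self.model_kind,
            "mode": self.mode,
            "converged": bool(self.converged),
            "mixing_ok": bool(self.mixing_ok),
            "flags": list(self.flags),
            "divergences": int(self.divergences),
            "n_chains": int(self.n_chains),
            "seed": int(self.seed),
            "data_hash": self.data_hash,
            "summary": json.loads(self.summary().to_json(orient="index")),
        }
        with open(f"{prefix}_summary.json", "w") as fh:
            json.dump(payload, fh, indent=2)


def summarize(result, credible_levels=(0.5, 0.9), transform=None) -> pd.DataFrame:
    """Mean and central credible intervals per parameter.

    ``transform`` optionally maps parameter name -> callable applied to the
    draws before summarizing (e.g. ``np.exp`` for count-scale summaries,
    ``scipy.special.expit`` for probability-scale ones); transforms are
    applied per draw, then summarized, which is the correct order for
    nonlinear maps.
    """
    draws = result.draws if hasattr(result, "draws") else result
    levels = sorted(set(credible_levels))
    rows = {}
    for col in draws.columns:
        v = draws[col].to_numpy(dtype=float)
        if transform and col in transform:
            v = transform[col](v)
        row = {"mean": float(np.mean(v))}
        for lev in levels:
            lo, hi = np.quantile(v, [(1 - lev) / 2, 1 - (1 - lev) / 2])
            row[f"lo{int(round(100 * lev))}"] = float(lo)
            row[f"hi{int(round(100 * lev))}"] = float(hi)
        rows[col] = row
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# MAP + Laplace
# ---------------------------------------------------------------------------


def _hessian_fd(fun_grad, x, lb, ub):
    _, g0 = fun_grad(x)
    d = len(x)
    H = np.empty((d, d))
    for k in range(d):
        h = 1e-5 * (1.0 + abs(x[k]))
        step = h if x[k] + h <= ub[k] else -h
        xk = x.copy()
        xk[k] += step
        _, gk = fun_grad(xk)
        H[:, k] = (gk - g0) / step
    return 0.5 * (H + H.T)


def _laplace_draws(xhat, H, free, n_draws, rng):
    d = len(xhat)
    draws = np.tile(xhat, (n_draws, 1))
    idx = np.flatnonzero(free)
    if idx.size == 0:
        return draws
    Hf = H[np.ix_(idx, idx)]
    scale = max(float(np.mean(np.abs(np.diag(Hf)))), 1e-12)
    L = None
    for ridge in (0.0, 1e-8, 1e-6, 1e-4, 1e-2, 1.0):
        try:
            L = np.linalg.cholesky(Hf + ridge * scale * np.eye(idx.size))
            break
        except np.linalg.LinAlgError:
            continue
    if L is None:  # pathological curvature: fall back to diagonal
        diag = np.maximum(np.abs(np.diag(Hf)), 1e-8)
        L = np.diag(np.sqrt(diag))
    z = rng.standard_normal((n_draws, idx.size))
    # cov = H^-1 = (L L^T)^-1, so draws = xhat + L^-T z
    delta = np.linalg.solve(L.T, z.T).T
    draws[:, idx] += delta
    return draws


def _sigma_blocks(core):
    """(dev-values name, hyper-mean name or None, log-sigma name) triples."""
    blocks = [
        ("alpha1_sp", "mu_alpha1", "log_sigma_alpha1"),
        ("alpha4_sp", "mu_alpha4", "log_sigma_alpha4"),
        ("alpha2_site", None, "log_sigma_alpha2"),
    ]
    if core.kind != "glmm":
        blocks += [
            ("beta1_sp", "mu_beta1", "log_sigma_beta1"),
            ("beta4_sp", "mu_beta4", "log_sigma_beta4"),
            ("beta2_site", None, "log_sigma_beta2"),
        ]
    return blocks


def _diag_curvature(fun_grad, x, idxs, ub):
    """Diagonal Hessian entries H_kk for selected coordinates (forward
    differences of the analytic gradient)."""
    _, g0 = fun_grad(x)
    out = np.empty(len(idxs))
    for j, k in enumerate(idxs):
        h = 1e-5 * (1.0 + abs(x[k]))
        step = h if x[k] + h <= ub[k] else -h
        xk = x.copy()
        xk[k] += step
        _, gk = fun_grad(xk)
        out[j] = (gk[k] - g0[k]) / step
    return out


def _update_sigma(values, mu, cond_var, s0, t_lo, t_hi):
    """Closed-form conditional-mode update of a random-effect variance.

    Maximizes -S log(sigma) - A/(2 sigma^2) - sigma^2/(2 s0^2) + log(sigma)
    (half-normal(s0) prior plus the log-scale Jacobian) where
    A = sum((v - mu)^2 + conditional posterior variance of v): the Laplace
    E-step of an EM iteration for the marginal mode of sigma. This sidesteps
    the funnel degeneracy of joint optimization, where the density diverges
    as sigma -> 0 with the deviations fully pooled.
    """
    S = values.size
    A = float(np.sum((values - mu) ** 2 + cond_var))
    disc = (S - 1) ** 2 + 4 * A / s0**2
    t = 0.5 * s0**2 * (-(S - 1) + np.sqrt(disc))
    return float(np.clip(t, t_lo, t_hi))


def _fit_map(core, config):
    ss = np.random.SeedSequence(config.seed)
    s_draws = np.random.default_rng(ss.spawn(1)[0])
    lay = core.layout
    lb = np.asarray(lay.lb)
    ub = np.asarray(lay.ub)
    x = core.init()

    blocks = _sigma_blocks(core)
    sigma_idx = np.array([lay.offsets[ls].start for _, _, ls in blocks])
    dev_idx = np.concatenate(
        [np.arange(lay.offsets[v].start, lay.offsets[v].stop) for v, _, _ in blocks]
    )
    t_lo, t_hi = np.exp(2 * LOG_SIGMA_BOUNDS[0]), np.exp(2 * LOG_SIGMA_BOUNDS[1])

    def optimize(x0, ftol=2.2e-9):
        # random-effect SDs held fixed (their coordinates get equal bounds);
        # they are updated by the EM step below, never by the optimizer
        b = list(zip(lb, ub))
        for k in sigma_idx:
            b[k] = (x0[k], x0[k])
        return minimize(
            core.neg_log_post,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=b,
            options={
                "maxiter": config.max_opt_iter,
                "maxfun": 4 * config.max_opt_iter,
                "ftol": ftol,
                    "maxcor": 25,
            },
        )

    res = optimize(x, ftol=1e-7)
    for _ in range(4):
        x = res.x
        curv = _diag_curvature(core.neg_log_post, x, dev_idx, ub)
        cond_var = 1.0 / np.clip(curv, 1e-8, np.inf)
        pos = 0
        delta = 0.0
        for vals_name, mu_name, ls_name in blocks:
            sl = lay.offsets[vals_name]
            size = sl.stop - sl.start
            mu = lay.get(x, mu_name) if mu_name else 0.0
            spec = core.priors.get(ls_name.replace("log_", ""))
            s0 = float(spec[-1]) if spec[0] == "half_normal" else 1.0
            t = _update_sigma(
                x[sl], mu, cond_var[pos : pos + size], s0, t_lo, t_hi
            )
            k = lay.offsets[ls_name].start
            delta = max(delta, abs(0.5 * np.log(t) - x[k]))
            x[k] = 0.5 * np.log(t)
            pos += size
        if delta < 5e-3:
            break
        res = optimize(x, ftol=1e-7)
    res = optimize(x)
    xhat = res.x
    gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    converged = bool(res.success or gnorm < 5e-2)
    H = _hessian_fd(core.neg_log_post, xhat, lb, ub)
    at_bound = (xhat - lb < 1e-6) | (ub - xhat < 1e-6)
    free = ~at_bound
    # SDs are empirical-Bayes point estimates: fixed in the Laplace draws
    free[sigma_idx] = False
    draws = _laplace_draws(xhat, H, free, config.map_draws, s_draws)
    names = core.flat_names()
    draws_df = pd.DataFrame(draws, columns=names)
    diagnostics = pd.DataFrame(
        {"rhat": np.nan, "ess_ratio": np.nan}, index=names
    )
    flags = ["deterministic_map"]
    if not converged:
        flags.append("optimizer_not_converged")
    result = PosteriorResult(
        model_kind=core.kind,
        mode="map",
        draws=draws_df,
        diagnostics=diagnostics,
        converged=converged,
        mixing_ok=True,
        flags=flags,
        divergences=0,
        n_chains=1,
        n_iterations=int(res.nit),
        n_warmup=0,
        seed=config.seed,
        data_hash=core.data_hash,
        map_estimate=dict(zip(names, xhat)),
        _core=core,
    )
    return result


# ---------------------------------------------------------------------------
# emcee MCMC
# ---------------------------------------------------------------------------


def _fit_mcmc(core, config):
    import emcee

    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(2)
    rng = np.random.default_rng(child[0])
    # initialize at a short MAP run
    map_cfg = replace(config, mode="map", max_opt_iter=300)
    map_res = _fit_map(core, map_cfg)
    xhat = np.array([map_res.map_estimate[k] for k in core.flat_names()])
    ndim = core.layout.n
    nwalkers = max(2 * ndim + 2, 2 * config.n_chains)
    nwalkers += nwalkers % 2
    lb = np.asarray(core.layout.lb)
    ub = np.asarray(core.layout.ub)
    p0 = xhat + 1e-3 * rng.standard_normal((nwalkers, ndim))
    p0 = np.clip(p0, lb + 1e-6, ub - 1e-6)

    def log_prob(x):
        if np.any(x < lb) or np.any(x > ub):
            return -np.inf
        v = core.neg_log_post(x, return_grad=False)
        return -v if np.isfinite(v) else -np.inf

    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob)
    sampler.random_state = np.random.RandomState(
        int(child[1].generate_state(1)[0]) % (2**31)
    ).get_state()
    sampler.run_mcmc(p0, config.n_iterations, progress=False)
    chain = sampler.get_chain()  # (steps, walkers, ndim)
    kept = chain[config.n_warmup :]
    n_kept = kept.shape[0]

    import arviz as az

    names = core.flat_names()
    posterior = {
        name: kept[:, :, k].T for k, name in enumerate(names)
    }  # (chain=walker, draw)
    idata = az.from_dict(posterior=posterior)
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    total = n_kept * nwalkers
    rhat = np.array([float(rhat_ds[name]) for name in names])
    ess_ratio = np.array([float(ess_ds[name]) / total for name in names])
    diagnostics = pd.DataFrame({"rhat": rhat, "ess_ratio": ess_ratio}, index=names)
    mixing_ok = bool(
        np.all(rhat < config.rhat_threshold)
        and np.all(ess_ratio > config.ess_ratio_threshold)
    )
    flags = [] if mixing_ok else ["non_mixing"]
    draws = kept.transpose(1, 0, 2).reshape(-1, ndim)
    result = PosteriorResult(
        model_kind=core.kind,
        mode="mcmc",
        draws=pd.DataFrame(draws, columns=names),
        diagnostics=diagnostics,
        converged=True,
        mixing_ok=mixing_ok,
        flags=flags,
        divergences=0,
        n_chains=nwalkers,
        n_iterations=config.n_iterations,
        n_warmup=config.n_warmup,
        seed=config.seed,
        data_hash=core.data_hash,
        map_estimate=map_res.map_estimate,
        _core=core,
    )
    return result


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def fit(
    model_kind: str,
    data,
    priors: PriorSpec | None = None,
    config: EngineConfig | None = None,
    abundance_dist: str = "nb",
    k_rule: KRule | None = None,
) -> PosteriorResult:
    """Fit one of the three models to a CountTable or HistoryTable."""
    config = config or EngineConfig()
    core = _Core(model_kind, data, abundance_dist, priors, k_rule)
    if config.mode == "map":
        return _fit_map(core, config)
    return _fit_mcmc(core, config)


@dataclass(frozen=True)
class PPCSummary:
    """Posterior predictive check result for one discrepancy statistic."""

    statistic: str
    observed: float
    replicated: np.ndarray
    p_value: float
    n_draws: int
    seed: int


def posterior_predictive_check(
    result: PosteriorResult,
    data=None,
    statistic: str = "total_count",
    n_draws: int | None = None,
    seed: int | None = None,
) -> PPCSummary:
    """Simulate replicate datasets from posterior draws and compare a
    discrepancy statistic with the observed value.

    Returns the Bayesian p-value: the fraction of replicates whose statistic
    exceeds the observed one (ties counted half).
    """
    core = result._core
    if core is None:
        raise ValueError("result does not carry fitted model internals")
    n_avail = len(result.draws)
    if n_avail < 100:
        raise ValueError("posterior predictive check requires >= 100 draws")
    n_draws = min(n_draws or 200, n_avail)
    seed = result.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence((seed, 9281)))
    names = core.flat_names()
    X = result.draws[names].to_numpy()
    idx = np.linspace(0, n_avail - 1, n_draws).astype(int)
    obs = core.observed_statistic(statistic)
    reps = np.empty(n_draws)
    for r, k in enumerate(idx):
        rep = core.simulate_replicate(X[k], rng)
        reps[r] = core.statistic(rep, statistic)
    p = float((np.sum(reps > obs) + 0.5 * np.sum(reps == obs)) / n_draws)
    return PPCSummary(
        statistic=statistic,
        observed=obs,
        replicated=reps,
        p_value=p,
        n_draws=n_draws,
        seed=seed,
    )
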