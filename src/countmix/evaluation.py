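"""Simulation-evaluation protocol: bias and precision of effect estimates.

Three experiments, each a grid of generating scenarios:

* detection grid — varies the community detection intercept (mu_beta1) and
  the effect of restoration on detection (mu_beta4) with closure holding;
* sites grid — varies the number of study sites at fixed detection
  intercept;
* closure grid — varies the availability intercept (theta0) and the effect
  of restoration on availability (theta1), the closure-violation process.

For every scenario cell and model, ``n_replicates`` datasets are simulated,
the model is fitted, and a fixed number of posterior draws of each target
parameter is pooled across replicates. Bias draws are (draw - truth); a
cell reports their mean, central 90% interval, and precision = 1 / sample
SD (n-1 denominator) of the pooled draws.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import SurveyDesign
from .inference import EngineConfig, PriorSpec
from .models import make_model
from .params import AbundanceParams, AvailabilityParams, DetectionParams
from .simulate import simulate_dataset

logger = logging.getLogger(__name__)

TRUE_RESTORATION_EFFECT = 1.0


@dataclass(frozen=True)
class BiasPrecision:
    mean_bias: float
    bias_lo90: float
    bias_hi90: float
    precision: float
    degenerate: bool
    n_draws: int


def bias_precision(pooled_draws, true_value: float) -> BiasPrecision:
    """Mean bias, central 90% bias interval and precision of pooled draws.

    Precision is the reciprocal of the sample SD (n-1 denominator) of the
    pooled posterior draws; a zero-SD pool is flagged degenerate and gets an
    infinite precision sentinel.
    """
    draws = np.asarray(pooled_draws, dtype=float)
    if draws.size < 2:
        raise ValueError("need at least 2 draws")
    bias = draws - true_value
    sd = float(np.std(draws, ddof=1))
    degenerate = sd == 0.0
    lo, hi = np.quantile(bias, [0.05, 0.95])
    return BiasPrecision(
        mean_bias=float(bias.mean()),
        bias_lo90=float(lo),
        bias_hi90=float(hi),
        precision=np.inf if degenerate else 1.0 / sd,
        degenerate=degenerate,
        n_draws=draws.size,
    )


@dataclass(frozen=True)
class ScenarioGrid:
    """One simulation experiment: scenario cells x models x replicates."""

    cells: list  # list of dicts with scenario parameters
    models: tuple = ("glmm", "binmix", "multimix")
    targets: tuple = ("mu_alpha4",)
    n_replicates: int = 20
    n_posterior_samples: int = 250
    n_species: int = 16
    n_years: int = 2
    n_surveys: int = 3

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


#: Default simulation conditions not varied by any grid: realized
#: species/site heterogeneity and year effects (community SDs and the year
#: shifts are not part of the scenario grids).
DEFAULT_SIM = dict(
    sigma_alpha1=0.5,
    sigma_alpha2=0.25,
    sigma_alpha4=0.25,
    alpha3=0.25,
    sigma_beta1=0.5,
    sigma_beta2=0.25,
    sigma_beta4=0.0,
    beta3=0.25,
)

def _cell_params(cell: dict):
    ap = AbundanceParams(
        mu_alpha1=cell.get("mu_alpha1", 2.0),
        sigma_alpha1=DEFAULT_SIM["sigma_alpha1"],
        sigma_alpha2=DEFAULT_SIM["sigma_alpha2"],
        alpha3=DEFAULT_SIM["alpha3"],
        mu_alpha4=cell.get("mu_alpha4", TRUE_RESTORATION_EFFECT),
        sigma_alpha4=DEFAULT_SIM["sigma_alpha4"],
        phi="poisson",
    )
    dp = DetectionParams(
        mu_beta1=cell.get("mu_beta1", -2.0),
        sigma_beta1=DEFAULT_SIM["sigma_beta1"],
        sigma_beta2=DEFAULT_SIM["sigma_beta2"],
        beta3=DEFAULT_SIM["beta3"],
        mu_beta4=cell.get("mu_beta4", 0.0),
        sigma_beta4=DEFAULT_SIM["sigma_beta4"],
    )
    av = None
    if "theta0" in cell or "theta1" in cell:
        av = AvailabilityParams(
            theta0=cell.get("theta0", 0.0), theta1=cell.get("theta1", 0.0)
        )
    return ap, dp, av


def run_grid(grid: ScenarioGrid, config: EngineConfig | None = None,
             priors: PriorSpec | None = None, seed: int = 0,
             k_rule=None) -> pd.DataFrame:
    """Run every (cell, model) combination and return a long results table.

    Columns: the cell's scenario parameters, model, target, true_value,
    mean_bias, bias_lo90, bias_hi90, precision, n_fits_used, n_fits_failed,
    n_draws.
    """
    config = config or EngineConfig()
    rows = []
    for ci, cell in enumerate(grid.cells):
        ap, dp, av = _cell_params(cell)
        design = SurveyDesign(
            n_sites=int(cell.get("n_sites", 20)),
            n_species=grid.n_species,
            n_years=grid.n_years,
            n_surveys=grid.n_surveys,
        )
        pooled = {(m, t): [] for m in grid.models for t in grid.targets}
        failed = {m: 0 for m in grid.models}
        for r in range(grid.n_replicates):
            rep_seed = int(
                np.random.SeedSequence([seed, ci, r]).generate_state(1)[0] % 2**31
            )
            ds = simulate_dataset(design, ap, dp, av, seed=rep_seed)
            for m in grid.models:
                data = ds.histories if m == "multimix" else ds.counts
                model = make_model(
                    m,
                    priors=priors,
                    mode=config.mode,
                    n_iterations=config.n_iterations,
                    n_warmup=config.n_warmup,
                    n_chains=config.n_chains,
                    map_draws=max(config.map_draws, grid.n_posterior_samples),
                    max_opt_iter=config.max_opt_iter,
                    k_rule=k_rule,
                    seed=rep_seed,
                )
                try:
                    model.fit(data)
                except Exception as exc:  # pragma: no cover - defensive
                    logger.warning("fit failed (%s, cell %d, rep %d): %s", m, ci, r, exc)
                    failed[m] += 1
                    continue
                if not model.result_.ok:
                    logger.info(
                        "fit flagged (%s, cell %d, rep %d): %s",
                        m, ci, r, model.result_.flags,
                    )
                    failed[m] += 1
                    continue
                for t in grid.targets:
                    pooled[(m, t)].append(
                        model.draws_[t].to_numpy()[: grid.n_posterior_samples]
                    )
        for m in grid.models:
            for t in grid.targets:
                chunks = pooled[(m, t)]
                if not chunks:
                    continue
                draws = np.concatenate(chunks)
                truth = float(
                    cell.get(t, TRUE_RESTORATION_EFFECT if t == "mu_alpha4" else 0.0)
                )
                bp = bias_precision(draws, truth)
                rows.append(
                    {
                        **cell,
                        "model": m,
                        "target": t,
                        "true_value": truth,
                        "mean_bias": bp.mean_bias,
                        "bias_lo90": bp.bias_lo90,
                        "bias_hi90": bp.bias_hi90,
                        "precision": bp.precision,
                        "n_fits_used": len(chunks),
                        "n_fits_failed": failed[m],
                        "n_draws": bp.n_draws,
                    }
                )
    return pd.DataFrame(rows)


def detection_grid(
    mu_beta1_values=(-3.0, -2.0, -1.0, 0.0),
    mu_beta4_values=(-0.5, 0.0, 0.5, 1.0),
    abundance_intercept=2.0,
    models=("glmm", "binmix", "multimix"),
    n_replicates=20,
    n_sites=20,
) -> ScenarioGrid:
    """Baseline-detection experiment: abundance intercept fixed at 2."""
    cells = [
        {"mu_beta1": b1, "mu_beta4": b4, "mu_alpha1": abundance_intercept,
         "n_sites": n_sites}
        for b1, b4 in itertools.product(mu_beta1_values, mu_beta4_values)
    ]
    return ScenarioGrid(cells=cells, models=tuple(models), n_replicates=n_replicates)


def sites_grid(
    site_values=(10, 20, 30),
    mu_beta4_values=(-0.5, 0.0, 0.5, 1.0),
    mu_beta1=-2.0,
    abundance_intercept=2.0,
    models=("glmm", "binmix", "multimix"),
    n_replicates=20,
) -> ScenarioGrid:
    """Number-of-sites experiment: detection intercept fixed at -2."""
    cells = [
        {"n_sites": s, "mu_beta4": b4, "mu_beta1": mu_beta1,
         "mu_alpha1": abundance_intercept}
        for s, b4 in itertools.product(site_values, mu_beta4_values)
    ]
    return ScenarioGrid(cells=cells, models=tuple(models), n_replicates=n_replicates)


def closure_grid(
    theta0_values=(-1.0, 0.0, 1.0),
    theta1_values=(-1.0, 0.0, 1.0),
    abundance_intercept=3.0,
    mu_beta1=-2.0,
    models=("binmix", "multimix"),
    n_replicates=20,
) -> ScenarioGrid:
    """Closure-violation experiment: availability process active, abundance
    intercept 3, detection intercept -2, no detection confound; bias is
    tracked for both the abundance intercept and the restoration effect."""
    cells = [
        {"theta0": t0, "theta1": t1, "mu_alpha1": abundance_intercept,
         "mu_beta1": mu_beta1, "mu_beta4": 0.0}
        for t0, t1 in itertools.product(theta0_values, theta1_values)
    ]
    return ScenarioGrid(
        cells=cells,
        models=tuple(models),
        targets=("mu_alpha4", "mu_alpha1"),
        n_replicates=n_replicates,
    )


def run_detection_grid(config=None, seed=0, **kwargs) -> pd.DataFrame:
    return run_grid(detection_grid(**kwargs), config=config, seed=seed)


def run_sites_grid(config=None, seed=0, **kwargs) -> pd.DataFrame:
    return run_grid(sites_grid(**kwargs), config=config, seed=seed)


def run_closure_grid(config=None, seed=0, **kwargs) -> pd.DataFrame:
    return run_grid(closure_grid(**kwargs), config=config, seed=seed)


@dataclass(frozen=True)
class AbundanceSummary:
    control: float
    restored: float
    fold_change: float


def derived_abundance_summaries(intercept: float, effect: float) -> AbundanceSummary:
    """Expected counts implied by a log-scale intercept and treatment effect:
    exp(intercept) in control, exp(intercept + effect) in restored units and
    the fold change exp(effect)."""
    return AbundanceSummary(
        control=float(np.exp(intercept)),
        restored=float(np.exp(intercept + effect)),
        fold_change=float(np.exp(effect)),
    )


@dataclass(frozen=True)
class DetectionSummary:
    control: float
    restored: float
    fold_change: float


def derived_detection_summaries(intercept: float, effect: float) -> DetectionSummary:
    """Detection probabilities implied by logit-scale intercept and effect."""
    from scipy.special import expit

    pc = float(expit(intercept))
    pr = float(expit(intercept + effect))
    return DetectionSummary(control=pc, restored=pr, fold_change=pr / pc)
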