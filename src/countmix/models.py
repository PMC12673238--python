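"""Estimator classes for the three abundance models.

These follow the scikit-learn estimator protocol: constructor parameters are
stored verbatim, ``fit`` returns ``self`` and populates trailing-underscore
attributes, and ``get_params`` / ``set_params`` come from
:class:`sklearn.base.BaseEstimator`, so the models compose with sklearn
pipelines and model-selection utilities. ``fit`` accepts the package's tidy
tables (a CountTable for count-based models, a HistoryTable for the
mark-recapture mixture).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .inference import (
    EngineConfig,
    PriorSpec,
    _Core,
    _fit_map,
    _fit_mcmc,
    posterior_predictive_check,
)
from .likelihoods import KRule


class _BaseCountModel(BaseEstimator):
    """Shared fitting machinery; subclasses set ``model_kind``."""

    model_kind: str = ""

    def __init__(
        self,
        abundance_dist="nb",
        priors=None,
        mode="map",
        n_iterations=4000,
        n_warmup=2000,
        n_chains=4,
        map_draws=250,
        max_opt_iter=1500,
        rhat_threshold=1.05,
        ess_ratio_threshold=0.1,
        k_rule=None,
        seed=0,
    ):
        self.abundance_dist = abundance_dist
        self.priors = priors
        self.mode = mode
        self.n_iterations = n_iterations
        self.n_warmup = n_warmup
        self.n_chains = n_chains
        self.map_draws = map_draws
        self.max_opt_iter = max_opt_iter
        self.rhat_threshold = rhat_threshold
        self.ess_ratio_threshold = ess_ratio_threshold
        self.k_rule = k_rule
        self.seed = seed

    def _config(self) -> EngineConfig:
        return EngineConfig(
            n_iterations=self.n_iterations,
            n_warmup=self.n_warmup,
            n_chains=self.n_chains,
            rhat_threshold=self.rhat_threshold,
            ess_ratio_threshold=self.ess_ratio_threshold,
            mode=self.mode,
            seed=self.seed,
            map_draws=self.map_draws,
            max_opt_iter=self.max_opt_iter,
        )

    def fit(self, X, y=None):
        """Fit the model to a data table (ignores ``y``; sklearn signature)."""
        priors = self.priors if isinstance(self.priors, PriorSpec) else (
            PriorSpec.from_dict(self.priors) if self.priors else None
        )
        k_rule = self.k_rule if isinstance(self.k_rule, (KRule, type(None))) else KRule(*self.k_rule)
        core = _Core(self.model_kind, X, self.abundance_dist, priors, k_rule)
        config = self._config()
        result = _fit_map(core, config) if config.mode == "map" else _fit_mcmc(core, config)
        self.result_ = result
        self.draws_ = result.draws
        self.summary_ = result.summary()
        self.diagnostics_ = result.diagnostics
        self.map_estimate_ = result.map_estimate
        self.converged_ = result.converged
        self.n_units_ = core.n_rows
        self._core_ = core
        return self

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise AttributeError("model is not fitted; call fit(data) first")

    def predict(self, X=None) -> np.ndarray:
        """Posterior-mean expected abundance lambda per unit of the training
        table (the per-draw exp of the abundance predictor, averaged)."""
        self._check_fitted()
        core = self._core_
        draws = self.result_.draws[core.flat_names()].to_numpy()
        out = np.zeros(core.n_rows)
        for x in draws:
            log_lam, _ = core.predictors(x)
            out += np.exp(np.clip(log_lam, -30, 25))
        return out / len(draws)

    def posterior_predictive_check(self, statistic="total_count", n_draws=None, seed=None):
        self._check_fitted()
        return posterior_predictive_check(
            self.result_, statistic=statistic, n_draws=n_draws, seed=seed
        )


class NegBinGLMM(_BaseCountModel):
    """Negative-binomial GLMM: each per-survey count is an independent NB
    draw with log-linear mean; detection is not modelled, so covariate
    effects on detection are absorbed into the abundance coefficients."""

    model_kind = "glmm"


class BinMixModel(_BaseCountModel):
    """Binomial N-mixture model ("binmix"): latent abundance N per unit with
    NB (or Poisson) prior, repeated counts Binomial(N, p), N marginalized."""

    model_kind = "binmix"


class MultiMixModel(_BaseCountModel):
    """Multinomial mark-recapture mixture ("multimix"): detection-history
    tallies are multinomial conditional on the number observed, which is a
    marginalized Binomial(N, 1 - pi0) draw."""

    model_kind = "multimix"


_MODEL_CLASSES = {
    "glmm": NegBinGLMM,
    "binmix": BinMixModel,
    "multimix": MultiMixModel,
}


def make_model(model_kind: str, **kwargs) -> _BaseCountModel:
    """Instantiate an estimator by model kind string."""
    try:
        cls = _MODEL_CLASSES[model_kind]
    except KeyError:
        raise ValueError(
            f"unknown model kind {model_kind!r}; expected one of {sorted(_MODEL_CLASSES)}"
        ) from None
    return cls(**kwargs)
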