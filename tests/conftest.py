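import numpy as np
import pandas as pd
import pytest

import countmix as cm


@pytest.fixture(scope="session")
def small_dataset():
    """Small mixed-count dataset with moderate detection, closure holding."""
    design = cm.SurveyDesign(n_sites=6, n_species=4, n_years=2, n_surveys=3)
    ap = cm.AbundanceParams(mu_alpha1=1.5)
    dp = cm.DetectionParams(mu_beta1=-0.5)
    return cm.simulate_dataset(design, ap, dp, seed=1)


@pytest.fixture(scope="session")
def unit_predictors(small_dataset):
    """Per-unit (lambda, p) implied by the small dataset's generating truth
    evaluated at phi = 2."""
    from scipy.special import expit

    ap = cm.AbundanceParams(mu_alpha1=1.5, phi=2.0)
    dp = small_dataset.detection
    units = small_dataset.histories[["site", "species", "year", "restored"]]
    log_lam, logit_p = cm.linear_predictors(units, ap, dp, small_dataset.effects)
    return np.exp(log_lam), expit(logit_p)


def simulate_glmm_counts(design, ap, dp, phi, seed):
    """Counts drawn from the GLMM's own generative process: independent NB
    (or Poisson) draws per survey, sharing the unit mean."""
    ss = np.random.SeedSequence(seed)
    s_eff, s_y = ss.spawn(2)
    effects = cm.draw_random_effects(design, ap, dp, s_eff)
    units = design.units()
    log_lam, _ = cm.linear_predictors(units, ap, None, effects)
    lam = np.exp(log_lam)
    rng = np.random.default_rng(s_y)
    frames = []
    for j in range(design.n_surveys):
        f = units.copy()
        f["survey"] = j
        if phi is None:
            f["count"] = rng.poisson(lam)
        else:
            f["count"] = rng.poisson(rng.gamma(phi, lam / phi))
        frames.append(f)
    return pd.concat(frames, ignore_index=True), effects
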