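"""Generator behaviour: random effects, abundance, detection histories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import countmix as cm
from countmix.simulate import (
    collapse_histories_to_counts,
    simulate_individuals,
    tally_histories,
)


def test_design_validation_and_treatment_balance():
    d = cm.SurveyDesign(n_sites=10, n_species=3)
    assert sum(d.restored) == 5
    assert d.units().shape[0] == 10 * 3 * 2
    with pytest.raises(ValueError):
        cm.SurveyDesign(n_sites=0, n_species=3)
    with pytest.raises(ValueError):
        cm.SurveyDesign(n_sites=4, n_species=3, restored=(1, 0, 1))  # wrong length
    with pytest.raises(ValueError):
        cm.AbundanceParams(sigma_alpha1=-0.1)
    with pytest.raises(ValueError):
        cm.AbundanceParams(phi=-2.0)


def test_zero_variance_effects_collapse_to_means():
    d = cm.SurveyDesign(n_sites=4, n_species=5)
    ap = cm.AbundanceParams(mu_alpha1=0.7, sigma_alpha1=0.0, sigma_alpha2=0.0,
                            mu_alpha4=0.3, sigma_alpha4=0.0)
    dp = cm.DetectionParams(mu_beta1=-1.2, sigma_beta1=0.0, sigma_beta2=0.0,
                            sigma_beta4=0.0)
    eff = cm.draw_random_effects(d, ap, dp, seed=0)
    assert np.allclose(eff.species["alpha1"], 0.7)
    assert np.allclose(eff.species["alpha4"], 0.3)
    assert np.allclose(eff.species["beta1"], -1.2)
    assert np.allclose(eff.sites["alpha2"], 0.0)


def test_effects_deterministic_and_lln_sd():
    d = cm.SurveyDesign(n_sites=3, n_species=10_000)
    ap = cm.AbundanceParams(sigma_alpha1=1.0)
    dp = cm.DetectionParams()
    e1 = cm.draw_random_effects(d, ap, dp, seed=42)
    e2 = cm.draw_random_effects(d, ap, dp, seed=42)
    pd.testing.assert_frame_equal(e1.species, e2.species)
    pd.testing.assert_frame_equal(e1.sites, e2.sites)
    sd = e1.species["alpha1"].std()
    assert 0.95 < sd < 1.05


def test_abundance_identity_predictor_and_log_link():
    # all effects zero, intercept 0 -> lambda = 1 everywhere
    d = cm.SurveyDesign(n_sites=100, n_species=100, n_years=1)
    ap = cm.AbundanceParams(mu_alpha1=0.0, sigma_alpha1=0.0, sigma_alpha2=0.0,
                            alpha3=0.0, mu_alpha4=0.0, sigma_alpha4=0.0)
    dp = cm.DetectionParams()
    eff = cm.draw_random_effects(d, ap, dp, seed=0)
    N = cm.simulate_abundance(d, ap, eff, seed=1)
    assert 0.95 < N.mean() < 1.05

    # intercept 2 -> mean approx exp(2)
    ap2 = cm.AbundanceParams(mu_alpha1=2.0, sigma_alpha1=0.0, sigma_alpha2=0.0,
                             alpha3=0.0, mu_alpha4=0.0, sigma_alpha4=0.0)
    eff2 = cm.draw_random_effects(d, ap2, dp, seed=0)
    N2 = cm.simulate_abundance(d, ap2, eff2, seed=1)
    assert abs(N2.mean() - np.exp(2)) < 0.1

    # restoration effect 1 -> lambda ratio e between restored and control
    ap3 = cm.AbundanceParams(mu_alpha1=1.0, sigma_alpha1=0.0, sigma_alpha2=0.0,
                             alpha3=0.0, mu_alpha4=1.0, sigma_alpha4=0.0)
    eff3 = cm.draw_random_effects(d, ap3, dp, seed=0)
    units = d.units()
    log_lam, _ = cm.linear_predictors(units, ap3, None, eff3)
    lam = np.exp(log_lam)
    r = units["restored"].to_numpy().astype(bool)
    assert np.isclose(lam[r].mean() / lam[~r].mean(), np.e)


def test_abundance_overflow_guard():
    d = cm.SurveyDesign(n_sites=2, n_species=2, n_years=1)
    ap = cm.AbundanceParams(mu_alpha1=25.0, sigma_alpha1=0.0, sigma_alpha2=0.0,
                            alpha3=0.0, sigma_alpha4=0.0)
    dp = cm.DetectionParams()
    eff = cm.draw_random_effects(d, ap, dp, seed=0)
    with pytest.raises(ValueError, match="implausible"):
        cm.simulate_abundance(d, ap, eff, seed=0)


def _degenerate_effects(d, ap, dp):
    return cm.draw_random_effects(d, ap, dp, seed=0)


def test_perfect_detection_gives_full_histories():
    d = cm.SurveyDesign(n_sites=4, n_species=2, n_years=1)
    ap = cm.AbundanceParams(mu_alpha1=2.0, sigma_alpha1=0.0, sigma_alpha2=0.0,
                            alpha3=0.0, sigma_alpha4=0.0)
    dp = cm.DetectionParams(mu_beta1=40.0, sigma_beta1=0.0, sigma_beta2=0.0,
                            beta3=0.0, sigma_beta4=0.0)  # p = 1 numerically
    eff = _degenerate_effects(d, ap, dp)
    N = cm.simulate_abundance(d, ap, eff, seed=3)
    hist, counts = cm.simulate_histories(N, d, dp, None, eff, seed=4)
    assert (hist["h111"] == N).all()
    assert (hist["n"] == N).all()
    other = [c for c in hist.columns if c.startswith("h") and c != "h111"]
    assert (hist[other].to_numpy() == 0).all()
    wide = counts.pivot_table(index=["site", "species", "year"], columns="survey",
                              values="count")
    assert (wide.to_numpy() == N[:, None]).all()


def test_zero_detection_gives_empty_tables():
    d = cm.SurveyDesign(n_sites=3, n_species=2, n_years=1)
    ap = cm.AbundanceParams(mu_alpha1=2.0)
    dp = cm.DetectionParams(mu_beta1=-40.0, sigma_beta1=0.0, sigma_beta2=0.0,
                            beta3=0.0)
    eff = _degenerate_effects(d, ap, dp)
    N = cm.simulate_abundance(d, ap, eff, seed=3)
    hist, counts = cm.simulate_histories(N, d, dp, None, eff, seed=4)
    assert (hist["n"] == 0).all()
    assert (counts["count"] == 0).all()


def test_availability_halves_counts_and_histories():
    """With availability 0.5 and p = 1, per-survey counts are ~N/2 and the
    111 history has probability ~1/8."""
    d = cm.SurveyDesign(n_sites=2, n_species=1, n_years=1)
    ap = cm.AbundanceParams(mu_alpha1=9.0, sigma_alpha1=0.0, sigma_alpha2=0.0,
                            alpha3=0.0, mu_alpha4=0.0, sigma_alpha4=0.0)
    dp = cm.DetectionParams(mu_beta1=40.0, sigma_beta1=0.0, sigma_beta2=0.0,
                            beta3=0.0, sigma_beta4=0.0)
    av = cm.AvailabilityParams(theta0=0.0, theta1=0.0)  # probability 0.5
    eff = _degenerate_effects(d, ap, dp)
    N = cm.simulate_abundance(d, ap, eff, seed=5)
    hist, counts = cm.simulate_histories(N, d, dp, av, eff, seed=6)
    frac = counts.groupby(["site"])["count"].mean().to_numpy() / N.reshape(2)
    assert np.allclose(frac, 0.5, atol=0.02)
    frac111 = (hist["h111"] / N).to_numpy()
    assert np.allclose(frac111, 0.125, atol=0.02)


def test_closure_limit_detection_fraction():
    """With closure, the observed fraction n/N converges to 1-(1-p)^J."""
    d = cm.SurveyDesign(n_sites=2, n_species=1, n_years=1)
    ap = cm.AbundanceParams(mu_alpha1=np.log(10_000), sigma_alpha1=0.0,
                            sigma_alpha2=0.0, alpha3=0.0, mu_alpha4=0.0,
                            sigma_alpha4=0.0)
    p = 0.3
    dp = cm.DetectionParams(mu_beta1=float(np.log(p / (1 - p))), sigma_beta1=0.0,
                            sigma_beta2=0.0, beta3=0.0, sigma_beta4=0.0)
    eff = _degenerate_effects(d, ap, dp)
    N = cm.simulate_abundance(d, ap, eff, seed=7)
    hist, _ = cm.simulate_histories(N, d, dp, None, eff, seed=8)
    expected = 1 - (1 - p) ** 3
    assert np.allclose(hist["n"] / N, expected, atol=0.02)


def test_collapse_matches_hand_count():
    # histories {110, 011} -> counts (1, 2, 1)
    ind = pd.DataFrame({"unit": [0, 0], "det_0": [1, 0], "det_1": [1, 1],
                        "det_2": [0, 1]})
    counts = collapse_histories_to_counts(ind, n_units=2, n_surveys=3)
    assert counts[0].tolist() == [1, 2, 1]
    assert counts[1].tolist() == [0, 0, 0]  # empty unit
    tallies, n = tally_histories(ind, n_units=2, n_surveys=3)
    # order: 111,110,101,100,011,010,001
    assert tallies[0].tolist() == [0, 1, 0, 0, 1, 0, 0]
    assert n.tolist() == [2, 0]


def test_collapse_mean_matches_binomial_rate():
    d = cm.SurveyDesign(n_sites=1, n_species=1, n_years=1)
    ap = cm.AbundanceParams(mu_alpha1=np.log(1000), sigma_alpha1=0.0,
                            sigma_alpha2=0.0, alpha3=0.0, sigma_alpha4=0.0)
    p = 0.3
    dp = cm.DetectionParams(mu_beta1=float(np.log(p / (1 - p))), sigma_beta1=0.0,
                            sigma_beta2=0.0, beta3=0.0, sigma_beta4=0.0)
    eff = _degenerate_effects(d, ap, dp)
    N = cm.simulate_abundance(d, ap, eff, seed=2)
    ind = simulate_individuals(N, d, dp, None, eff, seed=3)
    counts = collapse_histories_to_counts(ind, 1, 3)
    assert abs(counts.mean() / N[0] - p) < 0.03


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), mu_beta1=st.floats(-2.5, 1.5),
       theta0=st.sampled_from([None, -1.0, 0.0, 1.0]))
def test_tally_conservation_and_count_consistency(seed, mu_beta1, theta0):
    """For any seed and scenario: history tallies sum to n, n <= N, and
    counts computed directly agree with the collapsed individual records."""
    d = cm.SurveyDesign(n_sites=4, n_species=3, n_years=1)
    ap = cm.AbundanceParams(mu_alpha1=1.2)
    dp = cm.DetectionParams(mu_beta1=mu_beta1)
    av = None if theta0 is None else cm.AvailabilityParams(theta0=theta0)
    ds = cm.simulate_dataset(d, ap, dp, av, seed=seed)
    hcols = [c for c in ds.histories.columns if c.startswith("h")]
    assert (ds.histories[hcols].sum(axis=1) == ds.histories["n"]).all()
    assert (ds.histories["n"].to_numpy() <= ds.true_N).all()
    # per-survey counts equal the number of histories with a 1 in position j
    ss = np.random.SeedSequence(seed)
    _, _, s_det = ss.spawn(3)
    ind = simulate_individuals(ds.true_N, d, dp, av, ds.effects, s_det)
    direct = collapse_histories_to_counts(ind, d.n_units, d.n_surveys)
    wide = ds.counts.pivot_table(index=["site", "species", "year"],
                                 columns="survey", values="count").to_numpy()
    assert (direct == wide).all()


def test_dataset_determinism():
    d = cm.SurveyDesign(n_sites=4, n_species=3)
    ap, dp = cm.AbundanceParams(), cm.DetectionParams()
    a = cm.simulate_dataset(d, ap, dp, seed=99)
    b = cm.simulate_dataset(d, ap, dp, seed=99)
    pd.testing.assert_frame_equal(a.counts, b.counts)
    pd.testing.assert_frame_equal(a.histories, b.histories)
    assert (a.true_N == b.true_N).all()
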