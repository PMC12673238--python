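# countmix

Estimating the drivers of insect abundance when detection is imperfect.

Repeated counts of insects at a site mix two signals: how many individuals
are present and how likely each one is to be seen. When a site-level
treatment (the motivating case is habitat restoration in urban parks,
which raises both bee abundance and the ease of catching bees in taller
vegetation) affects *both*, a count regression misattributes the detection
response to abundance. `countmix` is for ecologists and biostatisticians
who want to quantify that failure mode and fit models that avoid it.

The package provides three hierarchical estimators of the community-mean
treatment effect on abundance, fitted to site x species x year units with
J repeated surveys:

- **`NegBinGLMM`** — counts `y_ij ~ NB(lambda_i, phi)` with
  `log lambda_i = alpha1[sp] + alpha2[site] + alpha3*year + alpha4[sp]*restored_i`;
  detection is not modelled.
- **`BinMixModel`** (binomial N-mixture) — latent `N_i ~ NB(lambda_i, phi)`,
  `y_ij ~ Binomial(N_i, p_i)` with logit-linear `p_i`; `N_i` marginalized
  over `[max_j y_ij, K_i]`.
- **`MultiMixModel`** (multinomial mark-recapture mixture) — tallies of the
  `2^J - 1` observable detection histories, multinomial with cell
  probabilities `pi_c/(1 - pi_0)` given the `n_i` individuals seen at least
  once, and `n_i ~ Binomial(N_i, 1 - pi_0)` with `pi_0 = (1-p_i)^J` and
  `N_i` marginalized over `[n_i, K_i]`.

Alongside the models: a synthetic-data generator whose availability process
(per-individual, per-survey Bernoulli with logit-linear probability
`theta0 + theta1*restored`) produces controlled violations of the
population-closure assumption, and an evaluation protocol that measures
estimator bias (pooled posterior draw minus truth) and precision
(reciprocal SD of pooled draws) over scenario grids. See
`docs/methods.md` for the full model and algorithm description.

Models are scikit-learn-style estimators (`fit`, fitted attributes with a
trailing underscore, `get_params`/`set_params`) over tidy pandas tables.
Fitting runs in a deterministic `map` mode (penalized MAP with EM-updated
variance components and Laplace draws; seconds per fit) or an `mcmc` mode
(emcee ensemble sampler with R-hat/ESS diagnostics via arviz).

## Worked example

Simulate a study in which restoration increases abundance (true community
effect +1 on the log scale) *and* detection (+1 on the logit scale, from a
low baseline), then fit the GLMM and the multinomial mixture:

```python
import countmix as cm

design = cm.SurveyDesign(n_sites=20, n_species=16, n_years=2, n_surveys=3)
ap = cm.AbundanceParams(mu_alpha1=2.0, mu_alpha4=1.0)        # abundance truth
dp = cm.DetectionParams(mu_beta1=-3.0, mu_beta4=1.0)         # detection confound
ds = cm.simulate_dataset(design, ap, dp, seed=1)

glmm = cm.NegBinGLMM(seed=1).fit(ds.counts)
mmix = cm.MultiMixModel(seed=1).fit(ds.histories)
for name, m in [("GLMM", glmm), ("multimix", mmix)]:
    s = m.summary_.loc["mu_alpha4"]
    print(f"{name:9s} restoration effect: {s['mean']:.2f} "
          f"[{s['lo90']:.2f}, {s['hi90']:.2f}]")
```

```
GLMM      restoration effect: 1.75 [1.48, 2.01]
multimix  restoration effect: 1.10 [0.80, 1.42]
```

The GLMM reports ~1.8: the true abundance effect (1.0) plus most of the
detection response, since at a logit intercept of -3 the confound raises
per-survey detectability from ~5% to ~12% (a log-scale count increase of
~0.9). The multinomial mixture separates the two processes through the
recapture structure and recovers the truth. Summaries on the count or
probability scale are per-draw transforms:

```python
import numpy as np
cm.summarize(mmix.result_, transform={"mu_alpha1": np.exp})
cm.derived_abundance_summaries(intercept=3.16, effect=0.91)
# AbundanceSummary(control=23.57, restored=58.56, fold_change=2.48)
```

A command-line interface wraps the same library calls:

```sh
countmix simulate --sites 20 --species 16 --seed 1 --out data/
countmix fit --model multimix --data data/histories.csv --seed 1 --out fits/mm
countmix evaluate-grid --grid grid.yaml --seed 1 --out results.csv
```

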