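"""Synthetic data generator for repeated-count / mark-recapture studies.

Generates, per site x species x year unit:

1. a latent superpopulation size ``N_i`` from a Poisson (or negative
   binomial) distribution with log-linear mean;
2. for every individual ``k <= N_i`` and survey ``j``, an availability draw
   (Bernoulli(theta_i), the temporary-emigration / closure-violation
   process) followed by a detection draw (Bernoulli(p_i), only possible
   while available);
3. the resulting individual detection histories, tallied into the
   2^J - 1 observable history categories (for J = 3, in the fixed order
   111, 110, 101, 100, 011, 010, 001) and collapsed into per-survey counts.

Counts on survey j equal the number of individuals detected on j regardless
of previous captures, matching a field protocol that records total captures
while ignoring marks. Individuals never detected (history 00...0) appear in
neither table but are part of ``N_i``.

Randomness is driven by a single master seed per dataset; each stochastic
stage uses a deterministically derived child seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import SurveyDesign
from .params import (
    AbundanceParams,
    AvailabilityParams,
    DetectionParams,
    EffectTables,
    linear_predictors,
)

#: Guard against implausible scenarios that would overflow Poisson draws.
MAX_LOG_LAMBDA = 20.0


def history_categories(n_surveys: int) -> list[str]:
    """Observable detection histories as bit strings, descending binary order.

    For J = 3 this is 111, 110, 101, 100, 011, 010, 001; the all-zero
    history is unobservable and excluded.
    """
    return [format(code, f"0{n_surveys}b") for code in range(2**n_surveys - 1, 0, -1)]


def history_columns(n_surveys: int) -> list[str]:
    return [f"h{h}" for h in history_categories(n_surveys)]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def draw_random_effects(
    design: SurveyDesign,
    ap: AbundanceParams,
    dp: DetectionParams,
    seed,
) -> EffectTables:
    """Draw species and site random effects from their normal distributions.

    Species intercepts/slopes are drawn around the community means; site
    intercepts around zero. Deterministic given ``seed``.
    """
    rng = _rng(seed)
    S, M = design.n_species, design.n_sites
    species = pd.DataFrame(
        {
            "alpha1": rng.normal(ap.mu_alpha1, ap.sigma_alpha1, S),
            "alpha4": rng.normal(ap.mu_alpha4, ap.sigma_alpha4, S),
            "beta1": rng.normal(dp.mu_beta1, dp.sigma_beta1, S),
            "beta4": rng.normal(dp.mu_beta4, dp.sigma_beta4, S),
        },
        index=pd.RangeIndex(S, name="species"),
    )
    sites = pd.DataFrame(
        {
            "alpha2": rng.normal(0.0, ap.sigma_alpha2, M),
            "beta2": rng.normal(0.0, dp.sigma_beta2, M),
        },
        index=pd.RangeIndex(M, name="site"),
    )
    return EffectTables(species=species, sites=sites)


def simulate_abundance(
    design: SurveyDesign,
    ap: AbundanceParams,
    effects: EffectTables,
    seed,
) -> np.ndarray:
    """Latent superpopulation size N_i per unit, Poisson or NB distributed."""
    units = design.units()
    log_lam, _ = linear_predictors(units, ap, None, effects)
    if np.any(log_lam > MAX_LOG_LAMBDA):
        raise ValueError(
            f"log lambda exceeds {MAX_LOG_LAMBDA}; implausible scenario"
        )
    lam = np.exp(log_lam)
    rng = _rng(seed)
    if ap.is_poisson:
        return rng.poisson(lam)
    # NB as gamma-Poisson mixture, mean lam, dispersion phi
    return rng.poisson(rng.gamma(ap.phi, lam / ap.phi))


def simulate_individuals(
    true_N: np.ndarray,
    design: SurveyDesign,
    dp: DetectionParams,
    av: AvailabilityParams | None,
    effects: EffectTables,
    seed,
) -> pd.DataFrame:
    """Individual-level detection records.

    Returns one row per individual (including never-detected ones) with
    columns ``unit`` and ``det_0 .. det_{J-1}`` (0/1 per survey). Each
    individual is available on each survey independently with probability
    theta_i (1 when ``av`` is None) and, if available, detected with
    probability p_i.
    """
    units = design.units()
    _, logit_p = linear_predictors(units, AbundanceParams(), dp, effects)
    p = expit(logit_p)
    theta = (
        np.ones(len(units))
        if av is None
        else av.prob(units["restored"].to_numpy())
    )
    J = design.n_surveys
    rng = _rng(seed)
    unit_col = np.repeat(np.arange(len(units)), true_N)
    total = int(true_N.sum())
    det = np.empty((total, J), dtype=np.int64)
    p_ind = p[unit_col]
    theta_ind = theta[unit_col]
    for j in range(J):
        available = rng.random(total) < theta_ind
        detected = available & (rng.random(total) < p_ind)
        det[:, j] = detected
    out = pd.DataFrame(det, columns=[f"det_{j}" for j in range(J)])
    out.insert(0, "unit", unit_col)
    return out


def tally_histories(
    individuals: pd.DataFrame, n_units: int, n_surveys: int
) -> tuple[np.ndarray, np.ndarray]:
    """Tally individual records into observable-history counts.

    Returns ``(tallies, n)`` where ``tallies`` is (n_units, 2^J - 1) in the
    fixed descending-binary ordering and ``n`` is the number of individuals
    detected at least once per unit.
    """
    J = n_surveys
    det = individuals[[f"det_{j}" for j in range(J)]].to_numpy()
    codes = det @ (2 ** np.arange(J - 1, -1, -1))
    unit = individuals["unit"].to_numpy()
    # category index: code 2^J-1 -> column 0 ... code 1 -> column 2^J-2
    n_cat = 2**J - 1
    tallies = np.zeros((n_units, n_cat), dtype=np.int64)
    observed = codes > 0
    np.add.at(tallies, (unit[observed], n_cat - codes[observed]), 1)
    return tallies, tallies.sum(axis=1)


def collapse_histories_to_counts(
    individuals: pd.DataFrame, n_units: int, n_surveys: int
) -> np.ndarray:
    """Per-survey counts: number of individuals detected on each survey,
    ignoring whether they were detected before."""
    counts = np.zeros((n_units, n_surveys), dtype=np.int64)
    unit = individuals["unit"].to_numpy()
    for j in range(n_surveys):
        np.add.at(counts[:, j], unit, individuals[f"det_{j}"].to_numpy())
    return counts


def _history_frame(units: pd.DataFrame, tallies, n, n_surveys) -> pd.DataFrame:
    df = units.copy()
    for k, col in enumerate(history_columns(n_surveys)):
        df[col] = tallies[:, k]
    df["n"] = n
    return df


def _count_frame(units: pd.DataFrame, counts, n_surveys) -> pd.DataFrame:
    frames = []
    for j in range(n_surveys):
        f = units.copy()
        f["survey"] = j
        f["count"] = counts[:, j]
        frames.append(f)
    return (
        pd.concat(frames, ignore_index=True)
        .sort_values(["site", "species", "year", "survey"], kind="stable")
        .reset_index(drop=True)
    )


def simulate_histories(
    true_N: np.ndarray,
    design: SurveyDesign,
    dp: DetectionParams,
    av: AvailabilityParams | None,
    effects: EffectTables,
    seed,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate detection and return (HistoryTable, CountTable) DataFrames.

    The two tables are produced from the same individual records and are
    internally consistent: per-survey counts equal the number of histories
    with a 1 in that position.
    """
    individuals = simulate_individuals(true_N, design, dp, av, effects, seed)
    units = design.units()
    tallies, n = tally_histories(individuals, len(units), design.n_surveys)
    counts = collapse_histories_to_counts(individuals, len(units), design.n_surveys)
    # cross-check: survey totals agree between the two tallies
    det_cols = [f"det_{j}" for j in range(design.n_surveys)]
    direct = individuals.groupby("unit")[det_cols].sum().sum().to_numpy()
    if not np.array_equal(direct, counts.sum(axis=0)):
        raise RuntimeError("internal inconsistency between histories and counts")
    return _history_frame(units, tallies, n, design.n_surveys), _count_frame(
        units, counts, design.n_surveys
    )


@dataclass(frozen=True)
class SimulatedDataset:
    """One synthetic dataset with its generating truth attached."""

    design: SurveyDesign
    true_N: np.ndarray
    effects: EffectTables
    histories: pd.DataFrame
    counts: pd.DataFrame
    abundance: AbundanceParams
    detection: DetectionParams
    availability: AvailabilityParams | None
    seed: int

    def true_params(self) -> dict:
        out = {
            "abundance": vars(self.abundance).copy(),
            "detection": vars(self.detection).copy(),
            "availability": None
            if self.availability is None
            else vars(self.availability).copy(),
            "seed": self.seed,
        }
        return out

    def to_dir(self, path) -> None:
        from .io import write_counts, write_histories

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        write_counts(self.counts, path / "counts.csv")
        write_histories(self.histories, path / "histories.csv")
        with open(path / "true_params.json", "w") as fh:
            json.dump(self.true_params(), fh, indent=2)


def simulate_dataset(
    design: SurveyDesign,
    ap: AbundanceParams,
    dp: DetectionParams,
    av: AvailabilityParams | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Full generator: effects -> abundance -> histories and counts.

    Sub-seeds for each stochastic stage are derived deterministically from
    the master ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_eff, s_ab, s_det = ss.spawn(3)
    effects = draw_random_effects(design, ap, dp, s_eff)
    true_N = simulate_abundance(design, ap, effects, s_ab)
    histories, counts = simulate_histories(true_N, design, dp, av, effects, s_det)
    return SimulatedDataset(
        design=design,
        true_N=true_N,
        effects=effects,
        histories=histories,
        counts=counts,
        abundance=ap,
        detection=dp,
        availability=av,
        seed=seed,
    )
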