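"""Likelihoods for the three abundance models, as pure functions.

* ``nb_glmm``: every per-survey count is an independent negative-binomial
  draw with unit mean lambda_i and shared dispersion phi
  (variance = lambda + lambda^2 / phi).
* ``binmix``: latent abundance N_i ~ NB(lambda_i, phi) (or Poisson), counts
  y_{i,j} ~ Binomial(N_i, p_i) conditionally independent across surveys;
  N_i is marginalized by a log-sum-exp stabilized finite sum from the
  largest observed count up to a bound K_i.
* ``multimix``: individual detection histories tallied over the 2^J - 1
  observable categories; y_i ~ Multinomial(n_i, pi_c / (1 - pi_0))
  conditionally on n_i, and n_i ~ Binomial(N_i, 1 - pi_0) with N_i
  marginalized as above (lower bound n_i).

The array cores optionally return analytic gradients with respect to the
unit-level linear predictors (log lambda_i, logit p_i) and log phi; these
power the gradient-based fitting engine. Gradients of the marginal sums are
posterior expectations over the latent N (self-normalized weights), e.g.
d/d log lambda = E_N[(N - lambda) phi / (phi + lambda)].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, expit, gammaln

from .params import AbundanceParams, DetectionParams, EffectTables, linear_predictors
from .simulate import history_categories, history_columns

#: Detection probabilities are clipped to [EPS, 1-EPS] before logs; the
#: logit-linear predictor cannot reach 0/1 but user-supplied fixed p can.
P_EPS = 1e-12


# ---------------------------------------------------------------------------
# detection-history cell probabilities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellProbs:
    """Probabilities of the observable detection histories plus pi0."""

    pi_obs: np.ndarray  # length 2^J - 1, fixed descending-binary order
    pi0: float
    histories: tuple[str, ...]

    def conditional(self) -> np.ndarray:
        """Cell probabilities conditional on being observed at least once."""
        return self.pi_obs / (1.0 - self.pi0)


def history_cell_probs(p: float, n_surveys: int = 3) -> CellProbs:
    """Multinomial cell probabilities for each detection history.

    Each history's probability is the product over surveys of p (detected)
    or 1 - p (not detected); e.g. for J = 3, pi(111) = p^3 and
    pi(110) = p * p * (1 - p). The unobservable history has
    pi0 = (1 - p)^J.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if n_surveys < 1:
        raise ValueError("n_surveys must be >= 1")
    cats = history_categories(n_surveys)
    pi = np.array(
        [np.prod([p if b == "1" else 1.0 - p for b in h]) for h in cats]
    )
    return CellProbs(pi_obs=pi, pi0=float((1.0 - p) ** n_surveys), histories=tuple(cats))


# ---------------------------------------------------------------------------
# latent bound K
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KRule:
    """Rule mapping a unit's lower bound to the latent summation bound K.

    The default reproduces K = (lower + 5) x 12. ``KRule.unmarked()`` gives
    the additive K = lower + 100 convention used by some other software.
    """

    addend: int = 5
    multiplier: int = 12

    @classmethod
    def unmarked(cls) -> "KRule":
        return cls(addend=100, multiplier=1)

    def bound(self, lower) -> np.ndarray:
        lower = np.asarray(lower)
        if np.any(lower < 0):
            raise ValueError("lower bound must be nonnegative")
        return (lower + self.addend) * self.multiplier


def compute_latent_bound(lower, rule: KRule | None = None) -> np.ndarray:
    """Upper summation bound K per unit; always >= the lower bound."""
    rule = rule or KRule()
    lower = np.asarray(lower)
    return np.maximum(rule.bound(lower), lower)


# ---------------------------------------------------------------------------
# negative binomial building blocks
# ---------------------------------------------------------------------------


def _nb_logpmf(y, lam, phi):
    """NB log-pmf, mean/dispersion parameterization; phi=None -> Poisson."""
    y = np.asarray(y, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if phi is None:
        return y * np.log(lam) - lam - gammaln(y + 1.0)
    return (
        gammaln(y + phi)
        - gammaln(phi)
        - gammaln(y + 1.0)
        + phi * np.log(phi / (phi + lam))
        + y * np.log(lam / (phi + lam))
    )


def nb_glmm_loglik_arrays(y, log_lam, phi, return_grad: bool = False):
    """Sum of NB log-densities; optional gradients wrt log lambda, log phi."""
    y = np.asarray(y, dtype=float)
    lam = np.exp(np.asarray(log_lam, dtype=float))
    if np.any(lam <= 0) or (phi is not None and phi <= 0):
        raise ValueError("lambda and phi must be positive")
    ll = float(_nb_logpmf(y, lam, phi).sum())
    if not return_grad:
        return ll
    if phi is None:
        g_loglam = y - lam
        g_logphi = 0.0
    else:
        g_loglam = (y - lam) * phi / (phi + lam)
        g_logphi = phi * float(
            np.sum(
                digamma(y + phi)
                - digamma(phi)
                + np.log(phi / (phi + lam))
                + 1.0
                - (y + phi) / (phi + lam)
            )
        )
    return ll, {"log_lam": g_loglam, "log_phi": g_logphi}


# ---------------------------------------------------------------------------
# marginalized binomial N-mixture ("binmix")
# ---------------------------------------------------------------------------


def _latent_grid(lower, K):
    """Shared N grid 0..max(K) and validity mask per unit."""
    lower = np.asarray(lower, dtype=np.int64)
    K = np.asarray(K, dtype=np.int64)
    N = np.arange(0, int(K.max()) + 1)
    mask = (N[None, :] >= lower[:, None]) & (N[None, :] <= K[:, None])
    return N, mask


def _k_buckets(K):
    """Partition unit indices into geometric K-buckets (by log2 of the
    bound) so each group's N grid is at most twice as wide as its own
    smallest bound; unit bounds are often very uneven and grid cost scales
    with the widest unit in a group."""
    K = np.asarray(K, dtype=np.int64)
    levels = np.ceil(np.log2(np.maximum(K, 1))).astype(np.int64)
    return [np.flatnonzero(levels == lev) for lev in np.unique(levels)]


def _nb_col_row(N, lam, phi):
    """NB grid log-pmf split into a shared column term, a per-unit row term
    and a per-unit slope on N (the pmf is separable on the shared grid)."""
    if phi is None:
        return -gammaln(N + 1.0), -lam, np.log(lam)
    col = gammaln(N + phi) - gammaln(phi) - gammaln(N + 1.0)
    row = phi * np.log(phi / (phi + lam))
    slope = np.log(lam / (phi + lam))
    return col, row, slope


def _masked_softmax(logw):
    """Row-wise (loglik, normalized weights) for -inf-masked log weights."""
    m = logw.max(axis=1)
    e = np.exp(logw - m[:, None])
    s = e.sum(axis=1)
    return m + np.log(s), e / s[:, None]


def _g_logphi_from_moments(EdG, EN, lam, phi):
    """d/d log phi of the summed marginal loglik from the per-unit posterior
    moments E[digamma(N + phi)] and E[N]."""
    return phi * float(
        np.sum(
            EdG
            - digamma(phi)
            + np.log(phi / (phi + lam))
            + 1.0
            - (EN + phi) / (phi + lam)
        )
    )


def binmix_aux(Y, lower, K):
    """Parameter-independent precomputation for the binmix marginal: per
    K-bucket N grids and masked sum_j ln C(N, y_j) matrices."""
    Y = np.asarray(Y, dtype=np.int64)
    lower = np.asarray(lower, dtype=np.int64)
    K = np.asarray(K, dtype=np.int64)
    if np.any(Y.max(axis=1) > K):
        raise ValueError("observed count exceeds latent bound K")
    gl = gammaln(np.arange(int(K.max()) + 2, dtype=float) + 1.0)  # gl[k]=ln k!
    groups = []
    for idx in _k_buckets(K):
        N, mask = _latent_grid(lower[idx], K[idx])
        Yg = Y[idx]
        const = -gl[Yg].sum(axis=1)[:, None] + (Y.shape[1] * gl[N])[None, :]
        for j in range(Y.shape[1]):
            const = const - gl[np.maximum(N[None, :] - Yg[:, j][:, None], 0)]
        const[~mask] = -np.inf
        groups.append({"idx": idx, "N": N, "const": const})
    return {"groups": groups, "ysum": Y.sum(axis=1)}


def binmix_marginal_loglik_arrays(
    Y,
    log_lam,
    logit_p,
    phi,
    lower,
    K,
    return_grad: bool = False,
    aux: dict | None = None,
):
    """Marginal binmix log-likelihood over all units.

    Parameters
    ----------
    Y : (U, J) integer counts; ``lower`` must equal ``Y.max(axis=1)`` or more.
    log_lam, logit_p : (U,) unit-level linear predictors.
    phi : positive float or None for Poisson abundance.
    lower, K : (U,) latent summation bounds.
    aux : optional output of :func:`binmix_aux` (reused across evaluations).
    """
    Y = np.asarray(Y, dtype=np.int64)
    U, J = Y.shape
    lam = np.exp(np.asarray(log_lam, dtype=float))
    p = np.clip(expit(np.asarray(logit_p, dtype=float)), P_EPS, 1.0 - P_EPS)
    if aux is None:
        aux = binmix_aux(Y, lower, K)
    ysum = aux["ysum"]
    log1mp = np.log1p(-p)
    row_extra = ysum * (np.log(p) - log1mp)
    ll = 0.0
    EN = np.empty(U)
    EdG = np.empty(U) if (return_grad and phi is not None) else None
    for grp in aux["groups"]:
        idx, N = grp["idx"], grp["N"]
        col, row, slope = _nb_col_row(N, lam[idx], phi)
        logw = np.multiply.outer(slope + J * log1mp[idx], N)
        logw += col[None, :]
        logw += (row + row_extra[idx])[:, None]
        logw += grp["const"]
        ll_u, w = _masked_softmax(logw)
        ll += float(ll_u.sum())
        if return_grad:
            EN[idx] = w @ N
            if EdG is not None:
                EdG[idx] = w @ digamma(N + phi)
    if not return_grad:
        return ll
    if phi is None:
        g_loglam = EN - lam
        g_logphi = 0.0
    else:
        g_loglam = (EN - lam) * phi / (phi + lam)
        g_logphi = _g_logphi_from_moments(EdG, EN, lam, phi)
    g_logitp = ysum - J * p * EN
    return ll, {"log_lam": g_loglam, "logit_p": g_logitp, "log_phi": g_logphi}


# ---------------------------------------------------------------------------
# multinomial mark-recapture mixture ("multimix")
# ---------------------------------------------------------------------------


def multimix_aux(T, n, K, n_surveys):
    """Parameter-independent precomputation for the multimix marginal."""
    T = np.asarray(T, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    K = np.asarray(K, dtype=np.int64)
    if np.any(T.sum(axis=1) != n):
        raise ValueError("history tallies do not sum to n")
    if np.any(n > K):
        raise ValueError("n exceeds latent bound K")
    gl = gammaln(np.arange(int(K.max()) + 2, dtype=float) + 1.0)
    groups = []
    for idx in _k_buckets(K):
        N, mask = _latent_grid(n[idx], K[idx])
        ng = n[idx]
        const = gl[N][None, :] - gl[np.maximum(N[None, :] - ng[:, None], 0)] - gl[ng][:, None]
        const[~mask] = -np.inf
        groups.append({"idx": idx, "N": N, "const": const})
    ones = np.array([h.count("1") for h in history_categories(n_surveys)])
    mult_const = gammaln(n + 1.0) - gammaln(T + 1.0).sum(axis=1)
    return {"groups": groups, "D": T @ ones, "mult_const": mult_const}


def multimix_loglik_arrays(
    T,
    n,
    log_lam,
    logit_p,
    phi,
    K,
    n_surveys: int,
    return_grad: bool = False,
    aux: dict | None = None,
):
    """Marginal multimix log-likelihood over all units.

    ``T`` is (U, 2^J - 1) tallies in descending-binary history order and
    ``n = T.sum(axis=1)``. Per unit the likelihood factorizes into a
    conditional multinomial over observable cells (probabilities
    pi_c / (1 - pi_0)) and a marginalized binomial n_i ~ Bin(N_i, 1 - pi_0)
    with N_i summed from n_i to K_i.
    """
    T = np.asarray(T, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    U, C = T.shape
    J = n_surveys
    if C != 2**J - 1:
        raise ValueError(f"expected {2**J - 1} history columns, got {C}")
    if aux is None:
        aux = multimix_aux(T, n, K, J)
    D = aux["D"]
    lam = np.exp(np.asarray(log_lam, dtype=float))
    p = np.clip(expit(np.asarray(logit_p, dtype=float)), P_EPS, 1.0 - P_EPS)
    log1mp = np.log1p(-p)
    q = -np.expm1(J * log1mp)  # 1 - (1-p)^J
    # conditional multinomial term
    mult = (
        aux["mult_const"]
        + D * np.log(p)
        + (J * n - D) * log1mp
        - n * np.log(q)
    )
    # marginalized binomial term: lnC(N, n) + n ln q + (N - n) J ln(1-p)
    row_extra = n * (np.log(q) - J * log1mp)
    ll = float(mult.sum())
    EN = np.empty(U)
    EdG = np.empty(U) if (return_grad and phi is not None) else None
    for grp in aux["groups"]:
        idx, N = grp["idx"], grp["N"]
        col, row, slope = _nb_col_row(N, lam[idx], phi)
        logw = np.multiply.outer(slope + J * log1mp[idx], N)
        logw += col[None, :]
        logw += (row + row_extra[idx])[:, None]
        logw += grp["const"]
        ll_u, w = _masked_softmax(logw)
        ll += float(ll_u.sum())
        if return_grad:
            EN[idx] = w @ N
            if EdG is not None:
                EdG[idx] = w @ digamma(N + phi)
    if not return_grad:
        return ll
    if phi is None:
        g_loglam = EN - lam
        g_logphi = 0.0
    else:
        g_loglam = (EN - lam) * phi / (phi + lam)
        g_logphi = _g_logphi_from_moments(EdG, EN, lam, phi)
    dq = J * p * np.exp(J * log1mp)  # dq/d logit p
    g_mult = (D - J * n * p) - n * dq / q
    g_marg = (n / q - (EN - n) / (1.0 - q)) * dq
    g_logitp = g_mult + g_marg
    return ll, {"log_lam": g_loglam, "logit_p": g_logitp, "log_phi": g_logphi}


# ---------------------------------------------------------------------------
# table-level wrappers (spec'd operation signatures)
# ---------------------------------------------------------------------------


def _phi(ap: AbundanceParams):
    return None if ap.is_poisson else float(ap.phi)


def nb_glmm_loglik(counts, ap: AbundanceParams, effects: EffectTables) -> float:
    """GLMM log-likelihood of a CountTable under given params and effects."""
    log_lam, _ = linear_predictors(counts, ap, None, effects)
    return nb_glmm_loglik_arrays(counts["count"].to_numpy(), log_lam, _phi(ap))


def _pivot_counts(counts):
    wide = counts.pivot_table(
        index=["site", "species", "year", "restored"],
        columns="survey",
        values="count",
        aggfunc="first",
    )
    units = wide.index.to_frame(index=False)
    return units, wide.to_numpy(dtype=np.int64)


def binmix_marginal_loglik(
    counts,
    ap: AbundanceParams,
    dp: DetectionParams,
    effects: EffectTables,
    rule: KRule | None = None,
) -> float:
    """Marginal binmix log-likelihood of a CountTable."""
    units, Y = _pivot_counts(counts)
    log_lam, logit_p = linear_predictors(units, ap, dp, effects)
    lower = Y.max(axis=1)
    K = compute_latent_bound(lower, rule)
    return binmix_marginal_loglik_arrays(Y, log_lam, logit_p, _phi(ap), lower, K)


def multimix_loglik(
    histories,
    ap: AbundanceParams,
    dp: DetectionParams,
    effects: EffectTables,
    rule: KRule | None = None,
) -> float:
    """Marginal multimix log-likelihood of a HistoryTable."""
    hcols = [c for c in histories.columns if c.startswith("h") and c[1:].isdigit()
             and set(c[1:]) <= {"0", "1"}]
    J = len(hcols[0]) - 1
    hcols = history_columns(J)
    T = histories[hcols].to_numpy(dtype=np.int64)
    n = histories["n"].to_numpy(dtype=np.int64)
    units = histories[["site", "species", "year", "restored"]]
    log_lam, logit_p = linear_predictors(units, ap, dp, effects)
    K = compute_latent_bound(n, rule)
    return multimix_loglik_arrays(T, n, log_lam, logit_p, _phi(ap), K, J)
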