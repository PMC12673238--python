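"""Independent brute-force oracles for the marginalized likelihoods.

Deliberately naive: plain Python loops over the latent abundance N and
scipy.stats pmf calls, no shared code with the package's vectorized
implementations.
"""

import numpy as np
from scipy.stats import binom, multinomial, nbinom, poisson


def nb_pmf(N, lam, phi):
    """NB pmf in mean/dispersion form; phi=None means Poisson."""
    if phi is None:
        return poisson.pmf(N, lam)
    return nbinom.pmf(N, phi, phi / (phi + lam))


def binmix_unit_loglik(y, lam, p, phi, lower, K):
    """Brute-force marginal likelihood of one unit's repeated counts."""
    total = 0.0
    for N in range(int(lower), int(K) + 1):
        term = nb_pmf(N, lam, phi)
        for yy in y:
            term *= binom.pmf(int(yy), N, p)
        total += term
    return float(np.log(total))


def cell_probs_enumerated(p, J):
    """All 2^J history probabilities by explicit enumeration, descending
    binary order with the all-zero history last."""
    out = []
    for code in range(2**J - 1, -1, -1):
        bits = format(code, f"0{J}b")
        out.append(np.prod([p if b == "1" else 1 - p for b in bits]))
    return np.array(out)


def multimix_unit_loglik(tallies, n, lam, p, phi, K, J=3):
    """Brute-force marginal likelihood of one unit's history tallies."""
    probs = cell_probs_enumerated(p, J)
    pi_obs, pi0 = probs[:-1], probs[-1]
    ll = 0.0
    if n > 0:
        ll += multinomial.logpmf(np.asarray(tallies), int(n), pi_obs / (1 - pi0))
    total = 0.0
    for N in range(int(n), int(K) + 1):
        total += nb_pmf(N, lam, phi) * binom.pmf(int(n), N, 1 - pi0)
    return float(ll + np.log(total))
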