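"""Bayesian mixture model of heartbeat-discrimination accuracy.

Each subject's correct-trial count k (out of n, typically 120) is modelled
as coming from either an at-chance component, k ~ Binomial(n, 0.5), or an
above-chance component in which the subject's accuracy is
p = 0.5 + B/2 with B ~ Beta(alpha, beta) — a *shifted* Beta law spanning
[0.5, 1.0], distinct from a standard Beta-Binomial.  Priors:
alpha ~ Exponential(rate 1.0), beta ~ Exponential(rate 0.5) (slightly
favouring accuracies near 0.5), and a Uniform(0, 1) prior on the
population prevalence of above-chance perceivers.

The above-chance marginal likelihood

    L(k) = integral_0^1 Binomial(k; n, 0.5 + b/2) Beta(b; alpha, beta) db

has a polynomial integrand in b, so it is evaluated exactly as a finite
sum of Beta functions in log space (numerically stable for any
alpha, beta > 0, including the endpoint-singular cases alpha < 1 or
beta < 1).

Sampling is over the marginalized mixture likelihood (no per-subject
latent labels); per-subject membership probabilities are recovered post
hoc by Bayes' rule.  Two backends: a deterministic gridded numerical
posterior (default) and an emcee MCMC sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln, gammaln, logsumexp

__all__ = [
    "MixturePosterior",
    "above_chance_likelihood",
    "fit_mixture",
    "membership_probability",
    "screen_at_chance",
    "binomial_above_chance",
    "posterior_predictive_pmf",
    "hdi",
]

#: Prior rates: alpha ~ Exp(1.0), beta ~ Exp(0.5).
ALPHA_RATE = 1.0
BETA_RATE = 0.5


def _log_l_above(
    k: np.ndarray, n: int, alpha: np.ndarray, beta: np.ndarray
) -> np.ndarray:
    """log L(k | above-chance) for each (alpha, beta) pair; shape (n_k, n_pair).

    Uses the exact expansion
    L = C(n,k) 2^-n sum_{j=0}^{k} C(k,j) B(a+j, b+n-k) / B(a, b),
    with all (positive) terms combined by log-sum-exp.
    """
    k = np.atleast_1d(np.asarray(k, dtype=int))
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    kmax = int(k.max())
    j = np.arange(kmax + 1)
    ga = gammaln(alpha[:, None] + j[None, :])            # (P, kmax+1)
    m = np.arange(n + 1)
    gs = gammaln(alpha[:, None] + beta[:, None] + m[None, :])  # (P, n+1)
    lnb0 = betaln(alpha, beta)                           # (P,)
    lnCnk = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    out = np.empty((k.size, alpha.size))
    for i, ki in enumerate(k):
        jj = j[: ki + 1]
        lnCkj = gammaln(ki + 1) - gammaln(jj + 1) - gammaln(ki - jj + 1)
        gb = gammaln(beta + (n - ki))                    # (P,)
        terms = lnCkj[None, :] + ga[:, : ki + 1] + gb[:, None] - gs[:, n - ki : n + 1]
        out[i] = lnCnk[i] - n * np.log(2.0) + logsumexp(terms, axis=1) - lnb0
    return out


def above_chance_likelihood(k: int, n: int, alpha: float, beta: float) -> float:
    """P(k | above-chance) under accuracy p = 0.5 + B/2, B ~ Beta(alpha, beta).

    Evaluated exactly (finite Beta-function sum); see module docstring.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    return float(np.exp(_log_l_above(k, n, alpha, beta)[0, 0]))


@dataclass
class MixturePosterior:
    """Posterior draws and per-subject membership for the mixture model."""

    prevalence: np.ndarray     # draws of pi_pop
    alpha: np.ndarray          # draws of alpha
    beta: np.ndarray           # draws of beta
    k: np.ndarray              # observed correct counts, one per subject
    n: int                     # trials per subject
    membership: np.ndarray     # P(above-chance | k_i), one per subject
    backend: str
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def mean_accuracy_draws(self) -> np.ndarray:
        """Draws of the mean above-chance accuracy 0.5 + 0.5 a/(a + b)."""
        return 0.5 + 0.5 * self.alpha / (self.alpha + self.beta)

    def summary(self) -> dict:
        prev_hdi = hdi(self.prevalence)
        acc_hdi = hdi(self.mean_accuracy_draws)
        return {
            "prevalence_mean": float(self.prevalence.mean()),
            "prevalence_hdi_low": prev_hdi[0],
            "prevalence_hdi_high": prev_hdi[1],
            "accuracy_mean": float(self.mean_accuracy_draws.mean()),
            "accuracy_hdi_low": acc_hdi[0],
            "accuracy_hdi_high": acc_hdi[1],
            "converged": self.converged,
            "backend": self.backend,
        }


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    m = max(1, int(np.ceil(mass * x.size)))
    if m >= x.size:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: x.size - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


def _check_table(table: pd.DataFrame) -> tuple[np.ndarray, int]:
    k = np.asarray(table["k"], dtype=int)
    ns = np.unique(np.asarray(table["n"], dtype=int))
    if ns.size != 1:
        raise ValueError("all subjects must share the same trial count n")
    n = int(ns[0])
    if np.any((k < 0) | (k > n)):
        raise ValueError("require 0 <= k <= n")
    if k.size < 2:
        raise ValueError("need at least 2 subjects")
    return k, n


def _mixture_loglik_terms(k: np.ndarray, n: int, alpha: np.ndarray, beta: np.ndarray):
    """Return (L_above (n_uk, P), chance pmf (n_uk,), inverse index)."""
    uk, inv = np.unique(k, return_inverse=True)
    la = np.exp(_log_l_above(uk, n, alpha, beta))
    chance = stats.binom.pmf(uk, n, 0.5)
    return la, chance, inv


def fit_mixture(
    table: pd.DataFrame,
    n_draws: int = 10_000,
    seed: int | None = None,
    backend: str = "grid",
    grid_shape: tuple[int, int, int] = (120, 60, 60),
    alpha_max: float = 10.0,
    beta_max: float = 20.0,
) -> MixturePosterior:
    """Posterior of (prevalence, alpha, beta) under the marginalized mixture.

    ``backend="grid"`` (default) evaluates the joint posterior on a
    regular grid over prevalence x alpha x beta, draws ``n_draws``
    weighted samples with within-cell jitter, and is fully deterministic
    for a fixed seed.  ``backend="mcmc"`` runs an emcee ensemble sampler
    in unconstrained coordinates and reports a split-chain R-hat
    diagnostic (flagged non-converged if R-hat >= 1.01).
    """
    k, n = _check_table(table)
    rng = np.random.default_rng(seed)
    if backend == "grid":
        draws, diag = _fit_grid(k, n, n_draws, rng, grid_shape, alpha_max, beta_max)
        converged = True
    elif backend == "mcmc":
        draws, diag = _fit_emcee(k, n, n_draws, rng)
        converged = diag["rhat"] < 1.01
    else:
        raise ValueError(f"unknown backend {backend!r}")
    post = MixturePosterior(
        prevalence=draws[:, 0], alpha=draws[:, 1], beta=draws[:, 2],
        k=k, n=n, membership=np.empty(0), backend=backend,
        converged=converged, diagnostics=diag,
    )
    post.membership = _membership_all(k, post)
    return post


def _membership_all(k: np.ndarray, post: "MixturePosterior") -> np.ndarray:
    """Vectorised membership probabilities for a set of counts."""
    uk, inv = np.unique(k, return_inverse=True)
    la = np.exp(_log_l_above(uk, post.n, post.alpha, post.beta))  # (n_uk, D)
    chance = stats.binom.pmf(uk, post.n, 0.5)[:, None]
    num = post.prevalence[None, :] * la
    mem = (num / (num + (1 - post.prevalence[None, :]) * chance)).mean(axis=1)
    return mem[inv]


def _fit_grid(k, n, n_draws, rng, grid_shape, alpha_max, beta_max):
    n_pi, n_a, n_b = grid_shape
    d_pi, d_a, d_b = 1.0 / n_pi, alpha_max / n_a, beta_max / n_b
    pi = (np.arange(n_pi) + 0.5) * d_pi
    a = (np.arange(n_a) + 0.5) * d_a
    b = (np.arange(n_b) + 0.5) * d_b
    aa, bb = np.meshgrid(a, b, indexing="ij")
    pairs_a, pairs_b = aa.ravel(), bb.ravel()
    la, chance, inv = _mixture_loglik_terms(k, n, pairs_a, pairs_b)
    la_s, chance_s = la[inv], chance[inv]          # per-subject rows
    lp_ab = -ALPHA_RATE * pairs_a - BETA_RATE * pairs_b  # log prior (to a constant)
    logpost = np.empty((n_pi, pairs_a.size))
    for ip, p in enumerate(pi):
        mix = p * la_s + (1 - p) * chance_s[:, None]
        logpost[ip] = np.log(mix).sum(axis=0) + lp_ab
    logpost -= logsumexp(logpost)
    w = np.exp(logpost).ravel()
    cells = rng.choice(w.size, size=n_draws, p=w / w.sum())
    ip, iab = np.divmod(cells, pairs_a.size)
    ia, ib = np.divmod(iab, b.size)
    jit = rng.uniform(-0.5, 0.5, size=(3, n_draws))
    draws = np.column_stack(
        [
            pi[ip] + jit[0] * d_pi,
            a[ia] + jit[1] * d_a,
            b[ib] + jit[2] * d_b,
        ]
    )
    draws[:, 0] = np.clip(draws[:, 0], 1e-9, 1 - 1e-9)
    draws[:, 1] = np.maximum(draws[:, 1], 1e-9)
    draws[:, 2] = np.maximum(draws[:, 2], 1e-9)
    return draws, {"grid_shape": grid_shape, "alpha_max": alpha_max,
                   "beta_max": beta_max}


def _fit_emcee(k, n, n_draws, rng):
    import emcee

    uk, inv = np.unique(k, return_inverse=True)
    chance = stats.binom.pmf(uk, n, 0.5)[inv]

    def log_prob(theta):
        lpi, lna, lnb = theta
        pi = 1.0 / (1.0 + np.exp(-lpi))
        a, b = np.exp(lna), np.exp(lnb)
        if not np.isfinite(a * b) or a <= 0 or b <= 0:
            return -np.inf
        # priors + Jacobians of the transforms
        lp = np.log(pi) + np.log1p(-pi)            # uniform pi, logit Jacobian
        lp += -ALPHA_RATE * a + lna - BETA_RATE * b + lnb
        la = np.exp(_log_l_above(uk, n, a, b)[:, 0])[inv]
        return lp + np.sum(np.log(pi * la + (1 - pi) * chance))

    nwalk = 24
    steps = int(np.ceil(n_draws / nwalk)) + 300
    p0 = np.column_stack(
        [rng.normal(-2, 0.5, nwalk), rng.normal(0, 0.5, nwalk),
         rng.normal(0.5, 0.5, nwalk)]
    )
    sampler = emcee.EnsembleSampler(nwalk, 3, log_prob)
    sampler.random_state = np.random.RandomState(rng.integers(2**31 - 1))
    sampler.run_mcmc(p0, steps, progress=False)
    chain = sampler.get_chain(discard=300)          # (steps, nwalk, 3)
    rhat = _split_rhat(chain[..., 0])
    flat = chain.reshape(-1, 3)[:n_draws]
    draws = np.column_stack(
        [1.0 / (1.0 + np.exp(-flat[:, 0])), np.exp(flat[:, 1]), np.exp(flat[:, 2])]
    )
    return draws, {"rhat": float(rhat), "n_walkers": nwalk, "n_steps": steps}


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor; chains (n_steps, n_chains)."""
    n = chains.shape[0] // 2
    halves = np.concatenate([chains[:n], chains[n : 2 * n]], axis=1)
    m, nn = halves.shape[1], halves.shape[0]
    means = halves.mean(axis=0)
    w = halves.var(axis=0, ddof=1).mean()
    bvar = nn * means.var(ddof=1)
    var_hat = (nn - 1) / nn * w + bvar / nn
    return float(np.sqrt(var_hat / w))


def membership_probability(k: int, posterior: MixturePosterior) -> float:
    """P(above-chance | k), averaged over posterior draws via Bayes' rule.

    Each draw contributes pi L_above(k) / [pi L_above(k) + (1 - pi)
    Binomial(k; n, 0.5)].
    """
    n = posterior.n
    la = np.exp(
        _log_l_above(
            np.array([k]), n, posterior.alpha, posterior.beta
        )[0]
    )
    chance = stats.binom.pmf(k, n, 0.5)
    pi = posterior.prevalence
    num = pi * la
    return float(np.mean(num / (num + (1 - pi) * chance)))


def screen_at_chance(
    table: pd.DataFrame, posterior: MixturePosterior, threshold: float = 0.05
):
    """Retain subjects confidently at chance.

    A subject is retained if their posterior probability of being an
    above-chance perceiver is at most ``threshold`` (equivalently, at
    least ``1 - threshold`` posterior probability of being at chance).

    Returns ``(retained_subject_ids, effective_cutoff)`` where the cutoff
    is the largest accuracy k/n among retained subjects.
    """
    k, n = _check_table(table)
    member = _membership_all(k, posterior)
    keep = member <= threshold
    subjects = np.asarray(table["subject"])[keep]
    cutoff = float((k[keep] / n).max()) if keep.any() else np.nan
    return subjects, cutoff


def binomial_above_chance(k: int, n: int, alpha: float = 0.05):
    """One-sided exact binomial test of above-chance accuracy.

    p = P(X >= k | n, 0.5); flag = (p < alpha).
    """
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    p = float(stats.binom.sf(k - 1, n, 0.5))
    return p, p < alpha


def posterior_predictive_pmf(posterior: MixturePosterior) -> np.ndarray:
    """Posterior-predictive pmf of k over 0..n under the fitted mixture."""
    n = posterior.n
    ks = np.arange(n + 1)
    la = np.exp(_log_l_above(ks, n, posterior.alpha, posterior.beta))  # (n+1, D)
    chance = stats.binom.pmf(ks, n, 0.5)[:, None]
    pi = posterior.prevalence[None, :]
    return (pi * la + (1 - pi) * chance).mean(axis=1)
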