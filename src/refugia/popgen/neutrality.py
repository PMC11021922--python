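"""Ewens-Watterson and Chakraborty neutrality tests.

Both tests rest on the Ewens sampling formula (ESF).  Conditional allele
configurations given (n, k) are theta-free, so they are sampled by running
the Chinese-restaurant construction at a theta tuned so that E[K] = k and
rejecting on the realized allele count.  The construction is vectorized
across draws: customer i either opens a new table (prob theta/(theta+i)) or
joins the table of a uniformly chosen earlier customer, which is equivalent
to joining an existing table with probability proportional to its size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq


@dataclass
class NeutralityResult:
    test: str  # "ewens-watterson" or "chakraborty"
    n: int
    k_obs: int | None
    F_obs: float | None
    F_exp: float | None
    k_exp: float | None
    theta_hat: float | None
    p_le: float | None  # Pr(F <= F_obs) (E-W) / unused (Chakraborty)
    p_ge: float | None  # Pr(F >= F_obs) (E-W) / Pr(K >= k_obs) (Chakraborty)
    n_draws: int = 0


def expected_k(theta: float, n: int) -> float:
    """E[number of alleles] = sum_{i=0}^{n-1} theta/(theta+i)."""
    i = np.arange(n)
    return float(np.sum(theta / (theta + i)))


def _theta_for_k(n: int, k: float) -> float:
    """theta with E[K] = k (maximizes rejection acceptance near k)."""
    if k <= 1:
        return 1e-6
    if k >= n:
        return 1e6
    return brentq(lambda t: expected_k(t, n) - k, 1e-9, 1e9, xtol=1e-9)


def _crt_batch(
    n: int, theta: float, n_batch: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n_batch ESF configurations at theta.

    Returns (counts, k): counts is (n_batch, n) table sizes (zero-padded,
    table ids in opening order), k the allele counts per draw.
    """
    table = np.zeros((n_batch, n), dtype=np.int32)  # table id per customer
    n_tables = np.ones(n_batch, dtype=np.int32)  # customer 0 opens table 0
    for i in range(1, n):
        new = rng.random(n_batch) * (theta + i) < theta
        j = rng.integers(0, i, size=n_batch)
        table[:, i] = np.where(new, n_tables, table[np.arange(n_batch), j])
        n_tables += new
    counts = np.zeros((n_batch, n), dtype=np.int32)
    rows = np.arange(n_batch)
    for i in range(n):
        counts[rows, table[:, i]] += 1
    return counts, n_tables


def sample_esf_conditional(
    n: int, k: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Allele-count configurations from the ESF conditional on (n, k).

    Returns an (n_draws, n) zero-padded count matrix whose rows each sum to
    n with exactly k positive entries.  Rejection on k at the tuned theta;
    aborts if acceptance collapses below 1e-4.
    """
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    theta = _theta_for_k(n, k)
    out = np.empty((n_draws, n), dtype=np.int32)
    got = 0
    attempts = 0
    batch = max(2 * n_draws // max(k, 1), 1000)
    while got < n_draws:
        counts, ks = _crt_batch(n, theta, batch, rng)
        keep = counts[ks == k]
        take = min(len(keep), n_draws - got)
        out[got : got + take] = keep[:take]
        got += take
        attempts += batch
        if attempts > 1e4 and got < attempts * 1e-4:
            raise RuntimeError(
                f"ESF rejection acceptance below 1e-4 for n={n}, k={k}"
            )
    return out


def homozygosity(counts: np.ndarray) -> np.ndarray:
    """F = sum p_i^2 per configuration row."""
    counts = np.atleast_2d(counts).astype(float)
    n = counts.sum(axis=1, keepdims=True)
    return np.sum((counts / n) ** 2, axis=1)


def ewens_watterson(
    n: int,
    k: int | None = None,
    counts=None,
    n_draws: int = 100_000,
    seed: int | None = None,
) -> NeutralityResult:
    """Ewens-Watterson homozygosity test conditional on (n, k).

    F_exp is the Monte-Carlo mean of sum p_i^2 over ESF configurations
    conditioned on the allele count.  When observed counts are supplied,
    both one-sided tail probabilities of F_obs are reported (the convention
    used by the original test is not standardized).
    """
    F_obs = None
    if counts is not None:
        counts = np.asarray(counts, dtype=int)
        if counts.sum() != n:
            raise ValueError("counts must sum to n")
        if k is None:
            k = int((counts > 0).sum())
        elif k != int((counts > 0).sum()):
            raise ValueError("k inconsistent with counts")
        F_obs = float(homozygosity(counts)[0])
    if k is None:
        raise ValueError("supply k or counts")
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    if n_draws < 1:
        raise ValueError("n_draws must be positive")
    rng = np.random.default_rng(seed)
    draws = sample_esf_conditional(n, k, n_draws, rng)
    F = homozygosity(draws)
    F_exp = float(F.mean())
    p_le = p_ge = None
    if F_obs is not None:
        p_le = (int(np.sum(F <= F_obs + 1e-12)) + 1) / (n_draws + 1)
        p_ge = (int(np.sum(F >= F_obs - 1e-12)) + 1) / (n_draws + 1)
    return NeutralityResult(
        "ewens-watterson", n, k, F_obs, F_exp, None, None, p_le, p_ge, n_draws
    )


def chakraborty(
    n: int,
    F_obs: float,
    k_obs: int | None = None,
    n_draws: int = 100_000,
    seed: int | None = None,
) -> NeutralityResult:
    """Chakraborty test: observed allele count vs expectation at theta-hat.

    theta-hat comes from the homozygosity moment E[F] = 1/(1+theta);
    k_exp = sum_{i=0}^{n-1} theta/(theta+i).  The p-value Pr(K >= k_obs) is
    estimated from unconditional ESF draws of K at theta-hat (K is a sum of
    independent Bernoulli(theta/(theta+i)) indicators).
    """
    if not (1.0 / n) - 1e-12 <= F_obs <= 1.0 + 1e-12:
        raise ValueError("F_obs must lie in [1/n, 1]")
    theta_hat = max(1.0 / F_obs - 1.0, 0.0)
    k_exp = expected_k(theta_hat, n) if theta_hat > 0 else 1.0
    p_ge = None
    if k_obs is not None:
        rng = np.random.default_rng(seed)
        i = np.arange(n)
        probs = theta_hat / (theta_hat + i) if theta_hat > 0 else (i == 0).astype(float)
        ks = (rng.random((n_draws, n)) < probs).sum(axis=1)
        p_ge = (int(np.sum(ks >= k_obs)) + 1) / (n_draws + 1)
    return NeutralityResult(
        "chakraborty", n, k_obs, F_obs, None, float(k_exp), float(theta_hat),
        None, p_ge, n_draws if k_obs is not None else 0,
    )
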