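"""Numba kernels for the collapsed Gibbs sampler (direct-assignment scheme).

Topics live in a fixed pool of ``Kmax`` slots; a slot is active iff its
global count ``n_k > 0``.  Dead slots carry zero stick weight, so they
contribute zero probability and need no masking in the inner loop.
All randomness flows through numba's internal np.random state, seeded
once per run, which makes runs bit-reproducible.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Gibbs sweep


@njit(cache=False)
def init_state(token_word, token_doc, n_dk, n_kw, n_k, z, k_init, seed):
    np.random.seed(seed)
    for t in range(token_word.shape[0]):
        k = np.random.randint(0, k_init)
        z[t] = k
        n_dk[token_doc[t], k] += 1
        n_kw[k, token_word[t]] += 1
        n_k[k] += 1


@njit(cache=False)
def sweep(token_word, token_doc, z, n_dk, n_kw, n_k, beta, beta_u, alpha0, gamma, eta):
    """One full Gibbs sweep over all tokens.

    Returns 1 if the slot pool overflowed during the sweep (state stays
    consistent; the caller should grow the arrays), else 0.
    """
    Kmax = n_k.shape[0]
    V = n_kw.shape[1]
    p = np.empty(Kmax + 1)
    overflow = 0
    veta = V * eta
    for t in range(token_word.shape[0]):
        w = token_word[t]
        d = token_doc[t]
        k = z[t]
        n_dk[d, k] -= 1
        n_kw[k, w] -= 1
        n_k[k] -= 1
        if n_k[k] == 0:
            # topic died: return its stick mass to the unused remainder
            beta_u[0] += beta[k]
            beta[k] = 0.0

        total = 0.0
        for kk in range(Kmax):
            pr = (n_dk[d, kk] + alpha0 * beta[kk]) * (n_kw[kk, w] + eta) / (
                n_k[kk] + veta
            )
            total += pr
            p[kk] = total
        p_new = alpha0 * beta_u[0] / V
        total += p_new
        p[Kmax] = total

        u = np.random.random() * total
        knew = Kmax
        for kk in range(Kmax + 1):
            if u < p[kk]:
                knew = kk
                break
        if knew == Kmax:
            # brand-new topic: claim a free slot and break a stick piece
            slot = -1
            for kk in range(Kmax):
                if n_k[kk] == 0:
                    slot = kk
                    break
            if slot < 0:
                overflow = 1
                # fall back to the best existing topic to keep state valid
                best = 0
                bestp = -1.0
                prev = 0.0
                for kk in range(Kmax):
                    pr = p[kk] - prev
                    prev = p[kk]
                    if pr > bestp:
                        bestp = pr
                        best = kk
                knew = best
            else:
                b = np.random.beta(1.0, gamma)
                beta[slot] = b * beta_u[0]
                beta_u[0] = (1.0 - b) * beta_u[0]
                knew = slot

        z[t] = knew
        n_dk[d, knew] += 1
        n_kw[knew, w] += 1
        n_k[knew] += 1
    return overflow


# ---------------------------------------------------------------------------
# Global updates (tables, sticks, concentrations)


@njit(cache=False)
def sample_tables(n_dk, n_k, beta, alpha0, T_k):
    """Sample table counts per topic via the Chinese-restaurant table scheme."""
    D, Kmax = n_dk.shape
    T_k[:] = 0
    for k in range(Kmax):
        if n_k[k] == 0:
            continue
        a = alpha0 * beta[k]
        for d in range(D):
            n = n_dk[d, k]
            if n == 0:
                continue
            m = 1  # the first customer always opens a table
            for i in range(1, n):
                if np.random.random() < a / (a + i):
                    m += 1
            T_k[k] += m


@njit(cache=False)
def sample_beta(n_k, T_k, beta, beta_u, gamma):
    """Draw stick weights ~ Dirichlet(T_1..T_K, gamma) over active topics."""
    Kmax = n_k.shape[0]
    total = 0.0
    for k in range(Kmax):
        if n_k[k] > 0:
            g = np.random.gamma(float(T_k[k]), 1.0)
            beta[k] = g
            total += g
        else:
            beta[k] = 0.0
    gu = np.random.gamma(gamma, 1.0)
    total += gu
    for k in range(Kmax):
        beta[k] /= total
    beta_u[0] = gu / total


@njit(cache=False)
def sample_alpha0(alpha0, doc_len, T_total, a_prior, b_prior):
    """Auxiliary-variable resampling of the document-level concentration."""
    log_w_sum = 0.0
    s_sum = 0.0
    for j in range(doc_len.shape[0]):
        n = float(doc_len[j])
        if n <= 0.0:
            continue
        w = np.random.beta(alpha0 + 1.0, n)
        log_w_sum += math.log(w)
        if np.random.random() < n / (n + alpha0):
            s_sum += 1.0
    shape = a_prior + T_total - s_sum
    rate = b_prior - log_w_sum
    return np.random.gamma(shape, 1.0 / rate)


@njit(cache=False)
def sample_gamma(gamma, K, T_total, a_prior, b_prior):
    """Escobar-West resampling of the top-level concentration."""
    if T_total <= 0:
        return gamma
    x = np.random.beta(gamma + 1.0, float(T_total))
    logx = math.log(x)
    pi_num = a_prior + K - 1.0
    pi = pi_num / (pi_num + T_total * (b_prior - logx))
    if np.random.random() < pi:
        shape = a_prior + K
    else:
        shape = a_prior + K - 1.0
    return np.random.gamma(shape, 1.0 / (b_prior - logx))


# ---------------------------------------------------------------------------
# Joint log-likelihood (words given assignments + assignment prior)


@njit(cache=False)
def log_likelihood(n_dk, n_kw, n_k, doc_len, beta, alpha0, eta):
    Kmax, V = n_kw.shape
    lg_eta = math.lgamma(eta)
    ll = 0.0
    for k in range(Kmax):
        if n_k[k] == 0:
            continue
        ll += math.lgamma(V * eta) - math.lgamma(n_k[k] + V * eta)
        for w in range(V):
            if n_kw[k, w] > 0:
                ll += math.lgamma(n_kw[k, w] + eta) - lg_eta
    D = n_dk.shape[0]
    lg_a = math.lgamma(alpha0)
    for d in range(D):
        ll += lg_a - math.lgamma(alpha0 + doc_len[d])
        for k in range(Kmax):
            if n_dk[d, k] > 0:
                ab = alpha0 * beta[k]
                ll += math.lgamma(ab + n_dk[d, k]) - math.lgamma(ab)
    return ll
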