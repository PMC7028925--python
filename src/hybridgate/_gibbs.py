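"""Numba kernel for the K=2 admixture-model Gibbs sampler.

Implements the standard admixture model with independent allele frequencies:
each allele copy ``x_{ila}`` has a latent origin ``Z_{ila} in {0,1}`` with
``Pr(Z=k) = q_{ik}``; given its origin it is a draw from that cluster's
frequency vector ``p_{k,l,.}``.  Conjugate updates per sweep:

* ``Z_{ila} | q, P``  categorical, proportional to ``q_{ik} p_{k,l,x}``;
* ``P_{k,l,.} | Z``   Dirichlet(lambda + origin-specific allele counts);
* ``q_i | Z``         Dirichlet(alpha + per-cluster copy counts);
* ``alpha``           random-walk Metropolis under a uniform prior on
                      (0, alpha_max], shared across all individuals.

Missing allele copies are simply absent from the copy list and contribute
nothing to the likelihood or the counts.

This is the hot path of the whole package (hundreds of millions of origin
updates per run), so the sampler is written as a flat scalar loop over
non-missing allele copies with an inline xorshift64* generator: uniforms
come straight from the integer state, normals via Box-Muller and gamma
variates via Marsaglia-Tsang (with the shape<1 boost).  Everything is
deterministic given the integer seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit, uint64

_INV_2_64 = 1.0 / 18446744073709551616.0  # 2**-64
_MULT = uint64(2685821657736338717)


@njit(inline="always")
def _next_uniform(state):
    """xorshift64* step; returns (new_state, uniform in (0,1))."""
    state ^= state >> uint64(12)
    state ^= state << uint64(25)
    state ^= state >> uint64(27)
    u = np.float64(state * _MULT) * _INV_2_64
    if u <= 0.0:
        u = 2.7e-20
    elif u >= 1.0:
        u = 1.0 - 2.2e-16
    return state, u


@njit(inline="always")
def _next_normal(state):
    state, u1 = _next_uniform(state)
    state, u2 = _next_uniform(state)
    return state, math.sqrt(-2.0 * math.log(u1)) * math.cos(6.283185307179586 * u2)


@njit(inline="always")
def _next_gamma(state, shape):
    """Marsaglia-Tsang gamma(shape, 1); shape<1 handled by the boost trick."""
    boost = 1.0
    a = shape
    if a < 1.0:
        state, u = _next_uniform(state)
        boost = math.pow(u, 1.0 / a)
        a = a + 1.0
    d = a - 1.0 / 3.0
    c = 1.0 / math.sqrt(9.0 * d)
    while True:
        state, x = _next_normal(state)
        v = 1.0 + c * x
        if v <= 0.0:
            continue
        v = v * v * v
        state, u = _next_uniform(state)
        x2 = x * x
        if u < 1.0 - 0.0331 * x2 * x2:
            return state, boost * d * v
        if math.log(u) < 0.5 * x2 + d * (1.0 - v + math.log(v)):
            return state, boost * d * v


@njit(cache=True)
def k2_admixture_gibbs(
    copy_ind,      # (n_copies,) int64 individual index of each allele copy
    copy_off,      # (n_copies,) int64 flattened locus*max_a + support index
    n_ind,
    n_alleles,     # (n_loci,) int64 support size per locus
    max_a,
    lam,
    alpha_init,
    alpha_max,
    alpha_sd,
    update_alpha,
    n_burnin,
    n_iter,
    thin,
    seed,
):
    """Run the sampler; returns (q0_samples, alpha_trace).

    ``q0_samples`` has shape (n_kept, n_ind) and holds each individual's
    membership to (arbitrary) cluster 0 at every thinned post-burn-in sweep.
    Cluster anchoring/label switching is resolved by the caller.
    """
    state = uint64(seed) * uint64(6364136223846793005) + uint64(1442695040888963407)
    if state == uint64(0):
        state = uint64(88172645463325252)
    # warm up the state so small seeds decorrelate
    for _ in range(8):
        state, _u = _next_uniform(state)

    n_copies = copy_ind.shape[0]
    n_loci = n_alleles.shape[0]
    size = n_loci * max_a

    P = np.zeros(2 * size)
    for l in range(n_loci):
        for j in range(n_alleles[l]):
            P[l * max_a + j] = 1.0 / n_alleles[l]
            P[size + l * max_a + j] = 1.0 / n_alleles[l]
    q0 = np.full(n_ind, 0.5)
    q1 = np.full(n_ind, 0.5)
    alpha = alpha_init

    counts = np.zeros(2 * size)
    m = np.zeros(2 * n_ind)

    n_kept = n_iter // thin
    samples = np.zeros((n_kept, n_ind))
    alpha_trace = np.zeros(n_kept)
    kept = 0

    total = n_burnin + n_iter
    for sweep in range(total):
        # --- latent origins Z (branchless tally into [cluster0 | cluster1]) ---
        for o in range(2 * size):
            counts[o] = 0.0
        for i in range(2 * n_ind):
            m[i] = 0.0
        for c in range(n_copies):
            i = copy_ind[c]
            o = copy_off[c]
            w0 = q0[i] * P[o]
            w1 = q1[i] * P[size + o]
            state ^= state >> uint64(12)
            state ^= state << uint64(25)
            state ^= state >> uint64(27)
            r = np.float64(state * _MULT) * _INV_2_64
            zi = 1 if r * (w0 + w1) < w1 else 0
            counts[zi * size + o] += 1.0
            m[zi * n_ind + i] += 1.0

        # --- allele frequencies P | Z ---
        for k in range(2):
            for l in range(n_loci):
                base = k * size + l * max_a
                s = 0.0
                for j in range(n_alleles[l]):
                    state, g = _next_gamma(state, lam + counts[base + j])
                    if g < 1e-300:
                        g = 1e-300
                    P[base + j] = g
                    s += g
                for j in range(n_alleles[l]):
                    P[base + j] /= s

        # --- admixture proportions q | Z ---
        sum_log = 0.0
        for i in range(n_ind):
            state, g0 = _next_gamma(state, alpha + m[i])
            state, g1 = _next_gamma(state, alpha + m[n_ind + i])
            t = g0 + g1
            if t <= 0.0:
                a = 0.5
            else:
                a = g0 / t
            if a < 1e-12:
                a = 1e-12
            elif a > 1.0 - 1e-12:
                a = 1.0 - 1e-12
            q0[i] = a
            q1[i] = 1.0 - a
            sum_log += math.log(a) + math.log(1.0 - a)

        # --- alpha | q (random-walk Metropolis, uniform prior) ---
        if update_alpha:
            state, z = _next_normal(state)
            prop = alpha + alpha_sd * z
            if 0.0 < prop <= alpha_max:
                log_ratio = n_ind * (
                    math.lgamma(2.0 * prop) - 2.0 * math.lgamma(prop)
                    - math.lgamma(2.0 * alpha) + 2.0 * math.lgamma(alpha)
                ) + (prop - alpha) * sum_log
                state, u = _next_uniform(state)
                if math.log(u) < log_ratio:
                    alpha = prop

        # --- record ---
        if sweep >= n_burnin and (sweep - n_burnin) % thin == thin - 1:
            for i in range(n_ind):
                samples[kept, i] = q0[i]
            alpha_trace[kept] = alpha
            kept += 1

    return samples[:kept], alpha_trace[:kept]
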