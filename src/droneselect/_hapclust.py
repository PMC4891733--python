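"""Numba kernels for the haplotype-cluster hidden Markov model.

The model is the fastPHASE-style jump HMM: each haplotype follows a hidden
cluster path along the chromosome; between adjacent loci it stays in its
cluster with probability 1 − ρ_l or jumps to a cluster drawn from the
per-locus weights α_{l+1,·}; the emitted allele at locus l in cluster k is
Bernoulli(θ_{l,k}).  The kernel runs one scaled forward–backward E-step
over all haplotypes and accumulates the sufficient statistics for the
M-step, returning the data log-likelihood.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def estep(G, theta, alpha, rho, num, den, jc, stay_acc, gamma_out, store_gamma):
    """One E-step pass; accumulators must be zeroed by the caller.

    G: (n, L) int8 alleles in {0,1}; theta, alpha: (L, K); rho: (L-1,).
    num/den: (L, K) weighted allele / occupancy sums; jc: (L-1, K) expected
    jump-destination counts; stay_acc: (L-1,) expected stay probabilities.
    gamma_out: (n, L, K) posteriors, filled when store_gamma is True.
    Returns the total log-likelihood.
    """
    n, L = G.shape
    K = theta.shape[1]
    f = np.empty((L, K))
    b = np.empty((L, K))
    e = np.empty((L, K))
    c = np.empty(L)
    total_ll = 0.0
    for h in range(n):
        for l in range(L):
            g = G[h, l]
            for k in range(K):
                e[l, k] = theta[l, k] if g == 1 else 1.0 - theta[l, k]
        # scaled forward
        s = 0.0
        for k in range(K):
            f[0, k] = alpha[0, k] * e[0, k]
            s += f[0, k]
        c[0] = s
        for k in range(K):
            f[0, k] /= s
        for l in range(L - 1):
            s = 0.0
            for k in range(K):
                v = e[l + 1, k] * (
                    (1.0 - rho[l]) * f[l, k] + rho[l] * alpha[l + 1, k]
                )
                f[l + 1, k] = v
                s += v
            c[l + 1] = s
            for k in range(K):
                f[l + 1, k] /= s
        for l in range(L):
            total_ll += np.log(c[l])
        # scaled backward
        for k in range(K):
            b[L - 1, k] = 1.0
        for l in range(L - 2, -1, -1):
            jsum = 0.0
            for k in range(K):
                jsum += alpha[l + 1, k] * e[l + 1, k] * b[l + 1, k]
            for k in range(K):
                b[l, k] = (
                    (1.0 - rho[l]) * e[l + 1, k] * b[l + 1, k] + rho[l] * jsum
                ) / c[l + 1]
        # posteriors and occupancy counts
        for l in range(L):
            g = G[h, l]
            tot = 0.0
            for k in range(K):
                tot += f[l, k] * b[l, k]
            for k in range(K):
                gam = f[l, k] * b[l, k] / tot
                den[l, k] += gam
                if g == 1:
                    num[l, k] += gam
                if store_gamma:
                    gamma_out[h, l, k] = gam
        # transition posteriors (stay vs jump-to-k')
        for l in range(L - 1):
            for k in range(K):
                jc[l, k] += (
                    rho[l] * alpha[l + 1, k] * e[l + 1, k] * b[l + 1, k] / c[l + 1]
                )
                stay_acc[l] += (
                    (1.0 - rho[l]) * f[l, k] * e[l + 1, k] * b[l + 1, k] / c[l + 1]
                )
    return total_ll
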