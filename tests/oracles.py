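"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's implementations (and numpy
vectorization where feasible): plain-Python formula evaluation, rank
construction by sorting, exhaustive enumeration for the variational bound
and the permutation test.
"""

import itertools
import math


def jaccard_distance(x, y) -> float:
    inter = sum(1 for a, b in zip(x, y) if a and b)
    union = sum(1 for a, b in zip(x, y) if a or b)
    return 1.0 - inter / union if union else 1.0


def pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def _average_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman(x, y) -> float:
    return pearson(_average_ranks(list(x)), _average_ranks(list(y)))


def _sample_var(v) -> float:
    n = len(v)
    m = sum(v) / n
    return sum((a - m) ** 2 for a in v) / (n - 1)


def phi(cx, cy) -> float:
    return _sample_var([a - b for a, b in zip(cx, cy)]) / _sample_var(
        [a + b for a, b in zip(cx, cy)]
    )


def poisson_sbm_elbo(A, tau, pi, lam, mask=None) -> float:
    """ELBO by exhaustive enumeration over all label assignments.

    ELBO = sum_z q(z) [log p(A, z) - log q(z)] for the factorized
    q(z) = prod_i tau_{i, z_i}; feasible for a handful of nodes.
    """
    L = len(A)
    N = len(tau)
    Q = len(pi)
    total = 0.0
    for z in itertools.product(range(Q), repeat=N):
        q = 1.0
        for i in range(N):
            q *= tau[i][z[i]]
        if q == 0.0:
            continue
        logp = sum(math.log(pi[z[i]]) for i in range(N))
        for l in range(L):
            for i in range(N):
                for j in range(i + 1, N):
                    if mask is not None and not mask[l][i][j]:
                        continue
                    rate = lam[l][z[i]][z[j]]
                    a = A[l][i][j]
                    logp += a * math.log(rate) - rate - math.lgamma(a + 1)
        total += q * (logp - math.log(q))
    return total


def sbm_m_step(A, tau, mask=None):
    """pi and lambda by direct loops over node pairs."""
    L = len(A)
    N = len(tau)
    Q = len(tau[0])
    pi = [sum(tau[i][q] for i in range(N)) / N for q in range(Q)]
    lam = [[[0.0] * Q for _ in range(Q)] for _ in range(L)]
    for l in range(L):
        for q in range(Q):
            for r in range(Q):
                num = den = 0.0
                for i in range(N):
                    for j in range(N):
                        if i == j:
                            continue
                        if mask is not None and not mask[l][i][j]:
                            continue
                        w = tau[i][q] * tau[j][r]
                        num += w * A[l][i][j]
                        den += w
                lam[l][q][r] = num / den if den > 0 else 0.0
    return pi, lam


def permutation_pvalue(a, b, n_perm=None) -> float:
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += (x > y) + 0.5 * (x == y)
        return u

    observed = u_stat(a, b)
    mu = n1 * len(b) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_stat(ga, gb)
        if abs(u - mu) >= abs(observed - mu) - 1e-12:
            count += 1
        total += 1
    return count / total
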