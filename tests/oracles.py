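"""Independent brute-force oracles used to check the statistical estimators.

Everything here is written as directly as possible from first principles
(pair enumeration, nested ANOVA sums of squares, exhaustive sign/table
enumeration, scalar likelihood maximisation) and deliberately shares no code
with the package implementations it verifies.
"""

import itertools
import math

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import hypergeom


def pi_site_oracle(dosages) -> float:
    """Per-site pi by enumerating every pair of called allele copies."""
    alleles = []
    for d in dosages:
        if d == -1:
            continue
        alleles.extend([1] * int(d) + [0] * (2 - int(d)))
    n = len(alleles)
    if n < 2:
        return float("nan")
    diffs = sum(1 for a, b in itertools.combinations(alleles, 2) if a != b)
    return diffs / (n * (n - 1) / 2)


def watterson_oracle(S, n, L) -> float:
    a = 0.0
    for i in range(1, n):
        a += 1.0 / i
    return S / (a * L)


def tajima_d_oracle(dosage_matrix) -> float:
    """Tajima's D from a complete (sites x samples) dosage matrix.

    pi summed by pair enumeration per site; constants written out from the
    1989 definitions with explicit loops; n = 2 x samples.
    """
    m = np.asarray(dosage_matrix)
    n = 2 * m.shape[1]
    pis = [pi_site_oracle(row) for row in m]
    pis = [p for p in pis if p > 0]
    S = len(pis)
    if S == 0 or n < 4:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (sum(pis) - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def fst_anova_oracle(dosages, pops) -> float:
    """WC84 F_ST via the nested allele-level ANOVA mean squares."""
    dosages = np.asarray(dosages)
    pops = np.asarray(pops)
    groups = []
    for lab in dict.fromkeys(pops):
        d = dosages[pops == lab]
        d = d[d != -1]
        if len(d):
            groups.append(d)
    r = len(groups)
    if r < 2:
        raise ValueError("need two populations")
    alleles = [
        [(1, 1) if x == 2 else (1, 0) if x == 1 else (0, 0) for x in g] for g in groups
    ]
    n_i = [len(g) for g in groups]
    N = sum(n_i)
    ybar = sum(a + b for g in alleles for a, b in g) / (2.0 * N)
    ybar_i = [sum(a + b for a, b in g) / (2.0 * len(g)) for g in alleles]
    SSP = sum(2 * n * (yi - ybar) ** 2 for n, yi in zip(n_i, ybar_i))
    SSI = sum(2 * ((a + b) / 2.0 - yi) ** 2 for g, yi in zip(alleles, ybar_i) for a, b in g)
    SSW = sum(
        (a - (a + b) / 2.0) ** 2 + (b - (a + b) / 2.0) ** 2 for g in alleles for a, b in g
    )
    MSP = SSP / (r - 1)
    MSI = SSI / (N - r) if N > r else 0.0
    MSW = SSW / N
    n_c = (N - sum(n * n for n in n_i) / N) / (r - 1)
    sa = (MSP - MSI) / (2 * n_c)
    sb = (MSI - MSW) / 2.0
    sc = MSW
    denom = sa + sb + sc
    if denom == 0 or np.isnan(denom):
        return float("nan")
    return sa / denom


def wilcoxon_exact_oracle(deltas) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray([x for x in deltas if x != 0], dtype=float)
    n = len(d)
    absd = np.abs(d)
    # mid-ranks
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_abs[j] == sorted_abs[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    w_obs = ranks[d > 0].sum()
    w_all = []
    for signs in itertools.product([0, 1], repeat=n):
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.asarray(w_all)
    eps = 1e-9
    p_le = np.mean(w_all <= w_obs + eps)
    p_ge = np.mean(w_all >= w_obs - eps)
    return min(1.0, 2.0 * min(p_le, p_ge))


def fisher_exact_oracle(table):
    """Two-sided Fisher p by enumeration over tables with fixed margins,
    plus the conditional-MLE odds ratio by direct likelihood maximisation."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(support, n, col1, row1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    p = float(probs[probs <= p_obs * (1 + 1e-7)].sum())

    # conditional MLE of the odds ratio: maximise the noncentral
    # hypergeometric log-likelihood at the observed cell
    log_binom = (
        np.array([math.lgamma(row1 + 1) - math.lgamma(k + 1) - math.lgamma(row1 - k + 1)
                  for k in support])
        + np.array([math.lgamma(n - row1 + 1) - math.lgamma(col1 - k + 1)
                    - math.lgamma(n - row1 - (col1 - k) + 1) for k in support])
    )

    def neg_loglik(log_psi):
        w = log_binom + support * log_psi
        mx = w.max()
        denom = mx + math.log(np.exp(w - mx).sum())
        a_w = log_binom[support == a][0] + a * log_psi
        return -(a_w - denom)

    if a == lo:
        return 0.0, p
    if a == hi:
        return float("inf"), p
    res = minimize_scalar(neg_loglik, bounds=(-30, 30), method="bounded")
    return float(math.exp(res.x)), p


def bh_oracle(pvals):
    """Step-up BH applied by hand."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj
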