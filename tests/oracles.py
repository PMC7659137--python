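"""Independent brute-force oracles for the stability statistics.

Everything here is written directly from the definitional formulas with
plain Python loops and no shared code with the package, so tests can check
the vectorized implementations against an independent route.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def sd(xs) -> float:
    xs = list(xs)
    m = sum(xs) / len(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def genorm_m_oracle(q: np.ndarray) -> list[float]:
    """M per gene: mean over partners of SD of pairwise log2 ratios."""
    m_genes, n = q.shape
    out = []
    for j in range(m_genes):
        vs = []
        for k in range(m_genes):
            if k == j:
                continue
            ratios = [math.log2(q[j, s] / q[k, s]) for s in range(n)]
            vs.append(sd(ratios))
        out.append(sum(vs) / len(vs))
    return out


def genorm_v_curve_oracle(q: np.ndarray, order: list[int]) -> list[float]:
    """V(n/n+1) from scratch: geometric-mean NFs along the given order."""
    n_samples = q.shape[1]
    m = len(order)
    curve = []
    for n in range(2, m):
        vals = []
        for s in range(n_samples):
            nf_n = math.prod(q[g, s] for g in order[:n]) ** (1.0 / n)
            nf_n1 = math.prod(q[g, s] for g in order[: n + 1]) ** (1.0 / (n + 1))
            vals.append(math.log2(nf_n / nf_n1))
        curve.append(sd(vals))
    return curve


def bestkeeper_oracle(cq: np.ndarray):
    """(sd, cv%, index, r) per the definitional formulas."""
    m, n = cq.shape
    sds = [sd(cq[i]) for i in range(m)]
    cvs = [100.0 * sds[i] / (sum(cq[i]) / n) for i in range(m)]
    index = [math.prod(cq[i, s] for i in range(m)) ** (1.0 / m) for s in range(n)]
    rs = []
    for i in range(m):
        x, y = cq[i], index
        mx, my = sum(x) / n, sum(y) / n
        sxy = sum((x[s] - mx) * (y[s] - my) for s in range(n))
        sxx = sum((x[s] - mx) ** 2 for s in range(n))
        syy = sum((y[s] - my) ** 2 for s in range(n))
        rs.append(sxy / math.sqrt(sxx * syy) if sxx > 0 and syy > 0 else float("nan"))
    return sds, cvs, index, rs


def delta_ct_oracle(cq: np.ndarray) -> list[float]:
    """Mean over partners of SD of pairwise Cq differences."""
    m, n = cq.shape
    out = []
    for j in range(m):
        pair_sds = []
        for k in range(m):
            if k != j:
                pair_sds.append(sd([cq[j, s] - cq[k, s] for s in range(n)]))
        out.append(sum(pair_sds) / (m - 1))
    return out


def rank_average_ties(values: list[float]) -> list[float]:
    """1..m ranks ascending, ties get the mean of tied positions."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def geomean(xs) -> float:
    return math.prod(xs) ** (1.0 / len(xs))


def pooled_t_oracle(a: list[float], b: list[float]) -> tuple[float, float]:
    """Unpaired two-tailed Student's t with pooled variance."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    s2 = (sum((x - ma) ** 2 for x in a) + sum((x - mb) ** 2 for x in b)) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(s2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p


def normfinder_oracle(y: np.ndarray, groups: list):
    """Grouped NormFinder stability values via the moment formulas, by loops.

    y: gene x sample log2 quantities.
    """
    k, n = y.shape
    glabels = list(dict.fromkeys(groups))
    G = len(glabels)
    # center each sample across genes
    z = np.array([[y[i, s] - sum(y[ii, s] for ii in range(k)) / k for s in range(n)]
                  for i in range(k)])
    n_g = {g: groups.count(g) for g in glabels}
    s2 = {}
    zbar = {}
    for g in glabels:
        cols = [s for s in range(n) if groups[s] == g]
        for i in range(k):
            vals = [z[i, s] for s in cols]
            mu = sum(vals) / len(vals)
            s2[(i, g)] = sum((v - mu) ** 2 for v in vals) / (len(vals) - 1)
            zbar[(i, g)] = mu
    sigma2 = {}
    for g in glabels:
        tot = sum(s2[(i, g)] for i in range(k))
        for i in range(k):
            sigma2[(i, g)] = max(0.0, (s2[(i, g)] - tot / (k * (k - 1))) * k / (k - 2))
    d = {}
    for i in range(k):
        mean_over_groups = sum(zbar[(i, g)] for g in glabels) / G
        for g in glabels:
            d[(i, g)] = zbar[(i, g)] - mean_over_groups
    gamma2 = max(
        0.0,
        sum(d[(i, g)] ** 2 for i in range(k) for g in glabels) / (k * (G - 1))
        - sum(sigma2[(i, g)] / n_g[g] for i in range(k) for g in glabels) / (k * G),
    )
    stability = []
    for i in range(k):
        terms = []
        for g in glabels:
            vterm = sigma2[(i, g)] / n_g[g]
            denom = gamma2 + vterm
            dt = d[(i, g)] * gamma2 / denom if denom > 0 else 0.0
            post = gamma2 * vterm / denom if denom > 0 else 0.0
            terms.append(abs(dt) + math.sqrt(post))
        stability.append(sum(terms) / G)
    return stability
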