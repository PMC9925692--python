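"""Independent brute-force oracles used to validate the implementation.

These are deliberately naive: explicit loops, exact rational arithmetic and
literal enumeration, kept free of any code path from the package itself.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
from scipy import stats


def brute_force_anova(obs: np.ndarray):
    """Naive balanced two-way ANOVA from the mean decomposition.

    ``obs`` has shape (2, T, r): condition x timepoint x replicate.
    Returns dict with SS, F and p per term, via explicit loops.
    """
    a, b, r = obs.shape
    grand = obs.mean()
    ss_a = ss_b = ss_ab = ss_e = ss_tot = 0.0
    for i in range(a):
        ss_a += b * r * (obs[i].mean() - grand) ** 2
    for j in range(b):
        ss_b += a * r * (obs[:, j].mean() - grand) ** 2
    for i in range(a):
        for j in range(b):
            ss_ab += r * (obs[i, j].mean() - obs[i].mean() - obs[:, j].mean() + grand) ** 2
            for k in range(r):
                ss_e += (obs[i, j, k] - obs[i, j].mean()) ** 2
                ss_tot += (obs[i, j, k] - grand) ** 2
    df_a, df_b, df_ab, df_e = a - 1, b - 1, (a - 1) * (b - 1), a * b * (r - 1)
    mse = ss_e / df_e
    out = {"ss_total": ss_tot, "ss_error": ss_e, "mse": mse}
    for name, ss, df in (("drug", ss_a, df_a), ("time", ss_b, df_b),
                         ("interaction", ss_ab, df_ab)):
        F = (ss / df) / mse
        out[f"F_{name}"] = F
        out[f"p_{name}"] = float(stats.f.sf(F, df, df_e))
    return out


def binom_upper_tail(observed: int, n: int, p: Fraction) -> Fraction:
    """Exact P(X >= observed) for X ~ Binomial(n, p), rational arithmetic."""
    total = Fraction(0)
    for k in range(observed, n + 1):
        total += math.comb(n, k) * p**k * (1 - p) ** (n - k)
    return total


def hypergeom_upper_tail_enum(n_universe: int, n_in_set: int, n_query: int,
                              observed: int) -> Fraction:
    """P(overlap >= observed) by literal enumeration of all query draws."""
    universe = range(n_universe)
    in_set = set(range(n_in_set))
    hits = total = 0
    for draw in itertools.combinations(universe, n_query):
        total += 1
        if len(in_set.intersection(draw)) >= observed:
            hits += 1
    return Fraction(hits, total)


def bh_step_up(pvalues):
    """Hand step-up BH: sort, q_(i) = min_{j>=i} m p_(j)/j, unsort."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvalues[i] / rank)
        q[i] = min(running, 1.0)
    return q


def pooled_t_test(a, b, conf=0.95):
    """Textbook two-sample pooled-variance t-test with CI."""
    a, b = list(a), list(b)
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    se = math.sqrt(sp2 * (1 / na + 1 / nb))
    t = (ma - mb) / se
    p = float(2 * stats.t.sf(abs(t), df))
    tc = float(stats.t.ppf(0.5 + conf / 2, df))
    return {"t": t, "p": p, "ci": ((ma - mb) - tc * se, (ma - mb) + tc * se),
            "diff": ma - mb}
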