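"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately implemented with elementary arithmetic
(exact integers, exhaustive enumeration, golden-section search) and never
calls the library routine it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

# tables whose point probability exceeds the observed one by at most this
# relative margin still count as "as extreme" (float-tie absorption, the
# standard exact-test convention)
_REL_TIE = Fraction(10**7 + 1, 10**7)


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration with exact rationals.

    All tables with margins (a+b, c+d | a+c, b+d) are enumerated; the
    p-value sums the hypergeometric probabilities of those whose point
    probability is <= the observed table's (with the standard 1e-7 relative
    tie margin). Probabilities share the denominator C(n, a+c), so the
    comparison is done on exact integer numerators.
    """
    r1, r2, m = a + b, c + d, a + c
    lo, hi = max(0, m - r2), min(r1, m)
    weights = {x: math.comb(r1, x) * math.comb(r2, m - x) for x in range(lo, hi + 1)}
    obs = weights[a]
    total = sum(weights.values())
    tail = sum(w for w in weights.values() if Fraction(w) <= obs * _REL_TIE)
    return float(Fraction(tail, total))


def cmle_odds_ratio_grid(a: int, b: int, c: int, d: int,
                         lo: float = 1e-8, hi: float = 1e8,
                         tol: float = 1e-10) -> float:
    """Conditional-MLE odds ratio by brute-force likelihood maximisation.

    Maximises Fisher's noncentral hypergeometric conditional likelihood of
    the table — oriented so the estimated ratio is comparator-odds/case-odds,
    i.e. the noncentrality weights the comparator row — over log(psi) with a
    coarse grid refined by golden-section search.
    """
    # support of the comparator count c given margins
    r1, r2, m = c + d, a + b, a + c  # comparator row first
    xlo, xhi = max(0, m - r2), min(r1, m)
    binoms = [(x, math.comb(r1, x) * math.comb(r2, m - x)) for x in range(xlo, xhi + 1)]

    def loglik(logpsi: float) -> float:
        mx = max(math.log(w) + x * logpsi for x, w in binoms)
        denom = sum(math.exp(math.log(w) + x * logpsi - mx) for x, w in binoms)
        return math.log(binoms[c - xlo][1]) + c * logpsi - (mx + math.log(denom))

    grid = [math.log(lo) + i * (math.log(hi) - math.log(lo)) / 400 for i in range(401)]
    best = max(range(len(grid)), key=lambda i: loglik(grid[i]))
    left = grid[max(best - 1, 0)]
    right = grid[min(best + 1, len(grid) - 1)]
    # golden-section refinement on [left, right]
    invphi = (math.sqrt(5) - 1) / 2
    x1 = right - invphi * (right - left)
    x2 = left + invphi * (right - left)
    f1, f2 = loglik(x1), loglik(x2)
    while right - left > tol:
        if f1 < f2:
            left, x1, f1 = x1, x2, f2
            x2 = left + invphi * (right - left)
            f2 = loglik(x2)
        else:
            right, x2, f2 = x2, x1, f1
            x1 = right - invphi * (right - left)
            f1 = loglik(x1)
    return math.exp((left + right) / 2)


def auc_all_pairs(case_scores, comparator_scores) -> float:
    """AUC as the normalised concordance count (ties worth 1/2)."""
    conc = 0.0
    for s1 in case_scores:
        for s0 in comparator_scores:
            if s1 > s0:
                conc += 1.0
            elif s1 == s0:
                conc += 0.5
    return conc / (len(case_scores) * len(comparator_scores))


def softmax_by_hand(intercepts, slopes, x):
    """Spreadsheet-style softmax evaluation: exp(eta)/sum over classes.

    intercepts/slopes describe the non-reference classes; the reference
    class contributes exp(0).
    """
    etas = []
    for b0, bs in zip(intercepts, slopes):
        etas.append(b0 + sum(bj * xj for bj, xj in zip(bs, x)))
    exps = [math.exp(e) for e in etas] + [1.0]
    total = sum(exps)
    return [e / total for e in exps]
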