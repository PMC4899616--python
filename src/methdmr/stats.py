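"""Exact count statistics used by the DMR caller and overlap tests.

The two-sided Fisher exact p-value follows the classical definition: the
sum, over all 2x2 tables with the observed margins, of the probabilities of
tables no more probable than the observed one.  For small tables the tail
is evaluated in exact integer arithmetic (the hypergeometric pmf shares the
denominator C(N, r1), so "no more probable" is an integer comparison with
no floating-point tie ambiguity).  Large tables switch to a vectorised
floating pmf with a relative tie tolerance, where ties are numerically
irrelevant.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy.stats import hypergeom

# Largest table total handled by the exact integer path.  Above this the
# float path is indistinguishable at the precision anything downstream uses.
EXACT_LIMIT = 500

_TIE_RTOL = 1e-9


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    a,b = methylated/unmethylated in sample 1; c,d = sample 2.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1 = a + b
    c1 = a + c
    n = a + b + c + d
    if n == 0:
        return 1.0
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0  # degenerate margin: only one table possible

    k_min = max(0, r1 - (n - c1))
    k_max = min(r1, c1)
    if n <= EXACT_LIMIT:
        return _fisher_exact_int(a, r1, c1, n, k_min, k_max)
    return _fisher_float(a, r1, c1, n, k_min, k_max)


def _fisher_exact_int(a: int, r1: int, c1: int, n: int,
                      k_min: int, k_max: int) -> float:
    # numerators of the hypergeometric pmf over the common denominator
    # C(n, r1): num(k) = C(c1, k) * C(n - c1, r1 - k), built by the exact
    # integer recurrence num(k+1) = num(k)*(c1-k)*(r1-k) / ((k+1)*(n-c1-r1+k+1))
    c2 = n - c1
    num = comb(c1, k_min) * comb(c2, r1 - k_min)
    nums = [num]
    for k in range(k_min, k_max):
        num = num * (c1 - k) * (r1 - k) // ((k + 1) * (c2 - r1 + k + 1))
        nums.append(num)
    num_obs = nums[a - k_min]
    tail = sum(v for v in nums if v <= num_obs)
    return float(Fraction(tail, comb(n, r1)))


def _fisher_float(a: int, r1: int, c1: int, n: int,
                  k_min: int, k_max: int) -> float:
    support = np.arange(k_min, k_max + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - k_min]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return min(p, 1.0)


def hypergeom_upper_tail(k: int, n_total: int, n_success: int, n_draws: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N=n_total, K=n_success, n=n_draws).

    Upper tail including the observed value; k=0 gives 1 exactly.
    """
    if not (0 <= n_success <= n_total and 0 <= n_draws <= n_total):
        raise ValueError("inconsistent hypergeometric parameters")
    if k < 0 or k > min(n_success, n_draws):
        raise ValueError(f"k={k} outside [0, min(K, n)]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, n_total, n_success, n_draws))
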