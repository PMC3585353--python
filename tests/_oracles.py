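"""Independent oracles shared by the test suite.

These deliberately avoid the package's own enumeration and fitting code:
pair compatibility is checked by brute force over all 2^w haplotypes and the
likelihood is maximized by a generic multi-start simplex optimizer.
"""

import itertools
import math

import numpy as np
from scipy.optimize import minimize


def oracle_loglik(freqs, haps, calls):
    ll = 0.0
    for row in calls:
        s = 0.0
        for i, h1 in enumerate(haps):
            for j in range(i, len(haps)):
                h2 = haps[j]
                compatible = all(
                    g == -1 or h1[k] + h2[k] == g for k, g in enumerate(row)
                )
                if compatible:
                    s += freqs[i] * freqs[j] * (2.0 if i != j else 1.0)
        if s <= 0:
            return -math.inf
        ll += math.log(s)
    return ll


def oracle_max_loglik(calls, w, n_starts=8, seed=0):
    """Maximize the observed-data likelihood over the full 2^w simplex by
    multi-start Nelder-Mead on softmax coordinates."""
    haps = list(itertools.product((0, 1), repeat=w))
    rng = np.random.default_rng(seed)

    def neg(theta):
        e = np.exp(theta - theta.max())
        f = e / e.sum()
        return -oracle_loglik(f, haps, calls)

    best = math.inf
    best_f = None
    starts = [np.zeros(len(haps))] + [rng.normal(size=len(haps))
                                      for _ in range(n_starts - 1)]
    for x0 in starts:
        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "fatol": 1e-10, "xatol": 1e-8})
        if res.fun < best:
            best = res.fun
            e = np.exp(res.x - res.x.max())
            best_f = e / e.sum()
    return -best, dict(zip(haps, best_f))
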