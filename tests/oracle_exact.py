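"""Brute-force enumeration oracle for the conditional NB exact test.

Group sums of i.i.d. NB (or Poisson) libraries are themselves NB (Poisson),
so conditional split probabilities come straight from scipy pmf products.
The nuisance per-library mean cancels in the conditioning; any value gives
the same answer.  Independent of the gammaln-based implementation it checks.
"""

import numpy as np
from scipy import stats


def enumeration_exact_test(a, b, phi, mean_per_lib=7.0):
    sa, sb = int(sum(a)), int(sum(b))
    t = sa + sb
    na, nb = len(a), len(b)
    ks = np.arange(t + 1)
    if phi == 0.0:
        pa = stats.poisson.pmf(ks, na * mean_per_lib)
        pb = stats.poisson.pmf(t - ks, nb * mean_per_lib)
    else:
        r = 1.0 / phi
        p_nb = r / (r + mean_per_lib)
        pa = stats.nbinom.pmf(ks, na * r, p_nb)
        pb = stats.nbinom.pmf(t - ks, nb * r, p_nb)
    probs = pa * pb
    probs = probs / probs.sum()
    p_obs = probs[sa]
    return float(probs[probs <= p_obs * (1 + 1e-10)].sum())
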