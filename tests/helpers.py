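"""Shared simulation experiments used by more than one test module."""

import numpy as np

from genoscape._mutation import coalescent_microsat
from genoscape.demography import bottleneck_test, m_eq_null

def bottleneck_experiment(n_rep: int, seed: int = 77,
                           nsim_null: int = 300) -> tuple[int, int]:
    """Rejection counts (equilibrium arm, planted-crash arm) at alpha=0.05.

    Equilibrium: coalescent samples at theta = 6.  Crash: a deme of Ne 100
    drops to Ne 10 for 5 generations before sampling.  As in the real
    procedure, the null theta is estimated from the observed sample (SMM
    heterozygosity), so the crashed samples are judged against the
    equilibrium expected at their own reduced diversity.
    """
    rng = np.random.default_rng(seed)
    theta_pre, n_loci, n_copies = 6.0, 9, 30

    def _m(a):
        return len(np.unique(a)) / (a.max() - a.min() + 1.0)

    def _theta_hat(samples):
        hs = []
        for a in samples:
            n = len(a)
            _, c = np.unique(a, return_counts=True)
            hs.append((1 - ((c / n) ** 2).sum()) * n / (n - 1))
        he = min(float(np.mean(hs)), 0.999)
        return ((1 / (1 - he)) ** 2 - 1) / 2

    def _p(samples):
        m_obs = np.array([_m(a) for a in samples])
        null = m_eq_null(_theta_hat(samples), nsim=nsim_null,
                         n_gene_copies=n_copies, p_ss=0.88, rng=rng)
        return bottleneck_test(m_obs, np.full(n_loci, null.mean()))

    def _eq():
        return [coalescent_microsat(rng, n_copies, theta_pre, 0.88)
                for _ in range(n_loci)]

    def _bn():
        out = []
        for _ in range(n_loci):
            pool = coalescent_microsat(rng, 120, theta_pre, 0.88)
            crash = rng.choice(pool, size=20, replace=False)
            for _g in range(5):
                crash = crash[rng.integers(0, 20, size=20)]
            out.append(rng.choice(crash, size=n_copies, replace=True))
        return out

    rej_eq = sum(_p(_eq()) < 0.05 for _ in range(n_rep))
    rej_bn = sum(_p(_bn()) < 0.05 for _ in range(n_rep))
    return rej_eq, rej_bn
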