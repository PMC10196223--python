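"""Microsatellite mutation engine and single-locus coalescent simulator.

One mutation model serves two consumers: the forward Wright-Fisher
generator of synthetic genotypes and the coalescent equilibrium null of the
M-ratio bottleneck test.  Mutations follow a two-phase model (TPM): with
probability ``p_ss`` a mutation is a single repeat step (+/-1), otherwise a
multistep jump whose magnitude is geometric with mean ``mean_jump``; the sign
is always symmetric.  ``p_ss = 1`` recovers the strict stepwise model (SMM).
The allele-size ladder is unbounded (no reflecting range constraints).
"""

from __future__ import annotations

import numpy as np


def tpm_steps(rng: np.random.Generator, n: int,
              p_ss: float = 1.0, mean_jump: float = 2.8) -> np.ndarray:
    """Draw ``n`` signed mutation step sizes in repeat units."""
    if not 0.0 <= p_ss <= 1.0:
        raise ValueError("p_ss must lie in [0, 1]")
    if mean_jump < 1.0:
        raise ValueError("mean multistep jump must be >= 1")
    mag = np.ones(n, dtype=np.int64)
    multi = rng.random(n) >= p_ss
    if multi.any():
        # geometric on {1, 2, ...} with mean mean_jump
        mag[multi] = rng.geometric(1.0 / mean_jump, size=int(multi.sum()))
    sign = rng.integers(0, 2, size=n) * 2 - 1
    return mag * sign


def mutate_lattice(alleles: np.ndarray, mu: float, repeat_unit: int,
                   rng: np.random.Generator,
                   p_ss: float = 1.0, mean_jump: float = 2.8) -> np.ndarray:
    """Apply one generation of TPM mutation to an allele-size array (bp)."""
    out = alleles.copy()
    hit = rng.random(alleles.shape) < mu
    k = int(hit.sum())
    if k:
        out[hit] += tpm_steps(rng, k, p_ss, mean_jump) * repeat_unit
    return out


def coalescent_microsat(rng: np.random.Generator, n_copies: int, theta: float,
                        p_ss: float = 1.0, mean_jump: float = 2.8) -> np.ndarray:
    """Simulate one neutral equilibrium microsatellite sample.

    Kingman coalescent with time in units of 2N generations; mutations occur
    at rate ``theta / 2`` per lineage per unit time (theta = 4*Ne*mu), so the
    expected pairwise difference count equals ``theta``.  Returns ``n_copies``
    allele values in repeat units relative to the root allele (0).
    """
    if n_copies < 2:
        return np.zeros(max(n_copies, 0), dtype=np.int64)
    if theta < 0:
        raise ValueError("theta must be >= 0")
    alleles = np.zeros(n_copies, dtype=np.int64)
    # members[i] = sample indices below active lineage i
    members: list[np.ndarray] = [np.array([i]) for i in range(n_copies)]
    k = n_copies
    while k > 1:
        t = rng.exponential(2.0 / (k * (k - 1)))
        if theta > 0:
            n_mut = rng.poisson(theta / 2.0 * t, size=k)
            for lin in np.nonzero(n_mut)[0]:
                delta = int(tpm_steps(rng, int(n_mut[lin]), p_ss, mean_jump).sum())
                if delta:
                    alleles[members[lin]] += delta
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        members[i] = np.concatenate([members[i], members[j]])
        members.pop(j)
        k -= 1
    return alleles
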