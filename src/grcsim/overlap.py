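"""Overlap spectra of stored parallel-fiber patterns.

A pattern is the set of parallel fibers active at the scale of input to
one Purkinje cell (~1200 of 350,000 under regulation). When ``n + 1``
patterns are stored, the fraction of a focal pattern's synapses that also
participate in exactly ``k`` of the other ``n`` patterns is binomial,
``C(n, k) p^k (1 - p)^(n - k)``, with ``p`` the fraction of parallel
fibers active per pattern. The spectrum is the same for every stored
pattern, which is why training cannot teach a pattern-specific response.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "OverlapSpectrum",
    "overlap_proportions",
    "simulate_pattern_overlap",
    "total_variation",
]


@dataclass(frozen=True)
class OverlapSpectrum:
    """Proportions of a pattern's synapses shared with exactly k others."""

    n_other: int
    p_active: float
    proportions: np.ndarray  # index k = 0..n_other

    def __post_init__(self):
        s = float(np.sum(self.proportions))
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {s}, not 1")


def overlap_proportions(n_other: int, p_active: float) -> OverlapSpectrum:
    """Analytic overlap spectrum for ``n_other`` other stored patterns."""
    if n_other < 0:
        raise ValueError("n_other must be >= 0")
    if not 0.0 <= p_active <= 1.0:
        raise ValueError(f"p_active ({p_active}) outside [0, 1]")
    k = np.arange(n_other + 1)
    props = stats.binom.pmf(k, n_other, p_active)
    props = props / props.sum()  # renormalize away pmf rounding at extreme p
    return OverlapSpectrum(n_other=n_other, p_active=p_active, proportions=props)


def simulate_pattern_overlap(
    n_patterns: int,
    n_pf: int,
    n_active: int,
    rng: np.random.Generator,
) -> OverlapSpectrum:
    """Monte-Carlo overlap spectrum from random fixed-size patterns.

    Draws ``n_patterns`` subsets of ``n_active`` of ``n_pf`` parallel
    fibers; for one focal pattern, tabulates how many *other* patterns
    each of its fibers participates in. With ``n_active << n_pf`` the
    fixed-size (hypergeometric) construction is indistinguishable from
    the independent-Bernoulli assumption of the analytic spectrum.
    """
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    if not 0 < n_active <= n_pf:
        raise ValueError(f"n_active ({n_active}) must lie in (0, n_pf={n_pf}]")

    focal = rng.choice(n_pf, size=n_active, replace=False)
    in_focal = np.zeros(n_pf, dtype=bool)
    in_focal[focal] = True
    shared = np.zeros(n_pf, dtype=np.int64)
    for _ in range(n_patterns - 1):
        other = rng.choice(n_pf, size=n_active, replace=False)
        shared[other] += 1
    counts = np.bincount(shared[in_focal], minlength=n_patterns)
    return OverlapSpectrum(
        n_other=n_patterns - 1,
        p_active=n_active / n_pf,
        proportions=counts / n_active,
    )


def total_variation(a: OverlapSpectrum, b: OverlapSpectrum) -> float:
    """TV distance between two spectra over the common support."""
    n = max(a.proportions.size, b.proportions.size)
    pa = np.zeros(n)
    pb = np.zeros(n)
    pa[: a.proportions.size] = a.proportions
    pb[: b.proportions.size] = b.proportions
    return float(0.5 * np.abs(pa - pb).sum())
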