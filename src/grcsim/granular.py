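"""Per-field binomial threshold model of granule-cell activation.

A cluster field holds ``N`` granule cells with ``n`` dendrites each, every
dendrite contacted by one of the field's ``y`` mossy fibers. When ``x`` of
the ``y`` mossy fibers are active and Golgi inhibition vetoes a glomerulus
with probability ``P(v)``, a dendrite delivers effective excitation with
probability ``(1 - P(v)) * x / y``, independently across dendrites. A cell
fires when at least ``m`` (the input threshold) dendrites deliver, so the
expected firing count is ``N * P(Binomial(n, q) >= m)``.

The veto is applied per glomerulus (per dendrite), not per cell: a granule
cell may be inhibited by a different Golgi cell at each of its dendrites,
so the (input, veto) pairs are independent across dendrites.
"""
from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike
from scipy import stats

from .params import AnatomyParams

__all__ = [
    "expected_firing_count",
    "expected_full_input_count",
    "realize_threshold_counts",
]


def _validate(x: ArrayLike, p_veto: ArrayLike, params: AnatomyParams) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    p = np.asarray(p_veto, dtype=float)
    if np.any(x < 0) or np.any(x > params.n_mf_per_field):
        raise ValueError(
            f"x (active mossy fibers) must lie in [0, {params.n_mf_per_field}]"
        )
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p_veto must lie in [0, 1]")
    return x, p


def expected_firing_count(x: ArrayLike, p_veto: ArrayLike, params: AnatomyParams):
    """Expected granule cells firing in one field.

    Parameters
    ----------
    x
        Active mossy fibers in the field (scalar or array; broadcast
        against ``p_veto``).
    p_veto
        Glomerular veto probability in [0, 1].
    params
        Anatomical constants (N, n, m, y).

    Returns
    -------
    float or ndarray
        ``N * P(K >= m)`` with ``K ~ Binomial(n, (1 - p_veto) * x / y)``.
    """
    x, p = _validate(x, p_veto, params)
    q = (1.0 - p) * x / params.n_mf_per_field
    tail = stats.binom.sf(params.input_threshold - 1, params.n_dendrites, q)
    out = params.n_grc_per_field * tail
    return float(out) if np.ndim(out) == 0 else out


def expected_full_input_count(x: ArrayLike, params: AnatomyParams):
    """Expected granule cells with input to all ``n`` dendrites, veto ignored.

    This is ``N * (x / y) ** n`` — the all-dendrites-active population
    reported alongside the threshold counts.
    """
    x, _ = _validate(x, 0.0, params)
    out = params.n_grc_per_field * (x / params.n_mf_per_field) ** params.n_dendrites
    return float(out) if np.ndim(out) == 0 else out


def _realize(
    x: int,
    p_veto: float,
    params: AnatomyParams,
    rng: np.random.Generator,
) -> tuple[int, int, int]:
    """Draw one field realization; returns (threshold, firing, full-input) counts.

    Sampling note: per cell, the number of active dendrites is
    Binomial(n, x/y) and, given k active dendrites, the number that
    additionally escape the veto is Binomial(k, 1 - p_veto). Drawing these
    two binomials per cell is distributionally identical to drawing the
    n individual (input, veto) Bernoulli pairs, and preserves
    firing <= threshold draw by draw.
    """
    p_in = x / params.n_mf_per_field
    k_active = rng.binomial(params.n_dendrites, p_in, size=params.n_grc_per_field)
    k_clear = rng.binomial(k_active, 1.0 - p_veto)
    m = params.input_threshold
    count_threshold = int(np.count_nonzero(k_active >= m))
    count_firing = int(np.count_nonzero(k_clear >= m))
    count_full = int(np.count_nonzero(k_active == params.n_dendrites))
    return count_threshold, count_firing, count_full


def realize_threshold_counts(
    x: int,
    p_veto: float,
    params: AnatomyParams,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Monte-Carlo twin of :func:`expected_firing_count`.

    Draws the activation state of all ``N`` granule cells in one field
    and returns ``(count_threshold, count_firing)``: cells with at least
    ``m`` active dendrites, and cells with at least ``m`` active and
    un-vetoed dendrites. ``count_firing <= count_threshold`` in every draw.
    """
    xv, pv = _validate(x, p_veto, params)
    if xv.ndim != 0:
        raise ValueError("realize_threshold_counts takes scalar x")
    count_threshold, count_firing, _ = _realize(int(x), float(p_veto), params, rng)
    return count_threshold, count_firing
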