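"""Homeostatic regulation of parallel-fiber activity by Golgi cells.

Parallel fibers from every field in a beam excite Golgi apical dendrites
all along the beam, and each Golgi cell translates the *density* of that
activity into a glomerular veto probability through a sigmoid spanning
4-16 active inputs. The resulting negative-feedback loop (granule counts
-> Golgi drive -> veto -> granule counts) is iterated with damping to its
fixed point on a 5-beam x 20-field grid. Three local refinements enter
each field's Golgi drive:

* the same-field granule contribution is up-weighted (``local_weight``),
  since a Golgi cell is far more likely to receive contact from a granule
  cell in its own field;
* the sagittally adjacent field in each adjacent beam contributes with
  weight ``neighbor_weight``, because the Golgi axonal plexus is
  sagittally elongated and spills into neighbouring cluster fields;
* direct mossy-fiber contact on Golgi basal dendrites adds
  ``basal_boost`` scaled by the hypergeometric probability of at least
  ``basal_mf_min`` active inputs among ``basal_contacts`` sampled fibers.

The middle beam of the five is the reported statistic; the outer beams
exist to give it realistic neighbours (no wraparound).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .granular import (
    _realize,
    expected_firing_count,
    expected_full_input_count,
)
from .params import AnatomyParams, GolgiFeedbackParams

__all__ = [
    "FieldState",
    "BeamTrialResult",
    "CalibrationResult",
    "golgi_active_inputs",
    "veto_from_inputs",
    "basal_tail_probability",
    "field_drive",
    "run_beam_regulation",
    "run_trials",
    "summarize_trials",
    "calibrate_gain",
]


@dataclass(frozen=True)
class FieldState:
    """One cluster field at the end of a beam-regulation run."""

    x_active_mf: int
    p_veto: float
    count_threshold: float
    count_firing: float


@dataclass(frozen=True)
class BeamTrialResult:
    """Converged state of the beam grid for one trial.

    Array attributes have shape (n_beams, fields_per_beam). ``count_threshold``
    is the unregulated (veto = 0) threshold population; ``count_full_input``
    counts cells with input to all dendrites, veto ignored.
    """

    x_grid: np.ndarray
    p_veto: np.ndarray
    count_threshold: np.ndarray
    count_firing: np.ndarray
    count_full_input: np.ndarray
    iterations: int
    converged: bool

    @property
    def beam_totals(self) -> np.ndarray:
        """Regulated firing count summed along each beam."""
        return self.count_firing.sum(axis=1)

    @property
    def unregulated_totals(self) -> np.ndarray:
        return self.count_threshold.sum(axis=1)

    @property
    def middle_beam(self) -> int:
        return self.x_grid.shape[0] // 2

    @property
    def middle_beam_total(self) -> float:
        return float(self.beam_totals[self.middle_beam])

    def fields(self) -> list[list[FieldState]]:
        """Grid of per-field states (row = beam)."""
        B, F = self.x_grid.shape
        return [
            [
                FieldState(
                    x_active_mf=int(self.x_grid[b, i]),
                    p_veto=float(self.p_veto[b, i]),
                    count_threshold=float(self.count_threshold[b, i]),
                    count_firing=float(self.count_firing[b, i]),
                )
                for i in range(F)
            ]
            for b in range(B)
        ]


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the homeostasis-plateau gain search."""

    params: GolgiFeedbackParams
    spread: float
    table: pd.DataFrame = field(repr=False)


def golgi_active_inputs(beam_pf_total, anatomy: AnatomyParams):
    """Active parallel-fiber inputs per Golgi cell for a given PF drive.

    A Golgi cell receives ``pf_per_golgi`` contacts out of the
    ``pf_per_purkinje`` fibers that traverse its territory, so its
    expected number of *active* inputs is linear in the local density of
    parallel-fiber activity.
    """
    a = np.asarray(beam_pf_total, dtype=float)
    if np.any(a < 0):
        raise ValueError("beam_pf_total must be non-negative")
    out = anatomy.pf_per_golgi * a / anatomy.pf_per_purkinje
    return float(out) if np.ndim(out) == 0 else out


def veto_from_inputs(active_inputs, fb: GolgiFeedbackParams, anatomy: AnatomyParams):
    """Veto probability from active parallel-fiber inputs per Golgi cell.

    Logistic in ``active_inputs``, rescaled so the curve is exactly 0 at
    ``golgi_pf_floor`` (no effect below 4 inputs) and exactly ``veto_max``
    at ``golgi_pf_sat`` (saturation above 16); clipped outside that span.
    Monotone non-decreasing.
    """
    a = np.asarray(active_inputs, dtype=float)
    if np.any(a < 0):
        raise ValueError("active_inputs must be non-negative")

    def logistic(t):
        return 1.0 / (1.0 + np.exp(-fb.sigmoid_steepness * (np.asarray(t, float) - fb.sigmoid_midpoint)))

    lo = logistic(anatomy.golgi_pf_floor)
    hi = logistic(anatomy.golgi_pf_sat)
    r = (logistic(a) - lo) / (hi - lo)
    out = fb.veto_max * np.clip(r, 0.0, 1.0)
    return float(out) if np.ndim(out) == 0 else out


def basal_tail_probability(x, fb: GolgiFeedbackParams, anatomy: AnatomyParams):
    """P(>= basal_mf_min active) among basal_contacts fibers sampled from the field.

    Hypergeometric tail: a Golgi cell's basal dendrites sample
    ``basal_contacts`` of the field's ``n_mf_per_field`` mossy fibers, of
    which ``x`` are active.
    """
    x = np.asarray(x)
    out = stats.hypergeom.sf(
        anatomy.basal_mf_min - 1,
        anatomy.n_mf_per_field,
        x,
        fb.basal_contacts,
    )
    return float(out) if np.ndim(out) == 0 else out


def _drive_grid(
    counts: np.ndarray,
    basal_tail: np.ndarray,
    fb: GolgiFeedbackParams,
    anatomy: AnatomyParams,
) -> np.ndarray:
    """Effective active-PF drive of each field's Golgi population.

    Local part = own-beam total with the same-field term up-weighted,
    plus the basal-dendrite increment; the total adds ``neighbor_weight``
    times the local part of the sagittally adjacent field in each
    adjacent beam (truncated at the outer beams).
    """
    beam_totals = counts.sum(axis=1, keepdims=True)
    local = beam_totals + (fb.local_weight - 1.0) * counts + fb.basal_boost * basal_tail
    drive = local.copy()
    drive[1:] += fb.neighbor_weight * local[:-1]
    drive[:-1] += fb.neighbor_weight * local[1:]
    return drive


def field_drive(
    counts: np.ndarray,
    x_grid: np.ndarray,
    beam: int,
    fld: int,
    fb: GolgiFeedbackParams,
    anatomy: AnatomyParams,
) -> float:
    """Golgi drive of one field given the current firing-count grid."""
    counts = np.asarray(counts, dtype=float)
    x_grid = np.asarray(x_grid)
    B, F = counts.shape
    if not (0 <= beam < B and 0 <= fld < F):
        raise IndexError(f"field ({beam}, {fld}) outside grid {counts.shape}")
    tail = basal_tail_probability(x_grid, fb, anatomy)
    return float(_drive_grid(counts, tail, fb, anatomy)[beam, fld])


def _counts(x, p, fb, anatomy, rng):
    """Firing-count grid given the veto grid, per the configured mode."""
    if fb.mode == "expectation":
        return expected_firing_count(x, p, anatomy)
    out = np.empty(x.shape, dtype=float)
    for idx in np.ndindex(x.shape):
        out[idx] = _realize(int(x[idx]), float(p[idx]), anatomy, rng)[1]
    return out


def run_beam_regulation(
    x_grid,
    fb: GolgiFeedbackParams,
    anatomy: AnatomyParams,
    rng: np.random.Generator | None = None,
) -> BeamTrialResult:
    """Iterate the Golgi feedback loop to its fixed point for one trial.

    Starts with all veto probabilities at 0 and alternates count updates
    (from :mod:`grcsim.granular`) with damped veto updates
    ``p <- (1 - damping) p + damping p_new`` until the maximum relative
    change of any field's firing count falls below ``tol`` or ``max_iter``
    is reached. Non-convergence is reported in the result, not raised.
    In realization mode the counts are redrawn each iteration, so the
    count-change criterion rarely drops below ``tol`` and such runs
    typically report ``converged=False`` at ``max_iter``; the returned
    state is the damped end state.
    """
    x = np.asarray(x_grid, dtype=int)
    if x.shape != (anatomy.n_beams, anatomy.fields_per_beam):
        raise ValueError(
            f"x_grid shape {x.shape} != (n_beams, fields_per_beam) = "
            f"({anatomy.n_beams}, {anatomy.fields_per_beam})"
        )
    if np.any(x < 0) or np.any(x > anatomy.n_mf_per_field):
        raise ValueError("x values outside [0, n_mf_per_field]")
    if fb.mode == "realization" and rng is None:
        raise ValueError("realization mode requires a seeded rng")

    tail = basal_tail_probability(x, fb, anatomy)
    p = np.zeros(x.shape, dtype=float)

    if fb.mode == "expectation":
        count_threshold = np.asarray(expected_firing_count(x, 0.0, anatomy), float)
        count_full = np.asarray(expected_full_input_count(x, anatomy), float)
        f = count_threshold.copy()
    else:
        count_threshold = np.empty(x.shape, float)
        count_full = np.empty(x.shape, float)
        f = np.empty(x.shape, float)
        for idx in np.ndindex(x.shape):
            ct, _, cfull = _realize(int(x[idx]), 0.0, anatomy, rng)
            count_threshold[idx] = ct
            count_full[idx] = cfull
            f[idx] = ct

    converged = False
    iterations = 0
    for iterations in range(1, fb.max_iter + 1):
        drive = _drive_grid(f, tail, fb, anatomy)
        p_new = veto_from_inputs(golgi_active_inputs(drive, anatomy), fb, anatomy)
        p = (1.0 - fb.damping) * p + fb.damping * p_new
        f_new = np.asarray(_counts(x, p, fb, anatomy, rng), float)
        rel = np.max(np.abs(f_new - f) / np.maximum(np.abs(f), 1.0))
        f = f_new
        if rel < fb.tol:
            converged = True
            break

    return BeamTrialResult(
        x_grid=x,
        p_veto=p,
        count_threshold=count_threshold,
        count_firing=f,
        count_full_input=count_full,
        iterations=iterations,
        converged=converged,
    )


def run_trials(
    n_trials: int,
    fb: GolgiFeedbackParams,
    anatomy: AnatomyParams,
    *,
    seed: int,
    x_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Run the beam-regulation experiment over many trials.

    Each trial draws every field's active-mossy-fiber count uniformly
    from ``x_range`` (default: the anatomical range, 3..30) and iterates
    the feedback loop. Trials use independently spawned child streams of
    the root seed, so any trial is reproducible regardless of execution
    order.

    Returns a tidy table keyed by (trial, beam, field) with columns
    x, p_veto, count_threshold, count_firing, count_full_input, plus the
    per-trial diagnostics iterations and converged.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    lo, hi = x_range if x_range is not None else anatomy.x_range
    if not (0 <= lo <= hi <= anatomy.n_mf_per_field):
        raise ValueError(f"x_range ({lo}, {hi}) outside [0, {anatomy.n_mf_per_field}]")

    B, F = anatomy.n_beams, anatomy.fields_per_beam
    beams, flds = np.meshgrid(np.arange(B), np.arange(F), indexing="ij")
    frames = []
    for t, child in enumerate(np.random.SeedSequence(seed).spawn(n_trials)):
        rng = np.random.default_rng(child)
        x = rng.integers(lo, hi + 1, size=(B, F))
        res = run_beam_regulation(x, fb, anatomy, rng=rng)
        frames.append(
            pd.DataFrame(
                {
                    "trial": t,
                    "beam": beams.ravel(),
                    "field": flds.ravel(),
                    "x": res.x_grid.ravel(),
                    "p_veto": res.p_veto.ravel(),
                    "count_threshold": res.count_threshold.ravel(),
                    "count_firing": res.count_firing.ravel(),
                    "count_full_input": res.count_full_input.ravel(),
                    "iterations": res.iterations,
                    "converged": res.converged,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def summarize_trials(table: pd.DataFrame, anatomy: AnatomyParams) -> pd.DataFrame:
    """Per-trial middle-beam totals from a :func:`run_trials` table."""
    mid = anatomy.n_beams // 2
    sub = table[table["beam"] == mid]
    out = sub.groupby("trial").agg(
        regulated_total=("count_firing", "sum"),
        unregulated_total=("count_threshold", "sum"),
        full_input_total=("count_full_input", "sum"),
        iterations=("iterations", "first"),
        converged=("converged", "first"),
    )
    return out.reset_index()


def calibrate_gain(
    fb: GolgiFeedbackParams,
    anatomy: AnatomyParams,
    input_ranges: list[tuple[int, int]],
    seed: int,
    *,
    veto_max_grid=(0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    steepness_grid=(0.4, 0.6, 0.8),
    n_trials: int = 30,
) -> CalibrationResult:
    """Grid-search the sigmoid gain for the homeostasis plateau.

    For each (veto_max, sigmoid_steepness) candidate, measures the mean
    regulated middle-beam total over ``n_trials`` for every input range
    and scores the candidate by the coefficient of variation of those
    means (relative spread across ranges). All candidates see the same
    trial seeds (common random numbers), so the search is deterministic
    given ``seed``. Returns the best candidate, its spread, and the full
    search table.
    """
    if len(input_ranges) < 2:
        raise ValueError("calibration needs at least 2 input ranges")
    candidates = [(float(v), float(s)) for v in veto_max_grid for s in steepness_grid]
    if not candidates:
        raise ValueError("empty search grid")

    rows = []
    best = None
    for vm, st in candidates:
        cand = fb.model_copy(update={"veto_max": vm, "sigmoid_steepness": st})
        means = []
        for rng_lo, rng_hi in input_ranges:
            table = run_trials(n_trials, cand, anatomy, seed=seed, x_range=(rng_lo, rng_hi))
            means.append(summarize_trials(table, anatomy)["regulated_total"].mean())
        means = np.asarray(means)
        spread = float(means.std() / means.mean()) if means.mean() > 0 else np.inf
        rows.append(
            {
                "veto_max": vm,
                "sigmoid_steepness": st,
                "spread": spread,
                **{f"mean_{lo}_{hi}": m for (lo, hi), m in zip(input_ranges, means)},
            }
        )
        if best is None or spread < best[0]:
            best = (spread, cand)

    table = pd.DataFrame(rows)
    return CalibrationResult(params=best[1], spread=best[0], table=table)
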