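"""Validated parameter models for the granular-layer simulator.

All anatomical constants and free model parameters live here as frozen
pydantic models so that a run is fully described by one JSON document.
Defaults are the model's standard operating point: a 5-beam x 20-field
grid of mossy-fiber cluster fields, 8750 granule cells per field with
4 dendrites and an input threshold of 3 co-active inputs, and a Golgi
feedback sigmoid spanning 4-16 active parallel-fiber inputs.
"""
from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

Shape = Literal["uniform_grid", "uniform_random", "discontinuous", "top_weighted"]


class AnatomyParams(BaseModel):
    """Fixed anatomical constants of the granular-layer model.

    A *cluster field* is the territory of one mossy fiber's terminal
    cluster: ~100 mossy fibers innervate it and it contains 8750 granule
    cells. Twenty fields in a mediolateral row form a *beam* (3000 x 200
    um) whose parallel fibers traverse a shared Purkinje-cell territory
    of ~350,000 parallel fibers.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_mf_per_field: int = Field(100, gt=0, description="mossy fibers innervating one cluster field (y)")
    n_grc_per_field: int = Field(8750, gt=0, description="granule cells per cluster field (N)")
    n_dendrites: int = Field(4, gt=0, description="dendrites per granule cell (n), one mossy fiber each")
    input_threshold: int = Field(3, gt=0, description="minimum co-active, un-vetoed inputs to fire (m)")
    fields_per_beam: int = Field(20, gt=0)
    n_beams: int = Field(5, gt=0, description="beams simulated side by side; the middle one is reported")
    beam_length_um: float = Field(3000.0, gt=0)
    beam_width_um: float = Field(200.0, gt=0)
    pf_per_purkinje: int = Field(350_000, gt=0, description="parallel fibers traversing one Purkinje territory")
    pf_per_golgi: int = Field(1600, gt=0, description="parallel-fiber contacts on one Golgi cell")
    golgi_pf_floor: float = Field(4.0, ge=0, description="active PF inputs at onset of the Golgi response")
    golgi_pf_sat: float = Field(16.0, gt=0, description="active PF inputs at saturation of the Golgi response")
    basal_mf_min: int = Field(4, gt=0, description="minimum active mossy-fiber inputs for a direct basal-dendrite effect")
    x_range: tuple[int, int] = Field((3, 30), description="inclusive range of active mossy fibers per field per trial")

    @model_validator(mode="after")
    def _check(self) -> "AnatomyParams":
        if self.input_threshold > self.n_dendrites:
            raise ValueError(
                f"input_threshold ({self.input_threshold}) must not exceed "
                f"n_dendrites ({self.n_dendrites})"
            )
        if not self.golgi_pf_floor < self.golgi_pf_sat:
            raise ValueError("golgi_pf_floor must be below golgi_pf_sat")
        lo, hi = self.x_range
        if not (0 <= lo <= hi <= self.n_mf_per_field):
            raise ValueError(
                f"x_range {self.x_range} must satisfy 0 <= lo <= hi <= "
                f"n_mf_per_field ({self.n_mf_per_field})"
            )
        return self


class GolgiFeedbackParams(BaseModel):
    """Free parameters of the Golgi feedback loop.

    The density of active parallel fibers over a field is translated into
    active inputs per Golgi cell and then, through a rescaled logistic,
    into a glomerular veto probability. ``veto_max`` and
    ``sigmoid_steepness`` defaults were frozen from :func:`calibrate_gain`
    run against the homeostasis-plateau criterion (flat regulated totals
    across widely different input ranges), which is the behaviour the
    model specifies; no single published count was targeted.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    veto_max: float = Field(0.6, ge=0, le=1, description="veto probability at sigmoid saturation (calibrated)")
    sigmoid_midpoint: float = Field(10.0, gt=0, description="active PF inputs per Golgi cell at half-maximal veto")
    sigmoid_steepness: float = Field(0.8, gt=0, description="logistic slope per active input (calibrated)")
    local_weight: float = Field(2.0, ge=1, description="multiplier on the same-field granule contribution to Golgi drive")
    neighbor_weight: float = Field(0.5, ge=0, le=1, description="weight of the sagittally adjacent field of each adjacent beam")
    basal_boost: float = Field(800.0, ge=0, description="drive increment (active-PF units) scaled by the basal-input tail probability")
    basal_contacts: int = Field(12, gt=0, description="mossy fibers sampled by one Golgi cell's basal dendrites")
    damping: float = Field(0.2, gt=0, le=1, description="fixed-point update relaxation factor")
    tol: float = Field(0.01, gt=0, description="max relative change of any field's firing count at convergence")
    max_iter: int = Field(50, ge=1)
    mode: Literal["expectation", "realization"] = "expectation"


class RateDistributionSpec(BaseModel):
    """One mossy-fiber firing-rate population for the rate-recoding pipeline."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    shape: Shape = "uniform_random"
    rate_min: float = Field(50.0, ge=0, description="Hz")
    rate_max: float = Field(300.0, gt=0, description="Hz")
    n_active_mf: int = Field(300, ge=1, description="active mossy fibers in the beam")
    gap_bands: tuple[tuple[float, float], ...] = Field(
        ((120.0, 160.0), (200.0, 280.0)),
        description="excluded Hz bands (discontinuous shape only)",
    )
    skew_power: float = Field(2.0, gt=0, description="exponent pushing top_weighted density toward rate_max")

    @model_validator(mode="after")
    def _check(self) -> "RateDistributionSpec":
        if not self.rate_min < self.rate_max:
            raise ValueError("rate_min must be below rate_max")
        span = self.rate_max - self.rate_min
        gap_total = 0.0
        for lo, hi in self.gap_bands:
            if not (self.rate_min <= lo < hi <= self.rate_max):
                raise ValueError(
                    f"gap band ({lo}, {hi}) must lie within "
                    f"[{self.rate_min}, {self.rate_max}]"
                )
            gap_total += hi - lo
        if self.shape == "discontinuous" and gap_total >= span:
            raise ValueError("gap_bands cover the whole rate range")
        return self


class RateRecodingParams(BaseModel):
    """Sampling parameters for the granule-cell sample-means pipeline."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    sample_size: int = Field(3, ge=1, description="mossy fibers sampled per granule cell (one per dendrite)")
    n_samples: int = Field(4500, ge=1, description="granule cells receiving threshold-many active inputs per beam")
    top_slice_size: int = Field(1200, ge=1, description="granule cells that actually fire after Golgi competition")
    shift_offsets: tuple[float, ...] = Field(
        (-50.0, -25.0, 0.0, 25.0, 50.0),
        description="Hz location shifts used for the linearity check",
    )

    @model_validator(mode="after")
    def _check(self) -> "RateRecodingParams":
        if self.top_slice_size > self.n_samples:
            raise ValueError("top_slice_size must not exceed n_samples")
        return self


class OverlapParams(BaseModel):
    """Settings for the stored-pattern overlap spectra."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    p_values: tuple[float, ...] = Field(
        (0.05, 0.0214, 0.01, 0.00343),
        description="fractions of parallel fibers active per pattern",
    )
    n_other_max: int = Field(10, ge=1, description="sweep k-spectra for 1..n_other_max other stored patterns")
    n_patterns_sim: int = Field(5, ge=1, description="patterns drawn in the Monte-Carlo cross-check")

    @model_validator(mode="after")
    def _check(self) -> "OverlapParams":
        for p in self.p_values:
            if not 0 <= p <= 1:
                raise ValueError(f"p_value {p} outside [0, 1]")
        return self


class RunConfig(BaseModel):
    """Top-level configuration for a full simulator run."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    anatomy: AnatomyParams = AnatomyParams()
    feedback: GolgiFeedbackParams = GolgiFeedbackParams()
    rate_specs: tuple[RateDistributionSpec, ...] = (
        RateDistributionSpec(shape="uniform_grid"),
        RateDistributionSpec(shape="uniform_random"),
        RateDistributionSpec(shape="discontinuous"),
        RateDistributionSpec(shape="top_weighted"),
    )
    rate_recoding: RateRecodingParams = RateRecodingParams()
    overlap: OverlapParams = OverlapParams()
    n_trials: int = Field(100, ge=1)
    seed: int = Field(0, ge=0)
    out_dir: Optional[str] = None
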