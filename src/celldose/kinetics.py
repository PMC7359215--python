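"""Gamma-counter bookkeeping: cpm to Bq, decay correction, cumulated activity.

The cellular experiments measure compartment activities (surface-bound,
internalized, nuclear) with a gamma counter at a fixed time after the start
of incubation. Dose calculations need the *cumulated* (time-integrated)
activity in each subcellular compartment over the incubation interval. The
chain implemented here is

    cpm --(counter efficiency)--> Bq at measurement time
        --(inverse decay law)--> initial activity A0
        --(closed-form integral)--> cumulated activity Ã  [Bq·s]
        --(nuclear fraction)--> (Ã_nucleus, Ã_cytoplasm)

The model assumes the internalized activity was present from t = 0 and only
decayed physically (no uptake ramp, no biological clearance). Surface-bound
activity is excluded from the dose chain entirely: Auger electrons emitted
at the cell membrane or in the medium do not reach the nucleus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "UptakeRecord",
    "DecayParams",
    "CumulatedActivity",
    "cpm_to_bq",
    "back_extrapolate_a0",
    "time_integrated_activity",
    "partition_cumulated_activity",
]

#: 1/ln 2, the mean-life prefactor often printed as 1.44
_MEAN_LIFE_FACTOR = 1.0 / math.log(2.0)

TC99M_HALF_LIFE_H = 6.02
DEFAULT_COUNTER_EFFICIENCY = 0.54


@dataclass(frozen=True)
class UptakeRecord:
    """One uptake measurement: applied activity and compartment counts.

    Parameters
    ----------
    applied_activity_bq : float
        Activity applied to the well at the start of incubation (Bq).
    surface_cpm : float
        Membrane-bound counts per minute (acid-wash fraction). Recorded but
        never contributes to dose.
    internalized_cpm : float
        Counts per minute of the internalized fraction at measurement time.
    nuclear_fraction : float
        Fraction of the *internalized* activity found in the nucleus,
        in [0, 1].
    measurement_time_h : float
        Hours after the start of incubation at which counts were taken.
    compound : str, optional
        Label of the radiocompound (e.g. ``"Tc99m-C3"``).
    """

    applied_activity_bq: float
    surface_cpm: float
    internalized_cpm: float
    nuclear_fraction: float
    measurement_time_h: float = 24.0
    compound: str | None = None

    def __post_init__(self) -> None:
        if self.applied_activity_bq < 0:
            raise ValueError("applied_activity_bq must be >= 0")
        if self.surface_cpm < 0 or self.internalized_cpm < 0:
            raise ValueError("cpm values must be >= 0")
        if not 0.0 <= self.nuclear_fraction <= 1.0:
            raise ValueError(
                f"nuclear_fraction must be in [0, 1], got {self.nuclear_fraction}"
            )
        if self.measurement_time_h <= 0:
            raise ValueError("measurement_time_h must be > 0")


@dataclass(frozen=True)
class DecayParams:
    """Physical decay constants and counting efficiency.

    Defaults are the Tc-99m half-life (6.02 h) and a 54% gamma-counter
    efficiency.
    """

    half_life_h: float = TC99M_HALF_LIFE_H
    counter_efficiency: float = DEFAULT_COUNTER_EFFICIENCY

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError("half_life_h must be > 0")
        if not 0.0 < self.counter_efficiency <= 1.0:
            raise ValueError("counter_efficiency must be in (0, 1]")

    @property
    def half_life_s(self) -> float:
        return self.half_life_h * 3600.0

    @property
    def decay_constant_per_h(self) -> float:
        return math.log(2.0) / self.half_life_h


@dataclass(frozen=True)
class CumulatedActivity:
    """Time-integrated decays (Bq·s) split into nucleus and cytoplasm."""

    nucleus_bqs: float
    cytoplasm_bqs: float
    a0_bq: float
    delta_t_h: float
    half_life_h: float = TC99M_HALF_LIFE_H

    def __post_init__(self) -> None:
        if self.nucleus_bqs < 0 or self.cytoplasm_bqs < 0:
            raise ValueError("cumulated activities must be >= 0")
        # infinite-time bound: Ã cannot exceed A0 times the mean life
        bound = _MEAN_LIFE_FACTOR * self.half_life_h * 3600.0 * self.a0_bq
        if self.nucleus_bqs + self.cytoplasm_bqs > bound * (1.0 + 1e-9):
            raise ValueError(
                "nucleus + cytoplasm cumulated activity exceeds the "
                "infinite-time bound A0 * T_p / ln 2"
            )

    @property
    def total_bqs(self) -> float:
        return self.nucleus_bqs + self.cytoplasm_bqs


def cpm_to_bq(counts_cpm: float, efficiency: float = DEFAULT_COUNTER_EFFICIENCY) -> float:
    """Convert gamma-counter counts per minute to activity in Bq.

    The counter registers ``efficiency`` of the true decays over a 1-minute
    window, so activity = (cpm / 60) / efficiency.
    """
    if not 0.0 < efficiency <= 1.0:
        raise ValueError(f"efficiency must be in (0, 1], got {efficiency}")
    if counts_cpm < 0:
        raise ValueError("counts must be >= 0")
    return (counts_cpm / 60.0) / efficiency


def back_extrapolate_a0(
    activity_at_t_bq: float, t_h: float, params: DecayParams = DecayParams()
) -> float:
    """Initial activity A0 from the activity measured at ``t_h`` hours.

    Inverts the exponential decay law A(t) = A0 exp(-ln2 t / T_p).
    """
    if activity_at_t_bq < 0:
        raise ValueError("activity must be >= 0")
    if t_h < 0:
        raise ValueError("time must be >= 0")
    return activity_at_t_bq * math.exp(params.decay_constant_per_h * t_h)


def time_integrated_activity(
    a0_bq: float, delta_t_h: float, params: DecayParams = DecayParams()
) -> float:
    """Cumulated activity Ã (Bq·s) over ``[0, delta_t_h]``.

    Closed-form integral of the decay law,
    Ã = (T_p / ln 2) A0 (1 - exp(-ln2 Δt / T_p)), the mean-life prefactor
    conventionally printed as 1.44 T_p. Monotone in Δt with asymptote
    A0 T_p / ln 2.
    """
    if a0_bq < 0:
        raise ValueError("a0 must be >= 0")
    if delta_t_h < 0:
        raise ValueError("delta_t must be >= 0")
    t_s = params.half_life_s
    return (
        _MEAN_LIFE_FACTOR
        * t_s
        * a0_bq
        * (1.0 - math.exp(-math.log(2.0) * delta_t_h / params.half_life_h))
    )


def partition_cumulated_activity(
    record: UptakeRecord,
    params: DecayParams = DecayParams(),
    delta_t_h: float | None = None,
    nuclear_fraction: float | None = None,
) -> CumulatedActivity:
    """Compartment-resolved cumulated activity for one uptake measurement.

    Chains cpm → Bq → A0 → Ã, then splits Ã between nucleus and cytoplasm
    with the record's nuclear fraction (or an externally supplied one, e.g.
    a per-compound mean). Surface-bound counts never enter.

    Parameters
    ----------
    delta_t_h : float, optional
        Integration interval; defaults to the record's measurement time
        (the incubation duration).
    nuclear_fraction : float, optional
        Override for the record's nuclear fraction.
    """
    f = record.nuclear_fraction if nuclear_fraction is None else nuclear_fraction
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"nuclear_fraction must be in [0, 1], got {f}")
    dt = record.measurement_time_h if delta_t_h is None else delta_t_h

    a_t = cpm_to_bq(record.internalized_cpm, params.counter_efficiency)
    a0 = back_extrapolate_a0(a_t, record.measurement_time_h, params)
    a_tilde = time_integrated_activity(a0, dt, params)
    nucleus = a_tilde * f
    # computed as the complement so nucleus + cytoplasm == Ã exactly
    cytoplasm = a_tilde - nucleus
    return CumulatedActivity(
        nucleus_bqs=nucleus,
        cytoplasm_bqs=cytoplasm,
        a0_bq=a0,
        delta_t_h=dt,
        half_life_h=params.half_life_h,
    )
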