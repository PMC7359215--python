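"""Synthetic uptake, spectrum and survival generators for pipeline testing.

These generators reproduce the *statistical structure* the analysis
assumes, not any particular experiment: activity-dependent internalization
that saturates (percent uptake highest at the lowest applied activities),
near-constant nuclear fractions drawn around a compound-specific mean,
Poisson counting noise at the gamma-counter efficiency, and exponential
clonogenic survival with multiplicative lognormal scatter. Everything is
deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .kinetics import DEFAULT_COUNTER_EFFICIENCY, UptakeRecord
from .transport import ElectronSpectrum

__all__ = [
    "UptakeModelParams",
    "SurvivalModelParams",
    "generate_uptake_table",
    "generate_survival_data",
    "toy_spectrum",
]

#: gamma-counter counting window assumed throughout (minutes)
COUNT_WINDOW_MIN = 1.0


@dataclass(frozen=True)
class UptakeModelParams:
    """Parameters of the saturable-uptake measurement model.

    The internalized fraction follows the hyperbola
    f(A) = f_int_max / (1 + A / k_sat_bq), which decreases with applied
    activity as saturation sets in; surface-bound counts are a fixed
    multiple of internalized counts; the nuclear fraction is
    truncated-normal in [0, 1]. ``poisson_noise=False`` gives the exact
    deterministic means (useful as an oracle).
    """

    f_int_max: float = 0.08
    k_sat_bq: float = 2.0e6
    surface_to_internal_ratio: float = 4.0
    nuclear_fraction_mean: float = 0.45
    nuclear_fraction_sd: float = 0.05
    efficiency: float = DEFAULT_COUNTER_EFFICIENCY
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_int_max <= 1.0:
            raise ValueError("f_int_max must be in [0, 1]")
        if not 0.0 <= self.nuclear_fraction_mean <= 1.0:
            raise ValueError("nuclear_fraction_mean must be in [0, 1]")
        if self.k_sat_bq <= 0:
            raise ValueError("k_sat_bq must be > 0")
        if self.nuclear_fraction_sd < 0 or self.surface_to_internal_ratio < 0:
            raise ValueError("sd and surface ratio must be >= 0")
        if not 0.0 < self.efficiency <= 1.0:
            raise ValueError("efficiency must be in (0, 1]")


@dataclass(frozen=True)
class SurvivalModelParams:
    """Exponential-survival generator: κ, lognormal CV, dose grid, replicates."""

    kappa_true: float = 0.3
    noise_cv: float = 0.05
    doses_gy: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0)
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa_true < 0:
            raise ValueError("kappa_true must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def internalized_fraction(applied_bq: float, params: UptakeModelParams) -> float:
    """Saturable internalized fraction f(A) = f_max / (1 + A/k_sat)."""
    return params.f_int_max / (1.0 + applied_bq / params.k_sat_bq)


def generate_uptake_table(
    params: UptakeModelParams,
    activities_bq: "list[float] | np.ndarray",
    compound: str | None = None,
    measurement_time_h: float = 24.0,
) -> list[UptakeRecord]:
    """One synthetic :class:`UptakeRecord` per applied activity.

    Mean internalized cpm at activity A is f(A)·A·60·efficiency (a 1-minute
    counting window); with ``poisson_noise`` the registered counts are
    Poisson around that mean, matching a counting-statistics experiment.
    """
    activities = np.asarray(activities_bq, dtype=float)
    if np.any(activities <= 0):
        raise ValueError("applied activities must be > 0")
    rng = np.random.default_rng(params.seed)
    records = []
    for a in activities:
        mean_int_cpm = internalized_fraction(a, params) * a * 60.0 * params.efficiency
        mean_surf_cpm = mean_int_cpm * params.surface_to_internal_ratio
        if params.poisson_noise:
            int_cpm = float(rng.poisson(mean_int_cpm * COUNT_WINDOW_MIN)) / COUNT_WINDOW_MIN
            surf_cpm = float(rng.poisson(mean_surf_cpm * COUNT_WINDOW_MIN)) / COUNT_WINDOW_MIN
        else:
            int_cpm, surf_cpm = mean_int_cpm, mean_surf_cpm
        if params.nuclear_fraction_sd > 0:
            lo = (0.0 - params.nuclear_fraction_mean) / params.nuclear_fraction_sd
            hi = (1.0 - params.nuclear_fraction_mean) / params.nuclear_fraction_sd
            f_nuc = float(
                stats.truncnorm.rvs(
                    lo,
                    hi,
                    loc=params.nuclear_fraction_mean,
                    scale=params.nuclear_fraction_sd,
                    random_state=rng,
                )
            )
        else:
            f_nuc = params.nuclear_fraction_mean
        records.append(
            UptakeRecord(
                applied_activity_bq=float(a),
                surface_cpm=surf_cpm,
                internalized_cpm=int_cpm,
                nuclear_fraction=f_nuc,
                measurement_time_h=measurement_time_h,
                compound=compound,
            )
        )
    return records


def generate_survival_data(params: SurvivalModelParams) -> list[tuple[float, float]]:
    """Synthetic (dose, SF) points from SF = exp(-κD)·lognormal noise.

    The lognormal factor has median 1 and log-scale SD √ln(1+cv²). The
    exact control point (0, 1) is always included once.
    """
    rng = np.random.default_rng(params.seed)
    sigma = float(np.sqrt(np.log1p(params.noise_cv**2)))
    out: list[tuple[float, float]] = [(0.0, 1.0)]
    for d in params.doses_gy:
        for _ in range(params.replicates):
            noise = float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
            out.append((float(d), float(np.exp(-params.kappa_true * d)) * noise))
    return out


#: Synthetic stand-in for a Tc-99m electron emission spectrum. The line
#: placement mimics the qualitative structure of the real decay — a cascade
#: of sub-keV Auger/Coster-Kronig electrons, heavily-converted ~1.6-1.9 keV
#: electrons from the low-lying 2.17 keV transition, and sparse 119-140 keV
#: conversion electrons of the 140 keV gamma transition — but the energies
#: and yields are round fixture numbers, NOT evaluated nuclear data.
_TC99M_LIKE = (
    (0.05, 1.2),
    (0.14, 1.1),
    (0.33, 1.1),
    (0.45, 0.6),
    (1.63, 0.65),
    (1.85, 0.25),
    (119.5, 0.088),
    (137.5, 0.011),
    (140.5, 0.0022),
)


def toy_spectrum(kind: str, energy_kev: float = 1.0, yield_per_decay: float = 1.0) -> ElectronSpectrum:
    """Fixture spectra for the transport engine.

    - ``"single_line"``: one (energy_kev, yield_per_decay) line.
    - ``"low_energy_only"``: sub-keV lines whose ranges are far below the
      nucleus radius (full local absorption).
    - ``"tc99m_like"``: synthetic mix of sub-keV Auger-like lines and
      ~120-140 keV conversion-electron lines; a fixture, not nuclear data.
    """
    if kind == "single_line":
        return ElectronSpectrum(((energy_kev, yield_per_decay),), label="single_line")
    if kind == "low_energy_only":
        return ElectronSpectrum(
            ((0.05, 2.0), (0.2, 1.5), (0.5, 1.0)), label="low_energy_only"
        )
    if kind == "tc99m_like":
        return ElectronSpectrum(_TC99M_LIKE, label="tc99m_like(synthetic)")
    raise ValueError(
        f"unknown spectrum kind {kind!r}; options: single_line, low_energy_only, tc99m_like"
    )
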