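"""Clonogenic survival statistics, exponential survival fits, IC50 and RBE.

Survival is modeled with the single-parameter exponential ("single-hit
linear") model SF = exp(-κD). κ (Gy⁻¹) is the slope of ln SF against dose
and the only radiobiological parameter; its standard error propagates into
the relative biological effectiveness (RBE) figures:

    RBE_0.5  = D_ref(SF=0.5) / D_test(SF=0.5) = κ_test / κ_ref
    RBE_2Gy  = SF_ref(2 Gy) / SF_test(2 Gy)   = exp(2 (κ_test - κ_ref))

Uncertainties use first-order (delta-method) propagation by default; a
sampling-based propagation is provided for cross-checking.

The module also carries the small arithmetic of clonogenic assays
(plating efficiency, survival fraction) and the normalized summaries of
early (γ-H2AX foci) and late (micronucleus) DNA-damage endpoints.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ColonyCount",
    "SurvivalFit",
    "RBEResult",
    "FociSummary",
    "plating_efficiency",
    "survival_fraction",
    "fit_linear_survival",
    "ic50_from_activity",
    "rbe",
    "rbe_sampling",
    "foci_summary",
    "mn_yield",
]


@dataclass(frozen=True)
class ColonyCount:
    """Colony-forming outcome of one clonogenic well.

    ``min_colony_size_enforced`` records whether only colonies of at least
    50 cells were scored (the standard counting rule).
    """

    cells_seeded: int
    colonies_formed: int
    treatment_label: str = ""
    applied_activity_bq: float | None = None
    dose_gy: float | None = None
    min_colony_size_enforced: bool = True

    def __post_init__(self) -> None:
        if self.cells_seeded < 1:
            raise ValueError("cells_seeded must be >= 1")
        if self.colonies_formed < 0:
            raise ValueError("colonies_formed must be >= 0")


@dataclass(frozen=True)
class SurvivalFit:
    """Fitted exponential survival model SF = exp(-κ·x).

    ``covariate`` names the abscissa: absorbed dose ("dose_gy", κ in Gy⁻¹)
    or applied activity ("activity_bq", κ in Bq⁻¹).
    """

    kappa: float
    kappa_se: float
    model_label: str = "linear"
    covariate: str = "dose_gy"
    n_points: int = 0
    dof: int = 0

    def __post_init__(self) -> None:
        if self.kappa_se < 0:
            raise ValueError("kappa_se must be >= 0")

    def survival(self, x: float) -> float:
        return math.exp(-self.kappa * x)

    def ci95(self) -> tuple[float, float]:
        """95% confidence interval on κ (t-based when dof is available)."""
        q = stats.t.ppf(0.975, self.dof) if self.dof > 0 else stats.norm.ppf(0.975)
        return (self.kappa - q * self.kappa_se, self.kappa + q * self.kappa_se)


@dataclass(frozen=True)
class RBEResult:
    """RBE at 50% survival and at 2 Gy, with propagated standard errors."""

    rbe_05: float
    rbe_05_se: float
    rbe_2gy: float
    rbe_2gy_se: float
    reference_label: str = "60Co"

    def __post_init__(self) -> None:
        if self.rbe_05 <= 0 or self.rbe_2gy <= 0:
            raise ValueError("RBE values must be > 0")
        if self.rbe_05_se < 0 or self.rbe_2gy_se < 0:
            raise ValueError("standard errors must be >= 0")


def plating_efficiency(count: ColonyCount) -> float:
    """Plating efficiency in percent: colonies / cells seeded × 100."""
    return count.colonies_formed / count.cells_seeded * 100.0


def survival_fraction(treated: ColonyCount, control_pe_percent: float) -> float:
    """Survival fraction normalized to the untreated plating efficiency.

    SF = colonies_treated / (cells_seeded × PE_control/100); a control
    sample evaluated against its own PE gives exactly 1.
    """
    if control_pe_percent <= 0:
        raise ZeroDivisionError(
            "control plating efficiency must be > 0 to normalize survival"
        )
    expected = treated.cells_seeded * control_pe_percent / 100.0
    return treated.colonies_formed / expected


def fit_linear_survival(
    points: Iterable[tuple[float, float] | tuple[float, float, float]],
    covariate: str = "dose_gy",
) -> SurvivalFit:
    """Fit SF = exp(-κ·x) by (weighted) least squares on ln SF.

    ``points`` are (x, SF) or (x, SF, se_SF) tuples; when standard errors
    are supplied the log-residuals are weighted by 1/(se/SF)². The model
    has no intercept — SF(0) = 1 by construction — so the x = 0 control
    points constrain only the residual variance. Zero or negative SF
    points cannot enter a log fit and are dropped with a warning.

    κ's standard error comes from the weighted-least-squares covariance
    with the residual variance estimated on n−1 degrees of freedom; for
    noiseless exponential input the residuals, and hence the reported
    standard error, are zero.
    """
    xs, ys, ws = [], [], []
    n_dropped = 0
    for pt in points:
        x, sf = pt[0], pt[1]
        se = pt[2] if len(pt) > 2 else None
        if x < 0:
            raise ValueError("doses/activities must be >= 0")
        if sf <= 0:
            n_dropped += 1
            continue
        xs.append(float(x))
        ys.append(math.log(sf))
        ws.append(1.0 / (se / sf) ** 2 if se else 1.0)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} point(s) with SF <= 0 from the log-scale fit",
            stacklevel=2,
        )
    if len(xs) < 2:
        raise ValueError("need at least 2 points with SF > 0 to fit")
    x = np.asarray(xs)
    y = np.asarray(ys)
    w = np.asarray(ws)
    sxx = float(np.sum(w * x * x))
    if sxx <= 0:
        raise ValueError("all points at x = 0; slope is underdetermined")
    kappa = -float(np.sum(w * x * y)) / sxx
    resid = y + kappa * x
    dof = len(xs) - 1
    sigma2 = float(np.sum(w * resid * resid)) / dof if dof > 0 else 0.0
    kappa_se = math.sqrt(sigma2 / sxx)
    return SurvivalFit(
        kappa=kappa,
        kappa_se=kappa_se,
        covariate=covariate,
        n_points=len(xs),
        dof=dof,
    )


def ic50_from_activity(points: Iterable[tuple[float, float]]) -> float:
    """Activity at which the fitted survival-vs-activity curve crosses 0.5.

    Fits SF = exp(-λA) and returns IC50 = ln 2 / λ. Data that do not
    support a decreasing monotone fit (λ ≤ 0) raise.
    """
    pts = list(points)
    fit = fit_linear_survival(pts, covariate="activity_bq")
    if fit.kappa <= 0:
        raise ValueError(
            "survival does not decrease with activity; no 50% crossing exists"
        )
    return math.log(2.0) / fit.kappa


def rbe(reference: SurvivalFit, test: SurvivalFit, reference_label: str = "60Co") -> RBEResult:
    """RBE of the test radiation against a reference, with delta-method errors.

    Under the exponential model the iso-effect ratio at 50% survival
    reduces to κ_test/κ_ref and the iso-dose ratio at 2 Gy to
    exp(2(κ_test − κ_ref)); errors are first-order in both κ standard
    errors, treated as independent.
    """
    if reference.kappa <= 0:
        raise ZeroDivisionError("reference kappa must be > 0")
    if test.kappa <= 0:
        raise ValueError("test kappa must be > 0")
    r05 = test.kappa / reference.kappa
    r05_se = r05 * math.sqrt(
        (test.kappa_se / test.kappa) ** 2 + (reference.kappa_se / reference.kappa) ** 2
    )
    r2 = math.exp(2.0 * (test.kappa - reference.kappa))
    r2_se = r2 * 2.0 * math.sqrt(test.kappa_se**2 + reference.kappa_se**2)
    return RBEResult(
        rbe_05=r05,
        rbe_05_se=r05_se,
        rbe_2gy=r2,
        rbe_2gy_se=r2_se,
        reference_label=reference_label,
    )


def rbe_sampling(
    reference: SurvivalFit,
    test: SurvivalFit,
    n_draws: int = 100_000,
    rng_seed: int = 0,
) -> tuple[float, float]:
    """Sampling-based standard errors (se_rbe05, se_rbe2gy) for validation.

    Draws both κ from independent normals and returns the empirical SDs of
    the two RBE statistics; a cross-check of the delta-method formulas.
    """
    rng = np.random.default_rng(rng_seed)
    k_ref = rng.normal(reference.kappa, reference.kappa_se, n_draws)
    k_test = rng.normal(test.kappa, test.kappa_se, n_draws)
    ok = k_ref > 0
    r05 = k_test[ok] / k_ref[ok]
    r2 = np.exp(2.0 * (k_test - k_ref))
    return float(np.std(r05, ddof=1)), float(np.std(r2, ddof=1))


@dataclass(frozen=True)
class FociSummary:
    """Mean γ-H2AX foci per nucleus with both control normalizations."""

    mean_foci: float
    sd_foci: float
    normalized_ratio: float
    normalized_difference: float
    n_nuclei: int


def foci_summary(
    per_cell_counts: Sequence[int], control_counts: Sequence[int]
) -> FociSummary:
    """Average foci per nucleus, normalized to the unirradiated control.

    "Normalized to control" is reported both ways — treated/control ratio
    and treated − control difference — since either convention appears in
    foci work. Samples below 200 nuclei trigger a warning (foci
    distributions are overdispersed; small fields are unreliable).
    """
    treated = np.asarray(per_cell_counts, dtype=float)
    control = np.asarray(control_counts, dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValueError("foci count arrays must be non-empty")
    if np.any(treated < 0) or np.any(control < 0):
        raise ValueError("foci counts must be >= 0")
    if treated.size < 200:
        warnings.warn(
            f"only {treated.size} nuclei analyzed; at least 200 recommended",
            stacklevel=2,
        )
    mean = float(treated.mean())
    sd = float(treated.std(ddof=1)) if treated.size > 1 else 0.0
    c_mean = float(control.mean())
    ratio = mean / c_mean if c_mean > 0 else math.inf
    return FociSummary(
        mean_foci=mean,
        sd_foci=sd,
        normalized_ratio=ratio,
        normalized_difference=mean - c_mean,
        n_nuclei=int(treated.size),
    )


def mn_yield(
    mn_counts: int, binucleated_cells: int, control_yield_per_1000: float | None = None
) -> tuple[float, float | None]:
    """Micronucleus yield per 1000 binucleated cells, optionally normalized.

    Returns ``(yield_per_1000, normalized)``; ``normalized`` is None when
    no control yield is given.
    """
    if binucleated_cells < 1:
        raise ValueError("binucleated_cells must be >= 1")
    if mn_counts < 0:
        raise ValueError("mn_counts must be >= 0")
    y = mn_counts / binucleated_cells * 1000.0
    if control_yield_per_1000 is None:
        return y, None
    if control_yield_per_1000 <= 0:
        raise ValueError("control yield must be > 0 to normalize")
    return y, y / control_yield_per_1000
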