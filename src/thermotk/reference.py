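"""Published pooled-regression coefficients used as defaults and cross-checks.

A multispecies literature compilation of uptake (n = 530) and elimination
(n = 958) rate constants for organic chemicals in aquatic animals reports
linearized Arrhenius fits, with and without allometric mass correction, as
``estimate ± SD (CV%) [95% CI]``.  Those printed coefficient sets are
bundled here verbatim: they parameterize the synthetic-data generator's
defaults and serve as inputs to consistency checks (a CV% must recompute
from its estimate/SD pair; a CI must recompute as estimate ± t(0.975, n-2)·SD).

The "SD" of such tables is the coefficient standard error: only under that
reading do the printed confidence intervals reproduce from the printed
estimate and SD, which they do here to well under 0.05% relative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from .core_model import Process

__all__ = [
    "ReferenceFit",
    "REFERENCE_FITS",
    "PHYSIOLOGICAL_SLOPE_K",
    "PHYSIOLOGICAL_SLOPE_RANGE_K",
]


@dataclass(frozen=True)
class ReferenceFit:
    """One published row: a pooled linearized-Arrhenius fit."""

    process: Process
    mass_corrected: bool
    n: int                       # pooled record count for the rate type
    slope_K: float
    slope_sd: float              # coefficient SE, printed as "SD"
    slope_cv_pct: float          # printed CV% = 100*SD/|estimate|
    slope_ci95: Tuple[float, float]  # (lower, upper), ascending
    intercept: float             # ln A
    intercept_sd: float
    intercept_cv_pct: float
    r_squared: float


REFERENCE_FITS = {
    ("uptake", False): ReferenceFit(
        process=Process.UPTAKE, mass_corrected=False, n=530,
        slope_K=-10_000.0, slope_sd=1496.0, slope_cv_pct=15.0,
        slope_ci95=(-12_939.0, -7060.0),
        intercept=40.11, intercept_sd=5.14, intercept_cv_pct=12.8,
        r_squared=0.093,
    ),
    ("elimination", False): ReferenceFit(
        process=Process.ELIMINATION, mass_corrected=False, n=958,
        slope_K=-7888.0, slope_sd=1081.0, slope_cv_pct=13.7,
        slope_ci95=(-10_009.0, -5766.0),
        intercept=25.73, intercept_sd=3.73, intercept_cv_pct=14.5,
        r_squared=0.061,
    ),
    ("uptake", True): ReferenceFit(
        process=Process.UPTAKE, mass_corrected=True, n=530,
        slope_K=-10_026.0, slope_sd=1516.0, slope_cv_pct=15.1,
        slope_ci95=(-13_005.0, -7046.0),
        intercept=37.65, intercept_sd=5.22, intercept_cv_pct=13.9,
        r_squared=0.091,
    ),
    ("elimination", True): ReferenceFit(
        process=Process.ELIMINATION, mass_corrected=True, n=958,
        slope_K=-5905.0, slope_sd=974.0, slope_cv_pct=16.5,
        slope_ci95=(-7816.0, -3994.0),
        intercept=16.83, intercept_sd=3.36, intercept_cv_pct=20.0,
        r_squared=0.043,
    ),
}

#: Average Arrhenius slope reported for general physiological rates of
#: ectotherms (growth, development, metabolism), usable as an external
#: reference line in plots and comparisons.
PHYSIOLOGICAL_SLOPE_K = -7195.0

#: Reported range around :data:`PHYSIOLOGICAL_SLOPE_K` (lower, upper).
PHYSIOLOGICAL_SLOPE_RANGE_K = (-8588.0, -4758.0)
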