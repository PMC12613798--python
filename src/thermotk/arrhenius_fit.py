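"""Linearized Arrhenius regression with the full reporting statistics.

The working model is ordinary least squares of ``y = ln k`` (or
``ln k*`` after allometric mass correction) on ``x = 1/T`` in inverse
Kelvin:

    ln k = ln A + slope_K * (1/T),        slope_K = -E_A / R.

The fit is solved in closed form from centered sums (x is centered for
numerical stability and the intercept back-transformed), and every
statistic of the standard reporting format is attached: coefficient
standard errors, coefficients of variation (100*SE/|estimate|),
t-based 95% confidence intervals, R², and the two-sided t-test p-value
of the slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import GAS_CONSTANT, mass_correct
from .errors import InvalidInputError, UnfittableError

__all__ = [
    "RegressionResult",
    "ModelComparison",
    "ols_inverse_temperature",
    "fit_arrhenius",
    "compare_models",
    "activation_energy",
    "coefficient_of_variation_pct",
    "confidence_interval",
]


def coefficient_of_variation_pct(estimate: float, se: float) -> float:
    """CV% of a coefficient: ``100 * SE / |estimate|``."""
    if estimate == 0:
        raise InvalidInputError("CV% undefined for a zero estimate")
    return 100.0 * se / abs(estimate)


def confidence_interval(estimate: float, se: float, df: int,
                        level: float = 0.95) -> Tuple[float, float]:
    """Two-sided t interval ``estimate ± t((1+level)/2, df) * SE``."""
    if df < 1:
        raise InvalidInputError(f"need df >= 1, got {df}")
    half = stats.t.ppf(0.5 + level / 2.0, df) * se
    return (estimate - half, estimate + half)


@dataclass(frozen=True)
class RegressionResult:
    """A fitted linearized Arrhenius regression, reporting-format complete.

    ``slope_K`` estimates ``-E_A/R`` (Kelvin); ``intercept`` estimates
    ``ln A``.  ``se_*`` are coefficient standard errors, ``cv_*_pct``
    the corresponding CV%, ``ci95_*`` t-based 95% intervals, and
    ``p_value_slope`` the two-sided t-test of slope = 0 (identical to
    the regression F-test for a single predictor).
    """

    slope_K: float
    intercept: float
    se_slope: float
    se_intercept: float
    cv_slope_pct: float
    cv_intercept_pct: float
    ci95_slope: Tuple[float, float]
    ci95_intercept: Tuple[float, float]
    r_squared: float
    p_value_slope: float
    n: int
    df: int
    residual_variance: float
    rate_type: Optional[str] = None
    mass_corrected: bool = False

    @property
    def activation_energy(self) -> float:
        """E_A = -slope_K * R in J mol^-1."""
        return -self.slope_K * GAS_CONSTANT

    def to_dict(self) -> dict:
        d = {
            "rate_type": self.rate_type, "mass_corrected": self.mass_corrected,
            "slope_K": self.slope_K, "se_slope": self.se_slope,
            "cv_slope_pct": self.cv_slope_pct,
            "ci95_slope_low": self.ci95_slope[0], "ci95_slope_high": self.ci95_slope[1],
            "intercept": self.intercept, "se_intercept": self.se_intercept,
            "cv_intercept_pct": self.cv_intercept_pct,
            "ci95_intercept_low": self.ci95_intercept[0],
            "ci95_intercept_high": self.ci95_intercept[1],
            "r_squared": self.r_squared, "p_value_slope": self.p_value_slope,
            "n": self.n, "activation_energy_J_mol": self.activation_energy,
        }
        return d

    def format_block(self) -> str:
        """Human-readable block in the ``estimate ± SE (CV%) [CI]`` style."""
        lo, hi = self.ci95_slope
        label = f"{self.rate_type or 'rate'}" + (
            " (mass-corrected)" if self.mass_corrected else " (uncorrected)"
        )
        return (
            f"{label}: n = {self.n}\n"
            f"  slope [K]     : {self.slope_K:.1f} ± {self.se_slope:.1f} "
            f"({self.cv_slope_pct:.1f}%) [{lo:.1f}, {hi:.1f}]\n"
            f"  intercept [/] : {self.intercept:.2f} ± {self.se_intercept:.2f} "
            f"({self.cv_intercept_pct:.1f}%)\n"
            f"  R^2 = {self.r_squared:.3f}, p(slope) = {self.p_value_slope:.3g}, "
            f"E_A = {self.activation_energy:.0f} J/mol"
        )


@dataclass(frozen=True)
class ModelComparison:
    """Uncorrected vs mass-corrected fits of one rate type."""

    uncorrected: RegressionResult
    corrected: RegressionResult
    slope_ci_overlap: bool
    delta_cv_slope_pct: float       # corrected minus uncorrected
    delta_cv_intercept_pct: float
    delta_r_squared: float
    n_excluded_missing_mass: int


def ols_inverse_temperature(inv_temperature: np.ndarray, ln_k: np.ndarray,
                            rate_type: Optional[str] = None,
                            mass_corrected: bool = False) -> RegressionResult:
    """Closed-form OLS of ln k on 1/T from centered sums.

    Low-level entry point; :func:`fit_arrhenius` is the record-level
    surface.  Requires n >= 3 and non-degenerate predictor variance.
    """
    x = np.asarray(inv_temperature, dtype=float)
    y = np.asarray(ln_k, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("inv_temperature and ln_k must be equal-length 1-D")
    n = x.size
    if n < 3:
        raise UnfittableError(f"need >= 3 records to fit, got {n}")
    xbar = x.mean()
    xc = x - xbar
    sxx = float(xc @ xc)
    if sxx <= 0.0:
        raise UnfittableError("zero variance in 1/T: all temperatures identical")
    ybar = y.mean()
    slope = float(xc @ (y - ybar)) / sxx
    intercept_c = ybar                      # intercept in the centered parameterization
    resid = y - (intercept_c + slope * xc)
    rss = float(resid @ resid)
    syy = float((y - ybar) @ (y - ybar))
    dof = n - 2
    s2 = rss / dof
    se_slope = np.sqrt(s2 / sxx)
    # back-transform to the uncentered intercept ln A
    intercept = intercept_c - slope * xbar
    se_intercept = np.sqrt(s2 * (1.0 / n + xbar ** 2 / sxx))
    r_squared = 1.0 - rss / syy if syy > 0 else 1.0
    if se_slope > 0:
        t_stat = slope / se_slope
        p = float(2.0 * stats.t.sf(abs(t_stat), dof))
    else:
        p = 0.0 if slope != 0 else 1.0
    return RegressionResult(
        slope_K=slope, intercept=intercept,
        se_slope=float(se_slope), se_intercept=float(se_intercept),
        cv_slope_pct=coefficient_of_variation_pct(slope, se_slope) if slope != 0 else np.inf,
        cv_intercept_pct=(
            coefficient_of_variation_pct(intercept, se_intercept)
            if intercept != 0 else np.inf
        ),
        ci95_slope=confidence_interval(slope, float(se_slope), dof),
        ci95_intercept=confidence_interval(intercept, float(se_intercept), dof),
        r_squared=float(min(max(r_squared, 0.0), 1.0)),
        p_value_slope=max(p, np.finfo(float).tiny),
        n=n, df=dof, residual_variance=float(s2),
        rate_type=rate_type, mass_corrected=mass_corrected,
    )


def _single_rate_type(records: pd.DataFrame, rate_type: Optional[str]) -> pd.DataFrame:
    present = records["rate_type"].unique()
    if rate_type is not None:
        sub = records[records["rate_type"] == rate_type]
        if sub.empty:
            raise UnfittableError(f"no records of rate_type {rate_type!r}")
        return sub
    if len(present) != 1:
        raise InvalidInputError(
            f"records mix rate types {sorted(present)}; pass rate_type= to select one"
        )
    return records


def fit_arrhenius(records: pd.DataFrame, *, use_mass_correction: bool = False,
                  rate_type: Optional[str] = None) -> RegressionResult:
    """Fit the linearized Arrhenius model to a frame of rate records.

    ``records`` must carry ``temperature_K``, ``k`` and ``rate_type``
    columns (one rate type, or select with ``rate_type=``), plus
    ``mass_kg`` when ``use_mass_correction`` is set — records with
    missing mass then raise rather than being dropped silently (use
    :func:`compare_models` for the drop-and-count behaviour).
    """
    sub = _single_rate_type(records, rate_type)
    k = sub["k"].to_numpy(dtype=float)
    if use_mass_correction:
        if "mass_kg" not in sub.columns:
            raise InvalidInputError("mass correction requires a mass_kg column")
        mass = sub["mass_kg"].to_numpy(dtype=float)
        missing = np.flatnonzero(~np.isfinite(mass))
        if missing.size:
            idx = sub.index[missing].tolist()
            raise InvalidInputError(
                f"mass correction requested but {missing.size} record(s) lack mass "
                f"(frame index {idx[:10]}{'...' if len(idx) > 10 else ''})"
            )
        k = mass_correct(k, mass)
    x = 1.0 / sub["temperature_K"].to_numpy(dtype=float)
    rt = str(sub["rate_type"].iloc[0])
    return ols_inverse_temperature(x, np.log(k), rate_type=rt,
                                   mass_corrected=use_mass_correction)


def compare_models(records: pd.DataFrame,
                   rate_type: Optional[str] = None) -> ModelComparison:
    """Fit uncorrected and mass-corrected variants on one rate type.

    The corrected fit uses only records with a known mass (counted in
    ``n_excluded_missing_mass``); the uncorrected fit uses all records.
    """
    sub = _single_rate_type(records, rate_type)
    uncorrected = fit_arrhenius(sub)
    has_mass = sub["mass_kg"].notna() if "mass_kg" in sub.columns else pd.Series(
        False, index=sub.index
    )
    n_excluded = int((~has_mass).sum())
    with_mass = sub[has_mass]
    if with_mass.empty:
        raise UnfittableError(
            "mass-corrected comparison impossible: no record carries a mass"
        )
    corrected = fit_arrhenius(with_mass, use_mass_correction=True)
    lo_u, hi_u = uncorrected.ci95_slope
    lo_c, hi_c = corrected.ci95_slope
    overlap = (lo_u <= hi_c) and (lo_c <= hi_u)
    return ModelComparison(
        uncorrected=uncorrected, corrected=corrected,
        slope_ci_overlap=bool(overlap),
        delta_cv_slope_pct=corrected.cv_slope_pct - uncorrected.cv_slope_pct,
        delta_cv_intercept_pct=corrected.cv_intercept_pct - uncorrected.cv_intercept_pct,
        delta_r_squared=corrected.r_squared - uncorrected.r_squared,
        n_excluded_missing_mass=n_excluded,
    )


def activation_energy(result: RegressionResult) -> float:
    """Activation energy E_A = -slope_K * R (J mol^-1) of a fitted result."""
    return -result.slope_K * GAS_CONSTANT
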