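"""Stratified (chemical- and species-specific) analyses, BCF assessment,
and the end-to-end pipeline.

Pooled Arrhenius fits mask chemical- and species-level structure:
hydrophobicity (log D_ow) shifts intercepts (higher D_ow -> faster
uptake, slower elimination) while slopes stay similar, and single-species
datasets allow cleaner regressions.  This module fits per-stratum
regressions (after the minimum-distinct-temperature filter), tests slope
homogeneity across strata with a nested-model F-test, and assesses
whether the bioconcentration factor is temperature-independent by
comparing the uptake and elimination Arrhenius slopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .arrhenius_fit import (
    ModelComparison, RegressionResult, compare_models, fit_arrhenius,
    ols_inverse_temperature,
)
from .dataset_prep import (
    average_duplicates, filter_min_temperatures, impute_mass, read_dataset,
    rounded_celsius, write_dataset,
)
from .errors import InvalidInputError, PipelineError, UnfittableError
from .synthetic_data import GeneratorConfig, generate_dataset

__all__ = [
    "assign_dow_bins",
    "pairwise_slope_tests",
    "StratumResult",
    "StratifiedAnalysis",
    "SlopeEqualityTest",
    "BCFAssessment",
    "PipelineResult",
    "stratified_fits",
    "test_slope_equality",
    "assess_bcf_temperature_dependence",
    "holm_adjust",
    "run_pipeline",
]

logger = logging.getLogger("thermotk")


@dataclass(frozen=True)
class StratumResult:
    """One stratum's fitted regression (a chemical, a species, or a D_ow bin)."""

    stratum_key: str
    result: RegressionResult
    n: int


@dataclass
class StratifiedAnalysis:
    """Fitted strata plus the strata excluded by the temperature filter."""

    strata: List[StratumResult]
    excluded: List[Tuple[str, str]]  # (stratum key, reason)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        p_values = [s.result.p_value_slope for s in self.strata]
        adjusted = holm_adjust(p_values) if p_values else []
        for s, p_adj in zip(self.strata, adjusted):
            d = s.result.to_dict()
            d["stratum"] = s.stratum_key
            d["p_value_holm"] = p_adj
            rows.append(d)
        df = pd.DataFrame(rows)
        if not df.empty:
            df = df[["stratum"] + [c for c in df.columns if c != "stratum"]]
        return df


@dataclass(frozen=True)
class SlopeEqualityTest:
    """Nested-model F-test of a common Arrhenius slope across strata.

    Separate-slopes model: per-stratum slope and intercept.  Common-slope
    model: one shared slope, per-stratum intercepts.  ``df_num`` is the
    number of strata minus one, ``df_den`` the residual df of the
    separate-slopes model.
    """

    f_statistic: float
    p_value: float
    df_num: int
    df_den: int
    common_slope: float
    n_strata: int


@dataclass(frozen=True)
class BCFAssessment:
    """Difference of uptake and elimination Arrhenius slopes.

    Since ln BCF = ln k_u - ln k_e, the slope of ln BCF against 1/T is
    slope_u - slope_e; the BCF is temperature-independent exactly when
    that difference is zero.  The CI treats the two fits as independent
    (they share no records), a documented approximation.
    """

    delta_slope_K: float
    se_delta: float
    ci95_delta: Tuple[float, float]
    temperature_independent: bool
    paired_fit: Optional[RegressionResult] = None


def holm_adjust(p_values: Sequence[float]) -> List[float]:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted.tolist()


def assign_dow_bins(records: pd.DataFrame, n_bins: int = 4,
                    column: str = "dow_bin") -> pd.DataFrame:
    """Add an equal-width log D_ow bin column for sparse-data stratification.

    By default every chemical is its own stratum (one log D_ow per
    substance); binning pools chemicals of similar hydrophobicity when
    per-chemical strata are too thin to fit.  Records with missing
    log_dow get an ``"unknown"`` bin.
    """
    if n_bins < 1:
        raise InvalidInputError("n_bins must be >= 1")
    out = records.copy()
    ldow = out["log_dow"].to_numpy(dtype=float)
    finite = np.isfinite(ldow)
    labels = np.full(len(out), "unknown", dtype=object)
    if finite.any():
        lo, hi = ldow[finite].min(), ldow[finite].max()
        edges = np.linspace(lo, hi, n_bins + 1)
        idx = np.clip(np.digitize(ldow[finite], edges[1:-1]), 0, n_bins - 1)
        labels[finite] = [
            f"dow[{edges[i]:.2f},{edges[i + 1]:.2f}]" for i in idx
        ]
    out[column] = labels
    return out


def _strata_groups(records: pd.DataFrame, key: str) -> Dict[str, pd.DataFrame]:
    if key not in records.columns:
        raise InvalidInputError(f"stratification key {key!r} is not a column")
    return {str(name): grp for name, grp in records.groupby(key, dropna=False, sort=True)}


def stratified_fits(records: pd.DataFrame, key: str, *,
                    min_distinct_temps: int = 4,
                    use_mass_correction: bool = False,
                    rate_type: Optional[str] = None) -> StratifiedAnalysis:
    """Fit the Arrhenius model per stratum after the distinct-T filter.

    ``key`` names the grouping column (``'chemical'`` for D_ow strata,
    since each chemical carries one log D_ow value; ``'species'`` for the
    species-specific analysis).  Strata failing the filter or unfittable
    are reported in ``excluded``, never silently dropped.
    """
    if rate_type is not None:
        records = records[records["rate_type"] == rate_type]
    strata: List[StratumResult] = []
    excluded: List[Tuple[str, str]] = []
    for name, grp in _strata_groups(records, key).items():
        n_temps = int(pd.Series(rounded_celsius(grp["temperature_K"])).nunique())
        if n_temps < min_distinct_temps:
            excluded.append(
                (name, f"only {n_temps} distinct temperature(s), "
                       f"need {min_distinct_temps}")
            )
            continue
        try:
            res = fit_arrhenius(grp, use_mass_correction=use_mass_correction)
        except (UnfittableError, InvalidInputError) as exc:
            excluded.append((name, str(exc)))
            continue
        strata.append(StratumResult(stratum_key=name, result=res, n=len(grp)))
    if not strata and excluded:
        logger.warning("no stratum survived filtering by %r", key)
    return StratifiedAnalysis(strata=strata, excluded=excluded)


def test_slope_equality(records: pd.DataFrame, key: str, *,
                        rate_type: Optional[str] = None) -> SlopeEqualityTest:
    """F-test separate per-stratum slopes against a single common slope.

    Both models allow per-stratum intercepts; the test statistic is
    ``F = [(RSS_common - RSS_separate)/(G-1)] / [RSS_separate/(N-2G)]``
    with G strata and N records.  Every stratum must be individually
    fittable (>= 3 records, temperature variation).
    """
    if rate_type is not None:
        records = records[records["rate_type"] == rate_type]
    groups = _strata_groups(records, key)
    if len(groups) < 2:
        raise UnfittableError(
            f"slope-equality test needs >= 2 strata, got {len(groups)}"
        )
    rss_sep = 0.0
    sxx_total = sxy_total = 0.0
    n_total = 0
    per_group = []
    for name, grp in groups.items():
        x = 1.0 / grp["temperature_K"].to_numpy(dtype=float)
        y = np.log(grp["k"].to_numpy(dtype=float))
        if x.size < 3:
            raise UnfittableError(f"stratum {name!r} has {x.size} record(s), need >= 3")
        xc = x - x.mean()
        yc = y - y.mean()
        sxx = float(xc @ xc)
        if sxx <= 0:
            raise UnfittableError(f"stratum {name!r} has no temperature variation")
        sxy = float(xc @ yc)
        syy = float(yc @ yc)
        rss_sep += syy - sxy ** 2 / sxx
        sxx_total += sxx
        sxy_total += sxy
        per_group.append((sxx, sxy, syy))
        n_total += x.size
    g = len(groups)
    common_slope = sxy_total / sxx_total
    rss_common = sum(
        syy - 2.0 * common_slope * sxy + common_slope ** 2 * sxx
        for sxx, sxy, syy in per_group
    )
    df_num = g - 1
    df_den = n_total - 2 * g
    if df_den < 1:
        raise UnfittableError(
            f"not enough records ({n_total}) for {g} strata in the F-test"
        )
    num = max(rss_common - rss_sep, 0.0) / df_num
    if rss_sep <= 0:
        f_stat = np.inf if num > 0 else 0.0
    else:
        f_stat = num / (rss_sep / df_den)
    p = float(stats.f.sf(f_stat, df_num, df_den)) if np.isfinite(f_stat) else 0.0
    return SlopeEqualityTest(
        f_statistic=float(f_stat), p_value=max(p, np.finfo(float).tiny),
        df_num=df_num, df_den=df_den,
        common_slope=float(common_slope), n_strata=g,
    )


def pairwise_slope_tests(records: pd.DataFrame, key: str, *,
                         rate_type: Optional[str] = None) -> pd.DataFrame:
    """All pairwise two-stratum slope-equality F-tests, with Holm column.

    Optional companion to the joint :func:`test_slope_equality`; reported
    without multiplicity correction alongside Holm-adjusted p-values.
    """
    if rate_type is not None:
        records = records[records["rate_type"] == rate_type]
    names = sorted(_strata_groups(records, key))
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sub = records[records[key].isin([a, b])]
            t = test_slope_equality(sub, key)
            rows.append({"stratum_a": a, "stratum_b": b,
                         "f_statistic": t.f_statistic, "p_value": t.p_value})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_value_holm"] = holm_adjust(out["p_value"].tolist())
    return out


def assess_bcf_temperature_dependence(
    uptake_fit: RegressionResult, elimination_fit: RegressionResult,
    paired_records: Optional[pd.DataFrame] = None,
) -> BCFAssessment:
    """Assess temperature independence of the bioconcentration factor.

    Reports the slope difference ``slope_u - slope_e`` with the
    independent-fits standard error ``sqrt(SE_u^2 + SE_e^2)`` and a
    normal-approximation 95% CI; the verdict is temperature-independent
    iff that CI contains zero.  When ``paired_records`` (columns ``k_u``,
    ``k_e``, ``temperature_K``) are supplied, ln(k_u/k_e) is additionally
    regressed on 1/T directly.
    """
    if uptake_fit is None or elimination_fit is None:
        raise InvalidInputError("both uptake and elimination fits are required")
    delta = uptake_fit.slope_K - elimination_fit.slope_K
    se = float(np.hypot(uptake_fit.se_slope, elimination_fit.se_slope))
    z = stats.norm.ppf(0.975)
    ci = (delta - z * se, delta + z * se)
    paired_fit = None
    if paired_records is not None:
        x = 1.0 / paired_records["temperature_K"].to_numpy(dtype=float)
        y = np.log(paired_records["k_u"].to_numpy(dtype=float)
                   / paired_records["k_e"].to_numpy(dtype=float))
        paired_fit = ols_inverse_temperature(x, y, rate_type="ln(BCF)")
    return BCFAssessment(
        delta_slope_K=float(delta), se_delta=se, ci95_delta=ci,
        temperature_independent=bool(ci[0] <= 0.0 <= ci[1]),
        paired_fit=paired_fit,
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineResult:
    dataset: pd.DataFrame
    prepped: pd.DataFrame
    pooled: Dict[str, ModelComparison]                 # by rate type
    chemical_strata: Dict[str, StratifiedAnalysis]     # by rate type
    species_strata: Dict[str, StratifiedAnalysis]
    slope_equality: Dict[str, Optional[SlopeEqualityTest]]
    bcf: BCFAssessment
    report_text: str


def _pooled_frame(pooled: Dict[str, ModelComparison]) -> pd.DataFrame:
    rows = []
    for rt, cmp_ in pooled.items():
        for res in (cmp_.uncorrected, cmp_.corrected):
            rows.append(res.to_dict())
    return pd.DataFrame(rows)


def _build_report(result_parts: dict, counts: dict) -> str:
    lines = ["Temperature-toxicokinetics analysis report", "=" * 44, ""]
    lines.append("Record counts by stage:")
    for stage, n in counts.items():
        lines.append(f"  {stage}: {n}")
    lines.append("")
    lines.append("Pooled linearized Arrhenius fits (estimate ± SE (CV%) [95% CI]):")
    for rt, cmp_ in result_parts["pooled"].items():
        lines.append(cmp_.uncorrected.format_block())
        lines.append(cmp_.corrected.format_block())
        lines.append(
            f"  model comparison ({rt}): slope CIs overlap = {cmp_.slope_ci_overlap}, "
            f"dCV(slope) = {cmp_.delta_cv_slope_pct:+.1f}%, "
            f"dR^2 = {cmp_.delta_r_squared:+.3f}, "
            f"excluded for missing mass = {cmp_.n_excluded_missing_mass}"
        )
        lines.append("")
    for label, key in (("Chemical-specific", "chemical_strata"),
                       ("Species-specific", "species_strata")):
        lines.append(f"{label} strata:")
        for rt, analysis in result_parts[key].items():
            lines.append(f"  {rt}: {len(analysis.strata)} fitted, "
                         f"{len(analysis.excluded)} excluded by the "
                         "distinct-temperature filter")
            for name, reason in analysis.excluded:
                lines.append(f"    excluded {name}: {reason}")
        lines.append("")
    lines.append("Slope homogeneity across chemicals (nested F-test):")
    for rt, test in result_parts["slope_equality"].items():
        if test is None:
            lines.append(f"  {rt}: not testable (<2 fittable strata)")
        else:
            lines.append(
                f"  {rt}: F({test.df_num}, {test.df_den}) = {test.f_statistic:.3f}, "
                f"p = {test.p_value:.3g}, common slope = {test.common_slope:.0f} K"
            )
    lines.append("")
    bcf = result_parts["bcf"]
    lo, hi = bcf.ci95_delta
    verdict = ("temperature-independent BCF (CI contains 0)"
               if bcf.temperature_independent
               else "temperature-DEPENDENT BCF (CI excludes 0)")
    lines.append("Bioconcentration factor:")
    lines.append(
        f"  dslope (uptake - elimination) = {bcf.delta_slope_K:.0f} ± "
        f"{bcf.se_delta:.0f} K, 95% CI [{lo:.0f}, {hi:.0f}] -> {verdict}"
    )
    return "\n".join(lines) + "\n"


def run_pipeline(config: Optional[GeneratorConfig] = None, *,
                 dataset_path: Optional[Union[str, Path]] = None,
                 mass_table: Optional[pd.DataFrame] = None,
                 min_distinct_temps: int = 4,
                 out_dir: Optional[Union[str, Path]] = None,
                 make_plots: bool = False) -> PipelineResult:
    """Run prep -> pooled fits -> stratified analyses -> BCF assessment.

    Provide either a ``dataset_path`` (canonical CSV) or a
    ``GeneratorConfig`` to synthesize the data.  With ``out_dir`` set the
    dataset, results CSVs and a plain-text report are written there.  Any
    stage failure raises :class:`PipelineError` naming the stage.
    """
    # --- input stage
    if dataset_path is not None:
        ingest = read_dataset(dataset_path)
        dataset = ingest.records
        for diag in ingest.rejected:
            logger.warning("rejected %s", diag)
    elif config is not None:
        dataset = generate_dataset(config)
        logger.info("generated %d synthetic records (seed=%d)", len(dataset), config.seed)
    else:
        raise PipelineError("input stage: provide dataset_path or a GeneratorConfig")
    counts = {"ingested": len(dataset)}

    # --- prep stage
    try:
        prepped = average_duplicates(dataset)
        if mass_table is not None:
            prepped, summary = impute_mass(prepped, mass_table)
            logger.info("mass imputation: %s", summary)
        counts["after duplicate averaging"] = len(prepped)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(f"prep stage: {exc}") from exc

    # --- pooled fits (never filtered by distinct temperatures)
    pooled: Dict[str, ModelComparison] = {}
    try:
        for rt in ("uptake", "elimination"):
            pooled[rt] = compare_models(prepped, rate_type=rt)
    except Exception as exc:
        raise PipelineError(f"pooled-fit stage: {exc}") from exc

    # --- stratified analyses (with the distinct-temperature filter)
    chemical_strata: Dict[str, StratifiedAnalysis] = {}
    species_strata: Dict[str, StratifiedAnalysis] = {}
    slope_eq: Dict[str, Optional[SlopeEqualityTest]] = {}
    try:
        for rt in ("uptake", "elimination"):
            chemical_strata[rt] = stratified_fits(
                prepped, "chemical", min_distinct_temps=min_distinct_temps,
                rate_type=rt)
            species_strata[rt] = stratified_fits(
                prepped, "species", min_distinct_temps=min_distinct_temps,
                rate_type=rt)
            fitted_keys = [s.stratum_key for s in chemical_strata[rt].strata]
            if len(fitted_keys) >= 2:
                surviving = prepped[(prepped["rate_type"] == rt)
                                    & prepped["chemical"].isin(fitted_keys)]
                slope_eq[rt] = test_slope_equality(surviving, "chemical")
            else:
                slope_eq[rt] = None
    except Exception as exc:
        raise PipelineError(f"stratified stage: {exc}") from exc

    # --- BCF assessment from the pooled uncorrected fits
    try:
        bcf = assess_bcf_temperature_dependence(
            pooled["uptake"].uncorrected, pooled["elimination"].uncorrected)
    except Exception as exc:
        raise PipelineError(f"BCF stage: {exc}") from exc

    parts = {
        "pooled": pooled, "chemical_strata": chemical_strata,
        "species_strata": species_strata, "slope_equality": slope_eq,
        "bcf": bcf,
    }
    report_text = _build_report(parts, counts)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_dataset(dataset, out / "dataset.csv")
        _pooled_frame(pooled).to_csv(out / "pooled_fits.csv", index=False)
        for rt in ("uptake", "elimination"):
            chemical_strata[rt].to_frame().to_csv(
                out / f"strata_chemical_{rt}.csv", index=False)
            species_strata[rt].to_frame().to_csv(
                out / f"strata_species_{rt}.csv", index=False)
        (out / "report.txt").write_text(report_text)
        if make_plots:
            from .plots import plot_arrhenius
            for rt in ("uptake", "elimination"):
                sub = prepped[prepped["rate_type"] == rt]
                plot_arrhenius(sub, pooled[rt].uncorrected,
                               out / f"arrhenius_{rt}.png",
                               title=f"{rt} rate constants")
        logger.info("wrote results to %s", out)

    return PipelineResult(
        dataset=dataset, prepped=prepped, pooled=pooled,
        chemical_strata=chemical_strata, species_strata=species_strata,
        slope_equality=slope_eq, bcf=bcf, report_text=report_text,
    )
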