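"""Ingestion and data-treatment rules for compiled rate-constant tables.

The compiled dataset mixes sources that report temperatures at slightly
different precisions and often omit organism mass, so three treatment
rules are applied before analysis:

* records of the same species, chemical and rate type at the same
  temperature (rounded to the nearest whole degree Celsius) are averaged
  to avoid over-weighting well-studied combinations;
* missing masses are imputed from a species mass-reference table, using
  the matching life stage where one is recorded and the species-level
  average otherwise;
* chemical- and species-specific regressions use only groups observed at
  a minimum number of distinct temperatures (default four) — the pooled
  fits are never filtered this way.

Collections of records travel as pandas DataFrames in a canonical
internal schema (:data:`COLUMNS`); the on-disk CSV schema
(:data:`CSV_COLUMNS`) differs only in carrying an explicit per-row
temperature unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core_model import KELVIN_OFFSET, Process, RateRecord
from .errors import InvalidInputError, SchemaError

__all__ = [
    "COLUMNS",
    "CSV_COLUMNS",
    "MassReference",
    "IngestResult",
    "MassImputationSummary",
    "read_dataset",
    "write_dataset",
    "records_to_frame",
    "frame_to_records",
    "round_half_away",
    "rounded_celsius",
    "average_duplicates",
    "read_mass_reference",
    "impute_mass",
    "filter_min_temperatures",
]

#: Canonical in-memory schema (temperatures always Kelvin).
COLUMNS = [
    "source_id", "species", "taxon", "life_stage", "chemical",
    "chemical_group", "log_dow", "temperature_K", "rate_type", "k",
    "k_unit", "mass_kg",
]

#: On-disk CSV schema; temperature_unit is 'C' or 'K' per row.
CSV_COLUMNS = [
    "source_id", "species", "taxon", "life_stage", "chemical",
    "chemical_group", "log_dow", "temperature_value", "temperature_unit",
    "rate_type", "k_value", "k_unit", "mass_kg",
]

_DUPLICATE_KEYS = ["species", "chemical", "rate_type"]


@dataclass(frozen=True)
class MassReference:
    """One species/life-stage entry of the mass-reference table."""

    species: str
    mass_kg: float
    life_stage: Optional[str] = None
    n_source_studies: int = 1

    def __post_init__(self) -> None:
        if not self.mass_kg > 0:
            raise InvalidInputError(f"mass_kg must be positive, got {self.mass_kg!r}")
        if self.n_source_studies < 1:
            raise InvalidInputError("n_source_studies must be >= 1")


@dataclass
class IngestResult:
    """Typed records plus row-level diagnostics for rejected rows."""

    records: pd.DataFrame
    rejected: List[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass
class MassImputationSummary:
    n_observed: int
    n_filled_life_stage: int
    n_filled_species: int
    n_unmatched: int
    unmatched_species: List[str] = field(default_factory=list)


def round_half_away(x):
    """Round to nearest integer with ties (x.5) away from zero."""
    x = np.asarray(x, dtype=float)
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def rounded_celsius(temperature_K) -> np.ndarray:
    """Whole-degree Celsius used for duplicate detection and distinct-T counts."""
    return round_half_away(np.asarray(temperature_K, dtype=float) - KELVIN_OFFSET)


def records_to_frame(records: Iterable[RateRecord]) -> pd.DataFrame:
    rows = [
        {
            "source_id": r.source_id, "species": r.species, "taxon": r.taxon,
            "life_stage": r.life_stage, "chemical": r.chemical,
            "chemical_group": r.chemical_group, "log_dow": r.log_dow,
            "temperature_K": r.temperature_K, "rate_type": r.rate_type.value,
            "k": r.k, "k_unit": "", "mass_kg": r.mass_kg,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=COLUMNS)


def frame_to_records(df: pd.DataFrame) -> List[RateRecord]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            RateRecord(
                species=row.species, taxon=row.taxon, chemical=row.chemical,
                chemical_group=row.chemical_group,
                temperature_K=float(row.temperature_K),
                rate_type=Process(row.rate_type), k=float(row.k),
                log_dow=None if pd.isna(row.log_dow) else float(row.log_dow),
                mass_kg=None if pd.isna(row.mass_kg) else float(row.mass_kg),
                life_stage=None if pd.isna(row.life_stage) else str(row.life_stage),
                source_id="" if pd.isna(row.source_id) else str(row.source_id),
            )
        )
    return out


def read_dataset(path: Union[str, Path]) -> IngestResult:
    """Read a rate-constant CSV into the canonical internal frame.

    Rows violating the record invariants (non-positive k, implausible
    temperature, non-positive mass, unknown unit or rate type) are
    rejected with a diagnostic naming the file line and the rule; valid
    rows pass through with temperatures converted to Kelvin.
    """
    raw = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    rejected: List[str] = []
    rows = []
    for i, row in raw.iterrows():
        line = i + 2  # 1-based, after the header line
        problems = []
        k = pd.to_numeric(pd.Series([row["k_value"]]), errors="coerce").iloc[0]
        t = pd.to_numeric(pd.Series([row["temperature_value"]]), errors="coerce").iloc[0]
        unit = str(row["temperature_unit"]).strip()
        rate_type = str(row["rate_type"]).strip()
        if pd.isna(k):
            problems.append(f"k_value is not numeric ({row['k_value']!r})")
        elif not k > 0:
            problems.append(f"k_value must be positive (got {k})")
        if pd.isna(t):
            problems.append(f"temperature_value is not numeric ({row['temperature_value']!r})")
        if unit not in ("C", "K"):
            problems.append(f"temperature_unit must be 'C' or 'K' (got {unit!r})")
        if rate_type not in ("uptake", "elimination"):
            problems.append(f"rate_type must be 'uptake' or 'elimination' (got {rate_type!r})")
        t_K = np.nan
        if not problems:
            t_K = t + KELVIN_OFFSET if unit == "C" else t
            if not t_K > 200:
                problems.append(f"temperature {t_K:.2f} K must exceed 200 K")
        mass = pd.to_numeric(pd.Series([row["mass_kg"]]), errors="coerce").iloc[0]
        if not pd.isna(row["mass_kg"]) and (pd.isna(mass) or not mass > 0):
            problems.append(f"mass_kg must be positive if present (got {row['mass_kg']!r})")
        if problems:
            rejected.extend(f"line {line}: {p}" for p in problems)
            continue
        rows.append({
            "source_id": row["source_id"], "species": row["species"],
            "taxon": row["taxon"], "life_stage": row["life_stage"],
            "chemical": row["chemical"], "chemical_group": row["chemical_group"],
            "log_dow": pd.to_numeric(pd.Series([row["log_dow"]]), errors="coerce").iloc[0],
            "temperature_K": t_K, "rate_type": rate_type, "k": float(k),
            "k_unit": row["k_unit"], "mass_kg": np.nan if pd.isna(mass) else float(mass),
        })
    return IngestResult(records=pd.DataFrame(rows, columns=COLUMNS), rejected=rejected)


def write_dataset(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a canonical internal frame to the on-disk CSV schema (Kelvin)."""
    out = pd.DataFrame({
        "source_id": df["source_id"], "species": df["species"],
        "taxon": df["taxon"], "life_stage": df["life_stage"],
        "chemical": df["chemical"], "chemical_group": df["chemical_group"],
        "log_dow": df["log_dow"], "temperature_value": df["temperature_K"],
        "temperature_unit": "K", "rate_type": df["rate_type"],
        "k_value": df["k"], "k_unit": df["k_unit"], "mass_kg": df["mass_kg"],
    }, columns=CSV_COLUMNS)
    out.to_csv(path, index=False)


def average_duplicates(df: pd.DataFrame, method: str = "arithmetic") -> pd.DataFrame:
    """Average records duplicated at the same rounded whole-degree-Celsius
    temperature within (species, chemical, rate_type).

    Each multi-member group collapses to one record carrying the mean rate
    constant (arithmetic on the natural scale by default;
    ``method='geometric'`` averages on the ln scale instead) and the mean
    *exact* temperature; singleton groups pass through.  Idempotent: the
    mean of temperatures that round to the same degree rounds to that
    degree again.
    """
    if method not in ("arithmetic", "geometric"):
        raise InvalidInputError(f"method must be 'arithmetic' or 'geometric', got {method!r}")
    if df.empty:
        return df.copy()
    work = df.copy()
    work["_t_round"] = rounded_celsius(work["temperature_K"])
    keys = _DUPLICATE_KEYS + ["_t_round"]

    parts = []
    for _, g in work.groupby(keys, dropna=False, sort=False):
        first = g.iloc[0]
        out = {c: first[c] for c in COLUMNS}
        if len(g) > 1:
            out["k"] = (g["k"].mean() if method == "arithmetic"
                        else float(np.exp(np.log(g["k"]).mean())))
            out["temperature_K"] = g["temperature_K"].mean()
            mass = g["mass_kg"].dropna()
            out["mass_kg"] = mass.mean() if len(mass) else np.nan
            ldow = g["log_dow"].dropna()
            out["log_dow"] = ldow.mean() if len(ldow) else np.nan
            out["source_id"] = "|".join(dict.fromkeys(g["source_id"].astype(str)))
        parts.append(out)
    return pd.DataFrame(parts, columns=COLUMNS)


def read_mass_reference(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a mass-reference CSV (one row per species/life stage)."""
    table = pd.read_csv(path)
    required = ["species", "life_stage", "mass_kg", "n_source_studies"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    return validate_mass_reference(table)


def validate_mass_reference(table: pd.DataFrame) -> pd.DataFrame:
    dup = table.duplicated(subset=["species", "life_stage"], keep=False)
    if dup.any():
        pairs = table.loc[dup, ["species", "life_stage"]].drop_duplicates()
        raise SchemaError(
            "mass reference must have one entry per (species, life_stage); "
            f"duplicated: {pairs.to_dict('records')}"
        )
    if not (table["mass_kg"] > 0).all():
        raise SchemaError("mass reference mass_kg values must all be positive")
    return table


def impute_mass(df: pd.DataFrame, mass_table: pd.DataFrame
                ) -> Tuple[pd.DataFrame, MassImputationSummary]:
    """Fill missing organism masses from a species mass-reference table.

    Matching order per record: (species, life_stage) exactly, then the
    species-level entry (a table row with no life stage; failing that the
    mean over the species' entries).  Records with observed mass are
    untouched; records that stay unmatched keep a missing mass and are
    thereby excluded from mass-corrected analyses only.  A
    ``mass_source`` column records the provenance of every mass.
    """
    mass_table = validate_mass_reference(mass_table)
    stage_map = {
        (r.species, r.life_stage): r.mass_kg
        for r in mass_table.itertuples(index=False)
        if not pd.isna(r.life_stage)
    }
    species_level = {}
    for sp, grp in mass_table.groupby("species"):
        no_stage = grp[grp["life_stage"].isna()]
        species_level[sp] = (
            float(no_stage["mass_kg"].iloc[0]) if len(no_stage)
            else float(grp["mass_kg"].mean())
        )

    out = df.copy()
    source = np.where(out["mass_kg"].notna(), "observed", "").astype(object)
    n_stage = n_species = 0
    unmatched: List[str] = []
    for idx in out.index[out["mass_kg"].isna()]:
        sp = out.at[idx, "species"]
        stage = out.at[idx, "life_stage"]
        key = (sp, stage) if not pd.isna(stage) else None
        if key is not None and key in stage_map:
            out.at[idx, "mass_kg"] = stage_map[key]
            source[out.index.get_loc(idx)] = "imputed_life_stage"
            n_stage += 1
        elif sp in species_level:
            out.at[idx, "mass_kg"] = species_level[sp]
            source[out.index.get_loc(idx)] = "imputed_species"
            n_species += 1
        else:
            source[out.index.get_loc(idx)] = "unmatched"
            unmatched.append(str(sp))
    out["mass_source"] = source
    summary = MassImputationSummary(
        n_observed=int((out["mass_source"] == "observed").sum()),
        n_filled_life_stage=n_stage, n_filled_species=n_species,
        n_unmatched=len(unmatched),
        unmatched_species=sorted(set(unmatched)),
    )
    return out, summary


def filter_min_temperatures(df: pd.DataFrame, min_distinct: int = 4,
                            keys: Sequence[str] = ("species", "chemical", "rate_type"),
                            ) -> pd.DataFrame:
    """Keep only groups observed at >= ``min_distinct`` distinct rounded
    whole-degree temperatures.

    Applied to chemical- and species-specific analyses only; pooled fits
    use the unfiltered records.
    """
    if df.empty or min_distinct <= 1:
        return df.copy()
    work = df.copy()
    work["_t_round"] = rounded_celsius(work["temperature_K"])
    counts = work.groupby(list(keys), dropna=False)["_t_round"].transform("nunique")
    return df.loc[(counts >= min_distinct).to_numpy()].copy()
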