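"""Ingestion and data-treatment rules (duplicate averaging, mass imputation,
minimum-distinct-temperature filtering)."""

import numpy as np
import pandas as pd
import pytest

from thermotk import (
    GeneratorConfig,
    SchemaError,
    average_duplicates,
    filter_min_temperatures,
    generate_dataset,
    impute_mass,
    read_dataset,
    write_dataset,
)
from thermotk.core_model import KELVIN_OFFSET
from thermotk.dataset_prep import CSV_COLUMNS, round_half_away

from conftest import make_records


def _csv(tmp_path, rows, name="data.csv"):
    path = tmp_path / name
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False)
    return path


def _row(**overrides):
    base = dict(source_id="s1", species="sp1", taxon="Crustacea", life_stage="",
                chemical="chemA", chemical_group="PCBs", log_dow=4.2,
                temperature_value=20.0, temperature_unit="C", rate_type="uptake",
                k_value=2.0, k_unit="L/kg/d", mass_kg="")
    base.update(overrides)
    return base


class TestReadDataset:
    def test_valid_rows_become_typed_records(self, tmp_path):
        path = _csv(tmp_path, [_row(), _row(species="sp2", temperature_value=288.15,
                                         temperature_unit="K"),
                               _row(rate_type="elimination", k_value=0.3)])
        result = read_dataset(path)
        assert len(result.records) == 3
        assert result.rejected == []
        assert result.records["temperature_K"].iloc[0] == pytest.approx(293.15)
        assert result.records["temperature_K"].iloc[1] == pytest.approx(288.15)

    def test_invalid_rows_rejected_with_line_diagnostics(self, tmp_path):
        path = _csv(tmp_path, [_row(), _row(k_value=-1.0), _row(temperature_unit="F")])
        result = read_dataset(path)
        assert len(result.records) == 1
        assert len(result.rejected) == 2
        assert any("line 3" in d and "k_value" in d for d in result.rejected)
        assert any("line 4" in d and "temperature_unit" in d for d in result.rejected)

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"species": ["x"], "k_value": [1.0]}).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="missing mandatory column"):
            read_dataset(path)

    def test_write_read_roundtrip(self, tmp_path):
        df = generate_dataset(GeneratorConfig(seed=4, n_uptake=20, n_elimination=20))
        path = tmp_path / "ds.csv"
        write_dataset(df, path)
        back = read_dataset(path)
        assert back.rejected == []
        assert np.allclose(back.records["k"], df["k"])
        assert np.allclose(back.records["temperature_K"], df["temperature_K"])


class TestAverageDuplicates:
    def test_rounded_degree_duplicates_average_k_and_exact_temperature(self):
        # 19.6 and 20.4 degC both round to 20: one record, k = (2+4)/2 = 3
        df = make_records([19.6 + KELVIN_OFFSET, 20.4 + KELVIN_OFFSET], [2.0, 4.0])
        out = average_duplicates(df)
        assert len(out) == 1
        assert out["k"].iloc[0] == pytest.approx(3.0)
        assert out["temperature_K"].iloc[0] == pytest.approx(20.0 + KELVIN_OFFSET)

    def test_temperatures_rounding_apart_are_retained(self):
        # 19.4 -> 19 and 20.6 -> 21: two distinct groups survive
        df = make_records([19.4 + KELVIN_OFFSET, 20.6 + KELVIN_OFFSET], [2.0, 4.0])
        assert len(average_duplicates(df)) == 2

    def test_rate_types_never_merge(self):
        up = make_records([20.0 + KELVIN_OFFSET], [2.0], rate_type="uptake")
        el = make_records([20.0 + KELVIN_OFFSET], [4.0], rate_type="elimination")
        out = average_duplicates(pd.concat([up, el], ignore_index=True))
        assert len(out) == 2

    def test_idempotent_and_never_grows(self):
        df = generate_dataset(GeneratorConfig(seed=8, n_uptake=120, n_elimination=120,
                                              duplicate_fraction=0.2))
        once = average_duplicates(df)
        twice = average_duplicates(once)
        assert len(once) <= len(df)
        pd.testing.assert_frame_equal(
            once.sort_values(["rate_type", "species", "chemical", "temperature_K"])
                .reset_index(drop=True),
            twice.sort_values(["rate_type", "species", "chemical", "temperature_K"])
                .reset_index(drop=True),
        )

    def test_commutes_with_rate_type_restriction(self):
        df = generate_dataset(GeneratorConfig(seed=8, n_uptake=80, n_elimination=80,
                                              duplicate_fraction=0.2))
        prep_then_restrict = average_duplicates(df)
        prep_then_restrict = prep_then_restrict[
            prep_then_restrict["rate_type"] == "uptake"]
        restrict_then_prep = average_duplicates(df[df["rate_type"] == "uptake"])
        key = ["species", "chemical", "temperature_K"]
        pd.testing.assert_frame_equal(
            prep_then_restrict.sort_values(key).reset_index(drop=True),
            restrict_then_prep.sort_values(key).reset_index(drop=True),
        )

    def test_empty_input_passes_through(self):
        df = make_records([], [])
        assert len(average_duplicates(df)) == 0

    def test_geometric_averaging_option(self):
        df = make_records([20.0 + KELVIN_OFFSET, 20.0 + KELVIN_OFFSET], [2.0, 8.0])
        arith = average_duplicates(df)
        geom = average_duplicates(df, method="geometric")
        assert arith["k"].iloc[0] == pytest.approx(5.0)
        assert geom["k"].iloc[0] == pytest.approx(4.0)  # sqrt(2*8)
        with pytest.raises(Exception, match="arithmetic"):
            average_duplicates(df, method="harmonic")

    def test_tie_rounding_is_away_from_zero(self):
        assert round_half_away(19.5) == 20.0
        assert round_half_away(-0.5) == -1.0
        assert round_half_away(20.4) == 20.0


MASS_TABLE = pd.DataFrame({
    "species": ["sp1", "sp1", "sp2"],
    "life_stage": ["juvenile", None, None],
    "mass_kg": [0.001, 0.01, 0.2],
    "n_source_studies": [2, 3, 1],
})


class TestImputeMass:
    def test_life_stage_match_preferred_over_species_level(self):
        df = make_records([293.15], [2.0], species="sp1")
        df["life_stage"] = "juvenile"
        out, summary = impute_mass(df, MASS_TABLE)
        assert out["mass_kg"].iloc[0] == pytest.approx(0.001)
        assert summary.n_filled_life_stage == 1

    def test_species_level_fallback_without_stage(self):
        df = make_records([293.15], [2.0], species="sp1")
        out, summary = impute_mass(df, MASS_TABLE)
        assert out["mass_kg"].iloc[0] == pytest.approx(0.01)
        assert summary.n_filled_species == 1

    def test_observed_mass_untouched(self):
        df = make_records([293.15], [2.0], species="sp1", mass_kg=0.5)
        df["life_stage"] = "juvenile"
        out, summary = impute_mass(df, MASS_TABLE)
        assert out["mass_kg"].iloc[0] == pytest.approx(0.5)
        assert out["mass_source"].iloc[0] == "observed"
        assert summary.n_observed == 1

    def test_unknown_species_flagged_and_retained(self):
        df = make_records([293.15], [2.0], species="sp_missing")
        out, summary = impute_mass(df, MASS_TABLE)
        assert len(out) == 1
        assert np.isnan(out["mass_kg"].iloc[0])
        assert out["mass_source"].iloc[0] == "unmatched"
        assert summary.unmatched_species == ["sp_missing"]

    def test_duplicate_reference_entries_rejected(self):
        bad = pd.DataFrame({"species": ["x", "x"], "life_stage": ["adult", "adult"],
                            "mass_kg": [1.0, 2.0], "n_source_studies": [1, 1]})
        with pytest.raises(SchemaError, match="one entry per"):
            impute_mass(make_records([293.15], [2.0]), bad)


class TestFilterMinTemperatures:
    def _two_groups(self):
        a = make_records([283.15, 288.15, 293.15, 298.15], [1, 2, 3, 4],
                         species="A", chemical="P")
        b = make_records([283.15, 288.15, 293.15], [1, 2, 3],
                         species="B", chemical="P")
        return pd.concat([a, b], ignore_index=True)

    def test_threshold_keeps_four_distinct_drops_three(self):
        out = filter_min_temperatures(self._two_groups())
        assert set(out["species"]) == {"A"}
        assert len(out) == 4

    def test_min_distinct_one_is_identity(self):
        df = self._two_groups()
        out = filter_min_temperatures(df, min_distinct=1)
        pd.testing.assert_frame_equal(out.reset_index(drop=True),
                                      df.reset_index(drop=True))

    def test_duplicate_temperatures_count_once(self):
        # 4 records at only 2 distinct rounded temperatures: dropped at default
        df = make_records([283.15, 283.2, 293.15, 293.1], [1, 2, 3, 4])
        assert len(filter_min_temperatures(df)) == 0

    def test_count_never_increases(self):
        df = generate_dataset(GeneratorConfig(seed=14, n_uptake=100, n_elimination=100))
        assert len(filter_min_temperatures(df)) <= len(df)
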