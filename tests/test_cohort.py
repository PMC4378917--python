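import warnings
from io import StringIO

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import phenoforest as pf
from phenoforest.cohort import ORGANISMS, SchemaError, VocabularyError


def test_write_then_load_round_trips_exactly(tiny_cohort, tmp_path):
    path = tmp_path / "cohort.csv"
    pf.write_cohort(tiny_cohort, path)
    loaded, rejections = pf.load_cohort(path, tiny_cohort.schema)
    assert len(rejections) == 0
    pd.testing.assert_frame_equal(
        loaded.data[tiny_cohort.schema.names],
        tiny_cohort.data[tiny_cohort.schema.names],
        check_dtype=False,
    )


def test_simulated_cohort_round_trips(tmp_path):
    cohort, _ = pf.simulate_cohort(pf.preset("separable_k3", n=30, seed=3))
    path = tmp_path / "sim.csv"
    pf.write_cohort(cohort, path)
    loaded, _ = pf.load_cohort(path, cohort.schema)
    for name in cohort.schema.names:
        a, b = loaded.data[name], cohort.data[name]
        if cohort.schema[name].role == "continuous":
            assert (a.to_numpy() == b.to_numpy()).all(), name
        else:
            assert (a.astype(str).to_numpy() == b.astype(str).to_numpy()).all()


def test_missing_cell_rejects_row_with_line_number(tiny_cohort, tmp_path):
    path = tmp_path / "cohort.csv"
    pf.write_cohort(tiny_cohort, path)
    lines = path.read_text().splitlines()
    # blank the FEV1% of the second subject (file line 3)
    header = lines[0].split(",")
    cells = lines[2].split(",")
    cells[header.index("fev1_pct")] = ""
    lines[2] = ",".join(cells)
    path.write_text("\n".join(lines) + "\n")
    cohort, rejections = pf.load_cohort(path, tiny_cohort.schema)
    assert cohort.n == 3
    assert len(rejections) == 1
    assert rejections.iloc[0]["line"] == 3
    assert "fev1_pct" in rejections.iloc[0]["reason"]


def test_missing_column_raises_schema_error(tiny_cohort, tmp_path):
    path = tmp_path / "cohort.csv"
    df = tiny_cohort.data.drop(columns=["brasfield"])
    df.to_csv(path)
    with pytest.raises(SchemaError, match="brasfield"):
        pf.load_cohort(path, tiny_cohort.schema)


class TestDeriveFeatures:
    def test_arithmetic(self, tiny_cohort):
        df = tiny_cohort.data.copy()
        df.loc["s1", ["age", "fev1_pct", "height", "weight"]] = [40.0, 50.0, 1.70, 57.8]
        out = pf.derive_features(pf.Cohort(df, tiny_cohort.schema)).data
        assert out.loc["s1", "age_fev1_product"] == pytest.approx(2000.0)
        assert out.loc["s1", "bmi"] == pytest.approx(20.0, abs=0.01)

    def test_idempotent(self, tiny_cohort):
        once = pf.derive_features(tiny_cohort)
        twice = pf.derive_features(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_inconsistent_stored_bmi_warns(self, tiny_cohort):
        df = tiny_cohort.data.copy()
        df.loc["s1", "bmi"] = df.loc["s1", "bmi"] * 1.10
        with pytest.warns(UserWarning, match="bmi"):
            out = pf.derive_features(pf.Cohort(df, tiny_cohort.schema))
        # recomputed value wins
        assert out.data.loc["s1", "bmi"] == pytest.approx(
            df.loc["s1", "weight"] / df.loc["s1", "height"] ** 2
        )

    def test_zero_height_raises(self, tiny_cohort):
        df = tiny_cohort.data.copy()
        df.loc["s1", "height"] = 0.0
        with pytest.raises(ValueError, match="height"):
            pf.derive_features(pf.Cohort(df, tiny_cohort.schema))


class TestSeverityBand:
    @pytest.mark.parametrize(
        "product,band",
        [(900, "severe"), (1300, "moderate"), (1700, "mild"),
         (1000, "moderate"), (1600, "moderate"), (0, "severe")],
    )
    def test_examples(self, product, band):
        assert pf.severity_band(product) == band

    def test_negative_product_raises(self):
        with pytest.raises(ValueError):
            pf.severity_band(-1.0)

    @given(st.floats(min_value=0, max_value=1e7, allow_nan=False))
    def test_partitions_nonnegative_axis(self, product):
        assert pf.severity_band(product) in {"severe", "moderate", "mild"}


class TestMicrobiologyAggregation:
    @staticmethod
    def _records(rows):
        return pd.DataFrame(rows, columns=["subject_id", "date", "organism", "positive"])

    def test_two_positives_in_window_present(self):
        rec = self._records([
            ("s1", "2014-01-10", "pa", 1),
            ("s1", "2014-04-10", "pa", 1),
        ])
        flags = pf.aggregate_microbiology(rec, pd.Timestamp("2014-07-01"))
        assert flags.loc["s1", "pa"] == 1

    def test_single_positive_absent(self):
        rec = self._records([("s1", "2014-01-10", "pa", 1)])
        flags = pf.aggregate_microbiology(rec, pd.Timestamp("2014-07-01"))
        assert flags.loc["s1", "pa"] == 0

    def test_culture_outside_window_ignored(self):
        rec = self._records([
            ("s1", "2013-05-01", "pa", 1),  # 426 days before reference
            ("s1", "2014-04-10", "pa", 1),
        ])
        flags = pf.aggregate_microbiology(rec, pd.Timestamp("2014-07-01"))
        assert flags.loc["s1", "pa"] == 0

    def test_negative_cultures_do_not_count(self):
        rec = self._records([
            ("s1", "2014-01-10", "candida", 0),
            ("s1", "2014-04-10", "candida", 1),
        ])
        flags = pf.aggregate_microbiology(rec, pd.Timestamp("2014-07-01"))
        assert flags.loc["s1", "candida"] == 0

    def test_unknown_organism_raises(self):
        rec = self._records([("s1", "2014-01-10", "klebsiella", 1)])
        with pytest.raises(VocabularyError, match="klebsiella"):
            pf.aggregate_microbiology(rec, pd.Timestamp("2014-07-01"))

    def test_per_subject_reference_dates(self):
        rec = self._records([
            ("s1", "2014-01-10", "pa", 1), ("s1", "2014-02-10", "pa", 1),
            ("s2", "2014-01-10", "pa", 1), ("s2", "2014-02-10", "pa", 1),
        ])
        refs = pd.Series({"s1": pd.Timestamp("2014-06-01"),
                          "s2": pd.Timestamp("2016-06-01")})
        flags = pf.aggregate_microbiology(rec, refs)
        assert flags.loc["s1", "pa"] == 1
        assert flags.loc["s2", "pa"] == 0  # cultures predate s2's window

    def test_adding_positive_culture_is_monotone(self, rng):
        base = [("s1", "2014-01-10", "pa", 1), ("s1", "2014-03-10", "pa", 1)]
        flags0 = pf.aggregate_microbiology(
            self._records(base), pd.Timestamp("2014-07-01"))
        extra = base + [("s1", "2014-05-01", "pa", 1)]
        flags1 = pf.aggregate_microbiology(
            self._records(extra), pd.Timestamp("2014-07-01"))
        assert (flags1.loc["s1"] >= flags0.loc["s1"]).all()


class TestComboTrait:
    @pytest.mark.parametrize("a,b,expected", [(1, 1, 1), (1, 0, 0),
                                              (0, 1, 0), (0, 0, 0)])
    def test_truth_table(self, a, b, expected):
        assert pf.combo_trait(np.array([a]), np.array([b]))[0] == expected

    def test_commutative_on_cohort(self, tiny_cohort):
        a = tiny_cohort.data["pa"]
        b = tiny_cohort.data["candida"]
        assert (pf.combo_trait(a, b) == pf.combo_trait(b, a)).all()


def test_validate_cohort_flags_violations(tiny_cohort):
    assert pf.validate_cohort(tiny_cohort) == []
    df = tiny_cohort.data.copy()
    df.loc["s1", "brasfield"] = 31.0
    df.loc["s2", "bmi"] = 99.0
    problems = pf.validate_cohort(pf.Cohort(df, tiny_cohort.schema))
    assert any("brasfield" in p for p in problems)
    assert any("bmi" in p for p in problems)
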