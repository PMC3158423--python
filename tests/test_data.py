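"""Dataset schema, CSV round-trips and domain harmonization."""

import numpy as np
import pytest

from qsarkit.data import (
    CONTINUOUS,
    ENUMERATED,
    FEATURE,
    META,
    RESPONSE,
    VariableSchema,
    harmonize,
    harmonize_to_schema,
    read_csv,
    write_csv,
)
from qsarkit.exceptions import NoDataError, SchemaConflictError

from conftest import make_dataset


def enum_col(values, levels):
    idx = {lv: i for i, lv in enumerate(levels)}
    return [idx[v] if v is not None else np.nan for v in values]


class TestHarmonize:
    def test_numeric_text_column_converted_to_continuous(self):
        a = make_dataset(
            {"act": (ENUMERATED, FEATURE, enum_col(["3.2", "4.1"], ["3.2", "4.1"]), ("3.2", "4.1"))}
        )
        b = make_dataset({"act": (CONTINUOUS, FEATURE, [1.0, 2.0], ())})
        a2, b2, report = harmonize(a, b)
        assert a2.var("act").kind == CONTINUOUS
        assert list(a2.df["act"]) == [3.2, 4.1]
        assert any("act" in line for line in report)

    def test_level_order_aligned_with_values_preserved(self):
        a = make_dataset(
            {"col": (ENUMERATED, FEATURE, enum_col(["b", "a"], ["b", "a"]), ("b", "a"))}
        )
        b = make_dataset(
            {"col": (ENUMERATED, FEATURE, enum_col(["a", "b"], ["a", "b"]), ("a", "b"))}
        )
        a2, b2, report = harmonize(a, b)
        assert a2.var("col").levels == b2.var("col").levels
        # relabeling is a bijection: each row keeps its label
        for before, after in [(a, a2), (b, b2)]:
            lab_before = [before.var("col").levels[int(c)] for c in before.df["col"]]
            lab_after = [after.var("col").levels[int(c)] for c in after.df["col"]]
            assert lab_before == lab_after
        assert report

    def test_irreconcilable_text_vs_continuous_raises(self):
        a = make_dataset({"act": (ENUMERATED, FEATURE, [0, 1], ("high", "low"))})
        b = make_dataset({"act": (CONTINUOUS, FEATURE, [1.0, 2.0], ())})
        with pytest.raises(SchemaConflictError, match="act"):
            harmonize(a, b)

    def test_harmonize_is_idempotent(self):
        a = make_dataset(
            {"col": (ENUMERATED, FEATURE, enum_col(["b", "a"], ["b", "a"]), ("b", "a"))}
        )
        b = make_dataset(
            {"col": (ENUMERATED, FEATURE, enum_col(["a", "b"], ["a", "b"]), ("a", "b"))}
        )
        a2, b2, _ = harmonize(a, b)
        a3, b3, report = harmonize(a2, b2)
        assert report == []
        assert a3.df.equals(a2.df) and b3.df.equals(b2.df)

    def test_disjoint_level_sets_merge(self):
        a = make_dataset({"c": (ENUMERATED, FEATURE, [0, 1], ("x", "y"))})
        b = make_dataset({"c": (ENUMERATED, FEATURE, [0, 1], ("y", "z"))})
        a2, b2, _ = harmonize(a, b)
        assert a2.var("c").levels == b2.var("c").levels == ("x", "y", "z")

    def test_empty_input_rejected(self):
        a = make_dataset({"c": (CONTINUOUS, FEATURE, [], ())})
        b = make_dataset({"c": (CONTINUOUS, FEATURE, [1.0], ())})
        with pytest.raises(NoDataError):
            harmonize(a, b)


class TestHarmonizeToSchema:
    def test_missing_training_feature_named_in_error(self):
        ref = [VariableSchema("x1"), VariableSchema("x2")]
        data = make_dataset({"x1": (CONTINUOUS, FEATURE, [1.0], ())})
        with pytest.raises(SchemaConflictError, match="x2"):
            harmonize_to_schema(data, ref)

    def test_extra_columns_dropped_and_order_restored(self):
        ref = [VariableSchema("x1"), VariableSchema("x2")]
        data = make_dataset(
            {
                "extra": (CONTINUOUS, FEATURE, [9.0], ()),
                "x2": (CONTINUOUS, FEATURE, [2.0], ()),
                "x1": (CONTINUOUS, FEATURE, [1.0], ()),
            }
        )
        out, _ = harmonize_to_schema(data, ref)
        assert out.feature_names == ["x1", "x2"]

    def test_unseen_level_maps_to_missing(self):
        ref = [VariableSchema("c", ENUMERATED, ("a", "b"))]
        data = make_dataset({"c": (ENUMERATED, FEATURE, [0, 1, 2], ("a", "b", "zzz"))})
        out, report = harmonize_to_schema(data, ref)
        assert np.isnan(out.df["c"].iloc[2])
        assert any("zzz" in line for line in report)


class TestCSV:
    def test_roundtrip_with_missing_and_meta(self, tmp_path):
        data = make_dataset(
            {
                "SMILES": (CONTINUOUS, META, ["CCO", "CC"], ()),
                "x": (CONTINUOUS, FEATURE, [1.5, np.nan], ()),
                "cls": (ENUMERATED, RESPONSE, [0, 1], ("neg", "pos")),
            }
        )
        path = tmp_path / "d.csv"
        write_csv(data, path)
        text = path.read_text()
        assert "?" in text  # missing cell rendered as ?
        back = read_csv(path)
        assert back.var("cls").levels == ("neg", "pos")
        assert back.response_schema.name == "cls"
        assert np.isnan(back.df["x"].iloc[1])
        assert back.df["x"].iloc[0] == 1.5
        assert list(back.df["SMILES"]) == ["CCO", "CC"]

    def test_schema_inference_without_sidecar(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("SMILES,x,cls\nCCO,1.0,pos\nCC,?,neg\n")
        data = read_csv(path, response="cls")
        assert data.var("x").kind == CONTINUOUS
        assert data.var("cls").kind == ENUMERATED
        assert data.var("SMILES").role == META  # by name convention
        assert data.task == "classification"

    def test_empty_csv_rejected(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("x,y\n")
        with pytest.raises(NoDataError):
            read_csv(path)


def test_exactly_one_response_enforced():
    with pytest.raises(ValueError):
        make_dataset(
            {
                "a": (CONTINUOUS, RESPONSE, [1.0], ()),
                "b": (CONTINUOUS, RESPONSE, [2.0], ()),
            }
        ).task


def test_select_features_keeps_response_and_meta():
    data = make_dataset(
        {
            "id": (CONTINUOUS, META, ["m1"], ()),
            "x1": (CONTINUOUS, FEATURE, [1.0], ()),
            "x2": (CONTINUOUS, FEATURE, [2.0], ()),
            "y": (CONTINUOUS, RESPONSE, [3.0], ()),
        }
    )
    out = data.select_features(["x2"])
    assert out.feature_names == ["x2"]
    assert out.response_schema is not None
    assert "id" in out.names
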