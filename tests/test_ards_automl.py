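"""Stage-graph validation/extraction and the voting ensemble scaffold."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from icufusion import ards_automl as aa, clinical_indices as ci, synthgen as sg


class TestValidateGraph:
    def test_default_graph_has_eight_output_features(self):
        graph = aa.default_ards_graph()
        assert len(graph.output_features) == 8
        assert "PBW" in graph.output_features
        assert "ventilatory_ratio" in graph.output_features

    def test_node_consuming_its_own_output_is_a_cycle(self):
        spec = {
            "source_features": ["a"],
            "stages": [[{"kind": "user_expression", "expression": "x + 1",
                         "inputs": ["x"], "output": "x"}]],
            "label": "a",
        }
        with pytest.raises(aa.GraphValidationError):
            aa.validate_graph(spec)

    def test_dangling_input_rejected(self):
        spec = {
            "source_features": ["a", "label"],
            "stages": [[{"kind": "bypass", "inputs": ["missing"], "output": "b"}]],
            "label": "label",
        }
        with pytest.raises(aa.GraphValidationError, match="not available"):
            aa.validate_graph(spec)

    def test_missing_label_rejected(self):
        spec = {"source_features": ["a"], "stages": [], "label": ""}
        with pytest.raises(aa.GraphValidationError, match="label"):
            aa.validate_graph(spec)

    def test_same_stage_predecessor_is_visible(self):
        spec = {
            "source_features": ["a", "label"],
            "stages": [[
                {"kind": "user_expression", "expression": "a * 2", "inputs": ["a"], "output": "b"},
                {"kind": "user_expression", "expression": "b + 1", "inputs": ["b"], "output": "c"},
            ]],
            "label": "label",
        }
        graph = aa.validate_graph(spec)
        assert graph.output_features == ("b", "c")


class TestExtractFeatures:
    @pytest.fixture()
    def records(self):
        return sg.generate_ards_dataset(sg.ArdsSimSpec(n=200, seed=4))

    def test_builtin_outputs_equal_direct_calls_bit_for_bit(self, records):
        result = aa.extract_features(aa.default_ards_graph(), records)
        for i, row in records.iterrows():
            pbw = ci.pbw(row["sex"], row["height"])
            assert result.table.loc[i, "PBW"] == pbw
            assert result.table.loc[i, "ventilatory_ratio"] == ci.ventilatory_ratio(
                row["Ve"], row["PCO2"], row["Vt"], pbw
            )

    def test_bypass_copies_values_unchanged(self, records):
        result = aa.extract_features(aa.default_ards_graph(), records)
        assert (result.table["FiO2"] == records["FiO2"]).all()

    def test_incomplete_rows_dropped_and_counted(self, records):
        records = records.copy()
        records.loc[records.index[:7], "PCO2"] = np.nan
        result = aa.extract_features(aa.default_ards_graph(), records)
        assert result.n_dropped == 7
        assert len(result.table) == len(records) - 7

    def test_extraction_is_referentially_transparent(self, records):
        graph = aa.default_ards_graph()
        assert aa.extract_features(graph, records).table.equals(
            aa.extract_features(graph, records).table
        )

    def test_expression_referencing_unknown_feature_names_it(self):
        spec = {
            "source_features": ["a", "label"],
            "stages": [[{"kind": "user_expression", "expression": "a + ghost",
                         "inputs": ["a"], "output": "b"}]],
            "label": "label",
        }
        with pytest.raises(aa.GraphValidationError, match="ghost"):
            aa.validate_graph(spec)


class TestExpressions:
    def test_arithmetic_over_columns(self):
        env = {"x": pd.Series([1.0, 2.0]), "y": pd.Series([10.0, 20.0])}
        out = aa.evaluate_expression("(x + y) / 2 - 0.5", env)
        assert list(out) == [5.0, 10.5]

    @pytest.mark.parametrize("expr", ["__import__('os')", "x ** 2", "f(x)", "x[0]"])
    def test_non_arithmetic_constructs_rejected(self, expr):
        with pytest.raises(aa.GraphValidationError):
            aa.evaluate_expression(expr, {"x": 1.0})


class TestMajorityVote:
    def test_strict_majorities(self):
        votes = np.array([[1, 0, 1], [0, 0, 1], [1, 1, 1], [0, 0, 0]])
        assert list(aa.majority_vote(votes)) == [1, 0, 1, 0]

    def test_even_tie_breaks_positive_with_warning(self):
        with pytest.warns(UserWarning, match="tie"):
            assert list(aa.majority_vote(np.array([[1, 0]]))) == [1]

    @settings(derandomize=True, max_examples=30)
    @given(label=st.integers(0, 1), members=st.integers(1, 7))
    def test_unanimous_vote_returns_the_label(self, label, members):
        votes = np.full((5, members), label)
        assert list(aa.majority_vote(votes)) == [label] * 5

    def test_empty_predictions_rejected(self):
        with pytest.raises(ValueError):
            aa.majority_vote(np.empty((3, 0)))


@pytest.fixture(scope="module")
def trained():
    import warnings

    table = sg.generate_ards_dataset(sg.ArdsSimSpec(n=1000, seed=0))
    extracted = aa.extract_features(aa.default_ards_graph(), table).table
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return aa.train_ensemble(extracted, aa.EnsembleSpec(), seed=0)


class TestEnsemble:
    def test_reports_metric_per_member_and_for_fusion(self, trained):
        assert set(trained.member_metrics) == {"svm", "xgb", "mlp"}
        assert 0 <= trained.ensemble_metric <= 1

    def test_split_arithmetic(self, trained):
        assert trained.manifest["n_train"] == 800
        assert trained.manifest["n_validation"] == 200

    def test_deterministic_under_seed(self, no_sklearn_noise):
        table = sg.generate_ards_dataset(sg.ArdsSimSpec(n=400, seed=2))
        extracted = aa.extract_features(aa.default_ards_graph(), table).table
        spec = aa.EnsembleSpec(members=("xgb",))
        a = aa.train_ensemble(extracted, spec, seed=3)
        b = aa.train_ensemble(extracted, spec, seed=3)
        assert a.member_metrics == b.member_metrics

    def test_single_class_table_rejected(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0], "label": [1, 1, 1]})
        with pytest.raises(ValueError, match="both classes"):
            aa.train_ensemble(table, aa.EnsembleSpec(), seed=0)

    def test_select_best_is_argmax_with_declaration_tiebreak(self, trained):
        result = aa.EnsembleResult(
            models={},
            member_metrics={"svm": 0.81, "xgb": 0.88, "mlp": 0.84},
            ensemble_metric=0.9,
            manifest={"metric": "auc"},
            declaration_order=("svm", "xgb", "mlp"),
        )
        assert aa.select_best(result, "auc") == "xgb"
        result.member_metrics = {"svm": 0.8, "xgb": 0.8, "mlp": 0.8}
        assert aa.select_best(result, "auc") == "svm"
        with pytest.raises(ValueError):
            aa.select_best(result, "bogus")
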