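"""Linear and CART regression models with the confounding harness."""

import numpy as np
import pandas as pd
import pytest

from plastcov.models import (
    ModelSpec,
    fit_linear,
    fit_tree,
    variable_importance,
)


def _confounded_cohort(rng, n=240, effect_through_length=True):
    """Partition length drives the outcome; partitions differ only via their
    typical length.  The categorical 'partition' carries no direct effect.
    Length varies substantially within partitions (cv 0.3) so the covariate
    is separable from the factor."""
    parts = np.array(["LSC", "IRb", "SSC", "IRa"])[rng.integers(0, 4, n)]
    base_len = {"LSC": 85.0, "IRb": 25.5, "SSC": 18.0, "IRa": 25.5}
    length = np.array([base_len[p] for p in parts]) * rng.normal(1, 0.3, n)
    y = (0.05 * length if effect_through_length
         else rng.normal(0, 1, n)) + rng.normal(0, 0.5, n)
    return pd.DataFrame({"y": y, "partition": parts,
                         "partition_length": length})


class TestLinear:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"y": 2 + 3 * x, "x": x})
        res = fit_linear(df, ModelSpec("y", ["x"]))
        coef = res.coef_table.set_index("term")
        assert coef.loc["x", "estimate"] == pytest.approx(3.0)
        assert coef.loc["const", "estimate"] == pytest.approx(2.0)
        assert res.r2_adj == pytest.approx(1.0)

    def test_null_outcome_r2adj_near_zero(self):
        rng = np.random.default_rng(61)
        r2s = []
        for _ in range(200):
            df = pd.DataFrame({"y": rng.normal(0, 1, 50),
                               "x": rng.normal(0, 1, 50),
                               "z": rng.normal(0, 1, 50)})
            r2s.append(fit_linear(df, ModelSpec("y", ["x", "z"])).r2_adj)
        assert abs(np.mean(r2s)) < 0.02

    def test_treatment_coding_reference_is_canonical_first(self):
        rng = np.random.default_rng(67)
        df = pd.DataFrame({
            "y": rng.normal(0, 1, 80),
            "partition": np.array(["LSC", "IRb", "SSC", "IRa"])[
                rng.integers(0, 4, 80)],
        })
        res = fit_linear(df, ModelSpec("y", ["partition"]))
        terms = set(res.coef_table["term"])
        assert "partition_LSC" not in terms  # LSC is the reference level
        assert {"partition_IRb", "partition_SSC", "partition_IRa"} <= terms

    def test_rank_deficiency_names_aliased_terms(self):
        rng = np.random.default_rng(71)
        x = rng.normal(0, 1, 40)
        df = pd.DataFrame({"y": rng.normal(0, 1, 40), "x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="x2"):
            fit_linear(df, ModelSpec("y", ["x", "x2"]))

    def test_missing_category_rows_dropped(self):
        rng = np.random.default_rng(73)
        df = pd.DataFrame({
            "y": rng.normal(0, 1, 60),
            "platform": ["A"] * 25 + ["B"] * 25 + ["missing"] * 10,
        })
        res = fit_linear(df, ModelSpec("y", ["platform"]))
        assert res.n == 50

    def test_software_refused(self):
        with pytest.raises(ValueError, match="software"):
            ModelSpec("y", ["software"])


class TestTree:
    def test_clean_group_split(self):
        df = pd.DataFrame({
            "y": [0.0] * 20 + [10.0] * 20,
            "group": ["A"] * 20 + ["B"] * 20,
        })
        res = fit_tree(df, ModelSpec("y", ["group"], seed=1))
        assert res.rmse == pytest.approx(0.0)
        assert res.r2_train == pytest.approx(1.0)
        assert res.importance["group"] == 100.0

    def test_constant_outcome_single_node(self):
        df = pd.DataFrame({"y": [5.0] * 40, "x": np.arange(40.0)})
        res = fit_tree(df, ModelSpec("y", ["x"], seed=1))
        assert res.rmse == 0.0
        assert all(v == 0.0 for v in res.importance.values())
        assert res.tree_dump["leaf"]

    def test_seeded_determinism(self):
        rng = np.random.default_rng(79)
        df = pd.DataFrame({"y": rng.normal(0, 1, 100),
                           "x": rng.normal(0, 1, 100),
                           "g": np.array(["A", "B", "C"])[rng.integers(0, 3, 100)]})
        a = fit_tree(df, ModelSpec("y", ["x", "g"], seed=5))
        b = fit_tree(df, ModelSpec("y", ["x", "g"], seed=5))
        assert a.tree_dump == b.tree_dump
        assert a.importance == b.importance
        assert a.cv_rmse == b.cv_rmse

    def test_unused_variable_importance_zero(self):
        rng = np.random.default_rng(83)
        x = rng.normal(0, 1, 200)
        df = pd.DataFrame({"y": 3 * x + rng.normal(0, 0.1, 200), "x": x,
                           "noise": rng.normal(0, 1, 200)})
        res = fit_tree(df, ModelSpec("y", ["x", "noise"], seed=2))
        assert res.importance["x"] == 100.0
        assert res.importance["noise"] < 5.0

    def test_importance_table_ordered(self):
        rng = np.random.default_rng(89)
        x = rng.normal(0, 1, 150)
        df = pd.DataFrame({"y": x + rng.normal(0, 0.3, 150), "x": x,
                           "z": rng.normal(0, 1, 150)})
        res = fit_tree(df, ModelSpec("y", ["x", "z"], seed=3))
        tab = variable_importance(res)
        assert list(tab["variable"])[0] == "x"
        assert (tab["importance"].diff().dropna() <= 0).all()

    def test_too_few_cases_rejected(self):
        df = pd.DataFrame({"y": np.arange(10.0), "x": np.arange(10.0)})
        with pytest.raises(ValueError, match="30"):
            fit_tree(df, ModelSpec("y", ["x"]))


class TestConfounding:
    def test_covariate_inclusion_demotes_categorical(self):
        """When the signal is routed through partition length, adding the
        length covariate transfers tree importance and linear |t| away from
        the partition factor."""
        rng = np.random.default_rng(97)
        demoted_tree = demoted_linear = total = 0
        for _ in range(20):
            df = _confounded_cohort(rng)
            spec0 = ModelSpec("y", ["partition"], seed=11)
            spec1 = ModelSpec("y", ["partition"], ["partition_length"], seed=11)
            t0 = fit_tree(df, spec0)
            t1 = fit_tree(df, spec1)
            demoted_tree += (t1.importance["partition"]
                             < t0.importance["partition"])
            l0 = fit_linear(df, spec0)
            l1 = fit_linear(df, spec1)
            demoted_linear += (_max_abs_t(l1, "partition_")
                               < _max_abs_t(l0, "partition_"))
            total += 1
        assert demoted_tree / total >= 0.9
        assert demoted_linear / total >= 0.9

    def test_length_becomes_top_importance(self):
        rng = np.random.default_rng(101)
        length_imp, part_imp = [], []
        for _ in range(10):
            df = _confounded_cohort(rng)
            res = fit_tree(df, ModelSpec("y", ["partition"],
                                         ["partition_length"], seed=7))
            length_imp.append(res.importance["partition_length"])
            part_imp.append(res.importance["partition"])
        assert np.median(length_imp) == 100.0
        assert np.mean(length_imp) > np.mean(part_imp)


def _max_abs_t(result, prefix):
    coef = result.coef_table
    rows = coef[coef["term"].str.fullmatch(f"{prefix}(LSC|IRb|SSC|IRa)")]
    return rows["t"].abs().max()
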