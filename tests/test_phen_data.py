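"""Ingestion, terminology normalization, missing/redundancy policies and
spec validation."""

import numpy as np
import pandas as pd
import pytest

import phenoscreen as ps
from phenoscreen.phen_data import ValidationError


def _table(df):
    return ps.RawTable(df.copy())


class TestLoadTable:
    def test_parses_csv_with_missing_tokens(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("Genotype,Value\ncontrol,1.2\nmutant,NA\ncontrol,3\n")
        t = ps.load_table(p)
        assert t.n_rows == 3
        assert pd.api.types.is_numeric_dtype(t.data["Value"])
        assert t.data["Value"].isna().sum() == 1

    def test_tsv_delimiter_sniffed_from_extension(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("A\tB\n1\tx\n2\ty\n")
        t = ps.load_table(p)
        assert t.columns == ["A", "B"] and t.n_rows == 2

    def test_header_only_file_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("A,B\n")
        with pytest.raises(ValidationError, match="empty table"):
            ps.load_table(p)

    def test_duplicate_headers_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("A,A,B\n1,2,3\n")
        with pytest.raises(ValidationError, match="duplicate header.*A"):
            ps.load_table(p)

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(OSError):
            ps.load_table(tmp_path / "absent.csv")


class TestNormalizeTerms:
    def test_gender_column_and_values_unified(self):
        t = _table(pd.DataFrame({"gender": ["f", "m", "F"], "x": [1, 2, 3]}))
        out = ps.normalize_terms(t)
        assert "Sex" in out.columns and "gender" not in out.columns
        assert list(out.data["Sex"]) == ["Female", "Male", "Female"]
        assert out.prep.renamed == {"gender": "Sex"}

    @pytest.mark.parametrize("col,target", [
        ("weight", "BodyWeight"), ("body_weight", "BodyWeight"),
        ("date_of_experiment", "Batch"), ("biological_sample_group", "Genotype"),
    ])
    def test_synonyms_renamed(self, col, target):
        out = ps.normalize_terms(_table(pd.DataFrame({col: [1, 2]})))
        assert out.columns == [target]

    def test_already_unified_and_unknown_columns_untouched(self):
        t = _table(pd.DataFrame({"Sex": ["Female"], "Diet": ["chow"]}))
        out = ps.normalize_terms(t)
        assert out.columns == ["Sex", "Diet"]
        assert out.prep.renamed == {}

    def test_collision_onto_same_unified_name_rejected(self):
        t = _table(pd.DataFrame({"sex": ["f"], "gender": ["m"]}))
        with pytest.raises(ValidationError, match="collide"):
            ps.normalize_terms(t)

    def test_idempotent(self):
        t = _table(pd.DataFrame({"gender": ["f", "m"], "weight": [20.0, 25.0]}))
        once = ps.normalize_terms(t)
        twice = ps.normalize_terms(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert once.prep.renamed == twice.prep.renamed


class TestHandleMissing:
    def _frame(self, n_missing, n=100):
        vals = [np.nan] * n_missing + list(range(n - n_missing))
        return pd.DataFrame({"x": vals, "keep": range(n)})

    def test_column_over_threshold_dropped(self):
        out = ps.handle_missing(_table(self._frame(60)))
        assert "x" not in out.columns
        assert ("x", "missing>50%") in out.prep.dropped_variables

    def test_exactly_at_threshold_retained(self):
        out = ps.handle_missing(_table(self._frame(50)))
        assert "x" in out.columns

    def test_substitution_retains_and_counts(self):
        out = ps.handle_missing(_table(self._frame(60)), substitutions={"x": 0})
        assert "x" in out.columns
        assert out.prep.substituted_counts["x"] == 60
        assert out.data["x"].isna().sum() == 0

    def test_incompatible_substitution_type_rejected(self):
        with pytest.raises(ValidationError, match="numeric"):
            ps.handle_missing(_table(self._frame(60)),
                              substitutions={"x": "zero"})

    def test_clean_column_untouched(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out = ps.handle_missing(_table(df))
        pd.testing.assert_frame_equal(out.data, df)


class TestDropRedundant:
    def test_duplicate_column_dropped_first_wins(self):
        df = pd.DataFrame({"A": [1, 2, 3], "A2": [1, 2, 3]})
        out = ps.drop_redundant(_table(df))
        assert out.columns == ["A"]
        assert ("A2", "redundant") in out.prep.dropped_variables

    def test_exact_linear_transform_dropped(self):
        x = np.arange(50, dtype=float)
        df = pd.DataFrame({"X": x, "Y": 2 * x + 3})
        # oracle: |Pearson r| of an affine pair is exactly 1
        assert abs(np.corrcoef(x, 2 * x + 3)[0, 1]) == pytest.approx(1.0)
        out = ps.drop_redundant(_table(df))
        assert out.columns == ["X"]

    def test_near_collinear_pair_retained(self):
        rng = np.random.default_rng(0)
        x = np.arange(200, dtype=float)
        df = pd.DataFrame({"X": x, "Y": x + rng.normal(0, 5, 200)})
        out = ps.drop_redundant(_table(df))
        assert set(out.columns) == {"X", "Y"}

    def test_constant_column_flagged_not_dropped(self):
        df = pd.DataFrame({"c": [7, 7, 7], "x": [1, 2, 3]})
        out = ps.drop_redundant(_table(df))
        assert "c" in out.columns and "c" in out.prep.constant_columns

    def test_pipeline_idempotent_and_conserving(self):
        df = pd.DataFrame({
            "gender": ["f", "m"] * 30,
            "Genotype": ["control"] * 50 + ["mutant"] * 10,
            "Response": np.arange(60, dtype=float),
            "dup": np.arange(60, dtype=float),
            "mostly_missing": [np.nan] * 40 + list(range(20)),
        })
        def chain(t):
            return ps.drop_redundant(ps.handle_missing(ps.normalize_terms(t)))
        once = chain(_table(df))
        twice = chain(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        dropped = {n for n, _ in once.prep.dropped_variables}
        renamed_from = set(once.prep.renamed)
        survived = set(once.columns)
        renamed_to = set(once.prep.renamed.values())
        assert dropped | renamed_from | (survived - renamed_to) == set(df.columns)
        assert not dropped & survived


class TestValidateSpec:
    def _raw(self, **cols):
        base = {"Genotype": ["control"] * 6 + ["mutant"] * 4,
                "Response": np.arange(10, dtype=float)}
        base.update(cols)
        return _table(pd.DataFrame(base))

    def test_numeric_response_with_fisher_is_type_mismatch(self):
        with pytest.raises(ValidationError, match="type mismatch"):
            ps.validate_spec(self._raw(), ps.ModelSpec(
                framework="FisherExact", fixed_terms=["Genotype"]))

    def test_missing_genotype_is_essential_term_error(self):
        t = _table(pd.DataFrame({"Response": [1.0, 2.0]}))
        with pytest.raises(ValidationError, match="essential term absent"):
            ps.validate_spec(t, ps.ModelSpec(fixed_terms=["Genotype"],
                                             random_groups=[]))

    def test_unobserved_reference_rejected(self):
        with pytest.raises(ValidationError, match="reference genotype"):
            ps.validate_spec(self._raw(), ps.ModelSpec(
                fixed_terms=["Genotype"], random_groups=[],
                reference_genotype="wildtype9"))

    def test_single_sex_drops_sex_terms_and_records(self):
        t = self._raw(Sex=["Female"] * 10, Batch=["b1", "b2"] * 5)
        ds = ps.validate_spec(t, ps.ModelSpec(
            fixed_terms=["Genotype", "Sex", "Genotype:Sex"],
            random_groups=["Batch"]))
        assert "Sex" not in ds.spec.fixed_terms
        assert "Genotype:Sex" not in ds.spec.fixed_terms
        assert any("Sex" in d for d in ds.prep.degradations)

    def test_single_level_random_group_dropped_with_fallback(self):
        t = self._raw(Sex=["Female", "Male"] * 5, Batch=["b1"] * 10)
        ds = ps.validate_spec(t, ps.ModelSpec(
            fixed_terms=["Genotype", "Sex"], random_groups=["Batch"]))
        assert ds.spec.random_groups == []
        assert ds.fallback_fixed_only
        assert any("random group" in d for d in ds.prep.degradations)

    def test_genotype_never_silently_dropped(self):
        t = self._raw()
        ds = ps.validate_spec(t, ps.ModelSpec(fixed_terms=["Genotype"],
                                              random_groups=[]))
        assert "Genotype" in ds.spec.fixed_terms


class TestSummarize:
    def test_group_counts_match_construction(self):
        df, _ = ps.gen_continuous_dataset(ps.SimConfig(
            n_control=200, n_batches=10, seed=4))
        ds = ps.prepare(ps.RawTable(df), ps.default_spec("LMM"))
        s = ps.summarize_dataset(ds)
        counts = {(g["Genotype"], g["Sex"]): g["n"] for g in s["group_counts"]}
        assert counts[("control", "Female")] == 100
        assert counts[("control", "Male")] == 100
        assert counts[("mutant", "Female")] == 7
        assert counts[("mutant", "Male")] == 7

    def test_summary_mean_close_to_simulated_truth(self):
        rng = np.random.default_rng(1)
        n = 10000
        df = pd.DataFrame({
            "Genotype": ["control"] * (n - 10) + ["mutant"] * 10,
            "Response": rng.normal(10.0, 1.0, n)})
        ds = ps.validate_spec(ps.RawTable(df), ps.ModelSpec(
            fixed_terms=["Genotype"], random_groups=[]))
        s = ps.summarize_dataset(ds)
        assert abs(s["response"]["mean"] - 10.0) < 3.0 / np.sqrt(n)
        assert abs(s["response"]["sd"] - 1.0) < 0.05
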