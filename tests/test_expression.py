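import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from denovotx.expression import (
    compute_tpm,
    expressed_call,
    fraction_annotated_above_candidate_max,
    pool_isoforms,
    summarize_candidates,
)


def _tpm(counts_dict, lengths_dict):
    counts = pd.DataFrame(counts_dict)
    return compute_tpm(counts, pd.Series(lengths_dict))


class TestComputeTpm:
    def test_single_transcript_takes_the_whole_million(self):
        tpm = _tpm({"lib": pd.Series({"t1": 17})}, {"t1": 500})
        assert tpm.loc["t1", "lib"] == pytest.approx(1e6)

    def test_two_transcripts_equal_counts_length_ratio(self):
        tpm = _tpm(
            {"lib": pd.Series({"a": 100, "b": 100})}, {"a": 1000, "b": 2000}
        )
        assert tpm.loc["a", "lib"] == pytest.approx(666_666.67, abs=0.01)
        assert tpm.loc["b", "lib"] == pytest.approx(333_333.33, abs=0.01)

    def test_zero_count_transcript_gets_zero(self):
        tpm = _tpm({"lib": pd.Series({"a": 0, "b": 10})}, {"a": 100, "b": 100})
        assert tpm.loc["a", "lib"] == 0

    def test_all_zero_library_stays_zero(self):
        tpm = _tpm({"lib": pd.Series({"a": 0, "b": 0})}, {"a": 100, "b": 100})
        assert (tpm["lib"] == 0).all()

    def test_missing_length_raises(self):
        with pytest.raises(KeyError, match="missing lengths"):
            _tpm({"lib": pd.Series({"a": 5})}, {"b": 100})

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_columns_sum_to_one_million(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(2, 30)), int(rng.integers(1, 6))
        counts = pd.DataFrame(
            rng.integers(0, 5000, size=(n, m)),
            index=[f"t{i}" for i in range(n)],
            columns=[f"lib{j}" for j in range(m)],
        )
        lengths = pd.Series(rng.integers(100, 5000, n), index=counts.index)
        tpm = compute_tpm(counts, lengths)
        for lib in tpm.columns:
            total = tpm[lib].sum()
            if counts[lib].sum() > 0:
                assert total == pytest.approx(1e6, rel=1e-6)
            else:
                assert total == 0

    def test_scaling_one_library_leaves_its_tpm_unchanged(self):
        counts = pd.DataFrame(
            {"lib1": [10, 30, 5], "lib2": [7, 7, 7]}, index=["a", "b", "c"]
        )
        lengths = pd.Series({"a": 500, "b": 1000, "c": 1500})
        before = compute_tpm(counts, lengths)
        counts["lib1"] *= 13
        after = compute_tpm(counts, lengths)
        pd.testing.assert_frame_equal(before, after)


class TestExpressedCall:
    @pytest.mark.parametrize(
        "values,mode,expected",
        [
            ([1.0], "any_library", True),           # inclusive threshold
            ([0.99, 0.5], "any_library", False),
            ([0.8, 1.4], "replicate_mean", True),   # mean 1.1 > 1
            ([1.0], "replicate_mean", False),       # strict > 1
            ([1.0, 1.0], "replicate_mean", False),
        ],
    )
    def test_call_conventions(self, values, mode, expected):
        assert expressed_call(values, mode) is expected

    def test_empty_replicate_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            expressed_call([], "any_library")


class TestPoolIsoforms:
    TPM = pd.DataFrame({"lib1": [0.6, 0.5], "lib2": [2.0, 0.0]}, index=["i1", "i2"])

    def test_sum_rule(self):
        pooled = pool_isoforms(self.TPM, ["i1", "i2"])
        assert pooled["lib1"] == pytest.approx(1.1)

    def test_single_isoform_is_identity(self):
        pd.testing.assert_series_equal(
            pool_isoforms(self.TPM, ["i1"]), self.TPM.loc["i1"], check_names=False
        )

    def test_absent_isoform_contributes_zero(self):
        pooled = pool_isoforms(self.TPM, ["i1", "ghost"])
        assert pooled["lib2"] == pytest.approx(2.0)

    def test_permutation_invariance(self):
        a = pool_isoforms(self.TPM, ["i1", "i2"])
        b = pool_isoforms(self.TPM, ["i2", "i1"])
        pd.testing.assert_series_equal(a, b)


class TestSummaries:
    def test_per_candidate_summary_arithmetic(self):
        tpm = pd.DataFrame(
            [[1.2, 2.0, 0.5, 0.0]], index=["c1_i1"],
            columns=["l1", "l2", "l3", "l4"],
        )
        df, cohort = summarize_candidates(tpm, {"c1": ["c1_i1"]})
        row = df.iloc[0]
        assert row["n_libraries_expressed"] == 2
        assert row["n_libraries_nonzero"] == 3
        assert row["mean_TPM_of_expressed"] == pytest.approx(1.6)
        assert row["max_TPM"] == pytest.approx(2.0)
        assert cohort["mean_tpm_of_expressed_obs"] == pytest.approx(1.6)

    def test_never_expressed_candidate_excluded_from_cohort_mean(self):
        tpm = pd.DataFrame(
            [[1.5, 0.0], [0.4, 0.2]], index=["a_i1", "b_i1"], columns=["l1", "l2"]
        )
        df, cohort = summarize_candidates(tpm, {"a": ["a_i1"], "b": ["b_i1"]})
        assert np.isnan(df.set_index("candidate_id").loc["b", "mean_TPM_of_expressed"])
        assert cohort["mean_tpm_of_expressed_obs"] == pytest.approx(1.5)

    def test_empty_candidate_set_flagged_undefined(self):
        tpm = pd.DataFrame([[1.0]], index=["x"], columns=["l1"])
        df, cohort = summarize_candidates(tpm, {})
        assert len(df) == 0 and cohort["defined"] is False


class TestFractionAboveCandidateMax:
    TPM = pd.DataFrame(
        {
            "lib": pd.Series({"g1": 10.0, "g2": 5.0, "g3": 0.5, "g4": 2.0, "c1": 1.59})
        }
    )

    def test_worked_example(self):
        frac = fraction_annotated_above_candidate_max(
            self.TPM, ["g1", "g2", "g3", "g4"], ["c1"], "lib"
        )
        assert frac == pytest.approx(0.75)

    def test_zero_candidate_max_counts_positive_genes(self):
        tpm = self.TPM.copy()
        tpm.loc["c1"] = 0.0
        frac = fraction_annotated_above_candidate_max(
            tpm, ["g1", "g2", "g3", "g4"], ["c1"], "lib"
        )
        assert frac == 1.0

    def test_all_genes_below_gives_zero(self):
        tpm = self.TPM.copy()
        tpm.loc["c1"] = 100.0
        frac = fraction_annotated_above_candidate_max(
            tpm, ["g1", "g2", "g3", "g4"], ["c1"], "lib"
        )
        assert frac == 0.0

    def test_non_increasing_in_candidate_max(self):
        fracs = []
        for cmax in (0.1, 2.0, 6.0, 20.0):
            tpm = self.TPM.copy()
            tpm.loc["c1"] = cmax
            fracs.append(
                fraction_annotated_above_candidate_max(
                    tpm, ["g1", "g2", "g3", "g4"], ["c1"], "lib"
                )
            )
        assert fracs == sorted(fracs, reverse=True)

    def test_requires_candidates_and_genes(self):
        with pytest.raises(ValueError):
            fraction_annotated_above_candidate_max(self.TPM, [], ["c1"], "lib")
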