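import numpy as np
import pandas as pd
import pytest

from hccomics.preprocess import (
    binarize_lesions,
    counts_to_tpm,
    filter_expression_features,
    knn_impute_rows,
    prepare_methylation_features,
)


def _manifest(rows):
    return pd.DataFrame(rows).set_index("probe_id")


class TestCountsToTpm:
    def test_equal_counts_equal_lengths_split_evenly(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["A", "B"])
        lengths = pd.Series([1000, 1000], index=["A", "B"])
        tpm = counts_to_tpm(counts, lengths)
        assert np.allclose(tpm["s1"], [5e5, 5e5])

    def test_length_normalization(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["A", "B"])
        lengths = pd.Series([1000, 2000], index=["A", "B"])
        tpm = counts_to_tpm(counts, lengths)
        assert np.allclose(tpm["s1"], [2e6 / 3, 1e6 / 3])

    def test_single_gene_gets_million(self):
        counts = pd.DataFrame({"s1": [7]}, index=["A"])
        tpm = counts_to_tpm(counts, pd.Series([500], index=["A"]))
        assert tpm.loc["A", "s1"] == pytest.approx(1e6)

    def test_column_sums_are_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 100, (20, 4)) + 1)
        lengths = pd.Series(rng.integers(200, 5000, 20), index=counts.index)
        tpm = counts_to_tpm(counts, lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6)

    def test_zero_sample_named_in_error(self):
        counts = pd.DataFrame({"good": [5], "empty": [0]}, index=["A"])
        with pytest.raises(ValueError, match="empty"):
            counts_to_tpm(counts, pd.Series([1000], index=["A"]))


class TestExpressionFilter:
    def test_constant_gene_dropped(self):
        expr = pd.DataFrame({"s1": [5.0, 5.0], "s2": [5.0, 9.0]}, index=["flat", "var"])
        # make 'var' survive: log2 values spread > 1 SD
        expr.loc["var"] = [0.0, 1000.0]
        out = filter_expression_features(expr)
        assert "flat" not in out.index

    def test_sd_threshold_on_log2_values(self):
        # log2(TPM+1) = v when TPM = 2^v - 1
        kept_v = np.array([0.0, 1.0, 2.0, 3.0, 4.0])  # population SD ~1.414
        drop_v = np.array([1.0, 1.0, 2.0, 2.0, 2.0])  # SD < 1
        expr = pd.DataFrame([2.0 ** kept_v - 1, 2.0 ** drop_v - 1],
                            index=["keep", "drop"],
                            columns=[f"s{i}" for i in range(5)])
        out = filter_expression_features(expr)
        assert list(out.index) == ["keep"]
        assert np.allclose(out.loc["keep"], kept_v)

    def test_missingness_filter_precedes_sd(self):
        vals = np.full(10, np.nan)
        vals[:2] = [0.0, 1e6]  # huge SD on observed values, but 80% missing
        expr = pd.DataFrame([vals], index=["mostly_missing"],
                            columns=[f"s{i}" for i in range(10)])
        out = filter_expression_features(expr)
        assert out.empty

    def test_idempotent_on_own_output(self, rng):
        expr = pd.DataFrame(rng.lognormal(4, 2, (30, 12)))
        once = filter_expression_features(expr)
        twice = filter_expression_features(once, log2_transform=False)
        pd.testing.assert_frame_equal(once, twice)


class TestMethylationPrep:
    def _betas_manifest(self):
        betas = pd.DataFrame(
            [[0.1, 0.2, 0.3, 0.4], [0.5, 0.6, 0.7, 0.8], [0.2, 0.2, 0.2, 0.9],
             [0.1, 0.1, 0.1, 0.1], [0.0, 0.5, 0.5, 1.0]],
            index=[f"cg{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(4)],
        )
        man = _manifest([
            {"probe_id": f"cg{i}", "chromosome": "1", "tss_distance": 0,
             "gene": f"G{i}", "snp_associated": False}
            for i in range(5)
        ])
        return betas, man

    def test_sex_chromosome_and_snp_probes_removed(self):
        betas, man = self._betas_manifest()
        man.loc["cg0", "chromosome"] = "X"
        man.loc["cg1", "snp_associated"] = True
        out = prepare_methylation_features(betas, man, k_top=5)
        assert "cg0" not in out.index and "cg1" not in out.index

    def test_missingness_boundary_strict(self):
        betas = pd.DataFrame(np.tile([0.1, 0.3, 0.5, 0.7, 0.2] * 4, (3, 1)),
                             index=["at20", "at25", "full"],
                             columns=[f"s{i}" for i in range(20)])
        betas.iloc[0, :4] = np.nan  # exactly 20% -> kept
        betas.iloc[1, :5] = np.nan  # 25% -> removed
        man = _manifest([
            {"probe_id": p, "chromosome": "1", "tss_distance": 0,
             "gene": "G", "snp_associated": False} for p in betas.index
        ])
        out = prepare_methylation_features(betas, man, k_top=5, knn_k=1)
        assert "at20" in out.index and "at25" not in out.index

    def test_top_mad_matches_brute_force(self, rng):
        betas = pd.DataFrame(rng.random((8, 10)),
                             index=[f"cg{i}" for i in range(8)],
                             columns=[f"s{i}" for i in range(10)])
        man = _manifest([
            {"probe_id": p, "chromosome": "2", "tss_distance": 10,
             "gene": "G", "snp_associated": False} for p in betas.index
        ])
        out = prepare_methylation_features(betas, man, k_top=3)
        # brute-force MAD ranking
        mads = {}
        for p in betas.index:
            v = betas.loc[p].to_numpy()
            med = np.median(v)
            mads[p] = np.median(np.abs(v - med))
        expected = sorted(mads, key=lambda p: -mads[p])[:3]
        assert set(out.index) == set(expected)

    def test_k_top_larger_than_probes_warns_keeps_all(self):
        betas, man = self._betas_manifest()
        with pytest.warns(UserWarning, match="keeping all"):
            out = prepare_methylation_features(betas, man, k_top=99)
        assert len(out) == 5


class TestKnnImpute:
    def test_observed_entries_unchanged_and_within_donor_range(self, rng):
        df = pd.DataFrame(rng.random((12, 8)))
        df.iloc[0, 0] = np.nan
        df.iloc[5, 3] = np.nan
        out = knn_impute_rows(df, k=3)
        obs = ~df.isna()
        assert (out.to_numpy()[obs.to_numpy()] == df.to_numpy()[obs.to_numpy()]).all()
        assert not out.isna().any().any()
        # imputed value within [min, max] of column donors
        col0 = df.iloc[1:, 0].dropna()
        assert col0.min() <= out.iloc[0, 0] <= col0.max()

    def test_k1_uses_single_nearest_row(self):
        df = pd.DataFrame(
            [[1.0, 1.0, np.nan], [1.0, 1.0, 5.0], [10.0, 10.0, 99.0]],
            index=["target", "near", "far"], columns=["a", "b", "c"],
        )
        out = knn_impute_rows(df, k=1)
        assert out.loc["target", "c"] == 5.0

    def test_no_donor_raises_with_name(self):
        df = pd.DataFrame(
            [[np.nan, 1.0], [2.0, np.nan]],
            index=["r1", "r2"], columns=["a", "b"],
        )
        with pytest.raises(ValueError, match="r1"):
            knn_impute_rows(df, k=1)

    def test_idempotent(self, rng):
        df = pd.DataFrame(rng.random((10, 6)))
        df.iloc[2, 2] = np.nan
        once = knn_impute_rows(df, k=2)
        pd.testing.assert_frame_equal(knn_impute_rows(once, k=2), once)


class TestBinarizeLesions:
    def test_threshold_calls(self):
        values = pd.DataFrame([[0, 1, 2]], index=["Amplification Peak 1"],
                              columns=["s1", "s2", "s3"]).astype(float)
        binary, _ = binarize_lesions(values)
        assert binary.iloc[0].tolist() == [0, 1, 1]

    def test_all_zero_row_retained(self):
        values = pd.DataFrame([[0, 0], [1, 2]], index=["a", "b"],
                              columns=["s1", "s2"]).astype(float)
        binary, _ = binarize_lesions(values)
        assert binary.loc["a"].sum() == 0 and "a" in binary.index

    def test_matches_elementwise_oracle(self, rng):
        values = pd.DataFrame(rng.integers(0, 3, (3, 3)).astype(float))
        binary, _ = binarize_lesions(values)
        assert (binary.to_numpy() == (values.to_numpy() > 0).astype(int)).all()

    def test_negative_calls_rejected(self):
        values = pd.DataFrame([[-1.0, 0.0]], index=["Deletion Peak 1"],
                              columns=["s1", "s2"])
        with pytest.raises(ValueError, match="negative"):
            binarize_lesions(values)
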