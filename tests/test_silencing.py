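import numpy as np
import pandas as pd
import pytest

from hccomics import (
    CohortConfig,
    call_silenced,
    generate_cohort,
    run_silencing,
    select_candidate_probes,
    silencing_burden,
    test_probe_silencing as probe_silencing_test,
)
from tests.conftest import log2_tpm
from tests.oracles import naive_silencing


def _manifest(probes, gene="G1", chrom="1", tss=100, snp=False):
    return pd.DataFrame({
        "chromosome": chrom, "tss_distance": tss, "gene": gene,
        "snp_associated": snp,
    }, index=pd.Index(probes, name="probe_id"))


class TestCandidateSelection:
    def test_normal_beta_filter_boundary(self):
        man = _manifest(["pass", "fail"])
        normal = pd.DataFrame({"n1": [0.15, 0.25], "n2": [0.15, 0.25]},
                              index=["pass", "fail"])
        tumor = pd.DataFrame(
            np.tile([0.4, 0.4, 0.1, 0.1], (2, 1)),
            index=["pass", "fail"], columns=[f"t{i}" for i in range(4)],
        )
        probes, calls = select_candidate_probes(man, normal, tumor)
        assert probes == ["pass"]

    def test_min_methylated_fraction(self):
        man = _manifest(["rare"])
        normal = pd.DataFrame({"n1": [0.1]}, index=["rare"])
        # methylated in 1 of 40 tumors = 2.5% < 5%
        row = np.full(40, 0.1)
        row[0] = 0.5
        tumor = pd.DataFrame([row], index=["rare"],
                             columns=[f"t{i}" for i in range(40)])
        probes, _ = select_candidate_probes(man, normal, tumor)
        assert probes == []

    def test_methylation_call_threshold(self):
        man = _manifest(["p"])
        normal = pd.DataFrame({"n1": [0.1], "n2": [0.1]}, index=["p"])
        tumor = pd.DataFrame([[0.10, 0.35, 0.29]], index=["p"],
                             columns=["t1", "t2", "t3"])
        probes, calls = select_candidate_probes(man, normal, tumor)
        assert probes == ["p"]
        assert calls.loc["p"].tolist() == [False, True, False]

    def test_location_filters(self):
        man = pd.concat([
            _manifest(["ok"]),
            _manifest(["chrx"], chrom="X"),
            _manifest(["snp"], snp=True),
            _manifest(["distal"], tss=2000),
        ])
        normal = pd.DataFrame({"n1": 0.1}, index=man.index)
        tumor = pd.DataFrame(np.tile([0.5, 0.5, 0.1], (4, 1)),
                             index=man.index, columns=["t1", "t2", "t3"])
        probes, _ = select_candidate_probes(man, normal, tumor)
        assert probes == ["ok"]

    def test_no_normals_is_fatal(self):
        man = _manifest(["p"])
        normal = pd.DataFrame(index=["p"])
        tumor = pd.DataFrame([[0.5]], index=["p"], columns=["t1"])
        with pytest.raises(ValueError, match="no normal samples"):
            select_candidate_probes(man, normal, tumor)


class TestSuppressionTest:
    def _setup(self, meth_expr):
        man = _manifest(["p"])
        calls = pd.DataFrame([[True, False, False, False]], index=["p"],
                             columns=["t1", "t2", "t3", "t4"])
        expr = pd.DataFrame([[meth_expr, 10.0, 12.0, 14.0]], index=["G1"],
                            columns=["t1", "t2", "t3", "t4"])
        return expr, calls, man

    def test_selected_at_1_64_sd(self):
        # unmeth {10,12,14}: mean 12, sd 2 -> cutoff 12 - 3.28 = 8.72
        expr, calls, man = self._setup(8.0)
        res = probe_silencing_test(expr, calls, man)
        assert bool(res.loc["p", "selected"])
        assert res.loc["p", "mean_unmeth_expr"] == pytest.approx(12.0)
        assert res.loc["p", "sd_unmeth_expr"] == pytest.approx(2.0)

    def test_not_selected_above_cutoff(self):
        expr, calls, man = self._setup(9.0)
        res = probe_silencing_test(expr, calls, man)
        assert not bool(res.loc["p", "selected"])

    def test_zero_sd_equal_means_selected_inclusive(self):
        man = _manifest(["p"])
        calls = pd.DataFrame([[True, False, False]], index=["p"],
                             columns=["t1", "t2", "t3"])
        expr = pd.DataFrame([[5.0, 5.0, 5.0]], index=["G1"],
                            columns=["t1", "t2", "t3"])
        res = probe_silencing_test(expr, calls, man)
        assert bool(res.loc["p", "selected"])  # 5 <= 5 - 0 holds

    def test_untestable_cases_reported_not_fatal(self):
        man = pd.concat([_manifest(["p1"], gene="MISSING"), _manifest(["p2"])])
        calls = pd.DataFrame([[True, True, False], [True, True, False]],
                             index=["p1", "p2"], columns=["t1", "t2", "t3"])
        # p2's unmethylated group has a single sample: sd undefined
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["G1"],
                            columns=["t1", "t2", "t3"])
        res = probe_silencing_test(expr, calls, man)
        assert not res["testable"].any()
        assert not res["selected"].any()


class TestGeneCalls:
    def _three_probe_case(self, n_silenced_probes, n_probes=3):
        probes = [f"p{i}" for i in range(n_probes)]
        man = _manifest(probes)
        # sample t0 methylated at the first n_silenced_probes probes
        calls = pd.DataFrame(False, index=probes, columns=["t0", "t1", "t2", "t3"])
        calls.loc[probes[:n_silenced_probes], "t0"] = True
        expr = pd.DataFrame([[1.0, 10.0, 12.0, 14.0]], index=["G1"],
                            columns=calls.columns)
        results = probe_silencing_test(expr, calls, man)
        results["selected"] = True  # all probes selected for the gene
        return expr, calls, results, man

    def test_majority_rule_two_of_three(self):
        expr, calls, results, man = self._three_probe_case(2, 3)
        gc = call_silenced(expr, calls, results, man)
        assert bool(gc.loc["G1", "t0"])

    def test_exactly_half_not_silenced(self):
        expr, calls, results, man = self._three_probe_case(2, 4)
        gc = call_silenced(expr, calls, results, man)
        assert not bool(gc.loc["G1", "t0"])

    def test_single_probe_gene_equals_probe_call(self):
        expr, calls, results, man = self._three_probe_case(1, 1)
        gc = call_silenced(expr, calls, results, man)
        assert bool(gc.loc["G1", "t0"])
        assert not gc.loc["G1", ["t1", "t2", "t3"]].any()


class TestBurden:
    def test_burden_equals_column_counts(self, rng):
        mat = pd.DataFrame(rng.random((5, 4)) < 0.4,
                           index=[f"g{i}" for i in range(5)],
                           columns=[f"s{i}" for i in range(4)])
        burden = silencing_burden(mat)
        for s in mat.columns:
            assert burden[s] == sum(bool(mat.loc[g, s]) for g in mat.index)

    def test_all_false_gives_zeros(self):
        mat = pd.DataFrame(False, index=["g1"], columns=["s1", "s2"])
        assert (silencing_burden(mat) == 0).all()


class TestPipelineProperties:
    def test_matches_naive_oracle(self):
        cfg = CohortConfig(n_tumor=50, n_normal=8, n_genes=30, probes_per_gene=3,
                           n_decoy_probes=6, n_normal_methylated_probes=4,
                           planted_silenced_genes=3, seed=21)
        b = generate_cohort(cfg)
        expr = log2_tpm(b.tumor_expression)
        res = run_silencing(b.manifest, b.normal_betas, b.tumor_betas, expr)
        sel_naive, calls_naive = naive_silencing(
            b.manifest, b.normal_betas, b.tumor_betas, expr)
        selected = set(res.probe_results.index[res.probe_results["selected"]])
        assert selected == sel_naive
        got = {g: set(res.gene_calls.columns[res.gene_calls.loc[g]])
               for g in res.gene_calls.index}
        assert got == {g: s for g, s in calls_naive.items()}

    def test_lowering_expression_never_removes_calls(self):
        cfg = CohortConfig(n_tumor=60, n_normal=8, n_genes=30, probes_per_gene=2,
                           planted_silenced_genes=3, seed=5)
        b = generate_cohort(cfg)
        expr = log2_tpm(b.tumor_expression)
        res = run_silencing(b.manifest, b.normal_betas, b.tumor_betas, expr)
        # pick a methylated (gene, sample) pair and push its expression down
        gene = res.gene_calls.index[0]
        sample = b.tumor_expression.columns[0]
        expr2 = expr.copy()
        expr2.loc[gene, sample] -= 5.0
        res2 = run_silencing(b.manifest, b.normal_betas, b.tumor_betas, expr2)
        before = res.gene_calls.loc[gene, sample]
        after = res2.gene_calls.loc[gene, sample]
        assert (not before) or after
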