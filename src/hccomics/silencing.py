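"""Promoter-hypermethylation silencing detection.

The workflow, per probe/gene pair:

1. candidate probes: non-SNP, autosomal, within ±1500 bp of the TSS,
   mean normal-tissue β ≤ 0.2, and methylated (β ≥ 0.3) in at least 5%
   of tumor samples;
2. split tumors into methylated (β ≥ 0.3) and unmethylated (β < 0.3)
   groups; select the probe when the methylated group's mean expression
   is at least 1.64 unmethylated-group standard deviations below the
   unmethylated mean (inclusive);
3. a tumor is silenced at a selected probe when it is methylated AND the
   gene's expression is below the unmethylated-group mean; a gene is
   silenced in a sample when more than half of its selected probes call
   it silenced there;
4. the per-patient silencing burden is the number of silenced genes.

All thresholds default to the published values and are configurable.
The unmethylated-group SD is the sample SD (ddof=1); probes with fewer
than two unmethylated samples are untestable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "select_candidate_probes",
    "test_probe_silencing",
    "call_silenced",
    "silencing_burden",
    "run_silencing",
    "SilencingResult",
]


def select_candidate_probes(
    manifest: pd.DataFrame,
    normal_betas: pd.DataFrame,
    tumor_betas: pd.DataFrame,
    promoter_bp: int = 1500,
    normal_max: float = 0.2,
    meth_thresh: float = 0.3,
    min_meth_frac: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the candidate-probe filters; return (probe ids, call matrix).

    The call matrix is boolean probe x tumor (True = methylated,
    β ≥ ``meth_thresh``) restricted to the candidate probes. The
    min_meth_frac denominator is all tumor samples in the β matrix.
    """
    if normal_betas.shape[1] == 0:
        raise ValueError("no normal samples: the normal-reference filter cannot run")
    man = manifest.reindex(tumor_betas.index)
    if man["chromosome"].isna().any():
        unknown = man.index[man["chromosome"].isna()].tolist()
        raise ValueError(f"manifest does not cover probes: {unknown[:5]}")

    autosomal = ~man["chromosome"].astype(str).isin(["X", "Y"])
    non_snp = ~man["snp_associated"].astype(bool)
    promoter = man["tss_distance"].abs() <= promoter_bp
    normal_mean = normal_betas.reindex(tumor_betas.index).mean(axis=1)
    normal_ok = normal_mean <= normal_max
    calls_all = tumor_betas >= meth_thresh  # NaN compares False: unmethylated
    meth_frac = calls_all.sum(axis=1) / tumor_betas.shape[1]
    frac_ok = meth_frac >= min_meth_frac

    keep = autosomal & non_snp & promoter & normal_ok & frac_ok
    probes = tumor_betas.index[keep].tolist()
    if not probes:
        warnings.warn("no candidate probes survive the filters")
    return probes, calls_all.loc[probes]


def test_probe_silencing(
    expr: pd.DataFrame,
    calls: pd.DataFrame,
    manifest: pd.DataFrame,
    z: float = 1.64,
) -> pd.DataFrame:
    """The z-SD suppression test per candidate probe/gene pair.

    ``expr`` is the log2 gene x tumor matrix; ``calls`` the boolean
    methylation call matrix from :func:`select_candidate_probes`.
    Returns one row per probe with columns gene, n_meth, n_unmeth,
    mean_meth_expr, mean_unmeth_expr, sd_unmeth_expr, testable, selected.
    Probes whose gene is absent from ``expr``, or whose methylated group
    is empty, or whose unmethylated group has fewer than two samples
    (SD undefined) are reported untestable.
    """
    records = []
    samples = calls.columns
    for probe in calls.index:
        gene = manifest.loc[probe, "gene"]
        meth_mask = calls.loc[probe].to_numpy(dtype=bool)
        rec = {
            "probe_id": probe, "gene": gene,
            "n_meth": int(meth_mask.sum()), "n_unmeth": int((~meth_mask).sum()),
            "mean_meth_expr": np.nan, "mean_unmeth_expr": np.nan,
            "sd_unmeth_expr": np.nan, "testable": False, "selected": False,
        }
        if gene in expr.index and rec["n_meth"] >= 1 and rec["n_unmeth"] >= 2:
            e = expr.loc[gene, samples].to_numpy(dtype=float)
            e_meth, e_unmeth = e[meth_mask], e[~meth_mask]
            rec["mean_meth_expr"] = float(e_meth.mean())
            rec["mean_unmeth_expr"] = float(e_unmeth.mean())
            rec["sd_unmeth_expr"] = float(e_unmeth.std(ddof=1))
            rec["testable"] = True
            rec["selected"] = bool(
                rec["mean_meth_expr"]
                <= rec["mean_unmeth_expr"] - z * rec["sd_unmeth_expr"]
            )
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("probe_id")


def call_silenced(
    expr: pd.DataFrame,
    calls: pd.DataFrame,
    probe_results: pd.DataFrame,
    manifest: pd.DataFrame,
) -> pd.DataFrame:
    """Probe-level then gene-level (majority over selected probes) calls.

    A sample is silenced at a selected probe when it is methylated there
    AND the gene's expression is below the probe's unmethylated-group
    mean. A gene is silenced in a sample when strictly more than half of
    its selected probes call it silenced. Returns the boolean gene x
    tumor matrix (genes with >= 1 selected probe).
    """
    selected = probe_results.index[probe_results["selected"].astype(bool)]
    samples = calls.columns
    gene_rows: dict[str, list[np.ndarray]] = {}
    for probe in selected:
        gene = manifest.loc[probe, "gene"]
        meth = calls.loc[probe].to_numpy(dtype=bool)
        below = (
            expr.loc[gene, samples].to_numpy(dtype=float)
            < probe_results.loc[probe, "mean_unmeth_expr"]
        )
        gene_rows.setdefault(gene, []).append(meth & below)
    out = {}
    for gene, probe_calls in gene_rows.items():
        stacked = np.vstack(probe_calls)
        out[gene] = stacked.sum(axis=0) > stacked.shape[0] / 2.0
    result = pd.DataFrame(out, index=samples).T.astype(bool)
    result.index.name = "gene"
    return result.sort_index()


def silencing_burden(gene_calls: pd.DataFrame) -> pd.Series:
    """Per-sample count of silenced genes (column sums)."""
    burden = gene_calls.astype(bool).sum(axis=0)
    burden.name = "silencing_burden"
    return burden


@dataclass
class SilencingResult:
    candidate_probes: list[str]
    probe_results: pd.DataFrame
    gene_calls: pd.DataFrame
    burden: pd.Series


def run_silencing(
    manifest: pd.DataFrame,
    normal_betas: pd.DataFrame,
    tumor_betas: pd.DataFrame,
    expr_log2: pd.DataFrame,
    promoter_bp: int = 1500,
    normal_max: float = 0.2,
    meth_thresh: float = 0.3,
    min_meth_frac: float = 0.05,
    z: float = 1.64,
) -> SilencingResult:
    """End-to-end silencing pipeline on one cohort."""
    probes, calls = select_candidate_probes(
        manifest, normal_betas, tumor_betas,
        promoter_bp=promoter_bp, normal_max=normal_max,
        meth_thresh=meth_thresh, min_meth_frac=min_meth_frac,
    )
    probe_results = test_probe_silencing(expr_log2, calls, manifest, z=z)
    if probe_results["selected"].any():
        gene_calls = call_silenced(expr_log2, calls, probe_results, manifest)
    else:
        gene_calls = pd.DataFrame(
            np.zeros((0, tumor_betas.shape[1]), dtype=bool),
            columns=tumor_betas.columns,
        )
        gene_calls.index.name = "gene"
    burden = silencing_burden(gene_calls) if len(gene_calls) else pd.Series(
        0, index=tumor_betas.columns, name="silencing_burden"
    )
    return SilencingResult(probes, probe_results, gene_calls, burden)
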