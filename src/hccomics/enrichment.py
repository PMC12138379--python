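"""Subtype-specific alteration enrichment and burden metrics.

Each binary alteration (mutation, CNV amp/del, silencing) is tested for
over-representation in each subtype against all remaining samples with
a two-sided Fisher exact test on the 2x2 table, BH-corrected across
features within each subtype. Odds ratios use the Haldane-Anscombe +0.5
correction when any cell is zero. Burden metrics count altered genes per
sample; group comparisons use Kruskal-Wallis plus pairwise rank-sum
tests with the figure-legend star scheme.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "exact_test_2x2",
    "subtype_feature_enrichment",
    "cnv_burden",
    "mutation_burden",
    "compare_groups",
    "tissue_preference_or",
    "p_to_stars",
]


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """(a*d)/(b*c), with +0.5 added to every cell if any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def exact_test_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test of [[a, b], [c, d]].

    Returns (odds_ratio, p) with the +0.5 zero-cell correction applied to
    the odds ratio only. This is the primitive behind both the subtype
    enrichment and the tissue-preference tables.
    """
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return _odds_ratio(a, b, c, d), float(p)


def subtype_feature_enrichment(
    alts: pd.DataFrame,
    labels: pd.Series,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per (feature, subtype) exact test of alteration vs subtype membership.

    ``alts`` is a binary feature x sample matrix; ``labels`` maps every
    sample to its subtype. Returns one row per (feature, subtype) with
    counts, odds_ratio, p, BH q (within-subtype family across features)
    and ``specific`` (q < q_threshold and in-subtype proportion greater
    than the out proportion). Subtypes with fewer than two samples are
    excluded with a warning.
    """
    samples = [s for s in alts.columns if s in labels.index]
    if len(samples) < len(alts.columns):
        raise ValueError("labels do not cover all samples in the alteration matrix")
    labels = labels.loc[samples]
    subtype_counts = labels.value_counts()
    usable = sorted(subtype_counts.index[subtype_counts >= 2])
    dropped = sorted(set(subtype_counts.index) - set(usable))
    if dropped:
        warnings.warn(f"subtypes with <2 samples excluded: {dropped}")
    if len(usable) < 2:
        raise ValueError("need at least 2 subtypes with >=2 samples")

    mat = alts[samples].astype(bool)
    records = []
    for st in usable:
        in_mask = (labels == st).to_numpy()
        n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
        for feat in mat.index:
            altered = mat.loc[feat].to_numpy()
            a = int((altered & in_mask).sum())
            c = int((altered & ~in_mask).sum())
            b, d = n_in - a, n_out - c
            oratio, p = exact_test_2x2(a, b, c, d)
            records.append({
                "feature": feat, "subtype": st,
                "n_in_altered": a, "n_in": n_in,
                "n_out_altered": c, "n_out": n_out,
                "odds_ratio": oratio, "p": p,
            })
    res = pd.DataFrame.from_records(records)
    res["q"] = np.nan
    for st in usable:
        m = res["subtype"] == st
        res.loc[m, "q"] = multipletests(res.loc[m, "p"], method="fdr_bh")[1]
    res["q"] = np.maximum(res["q"], res["p"])  # BH never below the raw p
    res["specific"] = (res["q"] < q_threshold) & (
        res["n_in_altered"] / res["n_in"] > res["n_out_altered"] / res["n_out"]
    )
    return res


def cnv_burden(
    binary_lesions: pd.DataFrame, lesion_meta: pd.DataFrame
) -> pd.DataFrame:
    """Focal and arm-level CNV burden: total genes in altered lesions.

    ``lesion_meta`` must provide ``level`` (focal|arm) and ``gene_count``
    per lesion. Genes in overlapping lesions count once per lesion (no
    cross-lesion deduplication). Returns a sample-indexed table with
    columns focal_cnv_burden and arm_cnv_burden.
    """
    meta = lesion_meta.reindex(binary_lesions.index)
    if meta["gene_count"].isna().any():
        bad = meta.index[meta["gene_count"].isna()].tolist()
        raise ValueError(f"missing gene_count for lesion(s): {bad[:5]}")
    out = {}
    for level in ("focal", "arm"):
        rows = meta.index[meta["level"] == level]
        weights = meta.loc[rows, "gene_count"].astype(float)
        out[f"{level}_cnv_burden"] = (
            binary_lesions.loc[rows].astype(int).mul(weights, axis=0).sum(axis=0)
        )
    return pd.DataFrame(out)


def mutation_burden(muts: pd.DataFrame) -> pd.Series:
    """Per-sample count of mutated genes (column sums of the binary matrix)."""
    burden = muts.astype(bool).sum(axis=0)
    burden.name = "mutation_burden"
    return burden


_STAR_LEVELS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def p_to_stars(p: float) -> str:
    """Figure-legend star scheme: ns, *, **, ***, ****."""
    for cut, stars in _STAR_LEVELS:
        if p <= cut:
            return stars
    return "ns"


def compare_groups(values: pd.Series, labels: pd.Series) -> dict:
    """Kruskal-Wallis omnibus + pairwise two-sided rank-sum with BH stars.

    Returns ``{"omnibus_p": float, "pairwise": DataFrame}`` where the
    pairwise table has group_a, group_b, p, q, stars. Constant values
    yield p = 1 with a warning.
    """
    labels = labels.loc[values.index]
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: values[labels == g].to_numpy(dtype=float) for g in groups}
    for g, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    if values.nunique() <= 1:
        warnings.warn("constant values: comparisons are uninformative (p = 1)")
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
        pairwise = pd.DataFrame({
            "group_a": [a for a, _ in pairs], "group_b": [b for _, b in pairs],
            "p": 1.0, "q": 1.0, "stars": "ns",
        })
        return {"omnibus_p": 1.0, "pairwise": pairwise}

    _, omnibus_p = stats.kruskal(*arrays.values())
    records = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            _, p = stats.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided")
            records.append({"group_a": a, "group_b": b, "p": float(p)})
    pairwise = pd.DataFrame.from_records(records)
    pairwise["q"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    pairwise["stars"] = pairwise["p"].map(p_to_stars)
    return {"omnibus_p": float(omnibus_p), "pairwise": pairwise}


def tissue_preference_or(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell odds ratio of the collapsed 2x2 table, plus exact p.

    For subpopulation i and tissue j the table is
    [[counts[i,j], rest of row i], [rest of column j, everything else]];
    the OR uses the +0.5 zero-cell correction and p is the two-sided
    Fisher exact test.
    """
    arr = counts.to_numpy(dtype=int)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero count table")
    ors = np.empty(arr.shape)
    ps = np.empty(arr.shape)
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            a = arr[i, j]
            b = row_sums[i] - a
            c = col_sums[j] - a
            d = total - a - b - c
            ors[i, j], ps[i, j] = exact_test_2x2(a, b, c, d)
    or_df = pd.DataFrame(ors, index=counts.index, columns=counts.columns)
    p_df = pd.DataFrame(ps, index=counts.index, columns=counts.columns)
    return or_df, p_df
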