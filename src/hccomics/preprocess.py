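"""Per-layer feature preparation: TPM conversion, expression filtering,
methylation probe selection and lesion binarization.

Expression filtering drops high-missingness genes on the TPM scale,
log2(TPM+1)-transforms, then drops low-variance genes (population SD over
non-missing tumor values). Methylation preparation removes
high-missingness, SNP-associated and sex-chromosome probes, imputes the
rest by probe-space K-nearest-neighbors, and keeps the top-MAD probes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "counts_to_tpm",
    "filter_expression_features",
    "prepare_methylation_features",
    "binarize_lesions",
    "knn_impute_rows",
]


def counts_to_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Convert raw counts (gene x sample) to TPM given gene lengths in bp.

    tpm[g, s] = rate[g, s] / sum_g' rate[g', s] * 1e6 where
    rate = count / length_kb. Column sums are 1e6 by construction.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"gene lengths missing for: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    rate = counts.div(lengths / 1_000.0, axis=0)
    totals = rate.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero total count for sample(s): {zero.index.tolist()}")
    return rate.div(totals, axis=1) * 1e6


def filter_expression_features(
    expr_tpm: pd.DataFrame,
    sd_min: float = 1.0,
    missing_max: float = 0.75,
    log2_transform: bool = True,
) -> pd.DataFrame:
    """Missingness filter -> log2(TPM+1) -> SD filter; returns log2 matrix.

    Features with missing fraction strictly greater than ``missing_max``
    are dropped before the transform; features whose population SD
    (ddof=0, non-missing values) is below ``sd_min`` are dropped after.
    Pass ``log2_transform=False`` when the input is already on the log2
    scale (the filters are then idempotent).
    """
    frac_missing = expr_tpm.isna().mean(axis=1)
    kept = expr_tpm.loc[frac_missing <= missing_max]
    log2 = np.log2(kept + 1.0) if log2_transform else kept
    sds = log2.std(axis=1, ddof=0)
    out = log2.loc[sds >= sd_min]
    if out.empty:
        warnings.warn("no expression features survive the SD filter")
    return out


def knn_impute_rows(df: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Impute missing entries of a feature x sample matrix by row-space KNN.

    Distance between two rows is the root-mean-square difference over
    columns observed in both. A missing cell (r, c) is filled with the
    unweighted mean over the k nearest rows that (a) have a finite
    distance to r and (b) are observed at c. Observed entries are never
    altered. Ties are broken by row order for determinism.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = df.to_numpy(dtype=float).copy()
    obs = ~np.isnan(values)
    missing_rows = np.where(~obs.all(axis=1))[0]
    if len(missing_rows) == 0:
        return df.copy()
    out = values.copy()
    for r in missing_rows:
        shared = obs[r] & obs  # (n_rows, n_cols) co-observed mask vs row r
        n_shared = shared.sum(axis=1)
        with np.errstate(invalid="ignore"):
            diff = np.where(shared, values - values[r], 0.0)
            dist = np.sqrt((diff ** 2).sum(axis=1) / np.maximum(n_shared, 1))
        dist[n_shared == 0] = np.inf
        dist[r] = np.inf
        order = np.argsort(dist, kind="stable")
        for c in np.where(~obs[r])[0]:
            donors = [i for i in order
                      if np.isfinite(dist[i]) and obs[i, c]][:k]
            if not donors:
                raise ValueError(
                    f"no co-observed neighbor to impute {df.index[r]!r} "
                    f"at column {df.columns[c]!r}"
                )
            out[r, c] = values[donors, c].mean()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def prepare_methylation_features(
    betas: pd.DataFrame,
    manifest: pd.DataFrame,
    k_top: int = 1000,
    knn_k: int = 5,
    missing_max: float = 0.20,
) -> pd.DataFrame:
    """Probe filters -> KNN imputation -> top-MAD selection.

    Drops probes with missing fraction strictly greater than
    ``missing_max``, SNP-associated probes and sex-chromosome probes;
    imputes the remaining missing entries by probe-space KNN; ranks by
    median absolute deviation and keeps the ``k_top`` largest.
    """
    man = manifest.reindex(betas.index)
    if man["chromosome"].isna().any():
        unknown = man.index[man["chromosome"].isna()].tolist()
        raise ValueError(f"manifest does not cover probes: {unknown[:5]}")
    keep = (
        (betas.isna().mean(axis=1) <= missing_max)
        & ~man["snp_associated"].astype(bool)
        & ~man["chromosome"].astype(str).isin(["X", "Y"])
    )
    kept = betas.loc[keep]
    if kept.isna().any().any():
        kept = knn_impute_rows(kept, k=knn_k)
    med = kept.median(axis=1)
    mad = (kept.sub(med, axis=0)).abs().median(axis=1)
    if k_top > len(kept):
        warnings.warn(
            f"k_top={k_top} exceeds {len(kept)} surviving probes; keeping all"
        )
        k_top = len(kept)
    top = mad.sort_values(ascending=False, kind="stable").index[:k_top]
    return kept.loc[top]


def binarize_lesions(
    lesion_values: pd.DataFrame, lesion_meta: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Discrete GISTIC calls -> binary altered / not-altered matrix.

    Call values are 0 (no alteration) or >= 1 (altered at increasing
    amplitude thresholds); negative values indicate a continuous-CN file
    was supplied by mistake and raise.
    """
    if (lesion_values.to_numpy() < 0).any():
        raise ValueError("negative lesion calls: expected discrete 0/1/2 dialect")
    binary = (lesion_values > 0).astype(int)
    meta = None
    if lesion_meta is not None:
        meta = lesion_meta.reindex(binary.index)
    return binary, meta
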