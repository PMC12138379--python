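"""Expression-based compound prioritization.

Compounds with more than 20% missing AUC values are excluded and the
rest imputed by K-nearest-neighbor over compound profiles. A ridge
regression of AUC on standardized cell-line expression (penalty picked
by internal cross-validation) predicts per-patient AUC, and compounds
are prioritized when (a) predicted AUC is lower in the top risk-score
decile than the bottom decile (two-sided rank-sum p < 0.05) and
(b) Spearman r between predicted AUC and risk score over all patients
is below -0.35 (strict). Lower AUC always means greater sensitivity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import RidgeCV

from .preprocess import knn_impute_rows

__all__ = [
    "filter_and_impute_auc",
    "predict_drug_response",
    "prioritize_compounds",
]


def filter_and_impute_auc(
    auc: pd.DataFrame, max_missing: float = 0.2, k: int = 5
) -> pd.DataFrame:
    """Drop high-missingness compounds, KNN-impute the rest.

    Compounds (rows) with missing fraction strictly greater than
    ``max_missing`` are removed; remaining missing entries are filled
    with the mean AUC of the ``k`` nearest compounds (root-mean-square
    distance over cell lines observed in both profiles). Observed values
    are never altered.
    """
    keep = auc.isna().mean(axis=1) <= max_missing
    kept = auc.loc[keep]
    if len(kept) < 2:
        raise ValueError("fewer than 2 compounds survive the missingness filter")
    return knn_impute_rows(kept, k=k)


def predict_drug_response(
    ccl_expr: pd.DataFrame,
    auc: pd.DataFrame,
    patient_expr: pd.DataFrame,
    alphas: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0, 1000.0),
) -> pd.DataFrame:
    """Ridge model per compound: cell-line expression -> AUC -> patients.

    Genes are restricted to those shared by both panels; each gene is
    standardized to zero mean / unit variance within each panel
    separately (the cross-panel harmonization contract). Zero-variance
    genes are dropped with a warning. Returns compound x patient
    predicted AUC.
    """
    shared = [g for g in ccl_expr.index if g in set(patient_expr.index)]
    if not shared:
        raise ValueError("no shared genes between cell-line and patient panels")
    if auc.isna().any().any():
        raise ValueError("AUC matrix must be complete; run filter_and_impute_auc")

    Xc = ccl_expr.loc[shared, auc.columns].T.to_numpy(dtype=float)
    Xp = patient_expr.loc[shared].T.to_numpy(dtype=float)
    sd_c = Xc.std(axis=0, ddof=0)
    sd_p = Xp.std(axis=0, ddof=0)
    ok = (sd_c > 0) & (sd_p > 0)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} zero-variance gene(s) dropped")
        if not ok.any():
            raise ValueError("no shared gene with variance in both panels")
    Zc = (Xc[:, ok] - Xc[:, ok].mean(axis=0)) / sd_c[ok]
    Zp = (Xp[:, ok] - Xp[:, ok].mean(axis=0)) / sd_p[ok]

    preds = np.empty((auc.shape[0], Zp.shape[0]))
    for i, compound in enumerate(auc.index):
        y = auc.loc[compound].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            preds[i] = y[0]
            continue
        model = RidgeCV(alphas=list(alphas))
        model.fit(Zc, y)
        preds[i] = model.predict(Zp)
    return pd.DataFrame(preds, index=auc.index, columns=patient_expr.columns)


def prioritize_compounds(
    pred_auc: pd.DataFrame,
    risk_scores: pd.Series,
    top_frac: float = 0.1,
    r_threshold: float = -0.35,
    diff_alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential-response + Spearman filter for candidate compounds.

    High/low groups are the top and bottom ``top_frac`` of risk scores.
    Per compound: two-sided rank-sum test between the groups, direction
    = (median predicted AUC lower in high-risk), Spearman correlation of
    predicted AUC with risk score over all patients. A candidate
    satisfies direction AND diff_p < ``diff_alpha`` AND spearman_r
    strictly below ``r_threshold``. Rows are sorted by spearman_r.
    """
    patients = [p for p in pred_auc.columns if p in risk_scores.index]
    if len(patients) < 10:
        raise ValueError("need at least 10 patients")
    scores = risk_scores.loc[patients]
    n_grp = int(np.floor(top_frac * len(patients)))
    if n_grp < 1:
        raise ValueError("top_frac yields empty risk groups")
    ranked = scores.sort_values(kind="stable")
    low = ranked.index[:n_grp]
    high = ranked.index[-n_grp:]

    records = []
    for compound in pred_auc.index:
        vals = pred_auc.loc[compound, patients]
        hi, lo = vals.loc[high].to_numpy(), vals.loc[low].to_numpy()
        if np.ptp(vals.to_numpy()) == 0:
            diff_p, r, sp_p = 1.0, 0.0, 1.0
        else:
            _, diff_p = stats.mannwhitneyu(hi, lo, alternative="two-sided")
            r, sp_p = stats.spearmanr(vals.to_numpy(), scores.to_numpy())
        direction = bool(np.median(hi) < np.median(lo))
        records.append({
            "compound": compound,
            "spearman_r": float(r),
            "spearman_p": float(sp_p),
            "diff_p": float(diff_p),
            "lower_in_high_risk": direction,
            "candidate": direction and diff_p < diff_alpha and r < r_threshold,
        })
    out = pd.DataFrame.from_records(records).set_index("compound")
    return out.sort_values("spearman_r", kind="stable")
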