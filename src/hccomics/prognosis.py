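"""Prognostic risk modeling.

Univariate Cox screening of genes, a seeded 70/30 train/test split,
LASSO-penalized Cox with cross-validated penalty selection, the linear
risk score sum_i Coef_i * Expr_i, median stratification into high/low
risk, the log-rank test, IPCW time-dependent AUC, and a multivariate
Cox independence check against clinical covariates.

The penalty is picked by the cross-validation-minimum rule (the alpha
maximizing the held-out log partial likelihood), and partial-likelihood
ties are handled with the Breslow approximation inside the penalized
path (Efron in the unpenalized lifelines fits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

__all__ = [
    "RiskModel",
    "univariate_cox_screen",
    "fit_lasso_cox",
    "compute_risk_score",
    "stratify_by_median",
    "logrank_test",
    "time_dependent_auc",
    "multivariate_cox",
]


@dataclass
class RiskModel:
    """Selected genes, their Cox coefficients, and the training-median cutoff."""

    genes: list[str]
    coefficients: pd.Series  # indexed by gene, original expression scale
    cutoff: float


def _surv_df(surv: pd.DataFrame) -> pd.DataFrame:
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be > 0")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event must be 0/1")
    return surv


def univariate_cox_screen(
    expr: pd.DataFrame, surv: pd.DataFrame, alpha: float = 0.01
) -> pd.DataFrame:
    """Per-gene proportional-hazards fit; returns gene, hr, p, selected.

    Constant genes and genes whose fit does not converge are dropped with
    a warning. ``selected`` is Wald p < alpha.
    """
    surv = _surv_df(surv.loc[expr.columns])
    if surv["event"].sum() < 2:
        raise ValueError("need at least 2 events to screen")
    records, dropped = [], []
    base = surv[["time", "event"]].copy()
    for gene in expr.index:
        x = expr.loc[gene]
        if x.nunique() <= 1:
            dropped.append(gene)
            continue
        df = base.copy()
        df["x"] = x.values
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
        except Exception:
            dropped.append(gene)
            continue
        records.append({
            "gene": gene,
            "hr": float(np.exp(cph.params_["x"])),
            "p": float(cph.summary.loc["x", "p"]),
        })
    if dropped:
        warnings.warn(f"{len(dropped)} gene(s) dropped (constant or non-convergent)")
    res = pd.DataFrame.from_records(records).set_index("gene") if records else \
        pd.DataFrame(columns=["hr", "p"])
    res["selected"] = res["p"] < alpha
    return res


def _log_partial_likelihood(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow log partial likelihood of linear predictors ``eta``."""
    order = np.argsort(time, kind="stable")
    eta, time, event = eta[order], time[order], event[order]
    # suffix log-sum-exp of eta (risk sets are suffixes of the sorted order)
    rev = eta[::-1]
    suffix = np.logaddexp.accumulate(rev)[::-1]
    # ties: risk set is every subject with t_j >= t_i
    first_idx = np.searchsorted(time, time, side="left")
    ll = 0.0
    for i in np.where(event == 1)[0]:
        ll += eta[i] - suffix[first_idx[i]]
    return float(ll)


def fit_lasso_cox(
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    train_frac: float = 0.7,
    folds: int = 10,
    seed: int = 0,
    n_alphas: int = 50,
    alpha_min_ratio: float = 0.01,
) -> tuple[RiskModel, list[str], list[str]]:
    """Seeded train/test split + L1-penalized Cox with CV-min penalty.

    Genes are standardized within the training set for the penalized
    fit; coefficients are mapped back to the original expression scale
    so the risk score is sum_i Coef_i * Expr_i on raw log2 values. The
    cutoff is the median training risk score. Returns
    (model, train_samples, test_samples).
    """
    samples = list(expr.columns)
    surv = _surv_df(surv.loc[samples])
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(samples))
    n_train = int(round(train_frac * len(samples)))
    train = [samples[i] for i in sorted(perm[:n_train])]
    test = [samples[i] for i in sorted(perm[n_train:])]

    X = expr[train].T.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} constant gene(s) excluded from the fit")
    genes = [g for g, k in zip(expr.index, keep) if k]
    Xs = (X[:, keep] - mean[keep]) / sd[keep]
    t = surv.loc[train, "time"].to_numpy(dtype=float)
    e = surv.loc[train, "event"].to_numpy(dtype=int)
    y = Surv.from_arrays(event=e.astype(bool), time=t)

    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio,
        fit_baseline_model=False,
    )
    path.fit(Xs, y)
    alphas = path.alphas_

    kf = KFold(n_splits=folds, shuffle=True,
               random_state=int(rng.integers(2 ** 31 - 1)))
    cv_ll = np.zeros(len(alphas))
    n_ok = np.zeros(len(alphas))
    for tr_idx, te_idx in kf.split(Xs):
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                   fit_baseline_model=False)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m.fit(Xs[tr_idx], y[tr_idx])
        except Exception:
            continue
        fitted = np.asarray(m.alphas_)
        for ai, a in enumerate(alphas):
            hits = np.where(np.isclose(fitted, a, rtol=1e-8))[0]
            if len(hits) == 0:
                continue
            coef = m.coef_[:, hits[0]]
            eta = Xs[te_idx] @ coef
            cv_ll[ai] += _log_partial_likelihood(eta, t[te_idx], e[te_idx])
            n_ok[ai] += 1
    valid = n_ok == n_ok.max()
    best_ai = int(np.arange(len(alphas))[valid][np.argmax(cv_ll[valid])])
    best_alpha = alphas[best_ai]

    coef_std = path.coef_[:, best_ai]
    nz = coef_std != 0
    if not nz.any():
        raise ValueError(
            "no nonzero coefficients at the selected penalty; "
            "consider a denser alpha grid or a smaller alpha_min_ratio"
        )
    coef_orig = coef_std[nz] / sd[keep][nz]
    sel_genes = [g for g, f in zip(genes, nz) if f]
    coefficients = pd.Series(coef_orig, index=sel_genes, name="coefficient")
    scores = compute_risk_score(expr[train], RiskModel(sel_genes, coefficients, 0.0))
    model = RiskModel(sel_genes, coefficients, float(scores.median()))
    return model, train, test


def compute_risk_score(expr: pd.DataFrame, model: RiskModel) -> pd.Series:
    """risk score[s] = sum_i Coef_i * Expr_i[s]."""
    missing = [g for g in model.genes if g not in expr.index]
    if missing:
        raise ValueError(f"model gene(s) absent from expression matrix: {missing}")
    scores = expr.loc[model.genes].T @ model.coefficients.loc[model.genes]
    scores.name = "risk_score"
    return scores


def stratify_by_median(scores: pd.Series, cutoff: float | None = None) -> pd.Series:
    """high iff score > cutoff (default: in-sample median)."""
    if len(scores) < 2:
        raise ValueError("need at least 2 samples to stratify")
    if scores.nunique() <= 1 and cutoff is None:
        raise ValueError("all scores identical; cannot stratify")
    if cutoff is None:
        cutoff = float(scores.median())
    groups = pd.Series(np.where(scores > cutoff, "high", "low"),
                       index=scores.index, name="risk_group")
    return groups


def logrank_test(groups: pd.Series, surv: pd.DataFrame) -> dict:
    """Standard log-rank test across >= 2 groups.

    Returns statistic, p and a per-group (n, events) table.
    """
    surv = _surv_df(surv.loc[groups.index])
    counts = groups.value_counts()
    if (counts == 0).any() or len(counts) < 2:
        raise ValueError("need >= 2 non-empty groups")
    if surv["event"].sum() < 1:
        raise ValueError("need at least one event")
    res = multivariate_logrank_test(surv["time"], groups, surv["event"])
    per_group = pd.DataFrame({
        "n": counts,
        "events": surv.groupby(groups)["event"].sum(),
    })
    return {"statistic": float(res.test_statistic), "p": float(res.p_value),
            "groups": per_group}


def time_dependent_auc(
    scores: pd.Series,
    surv: pd.DataFrame,
    horizons: tuple[float, ...] = (365.0, 1095.0, 1825.0),
    train_surv: pd.DataFrame | None = None,
) -> pd.Series:
    """Cumulative-case / dynamic-control AUC with IPCW at each horizon.

    The censoring distribution is estimated from ``train_surv`` when
    given, else from the evaluated cohort. Horizons with no prior event
    (or outside the follow-up range) are reported as NaN.
    """
    surv = _surv_df(surv.loc[scores.index])
    ref = _surv_df(train_surv) if train_surv is not None else surv
    y_train = Surv.from_arrays(event=ref["event"].astype(bool), time=ref["time"])
    y_test = Surv.from_arrays(event=surv["event"].astype(bool), time=surv["time"])
    out = {}
    for h in horizons:
        has_case = ((surv["time"] <= h) & (surv["event"] == 1)).any()
        has_control = (surv["time"] > h).any()
        if not (has_case and has_control):
            out[h] = np.nan
            continue
        try:
            auc, _ = cumulative_dynamic_auc(y_train, y_test,
                                            scores.to_numpy(), [h])
            out[h] = float(auc[0])
        except ValueError:
            out[h] = np.nan
    return pd.Series(out, name="auc")


def multivariate_cox(
    scores: pd.Series, covariates: pd.DataFrame, surv: pd.DataFrame
) -> pd.DataFrame:
    """Joint Cox fit of the risk score plus clinical covariates.

    Returns hazard ratios, p and ``independent`` flag (p < 0.05) per
    term. Collinear covariates produce a ValueError with diagnostics.
    """
    surv = _surv_df(surv.loc[scores.index])
    df = covariates.loc[scores.index].copy()
    df["risk_score"] = scores
    corr = df.corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    if (corr > 0.999).any().any():
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        raise ValueError(
            f"collinear covariates: {corr.index[i]!r} ~ {corr.columns[j]!r}"
        )
    df["time"] = surv["time"]
    df["event"] = surv["event"]
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # pragma: no cover - lifelines-specific messages
        raise ValueError(f"multivariate Cox fit did not converge: {exc}") from exc
    out = cph.summary[["exp(coef)", "p"]].rename(
        columns={"exp(coef)": "hr"}
    )
    out["independent"] = out["p"] < 0.05
    return out
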