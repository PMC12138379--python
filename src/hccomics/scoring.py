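"""Single-sample gene-set enrichment (ssGSEA).

For each sample, genes are ranked by expression (average ranks on ties,
largest expression = largest rank). Walking the list in decreasing
expression order, the enrichment score is the sum over positions of the
difference between the weighted in-set empirical CDF (weights = rank^alpha,
normalized over the set) and the unweighted out-of-set ECDF — the
standard rank-weighted running-sum integral. Scoring is purely
rank-based, so any strictly increasing per-sample transform of the
expression values leaves the scores unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import GeneSet

__all__ = ["ssgsea_scores", "normalize_scores"]


def ssgsea_scores(
    expr: pd.DataFrame, sets: list[GeneSet], alpha: float = 0.25
) -> pd.DataFrame:
    """Score each gene set in each sample; returns a set x sample matrix.

    Genes absent from ``expr`` are dropped from each set; sets left with
    no genes are skipped with a warning. ``alpha`` is the rank-weighting
    exponent (0.25 by ssGSEA convention).
    """
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 genes to score")
    if not sets:
        raise ValueError("no gene sets supplied")
    genes = expr.index.to_numpy()
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    memberships = []
    kept_names = []
    for s in sets:
        present = [g for g in s.genes if g in gene_pos]
        if not present:
            warnings.warn(f"gene set {s.name!r} has no genes in the matrix; skipped")
            continue
        mask = np.zeros(n, dtype=bool)
        mask[[gene_pos[g] for g in present]] = True
        memberships.append(mask)
        kept_names.append(s.name)
    if not memberships:
        raise ValueError("no gene set overlaps the expression matrix")
    member = np.vstack(memberships)  # set x gene

    scores = np.empty((len(kept_names), expr.shape[1]))
    x = expr.to_numpy(dtype=float)
    # deterministic tie-break within equal expression: original gene order
    for j in range(expr.shape[1]):
        col = x[:, j]
        ranks = rankdata(col)  # ascending, average ties: top gene -> rank n
        order = np.lexsort((np.arange(n), -col))  # decreasing expression
        w = ranks[order] ** alpha
        in_set = member[:, order]  # set x position
        win = np.where(in_set, w[None, :], 0.0)
        cum_in = np.cumsum(win, axis=1)
        tot_in = cum_in[:, -1][:, None]
        p_in = cum_in / tot_in
        n_out = (~in_set).sum(axis=1)[:, None].astype(float)
        cum_out = np.cumsum(~in_set, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_out = np.where(n_out > 0, cum_out / np.maximum(n_out, 1.0), 0.0)
        scores[:, j] = (p_in - p_out).sum(axis=1)

    return pd.DataFrame(scores, index=kept_names, columns=expr.columns)


def normalize_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Divide every score by the global (max - min) of the matrix."""
    lo = np.nanmin(scores.to_numpy())
    hi = np.nanmax(scores.to_numpy())
    if not np.isfinite(hi - lo) or hi == lo:
        raise ValueError("degenerate score range")
    return scores / (hi - lo)
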