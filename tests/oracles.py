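"""Independent, naive reference implementations used only by tests.

Each oracle is a straight transliteration of the published procedure
with plain Python loops and the standard library where possible, kept
deliberately separate from the package's vectorized code paths.
"""

from __future__ import annotations

import math
import statistics
from fractions import Fraction


def naive_silencing(manifest, normal_betas, tumor_betas, expr,
                    promoter_bp=1500, normal_max=0.2, thresh=0.3,
                    min_frac=0.05, z=1.64):
    """Loop transliteration of the silencing workflow.

    Returns (selected_probes: set, gene_calls: dict gene -> set of
    silenced samples).
    """
    tumors = list(tumor_betas.columns)

    candidates = []
    for p in tumor_betas.index:
        row = manifest.loc[p]
        if bool(row["snp_associated"]):
            continue
        if str(row["chromosome"]) in ("X", "Y"):
            continue
        if abs(int(row["tss_distance"])) > promoter_bp:
            continue
        normals = [v for v in normal_betas.loc[p] if v == v]
        if statistics.mean(normals) > normal_max:
            continue
        n_meth = sum(1 for s in tumors
                     if tumor_betas.loc[p, s] == tumor_betas.loc[p, s]
                     and tumor_betas.loc[p, s] >= thresh)
        if n_meth / len(tumors) < min_frac:
            continue
        candidates.append(p)

    selected = {}  # probe -> (gene, mean_unmeth)
    for p in candidates:
        gene = manifest.loc[p, "gene"]
        if gene not in expr.index:
            continue
        meth, unmeth = [], []
        for s in tumors:
            v = tumor_betas.loc[p, s]
            if v == v and v >= thresh:
                meth.append(s)
            else:
                unmeth.append(s)
        if len(meth) < 1 or len(unmeth) < 2:
            continue
        mean_meth = statistics.mean(expr.loc[gene, s] for s in meth)
        mean_unmeth = statistics.mean(expr.loc[gene, s] for s in unmeth)
        sd_unmeth = statistics.stdev([expr.loc[gene, s] for s in unmeth])
        if mean_meth <= mean_unmeth - z * sd_unmeth:
            selected[p] = (gene, mean_unmeth)

    by_gene = {}
    for p, (gene, mean_unmeth) in selected.items():
        by_gene.setdefault(gene, []).append((p, mean_unmeth))
    gene_calls = {}
    for gene, probes in by_gene.items():
        silenced = set()
        for s in tumors:
            n_hit = 0
            for p, mean_unmeth in probes:
                v = tumor_betas.loc[p, s]
                methylated = v == v and v >= thresh
                if methylated and expr.loc[gene, s] < mean_unmeth:
                    n_hit += 1
            if n_hit > len(probes) / 2:
                silenced.add(s)
        gene_calls[gene] = silenced
    return set(selected), gene_calls


def fisher_exact_oracle(a, b, c, d):
    """Two-sided Fisher exact p by exact-rational hypergeometric enumeration."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = math.comb(n, col1)

    def pmf(k):
        if k < 0 or k > row1 or col1 - k > row2 or col1 - k < 0:
            return Fraction(0)
        return Fraction(math.comb(row1, k) * math.comb(row2, col1 - k), denom)

    p_obs = pmf(a)
    total = Fraction(0)
    for k in range(max(0, col1 - row2), min(row1, col1) + 1):
        if pmf(k) <= p_obs:
            total += pmf(k)
    return float(total)


def naive_ssgsea(expr, gene_set, alpha=0.25):
    """Literal running-sum ssGSEA for one gene set; returns sample -> score."""
    genes = list(expr.index)
    members = set(g for g in gene_set if g in genes)
    scores = {}
    for s in expr.columns:
        x = {g: float(expr.loc[g, s]) for g in genes}
        # average ranks, ascending (top expression -> largest rank)
        by_value = sorted(genes, key=lambda g: x[g])
        ranks = {}
        i = 0
        while i < len(by_value):
            j = i
            while j + 1 < len(by_value) and x[by_value[j + 1]] == x[by_value[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[by_value[k]] = avg
            i = j + 1
        # walk in decreasing expression, ties broken by original order
        order = sorted(genes, key=lambda g: (-x[g], genes.index(g)))
        total_in = sum(ranks[g] ** alpha for g in order if g in members)
        n_out = sum(1 for g in order if g not in members)
        cum_in = 0.0
        cum_out = 0
        es = 0.0
        for g in order:
            if g in members:
                cum_in += ranks[g] ** alpha
            else:
                cum_out += 1
            p_in = cum_in / total_in
            p_out = cum_out / n_out if n_out > 0 else 0.0
            es += p_in - p_out
        scores[s] = es
    return scores
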