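"""Synthetic multi-omics cohorts with planted, known ground truth.

The generator emulates the statistical structure each downstream stage
is designed to detect:

* methylation β-values drawn from a bimodal beta-distribution mixture —
  an unmethylated mode (mean ≈ 0.1) and a methylated mode (mean ≈ 0.6) —
  with planted promoter hypermethylation coupled to expression
  suppression in chosen (gene, tumor) pairs;
* log-normal gene expression (stored as TPM) whose planted silenced
  pairs are shifted down by ``silencing_effect`` gene standard
  deviations;
* binary mutation and discrete copy-number lesion matrices with
  subtype-specific frequencies;
* survival times from an exponential-baseline proportional-hazards model
  driven by planted prognostic genes;
* cell-line expression/drug-AUC panels where sensitive compounds have
  AUC linearly decreasing in a planted expression program (lower AUC =
  more sensitive);
* multinomial subpopulation x tissue cell-count tables with planted
  tissue preferences.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneSet

__all__ = [
    "CohortConfig",
    "PanelConfig",
    "GroundTruth",
    "CohortBundle",
    "generate_cohort",
    "generate_ccl_panel",
    "generate_cell_counts",
    "generate_gene_sets",
]

# beta-distribution parameters for the two methylation modes
_UNMETH_AB = (2.0, 18.0)  # mean 0.10
_METH_AB = (6.0, 4.0)  # mean 0.60

_AUTOSOMES = [str(i) for i in range(1, 23)]


@dataclass
class CohortConfig:
    """Study conditions for the synthetic tumor/normal cohort."""

    n_tumor: int = 200
    n_normal: int = 30
    n_subtypes: int = 3
    n_genes: int = 300
    probes_per_gene: int = 3
    n_decoy_probes: int = 30  # SNP-flagged / sex-chromosome / distal probes
    n_normal_methylated_probes: int = 10  # promoter probes methylated in normals
    planted_silenced_genes: int = 8  # per subtype
    silencing_fraction: float = 0.4  # of tumors within the target subtype
    silencing_effect: float = 3.0  # expression suppression in gene-SD units
    noise_meth_rate: float = 0.01  # sporadic per-(probe,tumor) methylation
    planted_mutations: int = 3  # subtype-specific mutated genes per subtype
    mut_freq_in: float = 0.6
    mut_freq_out: float = 0.05
    background_mutations: int = 10
    background_mut_rate: float = 0.10
    planted_lesions: int = 2  # subtype-specific lesions per subtype
    lesion_freq_in: float = 0.5
    lesion_freq_out: float = 0.05
    background_lesions: int = 6
    background_lesion_rate: float = 0.10
    n_prognostic_genes: int = 5
    prognostic_effect: float = 1.0  # |log-hazard| per SD of expression
    censoring_rate: float = 0.3
    median_survival_days: float = 730.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_tumor": self.n_tumor,
            "n_normal": self.n_normal,
            "n_subtypes": self.n_subtypes,
            "n_genes": self.n_genes,
            "probes_per_gene": self.probes_per_gene,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0 (got {v})")
        for name in ("silencing_fraction", "censoring_rate", "noise_meth_rate",
                     "mut_freq_in", "mut_freq_out", "lesion_freq_in", "lesion_freq_out",
                     "background_mut_rate", "background_lesion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1] (got {v})")
        if self.silencing_effect < 0:
            raise ValueError("silencing_effect must be >= 0")
        needed = (self.planted_silenced_genes * self.n_subtypes
                  + self.n_prognostic_genes)
        if needed > self.n_genes:
            raise ValueError(
                f"infeasible config: {needed} planted genes > n_genes={self.n_genes}"
            )


@dataclass
class GroundTruth:
    """Planted signal locations for scoring recovery downstream."""

    subtype_labels: pd.Series
    silenced_pairs: set[tuple[str, str]]
    silenced_genes: dict[str, str]  # gene -> subtype
    subtype_specific_features: dict[str, str]  # feature -> subtype
    prognostic_genes: dict[str, float]  # gene -> true log-hazard coefficient


@dataclass
class CohortBundle:
    tumor_expression: pd.DataFrame  # gene x tumor, TPM
    tumor_betas: pd.DataFrame  # probe x tumor
    normal_betas: pd.DataFrame  # probe x normal
    manifest: pd.DataFrame
    mutations: pd.DataFrame  # gene x tumor binary
    lesion_values: pd.DataFrame  # lesion x tumor discrete calls
    lesion_meta: pd.DataFrame  # type / level / gene_count
    survival: pd.DataFrame  # sample-indexed: time, event, age, stage
    truth: GroundTruth


def _draw_betas(rng: np.random.Generator, shape, mode: str) -> np.ndarray:
    a, b = _METH_AB if mode == "meth" else _UNMETH_AB
    return rng.beta(a, b, size=shape)


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a full multi-omics cohort with planted ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    tumors = [f"T{i:04d}" for i in range(config.n_tumor)]
    normals = [f"N{i:04d}" for i in range(config.n_normal)]
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    subtypes = [f"C{k + 1}" for k in range(config.n_subtypes)]
    labels = pd.Series(
        rng.permutation([subtypes[i % config.n_subtypes] for i in range(config.n_tumor)]),
        index=tumors, name="subtype",
    )

    # --- probe manifest: promoter probes per gene + decoys -----------------
    rows = []
    for gi, g in enumerate(genes):
        for p in range(config.probes_per_gene):
            rows.append({
                "probe_id": f"cg{gi:05d}{p}",
                "chromosome": _AUTOSOMES[gi % len(_AUTOSOMES)],
                "tss_distance": int(rng.integers(-1500, 1501)),
                "gene": g,
                "snp_associated": False,
            })
    n_dec = config.n_decoy_probes
    for d in range(n_dec):
        kind = d % 3
        rows.append({
            "probe_id": f"cgD{d:05d}",
            "chromosome": "X" if kind == 0 else _AUTOSOMES[d % len(_AUTOSOMES)],
            "tss_distance": int(rng.integers(3000, 20000)) if kind == 1 else int(rng.integers(-1500, 1501)),
            "gene": genes[int(rng.integers(config.n_genes))],
            "snp_associated": kind == 2,
        })
    for d in range(config.n_normal_methylated_probes):
        rows.append({
            "probe_id": f"cgM{d:05d}",
            "chromosome": _AUTOSOMES[d % len(_AUTOSOMES)],
            "tss_distance": int(rng.integers(-1500, 1501)),
            "gene": genes[int(rng.integers(config.n_genes))],
            "snp_associated": False,
        })
    manifest = pd.DataFrame(rows).set_index("probe_id")
    probes = manifest.index.tolist()
    normal_meth_probes = {p for p in probes if p.startswith("cgM")}

    # --- plant silenced genes and prognostic genes -------------------------
    pool = list(genes)
    rng.shuffle(pool)
    silenced_genes: dict[str, str] = {}
    cursor = 0
    for st in subtypes:
        for _ in range(config.planted_silenced_genes):
            silenced_genes[pool[cursor]] = st
            cursor += 1
    prognostic = {}
    for j in range(config.n_prognostic_genes):
        sign = 1.0 if j % 2 == 0 else -1.0
        prognostic[pool[cursor]] = sign * config.prognostic_effect
        cursor += 1

    silenced_pairs: set[tuple[str, str]] = set()
    for g, st in silenced_genes.items():
        members = [s for s in tumors if labels[s] == st]
        n_sil = int(round(config.silencing_fraction * len(members)))
        chosen = rng.choice(members, size=n_sil, replace=False) if n_sil else []
        for s in chosen:
            silenced_pairs.add((g, s))

    # --- methylation ---------------------------------------------------------
    tumor_betas = pd.DataFrame(
        _draw_betas(rng, (len(probes), config.n_tumor), "unmeth"),
        index=probes, columns=tumors,
    )
    normal_betas = pd.DataFrame(
        _draw_betas(rng, (len(probes), config.n_normal), "unmeth"),
        index=probes, columns=normals,
    )
    for p in normal_meth_probes:
        normal_betas.loc[p] = _draw_betas(rng, config.n_normal, "meth")
        tumor_betas.loc[p] = _draw_betas(rng, config.n_tumor, "meth")
    if config.noise_meth_rate > 0:
        noise = rng.random((len(probes), config.n_tumor)) < config.noise_meth_rate
        arr = tumor_betas.to_numpy()
        arr[noise] = _draw_betas(rng, int(noise.sum()), "meth")
        tumor_betas = pd.DataFrame(arr, index=probes, columns=tumors)
    gene_probes = {g: manifest.index[(manifest["gene"] == g)
                                     & ~manifest.index.str.startswith(("cgD", "cgM"))]
                   for g in silenced_genes}
    for (g, s) in sorted(silenced_pairs):
        ps = gene_probes[g]
        tumor_betas.loc[ps, s] = _draw_betas(rng, len(ps), "meth")

    # --- expression (log2-normal, stored as TPM) ---------------------------
    mu = rng.uniform(3.0, 8.0, size=config.n_genes)
    sd = rng.uniform(1.1, 1.6, size=config.n_genes)
    log2e = rng.normal(mu[:, None], sd[:, None], size=(config.n_genes, config.n_tumor))
    log2e = pd.DataFrame(log2e, index=genes, columns=tumors)
    gene_sd = pd.Series(sd, index=genes)
    for (g, s) in sorted(silenced_pairs):
        log2e.loc[g, s] -= config.silencing_effect * gene_sd[g]
    tumor_expression = (2.0 ** log2e - 1.0).clip(lower=0.0)

    # --- mutations ----------------------------------------------------------
    subtype_specific: dict[str, str] = {}
    mut_rows = {}
    for k, st in enumerate(subtypes):
        for j in range(config.planted_mutations):
            name = f"MUT_{st}_{j}"
            freq = np.where(labels.values == st, config.mut_freq_in, config.mut_freq_out)
            mut_rows[name] = (rng.random(config.n_tumor) < freq).astype(int)
            subtype_specific[name] = st
    for j in range(config.background_mutations):
        name = f"MUTBG_{j}"
        mut_rows[name] = (rng.random(config.n_tumor) < config.background_mut_rate).astype(int)
    mutations = pd.DataFrame(mut_rows, index=tumors).T

    # --- copy-number lesions -------------------------------------------------
    lesion_rows, meta_rows = {}, []
    li = 0
    for st in subtypes:
        for j in range(config.planted_lesions):
            typ = "Amplification" if li % 2 == 0 else "Deletion"
            name = f"{typ} Peak {li + 1}"
            freq = np.where(labels.values == st, config.lesion_freq_in, config.lesion_freq_out)
            altered = rng.random(config.n_tumor) < freq
            calls = np.where(altered, rng.integers(1, 3, size=config.n_tumor), 0)
            lesion_rows[name] = calls
            meta_rows.append({"lesion": name, "type": "amp" if typ[0] == "A" else "del",
                              "level": "focal" if li % 2 == 0 else "arm",
                              "gene_count": int(rng.integers(5, 60))})
            subtype_specific[name] = st
            li += 1
    for j in range(config.background_lesions):
        typ = "Amplification" if li % 2 == 0 else "Deletion"
        name = f"{typ} Peak {li + 1}"
        altered = rng.random(config.n_tumor) < config.background_lesion_rate
        lesion_rows[name] = np.where(altered, rng.integers(1, 3, size=config.n_tumor), 0)
        meta_rows.append({"lesion": name, "type": "amp" if typ[0] == "A" else "del",
                          "level": "focal" if li % 2 == 0 else "arm",
                          "gene_count": int(rng.integers(5, 60))})
        li += 1
    lesion_values = pd.DataFrame(lesion_rows, index=tumors).T.astype(float)
    lesion_meta = pd.DataFrame(
        meta_rows, columns=["lesion", "type", "level", "gene_count"]
    ).set_index("lesion")

    # --- survival: exponential baseline proportional hazards ----------------
    z = log2e.loc[list(prognostic)].sub(
        log2e.loc[list(prognostic)].mean(axis=1), axis=0
    ).div(log2e.loc[list(prognostic)].std(axis=1, ddof=0), axis=0)
    lp = pd.Series(0.0, index=tumors)
    for g, beta in prognostic.items():
        lp += beta * z.loc[g]
    h0 = np.log(2.0) / config.median_survival_days
    event_t = rng.exponential(1.0 / (h0 * np.exp(lp.values)))
    if config.censoring_rate > 0:
        mu_c = h0 * config.censoring_rate / max(1e-12, 1.0 - config.censoring_rate)
        censor_t = rng.exponential(1.0 / mu_c, size=config.n_tumor)
    else:
        censor_t = np.full(config.n_tumor, np.inf)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    survival = pd.DataFrame({
        "time": np.maximum(time, 1e-6),
        "event": event,
        "age": np.round(rng.normal(60.0, 10.0, size=config.n_tumor), 1),
        "stage": rng.integers(1, 5, size=config.n_tumor),
    }, index=pd.Index(tumors, name="sample"))

    truth = GroundTruth(
        subtype_labels=labels,
        silenced_pairs=silenced_pairs,
        silenced_genes=silenced_genes,
        subtype_specific_features=subtype_specific,
        prognostic_genes=prognostic,
    )
    return CohortBundle(
        tumor_expression=tumor_expression,
        tumor_betas=tumor_betas,
        normal_betas=normal_betas,
        manifest=manifest,
        mutations=mutations,
        lesion_values=lesion_values,
        lesion_meta=lesion_meta,
        survival=survival,
        truth=truth,
    )


@dataclass
class PanelConfig:
    """Study conditions for the synthetic cell-line drug panel."""

    n_ccl: int = 150
    n_compounds: int = 30
    n_genes: int = 200
    program_size: int = 15
    n_sensitive: int = 3
    target_r: float = 0.6  # |corr(AUC, program score)| for sensitive compounds
    missingness: float = 0.05
    auc_center: float = 10.0
    auc_scale: float = 2.0
    gene_names: list[str] | None = None  # reuse patient gene symbols if given
    program_genes: list[str] | None = None  # planted program (subset of genes)
    program_weights: dict[str, float] | None = None  # signed weights per program gene
    seed: int = 0


def generate_ccl_panel(config: PanelConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (ccl_expression, auc, truth) for the compound screen.

    Sensitive compounds have ``AUC = a - b * program + noise`` with b > 0,
    so lower AUC (greater sensitivity) tracks higher program expression.
    ``truth`` maps compound -> ("sensitive"|"null").
    """
    if not 0.0 <= config.missingness < 1.0:
        raise ValueError("missingness must be in [0, 1)")
    if config.target_r < 0 or config.target_r > 1:
        raise ValueError("target_r must be in [0, 1]")
    rng = np.random.default_rng(config.seed)

    ccls = [f"CCL{i:04d}" for i in range(config.n_ccl)]
    genes = list(config.gene_names) if config.gene_names is not None else [
        f"G{i:04d}" for i in range(config.n_genes)
    ]
    mu = rng.uniform(3.0, 8.0, size=len(genes))
    sd = rng.uniform(0.8, 1.5, size=len(genes))
    log2e = rng.normal(mu[:, None], sd[:, None], size=(len(genes), config.n_ccl))
    expr = pd.DataFrame(log2e, index=genes, columns=ccls)

    if config.program_genes is not None:
        program_genes = [g for g in config.program_genes if g in expr.index]
        if not program_genes:
            raise ValueError("no program gene present in panel expression")
    else:
        program_genes = list(rng.choice(genes, size=min(config.program_size, len(genes)),
                                        replace=False))
    prog = expr.loc[program_genes]
    prog_z = prog.sub(prog.mean(axis=1), axis=0).div(prog.std(axis=1, ddof=0), axis=0)
    if config.program_weights is not None:
        w = pd.Series({g: config.program_weights.get(g, 0.0) for g in program_genes})
        program = prog_z.mul(w, axis=0).sum(axis=0)
    else:
        program = prog_z.mean(axis=0)
    program = (program - program.mean()) / program.std(ddof=0)

    r = config.target_r
    truth: dict[str, str] = {}
    rows = {}
    for j in range(config.n_compounds):
        name = f"CPD{j:03d}"
        eps = rng.standard_normal(config.n_ccl)
        if j < config.n_sensitive:
            zauc = -(r * program.values + np.sqrt(max(0.0, 1 - r * r)) * eps)
            truth[name] = "sensitive"
        else:
            zauc = eps
            truth[name] = "null"
        rows[name] = config.auc_center + config.auc_scale * zauc
    auc = pd.DataFrame(rows, index=ccls).T

    if config.missingness > 0:
        mask = rng.random(auc.shape) < config.missingness
        auc = auc.mask(mask)

    truth_full = {"compounds": truth, "program_genes": program_genes}
    return expr, auc, truth_full


def generate_cell_counts(
    preference: pd.DataFrame, n_cells: int = 2000, seed: int = 0
) -> pd.DataFrame:
    """Multinomial subpopulation x tissue cell counts with planted preferences.

    ``preference`` holds positive multipliers on a uniform baseline; a
    multiplier of 1 everywhere yields no tissue preference (all odds
    ratios near 1 in expectation).
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    if (preference.values <= 0).any():
        raise ValueError("preference multipliers must be > 0")
    rng = np.random.default_rng(seed)
    w = preference.values.astype(float)
    p = (w / w.sum()).ravel()
    draws = rng.multinomial(n_cells, p).reshape(w.shape)
    return pd.DataFrame(draws, index=preference.index, columns=preference.columns)


def generate_gene_sets(
    genes: list[str], n_sets: int = 10, set_size: int = 20, seed: int = 0
) -> list[GeneSet]:
    """Random gene sets over the cohort's gene symbols (GMT fixture stand-in)."""
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n_sets):
        members = rng.choice(genes, size=min(set_size, len(genes)), replace=False)
        sets.append(GeneSet(name=f"SET_{i:02d}", description="synthetic",
                            genes=tuple(sorted(members))))
    return sets
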