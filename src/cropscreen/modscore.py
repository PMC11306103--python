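"""Gene-module perturbation scoring.

A module (an explicit gene set, e.g. the 25-gene TNF module active in
epidermal stem cells) is summarized per cell by its eigengene — the first
principal component of the standardized module-gene submatrix, sign-fixed
to correlate positively with mean module expression and rescaled to unit
variance.  Each perturbation's effect on the module is the coefficient of a
two-group linear model of the scaled eigengene on a perturbation-vs-control
indicator.  Per-gene differential expression (Wilcoxon rank-sum on
log-normalized expression) is combined across module genes with Fisher's
method alongside the average log2 fold change, and Benjamini–Hochberg
adjustment is applied across perturbations.  The module also clusters
perturbation module profiles, fits the linear model predicting clonal
expansion from module-gene means, and runs Fisher's-exact
overrepresentation tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from cropscreen.indices import normalize_counts

_TINY = np.finfo(float).tiny


# ---------------------------------------------------------------------------
# Eigengene


def module_eigengene(adata, module_genes: Sequence[str], ddof: int = 1) -> np.ndarray:
    """Per-cell module eigengene.

    The module-gene submatrix of log-normalized expression is standardized
    per gene, its first principal component is extracted by SVD, the sign is
    fixed so the eigengene correlates positively with the mean standardized
    module expression, and the result is standardized to mean 0 / unit
    variance.  Requires at least two module genes with nonzero variance.
    """
    genes = [g for g in module_genes if g in adata.var_names]
    if len(genes) < 2:
        raise ValueError("need at least two module genes present in the matrix")
    X = adata.X.toarray() if hasattr(adata.X, "toarray") else np.asarray(adata.X)
    norm = normalize_counts(X, log1p=True)
    cols = [list(adata.var_names).index(g) for g in genes]
    sub = norm[:, cols]
    sd = sub.std(axis=0, ddof=0)
    keep = sd > 1e-10 * (np.abs(sub).max() + 1.0)  # tolerate float noise on constants
    if keep.sum() < 2:
        raise ValueError("fewer than two module genes have nonzero variance")
    z = (sub[:, keep] - sub[:, keep].mean(axis=0)) / sd[keep]
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    pc = u[:, 0] * s[0]
    if np.corrcoef(pc, z.mean(axis=1))[0, 1] < 0:
        pc = -pc
    return (pc - pc.mean()) / pc.std(ddof=ddof)


# ---------------------------------------------------------------------------
# Perturbation score


def perturbation_score(
    eigengene: np.ndarray,
    perturbations: pd.Series,
    control_ids: Iterable[str],
    downsample: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Linear-model effect of each perturbation on the scaled eigengene.

    For each perturbation a two-group model ``eigengene ~ is_perturbed`` is
    fitted against the pooled control cells; the coefficient, its standard
    error and the t-test p-value are reported.  The coefficient p-value is
    identical to a pooled-variance two-sample t-test.  Perturbations with
    fewer than two cells are skipped with a warning.  ``downsample`` caps
    the number of cells used per perturbation (seeded draw).
    """
    import statsmodels.api as sm

    eigengene = np.asarray(eigengene, float)
    control_ids = set(control_ids)
    is_ctrl = perturbations.isin(control_ids).to_numpy()
    if is_ctrl.sum() < 2:
        raise ValueError("need at least two control cells")
    rng = np.random.default_rng(seed)
    ctrl_vals = eigengene[is_ctrl]
    rows = []
    for pert in pd.unique(perturbations):
        if pert in control_ids:
            continue
        vals = eigengene[(perturbations == pert).to_numpy()]
        if len(vals) < 2:
            warnings.warn(f"perturbation {pert!r} has fewer than 2 cells; skipped")
            continue
        if downsample is not None and len(vals) > downsample:
            vals = rng.choice(vals, size=downsample, replace=False)
        y = np.concatenate([ctrl_vals, vals])
        x = sm.add_constant(np.r_[np.zeros(len(ctrl_vals)), np.ones(len(vals))])
        fit = sm.OLS(y, x).fit()
        rows.append((pert, fit.params[1], fit.bse[1], fit.pvalues[1], len(vals)))
    return pd.DataFrame(
        rows, columns=["perturbation", "effect", "se", "p", "n_cells"]
    ).set_index("perturbation")


# ---------------------------------------------------------------------------
# Differential expression and Fisher combination


def per_gene_de(
    adata,
    perturbations: pd.Series,
    control_ids: Iterable[str],
    module_genes: Sequence[str],
    target: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-module-gene log2FC and rank-sum p for one perturbation vs control.

    log2FC compares mean per-10k-normalized expression with a fixed
    pseudocount; p-values are two-sided Wilcoxon rank-sum on the
    log-normalized values.  Genes absent from the matrix are skipped and
    recorded with NaN.
    """
    X = adata.X.toarray() if hasattr(adata.X, "toarray") else np.asarray(adata.X)
    norm = normalize_counts(X, log1p=False)
    lognorm = np.log1p(norm)
    gene_index = {g: i for i, g in enumerate(adata.var_names)}
    pert_mask = (perturbations == target).to_numpy()
    ctrl_mask = perturbations.isin(set(control_ids)).to_numpy()
    if not pert_mask.any() or not ctrl_mask.any():
        raise ValueError("perturbation or control group is empty")
    rows = []
    for gene in module_genes:
        i = gene_index.get(gene)
        if i is None:
            rows.append((gene, np.nan, np.nan, False))
            continue
        a, b = norm[pert_mask, i], norm[ctrl_mask, i]
        lfc = np.log2((a.mean() + pseudocount) / (b.mean() + pseudocount))
        if np.all(lognorm[pert_mask, i] == lognorm[pert_mask, i][0]) and np.all(
            lognorm[ctrl_mask, i] == lognorm[pert_mask, i][0]
        ):
            p = 1.0  # both groups constant and equal
        else:
            p = stats.mannwhitneyu(
                lognorm[pert_mask, i], lognorm[ctrl_mask, i], alternative="two-sided"
            ).pvalue
        rows.append((gene, lfc, p, True))
    return pd.DataFrame(rows, columns=["gene", "log2fc", "p", "present"]).set_index("gene")


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's method: X2 = -2 sum(ln p) with 2k degrees of freedom."""
    p = np.asarray(list(p_values), float)
    if len(p) == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any():
        warnings.warn("p-values of 0 clipped to the smallest positive float")
        p = np.clip(p, _TINY, None)
    if (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    stat = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(stat, df=2 * len(p)))


def bh_adjust(p: pd.Series) -> pd.Series:
    """Benjamini–Hochberg adjusted p-values (order-preserving)."""
    adj = multipletests(p.to_numpy(float), method="fdr_bh")[1]
    return pd.Series(adj, index=p.index, name="p_adj")


def module_perturbation_table(
    adata,
    module_genes: Sequence[str],
    perturbations: pd.Series,
    control_ids: Iterable[str],
    downsample: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Full module scoring across perturbations.

    Combines the eigengene linear-model effect with the Fisher-combined
    per-gene DE p-value and average module log2FC, and BH-adjusts the
    combined p-values across perturbations.
    """
    eig = module_eigengene(adata, module_genes)
    scores = perturbation_score(eig, perturbations, control_ids, downsample=downsample, seed=seed)
    combined, avg_lfc = [], []
    for pert in scores.index:
        de = per_gene_de(adata, perturbations, control_ids, module_genes, pert)
        de = de[de["present"]]
        combined.append(fisher_combine(de["p"].dropna()))
        avg_lfc.append(de["log2fc"].mean())
    scores["combined_p"] = combined
    scores["avg_log2fc"] = avg_lfc
    scores["p_adj"] = bh_adjust(scores["combined_p"])
    return scores


# ---------------------------------------------------------------------------
# Module-profile clustering and the expansion model


def cluster_module_profiles(
    profiles: pd.DataFrame, k: int, expansion: pd.Series | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Ward-cluster perturbation module profiles; compare expansion by cluster.

    Rows (perturbations x module genes) are z-scaled, clustered with Ward
    linkage on Euclidean distance and cut at ``k`` clusters.  When an
    expansion series is given, every cluster pair is compared with a
    two-sided Wilcoxon rank-sum test.
    """
    if k < 2 or k > len(profiles):
        raise ValueError("k must be in [2, n perturbations]")
    X = profiles.to_numpy(float)
    sd = X.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    labels = hierarchy.fcluster(hierarchy.ward(Z), t=k, criterion="maxclust")
    labels = pd.Series(labels, index=profiles.index, name="cluster")
    tests = []
    if expansion is not None:
        expansion = expansion.reindex(profiles.index)
        for a in range(1, k + 1):
            for b in range(a + 1, k + 1):
                xa = expansion[labels == a].dropna()
                xb = expansion[labels == b].dropna()
                if len(xa) and len(xb):
                    res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
                    tests.append((a, b, xa.median(), xb.median(), res.pvalue))
    tests = pd.DataFrame(tests, columns=["cluster_a", "cluster_b", "median_a", "median_b", "p"])
    return labels, tests


@dataclass
class ExpansionModelFit:
    """OLS fit of clonal expansion on per-perturbation module-gene means."""

    coef: pd.Series
    intercept: float
    fitted: pd.Series
    pearson_r: float
    pearson_p: float
    used_ridge: bool

    def predict(self, X: pd.DataFrame) -> pd.Series:
        return X[self.coef.index] @ self.coef + self.intercept


def expansion_model(
    module_means: pd.DataFrame, expansion: pd.Series, ridge_alpha: float = 1e-2
) -> ExpansionModelFit:
    """Linear model predicting expansion log2FC from module-gene means.

    Ordinary least squares of expansion on the perturbation x module-gene
    mean-expression matrix; reports the Pearson correlation between fitted
    and observed values.  Collinear predictors trigger a ridge fallback
    (flagged on the result).
    """
    y = expansion.reindex(module_means.index)
    if y.isna().any():
        raise ValueError("expansion values missing for some perturbations")
    X = module_means.to_numpy(float)
    n, p = X.shape
    centered = X - X.mean(axis=0)
    collinear = n <= p or np.linalg.matrix_rank(centered) < p
    if collinear:
        warnings.warn("collinear or underdetermined predictors; using ridge")
        from sklearn.linear_model import Ridge

        model = Ridge(alpha=ridge_alpha).fit(X, y.to_numpy())
        coef, intercept = model.coef_, model.intercept_
        fitted = model.predict(X)
    else:
        import statsmodels.api as sm

        design = sm.add_constant(X)
        fit = sm.OLS(y.to_numpy(), design).fit()
        coef, intercept = fit.params[1:], fit.params[0]
        fitted = fit.fittedvalues
    r, rp = stats.pearsonr(fitted, y.to_numpy())
    return ExpansionModelFit(
        coef=pd.Series(coef, index=module_means.columns),
        intercept=float(intercept),
        fitted=pd.Series(fitted, index=module_means.index),
        pearson_r=float(r),
        pearson_p=float(rp),
        used_ridge=bool(collinear),
    )


# ---------------------------------------------------------------------------
# Overrepresentation


def ora_fisher(
    hits: Iterable[str], gene_set: Iterable[str], universe: Iterable[str]
) -> tuple[float, float]:
    """One-sided Fisher's exact test for overrepresentation of a gene set.

    Returns ``(odds_ratio, p)`` for the 2x2 overlap table of hits vs the
    gene set within the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits, gene_set = set(hits), set(gene_set)
    if not hits <= universe or not gene_set <= universe:
        raise ValueError("hits and gene set must be subsets of the universe")
    a = len(hits & gene_set)
    b = len(hits - gene_set)
    c = len(gene_set - hits)
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)


def ora_table(
    hits: Iterable[str], gene_sets: Mapping[str, Iterable[str]], universe: Iterable[str]
) -> pd.DataFrame:
    """Fisher overrepresentation across gene sets with BH adjustment."""
    rows = []
    for name, gs in gene_sets.items():
        odds, p = ora_fisher(hits, gs, universe)
        rows.append((name, odds, p))
    out = pd.DataFrame(rows, columns=["gene_set", "odds_ratio", "p"]).set_index("gene_set")
    out["p_adj"] = bh_adjust(out["p"])
    return out
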