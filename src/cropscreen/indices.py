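"""Per-perturbation phenotype indices.

Control-relative indices summarize how a perturbation shifts cell behaviour
relative to the pooled non-targeting controls: the proliferation index is
the perturbation's cycling-cell fraction over the control cycling fraction,
and the anti-differentiation index is the perturbation's basal share of the
basal+differentiated compartment over the control share.  Cell-cycle phases
are called Tirosh-style from S/G2M marker scores against size-matched
random background genes.  The module also computes cell-type composition
percentages with named pairwise ratios, and threshold-based fractions of
cells positive for a gene on the per-10k normalized scale.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


def normalize_counts(X: np.ndarray, target_sum: float = 1e4, log1p: bool = False) -> np.ndarray:
    """Scale each cell's counts to ``target_sum`` total, optionally log1p."""
    X = np.asarray(X, dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    out = X / totals * target_sum
    return np.log1p(out) if log1p else out


def _marker_columns(genes: Sequence[str], markers: Sequence[str], what: str) -> list[int]:
    idx = {g: i for i, g in enumerate(genes)}
    cols = [idx[g] for g in markers if g in idx]
    if not cols:
        raise ValueError(f"no {what} marker genes present in the gene universe")
    return cols


def assign_cycle_phase(
    adata,
    s_genes: Sequence[str],
    g2m_genes: Sequence[str],
    seed: int = 0,
) -> pd.DataFrame:
    """Call G1/S/G2M per cell from marker scores.

    Each score is the mean per-gene-standardized log-normalized expression of
    the marker list minus the mean of a size-matched random background gene
    set (drawn once, seeded, from the non-marker genes).  Standardizing genes
    first keeps the score centred regardless of baseline expression levels.
    A cell is labelled S or G2M by the larger of the two scores when that
    score is positive, else G1.

    Returns a DataFrame ``s_score, g2m_score, phase`` indexed like
    ``adata.obs`` (nothing is written back into the AnnData).
    """
    genes = list(adata.var_names)
    s_cols = _marker_columns(genes, s_genes, "S")
    g2m_cols = _marker_columns(genes, g2m_genes, "G2M")
    X = adata.X.toarray() if hasattr(adata.X, "toarray") else np.asarray(adata.X)
    norm = normalize_counts(X, log1p=True)
    sd = norm.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0  # constant genes score 0
    z = (norm - norm.mean(axis=0)) / sd

    rng = np.random.default_rng(seed)
    marker_set = set(s_cols) | set(g2m_cols)
    pool = np.array([i for i in range(len(genes)) if i not in marker_set])
    scores = {}
    for name, cols in (("s_score", s_cols), ("g2m_score", g2m_cols)):
        k = min(len(cols), len(pool))
        background = rng.choice(pool, size=k, replace=False) if k else np.array([], int)
        bg = z[:, background].mean(axis=1) if k else 0.0
        scores[name] = z[:, cols].mean(axis=1) - bg

    s, g2m = scores["s_score"], scores["g2m_score"]
    phase = np.where((s <= 0) & (g2m <= 0), "G1", np.where(s >= g2m, "S", "G2M"))
    return pd.DataFrame({"s_score": s, "g2m_score": g2m, "phase": phase}, index=adata.obs_names)


def _control_mask(perturbations: pd.Series, control_ids: Iterable[str]) -> np.ndarray:
    mask = perturbations.isin(set(control_ids)).to_numpy()
    if not mask.any():
        raise ValueError("no control cells found")
    return mask


def proliferation_index(
    phases: pd.Series,
    perturbations: pd.Series,
    control_ids: Iterable[str],
    cycling_phases: Sequence[str] = ("S", "G2M"),
) -> pd.Series:
    """Cycling-cell fraction of each perturbation over the control fraction."""
    ctrl = _control_mask(perturbations, control_ids)
    cycling = phases.isin(cycling_phases).to_numpy()
    ctrl_frac = cycling[ctrl].mean()
    if ctrl_frac == 0:
        raise ValueError("control cells have zero cycling fraction")
    frac = pd.Series(cycling, index=perturbations.to_numpy()).groupby(level=0).mean()
    return (frac / ctrl_frac).rename("proliferation_index")


def anti_differentiation_index(
    cell_types: pd.Series,
    perturbations: pd.Series,
    control_ids: Iterable[str],
    basal_types: Sequence[str],
    differentiated_types: Sequence[str],
) -> pd.Series:
    """Basal share of the basal+differentiated compartment, control-relative.

    ``index_p = [basal / (basal + differentiated)]_p / [same]_controls``.
    Perturbations with no cells in either compartment are NaN.
    """
    basal_types, differentiated_types = set(basal_types), set(differentiated_types)
    if not basal_types or not differentiated_types or basal_types & differentiated_types:
        raise ValueError("basal and differentiated type sets must be disjoint and non-empty")
    ctrl = _control_mask(perturbations, control_ids)
    basal = cell_types.isin(basal_types).to_numpy().astype(float)
    either = (basal > 0) | cell_types.isin(differentiated_types).to_numpy()

    def share(b, e):
        return b[e].mean() if e.any() else np.nan

    ctrl_share = share(basal, either & ctrl)
    if not ctrl_share or np.isnan(ctrl_share):
        raise ValueError("control basal share is zero or undefined")
    df = pd.DataFrame({"basal": basal, "either": either, "pert": perturbations.to_numpy()})
    out = df[df["either"]].groupby("pert")["basal"].mean() / ctrl_share
    return out.reindex(pd.unique(df["pert"])).rename("anti_differentiation_index")


def celltype_shares(
    cell_types: pd.Series,
    perturbations: pd.Series,
    ratios: Mapping[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Cell-type composition per perturbation, in percent, plus named ratios.

    Percentages sum to 100 within each perturbation.  ``ratios`` maps an
    output column name to a ``(numerator_type, denominator_type)`` pair;
    a zero denominator yields NaN, an unknown type name raises.
    """
    tab = pd.crosstab(perturbations.to_numpy(), cell_types.to_numpy())
    shares = tab.div(tab.sum(axis=1), axis=0) * 100.0
    if ratios:
        for name, (num, den) in ratios.items():
            for t in (num, den):
                if t not in shares.columns:
                    raise ValueError(f"unknown cell type {t!r} in ratio request")
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = shares[num].to_numpy() / shares[den].to_numpy()
            shares[name] = np.where(shares[den].to_numpy() > 0, vals, np.nan)
    return shares


def positive_fraction(
    adata,
    cluster_labels: pd.Series,
    gene: str,
    threshold: float = 0.5,
    log1p: bool = False,
) -> pd.Series:
    """Per-cluster fraction of cells with normalized expression above threshold.

    Expression is scaled to 10,000 counts per cell; by default the threshold
    applies on that (pre-log) scale, with ``log1p=True`` switching to the
    log-transformed scale.  Empty clusters are NaN.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if gene not in adata.var_names:
        raise ValueError(f"gene {gene!r} not in the expression matrix")
    X = adata.X.toarray() if hasattr(adata.X, "toarray") else np.asarray(adata.X)
    norm = normalize_counts(X, log1p=log1p)
    col = norm[:, list(adata.var_names).index(gene)]
    positive = pd.Series(col > threshold, index=cluster_labels.to_numpy())
    return positive.groupby(level=0).mean().rename(f"{gene}_positive_fraction")
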