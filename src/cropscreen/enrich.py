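"""Clonal-expansion enrichment statistics.

Per-sample guide cell counts are converted to proportions and divided by
the matching T0 plasmid-batch proportions, giving a fold change of ratios.
Guide fold changes are averaged within triplets targeting the same gene and
within consecutive pseudo-triplets of control guides (150 genes + 17
control groups = 167 perturbation values for the default 500-guide
library).  Perturbations are ranked by decreasing fold change with min-rank
tie handling, replicate samples are combined with a weighted mean (weights
= guide-positive cell counts), and the average is reported in log2.  The
module also provides median-of-ratios size-factor normalization on control
guides and the knockout/wild-type dependency ratio built on it.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from cropscreen.synth import GuideLibrary


def guide_fold_change(sample_counts: pd.Series, t0_counts: pd.Series) -> pd.Series:
    """Per-guide fold change of sample proportion over T0 proportion.

    ``FC_g = (c_g / sum c) / (t_g / sum t)``.  Guides absent from the sample
    (zero cells) get FC 0; every sampled guide must exist in the T0 table and
    all T0 counts must be strictly positive.
    """
    t0 = t0_counts.astype(float)
    if (t0 <= 0).any():
        raise ValueError("T0 counts must be strictly positive for all guides")
    extra = sample_counts.index.difference(t0.index)
    if len(extra):
        raise ValueError(f"guides not in library/T0 table: {list(extra)[:5]}")
    counts = sample_counts.reindex(t0.index).fillna(0.0).astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("sample has no cells")
    return (counts / total) / (t0 / t0.sum())


def collapse_perturbations(
    guide_fc: pd.Series, library: GuideLibrary, group_size: int = 3
) -> pd.Series:
    """Average guide fold changes within genes and control pseudo-triplets.

    Gene value = arithmetic mean of its guides' fold changes; control guides
    are grouped by ascending control index into consecutive groups of
    ``group_size`` (the final group may be smaller).  Output length is
    ``n_genes + ceil(n_controls / group_size)``.
    """
    pert = library.perturbation_map(group_size=group_size)
    missing = pert.index.difference(guide_fc.index)
    if len(missing):
        raise ValueError(f"fold changes missing for guides: {list(missing)[:5]}")
    collapsed = guide_fc.reindex(pert.index).groupby(pert, sort=False).mean()
    return collapsed.reindex(pd.unique(pert))


def rank_perturbations(perturbation_fc: pd.Series) -> pd.Series:
    """Ranks with 1 = highest fold change; ties share the minimum rank."""
    ranks = rankdata(-perturbation_fc.to_numpy(float), method="min")
    return pd.Series(ranks.astype(int), index=perturbation_fc.index, name="rank")


def weighted_average_fc(
    samples: Mapping[str, pd.Series], weights: Mapping[str, float]
) -> pd.DataFrame:
    """Weighted mean fold change across replicate samples, then log2.

    Weights are the per-sample guide-positive cell counts.  Averaging is on
    the ratio scale; log2 is applied last and a zero average fold change is
    reported as missing (no pseudocount).
    """
    if not samples:
        raise ValueError("need at least one sample")
    names = list(samples)
    first = samples[names[0]].index
    for name in names[1:]:
        if not samples[name].index.equals(first):
            raise ValueError(f"perturbation sets differ between samples ({name})")
    w = np.asarray([float(weights[name]) for name in names])
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    mat = np.column_stack([samples[name].to_numpy(float) for name in names])
    avg = mat @ (w / w.sum())
    log2fc = np.where(avg > 0, np.log2(np.where(avg > 0, avg, 1.0)), np.nan)
    return pd.DataFrame({"avg_fc": avg, "log2fc": log2fc}, index=first)


def timepoint_ratio(fc_late: pd.Series, fc_early: pd.Series) -> pd.DataFrame:
    """Late/early fold-change ratio per perturbation, re-ranked.

    A zero early fold change makes the ratio undefined (NaN, flagged in the
    ``undefined`` column); defined ratios are re-ranked with min-rank ties.
    """
    if not fc_late.index.equals(fc_early.index):
        fc_early = fc_early.reindex(fc_late.index)
        if fc_early.isna().any():
            raise ValueError("perturbation ids do not match between time points")
    early = fc_early.to_numpy(float)
    ratio = np.where(early != 0, fc_late.to_numpy(float) / np.where(early != 0, early, 1.0), np.nan)
    out = pd.DataFrame({"ratio": ratio, "undefined": early == 0}, index=fc_late.index)
    filled = out["ratio"].fillna(-np.inf)  # undefined sink to the bottom of the ranking
    out["rank"] = rank_perturbations(filled)
    return out


def sample_enrichment(
    cell_table: pd.DataFrame,
    library: GuideLibrary,
    batch_of_sample: Mapping[str, int],
    group_size: int = 3,
) -> pd.DataFrame:
    """Per-sample perturbation fold changes, ranks and weights.

    ``cell_table`` needs columns ``cell_id, guide_id, sample``; unassigned
    cells (missing guide) are ignored.  Each sample is normalized against the
    T0 counts of its own library batch.

    Returns a long table ``perturbation, sample, fc, rank, weight``.
    """
    assigned = cell_table.dropna(subset=["guide_id"])
    if assigned.empty:
        raise ValueError("no assigned cells")
    out = []
    for sample, sub in assigned.groupby("sample", sort=True):
        t0 = library.t0_for_batch(int(batch_of_sample[sample]))
        fc = guide_fold_change(sub["guide_id"].value_counts(), t0)
        pert_fc = collapse_perturbations(fc, library, group_size=group_size)
        out.append(pd.DataFrame({
            "perturbation": pert_fc.index,
            "sample": sample,
            "fc": pert_fc.to_numpy(),
            "rank": rank_perturbations(pert_fc).to_numpy(),
            "weight": len(sub),
        }))
    return pd.concat(out, ignore_index=True)


def enrichment_table(
    cell_table: pd.DataFrame,
    library: GuideLibrary,
    batch_of_sample: Mapping[str, int],
    group_size: int = 3,
) -> pd.DataFrame:
    """Full enrichment table: per-sample values plus the weighted average.

    Returns a wide table indexed by perturbation with per-sample ``fc_*`` and
    ``rank_*`` columns, ``avg_fc``, ``log2fc`` and ``rank`` of the average.
    """
    long = sample_enrichment(cell_table, library, batch_of_sample, group_size=group_size)
    fc_by_sample = {
        s: sub.set_index("perturbation")["fc"] for s, sub in long.groupby("sample")
    }
    weights = {s: sub["weight"].iloc[0] for s, sub in long.groupby("sample")}
    avg = weighted_average_fc(fc_by_sample, weights)
    wide = long.pivot(index="perturbation", columns="sample")
    result = pd.concat(
        [wide["fc"].add_prefix("fc_"), wide["rank"].add_prefix("rank_"), avg], axis=1
    ).reindex(avg.index)
    result["rank"] = rank_perturbations(result["avg_fc"])
    return result


def subset_enrichment(
    cell_table: pd.DataFrame,
    cell_type_labels: pd.Series,
    target_type: str,
    library: GuideLibrary,
    batch_of_sample: Mapping[str, int],
    group_size: int = 3,
) -> pd.DataFrame:
    """Enrichment restricted to cells of one type (e.g. epidermal stem cells).

    ``cell_type_labels`` is indexed by cell id and must cover every cell in
    the table.  The identical pipeline is applied to the restricted cell set.
    """
    labels = cell_type_labels.reindex(cell_table["cell_id"])
    if labels.isna().any():
        raise ValueError("cell type labels do not cover all cells")
    subset = cell_table[(labels == target_type).to_numpy()]
    if subset.empty:
        raise ValueError(f"no cells of type {target_type!r}")
    return enrichment_table(subset, library, batch_of_sample, group_size=group_size)


def control_normalize(
    counts: pd.DataFrame, control_ids: Sequence[str]
) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors estimated on control guides only.

    ``counts`` is guides x samples.  For each sample ``s`` the size factor is
    the median over control guides ``g`` of ``count[g, s] / geomean_s(count[g, :])``
    (controls with a zero anywhere are excluded from the geometric means, as
    in the standard median-of-ratios estimator).  Returns the size factors
    and the normalized count table ``counts / size_factor``.
    """
    control_ids = [c for c in control_ids if c in counts.index]
    if not control_ids:
        raise ValueError("no control guides present in the count table")
    ctrl = counts.loc[control_ids].astype(float)
    if (ctrl.sum(axis=0) == 0).any():
        raise ValueError("all control guides are zero in at least one sample")
    positive = ctrl[(ctrl > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no control guide has positive counts in every sample")
    log_geomean = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geomean, axis=0)
    size_factors = np.exp(ratios.median(axis=0)).rename("size_factor")
    return size_factors, counts.div(size_factors, axis=1)


def control_relative_representation(
    counts: pd.DataFrame,
    library: GuideLibrary,
    group_size: int = 3,
) -> pd.Series:
    """Per-perturbation mean normalized counts, scaled so controls center on 1.

    Counts (guides x samples) are size-factor normalized on the control
    guides, averaged across samples, collapsed to perturbation units and
    divided by the median of the control pseudo-triplet values.
    """
    _, normed = control_normalize(counts, library.control_guide_ids())
    mean_guide = normed.mean(axis=1)
    pert = collapse_perturbations(mean_guide, library, group_size=group_size)
    ctrl_level = pert[pert.index.str.startswith("ctrl_")].median()
    if ctrl_level <= 0:
        raise ValueError("control level is not positive")
    return pert / ctrl_level


def dependency_ratio(enrich_wt: pd.Series, enrich_ko: pd.Series) -> pd.DataFrame:
    """Knockout / wild-type ratio of control-normalized enrichment.

    Values below 1 indicate that the perturbation's expansion depends on the
    knocked-out receptor.  Ratios are undefined (NaN, flagged) where the
    wild-type enrichment is zero.
    """
    ko = enrich_ko.reindex(enrich_wt.index)
    if ko.isna().any():
        raise ValueError("perturbation ids do not match between tables")
    wt = enrich_wt.to_numpy(float)
    ratio = np.where(wt > 0, ko.to_numpy(float) / np.where(wt > 0, wt, 1.0), np.nan)
    return pd.DataFrame(
        {"wt": wt, "ko": ko.to_numpy(float), "ratio": ratio, "undefined": wt <= 0},
        index=enrich_wt.index,
    )
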