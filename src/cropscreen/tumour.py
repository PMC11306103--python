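"""Per-tumour guide counting and the P60-to-tumour selection score.

Individually sequenced tumour amplicons are counted by exact 20-nt
protospacer substring matching (no mismatch tolerance; reads matching two
or more distinct protospacers are excluded as ambiguous).  Counts pooled
over tumours collapse to perturbation units and convert to representation
fractions, which are compared with the pre-tumour (P60) skin representation
through a log2 selection score over perturbations passing a coverage
filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from cropscreen.synth import GuideLibrary


@dataclass
class TumourCountResult:
    """Per-tumour guide counts plus unmapped/ambiguous read tallies."""

    counts: pd.DataFrame  # tumours x guides
    stats: pd.DataFrame  # tumours x (n_reads, n_mapped, n_unmapped, n_ambiguous)


def count_tumour_guides(
    reads_by_tumour: Mapping[str, Iterable[str]], library: GuideLibrary
) -> TumourCountResult:
    """Count guides in each tumour's reads by exact protospacer matching.

    A read increments a guide when that guide's protospacer occurs anywhere
    in the read; reads containing no protospacer are tallied as unmapped and
    reads containing two or more distinct protospacers as ambiguous
    (excluded from counts).
    """
    protos = library.guides["protospacer"]
    if protos.duplicated().any():
        raise ValueError("library protospacers must be unique")
    plen = len(protos.iloc[0])
    guide_of = dict(zip(protos, library.guides["guide_id"]))
    guide_ids = library.guides["guide_id"].to_numpy()
    col = {g: i for i, g in enumerate(guide_ids)}

    count_rows, stat_rows, tumours = [], [], []
    for tumour, reads in reads_by_tumour.items():
        counts = np.zeros(len(guide_ids), dtype=np.int64)
        n_reads = n_unmapped = n_ambiguous = 0
        for read in reads:
            n_reads += 1
            found: set[str] = set()
            for i in range(len(read) - plen + 1):
                g = guide_of.get(read[i : i + plen])
                if g is not None:
                    found.add(g)
                    if len(found) > 1:
                        break
            if not found:
                n_unmapped += 1
            elif len(found) > 1:
                n_ambiguous += 1
            else:
                counts[col[found.pop()]] += 1
        tumours.append(str(tumour))
        count_rows.append(counts)
        stat_rows.append((n_reads, int(counts.sum()), n_unmapped, n_ambiguous))
    counts = pd.DataFrame(count_rows, index=tumours, columns=guide_ids)
    stats = pd.DataFrame(
        stat_rows, index=tumours, columns=["n_reads", "n_mapped", "n_unmapped", "n_ambiguous"]
    )
    return TumourCountResult(counts=counts, stats=stats)


def tumour_representation(
    counts: pd.DataFrame, library: GuideLibrary, group_size: int = 3
) -> pd.Series:
    """Pooled per-perturbation representation fractions across tumours.

    Guide counts are summed over tumours, summed within perturbation units
    (gene triplets / control pseudo-triplets) and converted to fractions of
    the pooled total.
    """
    if counts.empty:
        raise ValueError("need at least one tumour")
    pooled = counts.sum(axis=0).reindex(library.guides["guide_id"].to_numpy()).fillna(0.0)
    pert = library.perturbation_map(group_size=group_size)
    grouped = pooled.groupby(pert.reindex(pooled.index), sort=False).sum()
    grouped = grouped.reindex(pd.unique(pert))
    total = grouped.sum()
    if total <= 0:
        raise ValueError("no mapped reads")
    return (grouped / total).rename("tumour_fraction")


def guide_representation(counts: pd.Series) -> pd.Series:
    """Normalize raw per-guide counts to fractions summing to 1."""
    total = counts.sum()
    if total <= 0:
        raise ValueError("counts sum to zero")
    return counts / total


def selection_score(
    tumour_repr: pd.Series,
    p60_repr: pd.Series,
    min_coverage: float | None = None,
) -> pd.DataFrame:
    """log2 tumour/P60 representation over covered perturbations.

    A perturbation passes the coverage filter when its fraction is at least
    ``min_coverage`` (default ``1 / (2 * n_perturbations)``) in at least one
    of the two representations.  Both representations are renormalized over
    the covered set (so each sums to 1) before the log2 ratio; perturbations
    failing coverage are flagged and carry no score, and covered
    perturbations with a zero on either side get an undefined (NaN) score.
    """
    p60 = p60_repr.reindex(tumour_repr.index)
    if p60.isna().any():
        raise ValueError("perturbation ids do not match between representations")
    n = len(tumour_repr)
    if min_coverage is None:
        min_coverage = 1.0 / (2 * n)
    covered = (tumour_repr >= min_coverage) | (p60 >= min_coverage)
    covered &= (tumour_repr > 0) | (p60 > 0)  # both-zero entries are excluded outright

    t = tumour_repr[covered]
    p = p60[covered]
    t = t / t.sum()
    p = p / p.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where((t > 0) & (p > 0), np.log2(t.to_numpy() / p.to_numpy()), np.nan)
    out = pd.DataFrame(
        {"tumour_fraction": tumour_repr, "p60_fraction": p60, "covered": covered}
    )
    out.loc[covered, "tumour_fraction_renorm"] = t
    out.loc[covered, "p60_fraction_renorm"] = p
    out.loc[covered, "selection_score"] = score
    return out
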