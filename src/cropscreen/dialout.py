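"""Guide capture from dial-out amplicon read pairs.

Read 1 of the amplicon carries three 9-nt cell-barcode sections (each drawn
from a 97-entry whitelist) and an 8-nt UMI at fixed offsets; Read 2 carries
the 20-nt protospacer of the captured sgRNA.  Decoding allows one mismatch
per barcode section (unambiguous when the whitelist has minimum pairwise
Hamming distance 3) and requires an exact protospacer match.  Reads collapse
to molecules by exact (cell, guide, UMI) deduplication, and each cell is
assigned its guide either uniquely or, when several guides are detected, only
if the top guide's UMI count strictly exceeds a high quantile of a reference
count distribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"

REJECT_REASONS = ("short_read", "bad_barcode_1", "bad_barcode_2", "bad_barcode_3", "bad_guide")


def hamming(a: str, b: str) -> int:
    """Hamming distance; any position containing N counts as a mismatch."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y or x == "N" or y == "N" for x, y in zip(a, b))


@dataclass(frozen=True)
class ReadLayout:
    """Positions of barcode sections, UMI and protospacer within a read pair.

    Offsets are 0-based.  The default mimics a bead design with three 9-nt
    sections separated by linkers (sections at 0, 21 and 43) followed by an
    8-nt UMI; the protospacer starts at the beginning of Read 2.
    """

    barcode_offsets: tuple[int, int, int] = (0, 21, 43)
    barcode_length: int = 9
    umi_offset: int = 52
    umi_length: int = 8
    protospacer_offset: int = 0
    protospacer_length: int = 20

    def __post_init__(self):
        segs = [(o, o + self.barcode_length) for o in self.barcode_offsets]
        segs.append((self.umi_offset, self.umi_offset + self.umi_length))
        if any(o < 0 for o, _ in segs) or self.protospacer_offset < 0:
            raise ValueError("offsets must be non-negative")
        for (a0, a1), (b0, b1) in itertools.combinations(segs, 2):
            if a0 < b1 and b0 < a1:
                raise ValueError("read 1 sections overlap")

    @property
    def min_read1_length(self) -> int:
        return max(
            max(o + self.barcode_length for o in self.barcode_offsets),
            self.umi_offset + self.umi_length,
        )

    @property
    def min_read2_length(self) -> int:
        return self.protospacer_offset + self.protospacer_length

    def to_dict(self) -> dict:
        return {
            "barcode_offsets": list(self.barcode_offsets),
            "barcode_length": self.barcode_length,
            "umi_offset": self.umi_offset,
            "umi_length": self.umi_length,
            "protospacer_offset": self.protospacer_offset,
            "protospacer_length": self.protospacer_length,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReadLayout":
        d = dict(d)
        d["barcode_offsets"] = tuple(d["barcode_offsets"])
        return cls(**d)


class BarcodeMatcher:
    """Decode observed barcodes against a whitelist, allowing one mismatch.

    Returns the index of the *unique* whitelist entry within Hamming distance
    1 of the observed sequence, or ``None`` when no entry or two or more
    entries lie within distance 1.  N bases count as mismatches, so a section
    with two or more Ns can never decode.
    """

    def __init__(self, whitelist: Sequence[str]):
        whitelist = list(whitelist)
        if not whitelist:
            raise ValueError("empty whitelist")
        self.length = len(whitelist[0])
        if any(len(b) != self.length for b in whitelist):
            raise ValueError("whitelist entries differ in length")
        self.whitelist = whitelist
        # map every sequence within distance <=1 of an entry to the set of
        # entry indices that close; a lookup hitting >1 index is ambiguous
        near: dict[str, set[int]] = {}
        for idx, bc in enumerate(whitelist):
            near.setdefault(bc, set()).add(idx)
            for pos in range(self.length):
                for base in BASES:
                    if base != bc[pos]:
                        variant = bc[:pos] + base + bc[pos + 1 :]
                        near.setdefault(variant, set()).add(idx)
        self._near = near

    def match(self, observed: str) -> int | None:
        if len(observed) != self.length:
            raise ValueError(f"observed barcode has length {len(observed)}, expected {self.length}")
        n_count = observed.count("N")
        if n_count == 0:
            hits = self._near.get(observed)
        elif n_count == 1:
            pos = observed.index("N")
            hits: set[int] = set()
            for base in BASES:
                cand = observed[:pos] + base + observed[pos + 1 :]
                # N is itself a mismatch, so only exact matches of the
                # substituted sequence stay within total distance 1
                for idx in self._near.get(cand, ()):  # pragma: no branch
                    if self.whitelist[idx] == cand:
                        hits.add(idx)
        else:
            return None
        if hits and len(hits) == 1:
            return next(iter(hits))
        return None


def match_barcode(observed: str, whitelist: Sequence[str]) -> int | None:
    """One-shot form of :class:`BarcodeMatcher` for a single query."""
    return BarcodeMatcher(whitelist).match(observed)


@dataclass
class RunSummary:
    """Tally of accepted and per-reason rejected reads for one parsing run."""

    n_reads: int = 0
    n_ok: int = 0
    rejects: dict = field(default_factory=lambda: {r: 0 for r in REJECT_REASONS})

    def to_dict(self) -> dict:
        return {"n_reads": self.n_reads, "n_ok": self.n_ok, "rejects": dict(self.rejects)}


def parse_read_pair(
    read1: str,
    read2: str,
    layout: ReadLayout,
    matchers: Sequence[BarcodeMatcher],
    guide_of_protospacer: Mapping[str, str],
):
    """Decode one read pair into ``(cell_id, umi, guide_id)`` or a reject reason.

    Returns ``("ok", (cell, umi, guide))`` on success, otherwise
    ``(reason, None)`` with reason one of :data:`REJECT_REASONS`.  The cell id
    is the concatenation of the three *decoded whitelist* sequences, not the
    observed ones.
    """
    if len(read1) < layout.min_read1_length or len(read2) < layout.min_read2_length:
        return "short_read", None
    decoded = []
    for section, (offset, matcher) in enumerate(zip(layout.barcode_offsets, matchers), start=1):
        observed = read1[offset : offset + layout.barcode_length]
        idx = matcher.match(observed)
        if idx is None:
            return f"bad_barcode_{section}", None
        decoded.append(matcher.whitelist[idx])
    proto = read2[layout.protospacer_offset : layout.protospacer_offset + layout.protospacer_length]
    guide = guide_of_protospacer.get(proto)
    if guide is None:
        return "bad_guide", None
    umi = read1[layout.umi_offset : layout.umi_offset + layout.umi_length]
    return "ok", ("".join(decoded), umi, guide)


def parse_read_pairs(
    pairs: Iterable[tuple[str, str]],
    layout: ReadLayout,
    whitelists: Sequence[Sequence[str]],
    guide_of_protospacer: Mapping[str, str],
) -> tuple[pd.DataFrame, RunSummary]:
    """Parse a stream of ``(read1_seq, read2_seq)`` pairs.

    Returns the accepted records as a DataFrame with columns
    ``cell_id, umi, guide_id`` and a :class:`RunSummary` of reject tallies.
    """
    if len(whitelists) != 3:
        raise ValueError("expected three section whitelists")
    matchers = [BarcodeMatcher(wl) for wl in whitelists]
    summary = RunSummary()
    rows = []
    for read1, read2 in pairs:
        summary.n_reads += 1
        status, payload = parse_read_pair(read1, read2, layout, matchers, guide_of_protospacer)
        if status == "ok":
            summary.n_ok += 1
            rows.append(payload)
        else:
            summary.rejects[status] += 1
    records = pd.DataFrame(rows, columns=["cell_id", "umi", "guide_id"])
    return records, summary


def dedup_and_count(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse identical (cell, guide, UMI) triples and count distinct UMIs.

    Parameters
    ----------
    records
        DataFrame with columns ``cell_id, umi, guide_id`` (one row per read).

    Returns
    -------
    Long-form guide count matrix with columns ``cell_id, guide_id, umi_count``.
    """
    required = {"cell_id", "umi", "guide_id"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    if records.empty:
        return pd.DataFrame(columns=["cell_id", "guide_id", "umi_count"])
    dedup = records.drop_duplicates(["cell_id", "guide_id", "umi"])
    counts = (
        dedup.groupby(["cell_id", "guide_id"], sort=True)
        .size()
        .rename("umi_count")
        .reset_index()
    )
    return counts


def counts_to_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long-form count table into a cells x guides matrix."""
    return counts.pivot_table(
        index="cell_id", columns="guide_id", values="umi_count", fill_value=0
    ).astype(int)


def assign_guides(
    counts: pd.DataFrame, q: float = 0.99, strategy: str = "global"
) -> pd.DataFrame:
    """Assign each cell to at most one guide.

    Cells with a single detected guide are assigned to it.  For cells with two
    or more guides, the top guide is assigned only if its UMI count *strictly*
    exceeds the ``q``-quantile of a reference distribution; ties for the top
    guide are never assigned.

    ``strategy`` selects the reference distribution:

    - ``"global"`` (default): all per-(cell, guide) UMI counts in the dataset;
    - ``"competing"``: the non-top (losing) guide counts pooled over all
      multi-guide cells.

    Returns a cell table with columns
    ``cell_id, guide_id, umi_count, n_guides_detected`` where unassigned
    cells carry a missing ``guide_id``.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if strategy not in ("global", "competing"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if counts.empty:
        raise ValueError("empty guide count matrix")

    top = (
        counts.sort_values(["cell_id", "umi_count", "guide_id"], ascending=[True, False, True])
        .groupby("cell_id", sort=True)
        .agg(
            guide_id=("guide_id", "first"),
            umi_count=("umi_count", "first"),
            n_guides_detected=("guide_id", "size"),
            max_count=("umi_count", "max"),
            n_at_max=("umi_count", lambda s: int((s == s.max()).sum())),
        )
        .reset_index()
    )

    if strategy == "global":
        reference = counts["umi_count"].to_numpy()
    else:
        multi = counts.merge(top[["cell_id", "n_guides_detected"]], on="cell_id")
        multi = multi[multi["n_guides_detected"] >= 2]
        losing = multi.sort_values("umi_count", ascending=False).groupby("cell_id").apply(
            lambda df: df["umi_count"].iloc[1:], include_groups=False
        )
        reference = np.asarray(losing.to_numpy() if len(losing) else [0], dtype=float)
    threshold = float(np.quantile(reference, q))

    multi_mask = top["n_guides_detected"] >= 2
    tie_mask = top["n_at_max"] >= 2
    fail_quantile = multi_mask & (top["umi_count"] <= threshold)
    unassigned = (multi_mask & tie_mask) | fail_quantile
    top.loc[unassigned, "guide_id"] = pd.NA
    return top[["cell_id", "guide_id", "umi_count", "n_guides_detected"]]


def process_dialout(
    pairs: Iterable[tuple[str, str]],
    layout: ReadLayout,
    whitelists: Sequence[Sequence[str]],
    guide_of_protospacer: Mapping[str, str],
    q: float = 0.99,
    strategy: str = "global",
):
    """Full dial-out chain: parse, deduplicate, assign.

    Returns ``(cell_table, counts, summary)``.
    """
    records, summary = parse_read_pairs(pairs, layout, whitelists, guide_of_protospacer)
    counts = dedup_and_count(records)
    cells = assign_guides(counts, q=q, strategy=strategy) if not counts.empty else pd.DataFrame(
        columns=["cell_id", "guide_id", "umi_count", "n_guides_detected"]
    )
    return cells, counts, summary
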