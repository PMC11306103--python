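"""Synthetic screens with planted ground truth.

Generates every input the analysis chain consumes: a guide library
(by default 150 genes x 3 guides + 50 non-targeting controls = 500 guides)
with log-normal T0 plasmid-batch abundances, per-sample cell-to-guide
assignments with planted per-gene expansion fold changes, dial-out amplicon
read pairs with barcode/UMI structure and substitution errors, expression
count matrices with planted module-gene shifts, and per-tumour amplicon
counts with planted selection effects.

All generators take explicit seeds and are deterministic; the planted
effects live in :class:`PlantedTruth` so downstream recovery can be tested.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cropscreen.dialout import BASES, ReadLayout, hamming

# ---------------------------------------------------------------------------
# Library


@dataclass(frozen=True)
class LibrarySpec:
    """Shape of the guide library.

    Defaults describe a 500-guide screen: 150 target genes with 3 guides
    each plus 50 non-targeting controls, with three independently prepared
    T0 plasmid batches.
    """

    n_genes: int = 150
    guides_per_gene: int = 3
    n_controls: int = 50
    t0_batches: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 0 or self.guides_per_gene < 1 or self.n_controls < 0:
            raise ValueError("library counts must be positive")
        if self.t0_batches < 1:
            raise ValueError("need at least one T0 batch")
        if self.n_genes * self.guides_per_gene + self.n_controls < 1:
            raise ValueError("library would be empty")

    @property
    def n_guides(self) -> int:
        return self.n_genes * self.guides_per_gene + self.n_controls


@dataclass
class GuideLibrary:
    """Guide library plus its T0 batch counts.

    ``guides`` columns: ``guide_id, gene, protospacer, is_control,
    control_index`` (1-based for controls, <NA> otherwise).
    ``t0_counts`` columns: ``guide_id, batch, count``.
    """

    guides: pd.DataFrame
    t0_counts: pd.DataFrame

    def __post_init__(self):
        if self.guides["protospacer"].duplicated().any():
            raise ValueError("protospacers must be unique")
        if self.guides["guide_id"].duplicated().any():
            raise ValueError("guide ids must be unique")

    @property
    def n_guides(self) -> int:
        return len(self.guides)

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self.guides["guide_id"])

    @property
    def target_genes(self) -> list[str]:
        return list(dict.fromkeys(self.guides.loc[~self.guides["is_control"], "gene"]))

    @property
    def batches(self) -> list[int]:
        return sorted(self.t0_counts["batch"].unique())

    def protospacer_to_guide(self) -> dict[str, str]:
        return dict(zip(self.guides["protospacer"], self.guides["guide_id"]))

    def perturbation_map(self, group_size: int = 3) -> pd.Series:
        """Map each guide to its perturbation unit.

        Targeting guides map to their gene symbol; control guides are grouped
        by ascending control index into consecutive pseudo-triplets named
        ``ctrl_1, ctrl_2, ...`` (the final group may have fewer members).
        """
        pert = []
        for _, row in self.guides.iterrows():
            if row["is_control"]:
                pert.append(f"ctrl_{(int(row['control_index']) - 1) // group_size + 1}")
            else:
                pert.append(row["gene"])
        return pd.Series(pert, index=self.guides["guide_id"].to_numpy(), name="perturbation")

    @property
    def perturbations(self) -> list[str]:
        seen = dict.fromkeys(self.perturbation_map())
        return list(seen)

    def t0_for_batch(self, batch: int) -> pd.Series:
        sub = self.t0_counts[self.t0_counts["batch"] == batch]
        if sub.empty:
            raise KeyError(f"no T0 counts for batch {batch}")
        return sub.set_index("guide_id")["count"].reindex(self.guides["guide_id"].to_numpy())

    def control_guide_ids(self) -> list[str]:
        return list(self.guides.loc[self.guides["is_control"], "guide_id"])


def _random_kmers(rng: np.random.Generator, n: int, k: int, max_tries: int = 50) -> list[str]:
    """Draw n unique k-mers, retrying bounded-many times on collisions."""
    kmers: dict[str, None] = {}
    for _ in range(max_tries):
        need = n - len(kmers)
        if need == 0:
            break
        draws = rng.integers(0, 4, size=(need, k))
        for row in draws:
            kmers.setdefault("".join(BASES[i] for i in row), None)
    if len(kmers) < n:
        raise RuntimeError("failed to generate unique sequences after bounded retries")
    return list(kmers)[:n]


def make_library(spec: LibrarySpec, t0_sigma: float = 0.5, t0_mean: float = 1000.0) -> GuideLibrary:
    """Build a guide library with unique 20-nt protospacers and T0 counts.

    T0 counts per batch are drawn log-normal around ``t0_mean`` with
    log-scale standard deviation ``t0_sigma`` (``t0_sigma=0`` gives equal
    counts within each batch), rounded and clipped to be strictly positive.
    """
    rng = np.random.default_rng(spec.seed)
    protospacers = _random_kmers(rng, spec.n_guides, 20)
    rows = []
    i = 0
    for g in range(spec.n_genes):
        gene = f"gene{g + 1:03d}"
        for k in range(spec.guides_per_gene):
            rows.append((f"{gene}_sg{k + 1}", gene, protospacers[i], False, pd.NA))
            i += 1
    for c in range(spec.n_controls):
        rows.append((f"ctrl_sg{c + 1:02d}", "control", protospacers[i], True, c + 1))
        i += 1
    guides = pd.DataFrame(
        rows, columns=["guide_id", "gene", "protospacer", "is_control", "control_index"]
    )

    t0_rows = []
    for batch in range(1, spec.t0_batches + 1):
        draws = t0_mean * np.exp(rng.normal(0.0, t0_sigma, size=spec.n_guides) if t0_sigma > 0
                                 else np.zeros(spec.n_guides))
        counts = np.maximum(np.rint(draws).astype(int), 1)
        t0_rows.append(pd.DataFrame({
            "guide_id": guides["guide_id"], "batch": batch, "count": counts,
        }))
    return GuideLibrary(guides=guides, t0_counts=pd.concat(t0_rows, ignore_index=True))


# ---------------------------------------------------------------------------
# Planted truth


@dataclass
class PlantedTruth:
    """Ground-truth effects planted into a synthetic screen.

    All effect tables are indexed by target gene; control pseudo-genes have
    no entries, i.e. all their effects are zero by construction.
    """

    expansion_log2fc: pd.Series
    module_effects: pd.DataFrame
    selection_log2fc: pd.Series
    barcode_error_rate: float = 0.0
    multiplet_rate: float = 0.0

    def __post_init__(self):
        for p, name in ((self.barcode_error_rate, "barcode_error_rate"),
                        (self.multiplet_rate, "multiplet_rate")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def null(cls, library: GuideLibrary, modules: Sequence[str] = ()) -> "PlantedTruth":
        genes = library.target_genes
        return cls(
            expansion_log2fc=pd.Series(0.0, index=genes),
            module_effects=pd.DataFrame(0.0, index=genes, columns=list(modules)),
            selection_log2fc=pd.Series(0.0, index=genes),
        )

    def expansion_multiplier(self, library: GuideLibrary) -> np.ndarray:
        """Per-guide 2**log2FC multiplier in library guide order (controls: 1)."""
        return self._guide_multiplier(library, self.expansion_log2fc)

    def selection_multiplier(self, library: GuideLibrary) -> np.ndarray:
        return self._guide_multiplier(library, self.selection_log2fc)

    def _guide_multiplier(self, library: GuideLibrary, log2fc: pd.Series) -> np.ndarray:
        eff = library.guides["gene"].map(log2fc).fillna(0.0).to_numpy(float)
        return np.exp2(eff)


# ---------------------------------------------------------------------------
# Whitelists


def generate_whitelist(
    n: int = 97, length: int = 9, min_dist: int = 3, seed: int = 0, max_tries: int = 200_000
) -> list[str]:
    """Random-search a barcode whitelist with guaranteed min pairwise distance.

    With ``min_dist=3`` any observed sequence lies within Hamming distance 1
    of at most one entry, so one-mismatch decoding is unambiguous.
    """
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    for _ in range(max_tries):
        cand = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
        if all(hamming(cand, bc) >= min_dist for bc in accepted):
            accepted.append(cand)
            if len(accepted) == n:
                return accepted
    raise RuntimeError(f"could not build a {n}-entry whitelist in {max_tries} tries")


def make_whitelists(seed: int = 0, n: int = 97, length: int = 9) -> list[list[str]]:
    """Three section whitelists (Read 1 carries three barcode sections)."""
    return [generate_whitelist(n=n, length=length, seed=seed + section) for section in range(3)]


def _check_whitelists(whitelists: Sequence[Sequence[str]], min_dist: int = 3) -> None:
    for wl in whitelists:
        wl = list(wl)
        for i in range(len(wl)):
            for j in range(i + 1, len(wl)):
                if hamming(wl[i], wl[j]) < min_dist:
                    raise ValueError(
                        f"whitelist pair {wl[i]}/{wl[j]} closer than Hamming {min_dist}"
                    )


# ---------------------------------------------------------------------------
# Screen simulation


def simulate_screen(
    library: GuideLibrary,
    truth: PlantedTruth,
    n_cells_per_sample: int,
    n_samples: int,
    seed: int = 0,
    multiplet_rate: float | None = None,
) -> pd.DataFrame:
    """Draw true cell-to-guide assignments for replicate samples.

    Each sample is paired round-robin with a T0 batch; cell counts per guide
    follow a multinomial with probabilities proportional to the batch T0
    proportions times ``2**planted_log2FC``, renormalized.  A configurable
    fraction of cells carries a second, distinct guide (multiplets).

    Returns a long DataFrame ``cell_id, guide_id, sample, batch`` in which
    multiplet cells appear on two rows.
    """
    if library.n_guides == 0:
        raise ValueError("empty library")
    if n_cells_per_sample < 1 or n_samples < 1:
        raise ValueError("need at least one cell and one sample")
    rate = truth.multiplet_rate if multiplet_rate is None else multiplet_rate
    rng = np.random.default_rng(seed)
    guide_ids = library.guides["guide_id"].to_numpy()
    mult = truth.expansion_multiplier(library)
    batches = library.batches
    frames = []
    for s in range(n_samples):
        batch = batches[s % len(batches)]
        t0 = library.t0_for_batch(batch).to_numpy(float)
        probs = t0 / t0.sum() * mult
        probs /= probs.sum()
        choice = rng.choice(library.n_guides, size=n_cells_per_sample, p=probs)
        sample = f"S{s + 1}"
        cells = np.array([f"{sample}_c{i:06d}" for i in range(n_cells_per_sample)])
        frames.append(pd.DataFrame({
            "cell_id": cells, "guide_id": guide_ids[choice], "sample": sample, "batch": batch,
        }))
        if rate > 0:
            multi = np.flatnonzero(rng.random(n_cells_per_sample) < rate)
            second = rng.choice(library.n_guides, size=len(multi), p=probs)
            for _ in range(10):  # redraw collisions so the two guides differ
                clash = second == choice[multi]
                if not clash.any():
                    break
                second[clash] = rng.choice(library.n_guides, size=clash.sum(), p=probs)
            keep = second != choice[multi]
            frames.append(pd.DataFrame({
                "cell_id": cells[multi[keep]], "guide_id": guide_ids[second[keep]],
                "sample": sample, "batch": batch,
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Dial-out reads


@dataclass
class DialoutReads:
    """Simulated read pairs plus the planted truth they encode."""

    r1: list  # (read_id, sequence)
    r2: list
    truth: pd.DataFrame  # read_id, cell_id, umi, guide_id
    cell_barcodes: pd.DataFrame  # cell_id, bc1, bc2, bc3
    layout: ReadLayout = field(default_factory=ReadLayout)

    def molecule_table(self) -> pd.DataFrame:
        """Distinct planted (cell, guide, UMI) molecules."""
        return self.truth.drop_duplicates(["cell_id", "guide_id", "umi"])[
            ["cell_id", "guide_id", "umi"]
        ].reset_index(drop=True)


def _inject_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for pos in hits:
        alternatives = [b for b in BASES if b != arr[pos]]
        arr[pos] = alternatives[rng.integers(0, 3)]
    return "".join(arr)


def simulate_dialout_reads(
    assignments: pd.DataFrame,
    library: GuideLibrary,
    whitelists: Sequence[Sequence[str]] | None = None,
    layout: ReadLayout | None = None,
    error_rate: float = 0.0,
    reads_per_cell_guide: int = 3,
    seed: int = 0,
) -> DialoutReads:
    """Emit dial-out amplicon read pairs for true cell-guide assignments.

    Read 1 carries the cell's three 9-nt section barcodes and an 8-nt UMI at
    the layout offsets (linker gaps filled with a fixed spacer sequence);
    Read 2 carries the guide's 20-nt protospacer.  Substitution errors are
    injected per base at ``error_rate`` on both reads.  The planted
    (cell, guide, UMI) table is returned alongside the reads.
    """
    layout = layout or ReadLayout()
    if whitelists is None:
        whitelists = make_whitelists(seed=seed)
    _check_whitelists(whitelists)
    rng = np.random.default_rng(seed + 1)

    cells = pd.unique(assignments["cell_id"])
    n_wl = len(whitelists[0])
    triples: dict[tuple, None] = {}
    while len(triples) < len(cells):
        need = len(cells) - len(triples)
        draws = rng.integers(0, n_wl, size=(need, 3))
        for row in draws:
            triples.setdefault(tuple(row), None)
    triple_list = list(triples)[: len(cells)]
    cell_bc = pd.DataFrame(
        {
            "cell_id": cells,
            "bc1": [whitelists[0][t[0]] for t in triple_list],
            "bc2": [whitelists[1][t[1]] for t in triple_list],
            "bc3": [whitelists[2][t[2]] for t in triple_list],
        }
    )
    bc_of_cell = cell_bc.set_index("cell_id")

    spacer_len = layout.min_read1_length
    spacer = "".join(BASES[i] for i in np.random.default_rng(seed + 2).integers(0, 4, spacer_len))
    r2_template = list(spacer[: layout.min_read2_length].ljust(layout.min_read2_length, "A"))

    proto_of_guide = library.guides.set_index("guide_id")["protospacer"]
    r1, r2, truth_rows = [], [], []
    ridx = 0
    for _, row in assignments.iterrows():
        bcs = bc_of_cell.loc[row["cell_id"]]
        proto = proto_of_guide[row["guide_id"]]
        for _ in range(reads_per_cell_guide):
            umi = "".join(BASES[i] for i in rng.integers(0, 4, size=layout.umi_length))
            read1 = list(spacer)
            for offset, bc in zip(layout.barcode_offsets, (bcs["bc1"], bcs["bc2"], bcs["bc3"])):
                read1[offset : offset + layout.barcode_length] = bc
            read1[layout.umi_offset : layout.umi_offset + layout.umi_length] = umi
            read2 = list(r2_template)
            read2[layout.protospacer_offset : layout.protospacer_offset + layout.protospacer_length] = proto
            read_id = f"r{ridx:07d}"
            ridx += 1
            r1.append((read_id, _inject_errors("".join(read1), rng, error_rate)))
            r2.append((read_id, _inject_errors("".join(read2), rng, error_rate)))
            truth_rows.append((read_id, row["cell_id"], umi, row["guide_id"]))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "cell_id", "umi", "guide_id"])
    return DialoutReads(r1=r1, r2=r2, truth=truth, cell_barcodes=cell_bc, layout=layout)


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    assignments: pd.DataFrame,
    modules: Mapping[str, Sequence[str]],
    truth: PlantedTruth,
    n_genes_total: int = 200,
    seed: int = 0,
    dispersion: float = 0.3,
    base_mean_sigma: float = 0.7,
    cell_type_props: Mapping[str, float] | None = None,
    phase_props: Mapping[str, float] | None = None,
    n_cycle_markers: int = 40,
    cycle_marker_fold: float = 4.0,
):
    """Negative-binomial expression counts with planted module shifts.

    Cells whose perturbation carries a planted module effect delta have the
    means of that module's genes scaled by ``2**delta``.  Cell-type and
    cell-cycle labels are drawn from the configured proportions, and
    dedicated S / G2M marker genes are elevated ``cycle_marker_fold``-fold in
    cycling cells.  ``dispersion=0`` gives pure Poisson counts.

    Returns an :class:`anndata.AnnData` (cells x genes, raw counts in ``X``)
    with obs columns ``guide_id, perturbation, sample, cell_type, phase`` and
    marker/module definitions in ``uns``.
    """
    import anndata as ad

    rng = np.random.default_rng(seed)
    for name, genes in modules.items():
        if len(set(genes)) < 2:
            warnings.warn(f"module {name!r} has fewer than 2 genes")

    s_genes = [f"S_mk{i + 1}" for i in range(n_cycle_markers)]
    g2m_genes = [f"G2M_mk{i + 1}" for i in range(n_cycle_markers)]
    module_genes = list(dict.fromkeys(g for genes in modules.values() for g in genes))
    fixed = module_genes + s_genes + g2m_genes
    if n_genes_total < len(fixed):
        raise ValueError(f"n_genes_total must be >= {len(fixed)} to hold modules and markers")
    fillers = [f"filler_g{i + 1:04d}" for i in range(n_genes_total - len(fixed))]
    genes = fixed + fillers
    gene_idx = {g: i for i, g in enumerate(genes)}

    cell_type_props = dict(cell_type_props or {
        "EpSC": 0.45, "suprabasal": 0.25, "hair_follicle": 0.12,
        "sebaceous": 0.05, "T_cell": 0.07, "macrophage": 0.06,
    })
    phase_props = dict(phase_props or {"G1": 0.70, "S": 0.15, "G2M": 0.15})

    # one row per cell; multiplet cells keep their first guide for labelling
    per_cell = assignments.drop_duplicates("cell_id").reset_index(drop=True)
    pert_of_guide = library_free_perturbations(per_cell["guide_id"])
    n_cells = len(per_cell)

    base_mean = np.exp(rng.normal(0.0, base_mean_sigma, size=len(genes)))
    means = np.tile(base_mean, (n_cells, 1))

    if not truth.module_effects.empty:
        for mod_name, mod_genes in modules.items():
            if mod_name not in truth.module_effects.columns:
                continue
            cols = [gene_idx[g] for g in mod_genes]
            delta = per_cell["guide_id"].map(
                lambda gid: _gene_of_guide(gid)
            ).map(truth.module_effects[mod_name]).fillna(0.0).to_numpy(float)
            means[:, cols] *= np.exp2(delta)[:, None]

    cell_types = rng.choice(
        list(cell_type_props), size=n_cells,
        p=np.asarray(list(cell_type_props.values())) / sum(cell_type_props.values()),
    )
    phases = rng.choice(
        list(phase_props), size=n_cells,
        p=np.asarray(list(phase_props.values())) / sum(phase_props.values()),
    )
    s_cols = [gene_idx[g] for g in s_genes]
    g2m_cols = [gene_idx[g] for g in g2m_genes]
    means[np.ix_(phases == "S", s_cols)] *= cycle_marker_fold
    means[np.ix_(phases == "G2M", g2m_cols)] *= cycle_marker_fold

    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=means * dispersion)
    else:
        lam = means
    counts = rng.poisson(lam).astype(np.int32)

    obs = pd.DataFrame(
        {
            "guide_id": per_cell["guide_id"].to_numpy(),
            "perturbation": pert_of_guide.to_numpy(),
            "sample": per_cell["sample"].to_numpy(),
            "cell_type": cell_types,
            "phase": phases,
        },
        index=per_cell["cell_id"].to_numpy(),
    )
    adata = ad.AnnData(X=counts, obs=obs, var=pd.DataFrame(index=genes))
    adata.uns["modules"] = {k: list(v) for k, v in modules.items()}
    adata.uns["s_genes"] = s_genes
    adata.uns["g2m_genes"] = g2m_genes
    return adata


def _gene_of_guide(guide_id: str) -> str:
    """Perturbation unit of a guide id as produced by :func:`make_library`."""
    if guide_id.startswith("ctrl_sg"):
        idx = int(guide_id.removeprefix("ctrl_sg"))
        return f"ctrl_{(idx - 1) // 3 + 1}"
    return guide_id.rsplit("_sg", 1)[0]


def library_free_perturbations(guide_ids: pd.Series) -> pd.Series:
    """Perturbation labels derived from guide-id naming conventions alone."""
    return guide_ids.map(_gene_of_guide)


# ---------------------------------------------------------------------------
# Tumours


def simulate_tumours(
    p60_representation: pd.Series,
    library: GuideLibrary,
    truth: PlantedTruth,
    n_tumours: int,
    reads_per_tumour: int = 50_000,
    seed: int = 0,
    dominant_clone: bool = False,
    dominant_share: float = 0.85,
) -> pd.DataFrame:
    """Per-tumour guide read counts with planted selection effects.

    Each tumour draws reads multinomially from the P60 guide proportions
    scaled by ``2**selection_log2fc`` and renormalized.  In dominant-clone
    mode a single guide (drawn from the same probabilities) takes
    ``dominant_share`` of each tumour's reads, emulating clonal tumours.
    """
    if n_tumours < 1:
        raise ValueError("n_tumours must be >= 1")
    repr_ = p60_representation.reindex(library.guides["guide_id"].to_numpy()).fillna(0.0)
    total = float(repr_.sum())
    if not math.isclose(total, 1.0, rel_tol=1e-6):
        raise ValueError("p60 representation must sum to 1")
    rng = np.random.default_rng(seed)
    probs = repr_.to_numpy(float) * truth.selection_multiplier(library)
    probs /= probs.sum()
    rows = []
    for t in range(n_tumours):
        if dominant_clone:
            g = rng.choice(len(probs), p=probs)
            n_dom = int(round(dominant_share * reads_per_tumour))
            counts = rng.multinomial(reads_per_tumour - n_dom, probs)
            counts[g] += n_dom
        else:
            counts = rng.multinomial(reads_per_tumour, probs)
        rows.append(counts)
    return pd.DataFrame(rows, index=[f"tumour{t + 1:03d}" for t in range(n_tumours)],
                        columns=library.guides["guide_id"].to_numpy())


def simulate_tumour_reads(
    tumour_counts: pd.DataFrame,
    library: GuideLibrary,
    read_length: int = 64,
    seed: int = 0,
    error_rate: float = 0.0,
) -> dict[str, list[str]]:
    """Amplicon reads per tumour, each embedding its guide's protospacer."""
    rng = np.random.default_rng(seed)
    proto = library.guides.set_index("guide_id")["protospacer"]
    plen = len(proto.iloc[0])
    if read_length < plen:
        raise ValueError("read_length shorter than protospacer")
    out: dict[str, list[str]] = {}
    for tumour, row in tumour_counts.iterrows():
        reads = []
        for guide_id, n in row.items():
            p = proto[guide_id]
            for _ in range(int(n)):
                offset = int(rng.integers(0, read_length - plen + 1))
                flank = "".join(BASES[i] for i in rng.integers(0, 4, size=read_length))
                read = flank[:offset] + p + flank[offset + plen :]
                reads.append(_inject_errors(read, rng, error_rate))
        rng.shuffle(reads)
        out[str(tumour)] = reads
    return out
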