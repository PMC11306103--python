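"""Plain-text I/O helpers: FASTQ, TSV tables, MTX matrices, YAML layouts."""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield ``(read_id, sequence)`` pairs from a (optionally gzipped) FASTQ."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield rec.id, str(rec.seq)


def write_fastq(records: Iterable[tuple[str, str]], path) -> int:
    """Write ``(read_id, sequence)`` pairs as FASTQ with constant 'I' quality."""
    n = 0
    with _open_text(path, "wt") as handle:
        for read_id, seq in records:
            rec = SeqRecord(Seq(seq), id=read_id, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            SeqIO.write(rec, handle, "fastq")
            n += 1
    return n


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path, index=False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh)


def write_library(library, guides_path, t0_path) -> None:
    write_tsv(library.guides, guides_path)
    write_tsv(library.t0_counts, t0_path)


def read_library(guides_path, t0_path):
    from cropscreen.synth import GuideLibrary

    guides = read_tsv(guides_path)
    guides["is_control"] = guides["is_control"].astype(bool)
    guides["control_index"] = guides["control_index"].astype("Int64")
    return GuideLibrary(guides=guides, t0_counts=read_tsv(t0_path))


def write_whitelists(whitelists, path) -> None:
    rows = [
        {"section": i + 1, "barcode": bc}
        for i, wl in enumerate(whitelists)
        for bc in wl
    ]
    write_tsv(pd.DataFrame(rows), path)


def read_whitelists(path) -> list[list[str]]:
    df = read_tsv(path)
    return [list(df.loc[df["section"] == s, "barcode"]) for s in sorted(df["section"].unique())]


def write_count_matrix(counts: pd.DataFrame, prefix) -> None:
    """Write a cells x guides (or tumours x guides) count table as MTX + axis TSVs."""
    from scipy import io as spio
    from scipy import sparse

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(prefix) + ".mtx", sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index, name="row").to_csv(str(prefix) + ".rows.tsv", sep="\t", index=False)
    pd.Series(counts.columns, name="col").to_csv(str(prefix) + ".cols.tsv", sep="\t", index=False)


def read_count_matrix(prefix) -> pd.DataFrame:
    from scipy import io as spio

    prefix = str(prefix)
    mat = spio.mmread(prefix + ".mtx").toarray()
    rows = pd.read_csv(prefix + ".rows.tsv", sep="\t")["row"]
    cols = pd.read_csv(prefix + ".cols.tsv", sep="\t")["col"]
    return pd.DataFrame(mat, index=rows.to_numpy(), columns=cols.to_numpy())
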