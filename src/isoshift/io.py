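"""Readers and writers for the pipeline's on-disk formats.

All tabular formats are plain TSV; region coordinates use a single internal
convention (0-based, half-open, BED-style), with GFF3 (1-based, inclusive)
converted at the boundary.  Writers can stamp a ``# config_hash=...`` comment
line; readers skip ``#`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "write_tpm",
    "read_tpm",
    "write_bed",
    "read_bed",
    "read_gff3_regions",
    "write_fasta",
    "read_fasta",
    "write_regions",
    "read_regions",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def _open_write(path, header_hash=None):
    fh = open(path, "w")
    if header_hash is not None:
        fh.write(f"# config_hash={header_hash}\n")
    return fh


def write_table(df: pd.DataFrame, path, *, index: bool = False,
                header_hash: str | None = None) -> None:
    with _open_write(path, header_hash) as fh:
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_tpm(quant: pd.DataFrame, path, header_hash: str | None = None) -> None:
    """TPM matrix: rows = isoforms, a gene_id column, one column per sample."""
    with _open_write(path, header_hash) as fh:
        quant.to_csv(fh, sep="\t", index=True)


def read_tpm(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: TPM matrix must carry a gene_id column")
    return df


def write_bed(df: pd.DataFrame, path, header_hash: str | None = None) -> None:
    """BED6, 0-based half-open."""
    out = df[BED_COLUMNS]
    _validate_coords(out, str(path))
    with _open_write(path, header_hash) as fh:
        out.to_csv(fh, sep="\t", index=False, header=False)


def _validate_coords(df: pd.DataFrame, origin: str) -> None:
    bad = df.index[(df["start"] < 0) | (df["end"] <= df["start"])]
    if len(bad):
        raise ValueError(f"{origin}: coordinate out of range at row(s) {list(bad[:5])}")
    if not df["strand"].isin(["+", "-", "."]).all():
        raise ValueError(f"{origin}: invalid strand value")


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BED fields")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]),
                             parts[3], parts[4], parts[5]))
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed BED line ({err})") from None
    df = pd.DataFrame(rows, columns=BED_COLUMNS)
    df["score"] = pd.to_numeric(df["score"], errors="coerce").fillna(0)
    _validate_coords(df, str(path))
    return df


def read_gff3_regions(path) -> pd.DataFrame:
    """GFF3 features as 0-based half-open regions.

    GFF3 is 1-based inclusive: start=101, end=200 becomes internal
    (100, 200).  The feature ID attribute (or Name) becomes ``name``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 fields")
            chrom, _source, ftype, start, end, score, strand, _phase, attrs = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start_i < 1 or end_i < start_i:
                raise ValueError(f"{path}:{lineno}: coordinate out of range")
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            name = attr.get("ID", attr.get("Name", f"feature_{lineno}"))
            rows.append((chrom, start_i - 1, end_i, name,
                         0 if score == "." else score, strand, ftype))
    df = pd.DataFrame(rows, columns=BED_COLUMNS + ["feature_type"])
    if df["name"].duplicated().any():
        dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    return df


def write_fasta(records: dict[str, str], path) -> None:
    seqrecs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_regions(regions: pd.DataFrame, prefix, header_hash: str | None = None) -> None:
    """UTR region set -> FASTA (core+extension sequences) + BED + class TSV."""
    prefix = Path(prefix)
    fasta = {}
    bed_rows = []
    for rec in regions.itertuples(index=False):
        fasta[f"{rec.event_id}|core"] = rec.core_seq
        fasta[f"{rec.event_id}|ext"] = rec.ext_seq
        bed_rows.append((rec.chrom, rec.core_start, rec.core_end,
                         f"{rec.event_id}|core", 0, rec.strand))
        if rec.ext_end > rec.ext_start:
            bed_rows.append((rec.chrom, rec.ext_start, rec.ext_end,
                             f"{rec.event_id}|ext", 0, rec.strand))
    write_fasta(fasta, prefix.with_suffix(".fasta"))
    write_bed(pd.DataFrame(bed_rows, columns=BED_COLUMNS), prefix.with_suffix(".bed"),
              header_hash)
    write_table(regions.drop(columns=["core_seq", "ext_seq"]),
                prefix.with_suffix(".classes.tsv"), header_hash=header_hash)


def read_regions(prefix) -> pd.DataFrame:
    prefix = Path(prefix)
    seqs = read_fasta(prefix.with_suffix(".fasta"))
    classes = read_table(prefix.with_suffix(".classes.tsv"))
    classes["core_seq"] = [seqs.get(f"{e}|core", "") for e in classes["event_id"]]
    classes["ext_seq"] = [seqs.get(f"{e}|ext", "") for e in classes["event_id"]]
    return classes
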