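"""Readers and writers for the plain-text formats the pipeline consumes.

Coordinate conventions
----------------------
Annotations are held internally as 0-based half-open intervals.  BED is read
and written as-is (it is already 0-based half-open); GFF3 is converted on the
way in (1-based closed -> 0-based half-open) and back on the way out.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ANNOTATION_COLUMNS = ["mirna_id", "chrom", "start", "end", "strand"]


class FormatError(ValueError):
    """Raised for malformed input files; carries the offending line number."""


# ---------------------------------------------------------------------------
# annotation: BED6 / GFF3
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file (>=4 columns) into an annotation frame.

    Columns used: chrom, start, end, name, [score], [strand].  Coordinates
    stay 0-based half-open.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: BED line has {len(fields)} fields, need >=4")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            strand = fields[5] if len(fields) >= 6 else "."
            rows.append((fields[3], fields[0], start, end, strand))
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_bed(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write an annotation frame as BED6 (score column fixed at 0)."""
    with open(path, "w") as fh:
        for row in annotation.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.mirna_id}\t0\t{row.strand}\n")


def read_gff3(path: str | Path, feature_types: set[str] | None = None) -> pd.DataFrame:
    """Read a GFF3 file, converting to the internal 0-based half-open frame.

    The feature id is taken from the ``ID`` (or ``Name``) attribute.
    ``feature_types`` optionally restricts which rows are kept.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 line has {len(fields)} fields, need 9")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if feature_types is not None and ftype not in feature_types:
                continue
            try:
                start1, end1 = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start1 < 1 or end1 < start1:
                raise FormatError(f"{path}:{lineno}: bad GFF3 interval {start1}-{end1}")
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    key, val = item.split("=", 1)
                    attr_map[key.strip()] = val.strip()
            name = attr_map.get("ID") or attr_map.get("Name")
            if not name:
                raise FormatError(f"{path}:{lineno}: no ID/Name attribute")
            rows.append((name, chrom, start1 - 1, end1, strand))
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_gff3(annotation: pd.DataFrame, path: str | Path, feature_type: str = "miRNA") -> None:
    """Write an annotation frame as GFF3 (converting back to 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t.\t{feature_type}\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.mirna_id}\n"
            )


def read_annotation(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Dispatch on ``format`` ('bed' or 'gff3'), inferring from the suffix if None."""
    if format is None:
        suffix = Path(path).suffix.lower()
        format = {"bed": "bed", "gff": "gff3", "gff3": "gff3"}.get(suffix.lstrip("."))
        if format is None:
            raise ValueError(f"cannot infer annotation format from {path!r}")
    if format == "bed":
        return read_bed(path)
    if format == "gff3":
        return read_gff3(path)
    raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# counts / samples / generic TSV
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a miRNA x sample count matrix (first column = miRNA id)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "mirna_id"
    return counts


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="mirna_id")


def read_samples(path: str | Path) -> pd.Series:
    """Read a two-column samples table (sample_id, group) into a Series."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise FormatError(f"{path}: samples table needs columns sample_id and group")
    return pd.Series(table.iloc[:, 1].values, index=table.iloc[:, 0].values, name="group")


def write_samples(groups: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", index=False
    )


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {id: sequence} mapping (sequences uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_reads_fasta(path: str | Path) -> list[tuple[str, int]]:
    """Read a unique-read FASTA whose headers carry ``count=N`` abundances."""
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        count = 1
        for token in rec.description.split():
            if token.startswith("count="):
                count = int(token.split("=", 1)[1])
        reads.append((str(rec.seq).upper(), count))
    return reads


def write_reads_fasta(reads: Iterable[tuple[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(reads, start=1):
            fh.write(f">read{i:06d} count={count}\n{seq}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT (pathway id, description, genes...) into {pathway: gene set}."""
    genesets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >=3 fields")
            genesets[fields[0]] = set(fields[2:])
    return genesets


def write_gmt(genesets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in genesets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# qPCR table
# ---------------------------------------------------------------------------

QPCR_COLUMNS = ["sample_id", "group", "assay_id", "replicate", "ct"]


def read_qpcr(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample_id", "group", "assay_id", "ct") if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: qPCR table missing columns {missing}")
    if "replicate" not in table.columns:
        table["replicate"] = 1
    return table[QPCR_COLUMNS]


def write_qpcr(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_NONE)
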