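"""Read-level small-RNA summaries: length filtering, category annotation,
first-base composition and per-chromosome abundance.

"Mapping" at this stage is exact substring membership against reference
sequences — a deliberate, deterministic simplification of aligner-based
annotation.  T and U are treated as equivalent; the canonical internal
alphabet is U.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

RNA_ALPHABET = frozenset("ACGU")
OTHER_CATEGORY = "other"


def canonical(seq: str) -> str:
    """Uppercase and convert T->U; reject anything outside {A,C,G,U,T}."""
    seq = seq.upper().replace("T", "U")
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)} in sequence")
    return seq


@dataclass(frozen=True)
class ReadRecord:
    sequence: str
    abundance: int


@dataclass
class SmallReadSet:
    """De-duplicated reads with abundances; sequences unique within the set."""

    records: list[ReadRecord] = field(default_factory=list)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "SmallReadSet":
        merged: dict[str, int] = {}
        for seq, abundance in pairs:
            if abundance < 1:
                raise ValueError(f"abundance must be >= 1, got {abundance}")
            merged[canonical(seq)] = merged.get(canonical(seq), 0) + int(abundance)
        return cls([ReadRecord(s, a) for s, a in merged.items()])

    def total_abundance(self) -> int:
        return sum(r.abundance for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class ReferenceSets:
    """Ordered reference categories; order is the annotation priority."""

    categories: list[tuple[str, list[str]]]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.categories]
        if len(names) != len(set(names)):
            raise ValueError("duplicate reference category names")
        self.categories = [
            (name, [canonical(s) for s in seqs]) for name, seqs in self.categories
        ]

    @property
    def order(self) -> list[str]:
        return [name for name, _ in self.categories]


def filter_by_length(reads: SmallReadSet, min_len: int = 18, max_len: int = 36) -> SmallReadSet:
    """Keep reads with min_len <= length <= max_len (both ends inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept = [r for r in reads if min_len <= len(r.sequence) <= max_len]
    return SmallReadSet(kept)


def length_distribution(reads: SmallReadSet) -> pd.Series:
    """Abundance-weighted histogram of read lengths (length -> summed abundance)."""
    hist: dict[int, int] = {}
    for rec in reads:
        hist[len(rec.sequence)] = hist.get(len(rec.sequence), 0) + rec.abundance
    series = pd.Series(hist, dtype=int).sort_index()
    series.index.name = "length"
    series.name = "abundance"
    return series


def annotate_by_priority(
    reads: SmallReadSet, refsets: ReferenceSets
) -> tuple[list[str], pd.DataFrame]:
    """Assign each read to the first category whose references contain it.

    A read belongs to a category when it is an exact substring of any
    reference sequence in that category; the first matching category in
    priority order wins.  Unmatched reads fall into ``other``.

    Returns the per-read category list (aligned with ``reads.records``) and a
    count table with both read-weighted and unique-sequence-weighted columns.
    """
    assignments: list[str] = []
    for rec in reads:
        label = OTHER_CATEGORY
        for name, refs in refsets.categories:
            if any(rec.sequence in ref for ref in refs):
                label = name
                break
        assignments.append(label)

    rows = []
    for name in refsets.order + [OTHER_CATEGORY]:
        weighted = sum(r.abundance for r, lab in zip(reads, assignments) if lab == name)
        unique = sum(1 for lab in assignments if lab == name)
        rows.append((name, weighted, unique))
    table = pd.DataFrame(rows, columns=["category", "reads", "unique_sequences"])
    return assignments, table


def first_base_preference(
    reads: SmallReadSet, len_min: int = 20, len_max: int = 24
) -> pd.DataFrame:
    """Abundance-weighted first-nucleotide composition per read length.

    Rows are lengths in [len_min, len_max] that are present in the input;
    columns A/C/G/U are fractions summing to 1 within each row.
    """
    counts: dict[int, dict[str, int]] = {}
    for rec in reads:
        n = len(rec.sequence)
        if len_min <= n <= len_max:
            row = counts.setdefault(n, {b: 0 for b in "ACGU"})
            row[rec.sequence[0]] += rec.abundance
    if not counts:
        return pd.DataFrame(columns=list("ACGU"))
    table = pd.DataFrame.from_dict(counts, orient="index").sort_index()[list("ACGU")]
    table = table.div(table.sum(axis=1), axis=0)
    table.index.name = "length"
    return table


def chromosome_distribution(
    annotation: pd.DataFrame,
    counts: pd.DataFrame,
    chromosomes: Sequence[str] | None = None,
) -> pd.Series:
    """Summed count-matrix abundance per chromosome.

    ``chromosomes`` fixes the output rows (reporting 0 for chromosomes with no
    features); by default the chromosomes present in the annotation are used.
    """
    chrom_of = annotation.set_index("mirna_id")["chrom"]
    missing = counts.index.difference(chrom_of.index)
    if len(missing):
        raise KeyError(f"count matrix ids missing from annotation: {sorted(missing)[:5]}")
    totals = counts.sum(axis=1).groupby(chrom_of.loc[counts.index].values).sum()
    if chromosomes is None:
        chromosomes = sorted(annotation["chrom"].unique())
    result = pd.Series(0.0, index=list(chromosomes), name="abundance")
    result.update(totals)
    result.index.name = "chrom"
    return result
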