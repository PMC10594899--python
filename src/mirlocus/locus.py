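"""Co-localization of differentially expressed miRNAs within a named genomic
locus: membership flags, fraction reports, hypergeometric and permutation
nulls, and an effect-size comparison between locus and non-locus miRNAs.

Membership is >=1 bp overlap between the feature interval and the locus
interval on the same chromosome, strand ignored.  All coordinates are
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class LocusInterval:
    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"locus {self.name}: start {self.start} >= end {self.end}")


@dataclass
class LocusTestResult:
    locus: LocusInterval
    n_de: int
    n_de_in_locus: int
    fraction_in_locus: float
    n_annotated_in_locus: int
    hypergeom_p: float
    permutation_p: float | None
    per_chromosome: pd.Series = field(repr=False)


def in_locus_flags(annotation: pd.DataFrame, locus: LocusInterval) -> pd.Series:
    """Boolean per-annotation-feature locus membership, indexed by miRNA id."""
    flags = (
        (annotation["chrom"] == locus.chrom)
        & (annotation["start"] < locus.end)
        & (annotation["end"] > locus.start)
    )
    return pd.Series(flags.values, index=annotation["mirna_id"].values, name="in_locus")


def assign_locus(
    de_ids: list[str], annotation: pd.DataFrame, locus: LocusInterval
) -> tuple[pd.Series, pd.Series]:
    """Flag each DE miRNA as inside/outside the locus; also count DE per chromosome.

    Every DE id must be present in the annotation; missing ids raise a
    KeyError naming them.
    """
    flags = in_locus_flags(annotation, locus)
    missing = [i for i in de_ids if i not in flags.index]
    if missing:
        raise KeyError(f"DE miRNAs absent from annotation: {missing}")
    de_flags = flags.loc[list(de_ids)]
    chrom_of = annotation.set_index("mirna_id")["chrom"]
    per_chrom = chrom_of.loc[list(de_ids)].value_counts().sort_index()
    per_chrom.index.name = "chrom"
    per_chrom.name = "n_de"
    return de_flags, per_chrom


def locus_fraction_report(
    up_ids: list[str],
    annotation: pd.DataFrame,
    locus: LocusInterval,
    denominator: str = "locus",
) -> float:
    """Percentage of locus co-localization for a DE set.

    denominator="locus": 100 * (DE miRNAs in locus) / (all annotated miRNAs in
    locus) — the share of the locus that is differentially expressed.
    denominator="de": 100 * (DE miRNAs in locus) / |DE set| — the share of the
    DE set residing in the locus.
    """
    flags = in_locus_flags(annotation, locus)
    de_flags, _ = assign_locus(up_ids, annotation, locus)
    n_in = int(de_flags.sum())
    if denominator == "locus":
        denom = int(flags.sum())
        if denom == 0:
            raise ZeroDivisionError(f"no annotated miRNAs inside locus {locus.name}")
    elif denominator == "de":
        denom = len(up_ids)
        if denom == 0:
            raise ZeroDivisionError("empty DE set")
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * n_in / denom


def locus_hypergeom_test(
    up_ids: list[str], annotation: pd.DataFrame, locus: LocusInterval
) -> float:
    """Upper-tail hypergeometric P(X >= k) for locus membership of the DE set.

    X ~ Hypergeom(N = annotated miRNAs, K = annotated in locus, n = |DE set|),
    k = observed DE miRNAs in locus.
    """
    flags = in_locus_flags(annotation, locus)
    de_flags, _ = assign_locus(up_ids, annotation, locus)
    N = len(flags)
    K = int(flags.sum())
    n = len(up_ids)
    k = int(de_flags.sum())
    if K == 0 or n == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def locus_permutation_test(
    up_ids: list[str],
    annotation: pd.DataFrame,
    locus: LocusInterval,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p for locus co-localization, resampling miRNA identity.

    The null redraws |up set| ids uniformly without replacement from the full
    annotation, keeping genomic positions fixed — so the genome's clustered
    structure is preserved under the null.  p = (1 + #{perm fraction >= observed})
    / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    flags = in_locus_flags(annotation, locus).sort_index()
    de_flags, _ = assign_locus(up_ids, annotation, locus)
    n = len(up_ids)
    observed = de_flags.sum() / n
    rng = np.random.default_rng(seed)
    inloc = flags.values.astype(np.int64)
    # without-replacement draws via row-wise argpartition of random keys
    keys = rng.random((n_perm, len(inloc)))
    picks = np.argpartition(keys, n - 1, axis=1)[:, :n]
    perm_frac = inloc[picks].sum(axis=1) / n
    exceed = int((perm_frac >= observed - 1e-12).sum())
    return (1 + exceed) / (n_perm + 1)


def compare_effect_sizes(
    de_results: pd.DataFrame,
    in_locus: pd.Series,
    metric: str = "abs_log2fc",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing locus vs non-locus DE miRNAs.

    ``metric`` is "abs_log2fc" (|log2 fold change|) or "neg_log10_padj".
    ``de_results`` must be indexed by miRNA id with log2fc/padj columns;
    ``in_locus`` is a boolean Series over the same ids.
    """
    if metric == "abs_log2fc":
        values = de_results["log2fc"].abs()
    elif metric == "neg_log10_padj":
        values = -np.log10(de_results["padj"].clip(lower=1e-300))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    aligned = in_locus.reindex(values.index)
    if aligned.isna().any():
        raise KeyError("in_locus flags missing for some DE miRNAs")
    x = values[aligned.astype(bool)]
    y = values[~aligned.astype(bool)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError(f"need >=2 miRNAs per group, got {len(x)} in locus vs {len(y)} outside")
    stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(stat), float(p)


def locus_test(
    up_ids: list[str],
    annotation: pd.DataFrame,
    locus: LocusInterval,
    n_perm: int = 999,
    seed: int = 0,
) -> LocusTestResult:
    """Bundle membership counts with hypergeometric and permutation nulls."""
    flags = in_locus_flags(annotation, locus)
    de_flags, per_chrom = assign_locus(up_ids, annotation, locus)
    n_de = len(up_ids)
    k = int(de_flags.sum())
    return LocusTestResult(
        locus=locus,
        n_de=n_de,
        n_de_in_locus=k,
        fraction_in_locus=k / n_de if n_de else float("nan"),
        n_annotated_in_locus=int(flags.sum()),
        hypergeom_p=locus_hypergeom_test(up_ids, annotation, locus),
        permutation_p=locus_permutation_test(up_ids, annotation, locus, n_perm, seed)
        if n_perm
        else None,
        per_chromosome=per_chrom,
    )
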