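"""Per-miRNA pathway enrichment and the cross-miRNA recurrence statistic.

For each miRNA, predicted target genes are tested against every pathway with
an upper-tail hypergeometric test (BH-corrected within the miRNA's list);
pathways are ranked by p-value, ties broken by the number of enriched genes,
and the top-k lists from all miRNAs of one DE direction are pooled into a
recurrence table: how many per-miRNA top lists contain each pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mirlocus.de import bh_adjust

logger = logging.getLogger(__name__)

ENRICH_COLUMNS = ["pathway", "k", "K", "n", "N", "pvalue", "padj"]


@dataclass
class GeneSetCollection:
    """Pathway -> gene set mapping over an explicit gene universe.

    Genes outside the universe are dropped from their pathways with a logged
    warning, so invariants hold by construction.
    """

    genesets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        cleaned = {}
        for name, genes in self.genesets.items():
            outside = set(genes) - self.universe
            if outside:
                logger.warning(
                    "pathway %s: dropping %d genes outside the universe", name, len(outside)
                )
            cleaned[name] = set(genes) & self.universe
        self.genesets = cleaned

    @classmethod
    def from_gmt(
        cls, genesets: Mapping[str, Iterable[str]], universe: Iterable[str]
    ) -> "GeneSetCollection":
        return cls({k: set(v) for k, v in genesets.items()}, set(universe))


def hypergeom_enrich(
    target_genes: Iterable[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of the targets in every pathway.

    Target genes outside the universe are dropped (counted in the log).  For
    each pathway: k = targets in pathway, K = pathway size, n = targets in
    universe, N = universe size; p = P(X >= k); BH across pathways.
    """
    targets = set(target_genes)
    outside = targets - collection.universe
    if outside:
        logger.warning("dropping %d target genes outside the universe", len(outside))
        targets &= collection.universe
    N = len(collection.universe)
    n = len(targets)
    rows = []
    for name in sorted(collection.genesets):
        genes = collection.genesets[name]
        K = len(genes)
        k = len(targets & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((name, k, K, n, N, p))
    result = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:-1])
    result["padj"] = bh_adjust(result["pvalue"].to_numpy()) if len(result) else []
    return result


def rank_top(results: pd.DataFrame, top_k: int = 10) -> list[str]:
    """Top-k pathway ids: ascending p-value, ties by larger k, then id."""
    ordered = results.sort_values(
        by=["pvalue", "k", "pathway"], ascending=[True, False, True], kind="stable"
    )
    return list(ordered["pathway"].head(top_k))


def recurrence(per_mirna_toplists: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Pathway recurrence across per-miRNA top lists.

    frequency = number of lists containing the pathway; fraction = frequency
    divided by the number of miRNA groups; rows ranked by descending
    frequency with lexicographic tie-break, rank 1-based.
    """
    n_groups = len(per_mirna_toplists)
    freq: dict[str, int] = {}
    for toplist in per_mirna_toplists.values():
        for pathway in set(toplist):
            freq[pathway] = freq.get(pathway, 0) + 1
    table = pd.DataFrame(
        sorted(freq.items(), key=lambda item: (-item[1], item[0])),
        columns=["pathway", "frequency"],
    )
    table["n_groups"] = n_groups
    table["fraction"] = table["frequency"] / n_groups if n_groups else np.nan
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def enrich_direction(
    targets_by_mirna: Mapping[str, Iterable[str]],
    collection: GeneSetCollection,
    top_k: int = 10,
) -> tuple[dict[str, pd.DataFrame], dict[str, list[str]], pd.DataFrame]:
    """Enrichment -> top-k list per miRNA -> recurrence table, in one sweep."""
    enrichments = {
        mirna: hypergeom_enrich(genes, collection)
        for mirna, genes in targets_by_mirna.items()
    }
    toplists = {mirna: rank_top(result, top_k) for mirna, result in enrichments.items()}
    return enrichments, toplists, recurrence(toplists)
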