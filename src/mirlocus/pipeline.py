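"""End-to-end driver: simulate (optional) -> profile -> DE -> locus ->
targets -> enrichment -> qPCR, emitting TSV tables plus one JSON run report.

The report is deterministic for a fixed config (seeds included, no
timestamps), so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

import mirlocus
from mirlocus import de, enrich, io, qpcr, smallrna, synthdata, targets
from mirlocus import locus as locus_mod
from mirlocus.config import PipelineConfig
from mirlocus.locus import LocusInterval

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_inputs(config: PipelineConfig) -> dict:
    """Either simulate everything or read the configured files."""
    if config.stages.simulate:
        sim = config.simulation.with_seed(config.seed)
        return synthdata.simulate_all(sim)
    paths = config.inputs
    data: dict = {}
    if paths.annotation:
        data["annotation"] = io.read_annotation(paths.annotation, paths.annotation_format)
    if paths.counts:
        data["counts"] = io.read_counts(paths.counts)
    if paths.samples:
        data["groups"] = io.read_samples(paths.samples)
    if paths.mirna_fasta:
        data["mirna_seqs"] = io.read_fasta(paths.mirna_fasta)
    if paths.utr_fasta:
        data["utr_seqs"] = io.read_fasta(paths.utr_fasta)
    if paths.genesets:
        data["genesets"] = io.read_gmt(paths.genesets)
    if paths.reads_fasta:
        data["reads"] = smallrna.SmallReadSet.from_pairs(io.read_reads_fasta(paths.reads_fasta))
        data["refsets"] = smallrna.ReferenceSets([("miRNA", list(data.get("mirna_seqs", {}).values()))])
    if paths.qpcr:
        data["qpcr"] = io.read_qpcr(paths.qpcr)
    if config.locus_chrom is not None:
        data["locus"] = LocusInterval(
            config.locus_name or "locus", config.locus_chrom,
            int(config.locus_start), int(config.locus_end),
        )
    data["truth"] = None
    return data


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Execute every enabled stage; return the machine-readable run report."""
    config.validate()
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    report: dict = {
        "package": "mirlocus",
        "version": mirlocus.__version__,
        "seed": config.seed,
        "parameters": {
            "alpha": thr.alpha, "lfc_min": thr.lfc_min,
            "min_total_count": thr.min_total_count, "score_min": thr.score_min,
            "energy_max": thr.energy_max, "score_scale": thr.score_scale,
            "top_k": thr.top_k, "n_perm": thr.n_perm,
        },
        "stages": {},
    }

    data = _run_stage("inputs", _load_inputs, config)
    if write and config.stages.simulate:
        _write_simulated(data, outdir)

    if config.stages.profile and "reads" in data:
        report["stages"]["profile"] = _run_stage(
            "profile", _profile_stage, data, config, outdir if write else None
        )

    up_ids: list[str] = []
    down_ids: list[str] = []
    if config.stages.de:
        result, up_ids, down_ids = _run_stage("de", _de_stage, data, config, outdir if write else None)
        data["de_results"] = result
        report["stages"]["de"] = {
            "n_tested": int(result["tested"].sum()),
            "n_up": len(up_ids),
            "n_down": len(down_ids),
        }

    if config.stages.locus and "annotation" in data and "locus" in data:
        report["stages"]["locus"] = _run_stage(
            "locus", _locus_stage, data, config, up_ids, down_ids, outdir if write else None
        )

    hits = pd.DataFrame(columns=targets.HIT_COLUMNS)
    if config.stages.targets and "mirna_seqs" in data and "utr_seqs" in data:
        hits = _run_stage("targets", _targets_stage, data, config, up_ids, outdir if write else None)
        report["stages"]["targets"] = {
            "n_hits": int(len(hits)),
            "n_mirnas_with_hits": int(hits["mirna_id"].nunique()) if len(hits) else 0,
        }

    if config.stages.enrich and "genesets" in data:
        report["stages"]["enrich"] = _run_stage(
            "enrich", _enrich_stage, data, config, hits, outdir if write else None
        )

    if config.stages.qpcr and "qpcr" in data:
        report["stages"]["qpcr"] = _run_stage(
            "qpcr", _qpcr_stage, data, config, outdir if write else None
        )

    if write:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _run_stage(name, func, *args):
    logger.info("running stage %s", name)
    try:
        return func(*args)
    except Exception as exc:  # halt with the stage name and cause
        raise StageError(name, exc) from exc


# ---------------------------------------------------------------------------
# stage bodies
# ---------------------------------------------------------------------------

def _write_simulated(data: dict, outdir: Path) -> None:
    io.write_bed(data["annotation"], outdir / "annotation.bed")
    io.write_gff3(data["annotation"], outdir / "annotation.gff3")
    io.write_counts(data["counts"], outdir / "counts.tsv")
    io.write_samples(data["groups"], outdir / "samples.tsv")
    io.write_fasta(data["mirna_seqs"], outdir / "mirna.fa")
    io.write_fasta(data["utr_seqs"], outdir / "utr.fa")
    io.write_gmt(data["genesets"], outdir / "genesets.gmt")
    io.write_reads_fasta(
        ((r.sequence, r.abundance) for r in data["reads"]), outdir / "reads.fa"
    )
    io.write_qpcr(data["qpcr"], outdir / "qpcr.tsv")
    truth = data["truth"]
    io.write_tsv(
        pd.DataFrame(sorted(truth.de_truth.items()), columns=["mirna_id", "truth"]),
        outdir / "truth_de.tsv",
    )
    io.write_tsv(
        pd.DataFrame(sorted(truth.target_truth), columns=["mirna_id", "gene_id", "position"]),
        outdir / "truth_targets.tsv",
    )


def _profile_stage(data: dict, config: PipelineConfig, outdir: Path | None) -> dict:
    reads = data["reads"]
    filtered = smallrna.filter_by_length(reads)
    lengths = smallrna.length_distribution(filtered)
    assignments, categories = smallrna.annotate_by_priority(filtered, data["refsets"])
    mirna_reads = smallrna.SmallReadSet(
        [r for r, lab in zip(filtered, assignments) if lab == "miRNA"]
    )
    first_base = smallrna.first_base_preference(mirna_reads)
    if outdir is not None:
        io.write_tsv(lengths.reset_index(), outdir / "length_distribution.tsv")
        io.write_tsv(categories, outdir / "read_categories.tsv")
        io.write_tsv(first_base.reset_index(), outdir / "first_base.tsv")
    out = {
        "n_unique_reads": len(reads),
        "n_after_length_filter": len(filtered),
        "abundance_total": reads.total_abundance(),
        "abundance_after_filter": filtered.total_abundance(),
        "category_reads": dict(zip(categories["category"], categories["reads"].astype(int))),
    }
    if "annotation" in data and "counts" in data:
        chrom = smallrna.chromosome_distribution(data["annotation"], data["counts"])
        if outdir is not None:
            io.write_tsv(chrom.reset_index(), outdir / "chromosome_distribution.tsv")
        out["chromosome_abundance"] = {k: float(v) for k, v in chrom.items()}
    return out


def _de_stage(data: dict, config: PipelineConfig, outdir: Path | None):
    thr = config.thresholds
    results = de.de_analysis(
        data["counts"], data["groups"],
        alpha=thr.alpha, lfc_min=thr.lfc_min, min_total_count=thr.min_total_count,
    )
    up_ids, down_ids = list(results.index[results["call"] == "up"]), list(
        results.index[results["call"] == "down"]
    )
    factors = de.size_factors(data["counts"])
    if outdir is not None:
        # header comment states the direction convention
        with open(outdir / "de_results.tsv", "w") as fh:
            fh.write("# log2fc = group A (newborn-like) over group B (adult-like)\n")
            results.to_csv(fh, sep="\t")
        io.write_tsv(de.pca_samples(data["counts"], factors).reset_index(names="sample_id"),
                     outdir / "pca.tsv")
        io.write_tsv(de.sample_correlation(data["counts"], factors).reset_index(names="sample_id"),
                     outdir / "correlation.tsv")
        clusters = de.cluster_patterns(
            data["counts"], factors, k=min(thr.n_clusters, len(data["counts"])),
            seed=config.seed,
        )
        io.write_tsv(clusters.reset_index(), outdir / "clusters.tsv")
    return results, up_ids, down_ids


def _locus_stage(data, config, up_ids, down_ids, outdir: Path | None) -> dict:
    annotation, locus = data["annotation"], data["locus"]
    thr = config.thresholds
    out: dict = {"locus": {"name": locus.name, "chrom": locus.chrom,
                           "start": locus.start, "end": locus.end}}
    for label, ids in (("up", up_ids), ("down", down_ids)):
        if not ids:
            out[label] = {"n_de": 0}
            continue
        result = locus_mod.locus_test(
            ids, annotation, locus, n_perm=thr.n_perm, seed=config.seed
        )
        out[label] = {
            "n_de": result.n_de,
            "n_de_in_locus": result.n_de_in_locus,
            "fraction_in_locus": result.fraction_in_locus,
            "n_annotated_in_locus": result.n_annotated_in_locus,
            "hypergeom_p": result.hypergeom_p,
            "permutation_p": result.permutation_p,
        }
        if outdir is not None:
            io.write_tsv(result.per_chromosome.reset_index(),
                         outdir / f"locus_chromosomes_{label}.tsv")
    de_ids = list(up_ids) + list(down_ids)
    if "de_results" in data and len(de_ids):
        flags, _ = locus_mod.assign_locus(de_ids, annotation, locus)
        de_subset = data["de_results"].loc[de_ids]
        if flags.sum() >= 2 and (~flags).sum() >= 2:
            stat, p = locus_mod.compare_effect_sizes(de_subset, flags, "abs_log2fc")
            out["effect_size_compare"] = {"metric": "abs_log2fc", "U": stat, "pvalue": p}
    if outdir is not None:
        with open(outdir / "locus_report.json", "w") as fh:
            json.dump(out, fh, indent=2, sort_keys=True)
    return out


def _targets_stage(data, config, up_ids, outdir: Path | None) -> pd.DataFrame:
    thr = config.thresholds
    mirnas = data["mirna_seqs"]
    subset = {m: mirnas[m] for m in up_ids if m in mirnas} if up_ids else dict(mirnas)
    hits = targets.predict_targets(
        subset, data["utr_seqs"],
        score_min=thr.score_min, energy_max=thr.energy_max, score_scale=thr.score_scale,
    )
    if outdir is not None:
        io.write_tsv(hits, outdir / "targets.tsv")
    return hits


def _enrich_stage(data, config, hits: pd.DataFrame, outdir: Path | None) -> dict:
    thr = config.thresholds
    collection = enrich.GeneSetCollection.from_gmt(data["genesets"], data["utr_seqs"].keys())
    targets_by_mirna = {
        mirna: sorted(set(chunk["gene_id"]))
        for mirna, chunk in hits.groupby("mirna_id")
    }
    enrichments, toplists, table = enrich.enrich_direction(
        targets_by_mirna, collection, top_k=thr.top_k
    )
    if outdir is not None:
        io.write_tsv(table, outdir / "recurrence.tsv")
        rows = [
            {"mirna_id": m, "rank": i + 1, "pathway": p}
            for m, lst in sorted(toplists.items())
            for i, p in enumerate(lst)
        ]
        io.write_tsv(pd.DataFrame(rows, columns=["mirna_id", "rank", "pathway"]),
                     outdir / "toplists.tsv")
        stacked = pd.concat(
            [chunk.assign(mirna_id=m) for m, chunk in sorted(enrichments.items())],
            ignore_index=True,
        ) if enrichments else pd.DataFrame(columns=enrich.ENRICH_COLUMNS + ["mirna_id"])
        io.write_tsv(stacked, outdir / "enrichment.tsv")
    out = {"n_mirna_groups": len(toplists)}
    if len(table):
        out["top_pathway"] = table.iloc[0]["pathway"]
        out["top_frequency"] = int(table.iloc[0]["frequency"])
        out["top_fraction"] = float(table.iloc[0]["fraction"])
    truth = data.get("truth")
    if truth is not None and truth.pathway_truth is not None and len(table):
        row = table[table["pathway"] == truth.pathway_truth]
        out["planted_pathway_rank"] = int(row["rank"].iloc[0]) if len(row) else None
    return out


def _qpcr_stage(data, config, outdir: Path | None) -> dict:
    sim = config.simulation
    rel = qpcr.ddct(data["qpcr"], reference_assay=sim.reference_assay, calibrator_group="B")
    tests = qpcr.group_compare(rel, alpha=config.thresholds.alpha)
    if outdir is not None:
        io.write_tsv(rel, outdir / "relative_expression.tsv")
        io.write_tsv(tests, outdir / "qpcr_tests.tsv")
    return {
        row["assay_id"]: {"test": row["test"], "pvalue": row["pvalue"],
                          "significant": row["significant"]}
        for _, row in tests.iterrows()
    }
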