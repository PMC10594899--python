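"""Simulators for every input the analysis chain consumes, plus ground truth.

The default configuration mirrors the scale of the study design the pipeline
targets: ~150 miRNAs of which 101 sit in one dense cluster on a single
chromosome, 32 planted up-regulated inside the cluster, 48 planted
down-regulated scattered elsewhere, and a 5 vs 5 two-group design with
negative-binomial counts.

Randomness: one root seed; each simulate_* operation derives its own stream
as ``default_rng([root_seed, blake2b(operation_name)])`` so operations can be
re-run independently and stay byte-identical under a fixed seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from mirlocus.locus import LocusInterval
from mirlocus.smallrna import ReferenceSets, SmallReadSet

RNA_BASES = np.array(list("ACGU"))
_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(seq: str) -> str:
    """RNA reverse complement (A<->U, C<->G)."""
    return seq.translate(_COMPLEMENT)[::-1]


def derived_rng(seed: int, label: str) -> np.random.Generator:
    """Per-operation RNG stream: root seed + 64-bit hash of the label."""
    digest = hashlib.blake2b(label.encode(), digest_size=8).digest()
    return np.random.default_rng([int(seed), int.from_bytes(digest, "little")])


@dataclass
class SimulationConfig:
    """All knobs for the synthetic inputs.  See module docstring for defaults."""

    n_chroms: int = 26
    chrom_length: int = 3_000_000
    n_mirnas_total: int = 150
    locus_chrom: str = "chr18"
    locus_interval: tuple[int, int] = (1_000_000, 1_800_000)
    locus_name: str = "cluster-locus"
    n_locus_mirnas: int = 101
    n_up_planted: int = 32
    n_down_planted: int = 48
    lfc_up: float = 2.0
    lfc_down: float = -2.0
    nb_mean_log_range: tuple[float, float] = (1.0, 3.0)
    nb_dispersion: float = 0.1
    n_per_group: int = 5
    feature_length: int = 22
    # sequences / targets / pathways
    n_genes: int = 300
    utr_length: int = 500
    targets_per_mirna: int = 3
    n_pathways: int = 20
    geneset_size_range: tuple[int, int] = (10, 40)
    planted_pathway_coverage: float = 1.0
    u_bias: float = 0.78
    # read simulation
    n_unique_reads: int = 300
    total_read_count: int = 100_000
    decoy_fraction: float = 0.2
    other_fraction: float = 0.1
    # qPCR
    qpcr_assays: tuple[str, ...] = ("mir-q1", "mir-q2")
    qpcr_fold_change: float = 8.0
    qpcr_noise_sd: float = 0.25
    qpcr_n_per_group: int = 3
    qpcr_n_technical: int = 3
    reference_assay: str = "U6"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 <= self.n_up_planted <= self.n_locus_mirnas <= self.n_mirnas_total):
            raise ValueError(
                "need n_up_planted <= n_locus_mirnas <= n_mirnas_total, got "
                f"{self.n_up_planted}/{self.n_locus_mirnas}/{self.n_mirnas_total}"
            )
        if self.n_down_planted > self.n_mirnas_total - self.n_locus_mirnas:
            raise ValueError("n_down_planted exceeds the number of non-locus miRNAs")
        start, end = self.locus_interval
        if not (0 <= start < end <= self.chrom_length):
            raise ValueError(f"locus interval {self.locus_interval} outside chromosome")
        if not (0 < self.planted_pathway_coverage <= 1):
            raise ValueError("planted_pathway_coverage must be in (0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not (0 <= self.u_bias <= 1):
            raise ValueError("u_bias must be in [0, 1]")
        for name in ("n_chroms", "n_per_group", "n_genes", "n_pathways", "feature_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i}" for i in range(1, self.n_chroms + 1)]

    @property
    def locus(self) -> LocusInterval:
        return LocusInterval(
            self.locus_name, self.locus_chrom, self.locus_interval[0], self.locus_interval[1]
        )

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class TruthTables:
    """Ground truth of the planted structure, for recovery tests."""

    de_truth: dict[str, str] = field(default_factory=dict)  # id -> up|down
    target_truth: set[tuple[str, str, int]] = field(default_factory=set)
    pathway_truth: str | None = None

    def up_ids(self) -> list[str]:
        return sorted(m for m, lab in self.de_truth.items() if lab == "up")

    def down_ids(self) -> list[str]:
        return sorted(m for m, lab in self.de_truth.items() if lab == "down")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig) -> tuple[pd.DataFrame, LocusInterval]:
    """Place miRNA features: a dense non-overlapping cluster inside the locus
    interval, the remainder uniform over the other chromosomes."""
    rng = derived_rng(config.seed, "annotation")
    locus = config.locus
    start, end = config.locus_interval
    flen = config.feature_length

    n_slots = (end - start) // flen
    if config.n_locus_mirnas > n_slots:
        raise ValueError(
            f"locus interval holds at most {n_slots} non-overlapping features "
            f"of length {flen}; {config.n_locus_mirnas} requested"
        )
    rows = []
    if config.n_locus_mirnas:
        slots = np.sort(rng.choice(n_slots, size=config.n_locus_mirnas, replace=False))
        for i, slot in enumerate(slots, start=1):
            pos = start + int(slot) * flen
            rows.append((f"mir-L{i:03d}", locus.chrom, pos, pos + flen, "+"))

    others = [c for c in config.chromosomes if c != config.locus_chrom]
    if not others and config.n_mirnas_total > config.n_locus_mirnas:
        raise ValueError("no non-locus chromosome available for scattered miRNAs")
    n_rest = config.n_mirnas_total - config.n_locus_mirnas
    if n_rest:
        chroms = rng.choice(len(others), size=n_rest)
        starts = rng.integers(0, config.chrom_length - flen, size=n_rest)
        strands = rng.choice(["+", "-"], size=n_rest)
        for i in range(n_rest):
            rows.append(
                (f"mir-G{i + 1:03d}", others[chroms[i]], int(starts[i]), int(starts[i]) + flen,
                 str(strands[i]))
            )
    annotation = pd.DataFrame(rows, columns=["mirna_id", "chrom", "start", "end", "strand"])
    return annotation, locus


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB with Var = mu + alpha*mu^2: shape r = 1/alpha, p = r/(r+mu)."""
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    annotation: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.Series, TruthTables]:
    """Two-group NB count matrix with planted fold changes and truth labels.

    Group A carries the planted effects (up: mean * 2**lfc_up inside the
    locus; down: mean * 2**lfc_down outside); per-sample size factors are
    drawn log-uniform in [0.5, 2].
    """
    if annotation["mirna_id"].duplicated().any():
        raise ValueError("annotation ids must be unique")
    rng = derived_rng(config.seed, "counts")
    locus = config.locus
    in_locus = (
        (annotation["chrom"] == locus.chrom)
        & (annotation["start"] < locus.end)
        & (annotation["end"] > locus.start)
    ).values
    ids = annotation["mirna_id"].values
    locus_ids = ids[in_locus]
    outside_ids = ids[~in_locus]
    if config.n_up_planted > len(locus_ids):
        raise ValueError("not enough locus miRNAs to plant the up set")
    if config.n_down_planted > len(outside_ids):
        raise ValueError("not enough non-locus miRNAs to plant the down set")
    up_ids = rng.choice(locus_ids, size=config.n_up_planted, replace=False)
    down_ids = rng.choice(outside_ids, size=config.n_down_planted, replace=False)

    lo, hi = config.nb_mean_log_range
    base_mean = 10.0 ** rng.uniform(lo, hi, size=len(ids))
    lfc = pd.Series(0.0, index=ids)
    lfc.loc[up_ids] = config.lfc_up
    lfc.loc[down_ids] = config.lfc_down

    n = config.n_per_group
    samples = [f"A{i + 1}" for i in range(n)] + [f"B{i + 1}" for i in range(n)]
    groups = pd.Series(["A"] * n + ["B"] * n, index=samples, name="group")
    size_factors = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=2 * n))

    mean_a = base_mean * 2.0 ** lfc.values
    mean_b = base_mean
    means = np.column_stack([mean_a] * n + [mean_b] * n) * size_factors[None, :]
    counts = pd.DataFrame(
        _nb_draw(rng, means, config.nb_dispersion), index=ids, columns=samples, dtype=int
    )
    counts.index.name = "mirna_id"

    de_truth: dict[str, str] = {}
    if config.lfc_up != 0:
        de_truth.update({m: "up" for m in up_ids})
    if config.lfc_down != 0:
        de_truth.update({m: "down" for m in down_ids})
    return counts, groups, TruthTables(de_truth=de_truth)


# ---------------------------------------------------------------------------
# sequences / targets
# ---------------------------------------------------------------------------

def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(RNA_BASES, size=length))


def _random_mirna(rng: np.random.Generator, u_bias: float) -> str:
    length = int(rng.choice([21, 22]))
    first = "U" if rng.random() < u_bias else str(rng.choice(np.array(list("ACG"))))
    # keep at least one G/C in the body so a planted full-complement duplex
    # always clears the default energy cutoff
    while True:
        body = _random_rna(rng, length - 1)
        if "G" in body or "C" in body:
            return first + body


def simulate_sequences(
    annotation: pd.DataFrame, config: SimulationConfig, truth: TruthTables | None = None
) -> tuple[dict[str, str], dict[str, str], set[tuple[str, str, int]]]:
    """Mature miRNA and 3'UTR FASTA sequences, with planted target sites.

    Each planted up-regulated miRNA receives ``targets_per_mirna`` UTRs that
    contain the exact reverse complement of the full mature sequence (so the
    planted duplex is the best-scoring window of its UTR by construction).
    Returns (mirna_seqs, utr_seqs, target_truth).
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = derived_rng(config.seed, "sequences")
    mirna_seqs = {m: _random_mirna(rng, config.u_bias) for m in annotation["mirna_id"]}

    genes = [f"gene{i + 1:04d}" for i in range(config.n_genes)]
    utr_seqs = {g: _random_rna(rng, config.utr_length) for g in genes}

    target_truth: set[tuple[str, str, int]] = set()
    planted_ids = truth.up_ids() if truth is not None else []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for mirna in planted_ids:
        site = reverse_complement(mirna_seqs[mirna])
        k = min(config.targets_per_mirna, len(genes))
        for gene in rng.choice(genes, size=k, replace=False):
            utr = utr_seqs[gene]
            # never overwrite a previously planted site
            taken = occupied.setdefault(gene, [])
            pos = None
            for _ in range(50):
                cand = int(rng.integers(0, len(utr) - len(site) + 1))
                if all(cand + len(site) <= s or cand >= e for s, e in taken):
                    pos = cand
                    break
            if pos is None:
                continue
            taken.append((pos, pos + len(site)))
            utr_seqs[gene] = utr[:pos] + site + utr[pos + len(site):]
            target_truth.add((mirna, gene, pos))
    return mirna_seqs, utr_seqs, target_truth


def simulate_genesets(
    config: SimulationConfig,
    target_truth: set[tuple[str, str, int]],
    truth: TruthTables | None = None,
) -> tuple[dict[str, set[str]], str]:
    """GMT-style gene sets with one pathway enriched for planted target genes.

    The planted pathway collects every planted target gene of a
    ``planted_pathway_coverage`` fraction of the up-planted miRNAs, padded
    with random genes up to the configured size range; the remaining pathways
    are uniform random draws from the gene universe.
    """
    rng = derived_rng(config.seed, "genesets")
    universe = [f"gene{i + 1:04d}" for i in range(config.n_genes)]
    lo, hi = config.geneset_size_range
    if hi > len(universe):
        raise ValueError(f"geneset size {hi} exceeds gene universe of {len(universe)}")

    targets_by_mirna: dict[str, set[str]] = {}
    for mirna, gene, _pos in target_truth:
        targets_by_mirna.setdefault(mirna, set()).add(gene)
    mirnas = sorted(targets_by_mirna)
    n_covered = max(1, int(round(config.planted_pathway_coverage * len(mirnas)))) if mirnas else 0
    covered = list(rng.choice(mirnas, size=n_covered, replace=False)) if mirnas else []

    planted_genes: set[str] = set()
    for mirna in covered:
        planted_genes |= targets_by_mirna[mirna]
    size = max(int(rng.integers(lo, hi + 1)), len(planted_genes))
    if size > len(universe):
        raise ValueError("planted pathway larger than the gene universe")
    filler = [g for g in universe if g not in planted_genes]
    pad = rng.choice(filler, size=size - len(planted_genes), replace=False)
    pathway_truth = "pw001"
    genesets: dict[str, set[str]] = {pathway_truth: planted_genes | set(pad)}
    for i in range(2, config.n_pathways + 1):
        psize = int(rng.integers(lo, hi + 1))
        genesets[f"pw{i:03d}"] = set(rng.choice(universe, size=psize, replace=False))
    return genesets, pathway_truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

_DECOY_CATEGORIES = ("rRNA", "tRNA", "snRNA", "snoRNA")


def simulate_reads(
    annotation: pd.DataFrame,
    config: SimulationConfig,
    mirna_seqs: Mapping[str, str] | None = None,
) -> tuple[SmallReadSet, ReferenceSets]:
    """Unique reads (sequence, abundance) drawn from mature miRNAs, decoy
    ncRNA fragments and random background, lengths spanning 16-40 nt so that
    the 18-36 length filter removes something.

    Abundances are a multinomial split of ``total_read_count`` (one read
    guaranteed per unique sequence), so they sum exactly to the configured
    total.
    """
    rng = derived_rng(config.seed, "reads")
    if mirna_seqs is None:
        mirna_seqs, _, _ = simulate_sequences(annotation, config)
    mature = list(mirna_seqs.values())

    decoys = {
        cat: [_random_rna(rng, int(rng.integers(80, 151))) for _ in range(3)]
        for cat in _DECOY_CATEGORIES
    }
    refsets = ReferenceSets([("miRNA", mature)] + [(c, decoys[c]) for c in _DECOY_CATEGORIES])

    n_total = config.n_unique_reads
    n_decoy = int(round(config.decoy_fraction * n_total))
    n_other = int(round(config.other_fraction * n_total))
    n_mirna = n_total - n_decoy - n_other
    if n_mirna < 0:
        raise ValueError("decoy_fraction + other_fraction exceed 1")

    seqs: list[str] = []
    for _ in range(n_mirna):
        src = mature[int(rng.integers(len(mature)))]
        if rng.random() < 0.7:  # intact mature read
            seqs.append(src)
        else:  # truncated/degraded fragment
            cut = int(rng.integers(16, len(src)))
            seqs.append(src[:cut])
    for _ in range(n_decoy):
        cat = _DECOY_CATEGORIES[int(rng.integers(len(_DECOY_CATEGORIES)))]
        ref = decoys[cat][int(rng.integers(3))]
        length = int(rng.integers(16, 41))
        start = int(rng.integers(0, len(ref) - length + 1))
        seqs.append(ref[start:start + length])
    for i in range(n_other):
        # pin the boundary lengths so the 18-36 filter is exercised
        length = 16 if i == 0 else 40 if i == 1 else int(rng.integers(16, 41))
        seqs.append(_random_rna(rng, length))

    unique = sorted(set(seqs))
    if config.total_read_count < len(unique):
        raise ValueError("total_read_count smaller than the number of unique reads")
    weights = rng.dirichlet(np.ones(len(unique)))
    extra = rng.multinomial(config.total_read_count - len(unique), weights)
    reads = SmallReadSet.from_pairs((s, 1 + int(e)) for s, e in zip(unique, extra))
    return reads, refsets


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(config: SimulationConfig) -> pd.DataFrame:
    """Per-well Ct table for target assays plus the reference assay.

    Group A expresses each target ``qpcr_fold_change``-fold over group B (the
    calibrator), i.e. its delta-Ct is lower by log2(fold change); Gaussian
    noise of sd ``qpcr_noise_sd`` is added per well.
    """
    rng = derived_rng(config.seed, "qpcr")
    n = config.qpcr_n_per_group
    rows = []
    shift = float(np.log2(config.qpcr_fold_change))
    for group, prefix in (("A", "A"), ("B", "B")):
        for i in range(n):
            sample = f"{prefix}{i + 1}"
            ref_ct = 15.0
            for rep in range(1, config.qpcr_n_technical + 1):
                rows.append(
                    (sample, group, config.reference_assay, rep,
                     ref_ct + config.qpcr_noise_sd * rng.standard_normal())
                )
            for assay in config.qpcr_assays:
                dct = 6.0 - (shift if group == "A" else 0.0)
                for rep in range(1, config.qpcr_n_technical + 1):
                    rows.append(
                        (sample, group, assay, rep,
                         ref_ct + dct + config.qpcr_noise_sd * rng.standard_normal())
                    )
    return pd.DataFrame(rows, columns=["sample_id", "group", "assay_id", "replicate", "ct"])


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig) -> dict:
    """Run every simulator and return one bundle keyed by input kind."""
    annotation, locus = simulate_annotation(config)
    counts, groups, truth = simulate_counts(annotation, config)
    mirna_seqs, utr_seqs, target_truth = simulate_sequences(annotation, config, truth)
    truth.target_truth = target_truth
    genesets, pathway_truth = simulate_genesets(config, target_truth, truth)
    truth.pathway_truth = pathway_truth
    reads, refsets = simulate_reads(annotation, config, mirna_seqs)
    qpcr = simulate_qpcr(config)
    return {
        "annotation": annotation,
        "locus": locus,
        "counts": counts,
        "groups": groups,
        "truth": truth,
        "mirna_seqs": mirna_seqs,
        "utr_seqs": utr_seqs,
        "genesets": genesets,
        "reads": reads,
        "refsets": refsets,
        "qpcr": qpcr,
    }
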