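"""Seed-match scanning and duplex alignment for miRNA target prediction.

Two layers:

* :func:`find_seed_sites` scans a 3'UTR for Watson-Crick complementarity to
  miRNA positions 2-8 (position 1 = 5' nucleotide) and classifies sites into
  the canonical 8mer / 7mer-m8 / 7mer-A1 / 6mer classes.
* :func:`align_duplex` locally aligns the reversed miRNA against a UTR window
  (match +5, G:U wobble +2, mismatch -3, gap open -8, gap extend -2; pair
  scores at miRNA positions 2-8 are doubled) and returns the raw score plus
  the paired positions; :func:`duplex_energy` converts the pairing into a
  stacking-energy proxy in kcal/mol.

Reported scores are raw alignment units times ``DEFAULT_SCORE_SCALE``, a
calibration constant anchoring a perfect 22-mer duplex at ~218 so that the
conventional "Max Score > 150 / Max Energy < -20" screen is meaningful on
this scale.  Both thresholds and the calibration are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

import pandas as pd

from mirlocus.smallrna import canonical

MATCH = 5.0
WOBBLE = 2.0
MISMATCH = -3.0
GAP_OPEN = -8.0
GAP_EXTEND = -2.0
SEED_FIRST, SEED_LAST = 2, 8  # 1-based miRNA positions with doubled pair scores
SEED_WEIGHT = 2.0

DEFAULT_SCORE_MIN = 150.0
DEFAULT_ENERGY_MAX = -20.0
DEFAULT_SCORE_SCALE = 1.5

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WC_PAIRS = {frozenset(("A", "U")), frozenset(("G", "C"))}
_WOBBLE_PAIR = frozenset(("G", "U"))

MATCH_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer", "alignment-only")


@dataclass(frozen=True)
class SeedSite:
    start: int  # 0-based half-open on the UTR
    end: int
    match_class: str


class BasePair(NamedTuple):
    mirna_pos: int  # 1-based position on the miRNA (1 = 5' end)
    target_pos: int  # 0-based position on the aligned window
    mirna_base: str
    target_base: str


def _pair_kind(x: str, y: str) -> str | None:
    key = frozenset((x, y))
    if key in _WC_PAIRS:
        return "wc"
    if key == _WOBBLE_PAIR:
        return "wobble"
    return None


def find_seed_sites(mirna_seq: str, utr_seq: str) -> list[SeedSite]:
    """All seed-complementary sites of a miRNA in a UTR, strongest class per site.

    The UTR site pairs antiparallel with the seed, so in UTR 5'->3'
    orientation a 6mer core reads as the reverse complement of miRNA
    positions 2-7; a matched position 8 extends the core one base 5'-ward on
    the UTR, and the 8mer/7mer-A1 adenine sits at the UTR position opposite
    miRNA position 1 (the 3' end of the site).
    """
    m = canonical(mirna_seq)
    utr = canonical(utr_seq)
    if len(m) < 8:
        raise ValueError(f"miRNA too short for seed classification: {len(m)} nt")
    core = "".join(_COMPLEMENT[b] for b in m[1:7])[::-1]  # rc of positions 2-7
    m8_comp = _COMPLEMENT[m[7]]
    sites = []
    j = utr.find(core)
    while j != -1:
        has_m8 = j > 0 and utr[j - 1] == m8_comp
        has_a1 = j + 6 < len(utr) and utr[j + 6] == "A"
        if has_m8 and has_a1:
            sites.append(SeedSite(j - 1, j + 7, "8mer"))
        elif has_m8:
            sites.append(SeedSite(j - 1, j + 6, "7mer-m8"))
        elif has_a1:
            sites.append(SeedSite(j, j + 7, "7mer-A1"))
        else:
            sites.append(SeedSite(j, j + 6, "6mer"))
        j = utr.find(core, j + 1)
    return sites


def _pair_score(mirna_pos: int, x: str, y: str) -> float:
    kind = _pair_kind(x, y)
    base = MATCH if kind == "wc" else WOBBLE if kind == "wobble" else MISMATCH
    if SEED_FIRST <= mirna_pos <= SEED_LAST:
        base *= SEED_WEIGHT
    return base


def align_duplex(mirna_seq: str, utr_window: str) -> tuple[float, list[BasePair]]:
    """Local (Smith-Waterman/Gotoh) alignment of the reversed miRNA against a
    UTR window; returns (max raw score, complementary paired positions).

    The miRNA is reversed so both strings run in the window's 5'->3' frame;
    gap penalties are affine and not seed-weighted, and a gap on one strand
    cannot be immediately followed by a gap on the other (an aligned pair
    must intervene).  Only Watson-Crick and G:U paired positions are
    reported in the pairing (mismatched aligned positions break stacking
    adjacency).
    """
    a = canonical(mirna_seq)[::-1] if mirna_seq else ""
    b = canonical(utr_window) if utr_window else ""
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0.0, []
    mirna_len = len(a)
    neg = float("-inf")
    # DP matrices: M = a[i-1] aligned to b[j-1]; X = gap in window; Y = gap in miRNA
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]
    Y = [[neg] * (m + 1) for _ in range(n + 1)]
    best, best_ij = 0.0, None
    for i in range(1, n + 1):
        pos = mirna_len - (i - 1)  # 1-based miRNA position of a[i-1]
        Mi, Mi1 = M[i], M[i - 1]
        Xi, Xi1 = X[i], X[i - 1]
        Yi = Y[i]
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = _pair_score(pos, ai, b[j - 1])
            diag = max(Mi1[j - 1], Xi1[j - 1], Y[i - 1][j - 1])
            Mi[j] = max(0.0, diag + s)
            Xi[j] = max(Mi1[j] + GAP_OPEN, Xi1[j] + GAP_EXTEND)
            Yi[j] = max(Mi[j - 1] + GAP_OPEN, Yi[j - 1] + GAP_EXTEND)
            if Mi[j] > best:
                best, best_ij = Mi[j], (i, j)

    if best_ij is None:
        return 0.0, []
    # traceback from the best match cell
    pairing: list[BasePair] = []
    i, j = best_ij
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            pos = mirna_len - (i - 1)
            if _pair_kind(a[i - 1], b[j - 1]) is not None:
                pairing.append(BasePair(pos, j - 1, a[i - 1], b[j - 1]))
            # M[i][j] = diag + s with diag = max(M,X,Y)[i-1][j-1] (>= 0)
            diag = M[i][j] - _pair_score(pos, a[i - 1], b[j - 1])
            if abs(M[i - 1][j - 1] - diag) < 1e-9:
                if M[i - 1][j - 1] <= 1e-12:
                    break  # local alignment starts here
                state = "M"
            elif abs(X[i - 1][j - 1] - diag) < 1e-9:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "X":
            if abs(M[i - 1][j] + GAP_OPEN - X[i][j]) < 1e-9:
                state = "M"
            i -= 1
        else:  # Y
            if abs(M[i][j - 1] + GAP_OPEN - Y[i][j]) < 1e-9:
                state = "M"
            j -= 1
    pairing.reverse()
    return best, pairing


def duplex_energy(pairing: list[BasePair]) -> float:
    """Stacking-energy proxy (kcal/mol) of a duplex pairing.

    Each stack of two pairs adjacent on both strands contributes -3.0 (both
    G:C), -2.0 (one G:C), or -1.0 (both A:U / G:U); everything else 0.
    """
    energy = 0.0
    for p, q in zip(pairing, pairing[1:]):
        if q.target_pos == p.target_pos + 1 and q.mirna_pos == p.mirna_pos - 1:
            gc_p = frozenset((p.mirna_base, p.target_base)) == frozenset(("G", "C"))
            gc_q = frozenset((q.mirna_base, q.target_base)) == frozenset(("G", "C"))
            energy += -3.0 if gc_p and gc_q else -2.0 if gc_p or gc_q else -1.0
    return energy


HIT_COLUMNS = ["mirna_id", "gene_id", "start", "end", "match_class", "score", "energy", "best_site"]


def predict_targets(
    mirnas: Mapping[str, str],
    utrs: Mapping[str, str],
    score_min: float = DEFAULT_SCORE_MIN,
    energy_max: float = DEFAULT_ENERGY_MAX,
    score_scale: float = DEFAULT_SCORE_SCALE,
    flank: int = 4,
) -> pd.DataFrame:
    """Predict target sites for every (miRNA, UTR) pair.

    Seed sites anchor candidate windows (extended by the miRNA length
    5'-ward on the UTR to accommodate 3'-end pairing, plus ``flank`` bases);
    each window is re-scored by :func:`align_duplex` and kept iff
    ``score > score_min`` and ``energy < energy_max`` (both strict).  The
    best-scoring site per (miRNA, gene) pair is flagged.
    """
    rows = []
    for mirna_id, mseq in mirnas.items():
        m = canonical(mseq)
        for gene_id, useq in utrs.items():
            utr = canonical(useq)
            seen: set[tuple[int, int]] = set()
            for site in find_seed_sites(m, utr):
                w_start = max(0, site.start - len(m) - flank)
                w_end = min(len(utr), site.end + flank)
                raw, pairing = align_duplex(m, utr[w_start:w_end])
                if not pairing:
                    continue
                score = raw * score_scale
                energy = duplex_energy(pairing)
                if not (score > score_min and energy < energy_max):
                    continue
                start = w_start + min(p.target_pos for p in pairing)
                end = w_start + max(p.target_pos for p in pairing) + 1
                if (start, end) in seen:
                    continue
                seen.add((start, end))
                rows.append((mirna_id, gene_id, start, end, site.match_class, score, energy))
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS[:-1])
    hits["best_site"] = False
    if len(hits):
        best_idx = hits.groupby(["mirna_id", "gene_id"])["score"].idxmax()
        hits.loc[best_idx, "best_site"] = True
    return hits


def intersect_predictions(hits_a: pd.DataFrame, hits_b: pd.DataFrame) -> pd.DataFrame:
    """Rows of ``hits_a`` whose (miRNA, gene) pair also occurs in ``hits_b``."""
    keys_b = set(zip(hits_b["mirna_id"], hits_b["gene_id"]))
    mask = [
        (m, g) in keys_b for m, g in zip(hits_a["mirna_id"], hits_a["gene_id"])
    ]
    return hits_a[pd.Series(mask, index=hits_a.index)].copy()
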