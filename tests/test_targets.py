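import itertools

import numpy as np
import pandas as pd
import pytest

from mirlocus.synthdata import reverse_complement
from mirlocus.targets import (
    GAP_EXTEND,
    GAP_OPEN,
    BasePair,
    align_duplex,
    duplex_energy,
    find_seed_sites,
    intersect_predictions,
    predict_targets,
)

BASES = "ACGU"
COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def random_rna(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_seed_sites(mirna, utr):
    """Window-by-window re-derivation of the seed classes."""
    sites = []
    core = "".join(COMP[b] for b in mirna[1:7])[::-1]
    for j in range(len(utr) - 5):
        if utr[j:j + 6] != core:
            continue
        m8 = j >= 1 and utr[j - 1] == COMP[mirna[7]]
        a1 = j + 6 < len(utr) and utr[j + 6] == "A"
        if m8 and a1:
            sites.append((j - 1, j + 7, "8mer"))
        elif m8:
            sites.append((j - 1, j + 6, "7mer-m8"))
        elif a1:
            sites.append((j, j + 7, "7mer-A1"))
        else:
            sites.append((j, j + 6, "6mer"))
    return sites


def pair_score(mirna_len, pos, x, y):
    pair = frozenset((x, y))
    if pair == frozenset(("A", "U")) or pair == frozenset(("G", "C")):
        s = 5.0
    elif pair == frozenset(("G", "U")):
        s = 2.0
    else:
        s = -3.0
    if 2 <= pos <= 8:
        s *= 2.0
    return s


def gap_cost(k):
    return 0.0 if k == 0 else GAP_OPEN + GAP_EXTEND * (k - 1)


def oracle_align_cubic(mirna, window):
    """Best-chain DP written from the model definition: P(i,j) is the best
    score of a local alignment whose last aligned pair is (reversed-miRNA i,
    window j); predecessors may be separated by a gap on one strand only."""
    a = mirna[::-1]
    n, m = len(a), len(window)
    P = np.full((n, m), -np.inf)
    best = 0.0
    for i in range(n):
        pos = len(a) - i  # 1-based miRNA position
        for j in range(m):
            s = pair_score(n, pos, a[i], window[j])
            cand = [0.0]
            if i > 0 and j > 0:
                cand.append(P[i - 1, j - 1])
                for k in range(1, i):  # gap in window strand
                    cand.append(P[i - 1 - k, j - 1] + gap_cost(k))
                for k in range(1, j):  # gap in miRNA strand
                    cand.append(P[i - 1, j - 1 - k] + gap_cost(k))
            P[i, j] = s + max(cand)
            best = max(best, P[i, j])
    return best


def oracle_align_enumerate(mirna, window):
    """Exhaustive enumeration over all monotone pair chains (tiny inputs)."""
    a = mirna[::-1]
    n, m = len(a), len(window)
    best = 0.0
    cells = [(i, j) for i in range(n) for j in range(m)]

    def extend(chain_score, i, j):
        nonlocal best
        best = max(best, chain_score)
        for i2 in range(i + 1, n):
            for j2 in range(j + 1, m):
                gi, gj = i2 - i - 1, j2 - j - 1
                if gi > 0 and gj > 0:
                    continue  # double gap not allowed by the model
                s = pair_score(n, len(a) - i2, a[i2], window[j2])
                extend(chain_score + gap_cost(gi) + gap_cost(gj) + s, i2, j2)

    for i, j in cells:
        extend(pair_score(n, len(a) - i, a[i], window[j]), i, j)
    return best


# ---------------------------------------------------------------------------
# seed scanner
# ---------------------------------------------------------------------------

class TestSeedSites:
    MIRNA = "UGAGGUAGUAGGUUGUAUAGUU"

    def site_core(self):  # rc of positions 2-7 (GAGGUA)
        return reverse_complement(self.MIRNA[1:7])

    def test_8mer_construction(self):
        # rc of nt 2-8 with an A at the UTR position opposite nt 1
        utr = "CCCC" + reverse_complement(self.MIRNA[1:8]) + "A" + "CCCC"
        sites = find_seed_sites(self.MIRNA, utr)
        assert [(s.start, s.end, s.match_class) for s in sites] == [(4, 12, "8mer")]

    def test_7mer_m8(self):
        utr = "CCCC" + reverse_complement(self.MIRNA[1:8]) + "C" + "CCCC"
        assert [s.match_class for s in find_seed_sites(self.MIRNA, utr)] == ["7mer-m8"]

    def test_7mer_a1(self):
        # left flank must not complement miRNA nt 8 (G), so avoid C there
        utr = "AAAG" + reverse_complement(self.MIRNA[1:7]) + "A" + "CCCC"
        assert [s.match_class for s in find_seed_sites(self.MIRNA, utr)] == ["7mer-A1"]

    def test_6mer(self):
        utr = "AAAG" + reverse_complement(self.MIRNA[1:7]) + "C" + "CCCC"
        assert [s.match_class for s in find_seed_sites(self.MIRNA, utr)] == ["6mer"]

    def test_no_complement_no_hits(self):
        assert find_seed_sites(self.MIRNA, "CCCCCCCCCCCCCCCCCC") == []

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            find_seed_sites("ACGUACG", "ACGUACGUACGU")

    def test_matches_oracle_on_random_pairs(self, rng):
        for _ in range(300):
            mirna = random_rna(rng, int(rng.integers(19, 23)))
            # enrich the UTR with seed complements so hits actually occur
            utr = random_rna(rng, 80)
            if rng.random() < 0.5:
                ins = reverse_complement(mirna[1:8]) + ("A" if rng.random() < 0.5 else "C")
                pos = int(rng.integers(0, 70))
                utr = utr[:pos] + ins + utr[pos + len(ins):]
            got = [(s.start, s.end, s.match_class) for s in find_seed_sites(mirna, utr)]
            assert got == oracle_seed_sites(mirna, utr)


# ---------------------------------------------------------------------------
# aligner / energy
# ---------------------------------------------------------------------------

class TestAlignDuplex:
    def test_perfect_22mer_hand_sum(self):
        m = "UGAGGUAGUAGGUUGUAUAGUU"
        score, pairing = align_duplex(m, reverse_complement(m))
        # 22 matches at +5 plus doubled seed (nt 2-8) adds 7 * 5
        assert score == 5 * 22 + 5 * 7 == 145
        assert len(pairing) == 22

    def test_empty_window(self):
        assert align_duplex("UGAGGUAGUAGGUUGUAUAGUU", "") == (0.0, [])

    def test_planted_site_is_best_window(self, rng):
        for _ in range(20):
            m = random_rna(rng, 22)
            site = reverse_complement(m)
            utr = random_rna(rng, 60) + site + random_rna(rng, 60)
            full_score, _ = align_duplex(m, utr)
            site_score, _ = align_duplex(m, site)
            assert full_score == site_score  # perfect duplex dominates

    def test_matches_cubic_oracle(self, rng):
        for _ in range(250):
            m = random_rna(rng, int(rng.integers(9, 13)))
            w = random_rna(rng, int(rng.integers(10, 21)))
            got, _ = align_duplex(m, w)
            assert got == pytest.approx(oracle_align_cubic(m, w))

    def test_matches_exhaustive_enumeration_tiny(self, rng):
        for _ in range(40):
            m = random_rna(rng, int(rng.integers(8, 10)))
            w = random_rna(rng, int(rng.integers(3, 6)))
            got, _ = align_duplex(m, w)
            assert got == pytest.approx(oracle_align_enumerate(m, w))


class TestDuplexEnergy:
    def pairs(self, bases):
        # contiguous duplex over the given miRNA bases
        return [
            BasePair(len(bases) - i, i, b, COMP[b]) for i, b in enumerate(bases)
        ]

    def test_empty(self):
        assert duplex_energy([]) == 0.0

    def test_ten_gc_stacks(self):
        assert duplex_energy(self.pairs("G" * 10)) == pytest.approx(-27.0)

    def test_mixed_stacks(self):
        # G:C next to A:U -> -2; A:U next to A:U -> -1
        assert duplex_energy(self.pairs("GA")) == pytest.approx(-2.0)
        assert duplex_energy(self.pairs("AA")) == pytest.approx(-1.0)

    def test_gap_breaks_stacking(self):
        pairing = self.pairs("GG")
        broken = [pairing[0], pairing[1]._replace(target_pos=pairing[1].target_pos + 1)]
        assert duplex_energy(broken) == 0.0

    def test_monotone_in_added_pairs(self, rng):
        bases = random_rna(rng, 12)
        energies = [duplex_energy(self.pairs(bases[:k])) for k in range(1, 13)]
        assert all(b <= a for a, b in zip(energies, energies[1:]))


# ---------------------------------------------------------------------------
# prediction / filtering
# ---------------------------------------------------------------------------

class TestPredictTargets:
    def planted(self, rng, n=5):
        mirnas, utrs = {}, {}
        for i in range(n):
            m = "U" + random_rna(rng, 21)
            while "G" not in m[1:] and "C" not in m[1:]:
                m = "U" + random_rna(rng, 21)
            mirnas[f"mir{i}"] = m
            utrs[f"gene{i}"] = random_rna(rng, 50) + reverse_complement(m) + random_rna(rng, 50)
        return mirnas, utrs

    def test_planted_complements_pass_default_filters(self, rng):
        mirnas, utrs = self.planted(rng)
        hits = predict_targets(mirnas, utrs)
        found = set(zip(hits["mirna_id"], hits["gene_id"]))
        assert {(f"mir{i}", f"gene{i}") for i in range(5)} <= found
        planted = hits[hits["score"] == hits["score"].max()]
        assert (planted["score"] > 150).all() and (planted["energy"] < -20).all()

    def test_score_threshold_strict(self, rng):
        mirnas, utrs = self.planted(rng, n=1)
        best = predict_targets(mirnas, utrs)["score"].max()
        at_cut = predict_targets(mirnas, utrs, score_min=best)
        assert not ((at_cut["mirna_id"] == "mir0") & (at_cut["gene_id"] == "gene0") &
                    (at_cut["score"] >= best)).any()  # strict >
        below = predict_targets(mirnas, utrs, score_min=best - 1)
        assert (below["score"] == best).any()

    def test_energy_threshold_strict(self, rng):
        mirnas, utrs = self.planted(rng, n=1)
        hits = predict_targets(mirnas, utrs)
        e = hits["energy"].min()
        assert len(predict_targets(mirnas, utrs, energy_max=e)) < len(hits)  # strict <

    def test_best_site_flag(self, rng):
        mirnas, utrs = self.planted(rng, n=1)
        m = mirnas["mir0"]
        utrs["gene0"] += random_rna(rng, 10) + reverse_complement(m)  # second site
        hits = predict_targets(mirnas, utrs)
        chunk = hits[(hits["mirna_id"] == "mir0") & (hits["gene_id"] == "gene0")]
        assert len(chunk) >= 2 and chunk["best_site"].sum() == 1
        assert chunk.loc[chunk["best_site"], "score"].iloc[0] == chunk["score"].max()

    def test_random_utr_rarely_hits(self, rng):
        mirnas = {"m": "U" + random_rna(rng, 21)}
        utrs = {f"g{i}": random_rna(rng, 300) for i in range(30)}
        hits = predict_targets(mirnas, utrs)
        assert len(hits) <= 2  # default filters remove chance seed matches


class TestIntersect:
    def frame(self, pairs):
        return pd.DataFrame(
            [(m, g, 0, 10, "8mer", 200.0, -30.0, True) for m, g in pairs],
            columns=["mirna_id", "gene_id", "start", "end", "match_class",
                     "score", "energy", "best_site"],
        )

    def test_disjoint_empty(self):
        a, b = self.frame([("m1", "g1")]), self.frame([("m2", "g2")])
        assert len(intersect_predictions(a, b)) == 0

    def test_identical_identity(self):
        a = self.frame([("m1", "g1"), ("m2", "g2")])
        pd.testing.assert_frame_equal(intersect_predictions(a, a), a)

    def test_matches_key_intersection_oracle(self, rng):
        keys = [(f"m{i}", f"g{j}") for i in range(6) for j in range(6)]
        pick = lambda: [keys[i] for i in rng.choice(len(keys), size=12, replace=False)]
        a, b = self.frame(pick()), self.frame(pick())
        got = set(zip(intersect_predictions(a, b)["mirna_id"],
                      intersect_predictions(a, b)["gene_id"]))
        expect = set(zip(a["mirna_id"], a["gene_id"])) & set(zip(b["mirna_id"], b["gene_id"]))
        assert got == expect


def test_involution_property(rng):
    # planting a site guarantees discovery; shuffling the UTR destroys it
    hits = misses = 0
    for _ in range(40):
        m = "U" + random_rna(rng, 21)
        utr = random_rna(rng, 40) + reverse_complement(m) + random_rna(rng, 40)
        assert find_seed_sites(m, utr)
        shuffled = "".join(rng.permutation(list(utr)))
        if not find_seed_sites(m, shuffled):
            misses += 1
    assert misses >= 35  # destroyed with probability -> 1
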