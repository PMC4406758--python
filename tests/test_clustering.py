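"""Dereplication and greedy 97% clustering, checked against an independent
Needleman-Wunsch + first-fit oracle, plus the two-parent chimera check."""

import numpy as np
import pytest

import ampliqc as aq
from ampliqc._core import Read


# --- independent oracle: plain NW (match +1 / mismatch -1 / gap -2) ----------

def nw_identity(a: str, b: str) -> float:
    """Max-score global alignment, then identity = matches / columns.

    Pure-DP reimplementation with traceback, independent of the package's
    alignment backend.
    """
    if not a and not b:
        return 1.0
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = -2.0 * np.arange(n + 1)
    score[0, :] = -2.0 * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + (1.0 if a[i - 1] == b[j - 1] else -1.0)
            score[i, j] = max(diag, score[i - 1, j] - 2.0, score[i, j - 1] - 2.0)
    # traceback counting matches and columns
    i, j, matches, cols = n, m, 0, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
            1.0 if a[i - 1] == b[j - 1] else -1.0
        ):
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and score[i, j] == score[i - 1, j] - 2.0:
            i -= 1
        else:
            j -= 1
        cols += 1
    return matches / cols


def first_fit_oracle(uniques, threshold):
    """First-fit clustering by abundance order, over the oracle identity."""
    centroids = []
    assignment = []
    for u in uniques:
        for k, c in enumerate(centroids):
            if nw_identity(u.sequence, c) >= threshold:
                assignment.append(k)
                break
        else:
            centroids.append(u.sequence)
            assignment.append(len(centroids) - 1)
    return centroids, assignment


def _reads(seqs):
    return [Read(id=f"r{i}", sequence=s, quality="I" * len(s)) for i, s in enumerate(seqs)]


class TestDereplicate:
    def test_identical_reads_collapse(self):
        uniques = aq.dereplicate(_reads(["ACGT"] * 5))
        assert len(uniques) == 1 and uniques[0].count == 5
        assert uniques[0].member_ids == [f"r{i}" for i in range(5)]

    def test_order_count_desc_sequence_asc(self):
        uniques = aq.dereplicate(_reads(["AT", "AA", "AA"]))
        assert [(u.sequence, u.count) for u in uniques] == [("AA", 2), ("AT", 1)]

    def test_count_conservation(self):
        seqs = ["ACGT", "ACGA", "ACGT", "TTTT", "ACGA", "ACGT"]
        assert sum(u.count for u in aq.dereplicate(_reads(seqs))) == len(seqs)


class TestIdentity:
    def test_identical(self):
        s = "ACGT" * 25
        assert aq.identity(s, s) == 1.0

    def test_three_mismatches_in_hundred(self):
        a = "A" * 100
        b = "T" * 3 + "A" * 97
        assert aq.identity(a, b) == pytest.approx(0.97)

    def test_single_base_mismatch(self):
        assert aq.identity("A", "T") == 0.0

    def test_terminal_gap_penalized(self):
        # 100-mer vs its 90-mer prefix: 10 gap columns count in the denominator
        a = "ACGT" * 25
        assert aq.identity(a, a[:90]) == pytest.approx(0.90)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nw_oracle_on_near_identical(self, seed):
        """On lightly mutated pairs the optimal alignment is essentially
        unique, so the oracle identity must agree exactly.  (Unrelated random
        pairs admit many co-optimal alignments with different match counts,
        so identity there is not uniquely defined.)"""
        rng = np.random.default_rng(seed)
        a = "".join("ACGT"[i] for i in rng.integers(4, size=60))
        b = list(a)
        for pos in rng.choice(60, size=3, replace=False):
            b[pos] = "ACGT"[rng.integers(4)]
        if seed % 2:
            del b[30]  # one interior deletion
        b = "".join(b)
        assert aq.identity(a, b) == pytest.approx(nw_identity(a, b))


class TestClusterOTUs:
    def test_close_unique_joins_top_centroid(self):
        base = "ACGT" * 25
        variant = "T" + base[1:]  # 99% identical
        otus = aq.cluster_otus([aq.UniqueSeq(base, 10), aq.UniqueSeq(variant, 2)])
        assert len(otus) == 1 and otus[0].abundance == 12

    def test_divergent_uniques_split(self):
        a = "A" * 100
        b = "T" * 4 + "A" * 96  # 96% < 97%
        otus = aq.cluster_otus([aq.UniqueSeq(a, 5), aq.UniqueSeq(b, 3)])
        assert len(otus) == 2

    def test_empty_input(self):
        assert aq.cluster_otus([]) == []

    def test_abundance_conservation_and_member_identity(self, panel3):
        rng = np.random.default_rng(0)
        seqs = []
        for rec in panel3:
            seqs += [rec.sequence] * int(rng.integers(5, 20))
            mutated = "T" + rec.sequence[1:]
            seqs += [mutated] * 2
        uniques = aq.dereplicate(_reads(seqs))
        otus = aq.cluster_otus(uniques)
        assert sum(o.abundance for o in otus) == sum(u.count for u in uniques) == len(seqs)
        for o in otus:
            for m in o.members:
                assert aq.identity(m.sequence, o.centroid) >= 0.97

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_exhaustive_first_fit_oracle(self, seed):
        """Random abundance-ordered sets of <= 8 uniques match the oracle."""
        rng = np.random.default_rng(seed)
        base = "".join("ACGT"[i] for i in rng.integers(4, size=40))
        uniques = []
        counts = sorted(rng.integers(1, 100, size=rng.integers(2, 9)), reverse=True)
        for k, c in enumerate(counts):
            seq = list(base)
            for pos in rng.choice(40, size=rng.integers(0, 6), replace=False):
                seq[pos] = "ACGT"[rng.integers(4)]
            uniques.append(aq.UniqueSeq("".join(seq), int(c)))
        uniques.sort(key=lambda u: (-u.count, u.sequence))
        otus = aq.cluster_otus(uniques, 0.95)
        centroids, assignment = first_fit_oracle(uniques, 0.95)
        assert [o.centroid for o in otus] == centroids
        got = [
            next(k for k, o in enumerate(otus) if u in o.members) for u in uniques
        ]
        assert got == assignment


class TestChimeraDetection:
    def _parents(self):
        p = aq.random_panel(2, 100, min_divergence=0.08, seed=13)
        return p.records[0].sequence, p.records[1].sequence

    def test_exact_recombinant_flagged(self):
        a, b = self._parents()
        uniques = [
            aq.UniqueSeq(a, 100),
            aq.UniqueSeq(b, 80),
            aq.UniqueSeq(a[:50] + b[50:], 10),
        ]
        assert aq.detect_chimeras(uniques) == [False, False, True]

    def test_parent_never_flagged(self):
        a, b = self._parents()
        flags = aq.detect_chimeras([aq.UniqueSeq(a, 50), aq.UniqueSeq(b, 50)])
        assert flags == [False, False]

    def test_abundant_candidate_not_flagged(self):
        a, b = self._parents()
        uniques = [
            aq.UniqueSeq(a[:50] + b[50:], 200),  # more abundant than both parents
            aq.UniqueSeq(a, 100),
            aq.UniqueSeq(b, 80),
        ]
        assert aq.detect_chimeras(uniques)[0] is False

    def test_breakpoint_scan_oracle(self):
        """Flagged iff some breakpoint beats the best single parent by >= 3."""
        a, b = self._parents()
        cand = a[:30] + b[30:]
        uniques = [aq.UniqueSeq(a, 100), aq.UniqueSeq(b, 100), aq.UniqueSeq(cand, 5)]
        mism_a = [x != y for x, y in zip(cand, a)]
        mism_b = [x != y for x, y in zip(cand, b)]
        best_single = min(sum(mism_a), sum(mism_b))
        best_two = min(
            min(sum(mism_a[:k]) + sum(mism_b[k:]) for k in range(1, 100)),
            min(sum(mism_b[:k]) + sum(mism_a[k:]) for k in range(1, 100)),
        )
        expected = best_two <= best_single - 3
        assert aq.detect_chimeras(uniques)[2] == expected is True
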