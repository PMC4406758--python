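"""Dereplication, greedy abundance-ordered 97% centroid clustering, and a
minimal de-novo two-parent chimera (bimera) check.

The clustering follows the greedy centroid family: uniques are scanned in
decreasing-abundance order and each one joins the FIRST existing centroid
whose global-alignment identity reaches the threshold, else founds a new
centroid.  Identity is matches / alignment columns with terminal gaps
penalized, so length differences are meaningful — consistent with
full-length dereplication upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio.Align import PairwiseAligner

from ._core import Read


@dataclass
class UniqueSeq:
    """A dereplicated sequence with retained abundance."""

    sequence: str
    count: int
    member_ids: list[str] = field(default_factory=list)


@dataclass
class OTU:
    """A 97%-identity cluster: centroid plus members with summed abundance."""

    centroid: str
    members: list[UniqueSeq] = field(default_factory=list)

    @property
    def abundance(self) -> int:
        return sum(m.count for m in self.members)


def dereplicate(reads: Sequence[Read | str]) -> list[UniqueSeq]:
    """Collapse exactly identical full-length sequences, keeping counts.

    Output is sorted by (count desc, sequence asc) — the deterministic
    abundance order the clustering step assumes.
    """
    buckets: dict[str, UniqueSeq] = {}
    for i, r in enumerate(reads):
        seq = r if isinstance(r, str) else r.sequence
        rid = str(i) if isinstance(r, str) else r.id
        u = buckets.get(seq)
        if u is None:
            buckets[seq] = UniqueSeq(seq, 1, [rid])
        else:
            u.count += 1
            u.member_ids.append(rid)
    return sorted(buckets.values(), key=lambda u: (-u.count, u.sequence))


def _aligner(match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0) -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap
    a.extend_gap_score = gap
    return a


_DEFAULT_ALIGNER = _aligner()


@lru_cache(maxsize=200_000)
def _align_counts(a: str, b: str) -> tuple[int, int, int]:
    """(identities, mismatches, gap columns) of the best global alignment."""
    if a == b:
        return len(a), 0, 0
    aln = _DEFAULT_ALIGNER.align(a, b)[0]
    c = aln.counts()
    return int(c.identities), int(c.mismatches), int(c.gaps)


def identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns (gaps included)."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    ident, mism, gaps = _align_counts(a, b)
    return ident / (ident + mism + gaps)


def cluster_otus(uniques: Sequence[UniqueSeq], threshold: float = 0.97) -> list[OTU]:
    """Greedy first-fit centroid clustering over abundance-ordered uniques."""
    otus: list[OTU] = []
    for u in uniques:
        for otu in otus:
            if identity(u.sequence, otu.centroid) >= threshold:
                otu.members.append(u)
                break
        else:
            otus.append(OTU(centroid=u.sequence, members=[u]))
    return otus


def _mismatch_profile(candidate: str, parent: str) -> tuple[np.ndarray, int]:
    """Per-candidate-position mismatch indicator against one parent.

    Derived from the global alignment; a candidate base aligned to a gap or
    a differing parent base counts as a mismatch at that candidate position.
    Returns (indicator vector over candidate positions, total mismatches
    including parent bases deleted from the candidate).
    """
    if candidate == parent:
        return np.zeros(len(candidate), dtype=np.int64), 0
    aln = _DEFAULT_ALIGNER.align(candidate, parent)[0]
    prof = np.zeros(len(candidate), dtype=np.int64)
    extra = 0  # parent bases absent from the candidate
    ca, pa = aln[0], aln[1]  # aligned strings with '-'
    ci = 0
    for x, y in zip(ca, pa):
        if x == "-":
            extra += 1
            continue
        if y == "-" or x != y:
            prof[ci] += 1
        ci += 1
    return prof, int(prof.sum() + extra)


def detect_chimeras(
    uniques: Sequence[UniqueSeq],
    min_fold: float = 2.0,
    min_improve: int = 3,
) -> list[bool]:
    """Flag uniques explainable as a two-parent recombinant.

    A candidate is flagged iff two distinct more-abundant uniques (each with
    count >= min_fold * candidate count) admit a breakpoint where the
    left-from-A plus right-from-B mismatch total undercuts the best single
    parent by at least ``min_improve`` mismatches.
    """
    flags = [False] * len(uniques)
    for ci, cand in enumerate(uniques):
        parents = [
            u for u in uniques
            if u.sequence != cand.sequence and u.count >= min_fold * cand.count
        ]
        if len(parents) < 2:
            continue
        profiles = [_mismatch_profile(cand.sequence, p.sequence) for p in parents]
        best_single = min(total for _, total in profiles)
        if best_single < min_improve:
            continue
        L = len(cand.sequence)
        # prefix sums: pref[k] = mismatches of candidate[:k] against the parent
        prefs = [np.concatenate(([0], np.cumsum(prof))) for prof, _ in profiles]
        best_two = best_single
        for ai in range(len(parents)):
            for bi in range(len(parents)):
                if ai == bi:
                    continue
                combo = prefs[ai][:L + 1] + (prefs[bi][L] - prefs[bi][:L + 1])
                # interior breakpoints only
                if L >= 2:
                    best_two = min(best_two, int(combo[1:L].min()))
        if best_two <= best_single - min_improve:
            flags[ci] = True
    return flags
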