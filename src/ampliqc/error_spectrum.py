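"""Per-base error spectrum of a single-source amplicon.

Reads are repeatedly subsampled (default 25 subsamples of 1,000 reads);
within each subsample the most abundant unique sequence is taken as the
reference — for a single-source sample it is very likely the true template
— and every read is globally aligned to it.  The error at each reference
position is the percentage of reads whose aligned symbol differs from the
reference base there (a gap counts as a difference; read insertions are
not scored, keeping the profile anchored on reference coordinates).  The
per-subsample error is the mean over positions, and the overall error the
mean over subsamples.  Errors above 1% at a single base are flagged as
hotspots; 5-bp window means reproduce the segment-level view.

The original procedure built one multiple alignment per subsample; this
module substitutes per-read pairwise global alignment to the reference,
which is deterministic and equivalent when indel rates are low.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

from typing import Sequence

import edlib
import numpy as np

from ._core import Read
from .clustering import dereplicate

HOTSPOT_PCT = 1.0

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class SubsampleSpec:
    depth: int = 1000
    reps: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.reps < 1:
            raise ValueError("depth and reps must be >= 1")


@dataclass
class ErrorProfile:
    reference: str
    per_base_pct: np.ndarray          # % over reference positions, averaged over reps
    per_subsample_mean: np.ndarray    # % per subsample
    overall_mean: float               # % — mean over subsamples
    overall_sd: float                 # % — sd over subsamples (ddof=1)
    windows_5bp: np.ndarray           # % per 5-bp window
    hotspots: list[int]               # 0-based reference positions > 1%


def subsample(reads: Sequence[Read], spec: SubsampleSpec) -> list[list[Read]]:
    """Draw ``reps`` independent subsamples of ``depth`` reads, without replacement."""
    if len(reads) < spec.depth:
        raise ValueError(f"cannot subsample {spec.depth} from {len(reads)} reads")
    rng = np.random.default_rng(spec.seed)
    return [
        [reads[i] for i in rng.choice(len(reads), size=spec.depth, replace=False)]
        for _ in range(spec.reps)
    ]


def reference_from_abundance(reads: Sequence[Read | str]) -> str:
    """Most abundant sequence after dereplication; ties break lexicographically."""
    uniques = dereplicate(reads)
    if not uniques:
        raise ValueError("no reads")
    return uniques[0].sequence  # dereplicate sorts (count desc, sequence asc)


def _diff_positions(seq: str, reference: str) -> tuple[np.ndarray, np.ndarray]:
    """Reference positions where an aligned read differs (mismatch or deletion)."""
    res = edlib.align(seq, reference, task="path")
    mism: list[int] = []
    dele: list[int] = []
    pos = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        if op == "=":
            pos += n
        elif op in ("X", "M"):
            mism.extend(range(pos, pos + n))
            pos += n
        elif op == "D":  # reference bases missing from the read
            dele.extend(range(pos, pos + n))
            pos += n
        # op == "I": read insertion, not a reference column — unscored
    return np.array(mism, dtype=np.int64), np.array(dele, dtype=np.int64)


def per_base_error(reads: Sequence[Read | str], reference: str) -> np.ndarray:
    """Percentage of reads differing from the reference at each of its positions."""
    L = len(reference)
    counts = np.zeros(L, dtype=np.int64)
    # dereplicate to align each distinct sequence once, then expand by count
    for u in dereplicate(reads):
        if u.sequence == reference:
            continue
        mism, dele = _diff_positions(u.sequence, reference)
        for idx in (mism, dele):
            if idx.size:
                counts[idx[idx < L]] += u.count
    n = len(reads)
    return 100.0 * counts / n if n else np.zeros(L)


def windows(per_base_pct: np.ndarray, width: int = 5) -> np.ndarray:
    """Mean error over consecutive non-overlapping windows (last may be short)."""
    return np.array(
        [per_base_pct[i : i + width].mean() for i in range(0, len(per_base_pct), width)]
    )


def profile(reads: Sequence[Read], spec: SubsampleSpec) -> ErrorProfile:
    """Full error-spectrum computation: subsample, re-reference, align, summarise."""
    subs = subsample(reads, spec)
    refs = [reference_from_abundance(s) for s in subs]
    per_rep = [per_base_error(s, r) for s, r in zip(subs, refs)]
    per_subsample_mean = np.array([p.mean() for p in per_rep])
    overall_mean = float(per_subsample_mean.mean())
    overall_sd = (
        float(per_subsample_mean.std(ddof=1)) if spec.reps > 1 else 0.0
    )
    # aggregate per-base profile over the subsamples sharing the modal reference
    modal_ref = Counter(refs).most_common(1)[0][0]
    stack = [p for p, r in zip(per_rep, refs) if r == modal_ref]
    per_base_pct = np.mean(stack, axis=0)
    return ErrorProfile(
        reference=modal_ref,
        per_base_pct=per_base_pct,
        per_subsample_mean=per_subsample_mean,
        overall_mean=overall_mean,
        overall_sd=overall_sd,
        windows_5bp=windows(per_base_pct),
        hotspots=[int(i) for i in np.nonzero(per_base_pct > HOTSPOT_PCT)[0]],
    )


def top_cluster_fraction(reads: Sequence[Read | str]) -> float:
    """Percentage of reads contained in the most abundant unique sequence."""
    if not reads:
        return 0.0
    return 100.0 * dereplicate(reads)[0].count / len(reads)
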