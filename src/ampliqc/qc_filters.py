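"""Quality-filtering (QFM) and abundance-filtering (AFM) variants.

Four named quality-filtering presets span the common definitions of a
"high quality sequence": no filtering, a minimum-Q-for-all-bases rule, a
mean-Q rule, and maximum-expected-error (maxee) filtering at 0.5.  The
abundance filters cover singleton removal and the "below 1% of the total"
rule with either reads or unique-sequence richness as the denominator.
All thresholds use strict inequality for "below": ties are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

from ._core import Read, expected_errors, qual_to_phred

if TYPE_CHECKING:  # pragma: no cover
    from .clustering import UniqueSeq

QFM_MODES = ("NONE", "MIN_Q_PERCENT", "MEAN_Q", "MAXEE")
AFM_MODES = ("NONE", "DROP_SINGLETONS", "FRACTION")


@dataclass(frozen=True)
class QFMSpec:
    name: str
    mode: str = "NONE"
    q: int = 15
    p: float = 100.0
    q_mean: float = 20.0
    threshold: float = 0.5
    primer_mismatch: int = 0

    def __post_init__(self) -> None:
        if self.mode not in QFM_MODES:
            raise ValueError(f"mode must be one of {QFM_MODES}")
        if not 0 <= self.q <= 41:
            raise ValueError("q must be in [0, 41]")
        if not 0 < self.p <= 100:
            raise ValueError("p must be in (0, 100]")
        if self.threshold <= 0:
            raise ValueError("maxee threshold must be > 0")
        if self.primer_mismatch not in (0, 2):
            raise ValueError("primer_mismatch must be 0 or 2")


@dataclass(frozen=True)
class AFMSpec:
    name: str
    mode: str = "NONE"
    f: float = 0.01
    denominator: str = "reads"  # or "uniques"

    def __post_init__(self) -> None:
        if self.mode not in AFM_MODES:
            raise ValueError(f"mode must be one of {AFM_MODES}")
        if not 0.0 < self.f < 1.0:
            raise ValueError("f must be in (0, 1)")
        if self.denominator not in ("reads", "uniques"):
            raise ValueError("denominator must be 'reads' or 'uniques'")


# Named presets.  QFM1/QFM4 permit individual bases below Q15; QFM2 does not.
QFM_PRESETS = {
    "QFM1": QFMSpec("QFM1", mode="NONE", primer_mismatch=0),
    "QFM2": QFMSpec("QFM2", mode="MIN_Q_PERCENT", q=15, p=100.0),
    "QFM3": QFMSpec("QFM3", mode="MEAN_Q", q_mean=20.0, primer_mismatch=2),
    "QFM4": QFMSpec("QFM4", mode="MAXEE", threshold=0.5),
}
AFM_PRESETS = {
    "AFM_none": AFMSpec("AFM_none", mode="NONE"),
    "AFM_singletons": AFMSpec("AFM_singletons", mode="DROP_SINGLETONS"),
    "AFM_1pct_reads": AFMSpec("AFM_1pct_reads", mode="FRACTION", f=0.01, denominator="reads"),
    "AFM_1pct_uniques": AFMSpec("AFM_1pct_uniques", mode="FRACTION", f=0.01, denominator="uniques"),
}


def filter_maxee(reads: Sequence[Read], threshold: float = 0.5) -> list[Read]:
    """Keep reads whose expected error sum(10^(-Q/10)) is <= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return [r for r in reads if expected_errors(r.quality) <= threshold]


def filter_qscore(reads: Sequence[Read], spec: QFMSpec) -> list[Read]:
    """Apply one quality-filtering variant to a read pool."""
    if spec.mode == "NONE":
        return list(reads)
    if spec.mode == "MAXEE":
        return filter_maxee(reads, spec.threshold)
    kept = []
    for r in reads:
        q = r.phred
        if q.size == 0:
            kept.append(r)
            continue
        if spec.mode == "MIN_Q_PERCENT":
            if 100.0 * np.count_nonzero(q >= spec.q) / q.size >= spec.p:
                kept.append(r)
        elif spec.mode == "MEAN_Q":
            if q.mean() >= spec.q_mean:
                kept.append(r)
    return kept


@dataclass(frozen=True)
class QualitySummary:
    """Post-filter quality statistics of a read pool at one Q cutoff."""

    q: int
    n_reads: int
    n_bases: int
    pct_reads_with_base_below_q: float
    pct_bases_below_q: float
    min_mean_q: float


def quality_summary(reads: Sequence[Read], q: int = 15) -> QualitySummary:
    """Exact counting of reads/bases below a Q cutoff, plus the minimum mean Q."""
    n_reads = len(reads)
    n_bases = 0
    reads_below = 0
    bases_below = 0
    min_mean = float("inf")
    for r in reads:
        phred = r.phred
        n_bases += phred.size
        below = int(np.count_nonzero(phred < q))
        bases_below += below
        if below:
            reads_below += 1
        if phred.size:
            min_mean = min(min_mean, float(phred.mean()))
    return QualitySummary(
        q=q,
        n_reads=n_reads,
        n_bases=n_bases,
        pct_reads_with_base_below_q=100.0 * reads_below / n_reads if n_reads else 0.0,
        pct_bases_below_q=100.0 * bases_below / n_bases if n_bases else 0.0,
        min_mean_q=min_mean if min_mean != float("inf") else float("nan"),
    )


def filter_abundance(
    uniques: Sequence["UniqueSeq"], afm: AFMSpec, total_reads: int
) -> list["UniqueSeq"]:
    """Remove low-abundance unique-sequence clusters.

    FRACTION mode removes clusters whose count is strictly below
    ``f * denominator`` where the denominator is either the total read count
    or the number of unique sequences (richness).  Counts of kept clusters
    are never modified.
    """
    if afm.mode == "NONE":
        return list(uniques)
    if afm.mode == "DROP_SINGLETONS":
        return [u for u in uniques if u.count > 1]
    denom = total_reads if afm.denominator == "reads" else len(uniques)
    cutoff = afm.f * denom
    return [u for u in uniques if not u.count < cutoff]
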