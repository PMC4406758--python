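"""Demultiplexing by dual MID tags, tag/primer trimming, and tag auditing.

Reads are assumed to be in forward orientation:

    tag_f + primer_f + insert + revcomp(primer_r) + revcomp(tag_r)

Tag matching is anchored and exact (no mismatches in length or base
composition); only the template-specific primers get a 0–2 substitution
allowance, IUPAC-aware and without indels.  A read that cannot be assigned
to a manifest (tag_f, tag_r) pair is either *unassigned* (tags absent or
mismatched) or *discarded* (contains an ambiguous base call such as N);
every input read lands in exactly one of the three bins.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._core import DNA_ALPHABET, Read, iupac_mismatches, revcomp

SAMPLESHEET_COLUMNS = ("sample", "tag_f", "tag_r", "primer_f", "primer_r")


@dataclass(frozen=True)
class SampleRow:
    sample_id: str
    tag_f: str
    tag_r: str
    primer_f: str
    primer_r: str


@dataclass
class SampleSheet:
    """Run manifest mapping samples to MID tag pairs and primer sets."""

    rows: list[SampleRow]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        pairs = [(r.tag_f, r.tag_r) for r in self.rows]
        if len(set(pairs)) != len(pairs):
            raise ValueError("(tag_f, tag_r) pairs must be unique")
        if self.rows:
            if len({len(r.tag_f) for r in self.rows}) != 1 or len(
                {len(r.tag_r) for r in self.rows}
            ) != 1:
                raise ValueError("tags must be fixed-length per run")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def tag_f_len(self) -> int:
        return len(self.rows[0].tag_f)

    @property
    def tag_r_len(self) -> int:
        return len(self.rows[0].tag_r)

    @property
    def tags_f(self) -> set[str]:
        return {r.tag_f for r in self.rows}

    @property
    def tags_r(self) -> set[str]:
        return {r.tag_r for r in self.rows}

    def pair_lookup(self) -> dict[tuple[str, str], SampleRow]:
        return {(r.tag_f, r.tag_r): r for r in self.rows}

    @classmethod
    def from_records(cls, records: Iterable[Sequence[str]]) -> "SampleSheet":
        return cls([SampleRow(*map(str, rec)) for rec in records])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = set(SAMPLESHEET_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"samplesheet missing columns: {sorted(missing)}")
        return cls.from_records(df[list(SAMPLESHEET_COLUMNS)].itertuples(index=False))

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(r.sample_id, r.tag_f, r.tag_r, r.primer_f, r.primer_r) for r in self.rows],
            columns=list(SAMPLESHEET_COLUMNS),
        )
        df.to_csv(path, sep="\t", index=False)


@dataclass
class DemuxReport:
    """Accounting of a demultiplexing pass over one read pool."""

    sample_counts: dict[str, int] = field(default_factory=dict)
    discarded_ambiguous: int = 0
    unassigned: int = 0
    total: int = 0
    # (tag_f, tag_r) -> count; both tags known but the pair is not in the manifest
    cross_combinations: Counter = field(default_factory=Counter)
    # (tag_f, tag_r) -> count; at least one tag absent from the manifest
    foreign_tags: Counter = field(default_factory=Counter)

    @property
    def assigned(self) -> int:
        return sum(self.sample_counts.values())

    @property
    def foreign_fraction(self) -> float:
        """Percentage of all input reads bearing >=1 tag absent from the manifest."""
        if self.total == 0:
            return 0.0
        return 100.0 * sum(self.foreign_tags.values()) / self.total

    def check_partition(self) -> None:
        if self.assigned + self.unassigned + self.discarded_ambiguous != self.total:
            raise AssertionError("demux partition accounting violated")


def discard_ambiguous(reads: Sequence[Read]) -> tuple[list[Read], int]:
    """Drop reads containing any base outside {A,C,G,T} (e.g. N calls)."""
    kept = [r for r in reads if set(r.sequence) <= DNA_ALPHABET]
    return kept, len(reads) - len(kept)


def _match_read(read: Read, row: SampleRow, primer_mismatch: int) -> Read | None:
    """Try to assign one read to one manifest row; return the trimmed read."""
    seq = read.sequence
    lf, lr = len(row.tag_f), len(row.tag_r)
    pf = row.primer_f
    pr_rc = revcomp(row.primer_r)
    trim_left = lf + len(pf)
    trim_right = lr + len(pr_rc)
    if len(seq) < trim_left + trim_right + 1:
        return None
    if not seq.startswith(row.tag_f):
        return None
    if not seq.endswith(revcomp(row.tag_r)):
        return None
    if iupac_mismatches(pf, seq[lf:trim_left]) > primer_mismatch:
        return None
    right_start = len(seq) - trim_right
    if iupac_mismatches(pr_rc, seq[right_start : len(seq) - lr]) > primer_mismatch:
        return None
    return read.replace(
        sequence=seq[trim_left : len(seq) - trim_right],
        quality=read.quality[trim_left : len(seq) - trim_right],
        sample=row.sample_id,
        prefix_len=0,
        suffix_len=0,
    )


def demultiplex(
    reads: Sequence[Read],
    sheet: SampleSheet,
    primer_mismatch: int = 0,
) -> tuple[dict[str, list[Read]], DemuxReport]:
    """Assign reads to samples by exact dual-tag match and trim tags+primers.

    Parameters
    ----------
    primer_mismatch:
        Substitutions tolerated in each template-specific primer (0, 1 or 2).
        Tags never tolerate mismatches.

    Returns per-sample trimmed reads plus a :class:`DemuxReport` whose audit
    tables (cross combinations, foreign tags) are filled in from the
    unassigned pool.
    """
    if primer_mismatch not in (0, 1, 2):
        raise ValueError("primer_mismatch must be 0, 1 or 2")
    report = DemuxReport(total=len(reads))
    by_sample: dict[str, list[Read]] = {r.sample_id: [] for r in sheet}
    kept, report.discarded_ambiguous = discard_ambiguous(reads)

    by_tag_f: dict[str, list[SampleRow]] = {}
    for row in sheet:
        by_tag_f.setdefault(row.tag_f, []).append(row)

    unassigned: list[Read] = []
    lf = sheet.tag_f_len if len(sheet) else 0
    for read in kept:
        assigned = None
        for row in by_tag_f.get(read.sequence[:lf], ()):
            assigned = _match_read(read, row, primer_mismatch)
            if assigned is not None:
                by_sample[row.sample_id].append(assigned)
                break
        if assigned is None:
            unassigned.append(read)

    report.sample_counts = {s: len(v) for s, v in by_sample.items()}
    report.unassigned = len(unassigned)
    _audit_into(unassigned, sheet, report)
    report.check_partition()
    return by_sample, report


def _audit_into(reads: Sequence[Read], sheet: SampleSheet, report: DemuxReport) -> None:
    """Classify observed tag pairs of unassignable reads into the audit tables."""
    if not len(sheet):
        return
    lf, lr = sheet.tag_f_len, sheet.tag_r_len
    known_f, known_r = sheet.tags_f, sheet.tags_r
    pairs = sheet.pair_lookup()
    for read in reads:
        if len(read.sequence) < lf + lr:
            continue
        tf = read.sequence[:lf]
        tr = revcomp(read.sequence[-lr:])
        if tf in known_f and tr in known_r:
            if (tf, tr) not in pairs:
                report.cross_combinations[(tf, tr)] += 1
        else:
            report.foreign_tags[(tf, tr)] += 1


def audit_tags(reads: Sequence[Read], sheet: SampleSheet) -> DemuxReport:
    """Audit tag combinations across a read pool without trimming.

    Reads whose (tag_f, tag_r) is a manifest pair count as assigned; pairs of
    two known tags never used together are *cross combinations* (within-run
    tag jumping); pairs with at least one unknown tag are *foreign*
    (carry-over from another run or library).  ``foreign_fraction`` is the
    foreign read percentage of the total pool.
    """
    report = DemuxReport(total=len(reads))
    lf, lr = sheet.tag_f_len, sheet.tag_r_len
    pairs = sheet.pair_lookup()
    counts: Counter = Counter()
    others: list[Read] = []
    for read in reads:
        tf = read.sequence[:lf]
        tr = revcomp(read.sequence[-lr:]) if len(read.sequence) >= lf + lr else ""
        row = pairs.get((tf, tr))
        if row is not None:
            counts[row.sample_id] += 1
        else:
            others.append(read)
    report.sample_counts = dict(counts)
    report.unassigned = len(others)
    _audit_into(others, sheet, report)
    return report
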