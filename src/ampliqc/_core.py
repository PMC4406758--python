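"""Shared primitives: the Read container, Phred/IUPAC helpers and file I/O.

Reads carry their quality string in Phred+33 encoding throughout the
pipeline; numeric Q arrays are materialised on demand.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

PHRED_OFFSET = 33
Q_MIN, Q_MAX = 2, 41

DNA_ALPHABET = frozenset("ACGT")

# IUPAC degeneracy codes -> the set of concrete bases each one admits.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
_IUPAC_SETS = {code: frozenset(bases) for code, bases in IUPAC.items()}


_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"
)


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware (R<->Y, etc.)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_matches(pattern_base: str, read_base: str) -> bool:
    """True if a concrete read base is admitted by an IUPAC pattern base."""
    allowed = _IUPAC_SETS.get(pattern_base)
    return allowed is not None and read_base in allowed


def iupac_mismatches(pattern: str, window: str) -> int:
    """Substitution count of a read window against an IUPAC pattern (no indels).

    Length difference counts every unmatched position as a mismatch.
    """
    n = min(len(pattern), len(window))
    m = sum(1 for i in range(n) if not iupac_matches(pattern[i], window[i]))
    return m + abs(len(pattern) - len(window))


def qual_to_phred(qual: str) -> np.ndarray:
    """Decode a Phred+33 quality string into an int array of Q scores."""
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64) - PHRED_OFFSET


def phred_to_qual(q: Sequence[int] | np.ndarray) -> str:
    arr = np.asarray(q, dtype=np.int64)
    if arr.size and (arr.min() < 0 or arr.max() > 93):
        raise ValueError("Phred scores must lie in [0, 93] for +33 encoding")
    return (arr + PHRED_OFFSET).astype(np.uint8).tobytes().decode("ascii")


def expected_errors(qual: str) -> float:
    """Sum of per-base error probabilities implied by Phred qualities."""
    if not qual:
        return 0.0
    return float(np.sum(10.0 ** (-qual_to_phred(qual) / 10.0)))


@dataclass(slots=True)
class Read:
    """A sequencing read with per-base qualities and provenance annotations.

    ``sample``/``taxon`` hold ground truth when the read comes from the
    simulator and the assigned sample after demultiplexing.  ``prefix_len``
    and ``suffix_len`` record how many leading/trailing bases are tag+primer
    decoration (0 for a bare amplicon).
    """

    id: str
    sequence: str
    quality: str
    sample: str | None = None
    taxon: str | None = None
    prefix_len: int = 0
    suffix_len: int = 0
    is_chimera: bool = False
    is_contaminant: bool = False
    is_carryover: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )

    @property
    def phred(self) -> np.ndarray:
        return qual_to_phred(self.quality)

    @property
    def insert(self) -> str:
        """The amplicon portion of the read, with tag/primer decoration stripped."""
        end = len(self.sequence) - self.suffix_len
        return self.sequence[self.prefix_len : end]

    def replace(self, **changes) -> "Read":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# File I/O (FASTQ Sanger/Phred+33, FASTA, TSV) — plain text only.
# ---------------------------------------------------------------------------

def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> list[Read]:
    reads: list[Read] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()  # separator
            qual = fh.readline().strip()
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ record header: {header!r}")
            reads.append(Read(id=header[1:].strip(), sequence=seq, quality=qual))
    return reads


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def iter_tsv(path: str | Path) -> Iterator[dict[str, str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if line.strip():
                yield dict(zip(header, line.rstrip("\n").split("\t")))
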