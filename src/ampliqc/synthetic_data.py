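"""Synthetic amplicon libraries with known truth for every pipeline stage.

The generator emulates the statistical structure of single-direction
amplicon sequencing of short (~250 bp) mitochondrial markers: multi-taxon
template pools with skewed proportions, a template bottleneck that makes
rare taxa drop out of replicates when input copy number is low or the
extract is inhibited, per-base substitution/indel errors with elevated
indel rates in and just downstream of homopolymer runs, positional
substitution hotspots, Phred qualities derived from the realized per-base
error probabilities, PCR chimeras, control contaminants and cross-run tag
carry-over.  Every read retains its ground-truth sample and taxon label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._core import (
    DNA_ALPHABET,
    IUPAC,
    Q_MAX,
    Q_MIN,
    Read,
    phred_to_qual,
    read_fasta,
    read_fastq,
    revcomp,
    write_fasta,
    write_fastq,
)
from .demux import SampleSheet

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}
# alternatives[i] = the three bases that are not _BASES[i]
_ALT = np.array(
    [[_BASE_IDX[b] for b in _BASES if b != ref] for ref in _BASES], dtype=np.uint8
)
_BYTES = np.frombuffer(_BASES.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class PanelRecord:
    id: str
    taxon_label: str
    locus: str
    sequence: str


@dataclass
class ReferencePanel:
    """A set of known reference sequences standing in for source taxa."""

    records: list[PanelRecord]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("panel ids must be unique")
        for r in self.records:
            if not r.sequence or set(r.sequence) - DNA_ALPHABET:
                raise ValueError(f"panel record {r.id}: sequence must be non-empty ACGT")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, taxon_id: str) -> PanelRecord:
        for r in self.records:
            if r.id == taxon_id:
                return r
        raise KeyError(f"unknown taxon id {taxon_id!r}")

    def to_fasta(self, path: str | Path) -> None:
        write_fasta(((r.id, r.sequence) for r in self.records), path)

    @classmethod
    def from_fasta(cls, path: str | Path, locus: str = "unknown") -> "ReferencePanel":
        return cls([PanelRecord(n, n, locus, s) for n, s in read_fasta(path)])


@dataclass
class ErrorModel:
    """Per-base error process and the quality model tied to it.

    Qualities are Q = round(-10*log10(p_err)) + Normal(0, quality_noise_sd),
    clamped to [2, 41]; an error-free base reports the cap.  Indel rates are
    multiplied by ``homopolymer_multiplier`` inside runs of length >=
    ``h_min`` and for 2 bases downstream of each run, mirroring the
    observation that low quality extends beyond a homopolymer stretch.
    ``run_multiplier`` scales all error rates to emulate run-to-run
    variation on the same platform; no default other than 1 is claimed.
    """

    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    homopolymer_multiplier: float = 1.0
    h_min: int = 3
    hotspot_overrides: dict[int, float] = field(default_factory=dict)
    quality_noise_sd: float = 2.0
    run_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.homopolymer_multiplier < 1.0:
            raise ValueError("homopolymer_multiplier must be >= 1")
        for pos, r in self.hotspot_overrides.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"hotspot rate at {pos} must be in [0,1]")

    @property
    def is_error_free(self) -> bool:
        m = self.run_multiplier
        return (
            m * (self.sub_rate + self.ins_rate + self.del_rate) == 0.0
            and not any(m * r > 0 for r in self.hotspot_overrides.values())
        )

    def rate_arrays(
        self, construct: str, amplicon_start: int, amplicon_len: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-position (sub, ins, del, base-quality) arrays for one construct.

        Hotspot overrides are keyed on amplicon coordinates and shifted by
        ``amplicon_start`` so they land on the insert region of the read.
        """
        L = len(construct)
        m = self.run_multiplier
        sub = np.full(L, min(1.0, m * self.sub_rate))
        ins = np.full(L, min(1.0, m * self.ins_rate))
        dele = np.full(L, min(1.0, m * self.del_rate))
        for pos, rate in self.hotspot_overrides.items():
            i = amplicon_start + pos
            if 0 <= i < L and pos < amplicon_len:
                sub[i] = min(1.0, m * rate)
        if self.homopolymer_multiplier > 1.0:
            mask = _homopolymer_mask(construct, self.h_min, extend=2)
            ins[mask] = np.minimum(1.0, ins[mask] * self.homopolymer_multiplier)
            dele[mask] = np.minimum(1.0, dele[mask] * self.homopolymer_multiplier)
        p_tot = 1.0 - (1.0 - sub) * (1.0 - ins) * (1.0 - dele)
        qbase = np.full(L, Q_MAX, dtype=np.float64)
        nz = p_tot > 0
        qbase[nz] = np.clip(np.round(-10.0 * np.log10(p_tot[nz])), Q_MIN, Q_MAX)
        return sub, ins, dele, qbase


def _homopolymer_mask(seq: str, h_min: int, extend: int) -> np.ndarray:
    """Boolean mask over positions inside runs >= h_min, extended downstream."""
    L = len(seq)
    mask = np.zeros(L, dtype=bool)
    i = 0
    while i < L:
        j = i
        while j < L and seq[j] == seq[i]:
            j += 1
        if j - i >= h_min:
            mask[i : min(L, j + extend)] = True
        i = j
    return mask


ARCHITECTURES = ("TSP_only", "MID_TSP", "FULL_FUSION", "FULL_FUSION_SPIKED")


@dataclass
class LibraryDesign:
    """Which elements decorate each read, per the fusion-primer architecture.

    TSP_only:       primer_f + insert + rc(primer_r)
    MID_TSP:        tag_f + primer_f + insert + rc(primer_r) + rc(tag_r)
    FULL_FUSION:    adapter_f + [MID_TSP construct] + rc(adapter_r)
    FULL_FUSION_SPIKED reads are structurally identical to FULL_FUSION
    (spiking standard primers changes amplification efficiency, not the
    sequenced construct).
    """

    samplesheet: SampleSheet
    primer_f: str
    primer_r: str
    adapter_f: str = ""
    adapter_r: str = ""
    architecture: str = "MID_TSP"

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")

    def decorate(self, insert: str, tag_f: str, tag_r: str, rng: np.random.Generator) -> tuple[str, int, int]:
        """Build the full read sequence; returns (sequence, prefix_len, suffix_len)."""
        pf = _expand_iupac(self.primer_f, rng)
        pr = _expand_iupac(self.primer_r, rng)
        if self.architecture == "TSP_only":
            prefix, suffix = pf, revcomp(pr)
        else:
            prefix = tag_f + pf
            suffix = revcomp(pr) + revcomp(tag_r)
            if self.architecture in ("FULL_FUSION", "FULL_FUSION_SPIKED"):
                prefix = self.adapter_f + prefix
                suffix = suffix + revcomp(self.adapter_r)
        return prefix + insert + suffix, len(prefix), len(suffix)


def _expand_iupac(primer: str, rng: np.random.Generator) -> str:
    """Realize degenerate IUPAC bases uniformly at synthesis time."""
    if set(primer) <= DNA_ALPHABET:
        return primer
    return "".join(
        b if b in DNA_ALPHABET else IUPAC[b][rng.integers(len(IUPAC[b]))]
        for b in primer
    )


@dataclass
class MixtureSpec:
    """Per-sample taxon mixtures and the library-wide artefact rates."""

    samples: dict[str, list[tuple[str, float]]]
    template_copies: int = 100_000
    inhibition_factor: float = 0.0
    chimera_rate: float = 0.0
    carryover_rate: float = 0.0
    contaminant_records: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for sample, mix in self.samples.items():
            total = sum(p for _, p in mix)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"sample {sample}: proportions sum to {total}, not 1")
        for name in ("inhibition_factor", "chimera_rate", "carryover_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        for seq, rate in self.contaminant_records:
            if set(seq) - DNA_ALPHABET or not 0.0 <= rate <= 1.0:
                raise ValueError("contaminant records must be (ACGT sequence, rate in [0,1])")


def simulate_reads(
    panel: ReferencePanel,
    mix: MixtureSpec,
    design: LibraryDesign,
    model: ErrorModel,
    n_reads: int,
    seed: int,
) -> list[Read]:
    """Simulate ``n_reads`` FASTQ-writable reads across the manifest samples.

    Reads are split as evenly as possible across the samples named in the
    mixture.  Within a sample, the taxon of each read is drawn in two
    stages: a multinomial draw of ``template_copies * (1 - inhibition)``
    effective template molecules fixes the template pool (rare taxa may
    receive zero templates — the replicate-dropout mechanism), and reads
    are then resampled from that pool.  Contaminants displace true-taxon
    reads at their specified rates.

    Raises ``ValueError`` when inhibition leaves zero effective templates.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = np.random.default_rng(seed)
    tag_rows = {r.sample_id: r for r in design.samplesheet}
    for sample in mix.samples:
        if sample not in tag_rows:
            raise ValueError(f"sample {sample!r} not in samplesheet")
        for taxon, _ in mix.samples[sample]:
            panel.get(taxon)  # raises KeyError -> surface as ValueError
    eff_templates = min(
        int(mix.template_copies * (1.0 - mix.inhibition_factor)), mix.template_copies
    )
    if eff_templates <= 0:
        raise ValueError(
            "inhibition_factor leaves zero effective template molecules; "
            "nothing can amplify"
        )

    sample_ids = list(mix.samples)
    per_sample = np.full(len(sample_ids), n_reads // len(sample_ids))
    per_sample[: n_reads % len(sample_ids)] += 1

    contam_total = sum(r for _, r in mix.contaminant_records)
    if contam_total > 1.0:
        raise ValueError("contaminant rates sum above 1")

    reads: list[Read] = []
    cache: _ConstructCache = _ConstructCache(design, model)
    serial = 0
    for sample_id, n_sample in zip(sample_ids, per_sample):
        taxa = [t for t, _ in mix.samples[sample_id]]
        props = np.array([p for _, p in mix.samples[sample_id]], dtype=float)
        template_counts = rng.multinomial(eff_templates, props)
        pool = template_counts.astype(float)
        if pool.sum() == 0:  # unreachable for eff_templates >= 1, kept defensive
            continue
        pool_props = pool / pool.sum()
        # contaminants displace true reads at fixed rates
        labels = list(taxa)
        probs = pool_props * (1.0 - contam_total)
        contam_seqs: dict[str, str] = {}
        for k, (cseq, crate) in enumerate(mix.contaminant_records):
            label = f"contaminant_{k}"
            labels.append(label)
            probs = np.append(probs, crate)
            contam_seqs[label] = cseq
        draw = rng.multinomial(n_sample, probs / probs.sum())
        row = tag_rows[sample_id]
        for label, count in zip(labels, draw):
            template = (
                contam_seqs[label] if label in contam_seqs else panel.get(label).sequence
            )
            for _ in range(count):
                seq, qual, pre, suf = cache.emit(template, row.tag_f, row.tag_r, rng)
                reads.append(
                    Read(
                        id=f"read{serial:07d}",
                        sequence=seq,
                        quality=qual,
                        sample=sample_id,
                        taxon=label,
                        prefix_len=pre,
                        suffix_len=suf,
                        is_contaminant=label in contam_seqs,
                    )
                )
                serial += 1
    # restore read-order randomness lost to per-sample batching
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    for i, r in enumerate(reads):
        r.id = f"read{i:07d}"
    return reads


class _ConstructCache:
    """Caches per-construct rate arrays; degenerate primers defeat the cache."""

    def __init__(self, design: LibraryDesign, model: ErrorModel) -> None:
        self.design = design
        self.model = model
        self.degenerate = bool(
            (set(design.primer_f) | set(design.primer_r)) - DNA_ALPHABET
        )
        self._rates: dict[tuple[str, str, str], tuple] = {}
        self._const_qual: dict[int, str] = {}

    def emit(
        self, template: str, tag_f: str, tag_r: str, rng: np.random.Generator
    ) -> tuple[str, str, int, int]:
        construct, pre, suf = self.design.decorate(template, tag_f, tag_r, rng)
        if self.model.is_error_free:
            qual = self._const_qual.get(len(construct))
            if qual is None:
                qual = phred_to_qual(np.full(len(construct), Q_MAX))
                self._const_qual[len(construct)] = qual
            return construct, qual, pre, suf
        key = (template, tag_f, tag_r)
        if self.degenerate or key not in self._rates:
            rates = self.model.rate_arrays(construct, pre, len(template))
            if not self.degenerate:
                self._rates[key] = rates
        else:
            rates = self._rates[key]
        seq, q = _mutate(construct, *rates, rng, self.model.quality_noise_sd)
        return seq, q, pre, suf


def _mutate(
    construct: str,
    sub: np.ndarray,
    ins: np.ndarray,
    dele: np.ndarray,
    qbase: np.ndarray,
    rng: np.random.Generator,
    noise_sd: float,
) -> tuple[str, str]:
    """Apply one read's worth of errors and emit (sequence, quality string)."""
    L = len(construct)
    u = rng.random((3, L))
    do_sub = u[0] < sub
    do_ins = u[1] < ins
    do_del = u[2] < dele
    arr = np.frombuffer(construct.encode(), dtype=np.uint8)
    any_indel = bool(do_ins.any() or do_del.any())
    if not any_indel:
        if do_sub.any():
            arr = arr.copy()
            idx = np.nonzero(do_sub)[0]
            base_codes = np.array([_BASE_IDX[construct[i]] for i in idx], dtype=np.intp)
            choices = rng.integers(0, 3, size=idx.size)
            arr[idx] = _BYTES[_ALT[base_codes, choices]]
        seq = arr.tobytes().decode()
        q = qbase
    else:
        out_seq: list[str] = []
        out_q: list[float] = []
        for i in range(L):
            if do_ins[i]:
                out_seq.append(_BASES[rng.integers(4)])
                out_q.append(qbase[i])
            if do_del[i]:
                continue
            b = construct[i]
            if do_sub[i]:
                b = _BASES[_ALT[_BASE_IDX[b], rng.integers(3)]]
            out_seq.append(b)
            out_q.append(qbase[i])
        seq = "".join(out_seq)
        q = np.array(out_q)
    if noise_sd > 0:
        q = q + rng.normal(0.0, noise_sd, size=len(q))
    q = np.clip(np.round(q), Q_MIN, Q_MAX).astype(np.int64)
    return seq, phred_to_qual(q)


# ---------------------------------------------------------------------------
# Artefact injectors
# ---------------------------------------------------------------------------

def inject_chimeras(
    reads: Sequence[Read], parents: ReferencePanel, rate: float, seed: int
) -> list[Read]:
    """Replace a ``rate`` fraction of reads with two-parent recombinants.

    Each replaced read's insert becomes parentA[:k] + parentB[k:] with the
    breakpoint k uniform in the interior; tag/primer decoration is kept.
    Truth labels are retained (``is_chimera`` plus an A/B taxon label).
    """
    if len(parents) < 2:
        raise ValueError("need at least 2 parent sequences to form chimeras")
    rng = np.random.default_rng(seed)
    out: list[Read] = []
    for read in reads:
        if rng.random() >= rate:
            out.append(read)
            continue
        ia, ib = rng.choice(len(parents), size=2, replace=False)
        a, b = parents.records[ia], parents.records[ib]
        k = int(rng.integers(1, min(len(a.sequence), len(b.sequence))))
        insert = a.sequence[:k] + b.sequence[k:]
        prefix = read.sequence[: read.prefix_len]
        suffix = read.sequence[len(read.sequence) - read.suffix_len :] if read.suffix_len else ""
        seq = prefix + insert + suffix
        mean_q = int(round(float(np.mean(read.phred)))) if read.quality else Q_MAX
        out.append(
            read.replace(
                sequence=seq,
                quality=phred_to_qual(np.full(len(seq), np.clip(mean_q, Q_MIN, Q_MAX))),
                taxon=f"{a.id}/{b.id}",
                is_chimera=True,
            )
        )
    return out


def make_decoy_tags(
    sheet: SampleSheet, n: int, seed: int
) -> list[tuple[str, str]]:
    """Deterministic decoy (tag_f, tag_r) pairs disjoint from the manifest."""
    rng = np.random.default_rng(seed)
    used = sheet.tags_f | sheet.tags_r
    lf, lr = sheet.tag_f_len, sheet.tag_r_len
    decoys: list[tuple[str, str]] = []
    while len(decoys) < n:
        tf = "".join(_BASES[i] for i in rng.integers(4, size=lf))
        tr = "".join(_BASES[i] for i in rng.integers(4, size=lr))
        if tf not in used and tr not in used:
            decoys.append((tf, tr))
            used.update((tf, tr))
    return decoys


def inject_tag_carryover(
    reads: Sequence[Read],
    samplesheet: SampleSheet,
    rate: float,
    seed: int,
    decoy_tags: list[tuple[str, str]] | None = None,
) -> list[Read]:
    """Re-tag a ``rate`` fraction of reads with tags absent from the manifest.

    Emulates cross-run sample carry-over: the affected reads bear MID
    combinations never used in this library.  Decoy tag pairs are generated
    deterministically unless supplied; an explicitly empty decoy set with
    rate > 0 is an error.
    """
    if decoy_tags is None:
        decoy_tags = make_decoy_tags(samplesheet, 16, seed ^ 0x5EED) if rate > 0 else []
    if rate > 0 and not decoy_tags:
        raise ValueError("carry-over requested but decoy tag set is empty")
    rng = np.random.default_rng(seed)
    lf, lr = samplesheet.tag_f_len, samplesheet.tag_r_len
    out: list[Read] = []
    hits = rng.random(len(reads)) < rate
    for read, hit in zip(reads, hits):
        if not hit:
            out.append(read)
            continue
        tf, tr = decoy_tags[rng.integers(len(decoy_tags))]
        seq = tf + read.sequence[lf : len(read.sequence) - lr] + revcomp(tr)
        out.append(read.replace(sequence=seq, is_carryover=True))
    return out


# ---------------------------------------------------------------------------
# Panels, manifests, fixtures
# ---------------------------------------------------------------------------

def random_panel(
    n_taxa: int,
    length: int = 250,
    min_divergence: float = 0.06,
    seed: int = 0,
    locus: str = "12S",
) -> ReferencePanel:
    """A panel of random references with pairwise divergence >= min_divergence.

    The first sequence is uniform-random; each later one substitutes a fixed
    fraction of its positions, spread evenly along the length at disjoint
    offsets per taxon.  Isolated substitutions cannot be re-registered by
    gaps under the default alignment scoring, so the nominal divergence is
    also the aligned divergence.
    """
    rng = np.random.default_rng(seed)
    base = "".join(_BASES[i] for i in rng.integers(4, size=length))
    k = max(1, int(math.ceil(min_divergence * length)))
    stride = length // k
    if n_taxa > 1 and (n_taxa - 1) > stride:
        raise ValueError("length too short for requested divergence and taxon count")
    records = [PanelRecord("taxon_1", "taxon_1", locus, base)]
    for t in range(1, n_taxa):
        seq = list(base)
        for j in range(k):
            p = j * stride + (t - 1)
            seq[p] = _BASES[_ALT[_BASE_IDX[base[p]], rng.integers(3)]]
        records.append(PanelRecord(f"taxon_{t+1}", f"taxon_{t+1}", locus, "".join(seq)))
    return ReferencePanel(records)


def example_samplesheet(
    n_samples: int,
    tag_len: int = 8,
    primer_f: str = "ACTGGGATTAGATACCCC",
    primer_r: str = "GAGGGTGACGGGCGGTGT",
    seed: int = 0,
) -> SampleSheet:
    """Deterministic manifest with unique dual tags (default: avian-12S-like primers)."""
    rng = np.random.default_rng(seed)
    rows = []
    used: set[str] = set()
    for i in range(n_samples):
        while True:
            tf = "".join(_BASES[j] for j in rng.integers(4, size=tag_len))
            tr = "".join(_BASES[j] for j in rng.integers(4, size=tag_len))
            if tf not in used and tr not in used and tf != tr:
                used.update((tf, tr))
                break
        rows.append((f"sample_{i+1}", tf, tr, primer_f, primer_r))
    return SampleSheet.from_records(rows)


def write_fixtures(
    outdir: str | Path,
    panel: ReferencePanel,
    reads: Sequence[Read],
    sheet: SampleSheet,
) -> dict[str, Path]:
    """Write FASTQ reads, FASTA panel, TSV samplesheet and TSV truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": outdir / "reads.fastq",
        "panel": outdir / "panel.fasta",
        "samplesheet": outdir / "samplesheet.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fastq(reads, paths["reads"])
    panel.to_fasta(paths["panel"])
    sheet.to_tsv(paths["samplesheet"])
    with open(paths["truth"], "w") as fh:
        fh.write("read_id\tsample\ttaxon\tis_chimera\tis_contaminant\tis_carryover\n")
        for r in reads:
            fh.write(
                f"{r.id}\t{r.sample or ''}\t{r.taxon or ''}\t"
                f"{int(r.is_chimera)}\t{int(r.is_contaminant)}\t{int(r.is_carryover)}\n"
            )
    return paths


def read_fixtures(outdir: str | Path) -> tuple[ReferencePanel, list[Read], SampleSheet]:
    outdir = Path(outdir)
    panel = ReferencePanel.from_fasta(outdir / "panel.fasta")
    reads = read_fastq(outdir / "reads.fastq")
    sheet = SampleSheet.from_tsv(outdir / "samplesheet.tsv")
    return panel, reads, sheet
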