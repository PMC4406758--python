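"""Simulator: zero-error identity, rate recovery, artefact injection, fixtures."""

import numpy as np
import pytest

import ampliqc as aq
from ampliqc._core import revcomp


def test_zero_error_reads_are_exact_constructs(panel3, sheet2, design2):
    mix = aq.MixtureSpec(samples={"sample_1": [("taxon_1", 1.0)]})
    reads = aq.simulate_reads(panel3, mix, design2, aq.ErrorModel(), 10, seed=1)
    assert len(reads) == 10
    row = sheet2.rows[0]
    expected = (
        row.tag_f + design2.primer_f + panel3.records[0].sequence
        + revcomp(design2.primer_r) + revcomp(row.tag_r)
    )
    for r in reads:
        assert r.sequence == expected
        assert len(r.quality) == len(r.sequence)


def test_seeded_determinism(panel3, sheet2, design2, clean_mix):
    model = aq.ErrorModel(sub_rate=0.01, ins_rate=0.001, del_rate=0.001)
    a = aq.simulate_reads(panel3, clean_mix, design2, model, 200, seed=42)
    b = aq.simulate_reads(panel3, clean_mix, design2, model, 200, seed=42)
    assert [(r.sequence, r.quality, r.sample, r.taxon) for r in a] == [
        (r.sequence, r.quality, r.sample, r.taxon) for r in b
    ]
    c = aq.simulate_reads(panel3, clean_mix, design2, model, 200, seed=43)
    assert [r.sequence for r in a] != [r.sequence for r in c]


def test_substitution_rate_recovered_within_3se(panel3, sheet2, design2):
    """Realized mismatch fraction across reads matches the nominal rate (binomial)."""
    p = 0.01
    mix = aq.MixtureSpec(samples={"sample_1": [("taxon_1", 1.0)]})
    reads = aq.simulate_reads(
        panel3, mix, design2, aq.ErrorModel(sub_rate=p), 10_000, seed=3
    )
    row = sheet2.rows[0]
    truth = (
        row.tag_f + design2.primer_f + panel3.records[0].sequence
        + revcomp(design2.primer_r) + revcomp(row.tag_r)
    )
    mismatches = sum(
        sum(a != b for a, b in zip(r.sequence, truth)) for r in reads
    )
    n_bases = len(truth) * len(reads)
    se = (p * (1 - p) / n_bases) ** 0.5
    assert abs(mismatches / n_bases - p) < 3 * se


def test_full_inhibition_raises(panel3, sheet2, design2):
    mix = aq.MixtureSpec(
        samples={"sample_1": [("taxon_1", 1.0)]}, inhibition_factor=1.0
    )
    with pytest.raises(ValueError, match="zero effective template"):
        aq.simulate_reads(panel3, mix, design2, aq.ErrorModel(), 10, seed=1)


def test_template_bottleneck_drops_rare_taxa(panel3, sheet2, design2):
    # 10 templates at 2% proportion: the rare taxon frequently gets none
    mix = aq.MixtureSpec(
        samples={"sample_1": [("taxon_1", 0.98), ("taxon_2", 0.02)]},
        template_copies=10,
    )
    dropouts = 0
    for seed in range(20):
        reads = aq.simulate_reads(panel3, mix, design2, aq.ErrorModel(), 500, seed=seed)
        if not any(r.taxon == "taxon_2" for r in reads):
            dropouts += 1
    assert dropouts > 5  # P(no template) = 0.98^10 ~ 0.82 per replicate


def test_mixture_validation(panel3, sheet2, design2):
    with pytest.raises(ValueError, match="proportions"):
        aq.MixtureSpec(samples={"sample_1": [("taxon_1", 0.5)]})
    mix = aq.MixtureSpec(samples={"sample_1": [("nonexistent", 1.0)]})
    with pytest.raises(KeyError):
        aq.simulate_reads(panel3, mix, design2, aq.ErrorModel(), 5, seed=0)


class TestChimeras:
    def test_rate_zero_is_identity(self, panel3, sheet2, design2, clean_mix):
        reads = aq.simulate_reads(panel3, clean_mix, design2, aq.ErrorModel(), 50, seed=2)
        out = aq.inject_chimeras(reads, panel3, 0.0, seed=1)
        assert [r.sequence for r in out] == [r.sequence for r in reads]

    def test_rate_one_all_recombinant(self):
        two = aq.random_panel(2, 100, seed=7)
        a, b = two.records[0].sequence, two.records[1].sequence
        reads = [
            aq.Read(id=f"r{i}", sequence=a, quality="I" * len(a)) for i in range(30)
        ]
        out = aq.inject_chimeras(reads, two, 1.0, seed=1)
        for r in out:
            assert r.is_chimera
            k = next(
                i for i in range(1, len(a)) if r.sequence[:i] in (a[:i], b[:i])
                and r.sequence[i:] in (a[i:], b[i:])
            )
            assert 1 <= k < len(a)

    def test_rate_recovered_binomially(self, panel3, sheet2, design2, clean_mix):
        reads = aq.simulate_reads(
            panel3, clean_mix, design2, aq.ErrorModel(), 10_000, seed=4
        )
        out = aq.inject_chimeras(reads, panel3, 0.05, seed=5)
        n_chim = sum(r.is_chimera for r in out)
        se = (10_000 * 0.05 * 0.95) ** 0.5
        assert abs(n_chim - 500) < 3 * se

    def test_fewer_than_two_parents_errors(self, panel3):
        one = aq.ReferencePanel([panel3.records[0]])
        with pytest.raises(ValueError, match="2 parent"):
            aq.inject_chimeras([], one, 0.5, seed=1)


class TestCarryover:
    def test_rate_zero_keeps_manifest_tags(self, panel3, sheet2, design2, clean_mix):
        reads = aq.simulate_reads(panel3, clean_mix, design2, aq.ErrorModel(), 100, seed=6)
        out = aq.inject_tag_carryover(reads, sheet2, 0.0, seed=1)
        report = aq.audit_tags(out, sheet2)
        assert report.foreign_fraction == 0.0

    def test_empty_decoy_set_errors(self, panel3, sheet2, design2, clean_mix):
        reads = aq.simulate_reads(panel3, clean_mix, design2, aq.ErrorModel(), 10, seed=6)
        with pytest.raises(ValueError, match="decoy"):
            aq.inject_tag_carryover(reads, sheet2, 0.1, seed=1, decoy_tags=[])

    def test_decoys_disjoint_from_manifest(self, sheet2):
        decoys = aq.make_decoy_tags(sheet2, 10, seed=3)
        used = sheet2.tags_f | sheet2.tags_r
        for tf, tr in decoys:
            assert tf not in used and tr not in used

    def test_carryover_rate_recovered(self, panel3, sheet2, design2, clean_mix):
        reads = aq.simulate_reads(
            panel3, clean_mix, design2, aq.ErrorModel(), 20_000, seed=8
        )
        out = aq.inject_tag_carryover(reads, sheet2, 0.01, seed=9)
        n = sum(r.is_carryover for r in out)
        se = (20_000 * 0.01 * 0.99) ** 0.5
        assert abs(n - 200) < 3 * se
        report = aq.audit_tags(out, sheet2)
        assert sum(report.foreign_tags.values()) == n


class TestFixtures:
    def test_round_trip_byte_identical(self, tmp_path, panel3, sheet2, design2, clean_mix):
        reads = aq.simulate_reads(
            panel3, clean_mix, design2, aq.ErrorModel(sub_rate=0.01), 50, seed=10
        )
        d1 = tmp_path / "a"
        paths = aq.write_fixtures(d1, panel3, reads, sheet2)
        panel2, reads2, sheet_rt = aq.read_fixtures(d1)
        d2 = tmp_path / "b"
        aq.write_fixtures(d2, panel2, reads2, sheet_rt)
        for name in ("reads.fastq", "panel.fasta", "samplesheet.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_empty_read_set_valid_fastq(self, tmp_path, panel3, sheet2):
        paths = aq.write_fixtures(tmp_path, panel3, [], sheet2)
        assert aq.read_fastq(paths["reads"]) == []

    def test_samplesheet_rows_round_trip(self, tmp_path):
        sheet = aq.example_samplesheet(3, seed=1)
        p = tmp_path / "sheet.tsv"
        sheet.to_tsv(p)
        assert len(aq.SampleSheet.from_tsv(p)) == 3
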