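import numpy as np
import pytest

import ampliqc as aq


@pytest.fixture(scope="session")
def panel3():
    """Three random 250-bp references, pairwise divergence >= 6%."""
    return aq.random_panel(3, 250, min_divergence=0.06, seed=11)


@pytest.fixture(scope="session")
def sheet2():
    return aq.example_samplesheet(2, tag_len=8, seed=11)


@pytest.fixture()
def design2(sheet2):
    return aq.LibraryDesign(
        samplesheet=sheet2,
        primer_f=sheet2.rows[0].primer_f,
        primer_r=sheet2.rows[0].primer_r,
        architecture="MID_TSP",
    )


@pytest.fixture()
def clean_mix():
    return aq.MixtureSpec(
        samples={
            "sample_1": [("taxon_1", 0.6), ("taxon_2", 0.4)],
            "sample_2": [("taxon_3", 1.0)],
        }
    )


def make_single_source(n_reads, seed, model=None, length=250, **mix_kwargs):
    """One-sample single-taxon library; returns (panel, sheet, raw reads)."""
    panel = aq.random_panel(1, length, seed=5)
    sheet = aq.example_samplesheet(1, seed=5)
    design = aq.LibraryDesign(
        samplesheet=sheet,
        primer_f=sheet.rows[0].primer_f,
        primer_r=sheet.rows[0].primer_r,
    )
    mix = aq.MixtureSpec(samples={"sample_1": [("taxon_1", 1.0)]}, **mix_kwargs)
    reads = aq.simulate_reads(panel, mix, design, model or aq.ErrorModel(), n_reads, seed)
    return panel, sheet, reads


@pytest.fixture()
def single_source_factory():
    return make_single_source


def phred_read(qs, seq=None, rid="r"):
    """Build a Read from a list of Phred scores (sequence defaults to A's)."""
    from ampliqc._core import Read, phred_to_qual

    seq = seq or "A" * len(qs)
    return Read(id=rid, sequence=seq, quality=phred_to_qual(qs))
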