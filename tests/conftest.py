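import numpy as np
import pytest

from tadbound import (
    GenomicInterval,
    SignalTrack,
    SyntheticConfig,
    TadMap,
    TranscriptRecord,
    simulate_genome,
)


@pytest.fixture(scope="session")
def small_bundle():
    """One deterministic synthetic bundle shared across read-only tests."""
    return simulate_genome(SyntheticConfig(seed=42))


@pytest.fixture
def simple_tad_map():
    genome = {"chr1": 1_000_000}
    return TadMap([GenomicInterval("chr1", 0, 100_000),
                   GenomicInterval("chr1", 100_000, 400_000),
                   GenomicInterval("chr1", 500_000, 900_000)], genome)


def make_transcript(gene, tss, strand="+", length=10_000, chrom="chr1"):
    if strand == "+":
        iv = GenomicInterval(chrom, tss, tss + length)
    else:
        iv = GenomicInterval(chrom, max(0, tss - length + 1), tss + 1)
    return TranscriptRecord(gene, f"{gene}.1", iv, strand)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
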