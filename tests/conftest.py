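import pytest

from postvar.synthetic_fixtures import (
    AlignmentSimParams,
    VariantSimParams,
    simulate_variant_records,
)
from postvar.variant_io import ExonInterval


@pytest.fixture(scope="session")
def tier1_like_set():
    """Two-class variant set shaped like a validated exome call set (65/159)."""
    params = VariantSimParams(n_true=65, n_false=94, seed=42)
    records, truth = simulate_variant_records(params)
    return records, truth


@pytest.fixture(scope="session")
def planted_set():
    """Zero-noise set with a hard (QUAL, DP) separation between classes."""
    params = VariantSimParams.planted_separation(n_true=100, n_false=100, seed=7)
    records, truth = simulate_variant_records(params)
    return records, truth


def make_exons(n=10, length=200, gap=300, chrom="chr1"):
    exons = []
    pos = 1000
    for i in range(n):
        exons.append(
            ExonInterval(
                chrom=chrom, start=pos, end=pos + length,
                exon_id=f"GENE{i}|exon1", gene=f"GENE{i}",
            )
        )
        pos += length + gap
    return exons


@pytest.fixture(scope="session")
def exon_set():
    return make_exons()


@pytest.fixture(scope="session")
def alignment_cohort(tmp_path_factory, exon_set):
    """Four-sample SAM cohort with one planted spurious exon."""
    out = tmp_path_factory.mktemp("aln")
    params = AlignmentSimParams(
        exons=tuple(exon_set),
        spurious_exon_ids=("GENE3|exon1",),
        n_samples=4,
        seed=5,
    )
    from postvar.synthetic_fixtures import gen_alignment_set

    return gen_alignment_set(params, out), params
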