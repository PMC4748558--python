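import pytest

from aneukit.simulate import SimParams, make_genome_model
from aneukit.types import ChromosomeInfo, TranslocationCall


@pytest.fixture(scope="session")
def toy_chrom_info():
    return [
        ChromosomeInfo("chr1", 5_000_000, 5000, 2_500_000),
        ChromosomeInfo("chr2", 5_000_000, 5000, 2_500_000),
        ChromosomeInfo("chr3", 5_000_000, 5000, 2_500_000),
    ]


@pytest.fixture(scope="session")
def small_params():
    """Desk-scale genome small enough for per-test simulation."""
    return SimParams(
        seed=7,
        chromosomes={"chr1": 5_000_000, "chr2": 5_000_000, "chr3": 5_000_000},
        n_cn_segments=2,
        cn_segment_length_range=(500_000, 1_000_000),
        loh_fraction=0.0,
        loh_segment_mean_bp=1_500_000,
        variant_density=0.0005,
        n_translocations=8,
        fragments_per_well=12,
    )


@pytest.fixture(scope="session")
def small_model(small_params):
    return make_genome_model(small_params)


def make_call(chrom_a="chr1", start_a=100, end_a=200, chrom_b="chr2",
              start_b=1000, end_b=1100, orientation="ff", library="STD",
              **kw):
    return TranslocationCall(chrom_a, start_a, end_a, chrom_b, start_b,
                             end_b, orientation, library, **kw)
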