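"""Loaders for the small reference tables shipped with the package.

These are the published BT-474 summary tables (raw per-library
translocation calls with their published event ids, per-chromosome LOH
content, per-library SNV counts, RNA-seq fusion candidates) together
with the GRCh37 chromosome reference table and the NA12878 diploid SNV
counts used by the LOH thought experiment.
"""

from __future__ import annotations

from importlib import resources
from typing import List

import pandas as pd

from . import io as _io
from .types import ChromosomeInfo, DiploidCounts, FusionCandidate, TranslocationCall

__all__ = [
    "load_bt474_translocations",
    "load_grch37_chromosomes",
    "load_bt474_loh_table",
    "load_bt474_fusion_candidates",
    "load_bt474_library_stats",
    "load_na12878_counts",
]


def _data_path(name: str):
    return resources.files("aneukit.data").joinpath(name)


def load_bt474_translocations() -> List[TranslocationCall]:
    """All 430 raw per-library interchromosomal translocation calls.

    Calls carry their published post-clustering event id as
    ``recorded_id`` and per-side ``coarse`` flags where the published
    coordinates were rounded to 1 Mb precision.
    """
    with resources.as_file(_data_path("bt474_translocations.tsv")) as p:
        return _io.read_translocation_table(p)


def load_grch37_chromosomes() -> List[ChromosomeInfo]:
    """GRCh37 chromosome lengths, known-variant counts (Ensembl release
    68) and centromere positions for chr1-22 and chrX."""
    with resources.as_file(_data_path("grch37_chromosomes.tsv")) as p:
        return _io.read_chromosome_info(p)


def load_bt474_loh_table() -> pd.DataFrame:
    """Published per-chromosome LOH content of BT-474: percent of the
    chromosome in LOH, LOH base pairs, and known variants inside LOH."""
    with resources.as_file(_data_path("bt474_loh_by_chromosome.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_bt474_fusion_candidates() -> List[FusionCandidate]:
    """The five RNA-seq-reported interchromosomal fusion candidates."""
    with resources.as_file(_data_path("bt474_fusion_candidates.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return [
        FusionCandidate(
            gene_a=r.gene_a, chrom_a=r.chrom_a, start_a=int(r.start_a),
            end_a=int(r.end_a), strand_a=r.strand_a,
            gene_b=r.gene_b, chrom_b=r.chrom_b, start_b=int(r.start_b),
            end_b=int(r.end_b), strand_b=r.strand_b, source=r.source,
        )
        for r in df.itertuples()
    ]


def load_bt474_library_stats() -> pd.DataFrame:
    """Per-library SNV counts (total, homozygous, heterozygous) for the
    STD, LFR1 and LFR2 BT-474 libraries."""
    with resources.as_file(_data_path("bt474_library_stats.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_na12878_counts() -> DiploidCounts:
    """Homozygous and heterozygous SNV counts of the diploid NA12878
    genome, the baseline for the LOH het/hom-ratio simulation."""
    with resources.as_file(_data_path("na12878_snv_counts.tsv")) as p:
        df = pd.read_csv(p, sep="\t").set_index("category")["count"]
    return DiploidCounts(hom_count=int(df["hom"]), het_count=int(df["het"]))
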