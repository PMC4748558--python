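"""Core domain types shared across the toolkit.

All genomic coordinates held by these types are 1-based and inclusive at
both ends, matching the convention of published variant and breakpoint
tables.  Only BED export (see :mod:`aneukit.io`) converts to 0-based
half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "CHROM_ORDER",
    "ORIENTATIONS",
    "normalize_chrom",
    "chrom_sort_key",
    "TranslocationCall",
    "LFRAnnotation",
    "VariantRecord",
    "ChromosomeInfo",
    "PipelineConfig",
    "SVCluster",
    "FusionCandidate",
    "LAFWindow",
    "LOHSegment",
    "LOHSummary",
    "DiploidCounts",
    "LOHSimResult",
    "CoverageBin",
    "VariantKey",
    "WellObservation",
]

#: Fixed karyotype ordering used for canonicalization: 1..22, X, Y.
CHROM_ORDER = {f"chr{n}": i for i, n in enumerate(list(range(1, 23)) + ["X", "Y"])}

#: Valid two-letter breakpoint orientation codes (one letter per side;
#: ``f`` = forward, ``r`` = reverse relative to the reference strand).
ORIENTATIONS = frozenset({"ff", "fr", "rf", "rr"})

ZYGOSITIES = frozenset({"het", "hom", "half-called"})


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to its ``chr``-prefixed form.

    Accepts ``"1"``, ``"chr1"``, ``"X"``, ``"chrX"`` and so on; published
    tables mix both conventions.
    """
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    name = name.upper() if name.upper() in ("X", "Y", "M", "MT") else name
    return f"chr{name}"


def chrom_sort_key(chrom: str) -> tuple:
    """Sort key placing chr1..chr22, chrX, chrY first, others after."""
    if chrom in CHROM_ORDER:
        return (0, CHROM_ORDER[chrom])
    return (1, chrom)


@dataclass(frozen=True)
class TranslocationCall:
    """One raw per-library interchromosomal breakpoint-pair call.

    Each side is a breakpoint *window* ``[start, end]``.  ``orientation``
    holds one letter per side; the first letter describes side A.  Sides
    whose coordinates were recovered from a reduced-precision (rounded)
    printing are flagged ``coarse``; distance computations against such
    coordinates are only meaningful at that reduced precision.
    """

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    orientation: str
    library: str
    coarse_a: bool = False
    coarse_b: bool = False
    recorded_id: Optional[int] = None  # published event id, if the table had one

    def __post_init__(self):
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"invalid orientation {self.orientation!r}")
        if self.chrom_a == self.chrom_b:
            raise ValueError(
                f"intrachromosomal call on {self.chrom_a} is not a translocation"
            )
        if self.start_a > self.end_a or self.start_b > self.end_b:
            raise ValueError("breakpoint window has end < start")

    @property
    def is_canonical(self) -> bool:
        return chrom_sort_key(self.chrom_a) < chrom_sort_key(self.chrom_b)

    def swapped(self) -> "TranslocationCall":
        """Exchange the two sides (orientation letters exchanged, not
        complemented)."""
        return replace(
            self,
            chrom_a=self.chrom_b,
            start_a=self.start_b,
            end_a=self.end_b,
            chrom_b=self.chrom_a,
            start_b=self.start_a,
            end_b=self.end_a,
            orientation=self.orientation[::-1],
            coarse_a=self.coarse_b,
            coarse_b=self.coarse_a,
        )


@dataclass(frozen=True)
class LFRAnnotation:
    """Well-support metadata for a variant from a 384-well LFR library.

    ``well_count`` counts wells whose reads call the variant or the
    reference allele; it decomposes into wells calling exactly one allele
    (``exclusive_well_count``) and wells calling both
    (``shared_well_count``).  ``phase`` is a ``(contig, haplotype)`` pair
    parsed from a ``Phased_#_#_#`` identifier, or ``None``.
    """

    phase: Optional[tuple] = None  # ((contig_a, contig_b), haplotype in {0, 1})
    well_count: int = 0
    variant_well_ids: tuple = ()
    exclusive_well_count: int = 0
    shared_well_count: int = 0
    min_exclusive: int = 0
    max_exclusive: int = 0

    def __post_init__(self):
        if self.exclusive_well_count + self.shared_well_count != self.well_count:
            raise ValueError(
                "well_count must equal exclusive_well_count + shared_well_count"
            )
        if self.phase is not None and self.phase[1] not in (0, 1):
            raise ValueError("haplotype must be 0 or 1")
        for w in self.variant_well_ids:
            if not 1 <= w <= 384:
                raise ValueError(f"well index {w} outside [1, 384]")


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNV call with allele read depths.

    ``zygosity`` is ``het``, ``hom`` (single non-reference allele) or
    ``half-called`` (one allele could not be confidently called;
    retained but excluded from het/hom ratios and LAF computation).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: str
    ref_depth: int
    alt_depth: int
    library: str = ""
    lfr: Optional[LFRAnnotation] = None

    def __post_init__(self):
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"invalid zygosity {self.zygosity!r}")
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("allele depths must be >= 0")

    @property
    def key(self) -> "VariantKey":
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class VariantKey:
    """Identity of a biallelic SNV; genotype deliberately excluded."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class ChromosomeInfo:
    name: str
    length_bp: int
    known_variant_count: int
    centromere_position_bp: int

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValueError("chromosome length must be positive")
        if not 0 <= self.centromere_position_bp <= self.length_bp:
            raise ValueError("centromere outside chromosome")


@dataclass
class PipelineConfig:
    """Tunable analysis constants.

    Defaults encode the published analysis choices: 5 kb breakpoint
    clustering windows, 100 kb LAF/coverage bins, > 10 Mb LOH segments,
    tetraploid normalization, and a 2-well minimum for trusting a
    variant observed in a 384-well LFR library.
    """

    cluster_window_bp: int = 5000
    laf_bin_bp: int = 100_000
    loh_min_length_bp: int = 10_000_000
    laf_zero_epsilon: float = 0.0
    loh_max_gap_windows: int = 5
    target_ploidy: int = 4
    min_variant_wells: int = 2
    shared_well_fraction_threshold: float = 0.5
    random_seed: int = 0

    def __post_init__(self):
        for name in ("cluster_window_bp", "laf_bin_bp", "loh_min_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.laf_zero_epsilon < 0.5:
            raise ValueError("laf_zero_epsilon must lie in [0, 0.5)")


@dataclass
class SVCluster:
    """A merged cross-library translocation event."""

    cluster_id: int
    members: list
    chrom_a: str
    chrom_b: str
    span_a: tuple  # (start, end) union of member side-A windows
    span_b: tuple
    orientation: str
    libraries: frozenset

    @property
    def recorded_ids(self) -> frozenset:
        return frozenset(
            m.recorded_id for m in self.members if m.recorded_id is not None
        )


@dataclass(frozen=True)
class FusionCandidate:
    """An externally reported gene-fusion candidate (two gene loci)."""

    gene_a: str
    chrom_a: str
    start_a: int
    end_a: int
    strand_a: str
    gene_b: str
    chrom_b: str
    start_b: int
    end_b: int
    strand_b: str
    source: str = ""

    def __post_init__(self):
        if self.chrom_a == self.chrom_b:
            raise ValueError("fusion candidate must be interchromosomal")
        if self.start_a > self.end_a or self.start_b > self.end_b:
            raise ValueError("gene interval has end < start")


@dataclass(frozen=True)
class LAFWindow:
    """Lesser-allele fraction summarized over one fixed genomic window."""

    chrom: str
    window_index: int
    start: int
    end: int
    laf: Optional[float]
    n_variants: int

    def __post_init__(self):
        if (self.laf is None) != (self.n_variants == 0):
            raise ValueError("laf must be missing iff the window holds no variants")
        if self.laf is not None and not 0.0 <= self.laf <= 0.5:
            raise ValueError("laf outside [0, 0.5]")


@dataclass
class LOHSegment:
    chrom: str
    start: int
    end: int
    n_known_variants: Optional[int] = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class LOHSummary:
    """Per-chromosome and genome-wide LOH content, by length and by
    known-variant count."""

    per_chromosome: dict  # name -> {loh_bp, loh_variants, percent_loh}
    total_bp: int
    total_variants: int
    loh_bp: int
    loh_variants: int

    @property
    def percent_loh_by_bp(self) -> float:
        return 100.0 * self.loh_bp / self.total_bp

    @property
    def percent_loh_by_variants(self) -> float:
        if self.total_variants == 0:
            return float("nan")
        return 100.0 * self.loh_variants / self.total_variants


@dataclass(frozen=True)
class DiploidCounts:
    hom_count: int
    het_count: int

    def __post_init__(self):
        if self.hom_count < 0 or self.het_count < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class LOHSimResult:
    """Outcome of transferring heterozygous variants to the homozygous
    class under a given LOH extent."""

    hom_after: int
    het_after: int
    ratio_before: float
    ratio_after: float
    loh_fraction: float
    mode: str

    def round2(self) -> tuple:
        """(ratio_before, ratio_after) at the 2-decimal reporting precision."""
        return (round(self.ratio_before, 2), round(self.ratio_after, 2))


@dataclass
class CoverageBin:
    chrom: str
    bin_index: int
    start: int
    end: int
    read_count: int
    normalized_copy: Optional[float] = None


@dataclass(frozen=True)
class WellObservation:
    """Per-well allele observations at one variant locus."""

    key: VariantKey
    wells: tuple  # tuple of (well_index, frozenset of alleles in {"ref", "alt"})

    def as_dict(self) -> dict:
        return {w: set(a) for w, a in self.wells}
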