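"""Well-support statistics and error filtering for 384-well LFR data.

In a Long Fragment Read library, long (~40 kb) genomic fragments are
dispersed across 384 wells before amplification, so reads can be
attributed to a physical compartment.  A true variant is observed in
many wells; a random polymerase error arises during in-well
amplification and is confined to a single well.  This module recomputes
the per-variant well statistics, classifies weakly supported calls, and
verifies phasing-contig consistency.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .types import LFRAnnotation, VariantRecord, WellObservation

__all__ = [
    "parse_haplink",
    "compute_well_support",
    "classify_well_support",
    "check_phase_consistency",
    "PhaseReport",
    "SUPPORTED",
    "POLYMERASE_ERROR_SUSPECT",
    "MAPPING_ERROR_SUSPECT",
]

SUPPORTED = "supported"
POLYMERASE_ERROR_SUSPECT = "polymerase_error_suspect"
MAPPING_ERROR_SUSPECT = "mapping_error_suspect"

_HAPLINK_RE = re.compile(r"^Phased_(\d+)_(\d+)_(\d+)$")


def parse_haplink(text: Optional[str]) -> Optional[tuple]:
    """Parse a ``Phased_a_b_h`` phasing identifier.

    The first two integers name the phasing contig, the last is the
    haplotype and must be 0 or 1.  Empty or absent input yields
    ``None``; anything else malformed raises ``ValueError``.
    """
    if text is None or text == "" or text == ".":
        return None
    m = _HAPLINK_RE.match(text)
    if not m:
        raise ValueError(f"malformed hapLink identifier {text!r}")
    hap = int(m.group(3))
    if hap not in (0, 1):
        raise ValueError(f"haplotype must be 0 or 1, got {hap} in {text!r}")
    return ((int(m.group(1)), int(m.group(2))), hap)


def compute_well_support(obs: WellObservation,
                         phase: Optional[tuple] = None) -> LFRAnnotation:
    """Recompute well-support statistics from per-well allele observations.

    ``well_count`` counts wells observing the variant or the reference
    allele; ``shared_well_count`` those observing both;
    ``exclusive_well_count`` is their difference.  ``variant_well_ids``
    lists wells observing the variant allele.  The min/max exclusive
    counts are taken over the two per-allele exclusive tallies (wells
    calling only the reference vs. only the variant).
    """
    well_count = shared = ref_only = alt_only = 0
    variant_wells = []
    for well, alleles in sorted(obs.wells):
        alleles = frozenset(alleles) & {"ref", "alt"}
        if not alleles:
            continue
        well_count += 1
        if alleles == {"ref", "alt"}:
            shared += 1
        elif alleles == {"ref"}:
            ref_only += 1
        else:
            alt_only += 1
        if "alt" in alleles:
            variant_wells.append(well)
    return LFRAnnotation(
        phase=phase,
        well_count=well_count,
        variant_well_ids=tuple(variant_wells),
        exclusive_well_count=well_count - shared,
        shared_well_count=shared,
        min_exclusive=min(ref_only, alt_only),
        max_exclusive=max(ref_only, alt_only),
    )


def classify_well_support(
    ann: LFRAnnotation,
    zygosity: str,
    min_variant_wells: int = 2,
    shared_fraction_threshold: float = 0.5,
) -> str:
    """Label a variant by its compartment support.

    A variant observed in fewer than ``min_variant_wells`` wells is a
    polymerase-error suspect: independent wells amplify independently,
    so a random polymerase error is confined to one well while a true
    allele recurs across many.  A heterozygote whose shared-well
    fraction (wells calling both alleles) exceeds
    ``shared_fraction_threshold`` is a mapping-error suspect — reads
    from two collapsed loci produce both alleles inside single wells.
    Everything else is supported.
    """
    if len(ann.variant_well_ids) < min_variant_wells:
        return POLYMERASE_ERROR_SUSPECT
    if (
        zygosity == "het"
        and ann.well_count > 0
        and ann.shared_well_count / ann.well_count > shared_fraction_threshold
    ):
        return MAPPING_ERROR_SUSPECT
    return SUPPORTED


@dataclass
class PhaseReport:
    """Grouping of phased variants by contig and haplotype."""

    groups: Dict[tuple, List[VariantRecord]] = field(default_factory=dict)
    contig_sizes: Dict[tuple, int] = field(default_factory=dict)
    switch_errors: int = 0
    checked_against_truth: bool = False


def check_phase_consistency(
    records: Sequence[VariantRecord],
    truth: Optional[Dict[tuple, int]] = None,
) -> PhaseReport:
    """Group phased records and, given truth, count switch errors.

    Records sharing a ``Phased_a_b_h`` identifier belong to one
    haplotype of one phasing contig.  ``truth`` maps a variant locus
    ``(chrom, pos)`` to its parental haplotype; within each phased
    group every member must then derive from a single parental
    haplotype, and each minority member counts as one switch error.
    Records without phase are ignored; no phased records yield an empty
    report.
    """
    groups: Dict[tuple, List[VariantRecord]] = defaultdict(list)
    for r in records:
        if r.lfr is not None and r.lfr.phase is not None:
            groups[r.lfr.phase].append(r)

    report = PhaseReport(groups=dict(groups))
    for key, members in groups.items():
        contig = key[0]
        report.contig_sizes[contig] = report.contig_sizes.get(contig, 0) + len(members)
    if truth is not None:
        report.checked_against_truth = True
        for members in groups.values():
            parental = [truth[(m.chrom, m.pos)] for m in members
                        if (m.chrom, m.pos) in truth]
            if parental:
                majority = max(set(parental), key=parental.count)
                report.switch_errors += sum(1 for p in parental if p != majority)
    return report
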