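"""Loss-of-heterozygosity quantification from lesser-allele fractions.

At a fully called variant site the lesser-allele fraction (LAF) is the
read fraction of the less-abundant allele: 0.5 for a balanced
heterozygote, 0 for a homozygote.  LAF is summarized as the median over
100 kb windows; maximal runs of (near-)zero windows longer than 10 Mb
are called LOH segments, and LOH content is reported genome-wide both
by base pairs and by known-variant content.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .types import (
    ChromosomeInfo,
    LAFWindow,
    LOHSegment,
    LOHSummary,
    VariantRecord,
    chrom_sort_key,
)

__all__ = [
    "variant_laf",
    "compute_laf_windows",
    "segment_loh",
    "summarize_loh",
    "summarize_loh_entries",
    "het_hom_ratio",
]


def variant_laf(record: VariantRecord) -> Optional[float]:
    """Lesser-allele read fraction, ``min(ref, alt) / (ref + alt)``.

    Returns ``None`` (missing) at zero total depth.
    """
    total = record.ref_depth + record.alt_depth
    if total == 0:
        return None
    return min(record.ref_depth, record.alt_depth) / total


def compute_laf_windows(
    variants: Sequence[VariantRecord],
    chrom_info: Sequence[ChromosomeInfo],
    bin_bp: int = 100_000,
) -> List[LAFWindow]:
    """Median LAF in fixed windows tiling each chromosome.

    Windows are anchored at position 1 and the final partial window is
    kept.  Half-called variants and zero-depth sites are excluded; a
    window with no usable variants has missing LAF.  A variant beyond
    its chromosome's length is refused.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be > 0")
    lengths = {ci.name: ci.length_bp for ci in chrom_info}
    lafs: Dict[str, Dict[int, list]] = defaultdict(lambda: defaultdict(list))
    for v in variants:
        if v.chrom not in lengths:
            raise ValueError(f"variant on unknown chromosome {v.chrom}")
        if not 1 <= v.pos <= lengths[v.chrom]:
            raise ValueError(f"variant {v.chrom}:{v.pos} outside chromosome")
        if v.zygosity == "half-called":
            continue
        laf = variant_laf(v)
        if laf is None:
            continue
        lafs[v.chrom][(v.pos - 1) // bin_bp].append(laf)

    windows = []
    for ci in sorted(chrom_info, key=lambda c: chrom_sort_key(c.name)):
        n_windows = math.ceil(ci.length_bp / bin_bp)
        per_chrom = lafs.get(ci.name, {})
        for w in range(n_windows):
            values = per_chrom.get(w, [])
            windows.append(LAFWindow(
                chrom=ci.name,
                window_index=w,
                start=w * bin_bp + 1,
                end=min((w + 1) * bin_bp, ci.length_bp),
                laf=float(np.median(values)) if values else None,
                n_variants=len(values),
            ))
    return windows


def segment_loh(
    windows: Sequence[LAFWindow],
    epsilon: float = 0.0,
    min_length_bp: int = 10_000_000,
    max_gap_windows: int = 5,
) -> List[LOHSegment]:
    """Maximal runs of LOH windows longer than ``min_length_bp``.

    A window belongs to a run when its LAF is at most ``epsilon``.  Up
    to ``max_gap_windows`` consecutive variant-free (missing-LAF)
    windows are tolerated inside a run — centromeric and otherwise
    unmappable stretches would otherwise split whole-arm LOH — but runs
    begin and end on zero-LAF windows.  The length cutoff is strict
    (``> min_length_bp``).  Segment bounds snap to window bounds.
    """
    by_chrom: Dict[str, List[LAFWindow]] = defaultdict(list)
    for w in windows:
        by_chrom[w.chrom].append(w)
    segments = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        ws = sorted(by_chrom[chrom], key=lambda w: w.window_index)
        run: List[LAFWindow] = []
        pending_gap = 0
        for w in ws:
            if w.laf is not None and w.laf <= epsilon:
                run.append(w)
                pending_gap = 0
            elif w.laf is None and run and pending_gap < max_gap_windows:
                pending_gap += 1  # provisionally bridge a variant-free window
            else:
                _flush_run(run, min_length_bp, segments)
                run, pending_gap = [], 0
        _flush_run(run, min_length_bp, segments)
    return segments


def _flush_run(run: List[LAFWindow], min_length_bp: int,
               out: List[LOHSegment]) -> None:
    if not run:
        return
    start, end = run[0].start, run[-1].end
    if end - start + 1 > min_length_bp:
        out.append(LOHSegment(chrom=run[0].chrom, start=start, end=end))


def summarize_loh(
    segments: Sequence[LOHSegment],
    chrom_info: Sequence[ChromosomeInfo],
    variant_catalog: Optional[Dict[str, Sequence[int]]] = None,
) -> LOHSummary:
    """Genome-wide LOH fractions by length and by known-variant content.

    With a positional ``variant_catalog`` (chromosome -> sorted known
    variant positions), variants inside each segment are counted
    exactly.  Without one, a segment's variant content is scaled from
    the chromosome's total known-variant count in proportion to the
    segment's share of the chromosome length (a whole-chromosome
    segment therefore receives the full count).
    """
    info = {ci.name: ci for ci in chrom_info}
    per_chrom: Dict[str, dict] = {
        ci.name: {"loh_bp": 0, "loh_variants": 0} for ci in chrom_info
    }
    for seg in segments:
        if seg.chrom not in info:
            raise ValueError(f"segment on unknown chromosome {seg.chrom}")
        ci = info[seg.chrom]
        if seg.end > ci.length_bp or seg.start < 1:
            raise ValueError(
                f"segment {seg.chrom}:{seg.start}-{seg.end} exceeds "
                f"chromosome length {ci.length_bp}"
            )
        if seg.n_known_variants is not None:
            n_var = seg.n_known_variants
        elif variant_catalog is not None:
            positions = np.asarray(variant_catalog.get(seg.chrom, ()))
            n_var = int(np.count_nonzero(
                (positions >= seg.start) & (positions <= seg.end)))
        else:
            n_var = round(ci.known_variant_count * seg.length / ci.length_bp)
        per_chrom[seg.chrom]["loh_bp"] += seg.length
        per_chrom[seg.chrom]["loh_variants"] += n_var

    for name, entry in per_chrom.items():
        entry["percent_loh"] = 100.0 * entry["loh_bp"] / info[name].length_bp
    return LOHSummary(
        per_chromosome=per_chrom,
        total_bp=sum(ci.length_bp for ci in chrom_info),
        total_variants=sum(ci.known_variant_count for ci in chrom_info),
        loh_bp=sum(e["loh_bp"] for e in per_chrom.values()),
        loh_variants=sum(e["loh_variants"] for e in per_chrom.values()),
    )


def summarize_loh_entries(entries, chrom_info: Sequence[ChromosomeInfo]) -> LOHSummary:
    """Build an :class:`LOHSummary` from precomputed per-chromosome LOH
    entries (``name``, ``loh_bp``, ``loh_variants`` columns or dicts),
    e.g. a published per-chromosome LOH table."""
    import pandas as pd

    df = pd.DataFrame(entries)
    info = {ci.name: ci for ci in chrom_info}
    per_chrom = {}
    for row in df.itertuples():
        if row.name not in info:
            raise ValueError(f"unknown chromosome {row.name}")
        per_chrom[row.name] = {
            "loh_bp": int(row.loh_bp),
            "loh_variants": int(row.loh_variants),
            "percent_loh": 100.0 * int(row.loh_bp) / info[row.name].length_bp,
        }
    return LOHSummary(
        per_chromosome=per_chrom,
        total_bp=sum(ci.length_bp for ci in chrom_info),
        total_variants=sum(ci.known_variant_count for ci in chrom_info),
        loh_bp=sum(e["loh_bp"] for e in per_chrom.values()),
        loh_variants=sum(e["loh_variants"] for e in per_chrom.values()),
    )


def het_hom_ratio(het_count: int, hom_count: int) -> float:
    """Heterozygous over homozygous variant count.

    Reported at two decimals in summary tables; the full-precision value
    is returned.  A zero homozygous count leaves the ratio undefined.
    """
    if hom_count == 0:
        raise ValueError("het/hom ratio undefined for hom_count = 0")
    return het_count / hom_count
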