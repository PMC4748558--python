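"""Binned read-coverage profiles normalized to a stated ploidy.

Read evidence is counted in fixed windows (100 kb by default) tiling
each chromosome from position 1, and scaled so that the median
autosomal bin sits at the target ploidy (tetraploid for a near-
tetraploid genome) — a robust normalization that is insensitive to
amplified tails.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np

from .types import ChromosomeInfo, CoverageBin, chrom_sort_key

__all__ = ["bin_reads", "normalize_copy_number"]


def bin_reads(
    read_positions: Dict[str, Sequence[int]],
    chrom_info: Sequence[ChromosomeInfo],
    bin_bp: int = 100_000,
) -> List[CoverageBin]:
    """Count read start positions per tiling window anchored at 1.

    ``read_positions`` maps chromosome name to 1-based positions.  A
    position outside its chromosome is refused with its coordinate.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be > 0")
    lengths = {ci.name: ci.length_bp for ci in chrom_info}
    bins: List[CoverageBin] = []
    for ci in sorted(chrom_info, key=lambda c: chrom_sort_key(c.name)):
        positions = np.asarray(read_positions.get(ci.name, ()), dtype=np.int64)
        if positions.size:
            bad = positions[(positions < 1) | (positions > ci.length_bp)]
            if bad.size:
                raise ValueError(
                    f"read position {ci.name}:{int(bad[0])} outside chromosome "
                    f"of length {ci.length_bp}"
                )
        n_bins = -(-ci.length_bp // bin_bp)
        counts = np.bincount((positions - 1) // bin_bp, minlength=n_bins)
        for w in range(n_bins):
            bins.append(CoverageBin(
                chrom=ci.name,
                bin_index=w,
                start=w * bin_bp + 1,
                end=min((w + 1) * bin_bp, ci.length_bp),
                read_count=int(counts[w]),
            ))
    return bins


_SEX_CHROMS = {"chrX", "chrY"}


def normalize_copy_number(
    bins: Sequence[CoverageBin], target_ploidy: int = 4
) -> List[CoverageBin]:
    """Scale bin counts to haploid copy number.

    ``normalized_copy = target_ploidy * count / median(nonzero autosomal
    counts)``; the median autosomal bin therefore sits at the target
    ploidy by construction, and the scaling is invariant under global
    multiplication of the counts.  All-zero coverage is refused.
    """
    autosomal = np.array(
        [b.read_count for b in bins
         if b.chrom not in _SEX_CHROMS and b.read_count > 0],
        dtype=float,
    )
    if autosomal.size == 0:
        raise ValueError("no nonzero autosomal coverage to normalize against")
    baseline = float(np.median(autosomal))
    return [
        CoverageBin(
            chrom=b.chrom, bin_index=b.bin_index, start=b.start, end=b.end,
            read_count=b.read_count,
            normalized_copy=target_ploidy * b.read_count / baseline,
        )
        for b in bins
    ]
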