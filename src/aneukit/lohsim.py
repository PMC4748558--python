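"""Effect of LOH on a diploid genome's het/hom variant counts.

A loss-of-heterozygosity event converts formerly heterozygous sites to
homozygous ones while leaving the total variant count unchanged.  Given
a diploid genome's (hom, het) SNV counts and the fraction of the genome
(or of its variants) subject to LOH, the expected post-LOH counts
follow in closed form; a regional Monte-Carlo counterpart draws
contiguous LOH blocks over an explicit genome model and converts the
heterozygous variants they contain.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .types import DiploidCounts, LOHSimResult

__all__ = ["simulate_loh_expected", "simulate_loh_regions"]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def simulate_loh_expected(
    counts: DiploidCounts, loh_fraction: float, mode: str = "by_length"
) -> LOHSimResult:
    """Deterministic expectation: a fraction ``loh_fraction`` of the
    heterozygous variants becomes homozygous.

    The transferred count is rounded to the nearest integer, half away
    from zero.  ``mode`` is a label recording which fraction was
    supplied (genome length in LOH vs. variants in LOH); the arithmetic
    is identical.
    """
    if not 0.0 <= loh_fraction <= 1.0:
        raise ValueError("loh_fraction must lie in [0, 1]")
    transferred = _round_half_away(counts.het_count * loh_fraction)
    het_after = counts.het_count - transferred
    hom_after = counts.hom_count + transferred
    return LOHSimResult(
        hom_after=hom_after,
        het_after=het_after,
        ratio_before=counts.het_count / counts.hom_count,
        ratio_after=het_after / hom_after,
        loh_fraction=loh_fraction,
        mode=mode,
    )


def simulate_loh_regions(
    model,
    target_fraction: float,
    seed: int = 0,
    mean_region_bp: float = 30e6,
    max_attempts: int = 10_000,
) -> LOHSimResult:
    """Monte-Carlo counterpart: draw contiguous LOH regions until at
    least ``target_fraction`` of the genome is covered, then convert the
    heterozygous variants inside them.

    ``model`` is a :class:`~aneukit.simulate.GenomeModel` (any object
    with ``chromosomes`` name->length and a ``variants`` frame holding
    ``chrom``, ``pos`` and ``zygosity``).  Region lengths are drawn from
    an exponential distribution of mean ``mean_region_bp`` truncated to
    the host chromosome; regions never overlap (drawn without
    replacement).  Counts are exact for the drawn regions and seeded
    runs are reproducible.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    chroms = list(model.chromosomes.items())
    genome_bp = sum(L for _, L in chroms)
    weights = np.array([L for _, L in chroms], dtype=float) / genome_bp

    taken = {name: [] for name, _ in chroms}  # disjoint (start, end) per chrom
    covered = 0
    attempts = 0
    while covered < target_fraction * genome_bp and attempts < max_attempts:
        attempts += 1
        ci = rng.choice(len(chroms), p=weights)
        name, length = chroms[ci]
        span = int(min(max(1, rng.exponential(mean_region_bp)), length))
        # allow the draw to hang over either chromosome end and clip:
        # every position is then covered with equal probability, so the
        # realized coverage is position-uniform
        anchor = int(rng.integers(2 - span, length + 1))
        start = max(1, anchor)
        end = min(length, anchor + span - 1)
        span = end - start + 1
        if any(s <= end and start <= e for s, e in taken[name]):
            continue
        taken[name].append((start, end))
        covered += span
    if covered < target_fraction * genome_bp:
        raise RuntimeError(
            "could not reach the target LOH fraction; the genome is too "
            "fragmented for non-overlapping regions of this size"
        )

    variants = model.variants
    het = variants["zygosity"] == "het"
    in_loh = np.zeros(len(variants), dtype=bool)
    for name, spans in taken.items():
        on_chrom = (variants["chrom"] == name).to_numpy()
        pos = variants["pos"].to_numpy()
        for s, e in spans:
            in_loh |= on_chrom & (pos >= s) & (pos <= e)
    transferred = int((het.to_numpy() & in_loh).sum())

    hom_count = int((variants["zygosity"] == "hom").sum())
    het_count = int(het.sum())
    return LOHSimResult(
        hom_after=hom_count + transferred,
        het_after=het_count - transferred,
        ratio_before=het_count / hom_count if hom_count else float("nan"),
        ratio_after=(het_count - transferred) / (hom_count + transferred)
        if hom_count + transferred
        else float("nan"),
        loh_fraction=covered / genome_bp,
        mode="regional",
    )
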