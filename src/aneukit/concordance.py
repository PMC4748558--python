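"""Concordance of variant call sets across libraries and panels.

Variant identity is the (chromosome, position, ref, alt) tuple;
genotype is deliberately excluded, since aneuploidy makes zygosity
sensitive to per-library sampling noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

from .types import VariantKey

__all__ = ["overlap_variants", "panel_recall", "PanelRecall"]


def _as_set(name: str, values) -> Set[VariantKey]:
    as_list = list(values)
    as_set = set(as_list)
    if len(as_set) != len(as_list):
        warnings.warn(
            f"call set {name!r} contained {len(as_list) - len(as_set)} "
            "duplicate keys; deduplicated",
            stacklevel=3,
        )
    return as_set


def overlap_variants(call_sets: Dict[str, Sequence[VariantKey]]
                     ) -> Dict[FrozenSet[str], int]:
    """Exact region counts of the 2- or 3-set overlap diagram.

    The returned mapping has one entry per non-empty subset of set
    names, counting the variants present in *exactly* those sets.
    Region counts sum to the union size; per-set totals are conserved.
    """
    if not 2 <= len(call_sets) <= 3:
        raise ValueError("overlap_variants expects 2 or 3 named call sets")
    sets = {name: _as_set(name, vals) for name, vals in call_sets.items()}
    names = list(sets)
    regions: Dict[FrozenSet[str], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            for other in names:
                if other not in combo:
                    inside = inside - sets[other]
            regions[frozenset(combo)] = len(inside)
    return regions


@dataclass
class PanelRecall:
    recall: float
    n_panel: int
    n_found: int
    missing: List[VariantKey] = field(default_factory=list)


def panel_recall(calls: Sequence[VariantKey],
                 panel: Sequence[VariantKey]) -> PanelRecall:
    """Fraction of panel variants present in the call set, with the
    missing panel entries listed.  An empty panel leaves recall
    undefined and is refused."""
    panel_set = set(panel)
    if not panel_set:
        raise ValueError("recall is undefined for an empty panel")
    call_set = set(calls)
    found = panel_set & call_set
    missing = sorted(panel_set - call_set,
                     key=lambda k: (k.chrom, k.pos, k.ref, k.alt))
    return PanelRecall(
        recall=len(found) / len(panel_set),
        n_panel=len(panel_set),
        n_found=len(found),
        missing=missing,
    )
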