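"""Cross-library clustering of interchromosomal translocation calls.

Raw breakpoint-pair calls from several sequencing libraries are merged
into events by single-linkage clustering: two calls are directly linked
iff they share the canonical chromosome pair and the two-letter
orientation code, and on *both* sides the gap between their breakpoint
windows is at most the clustering window (5 kb by default; overlapping
windows have gap 0).  Events are the transitive closure of that
relation.

Coordinates recovered from reduced-precision (1 Mb-rounded) printings
cannot support 5 kb decisions; :func:`resolve_coarse_ambiguity` lets a
table's recorded event ids arbitrate exactly those cases.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .types import (
    FusionCandidate,
    SVCluster,
    TranslocationCall,
    chrom_sort_key,
)

__all__ = [
    "canonicalize_call",
    "cluster_translocations",
    "resolve_coarse_ambiguity",
    "library_overlap_counts",
    "OverlapSummary",
    "support_fusion_candidates",
    "FusionSupport",
]


def canonicalize_call(call: TranslocationCall) -> TranslocationCall:
    """Return the call with side A preceding side B in karyotype order
    (chr1..chr22, chrX, chrY).

    When the sides are swapped the two orientation letters are
    exchanged (each letter stays attached to its breakpoint; letters are
    not strand-complemented).
    """
    return call if call.is_canonical else call.swapped()


def _window_gap(s1: int, e1: int, s2: int, e2: int) -> int:
    """Base pairs separating two closed intervals; 0 when they overlap."""
    if e1 < s2:
        return s2 - e1 - 1
    if e2 < s1:
        return s1 - e2 - 1
    return 0


def _linked(a: TranslocationCall, b: TranslocationCall, window: int) -> bool:
    return (
        _window_gap(a.start_a, a.end_a, b.start_a, b.end_a) <= window
        and _window_gap(a.start_b, a.end_b, b.start_b, b.end_b) <= window
    )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def cluster_translocations(
    calls: Sequence[TranslocationCall], window: int = 5000
) -> List[SVCluster]:
    """Partition canonicalized calls into single-linkage events.

    Cluster ids are assigned deterministically by (canonical chromosome
    pair, minimal side-A start, minimal side-B start, orientation).
    Non-canonical input is refused; run :func:`canonicalize_call` first.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    for c in calls:
        if not c.is_canonical:
            raise ValueError(
                f"call {c.chrom_a}/{c.chrom_b} is not canonicalized"
            )
    uf = _UnionFind(len(calls))
    groups: Dict[tuple, List[int]] = defaultdict(list)
    for i, c in enumerate(calls):
        groups[(c.chrom_a, c.chrom_b, c.orientation)].append(i)
    for idx in groups.values():
        idx.sort(key=lambda i: calls[i].start_a)
        # sweep on side A: once every later call starts more than
        # `window` past the running maximum side-A end, no further links
        # from i are possible
        max_end = [0] * len(idx)
        running = 0
        for k, i in enumerate(idx):
            running = max(running, calls[i].end_a)
            max_end[k] = running
        for k, i in enumerate(idx):
            for m in range(k + 1, len(idx)):
                j = idx[m]
                if calls[j].start_a - max_end[k] - 1 > window:
                    break
                if _linked(calls[i], calls[j], window):
                    uf.union(i, j)

    members: Dict[int, List[int]] = defaultdict(list)
    for i in range(len(calls)):
        members[uf.find(i)].append(i)
    return _build_clusters([[calls[i] for i in grp] for grp in members.values()])


def _build_clusters(groups: Sequence[Sequence[TranslocationCall]]) -> List[SVCluster]:
    protos = []
    for grp in groups:
        span_a = (min(c.start_a for c in grp), max(c.end_a for c in grp))
        span_b = (min(c.start_b for c in grp), max(c.end_b for c in grp))
        first = grp[0]
        protos.append((first.chrom_a, first.chrom_b, span_a, span_b,
                       first.orientation, list(grp)))
    protos.sort(key=lambda p: (chrom_sort_key(p[0]), chrom_sort_key(p[1]),
                               p[2], p[3], p[4]))
    return [
        SVCluster(
            cluster_id=cid,
            members=grp,
            chrom_a=ca, chrom_b=cb,
            span_a=sa, span_b=sb,
            orientation=ori,
            libraries=frozenset(c.library for c in grp),
        )
        for cid, (ca, cb, sa, sb, ori, grp) in enumerate(protos, start=1)
    ]


def resolve_coarse_ambiguity(clusters: Sequence[SVCluster]) -> List[SVCluster]:
    """Split clusters whose merge rests on reduced-precision coordinates.

    A coordinate printed at 1 Mb precision carries an uncertainty three
    orders of magnitude larger than the 5 kb linkage rule, so two events
    whose true breakpoints were more than 5 kb apart can collapse onto
    the same printed value.  Where a cluster mixes distinct *recorded*
    event ids and at least one member has a coarse side, the recorded
    ids are taken as authoritative and the cluster is split by them.
    Clusters without recorded ids, without coarse members, or with a
    single recorded id pass through unchanged.
    """
    groups: List[List[TranslocationCall]] = []
    for cl in clusters:
        ids = cl.recorded_ids
        coarse = any(m.coarse_a or m.coarse_b for m in cl.members)
        if len(ids) > 1 and coarse and all(
            m.recorded_id is not None for m in cl.members
        ):
            by_id = defaultdict(list)
            for m in cl.members:
                by_id[m.recorded_id].append(m)
            groups.extend(by_id.values())
        else:
            groups.append(list(cl.members))
    return _build_clusters(groups)


@dataclass
class OverlapSummary:
    """Cross-library sharing of clustered events."""

    total_clusters: int
    per_library: Dict[str, int]          # clusters containing that library
    shared_two_plus: int                 # clusters seen in >= 2 libraries
    regions: Dict[frozenset, int] = field(default_factory=dict)  # exact library set -> count


def library_overlap_counts(clusters: Sequence[SVCluster]) -> OverlapSummary:
    """Per-library event counts and the full region breakdown of a
    library-overlap diagram."""
    per_library: Dict[str, int] = defaultdict(int)
    regions: Dict[frozenset, int] = defaultdict(int)
    shared = 0
    for cl in clusters:
        for lib in cl.libraries:
            per_library[lib] += 1
        regions[cl.libraries] += 1
        if len(cl.libraries) >= 2:
            shared += 1
    return OverlapSummary(
        total_clusters=len(clusters),
        per_library=dict(per_library),
        shared_two_plus=shared,
        regions=dict(regions),
    )


@dataclass
class FusionSupport:
    candidate: FusionCandidate
    supported: bool
    supporting_cluster_ids: List[int]


def _near(span: Tuple[int, int], start: int, end: int, window: int) -> bool:
    return _window_gap(span[0], span[1], start, end) <= window


def support_fusion_candidates(
    clusters: Sequence[SVCluster],
    candidates: Sequence[FusionCandidate],
    window: int = 5000,
) -> List[FusionSupport]:
    """Check which fusion candidates have breakpoint-cluster support.

    A candidate is supported iff some cluster joins the candidate's two
    gene chromosomes and each cluster breakpoint span overlaps, or lies
    within ``window`` bp of, the corresponding gene interval — under
    either assignment of cluster sides to genes.  Orientation is not
    constrained (gene strand does not restrict which genomic strands a
    junction may join).
    """
    reports = []
    for cand in candidates:
        hits = []
        for cl in clusters:
            direct = (
                cl.chrom_a == cand.chrom_a and cl.chrom_b == cand.chrom_b
                and _near(cl.span_a, cand.start_a, cand.end_a, window)
                and _near(cl.span_b, cand.start_b, cand.end_b, window)
            )
            swapped = (
                cl.chrom_a == cand.chrom_b and cl.chrom_b == cand.chrom_a
                and _near(cl.span_a, cand.start_b, cand.end_b, window)
                and _near(cl.span_b, cand.start_a, cand.end_a, window)
            )
            if direct or swapped:
                hits.append(cl.cluster_id)
        reports.append(FusionSupport(cand, bool(hits), hits))
    return reports
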