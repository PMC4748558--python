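"""Breakpoint clustering: canonicalization, single linkage, overlap
counts, fusion support — checked against a brute-force graph oracle and
the published BT-474 grouping."""

import itertools

import networkx as nx
import numpy as np
import pytest

from aneukit import datasets
from aneukit.sv import (
    canonicalize_call,
    cluster_translocations,
    library_overlap_counts,
    resolve_coarse_ambiguity,
    support_fusion_candidates,
)
from aneukit.types import FusionCandidate, TranslocationCall

from conftest import make_call


def random_calls(rng, n, n_chroms=4, span=50_000):
    """Small dense call sets so clusters of several calls arise."""
    calls = []
    for _ in range(n):
        ca, cb = sorted(rng.choice(n_chroms, size=2, replace=False) + 1)
        sa = int(rng.integers(1, span))
        sb = int(rng.integers(1, span))
        calls.append(TranslocationCall(
            f"chr{ca}", sa, sa + int(rng.integers(50, 500)),
            f"chr{cb}", sb, sb + int(rng.integers(50, 500)),
            ["ff", "fr", "rf", "rr"][rng.integers(4)],
            ["STD", "LFR1", "LFR2"][rng.integers(3)],
        ))
    return calls


def gap(s1, e1, s2, e2):
    if e1 < s2:
        return s2 - e1 - 1
    if e2 < s1:
        return s1 - e2 - 1
    return 0


def brute_force_partition(calls, window):
    """Independent oracle: explicit pairwise-linkage graph, transitive
    closure via connected components."""
    g = nx.Graph()
    g.add_nodes_from(range(len(calls)))
    for i, j in itertools.combinations(range(len(calls)), 2):
        a, b = calls[i], calls[j]
        if (a.chrom_a, a.chrom_b, a.orientation) != (b.chrom_a, b.chrom_b, b.orientation):
            continue
        if (gap(a.start_a, a.end_a, b.start_a, b.end_a) <= window
                and gap(a.start_b, a.end_b, b.start_b, b.end_b) <= window):
            g.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(g)}


def as_partition(calls, clusters):
    index = {id(c): i for i, c in enumerate(calls)}
    return {frozenset(index[id(m)] for m in cl.members) for cl in clusters}


class TestCanonicalize:
    def test_side_swap_exchanges_orientation_letters(self):
        call = make_call(chrom_a="chr12", chrom_b="chr2", orientation="fr")
        out = canonicalize_call(call)
        assert (out.chrom_a, out.chrom_b) == ("chr2", "chr12")
        assert out.orientation == "rf"
        assert (out.start_a, out.end_a) == (call.start_b, call.end_b)

    def test_canonical_call_unchanged(self):
        call = make_call()
        assert canonicalize_call(call) is call

    def test_clustering_invariant_under_preswapping(self):
        rng = np.random.default_rng(3)
        calls = random_calls(rng, 50)
        swap = rng.random(50) < 0.5
        variant = [c.swapped() if s else c for c, s in zip(calls, swap)]
        base = [canonicalize_call(c) for c in calls]
        alt = [canonicalize_call(c) for c in variant]
        assert as_partition(base, cluster_translocations(base, 5000)) == \
            as_partition(alt, cluster_translocations(alt, 5000))


class TestClustering:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        calls = [canonicalize_call(c) for c in random_calls(rng, 30)]
        window = int(rng.integers(0, 10_000))
        got = as_partition(calls, cluster_translocations(calls, window))
        assert got == brute_force_partition(calls, window)

    def test_single_call_single_cluster(self):
        (cl,) = cluster_translocations([make_call()], 5000)
        assert len(cl.members) == 1 and cl.libraries == {"STD"}

    def test_non_canonical_input_refused(self):
        call = make_call(chrom_a="chr2", chrom_b="chr1")
        with pytest.raises(ValueError, match="canonical"):
            cluster_translocations([call], 5000)

    def test_order_invariance_and_deterministic_ids(self):
        rng = np.random.default_rng(9)
        calls = [canonicalize_call(c) for c in random_calls(rng, 40)]
        a = cluster_translocations(calls, 5000)
        b = cluster_translocations(calls[::-1], 5000)
        assert [(c.chrom_a, c.span_a, c.chrom_b, c.span_b, c.orientation)
                for c in a] == \
               [(c.chrom_a, c.span_a, c.chrom_b, c.span_b, c.orientation)
                for c in b]

    def test_window_monotonicity(self):
        rng = np.random.default_rng(5)
        calls = [canonicalize_call(c) for c in random_calls(rng, 40)]
        counts = [len(cluster_translocations(calls, w))
                  for w in (0, 1000, 5000, 20_000, 10**9)]
        assert counts == sorted(counts, reverse=True)

    def test_window_extremes(self):
        calls = [make_call(start_a=i * 10_000, end_a=i * 10_000 + 100,
                           start_b=i * 10_000, end_b=i * 10_000 + 100)
                 for i in range(5)]
        assert len(cluster_translocations(calls, 0)) == 5
        assert len(cluster_translocations(calls, 10**9)) == 1

    def test_published_event_5_rows_form_one_cluster(self):
        calls = [c for c in datasets.load_bt474_translocations()
                 if c.recorded_id == 5]
        assert len(calls) == 6
        (cl,) = cluster_translocations([canonicalize_call(c) for c in calls], 5000)
        assert cl.libraries == {"LFR1", "LFR2"}
        assert (cl.chrom_a, cl.chrom_b, cl.orientation) == ("chr1", "chr16", "ff")

    def test_full_precision_subset_matches_published_grouping(self):
        calls = [canonicalize_call(c)
                 for c in datasets.load_bt474_translocations()
                 if not (c.coarse_a or c.coarse_b)]
        clusters = cluster_translocations(calls, 5000)
        for cl in clusters:
            assert len(cl.recorded_ids) == 1, (
                f"cluster mixes published events {sorted(cl.recorded_ids)}")
        assert len(clusters) == len({c.recorded_id for c in calls})


class TestOverlapCounts:
    def test_single_library_has_no_sharing(self):
        calls = [make_call(start_a=i * 100_000, end_a=i * 100_000 + 100,
                           library="LFR1") for i in range(4)]
        summary = library_overlap_counts(cluster_translocations(calls, 5000))
        assert summary.shared_two_plus == 0
        assert summary.per_library == {"LFR1": summary.total_clusters}

    def test_region_counts_sum_to_total(self):
        calls = [canonicalize_call(c)
                 for c in datasets.load_bt474_translocations()]
        summary = library_overlap_counts(cluster_translocations(calls, 5000))
        assert sum(summary.regions.values()) == summary.total_clusters


class TestCoarseResolution:
    def test_reduced_precision_merge_is_split_by_recorded_ids(self):
        calls = [canonicalize_call(c)
                 for c in datasets.load_bt474_translocations()]
        merged = cluster_translocations(calls, 5000)
        resolved = resolve_coarse_ambiguity(merged)
        assert len(resolved) == len(merged) + 1
        for cl in resolved:
            assert len(cl.recorded_ids) == 1

    def test_full_precision_clusters_untouched(self):
        rng = np.random.default_rng(2)
        calls = [canonicalize_call(c) for c in random_calls(rng, 30)]
        clusters = cluster_translocations(calls, 5000)
        assert as_partition(calls, resolve_coarse_ambiguity(clusters)) == \
            as_partition(calls, clusters)


class TestFusionSupport:
    def test_published_candidates_three_of_five(self):
        calls = [canonicalize_call(c)
                 for c in datasets.load_bt474_translocations()]
        clusters = resolve_coarse_ambiguity(cluster_translocations(calls, 5000))
        candidates = datasets.load_bt474_fusion_candidates()
        reports = support_fusion_candidates(clusters, candidates, 5000)
        supported = {r.candidate.gene_a: r for r in reports if r.supported}
        assert len(supported) == 3
        by_id = {cl.cluster_id: cl for cl in clusters}
        named = {
            gene: {i for cid in rep.supporting_cluster_ids
                   for i in by_id[cid].recorded_ids}
            for gene, rep in supported.items()
        }
        assert 37 in named["AHCTF1"]
        assert 124 in named["VAPB"]
        assert 145 in named["RAB22A"]

    def test_empty_cluster_list_supports_nothing(self):
        candidates = datasets.load_bt474_fusion_candidates()
        assert not any(r.supported
                       for r in support_fusion_candidates([], candidates))

    def test_planted_fusion_inside_gene_bodies_supported(self):
        cand = FusionCandidate("GENEA", "chr1", 100_000, 150_000, "+",
                               "GENEB", "chr2", 500_000, 560_000, "-")
        call = make_call(start_a=120_000, end_a=120_400,
                         start_b=530_000, end_b=530_300, orientation="rf")
        clusters = cluster_translocations([call], 5000)
        (report,) = support_fusion_candidates(clusters, [cand])
        assert report.supported and report.supporting_cluster_ids == [1]
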