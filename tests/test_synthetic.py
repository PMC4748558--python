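"""Generator contracts: determinism, target realization, read-depth
expectations, planted-truth recovery, fixture round-trips."""

import json

import numpy as np
import pandas as pd
import pytest

from aneukit.io import read_translocation_table, read_variant_table
from aneukit.simulate import (
    SimParams,
    make_genome_model,
    simulate_translocation_calls,
    simulate_variant_reads,
    write_fixture_set,
)
from aneukit.sv import cluster_translocations, library_overlap_counts


class TestModel:
    def test_same_seed_identical_models(self, small_params):
        a = make_genome_model(small_params)
        b = make_genome_model(small_params)
        assert a.variants.equals(b.variants)
        assert a.loh_intervals == b.loh_intervals
        assert a.cn_segments == b.cn_segments
        assert a.translocations == b.translocations

    def test_different_seed_different_variants(self, small_params):
        import dataclasses
        other = dataclasses.replace(small_params, seed=small_params.seed + 1)
        a, b = make_genome_model(small_params), make_genome_model(other)
        assert not a.variants.equals(b.variants)

    def test_no_loh_gives_target_het_hom_ratio(self, small_model):
        assert small_model.loh_intervals == []
        assert small_model.het_hom_ratio_realized == pytest.approx(1.6, rel=0.05)

    def test_loh_target_realized_within_two_percent(self):
        params = SimParams(seed=5, loh_fraction=0.22)
        model = make_genome_model(params)
        assert 0.20 <= model.loh_fraction_realized <= 0.24
        # variants inside LOH are never heterozygous
        v = model.variants
        for iv in model.loh_intervals:
            inside = v[(v["chrom"] == iv.chrom) & (v["pos"] >= iv.start)
                       & (v["pos"] <= iv.end)]
            assert (inside["zygosity"] == "hom").all()

    def test_infeasible_fraction_refused(self, small_params):
        import dataclasses
        with pytest.raises(ValueError):
            make_genome_model(dataclasses.replace(small_params, loh_fraction=1.5))


class TestVariantReads:
    def test_zero_depth_sites_emitted_with_empty_depths(self, small_params):
        import dataclasses
        params = dataclasses.replace(small_params, read_depth=0.0)
        model = make_genome_model(params)
        recs = simulate_variant_reads(model)[params.libraries[0]]
        assert all(r.ref_depth + r.alt_depth == 0 for r in recs)

    def test_balanced_het_allele_fraction(self, small_model):
        from aneukit.loh import variant_laf

        hets = {(c, int(p)) for c, p, z in zip(
            small_model.variants["chrom"], small_model.variants["pos"],
            small_model.variants["zygosity"]) if z == "het"}
        baseline = {
            (c, int(p)) for c, p in hets
            if small_model.hap_copies_at(c, int(p)) == (2, 2)
        }
        recs = simulate_variant_reads(small_model)["STD"]
        lafs = []
        alt_fracs = []
        for r in recs:
            if (r.chrom, r.pos) in baseline and r.ref_depth + r.alt_depth > 0:
                lafs.append(variant_laf(r))
                alt_fracs.append(r.alt_depth / (r.alt_depth + r.ref_depth))
        assert len(lafs) >= 1000
        # the alt-allele fraction is unbiased at 0.5; the *lesser*-allele
        # fraction has mean E[min(X, N-X)/N] < 0.5 — compare against an
        # independent binomial-sampling oracle at the same depth law
        assert np.mean(alt_fracs) == pytest.approx(0.5, abs=0.02)
        oracle_rng = np.random.default_rng(12345)
        n = oracle_rng.poisson(small_model.params.read_depth, size=50_000)
        n = n[n > 0]
        x = oracle_rng.binomial(n, 0.5)
        oracle_mean = np.mean(np.minimum(x, n - x) / n)
        assert np.mean(lafs) == pytest.approx(oracle_mean, abs=0.02)

    def test_amplified_het_allele_fraction(self):
        """A het on a 3:1 amplified background averages allele fraction
        ~0.25 on the minor haplotype."""
        params = SimParams(
            seed=11, chromosomes={"chr1": 6_000_000},
            n_cn_segments=1, cn_segment_length_range=(5_999_998, 5_999_999),
            cn_total_copy_choices=(4,),  # (3, 1) or (1, 3) haplotype split
            loh_fraction=0.0, n_translocations=0, variant_density=0.001,
            baseline_ploidy=2,
        )
        model = make_genome_model(params)
        (seg,) = model.cn_segments
        assert sorted(seg.hap_copies) == [1, 3]
        minor_hap = seg.hap_copies.index(min(seg.hap_copies))
        v = model.variants
        minor = {(c, int(p)) for c, p, z, h in zip(
            v["chrom"], v["pos"], v["zygosity"], v["haplotype"])
            if z == "het" and h == minor_hap
            and seg.start <= p <= seg.end}
        recs = simulate_variant_reads(model)["STD"]
        fracs = [r.alt_depth / (r.alt_depth + r.ref_depth) for r in recs
                 if (r.chrom, r.pos) in minor and r.ref_depth + r.alt_depth > 0]
        assert len(fracs) >= 500
        assert np.mean(fracs) == pytest.approx(0.25, abs=0.03)


class TestTranslocationCalls:
    def test_clean_conditions_recover_planted_count_exactly(self):
        import dataclasses
        params = SimParams(seed=17, n_translocations=25,
                           dropout_probability=0.0,
                           false_events_per_library=0.0)
        model = make_genome_model(params)
        sim = simulate_translocation_calls(model)
        assert len(sim.calls) == 25 * 3
        clusters = cluster_translocations(sim.calls, 5000)
        assert len(clusters) == 25
        assert all(cl.libraries == {"STD", "LFR1", "LFR2"} for cl in clusters)

    def test_total_dropout_empty_tables(self, small_model):
        import dataclasses
        params = dataclasses.replace(small_model.params,
                                     dropout_probability=1.0,
                                     false_events_per_library=0.0)
        sim = simulate_translocation_calls(small_model, params)
        assert sim.calls == []

    def test_sharing_pattern_matches_planted_presence(self):
        params = SimParams(seed=23, n_translocations=20,
                           dropout_probability=0.4,
                           false_events_per_library=0.0)
        model = make_genome_model(params)
        sim = simulate_translocation_calls(model)
        summary = library_overlap_counts(cluster_translocations(sim.calls, 5000))
        planted = [libs for libs in sim.event_presence.values() if libs]
        assert summary.total_clusters == len(planted)
        assert summary.shared_two_plus == sum(len(l) >= 2 for l in planted)
        for lib in params.libraries:
            assert summary.per_library.get(lib, 0) == sum(
                lib in l for l in planted)


class TestFixtureSet:
    def test_round_trip_and_manifest(self, tmp_path, small_model):
        out = tmp_path / "fixtures"
        manifest = write_fixture_set(small_model, out, max_lfr_loci=200)
        calls = read_translocation_table(out / "translocations.tsv")
        sim = simulate_translocation_calls(small_model)
        assert calls == sim.calls
        recs = read_variant_table(out / "variants_STD.tsv")
        assert recs == simulate_variant_reads(small_model)["STD"]
        assert manifest["n_translocations"] == len(manifest["translocations"])
        assert set(manifest["files"]) == {
            p.name for p in out.iterdir()} - {"manifest.json"}

    def test_refuses_nonempty_directory(self, tmp_path, small_model):
        out = tmp_path / "fx"
        out.mkdir()
        (out / "existing.txt").write_text("x")
        with pytest.raises(FileExistsError):
            write_fixture_set(small_model, out)
        write_fixture_set(small_model, out, force=True, max_lfr_loci=50)

    def test_regeneration_is_byte_identical(self, tmp_path, small_model):
        out1, out2 = tmp_path / "a", tmp_path / "b"
        write_fixture_set(small_model, out1, max_lfr_loci=200)
        model2 = make_genome_model(small_model.params)
        write_fixture_set(model2, out2, max_lfr_loci=200)
        for p1 in sorted(out1.iterdir()):
            p2 = out2 / p1.name
            assert p1.read_bytes() == p2.read_bytes(), p1.name


class TestEndToEndRecovery:
    def test_pipeline_recovers_planted_truth(self):
        """Default-seed fixture: LOH fraction within 0.02 absolute,
        translocation count exact under clean conditions, copy numbers
        within 10 %."""
        import dataclasses

        from aneukit.coverage import bin_reads, normalize_copy_number
        from aneukit.loh import compute_laf_windows, segment_loh
        from aneukit.types import ChromosomeInfo

        params = SimParams(seed=0, dropout_probability=0.0,
                           false_events_per_library=0.0)
        model = make_genome_model(params)
        info = [ChromosomeInfo(c, l, 0, 0)
                for c, l in model.chromosomes.items()]

        # LOH recovery from noisy allele depths
        recs = simulate_variant_reads(model)["STD"]
        windows = compute_laf_windows(recs, info, 100_000)
        segments = segment_loh(windows, epsilon=0.02)
        est = sum(s.length for s in segments) / model.genome_bp
        assert est == pytest.approx(model.loh_fraction_realized, abs=0.02)

        # translocation recovery
        sim = simulate_translocation_calls(model)
        clusters = cluster_translocations(sim.calls, 5000)
        assert len(clusters) == params.n_translocations

        # copy-number recovery from binned pseudo-reads: expected reads
        # per bin proportional to local copies
        rng = np.random.default_rng(1)
        positions = {c: [] for c in model.chromosomes}
        rate = 0.002  # reads per bp at baseline
        for chrom, length in model.chromosomes.items():
            edges = np.arange(1, length + 2, 50_000)
            for lo, hi in zip(edges[:-1], edges[1:] - 1):
                copies = sum(model.hap_copies_at(chrom, int((lo + hi) // 2)))
                n = rng.poisson(rate * (hi - lo + 1) * copies / params.baseline_ploidy)
                positions[chrom].extend(rng.integers(lo, hi + 1, size=n))
        bins = normalize_copy_number(bin_reads(positions, info, 100_000), 4)
        by_bin = {(b.chrom, b.bin_index): b.normalized_copy for b in bins}
        for seg in model.cn_segments:
            inside = [by_bin[(seg.chrom, i)]
                      for i in range(seg.start // 100_000 + 1,
                                     seg.end // 100_000 - 1)]
            assert np.mean(inside) == pytest.approx(seg.total_copies, rel=0.10)
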