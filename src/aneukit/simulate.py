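"""Synthetic aneuploid-genome generator with planted truth.

Emulates the structure of a near-tetraploid tumor genome: a tetraploid
baseline with megabase-scale amplifications and deletions, large
copy-neutral LOH blocks, het/hom SNVs observed through noisy read
depths, interchromosomal translocations replicated across libraries
with breakpoint jitter, and 384-well LFR compartment assignments with
single-well polymerase errors.  Every planted feature is recorded so
downstream recovery can be scored without external data.

All randomness flows from a single seed through named substreams, so
individual fixtures can be regenerated independently and byte-
identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as _io
from .types import (
    LOHSegment,
    TranslocationCall,
    VariantKey,
    VariantRecord,
    WellObservation,
    chrom_sort_key,
)

__all__ = [
    "SimParams",
    "GenomeModel",
    "make_genome_model",
    "simulate_variant_reads",
    "simulate_translocation_calls",
    "SimulatedCalls",
    "simulate_lfr_wells",
    "LFRWellSim",
    "write_fixture_set",
]

# stable substream labels -> offsets mixed into the seed sequence
_STREAMS = {
    "loh": 1, "cn": 2, "variants": 3, "translocations": 4,
    "reads": 5, "calls": 6, "wells": 7, "errors": 8,
}

_BASES = np.array(["A", "C", "G", "T"])


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], seed])


@dataclass
class SimParams:
    """Study conditions for the synthetic genome.

    Defaults describe a desk-scale near-tetraploid genome: three 30 Mb
    chromosomes, a 1.6 het/hom ratio outside LOH (the value typical of
    a Caucasian diploid genome), one SNV per kilobase, 100x read depth,
    three libraries with 2 kb breakpoint jitter, and a 384-well LFR
    layout with ~40 kb fragments.
    """

    seed: int = 0
    chromosomes: Dict[str, int] = field(default_factory=lambda: {
        "chr1": 30_000_000, "chr2": 30_000_000, "chr3": 30_000_000})
    baseline_ploidy: int = 4
    n_cn_segments: int = 6
    cn_segment_length_range: Tuple[int, int] = (2_000_000, 8_000_000)
    cn_total_copy_choices: Tuple[int, ...] = (2, 3, 6, 8, 10)
    loh_fraction: float = 0.22
    loh_segment_mean_bp: float = 15_000_000
    het_hom_ratio: float = 1.6
    variant_density: float = 0.001          # SNVs per bp
    read_depth: float = 100.0
    libraries: Tuple[str, ...] = ("STD", "LFR1", "LFR2")
    n_translocations: int = 25
    breakpoint_jitter: int = 2000           # <= 2 kb, inside the 5 kb window
    call_window_range: Tuple[int, int] = (100, 1000)
    dropout_probability: float = 0.3        # per-library event dropout
    false_events_per_library: float = 3.0   # Poisson mean
    variant_call_dropout: float = 0.02      # per-library missed SNV call
    n_wells: int = 384
    fragment_length: int = 40_000
    fragments_per_well: int = 60
    polymerase_error_rate: float = 0.005    # error loci per true locus
    phase_block_variants: int = 50

    def __post_init__(self):
        for name in ("loh_fraction", "dropout_probability",
                     "variant_call_dropout", "polymerase_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.breakpoint_jitter < 0:
            raise ValueError("breakpoint_jitter must be >= 0")
        if self.het_hom_ratio <= 0:
            raise ValueError("het_hom_ratio must be > 0")


@dataclass
class CNSegment:
    chrom: str
    start: int
    end: int
    hap_copies: Tuple[int, int]

    @property
    def total_copies(self) -> int:
        return sum(self.hap_copies)


@dataclass
class LOHInterval:
    chrom: str
    start: int
    end: int
    surviving_haplotype: int


@dataclass
class TruthTranslocation:
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    orientation: str


@dataclass
class GenomeModel:
    """Planted truth: segments, copy numbers, LOH, variants,
    translocations."""

    params: SimParams
    chromosomes: Dict[str, int]
    cn_segments: List[CNSegment]
    loh_intervals: List[LOHInterval]
    variants: pd.DataFrame  # chrom, pos, ref, alt, zygosity, haplotype
    translocations: List[TruthTranslocation]

    @property
    def genome_bp(self) -> int:
        return sum(self.chromosomes.values())

    @property
    def loh_fraction_realized(self) -> float:
        return sum(iv.end - iv.start + 1 for iv in self.loh_intervals) / self.genome_bp

    @property
    def het_hom_ratio_realized(self) -> float:
        z = self.variants["zygosity"]
        return float((z == "het").sum() / (z == "hom").sum())

    def hap_copies_at(self, chrom: str, pos: int) -> Tuple[int, int]:
        """Per-haplotype copy numbers at a position (baseline elsewhere)."""
        base = self.params.baseline_ploidy // 2
        for seg in self.cn_segments:
            if seg.chrom == chrom and seg.start <= pos <= seg.end:
                return seg.hap_copies
        for iv in self.loh_intervals:
            if iv.chrom == chrom and iv.start <= pos <= iv.end:
                # copy-neutral LOH: the surviving haplotype carries the
                # full baseline copy number
                full = self.params.baseline_ploidy
                return (full, 0) if iv.surviving_haplotype == 0 else (0, full)
        return (base, base)

    def loh_segments(self) -> List[LOHSegment]:
        return [LOHSegment(iv.chrom, iv.start, iv.end) for iv in self.loh_intervals]


# ---------------------------------------------------------------------------
# model construction

def _place_loh(params: SimParams, rng: np.random.Generator) -> List[LOHInterval]:
    genome_bp = sum(params.chromosomes.values())
    target_bp = params.loh_fraction * genome_bp
    if target_bp == 0:
        return []
    margin = 1_000_000
    # split the target into blocks no larger than the largest chromosome
    # can host and, when the budget allows, large enough (> 10 Mb) to be
    # recoverable by the segmentation rule
    max_block = max(params.chromosomes.values()) - 2 * margin
    # prefer fewer, larger blocks so each stays above the > 10 Mb
    # recoverability threshold whenever the budget allows
    n_blocks = max(1, int(target_bp // min(13_000_000.0,
                                           params.loh_segment_mean_bp)))
    while target_bp / n_blocks > max_block:
        n_blocks += 1
    block = target_bp / n_blocks
    if block > max_block:
        raise ValueError("loh_fraction infeasible for these chromosome sizes")

    intervals: List[LOHInterval] = []
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in params.chromosomes}
    names = list(params.chromosomes)
    for _ in range(n_blocks):
        placed = False
        for _attempt in range(1000):
            chrom = names[rng.integers(len(names))]
            length = int(block)
            lo, hi = 1 + margin, params.chromosomes[chrom] - margin - length
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + length - 1
            # keep 2 Mb clearance between blocks so they stay distinct
            if any(s - 2_000_000 <= end and start <= e + 2_000_000
                   for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            intervals.append(LOHInterval(chrom, start, end,
                                         int(rng.integers(2))))
            placed = True
            break
        if not placed:
            raise ValueError(
                "could not place the requested LOH fraction; lower it or "
                "enlarge the chromosomes"
            )
    return intervals


def _place_cn_segments(params: SimParams, loh: List[LOHInterval],
                       rng: np.random.Generator) -> List[CNSegment]:
    base = params.baseline_ploidy // 2
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in params.chromosomes}
    for iv in loh:
        occupied[iv.chrom].append((iv.start, iv.end))
    segments: List[CNSegment] = []
    names = list(params.chromosomes)
    for _ in range(params.n_cn_segments):
        for _attempt in range(1000):
            chrom = names[rng.integers(len(names))]
            length = int(rng.integers(*params.cn_segment_length_range))
            hi = params.chromosomes[chrom] - length
            if hi <= 1:
                continue
            start = int(rng.integers(1, hi))
            end = start + length - 1
            if any(s <= end and start <= e for s, e in occupied[chrom]):
                continue
            total = int(rng.choice(params.cn_total_copy_choices))
            # put the imbalance on one haplotype; keep the other at baseline
            other = min(base, total)
            hap = (total - other, other) if rng.integers(2) else (other, total - other)
            occupied[chrom].append((start, end))
            segments.append(CNSegment(chrom, start, end, hap))
            break
    return segments


def _draw_variants(params: SimParams, loh: List[LOHInterval],
                   rng: np.random.Generator) -> pd.DataFrame:
    frames = []
    p_het = params.het_hom_ratio / (1.0 + params.het_hom_ratio)
    for chrom, length in params.chromosomes.items():
        n = rng.poisson(params.variant_density * length)
        pos = np.unique(rng.integers(1, length + 1, size=n))
        n = pos.size
        het = rng.random(n) < p_het
        hap = rng.integers(0, 2, size=n)
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        df = pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "ref": _BASES[ref_idx], "alt": _BASES[alt_idx],
            "zygosity": np.where(het, "het", "hom"),
            "haplotype": np.where(het, hap, -1),
        })
        # LOH transformation: het variants on the lost haplotype vanish,
        # het variants on the surviving haplotype become homozygous
        for iv in (x for x in loh if x.chrom == chrom):
            inside = (df["pos"] >= iv.start) & (df["pos"] <= iv.end)
            is_het = df["zygosity"] == "het"
            lost = inside & is_het & (df["haplotype"] != iv.surviving_haplotype)
            converted = inside & is_het & (df["haplotype"] == iv.surviving_haplotype)
            df = df[~lost]
            df.loc[converted[~lost], "zygosity"] = "hom"
            df.loc[converted[~lost], "haplotype"] = -1
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out


def _draw_translocations(params: SimParams,
                         rng: np.random.Generator) -> List[TruthTranslocation]:
    names = sorted(params.chromosomes, key=chrom_sort_key)
    margin = 500_000
    # events on the same chromosome pair must stay well apart so that
    # jittered calls from different events can never fall in one cluster
    min_separation = 10 * (params.breakpoint_jitter + params.call_window_range[1]) + 50_000
    events: List[TruthTranslocation] = []
    orientations = ["ff", "fr", "rf", "rr"]
    attempts = 0
    while len(events) < params.n_translocations and attempts < 100_000:
        attempts += 1
        ia, ib = sorted(rng.choice(len(names), size=2, replace=False))
        ca, cb = names[ia], names[ib]
        pa = int(rng.integers(margin, params.chromosomes[ca] - margin))
        pb = int(rng.integers(margin, params.chromosomes[cb] - margin))
        clash = any(
            ev.chrom_a == ca and ev.chrom_b == cb
            and (abs(ev.pos_a - pa) < min_separation
                 or abs(ev.pos_b - pb) < min_separation)
            for ev in events
        )
        if clash:
            continue
        events.append(TruthTranslocation(
            ca, pa, cb, pb, orientations[rng.integers(4)]))
    if len(events) < params.n_translocations:
        raise ValueError("could not place the requested translocation count")
    return events


def make_genome_model(params: SimParams) -> GenomeModel:
    """Build the planted-truth genome.  Deterministic given the seed."""
    if params.loh_fraction > 1:
        raise ValueError("loh_fraction must be <= 1")
    loh = _place_loh(params, _rng(params.seed, "loh"))
    cn = _place_cn_segments(params, loh, _rng(params.seed, "cn"))
    variants = _draw_variants(params, loh, _rng(params.seed, "variants"))
    transloc = _draw_translocations(params, _rng(params.seed, "translocations"))
    return GenomeModel(
        params=params,
        chromosomes=dict(params.chromosomes),
        cn_segments=cn,
        loh_intervals=loh,
        variants=variants,
        translocations=transloc,
    )


# ---------------------------------------------------------------------------
# read-level observations

def simulate_variant_reads(model: GenomeModel,
                           params: Optional[SimParams] = None
                           ) -> Dict[str, List[VariantRecord]]:
    """Per-library SNV call tables with noisy allele depths.

    Total depth at a site is Poisson with mean scaled by the local total
    copy number relative to baseline ploidy; the alt depth is binomial
    in the local alt-allele copy fraction.  A small per-library call
    dropout decorrelates the call sets.
    """
    params = params or model.params
    rng = _rng(params.seed, "reads")
    v = model.variants
    n = len(v)

    hap0 = np.empty(n, dtype=np.int64)
    hap1 = np.empty(n, dtype=np.int64)
    for i, (chrom, pos) in enumerate(zip(v["chrom"], v["pos"])):
        hap0[i], hap1[i] = model.hap_copies_at(chrom, int(pos))
    total_copies = hap0 + hap1
    hap = v["haplotype"].to_numpy()
    zyg = v["zygosity"].to_numpy()
    alt_copies = np.where(zyg == "hom", total_copies,
                          np.where(hap == 0, hap0, hap1))

    out: Dict[str, List[VariantRecord]] = {}
    for lib in params.libraries:
        depth_mean = params.read_depth * total_copies / params.baseline_ploidy
        depth = rng.poisson(depth_mean)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt = np.where(total_copies > 0, alt_copies / np.maximum(total_copies, 1), 0.0)
        alt_d = rng.binomial(depth, p_alt)
        ref_d = depth - alt_d
        keep = rng.random(n) >= params.variant_call_dropout
        records = [
            VariantRecord(
                chrom=c, pos=int(p), ref=r, alt=a, zygosity=z,
                ref_depth=int(rd), alt_depth=int(ad), library=lib,
            )
            for c, p, r, a, z, rd, ad, k in zip(
                v["chrom"], v["pos"], v["ref"], v["alt"], zyg,
                ref_d, alt_d, keep)
            if k
        ]
        out[lib] = records
    return out


@dataclass
class SimulatedCalls:
    """Per-library translocation calls plus the planted sharing truth."""

    calls: List[TranslocationCall]
    event_presence: Dict[int, frozenset]   # event index -> libraries carrying it
    n_false_by_library: Dict[str, int]


def simulate_translocation_calls(model: GenomeModel,
                                 params: Optional[SimParams] = None
                                 ) -> SimulatedCalls:
    """Observe each planted event in each library with probability
    ``1 - dropout``, with independent uniform breakpoint jitter and
    100-1000 bp call windows; library-specific false events are added at
    a Poisson rate.  Calls are emitted canonicalized."""
    params = params or model.params
    rng = _rng(params.seed, "calls")
    calls: List[TranslocationCall] = []
    presence: Dict[int, frozenset] = {}
    n_false: Dict[str, int] = {}

    def one_call(ev: TruthTranslocation, lib: str) -> TranslocationCall:
        def window(pos, chrom_len):
            center = pos + int(rng.integers(-params.breakpoint_jitter,
                                            params.breakpoint_jitter + 1))
            width = int(rng.integers(*params.call_window_range))
            start = max(1, center - width // 2)
            return start, min(chrom_len, start + width)
        sa, ea = window(ev.pos_a, model.chromosomes[ev.chrom_a])
        sb, eb = window(ev.pos_b, model.chromosomes[ev.chrom_b])
        return TranslocationCall(
            chrom_a=ev.chrom_a, start_a=sa, end_a=ea,
            chrom_b=ev.chrom_b, start_b=sb, end_b=eb,
            orientation=ev.orientation, library=lib,
        )

    for idx, ev in enumerate(model.translocations):
        libs = [lib for lib in params.libraries
                if rng.random() >= params.dropout_probability]
        presence[idx] = frozenset(libs)
        for lib in libs:
            calls.append(one_call(ev, lib))

    names = sorted(model.chromosomes, key=chrom_sort_key)
    for lib in params.libraries:
        k = int(rng.poisson(params.false_events_per_library))
        n_false[lib] = k
        for _ in range(k):
            ia, ib = sorted(rng.choice(len(names), size=2, replace=False))
            ev = TruthTranslocation(
                names[ia],
                int(rng.integers(500_000, model.chromosomes[names[ia]] - 500_000)),
                names[ib],
                int(rng.integers(500_000, model.chromosomes[names[ib]] - 500_000)),
                ["ff", "fr", "rf", "rr"][rng.integers(4)],
            )
            calls.append(one_call(ev, lib))
    return SimulatedCalls(calls=calls, event_presence=presence,
                          n_false_by_library=n_false)


# ---------------------------------------------------------------------------
# LFR wells

@dataclass
class LFRWellSim:
    """Well observations for variant loci plus injected error truth."""

    observations: Dict[VariantKey, WellObservation]
    error_keys: frozenset                  # injected single-well errors
    records: List[VariantRecord]           # annotated records (true + error)
    phase_truth: Dict[tuple, int]          # (chrom, pos) -> parental haplotype


def simulate_lfr_wells(model: GenomeModel,
                       params: Optional[SimParams] = None,
                       max_loci: Optional[int] = None) -> LFRWellSim:
    """Disperse ~40 kb fragments of either haplotype across 384 wells
    and derive per-locus well observations from fragment overlap.

    Polymerase errors are injected as novel single-well false alleles at
    ``polymerase_error_rate`` error loci per true locus.  With
    ``max_loci`` only a deterministic subsample of true loci is
    annotated (errors are always included).
    """
    from .lfr import compute_well_support

    params = params or model.params
    rng = _rng(params.seed, "wells")
    err_rng = _rng(params.seed, "errors")

    v = model.variants
    if max_loci is not None and len(v) > max_loci:
        idx = np.sort(rng.choice(len(v), size=max_loci, replace=False))
        v = v.iloc[idx].reset_index(drop=True)

    by_chrom = {}
    for chrom, grp in v.groupby("chrom"):
        grp = grp.sort_values("pos")
        keys = [VariantKey(chrom, int(p), r, a)
                for p, r, a in zip(grp["pos"], grp["ref"], grp["alt"])]
        by_chrom[chrom] = (
            grp["pos"].to_numpy(),
            (grp["zygosity"] == "hom").to_numpy(),
            grp["haplotype"].to_numpy(),
            keys,
        )
    obs_alleles: Dict[VariantKey, Dict[int, set]] = {}

    names = list(model.chromosomes)
    lengths = np.array([model.chromosomes[c] for c in names], dtype=float)
    weights = lengths / lengths.sum()
    frag_len = params.fragment_length

    for well in range(1, params.n_wells + 1):
        chrom_idx = rng.choice(len(names), size=params.fragments_per_well, p=weights)
        for ci in chrom_idx:
            chrom = names[ci]
            length = model.chromosomes[chrom]
            start = int(rng.integers(1, max(2, length - frag_len)))
            hap = int(rng.integers(2))
            if chrom not in by_chrom:
                continue
            pos, is_hom, var_hap, keys = by_chrom[chrom]
            lo, hi = np.searchsorted(pos, [start, start + frag_len])
            for i in range(lo, hi):
                allele = "alt" if (is_hom[i] or hap == var_hap[i]) else "ref"
                obs_alleles.setdefault(keys[i], {}).setdefault(well, set()).add(allele)

    # inject single-well polymerase errors at novel loci
    n_err = int(err_rng.poisson(params.polymerase_error_rate * len(v)))
    error_keys = set()
    taken = {(c, p) for c, p in zip(v["chrom"], v["pos"])}
    while len(error_keys) < n_err:
        chrom = names[int(err_rng.integers(len(names)))]
        pos = int(err_rng.integers(1, model.chromosomes[chrom]))
        if (chrom, pos) in taken:
            continue
        taken.add((chrom, pos))
        key = VariantKey(chrom, pos, "A", "G")
        well = int(err_rng.integers(1, params.n_wells + 1))
        obs_alleles.setdefault(key, {}).setdefault(well, set()).add("alt")
        error_keys.add(key)

    # phasing contigs: blocks of consecutive het variants per chromosome
    phase_truth: Dict[tuple, int] = {}
    phase_by_key: Dict[VariantKey, tuple] = {}
    for ci, chrom in enumerate(sorted(by_chrom, key=chrom_sort_key)):
        pos, is_hom, var_hap, keys = by_chrom[chrom]
        het_rank = 0
        for i in range(len(keys)):
            if is_hom[i]:
                continue
            block = het_rank // params.phase_block_variants
            hap = int(var_hap[i])
            phase_by_key[keys[i]] = ((ci, block), hap)
            phase_truth[(chrom, int(pos[i]))] = hap
            het_rank += 1

    observations: Dict[VariantKey, WellObservation] = {}
    records: List[VariantRecord] = []
    zyg_by_key = {
        VariantKey(c, int(p), r, a): z
        for c, p, r, a, z in zip(v["chrom"], v["pos"], v["ref"], v["alt"],
                                 v["zygosity"])
    }
    for key, wells in obs_alleles.items():
        obs = WellObservation(
            key=key,
            wells=tuple(sorted((w, frozenset(a)) for w, a in wells.items())),
        )
        observations[key] = obs
        ann = compute_well_support(obs, phase=phase_by_key.get(key))
        zygosity = zyg_by_key.get(key, "het")  # error loci masquerade as hets
        records.append(VariantRecord(
            chrom=key.chrom, pos=key.pos, ref=key.ref, alt=key.alt,
            zygosity=zygosity, ref_depth=0, alt_depth=0,
            library="LFR1", lfr=ann,
        ))
    return LFRWellSim(
        observations=observations,
        error_keys=frozenset(error_keys),
        records=records,
        phase_truth=phase_truth,
    )


# ---------------------------------------------------------------------------
# fixture emission

def write_fixture_set(model: GenomeModel, out_dir, force: bool = False,
                      max_lfr_loci: Optional[int] = 2000) -> dict:
    """Emit every fixture dialect plus a truth manifest into a directory.

    Refuses an existing non-empty directory unless ``force``.  Output is
    deterministic: regenerating from the same parameters reproduces the
    files byte for byte.  Returns the manifest.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    params = model.params

    from .types import ChromosomeInfo
    infos = [ChromosomeInfo(name, length, 0, 0)
             for name, length in model.chromosomes.items()]
    _io.write_chromosome_info(infos, out / "chromosomes.tsv")

    reads = simulate_variant_reads(model, params)
    for lib, recs in reads.items():
        _io.write_variant_table(recs, out / f"variants_{lib}.tsv", dialect="tsv")
    _io.write_variant_table(
        [r for recs in reads.values() for r in recs],
        out / "variants.vcf", dialect="vcf")

    sim_calls = simulate_translocation_calls(model, params)
    _io.write_translocation_table(sim_calls.calls, out / "translocations.tsv")

    lfr = simulate_lfr_wells(model, params, max_loci=max_lfr_loci)
    _io.write_variant_table(lfr.records, out / "lfr_variants.tsv", dialect="tsv")

    _io.write_segments_bed(model.loh_segments(), out / "truth_loh.bed")
    pd.DataFrame([{
        "chrom": s.chrom, "start": s.start, "end": s.end,
        "hap_copies_0": s.hap_copies[0], "hap_copies_1": s.hap_copies[1],
    } for s in model.cn_segments]).to_csv(out / "truth_cn.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "chrom_a": t.chrom_a, "pos_a": t.pos_a,
        "chrom_b": t.chrom_b, "pos_b": t.pos_b,
        "orientation": t.orientation,
    } for t in model.translocations]).to_csv(
        out / "truth_translocations.tsv", sep="\t", index=False)

    manifest = {
        "seed": params.seed,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(params).items()},
        "genome_bp": model.genome_bp,
        "n_variants": int(len(model.variants)),
        "loh_fraction_realized": model.loh_fraction_realized,
        "het_hom_ratio_realized": model.het_hom_ratio_realized,
        "n_translocations": len(model.translocations),
        "translocations": [asdict(t) for t in model.translocations],
        "loh_intervals": [asdict(iv) for iv in model.loh_intervals],
        "cn_segments": [asdict(s) for s in model.cn_segments],
        "event_presence": {str(k): sorted(v)
                           for k, v in sim_calls.event_presence.items()},
        "n_false_by_library": sim_calls.n_false_by_library,
        "lfr_error_loci": sorted(
            (k.chrom, k.pos) for k in lfr.error_keys),
        "files": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
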