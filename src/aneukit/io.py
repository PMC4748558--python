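"""Readers and writers for the external tables the pipeline touches.

Supported formats
-----------------
* translocation TSV/CSV with the breakpoint-pair schema
  ``sv_id (optional), chrA, chrA_start, chrA_end, chrB, chrB_start,
  chrB_end, orientation, library``;
* variant tables as a flat TSV or a VCF-4.x subset (``GT``/``AD`` plus the
  optional LFR extension FORMAT fields ``WC``, ``WIDS``, ``EWC``, ``SWC``,
  ``MINEWC``, ``MAXEWC``, ``HAPLINK``);
* the chromosome reference table (lengths, known-variant counts,
  centromere positions);
* BED3/BED4 export of genomic segments;
* a flat YAML configuration mirroring :class:`~aneukit.types.PipelineConfig`.

Internal coordinates are 1-based inclusive throughout; only the BED
writer converts to 0-based half-open.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import asdict
from decimal import Decimal
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import pandas as pd
import yaml

from .types import (
    ORIENTATIONS,
    ChromosomeInfo,
    LFRAnnotation,
    PipelineConfig,
    TranslocationCall,
    VariantRecord,
    normalize_chrom,
)

__all__ = [
    "TableFormatError",
    "read_translocation_table",
    "write_translocation_table",
    "read_variant_table",
    "write_variant_table",
    "read_chromosome_info",
    "write_chromosome_info",
    "write_segments_bed",
    "load_config",
    "save_config",
]


class TableFormatError(ValueError):
    """A malformed row or header in an input table."""


Source = Union[str, Path, _io.IOBase]

# Scientific-notation coordinate as printed in reduced-precision tables,
# e.g. "2.32E+08"; also tolerates unicode thin spaces around the sign.
_SCI_RE = re.compile(r"^([0-9.]+)\s*E\s*\+\s*(\d+)$", re.IGNORECASE)

_TRANSLOC_ALIASES = {
    "sv_id": "sv_id", "svid": "sv_id", "sv id": "sv_id",
    "chra": "chrom_a", "chrom_a": "chrom_a",
    "chra_start": "start_a", "chra start": "start_a", "start_a": "start_a",
    "chra_end": "end_a", "chra end": "end_a", "end_a": "end_a",
    "chrb": "chrom_b", "chrom_b": "chrom_b",
    "chrb_start": "start_b", "chrb start": "start_b", "start_b": "start_b",
    "chrb_end": "end_b", "chrb end": "end_b", "end_b": "end_b",
    "orientation": "orientation", "breakpoint orientation": "orientation",
    "library": "library",
    "coarse_a": "coarse_a", "coarse_b": "coarse_b",
}


def _coerce_coord(value) -> tuple:
    """Parse a coordinate that may be printed in scientific notation.

    Returns ``(position, coarse)`` where ``coarse`` marks precision lost
    to rounded printing.
    """
    if isinstance(value, (int,)) and not isinstance(value, bool):
        return int(value), False
    text = str(value).strip()
    m = _SCI_RE.match(text)
    if m:
        return int(Decimal(m.group(1)) * 10 ** int(m.group(2))), True
    try:
        return int(text.replace(",", "")), False
    except ValueError as exc:
        raise TableFormatError(f"unparseable coordinate {value!r}") from exc


def _read_table(source: Source, **kw) -> pd.DataFrame:
    df = pd.read_csv(source, sep=None, engine="python", dtype=str, **kw)
    df.columns = [str(c).strip() for c in df.columns]
    return df


def read_translocation_table(source: Source) -> List[TranslocationCall]:
    """Read raw per-library translocation calls.

    The ``sv_id`` column, when present, is carried along as
    ``recorded_id`` but plays no role in parsing.  Scientific-notation
    coordinates are parsed to exact integers and the affected side is
    flagged coarse.  Intrachromosomal rows and unknown orientation codes
    are rejected with their row index.
    """
    df = _read_table(source)
    cols = {}
    for c in df.columns:
        key = c.strip().lower()
        if key in _TRANSLOC_ALIASES:
            cols[_TRANSLOC_ALIASES[key]] = c
    required = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
                "orientation", "library"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise TableFormatError(f"missing translocation columns: {missing}")

    calls = []
    for i, row in df.iterrows():
        orientation = str(row[cols["orientation"]]).strip().lower()
        if orientation not in ORIENTATIONS:
            raise TableFormatError(f"row {i}: unknown orientation {orientation!r}")
        sa, ca1 = _coerce_coord(row[cols["start_a"]])
        ea, ca2 = _coerce_coord(row[cols["end_a"]])
        sb, cb1 = _coerce_coord(row[cols["start_b"]])
        eb, cb2 = _coerce_coord(row[cols["end_b"]])
        coarse_a, coarse_b = ca1 or ca2, cb1 or cb2
        if "coarse_a" in cols:
            coarse_a = coarse_a or str(row[cols["coarse_a"]]).strip() in ("1", "True")
        if "coarse_b" in cols:
            coarse_b = coarse_b or str(row[cols["coarse_b"]]).strip() in ("1", "True")
        chrom_a = normalize_chrom(row[cols["chrom_a"]])
        chrom_b = normalize_chrom(row[cols["chrom_b"]])
        if chrom_a == chrom_b:
            raise TableFormatError(
                f"row {i}: intrachromosomal record ({chrom_a}) rejected"
            )
        recorded = None
        if "sv_id" in cols and pd.notna(row[cols["sv_id"]]):
            recorded = int(str(row[cols["sv_id"]]).strip())
        calls.append(
            TranslocationCall(
                chrom_a=chrom_a, start_a=sa, end_a=ea,
                chrom_b=chrom_b, start_b=sb, end_b=eb,
                orientation=orientation,
                library=str(row[cols["library"]]).strip(),
                coarse_a=coarse_a, coarse_b=coarse_b,
                recorded_id=recorded,
            )
        )
    return calls


def write_translocation_table(calls: Sequence[TranslocationCall], sink: Source) -> None:
    rows = []
    for c in calls:
        rows.append({
            "sv_id": "" if c.recorded_id is None else c.recorded_id,
            "chrom_a": c.chrom_a, "start_a": c.start_a, "end_a": c.end_a,
            "chrom_b": c.chrom_b, "start_b": c.start_b, "end_b": c.end_b,
            "orientation": c.orientation, "library": c.library,
            "coarse_a": int(c.coarse_a), "coarse_b": int(c.coarse_b),
        })
    pd.DataFrame(rows, columns=["sv_id", "chrom_a", "start_a", "end_a", "chrom_b",
                                "start_b", "end_b", "orientation", "library",
                                "coarse_a", "coarse_b"]).to_csv(
        sink, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant tables

_TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "zygosity", "ref_depth",
                "alt_depth", "library", "hap_link", "well_count",
                "variant_well_ids", "exclusive_well_count", "shared_well_count",
                "min_exclusive", "max_exclusive"]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">
##FORMAT=<ID=WC,Number=1,Type=Integer,Description="Wells with reads calling variant or reference (of 384)">
##FORMAT=<ID=WIDS,Number=.,Type=String,Description="IDs of wells with reads calling the variant">
##FORMAT=<ID=EWC,Number=1,Type=Integer,Description="Wells calling only one allele">
##FORMAT=<ID=SWC,Number=1,Type=Integer,Description="Wells calling both alleles">
##FORMAT=<ID=MINEWC,Number=1,Type=Integer,Description="Minimum per-allele exclusive well count">
##FORMAT=<ID=MAXEWC,Number=1,Type=Integer,Description="Maximum per-allele exclusive well count">
##FORMAT=<ID=HAPLINK,Number=1,Type=String,Description="Phasing contig/haplotype id Phased_a_b_h">
"""


def _zygosity_from_gt(gt: tuple) -> str:
    alleles = list(gt)
    if any(a is None for a in alleles):
        return "half-called"
    if len(set(alleles)) == 1:
        if alleles[0] == 0:
            raise TableFormatError("homozygous-reference genotype is not a variant")
        return "hom"
    return "het"


def _field(fields: dict, key: str):
    v = fields.get(key)
    if isinstance(v, tuple):  # pysam yields ('.',) or (None,) for missing
        v = tuple(x for x in v if x not in (None, ".", ""))
        return v or None
    if v is None or (isinstance(v, float) and pd.isna(v)) or v in ("", "."):
        return None
    return v


def _lfr_from_fields(fields: dict) -> Optional[LFRAnnotation]:
    from .lfr import parse_haplink  # local import avoids a cycle

    if all(_field(fields, k) is None
           for k in ("HAPLINK", "WC", "EWC", "SWC", "WIDS")):
        return None
    wids = _field(fields, "WIDS") or ()
    if isinstance(wids, str):
        wids = tuple(int(w) for w in wids.split(",") if w)
    else:
        wids = tuple(int(w) for w in wids)
    as_int = lambda key: int(float(_field(fields, key) or 0))
    return LFRAnnotation(
        phase=parse_haplink(_field(fields, "HAPLINK")),
        well_count=as_int("WC"),
        variant_well_ids=wids,
        exclusive_well_count=as_int("EWC"),
        shared_well_count=as_int("SWC"),
        min_exclusive=as_int("MINEWC"),
        max_exclusive=as_int("MAXEWC"),
    )


def read_variant_table(source: Source, dialect: str = "auto",
                       require_depths: bool = False) -> List[VariantRecord]:
    """Read SNV records from a flat TSV or an uncompressed VCF subset.

    ``dialect`` is ``"vcf"``, ``"tsv"`` or ``"auto"`` (sniffed from the
    first bytes / file suffix).  With ``require_depths=True`` a table
    lacking allele depths raises, since LAF/LOH analysis would be
    impossible.
    """
    if dialect == "auto":
        if isinstance(source, (str, Path)):
            head = Path(source).open().readline()
        else:
            pos = source.tell()
            head = source.readline()
            source.seek(pos)
        dialect = "vcf" if str(head).startswith("##fileformat=VCF") else "tsv"
    if dialect == "vcf":
        records = _read_vcf(source)
    elif dialect == "tsv":
        records = _read_tsv_variants(source)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if require_depths and any(r.ref_depth + r.alt_depth == 0 for r in records):
        raise TableFormatError(
            "variant table lacks allele depths; allele-fraction analysis "
            "is not possible on it"
        )
    return records


def _read_vcf(source: Source) -> List[VariantRecord]:
    import pysam

    if not isinstance(source, (str, Path)):
        raise TableFormatError("VCF input requires a file path")
    records = []
    with pysam.VariantFile(str(source)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if len(rec.alts or ()) != 1:
                raise TableFormatError(
                    f"{rec.chrom}:{rec.pos}: only biallelic SNVs are supported"
                )
            for sample in samples:
                call = rec.samples[sample]
                gt = call.get("GT") or (None,)
                ad = call.get("AD") or (0, 0)
                ad = tuple(0 if a is None else int(a) for a in ad)
                fields = {k: call.get(k) for k in
                          ("WC", "WIDS", "EWC", "SWC", "MINEWC", "MAXEWC",
                           "HAPLINK") if k in vf.header.formats}
                records.append(VariantRecord(
                    chrom=normalize_chrom(rec.chrom), pos=rec.pos,
                    ref=rec.ref, alt=rec.alts[0],
                    zygosity=_zygosity_from_gt(gt),
                    ref_depth=ad[0], alt_depth=ad[1] if len(ad) > 1 else 0,
                    library=sample, lfr=_lfr_from_fields(fields),
                ))
    return records


def _read_tsv_variants(source: Source) -> List[VariantRecord]:
    df = _read_table(source)
    need = {"chrom", "pos", "ref", "alt", "zygosity"}
    if not need.issubset(df.columns):
        raise TableFormatError(f"variant TSV lacks columns {need - set(df.columns)}")
    records = []
    for _, row in df.iterrows():
        lfr = None
        if "well_count" in df.columns or "hap_link" in df.columns:
            lfr = _lfr_from_fields({
                "HAPLINK": row.get("hap_link"),
                "WC": row.get("well_count"),
                "WIDS": row.get("variant_well_ids"),
                "EWC": row.get("exclusive_well_count"),
                "SWC": row.get("shared_well_count"),
                "MINEWC": row.get("min_exclusive"),
                "MAXEWC": row.get("max_exclusive"),
            })
        records.append(VariantRecord(
            chrom=normalize_chrom(row["chrom"]), pos=int(row["pos"]),
            ref=str(row["ref"]), alt=str(row["alt"]),
            zygosity=str(row["zygosity"]),
            ref_depth=int(float(_field(row, "ref_depth") or 0)),
            alt_depth=int(float(_field(row, "alt_depth") or 0)),
            library=str(_field(row, "library") or ""),
            lfr=lfr,
        ))
    return records


def write_variant_table(records: Sequence[VariantRecord], sink: Source,
                        dialect: str = "tsv") -> None:
    """Write SNV records as a flat TSV or a minimal VCF-4.2 subset.

    The VCF dialect emits one sample column per distinct library and a
    ``GT:AD[:WC:WIDS:EWC:SWC:MINEWC:MAXEWC:HAPLINK]`` FORMAT.
    """
    if dialect == "tsv":
        rows = []
        for r in records:
            a = r.lfr
            rows.append({
                "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
                "zygosity": r.zygosity, "ref_depth": r.ref_depth,
                "alt_depth": r.alt_depth, "library": r.library,
                "hap_link": _haplink_text(a),
                "well_count": a.well_count if a else "",
                "variant_well_ids": ",".join(map(str, a.variant_well_ids)) if a else "",
                "exclusive_well_count": a.exclusive_well_count if a else "",
                "shared_well_count": a.shared_well_count if a else "",
                "min_exclusive": a.min_exclusive if a else "",
                "max_exclusive": a.max_exclusive if a else "",
            })
        pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(sink, sep="\t", index=False)
        return
    if dialect != "vcf":
        raise ValueError(f"unknown dialect {dialect!r}")
    _write_vcf(records, sink)


def _haplink_text(ann: Optional[LFRAnnotation]) -> str:
    if ann is None or ann.phase is None:
        return ""
    (a, b), h = ann.phase
    return f"Phased_{a}_{b}_{h}"


_GT_BY_ZYGOSITY = {"het": "0/1", "hom": "1/1", "half-called": "./1"}


def _write_vcf(records: Sequence[VariantRecord], sink: Source) -> None:
    libraries = sorted({r.library or "sample" for r in records})
    has_lfr = any(r.lfr is not None for r in records)
    fmt_keys = ["GT", "AD"]
    if has_lfr:
        fmt_keys += ["WC", "WIDS", "EWC", "SWC", "MINEWC", "MAXEWC", "HAPLINK"]

    by_site = {}
    for r in records:
        by_site.setdefault((r.chrom, r.pos, r.ref, r.alt), {})[r.library or "sample"] = r

    def sample_field(rec: Optional[VariantRecord]) -> str:
        if rec is None:
            return ":".join(["./."] + ["."] * (len(fmt_keys) - 1))
        parts = [_GT_BY_ZYGOSITY[rec.zygosity], f"{rec.ref_depth},{rec.alt_depth}"]
        if has_lfr:
            a = rec.lfr
            parts += [
                str(a.well_count) if a else ".",
                ",".join(map(str, a.variant_well_ids)) if a and a.variant_well_ids else ".",
                str(a.exclusive_well_count) if a else ".",
                str(a.shared_well_count) if a else ".",
                str(a.min_exclusive) if a else ".",
                str(a.max_exclusive) if a else ".",
                _haplink_text(a) or ".",
            ]
        return ":".join(parts)

    from .types import chrom_sort_key

    lines = [_VCF_HEADER.rstrip("\n")]
    for chrom in sorted({r.chrom for r in records}, key=chrom_sort_key):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(libraries))

    for (chrom, pos, ref, alt) in sorted(by_site, key=lambda k: (chrom_sort_key(k[0]), k[1:])):
        site = by_site[(chrom, pos, ref, alt)]
        fields = "\t".join(sample_field(site.get(lib)) for lib in libraries)
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t"
                     f"{':'.join(fmt_keys)}\t{fields}")
    text = "\n".join(lines) + "\n"
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text)
    else:
        sink.write(text)


# ---------------------------------------------------------------------------
# Chromosome reference table

def read_chromosome_info(source: Source) -> List[ChromosomeInfo]:
    df = _read_table(source)
    need = {"name", "length_bp"}
    if not need.issubset(df.columns):
        raise TableFormatError(f"chromosome table lacks columns {need - set(df.columns)}")
    infos, seen = [], set()
    for _, row in df.iterrows():
        name = normalize_chrom(row["name"])
        if name in seen:
            raise TableFormatError(f"duplicate chromosome {name}")
        seen.add(name)
        cen_mbp = float(row.get("centromere_mbp") or 0)
        infos.append(ChromosomeInfo(
            name=name,
            length_bp=int(row["length_bp"]),
            known_variant_count=int(row.get("variant_count") or 0),
            centromere_position_bp=int(cen_mbp * 1e6),
        ))
    return infos


def write_chromosome_info(infos: Sequence[ChromosomeInfo], sink: Source) -> None:
    pd.DataFrame([{
        "name": i.name, "length_bp": i.length_bp,
        "variant_count": i.known_variant_count,
        "centromere_mbp": i.centromere_position_bp / 1e6,
    } for i in infos]).to_csv(sink, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED export

def write_segments_bed(segments: Iterable, sink: Source) -> None:
    """Write intervals as BED3(+name), converting from 1-based inclusive
    to BED's 0-based half-open convention."""
    lines = []
    for seg in segments:
        chrom, start, end = seg.chrom, seg.start, seg.end
        if end < start:
            raise ValueError(f"refusing interval with end < start: {chrom}:{start}-{end}")
        name = getattr(seg, "name", None)
        line = f"{chrom}\t{start - 1}\t{end}"
        if name is not None:
            line += f"\t{name}"
        lines.append(line)
    text = "\n".join(lines) + ("\n" if lines else "")
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text)
    else:
        sink.write(text)


# ---------------------------------------------------------------------------
# Configuration

def load_config(source: Source) -> PipelineConfig:
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text()) or {}
    else:
        data = yaml.safe_load(source.read()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise TableFormatError(f"unknown configuration keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, sink: Source) -> None:
    text = yaml.safe_dump(asdict(config), sort_keys=True)
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text)
    else:
        sink.write(text)
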