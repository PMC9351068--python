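"""Readers and writers for the file formats the pipeline touches.

Formats
-------
- VCF 4.2 for somatic small variants (annotation INFO keys configurable
  via :class:`VcfFieldMap`); read through pysam, written as text.
- SEG-like TSV for copy-number segments: on disk 1-based inclusive
  coordinates (SEG convention), in memory 0-based half-open.
- TSV breakpoint tables for structural variants.
- GATK CollectAllelicCounts-style TSV for allelic read counts
  (``@``-prefixed header lines skipped).
- GMT gene-set files; YAML/JSON genome configuration (see genome module);
  TSV sample sheets.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import pysam

from .genome import GenomeConfig
from .types import AllelicCount, CnaSegment, SampleMeta, SmallVariant, SvCall


class FileFormatError(ValueError):
    """Raised when an input file violates the documented schema."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VcfFieldMap:
    """INFO keys carrying the annotations the pipeline consumes.

    Defaults match the files the cohort simulator writes. ``population_af``
    is stored as a String field so that values like 0.001 survive a
    round-trip exactly (htslib Float INFO fields are 32-bit).
    """

    depth: str = "DP"
    population_af: str = "POPAF"
    variant_class: str = "CLASS"
    region: str = "REGION"
    gene: str = "GENE"
    effect: str = "EFFECT"


DEFAULT_VCF_FIELDS = VcfFieldMap()


def _info_scalar(record, key: str, index: int, n_alts: int):
    if key not in record.info:
        return None
    val = record.info[key]
    if isinstance(val, tuple):
        val = val[index] if len(val) == n_alts else val[0]
    if isinstance(val, bytes):
        val = val.decode()
    if val in (".", "", None):
        return None
    return val


def read_small_variants(
    path: str | Path,
    sample_id: Optional[str] = None,
    genome: Optional[GenomeConfig] = None,
    fields: VcfFieldMap = DEFAULT_VCF_FIELDS,
) -> list[SmallVariant]:
    """Read somatic small variants from a VCF, one record per ALT allele.

    Multi-allelic records are decomposed; missing annotations are ``None``.
    Raises :class:`FileFormatError` for unknown chromosomes (when a genome
    is supplied) or duplicate (chrom, pos, ref, alt) keys.
    """
    out: list[SmallVariant] = []
    seen: set = set()
    with pysam.VariantFile(str(path)) as vf:
        for record in vf:
            chrom = record.chrom
            if genome is not None and chrom not in genome:
                raise FileFormatError(
                    f"{path}: record at {chrom}:{record.pos} on contig absent "
                    f"from the genome configuration"
                )
            alts = record.alts or ()
            for i, alt in enumerate(alts):
                dp = _info_scalar(record, fields.depth, i, len(alts))
                af = _info_scalar(record, fields.population_af, i, len(alts))
                try:
                    var = SmallVariant(
                        chrom=chrom,
                        pos=record.pos,
                        ref=record.ref,
                        alt=alt,
                        total_depth=None if dp is None else int(dp),
                        population_af=None if af is None else float(af),
                        variant_class=_info_scalar(record, fields.variant_class, i, len(alts)),
                        region=_info_scalar(record, fields.region, i, len(alts)),
                        gene=_info_scalar(record, fields.gene, i, len(alts)),
                        effect=_info_scalar(record, fields.effect, i, len(alts)),
                    )
                except (ValueError, TypeError) as exc:
                    raise FileFormatError(
                        f"{path}: malformed record at {chrom}:{record.pos}: {exc}"
                    ) from exc
                if var.key in seen:
                    raise FileFormatError(
                        f"{path}: duplicate variant key {var.key}"
                    )
                seen.add(var.key)
                out.append(var)
    return out


def write_small_variants(
    variants: Sequence[SmallVariant],
    path: str | Path,
    genome: Optional[GenomeConfig] = None,
    fields: VcfFieldMap = DEFAULT_VCF_FIELDS,
) -> None:
    """Write variants as a plain-text VCF 4.2 (one record per variant)."""
    lines = ["##fileformat=VCFv4.2"]
    if genome is not None:
        for c in genome.chromosomes:
            lines.append(f"##contig=<ID={c.name},length={c.length}>")
    lines.append(f'##INFO=<ID={fields.depth},Number=1,Type=Integer,Description="Total read depth">')
    for key, desc in (
        (fields.population_af, "Population allele frequency"),
        (fields.variant_class, "SNV or indel"),
        (fields.region, "coding or noncoding"),
        (fields.gene, "Gene symbol"),
        (fields.effect, "Functional effect"),
    ):
        lines.append(f'##INFO=<ID={key},Number=1,Type=String,Description="{desc}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        info = []
        if v.total_depth is not None:
            info.append(f"{fields.depth}={v.total_depth}")
        if v.population_af is not None:
            info.append(f"{fields.population_af}={v.population_af!r}")
        if v.variant_class is not None:
            info.append(f"{fields.variant_class}={v.variant_class}")
        if v.region is not None:
            info.append(f"{fields.region}={v.region}")
        if v.gene is not None:
            info.append(f"{fields.gene}={v.gene}")
        if v.effect is not None:
            info.append(f"{fields.effect}={v.effect}")
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t" + (";".join(info) or ".")
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SEG (copy-number segments)
# ---------------------------------------------------------------------------

SEG_COLUMNS = ["SAMPLE", "CHROM", "START", "END", "MEDIAN_LOGR", "DIRECTION"]


def write_seg(segments: Sequence[CnaSegment], path: str | Path) -> None:
    """Write segments as SEG-like TSV; coordinates become 1-based inclusive."""
    rows = ["\t".join(SEG_COLUMNS)]
    for s in segments:
        rows.append(
            f"{s.sample_id or '.'}\t{s.chrom}\t{s.start + 1}\t{s.end}\t"
            f"{s.median_logr!r}\t{s.direction}"
        )
    Path(path).write_text("\n".join(rows) + "\n")


def read_seg(path: str | Path) -> list[CnaSegment]:
    """Read a SEG-like TSV back into 0-based half-open segments.

    Overlapping segments within one sample trigger a warning, not an error
    (callers may legitimately emit subclonal overlaps).
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"SAMPLE": str, "CHROM": str},
        float_precision="round_trip",
    )
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing SEG columns {missing}")
    out: list[CnaSegment] = []
    for idx, row in df.iterrows():
        start1, end1 = int(row["START"]), int(row["END"])
        if end1 < start1:
            raise FileFormatError(
                f"{path}: row {idx + 2}: segment end {end1} < start {start1}"
            )
        sample = None if row["SAMPLE"] in (".", "", None) else str(row["SAMPLE"])
        out.append(
            CnaSegment(
                chrom=str(row["CHROM"]),
                start=start1 - 1,
                end=end1,
                median_logr=float(row["MEDIAN_LOGR"]),
                direction=str(row["DIRECTION"]),
                sample_id=sample,
            )
        )
    _warn_on_overlaps(out, path)
    return out


def _warn_on_overlaps(segments: Sequence[CnaSegment], path) -> None:
    by_sample: dict = {}
    for s in segments:
        by_sample.setdefault((s.sample_id, s.chrom), []).append(s)
    for (sample, chrom), segs in by_sample.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                warnings.warn(
                    f"{path}: overlapping segments for sample {sample} on {chrom} "
                    f"([{a.start},{a.end}) and [{b.start},{b.end}))",
                    stacklevel=2,
                )


# ---------------------------------------------------------------------------
# SV breakpoint tables
# ---------------------------------------------------------------------------

SV_COLUMNS = ["SAMPLE", "CHROM1", "POS1", "CHROM2", "POS2", "TYPE"]


def write_sv_table(svs: Sequence[SvCall], path: str | Path) -> None:
    rows = ["\t".join(SV_COLUMNS)]
    for s in svs:
        rows.append(
            f"{s.sample_id or '.'}\t{s.chrom1}\t{s.pos1}\t{s.chrom2}\t{s.pos2}\t{s.sv_type}"
        )
    Path(path).write_text("\n".join(rows) + "\n")


def read_sv_table(path: str | Path) -> list[SvCall]:
    df = pd.read_csv(path, sep="\t", dtype={"SAMPLE": str, "CHROM1": str, "CHROM2": str})
    missing = [c for c in SV_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing SV columns {missing}")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                SvCall(
                    chrom1=str(row["CHROM1"]),
                    pos1=int(row["POS1"]),
                    chrom2=str(row["CHROM2"]),
                    pos2=int(row["POS2"]),
                    sv_type=str(row["TYPE"]),
                    sample_id=None if row["SAMPLE"] in (".", "", None) else str(row["SAMPLE"]),
                )
            )
        except ValueError as exc:
            raise FileFormatError(f"{path}: row {idx + 2}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Allelic counts (GATK CollectAllelicCounts dialect)
# ---------------------------------------------------------------------------

AC_COLUMNS = ["CONTIG", "POSITION", "REF_COUNT", "ALT_COUNT"]


def write_allelic_counts(counts: Sequence[AllelicCount], path: str | Path) -> None:
    rows = ["\t".join(AC_COLUMNS)]
    for c in sorted(counts, key=lambda c: (c.chrom, c.pos)):
        rows.append(f"{c.chrom}\t{c.pos}\t{c.ref_count}\t{c.alt_count}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_allelic_counts(path: str | Path, sample_id: str) -> list[AllelicCount]:
    """Read allelic counts; ``@``-prefixed header lines are skipped.

    Rows are returned sorted by (chrom, pos). Negative counts or duplicate
    positions raise :class:`FileFormatError`.
    """
    text = Path(path).read_text()
    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("@"))
    df = pd.read_csv(_io.StringIO(body), sep="\t", dtype={"CONTIG": str})
    missing = [c for c in AC_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing allelic-count columns {missing}")
    out: list[AllelicCount] = []
    seen: set = set()
    for idx, row in df.iterrows():
        try:
            ac = AllelicCount(
                sample_id=sample_id,
                chrom=str(row["CONTIG"]),
                pos=int(row["POSITION"]),
                ref_count=int(row["REF_COUNT"]),
                alt_count=int(row["ALT_COUNT"]),
            )
        except ValueError as exc:
            raise FileFormatError(f"{path}: row {idx + 2}: {exc}") from exc
        if (ac.chrom, ac.pos) in seen:
            raise FileFormatError(f"{path}: duplicate position {ac.chrom}:{ac.pos}")
        seen.add((ac.chrom, ac.pos))
        out.append(ac)
    out.sort(key=lambda c: (c.chrom, c.pos))
    return out


# ---------------------------------------------------------------------------
# Sample sheet, GMT
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ["SAMPLE", "PATIENT", "TYPE", "PURITY"]


def write_sample_sheet(samples: Sequence[SampleMeta], path: str | Path) -> None:
    rows = ["\t".join(SAMPLE_COLUMNS)]
    for s in samples:
        purity = "." if s.purity is None else repr(s.purity)
        rows.append(f"{s.sample_id}\t{s.patient_id}\t{s.sample_type}\t{purity}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing sample-sheet columns {missing}")
    out = []
    for _, row in df.iterrows():
        purity = row["PURITY"]
        out.append(
            SampleMeta(
                sample_id=row["SAMPLE"],
                patient_id=row["PATIENT"],
                sample_type=row["TYPE"],
                purity=None if purity in (".", "", None) else float(purity),
            )
        )
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> gene..."""
    sets: dict[str, set[str]] = {}
    for ln_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FileFormatError(f"{path}: line {ln_no}: expected name, description, genes")
        name = parts[0]
        if name in sets:
            raise FileFormatError(f"{path}: duplicate gene set {name!r}")
        sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    rows = [f"{name}\tna\t" + "\t".join(sorted(genes)) for name, genes in sets.items()]
    Path(path).write_text("\n".join(rows) + "\n")
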