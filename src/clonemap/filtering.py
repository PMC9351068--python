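"""Post-calling inclusion/exclusion rules for small variants, CNAs and SVs.

The rules reproduce the downstream filters applied after somatic calling in
low-burden multifocal tumor studies, with every comparison on the exact
boundary side the rule states:

- small variants: remove if total depth <= 6 reads, or population allele
  frequency > 0.001 (a missing AF keeps the variant: absence of evidence
  must not remove a call);
- CNA segments: keep gains with median logR > 0.15 and losses with
  median logR < -0.15 (copy-neutral LOH segments are logR-neutral by
  definition and bypass the magnitude rule); remove segments shorter than
  10 kb, segments with an interior breakpoint inside a centromere, and
  segments with an interior breakpoint within 1 Mb of a chromosome end.
  Breakpoints are the first and last covered base; a segment boundary lying
  exactly at the chromosome end is not an interior breakpoint, so whole
  chromosome and arm-level events survive;
- SVs: remove intrachromosomal SVs spanning < 10 kb and any SV with a
  breakpoint inside a centromere.

Every decision is audited: each input record is either kept or tagged with
the first rule that removed it. The manual review step of the original
workflow (per-variant IGV inspection) is not computable; an explicit
exclusion-key list stands in for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .genome import GenomeConfig
from .types import CnaSegment, SmallVariant, SvCall, VariantKey


@dataclass
class FilterConfig:
    min_depth_exclusive: int = 6  # remove if depth <= this
    max_population_af: float = 0.001  # remove if AF > this
    logr_gain_threshold: float = 0.15  # keep gains if logR > this
    logr_loss_threshold: float = -0.15  # keep losses if logR < this
    min_cna_length: int = 10_000  # remove if length < this
    chrom_end_margin: int = 1_000_000
    min_sv_span: int = 10_000
    manual_exclusions: frozenset[VariantKey] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.chrom_end_margin < 0 or self.min_cna_length < 0 or self.min_sv_span < 0:
            raise ValueError("margins and length thresholds must be >= 0")


@dataclass(frozen=True)
class AuditRecord:
    record: object
    kept: bool
    rule: Optional[str]  # first failing rule when not kept

    def __post_init__(self) -> None:
        if self.kept == (self.rule is not None):
            raise ValueError("audit record must be kept xor name a failing rule")


FilterAudit = list[AuditRecord]


def _audit_partition(records: Iterable, failing_rule) -> tuple[list, FilterAudit]:
    kept, audit = [], []
    for rec in records:
        rule = failing_rule(rec)
        if rule is None:
            kept.append(rec)
        audit.append(AuditRecord(rec, rule is None, rule))
    return kept, audit


# ---------------------------------------------------------------------------
# Small variants
# ---------------------------------------------------------------------------

def filter_small_variants(
    variants: Sequence[SmallVariant], config: FilterConfig
) -> tuple[list[SmallVariant], FilterAudit]:
    """Keep variants with depth > 6 reads and population AF <= 0.001.

    A missing depth is treated as failing the depth rule (no read support
    evidence); a missing population AF keeps the variant. Input order is
    preserved.
    """

    def failing(v: SmallVariant) -> Optional[str]:
        if v.key in config.manual_exclusions:
            return "manual_exclusion"
        if v.total_depth is None or v.total_depth <= config.min_depth_exclusive:
            return "min_depth"
        if v.population_af is not None and v.population_af > config.max_population_af:
            return "population_af"
        return None

    return _audit_partition(variants, failing)


# ---------------------------------------------------------------------------
# CNA segments
# ---------------------------------------------------------------------------

def _breakpoints(seg: CnaSegment) -> tuple[int, int]:
    """First and last covered base of a half-open segment."""
    return seg.start, seg.end - 1


def filter_cna_segments(
    segments: Sequence[CnaSegment], config: FilterConfig, genome: GenomeConfig
) -> tuple[list[CnaSegment], FilterAudit]:
    """Apply logR-magnitude, size, centromere and chromosome-end rules."""

    def failing(seg: CnaSegment) -> Optional[str]:
        length = genome.length(seg.chrom)  # raises KeyError on unknown chrom
        if seg.direction != "cn_loh":
            in_gain = seg.median_logr > config.logr_gain_threshold
            in_loss = seg.median_logr < config.logr_loss_threshold
            if not (in_gain or in_loss):
                return "logr_threshold"
        if seg.length < config.min_cna_length:
            return "min_length"
        cen_start, cen_end = genome.centromere(seg.chrom)
        first, last = _breakpoints(seg)
        for bp in (first, last):
            if cen_start <= bp < cen_end:
                return "centromere_breakpoint"
        # interior breakpoints only: a boundary at the chromosome end is not
        # a breakpoint, so whole-chromosome segments pass
        if 0 < first < config.chrom_end_margin or 0 < length - 1 - first < config.chrom_end_margin:
            return "end_margin"
        if 0 < last < config.chrom_end_margin or 0 < length - 1 - last < config.chrom_end_margin:
            return "end_margin"
        return None

    for seg in segments:
        if seg.chrom not in genome:
            raise KeyError(f"segment on unknown chromosome {seg.chrom!r}")
    return _audit_partition(segments, failing)


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------

def filter_svs(
    svs: Sequence[SvCall], config: FilterConfig, genome: GenomeConfig
) -> tuple[list[SvCall], FilterAudit]:
    """Remove SVs with a centromeric breakpoint, and intrachromosomal SVs
    spanning less than the minimum (interchromosomal SVs have no span)."""

    def failing(sv: SvCall) -> Optional[str]:
        for chrom, pos in ((sv.chrom1, sv.pos1), (sv.chrom2, sv.pos2)):
            cen_start, cen_end = genome.centromere(chrom)
            if cen_start <= pos - 1 < cen_end:
                return "centromere_breakpoint"
        if sv.is_intrachromosomal and sv.span < config.min_sv_span:
            return "min_span"
        return None

    for sv in svs:
        for chrom in (sv.chrom1, sv.chrom2):
            if chrom not in genome:
                raise KeyError(f"SV breakpoint on unknown chromosome {chrom!r}")
    return _audit_partition(svs, failing)


# ---------------------------------------------------------------------------
# Caller-consensus helper
# ---------------------------------------------------------------------------

def consensus_intersection(
    calls_a: Sequence[SmallVariant], calls_b: Sequence[SmallVariant]
) -> list[SmallVariant]:
    """Variants from ``calls_a`` whose (chrom, pos, ref, alt) key is also
    called in ``calls_b`` — the two-caller intersection rule used for
    noncoding calls. Annotations are taken from ``calls_a``."""
    keys_b = {v.key for v in calls_b}
    return [v for v in calls_a if v.key in keys_b]
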