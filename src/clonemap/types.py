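"""Shared domain records for somatic variants, CNA segments, SVs and allelic counts."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

#: canonical variant identity used for all sharing/recurrence comparisons
VariantKey = tuple[str, int, str, str]  # (chrom, pos, ref, alt), pos 1-based

SNV = "SNV"
INDEL = "indel"

LOSS = "loss"
GAIN = "gain"
CN_LOH = "cn_loh"
DIRECTIONS = (LOSS, GAIN, CN_LOH)

SV_TYPES = ("deletion", "duplication", "inversion", "translocation", "interchromosomal")


@dataclass(frozen=True)
class SmallVariant:
    """One somatic SNV/indel call in one sample.

    ``pos`` is 1-based (VCF convention). Missing annotations are ``None``,
    never silently defaulted: an absent population AF must not be treated
    as evidence the variant is common.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    total_depth: Optional[int] = None
    population_af: Optional[float] = None
    variant_class: Optional[str] = None  # SNV | indel
    region: Optional[str] = None  # coding | noncoding
    gene: Optional[str] = None
    effect: Optional[str] = None  # missense | silent | nonsense | frameshift | splice | other

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    def inferred_class(self) -> str:
        if self.variant_class is not None:
            return self.variant_class
        return SNV if len(self.ref) == 1 and len(self.alt) == 1 else INDEL


@dataclass
class CnaSegment:
    """Copy-number segment, 0-based half-open in memory (SEG files are 1-based inclusive)."""

    chrom: str
    start: int
    end: int
    median_logr: float
    direction: str  # loss | gain | cn_loh
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"segment {self.chrom}:[{self.start},{self.end}) must have start < end"
            )
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class SvCall:
    """Structural-variant breakpoint pair; positions 1-based."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        intra = self.chrom1 == self.chrom2
        if self.sv_type == "interchromosomal" and intra:
            raise ValueError("interchromosomal SV with identical breakpoint chromosomes")
        if self.sv_type != "interchromosomal" and not intra:
            raise ValueError(
                f"{self.sv_type} SV must be intrachromosomal "
                f"({self.chrom1} != {self.chrom2})"
            )

    @property
    def is_intrachromosomal(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def span(self) -> Optional[int]:
        """Breakpoint distance for intrachromosomal SVs, else None."""
        return abs(self.pos2 - self.pos1) if self.is_intrachromosomal else None


@dataclass(frozen=True)
class AllelicCount:
    """Ref/alt read counts at one SNP position in one sample; ``pos`` 1-based."""

    sample_id: str
    chrom: str
    pos: int
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError(
                f"negative read count at {self.chrom}:{self.pos} "
                f"({self.ref_count}, {self.alt_count})"
            )

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def vaf(self) -> Optional[float]:
        return self.alt_count / self.depth if self.depth > 0 else None


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    patient_id: str
    sample_type: str  # primary | metastasis | normal
    purity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sample_type not in ("primary", "metastasis", "normal"):
            raise ValueError(f"unknown sample_type {self.sample_type!r}")
        if self.purity is not None and not (0.0 <= self.purity <= 1.0):
            raise ValueError(f"purity {self.purity} outside [0, 1]")

    @property
    def is_tumor(self) -> bool:
        return self.sample_type in ("primary", "metastasis")
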