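"""Allele-specific chromosome mapping of copy-number segments.

Given germline heterozygous SNPs from the matched normal, the procedure
asks, for each tumor CNA segment, which parental haplotype was lost or
amplified:

1. het SNPs are selected in the normal (read depth > 10, VAF in
   [0.4, 0.6]);
2. their tumor allelic counts are tested against a Binomial(n, 0.5) null
   with an exact two-sided test, separately per chromosome arm segment;
3. Benjamini-Hochberg FDR correction runs across the candidate SNPs of
   that one (tumor, arm-segment) family; SNPs with adjusted p below the
   level are "informative";
4. each informative SNP's major allele (the one with more reads) points at
   the retained haplotype for a loss and the amplified haplotype for a
   gain;
5. two tumors sharing a CNA on one arm are compared by the concordance of
   major alleles over their shared informative SNPs — near-1 concordance
   means the same parental allele was affected, near-0 means opposite
   alleles (independent events), intermediate is ambiguous.

When fewer than 1000 informative SNPs are shared at the primary FDR level
of 0.05, both tumors are re-called at the relaxed level 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .genome import GenomeConfig
from .types import AllelicCount, CnaSegment


@dataclass
class MappingConfig:
    normal_min_depth_exclusive: int = 10  # normal het SNP: depth > this
    normal_vaf_low: float = 0.4  # inclusive
    normal_vaf_high: float = 0.6  # inclusive
    tumor_min_depth_exclusive: int = 10  # tumor candidate: depth > this
    alpha_primary: float = 0.05
    alpha_relaxed: float = 0.1
    relaxation_snp_count: int = 1000  # relax when shared informative < this
    concordance_same_min: float = 0.9
    concordance_diff_max: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_primary <= self.alpha_relaxed < 1.0):
            raise ValueError("need 0 < alpha_primary <= alpha_relaxed < 1")
        if not (0.0 <= self.normal_vaf_low < self.normal_vaf_high <= 1.0):
            raise ValueError("need 0 <= vaf_low < vaf_high <= 1")


# ---------------------------------------------------------------------------
# Statistical primitives
# ---------------------------------------------------------------------------

def binomial_two_sided_p(ref_count: int, alt_count: int) -> float:
    """Exact two-sided binomial test against p = 0.5.

    Minimum-likelihood convention: the p-value sums P(k) over all outcomes
    k whose probability does not exceed that of the observed outcome. For
    the symmetric, unimodal Binomial(n, 0.5) null this set is exactly the
    two mirror tails, so p = min(1, 2 * CDF(min(ref, alt))). Symmetric in
    its arguments, in (0, 1].
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be non-negative")
    n = ref_count + alt_count
    if n == 0:
        raise ValueError("both counts are zero; test undefined")
    m = min(ref_count, alt_count)
    return float(min(1.0, 2.0 * stats.binom.cdf(m, n, 0.5)))


def _binomial_two_sided_p_vec(ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """Vectorized form of :func:`binomial_two_sided_p` (same convention)."""
    ref = np.asarray(ref)
    alt = np.asarray(alt)
    n = ref + alt
    m = np.minimum(ref, alt)
    return np.minimum(1.0, 2.0 * stats.binom.cdf(m, n, 0.5))


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adjusted[i] = min over j with p(j) >= p(i) of p(j) * m / rank(j),
    clipped to 1; monotone non-decreasing in the sorted order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


# ---------------------------------------------------------------------------
# SNP selection and informative calls
# ---------------------------------------------------------------------------

def select_het_snps(
    normal_counts: Sequence[AllelicCount], config: MappingConfig
) -> set[tuple[str, int]]:
    """Heterozygous germline SNP positions from the matched normal:
    depth > 10 and VAF within [0.4, 0.6] (inclusive). Depth-0 rows are
    skipped silently (VAF undefined)."""
    het: set[tuple[str, int]] = set()
    for c in normal_counts:
        if c.depth == 0 or c.depth <= config.normal_min_depth_exclusive:
            continue
        vaf = c.alt_count / c.depth
        if config.normal_vaf_low <= vaf <= config.normal_vaf_high:
            het.add((c.chrom, c.pos))
    return het


@dataclass(frozen=True)
class InformativeSnp:
    chrom: str
    pos: int
    ref_count: int
    alt_count: int
    p_raw: float
    p_adj: float

    @property
    def major_allele(self) -> str:
        if self.ref_count == self.alt_count:
            raise ValueError("major allele undefined for tied counts")
        return "REF" if self.ref_count > self.alt_count else "ALT"


def arm_restricted_interval(
    segment: CnaSegment, arm_interval: tuple[int, int]
) -> Optional[tuple[int, int]]:
    lo = max(segment.start, arm_interval[0])
    hi = min(segment.end, arm_interval[1])
    return (lo, hi) if lo < hi else None


def call_informative_snps(
    tumor_counts: Sequence[AllelicCount],
    het_positions: set[tuple[str, int]],
    segment: CnaSegment,
    arm_interval: tuple[int, int],
    alpha: float,
    config: MappingConfig = MappingConfig(),
) -> list[InformativeSnp]:
    """Informative SNPs for one tumor on one arm-restricted segment.

    Candidates are het SNPs inside the segment-arm intersection with tumor
    depth > 10; the BH family is exactly this candidate set; returned SNPs
    have adjusted p < ``alpha``. A tie (ref == alt) has p_raw = 1 and can
    never be informative, so the major allele is always defined.
    """
    window = arm_restricted_interval(segment, arm_interval)
    if window is None:
        return []
    lo, hi = window
    candidates = [
        c
        for c in tumor_counts
        if c.chrom == segment.chrom
        and lo <= c.pos - 1 < hi
        and (c.chrom, c.pos) in het_positions
        and c.depth > config.tumor_min_depth_exclusive
    ]
    if not candidates:
        return []
    p_raw = _binomial_two_sided_p_vec(
        np.array([c.ref_count for c in candidates]),
        np.array([c.alt_count for c in candidates]),
    )
    p_adj = adjust_bh(p_raw)
    return [
        InformativeSnp(c.chrom, c.pos, c.ref_count, c.alt_count, pr, pa)
        for c, pr, pa in zip(candidates, p_raw, p_adj)
        if pa < alpha
    ]


# ---------------------------------------------------------------------------
# Pairwise comparison
# ---------------------------------------------------------------------------

@dataclass
class ArmContext:
    """Everything needed to call informative SNPs for one tumor on one arm."""

    patient_id: str
    sample_id: str
    chrom: str
    arm: str  # 'p' | 'q' | 'whole'
    segment: CnaSegment
    arm_interval: tuple[int, int]
    tumor_counts: Sequence[AllelicCount]
    het_positions: set[tuple[str, int]]

    def __post_init__(self) -> None:
        self._cache: dict[float, dict[int, InformativeSnp]] = {}

    def informative(self, alpha: float, config: MappingConfig) -> dict[int, InformativeSnp]:
        if alpha not in self._cache:
            calls = call_informative_snps(
                self.tumor_counts, self.het_positions, self.segment,
                self.arm_interval, alpha, config,
            )
            self._cache[alpha] = {s.pos: s for s in calls}
        return self._cache[alpha]


@dataclass(frozen=True)
class ConcordanceResult:
    tumor_a: str
    tumor_b: str
    chrom: str
    arm: str
    n_shared_informative: int
    alpha_used: float
    concordance: Optional[float]  # None iff no shared informative SNPs
    verdict: str  # same_allele | different_allele | ambiguous | no_call


def compare_parental_alleles(
    ctx_a: ArmContext, ctx_b: ArmContext, config: MappingConfig = MappingConfig()
) -> ConcordanceResult:
    """Compare which parental allele two tumors' CNAs affected on one arm.

    The shared set is the positions informative in both tumors at the
    primary level; when it holds fewer than ``relaxation_snp_count`` SNPs,
    both tumors are re-called at the relaxed level and the shared set
    recomputed (symmetric by construction). Concordance is the fraction of
    shared SNPs whose major allele agrees.
    """
    if ctx_a.patient_id != ctx_b.patient_id:
        raise ValueError(
            f"cannot compare tumors from different patients "
            f"({ctx_a.patient_id} vs {ctx_b.patient_id}): germlines differ"
        )
    if (ctx_a.chrom, ctx_a.arm) != (ctx_b.chrom, ctx_b.arm):
        raise ValueError("contexts describe different chromosome arms")

    alpha_used = config.alpha_primary
    calls_a = ctx_a.informative(alpha_used, config)
    calls_b = ctx_b.informative(alpha_used, config)
    shared = sorted(set(calls_a) & set(calls_b))
    if len(shared) < config.relaxation_snp_count:
        alpha_used = config.alpha_relaxed
        calls_a = ctx_a.informative(alpha_used, config)
        calls_b = ctx_b.informative(alpha_used, config)
        shared = sorted(set(calls_a) & set(calls_b))

    if not shared:
        return ConcordanceResult(
            ctx_a.sample_id, ctx_b.sample_id, ctx_a.chrom, ctx_a.arm,
            0, alpha_used, None, "no_call",
        )
    agree = sum(
        1 for pos in shared if calls_a[pos].major_allele == calls_b[pos].major_allele
    )
    concordance = agree / len(shared)
    if concordance >= config.concordance_same_min:
        verdict = "same_allele"
    elif concordance <= config.concordance_diff_max:
        verdict = "different_allele"
    else:
        verdict = "ambiguous"
    return ConcordanceResult(
        ctx_a.sample_id, ctx_b.sample_id, ctx_a.chrom, ctx_a.arm,
        len(shared), alpha_used, concordance, verdict,
    )


# ---------------------------------------------------------------------------
# Per-segment mapping report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmMappingReport:
    sample_id: str
    chrom: str
    arm: str  # 'p' | 'q'
    direction: str
    n_candidates: int
    n_informative: int
    alpha: float
    fraction_major_ref: Optional[float]  # None when no informative SNPs
    interpretation: str  # e.g. "loss: major allele marks the retained haplotype"


_INTERPRETATION = {
    "loss": "loss: major allele marks the retained haplotype",
    "gain": "gain: major allele marks the amplified haplotype",
    "cn_loh": "cn_loh: major allele marks the duplicated (retained) haplotype",
}


def map_segment(
    tumor_counts: Sequence[AllelicCount],
    het_positions: set[tuple[str, int]],
    segment: CnaSegment,
    genome: GenomeConfig,
    config: MappingConfig = MappingConfig(),
    sample_id: Optional[str] = None,
    alpha: Optional[float] = None,
) -> list[ArmMappingReport]:
    """Map one filtered segment, split at the centromere, one BH family and
    report per arm. A segment entirely inside the centromere yields no
    reports (no call is possible)."""
    alpha = config.alpha_primary if alpha is None else alpha
    sample_id = sample_id or (segment.sample_id or "")
    reports = []
    for arm in ("p", "q"):
        arm_iv = genome.arm_interval(segment.chrom, arm)
        window = arm_restricted_interval(segment, arm_iv)
        if window is None:
            continue
        lo, hi = window
        candidates = [
            c
            for c in tumor_counts
            if c.chrom == segment.chrom
            and lo <= c.pos - 1 < hi
            and (c.chrom, c.pos) in het_positions
            and c.depth > config.tumor_min_depth_exclusive
        ]
        informative = call_informative_snps(
            tumor_counts, het_positions, segment, arm_iv, alpha, config
        )
        frac_ref = (
            sum(1 for s in informative if s.major_allele == "REF") / len(informative)
            if informative
            else None
        )
        reports.append(
            ArmMappingReport(
                sample_id, segment.chrom, arm, segment.direction,
                len(candidates), len(informative), alpha, frac_ref,
                _INTERPRETATION[segment.direction],
            )
        )
    return reports
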