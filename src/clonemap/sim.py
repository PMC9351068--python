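"""Synthetic multifocal-tumor cohort generator with known ground truth.

Emulates a cohort of patients each carrying several independent synchronous
primary tumors and a few metastases, the situation seen in multifocal ileal
neuroendocrine tumors: a very low somatic burden (~0.4 mutations/Mb), whole
chromosome and arm-level copy-number events dominated by loss of one
chromosome-18 homolog, tumor purity of 20% and up, ~60x tumor and ~30x
normal coverage. Primary tumors share no designed somatic variants (they
arise independently from normal mucosa); each metastasis inherits most of
one parent primary's variants plus private ones.

Ground truth — the per-SNP germline haplotype phase, the haplotype affected
by every copy-number event, and each metastasis' parent — is recorded so
that the filtering, chromosome-mapping, clonality and recurrence modules
can be scored against a known answer.

The default genome is a desk-scale toy: three 10-Mb chromosomes with
centromeres at 40-45% of their length. One chromosome is named "chr18" so
that the most common simulated event, whole-chromosome loss of one homolog,
reads naturally as the chr18-LOH analog.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as cio
from .genome import Chromosome, GenomeConfig
from .types import AllelicCount, CnaSegment, SampleMeta, SmallVariant, SvCall, VariantKey

HAPLOTYPES = ("A", "B")
_BASES = ("A", "C", "G", "T")
_EFFECTS = ("missense", "silent", "nonsense", "frameshift", "splice")
_EFFECT_PROBS = (0.65, 0.27, 0.05, 0.02, 0.01)


def default_toy_genome() -> GenomeConfig:
    """Three 10-Mb chromosomes, centromeres at 40-45% of length."""
    return GenomeConfig(
        chromosomes=[
            Chromosome("chr1", 10_000_000),
            Chromosome("chr2", 10_000_000),
            Chromosome("chr18", 10_000_000),
        ],
        centromeres={
            "chr1": (4_000_000, 4_500_000),
            "chr2": (4_200_000, 4_700_000),
            "chr18": (4_400_000, 4_900_000),
        },
    )


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the multifocal ileal NET setting: 13 patients with 2-18
    primaries and 0-4 metastases each, 0.41 somatic mutations/Mb, ~1.2% of
    variants coding, purity uniform on [0.2, 0.9], 60x/30x tumor/normal
    depth, and a CNA event table led by whole-chr18 loss in 57% of tumors.
    """

    seed: int
    n_patients: int = 13
    primaries_per_patient: tuple[int, int] = (2, 18)
    mets_per_patient: tuple[int, int] = (0, 4)
    mutation_rate: float = 0.41  # somatic mutations per Mb per tumor
    coding_fraction: float = 0.012
    indel_fraction: float = 0.1
    purity_range: tuple[float, float] = (0.2, 0.9)
    mean_tumor_depth: float = 60.0
    mean_normal_depth: float = 30.0
    het_snps_per_chrom: int = 2000
    cna_event_table: tuple[tuple[str, str, float], ...] = (
        ("chr18", "loss", 0.57),
        ("chr2", "gain", 0.13),
        ("chr1", "cn_loh", 0.08),
    )
    met_inherited_fraction: float = 0.9
    met_time_factor: float = 1.0  # met private burden as multiple of primary burden
    overdispersion: float = 0.01  # beta-binomial rho; 0 degenerates to binomial
    logr_noise_sd: float = 0.01
    mean_svs_per_tumor: float = 2.0
    sequencing_error_rate: float = 0.001
    genome: GenomeConfig = field(default_factory=default_toy_genome)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.primaries_per_patient
        if not (0 < lo <= hi):
            raise ValueError(f"empty primaries range {self.primaries_per_patient}")
        mlo, mhi = self.mets_per_patient
        if not (0 <= mlo <= mhi):
            raise ValueError(f"empty mets range {self.mets_per_patient}")
        plo, phi = self.purity_range
        if not (0.0 <= plo <= phi <= 1.0):
            raise ValueError(f"purity range {self.purity_range} outside [0, 1]")
        if not (0.0 <= self.overdispersion < 1.0):
            raise ValueError("overdispersion must be in [0, 1)")
        for frac in (self.coding_fraction, self.indel_fraction, self.met_inherited_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"fraction {frac} outside [0, 1]")
        for target, direction, prob in self.cna_event_table:
            parse_event_target(self.genome, target)
            if direction not in ("loss", "gain", "cn_loh"):
                raise ValueError(f"unknown CNA direction {direction!r}")
            if not (0.0 <= prob <= 1.0):
                raise ValueError(f"event probability {prob} outside [0, 1]")


def parse_event_target(genome: GenomeConfig, target: str) -> tuple[str, str]:
    """Parse an event target like ``"chr18"`` (whole) or ``"chr18q"`` (arm)."""
    if target in genome:
        return target, "whole"
    if target[-1:] in ("p", "q") and target[:-1] in genome:
        return target[:-1], target[-1]
    raise ValueError(f"event target {target!r} matches no chromosome or arm")


# ---------------------------------------------------------------------------
# Ground-truth records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HetSnp:
    """A germline heterozygous SNP; ``alt_hap`` is the haplotype carrying ALT."""

    chrom: str
    pos: int  # 1-based
    alt_hap: str  # 'A' | 'B'


@dataclass(frozen=True)
class CnaEvent:
    """A simulated copy-number event affecting one haplotype.

    loss: affected haplotype 0 copies; gain: affected haplotype 2 copies;
    cn_loh: affected haplotype 2 copies, the other 0 (copy-neutral).
    """

    chrom: str
    scope: str  # 'whole' | 'p' | 'q'
    direction: str
    affected_hap: str

    def interval(self, genome: GenomeConfig) -> tuple[int, int]:
        if self.scope == "whole":
            return (0, genome.length(self.chrom))
        return genome.arm_interval(self.chrom, self.scope)

    def copy_numbers(self) -> dict[str, int]:
        other = "B" if self.affected_hap == "A" else "A"
        if self.direction == "loss":
            return {self.affected_hap: 0, other: 1}
        if self.direction == "gain":
            return {self.affected_hap: 2, other: 1}
        return {self.affected_hap: 2, other: 0}  # cn_loh


@dataclass
class TumorTruth:
    sample_id: str
    sample_type: str
    purity: float
    events: list[CnaEvent]
    variant_keys: set[VariantKey]
    parent: Optional[str] = None  # parent primary for metastases
    inherited_keys: set[VariantKey] = field(default_factory=set)


@dataclass
class PatientTruth:
    patient_id: str
    normal_id: str
    snps: list[HetSnp]
    tumors: dict[str, TumorTruth]


@dataclass
class PatientDataset:
    """In-memory per-patient dataset plus its generating ground truth."""

    patient_id: str
    meta: list[SampleMeta]
    variants: dict[str, list[SmallVariant]]
    segments: dict[str, list[CnaSegment]]
    svs: dict[str, list[SvCall]]
    allelic_counts: dict[str, list[AllelicCount]]
    evidence: dict[str, dict[VariantKey, tuple[int, int]]]
    truth: PatientTruth

    @property
    def tumor_ids(self) -> list[str]:
        return [m.sample_id for m in self.meta if m.is_tumor]

    @property
    def primary_ids(self) -> list[str]:
        return [m.sample_id for m in self.meta if m.sample_type == "primary"]

    @property
    def metastasis_ids(self) -> list[str]:
        return [m.sample_id for m in self.meta if m.sample_type == "metastasis"]


# ---------------------------------------------------------------------------
# Allelic-count sampling model
# ---------------------------------------------------------------------------

def expected_alt_fraction(n_alt_hap: int, n_ref_hap: int, purity: float) -> float:
    """Expected ALT read fraction at a het SNP under a purity mixture.

    Tumor cells carry ``n_alt_hap`` copies of the ALT-bearing haplotype and
    ``n_ref_hap`` of the REF-bearing one; admixed normal cells carry one of
    each. Returns
    ``(purity*n_alt_hap + (1-purity)) / (purity*(n_alt_hap+n_ref_hap) + 2*(1-purity))``.
    """
    if n_alt_hap < 0 or n_ref_hap < 0:
        raise ValueError("haplotype copy numbers must be >= 0")
    if not (0.0 <= purity <= 1.0):
        raise ValueError(f"purity {purity} outside [0, 1]")
    denom = purity * (n_alt_hap + n_ref_hap) + (1.0 - purity) * 2.0
    if denom == 0.0:
        raise ValueError("total copy number is zero (pure tumor with 0+0 copies)")
    return (purity * n_alt_hap + (1.0 - purity) * 1.0) / denom


def _sample_allelic_depths(
    fractions: np.ndarray,
    mean_depth: float,
    overdispersion: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (ref, alt) counts: Poisson depth, beta-binomial ALT count."""
    fractions = np.asarray(fractions, dtype=float)
    depth = rng.poisson(mean_depth, size=fractions.shape)
    alt = np.zeros_like(depth)
    interior = (fractions > 0.0) & (fractions < 1.0)
    if overdispersion > 0.0 and interior.any():
        rho = overdispersion
        conc = (1.0 - rho) / rho
        f = fractions[interior]
        p = rng.beta(f * conc, (1.0 - f) * conc)
        alt[interior] = rng.binomial(depth[interior], p)
    elif interior.any():
        alt[interior] = rng.binomial(depth[interior], fractions[interior])
    alt[fractions >= 1.0] = depth[fractions >= 1.0]
    return depth - alt, alt


def sample_allelic_depth(
    expected_fraction: float,
    mean_depth: float,
    overdispersion: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Draw one (ref_count, alt_count) pair; depth 0 yields (0, 0)."""
    if not (0.0 <= expected_fraction <= 1.0):
        raise ValueError(f"expected_fraction {expected_fraction} outside [0, 1]")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    ref, alt = _sample_allelic_depths(
        np.array([expected_fraction]), mean_depth, overdispersion, rng
    )
    return int(ref[0]), int(alt[0])


def simulate_het_snps(
    genome: GenomeConfig, n_per_chrom: int, rng: np.random.Generator
) -> list[HetSnp]:
    """Draw het SNP positions uniformly over chromosome arms (centromeres
    excluded) with an independent fair-coin ALT haplotype per SNP."""
    snps: list[HetSnp] = []
    for chrom in genome.names:
        p_lo, p_hi = genome.arm_interval(chrom, "p")
        q_lo, q_hi = genome.arm_interval(chrom, "q")
        arm_total = (p_hi - p_lo) + (q_hi - q_lo)
        offsets = np.sort(rng.choice(arm_total, size=n_per_chrom, replace=False))
        haps = rng.integers(0, 2, size=n_per_chrom)
        for off, h in zip(offsets, haps):
            pos0 = p_lo + off if off < (p_hi - p_lo) else q_lo + (off - (p_hi - p_lo))
            snps.append(HetSnp(chrom, int(pos0) + 1, HAPLOTYPES[int(h)]))
    return snps


def simulate_tumor_allelic_counts(
    sample_id: str,
    snps: Sequence[HetSnp],
    events: Sequence[CnaEvent],
    purity: float,
    mean_depth: float,
    overdispersion: float,
    genome: GenomeConfig,
    rng: np.random.Generator,
) -> list[AllelicCount]:
    """Allelic counts at every het SNP for one sample.

    The copy state at each SNP follows from the events covering it and the
    recorded affected haplotype; the normal sample is the ``purity=0``,
    no-event case with expected VAF 0.5 everywhere.
    """
    chroms = np.array([s.chrom for s in snps])
    pos0 = np.array([s.pos - 1 for s in snps])
    is_a = np.array([s.alt_hap == "A" for s in snps])
    n_alt = np.ones(len(snps))
    n_ref = np.ones(len(snps))
    for ev in events:
        lo, hi = ev.interval(genome)
        mask = (chroms == ev.chrom) & (pos0 >= lo) & (pos0 < hi)
        if not mask.any():
            continue
        cn = ev.copy_numbers()
        n_alt[mask] = np.where(is_a[mask], cn["A"], cn["B"])
        n_ref[mask] = np.where(is_a[mask], cn["B"], cn["A"])
    denom = purity * (n_alt + n_ref) + (1.0 - purity) * 2.0
    if np.any(denom == 0.0):
        raise ValueError("total copy number is zero at some SNP (pure tumor, 0+0 copies)")
    fractions = (purity * n_alt + (1.0 - purity)) / denom
    ref, alt = _sample_allelic_depths(fractions, mean_depth, overdispersion, rng)
    return [
        AllelicCount(sample_id, snp.chrom, snp.pos, int(r), int(a))
        for snp, r, a in zip(snps, ref, alt)
    ]


# ---------------------------------------------------------------------------
# Somatic variants, segments, SVs
# ---------------------------------------------------------------------------

def _draw_variants(
    config: SimConfig,
    rng: np.random.Generator,
    time_factor: float,
    existing: set[VariantKey],
) -> list[SmallVariant]:
    genome = config.genome
    n = rng.poisson(config.mutation_rate * genome.genome_mb * time_factor)
    lengths = np.array([c.length for c in genome.chromosomes], dtype=float)
    out: list[SmallVariant] = []
    taken = set(existing)
    while len(out) < n:
        ci = rng.choice(len(lengths), p=lengths / lengths.sum())
        chrom = genome.names[int(ci)]
        pos = int(rng.integers(1, genome.length(chrom) + 1))
        ref = _BASES[int(rng.integers(4))]
        if rng.random() < config.indel_fraction:
            alt = ref + _BASES[int(rng.integers(4))]
        else:
            alt = _BASES[int(rng.integers(4))]
            if alt == ref:
                continue
        key = (chrom, pos, ref, alt)
        if key in taken:
            continue
        taken.add(key)
        coding = rng.random() < config.coding_fraction
        out.append(
            SmallVariant(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                total_depth=int(rng.poisson(config.mean_tumor_depth)),
                population_af=0.0,
                variant_class="SNV" if len(ref) == 1 and len(alt) == 1 else "indel",
                region="coding" if coding else "noncoding",
                gene=f"G{chrom[3:]}_{pos // 100_000:03d}" if coding else None,
                effect=(
                    str(rng.choice(_EFFECTS, p=_EFFECT_PROBS)) if coding else None
                ),
            )
        )
    return out


def _draw_events(
    config: SimConfig, rng: np.random.Generator, skip_chroms: set[str]
) -> list[CnaEvent]:
    events = []
    for target, direction, prob in config.cna_event_table:
        chrom, scope = parse_event_target(config.genome, target)
        if chrom in skip_chroms:
            continue
        if rng.random() < prob:
            hap = HAPLOTYPES[int(rng.integers(0, 2))]
            events.append(CnaEvent(chrom, scope, direction, hap))
    return events


def event_logr(direction: str, purity: float) -> float:
    """Expected segment logR under the purity mixture (total copy over 2)."""
    total = {"loss": 2.0 - purity, "gain": 2.0 + purity, "cn_loh": 2.0}[direction]
    return float(np.log2(total / 2.0))


def _segments_for_events(
    sample_id: str, events: Sequence[CnaEvent], purity: float,
    config: SimConfig, rng: np.random.Generator,
) -> list[CnaSegment]:
    segs = []
    for ev in events:
        lo, hi = ev.interval(config.genome)
        logr = event_logr(ev.direction, purity) + float(rng.normal(0.0, config.logr_noise_sd))
        segs.append(CnaSegment(ev.chrom, lo, hi, logr, ev.direction, sample_id))
    return segs


def _draw_svs(
    sample_id: str, config: SimConfig, rng: np.random.Generator
) -> list[SvCall]:
    genome = config.genome
    out = []
    for _ in range(int(rng.poisson(config.mean_svs_per_tumor))):
        if rng.random() < 0.7:
            chrom = genome.names[int(rng.integers(len(genome.names)))]
            span = int(10 ** rng.uniform(3.0, 6.5))
            length = genome.length(chrom)
            span = min(span, length - 2)
            pos1 = int(rng.integers(1, length - span))
            sv_type = str(rng.choice(("deletion", "duplication", "inversion", "translocation")))
            out.append(SvCall(chrom, pos1, chrom, pos1 + span, sv_type, sample_id))
        else:
            ci, cj = rng.choice(len(genome.names), size=2, replace=False)
            c1, c2 = genome.names[int(ci)], genome.names[int(cj)]
            out.append(
                SvCall(
                    c1, int(rng.integers(1, genome.length(c1) + 1)),
                    c2, int(rng.integers(1, genome.length(c2) + 1)),
                    "interchromosomal", sample_id,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Patient / cohort simulation
# ---------------------------------------------------------------------------

def simulate_patient(
    config: SimConfig,
    patient_id: str,
    rng: np.random.Generator,
    n_primaries: Optional[int] = None,
    n_mets: Optional[int] = None,
    include_allelic_counts: bool = True,
) -> PatientDataset:
    """Simulate one patient: germline het SNPs, independent primaries,
    metastases inheriting a parent primary, and a matched normal.

    Primaries share no designed variants (collisions only by chance at
    random positions). Each metastasis inherits ``met_inherited_fraction``
    of its parent's variants plus private ones, and its parent's CNA events
    on the same haplotypes.
    """
    genome = config.genome
    if n_primaries is None:
        lo, hi = config.primaries_per_patient
        n_primaries = int(rng.integers(lo, hi + 1))
    if n_mets is None:
        mlo, mhi = config.mets_per_patient
        n_mets = int(rng.integers(mlo, mhi + 1))
    if n_mets > 0 and n_primaries == 0:
        raise ValueError(f"{patient_id}: metastases requested with zero primaries")

    snps = simulate_het_snps(genome, config.het_snps_per_chrom, rng)
    normal_id = f"{patient_id}_N"
    meta = [SampleMeta(normal_id, patient_id, "normal")]
    truth_tumors: dict[str, TumorTruth] = {}
    variants: dict[str, list[SmallVariant]] = {}
    segments: dict[str, list[CnaSegment]] = {}
    svs: dict[str, list[SvCall]] = {}
    counts: dict[str, list[AllelicCount]] = {}

    plo, phi = config.purity_range

    def _finish_sample(sid: str, stype: str, purity, events, var_list, parent=None,
                       inherited=frozenset()):
        meta.append(SampleMeta(sid, patient_id, stype, purity))
        variants[sid] = sorted(var_list, key=lambda v: v.key)
        segments[sid] = _segments_for_events(sid, events, purity, config, rng)
        svs[sid] = _draw_svs(sid, config, rng)
        if include_allelic_counts:
            counts[sid] = simulate_tumor_allelic_counts(
                sid, snps, events, purity, config.mean_tumor_depth,
                config.overdispersion, genome, rng,
            )
        truth_tumors[sid] = TumorTruth(
            sid, stype, purity, list(events),
            {v.key for v in var_list}, parent, set(inherited),
        )

    for j in range(1, n_primaries + 1):
        sid = f"{patient_id}_P{j}"
        purity = float(rng.uniform(plo, phi))
        events = _draw_events(config, rng, skip_chroms=set())
        var_list = _draw_variants(config, rng, 1.0, set())
        _finish_sample(sid, "primary", purity, events, var_list)

    primary_ids = [m.sample_id for m in meta if m.sample_type == "primary"]
    for j in range(1, n_mets + 1):
        sid = f"{patient_id}_M{j}"
        parent = primary_ids[int(rng.integers(len(primary_ids)))]
        purity = float(rng.uniform(plo, phi))
        keep = rng.random(len(variants[parent])) < config.met_inherited_fraction
        inherited = [
            SmallVariant(
                v.chrom, v.pos, v.ref, v.alt,
                total_depth=int(rng.poisson(config.mean_tumor_depth)),
                population_af=v.population_af, variant_class=v.variant_class,
                region=v.region, gene=v.gene, effect=v.effect,
            )
            for v, k in zip(variants[parent], keep) if k
        ]
        private = _draw_variants(
            config, rng, config.met_time_factor, {v.key for v in inherited}
        )
        events = list(truth_tumors[parent].events)
        extra = _draw_events(config, rng, skip_chroms={e.chrom for e in events})
        _finish_sample(
            sid, "metastasis", purity, events + extra, inherited + private,
            parent=parent, inherited={v.key for v in inherited},
        )

    # matched normal: purity 0, no events, expected VAF 0.5 everywhere
    if include_allelic_counts:
        counts[normal_id] = simulate_tumor_allelic_counts(
            normal_id, snps, [], 0.0, config.mean_normal_depth,
            config.overdispersion, genome, rng,
        )

    evidence = _draw_evidence(config, truth_tumors, variants, rng)
    truth = PatientTruth(patient_id, normal_id, snps, truth_tumors)
    return PatientDataset(
        patient_id, meta, variants, segments, svs, counts, evidence, truth
    )


def _draw_evidence(
    config: SimConfig,
    truth_tumors: dict[str, TumorTruth],
    variants: dict[str, list[SmallVariant]],
    rng: np.random.Generator,
) -> dict[str, dict[VariantKey, tuple[int, int]]]:
    """Per-tumor read support at every variant position seen in the patient.

    A tumor carrying the variant yields ALT reads at ~purity/2 VAF (one
    mutated copy in a diploid mixture); a tumor without it yields only
    sequencing-error ALT reads.
    """
    union: list[VariantKey] = sorted({v.key for vs in variants.values() for v in vs})
    evidence: dict[str, dict[VariantKey, tuple[int, int]]] = {}
    for sid, tt in truth_tumors.items():
        depths = rng.poisson(config.mean_tumor_depth, size=len(union))
        table: dict[VariantKey, tuple[int, int]] = {}
        for key, depth in zip(union, depths):
            vaf = tt.purity / 2.0 if key in tt.variant_keys else config.sequencing_error_rate
            alt = int(rng.binomial(int(depth), vaf))
            table[key] = (int(depth) - alt, alt)
        evidence[sid] = table
    return evidence


@dataclass
class CohortDataset:
    config: SimConfig
    patients: list[PatientDataset]

    @property
    def genome(self) -> GenomeConfig:
        return self.config.genome


def simulate_cohort(
    config: SimConfig,
    out_dir: Optional[str | Path] = None,
    include_allelic_counts: bool = True,
) -> CohortDataset:
    """Simulate the whole cohort; optionally write it to disk.

    Deterministic given ``config.seed``: each patient draws from its own
    spawned random stream, so the byte-level manifest is identical across
    re-runs with the same seed and differs across seeds.
    ``include_allelic_counts=False`` skips the het-SNP count tables for
    analyses that only consume variant sets (the random stream then differs
    from the default mode, but each mode is itself deterministic).
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    patients = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        patients.append(
            simulate_patient(
                config, f"P{i + 1:03d}", rng,
                include_allelic_counts=include_allelic_counts,
            )
        )
    cohort = CohortDataset(config, patients)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def ground_truth_manifest(cohort: CohortDataset) -> dict:
    out: dict = {"seed": cohort.config.seed, "patients": {}}
    for p in cohort.patients:
        t = p.truth
        out["patients"][p.patient_id] = {
            "normal": t.normal_id,
            "snps": [[s.chrom, s.pos, s.alt_hap] for s in t.snps],
            "tumors": {
                sid: {
                    "type": tt.sample_type,
                    "purity": tt.purity,
                    "parent": tt.parent,
                    "events": [
                        [e.chrom, e.scope, e.direction, e.affected_hap] for e in tt.events
                    ],
                    "variants": sorted([list(k) for k in tt.variant_keys]),
                    "inherited": sorted([list(k) for k in tt.inherited_keys]),
                }
                for sid, tt in sorted(t.tumors.items())
            },
        }
    return out


def write_cohort(cohort: CohortDataset, out_dir: str | Path) -> None:
    """Write per-sample VCF/SEG/SV/allelic-count files, sample sheets,
    per-patient variant read-support tables, the genome configuration and
    the ground-truth ``manifest.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = cohort.genome
    all_meta: list[SampleMeta] = []
    for p in cohort.patients:
        pdir = out / p.patient_id
        pdir.mkdir(exist_ok=True)
        all_meta.extend(p.meta)
        cio.write_sample_sheet(p.meta, pdir / "samples.tsv")
        for sid in p.tumor_ids:
            cio.write_small_variants(p.variants[sid], pdir / f"{sid}.vcf", genome)
            cio.write_seg(p.segments[sid], pdir / f"{sid}.seg.tsv")
            cio.write_sv_table(p.svs[sid], pdir / f"{sid}.sv.tsv")
        for sid, counts in p.allelic_counts.items():
            cio.write_allelic_counts(counts, pdir / f"{sid}.counts.tsv")
        _write_evidence(p, pdir / "evidence.tsv")
    cio.write_sample_sheet(all_meta, out / "samples.tsv")
    from .genome import save_genome_config

    save_genome_config(genome, out / "genome.yaml")
    manifest = ground_truth_manifest(cohort)
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n"
    )


def _write_evidence(patient: PatientDataset, path: Path) -> None:
    rows = ["SAMPLE\tCHROM\tPOS\tREF\tALT\tREF_COUNT\tALT_COUNT"]
    for sid in sorted(patient.evidence):
        for key in sorted(patient.evidence[sid]):
            ref_n, alt_n = patient.evidence[sid][key]
            rows.append(f"{sid}\t{key[0]}\t{key[1]}\t{key[2]}\t{key[3]}\t{ref_n}\t{alt_n}")
    path.write_text("\n".join(rows) + "\n")


def load_patient(
    pdir: str | Path,
    genome: GenomeConfig,
    truth_entry: Optional[dict] = None,
) -> PatientDataset:
    """Rebuild a PatientDataset from a written patient directory.

    Ground truth is reconstructed from the manifest entry when given,
    otherwise left minimal (analysis does not require it)."""
    pdir = Path(pdir)
    meta = cio.read_sample_sheet(pdir / "samples.tsv")
    patient_id = meta[0].patient_id
    normal_id = next(m.sample_id for m in meta if m.sample_type == "normal")
    variants, segments, svs, counts = {}, {}, {}, {}
    for m in meta:
        if m.is_tumor:
            variants[m.sample_id] = cio.read_small_variants(
                pdir / f"{m.sample_id}.vcf", genome=genome
            )
            segments[m.sample_id] = cio.read_seg(pdir / f"{m.sample_id}.seg.tsv")
            svs[m.sample_id] = cio.read_sv_table(pdir / f"{m.sample_id}.sv.tsv")
        counts_path = pdir / f"{m.sample_id}.counts.tsv"
        if counts_path.exists():
            counts[m.sample_id] = cio.read_allelic_counts(counts_path, m.sample_id)
    evidence_path = pdir / "evidence.tsv"
    evidence = read_evidence(evidence_path) if evidence_path.exists() else {}
    if truth_entry is not None:
        snps = [HetSnp(c, int(p), h) for c, p, h in truth_entry["snps"]]
        tumors = {
            sid: TumorTruth(
                sid,
                t["type"],
                t["purity"],
                [CnaEvent(*e) for e in t["events"]],
                {tuple(k) for k in t["variants"]},
                t.get("parent"),
                {tuple(k) for k in t.get("inherited", [])},
            )
            for sid, t in truth_entry["tumors"].items()
        }
        truth = PatientTruth(patient_id, truth_entry["normal"], snps, tumors)
    else:
        truth = PatientTruth(patient_id, normal_id, [], {})
    return PatientDataset(
        patient_id, meta, variants, segments, svs, counts, evidence, truth
    )


def load_cohort(path: str | Path) -> CohortDataset:
    """Rebuild a CohortDataset from a directory written by write_cohort."""
    from .genome import load_genome_config

    root = Path(path)
    genome = load_genome_config(root / "genome.yaml")
    manifest_path = root / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    truth_by_patient = manifest.get("patients", {})
    all_meta = cio.read_sample_sheet(root / "samples.tsv")
    patient_ids = sorted({m.patient_id for m in all_meta})
    patients = [
        load_patient(root / pid, genome, truth_by_patient.get(pid))
        for pid in patient_ids
    ]
    config = SimConfig(seed=int(manifest.get("seed", 0)), genome=genome)
    return CohortDataset(config, patients)


def read_evidence(path: str | Path) -> dict[str, dict[VariantKey, tuple[int, int]]]:
    evidence: dict[str, dict[VariantKey, tuple[int, int]]] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        sid, chrom, pos, ref, alt, ref_n, alt_n = line.split("\t")
        evidence.setdefault(sid, {})[(chrom, int(pos), ref, alt)] = (int(ref_n), int(alt_n))
    return evidence
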