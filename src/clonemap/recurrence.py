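"""Cohort-level recurrence summaries and pathway enrichment.

Tallies across a multi-patient cohort: per-sample mutation burden
(mutations/Mb), genes recurrently hit by nonsynonymous mutations, noncoding
positions recurrently mutated at the exact same (chrom, pos, ref, alt) key,
recurrent CNA events classified as whole-chromosome / arm-level / focal,
minimally targeted regions (sub-5-Mb intersections of overlapping CNAs from
at least two patients), and hypergeometric (upper-tail) Reactome-style
pathway enrichment with Benjamini-Hochberg correction.

All "recurrent" flags count patients, not tumors: a gene hit in five tumors
of one patient counts once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

from .genome import GenomeConfig
from .mapping import adjust_bh
from .types import CnaSegment, SmallVariant


@dataclass
class RecurrenceConfig:
    min_patients: int = 2
    minimal_region_max_len: int = 5_000_000
    pathway_alpha: float = 0.1  # FDR level for pathway significance
    arm_coverage_threshold: float = 0.8  # fraction of arm/chrom for non-focal calls

    def __post_init__(self) -> None:
        if self.min_patients < 2:
            raise ValueError("min_patients must be >= 2")
        if self.minimal_region_max_len <= 0:
            raise ValueError("minimal_region_max_len must be > 0")


#: cohort variant container: patient -> sample -> variants
CohortVariants = Mapping[str, Mapping[str, Sequence[SmallVariant]]]
CohortSegments = Mapping[str, Mapping[str, Sequence[CnaSegment]]]


def mutation_burden(variants: Sequence[SmallVariant], genome_mb: float) -> float:
    """Somatic mutations per megabase for one sample."""
    if genome_mb <= 0:
        raise ValueError("genome_mb must be > 0")
    return len(variants) / genome_mb


NONSYNONYMOUS_EXCLUDED = frozenset({"silent"})


def recurrent_genes(
    cohort: CohortVariants, config: RecurrenceConfig = RecurrenceConfig()
) -> tuple[pd.DataFrame, list[SmallVariant]]:
    """Genes with nonsynonymous mutations, with per-gene patient and tumor
    counts and a cross-patient recurrence flag.

    Variants lacking gene or effect annotation are skipped and returned as
    the audit list. Returns (table, skipped).
    """
    gene_patients: dict[str, set[str]] = {}
    gene_tumors: dict[str, set[str]] = {}
    skipped: list[SmallVariant] = []
    for patient, samples in cohort.items():
        for sample, variants in samples.items():
            for v in variants:
                if v.region != "coding":
                    continue
                if v.gene is None or v.effect is None:
                    skipped.append(v)
                    continue
                if v.effect in NONSYNONYMOUS_EXCLUDED:
                    continue
                gene_patients.setdefault(v.gene, set()).add(patient)
                gene_tumors.setdefault(v.gene, set()).add(sample)
    rows = [
        {
            "gene": g,
            "n_patients": len(gene_patients[g]),
            "n_tumors": len(gene_tumors[g]),
            "recurrent_across_patients": len(gene_patients[g]) >= config.min_patients,
        }
        for g in sorted(gene_patients)
    ]
    df = pd.DataFrame(rows, columns=["gene", "n_patients", "n_tumors",
                                     "recurrent_across_patients"])
    return df.sort_values(
        ["n_patients", "n_tumors", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True), skipped


def recurrent_noncoding(
    cohort: CohortVariants, config: RecurrenceConfig = RecurrenceConfig()
) -> pd.DataFrame:
    """Noncoding variants keyed by exact (chrom, pos, ref, alt); a different
    ALT at the same position is a different row."""
    key_patients: dict = {}
    key_tumors: dict = {}
    for patient, samples in cohort.items():
        for sample, variants in samples.items():
            for v in variants:
                if v.region != "noncoding":
                    continue
                key_patients.setdefault(v.key, set()).add(patient)
                key_tumors.setdefault(v.key, set()).add(sample)
    rows = [
        {
            "chrom": k[0],
            "pos": k[1],
            "ref": k[2],
            "alt": k[3],
            "n_patients": len(key_patients[k]),
            "n_tumors": len(key_tumors[k]),
            "recurrent_across_patients": len(key_patients[k]) >= config.min_patients,
        }
        for k in sorted(key_patients)
    ]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "n_patients",
                                     "n_tumors", "recurrent_across_patients"])
    return df.sort_values(
        ["n_patients", "chrom", "pos", "ref", "alt"],
        ascending=[False, True, True, True, True],
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# CNA recurrence
# ---------------------------------------------------------------------------

def classify_segment_scope(
    segment: CnaSegment, genome: GenomeConfig, threshold: float = 0.8
) -> tuple[str, str]:
    """Classify a segment as ('whole', chrom), ('arm', 'chrNp'/'chrNq') or
    ('focal', chrom) by fractional coverage of the chromosome or arm."""
    chrom_len = genome.length(segment.chrom)
    if segment.length / chrom_len >= threshold:
        return "whole", segment.chrom
    for arm in ("p", "q"):
        lo, hi = genome.arm_interval(segment.chrom, arm)
        overlap = max(0, min(segment.end, hi) - max(segment.start, lo))
        if hi > lo and overlap / (hi - lo) >= threshold:
            return "arm", f"{segment.chrom}{arm}"
    return "focal", segment.chrom


def recurrent_cnas(
    cohort: CohortSegments,
    genome: GenomeConfig,
    config: RecurrenceConfig = RecurrenceConfig(),
    n_tumors_total: Optional[int] = None,
) -> pd.DataFrame:
    """Recurrent CNA events keyed by (target, direction, scope).

    Whole-chromosome and arm-level events aggregate by chromosome or arm;
    focal events (marked scope 'focal') aggregate by chromosome. Reports
    tumor count, tumor fraction and patient count per event.
    """
    if n_tumors_total is None:
        n_tumors_total = sum(len(samples) for samples in cohort.values())
    ev_tumors: dict = {}
    ev_patients: dict = {}
    for patient, samples in cohort.items():
        for sample, segments in samples.items():
            sample_events = set()
            for seg in segments:
                scope, target = classify_segment_scope(
                    seg, genome, config.arm_coverage_threshold
                )
                sample_events.add((target, seg.direction, scope))
            for ev in sample_events:
                ev_tumors.setdefault(ev, set()).add(sample)
                ev_patients.setdefault(ev, set()).add(patient)
    rows = [
        {
            "target": ev[0],
            "direction": ev[1],
            "scope": ev[2],
            "n_tumors": len(ev_tumors[ev]),
            "tumor_fraction": len(ev_tumors[ev]) / n_tumors_total if n_tumors_total else 0.0,
            "n_patients": len(ev_patients[ev]),
            "recurrent_across_patients": len(ev_patients[ev]) >= config.min_patients,
        }
        for ev in sorted(ev_tumors)
    ]
    df = pd.DataFrame(rows, columns=["target", "direction", "scope", "n_tumors",
                                     "tumor_fraction", "n_patients",
                                     "recurrent_across_patients"])
    return df.sort_values(
        ["n_tumors", "target", "direction"], ascending=[False, True, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Minimally targeted regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MinimalRegion:
    chrom: str
    start: int
    end: int
    direction: str
    n_patients: int
    n_segments: int

    @property
    def length(self) -> int:
        return self.end - self.start


def minimal_regions(
    segments: Sequence[CnaSegment],
    patient_of_sample: Mapping[str, str],
    config: RecurrenceConfig = RecurrenceConfig(),
) -> list[MinimalRegion]:
    """Minimally targeted regions: per direction, intersections of maximal
    mutually overlapping segment sets spanning >= ``min_patients`` patients,
    shorter than ``minimal_region_max_len``.

    For intervals, every mutually overlapping set shares a common point
    (Helly property), so maximal sets are found by sweeping elementary
    intervals and dropping covering sets strictly contained in another.
    Distinct maximal sets have disjoint intersection intervals, so output
    regions are pairwise disjoint and each is contained in every
    contributing segment.
    """
    out: list[MinimalRegion] = []
    groups: dict[tuple[str, str], list[CnaSegment]] = {}
    for seg in segments:
        groups.setdefault((seg.direction, seg.chrom), []).append(seg)
    for (direction, chrom), csegs in sorted(groups.items()):
        bounds = sorted({s.start for s in csegs} | {s.end for s in csegs})
        cliques: dict[frozenset, tuple[int, int, frozenset]] = {}
        for lo, hi in zip(bounds, bounds[1:]):
            covering = [s for s in csegs if s.start <= lo and s.end >= hi]
            if not covering:
                continue
            ids = frozenset(id(s) for s in covering)
            patients = frozenset(
                patient_of_sample.get(s.sample_id, s.sample_id) for s in covering
            )
            istart = max(s.start for s in covering)
            iend = min(s.end for s in covering)
            cliques[ids] = (istart, iend, patients)
        maximal = [
            ids for ids in cliques
            if not any(ids < other for other in cliques)
        ]
        for ids in maximal:
            istart, iend, patients = cliques[ids]
            if len(patients) < config.min_patients:
                continue
            if iend - istart >= config.minimal_region_max_len:
                continue
            out.append(
                MinimalRegion(chrom, istart, iend, direction, len(patients), len(ids))
            )
    return sorted(out, key=lambda r: (r.chrom, r.start, r.direction))


# ---------------------------------------------------------------------------
# Pathway enrichment
# ---------------------------------------------------------------------------

def hypergeom_enrichment_p(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric P(X >= k): probability of drawing at least
    k pathway genes when n of N universe genes are mutated and K belong to
    the pathway."""
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrichment(
    mutated_genes: set[str],
    pathways: Mapping[str, set[str]],
    universe: set[str],
    config: RecurrenceConfig = RecurrenceConfig(),
) -> pd.DataFrame:
    """Enrichment of mutated genes in each pathway (upper-tail
    hypergeometric), BH-corrected across all tested pathways.

    Pathways are intersected with the universe; mutated genes must be a
    subset of the universe.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not mutated_genes <= universe:
        raise ValueError(
            f"mutated genes outside the universe: {sorted(mutated_genes - universe)[:5]}"
        )
    N = len(universe)
    n = len(mutated_genes)
    rows = []
    for name in sorted(pathways):
        genes = pathways[name] & universe
        K = len(genes)
        k = len(genes & mutated_genes)
        rows.append(
            {"pathway": name, "k": k, "K": K, "n": n, "N": N,
             "p_raw": hypergeom_enrichment_p(N, K, n, k)}
        )
    df = pd.DataFrame(rows, columns=["pathway", "k", "K", "n", "N", "p_raw"])
    if len(df):
        df["p_adj"] = adjust_bh(df["p_raw"].to_numpy())
        df["significant"] = df["p_adj"] < config.pathway_alpha
    else:
        df["p_adj"] = []
        df["significant"] = []
    return df.sort_values(["p_raw", "pathway"]).reset_index(drop=True)
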