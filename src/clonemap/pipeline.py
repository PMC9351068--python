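"""End-to-end orchestration: filter -> map alleles -> clonality -> summarize.

Thin glue over the analysis modules, operating on the in-memory cohort
container the simulator produces (or that can be assembled from files via
the io module). All outputs are plain TSV/JSON written deterministically,
so a fixed-seed simulate-and-analyze run is byte-reproducible.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import clonality as clon
from . import filtering as filt
from . import mapping as amap
from . import recurrence as rec
from .genome import GenomeConfig
from .sim import CohortDataset, PatientDataset


@dataclass
class PipelineConfig:
    filters: filt.FilterConfig = field(default_factory=filt.FilterConfig)
    mapping: amap.MappingConfig = field(default_factory=amap.MappingConfig)
    clonality: clon.ClonalityConfig = field(default_factory=clon.ClonalityConfig)
    recurrence: rec.RecurrenceConfig = field(default_factory=rec.RecurrenceConfig)


@dataclass
class PatientAnalysis:
    patient_id: str
    kept_variants: dict[str, list]
    kept_segments: dict[str, list]
    kept_svs: dict[str, list]
    arm_reports: list[amap.ArmMappingReport]
    concordance: list[amap.ConcordanceResult]
    matrix: Optional[clon.SharedVariantMatrix]
    pair_classes: dict[tuple[str, str], str]
    origin_calls: list[clon.OriginCall]
    dissemination: Optional[str]


@dataclass
class CohortAnalysis:
    genome: GenomeConfig
    patients: list[PatientAnalysis]
    burden: pd.DataFrame
    recurrent_genes: pd.DataFrame
    recurrent_noncoding: pd.DataFrame
    recurrent_cnas: pd.DataFrame
    minimal_regions: list[rec.MinimalRegion]


def analyze_patient(
    patient: PatientDataset,
    genome: GenomeConfig,
    config: PipelineConfig = PipelineConfig(),
) -> PatientAnalysis:
    kept_variants, kept_segments, kept_svs = {}, {}, {}
    for sid in patient.tumor_ids:
        kept_variants[sid], _ = filt.filter_small_variants(
            patient.variants[sid], config.filters
        )
        kept_segments[sid], _ = filt.filter_cna_segments(
            patient.segments[sid], config.filters, genome
        )
        kept_svs[sid], _ = filt.filter_svs(patient.svs[sid], config.filters, genome)

    # --- allele mapping (requires allelic counts) -------------------------
    arm_reports: list[amap.ArmMappingReport] = []
    concordance: list[amap.ConcordanceResult] = []
    normal_id = patient.truth.normal_id
    if patient.allelic_counts.get(normal_id):
        het = amap.select_het_snps(patient.allelic_counts[normal_id], config.mapping)
        contexts: dict[tuple[str, str], list[amap.ArmContext]] = {}
        for sid in patient.tumor_ids:
            counts = patient.allelic_counts.get(sid)
            if not counts:
                continue
            for seg in kept_segments[sid]:
                arm_reports.extend(
                    amap.map_segment(
                        counts, het, seg, genome, config.mapping, sample_id=sid
                    )
                )
                for arm in ("p", "q"):
                    arm_iv = genome.arm_interval(seg.chrom, arm)
                    if amap.arm_restricted_interval(seg, arm_iv) is None:
                        continue
                    contexts.setdefault((seg.chrom, arm), []).append(
                        amap.ArmContext(
                            patient.patient_id, sid, seg.chrom, arm, seg,
                            arm_iv, counts, het,
                        )
                    )
        for (_chrom, _arm), ctxs in sorted(contexts.items()):
            for ctx_a, ctx_b in itertools.combinations(
                sorted(ctxs, key=lambda c: c.sample_id), 2
            ):
                concordance.append(
                    amap.compare_parental_alleles(ctx_a, ctx_b, config.mapping)
                )

    # --- clonality --------------------------------------------------------
    matrix = None
    pair_classes: dict[tuple[str, str], str] = {}
    origin_calls: list[clon.OriginCall] = []
    dissemination = None
    if len(patient.tumor_ids) >= 2:
        matrix = clon.shared_variant_matrix(
            patient.patient_id,
            {sid: kept_variants[sid] for sid in patient.tumor_ids},
            config.clonality,
        )
        primaries = patient.primary_ids
        if len(primaries) >= 2:
            pair_classes = clon.classify_primary_pairs(matrix, primaries, config.clonality)
        if primaries:
            for met in patient.metastasis_ids:
                origin_calls.append(
                    clon.assign_metastasis_origin(matrix, met, primaries, config.clonality)
                )
        if origin_calls:
            dissemination = clon.classify_dissemination(origin_calls)

    return PatientAnalysis(
        patient.patient_id, kept_variants, kept_segments, kept_svs,
        arm_reports, concordance, matrix, pair_classes, origin_calls,
        dissemination,
    )


def analyze_cohort(
    cohort: CohortDataset, config: PipelineConfig = PipelineConfig()
) -> CohortAnalysis:
    genome = cohort.genome
    analyses = [analyze_patient(p, genome, config) for p in cohort.patients]

    cohort_variants = {
        a.patient_id: a.kept_variants for a in analyses
    }
    cohort_segments = {
        a.patient_id: a.kept_segments for a in analyses
    }
    burden_rows = []
    for p, a in zip(cohort.patients, analyses):
        types = {m.sample_id: m.sample_type for m in p.meta}
        for sid in sorted(a.kept_variants):
            burden_rows.append(
                {
                    "patient": a.patient_id,
                    "sample": sid,
                    "sample_type": types[sid],
                    "n_variants": len(a.kept_variants[sid]),
                    "mut_per_mb": rec.mutation_burden(
                        a.kept_variants[sid], genome.genome_mb
                    ),
                }
            )
    burden = pd.DataFrame(
        burden_rows,
        columns=["patient", "sample", "sample_type", "n_variants", "mut_per_mb"],
    )
    genes, _skipped = rec.recurrent_genes(cohort_variants, config.recurrence)
    noncoding = rec.recurrent_noncoding(cohort_variants, config.recurrence)
    n_tumors = sum(len(a.kept_variants) for a in analyses)
    cnas = rec.recurrent_cnas(
        cohort_segments, genome, config.recurrence, n_tumors_total=n_tumors
    )
    flat_segments = [
        seg for a in analyses for segs in a.kept_segments.values() for seg in segs
    ]
    patient_of = {
        sid: a.patient_id for a in analyses for sid in a.kept_segments
    }
    regions = rec.minimal_regions(flat_segments, patient_of, config.recurrence)
    return CohortAnalysis(genome, analyses, burden, genes, noncoding, cnas, regions)


# ---------------------------------------------------------------------------
# Deterministic writers
# ---------------------------------------------------------------------------

def write_analysis(analysis: CohortAnalysis, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    analysis.burden.to_csv(out / "burden.tsv", sep="\t", index=False)
    analysis.recurrent_genes.to_csv(out / "recurrent_genes.tsv", sep="\t", index=False)
    analysis.recurrent_noncoding.to_csv(
        out / "recurrent_noncoding.tsv", sep="\t", index=False
    )
    analysis.recurrent_cnas.to_csv(out / "recurrent_cnas.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "chrom": r.chrom, "start": r.start, "end": r.end,
                "direction": r.direction, "length": r.length,
                "n_patients": r.n_patients, "n_segments": r.n_segments,
            }
            for r in analysis.minimal_regions
        ],
        columns=["chrom", "start", "end", "direction", "length",
                 "n_patients", "n_segments"],
    ).to_csv(out / "minimal_regions.tsv", sep="\t", index=False)

    matrix_rows = [
        row for a in analysis.patients if a.matrix for row in a.matrix.to_rows()
    ]
    pd.DataFrame(
        matrix_rows,
        columns=["patient", "tumor_a", "tumor_b", "size_a", "size_b",
                 "shared_count", "shared_fraction"],
    ).to_csv(out / "shared_matrix.tsv", sep="\t", index=False)

    origin_rows = [
        {
            "patient": a.patient_id,
            "metastasis": c.metastasis_id,
            "origin": c.origin_primary_id or ".",
            "shared_with_origin": c.shared_with_origin,
            "runner_up": c.runner_up,
            "evidence": c.evidence,
        }
        for a in analysis.patients
        for c in a.origin_calls
    ]
    pd.DataFrame(
        origin_rows,
        columns=["patient", "metastasis", "origin", "shared_with_origin",
                 "runner_up", "evidence"],
    ).to_csv(out / "origin_calls.tsv", sep="\t", index=False)

    dissemination = {
        a.patient_id: a.dissemination
        for a in analysis.patients
        if a.dissemination is not None
    }
    (out / "dissemination.json").write_text(
        json.dumps(dissemination, sort_keys=True, indent=1) + "\n"
    )

    pair_rows = [
        {"patient": a.patient_id, "tumor_a": pair[0], "tumor_b": pair[1],
         "classification": verdict}
        for a in analysis.patients
        for pair, verdict in sorted(a.pair_classes.items())
    ]
    pd.DataFrame(
        pair_rows, columns=["patient", "tumor_a", "tumor_b", "classification"]
    ).to_csv(out / "primary_pairs.tsv", sep="\t", index=False)

    arm_rows = [
        {
            "patient": a.patient_id, "sample": r.sample_id, "chrom": r.chrom,
            "arm": r.arm, "direction": r.direction,
            "n_candidates": r.n_candidates, "n_informative": r.n_informative,
            "alpha": r.alpha,
            "fraction_major_ref": "." if r.fraction_major_ref is None
            else repr(r.fraction_major_ref),
            "interpretation": r.interpretation,
        }
        for a in analysis.patients
        for r in a.arm_reports
    ]
    pd.DataFrame(
        arm_rows,
        columns=["patient", "sample", "chrom", "arm", "direction", "n_candidates",
                 "n_informative", "alpha", "fraction_major_ref", "interpretation"],
    ).to_csv(out / "arm_mapping.tsv", sep="\t", index=False)

    conc_rows = [
        {
            "patient": a.patient_id, "tumor_a": c.tumor_a, "tumor_b": c.tumor_b,
            "chrom": c.chrom, "arm": c.arm,
            "n_shared_informative": c.n_shared_informative,
            "alpha_used": c.alpha_used,
            "concordance": "." if c.concordance is None else repr(c.concordance),
            "verdict": c.verdict,
        }
        for a in analysis.patients
        for c in a.concordance
    ]
    pd.DataFrame(
        conc_rows,
        columns=["patient", "tumor_a", "tumor_b", "chrom", "arm",
                 "n_shared_informative", "alpha_used", "concordance", "verdict"],
    ).to_csv(out / "concordance.tsv", sep="\t", index=False)
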