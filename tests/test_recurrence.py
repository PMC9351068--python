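"""Cohort recurrence tallies, minimal regions and hypergeometric enrichment."""

from fractions import Fraction
from math import comb

import pytest

from clonemap import (
    CnaSegment,
    RecurrenceConfig,
    SmallVariant,
    hypergeom_enrichment,
    minimal_regions,
    mutation_burden,
    recurrent_cnas,
    recurrent_genes,
    recurrent_noncoding,
)
from clonemap.recurrence import classify_segment_scope, hypergeom_enrichment_p


def _var(pos, gene=None, effect=None, region="coding", chrom="chrT", ref="A", alt="T"):
    return SmallVariant(chrom, pos, ref, alt, total_depth=30, gene=gene,
                        effect=effect, region=region)


# ---------------------------------------------------------------------------
# Burden
# ---------------------------------------------------------------------------

def test_burden_zero_and_simple_division():
    assert mutation_burden([], 300.0) == 0.0
    variants = [_var(i) for i in range(1, 91)]
    assert mutation_burden(variants, 300.0) == pytest.approx(0.30)


def test_burden_requires_positive_genome():
    with pytest.raises(ValueError):
        mutation_burden([], 0.0)


# ---------------------------------------------------------------------------
# Recurrent genes
# ---------------------------------------------------------------------------

def test_gene_counts_once_per_patient():
    cohort = {
        "P1": {f"T{i}": [_var(100 + i, "GENE1", "missense")] for i in range(5)},
    }
    table, skipped = recurrent_genes(cohort)
    row = table[table.gene == "GENE1"].iloc[0]
    assert row.n_patients == 1 and row.n_tumors == 5
    assert not row.recurrent_across_patients
    assert skipped == []


def test_silent_only_gene_excluded():
    cohort = {"P1": {"T1": [_var(100, "GENE1", "silent")]}}
    table, _ = recurrent_genes(cohort)
    assert "GENE1" not in set(table.gene)


def test_planted_cross_patient_gene_recovered():
    cohort = {
        f"P{i}": {"T1": [_var(100, "GENE1", "missense")]} for i in range(1, 4)
    }
    table, _ = recurrent_genes(cohort)
    row = table[table.gene == "GENE1"].iloc[0]
    assert row.n_patients == 3 and row.recurrent_across_patients


def test_missing_annotation_audited():
    cohort = {"P1": {"T1": [_var(100, None, None)]}}
    table, skipped = recurrent_genes(cohort)
    assert len(table) == 0 and len(skipped) == 1


def test_patient_count_invariant_to_duplicated_tumor():
    base = {"T1": [_var(100, "GENE1", "missense")]}
    one = recurrent_genes({"P1": base})[0]
    dup = recurrent_genes({"P1": {**base, "T1b": base["T1"]}})[0]
    assert one.iloc[0].n_patients == dup.iloc[0].n_patients == 1


# ---------------------------------------------------------------------------
# Recurrent noncoding
# ---------------------------------------------------------------------------

def test_noncoding_exact_key_rule():
    cohort = {
        "P1": {"T1": [_var(500, region="noncoding", alt="T")]},
        "P2": {"T1": [_var(500, region="noncoding", alt="T")]},
        "P3": {"T1": [_var(500, region="noncoding", alt="G")]},
    }
    table = recurrent_noncoding(cohort)
    assert len(table) == 2  # two distinct (pos, alt) keys
    flagged = table[table.recurrent_across_patients]
    assert len(flagged) == 1
    assert flagged.iloc[0].alt == "T" and flagged.iloc[0].n_patients == 2


def test_planted_noncoding_recurrence_recovered():
    k = 4
    cohort = {
        f"P{i}": {"T1": [_var(777, region="noncoding")]} for i in range(k)
    }
    table = recurrent_noncoding(cohort)
    assert table.iloc[0].n_patients == k


# ---------------------------------------------------------------------------
# Recurrent CNAs
# ---------------------------------------------------------------------------

def test_scope_classification(chrt_genome):
    whole = CnaSegment("chrT", 0, 9_500_000, -0.3, "loss", "S")
    focal = CnaSegment("chrT", 2_000_000, 4_000_000, 0.4, "gain", "S")
    arm = CnaSegment("chrT", 4_500_000, 10_000_000, 0.4, "gain", "S")
    assert classify_segment_scope(whole, chrt_genome) == ("whole", "chrT")
    assert classify_segment_scope(focal, chrt_genome) == ("focal", "chrT")
    assert classify_segment_scope(arm, chrt_genome) == ("arm", "chrTq")


def test_planted_loss_fraction_recovered_exactly(chrt_genome):
    # noise-free plant: 57 of 100 tumors carry a whole-chromosome loss
    cohort = {}
    n_with = 57
    for i in range(100):
        sid = f"T{i}"
        segs = (
            [CnaSegment("chrT", 0, 10_000_000, -0.3, "loss", sid)]
            if i < n_with
            else []
        )
        cohort.setdefault(f"P{i % 10}", {})[sid] = segs
    table = recurrent_cnas(cohort, chrt_genome, n_tumors_total=100)
    row = table[(table.target == "chrT") & (table.direction == "loss")].iloc[0]
    assert row.n_tumors == 57
    assert row.tumor_fraction == pytest.approx(0.57)
    assert row.scope == "whole"


# ---------------------------------------------------------------------------
# Minimal regions
# ---------------------------------------------------------------------------

PATIENT_OF = {"S1": "P1", "S2": "P2", "S3": "P1"}


def test_two_patient_intersection_reported():
    segs = [
        CnaSegment("chrT", 2_000_000, 9_000_000, -0.3, "loss", "S1"),
        CnaSegment("chrT", 5_500_000, 8_000_000, -0.3, "loss", "S2"),
    ]
    (region,) = minimal_regions(segs, PATIENT_OF)
    assert (region.start, region.end) == (5_500_000, 8_000_000)
    assert region.length == 2_500_000
    assert region.n_patients == 2


def test_wide_intersection_not_reported():
    segs = [
        CnaSegment("chrT", 2_000_000, 9_000_000, -0.3, "loss", "S1"),
        CnaSegment("chrT", 2_500_000, 8_500_000, -0.3, "loss", "S2"),
    ]
    assert minimal_regions(segs, PATIENT_OF) == []  # 6 Mb >= 5 Mb cap


def test_single_patient_not_reported():
    segs = [
        CnaSegment("chrT", 2_000_000, 9_000_000, -0.3, "loss", "S1"),
        CnaSegment("chrT", 5_500_000, 8_000_000, -0.3, "loss", "S3"),
    ]
    assert minimal_regions(segs, PATIENT_OF) == []


def test_directions_stratified():
    segs = [
        CnaSegment("chrT", 5_000_000, 8_000_000, -0.3, "loss", "S1"),
        CnaSegment("chrT", 5_500_000, 8_000_000, 0.3, "gain", "S2"),
    ]
    assert minimal_regions(segs, PATIENT_OF) == []


def test_regions_disjoint_and_contained():
    import numpy as np

    rng = np.random.default_rng(5)
    segs = []
    patient_of = {}
    for i in range(40):
        start = int(rng.integers(0, 8_000_000))
        end = start + int(rng.integers(100_000, 2_000_000))
        sid = f"S{i}"
        segs.append(CnaSegment("chrT", start, end, -0.3, "loss", sid))
        patient_of[sid] = f"P{i % 6}"
    regions = minimal_regions(segs, patient_of)
    for a, b in zip(regions, regions[1:]):
        assert a.end <= b.start  # pairwise disjoint
    for r in regions:
        covering = [s for s in segs if s.start <= r.start and s.end >= r.end]
        patients = {patient_of[s.sample_id] for s in covering}
        assert len(patients) >= 2
        assert r.length < 5_000_000


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

def exact_tail(N, K, n, k):
    if k == 0:
        return 1.0
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return float(total)


def test_worked_example():
    # universe 10, pathway 5, mutated 4, overlap 4: C(5,4)C(5,0)/C(10,4)
    assert hypergeom_enrichment_p(10, 5, 4, 4) == pytest.approx(5 / 210, abs=1e-12)


def test_degenerate_cases():
    assert hypergeom_enrichment_p(10, 5, 0, 0) == 1.0  # nothing mutated
    assert hypergeom_enrichment_p(10, 10, 4, 4) == pytest.approx(1.0)  # pathway = universe


def test_matches_enumeration_sampled():
    for N in (5, 10, 17, 25):
        for K in range(N + 1):
            for n in range(0, N + 1, 3):
                for k in range(max(0, n + K - N), min(K, n) + 1):
                    assert hypergeom_enrichment_p(N, K, n, k) == pytest.approx(
                        exact_tail(N, K, n, k), abs=1e-10
                    )


def test_enrichment_table_and_bh():
    universe = {f"g{i}" for i in range(10)}
    pathways = {"PWY1": {f"g{i}" for i in range(5)}, "PWY2": {"g8", "g9"}}
    mutated = {"g0", "g1", "g2", "g3"}
    table = hypergeom_enrichment(mutated, pathways, universe)
    row = table[table.pathway == "PWY1"].iloc[0]
    assert row.p_raw == pytest.approx(5 / 210)
    assert (row.k, row.K, row.n, row.N) == (4, 5, 4, 10)
    assert (table.p_adj >= table.p_raw).all()


def test_empty_universe_and_foreign_genes_rejected():
    with pytest.raises(ValueError):
        hypergeom_enrichment(set(), {}, set())
    with pytest.raises(ValueError):
        hypergeom_enrichment({"x"}, {}, {"a"})
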