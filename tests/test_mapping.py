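"""Chromosome-mapping statistics against exact oracles, and the informative
SNP / concordance machinery on constructed and simulated inputs."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from clonemap import (
    AllelicCount,
    ArmContext,
    CnaEvent,
    CnaSegment,
    MappingConfig,
    adjust_bh,
    binomial_two_sided_p,
    call_informative_snps,
    compare_parental_alleles,
    map_segment,
    select_het_snps,
)
from clonemap.sim import simulate_het_snps, simulate_tumor_allelic_counts


def exact_binomial_p(a: int, b: int) -> float:
    """Minimum-likelihood two-sided p by exact rational enumeration."""
    n = a + b
    p_obs = Fraction(comb(n, a), 2**n)
    return float(
        sum(Fraction(comb(n, k), 2**n) for k in range(n + 1)
            if Fraction(comb(n, k), 2**n) <= p_obs)
    )


# ---------------------------------------------------------------------------
# binomial_two_sided_p
# ---------------------------------------------------------------------------

def test_balanced_counts_give_p_one():
    assert binomial_two_sided_p(10, 10) == 1.0


def test_extreme_outcome_closed_form():
    assert binomial_two_sided_p(20, 0) == pytest.approx(2 * 0.5**20, rel=1e-12)


def test_skewed_example_matches_enumeration():
    assert binomial_two_sided_p(15, 5) == pytest.approx(exact_binomial_p(15, 5), abs=1e-12)
    assert binomial_two_sided_p(15, 5) == pytest.approx(0.04138946533203125, abs=1e-12)


def test_agrees_with_enumeration_oracle_small_totals():
    for n in range(1, 26):
        for a in range(n + 1):
            assert binomial_two_sided_p(a, n - a) == pytest.approx(
                exact_binomial_p(a, n - a), abs=1e-12
            )


def test_symmetry_exhaustive():
    for n in range(1, 51):
        for a in range(n + 1):
            assert binomial_two_sided_p(a, n - a) == binomial_two_sided_p(n - a, a)


def test_zero_total_rejected():
    with pytest.raises(ValueError):
        binomial_two_sided_p(0, 0)


# ---------------------------------------------------------------------------
# adjust_bh
# ---------------------------------------------------------------------------

def bh_reference(pvals):
    """Sort-based BH reference: min over j >= i of p(j) * m / j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    out = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        out[i] = running
    return out


def test_bh_single_value():
    assert adjust_bh([0.03]) == pytest.approx([0.03])


def test_bh_hand_worked_example():
    # step-up on (0.01, 0.02, 0.03, 0.04): every min_j>=i p(j)*4/j is 0.04
    assert adjust_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_all_ones():
    assert adjust_bh([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)


def test_bh_empty():
    assert len(adjust_bh([])) == 0


def test_bh_matches_reference_and_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(0)
    for _ in range(100):
        p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 200)))
        ours = adjust_bh(p)
        assert ours == pytest.approx(bh_reference(list(p)), abs=1e-12)
        assert ours == pytest.approx(multipletests(p, method="fdr_bh")[1], abs=1e-12)


def test_bh_monotone_in_sorted_order():
    rng = np.random.default_rng(1)
    p = rng.uniform(1e-6, 1.0, size=50)
    adj = adjust_bh(p)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)
    assert np.all(adj >= p)


# ---------------------------------------------------------------------------
# select_het_snps
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ref,alt,selected",
    [
        (5, 5, False),  # depth 10: need > 10
        (12, 8, True),  # depth 20, VAF 0.40: inclusive bound
        (8, 12, True),  # VAF 0.60: inclusive bound
        (14, 6, False),  # VAF 0.30
        (0, 0, False),  # depth 0 skipped silently
    ],
)
def test_het_snp_selection(ref, alt, selected):
    counts = [AllelicCount("N", "chrT", 100, ref, alt)]
    het = select_het_snps(counts, MappingConfig())
    assert (("chrT", 100) in het) is selected


# ---------------------------------------------------------------------------
# call_informative_snps
# ---------------------------------------------------------------------------

def _counts(rows):
    return [AllelicCount("T", "chrT", pos, r, a) for pos, r, a in rows]


SEG = CnaSegment("chrT", 0, 4_000_000, -0.3, "loss", "T")
ARM_P = (0, 4_000_000)


def test_depth_10_not_a_candidate():
    counts = _counts([(100, 5, 5)])  # tumor depth 10: need > 10
    het = {("chrT", 100)}
    out = call_informative_snps(counts, het, SEG, ARM_P, 0.05)
    assert out == []


def test_balanced_candidate_never_informative():
    counts = _counts([(100, 30, 30)])
    het = {("chrT", 100)}
    out = call_informative_snps(counts, het, SEG, ARM_P, 0.05)
    assert out == []


def test_constructed_family_exactly_the_skewed_snps():
    # 90 strongly skewed SNPs (40, 8) and 10 balanced (25, 25):
    # p(40,8) ~ 3.6e-6 by enumeration, BH keeps all 90; p=1 SNPs excluded
    rows = [(1000 + i, 40, 8) for i in range(90)] + [
        (5000 + i, 25, 25) for i in range(10)
    ]
    counts = _counts(rows)
    het = {("chrT", pos) for pos, _, _ in rows}
    out = call_informative_snps(counts, het, SEG, ARM_P, 0.05)
    assert len(out) == 90
    assert all(s.ref_count == 40 for s in out)
    assert all(s.major_allele == "REF" for s in out)
    assert binomial_two_sided_p(40, 8) == pytest.approx(exact_binomial_p(40, 8), abs=1e-12)


def test_rejection_monotone_in_alpha():
    rng = np.random.default_rng(2)
    rows = [(i + 1, int(rng.integers(5, 40)), int(rng.integers(5, 40)))
            for i in range(200)]
    counts = _counts(rows)
    het = {("chrT", pos) for pos, _, _ in rows}
    at_05 = {s.pos for s in call_informative_snps(counts, het, SEG, ARM_P, 0.05)}
    at_10 = {s.pos for s in call_informative_snps(counts, het, SEG, ARM_P, 0.1)}
    assert at_05 <= at_10


def test_zero_candidates_is_empty_not_error():
    assert call_informative_snps([], set(), SEG, ARM_P, 0.05) == []


# ---------------------------------------------------------------------------
# compare_parental_alleles
# ---------------------------------------------------------------------------

def _ctx(sample, rows, patient="P1"):
    counts = _counts_for(sample, rows)
    het = {("chrT", pos) for pos, _, _ in rows}
    return ArmContext(patient, sample, "chrT", "p", SEG, ARM_P, counts, het)


def _counts_for(sample, rows):
    return [AllelicCount(sample, "chrT", pos, r, a) for pos, r, a in rows]


def test_fully_concordant_pair_same_allele():
    rows = [(1000 + i, 40, 8) for i in range(50)]
    res = compare_parental_alleles(_ctx("A", rows), _ctx("B", rows))
    assert res.concordance == 1.0
    assert res.verdict == "same_allele"
    assert res.n_shared_informative == 50


def test_fully_discordant_pair_different_allele():
    rows_a = [(1000 + i, 40, 8) for i in range(50)]
    rows_b = [(1000 + i, 8, 40) for i in range(50)]
    res = compare_parental_alleles(_ctx("A", rows_a), _ctx("B", rows_b))
    assert res.concordance == 0.0
    assert res.verdict == "different_allele"


def test_cross_patient_comparison_rejected():
    rows = [(1000, 40, 8)]
    with pytest.raises(ValueError, match="different patients"):
        compare_parental_alleles(_ctx("A", rows, "P1"), _ctx("B", rows, "P2"))


def test_relaxation_triggered_below_1000_shared():
    rows = [(1000 + i, 40, 8) for i in range(800)]
    res = compare_parental_alleles(_ctx("A", rows), _ctx("B", rows))
    assert res.alpha_used == 0.1
    assert res.n_shared_informative == 800


def test_no_relaxation_at_1000_shared():
    rows = [(1000 + i, 40, 8) for i in range(1000)]
    res = compare_parental_alleles(_ctx("A", rows), _ctx("B", rows))
    assert res.alpha_used == 0.05
    assert res.n_shared_informative == 1000


def test_no_call_when_nothing_informative():
    rows = [(1000 + i, 20, 20) for i in range(30)]
    res = compare_parental_alleles(_ctx("A", rows), _ctx("B", rows))
    assert res.verdict == "no_call"
    assert res.n_shared_informative == 0
    assert res.concordance is None


def test_comparison_symmetric():
    rng = np.random.default_rng(3)
    rows_a = [(i + 1, int(rng.integers(0, 50)), int(rng.integers(0, 50)))
              for i in range(100)]
    rows_b = [(i + 1, int(rng.integers(0, 50)), int(rng.integers(0, 50)))
              for i in range(100)]
    ab = compare_parental_alleles(_ctx("A", rows_a), _ctx("B", rows_b))
    ba = compare_parental_alleles(_ctx("B", rows_b), _ctx("A", rows_a))
    assert (ab.n_shared_informative, ab.alpha_used, ab.concordance, ab.verdict) == (
        ba.n_shared_informative, ba.alpha_used, ba.concordance, ba.verdict
    )


# ---------------------------------------------------------------------------
# map_segment on simulated ground truth
# ---------------------------------------------------------------------------

def _retained_hap_fraction(informative, snps_by_pos, direction):
    """Fraction of informative SNPs whose major allele points at haplotype A
    as the retained (loss) / amplified (gain) haplotype."""
    votes_a = 0
    for s in informative:
        snp = snps_by_pos[(s.chrom, s.pos)]
        # major ALT means the ALT-carrying haplotype dominates the reads
        dominant_hap = snp.alt_hap if s.major_allele == "ALT" else (
            "B" if snp.alt_hap == "A" else "A"
        )
        votes_a += dominant_hap == "A"
    return votes_a / len(informative)


def test_whole_chromosome_loss_maps_to_retained_haplotype(toy_genome):
    rng = np.random.default_rng(11)
    snps = simulate_het_snps(toy_genome, 2000, rng)
    event = CnaEvent("chr18", "whole", "loss", "B")  # B lost, A retained
    counts = simulate_tumor_allelic_counts(
        "T", snps, [event], 0.6, 60, 0.01, toy_genome, rng
    )
    seg = CnaSegment("chr18", 0, 10_000_000, -0.25, "loss", "T")
    het = {(s.chrom, s.pos) for s in snps}
    reports = map_segment(counts, het, seg, toy_genome, MappingConfig(), "T")
    assert [r.arm for r in reports] == ["p", "q"]
    snps_by_pos = {(s.chrom, s.pos): s for s in snps}
    for arm in ("p", "q"):
        informative = call_informative_snps(
            counts, het, seg, toy_genome.arm_interval("chr18", arm), 0.05
        )
        assert len(informative) > 100
        assert _retained_hap_fraction(informative, snps_by_pos, "loss") >= 0.99


def test_pq_arms_can_disagree(toy_genome):
    rng = np.random.default_rng(13)
    snps = simulate_het_snps(toy_genome, 2000, rng)
    events = [CnaEvent("chr18", "p", "loss", "A"), CnaEvent("chr18", "q", "loss", "B")]
    counts = simulate_tumor_allelic_counts(
        "T", snps, events, 0.6, 60, 0.01, toy_genome, rng
    )
    seg = CnaSegment("chr18", 0, 10_000_000, -0.25, "loss", "T")
    het = {(s.chrom, s.pos) for s in snps}
    snps_by_pos = {(s.chrom, s.pos): s for s in snps}
    fractions = {}
    for arm in ("p", "q"):
        informative = call_informative_snps(
            counts, het, seg, toy_genome.arm_interval("chr18", arm), 0.05
        )
        fractions[arm] = _retained_hap_fraction(informative, snps_by_pos, "loss")
    # p lost A (B retained), q lost B (A retained): opposite calls
    assert fractions["p"] <= 0.01
    assert fractions["q"] >= 0.99


def test_purity_zero_yields_no_informative_snps(toy_genome):
    rng = np.random.default_rng(17)
    snps = simulate_het_snps(toy_genome, 500, rng)
    event = CnaEvent("chr18", "whole", "loss", "A")
    counts = simulate_tumor_allelic_counts(
        "T", snps, [event], 0.0, 60, 0.0, toy_genome, rng
    )
    seg = CnaSegment("chr18", 0, 10_000_000, -0.25, "loss", "T")
    het = {(s.chrom, s.pos) for s in snps}
    for arm in ("p", "q"):
        informative = call_informative_snps(
            counts, het, seg, toy_genome.arm_interval("chr18", arm), 0.05
        )
        assert informative == []


def test_segment_inside_centromere_gives_no_reports(toy_genome):
    seg = CnaSegment("chr18", 4_450_000, 4_850_000, -0.3, "loss", "T")
    assert map_segment([], set(), seg, toy_genome, MappingConfig(), "T") == []
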