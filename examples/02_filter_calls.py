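"""Apply the post-calling filters to records sitting on each rule's boundary.

Small variants are removed at depth <= 6 reads or population AF > 0.001;
CNA segments need |median logR| past +-0.15 (copy-neutral LOH is exempt),
length >= 10 kb and no interior breakpoint in a centromere or within 1 Mb
of a chromosome end; intrachromosomal SVs need a span >= 10 kb.
"""

from clonemap import (
    Chromosome,
    CnaSegment,
    FilterConfig,
    GenomeConfig,
    SmallVariant,
    filter_cna_segments,
    filter_small_variants,
)

genome = GenomeConfig(
    [Chromosome("chrT", 10_000_000)], {"chrT": (4_000_000, 4_500_000)}
)
config = FilterConfig()

variants = [
    SmallVariant("chrT", 100, "A", "T", total_depth=6, population_af=0.0),
    SmallVariant("chrT", 200, "A", "T", total_depth=7, population_af=0.0),
    SmallVariant("chrT", 300, "C", "G", total_depth=30, population_af=0.002),
    SmallVariant("chrT", 400, "C", "G", total_depth=30, population_af=0.001),
]
kept, audit = filter_small_variants(variants, config)
print("small variants:")
for a in audit:
    v = a.record
    outcome = "kept" if a.kept else f"removed ({a.rule})"
    print(f"  {v.chrom}:{v.pos} depth={v.total_depth} AF={v.population_af}: {outcome}")

segments = [
    CnaSegment("chrT", 2_000_000, 3_999_999, 0.15, "gain", "S1"),
    CnaSegment("chrT", 2_000_000, 3_999_999, 0.16, "gain", "S2"),
    CnaSegment("chrT", 2_000_000, 3_999_999, 0.0, "cn_loh", "S3"),
    CnaSegment("chrT", 0, 10_000_000, -0.3, "loss", "S4"),
]
kept, audit = filter_cna_segments(segments, config, genome)
print("\nCNA segments:")
for a in audit:
    s = a.record
    outcome = "kept" if a.kept else f"removed ({a.rule})"
    print(f"  {s.chrom}:[{s.start},{s.end}) logR={s.median_logr} {s.direction}: {outcome}")

# Note the strict boundaries: logR exactly 0.15 fails the strict '>' rule
# while 0.16 passes; AF exactly 0.001 is kept by the strict '>' removal;
# the whole-chromosome loss survives because its boundaries at the
# chromosome ends are not interior breakpoints.
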