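"""Shared-variant clonality inference within one patient.

Multifocal primaries that arise independently from normal mucosa share
essentially no somatic SNVs/indels, while a metastasis carries most of its
parent primary's variants. Counting exact-key (chrom, pos, ref, alt)
intersections between every tumor pair therefore separates independent
primaries (near-zero sharing) from clonally related pairs, identifies the
putative primary of origin of each metastasis (the primary with dominant
sharing), and classifies dissemination as clonal (all metastases from one
primary) or independent (metastases from several primaries).

Distinct substitutions at the same position are distinct keys: two tumors
with different ALT alleles at one site have converged, not shared, a
mutation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .types import SmallVariant, VariantKey


@dataclass
class ClonalityConfig:
    independence_max_shared_fraction: float = 0.01
    origin_min_shared: int = 5
    origin_dominance_ratio: float = 2.0
    subclonal_check_min_reads: int = 2
    shared_fraction_denominator: str = "min"  # 'min' | 'union'

    def __post_init__(self) -> None:
        if self.origin_min_shared <= 0 or self.independence_max_shared_fraction <= 0:
            raise ValueError("thresholds must be positive")
        if self.origin_dominance_ratio <= 1.0:
            raise ValueError("dominance ratio must be > 1")
        if self.shared_fraction_denominator not in ("min", "union"):
            raise ValueError("denominator must be 'min' or 'union'")


def variant_key_sets(
    variants: Mapping[str, Sequence[SmallVariant]]
) -> dict[str, set[VariantKey]]:
    return {sid: {v.key for v in vs} for sid, vs in variants.items()}


@dataclass
class SharedVariantMatrix:
    """Pairwise shared-variant counts for the tumors of one patient."""

    patient_id: str
    sets: dict[str, set[VariantKey]]
    config: ClonalityConfig = field(default_factory=ClonalityConfig)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.sets)

    def size(self, sample: str) -> int:
        return len(self.sets[sample])

    def shared_keys(self, a: str, b: str) -> set[VariantKey]:
        return self.sets[a] & self.sets[b]

    def shared_count(self, a: str, b: str) -> int:
        return len(self.shared_keys(a, b))

    def shared_fraction(self, a: str, b: str) -> float:
        shared = self.shared_count(a, b)
        if self.config.shared_fraction_denominator == "min":
            denom = min(len(self.sets[a]), len(self.sets[b]))
        else:
            denom = len(self.sets[a] | self.sets[b])
        return shared / denom if denom else 0.0

    def to_rows(self) -> list[dict]:
        rows = []
        for a, b in itertools.combinations(self.sample_ids, 2):
            rows.append(
                {
                    "patient": self.patient_id,
                    "tumor_a": a,
                    "tumor_b": b,
                    "size_a": self.size(a),
                    "size_b": self.size(b),
                    "shared_count": self.shared_count(a, b),
                    "shared_fraction": self.shared_fraction(a, b),
                }
            )
        return rows


def shared_variant_matrix(
    patient_id: str,
    variants: Mapping[str, Sequence[SmallVariant]] | Mapping[str, set[VariantKey]],
    config: Optional[ClonalityConfig] = None,
    patient_of: Optional[Mapping[str, str]] = None,
) -> SharedVariantMatrix:
    """Build the pairwise matrix; at least two tumors, all one patient."""
    if len(variants) < 2:
        raise ValueError("need at least two tumor samples")
    if patient_of is not None:
        foreign = {s for s, p in patient_of.items() if s in variants and p != patient_id}
        if foreign:
            raise ValueError(
                f"samples {sorted(foreign)} do not belong to patient {patient_id}"
            )
    sets: dict[str, set[VariantKey]] = {}
    for sid, vs in variants.items():
        vs = list(vs)
        if vs and isinstance(vs[0], SmallVariant):
            sets[sid] = {v.key for v in vs}
        else:
            sets[sid] = set(vs)
    return SharedVariantMatrix(patient_id, sets, config or ClonalityConfig())


# ---------------------------------------------------------------------------
# Pair classification and metastasis origin
# ---------------------------------------------------------------------------

def classify_primary_pairs(
    matrix: SharedVariantMatrix,
    primary_ids: Sequence[str],
    config: Optional[ClonalityConfig] = None,
) -> dict[tuple[str, str], str]:
    """Each unordered primary pair -> 'independent' | 'clonally_related'.

    Independent iff the shared fraction stays below the independence bound
    AND the absolute shared count stays below the origin threshold.
    """
    config = config or matrix.config
    out = {}
    for a, b in itertools.combinations(sorted(primary_ids), 2):
        independent = (
            matrix.shared_fraction(a, b) < config.independence_max_shared_fraction
            and matrix.shared_count(a, b) < config.origin_min_shared
        )
        out[(a, b)] = "independent" if independent else "clonally_related"
    return out


@dataclass(frozen=True)
class OriginCall:
    metastasis_id: str
    origin_primary_id: Optional[str]
    shared_with_origin: int
    runner_up: int
    evidence: str  # assigned | unassigned_no_sharing | unassigned_ambiguous


def assign_metastasis_origin(
    matrix: SharedVariantMatrix,
    metastasis_id: str,
    primary_ids: Sequence[str],
    config: Optional[ClonalityConfig] = None,
) -> OriginCall:
    """Assign the primary with dominant sharing as the origin.

    Assigned iff the best primary shares at least ``origin_min_shared``
    variants and at least ``origin_dominance_ratio`` times the runner-up.
    Zero sharing with every primary is reported as unassigned_no_sharing —
    interpretable as an origin among unsequenced primaries.
    """
    config = config or matrix.config
    if not primary_ids:
        raise ValueError("no primary tumors to compare against")
    counts = sorted(
        ((matrix.shared_count(metastasis_id, p), p) for p in primary_ids),
        key=lambda t: (-t[0], t[1]),
    )
    best_count, best_primary = counts[0]
    runner_up = counts[1][0] if len(counts) > 1 else 0
    if best_count == 0:
        return OriginCall(metastasis_id, None, 0, 0, "unassigned_no_sharing")
    if best_count < config.origin_min_shared or best_count < config.origin_dominance_ratio * runner_up:
        return OriginCall(
            metastasis_id, None, best_count, runner_up, "unassigned_ambiguous"
        )
    return OriginCall(metastasis_id, best_primary, best_count, runner_up, "assigned")


def classify_dissemination(origin_calls: Sequence[OriginCall]) -> str:
    """'clonal' | 'independent' | 'mixed_unassigned' for one patient.

    A clonal/independent verdict needs at least two assigned metastases:
    clonal when all assigned metastases share one origin, independent when
    at least two distinct origins appear.
    """
    origins = {c.origin_primary_id for c in origin_calls if c.evidence == "assigned"}
    n_assigned = sum(1 for c in origin_calls if c.evidence == "assigned")
    if n_assigned >= 2 and len(origins) == 1:
        return "clonal"
    if len(origins) >= 2:
        return "independent"
    return "mixed_unassigned"


# ---------------------------------------------------------------------------
# Subclonal presence check
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubclonalSupport:
    variant_key: VariantKey
    sample_id: str
    alt_reads: Optional[int]  # None when no evidence row exists
    called: bool
    status: str  # supported | not_supported | no_data


def check_subclonal_presence(
    shared_keys: Sequence[VariantKey],
    evidence: Mapping[str, Mapping[VariantKey, tuple[int, int]]],
    called_sets: Mapping[str, set[VariantKey]],
    config: Optional[ClonalityConfig] = None,
) -> list[SubclonalSupport]:
    """Audit read support for shared variants in every tumor of the patient.

    A tumor with >= ``subclonal_check_min_reads`` ALT reads at a shared
    variant's position is flagged supported even when the variant was not
    called there; a missing evidence row is flagged no_data, never assumed
    absent. The audit does not change matrix counts (see
    :func:`promote_supported_variants` for the opt-in promotion).
    """
    config = config or ClonalityConfig()
    rows = []
    for key in shared_keys:
        for sid in sorted(called_sets):
            ev = evidence.get(sid, {}).get(key)
            called = key in called_sets[sid]
            if ev is None:
                rows.append(SubclonalSupport(key, sid, None, called, "no_data"))
                continue
            alt = ev[1]
            status = (
                "supported" if alt >= config.subclonal_check_min_reads else "not_supported"
            )
            rows.append(SubclonalSupport(key, sid, alt, called, status))
    return rows


def promote_supported_variants(
    matrix: SharedVariantMatrix,
    support: Sequence[SubclonalSupport],
) -> SharedVariantMatrix:
    """Return a new matrix with supported-but-uncalled variants promoted
    into the supporting tumor's set; shared counts never decrease."""
    new_sets = {sid: set(keys) for sid, keys in matrix.sets.items()}
    for row in support:
        if row.status == "supported" and row.sample_id in new_sets:
            new_sets[row.sample_id].add(row.variant_key)
    return SharedVariantMatrix(matrix.patient_id, new_sets, matrix.config)
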