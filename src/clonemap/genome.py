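"""Genome coordinate frame: chromosome lengths, centromeres, arm boundaries.

All in-memory coordinates in this package are 0-based half-open; file
formats that use other conventions (VCF, SEG) convert at the I/O boundary.
The p arm of a chromosome is ``[0, centromere_start)`` and the q arm is
``[centromere_end, length)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml


class GenomeConfigError(ValueError):
    """Raised when a genome configuration violates its invariants."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int


@dataclass
class GenomeConfig:
    """Ordered chromosomes with centromere intervals.

    Parameters
    ----------
    chromosomes
        Ordered ``Chromosome`` records; names must be unique, lengths > 0.
    centromeres
        Map chromosome name -> ``(start, end)`` half-open interval, strictly
        inside the chromosome. Every chromosome must have one.
    """

    chromosomes: list[Chromosome]
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise GenomeConfigError(f"duplicate chromosome names: {dup}")
        for c in self.chromosomes:
            if c.length <= 0:
                raise GenomeConfigError(f"chromosome {c.name}: length must be > 0")
            if c.name not in self.centromeres:
                raise GenomeConfigError(f"missing centromere for chromosome {c.name}")
            start, end = self.centromeres[c.name]
            if not (0 < start < end < c.length):
                raise GenomeConfigError(
                    f"chromosome {c.name}: centromere [{start}, {end}) must lie "
                    f"strictly inside (0, {c.length})"
                )

    # -- lookups -----------------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def length(self, chrom: str) -> int:
        for c in self.chromosomes:
            if c.name == chrom:
                return c.length
        raise KeyError(f"unknown chromosome {chrom!r}")

    def __contains__(self, chrom: str) -> bool:
        return any(c.name == chrom for c in self.chromosomes)

    def centromere(self, chrom: str) -> tuple[int, int]:
        self.length(chrom)  # raises on unknown
        return self.centromeres[chrom]

    def arm_interval(self, chrom: str, arm: str) -> tuple[int, int]:
        """Half-open interval of arm ``'p'`` or ``'q'``."""
        cen_start, cen_end = self.centromere(chrom)
        if arm == "p":
            return (0, cen_start)
        if arm == "q":
            return (cen_end, self.length(chrom))
        raise ValueError(f"arm must be 'p' or 'q', got {arm!r}")

    def arms(self) -> Iterable[tuple[str, str, tuple[int, int]]]:
        for c in self.chromosomes:
            for arm in ("p", "q"):
                yield c.name, arm, self.arm_interval(c.name, arm)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    @property
    def genome_mb(self) -> float:
        return self.total_length / 1e6

    # -- (de)serialisation -------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeConfig":
        try:
            chroms = [Chromosome(str(c["name"]), int(c["length"])) for c in d["chromosomes"]]
            cens = {
                str(name): (int(iv[0]), int(iv[1]))
                for name, iv in d.get("centromeres", {}).items()
            }
        except (KeyError, TypeError, IndexError) as exc:
            raise GenomeConfigError(f"malformed genome configuration: {exc}") from exc
        return cls(chromosomes=chroms, centromeres=cens)

    def to_dict(self) -> dict:
        return {
            "chromosomes": [{"name": c.name, "length": c.length} for c in self.chromosomes],
            "centromeres": {k: list(v) for k, v in self.centromeres.items()},
        }


def load_genome_config(path: str | Path) -> GenomeConfig:
    """Load a genome configuration from YAML or JSON."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise GenomeConfigError(f"{path}: expected a mapping at top level")
    return GenomeConfig.from_dict(data)


def save_genome_config(genome: GenomeConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(genome.to_dict(), sort_keys=True))
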