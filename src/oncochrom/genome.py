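"""Genome assembly description: named chromosomes split into autosomes and a single X."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError

AUTOSOME = "autosome"
X = "X"


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    chrom_class: str  # AUTOSOME or X

    def __post_init__(self):
        if self.length <= 0:
            raise ConfigurationError(
                f"chromosome {self.name!r} has non-positive length {self.length}"
            )
        if self.chrom_class not in (AUTOSOME, X):
            raise ConfigurationError(
                f"chromosome {self.name!r} has unknown class {self.chrom_class!r}"
            )

    @property
    def is_x(self) -> bool:
        return self.chrom_class == X


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered chromosomes with exactly one X and at least one autosome."""

    chromosomes: tuple[Chromosome, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.chromosomes:
            raise ConfigurationError("assembly must contain at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate chromosome names in {names}")
        n_x = sum(c.is_x for c in self.chromosomes)
        if n_x != 1:
            raise ConfigurationError(f"assembly must have exactly one X chromosome, got {n_x}")
        if len(self.chromosomes) - n_x < 1:
            raise ConfigurationError("assembly must have at least one autosome")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def __iter__(self):
        return iter(self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    def length(self, name: str) -> int:
        return self.chromosome(name).length

    def autosome_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes if not c.is_x)

    def x_name(self) -> str:
        return next(c.name for c in self.chromosomes if c.is_x)

    def n_bins(self, name: str, bin_size: int) -> int:
        # trailing partial bins are real bins
        return -(-self.length(name) // bin_size)
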