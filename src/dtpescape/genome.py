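"""Toy genome description used by the synthetic-data generators.

A :class:`GenomeSpec` is a minimal stand-in for a reference genome: an
ordered set of named chromosomes with lengths and a baseline copy number
(ploidy) per chromosome.  Aneuploid baselines are supported by passing
per-chromosome ploidies.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeSpec", "gen_genome"]


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosomes with lengths (bp) and baseline copy numbers.

    Parameters
    ----------
    chromosomes
        Ordered list of ``(name, length_bp)`` tuples. Names must be unique
        and lengths positive.
    ploidy
        Baseline copy number. Either a single integer applied to every
        chromosome or a tuple with one entry per chromosome.
    """

    chromosomes: tuple[tuple[str, int], ...]
    ploidy: tuple[int, ...] = field(default=())

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("genome needs at least one chromosome")
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for n, ln in self.chromosomes:
            if ln <= 0:
                raise ValueError(f"chromosome {n!r} has non-positive length {ln}")
        if not self.ploidy:
            object.__setattr__(self, "ploidy", tuple(2 for _ in self.chromosomes))
        elif len(self.ploidy) != len(self.chromosomes):
            raise ValueError("ploidy must have one entry per chromosome")
        if any(p < 0 for p in self.ploidy):
            raise ValueError("ploidy must be non-negative")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {n: ln for n, ln in self.chromosomes}

    def ploidy_of(self, chrom: str) -> int:
        return dict(zip(self.names, self.ploidy))[chrom]

    @property
    def total_length(self) -> int:
        return int(sum(ln for _, ln in self.chromosomes))

    def contains(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) lies within chromosome ``chrom``."""
        ln = self.lengths.get(chrom)
        return ln is not None and 0 <= start < end <= ln


def gen_genome(
    n_chroms: int,
    chrom_length: int | float,
    ploidy: int | tuple[int, ...] = 2,
    seed: int | None = None,
) -> GenomeSpec:
    """Build a genome of ``n_chroms`` equal-length chromosomes.

    ``seed`` is accepted for interface symmetry with the stochastic
    generators; the construction itself is deterministic.
    """
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    chrom_length = int(chrom_length)
    if chrom_length < 1:
        raise ValueError("chrom_length must be >= 1")
    del seed  # deterministic construction
    names = [f"chr{i + 1}" for i in range(int(n_chroms))]
    if np.isscalar(ploidy):
        ploidies = tuple(int(ploidy) for _ in names)
    else:
        ploidies = tuple(int(p) for p in ploidy)
    return GenomeSpec(
        chromosomes=tuple((n, chrom_length) for n in names), ploidy=ploidies
    )
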