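"""Karyotype arithmetic and the registry of *Clonopsis* chromosome numbers.

The Moroccan *Clonopsis* complex forms a numerical polyploid series on a
haploid base of n = 18: *C. felicitatis* is diploid (cn = 36/35, XX/X0),
*C. gallica* triploid (cn = 54) and *C. soumiae* tetraploid (cn = 72).  A
:class:`Karyotype` records how many copies of each of the n homologous groups
an individual carries; the X chromosome is one designated group among them,
so X0 males simply hold one fewer copy at that group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "Karyotype",
    "SpeciesRecord",
    "species_registry",
    "total_cn",
    "ploidy_class",
]

#: haploid chromosome number of the Clonopsis polyploid series
HAPLOID_N = 18

_PLOIDY_LABELS = {1: "haploid", 2: "diploid", 3: "triploid", 4: "tetraploid"}


@dataclass(frozen=True)
class Karyotype:
    """Per-homologous-group chromosome copy counts.

    Parameters
    ----------
    copies
        Copy count of each homologous group, ordered by group index
        (group 1 first).  All counts must be non-negative.
    x_index
        1-based index of the X-bearing group.  Defaults to the last group,
        matching the convention that n = 18 counts the X.
    origin_labels
        Optional parental-genome label per haploid set (e.g. ``("P1", "P2")``
        for a species hybrid).  Purely numerical simulations may omit it.
    """

    copies: tuple[int, ...]
    x_index: int = 0  # 0 means "last group"; resolved in __post_init__
    origin_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.copies) < 1:
            raise ValueError("karyotype needs at least one homologous group")
        if any(c < 0 for c in self.copies):
            raise ValueError("copy counts must be non-negative")
        object.__setattr__(self, "copies", tuple(int(c) for c in self.copies))
        x = self.x_index if self.x_index else len(self.copies)
        if not 1 <= x <= len(self.copies):
            raise ValueError(f"x_index {x} outside 1..{len(self.copies)}")
        object.__setattr__(self, "x_index", x)

    @classmethod
    def uniform(
        cls,
        n_groups: int = HAPLOID_N,
        copy_count: int = 2,
        x_index: int = 0,
        origin_labels: Sequence[str] | None = None,
    ) -> "Karyotype":
        """A karyotype with the same copy count at every group."""
        labels = tuple(origin_labels) if origin_labels is not None else None
        return cls((copy_count,) * n_groups, x_index=x_index, origin_labels=labels)

    @property
    def n_groups(self) -> int:
        return len(self.copies)

    @property
    def cn(self) -> int:
        """Total chromosome number."""
        return sum(self.copies)

    @property
    def sex_copies(self) -> int:
        """Copy count of the X-bearing group."""
        return self.copies[self.x_index - 1]

    @property
    def group_copies(self) -> Mapping[int, int]:
        """Mapping group index (1-based) -> copy count."""
        return {i + 1: c for i, c in enumerate(self.copies)}

    def with_group(self, group_index: int, copy_count: int) -> "Karyotype":
        """Copy of this karyotype with one group's count replaced."""
        if not 1 <= group_index <= self.n_groups:
            raise ValueError(f"group {group_index} outside 1..{self.n_groups}")
        new = list(self.copies)
        new[group_index - 1] = int(copy_count)
        return Karyotype(tuple(new), x_index=self.x_index,
                         origin_labels=self.origin_labels)

    def to_table(self) -> str:
        """CSV table 'group,copies' (one row per homologous group)."""
        lines = ["group,copies"]
        lines += [f"{i + 1},{c}" for i, c in enumerate(self.copies)]
        return "\n".join(lines) + "\n"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"Karyotype(cn={self.cn}, n_groups={self.n_groups}, X×{self.sex_copies})"


def total_cn(k: Karyotype) -> int:
    """Total chromosome number: sum of copy counts over all groups."""
    return k.cn


def ploidy_class(k: Karyotype) -> str:
    """Classify a karyotype as haploid/diploid/triploid/tetraploid/aneuploid.

    A uniform copy count c in 1..4 maps to the c-ploid label; any non-uniform
    profile (and uniform counts outside that range) is ``aneuploid``.
    """
    counts = set(k.copies)
    if len(counts) == 1:
        (c,) = counts
        if c in _PLOIDY_LABELS:
            return _PLOIDY_LABELS[c]
    return "aneuploid"


@dataclass(frozen=True)
class SpeciesRecord:
    """Chromosome numbers and reproductive mode of one *Clonopsis* taxon.

    ``female_cn`` is absent for the androgenetic male clones, which have no
    female karyotype; for bisexual (XX/X0) taxa ``male_cn = female_cn - 1``.
    """

    name: str
    female_cn: int | None
    male_cn: int | None = None
    reproductive_mode: str = "bisexual"

    def __post_init__(self) -> None:
        if self.reproductive_mode not in {"bisexual", "parthenogenetic", "androgenetic"}:
            raise ValueError(f"unknown reproductive mode {self.reproductive_mode!r}")
        if (
            self.reproductive_mode == "bisexual"
            and self.male_cn is not None
            and self.female_cn is not None
            and self.male_cn != self.female_cn - 1
        ):
            raise ValueError("X0 males must have cn = female cn - 1")


_REGISTRY: tuple[SpeciesRecord, ...] = (
    SpeciesRecord("C. maroccana", 22, 21, "bisexual"),
    SpeciesRecord("C. algerica", 32, 31, "bisexual"),
    SpeciesRecord("C. felicitatis", 36, 35, "bisexual"),
    SpeciesRecord("C. gallica", 54, None, "parthenogenetic"),
    SpeciesRecord("C. soumiae", 72, None, "parthenogenetic"),
    SpeciesRecord("C. androgenes-35", None, 35, "androgenetic"),
    SpeciesRecord("C. androgenes-53", None, 53, "androgenetic"),
)


def species_registry() -> tuple[SpeciesRecord, ...]:
    """All *Clonopsis* taxa with their chromosome numbers.

    The diploid/triploid/tetraploid series (36, 54, 72) sits on the haploid
    base n = 18; the two androgenetic male clones carry cn = 35 and cn = 53.
    """
    return _REGISTRY


def registry_lookup(name: str) -> SpeciesRecord:
    """Fetch one registry record by exact species name."""
    for rec in _REGISTRY:
        if rec.name == name:
            return rec
    raise KeyError(f"no Clonopsis record named {name!r}")


def registry_to_json() -> str:
    """Serialize the species registry as a JSON array."""
    return json.dumps(
        [
            {
                "name": r.name,
                "female_cn": r.female_cn,
                "male_cn": r.male_cn,
                "reproductive_mode": r.reproductive_mode,
            }
            for r in _REGISTRY
        ],
        indent=2,
    )
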