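"""Meiosis of the intermediate triploid female: trivalent segregation,
anaphasic restitution, and the egg karyotypes they produce.

In a triploid oocyte each of the n homologous groups forms a trivalent that
segregates 2:1 — two chromosomes to one pole, the third to the other — with
each orientation equally likely and independent across trivalents.  Writing
m for the number of trivalents whose doubled complement reaches the oocyte-II
pole, the oocyte II carries n + m chromosomes and m is Binomial(n, 1/2).

Two outcomes matter for the origin of *Clonopsis* parthenogens:

* scheme A (m = n or m = 0 at the sister pole): one meiotic product receives
  two complete chromosome series; after anaphasic restitution (retention of
  the second polar body, doubling the complement) the egg is tetraploid with
  every chromosome in pairs — the cn = 72 *C. soumiae* constitution.  For
  n = 18 this happens with probability 2·(1/2)^18 ≈ 7.63×10⁻⁴ %.
* scheme B (m = n/2): half the groups doubled, half single; restitution
  yields a numerically triploid egg whose karyotype still looks diploid —
  the cn = 54 *C. gallica* constitution, probability ≈ 18.5 % for n = 18.

Androgenetic male karyotypes (cn = 53 by X loss from a 54 egg; cn = 35 by
X mis-segregation without restitution, or by direct hybridization) are
derived by :func:`derive_androgen`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from clonosim._rng import substream
from clonosim.karyotype import HAPLOID_N, Karyotype

__all__ = [
    "SegregationPattern",
    "Egg",
    "exact_m_distribution",
    "prob_scheme_A",
    "prob_scheme_B",
    "segregate",
    "apply_restitution",
    "classify_egg",
    "simulate_eggs",
    "derive_androgen",
    "SimulationResult",
]

EggClass = Literal[
    "soumiae_like", "gallica_like", "diploid_like", "other_aneuploid", "male_35_like"
]


@dataclass(frozen=True)
class SegregationPattern:
    """Orientation of every trivalent at meiosis I.

    ``to_oocyte_two[i]`` is True when trivalent i sends its doubled
    complement (two chromosomes) to the oocyte-II pole, False when the
    doubled complement goes to the first polocyte.
    """

    to_oocyte_two: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.to_oocyte_two) < 1:
            raise ValueError("pattern needs at least one trivalent")
        object.__setattr__(
            self, "to_oocyte_two", tuple(bool(f) for f in self.to_oocyte_two)
        )

    @property
    def n_trivalents(self) -> int:
        return len(self.to_oocyte_two)

    @property
    def m(self) -> int:
        """Number of doubled complements delivered to the oocyte-II pole."""
        return sum(self.to_oocyte_two)


@dataclass(frozen=True)
class Egg:
    """A post-meiotic egg: karyotype, restitution flag and class label."""

    karyotype: Karyotype
    restitution_applied: bool
    egg_class: str

    @property
    def cn(self) -> int:
        return self.karyotype.cn


def _check_n(n_trivalents: int) -> None:
    if n_trivalents < 1:
        raise ValueError(f"n_trivalents must be >= 1, got {n_trivalents}")


def exact_m_distribution(n_trivalents: int) -> dict[int, float]:
    """Exact distribution of m, the doubled complements at the oocyte pole.

    With fair, independent 2:1 orientations, m ~ Binomial(n_trivalents, 1/2).
    Returns the full probability mass function as ``{m: probability}``.
    """
    _check_n(n_trivalents)
    ms = np.arange(n_trivalents + 1)
    pmf = stats.binom.pmf(ms, n_trivalents, 0.5)
    return {int(m): float(p) for m, p in zip(ms, pmf)}


def prob_scheme_A(n_trivalents: int) -> float:
    """Probability that some meiotic product gets two complete series.

    All trivalents must orient concordantly; either pole may be the one
    receiving the doubled complements, hence the factor 2: 2·(1/2)^n.
    For n = 18 this is 7.629×10⁻⁶, i.e. 7.63×10⁻⁴ % of eggs.
    """
    _check_n(n_trivalents)
    return float(min(1.0, 2.0 * 0.5 ** n_trivalents))


def prob_scheme_B(n_trivalents: int) -> float:
    """Probability that exactly half the trivalents double toward the oocyte.

    Defined for even n only; equals the Binomial(n, 1/2) mass at n/2.
    For n = 18: C(18,9)/2^18 ≈ 0.18547 (the 18.5 % egg class).
    """
    _check_n(n_trivalents)
    if n_trivalents % 2:
        raise ValueError("scheme B needs an even number of trivalents")
    return exact_m_distribution(n_trivalents)[n_trivalents // 2]


def segregate(pattern: SegregationPattern, x_index: int = 0) -> Karyotype:
    """Oocyte-II karyotype produced by one meiosis-I segregation.

    The source is a triploid (three copies per group); each group ends up
    with 2 copies where the flag points to the oocyte pole and 1 elsewhere,
    for a total of n + m chromosomes.
    """
    copies = tuple(2 if f else 1 for f in pattern.to_oocyte_two)
    return Karyotype(copies, x_index=x_index)


def apply_restitution(oocyte: Karyotype) -> Egg:
    """Anaphasic restitution: retain the second polocyte, doubling every group.

    A cytologically normal second division followed by restitution leaves the
    egg with twice the oocyte-II complement, so every copy count is even and
    the karyotype pairs up into a diploid look regardless of actual ploidy.
    """
    doubled = Karyotype(
        tuple(2 * c for c in oocyte.copies),
        x_index=oocyte.x_index,
        origin_labels=oocyte.origin_labels,
    )
    egg = Egg(doubled, restitution_applied=True, egg_class="")
    return Egg(doubled, True, classify_egg(egg))


def classify_egg(egg: Egg) -> str:
    """Label an egg by the surviving *Clonopsis* constitutions.

    * ``soumiae_like``: cn = 72-type, every group ×4 (scheme A + restitution);
    * ``gallica_like``: cn = 54-type, half the groups ×4 and half ×2
      (scheme B + restitution);
    * ``diploid_like``: uniform ×2 (m = 0 then restitution);
    * ``male_35_like``: all autosomes ×2 with a single X and no restitution;
    * ``other_aneuploid``: everything else.
    """
    k = egg.karyotype
    counts = k.copies
    n = k.n_groups
    if all(c == 4 for c in counts):
        return "soumiae_like"
    if n % 2 == 0:
        n4 = sum(1 for c in counts if c == 4)
        n2 = sum(1 for c in counts if c == 2)
        if n4 == n2 == n // 2:
            return "gallica_like"
    if all(c == 2 for c in counts):
        return "diploid_like"
    if (
        not egg.restitution_applied
        and k.sex_copies == 1
        and all(c == 2 for i, c in enumerate(counts) if i != k.x_index - 1)
    ):
        return "male_35_like"
    return "other_aneuploid"


@dataclass(frozen=True)
class SimulationResult:
    """Outcome of a Monte-Carlo egg simulation."""

    n_trivalents: int
    n_eggs: int
    class_freq: dict[str, float]
    m_counts: np.ndarray  # length n_trivalents + 1
    eggs: tuple[Egg, ...] | None = None

    def summary_table(self) -> pd.DataFrame:
        """Per-m table: cn after restitution, class, exact and simulated freq."""
        n = self.n_trivalents
        exact = exact_m_distribution(n)
        rows = []
        for m in range(n + 1):
            karyo = Karyotype((4,) * m + (2,) * (n - m))
            cls = classify_egg(Egg(karyo, True, ""))
            rows.append(
                {
                    "m": m,
                    "cn": 2 * (n + m),
                    "class": cls,
                    "exact_prob": exact[m],
                    "sim_freq": self.m_counts[m] / self.n_eggs,
                }
            )
        return pd.DataFrame(rows)


def simulate_eggs(
    n_trivalents: int,
    n_eggs: int,
    seed: int,
    return_eggs: bool = False,
) -> SimulationResult:
    """Monte-Carlo meiosis: independent uniform segregation patterns per egg.

    Each egg draws a fresh orientation per trivalent (fair coin), segregates,
    and undergoes anaphasic restitution.  Class frequencies converge on the
    Binomial(n, 1/2) predictions; results are reproducible given the seed.
    """
    _check_n(n_trivalents)
    if n_eggs < 1:
        raise ValueError(f"n_eggs must be >= 1, got {n_eggs}")
    rng = substream(seed, "meiosis.simulate_eggs")
    flags = rng.random((n_eggs, n_trivalents)) < 0.5
    m_values = flags.sum(axis=1)
    m_counts = np.bincount(m_values, minlength=n_trivalents + 1)

    n = n_trivalents
    class_counts: dict[str, int] = {
        "soumiae_like": int(m_counts[n]),
        "gallica_like": int(m_counts[n // 2]) if n % 2 == 0 else 0,
        "diploid_like": int(m_counts[0]),
    }
    class_counts["other_aneuploid"] = n_eggs - sum(class_counts.values())
    class_freq = {c: cnt / n_eggs for c, cnt in class_counts.items()}

    eggs = None
    if return_eggs:
        eggs = tuple(
            apply_restitution(segregate(SegregationPattern(tuple(row))))
            for row in flags
        )
    return SimulationResult(n, n_eggs, class_freq, m_counts, eggs)


def derive_androgen(
    source: Karyotype,
    mode: Literal["x_loss", "scheme_A_mis_segregation", "direct_hybrid"],
) -> Karyotype:
    """Derive an X0 male karyotype from a female source.

    * ``x_loss``: accidental loss of one X — decrement the X group.  From a
      54-chromosome *C. gallica*-like genome this starts the cn = 53
      androgenetic clone.
    * ``scheme_A_mis_segregation``: the 17 autosomal trivalents of the
      triploid female segregate concordantly (doubled complements to one
      pole) while the X trivalent delivers a single X; no restitution
      follows, so the product is all autosomes ×2 plus one X (cn = 35).
    * ``direct_hybrid``: a diploid species hybrid that is male (X0) from the
      start — uniform ×2 with a single X (cn = 35 for n = 18).
    """
    if mode == "x_loss":
        if source.sex_copies < 1:
            raise ValueError("cannot lose an X from an X-free karyotype")
        return source.with_group(source.x_index, source.sex_copies - 1)
    if mode == "scheme_A_mis_segregation":
        if any(c != 3 for c in source.copies):
            raise ValueError("scheme-A mis-segregation requires a triploid source")
        male = Karyotype.uniform(source.n_groups, 2, x_index=source.x_index)
        return male.with_group(male.x_index, 1)
    if mode == "direct_hybrid":
        if any(c != 2 for c in source.copies):
            raise ValueError("direct hybridization mode requires a diploid source")
        return source.with_group(source.x_index, 1)
    raise ValueError(f"unknown androgenesis mode {mode!r}")
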