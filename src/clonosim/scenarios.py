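"""Origin scenarios: building the individuals that feed the meiosis model.

The hypothesised route to the *Clonopsis* parthenogens starts from a diploid
species (or race) hybrid.  Altered meiosis — pre-, intra- or post-meiotic
restitution — lets such a hybrid produce diploid gametes; the fusion of a
haploid and a diploid gamete (syngamy), or sperm-only development inside a
foreign egg (androgenesis), then yields the "intermediate triploid female".
Nuclear origin labels and the mtDNA lineage are tracked separately because
androgenesis decouples them: the embryo keeps the egg mother's mitochondria
while inheriting no nuclear set from her.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from clonosim.karyotype import HAPLOID_N, Karyotype

__all__ = [
    "Individual",
    "Gamete",
    "make_diploid_hybrid",
    "make_gamete",
    "fuse",
    "make_triploid_female",
    "run_scenario",
]


@dataclass(frozen=True)
class Individual:
    """An organism with karyotype, nuclear haploid-set labels and mtDNA lineage."""

    karyotype: Karyotype
    nuclear_origin: tuple[str, ...]  # one label per haploid set (multiset)
    mtdna_label: str
    sex: Literal["female", "male"] = "female"

    def __post_init__(self) -> None:
        modal = _modal_copy(self.karyotype)
        if len(self.nuclear_origin) != modal:
            raise ValueError(
                f"{len(self.nuclear_origin)} haploid-set labels for a karyotype "
                f"with modal copy count {modal}"
            )

    @property
    def cn(self) -> int:
        return self.karyotype.cn


@dataclass(frozen=True)
class Gamete:
    """A meiotic (or restitution) product carrying whole haploid sets."""

    karyotype: Karyotype
    ploidy: Literal["haploid", "diploid"]
    origin: Literal["egg", "sperm"]
    parent_labels: tuple[str, ...]
    mtdna_label: str | None = None  # carried only by eggs

    def __post_init__(self) -> None:
        want = 1 if self.ploidy == "haploid" else 2
        if any(c != want for c in self.karyotype.copies):
            raise ValueError(f"{self.ploidy} gamete must be uniform ×{want}")

    @property
    def cn(self) -> int:
        return self.karyotype.cn


def _modal_copy(k: Karyotype) -> int:
    counts = sorted(k.copies)
    return counts[len(counts) // 2]


def make_diploid_hybrid(
    p1_label: str, p2_label: str, n_groups: int = HAPLOID_N,
    mtdna_label: str | None = None,
) -> Individual:
    """A diploid F1: two complete chromosome series, one per parental label.

    Identical labels are allowed (race-level crosses or non-hybrid controls).
    The mtDNA lineage defaults to the first parent, taken as the egg mother.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    karyo = Karyotype.uniform(n_groups, 2, origin_labels=(p1_label, p2_label))
    return Individual(
        karyo, (p1_label, p2_label), mtdna_label if mtdna_label is not None else p1_label
    )


def make_gamete(
    parent: Individual,
    mechanism: Literal["normal_haploid", "premeiotic", "intrameiotic", "postmeiotic"],
    origin: Literal["egg", "sperm"] = "egg",
) -> Gamete:
    """One gamete from a diploid parent.

    ``normal_haploid`` passes a single full set (labelled by the parent's
    first haploid set, a bookkeeping convention — whole-set transmission,
    no recombination).  Any of the three restitution mechanisms (pre-,
    intra- or post-meiotic endomitosis) yields the same product: a diploid
    gamete carrying the parent's full complement.
    """
    if any(c != 2 for c in parent.karyotype.copies):
        raise ValueError("gamete formation is modelled for diploid parents only")
    n = parent.karyotype.n_groups
    mtdna = parent.mtdna_label if origin == "egg" else None
    if mechanism == "normal_haploid":
        karyo = Karyotype.uniform(n, 1, origin_labels=parent.nuclear_origin[:1])
        return Gamete(karyo, "haploid", origin, parent.nuclear_origin[:1], mtdna)
    if mechanism in ("premeiotic", "intrameiotic", "postmeiotic"):
        karyo = Karyotype.uniform(n, 2, origin_labels=parent.nuclear_origin)
        return Gamete(karyo, "diploid", origin, parent.nuclear_origin, mtdna)
    raise ValueError(f"unknown gamete mechanism {mechanism!r}")


def fuse(
    egg: Gamete,
    sperm: Sequence[Gamete],
    mode: Literal["syngamy", "androgenesis"],
    sex: Literal["female", "male"] = "female",
) -> Individual:
    """Fertilisation: syngamy or androgenetic (sperm-only) development.

    Syngamy sums the egg's and the single sperm's haploid sets.  Under
    androgenesis the egg pronucleus contributes nothing: one sperm's
    complement is doubled, or two-plus sperm heads fuse (stick-insect eggs
    are polyspermic).  Either way the offspring keeps the egg's mtDNA.
    """
    if len(sperm) == 0:
        raise ValueError("at least one sperm is required")
    n = egg.karyotype.n_groups
    if any(s.karyotype.n_groups != n for s in sperm):
        raise ValueError("all gametes must share the same group count")
    if egg.origin != "egg":
        raise ValueError("the egg argument must be an egg-origin gamete")
    egg_mtdna = egg.mtdna_label if egg.mtdna_label is not None else (
        egg.parent_labels[0] if egg.parent_labels else "maternal"
    )

    if mode == "syngamy":
        if len(sperm) != 1:
            raise ValueError("syngamy takes exactly one sperm")
        labels = tuple(egg.parent_labels) + tuple(sperm[0].parent_labels)
    elif mode == "androgenesis":
        if len(sperm) == 1:
            labels = tuple(sperm[0].parent_labels) * 2
        else:
            labels = tuple(l for s in sperm for l in s.parent_labels)
    else:
        raise ValueError(f"unknown fusion mode {mode!r}")

    karyo = Karyotype.uniform(n, len(labels), origin_labels=labels)
    return Individual(karyo, labels, egg_mtdna, sex=sex)


def make_triploid_female(
    mode: Literal["syngamy", "androgenesis"],
    labels: Sequence[str],
    mtdna_label: str,
    n_groups: int = HAPLOID_N,
) -> Individual:
    """The intermediate triploid female (uniform ×3, cn = 3n).

    ``labels`` names the three haploid sets; under androgenesis they are all
    paternal while the mtDNA still comes from the egg mother — consistent
    with parthenogens keeping a *C. felicitatis*-like mtDNA while embodying
    nuclear genomes of unsampled paternal bisexuals.  Whether the historical
    founder arose by syngamy or androgenesis is left open; both modes are
    first-class here and produce the same karyotype.
    """
    if len(labels) != 3:
        raise ValueError("a triploid female needs exactly three haploid-set labels")
    if mode not in ("syngamy", "androgenesis"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = tuple(labels)
    karyo = Karyotype.uniform(n_groups, 3, origin_labels=labels)
    return Individual(karyo, labels, mtdna_label, sex="female")


def run_scenario(spec: dict) -> dict[str, Individual | Gamete]:
    """Execute a declarative origin scenario.

    ``spec['steps']`` is an ordered list of operations; each step has a
    ``name`` it is stored under, an ``op`` and op-specific fields referring
    to earlier names:

    * ``diploid_hybrid``: p1, p2, optional n_groups / mtdna
    * ``gamete``: parent, mechanism, optional origin
    * ``fuse``: egg, sperm (list of names), mode, optional sex
    * ``triploid_female``: mode, labels (3), mtdna, optional n_groups

    Returns the name -> object mapping for inspection or further simulation.
    """
    objects: dict[str, Individual | Gamete] = {}
    for step in spec.get("steps", []):
        op = step["op"]
        name = step["name"]
        if op == "diploid_hybrid":
            objects[name] = make_diploid_hybrid(
                step["p1"], step["p2"], step.get("n_groups", HAPLOID_N),
                step.get("mtdna"),
            )
        elif op == "gamete":
            objects[name] = make_gamete(
                objects[step["parent"]], step["mechanism"], step.get("origin", "egg")
            )
        elif op == "fuse":
            objects[name] = fuse(
                objects[step["egg"]],
                [objects[s] for s in step["sperm"]],
                step["mode"],
                step.get("sex", "female"),
            )
        elif op == "triploid_female":
            objects[name] = make_triploid_female(
                step["mode"], step["labels"], step["mtdna"],
                step.get("n_groups", HAPLOID_N),
            )
        else:
            raise ValueError(f"unknown scenario op {op!r} in step {name!r}")
    return objects
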