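"""Synthetic dominant-AFLP data with the structure of the Moroccan survey.

AFLP bands are dominant: a band is seen whenever at least one of an
individual's allele copies carries the presence allele, so for a
diploid-scored individual with presence-allele frequency ``p`` the band
frequency is ``1 - (1 - p)**2``.  The generator draws per-population allele
frequencies around a common ancestral frequency (Balding–Nichols Beta model,
with the divergence parameter playing the role of F_ST), simulates
individuals from admixture proportions, and reproduces the survey's data
artefacts: unidirectional fragment elimination from one parental genome,
missing cells, and removal of markers with more than 5 % missing data.

Matrices are stored as individuals × markers tables with values 1 (band
present), 0 (absent) and NaN (missing), and round-trip through CSV and
single-row dominant STRUCTURE text files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from clonosim._rng import substream

__all__ = [
    "PopulationModel",
    "AFLPMatrix",
    "TrueAncestry",
    "sample_parental_frequencies",
    "simulate_matrix",
    "apply_fragment_elimination",
    "inject_missing",
    "filter_markers",
    "read_matrix",
    "write_matrix",
    "survey_dataset",
]

MISSING_STRUCTURE_CODE = -9


@dataclass(frozen=True)
class PopulationModel:
    """K parental populations × L markers of presence-allele frequencies."""

    p: np.ndarray  # shape (K, L), values in [0, 1]
    eliminated: tuple[int, ...] = ()  # marker indices zeroed by elimination

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2 or p.shape[0] < 1 or p.shape[1] < 1:
            raise ValueError("p must be a K × L array with K, L >= 1")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("presence-allele frequencies must lie in [0, 1]")
        object.__setattr__(self, "p", p)

    @property
    def K(self) -> int:
        return self.p.shape[0]

    @property
    def L(self) -> int:
        return self.p.shape[1]


@dataclass(frozen=True)
class TrueAncestry:
    """Ground-truth admixture proportions (and optional copy numbers)."""

    Q_true: np.ndarray  # shape (N, K), rows sum to 1
    individuals: tuple[str, ...] = ()
    copy_number: np.ndarray | None = None  # per-individual allele copies

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q_true, dtype=float)
        if Q.ndim != 2:
            raise ValueError("Q_true must be 2-D (individuals × populations)")
        if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of Q_true must sum to 1")
        if np.any(Q < 0):
            raise ValueError("Q_true entries must be non-negative")
        object.__setattr__(self, "Q_true", Q)
        if not self.individuals:
            ids = tuple(f"ind{i + 1}" for i in range(Q.shape[0]))
            object.__setattr__(self, "individuals", ids)
        elif len(self.individuals) != Q.shape[0]:
            raise ValueError("individuals and Q_true disagree on N")

    @property
    def N(self) -> int:
        return self.Q_true.shape[0]

    @property
    def K(self) -> int:
        return self.Q_true.shape[1]

    @classmethod
    def pure(cls, counts: Sequence[int], prefix: str = "pop") -> "TrueAncestry":
        """Non-admixed ancestry: ``counts[k]`` individuals fully from pop k."""
        K = len(counts)
        rows, ids = [], []
        for k, c in enumerate(counts):
            for j in range(c):
                row = np.zeros(K)
                row[k] = 1.0
                rows.append(row)
                ids.append(f"{prefix}{k + 1}_{j + 1}")
        return cls(np.array(rows), tuple(ids))


@dataclass(frozen=True)
class AFLPMatrix:
    """Individuals × dominant markers; 1 present, 0 absent, NaN missing."""

    data: pd.DataFrame
    ploidy_scored: int = 2

    def __post_init__(self) -> None:
        df = self.data.astype(float)
        vals = df.to_numpy()
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            raise ValueError("matrix cells must be 0, 1 or missing")
        object.__setattr__(self, "data", df)

    @property
    def individuals(self) -> tuple[str, ...]:
        return tuple(str(i) for i in self.data.index)

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(str(c) for c in self.data.columns)

    @property
    def n_individuals(self) -> int:
        return self.data.shape[0]

    @property
    def n_markers(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        """Float array with NaN for missing cells."""
        return self.data.to_numpy(dtype=float)

    def missing_fraction(self) -> pd.Series:
        """Per-marker fraction of missing cells."""
        return self.data.isna().mean(axis=0)

    def band_frequency(self) -> pd.Series:
        """Per-marker band frequency among scored (non-missing) cells."""
        return self.data.mean(axis=0, skipna=True)

    def drop_individuals(self, ids: Sequence[str]) -> "AFLPMatrix":
        keep = [i for i in self.data.index if str(i) not in set(map(str, ids))]
        if not keep:
            raise ValueError("dropping these individuals empties the matrix")
        return AFLPMatrix(self.data.loc[keep], self.ploidy_scored)


def sample_parental_frequencies(
    K: int, L: int, divergence: float, seed: int
) -> PopulationModel:
    """Draw per-population presence-allele frequencies.

    Each marker gets an ancestral frequency ~ Uniform(0.05, 0.95); each
    population then draws its own frequency from the Balding–Nichols Beta
    distribution Beta(a(1-F)/F, (1-a)(1-F)/F) centred on the ancestral value
    a, with F = ``divergence`` controlling the spread (the F_ST analogue).
    """
    if K < 1 or L < 1:
        raise ValueError("K and L must be >= 1")
    if not 0.0 < divergence < 1.0:
        raise ValueError("divergence must lie strictly in (0, 1)")
    rng = substream(seed, "aflp.sample_parental_frequencies")
    ancestral = rng.uniform(0.05, 0.95, size=L)
    scale = (1.0 - divergence) / divergence
    alpha = ancestral * scale
    beta = (1.0 - ancestral) * scale
    p = rng.beta(alpha, beta, size=(K, L))
    return PopulationModel(np.clip(p, 0.0, 1.0))


def simulate_matrix(
    model: PopulationModel,
    ancestry: TrueAncestry,
    seed: int,
    ploidy_scored: int = 2,
) -> AFLPMatrix:
    """Simulate a dominant band matrix under the admixture model.

    For individual i at marker l, each of c allele copies independently takes
    its origin population k with probability ``Q_true[i, k]`` and is a
    presence allele with probability ``p[k, l]``; the band is scored 1 iff at
    least one copy carries the presence allele.  c is ``ploidy_scored``
    everywhere unless the ancestry supplies per-individual copy numbers (the
    copy-number-aware mode for sensitivity analyses).
    """
    if ancestry.K != model.K:
        raise ValueError(
            f"ancestry has K={ancestry.K} but the model has K={model.K}"
        )
    rng = substream(seed, "aflp.simulate_matrix")
    N, L, K = ancestry.N, model.L, model.K
    copies = (
        np.asarray(ancestry.copy_number, dtype=int)
        if ancestry.copy_number is not None
        else np.full(N, ploidy_scored, dtype=int)
    )
    if copies.shape != (N,) or np.any(copies < 1):
        raise ValueError("copy_number must give a positive count per individual")

    bands = np.zeros((N, L), dtype=float)
    for i in range(N):
        present = np.zeros(L, dtype=bool)
        for _ in range(copies[i]):
            origins = rng.choice(K, size=L, p=ancestry.Q_true[i])
            present |= rng.random(L) < model.p[origins, np.arange(L)]
        bands[i] = present
    df = pd.DataFrame(
        bands,
        index=list(ancestry.individuals),
        columns=[f"M{l + 1}" for l in range(L)],
    )
    return AFLPMatrix(df, ploidy_scored=ploidy_scored)


def apply_fragment_elimination(
    model: PopulationModel,
    fraction: float,
    eliminated_parent: int,
    seed: int,
) -> PopulationModel:
    """Unidirectional fragment loss from one parental genome.

    Allopolyploid genomes can shed up to 14 % of one parent's loci in a
    single generation, and the loss is unidirectional — fragments disappear
    from one parental genome only.  A random subset of round(fraction · L)
    markers has the eliminated parent's presence-allele frequency set to 0;
    the other parents are untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if not 0 <= eliminated_parent < model.K:
        raise ValueError(
            f"eliminated_parent {eliminated_parent} outside 0..{model.K - 1}"
        )
    n_drop = int(round(fraction * model.L))
    if n_drop == 0:
        return model
    rng = substream(seed, "aflp.apply_fragment_elimination")
    idx = rng.choice(model.L, size=n_drop, replace=False)
    p = model.p.copy()
    p[eliminated_parent, idx] = 0.0
    return PopulationModel(p, eliminated=tuple(sorted(int(i) for i in idx)))


def inject_missing(matrix: AFLPMatrix, rate: float, seed: int) -> AFLPMatrix:
    """Set each cell missing independently with the given probability."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must lie in [0, 1)")
    if rate == 0.0:
        return matrix
    rng = substream(seed, "aflp.inject_missing")
    vals = matrix.values()
    mask = rng.random(vals.shape) < rate
    vals = vals.copy()
    vals[mask] = np.nan
    df = pd.DataFrame(vals, index=matrix.data.index, columns=matrix.data.columns)
    return AFLPMatrix(df, matrix.ploidy_scored)


def filter_markers(matrix: AFLPMatrix, max_missing: float = 0.05) -> AFLPMatrix:
    """Remove markers with more than ``max_missing`` missing data.

    The cut is strict: a marker at exactly the threshold is retained.  The
    default 5 % reproduces the survey's definitive-dataset rule.
    """
    frac = matrix.missing_fraction()
    keep = frac.index[frac.to_numpy() <= max_missing + 1e-12]
    return AFLPMatrix(matrix.data.loc[:, keep], matrix.ploidy_scored)


def write_matrix(
    matrix: AFLPMatrix, path: str | os.PathLike,
    format: Literal["csv", "structure"] = "csv",
) -> None:
    """Write a band matrix to CSV (NA missing) or STRUCTURE text (-9 missing).

    The STRUCTURE dialect is the dominant single-row coding: one row per
    individual, first column the individual label, then one 0/1 column per
    marker, whitespace separated, with a marker-name header line.
    """
    if format == "csv":
        matrix.data.to_csv(path, na_rep="NA")
        return
    if format == "structure":
        with open(path, "w") as fh:
            fh.write(" ".join(matrix.markers) + "\n")
            for ind in matrix.data.index:
                row = matrix.data.loc[ind]
                cells = [
                    str(MISSING_STRUCTURE_CODE) if pd.isna(v) else str(int(v))
                    for v in row
                ]
                fh.write(f"{ind} " + " ".join(cells) + "\n")
        return
    raise ValueError(f"unknown format {format!r}")


def read_matrix(
    path: str | os.PathLike, format: Literal["csv", "structure"] = "csv"
) -> AFLPMatrix:
    """Read a band matrix written by :func:`write_matrix` (round-trip safe)."""
    if format == "csv":
        df = pd.read_csv(path, index_col=0, na_values=["NA"])
        return AFLPMatrix(df)
    if format == "structure":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        if not lines:
            raise ValueError(f"{path}: empty STRUCTURE file")
        markers = lines[0].split()
        rows, ids = [], []
        for lineno, ln in enumerate(lines[1:], start=2):
            parts = ln.split()
            if len(parts) != len(markers) + 1:
                raise ValueError(
                    f"{path}: row {lineno} has {len(parts) - 1} genotype "
                    f"columns, expected {len(markers)}"
                )
            ids.append(parts[0])
            row = [
                np.nan if int(v) == MISSING_STRUCTURE_CODE else float(int(v))
                for v in parts[1:]
            ]
            rows.append(row)
        df = pd.DataFrame(rows, index=ids, columns=markers)
        return AFLPMatrix(df)
    raise ValueError(f"unknown format {format!r}")


def survey_dataset(
    seed: int,
    n_pure: Sequence[int] = (1, 8, 6, 2),
    n_admixed: int = 10,
    n_markers: int = 195,
    oversample_markers: int = 240,
    divergence: float = 0.25,
    missing_rate: float = 0.02,
    elimination_fraction: float = 0.0,
    eliminated_parent: int = 0,
) -> tuple[AFLPMatrix, TrueAncestry, PopulationModel]:
    """The default survey-shaped fixture: 27 individuals × 195 markers.

    Four parental populations (pure counts default 1 + 8 + 6 + 2, echoing a
    lone outgroup female, a bisexual population, a block of parthenogens and
    a pair of androgenetic males) plus admixed hybrids drawn as 50/50 mixes
    of two random parents.  Markers are oversampled, missing cells injected
    at 2 %, the >5 % missing filter applied, and the retained markers
    truncated to exactly ``n_markers`` columns.
    """
    K = len(n_pure)
    rng = substream(seed, "aflp.survey_dataset")
    model = sample_parental_frequencies(K, oversample_markers, divergence, seed)
    if elimination_fraction > 0.0:
        model = apply_fragment_elimination(
            model, elimination_fraction, eliminated_parent, seed
        )
    pure = TrueAncestry.pure(n_pure)
    rows = [*pure.Q_true]
    ids = list(pure.individuals)
    for j in range(n_admixed):
        a, b = rng.choice(K, size=2, replace=False)
        row = np.zeros(K)
        row[a] = row[b] = 0.5
        rows.append(row)
        ids.append(f"hyb{j + 1}")
    ancestry = TrueAncestry(np.array(rows), tuple(ids))
    matrix = simulate_matrix(model, ancestry, seed)
    matrix = inject_missing(matrix, missing_rate, seed)
    matrix = filter_markers(matrix, 0.05)
    if matrix.n_markers < n_markers:
        raise RuntimeError(
            f"only {matrix.n_markers} markers survived filtering; "
            f"raise oversample_markers"
        )
    kept = list(matrix.data.columns[:n_markers])
    return AFLPMatrix(matrix.data.loc[:, kept], matrix.ploidy_scored), ancestry, model
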