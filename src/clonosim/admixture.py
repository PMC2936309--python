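"""Admixture inference for dominant diploid-scored markers.

The model is the classic admixture model for K source populations: each of
an individual's two allele copies at marker l independently originates from
population k with probability Q_ik and is a presence allele with probability
p_kl.  Dominance means only the band is seen, so the observation layer is

    P(band_il = 1) = 1 - (1 - pi_il)^2,     pi_il = sum_k Q_ik p_kl.

Q and p are estimated by maximum-likelihood EM with multiple random
restarts; missing cells are skipped in the likelihood.  K is chosen on a
grid by two methods — the plateau (one-standard-error) rule on the mean
replicate log-likelihood, and the Evanno-style deltaK statistic
|L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)) — and individuals are assigned to a
population when their largest membership coefficient reaches the q >= 80 %
threshold, otherwise flagged admixed.

The EM treats the latent origin and allelic state of each copy as missing
data.  Writing u_k = Q_ik p_kl and v_k = Q_ik (1 - p_kl), the posterior
expected number of copies of origin k at an observed cell is

    band 0:  2 v_k / (1 - pi)                  (both copies null),
    band 1:  2 (u_k + v_k pi) / (1-(1-pi)^2),  presence copies 2 u_k / (...),

which feed closed-form M-step updates of Q (row-normalised copy counts) and
p (presence copies over total copies per population).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from clonosim._rng import substream
from clonosim.aflp import AFLPMatrix

__all__ = [
    "AdmixtureResult",
    "KSelection",
    "fit",
    "select_K",
    "assign",
    "align_labels",
    "forced_K2_analysis",
    "dominant_frequency_k1",
]

_P_EPS = 1e-9  # keeps log terms finite without visibly constraining p
_REL_TOL = 1e-8
_PARAM_TOL = 3e-8  # largest per-iteration parameter move at convergence
_MAX_ITER = 2000


@dataclass(frozen=True)
class AdmixtureResult:
    """Fitted admixture model: memberships, allele frequencies, likelihood."""

    Q: np.ndarray  # (N, K), rows sum to 1
    p_hat: np.ndarray  # (K, L)
    loglik: float
    K: int
    individuals: tuple[str, ...]
    markers: tuple[str, ...]
    replicate_logliks: tuple[float, ...] = ()
    n_iter: int = 0

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1")
        if np.any(self.p_hat < 0) or np.any(self.p_hat > 1):
            raise ValueError("p_hat must lie in [0, 1]")
        if not math.isfinite(self.loglik):
            raise ValueError("log-likelihood must be finite")

    def q_table(self) -> pd.DataFrame:
        """Q as a DataFrame (individuals × clusters)."""
        return pd.DataFrame(
            self.Q,
            index=list(self.individuals),
            columns=[f"cluster_{k + 1}" for k in range(self.K)],
        )

    def p_table(self) -> pd.DataFrame:
        """p_hat as a DataFrame (clusters × markers)."""
        return pd.DataFrame(
            self.p_hat,
            index=[f"cluster_{k + 1}" for k in range(self.K)],
            columns=list(self.markers),
        )


@dataclass(frozen=True)
class KSelection:
    """Grid evaluation of K with both selection rules."""

    K_grid: tuple[int, ...]
    mean_loglik: tuple[float, ...]
    sd_loglik: tuple[float, ...]
    penalized_loglik: tuple[float, ...]  # mean loglik - parameter count
    deltaK: dict[int, float]  # interior K only
    k_by_max_prob: int
    k_by_deltaK: int | None
    replicate_logliks: dict[int, tuple[float, ...]]
    method: str = "max_prob"

    @property
    def chosen_K(self) -> int:
        if self.method == "deltaK":
            if self.k_by_deltaK is None:
                raise ValueError("deltaK is undefined on this grid")
            return self.k_by_deltaK
        return self.k_by_max_prob

    @property
    def agreed_K(self) -> int | None:
        """The K both methods pick, or None if they disagree."""
        if self.k_by_deltaK is not None and self.k_by_deltaK == self.k_by_max_prob:
            return self.k_by_max_prob
        return None


def dominant_frequency_k1(band_freq: np.ndarray | float):
    """Closed-form K=1 MLE: p = 1 - sqrt(1 - band frequency)."""
    return 1.0 - np.sqrt(1.0 - np.asarray(band_freq, dtype=float))


def _loglik(X: np.ndarray, obs: np.ndarray, Q: np.ndarray, P: np.ndarray) -> float:
    pi = np.clip(Q @ P, _P_EPS, 1.0 - _P_EPS)
    band_p = 1.0 - (1.0 - pi) ** 2
    ll = np.where(X == 1.0, np.log(band_p), 2.0 * np.log(1.0 - pi))
    return float(ll[obs].sum())


def _em_single(
    X: np.ndarray, obs: np.ndarray, K: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """One EM run from a random start; returns (Q, P, loglik, n_iter)."""
    N, L = X.shape
    # random start: Dirichlet memberships; frequencies jittered around the
    # pooled dominant estimate so restarts explore distinct label bindings
    Q = rng.dirichlet(np.ones(K), size=N)
    f = np.nanmean(np.where(obs, X, np.nan), axis=0)
    f = np.nan_to_num(f, nan=0.5)
    p0 = dominant_frequency_k1(np.clip(f, 0.0, 1.0 - 1e-12))
    P = np.clip(p0[None, :] + rng.uniform(-0.3, 0.3, size=(K, L)), 0.01, 0.99)
    # monomorphic markers have a boundary MLE (p = 0 or 1) that the EM map
    # approaches only sublinearly; those boundaries are exact fixed points,
    # so start there and let the updates keep them
    mono1 = f == 1.0
    mono0 = f == 0.0
    P[:, mono1] = 1.0
    P[:, mono0] = 0.0

    X1 = (X == 1.0) & obs
    X0 = (X == 0.0) & obs
    n_obs = obs.sum(axis=1)  # per individual
    prev = -np.inf
    for it in range(1, _MAX_ITER + 1):
        pi = np.clip(Q @ P, _P_EPS, 1.0 - _P_EPS)  # (N, L)
        u = Q[:, :, None] * P[None, :, :]  # (N, K, L)
        v = Q[:, :, None] * (1.0 - P)[None, :, :]
        band_p = pi * (2.0 - pi)  # 1 - (1 - pi)^2

        # expected copy counts per (i, k, l)
        cnt1 = 2.0 * (u + v * pi[:, None, :]) / band_p[:, None, :]
        pres1 = 2.0 * u / band_p[:, None, :]
        cnt0 = 2.0 * v / (1.0 - pi)[:, None, :]

        w1 = X1[:, None, :]
        w0 = X0[:, None, :]
        cnt = np.where(w1, cnt1, 0.0) + np.where(w0, cnt0, 0.0)  # (N, K, L)
        pres = np.where(w1, pres1, 0.0)

        Q_old, P_old = Q, P
        Q = cnt.sum(axis=2) / (2.0 * n_obs)[:, None]
        Q = np.clip(Q, 0.0, None)
        Q /= Q.sum(axis=1, keepdims=True)
        denom = cnt.sum(axis=0)  # (K, L)
        P = np.where(denom > 0, pres.sum(axis=0) / np.maximum(denom, 1e-300), P)
        P = np.clip(P, _P_EPS, 1.0 - _P_EPS)

        ll = _loglik(X, obs, Q, P)
        if ll + 1e-6 < prev:  # EM must not decrease (numerical slack)
            raise RuntimeError(f"EM log-likelihood decreased: {prev} -> {ll}")
        delta = max(np.abs(P - P_old).max(), np.abs(Q - Q_old).max())
        if (
            prev > -np.inf
            and abs(ll - prev) <= _REL_TOL * abs(prev)
            and delta <= _PARAM_TOL
        ):
            prev = ll
            break
        prev = ll
    return Q, P, prev, it


def fit(
    matrix: AFLPMatrix, K: int, seed: int, n_init: int = 5
) -> AdmixtureResult:
    """Fit the dominant-marker admixture model by EM with random restarts.

    Runs ``n_init`` EM starts and returns the best by log-likelihood (ties
    broken by start order).  Markers that are missing in every individual
    must be filtered out beforehand.
    """
    X = matrix.values()
    obs = ~np.isnan(X)
    N, L = X.shape
    if N == 0 or L == 0:
        raise ValueError("matrix must contain individuals and markers")
    if not 1 <= K <= N:
        raise ValueError(f"K={K} outside 1..{N} (number of individuals)")
    if (~obs).all(axis=0).any():
        raise ValueError("all-missing marker present: filter markers first")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")

    Xf = np.nan_to_num(X, nan=0.0)
    best = None
    logliks = []
    for r in range(n_init):
        rng = substream(seed, f"admixture.fit.K{K}.restart{r}")
        Q, P, ll, it = _em_single(Xf, obs, K, rng)
        logliks.append(ll)
        if best is None or ll > best[2]:
            best = (Q, P, ll, it)
    Q, P, ll, it = best
    return AdmixtureResult(
        Q=Q,
        p_hat=P,
        loglik=ll,
        K=K,
        individuals=matrix.individuals,
        markers=matrix.markers,
        replicate_logliks=tuple(logliks),
        n_iter=it,
    )


def select_K(
    matrix: AFLPMatrix,
    K_grid: Sequence[int],
    replicates: int = 5,
    seed: int = 0,
    method: str = "max_prob",
    inits_per_replicate: int = 3,
) -> KSelection:
    """Evaluate a contiguous K grid and choose K by two rules.

    Each (K, replicate) pair is an independent EM fit; a replicate keeps the
    best of ``inits_per_replicate`` random starts so that a single start
    trapped in a poor local optimum cannot masquerade as between-replicate
    variance.

    The ``max_prob`` rule emulates picking the most probable K from the
    estimated probability of the data.  The MCMC estimate it replaces is a
    marginal likelihood, which plateaus once K exceeds the true number of
    sources; a maximised likelihood instead climbs with every extra cluster
    (each adds L allele frequencies to fit), so the mean replicate
    log-likelihood is first penalised by the free-parameter count,
    ``mean L(K) - [K*L + N*(K-1)]``, restoring the plateau.  The rule then
    takes the smallest K whose penalised value is within one standard error
    of the grid maximum.

    The ``deltaK`` rule picks the interior K maximising the Evanno-style
    statistic |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)) on the raw replicate
    log-likelihoods; it needs >= 3 replicates and >= 3 grid points and is
    undefined at the grid endpoints.  Replicate standard deviations are
    floored at one natural-log unit: with a convergent optimiser the
    replicates of a well-resolved K coincide almost exactly, and dividing
    the curvature by a near-zero sd would let numerical noise, not
    structure, pick K.
    """
    K_grid = tuple(sorted(int(k) for k in K_grid))
    if len(K_grid) < 1 or len(set(K_grid)) != len(K_grid):
        raise ValueError("K_grid must be a non-empty set of distinct K values")
    if any(b - a != 1 for a, b in zip(K_grid, K_grid[1:])):
        raise ValueError("K_grid must be contiguous")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    rep_lls: dict[int, tuple[float, ...]] = {}
    for K in K_grid:
        lls = [
            fit(matrix, K, seed=seed + 1000 * r, n_init=inits_per_replicate).loglik
            for r in range(replicates)
        ]
        rep_lls[K] = tuple(lls)
    means = np.array([np.mean(rep_lls[K]) for K in K_grid])
    sds = np.array([np.std(rep_lls[K], ddof=1) if replicates > 1 else 0.0
                    for K in K_grid])
    N, L = matrix.n_individuals, matrix.n_markers
    n_params = np.array([K * L + N * (K - 1) for K in K_grid])
    crit = means - n_params

    # plateau rule: smallest K within one SE of the best penalised mean
    i_max = int(np.argmax(crit))
    se = sds[i_max] / math.sqrt(replicates) if replicates > 1 else 0.0
    k_max_prob = K_grid[i_max]
    for i, K in enumerate(K_grid):
        if crit[i] >= crit[i_max] - se:
            k_max_prob = K
            break

    deltaK: dict[int, float] = {}
    k_delta = None
    if len(K_grid) >= 3 and replicates >= 3:
        for i in range(1, len(K_grid) - 1):
            num = abs(means[i + 1] - 2.0 * means[i] + means[i - 1])
            sd = max(sds[i], 1.0)  # floor: see docstring
            deltaK[K_grid[i]] = float(num / sd)
        k_delta = max(deltaK, key=deltaK.get)

    return KSelection(
        K_grid=K_grid,
        mean_loglik=tuple(float(m) for m in means),
        sd_loglik=tuple(float(s) for s in sds),
        penalized_loglik=tuple(float(c) for c in crit),
        deltaK=deltaK,
        k_by_max_prob=k_max_prob,
        k_by_deltaK=k_delta,
        replicate_logliks=rep_lls,
        method=method,
    )


def assign(result: AdmixtureResult, threshold: float = 0.80) -> pd.Series:
    """Assign individuals to populations by the q >= threshold rule.

    An individual goes to its arg-max cluster when the membership reaches
    the threshold (inclusive); below it the genotype is compatible with more
    than one parental population and is labelled ``admixed``.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    labels = []
    for row in result.Q:
        k = int(np.argmax(row))
        labels.append(f"cluster_{k + 1}" if row[k] >= threshold else "admixed")
    return pd.Series(labels, index=list(result.individuals), name="assignment")


def align_labels(
    reference: AdmixtureResult, other: AdmixtureResult
) -> AdmixtureResult:
    """Permute ``other``'s clusters to best match the reference.

    Uses Hungarian assignment on the L1 distance between the two p_hat
    tables; Q and p are permuted consistently.  The log-likelihood is
    invariant under relabelling.
    """
    if reference.K != other.K:
        raise ValueError("cannot align results with different K")
    cost = np.abs(
        reference.p_hat[:, None, :] - other.p_hat[None, :, :]
    ).sum(axis=2)
    _, perm = linear_sum_assignment(cost)
    return replace(other, Q=other.Q[:, perm], p_hat=other.p_hat[perm, :])


def forced_K2_analysis(
    matrix: AFLPMatrix,
    exclude: Sequence[str] = (),
    replicates: int = 10,
    seed: int = 0,
    threshold: float = 0.80,
) -> tuple[AdmixtureResult, pd.Series]:
    """K = 2 contrast after dropping outgroup-like individuals.

    Forcing K = 2 pulls the two most genetically distinct pools apart, so
    sub-threshold memberships flag admixed genotypes more sharply.  A strong
    outlier (the survey's lone *C. maroccana*) behaves as an outgroup and
    distorts the contrast, hence the ``exclude`` list.  ``replicates``
    independent runs are aligned to the best one and averaged into a
    consensus Q (renormalised), from which assignments are computed.
    """
    sub = matrix.drop_individuals(exclude) if exclude else matrix
    runs = [
        fit(sub, 2, seed=seed + 1000 * r, n_init=1) for r in range(replicates)
    ]
    best = max(runs, key=lambda r: r.loglik)
    aligned = [align_labels(best, r) for r in runs]
    Q = np.mean([r.Q for r in aligned], axis=0)
    Q /= Q.sum(axis=1, keepdims=True)
    p = np.mean([r.p_hat for r in aligned], axis=0)
    consensus = AdmixtureResult(
        Q=Q,
        p_hat=p,
        loglik=best.loglik,
        K=2,
        individuals=sub.individuals,
        markers=sub.markers,
        replicate_logliks=tuple(r.loglik for r in runs),
        n_iter=best.n_iter,
    )
    return consensus, assign(consensus, threshold)
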