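"""Config-driven end-to-end runs: meiosis → synthetic AFLP → admixture.

A :class:`PipelineConfig` (usually loaded from YAML) drives one reproducible
run: egg-class distribution of the intermediate triploid female, a synthetic
dominant-AFLP matrix with missing data and the >5 % marker filter, admixture
inference with K selection, and the q >= 80 % assignment table.  One master
seed feeds named sub-streams per stage, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from clonosim.admixture import assign, fit, select_K
from clonosim.aflp import AFLPMatrix, survey_dataset, write_matrix
from clonosim.meiosis import exact_m_distribution, simulate_eggs

__all__ = ["PipelineConfig", "run_pipeline", "jaccard_distance"]

logger = logging.getLogger("clonosim")


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one end-to-end run."""

    seed: int
    outdir: str
    # meiosis stage
    n_trivalents: int = 18
    n_eggs: int = 100_000
    # generator stage
    n_pure: tuple[int, ...] = (1, 8, 6, 2)
    n_admixed: int = 10
    n_markers: int = 195
    divergence: float = 0.25
    missing_rate: float = 0.02
    elimination_fraction: float = 0.0
    eliminated_parent: int = 0
    # inference stage
    k_min: int = 1
    k_max: int = 8
    replicates: int = 5
    threshold: float = 0.80

    def validate(self) -> None:
        if self.n_eggs < 1:
            raise ValueError("n_eggs must be >= 1")
        if self.n_trivalents < 1:
            raise ValueError("n_trivalents must be >= 1")
        if not 0.0 < self.divergence < 1.0:
            raise ValueError("divergence must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.elimination_fraction <= 1.0:
            raise ValueError("elimination_fraction must lie in [0, 1]")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("need 1 <= k_min <= k_max")
        if not 0.5 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0.5, 1]")
        if len(self.n_pure) < 1 or any(c < 0 for c in self.n_pure):
            raise ValueError("n_pure must list non-negative counts")
        if self.k_max > sum(self.n_pure) + self.n_admixed:
            raise ValueError("k_max exceeds the number of individuals")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set a master seed")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "n_pure" in raw:
            raw["n_pure"] = tuple(raw["n_pure"])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``.

    Outputs: ``egg_distribution.csv``, ``aflp_matrix.csv`` (filtered),
    ``q_matrix.csv``, ``p_hat.csv``, ``k_selection.json``,
    ``assignments.csv`` and ``run_log.json``.  Returns the in-memory bundle.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    from clonosim import __version__ as pkg_version

    log: dict = {"seed": config.seed, "version": pkg_version, "stages": []}

    def _stage(name):
        logger.info("stage %s", name)
        log["stages"].append(name)

    try:
        _stage("meiosis")
        sim = simulate_eggs(config.n_trivalents, config.n_eggs, config.seed)
        egg_table = sim.summary_table()
        egg_table.to_csv(out / "egg_distribution.csv", index=False)

        _stage("synthesis")
        matrix, ancestry, model = survey_dataset(
            seed=config.seed,
            n_pure=config.n_pure,
            n_admixed=config.n_admixed,
            n_markers=config.n_markers,
            divergence=config.divergence,
            missing_rate=config.missing_rate,
            elimination_fraction=config.elimination_fraction,
            eliminated_parent=config.eliminated_parent,
        )
        write_matrix(matrix, out / "aflp_matrix.csv", "csv")

        _stage("k_selection")
        ks = select_K(
            matrix,
            range(config.k_min, config.k_max + 1),
            replicates=config.replicates,
            seed=config.seed,
        )
        with open(out / "k_selection.json", "w") as fh:
            json.dump(
                {
                    "K_grid": list(ks.K_grid),
                    "mean_loglik": list(ks.mean_loglik),
                    "sd_loglik": list(ks.sd_loglik),
                    "penalized_loglik": list(ks.penalized_loglik),
                    "deltaK": {str(k): v for k, v in ks.deltaK.items()},
                    "k_by_max_prob": ks.k_by_max_prob,
                    "k_by_deltaK": ks.k_by_deltaK,
                },
                fh,
                indent=2,
            )

        _stage("admixture")
        res = fit(matrix, ks.k_by_max_prob, seed=config.seed,
                  n_init=config.replicates)
        res.q_table().to_csv(out / "q_matrix.csv")
        res.p_table().to_csv(out / "p_hat.csv")
        labels = assign(res, config.threshold)
        pd.DataFrame(
            {"assignment": labels, "max_q": res.Q.max(axis=1)}
        ).to_csv(out / "assignments.csv")
    except Exception as exc:  # annotate with the failing stage
        stage = log["stages"][-1] if log["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return {
        "egg_distribution": egg_table,
        "matrix": matrix,
        "ancestry": ancestry,
        "k_selection": ks,
        "admixture": res,
        "assignments": labels,
        "log": log,
    }


def jaccard_distance(matrix: AFLPMatrix) -> pd.DataFrame:
    """Pairwise Jaccard distance between individuals' band profiles.

    d(i, j) = 1 - |bands shared| / |bands present in either|, computed over
    markers scored in both individuals.  A pair with no co-scored present
    band gets distance 1 (with a warning): nothing ties them together.
    """
    if matrix.n_individuals < 2:
        raise ValueError("need at least two individuals")
    X = matrix.values()
    ids = list(matrix.individuals)
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both_scored = ~np.isnan(X[i]) & ~np.isnan(X[j])
            a, b = X[i][both_scored] == 1, X[j][both_scored] == 1
            union = (a | b).sum()
            if union == 0:
                warnings.warn(
                    f"individuals {ids[i]!r} and {ids[j]!r} share no scored "
                    "bands; Jaccard distance set to 1"
                )
                d = 1.0
            else:
                d = 1.0 - (a & b).sum() / union
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=ids, columns=ids)
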