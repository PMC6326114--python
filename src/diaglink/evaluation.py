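"""TPR/PPV scoring against gold or silver truth, and experiment grids."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .matching import MatchSet
from .simulate import LinkedTruth, SimulationConfig, simulate_linked_pair

__all__ = ["EvaluationResult", "evaluate", "run_experiment_grid"]


@dataclass
class EvaluationResult:
    """Counts and rates of a declared match set against a truth set.

    TPR = true positives / truth pairs; PPV = true positives / declared
    pairs.  A rate whose denominator is zero is reported as ``None``
    (missing), never as 0.
    """

    n_declared: int
    n_truth: int
    n_true_positive: int

    @property
    def tpr(self) -> float | None:
        return self.n_true_positive / self.n_truth if self.n_truth else None

    @property
    def ppv(self) -> float | None:
        return self.n_true_positive / self.n_declared if self.n_declared else None


def evaluate(declared: MatchSet, truth: LinkedTruth) -> EvaluationResult:
    """Exact set intersection of declared and truth (id_A, id_B) pairs."""
    raw = [(a, b) for a, b, _ in declared.pairs]
    declared_ids = set(raw)
    if len(raw) != len(declared_ids):
        warnings.warn("duplicate declared pairs collapsed", RuntimeWarning)
    tp = len(declared_ids & truth.pairs)
    return EvaluationResult(
        n_declared=len(declared_ids), n_truth=len(truth.pairs), n_true_positive=tp
    )


def _cell_seed(master_seed: int, cell_index: int, replicate: int) -> int:
    """Deterministic per-replicate seed from the master seed."""
    ss = np.random.SeedSequence([master_seed, cell_index, replicate])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_experiment_grid(
    cells: Iterable[dict],
    n_replicates: int = 1,
    master_seed: int = 0,
    alphas: tuple[float, ...] = (0.5, 0.9),
    eps: float = 0.01,
    fs_threshold: float = 0.0,
) -> pd.DataFrame:
    """Run the simulation experiment over a grid of conditions.

    Each cell is a dict of :class:`SimulationConfig` overrides (e.g.
    ``{"rho": 0.5, "K": 1000}``).  Per cell and replicate, a linked pair is
    simulated and matched with the Bayesian matcher at every ``alpha`` and
    with the Fellegi-Sunter comparator (plain and 1-1); the long-format
    table has one row per (cell, replicate, method).  Cell failures are
    recorded as rows with an ``error`` column, and the grid continues.
    """
    from .pipeline import match_datasets
    from .fellegi_sunter import fs_classify, fs_em_fit, fs_one_to_one, fs_score
    from .datasets import align_codes

    rows = []
    for ci, cell in enumerate(cells):
        for rep in range(n_replicates):
            seed = _cell_seed(master_seed, ci, rep)
            base = dict(cell)
            base["seed"] = seed
            try:
                cfg = SimulationConfig(**base)
                A, B, truth = simulate_linked_pair(cfg)
                common = {**cell, "replicate": rep, "seed": seed}
                result = match_datasets(
                    A, B, eps_minus=eps, eps_plus=eps, alphas=alphas
                )
                for alpha in alphas:
                    ev = evaluate(result.matches[alpha], truth)
                    rows.append(
                        {
                            **common,
                            "method": f"bayes_{alpha}",
                            "tpr": ev.tpr,
                            "ppv": ev.ppv,
                            "n_declared": ev.n_declared,
                        }
                    )
                align = align_codes(A, B)
                model = fs_em_fit(A, B, align)
                fscores = fs_score(model, A, B, align)
                for name, ms in (
                    ("fs", fs_classify(fscores, fs_threshold)),
                    ("fs_1to1", fs_one_to_one(fscores, fs_threshold)),
                ):
                    ev = evaluate(ms, truth)
                    rows.append(
                        {
                            **common,
                            "method": name,
                            "tpr": ev.tpr,
                            "ppv": ev.ppv,
                            "n_declared": ev.n_declared,
                        }
                    )
            except Exception as exc:  # cell failure must not kill the grid
                rows.append(
                    {**cell, "replicate": rep, "seed": seed, "error": str(exc)}
                )
    return pd.DataFrame(rows)
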