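"""End-to-end matching: align, estimate, score, decide.

`match_datasets` is the in-memory entry point; `match_pipeline` wraps it
with file I/O, configuration and a reproducible run report.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .datasets import BinaryRecordDataset, align_codes, filter_rare_codes
from .hyperparameters import auto_pi0, estimate_prevalence
from .matching import (
    HyperParameters,
    MatchSet,
    PosteriorMatrix,
    SimilarityMatrix,
    average_posteriors,
    compute_code_weights,
    compute_directed_posterior,
    compute_similarity,
    threshold_matches,
)

__all__ = ["MatchResult", "RunConfig", "match_datasets", "match_pipeline"]

log = logging.getLogger("diaglink")


@dataclass
class MatchResult:
    """Everything a matching run produced."""

    matches: dict[float, MatchSet]
    posterior: PosteriorMatrix
    similarity: SimilarityMatrix
    hyper: HyperParameters
    report: dict


def match_datasets(
    A: BinaryRecordDataset,
    B: BinaryRecordDataset,
    eps_minus=0.01,
    eps_plus=0.01,
    pi0: float | str = "auto",
    alphas: tuple[float, ...] = (0.5,),
    policy: str = "union",
    min_code_count: int = 1,
    clip: bool = True,
    seed: int | None = 0,
) -> MatchResult:
    """Match two binary-code datasets with the Bayesian posterior rule.

    ``pi0="auto"`` estimates the prior match probability from the
    similarity distribution (skew-t fit, rightmost inflexion, exceedance
    fraction); a float fixes it.  ``eps_minus``/``eps_plus`` may be scalars
    or per-aligned-code vectors.  Returns matches at every ``alpha``.
    """
    t0 = time.perf_counter()
    align = align_codes(A, B, policy=policy)
    align = filter_rare_codes(A, B, align, min_count=min_code_count)
    log.info("aligned %d codes (%s policy)", align.n_codes, policy)

    B_aligned = BinaryRecordDataset(
        list(B.patient_ids), align.shared_code_ids, B.reindexed(align.shared_code_ids)
    )
    A_aligned = BinaryRecordDataset(
        list(A.patient_ids), align.shared_code_ids, A.reindexed(align.shared_code_ids)
    )
    pi_B = estimate_prevalence(B_aligned, clip=clip)
    pi_A = estimate_prevalence(A_aligned, clip=clip)

    # provisional pi_0 only normalizes the posterior; the similarity scores
    # it is estimated from do not depend on it
    hyper = HyperParameters(
        pi_B=pi_B,
        eps_minus=eps_minus,
        eps_plus=eps_plus,
        pi_0=0.5,
        pi_A=pi_A,
        n_B=B.n_patients,
        clip=clip,
    )
    weights = compute_code_weights(hyper)
    sim = compute_similarity(A, B, align, weights)
    log.info("similarity computed for %d x %d pairs", *sim.scores.shape)

    skew_fit = None
    if pi0 == "auto":
        pi0_value, skew_fit = auto_pi0(sim, seed=seed)
        log.info("auto pi0 = %.3g (c0 = %.3g)", pi0_value, skew_fit.c0)
    else:
        pi0_value = float(pi0)
    hyper.pi_0 = pi0_value

    p_ab = compute_directed_posterior(sim, pi0_value, "A_to_B")
    p_ba = compute_directed_posterior(sim, pi0_value, "B_to_A")
    post = average_posteriors(p_ab, p_ba)
    matches = {alpha: threshold_matches(post, alpha) for alpha in alphas}

    report = {
        "version": __version__,
        "n_A": A.n_patients,
        "n_B": B.n_patients,
        "n_codes_aligned": align.n_codes,
        "policy": policy,
        "min_code_count": min_code_count,
        "eps_minus": np.mean(np.atleast_1d(eps_minus)).item(),
        "eps_plus": np.mean(np.atleast_1d(eps_plus)).item(),
        "pi0_mode": "auto" if pi0 == "auto" else "fixed",
        "pi0": pi0_value,
        "c0": None if skew_fit is None else skew_fit.c0,
        "skew_t": None
        if skew_fit is None
        else {
            "location": skew_fit.location,
            "scale": skew_fit.scale,
            "skewness": skew_fit.skewness,
            "df": skew_fit.df,
        },
        "alphas": list(alphas),
        "clip": clip,
        "seed": seed,
        "n_matches": {str(a): len(m) for a, m in matches.items()},
        "wall_time_s": time.perf_counter() - t0,
    }
    return MatchResult(matches, post, sim, hyper, report)


@dataclass
class RunConfig:
    """File-based configuration of a matching run."""

    path_A: str
    path_B: str
    out_matches: str
    policy: str = "union"
    eps_minus: float = 0.01
    eps_plus: float = 0.01
    pi0: float | str = "auto"
    alpha: float = 0.5
    min_code_count: int = 1
    out_posterior: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly in (0, 1)")


def match_pipeline(cfg: RunConfig) -> MatchResult:
    """read -> align -> filter -> estimate -> score -> decide -> write."""
    from .io import read_binary_dataset, write_match_table, write_posterior_mtx

    A = read_binary_dataset(cfg.path_A)
    B = read_binary_dataset(cfg.path_B)
    result = match_datasets(
        A,
        B,
        eps_minus=cfg.eps_minus,
        eps_plus=cfg.eps_plus,
        pi0=cfg.pi0,
        alphas=(cfg.alpha,),
        policy=cfg.policy,
        min_code_count=cfg.min_code_count,
        seed=cfg.seed,
    )
    write_match_table(result.matches[cfg.alpha], cfg.out_matches)
    if cfg.out_posterior:
        write_posterior_mtx(result.posterior, cfg.out_posterior)
    result.report["config"] = {
        "path_A": cfg.path_A,
        "path_B": cfg.path_B,
        "out_matches": cfg.out_matches,
        "alpha": cfg.alpha,
    }
    return result
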