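"""Bayesian posterior matching from binary code profiles.

The model: for a candidate pair (i, j) across datasets A and B, each shared
code k contributes a log-likelihood-ratio weight comparing the match
hypothesis (B's indicator is A's indicator flipped with discrepancy rates
``eps_minus`` = P(absent in B | present in A, match) and ``eps_plus`` =
P(present in B | absent in A, match)) against the non-match hypothesis
(B's indicator is an independent Bernoulli with prevalence ``pi_B[k]``).
Summing the K per-code weights under a naive-Bayes assumption gives the
similarity L(i, j).  Treating, for a fixed record i in A, the events
"i matches j" (j = 1..nB) and "i matches nobody" as mutually exclusive and
exhaustive yields a softmax posterior over the nB candidates plus a no-match
category whose score is 0, with the prior match probability ``pi_0``
entering through its logit.  The final rule averages the two directed
posteriors and declares pairs with averaged posterior >= alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logit

from .datasets import BinaryRecordDataset, CodeAlignment

__all__ = [
    "HyperParameters",
    "CodeWeightTable",
    "SimilarityMatrix",
    "PosteriorMatrix",
    "MatchSet",
    "compute_code_weights",
    "compute_similarity",
    "compute_directed_posterior",
    "average_posteriors",
    "threshold_matches",
]

#: clipping bound for discrepancy rates (keeps every log-weight finite)
EPS_CLIP = 1e-6


def clip_probability(p, lo: float, hi: float) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), lo, hi)


@dataclass
class HyperParameters:
    """Hyper-parameters of the matching likelihood.

    ``pi_B`` is the per-code prevalence in dataset B; ``eps_minus`` /
    ``eps_plus`` are discrepancy rates (scalar broadcast or per-code);
    ``pi_0`` is the prior probability that a random cross-dataset pair is a
    true match.  ``pi_A`` (optional) is only needed for the Fellegi-Sunter
    m/u bridge.  With ``clip=True`` (default) prevalences are clipped to
    [1/(2 nB), 1 - 1/(2 nB)] and discrepancy rates to [1e-6, 1 - 1e-6];
    with ``clip=False`` boundary values are rejected.
    """

    pi_B: np.ndarray
    eps_minus: np.ndarray
    eps_plus: np.ndarray
    pi_0: float = 0.01
    pi_A: np.ndarray | None = None
    n_B: int | None = None
    clip: bool = True

    def __post_init__(self) -> None:
        self.pi_B = np.atleast_1d(np.asarray(self.pi_B, dtype=float))
        K = self.pi_B.shape[0]
        self.eps_minus = np.broadcast_to(
            np.asarray(self.eps_minus, dtype=float), (K,)
        ).copy()
        self.eps_plus = np.broadcast_to(
            np.asarray(self.eps_plus, dtype=float), (K,)
        ).copy()
        if self.pi_A is not None:
            self.pi_A = np.broadcast_to(np.asarray(self.pi_A, dtype=float), (K,)).copy()
        if self.clip:
            lo = 1.0 / (2 * self.n_B) if self.n_B else EPS_CLIP
            self.pi_B = clip_probability(self.pi_B, lo, 1 - lo)
            self.eps_minus = clip_probability(self.eps_minus, EPS_CLIP, 1 - EPS_CLIP)
            self.eps_plus = clip_probability(self.eps_plus, EPS_CLIP, 1 - EPS_CLIP)
            if self.pi_A is not None:
                self.pi_A = clip_probability(self.pi_A, lo, 1 - lo)
        else:
            for name, v in (
                ("pi_B", self.pi_B),
                ("eps_minus", self.eps_minus),
                ("eps_plus", self.eps_plus),
            ):
                bad = (v <= 0) | (v >= 1)
                if bad.any():
                    k = int(np.argmax(bad))
                    raise ValueError(
                        f"{name}[{k}] = {v[k]} is outside the open interval (0, 1)"
                    )
        if not 0.0 < self.pi_0 < 1.0:
            raise ValueError(f"pi_0 = {self.pi_0} must lie strictly in (0, 1)")

    @property
    def n_codes(self) -> int:
        return self.pi_B.shape[0]


@dataclass
class CodeWeightTable:
    """Per-code log-likelihood-ratio weights for the four (a, b) patterns.

    w11[k] = log((1 - eps_minus[k]) / pi_B[k])        (present, present)
    w00[k] = log((1 - eps_plus[k]) / (1 - pi_B[k]))   (absent, absent)
    w10[k] = log(eps_minus[k] / (1 - pi_B[k]))        (present, absent)
    w01[k] = log(eps_plus[k] / pi_B[k])               (absent, present)
    """

    w11: np.ndarray
    w00: np.ndarray
    w10: np.ndarray
    w01: np.ndarray

    @property
    def n_codes(self) -> int:
        return self.w11.shape[0]


def compute_code_weights(hyper: HyperParameters) -> CodeWeightTable:
    """Evaluate the four per-code log-weights from the hyper-parameters."""
    pi_B, em, ep = hyper.pi_B, hyper.eps_minus, hyper.eps_plus
    table = CodeWeightTable(
        w11=np.log((1 - em) / pi_B),
        w00=np.log((1 - ep) / (1 - pi_B)),
        w10=np.log(em / (1 - pi_B)),
        w01=np.log(ep / pi_B),
    )
    for name in ("w11", "w00", "w10", "w01"):
        if not np.all(np.isfinite(getattr(table, name))):
            k = int(np.argmax(~np.isfinite(getattr(table, name))))
            raise ValueError(f"non-finite weight {name}[{k}]; check hyper-parameters")
    return table


@dataclass
class SimilarityMatrix:
    """nA × nB log-likelihood-ratio similarity scores."""

    scores: np.ndarray
    patient_ids_A: list[str]
    patient_ids_B: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.patient_ids_A), len(self.patient_ids_B)):
            raise ValueError("score matrix shape does not match identifier lists")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("similarity scores must be finite")


def compute_similarity(
    A: BinaryRecordDataset,
    B: BinaryRecordDataset,
    align: CodeAlignment,
    weights: CodeWeightTable,
) -> SimilarityMatrix:
    """All-pairs similarity L(i, j) = sum_k L_k(A_k(i), B_k(j)).

    Computed through the exact rank-1 + bilinear decomposition

        L = C + r_A(i) + c_B(j) + A diag(d) B^T

    with C = sum w00, r_A = A (w10 - w00), c_B = B (w01 - w00) and
    d = w11 - w10 - w01 + w00, which is algebraically identical to the
    per-code pattern sum but runs as one sparse-friendly matrix product.
    """
    if weights.n_codes != align.n_codes:
        raise ValueError(
            f"weight table covers {weights.n_codes} codes but the alignment "
            f"has {align.n_codes}"
        )
    MA = A.reindexed(align.shared_code_ids).astype(float)
    MB = B.reindexed(align.shared_code_ids).astype(float)
    w11, w00, w10, w01 = weights.w11, weights.w00, weights.w10, weights.w01
    C = w00.sum()
    rA = MA @ (w10 - w00)
    cB = MB @ (w01 - w00)
    d = w11 - w10 - w01 + w00
    scores = C + rA[:, None] + cB[None, :] + (MA * d) @ MB.T
    return SimilarityMatrix(scores, list(A.patient_ids), list(B.patient_ids))


@dataclass
class PosteriorMatrix:
    """nA × nB posterior match probabilities.

    ``direction`` is ``A_to_B`` (each row sums to <= 1, the deficit being the
    no-match probability), ``B_to_A`` (per column), or ``averaged``.
    """

    probs: np.ndarray
    direction: str
    patient_ids_A: list[str]
    patient_ids_B: list[str]

    def __post_init__(self) -> None:
        if self.direction not in ("A_to_B", "B_to_A", "averaged"):
            raise ValueError(f"unknown direction {self.direction!r}")
        self.probs = np.asarray(self.probs, dtype=float)

    def no_match_probability(self) -> np.ndarray:
        """Residual probability mass of the no-match category."""
        if self.direction == "A_to_B":
            return 1.0 - self.probs.sum(axis=1)
        if self.direction == "B_to_A":
            return 1.0 - self.probs.sum(axis=0)
        raise ValueError("no-match mass is only defined for directed posteriors")


def compute_directed_posterior(
    sim: SimilarityMatrix, pi_0: float, direction: str
) -> PosteriorMatrix:
    """Softmax posterior over candidates plus a no-match category.

    For direction ``A_to_B`` and row i:

        P(X_i = j) = exp(L(ij) + logit(pi_0)) / (1 + sum_l exp(L(il) + logit(pi_0)))

    The ``1`` in the denominator is the no-match category (score 0).
    Evaluated with a max-shift in log space so that similarity scores in the
    hundreds (K in the thousands) cannot overflow.
    """
    if not 0.0 < pi_0 < 1.0:
        raise ValueError("pi_0 must lie strictly in (0, 1)")
    if not np.all(np.isfinite(sim.scores)):
        raise ValueError("similarity scores must be finite")
    s = sim.scores + logit(pi_0)
    axis = 1 if direction == "A_to_B" else 0
    if direction not in ("A_to_B", "B_to_A"):
        raise ValueError(f"unknown direction {direction!r}")
    # no-match category has shifted score 0; include it in the max
    m = np.maximum(s.max(axis=axis, keepdims=True), 0.0)
    num = np.exp(s - m)
    den = np.exp(-m) + num.sum(axis=axis, keepdims=True)
    return PosteriorMatrix(num / den, direction, sim.patient_ids_A, sim.patient_ids_B)


def average_posteriors(p_ab: PosteriorMatrix, p_ba: PosteriorMatrix) -> PosteriorMatrix:
    """Elementwise mean of the two directed posteriors."""
    if {p_ab.direction, p_ba.direction} != {"A_to_B", "B_to_A"}:
        raise ValueError("need one A_to_B and one B_to_A posterior")
    if p_ab.probs.shape != p_ba.probs.shape:
        raise ValueError("posterior shapes differ")
    return PosteriorMatrix(
        (p_ab.probs + p_ba.probs) / 2.0,
        "averaged",
        p_ab.patient_ids_A,
        p_ab.patient_ids_B,
    )


@dataclass
class MatchSet:
    """Declared matches: (patient_id_A, patient_id_B, score) triples."""

    pairs: set[tuple[str, str, float]]
    threshold_used: float

    def id_pairs(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


def threshold_matches(post: PosteriorMatrix, alpha: float) -> MatchSet:
    """Declare every pair with averaged posterior >= alpha (ties included)."""
    if post.direction != "averaged":
        raise ValueError("thresholding applies to the averaged posterior")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly in (0, 1)")
    ii, jj = np.nonzero(post.probs >= alpha)
    pairs = {
        (post.patient_ids_A[i], post.patient_ids_B[j], float(post.probs[i, j]))
        for i, j in zip(ii, jj)
    }
    return MatchSet(pairs, alpha)
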