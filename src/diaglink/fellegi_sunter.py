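"""Fellegi-Sunter probabilistic linkage baseline with EM estimation.

The classical latent-class model: each candidate pair is a match (with
proportion p) or a non-match; field k *agrees* when the two records carry
the same indicator — and, deliberately, a (0, 0) concordance counts exactly
like a (1, 1) concordance, which is the known weakness of this comparator
on sparse binary codes.  Agreement on field k has probability m_k given a
match and u_k given a non-match; fields are conditionally independent.
(m, u, p) are estimated by EM over the all-pairs agreement patterns
(Winkler / Grannis style), pairs are scored with the classical log-weights,
and two decision rules are provided: score thresholding and the 1-1
"largest score, ties kept" variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .datasets import BinaryRecordDataset, CodeAlignment
from .matching import MatchSet

__all__ = [
    "FSModel",
    "FSScoreMatrix",
    "fs_em_fit",
    "fs_score",
    "fs_one_to_one",
    "fs_classify",
    "make_blocking_mask",
]

PARAM_CLIP = 1e-6


@dataclass
class FSModel:
    """Fitted Fellegi-Sunter parameters.

    m[k] = P(records agree on code k | pair is a match),
    u[k] = P(agree | non-match), p = match proportion among candidate pairs.
    """

    m: np.ndarray
    u: np.ndarray
    p: float
    n_iter: int
    converged: bool
    log_likelihood_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class FSScoreMatrix:
    """nA × nB agreement log-weights; blocked-out pairs carry NaN."""

    scores: np.ndarray
    patient_ids_A: list[str]
    patient_ids_B: list[str]
    blocking_mask: np.ndarray | None = None


def _aligned(A, B, align):
    return (
        A.reindexed(align.shared_code_ids).astype(float),
        B.reindexed(align.shared_code_ids).astype(float),
    )


def _agreement_weighted_sum(MA, MB, v):
    """S[i, j] = sum_k agree(i, j, k) * v[k], using
    agree = 1 - a - b + 2ab so no nA*nB*K tensor is formed."""
    return v.sum() - (MA @ v)[:, None] - (MB @ v)[None, :] + 2.0 * (MA * v) @ MB.T


def _em_loop(loglik_match_fn, loglik_non_fn, mstep_fn, init, tol, max_iter):
    """Generic EM driver shared by the plain and compressed paths."""
    m, u, p = init
    trace = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        l1 = np.log(p) + loglik_match_fn(m)
        l0 = np.log1p(-p) + loglik_non_fn(u)
        gamma = expit(l1 - l0)
        trace.append(float(np.sum(np.logaddexp(l1, l0) * mstep_fn.weights)))
        m_new, u_new, p_new = mstep_fn(gamma)
        delta = max(
            float(np.max(np.abs(m_new - m))),
            float(np.max(np.abs(u_new - u))),
            abs(p_new - p),
        )
        m, u, p = m_new, u_new, p_new
        if delta < tol:
            converged = True
            break
    return m, u, p, n_iter, converged, np.asarray(trace)


class _PlainMStep:
    def __init__(self, MA, MB, mask):
        self.MA, self.MB = MA, MB
        self.weights = mask if mask is not None else 1.0
        self.n_admissible = (
            float(mask.sum()) if mask is not None else MA.shape[0] * MB.shape[0]
        )

    def _weighted_agreement(self, W):
        # sum_ij W_ij * agree(i,j,k), decomposed the same way as the E-step
        G = W.sum()
        row = W.sum(axis=1)
        col = W.sum(axis=0)
        cross = (self.MA * (W @ self.MB)).sum(axis=0)
        return G - self.MA.T @ row - self.MB.T @ col + 2.0 * cross, G

    def __call__(self, gamma):
        g = gamma * self.weights
        v = (1.0 - gamma) * self.weights
        agr_m, Gm = self._weighted_agreement(g)
        agr_u, Gu = self._weighted_agreement(v)
        m = np.clip(agr_m / Gm, PARAM_CLIP, 1 - PARAM_CLIP)
        u = np.clip(agr_u / Gu, PARAM_CLIP, 1 - PARAM_CLIP)
        p = float(np.clip(Gm / self.n_admissible, PARAM_CLIP, 1 - PARAM_CLIP))
        return m, u, p


class _CompressedMStep:
    """EM over unique agreement patterns with multiplicities (K <= 64)."""

    def __init__(self, patterns, counts):
        self.patterns = patterns  # (n_unique, K) 0/1
        self.counts = counts.astype(float)
        self.weights = self.counts
        self.n_admissible = float(self.counts.sum())

    def __call__(self, gamma):
        g = gamma * self.counts
        v = (1.0 - gamma) * self.counts
        m = np.clip(self.patterns.T @ g / g.sum(), PARAM_CLIP, 1 - PARAM_CLIP)
        u = np.clip(self.patterns.T @ v / v.sum(), PARAM_CLIP, 1 - PARAM_CLIP)
        p = float(np.clip(g.sum() / self.n_admissible, PARAM_CLIP, 1 - PARAM_CLIP))
        return m, u, p


def _pack_bits(M):
    K = M.shape[1]
    bits = np.zeros(M.shape[0], dtype=np.uint64)
    for k in range(K):
        bits |= M[:, k].astype(np.uint64) << np.uint64(k)
    return bits


def _unique_agreement_patterns(MA, MB, mask):
    """Bit-pack records, XOR all pairs, and collapse identical agreement
    vectors; returns (patterns as 0/1 matrix, multiplicities)."""
    K = MA.shape[1]
    pa = _pack_bits(MA)
    pb = _pack_bits(MB)
    full = np.uint64((1 << K) - 1)
    agree = (~(pa[:, None] ^ pb[None, :])) & full
    if mask is not None:
        agree = agree[mask.astype(bool)]
    else:
        agree = agree.ravel()
    uniq, counts = np.unique(agree, return_counts=True)
    patterns = ((uniq[:, None] >> np.arange(K, dtype=np.uint64)) & np.uint64(1)).astype(
        float
    )
    return patterns, counts


def fs_em_fit(
    A: BinaryRecordDataset,
    B: BinaryRecordDataset,
    align: CodeAlignment,
    blocking_mask: np.ndarray | None = None,
    init: tuple | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    compress: str = "auto",
) -> FSModel:
    """Fit (m, u, p) by EM over all admissible pairs.

    Initialization defaults to m0 = 0.9, u0 = each code's empirical
    agreement rate over admissible pairs, p0 = 1/max(nA, nB).  Identical
    agreement patterns are collapsed with multiplicities when K <= 64
    (``compress="auto"``); force with ``"always"``/``"never"`` — both paths
    return identical estimates.  Non-convergence at ``max_iter`` returns
    the current estimates with ``converged=False`` and a warning.
    """
    MA, MB = _aligned(A, B, align)
    K = align.n_codes
    if K < 1:
        raise ValueError("need at least one aligned code")
    if blocking_mask is not None:
        blocking_mask = np.asarray(blocking_mask, dtype=float)
        if blocking_mask.shape != (A.n_patients, B.n_patients):
            raise ValueError("blocking mask shape mismatch")
        if blocking_mask.sum() == 0:
            raise ValueError("blocking mask admits no pairs")

    if init is None:
        # per-code empirical agreement count over admissible pairs, via the
        # same 1 - a - b + 2ab decomposition as the E-step
        if blocking_mask is not None:
            n_adm = float(blocking_mask.sum())
            row = blocking_mask.sum(axis=1)
            col = blocking_mask.sum(axis=0)
            cross = (MA * (blocking_mask @ MB)).sum(axis=0)
            per_code = n_adm - MA.T @ row - MB.T @ col + 2.0 * cross
        else:
            n_adm = float(A.n_patients * B.n_patients)
            per_code = (
                n_adm
                - MA.sum(axis=0) * B.n_patients
                - MB.sum(axis=0) * A.n_patients
                + 2.0 * MA.sum(axis=0) * MB.sum(axis=0)
            )
        u0 = np.clip(per_code / n_adm, 0.05, 0.95)
        init = (np.full(K, 0.9), u0, 1.0 / max(A.n_patients, B.n_patients))
    m0, u0, p0 = init
    m0 = np.broadcast_to(np.asarray(m0, dtype=float), (K,)).copy()
    u0 = np.broadcast_to(np.asarray(u0, dtype=float), (K,)).copy()
    if not (
        np.all((m0 > 0) & (m0 < 1)) and np.all((u0 > 0) & (u0 < 1)) and 0 < p0 < 1
    ):
        raise ValueError("EM initialization must lie strictly in (0, 1)")

    use_compress = compress == "always" or (compress == "auto" and K <= 64)
    if use_compress and K > 64:
        raise ValueError("agreement-pattern compression requires K <= 64")

    if use_compress:
        patterns, counts = _unique_agreement_patterns(MA, MB, blocking_mask)
        mstep = _CompressedMStep(patterns, counts)

        def l_match(m):
            return patterns @ logit(m) + np.log1p(-m).sum()

        def l_non(u):
            return patterns @ logit(u) + np.log1p(-u).sum()

    else:
        mask = blocking_mask
        mstep = _PlainMStep(MA, MB, mask)

        def l_match(m):
            return _agreement_weighted_sum(MA, MB, logit(m)) + np.log1p(-m).sum()

        def l_non(u):
            return _agreement_weighted_sum(MA, MB, logit(u)) + np.log1p(-u).sum()

    m, u, p, n_iter, converged, trace = _em_loop(
        l_match, l_non, mstep, (m0, u0, p0), tol, max_iter
    )
    if not converged:
        warnings.warn(
            f"Fellegi-Sunter EM did not converge in {max_iter} iterations",
            RuntimeWarning,
        )
    if np.all(m >= 1 - 2 * PARAM_CLIP) and np.all(u >= 1 - 2 * PARAM_CLIP):
        warnings.warn(
            "m and u both at the upper clip boundary: agreement is universal "
            "and the match proportion p is unidentifiable",
            RuntimeWarning,
        )
    return FSModel(m, u, float(p), n_iter, converged, trace)


def fs_score(
    model: FSModel,
    A: BinaryRecordDataset,
    B: BinaryRecordDataset,
    align: CodeAlignment,
    blocking_mask: np.ndarray | None = None,
) -> FSScoreMatrix:
    """Classical agreement log-weights:
    sum_k [agree_k log(m_k/u_k) + (1 - agree_k) log((1-m_k)/(1-u_k))]."""
    MA, MB = _aligned(A, B, align)
    base = float(np.sum(np.log1p(-model.m) - np.log1p(-model.u)))
    v = logit(model.m) - logit(model.u)
    scores = base + _agreement_weighted_sum(MA, MB, v)
    if blocking_mask is not None:
        scores = np.where(blocking_mask.astype(bool), scores, np.nan)
    return FSScoreMatrix(
        scores, list(A.patient_ids), list(B.patient_ids), blocking_mask
    )


def fs_classify(scores: FSScoreMatrix, threshold: float) -> MatchSet:
    """Unmodified baseline: every admissible pair scoring >= threshold."""
    with np.errstate(invalid="ignore"):
        sel = scores.scores >= threshold
    sel &= ~np.isnan(scores.scores)
    ii, jj = np.nonzero(sel)
    pairs = {
        (scores.patient_ids_A[i], scores.patient_ids_B[j], float(scores.scores[i, j]))
        for i, j in zip(ii, jj)
    }
    return MatchSet(pairs, threshold)


def fs_one_to_one(
    scores: FSScoreMatrix, threshold: float, mode: str = "col"
) -> MatchSet:
    """1-1 variant: keep only each record's largest score (ties kept).

    ``mode="col"`` (default) declares, for each record j of dataset B, the
    pair(s) attaining the column-j maximum; ``"row"`` does the same per
    record of A; ``"both"`` requires a pair to attain both its row and its
    column maximum (the strictest reading).  In every mode the pair must
    also score >= threshold, and ties at the maximum are all kept, so a
    record may still appear in several declared pairs.
    """
    if mode not in ("row", "col", "both"):
        raise ValueError(f"unknown 1-1 mode {mode!r}")
    S = scores.scores
    with np.errstate(invalid="ignore", all="ignore"):
        masked = np.where(np.isnan(S), -np.inf, S)
        row_max = masked.max(axis=1, keepdims=True)
        col_max = masked.max(axis=0, keepdims=True)
        sel = S >= threshold
        if mode in ("row", "both"):
            sel &= S == row_max
        if mode in ("col", "both"):
            sel &= S == col_max
    sel &= ~np.isnan(S)
    ii, jj = np.nonzero(sel)
    pairs = {
        (scores.patient_ids_A[i], scores.patient_ids_B[j], float(S[i, j]))
        for i, j in zip(ii, jj)
    }
    return MatchSet(pairs, threshold)


def make_blocking_mask(block_A, block_B) -> np.ndarray:
    """Admissibility mask: pair (i, j) is admissible iff the blocking labels
    agree.  Missing labels are rejected; disjoint label sets warn."""
    a = np.asarray(block_A, dtype=object)
    b = np.asarray(block_B, dtype=object)
    if any(x is None or (isinstance(x, float) and np.isnan(x)) for x in a) or any(
        x is None or (isinstance(x, float) and np.isnan(x)) for x in b
    ):
        raise ValueError("every patient needs a blocking label")
    mask = a[:, None] == b[None, :]
    if not mask.any():
        warnings.warn(
            "blocking label sets are disjoint: no admissible pairs", RuntimeWarning
        )
    return mask
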