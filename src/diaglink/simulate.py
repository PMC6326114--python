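"""Synthetic linked dataset pairs with known ground truth.

Emulates the structure of administrative-claims diagnosis data: a sparse
patient × code binary matrix with heavy-tailed per-code prevalence (many
rare codes, a few common ones) and code-code correlation, generated by a
Gaussian-copula threshold model.  A second, discrepant dataset is created
by the correlated-Gaussian perturbation

    X* = 1{X * N(1, rho * Sigma) + (1 - X) * N(-3, rho * Sigma) > 0}

so present codes survive with probability ~ Phi(1/sqrt(rho)) while absent
codes appear with the far smaller probability Phi(-3/sqrt(rho)) — an
asymmetry matching real claims discrepancies, where dropping a recorded
code is much likelier than inventing one.  Finally the two datasets are
subset to a configurable partial overlap, yielding a known 1-1 truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import BinaryRecordDataset

__all__ = [
    "SimulationConfig",
    "LinkedTruth",
    "generate_base_matrix",
    "empirical_correlation",
    "perturb",
    "split_overlap",
    "simulate_linked_pair",
]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated linkage problem.

    Defaults reproduce a scaled-down claims-like setting: 800 patients,
    1,000 codes, Beta(0.3, 6) heavy-tailed prevalences rescaled so patients
    carry 5 codes on average, noise level ``rho`` = 0.5, and two subsets of
    500 and 300 patients sharing 150 true matches.
    """

    n_patients: int = 800
    K: int = 1000
    prevalence_a: float = 0.3
    prevalence_b: float = 6.0
    mean_codes_per_patient: float | None = 5.0
    correlation_strength: float = 0.0
    rho: float = 0.5
    n_A: int = 500
    n_B: int = 300
    n_overlap: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be at least 1")
        if self.n_A > self.n_patients or self.n_B > self.n_patients:
            raise ValueError("subset sizes cannot exceed n_patients")
        if self.n_overlap > min(self.n_A, self.n_B):
            raise ValueError("n_overlap cannot exceed min(n_A, n_B)")
        if self.n_A + self.n_B - self.n_overlap > self.n_patients:
            raise ValueError(
                "n_A + n_B - n_overlap exceeds the patient pool; infeasible"
            )
        if self.rho < 0:
            raise ValueError("rho must be non-negative")
        if not 0 <= self.correlation_strength < 1:
            raise ValueError("correlation_strength must lie in [0, 1)")


@dataclass
class LinkedTruth:
    """Known 1-1 ground-truth pairs (patient_id_A, patient_id_B)."""

    pairs: set[tuple[str, str]]

    def __post_init__(self) -> None:
        ids_a = [a for a, _ in self.pairs]
        ids_b = [b for _, b in self.pairs]
        if len(set(ids_a)) != len(ids_a) or len(set(ids_b)) != len(ids_b):
            raise ValueError("truth must be a 1-1 pairing")

    def __len__(self) -> int:
        return len(self.pairs)


def sample_prevalences(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed per-code prevalences: Beta(a, b) draws, optionally
    rescaled so their sum (= expected codes per patient) hits the target."""
    p = rng.beta(cfg.prevalence_a, cfg.prevalence_b, size=cfg.K)
    p = np.clip(p, 1e-4, 0.99)
    if cfg.mean_codes_per_patient is not None:
        p = p * (cfg.mean_codes_per_patient / p.sum())
        p = np.clip(p, 1e-5, 0.99)
    return p


def nearest_psd_factor(Sigma: np.ndarray) -> np.ndarray:
    """Factor L with L L^T ~= Sigma, flooring negative eigenvalues at 0.

    Empirical binary correlation matrices need not be PSD after column
    filtering, so a spectral floor is applied before factorization.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    vals, vecs = np.linalg.eigh((Sigma + Sigma.T) / 2.0)
    if (vals < -1e-8 * max(1.0, vals.max())).any():
        import warnings

        warnings.warn(
            "correlation matrix is not PSD; projecting by flooring negative "
            "eigenvalues at zero",
            RuntimeWarning,
        )
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def generate_base_matrix(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    correlation: np.ndarray | None = None,
) -> BinaryRecordDataset:
    """Sparse binary matrix from a Gaussian-copula threshold model.

    Each patient draws a latent K-vector Z; code k is present iff
    Z_k exceeds the normal quantile matching its target prevalence, so the
    marginals are exact by construction.  The latent correlation is either
    a single-factor equicorrelation of strength ``correlation_strength``
    (default) or an explicit ``correlation`` matrix (PSD-projected).
    """
    from scipy.stats import norm

    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    p = sample_prevalences(cfg, rng)
    n, K = cfg.n_patients, cfg.K
    if correlation is not None:
        L = nearest_psd_factor(correlation)
        Z = rng.standard_normal((n, K)) @ L.T
        # renormalize to unit marginal variance so thresholds stay calibrated
        sd = np.sqrt(np.clip(np.diag(L @ L.T), 1e-12, None))
        Z = Z / sd
    elif cfg.correlation_strength > 0:
        r = cfg.correlation_strength
        common = rng.standard_normal((n, 1))
        Z = np.sqrt(r) * common + np.sqrt(1 - r) * rng.standard_normal((n, K))
    else:
        Z = rng.standard_normal((n, K))
    thresholds = norm.ppf(1.0 - p)
    X = (Z > thresholds[None, :]).astype(np.int8)
    ids = [f"P{idx:06d}" for idx in range(n)]
    codes = [f"C{k:05d}" for k in range(K)]
    return BinaryRecordDataset(ids, codes, X)


def empirical_correlation(D: BinaryRecordDataset) -> np.ndarray:
    """Pearson (phi) correlation of the binary columns; zero-variance
    columns get self-correlation 1 and zero cross-correlation."""
    if D.n_patients < 2:
        raise ValueError("need at least two patients")
    M = D.matrix.astype(float)
    sd = M.std(axis=0)
    ok = sd > 0
    C = np.zeros((D.n_codes, D.n_codes))
    np.fill_diagonal(C, 1.0)
    if ok.any():
        sub = np.corrcoef(M[:, ok], rowvar=False)
        sub = np.atleast_2d(sub)
        idx = np.nonzero(ok)[0]
        C[np.ix_(idx, idx)] = sub
    return C


def perturb(
    X: BinaryRecordDataset,
    rho: float,
    Sigma: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> BinaryRecordDataset:
    """Correlated-Gaussian perturbation of a binary matrix.

    Per patient, two independent latent draws Z1 ~ N(1, rho*Sigma) and
    Z2 ~ N(-3, rho*Sigma); the perturbed indicator is
    1{X*Z1 + (1-X)*Z2 > 0} (exactly 0 maps to 0).  ``rho=0`` returns the
    input unchanged.  ``Sigma`` defaults to the identity.
    """
    if rho < 0:
        raise ValueError("rho must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = X.n_codes
    M = X.matrix.astype(float)
    if rho == 0:
        Xstar = X.matrix.copy()
    else:
        Sigma = np.eye(K) if Sigma is None else np.asarray(Sigma, dtype=float)
        if Sigma.shape != (K, K):
            raise ValueError("Sigma must be K x K")
        L = nearest_psd_factor(Sigma) * np.sqrt(rho)
        n = X.n_patients
        Z1 = 1.0 + rng.standard_normal((n, K)) @ L.T
        Z2 = -3.0 + rng.standard_normal((n, K)) @ L.T
        Xstar = ((M * Z1 + (1.0 - M) * Z2) > 0).astype(np.int8)
    return BinaryRecordDataset(list(X.patient_ids), list(X.code_ids), Xstar)


def split_overlap(
    X: BinaryRecordDataset,
    X_star: BinaryRecordDataset,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[BinaryRecordDataset, BinaryRecordDataset, LinkedTruth]:
    """Subset the original and perturbed matrices to two partially
    overlapping datasets with re-randomized opaque identifiers.

    Exactly ``cfg.n_overlap`` patients appear in both subsets; row orders
    are shuffled independently so position carries no matching signal.
    """
    if X.matrix.shape != X_star.matrix.shape:
        raise ValueError("original and perturbed matrices differ in shape")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    n = X.n_patients
    perm = rng.permutation(n)
    shared = perm[: cfg.n_overlap]
    only_a = perm[cfg.n_overlap : cfg.n_A]
    only_b = perm[cfg.n_A : cfg.n_A + (cfg.n_B - cfg.n_overlap)]
    rows_a = np.concatenate([shared, only_a]).astype(int)
    rows_b = np.concatenate([shared, only_b]).astype(int)
    order_a = rng.permutation(cfg.n_A)
    order_b = rng.permutation(cfg.n_B)
    rows_a = rows_a[order_a]
    rows_b = rows_b[order_b]
    ids_a = [f"A{idx:06d}" for idx in range(cfg.n_A)]
    ids_b = [f"B{idx:06d}" for idx in range(cfg.n_B)]
    A = BinaryRecordDataset(ids_a, list(X.code_ids), X.matrix[rows_a])
    B = BinaryRecordDataset(ids_b, list(X.code_ids), X_star.matrix[rows_b])
    pos_a = {orig: ids_a[i] for i, orig in enumerate(rows_a)}
    pos_b = {orig: ids_b[j] for j, orig in enumerate(rows_b)}
    truth = LinkedTruth({(pos_a[s], pos_b[s]) for s in shared})
    return A, B, truth


def simulate_linked_pair(
    cfg: SimulationConfig,
    use_empirical_sigma: bool = True,
) -> tuple[BinaryRecordDataset, BinaryRecordDataset, LinkedTruth]:
    """End-to-end simulation: base matrix, perturbation (with the base
    data's own empirical code correlation as Sigma by default, mirroring
    how claims data would be perturbed), and overlap subsetting."""
    rng = np.random.default_rng(cfg.seed)
    X = generate_base_matrix(cfg, rng=rng)
    Sigma = empirical_correlation(X) if use_empirical_sigma else None
    X_star = perturb(X, cfg.rho, Sigma=Sigma, seed=rng)
    return split_overlap(X, X_star, cfg, rng=rng)
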