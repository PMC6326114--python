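"""Hyper-parameter estimation: prevalences, the prior match probability
pi_0, and (optionally) discrepancy rates.

The pairwise similarities of a linkage problem follow a two-component
mixture pi_0 * g + (1 - pi_0) * f where f is the (overwhelmingly dominant)
non-match component and g the match component.  Since pi_0 is tiny, f can be
estimated by fitting a four-parameter Azzalini skew-t density to *all*
similarities; pi_0 is then the fraction of pairs whose similarity exceeds
c0, the rightmost inflexion point of the fitted f — beyond the last
curvature change of f, mass is attributed to matches.  The match component g
is never fitted.  The procedure is deliberately rough: downstream matching
is insensitive to pi_0 over orders of magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .datasets import BinaryRecordDataset, CodeAlignment
from .matching import EPS_CLIP, SimilarityMatrix, clip_probability

__all__ = [
    "SkewTFit",
    "estimate_prevalence",
    "skew_t_logpdf",
    "skew_t_pdf",
    "fit_skew_t",
    "find_rightmost_inflexion",
    "estimate_pi0",
    "estimate_discrepancy_rates",
]

#: above this many pairwise similarities, fit on a seeded subsample
SUBSAMPLE_LIMIT = 5_000_000

NU_MAX = 200.0


def estimate_prevalence(D: BinaryRecordDataset, clip: bool = True) -> np.ndarray:
    """Per-code sample fractions, clipped into [1/(2n), 1 - 1/(2n)].

    Clipping keeps the log-weights of codes observed never (or always)
    finite; 1/(2n) is half an observation's worth of prevalence.
    """
    if D.n_patients < 1:
        raise ValueError("cannot estimate prevalence from an empty dataset")
    p = D.matrix.mean(axis=0).astype(float)
    if clip:
        lo = 1.0 / (2 * D.n_patients)
        p = clip_probability(p, lo, 1.0 - lo)
    return p


@dataclass
class SkewTFit:
    """Fitted Azzalini skew-t density.

    ``location`` (xi), ``scale`` (omega > 0), ``skewness`` (alpha, 0 means
    symmetric Student-t), ``df`` (nu > 0; large nu approaches skew-normal /
    normal).  ``c0`` is the rightmost inflexion abscissa of the fitted
    density, filled in by :func:`find_rightmost_inflexion`.
    """

    location: float
    scale: float
    skewness: float
    df: float
    log_likelihood: float
    converged: bool
    c0: float | None = None

    def pdf(self, x) -> np.ndarray:
        return skew_t_pdf(x, self.location, self.scale, self.skewness, self.df)


def skew_t_logpdf(x, location, scale, skewness, df) -> np.ndarray:
    """Log-density of the Azzalini skew-t: with z = (x - xi)/omega,

        f(x) = (2/omega) t_nu(z) T_{nu+1}(skew * z * sqrt((nu+1)/(nu+z^2)))

    where t and T are the Student-t density and distribution function.
    """
    x = np.asarray(x, dtype=float)
    z = (x - location) / scale
    w = skewness * z * np.sqrt((df + 1.0) / (df + z**2))
    return (
        np.log(2.0)
        - np.log(scale)
        + stats.t.logpdf(z, df)
        + stats.t.logcdf(w, df + 1.0)
    )


def skew_t_pdf(x, location, scale, skewness, df) -> np.ndarray:
    return np.exp(skew_t_logpdf(x, location, scale, skewness, df))


def _negloglik(theta: np.ndarray, x: np.ndarray) -> float:
    xi, log_omega, alpha, log_nu = theta
    ll = skew_t_logpdf(x, xi, np.exp(log_omega), alpha, np.exp(log_nu))
    # t.logcdf underflows to -inf for extreme arguments; keep the objective
    # finite so the quasi-Newton line search stays well-defined
    ll = np.nan_to_num(ll, nan=-1e10, neginf=-1e10)
    return -float(np.sum(ll))


def fit_skew_t(
    sample: np.ndarray,
    seed: int | None = None,
    subsample_limit: int = SUBSAMPLE_LIMIT,
) -> SkewTFit:
    """Maximum-likelihood Azzalini skew-t fit.

    Bounded quasi-Newton (L-BFGS-B) on (xi, log omega, alpha, log nu) with
    nu in [1, 200], multi-started from method-of-moments positions with
    positive, zero and negative initial skewness (small-sample skew-t
    likelihoods are multimodal).  Samples larger than ``subsample_limit``
    are thinned by a seeded uniform draw without replacement.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 100:
        raise ValueError(f"need at least 100 similarities to fit, got {x.size}")
    if x.size > subsample_limit:
        rng = np.random.default_rng(seed)
        x = rng.choice(x, size=subsample_limit, replace=False)
    # fitting must not depend on presentation order of the pairs
    x = np.sort(x)

    m, s = float(np.mean(x)), float(np.std(x))
    skew_sign = float(np.sign(stats.skew(x)) or 1.0)
    bounds = [
        (m - 10 * s, m + 10 * s),
        (np.log(s) - 8, np.log(s) + 8),
        (-50.0, 50.0),
        (0.0, np.log(NU_MAX)),
    ]
    starts = [
        (m, np.log(s), 0.0, np.log(10.0)),
        (m, np.log(s), 2.0 * skew_sign, np.log(10.0)),
        (m, np.log(s), -2.0 * skew_sign, np.log(5.0)),
        (m, np.log(s), 5.0 * skew_sign, np.log(50.0)),
    ]
    best = None
    n_failures = 0
    for theta0 in starts:
        res = optimize.minimize(
            _negloglik,
            np.asarray(theta0),
            args=(x,),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if not np.isfinite(res.fun):
            n_failures += 1
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            f"skew-t fit failed from all {len(starts)} starts "
            f"({n_failures} non-finite objectives); sample summary: "
            f"mean={m:.3g} sd={s:.3g} n={x.size}"
        )
    xi, log_omega, alpha, log_nu = best.x
    return SkewTFit(
        location=float(xi),
        scale=float(np.exp(log_omega)),
        skewness=float(alpha),
        df=float(np.exp(log_nu)),
        log_likelihood=-float(best.fun),
        converged=bool(best.success),
    )


def find_rightmost_inflexion(
    fit: SkewTFit, grid_lo: float, grid_hi: float, n_grid: int = 10_001
) -> float:
    """Largest abscissa where the fitted density's second derivative changes
    sign, located by central differences on a uniform grid.

    For a normal-limit fit this is location + scale.  Raises if the grid
    shows no sign change (degenerate fit or grid too narrow).
    """
    grid = np.linspace(grid_lo, grid_hi, n_grid)
    f = fit.pdf(grid)
    d2 = np.diff(f, 2)  # curvature sign at grid[1:-1]
    sign = np.sign(d2)
    nz = sign != 0
    change = np.nonzero(nz[:-1] & nz[1:] & (sign[:-1] != sign[1:]))[0]
    if change.size == 0:
        raise ValueError(
            "no inflexion point of the fitted density found on "
            f"[{grid_lo:.4g}, {grid_hi:.4g}]"
        )
    k = change[-1]
    # sign change between grid[k+1] and grid[k+2]; midpoint is within one
    # grid step of the true inflexion
    return float(0.5 * (grid[k + 1] + grid[k + 2]))


def estimate_pi0(sim: SimilarityMatrix, c0: float) -> float:
    """Fraction of pairs with similarity strictly above ``c0``, kept inside
    (0, 1) by flooring/capping at one pair's worth of probability."""
    if not np.isfinite(c0):
        raise ValueError("c0 must be finite")
    n_total = sim.scores.size
    frac = float(np.count_nonzero(sim.scores > c0)) / n_total
    return float(np.clip(frac, 1.0 / n_total, 1.0 - 1.0 / n_total))


def estimate_discrepancy_rates(
    A: BinaryRecordDataset,
    B: BinaryRecordDataset,
    align: CodeAlignment,
    sim: SimilarityMatrix,
    c0: float,
    default: float = 0.01,
    clip: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Rough per-code discrepancy rates from high-similarity pairs.

    Pairs with similarity above ``c0`` are treated as presumptive matches;
    among them, eps_minus[k] is the fraction of (present in A, absent in B)
    outcomes among pairs with the code present in A, eps_plus[k] the
    fraction of (absent, present) among pairs with it absent in A.  Codes
    with an empty denominator fall back to ``default``.
    """
    ii, jj = np.nonzero(sim.scores > c0)
    if ii.size == 0:
        raise ValueError(
            "no pair exceeds the similarity threshold; supply eps_minus/"
            "eps_plus manually instead"
        )
    MA = A.reindexed(align.shared_code_ids)[ii].astype(float)
    MB = B.reindexed(align.shared_code_ids)[jj].astype(float)
    n_present = MA.sum(axis=0)
    n_absent = MA.shape[0] - n_present
    with np.errstate(invalid="ignore", divide="ignore"):
        eps_minus = (MA * (1 - MB)).sum(axis=0) / n_present
        eps_plus = ((1 - MA) * MB).sum(axis=0) / n_absent
    eps_minus = np.where(n_present > 0, eps_minus, default)
    eps_plus = np.where(n_absent > 0, eps_plus, default)
    if clip:
        eps_minus = clip_probability(eps_minus, EPS_CLIP, 1 - EPS_CLIP)
        eps_plus = clip_probability(eps_plus, EPS_CLIP, 1 - EPS_CLIP)
    return eps_minus, eps_plus


def auto_pi0(
    sim: SimilarityMatrix, seed: int | None = None
) -> tuple[float, SkewTFit]:
    """Full automatic pi_0 path: skew-t fit of the pooled similarities,
    rightmost inflexion c0, then the exceedance fraction."""
    flat = sim.scores.ravel()
    fit = fit_skew_t(flat, seed=seed)
    lo = float(flat.min()) - 2.0 * fit.scale
    hi = float(flat.max()) + 2.0 * fit.scale
    c0 = find_rightmost_inflexion(fit, lo, hi)
    fit.c0 = c0
    return estimate_pi0(sim, c0), fit
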