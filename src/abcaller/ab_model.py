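"""Latent Gaussian-process model of allele balance along the genome.

Allele balance (AB) — the fraction of amplified DNA derived from one
haplotype — is modeled on the logit scale as a zero-mean Gaussian process
over genomic position, observed indirectly through binomial read counts at
phased heterozygous SNPs:

    Y_i | B_i ~ Binomial(D_i, logistic(B_i))
    B ~ GP(0, k),   k(x1,x2) = exp(a - (x1-x2)^2/b^2) + exp(c - (x1-x2)^2/d^2)

The kernel sums two squared-exponential terms: a short length scale ``d``
absorbing read-scale correlation (shared reads between neighboring sites)
and a longer scale ``b`` tracking amplicon-scale imbalance.  The binomial
likelihood makes the posterior non-Gaussian; inference uses the standard
Laplace approximation for GP classification-style models (Newton iteration
on the latent mode, Gaussian curvature at the mode), applied independently
to blocks of consecutive hSNPs.  Kernel parameters are fit per chromosome by
maximizing the summed Laplace evidence over a parameter grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular
from scipy.special import expit, gammaln

from .io_model import PhasedHetSNP

logger = logging.getLogger(__name__)

# relative log-likelihood convergence threshold: sqrt(machine epsilon)
NEWTON_EPS = np.sqrt(2.2e-16)
NEWTON_MAX_ITER = 50
JITTER_SCALE = 1e-6

DEFAULT_GRID = {
    "a": (-6.0, -4.0, -2.0, -1.0, 0.0, 1.0),
    "b": (500.0, 1_000.0, 2_000.0, 5_000.0, 10_000.0, 20_000.0, 50_000.0),
    "c": (-6.0, -4.0, -2.0, -1.0, 0.0, 1.0),
    "d": (10.0, 50.0, 150.0, 300.0, 1_000.0),
}


@dataclass(frozen=True)
class CovParams:
    """Covariance-function parameters.

    ``a``/``c`` are log-amplitudes and ``b``/``d`` length scales (bp) of the
    long- and short-range squared-exponential terms.  The convention d <= b
    (short-range term second) is enforced by swapping the two terms.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if not np.isfinite(v):
                raise ValueError(f"non-finite covariance parameter in {self}")
        if self.b <= 0 or self.d <= 0:
            raise ValueError("length scales must be positive")
        if self.d > self.b:
            a, b, c, d = self.a, self.b, self.c, self.d
            object.__setattr__(self, "a", c)
            object.__setattr__(self, "b", d)
            object.__setattr__(self, "c", a)
            object.__setattr__(self, "d", b)

    @property
    def prior_var(self) -> float:
        """k(x, x) = e^a + e^c."""
        return float(np.exp(self.a) + np.exp(self.c))


def covariance(x1, x2, params: CovParams):
    """Kernel value k(x1, x2); depends only on the distance |x1 - x2|."""
    d2 = (np.asarray(x1, dtype=float) - np.asarray(x2, dtype=float)) ** 2
    return np.exp(params.a - d2 / params.b**2) + np.exp(params.c - d2 / params.d**2)


def cov_matrix(positions: np.ndarray, params: CovParams, jitter: bool = True) -> np.ndarray:
    """Dense kernel matrix over a position vector, with stabilizing jitter."""
    x = np.asarray(positions, dtype=float)
    d2 = (x[:, None] - x[None, :]) ** 2
    K = np.exp(params.a - d2 / params.b**2) + np.exp(params.c - d2 / params.d**2)
    if jitter:
        K[np.diag_indices_from(K)] += JITTER_SCALE * params.prior_var
    return K


@dataclass
class BlockFit:
    """Laplace fit of one block of hSNPs.

    ``b_hat`` is the logit-scale posterior mode, ``w_diag`` the diagonal of
    the negative log-likelihood Hessian W = D p (1-p) at the mode, and
    ``log_marginal`` the Laplace estimate of the block's log evidence
    (binomial normalizing constants included).
    """

    positions: np.ndarray
    b_hat: np.ndarray
    w_diag: np.ndarray
    log_marginal: float
    # internals reused by prediction
    alpha: np.ndarray = field(repr=False, default=None)  # K^{-1} b_hat
    chol_B: np.ndarray = field(repr=False, default=None)  # chol(I + W^1/2 K W^1/2)
    params: CovParams | None = field(repr=False, default=None)


def _as_arrays(block: Sequence[PhasedHetSNP]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.array([s.pos for s in block], dtype=float)
    y = np.array([s.allele1_reads for s in block], dtype=float)
    d = np.array([s.depth for s in block], dtype=float)
    return x, y, d


def _log_binom_coeff(y: np.ndarray, d: np.ndarray) -> float:
    return float(np.sum(gammaln(d + 1) - gammaln(y + 1) - gammaln(d - y + 1)))


def laplace_fit_arrays(
    x: np.ndarray, y: np.ndarray, d: np.ndarray, params: CovParams, K: np.ndarray | None = None
) -> BlockFit:
    """Newton-Raphson Laplace approximation for one block (mode, curvature,
    evidence).  Initialized at B = 0; stops on relative log-posterior change
    below sqrt(machine eps) or after 50 iterations."""
    n = len(x)
    if K is None:
        K = cov_matrix(x, params)
    f = np.zeros(n)
    obj_prev = None
    alpha = np.zeros(n)
    L = np.eye(n)
    sqrt_w = np.zeros(n)
    for _ in range(NEWTON_MAX_ITER):
        p = expit(f)
        w = d * p * (1.0 - p)
        sqrt_w = np.sqrt(w)
        grad = y - d * p
        b = w * f + grad
        B = np.eye(n) + sqrt_w[:, None] * K * sqrt_w[None, :]
        try:
            L = cholesky(B, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - jittered K is PSD
            raise FloatingPointError(f"non-PSD system in Laplace fit: {exc}") from exc
        Kb = K @ b
        v = solve_triangular(L, sqrt_w * Kb, lower=True)
        u = solve_triangular(L.T, v, lower=False)
        alpha = b - sqrt_w * u
        f = K @ alpha
        if not np.all(np.isfinite(f)):
            raise FloatingPointError("Laplace mode diverged (non-finite latent values)")
        loglik = float(np.sum(y * f - d * np.logaddexp(0.0, f)))
        obj = -0.5 * float(alpha @ f) + loglik
        if obj_prev is not None and abs(obj - obj_prev) / max(abs(obj), 1e-300) <= NEWTON_EPS:
            obj_prev = obj
            break
        obj_prev = obj
    log_marginal = obj_prev - float(np.sum(np.log(np.diag(L)))) + _log_binom_coeff(y, d)
    return BlockFit(
        positions=x,
        b_hat=f,
        w_diag=d * expit(f) * (1.0 - expit(f)),
        log_marginal=log_marginal,
        alpha=alpha,
        chol_B=L,
        params=params,
    )


def laplace_block(block: Sequence[PhasedHetSNP], params: CovParams) -> BlockFit:
    """Laplace fit of a block (<= 100) of phase-standardized hSNPs."""
    if not 1 <= len(block) <= 100:
        raise ValueError("block size must be between 1 and 100 hSNPs")
    return laplace_fit_arrays(*_as_arrays(block), params)


@dataclass
class FitResult:
    params: CovParams
    report: pd.DataFrame  # full grid with log-likelihoods


def _iter_grid(grid: dict) -> list[CovParams]:
    pts = []
    for a, b, c, d in product(grid["a"], grid["b"], grid["c"], grid["d"]):
        if d > b:
            continue  # short-range term must have the smaller length scale
        pts.append(CovParams(a=a, b=b, c=c, d=d))
    return pts


def fit_params(
    hsnps: Sequence[PhasedHetSNP],
    grid: dict | None = None,
    block_size: int = 100,
) -> FitResult:
    """Grid-search maximum-likelihood fit of the kernel for one chromosome.

    The chromosome is split into consecutive blocks of ``block_size`` hSNPs
    (a trailing partial block stands alone) treated as independent; the
    objective is the summed Laplace log evidence over blocks.  Deterministic;
    the report carries the full grid for inspection.
    """
    if len(hsnps) == 0:
        raise ValueError("cannot fit parameters with zero hSNPs")
    grid = grid or DEFAULT_GRID
    x, y, d = _as_arrays(hsnps)
    blocks = [
        (x[i : i + block_size], y[i : i + block_size], d[i : i + block_size])
        for i in range(0, len(x), block_size)
    ]
    # distance matrices are reused across the whole grid
    d2s = [(bx[:, None] - bx[None, :]) ** 2 for bx, _, _ in blocks]
    # exp(-d2/scale^2) factors shared across amplitudes
    eb_cache = {s: [np.exp(-d2 / s**2) for d2 in d2s] for s in set(grid["b"]) | set(grid["d"])}

    rows = []
    best = (-np.inf, None)
    for params in _iter_grid(grid):
        ea, ec = np.exp(params.a), np.exp(params.c)
        jit = JITTER_SCALE * (ea + ec)
        total = 0.0
        for bi, (bx, by, bd) in enumerate(blocks):
            K = ea * eb_cache[params.b][bi] + ec * eb_cache[params.d][bi]
            K[np.diag_indices_from(K)] += jit
            total += laplace_fit_arrays(bx, by, bd, params, K=K).log_marginal
        rows.append({"a": params.a, "b": params.b, "c": params.c, "d": params.d,
                     "log_likelihood": total})
        if np.isfinite(total) and total > best[0]:
            best = (total, params)
    if best[1] is None:
        raise FloatingPointError("all grid evaluations were non-finite")
    report = pd.DataFrame(rows)
    logger.info("fit_params selected %s (logL=%.2f) over %d grid points",
                best[1], best[0], len(report))
    return FitResult(params=best[1], report=report)


@dataclass(frozen=True)
class ABPosterior:
    """Posterior of the logit-scale allele balance at one position."""

    mu: float
    sigma2: float
    informed: bool = True

    @property
    def ab(self) -> float:
        return float(expit(self.mu))

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.sigma2))


def predict_from_fit(x: float, fit: BlockFit) -> ABPosterior:
    """GP posterior mean/variance at ``x`` from an existing Laplace fit."""
    params = fit.params
    k_star = covariance(x, fit.positions, params)
    mu = float(k_star @ fit.alpha)
    sqrt_w = np.sqrt(fit.w_diag)
    v = solve_triangular(fit.chol_B, sqrt_w * k_star, lower=True)
    sigma2 = params.prior_var - float(v @ v)
    sigma2 = max(sigma2, 0.0)
    return ABPosterior(mu=mu, sigma2=sigma2)


def predict_ab(
    x: float,
    hsnps: Sequence[PhasedHetSNP],
    params: CovParams,
    window: float = 200_000.0,
    max_per_side: int = 100,
) -> ABPosterior:
    """Predict allele balance at position ``x`` from windowed hSNPs.

    hSNPs within ``window`` bp of ``x`` (capped at the nearest
    ``max_per_side`` on each side) are refit by the Laplace approximation
    and the GP predictive equations give (mu, sigma2).  With no hSNP in the
    window the GP prior is returned and the site flagged uninformed.
    """
    pos = np.array([s.pos for s in hsnps], dtype=float)
    sel = np.flatnonzero(np.abs(pos - x) <= window)
    if sel.size == 0:
        return ABPosterior(mu=0.0, sigma2=params.prior_var, informed=False)
    left = [i for i in sel if pos[i] <= x][-max_per_side:]
    right = [i for i in sel if pos[i] > x][:max_per_side]
    idx = list(left) + list(right)
    block = [hsnps[i] for i in idx]
    fit = laplace_fit_arrays(*_as_arrays(block), params)
    return predict_from_fit(x, fit)
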