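"""Statistical tests on candidate sSNVs given the local allele-balance posterior.

Three tests share one machinery: the probability of each possible alt-read
count y' in 0..D is computed by marginalizing a binomial (or binomial
mixture) likelihood over the Gaussian logit-AB posterior with Gauss-Hermite
quadrature, and the p-value of the observed count is the total probability
of all outcomes no more probable than it (a discrete, probability-ordered
two-sided tail).

* allele-balance consistency (ABC): the candidate is a true mutation whose
  VAF should track the AB of its carrier allele (mu or -mu, whichever fits).
* pre-amplification artifact: a single-stranded lesion present before
  amplification sits on half the carrier allele's amplicons (f = 2), on
  either allele with equal probability.
* amplification artifact: a first-round polymerase misincorporation sits on
  a quarter of the carrier allele's amplicons (f = 4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln
from scipy.stats import binom

GH_NODES_DEFAULT = 128
PROB_TIE_TOL = 1e-12


@dataclass(frozen=True)
class TestResult:
    p_value: float
    mu_star: float | None = None
    f: int | None = None
    pmf: np.ndarray | None = None


def mu_star(vaf: float, mu: float) -> float:
    """Signed logit-AB closest to the candidate VAF.

    A mutation may lie on either allele; the null AB is whichever of
    logistic(mu), logistic(-mu) is nearest the observed VAF (ties -> +mu).
    """
    if not (np.isfinite(vaf) and np.isfinite(mu)):
        raise ValueError("vaf and mu must be finite")
    if abs(vaf - expit(mu)) <= abs(vaf - expit(-mu)):
        return float(mu)
    return float(-mu)


def _log_binom_pmf_matrix(d: int, p: np.ndarray) -> np.ndarray:
    """log Binomial(y'; d, p_j) for y' in 0..d (rows) and nodes j (cols)."""
    y = np.arange(d + 1, dtype=float)[:, None]
    p = np.clip(np.asarray(p, dtype=float)[None, :], 1e-300, 1.0 - 1e-16)
    coeff = gammaln(d + 1) - gammaln(y + 1) - gammaln(d - y + 1)
    return coeff + y * np.log(p) + (d - y) * np.log1p(-p)


def marginal_pmf(
    d: int, mu: float, sigma2: float, f: int = 1, n_nodes: int = GH_NODES_DEFAULT
) -> np.ndarray:
    """Outcome distribution P(Y = y'), y' in 0..d, under the Gaussian logit-AB.

    ``f = 1`` gives the ABC null, Binomial(d, logistic(b)) marginalized over
    b ~ N(mu, sigma2).  ``f`` in {2, 4} gives the artifact nulls: an equal
    mixture of Binomial(d, logistic(b)/f) and Binomial(d, (1-logistic(b))/f).
    A degenerate posterior (sigma2 = 0) reduces to the exact (mixture)
    binomial.
    """
    if d < 1:
        raise ValueError("site with zero depth is untestable")
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    if sigma2 == 0.0:
        ab = expit(mu)
        if f == 1:
            return binom.pmf(np.arange(d + 1), d, ab)
        return 0.5 * binom.pmf(np.arange(d + 1), d, ab / f) + 0.5 * binom.pmf(
            np.arange(d + 1), d, (1.0 - ab) / f
        )
    t, w = np.polynomial.hermite.hermgauss(n_nodes)
    b = mu + np.sqrt(2.0 * sigma2) * t
    ab = expit(b)
    w = w / np.sqrt(np.pi)
    if f == 1:
        pmf = np.exp(_log_binom_pmf_matrix(d, ab)) @ w
    else:
        m1 = np.exp(_log_binom_pmf_matrix(d, ab / f))
        m2 = np.exp(_log_binom_pmf_matrix(d, (1.0 - ab) / f))
        pmf = (0.5 * m1 + 0.5 * m2) @ w
    return pmf


def probability_ordered_pvalue(pmf: np.ndarray, y: int, tol: float = PROB_TIE_TOL) -> float:
    """Total probability of outcomes no more probable than the observed count.

    Outcomes whose probability equals P(Y=y) within ``tol`` are included in
    the sum; observing a most-probable outcome therefore gives p = 1, and
    the test is conservative under its null by construction.
    """
    py = pmf[y]
    return float(np.sum(pmf[pmf <= py + tol]))


def abc_test(
    y: int, d: int, mu: float, sigma2: float, *,
    vaf: float | None = None, n_nodes: int = GH_NODES_DEFAULT, keep_pmf: bool = False,
) -> TestResult:
    """Allele-balance consistency test.

    ``mu`` is the posterior mean of the locus's logit AB; the carrier-allele
    orientation is chosen by :func:`mu_star` from the observed VAF (``vaf``
    defaults to y/d).  Small p-values indicate the alt-read count is
    inconsistent with the local allele balance.
    """
    if d < 1:
        raise ValueError("site with zero depth is untestable")
    if not 0 <= y <= d:
        raise ValueError("need 0 <= y <= d")
    v = y / d if vaf is None else vaf
    ms = mu_star(v, mu)
    pmf = marginal_pmf(d, ms, sigma2, f=1, n_nodes=n_nodes)
    p = probability_ordered_pvalue(pmf, y)
    return TestResult(p_value=min(p, 1.0), mu_star=ms, pmf=pmf if keep_pmf else None)


def artifact_test(
    y: int, d: int, mu: float, sigma2: float, f: int, *,
    n_nodes: int = GH_NODES_DEFAULT, keep_pmf: bool = False,
) -> TestResult:
    """Artifact test: pre-amplification lesions (f=2) or first-round
    amplification errors (f=4).

    The null allows the artifact on either allele, so the outcome law is a
    half/half binomial mixture and no carrier orientation is needed; it is
    symmetric under mu -> -mu.  Small p-values reject the artifact model.
    """
    if f not in (2, 4):
        raise ValueError("f must be 2 (pre-amplification) or 4 (amplification)")
    if not 0 <= y <= d:
        raise ValueError("need 0 <= y <= d")
    pmf = marginal_pmf(d, mu, sigma2, f=f, n_nodes=n_nodes)
    p = probability_ordered_pvalue(pmf, y)
    return TestResult(p_value=min(p, 1.0), f=f, pmf=pmf if keep_pmf else None)
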