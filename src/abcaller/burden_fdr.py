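"""Artifact-burden estimation and FDR-targeted tuning of artifact-test cutoffs.

True somatic SNVs sit on 50% of pre-amplification DNA, exactly like
germline hSNPs, so the VAF distribution of the (unknown) true-mutation
subset of candidates should resemble the hSNP VAF distribution.  Binning
both into 20 VAF bins, a multinomial simulation finds the largest
true-mutation count N_T whose expected bin occupancy fits under the
observed candidate counts; the remainder per bin is attributed to
artifacts.  These per-bin, per-depth burden estimates feed the relation

    FDR ~= alpha * N_A / (alpha * N_A + (1 - beta) * N_T)

which converts a user-supplied target FDR into a per-candidate p-value
cutoff alpha for each artifact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sig_tests import PROB_TIE_TOL, marginal_pmf, mu_star

N_BINS = 20
MIN_ARTIFACT_BURDEN = 0.1
CONSISTENCY_LEVEL = 0.005


def bin_vafs(vafs: Sequence[float]) -> np.ndarray:
    """Count VAFs into 20 equal bins: [0,.05), ..., [.90,.95), [.95,1]."""
    v = np.asarray(list(vafs), dtype=float)
    if v.size == 0:
        return np.zeros(N_BINS, dtype=int)
    if np.any((v < 0) | (v > 1)) or not np.all(np.isfinite(v)):
        raise ValueError("VAFs must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, N_BINS + 1)
    counts, _ = np.histogram(v, bins=edges)
    return counts.astype(int)


def _consistency_fraction(
    n_t: int, probs: np.ndarray, s_counts: np.ndarray, n_sims: int, seed: int
) -> float:
    # per-N_T stream: F(N_T) is a fixed function of (data, seed), independent
    # of the order in which the search evaluates it
    rng = np.random.default_rng([seed, n_t])
    draws = rng.multinomial(n_t, probs, size=n_sims)
    return float(np.mean(np.all(draws <= s_counts[None, :], axis=1)))


def estimate_nt(
    h_counts: Sequence[int],
    s_counts: Sequence[int],
    n_sims: int = 1000,
    seed: int = 1,
) -> int:
    """Upper bound on the number of true mutations among the candidates.

    For a trial N_T, candidate bin counts are simulated from a multinomial
    with hSNP bin proportions; the fit measure F is the fraction of
    simulations in which every simulated bin stays at or below the observed
    candidate bin count.  The bound is the largest N_T with F >= 0.005,
    located on a 50-point geometric grid over [1, sum(S)] and refined to
    integer resolution by bisection.
    """
    h = np.asarray(list(h_counts), dtype=float)
    s = np.asarray(list(s_counts), dtype=int)
    if h.sum() <= 0:
        raise ValueError("need at least one hSNP to estimate burden")
    total_s = int(s.sum())
    if total_s == 0:
        return 0
    probs = h / h.sum()

    def ok(n_t: int) -> bool:
        return _consistency_fraction(n_t, probs, s, n_sims, seed) >= CONSISTENCY_LEVEL

    if not ok(1):
        return 0
    if ok(total_s):
        return total_s
    grid = np.unique(np.geomspace(1, total_s, num=50).round().astype(int))
    lo = 1
    hi = total_s
    for g in grid:
        if ok(int(g)):
            lo = max(lo, int(g))
        else:
            hi = min(hi, int(g))
            break
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if ok(mid):
            lo = mid
        else:
            hi = mid
    return lo


def per_bin_burden(n_t: float, h_counts: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Expected true-mutation and artifact counts per VAF bin.

    N_T,i = N_T * H_i/H;  N_A,i = max(N_T * (1 - H_i/H), 0.1).  The 0.1
    floor keeps FDR estimates away from exactly zero.
    """
    h = np.asarray(list(h_counts), dtype=float)
    if n_t < 0 or h.sum() <= 0:
        raise ValueError("need n_t >= 0 and a nonempty hSNP bin vector")
    frac = h / h.sum()
    n_t_i = n_t * frac
    n_a_i = np.maximum(n_t * (1.0 - frac), MIN_ARTIFACT_BURDEN)
    return n_t_i, n_a_i


@dataclass
class Stratum:
    """Burden estimates for one sequencing-depth stratum."""

    h_counts: np.ndarray
    s_counts: np.ndarray
    n_t: int = 0
    n_t_i: np.ndarray = field(default=None)
    n_a_i: np.ndarray = field(default=None)


@dataclass
class BurdenTable:
    """Binned VAF counts and burden estimates, overall and per depth stratum.

    ``depth_cutoff`` is the 90th percentile of hSNP depths: sites at or
    below it are grouped by exact depth, deeper sites pool together under
    the key ``depth_cutoff + 1``.
    """

    h_counts: np.ndarray
    s_counts: np.ndarray
    n_t: int
    n_t_i: np.ndarray
    n_a_i: np.ndarray
    depth_cutoff: int
    strata: dict[int, Stratum]

    def stratum_key(self, depth: int) -> int:
        return depth if depth <= self.depth_cutoff else self.depth_cutoff + 1

    def burden_at(self, vaf: float, depth: int) -> tuple[float, float]:
        """(N_T,i,D, N_A,i,D) for a candidate's VAF bin and depth stratum.

        Falls back to the unstratified table when the stratum is absent or
        never received a burden estimate.
        """
        i = min(int(vaf * N_BINS), N_BINS - 1)
        st = self.strata.get(self.stratum_key(depth))
        if st is not None and st.n_t_i is not None:
            return float(st.n_t_i[i]), float(st.n_a_i[i])
        return float(self.n_t_i[i]), float(self.n_a_i[i])


def depth_stratify(
    hsnp_depths: Sequence[int],
    hsnp_vafs: Sequence[float],
    cand_depths: Sequence[int],
    cand_vafs: Sequence[float],
    n_sims: int = 1000,
    seed: int = 1,
) -> BurdenTable:
    """Build the burden table, stratified by sequencing depth.

    Sites are grouped by exact depth up to the hSNP-depth 90th percentile;
    all deeper sites form one pooled stratum.  N_T and per-bin burdens are
    estimated within each stratum that contains both hSNPs and candidates,
    and once overall (the fallback for sparse strata).
    """
    hd = np.asarray(list(hsnp_depths), dtype=int)
    hv = np.asarray(list(hsnp_vafs), dtype=float)
    cd = np.asarray(list(cand_depths), dtype=int)
    cv = np.asarray(list(cand_vafs), dtype=float)
    if hd.size == 0:
        raise ValueError("no hSNPs provided")
    cutoff = int(np.percentile(hd, 90))

    h_all = bin_vafs(hv)
    s_all = bin_vafs(cv)
    n_t_all = estimate_nt(h_all, s_all, n_sims=n_sims, seed=seed) if s_all.sum() else 0
    nti_all, nai_all = per_bin_burden(n_t_all, h_all)

    def key(depth: int) -> int:
        return depth if depth <= cutoff else cutoff + 1

    strata: dict[int, Stratum] = {}
    for depths, vafs, attr in ((hd, hv, "h"), (cd, cv, "s")):
        for dep, vaf in zip(depths, vafs):
            st = strata.setdefault(
                key(int(dep)),
                Stratum(h_counts=np.zeros(N_BINS, dtype=int), s_counts=np.zeros(N_BINS, dtype=int)),
            )
            i = min(int(vaf * N_BINS), N_BINS - 1)
            (st.h_counts if attr == "h" else st.s_counts)[i] += 1
    for k in sorted(strata):
        st = strata[k]
        if st.h_counts.sum() > 0 and st.s_counts.sum() > 0:
            st.n_t = estimate_nt(st.h_counts, st.s_counts, n_sims=n_sims, seed=seed + 7919 * (k + 1))
            st.n_t_i, st.n_a_i = per_bin_burden(st.n_t, st.h_counts)
    return BurdenTable(
        h_counts=h_all, s_counts=s_all, n_t=n_t_all, n_t_i=nti_all, n_a_i=nai_all,
        depth_cutoff=cutoff, strata=strata,
    )


def fdr_at(alpha: float, power: float, n_t: float, n_a: float) -> float:
    """FDR ~= alpha N_A / (alpha N_A + (1 - beta) N_T) with power = 1 - beta."""
    denom = alpha * n_a + power * n_t
    if denom <= 0:
        return 1.0
    return alpha * n_a / denom


def tune_alpha(
    y_depth: int,
    vaf: float,
    mu: float,
    sigma2: float,
    n_t: float,
    n_a: float,
    theta: float,
    f: int,
    n_nodes: int = 128,
) -> float:
    """Largest artifact-test cutoff alpha meeting the target FDR ``theta``.

    Achievable cutoffs are the discrete p-values of the artifact null over
    outcomes 0..D, ordered as highest-density (lowest-probability-first)
    rejection regions.  Power 1 - beta for each region is computed under
    the true-mutation alternative: the ABC null at mu* chosen from the
    candidate's VAF.  Returns 0.0 when no cutoff achieves the target —
    the candidate is then unpowered and cannot be exonerated.
    """
    null_pmf = marginal_pmf(y_depth, mu, sigma2, f=f, n_nodes=n_nodes)
    alt_pmf = marginal_pmf(y_depth, mu_star(vaf, mu), sigma2, f=1, n_nodes=n_nodes)
    # each outcome k defines the achievable cutoff alpha_k = p-value(k); its
    # rejection region is the highest-density set {y: P(y) <= P(k)}
    best = 0.0
    for k in range(y_depth + 1):
        region = null_pmf <= null_pmf[k] + PROB_TIE_TOL
        alpha = float(null_pmf[region].sum())
        power = float(alt_pmf[region].sum())
        if fdr_at(alpha, power, n_t, n_a) <= theta and alpha > best:
            best = alpha
    return min(best, 1.0)
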