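"""Genotyping orchestration: single-sample calling, joint calling, QC.

Single-sample calling evaluates each candidate against the locally
predicted allele balance: the allele-balance consistency (ABC) test must
not reject the true-mutation model (fixed cutoff 0.05), while both artifact
tests must reject their artifact nulls at per-candidate cutoffs tuned to
the target FDR from the estimated artifact burden.  A candidate whose tuned
cutoff is zero is unpowered — the artifact model cannot be rejected at any
achievable level — and is filtered.  Secondary filters flag candidates with
excess indel- or clip-containing reads relative to hSNP loci.

Joint calling across >= 2 related cells replaces the artifact machinery
with repeated allele-balance consistency: the J statistic multiplies ABC
p-values over supporting samples (each penalized 10x when the GP posterior
sd at the locus exceeds 1) and is thresholded against J statistics of
randomly sampled hSNPs with the same support count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ab_model import CovParams, predict_ab
from .burden_fdr import BurdenTable, tune_alpha
from .io_model import CallRecord, CandidateSNV, PhasedHetSNP
from .sig_tests import abc_test, artifact_test

logger = logging.getLogger(__name__)


@dataclass
class CallerConfig:
    target_fdr: float = 0.1
    abc_cutoff: float = 0.05
    window: float = 200_000.0
    max_per_side: int = 100
    min_depth: int = 1
    gh_nodes: int = 128
    hsnp_subsample: int = 4000
    hsnp_pass_fraction: float = 0.9
    seed: int = 1


@dataclass(frozen=True)
class CigarProfile:
    """Per-site fractions of reads carrying indel / clip CIGAR operations."""

    chrom: str
    pos: int
    frac_cell_indel: float
    frac_cell_clip: float
    frac_bulk_indel: float
    frac_bulk_clip: float

    def __post_init__(self) -> None:
        for v in (self.frac_cell_indel, self.frac_cell_clip,
                  self.frac_bulk_indel, self.frac_bulk_clip):
            if not 0.0 <= v <= 1.0:
                raise ValueError("CIGAR fractions must lie in [0, 1]")


def cigar_filter(
    candidates: Sequence[CigarProfile],
    hsnp_profiles: Sequence[CigarProfile],
    seed: int = 1,
    n_sample: int = 4000,
    percentile: float = 90.0,
) -> dict[tuple[str, int], set[str]]:
    """Flag candidates with excess indel/clip read fractions.

    Up to ``n_sample`` hSNP profiles are sampled without replacement; for
    each operation type a candidate is flagged when its single-cell fraction
    exceeds the ``percentile``-th percentile of single-cell fractions among
    sampled hSNPs whose bulk fraction is at most the candidate's (so a noisy
    locus in bulk is judged against equally noisy hSNP loci).  Falls back to
    the full sample when no hSNP has comparable bulk noise.
    """
    if len(hsnp_profiles) == 0:
        raise ValueError("need at least one hSNP CIGAR profile")
    rng = np.random.default_rng(seed)
    if len(hsnp_profiles) > n_sample:
        idx = rng.choice(len(hsnp_profiles), size=n_sample, replace=False)
        sample = [hsnp_profiles[i] for i in sorted(idx)]
    else:
        sample = list(hsnp_profiles)
    cell = {
        "indel": np.array([p.frac_cell_indel for p in sample]),
        "clip": np.array([p.frac_cell_clip for p in sample]),
    }
    bulk = {
        "indel": np.array([p.frac_bulk_indel for p in sample]),
        "clip": np.array([p.frac_bulk_clip for p in sample]),
    }
    flags: dict[tuple[str, int], set[str]] = {}
    for cand in candidates:
        site_flags = set()
        for op, cand_cell, cand_bulk in (
            ("indel", cand.frac_cell_indel, cand.frac_bulk_indel),
            ("clip", cand.frac_cell_clip, cand.frac_bulk_clip),
        ):
            mask = bulk[op] <= cand_bulk
            ref = cell[op][mask] if mask.any() else cell[op]
            if cand_cell > np.percentile(ref, percentile):
                site_flags.add(f"{op}_excess")
        flags[(cand.chrom, cand.pos)] = site_flags
    return flags


def genotype_single(
    candidates: Sequence[CandidateSNV],
    hsnps: Mapping[str, Sequence[PhasedHetSNP]],
    params: Mapping[str, CovParams],
    burden: BurdenTable,
    config: CallerConfig | None = None,
    cigar_flags: Mapping[tuple[str, int], set[str]] | None = None,
) -> list[CallRecord]:
    """Run all statistical tests and filters on each candidate.

    A candidate passes when the ABC p-value is at least the fixed cutoff,
    each artifact test rejects its null at the candidate's tuned cutoff
    (p <= alpha), no CIGAR flag is raised, and depth is sufficient.
    """
    cfg = config or CallerConfig()
    records: list[CallRecord] = []
    for cand in candidates:
        flags: set[str] = set()
        if cand.sc_depth < max(cfg.min_depth, 1):
            records.append(
                CallRecord(
                    candidate=cand, ab_mu=0.0, ab_sigma2=0.0,
                    p_abc=1.0, p_preamp=1.0, p_amp=1.0,
                    alpha_preamp=0.0, alpha_amp=0.0, filter_flags={"low_depth"},
                )
            )
            continue
        chrom_hsnps = hsnps.get(cand.chrom, [])
        chrom_params = params[cand.chrom]
        ab = predict_ab(
            cand.pos, chrom_hsnps, chrom_params,
            window=cfg.window, max_per_side=cfg.max_per_side,
        )
        res_abc = abc_test(cand.sc_alt, cand.sc_depth, ab.mu, ab.sigma2,
                           vaf=cand.vaf, n_nodes=cfg.gh_nodes)
        res_pre = artifact_test(cand.sc_alt, cand.sc_depth, ab.mu, ab.sigma2, f=2,
                                n_nodes=cfg.gh_nodes)
        res_amp = artifact_test(cand.sc_alt, cand.sc_depth, ab.mu, ab.sigma2, f=4,
                                n_nodes=cfg.gh_nodes)
        n_t, n_a = burden.burden_at(cand.vaf, cand.sc_depth)
        alpha_pre = tune_alpha(cand.sc_depth, cand.vaf, ab.mu, ab.sigma2,
                               n_t, n_a, cfg.target_fdr, f=2, n_nodes=cfg.gh_nodes)
        alpha_amp = tune_alpha(cand.sc_depth, cand.vaf, ab.mu, ab.sigma2,
                               n_t, n_a, cfg.target_fdr, f=4, n_nodes=cfg.gh_nodes)
        if res_abc.p_value < cfg.abc_cutoff:
            flags.add("abc_fail")
        # artifact hypothesis must be rejected (p <= tuned alpha) for the
        # candidate to survive; alpha = 0 means no achievable rejection
        if res_pre.p_value > alpha_pre:
            flags.add("preamp_fail")
        if res_amp.p_value > alpha_amp:
            flags.add("amp_fail")
        if cigar_flags:
            flags |= cigar_flags.get((cand.chrom, cand.pos), set())
        records.append(
            CallRecord(
                candidate=cand, ab_mu=ab.mu, ab_sigma2=ab.sigma2,
                p_abc=res_abc.p_value, p_preamp=res_pre.p_value, p_amp=res_amp.p_value,
                alpha_preamp=alpha_pre, alpha_amp=alpha_amp, filter_flags=flags,
            )
        )
    return records


@dataclass
class JointCallRecord:
    site: tuple[str, int, str, str]
    per_sample: list[tuple[str, int, int, float, float]]  # (sample, y, d, p_abc, gp_sd)
    j_stat: float
    n_support: int
    threshold: float
    passed: bool


GP_SD_PENALTY = 0.1
GP_SD_LIMIT = 1.0


def _j_statistic(p_abcs: np.ndarray, gp_sds: np.ndarray) -> float:
    pen = np.where(gp_sds > GP_SD_LIMIT, GP_SD_PENALTY, 1.0)
    return float(np.prod(p_abcs * pen))


def joint_call(
    site_table: pd.DataFrame,
    hsnp_table: pd.DataFrame,
    seed: int = 1,
    n_sample: int = 4000,
    hsnp_pass_fraction: float = 0.9,
) -> list[JointCallRecord]:
    """Multi-sample calling by allele-balance consistency across cells.

    Both tables need columns ``chrom, pos, ref, alt, sample, y, d, p_abc,
    gp_sd`` (ref/alt may be placeholder for hSNPs).  J statistics for up to
    ``n_sample`` randomly chosen hSNP sites, grouped by the number of
    supporting samples, set the per-class thresholds: the J value exceeded
    by ``hsnp_pass_fraction`` of hSNPs in the class (linear interpolation).
    A site passes when its J is at least its class threshold.  Artifact and
    CIGAR filters are not applied in joint mode.
    """
    required = {"chrom", "pos", "sample", "y", "d", "p_abc", "gp_sd"}
    for name, tab in (("site_table", site_table), ("hsnp_table", hsnp_table)):
        missing = required - set(tab.columns)
        if missing:
            raise ValueError(f"{name} lacks columns {missing}")
    if site_table["sample"].nunique() < 2:
        raise ValueError("joint calling needs >= 2 samples")

    def collect(tab: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for (chrom, pos), grp in tab.groupby(["chrom", "pos"], sort=True):
            sup = grp[grp["y"] >= 1]
            n_sup = len(sup)
            j = _j_statistic(sup["p_abc"].to_numpy(), sup["gp_sd"].to_numpy()) if n_sup else 0.0
            rows.append({"chrom": chrom, "pos": pos, "j": j, "n_support": n_sup})
        return pd.DataFrame(rows)

    hsnp_j = collect(hsnp_table)
    rng = np.random.default_rng(seed)
    if len(hsnp_j) > n_sample:
        hsnp_j = hsnp_j.iloc[np.sort(rng.choice(len(hsnp_j), size=n_sample, replace=False))]

    thresholds: dict[int, float] = {}
    for k, grp in hsnp_j.groupby("n_support"):
        thresholds[int(k)] = float(np.quantile(grp["j"].to_numpy(), 1.0 - hsnp_pass_fraction))

    def threshold_for(k: int) -> float:
        if k in thresholds:
            return thresholds[k]
        smaller = [c for c in thresholds if c < k]
        if smaller:
            c = max(smaller)
            logger.info("support class %d has no hSNPs; inheriting threshold from class %d", k, c)
            return thresholds[c]
        larger = [c for c in thresholds if c > k]
        if larger:
            return thresholds[min(larger)]
        return 0.0

    records: list[JointCallRecord] = []
    site_cols = ["chrom", "pos"] + [c for c in ("ref", "alt") if c in site_table.columns]
    for key, grp in site_table.groupby(site_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        site = (str(key[0]), int(key[1]), *map(str, key[2:]))
        sup = grp[grp["y"] >= 1]
        n_sup = len(sup)
        j = _j_statistic(sup["p_abc"].to_numpy(), sup["gp_sd"].to_numpy()) if n_sup else 0.0
        thr = threshold_for(n_sup)
        records.append(
            JointCallRecord(
                site=site,
                per_sample=[
                    (str(r["sample"]), int(r["y"]), int(r["d"]), float(r["p_abc"]), float(r["gp_sd"]))
                    for _, r in grp.iterrows()
                ],
                j_stat=j,
                n_support=n_sup,
                threshold=thr,
                passed=bool(n_sup >= 1 and j >= thr),
            )
        )
    return records


DOUBLET_BAND = (0.15, 0.35)


@dataclass
class QCReport:
    hsnp_density: np.ndarray
    ssnv_density: np.ndarray
    downsampled_density: np.ndarray | None
    doublet_score: float
    n_hsnps: int
    n_ssnvs: int


def qc_diagnostics(
    hsnp_vafs: Sequence[float],
    ssnv_vafs: Sequence[float],
    hsnp_alt: Sequence[int] | None = None,
    hsnp_depth: Sequence[int] | None = None,
    seed: int = 1,
    n_bins: int = 20,
) -> QCReport:
    """Doublet / sample-quality diagnostics from VAF distributions.

    An accidental doublet halves the template fraction of unshared sSNVs,
    producing a VAF peak near 25% absent from hSNPs.  The doublet score is
    the excess sSNV probability mass in the 0.15-0.35 VAF band over the
    hSNP-derived expectation; a binomially thinned copy of the hSNP read
    counts (alt reads halved in expectation) is reported as the reference
    shape for unshared sSNVs.
    """
    hv = np.asarray(list(hsnp_vafs), dtype=float)
    sv = np.asarray(list(ssnv_vafs), dtype=float)
    if sv.size < 100:
        logger.warning("only %d sSNVs; the doublet diagnostic is unreliable", sv.size)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    h_dens, _ = np.histogram(hv, bins=edges)
    s_dens, _ = np.histogram(sv, bins=edges)
    down = None
    if hsnp_alt is not None and hsnp_depth is not None:
        rng = np.random.default_rng(seed)
        alt = np.asarray(list(hsnp_alt), dtype=int)
        dep = np.asarray(list(hsnp_depth), dtype=int)
        thinned = rng.binomial(alt, 0.5)
        down, _ = np.histogram(thinned / dep, bins=edges)
    lo, hi = DOUBLET_BAND

    def band_mass(v: np.ndarray) -> float:
        if v.size == 0:
            return 0.0
        return float(np.mean((v >= lo) & (v <= hi)))

    score = band_mass(sv) - band_mass(hv)
    return QCReport(
        hsnp_density=h_dens, ssnv_density=s_dens, downsampled_density=down,
        doublet_score=score, n_hsnps=hv.size, n_ssnvs=sv.size,
    )
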