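"""Synthetic single-cell amplification data with known ground truth.

The generator reproduces the statistical structure the caller assumes: a
latent logit-scale allele-balance curve drawn from the squared-exponential
GP prior, binomial read sampling at hSNPs and candidate sites, and the
idealized strand-counting model of MDA artifacts.  A heterozygous variant
sits on 50% of pre-amplification template; a single-stranded
pre-amplification lesion on one strand of its allele sits on 25%; a
first-round polymerase misincorporation on one of the eight post-replication
strands sits on 12.5%.  Conditional on the local AB, the expected VAF of
each class is the carrier-allele fraction divided by f = 1, 2 or 4.  In
doublet mode, sSNVs unshared between the two co-isolated cells start on 25%
of template (half the carrier fraction of one cell, balanced mixing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.special import expit

from .ab_model import CovParams, cov_matrix

ROLES = ("hsnp", "true_ssnv", "preamp", "amp")

#: divisor applied to the carrier-allele fraction for each site class
ROLE_DIVISOR = {"hsnp": 1.0, "true_ssnv": 1.0, "preamp": 2.0, "amp": 4.0}

#: fraction of initial (pre-amplification) template carrying the variant in
#: the idealized 2-molecule / 4-strand -> 8-strand MDA model
TEMPLATE_FRACTION = {"true_ssnv": 0.5, "hsnp": 0.5, "preamp": 0.25, "amp": 0.125}


def expected_vaf(role: str, carrier_ab: float) -> float:
    """Mean VAF of a site class given its carrier allele's amplified fraction.

    A true heterozygous variant tracks the carrier fraction itself; a
    pre-amplification lesion half of it; a first-round amplification error a
    quarter (e.g. carrier AB 94% -> pre-amplification artifact VAF 47%).
    """
    if role not in ROLE_DIVISOR:
        raise ValueError(f"unknown role {role!r}")
    return carrier_ab / ROLE_DIVISOR[role]


def template_fraction(role: str) -> float:
    """Fraction of initial template DNA carrying the variant before
    amplification, under the idealized strand model (balanced genome)."""
    return TEMPLATE_FRACTION[role]


@dataclass
class SimConfig:
    """Study conditions for one simulated single-cell chromosome."""

    params: CovParams = field(default_factory=lambda: CovParams(a=0.0, b=10_000.0, c=-4.0, d=150.0))
    n_hsnps: int = 2000
    hsnp_spacing_mean: float = 1500.0
    depth_mean: float = 30.0
    bulk_depth_mean: float = 30.0
    n_true_ssnvs: int = 200
    n_preamp_artifacts: int = 400
    n_amp_artifacts: int = 400
    doublet: bool = False
    shared_fraction: float = 0.5
    chrom: str = "1"
    seed: int = 1

    def __post_init__(self) -> None:
        counts = (self.n_hsnps, self.n_true_ssnvs, self.n_preamp_artifacts, self.n_amp_artifacts)
        if any(c < 0 for c in counts) or self.hsnp_spacing_mean <= 0:
            raise ValueError("counts must be >= 0 and spacing > 0")


def simulate_ab(
    positions: Sequence[float], params: CovParams, seed: int | np.random.Generator = 1
) -> np.ndarray:
    """Exact draw of the latent logit-AB vector at sorted positions."""
    x = np.asarray(positions, dtype=float)
    if np.any(np.diff(x) < 0):
        raise ValueError("positions must be sorted")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = cov_matrix(x, params)
    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError as exc:
        raise FloatingPointError(f"covariance matrix not PSD: {exc}") from exc
    return L @ rng.standard_normal(len(x))


def _truncated_poisson(mean: float, size: int, rng: np.random.Generator) -> np.ndarray:
    d = rng.poisson(mean, size=size)
    while np.any(d == 0):
        zero = d == 0
        d[zero] = rng.poisson(mean, size=int(zero.sum()))
    return d


def simulate_reads(
    B: np.ndarray,
    depth_mean: float,
    site_roles: Sequence[str],
    doublet: bool = False,
    seed: int | np.random.Generator = 1,
    shared: np.ndarray | None = None,
    bulk_depth_mean: float = 30.0,
) -> pd.DataFrame:
    """Draw read counts for sites with latent AB ``B`` and the given roles.

    Returns one row per site with the sampled single-cell depth/alt counts,
    matching bulk counts (alt-free for somatic roles, balanced for hSNPs),
    the carrier-allele assignment and the per-site expected alt fraction.
    ``shared`` marks doublet-shared sSNVs; when ``doublet`` is set, unshared
    true sSNVs have their carrier fraction halved (25% template, balanced
    cell mixing).
    """
    B = np.asarray(B, dtype=float)
    roles = np.asarray(site_roles, dtype=object)
    if B.shape != roles.shape:
        raise ValueError("B and site_roles must align")
    unknown = set(roles) - set(ROLES)
    if unknown:
        raise ValueError(f"unknown roles {unknown}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(B)
    depth = _truncated_poisson(depth_mean, n, rng)
    bulk_depth = _truncated_poisson(bulk_depth_mean, n, rng)

    # carrier allele: haplotype 1 with probability 1/2, independently per site
    on_hap1 = rng.random(n) < 0.5
    ab1 = expit(B)
    carrier_frac = np.where(on_hap1, ab1, 1.0 - ab1)
    divisor = np.array([ROLE_DIVISOR[r] for r in roles])
    if doublet:
        if shared is None:
            shared = np.zeros(n, dtype=bool)
        halve = (roles == "true_ssnv") & ~np.asarray(shared, dtype=bool)
        divisor = np.where(halve, divisor * 2.0, divisor)
    frac = carrier_frac / divisor
    alt = rng.binomial(depth, frac)
    is_hsnp = roles == "hsnp"
    bulk_alt = np.where(is_hsnp, rng.binomial(bulk_depth, 0.5), 0)
    return pd.DataFrame(
        {
            "role": roles,
            "carrier_on_hap1": on_hap1,
            "B": B,
            "expected_frac": frac,
            "depth": depth,
            "alt": alt,
            "bulk_depth": bulk_depth,
            "bulk_alt": bulk_alt,
            "shared": np.ones(n, dtype=bool) if shared is None else np.asarray(shared, dtype=bool),
        }
    )


def simulate_dataset(config: SimConfig) -> pd.DataFrame:
    """Simulate one chromosome: hSNP grid, somatic/artifact candidates, reads.

    hSNP positions have exponential spacing with the configured mean;
    candidate sites are scattered uniformly over the covered span.  Returns
    one table for all sites with positions, roles, latent AB and counts.
    """
    rng = np.random.default_rng(config.seed)
    gaps = rng.exponential(config.hsnp_spacing_mean, size=config.n_hsnps)
    hsnp_pos = np.ceil(np.cumsum(gaps) + 1000).astype(int)
    hsnp_pos = np.unique(hsnp_pos)
    span = (int(hsnp_pos[0]), int(hsnp_pos[-1])) if hsnp_pos.size else (1000, 2000)
    n_cand = config.n_true_ssnvs + config.n_preamp_artifacts + config.n_amp_artifacts
    cand_pos = rng.integers(span[0], span[1] + 1, size=n_cand)
    roles = np.array(
        ["hsnp"] * hsnp_pos.size
        + ["true_ssnv"] * config.n_true_ssnvs
        + ["preamp"] * config.n_preamp_artifacts
        + ["amp"] * config.n_amp_artifacts,
        dtype=object,
    )
    pos = np.concatenate([hsnp_pos, cand_pos])
    # avoid candidate/hSNP collisions: nudge duplicates by one
    seen = set(hsnp_pos.tolist())
    for i in range(hsnp_pos.size, len(pos)):
        while pos[i] in seen:
            pos[i] += 1
        seen.add(int(pos[i]))
    order = np.argsort(pos, kind="stable")
    pos, roles = pos[order], roles[order]
    B = simulate_ab(pos.astype(float), config.params, rng)
    shared = rng.random(len(pos)) < config.shared_fraction
    df = simulate_reads(
        B,
        config.depth_mean,
        roles,
        doublet=config.doublet,
        seed=rng,
        shared=shared,
        bulk_depth_mean=config.bulk_depth_mean,
    )
    df.insert(0, "pos", pos)
    df.insert(0, "chrom", config.chrom)
    return df


def dataset_to_inputs(df: pd.DataFrame):
    """Convert a simulated site table into caller inputs.

    Returns (hsnps, candidates): phase-standardized hSNP records keyed by
    chromosome, and candidate records for every non-hSNP site with at least
    one sampled read.
    """
    from .io_model import CandidateSNV, PhasedHetSNP, standardize_allele1

    hsnps: dict[str, list[PhasedHetSNP]] = {}
    candidates: list[CandidateSNV] = []
    for row in df.itertuples(index=False):
        if row.depth < 1:
            continue
        if row.role == "hsnp":
            flip = not row.carrier_on_hap1  # variant allele on haplotype 2
            hsnps.setdefault(str(row.chrom), []).append(
                PhasedHetSNP(
                    chrom=str(row.chrom), pos=int(row.pos),
                    allele1_reads=standardize_allele1(int(row.alt), int(row.depth), flip),
                    depth=int(row.depth), raw_vaf=row.alt / row.depth, hap_flip=flip,
                )
            )
        else:
            candidates.append(
                CandidateSNV(
                    chrom=str(row.chrom), pos=int(row.pos), ref="N", alt="N",
                    sc_alt=int(row.alt), sc_depth=int(row.depth),
                    bulk_alt=int(row.bulk_alt), bulk_depth=int(row.bulk_depth),
                )
            )
    for chrom in hsnps:
        hsnps[chrom].sort(key=lambda s: s.pos)
    candidates.sort(key=lambda c: (c.chrom, c.pos))
    return hsnps, candidates


_BASES = ("A", "C", "G", "T")


def make_fixture(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset in the formats the readers consume.

    Emits ``hsnps.vcf`` (phased germline genotypes), ``counts.tsv`` (joint
    single-cell + bulk read counts), ``truth.tsv`` (site labels) and returns
    their paths.  Byte-identical across runs for a fixed config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = simulate_dataset(config)
    rng = np.random.default_rng(config.seed + 104729)
    ref_idx = rng.integers(0, 4, size=len(df))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(df))) % 4
    bases = np.array(_BASES)
    df = df.assign(ref=bases[ref_idx], alt_base=bases[alt_idx])

    vcf_path = outdir / "hsnps.vcf"
    header = pysam.VariantHeader()
    header.add_line('##source=abcaller-simulator')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(f"##contig=<ID={config.chrom},length=300000000>")
    header.add_sample("germline")
    hs = df[df["role"] == "hsnp"]
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vcf:
        for _, row in hs.iterrows():
            rec = vcf.new_record(
                contig=config.chrom, start=int(row["pos"]) - 1, stop=int(row["pos"]),
                alleles=(row["ref"], row["alt_base"]),
            )
            # alt allele on haplotype 2 when the carrier (allele-1) haplotype
            # does not carry it; GT is written phased
            gt = (0, 1) if not row["carrier_on_hap1"] else (1, 0)
            rec.samples["germline"]["GT"] = gt
            rec.samples["germline"].phased = True
            vcf.write(rec)

    counts_path = outdir / "counts.tsv"
    counts = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "ref": df["ref"],
            "alt": df["alt_base"],
            "cell_ref": df["depth"] - df["alt"],
            "cell_alt": df["alt"],
            "bulk_ref": df["bulk_depth"] - df["bulk_alt"],
            "bulk_alt": df["bulk_alt"],
        }
    )
    counts.to_csv(counts_path, sep="\t", index=False)

    truth_path = outdir / "truth.tsv"
    df[["chrom", "pos", "role", "shared", "B", "expected_frac", "carrier_on_hap1"]].to_csv(
        truth_path, sep="\t", index=False
    )
    return {"vcf": vcf_path, "counts": counts_path, "truth": truth_path}
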