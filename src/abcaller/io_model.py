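"""Domain types and file I/O for phased hSNPs, candidate sSNVs and call records.

External inputs are the tabular outputs of a standard short-read pipeline:
a VCF with phased germline genotypes, and TSV read-count tables with one
column pair ``<sample>_ref``/``<sample>_alt`` per sample.  Phase
standardization converts alt-allele read counts into haplotype-1 allele
counts so that the allele-balance signal is continuous across adjacent SNPs
that carry their variant allele on opposite haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

COUNT_TABLE_KEY = ["chrom", "pos", "ref", "alt"]


@dataclass(frozen=True)
class PhasedHetSNP:
    """A phase-standardized heterozygous SNP observation in one single cell.

    ``allele1_reads`` counts reads supporting the haplotype-1 allele: the alt
    read count when the alt allele is on haplotype 1, and ``depth - alt`` when
    it lies on haplotype 2 (``hap_flip`` true).
    """

    chrom: str
    pos: int
    allele1_reads: int
    depth: int
    raw_vaf: float
    hap_flip: bool

    def __post_init__(self) -> None:
        if not (0 <= self.allele1_reads <= self.depth) or self.depth < 1:
            raise ValueError(
                f"invalid counts at {self.chrom}:{self.pos}: "
                f"allele1={self.allele1_reads}, depth={self.depth}"
            )


@dataclass(frozen=True)
class CandidateSNV:
    """A candidate somatic SNV with single-cell and bulk read support."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sc_alt: int
    sc_depth: int
    bulk_alt: int
    bulk_depth: int
    cigar_fracs: dict | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.sc_alt <= self.sc_depth):
            raise ValueError(f"invalid single-cell counts at {self.chrom}:{self.pos}")

    @property
    def vaf(self) -> float:
        return self.sc_alt / self.sc_depth if self.sc_depth > 0 else float("nan")


@dataclass
class CallRecord:
    """Per-candidate test results, tuned thresholds and final verdict."""

    candidate: CandidateSNV
    ab_mu: float
    ab_sigma2: float
    p_abc: float
    p_preamp: float
    p_amp: float
    alpha_preamp: float
    alpha_amp: float
    filter_flags: set = field(default_factory=set)

    VALID_FLAGS = frozenset(
        {"abc_fail", "preamp_fail", "amp_fail", "indel_excess", "clip_excess", "low_depth"}
    )

    @property
    def passed(self) -> bool:
        return len(self.filter_flags) == 0

    @property
    def ab(self) -> float:
        return 1.0 / (1.0 + np.exp(-self.ab_mu))


@dataclass
class CandidateConfig:
    """Lenient read-support rules defining the candidate sSNV set."""

    min_sc_depth: int = 6
    min_sc_alt: int = 2
    min_bulk_depth: int = 10
    max_bulk_alt: int = 0


def standardize_allele1(alt_reads: int, depth: int, hap_flip: bool) -> int:
    """Haplotype-1 allele read count: alt reads, reflected when the alt allele
    is phased to haplotype 2."""
    return depth - alt_reads if hap_flip else alt_reads


def read_count_table(counts_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(counts_path, sep="\t", dtype={"chrom": str})
    missing = [c for c in COUNT_TABLE_KEY if c not in df.columns]
    if missing:
        raise ValueError(f"count table {counts_path} lacks columns {missing}")
    if not np.issubdtype(df["pos"].dtype, np.integer):
        raise ValueError(f"count table {counts_path} has malformed coordinates")
    return df


def _sample_counts(df: pd.DataFrame, sample: str, path) -> tuple[pd.Series, pd.Series]:
    ref_col, alt_col = f"{sample}_ref", f"{sample}_alt"
    if ref_col not in df.columns or alt_col not in df.columns:
        raise KeyError(f"sample '{sample}' has no {ref_col}/{alt_col} columns in {path}")
    return df[ref_col], df[alt_col]


def load_phased_hsnps(
    vcf_path: str | Path, counts_path: str | Path, sample: str
) -> dict[str, list[PhasedHetSNP]]:
    """Load phased heterozygous SNPs and standardize them to haplotype 1.

    Sites with unphased or homozygous genotypes, multi-allelic records,
    non-SNV alleles, or zero depth in the named single cell are dropped.
    Returns records sorted by position, grouped by chromosome.
    """
    counts = read_count_table(counts_path)
    _sample_counts(counts, sample, counts_path)
    counts = counts.set_index(["chrom", "pos"])

    out: dict[str, list[PhasedHetSNP]] = {}
    n_unphased = n_nonbiallelic = n_nocount = n_zerodepth = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf.fetch():
            if rec.alts is None or len(rec.alts) != 1:
                n_nonbiallelic += 1
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                n_nonbiallelic += 1
                continue
            smp = rec.samples[0]
            gt = smp.get("GT")
            if gt is None or None in gt or not smp.phased:
                n_unphased += 1
                continue
            if sorted(gt) != [0, 1]:  # homozygous or non-het
                n_unphased += 1
                continue
            key = (rec.chrom, rec.pos)
            try:
                row = counts.loc[key]
            except KeyError:
                n_nocount += 1
                continue
            if isinstance(row, pd.DataFrame):
                row = row.iloc[0]
            ref_n = int(row[f"{sample}_ref"])
            alt_n = int(row[f"{sample}_alt"])
            depth = ref_n + alt_n
            if depth == 0:
                n_zerodepth += 1
                continue
            hap_flip = gt[0] == 0  # alt allele on haplotype 2
            out.setdefault(rec.chrom, []).append(
                PhasedHetSNP(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    allele1_reads=standardize_allele1(alt_n, depth, hap_flip),
                    depth=depth,
                    raw_vaf=alt_n / depth,
                    hap_flip=hap_flip,
                )
            )
    if n_unphased or n_nonbiallelic:
        logger.info(
            "dropped %d unphased/non-het and %d non-biallelic sites",
            n_unphased,
            n_nonbiallelic,
        )
    if n_nocount:
        logger.warning("%d phased VCF sites had no count-table row; skipped", n_nocount)
    if n_zerodepth:
        logger.info("dropped %d sites with zero single-cell depth", n_zerodepth)
    for chrom in out:
        out[chrom].sort(key=lambda s: s.pos)
        pos = [s.pos for s in out[chrom]]
        if len(set(pos)) != len(pos):
            dedup: dict[int, PhasedHetSNP] = {}
            for s in out[chrom]:
                dedup.setdefault(s.pos, s)
            out[chrom] = list(dedup.values())
    return out


def select_candidates(
    counts_path: str | Path,
    bulk_sample: str,
    sc_sample: str,
    config: CandidateConfig | None = None,
    hsnp_positions: set[tuple[str, int]] | None = None,
    exclude_positions: set[tuple[str, int]] | None = None,
) -> list[CandidateSNV]:
    """Select candidate sSNVs from a joint read-count table.

    A site is retained when it meets the configured lenient support rules
    (single-cell depth and alt-read minimums, bulk depth minimum, bulk alt
    maximum) and is absent from the phased hSNP set and the optional
    population-SNP exclusion list.
    """
    cfg = config or CandidateConfig()
    df = read_count_table(counts_path)
    sc_ref, sc_alt = _sample_counts(df, sc_sample, counts_path)
    bulk_ref, bulk_alt = _sample_counts(df, bulk_sample, counts_path)
    sc_depth = sc_ref + sc_alt
    bulk_depth = bulk_ref + bulk_alt
    keep = (
        (sc_depth >= cfg.min_sc_depth)
        & (sc_alt >= cfg.min_sc_alt)
        & (bulk_depth >= cfg.min_bulk_depth)
        & (bulk_alt <= cfg.max_bulk_alt)
    )
    n_hsnp_overlap = 0
    cands: list[CandidateSNV] = []
    for i in np.flatnonzero(keep.to_numpy()):
        row = df.iloc[i]
        key = (str(row["chrom"]), int(row["pos"]))
        if hsnp_positions and key in hsnp_positions:
            n_hsnp_overlap += 1
            continue
        if exclude_positions and key in exclude_positions:
            continue
        cands.append(
            CandidateSNV(
                chrom=key[0],
                pos=key[1],
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                sc_alt=int(sc_alt.iloc[i]),
                sc_depth=int(sc_depth.iloc[i]),
                bulk_alt=int(bulk_alt.iloc[i]),
                bulk_depth=int(bulk_depth.iloc[i]),
            )
        )
    if n_hsnp_overlap:
        logger.info("removed %d candidates overlapping phased hSNPs", n_hsnp_overlap)
    cands.sort(key=lambda c: (c.chrom, c.pos))
    return cands


_TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "sc_alt", "sc_depth", "bulk_alt", "bulk_depth",
    "ab_mu", "ab_sigma2", "p_abc", "p_preamp", "p_amp", "alpha_preamp", "alpha_amp",
    "filter_flags", "pass",
]

_VCF_INFO = [
    ("ABMU", "Float", "Posterior mean of logit-scale allele balance"),
    ("ABSD", "Float", "Posterior sd of logit-scale allele balance"),
    ("PABC", "Float", "Allele balance consistency test p-value"),
    ("PPRE", "Float", "Pre-amplification artifact test p-value"),
    ("PAMP", "Float", "Amplification artifact test p-value"),
]


def write_calls(records: Sequence[CallRecord], out_prefix: str | Path) -> tuple[Path, Path]:
    """Write a full per-candidate TSV and a VCF containing passing calls only.

    Returns (tsv_path, vcf_path).  The TSV round-trips losslessly through
    :func:`read_calls`.
    """
    out_prefix = Path(out_prefix)
    tsv_path = Path(str(out_prefix) + ".tsv")
    vcf_path = Path(str(out_prefix) + ".vcf")

    rows = []
    for r in records:
        c = r.candidate
        rows.append(
            dict(
                chrom=c.chrom, pos=c.pos, ref=c.ref, alt=c.alt,
                sc_alt=c.sc_alt, sc_depth=c.sc_depth,
                bulk_alt=c.bulk_alt, bulk_depth=c.bulk_depth,
                ab_mu=repr(r.ab_mu), ab_sigma2=repr(r.ab_sigma2),
                p_abc=repr(r.p_abc), p_preamp=repr(r.p_preamp), p_amp=repr(r.p_amp),
                alpha_preamp=repr(r.alpha_preamp), alpha_amp=repr(r.alpha_amp),
                filter_flags=";".join(sorted(r.filter_flags)) or ".",
                **{"pass": r.passed},
            )
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(tsv_path, sep="\t", index=False)

    header = pysam.VariantHeader()
    header.add_line('##source=abcaller')
    for key, typ, desc in _VCF_INFO:
        header.add_line(f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">')
    contigs = sorted({r.candidate.chrom for r in records})
    for contig in contigs or ["1"]:
        header.add_line(f"##contig=<ID={contig}>")
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vcf:
        for r in records:
            if not r.passed:
                continue
            c = r.candidate
            rec = vcf.new_record(
                contig=c.chrom, start=c.pos - 1, stop=c.pos,
                alleles=(c.ref, c.alt), filter="PASS",
            )
            rec.info["ABMU"] = float(r.ab_mu)
            rec.info["ABSD"] = float(np.sqrt(r.ab_sigma2))
            rec.info["PABC"] = float(r.p_abc)
            rec.info["PPRE"] = float(r.p_preamp)
            rec.info["PAMP"] = float(r.p_amp)
            vcf.write(rec)
    return tsv_path, vcf_path


def read_calls(tsv_path: str | Path) -> list[CallRecord]:
    """Read back the per-candidate TSV written by :func:`write_calls`."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
    records = []
    for _, row in df.iterrows():
        cand = CandidateSNV(
            chrom=str(row["chrom"]), pos=int(row["pos"]),
            ref=str(row["ref"]), alt=str(row["alt"]),
            sc_alt=int(row["sc_alt"]), sc_depth=int(row["sc_depth"]),
            bulk_alt=int(row["bulk_alt"]), bulk_depth=int(row["bulk_depth"]),
        )
        flags = set() if row["filter_flags"] == "." else set(str(row["filter_flags"]).split(";"))
        records.append(
            CallRecord(
                candidate=cand,
                ab_mu=float(row["ab_mu"]), ab_sigma2=float(row["ab_sigma2"]),
                p_abc=float(row["p_abc"]), p_preamp=float(row["p_preamp"]),
                p_amp=float(row["p_amp"]),
                alpha_preamp=float(row["alpha_preamp"]), alpha_amp=float(row["alpha_amp"]),
                filter_flags=flags,
            )
        )
    return records
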