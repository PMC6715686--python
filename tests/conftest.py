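"""Shared fixtures: simulated datasets and one full labeled calling run."""

from __future__ import annotations

import pytest

from abcaller import fit_params
from abcaller.burden_fdr import depth_stratify
from abcaller.caller import CallerConfig, genotype_single
from abcaller.io_model import CandidateConfig, PhasedHetSNP
from abcaller.simulator import SimConfig, dataset_to_inputs, simulate_dataset


def make_hsnp(pos: int, allele1: int, depth: int, chrom: str = "1") -> PhasedHetSNP:
    return PhasedHetSNP(
        chrom=chrom, pos=pos, allele1_reads=allele1, depth=depth,
        raw_vaf=allele1 / depth, hap_flip=False,
    )


def apply_support_rules(cands, cfg: CandidateConfig | None = None):
    cfg = cfg or CandidateConfig()
    return [
        c for c in cands
        if c.sc_depth >= cfg.min_sc_depth and c.sc_alt >= cfg.min_sc_alt
        and c.bulk_depth >= cfg.min_bulk_depth and c.bulk_alt <= cfg.max_bulk_alt
    ]


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated chromosome with known labels (fast to genotype)."""
    cfg = SimConfig(n_hsnps=600, n_true_ssnvs=40, n_preamp_artifacts=40,
                    n_amp_artifacts=40, seed=42)
    df = simulate_dataset(cfg)
    hsnps, cands = dataset_to_inputs(df)
    truth = {(str(r.chrom), int(r.pos)): r.role for r in df.itertuples() if r.role != "hsnp"}
    return df, hsnps, cands, truth, cfg


@pytest.fixture(scope="session")
def labeled_call_run():
    """End-to-end single-sample calling on a labeled simulation.

    Study conditions: 200 true sSNVs, 400 pre-amplification + 400
    amplification artifacts, sequencing depth 30, hSNP spacing 1500 bp,
    target FDR 10%.
    """
    cfg = SimConfig(seed=7)
    df = simulate_dataset(cfg)
    hsnps, cands = dataset_to_inputs(df)
    cands = apply_support_rules(cands)
    truth = {(str(r.chrom), int(r.pos)): r.role for r in df.itertuples() if r.role != "hsnp"}
    fit = fit_params(hsnps["1"])
    allh = hsnps["1"]
    burden = depth_stratify(
        [s.depth for s in allh], [s.raw_vaf for s in allh],
        [c.sc_depth for c in cands], [c.vaf for c in cands], seed=7,
    )
    records = genotype_single(cands, hsnps, {"1": fit.params}, burden, CallerConfig())
    return records, truth, fit.params, cfg
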