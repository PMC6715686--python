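"""Genotyping orchestration, CIGAR filters, joint calling and QC."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from abcaller.ab_model import CovParams, predict_ab
from abcaller.burden_fdr import depth_stratify, tune_alpha
from abcaller.caller import (
    CigarProfile,
    cigar_filter,
    genotype_single,
    joint_call,
    qc_diagnostics,
)
from abcaller.io_model import CandidateSNV
from abcaller.sig_tests import abc_test
from conftest import make_hsnp


def profile(pos, cell_indel=0.0, cell_clip=0.0, bulk_indel=0.0, bulk_clip=0.0):
    return CigarProfile("1", pos, cell_indel, cell_clip, bulk_indel, bulk_clip)


class TestCigarFilter:
    def test_zero_fraction_never_flagged(self):
        hsnps = [profile(i, cell_indel=0.2, cell_clip=0.2) for i in range(10)]
        flags = cigar_filter([profile(999)], hsnps, seed=1)
        assert flags[("1", 999)] == set()

    def test_positive_fraction_against_all_zero_hsnps(self):
        hsnps = [profile(i) for i in range(10)]
        flags = cigar_filter([profile(999, cell_clip=0.5)], hsnps, seed=1)
        assert flags[("1", 999)] == {"clip_excess"}

    def test_empirical_percentile_cutoff(self):
        rng = np.random.default_rng(5)
        hsnps = [profile(i, cell_indel=f) for i, f in enumerate(rng.uniform(0, 0.1, 500))]
        hot = cigar_filter([profile(900, cell_indel=0.5)], hsnps, seed=1)
        cold = cigar_filter([profile(901, cell_indel=0.05)], hsnps, seed=1)
        assert hot[("1", 900)] == {"indel_excess"}
        assert cold[("1", 901)] == set()

    def test_bulk_conditioning(self):
        # noisy-in-bulk candidates are compared against equally noisy hSNPs
        hsnps = [profile(i, cell_indel=0.02, bulk_indel=0.0) for i in range(200)]
        hsnps += [profile(300 + i, cell_indel=0.4, bulk_indel=0.3) for i in range(200)]
        noisy = cigar_filter([profile(900, cell_indel=0.35, bulk_indel=0.3)], hsnps, seed=1)
        clean = cigar_filter([profile(901, cell_indel=0.35, bulk_indel=0.0)], hsnps, seed=1)
        assert noisy[("1", 900)] == set()
        assert clean[("1", 901)] == {"indel_excess"}

    def test_requires_hsnps(self):
        with pytest.raises(ValueError):
            cigar_filter([profile(1)], [], seed=1)


class TestGenotypeSingle:
    def test_zero_depth_flagged_low_depth(self, labeled_call_run):
        records, truth, params, cfg = labeled_call_run
        cand = CandidateSNV(chrom="1", pos=10, ref="A", alt="T",
                            sc_alt=0, sc_depth=0, bulk_alt=0, bulk_depth=30)
        burden_dummy = depth_stratify([30] * 10, [0.5] * 10, [30], [0.5], n_sims=20, seed=1)
        recs = genotype_single([cand], {"1": []}, {"1": params}, burden_dummy)
        assert recs[0].filter_flags == {"low_depth"}
        assert not recs[0].passed

    def test_imbalanced_region_artifact_scenario(self):
        # a VAF-44% candidate in a region with AB ~0.89 fails the consistency
        # test and is consistent with a pre-amplification artifact
        params = CovParams(a=0.0, b=10_000.0, c=-4.0, d=150.0)
        b_true = logit(0.89)
        rng = np.random.default_rng(2)
        snps = []
        for pos in range(2_000, 40_000, 1_500):
            d = 40
            y = int(rng.binomial(d, 0.89))
            snps.append(make_hsnp(pos, y, d))
        post = predict_ab(20_000.0, snps, params)
        assert expit(post.mu) == pytest.approx(0.89, abs=0.05)
        res = abc_test(22, 50, post.mu, post.sigma2, vaf=0.44)
        assert res.p_value < 0.05
        from abcaller.sig_tests import artifact_test
        pre = artifact_test(22, 50, post.mu, post.sigma2, f=2)
        assert pre.p_value > 0.2

    def test_labeled_run_verdicts(self, labeled_call_run):
        records, truth, params, cfg = labeled_call_run
        # a matched-VAF true sSNV in a balanced region passes the ABC test
        passing_true = [
            r for r in records
            if truth[(r.candidate.chrom, r.candidate.pos)] == "true_ssnv" and r.passed
        ]
        assert len(passing_true) > 0
        assert all("abc_fail" not in r.filter_flags for r in passing_true)
        # simulated pre-amplification artifacts are overwhelmingly rejected
        preamp = [r for r in records if truth[(r.candidate.chrom, r.candidate.pos)] == "preamp"]
        rejected = sum(1 for r in preamp if not r.passed)
        assert rejected / len(preamp) > 0.9

    def test_theta_monotonicity_of_tuned_alpha(self):
        # a candidate callable at theta is callable at any larger theta
        for theta_lo, theta_hi in ((0.05, 0.1), (0.1, 0.3)):
            lo = tune_alpha(30, 0.8, 1.4, 0.2, n_t=50.0, n_a=30.0, theta=theta_lo, f=2)
            hi = tune_alpha(30, 0.8, 1.4, 0.2, n_t=50.0, n_a=30.0, theta=theta_hi, f=2)
            assert hi >= lo


def _table(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "sample",
                                       "y", "d", "p_abc", "gp_sd"])


class TestJointCall:
    def make_hsnp_table(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            for smp in ("c1", "c2"):
                rows.append(("1", 1000 + i, "A", "C", smp,
                             int(rng.integers(1, 20)), 30, float(rng.uniform(0.2, 1.0)), 0.5))
        return _table(rows)

    def test_single_support_product_of_one(self):
        sites = _table([
            ("1", 5, "A", "T", "c1", 4, 30, 0.4, 0.5),
            ("1", 5, "A", "T", "c2", 0, 30, 0.9, 0.5),
        ])
        recs = joint_call(sites, self.make_hsnp_table(), seed=1)
        assert recs[0].n_support == 1
        assert recs[0].j_stat == pytest.approx(0.4)

    def test_gp_sd_penalty_arithmetic(self):
        sites = _table([
            ("1", 5, "A", "T", "c1", 4, 30, 0.4, 0.5),
            ("1", 5, "A", "T", "c2", 3, 30, 0.4, 1.5),
        ])
        recs = joint_call(sites, self.make_hsnp_table(), seed=1)
        assert recs[0].j_stat == pytest.approx(0.4 * 0.04)

    def test_missing_class_inherits_threshold(self):
        sites = _table([
            ("1", 5, "A", "T", s, 2, 30, 0.5, 0.5) for s in ("c1", "c2", "c3")
        ])
        hsnp = self.make_hsnp_table()  # only 2-sample support classes
        recs = joint_call(sites, hsnp, seed=1)
        assert recs[0].n_support == 3
        assert recs[0].threshold > 0.0  # inherited from class 2

    def test_requires_two_samples(self):
        sites = _table([("1", 5, "A", "T", "c1", 4, 30, 0.4, 0.5)])
        with pytest.raises(ValueError):
            joint_call(sites, self.make_hsnp_table(), seed=1)

    def test_shared_mutations_recovered_better_than_private_artifacts(self):
        # 4 cells share germline hSNP sites (per-cell reads, dropout included)
        # and true sSNVs; pre-amplification artifacts (half the carrier
        # fraction) are private to one cell.  Joint calling recovers shared
        # mutations at a much higher rate than it passes private artifacts.
        rng = np.random.default_rng(20)
        n_cells, n_hsnp, n_shared, n_art = 4, 300, 40, 160
        sig2 = 0.05

        def cell_obs(divisor: float, dropout: float = 0.0):
            b = rng.normal(0, 1.0)
            d = max(1, int(rng.poisson(30)))
            carrier = expit(b) if rng.random() < 0.5 else 1 - expit(b)
            y = 0 if rng.random() < dropout else int(rng.binomial(d, carrier / divisor))
            p = abc_test(y, d, b, sig2, vaf=y / d).p_value
            return y, d, p

        rows_h, rows_s, truth = [], [], {}
        for k in range(n_hsnp):
            for ci in range(n_cells):
                # allele dropout populates the low-support hSNP classes that
                # set thresholds for sparsely supported sSNVs
                y, d, p = cell_obs(1.0, dropout=0.25)
                rows_h.append(("1", 1000 + k, "A", "C", f"c{ci}", y, d, p, np.sqrt(sig2)))
        for k in range(n_shared):
            truth[("1", 50_000 + k)] = "true"
            for ci in range(n_cells):
                y, d, p = cell_obs(1.0)
                rows_s.append(("1", 50_000 + k, "A", "T", f"c{ci}", y, d, p, np.sqrt(sig2)))
        for k in range(n_art):
            truth[("1", 90_000 + k)] = "artifact"
            carrier_cell = k % n_cells
            for ci in range(n_cells):
                y, d, p = cell_obs(2.0) if ci == carrier_cell else (0, 30, 1.0)
                rows_s.append(("1", 90_000 + k, "A", "T", f"c{ci}", y, d, p, np.sqrt(sig2)))
        recs = joint_call(_table(rows_s), _table(rows_h), seed=1)
        true_recs = [r for r in recs if truth[r.site[:2]] == "true"]
        art_recs = [r for r in recs if truth[r.site[:2]] == "artifact"]
        recall_shared = sum(r.passed for r in true_recs) / len(true_recs)
        fp_rate = sum(r.passed for r in art_recs) / len(art_recs)
        assert recall_shared > 0.7
        assert recall_shared > fp_rate + 0.2

    def test_agrees_with_single_sample_abc_on_one_support(self):
        # a site supported in one sample passes joint calling iff its ABC
        # p-value (with penalty) clears the 1-support hSNP threshold
        hsnp = self.make_hsnp_table()
        hsnp.loc[hsnp["sample"] == "c2", "y"] = 0  # all hSNPs 1-support
        sites = _table([
            ("1", 5, "A", "T", "c1", 4, 30, 0.9, 0.5),
            ("1", 5, "A", "T", "c2", 0, 30, 0.9, 0.5),
            ("1", 6, "A", "T", "c1", 4, 30, 1e-6, 0.5),
            ("1", 6, "A", "T", "c2", 0, 30, 1e-6, 0.5),
        ])
        recs = {r.site[1]: r for r in joint_call(sites, hsnp, seed=1)}
        assert recs[5].passed
        assert not recs[6].passed


class TestQC:
    def test_null_score_near_zero_and_bins_conserve(self):
        rng = np.random.default_rng(0)
        hv = rng.beta(8, 8, size=4000)
        sv = rng.choice(hv, size=400, replace=False)
        rep = qc_diagnostics(hv, sv)
        assert abs(rep.doublet_score) < 0.05
        assert rep.hsnp_density.sum() == rep.n_hsnps
        assert rep.ssnv_density.sum() == rep.n_ssnvs

    def test_doublet_mixture_scores_positive(self):
        rng = np.random.default_rng(1)
        hv = rng.beta(8, 8, size=4000)
        sv = np.concatenate([rng.beta(8, 8, size=200), rng.beta(8, 24, size=200)])
        rep = qc_diagnostics(hv, sv)
        assert rep.doublet_score > 0.05

    def test_downsampled_reference_shifts_left(self):
        rng = np.random.default_rng(2)
        depth = np.full(2000, 30)
        alt = rng.binomial(30, 0.5, size=2000)
        rep = qc_diagnostics(alt / depth, alt / depth, hsnp_alt=alt, hsnp_depth=depth, seed=5)
        centers = (np.arange(20) + 0.5) / 20
        mean_ref = (rep.downsampled_density / rep.downsampled_density.sum() * centers).sum()
        mean_h = (rep.hsnp_density / rep.hsnp_density.sum() * centers).sum()
        assert mean_ref < mean_h - 0.15
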