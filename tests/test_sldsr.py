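"""Annotations, LD scores (vs brute-force oracle), and the partitioned
heritability fit (null calibration and parameter recovery)."""

import numpy as np
import pandas as pd
import pytest

from cellherit.datatypes import GeneSet, InputError, ParameterError, PeakSet
from cellherit.simulate import (
    enrichment_weights,
    simulate_genome,
    simulate_gwas,
    simulate_ld_panel,
)
from cellherit.sldsr import (
    StratifiedLDScoreRegression,
    exclusion_mask,
    fit_partitioned,
    gene_set_to_annotation,
    joint_enrichment,
    ld_scores,
    make_baseline,
    peaks_to_annotation,
)
from conftest import toy_panel_at


@pytest.fixture(scope="module")
def h2_panel():
    """Criterion-scale panel for recovery checks (shared, read-only)."""
    g = simulate_genome(2, 100, chrom_length=12_500_000, seed=21)
    p = simulate_ld_panel(g, m_snps=5_000, n_hap=500, block_len=50_000,
                          seed=21)
    return g, p


class TestGeneSetAnnotation:
    def test_window_boundaries(self, toy_genome):
        # gA + strand [100000,110000]; SLDSR window [1, 210000] (clipped)
        panel = toy_panel_at([1, 209_999, 210_000, 210_001])
        col = gene_set_to_annotation(
            GeneSet("s", ("gA",)), toy_genome, panel
        )
        np.testing.assert_array_equal(col, [1, 1, 1, 0])

    def test_inside_gene_body(self, toy_genome):
        panel = toy_panel_at([105_000])
        col = gene_set_to_annotation(GeneSet("s", ("gA",)), toy_genome, panel)
        assert col[0] == 1

    def test_overlapping_windows_union(self, toy_genome):
        # gA and gB windows overlap between them on chr1
        panel = toy_panel_at([205_000])
        col = gene_set_to_annotation(
            GeneSet("s", ("gA", "gB")), toy_genome, panel
        )
        assert col[0] == 1  # counted once, binary

    def test_empty_set_rejected(self, toy_genome):
        panel = toy_panel_at([100])
        with pytest.raises(ParameterError):
            gene_set_to_annotation(GeneSet("s", ()), toy_genome, panel)


class TestPeakAnnotation:
    def test_bed_half_open_convention(self):
        panel = toy_panel_at([101, 200, 201])
        peaks = pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [200]}
        )
        col = peaks_to_annotation(peaks, panel)
        # 1-based SNP at start+1 inside; at end inside; at end+1 outside
        np.testing.assert_array_equal(col, [1, 1, 0])

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(np.arange(1, 10_000), 20, replace=False))
        panel = toy_panel_at(list(pos))
        starts = np.sort(rng.choice(np.arange(0, 9_000), 5, replace=False))
        peaks = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 500}
        )
        col = peaks_to_annotation(peaks, panel)
        expect = [
            float(any(s < p <= e for s, e in zip(peaks["start"], peaks["end"])))
            for p in panel.snps["pos"]
        ]
        np.testing.assert_array_equal(col, expect)


class TestLDScores:
    def test_matches_brute_force_double_loop(self, genome):
        p = simulate_ld_panel(genome, m_snps=60, n_hap=100, seed=22)
        rng = np.random.default_rng(2)
        annot = pd.DataFrame(
            {
                "base": np.ones(p.m),
                "cat": rng.integers(0, 2, p.m).astype(float),
            },
            index=p.snps["snp_id"],
        )
        window = 400_000
        got = ld_scores(p, annot, window=window).to_numpy()
        h = p.haplotypes.astype(float)
        z = (h - h.mean(0)) / h.std(0)
        n = p.n_hap
        pos = p.snps["pos"].to_numpy()
        chrom = p.snps["chrom"].to_numpy()
        A = annot.to_numpy()
        expect = np.zeros_like(got)
        for j in range(p.m):
            for k in range(p.m):
                if chrom[j] != chrom[k] or abs(pos[j] - pos[k]) > window:
                    continue
                r = float((z[:, j] * z[:, k]).mean())
                r2 = r * r
                expect[j] += (r2 - (1 - r2) / (n - 2)) * A[k]
        np.testing.assert_allclose(got, expect, atol=1e-10)

    def test_isolated_snp_base_score_near_one(self):
        panel = toy_panel_at([1_000, 900_000], n_hap=200)
        annot = pd.DataFrame({"base": np.ones(2)}, index=panel.snps["snp_id"])
        sc = ld_scores(panel, annot, window=100_000)
        assert sc["base"].iloc[0] == pytest.approx(1.0, abs=0.1)

    def test_all_zero_category_gives_zero_scores(self, panel):
        annot = pd.DataFrame(
            {"base": np.ones(panel.m), "empty": np.zeros(panel.m)},
            index=panel.snps["snp_id"],
        )
        sc = ld_scores(panel, annot)
        assert (sc["empty"] == 0).all()

    def test_base_dominates_subcategories(self, panel):
        rng = np.random.default_rng(3)
        annot = pd.DataFrame(
            {
                "base": np.ones(panel.m),
                "sub": rng.integers(0, 2, panel.m).astype(float),
            },
            index=panel.snps["snp_id"],
        )
        sc = ld_scores(panel, annot)
        # base >= sub holds in expectation; the bias-adjusted estimator's
        # complement-SNP terms are zero-mean noise, hence the tolerance
        assert (sc["base"] >= sc["sub"] - 0.3).all()

    def test_tiny_reference_rejected(self):
        panel = toy_panel_at([100, 200], n_hap=2)
        annot = pd.DataFrame({"base": np.ones(2)}, index=panel.snps["snp_id"])
        with pytest.raises(ParameterError):
            ld_scores(panel, annot)


class TestPartitionedFit:
    def test_null_intercept_and_tau_coverage(self, h2_panel):
        g, p = h2_panel
        annot = make_baseline(g, p, seed=0)
        scores = ld_scores(p, annot)
        n_ok_int = n_ok_tau = 0
        n_seeds = 10
        for s in range(n_seeds):
            ss = simulate_gwas(p, None, 0.0, 50_000, seed=300 + s)
            fit = fit_partitioned(ss, scores, annot, n_blocks=200)
            n_ok_int += abs(fit.intercept_ - 1) <= 1.96 * fit.intercept_se_
            n_ok_tau += all(
                abs(t) <= 1.96 * se for t, se in zip(fit.tau_, fit.tau_se_)
            )
        assert n_ok_int >= 8
        assert n_ok_tau >= 7

    def test_h2_recovery_base_only(self, h2_panel):
        _, p = h2_panel
        annot = pd.DataFrame({"base": np.ones(p.m)}, index=p.snps["snp_id"])
        scores = ld_scores(p, annot)
        covered = 0
        n_seeds = 10
        for s in range(n_seeds):
            ss = simulate_gwas(p, None, 0.4, 50_000, seed=400 + s)
            fit = fit_partitioned(ss, scores, annot, n_blocks=200)
            lo, hi = fit.h2_ci()
            covered += lo <= 0.4 <= hi
        assert covered >= 9

    def test_duplicated_category_rejected(self, panel, null_stats):
        annot = pd.DataFrame(
            {"base": np.ones(panel.m), "dup": np.ones(panel.m)},
            index=panel.snps["snp_id"],
        )
        scores = ld_scores(panel, annot)
        with pytest.raises(ParameterError, match="base.*dup|collinear"):
            fit_partitioned(null_stats, scores, annot)

    def test_base_enrichment_is_one(self, h2_panel):
        _, p = h2_panel
        annot = make_baseline(h2_panel[0], p, seed=0)
        scores = ld_scores(p, annot)
        ss = simulate_gwas(p, None, 0.3, 50_000, seed=5)
        fit = fit_partitioned(ss, scores, annot, n_blocks=100)
        assert fit.enrichment_[fit.categories_.index("base")] == pytest.approx(1.0)
        assert (fit.prop_snps_ > 0).all()
        assert (fit.tau_se_ > 0).all()

    def test_estimator_params_roundtrip(self):
        est = StratifiedLDScoreRegression(n_blocks=50)
        assert est.get_params()["n_blocks"] == 50
        est.set_params(n_blocks=20)
        assert est.n_blocks == 20


class TestJointEnrichment:
    def test_planted_focal_beats_null_focal(self, h2_panel):
        g, p = h2_panel
        rng = np.random.default_rng(6)
        baseline = make_baseline(g, p, seed=0)
        wins = 0
        n_seeds = 6
        for s in range(n_seeds):
            focal = np.zeros(p.m)
            focal[rng.choice(p.m, p.m // 10, replace=False)] = 1
            null_focal = np.zeros(p.m)
            null_focal[rng.choice(p.m, p.m // 10, replace=False)] = 1
            w = enrichment_weights(focal.astype(bool), 5.0)
            ss = simulate_gwas(p, None, 0.4, 50_000, seed=500 + s,
                               causal_weights=w)
            fit_a = joint_enrichment(ss, focal, baseline, None, p,
                                     n_blocks=100)
            fit_b = joint_enrichment(ss, null_focal, baseline, None, p,
                                     n_blocks=100)
            pa = fit_a.p_one_tailed_[fit_a.categories_.index("focal")]
            pb = fit_b.p_one_tailed_[fit_b.categories_.index("focal")]
            wins += pa < pb
        assert wins >= 5

    def test_exclusion_region_removed_from_fit(self, h2_panel):
        g, p = h2_panel
        baseline = make_baseline(g, p, seed=0)
        focal = np.ones(p.m)
        focal[::2] = 0
        region = ("chr1", 1, 2_000_000)
        ss = simulate_gwas(p, None, 0.2, 20_000, seed=7)
        fit = joint_enrichment(ss, focal, baseline, None, p,
                               exclusion_region=region, n_blocks=50)
        keep = exclusion_mask(p, region)
        assert fit.n_snps_fit_ == int(keep.sum())
        assert not keep[
            (p.snps["chrom"] == "chr1") & (p.snps["pos"] <= 2_000_000)
        ].any()

    def test_focal_identical_to_union_rejected(self, h2_panel, null_stats):
        g, p = h2_panel
        baseline = make_baseline(g, p, seed=0)
        focal = np.zeros(p.m)
        focal[:100] = 1
        with pytest.raises(ParameterError):
            joint_enrichment(None, focal, baseline, focal.copy(), p)

    def test_empty_focal_rejected(self, h2_panel):
        g, p = h2_panel
        baseline = make_baseline(g, p, seed=0)
        with pytest.raises(ParameterError):
            joint_enrichment(None, np.zeros(p.m), baseline, None, p)
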