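"""Peak calling, context annotation, overlap accounting, SNP mapping,
co-accessibility."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cellherit.atac import (
    LocalPoissonPeakCaller,
    annotate_peak_context,
    call_peaks,
    coaccessibility,
    map_snps_to_peaks,
    merge_peaks,
    overlap_pattern_counts,
    peak_count_matrix,
    peak_set_overlap,
)
from cellherit.datatypes import CredibleSet, ParameterError, PeakSet


def reciprocal_overlap(a, b, frac=0.5):
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return ov >= frac * (a[1] - a[0]) and ov >= frac * (b[1] - b[0])


class TestPeakCalling:
    def test_planted_peaks_recovered(self, coverage):
        truth = coverage.truth_peaks
        for ct in ("T1", "T2"):
            ps = call_peaks(coverage, ct, fdr=0.05)
            want = truth[truth["cell_type"].isin([ct, "shared"])]
            called = list(zip(ps.df["start"], ps.df["end"]))
            tr = list(zip(want["start"], want["end"]))
            recall = np.mean([
                any(reciprocal_overlap(t, c) for c in called) for t in tr
            ])
            precision = np.mean([
                any(reciprocal_overlap(c, t) for t in tr) for c in called
            ])
            assert recall >= 0.9
            assert precision >= 0.9

    def test_null_coverage_yields_no_peaks(self, coverage):
        rng = np.random.default_rng(1)
        null = dataclasses.replace(
            coverage,
            counts=rng.poisson(2.0, size=coverage.counts.shape),
            truth_peaks=coverage.truth_peaks.iloc[:0],
            truth_pairs=[],
        )
        caller = LocalPoissonPeakCaller(fdr=0.05).fit(null, "T1")
        n_bins = null.counts.shape[1]
        assert (caller.bin_qvalues_ < 0.05).sum() / n_bins <= 0.05 + 0.01
        assert len(caller.peaks_) <= 2

    def test_all_zero_coverage_empty_set(self, coverage):
        zero = dataclasses.replace(
            coverage, counts=np.zeros_like(coverage.counts)
        )
        assert len(call_peaks(zero, "T1")) == 0

    def test_near_unity_fold_finds_no_peaks(self, atac_genome):
        from cellherit.simulate import simulate_atac

        cov = simulate_atac(
            atac_genome, k_types=2, peaks_per_type=20, fold=1.0001,
            background_rate=2.0, pseudo_cells_per_type=10, seed=17,
        )
        assert len(call_peaks(cov, "T1", fdr=0.05)) <= 2

    def test_bad_fdr_rejected(self, coverage):
        with pytest.raises(ParameterError):
            call_peaks(coverage, "T1", fdr=1.5)


class TestMerge:
    def test_merge_idempotent(self):
        df = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "start": [0, 50, 200],
                "end": [100, 150, 300],
                "score": [1.0, 2.0, 3.0],
                "qvalue": [0.01, 0.001, 0.02],
            }
        )
        once = merge_peaks(df)
        twice = merge_peaks(once)
        assert once.equals(twice)
        assert list(once["start"]) == [0, 200]
        assert once.loc[0, "score"] == 2.0
        assert once.loc[0, "qvalue"] == 0.001


class TestContextAnnotation:
    def _peaks(self, rows):
        return PeakSet(df=pd.DataFrame(
            rows, columns=["chrom", "start", "end"]
        ).assign(score=0.0, qvalue=0.0))

    def test_promoter_window_plus_strand(self, toy_genome):
        # gA + strand TSS=100000; promoter [99000, 100100]
        ps = self._peaks([("chr1", 99_400, 99_900)])
        assert annotate_peak_context(ps, toy_genome).iloc[0] == "promoter"

    def test_promoter_window_minus_strand(self, toy_genome):
        # gB - strand TSS=320000; promoter [319900, 321000]
        ps = self._peaks([("chr1", 320_500, 320_800)])
        assert annotate_peak_context(ps, toy_genome).iloc[0] == "promoter"

    def test_distal_far_from_genes(self, toy_genome):
        ps = self._peaks([("chr1", 600_000, 600_500)])
        assert annotate_peak_context(ps, toy_genome).iloc[0] == "distal_intergenic"

    def test_promoter_precedence_over_gene_body(self, toy_genome):
        # spans promoter and gene body of gA
        ps = self._peaks([("chr1", 99_500, 105_000)])
        assert annotate_peak_context(ps, toy_genome).iloc[0] == "promoter"

    def test_gene_body_is_intronic_without_exons(self, toy_genome):
        ps = self._peaks([("chr1", 104_000, 105_000)])
        assert annotate_peak_context(ps, toy_genome).iloc[0] == "intronic"

    def test_exonic_with_exon_table(self, toy_genome):
        exons = pd.DataFrame(
            {"chrom": ["chr1"], "start": [104_000], "end": [104_500]}
        )
        ps = self._peaks([("chr1", 104_100, 104_300)])
        ctx = annotate_peak_context(ps, toy_genome, exons=exons)
        assert ctx.iloc[0] == "exonic"

    def test_every_peak_gets_one_context(self, coverage, atac_genome):
        ps = call_peaks(coverage, "T1")
        ctx = annotate_peak_context(ps, atac_genome)
        assert len(ctx) == len(ps)
        assert ctx.isin(
            ["promoter", "exonic", "intronic", "distal_intergenic"]
        ).all()


class TestOverlap:
    def _ps(self, rows, source):
        return PeakSet(df=pd.DataFrame(
            rows, columns=["chrom", "start", "end"]
        ).assign(score=0.0, qvalue=0.0), source=source)

    def test_identical_sets_all_shared(self):
        rows = [("chr1", 0, 100), ("chr1", 500, 700)]
        tab = peak_set_overlap({"a": self._ps(rows, "a"), "b": self._ps(rows, "b")})
        assert tab[["a", "b"]].all().all()

    def test_disjoint_sets_all_unique(self):
        tab = peak_set_overlap({
            "a": self._ps([("chr1", 0, 100)], "a"),
            "b": self._ps([("chr1", 200, 300)], "b"),
        })
        assert not (tab["a"] & tab["b"]).any()

    def test_three_set_patterns_match_brute_force(self):
        rng = np.random.default_rng(2)
        sets = {}
        for name in "abc":
            starts = np.sort(rng.choice(np.arange(0, 5_000, 10), 8, replace=False))
            sets[name] = self._ps(
                [("chr1", int(s), int(s + rng.integers(5, 30))) for s in starts],
                name,
            )
        tab = peak_set_overlap(sets)
        for _, row in tab.iterrows():
            for other in "abc":
                if other == row["source"]:
                    continue
                d = sets[other].df
                expect = bool(
                    ((d["start"] < row["end"]) & (d["end"] > row["start"])).any()
                )
                assert row[other] == expect
        counts = overlap_pattern_counts(tab, list("abc"))
        assert counts.sum() == sum(len(s) for s in sets.values())


class TestSnpMapping:
    def _panel(self, positions):
        from conftest import toy_panel_at

        return toy_panel_at(positions)

    def test_rows_match_brute_force(self):
        panel = self._panel([50, 150, 250, 350, 450, 550, 650, 750, 850, 950])
        peaks = {
            "T1": PeakSet(df=pd.DataFrame(
                {"chrom": ["chr1"] * 2, "start": [100, 600], "end": [300, 700]}
            ).assign(score=0.0, qvalue=0.0), source="T1"),
            "T2": PeakSet(df=pd.DataFrame(
                {"chrom": ["chr1"], "start": [200], "end": [400]}
            ).assign(score=0.0, qvalue=0.0), source="T2"),
        }
        credible = [CredibleSet("L0", [f"s{i}" for i in range(10)],
                                np.full(10, 0.1))]
        tab = map_snps_to_peaks(credible, peaks, panel)
        got = dict(zip(tab["snp_id"], tab["cell_types"]))
        assert got == {"s1": "T1", "s2": "T1,T2", "s3": "T2", "s6": "T1"}

    def test_unknown_snp_skipped(self, caplog):
        panel = self._panel([50])
        peaks = {"T1": PeakSet(df=pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [100]}
        ).assign(score=0.0, qvalue=0.0), source="T1")}
        credible = [CredibleSet("L0", ["s0", "ghost"], np.array([0.5, 0.5]))]
        tab = map_snps_to_peaks(credible, peaks, panel)
        assert list(tab["snp_id"]) == ["s0"]


class TestCoaccessibility:
    def test_planted_pair_recovered_with_positive_correlation(self, coverage):
        truth = coverage.truth_peaks
        ctx = pd.Series("other", index=truth.index)
        for a, b in coverage.truth_pairs:
            ctx.loc[a] = "distal_intergenic"
            ctx.loc[b] = "promoter"
        pc = peak_count_matrix(coverage, truth)
        hits = coaccessibility(pc, truth, ctx, fdr=0.05)
        planted = {(a, b) for a, b in coverage.truth_pairs}
        got = set(zip(hits["peak_a"], hits["peak_b"]))
        assert planted <= got
        for a, b in planted:
            row = hits[(hits["peak_a"] == a) & (hits["peak_b"] == b)].iloc[0]
            assert row["correlation"] > 0
            assert row["qvalue"] < 0.05

    def test_correlations_match_brute_force_pearson(self, coverage):
        truth = coverage.truth_peaks
        ctx = pd.Series("other", index=truth.index)
        for a, b in coverage.truth_pairs:
            ctx.loc[a] = "distal_intergenic"
            ctx.loc[b] = "promoter"
        pc = peak_count_matrix(coverage, truth)
        hits = coaccessibility(pc, truth, ctx, fdr=1.0 - 1e-12)
        x = pc.to_numpy(dtype=float)
        x = np.log1p(x / x.sum(axis=1, keepdims=True) * 1e4)
        loc = {p: k for k, p in enumerate(pc.columns)}
        for _, row in hits.iterrows():
            a, b = loc[row["peak_a"]], loc[row["peak_b"]]
            expect = np.corrcoef(x[:, a], x[:, b])[0, 1]
            assert row["correlation"] == pytest.approx(expect, abs=1e-10)

    def test_distance_boundary_and_self_pairs_excluded(self):
        rng = np.random.default_rng(3)
        peaks = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "start": [0, 100_000, 200_002],
                "end": [1_000, 101_000, 203_002],
            }
        )
        # midpoints: 500, 100500, 201502: d(0,1)=100000 ok; d(1,2)=101002 too far
        ctx = pd.Series(["distal_intergenic", "promoter", "promoter"],
                        index=peaks.index)
        pc = pd.DataFrame(rng.poisson(20, size=(30, 3)), columns=peaks.index)
        hits = coaccessibility(pc, peaks, ctx, fdr=1.0 - 1e-12)
        tested = set(zip(hits["peak_a"], hits["peak_b"]))
        assert tested <= {(0, 1)}
        assert (0, 2) not in tested

    def test_zero_variance_peak_skipped_with_warning(self):
        peaks = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "start": [0, 10_000], "end": [1_000, 11_000]}
        )
        ctx = pd.Series(["distal_intergenic", "promoter"], index=peaks.index)
        pc = pd.DataFrame(
            {0: np.arange(30), 1: np.zeros(30, dtype=int)}, columns=peaks.index
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            hits = coaccessibility(pc, peaks, ctx)
        assert len(hits) == 0
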