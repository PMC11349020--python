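"""Open-chromatin analysis: peak calling on binned coverage, peak context
annotation, cross-cell-type overlap, credible-set SNP mapping, and distal
peak to promoter co-accessibility.

Peak calling follows the local-background logic of fragment-pileup callers:
each bin's count (summed over a cell type's pseudo-cells) is tested against
a Poisson null whose rate is the maximum of the genome-wide mean and the
mean in centered local windows, p-values are Benjamini-Hochberg corrected
across bins, and adjacent significant bins are merged into peaks reported
at FDR < 0.05.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    AtacCoverage,
    CredibleSet,
    GenomeModel,
    InputError,
    LDPanel,
    ParameterError,
    PeakSet,
)

__all__ = [
    "LocalPoissonPeakCaller",
    "call_peaks",
    "merge_peaks",
    "annotate_peak_context",
    "peak_set_overlap",
    "map_snps_to_peaks",
    "peak_count_matrix",
    "coaccessibility",
]

log = logging.getLogger(__name__)

CONTEXTS = ("promoter", "exonic", "intronic", "distal_intergenic")


def merge_peaks(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent half-open intervals; idempotent.

    Keeps the maximum score and the minimum q-value of merged members.
    """
    if len(df) == 0:
        return df.copy()
    out = []
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur = None
        for row in grp.itertuples(index=False):
            if cur is None or row.start > cur["end"]:
                if cur is not None:
                    out.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": int(row.start),
                    "end": int(row.end),
                    "score": float(getattr(row, "score", 0.0)),
                    "qvalue": float(getattr(row, "qvalue", 0.0)),
                }
            else:
                cur["end"] = max(cur["end"], int(row.end))
                cur["score"] = max(cur["score"], float(getattr(row, "score", 0.0)))
                cur["qvalue"] = min(cur["qvalue"], float(getattr(row, "qvalue", 0.0)))
        out.append(cur)
    return pd.DataFrame(out).sort_values(["chrom", "start"]).reset_index(drop=True)


class LocalPoissonPeakCaller(BaseEstimator):
    """Peak calling by one-sided Poisson tests against a local background.

    Parameters
    ----------
    fdr : float
        Benjamini-Hochberg threshold across bins.
    local_windows : list of int
        Widths (bp) of the centered windows whose mean rates compete with
        the genome-wide mean for the null rate lambda_local.

    Attributes (after ``fit``)
    --------------------------
    peaks_ : PeakSet of merged FDR-significant bins.
    bin_pvalues_, bin_qvalues_ : per-bin test results.
    """

    def __init__(self, fdr: float = 0.05, local_windows: tuple = (5_000, 10_000)):
        self.fdr = fdr
        self.local_windows = local_windows

    def fit(self, coverage: AtacCoverage, cell_type: str):
        if not 0 < self.fdr < 1:
            raise ParameterError("fdr must lie in (0, 1)")
        sel = coverage.pseudo_cell_type == cell_type
        if not sel.any():
            raise InputError(f"no pseudo-cells labeled {cell_type!r}")
        counts = coverage.counts[sel].sum(axis=0).astype(float)
        bin_size = coverage.bin_size
        genome_rate = counts.mean()
        lam = np.full(len(counts), max(genome_rate, 1e-12))
        for w in self.local_windows:
            half = max(1, int(round(w / bin_size)) // 2)
            for chrom in pd.unique(coverage.bin_chrom):
                idx = np.flatnonzero(coverage.bin_chrom == chrom)
                x = counts[idx]
                csum = np.concatenate([[0.0], np.cumsum(x)])
                n = len(x)
                lo = np.maximum(np.arange(n) - half, 0)
                hi = np.minimum(np.arange(n) + half + 1, n)
                local = (csum[hi] - csum[lo]) / (hi - lo)
                lam[idx] = np.maximum(lam[idx], local)
        pvals = stats.poisson.sf(counts - 1, lam)
        reject, qvals, *_ = multipletests(pvals, alpha=self.fdr, method="fdr_bh")
        self.bin_pvalues_ = pvals
        self.bin_qvalues_ = qvals
        rows = []
        if reject.any():
            sig = np.flatnonzero(reject)
            breaks = np.flatnonzero(
                (np.diff(sig) != 1)
                | (coverage.bin_chrom[sig[1:]] != coverage.bin_chrom[sig[:-1]])
            )
            for run in np.split(sig, breaks + 1):
                b0, b1 = run[0], run[-1]
                with np.errstate(divide="ignore"):
                    score = float(-np.log10(max(pvals[run].min(), 1e-300)))
                rows.append(
                    {
                        "chrom": coverage.bin_chrom[b0],
                        "start": int(coverage.bin_start[b0]),
                        "end": int(coverage.bin_start[b1] + bin_size),
                        "score": score,
                        "qvalue": float(qvals[run].min()),
                    }
                )
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "qvalue"])
        self.peaks_ = PeakSet(df=merge_peaks(df) if len(df) else df, source=cell_type)
        return self


def call_peaks(
    coverage: AtacCoverage,
    cell_type: str,
    fdr: float = 0.05,
    local_windows: tuple = (5_000, 10_000),
) -> PeakSet:
    """High-confidence (FDR < ``fdr``) open-chromatin regions for one cell
    type.  All-zero coverage yields an empty PeakSet."""
    caller = LocalPoissonPeakCaller(fdr=fdr, local_windows=local_windows)
    return caller.fit(coverage, cell_type).peaks_


def annotate_peak_context(
    peaks: PeakSet,
    genome: GenomeModel,
    exons: pd.DataFrame | None = None,
    promoter_up: int = 1_000,
    promoter_down: int = 100,
) -> pd.Series:
    """Assign each peak one genomic context with precedence
    promoter > exonic > intronic > distal_intergenic.

    The promoter is the strand-oriented window 1000 bp upstream to 100 bp
    downstream of the TSS.  Without an exon table the gene body counts as
    intronic (a single gene-body context); supply ``exons`` (chrom, start,
    end; 1-based inclusive) for the full four-way split.
    """
    g = genome.genes
    plus = g["strand"] == "+"
    prom_lo = np.where(plus, g["start"] - promoter_up, g["end"] - promoter_down)
    prom_hi = np.where(plus, g["start"] + promoter_down, g["end"] + promoter_up)
    tracks: list[tuple[str, pd.DataFrame]] = [
        (
            "promoter",
            pd.DataFrame({"chrom": g["chrom"], "lo": prom_lo, "hi": prom_hi}),
        )
    ]
    if exons is not None:
        tracks.append(
            (
                "exonic",
                pd.DataFrame(
                    {"chrom": exons["chrom"], "lo": exons["start"], "hi": exons["end"]}
                ),
            )
        )
    tracks.append(
        ("intronic", pd.DataFrame({"chrom": g["chrom"], "lo": g["start"], "hi": g["end"]}))
    )
    by_chrom = {
        name: {c: (grp["lo"].to_numpy(), grp["hi"].to_numpy())
               for c, grp in t.groupby("chrom", sort=False)}
        for name, t in tracks
    }
    out = []
    for row in peaks.df.itertuples(index=False):
        p_lo, p_hi = row.start + 1, row.end  # half-open -> 1-based inclusive
        context = "distal_intergenic"
        for name, _ in tracks:
            ivals = by_chrom[name].get(row.chrom)
            if ivals is not None and bool(
                np.any((ivals[0] <= p_hi) & (ivals[1] >= p_lo))
            ):
                context = name
                break
        out.append(context)
    return pd.Series(out, index=peaks.df.index, name="context")


def peak_set_overlap(sets: dict[str, PeakSet]) -> pd.DataFrame:
    """Membership pattern of every peak across cell types.

    Two peaks from different sets are shared iff they overlap by >= 1 bp.
    Returns one row per peak with boolean membership columns (one per set
    name) and the peak's own set under ``source``; pattern counts follow
    from ``groupby`` over the membership columns.
    """
    if len(sets) < 2:
        raise ParameterError("need at least two peak sets")
    names = list(sets)
    merged = {
        n: {
            c: (grp["start"].to_numpy(), grp["end"].to_numpy())
            for c, grp in merge_peaks(s.df).groupby("chrom", sort=False)
        }
        for n, s in sets.items()
    }
    rows = []
    for name, s in sets.items():
        for row in s.df.itertuples(index=False):
            member = {}
            for other in names:
                if other == name:
                    member[other] = True
                    continue
                ivals = merged[other].get(row.chrom)
                member[other] = ivals is not None and bool(
                    np.any((ivals[0] < row.end) & (ivals[1] > row.start))
                )
            rows.append(
                {"source": name, "chrom": row.chrom, "start": row.start,
                 "end": row.end, **member}
            )
    return pd.DataFrame(rows)


def overlap_pattern_counts(overlap: pd.DataFrame, names: list[str]) -> pd.Series:
    """Counts of peaks per membership pattern (tuple of booleans over
    ``names``)."""
    return overlap.groupby(names).size()


def map_snps_to_peaks(
    credible: list[CredibleSet],
    peaks_by_type: dict[str, PeakSet],
    panel: LDPanel,
    contexts: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Intersect credible-set SNPs with each cell type's peaks.

    One row per contained SNP, carrying the list of cell types whose peaks
    contain it, the containing peak coordinates (per type), and the context
    (from ``contexts``, keyed like ``peaks_by_type``, if given).  Unknown
    SNP ids are skipped with a logged count.
    """
    pos_map = dict(zip(panel.snps["snp_id"], zip(panel.snps["chrom"], panel.snps["pos"])))
    rows = []
    skipped = 0
    for cs in credible:
        for snp, post in zip(cs.snp_ids, cs.posterior):
            loc = pos_map.get(snp)
            if loc is None:
                skipped += 1
                continue
            chrom, pos = loc
            hits, hit_peaks, hit_ctx = [], [], []
            for ct, ps in peaks_by_type.items():
                d = ps.df
                sub = d[d["chrom"] == chrom]
                inside = (sub["start"] < pos) & (pos <= sub["end"])
                if inside.any():
                    i = inside.idxmax()
                    hits.append(ct)
                    hit_peaks.append(f"{chrom}:{d.loc[i,'start']}-{d.loc[i,'end']}")
                    if contexts is not None and ct in contexts:
                        hit_ctx.append(str(contexts[ct].loc[i]))
            if hits:
                rows.append(
                    {
                        "snp_id": snp,
                        "locus_id": cs.locus_id,
                        "posterior": float(post),
                        "chrom": chrom,
                        "pos": int(pos),
                        "cell_types": ",".join(hits),
                        "peaks": ";".join(hit_peaks),
                        "context": ",".join(sorted(set(hit_ctx))) if hit_ctx else "",
                    }
                )
    if skipped:
        log.warning("skipped %d credible-set SNPs absent from the panel", skipped)
    return pd.DataFrame(
        rows,
        columns=["snp_id", "locus_id", "posterior", "chrom", "pos",
                 "cell_types", "peaks", "context"],
    )


def peak_count_matrix(coverage: AtacCoverage, peaks: pd.DataFrame) -> pd.DataFrame:
    """Pseudo-cell x peak fragment counts (bins summed within each peak)."""
    cols = {}
    for i, row in peaks.iterrows():
        sel = (
            (coverage.bin_chrom == row["chrom"])
            & (coverage.bin_start >= row["start"])
            & (coverage.bin_start < row["end"])
        )
        cols[i] = coverage.counts[:, sel].sum(axis=1)
    return pd.DataFrame(cols, index=coverage.pseudo_cell_ids)


def coaccessibility(
    peak_counts: pd.DataFrame,
    peaks: pd.DataFrame,
    contexts: pd.Series,
    max_dist: int = 100_000,
    fdr: float = 0.05,
    norm_total: float = 1e4,
) -> pd.DataFrame:
    """Distal-peak to promoter-peak co-accessibility within ``max_dist``.

    Counts are normalized per pseudo-cell to ``norm_total`` and
    log1p-transformed; every (distal_intergenic, promoter) peak pair whose
    midpoint distance is <= ``max_dist`` on the same chromosome gets a
    Pearson correlation with a two-sided p-value, BH-corrected across all
    tested pairs.  Returns the q < ``fdr`` pairs (columns: peak_a distal,
    peak_b promoter, distance_bp, correlation, pvalue, qvalue).
    """
    if len(peak_counts) < 3:
        raise ParameterError("need at least 3 pseudo-cells")
    x = peak_counts.to_numpy(dtype=float)
    tot = x.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    x = np.log1p(x / tot * norm_total)
    mid = (peaks["start"].to_numpy() + peaks["end"].to_numpy()) / 2.0
    distal = [i for i in peaks.index if contexts.loc[i] == "distal_intergenic"]
    promoter = [i for i in peaks.index if contexts.loc[i] == "promoter"]
    loc = {p: k for k, p in enumerate(peak_counts.columns)}
    pairs = []
    n_zero_var = 0
    for a in distal:
        for b in promoter:
            if peaks.loc[a, "chrom"] != peaks.loc[b, "chrom"]:
                continue
            d = abs(mid[peaks.index.get_loc(a)] - mid[peaks.index.get_loc(b)])
            if d > max_dist:
                continue
            xa, xb = x[:, loc[a]], x[:, loc[b]]
            if xa.std() == 0 or xb.std() == 0:
                n_zero_var += 1
                continue
            r, p = stats.pearsonr(xa, xb)
            pairs.append({"peak_a": a, "peak_b": b, "distance_bp": float(d),
                          "correlation": float(r), "pvalue": float(p)})
    if n_zero_var:
        warnings.warn(f"skipped {n_zero_var} pairs with a zero-variance peak",
                      stacklevel=2)
    if not pairs:
        return pd.DataFrame(
            columns=["peak_a", "peak_b", "distance_bp", "correlation",
                     "pvalue", "qvalue"]
        )
    tab = pd.DataFrame(pairs)
    _, q, *_ = multipletests(tab["pvalue"], alpha=fdr, method="fdr_bh")
    tab["qvalue"] = q
    return tab[tab["qvalue"] < fdr].reset_index(drop=True)
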