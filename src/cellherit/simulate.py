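"""Synthetic-data generators with known ground truth.

Every generator is a pure function of its parameters and an integer seed, so
each downstream stage (specificity scoring, gene-set tests, partitioned
heritability, peak calling, co-accessibility, trajectory tests) can be
validated against planted truth at desk scale.

The GWAS generator draws marginal z-scores directly from the model the
heritability regression assumes: within each LD block with correlation R,
``z ~ MVN(sqrt(N) R beta, R)`` with per-SNP causal effects of variance
h2/|causal set| inside the causal annotation and zero outside.  R is the
model's population correlation when the panel carries it (the haplotype
sample is then a noisy LD reference, as in real analyses) and the empirical
haplotype correlation otherwise.  This is exact for the fitted model and
avoids individual-level phenotype simulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AtacCoverage,
    CellTypeCounts,
    CredibleSet,
    GenomeModel,
    LDPanel,
    ParameterError,
    SummaryStats,
)

__all__ = [
    "simulate_genome",
    "simulate_ld_panel",
    "simulate_gwas",
    "enrichment_weights",
    "simulate_expression",
    "simulate_atac",
    "simulate_credible_sets",
    "simulate_trajectory_expression",
]


def simulate_genome(
    n_chrom: int = 2,
    genes_per_chrom: int = 50,
    chrom_length: int = 10_000_000,
    gene_length_range: tuple[int, int] = (5_000, 20_000),
    exclusion_region: tuple | None = None,
    seed: int = 0,
) -> GenomeModel:
    """Place genes uniformly on equal-length chromosomes.

    Genes may overlap (as real genes do); they are sorted by position and get
    unique ids ``g<chrom>_<k>``.  Coordinates are 1-based inclusive.
    """
    if n_chrom < 1 or genes_per_chrom < 1:
        raise ParameterError("n_chrom and genes_per_chrom must be >= 1")
    lo, hi = gene_length_range
    if not (0 < lo <= hi < chrom_length):
        raise ParameterError("gene_length_range must satisfy 0 < lo <= hi < length")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    rows = []
    for ci, chrom in enumerate(chroms):
        lengths = rng.integers(lo, hi + 1, size=genes_per_chrom)
        starts = rng.integers(1, chrom_length - hi, size=genes_per_chrom)
        strands = rng.choice(["+", "-"], size=genes_per_chrom)
        order = np.argsort(starts, kind="stable")
        for k, j in enumerate(order):
            rows.append(
                {
                    "gene_id": f"g{ci + 1}_{k}",
                    "chrom": chrom,
                    "start": int(starts[j]),
                    "end": int(starts[j] + lengths[j] - 1),
                    "strand": strands[j],
                }
            )
    return GenomeModel(
        chromosomes=pd.DataFrame({"chrom": chroms, "length": chrom_length}),
        genes=pd.DataFrame(rows),
        exclusion_region=exclusion_region,
    )


def simulate_ld_panel(
    genome: GenomeModel,
    m_snps: int = 2_000,
    n_hap: int = 200,
    block_len: int = 100_000,
    rho: float | tuple[float, float] = (0.4, 0.98),
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> LDPanel:
    """Latent-Gaussian AR(1) haplotypes in independent fixed-length blocks.

    Within a block, adjacent latent Gaussians follow a first-order
    autoregression with parameter ``rho``; each latent is thresholded at its
    SNP's MAF quantile, so the expected allele frequency equals the drawn
    MAF.  Blocks are mutually independent, giving expected cross-block
    ``r^2`` of about ``1/n_hap`` (finite-sample noise only).

    ``rho`` may be a scalar (homogeneous LD) or a ``(lo, hi)`` range from
    which each block draws its own autoregression parameter — real genomes
    mix weak- and strong-LD regions, and heterogeneous LD is what gives LD
    scores the spread the heritability regression leans on.

    The panel also records the model's *population* block correlation
    matrices (via bivariate-normal orthant probabilities); downstream GWAS
    simulation treats those as the generative truth, so the haplotype sample
    plays its real-world role of a noisy LD reference.
    """
    rho_range = (rho, rho) if np.isscalar(rho) else tuple(rho)
    if not (0 <= rho_range[0] <= rho_range[1] < 1):
        raise ParameterError("rho must lie in [0, 1)")
    if not (0 < maf_range[0] <= maf_range[1] <= 0.5):
        raise ParameterError("maf_range must lie within (0, 0.5]")
    if m_snps < 1 or n_hap < 2:
        raise ParameterError("m_snps >= 1 and n_hap >= 2 required")
    rng = np.random.default_rng(seed)
    lengths = genome.chrom_lengths
    total = sum(lengths.values())
    # allocate SNPs to chromosomes proportional to length (largest remainder)
    alloc = {c: int(m_snps * L / total) for c, L in lengths.items()}
    short = m_snps - sum(alloc.values())
    for c in list(lengths)[:short]:
        alloc[c] += 1

    snp_rows, hap_cols, blocks, pop_rs = [], [], [], []
    idx = 0
    for chrom, L in lengths.items():
        m_c = alloc[chrom]
        if m_c == 0:
            continue
        pos = np.sort(rng.choice(np.arange(1, L + 1), size=m_c, replace=False))
        maf = rng.uniform(maf_range[0], maf_range[1], size=m_c)
        block_id = pos // block_len
        for b in np.unique(block_id):
            sel = np.flatnonzero(block_id == b)
            mb = len(sel)
            rho_b = rng.uniform(*rho_range)
            x = np.empty((n_hap, mb))
            x[:, 0] = rng.standard_normal(n_hap)
            if mb > 1:
                eps = rng.standard_normal((n_hap, mb - 1))
                for t in range(1, mb):
                    x[:, t] = rho_b * x[:, t - 1] + np.sqrt(1 - rho_b**2) * eps[:, t - 1]
            thr = stats.norm.ppf(maf[sel])
            h = (x < thr).astype(np.uint8)
            # avoid monomorphic SNPs: flip one haplotype at fixed columns
            freq = h.mean(axis=0)
            for j in np.flatnonzero((freq == 0) | (freq == 1)):
                h[0, j] = 1 - h[0, j]
            hap_cols.append(h)
            blocks.append((idx, idx + mb))
            pop_rs.append(_population_block_r(maf[sel], rho_b))
            idx += mb
        for j in range(m_c):
            snp_rows.append(
                {
                    "snp_id": f"rs_{chrom}_{j}",
                    "chrom": chrom,
                    "pos": int(pos[j]),
                    "a1": "A",
                    "a2": "G",
                    "maf": float(maf[j]),
                }
            )
    haplotypes = np.concatenate(hap_cols, axis=1)
    return LDPanel(
        snps=pd.DataFrame(snp_rows),
        haplotypes=haplotypes,
        blocks=blocks,
        pop_block_r=pop_rs,
    )


def _bvn_cdf(h: np.ndarray, k: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """P(X < h, Y < k) for standard bivariate normals, via Owen's T.

    Assumes h, k < 0 (always true here: thresholds are MAF quantiles with
    MAF <= 0.5, nudged off zero).
    """
    from scipy.special import owens_t

    denom = np.sqrt(np.clip(1.0 - rho**2, 1e-300, None))
    ah = (k / h - rho) / denom
    ak = (h / k - rho) / denom
    out = (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - owens_t(h, ah)
        - owens_t(k, ak)
    )
    near_one = rho > 1 - 1e-12
    if np.any(near_one):
        out = np.where(near_one, stats.norm.cdf(np.minimum(h, k)), out)
    return np.clip(out, 0.0, None)


def _population_block_r(maf: np.ndarray, rho: float) -> np.ndarray:
    """Population correlation of thresholded AR(1) latent Gaussians.

    Latent correlation between SNPs i, j in a block is rho^|i-j|; the binary
    allele indicators' correlation follows from the bivariate-normal orthant
    probability at the MAF thresholds.
    """
    mb = len(maf)
    t = stats.norm.ppf(np.minimum(maf, 0.5 - 1e-9))
    r = np.eye(mb)
    if mb == 1:
        return r
    iu, ju = np.triu_indices(mb, 1)
    lat = rho ** np.abs(iu - ju).astype(float)
    p11 = _bvn_cdf(t[iu], t[ju], lat)
    sd = np.sqrt(maf * (1 - maf))
    rr = (p11 - maf[iu] * maf[ju]) / (sd[iu] * sd[ju])
    rr = np.clip(rr, -1.0, 1.0)
    r[iu, ju] = rr
    r[ju, iu] = rr
    return r


def _block_correlation(panel: LDPanel, lo: int, hi: int) -> np.ndarray:
    """Empirical haplotype correlation of one block, unit diagonal."""
    h = panel.haplotypes[:, lo:hi].astype(float)
    sd = h.std(axis=0)
    sd[sd == 0] = 1.0
    z = (h - h.mean(axis=0)) / sd
    r = (z.T @ z) / h.shape[0]
    np.fill_diagonal(r, 1.0)
    return r


def _psd_sqrt(r: np.ndarray) -> np.ndarray:
    """Symmetric square root with negative eigenvalues clipped to zero."""
    w, v = np.linalg.eigh(r)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def enrichment_weights(
    annotation: np.ndarray, enrichment: float
) -> np.ndarray:
    """Per-SNP effect-variance weights planting a target heritability
    enrichment in a binary annotation of SNP fraction f.

    The enrichment statistic is (proportion of h2 in the annotation) /
    (proportion of SNPs), so the required inside:outside variance ratio is
    ``rho = E (1 - f) / (1 - E f)``, valid for ``E f < 1``.
    """
    a = np.asarray(annotation, dtype=bool)
    f = a.mean()
    if enrichment * f >= 1:
        raise ParameterError(
            "target enrichment infeasible: annotation holds >= all heritability"
        )
    rho = enrichment * (1 - f) / (1 - enrichment * f)
    return np.where(a, rho, 1.0)


def simulate_gwas(
    panel: LDPanel,
    causal_annotation: np.ndarray | None,
    h2: float,
    N: int,
    seed: int = 0,
    causal_weights: np.ndarray | None = None,
    rescale_effects: bool = True,
) -> SummaryStats:
    """Draw GWAS marginal z-scores under blockwise LD.

    Parameters
    ----------
    causal_annotation : bool array over panel SNPs or None
        SNPs allowed to be causal; None means all SNPs.
    h2 : float
        Total (standardized-scale) SNP heritability, split across the causal
        set: equally in variance, or proportionally to ``causal_weights``
        when given (e.g. from :func:`enrichment_weights`).
    rescale_effects : bool
        Rescale the drawn effect vector so the realized total marginal
        signal matches its expectation exactly (the usual variance-reduction
        step in heritability simulators); the per-SNP pattern stays random.
    """
    if not 0 <= h2 < 1:
        raise ParameterError("h2 must lie in [0, 1)")
    if N <= 0:
        raise ParameterError("N must be positive")
    m = panel.m
    if causal_annotation is None:
        causal = np.ones(m, dtype=bool)
    else:
        causal = np.asarray(causal_annotation, dtype=bool)
        if causal.shape != (m,):
            raise ParameterError("causal annotation must have one flag per SNP")
    n_causal = int(causal.sum())
    if h2 > 0 and n_causal == 0:
        raise ParameterError("empty causal set with h2 > 0")
    rng = np.random.default_rng(seed)
    var = np.where(causal, 1.0, 0.0)
    if causal_weights is not None:
        w = np.asarray(causal_weights, dtype=float)
        if w.shape != (m,) or np.any(w < 0):
            raise ParameterError("causal_weights must be non-negative, one per SNP")
        var = var * w
    total = var.sum()
    beta = np.zeros(m)
    if h2 > 0:
        if total == 0:
            raise ParameterError("causal variance weights sum to zero")
        var = h2 * var / total
        beta = rng.normal(0.0, 1.0, size=m) * np.sqrt(var)

    # population LD is the generative truth when the panel carries it; the
    # haplotype sample is then a noisy LD reference, as in real analyses
    def block_r(bi: int, lo: int, hi: int) -> np.ndarray:
        if panel.pop_block_r is not None:
            return panel.pop_block_r[bi]
        return _block_correlation(panel, lo, hi)

    marginal = [
        block_r(bi, lo, hi) @ beta[lo:hi]
        for bi, (lo, hi) in enumerate(panel.blocks)
    ]
    if h2 > 0 and rescale_effects:
        realized = sum(float(mb @ mb) for mb in marginal)
        expected = sum(
            float((block_r(bi, lo, hi) ** 2 @ var[lo:hi]).sum())
            for bi, (lo, hi) in enumerate(panel.blocks)
        )
        if realized > 0:
            scale = np.sqrt(expected / realized)
            marginal = [mb * scale for mb in marginal]
    z = np.empty(m)
    for bi, (lo, hi) in enumerate(panel.blocks):
        half = _psd_sqrt(block_r(bi, lo, hi))
        z[lo:hi] = np.sqrt(N) * marginal[bi] + half @ rng.standard_normal(hi - lo)
    return SummaryStats(
        snp_id=panel.snps["snp_id"].to_numpy(),
        z=z,
        n=np.full(m, N, dtype=float),
        a1=panel.snps["a1"].to_numpy(),
        a2=panel.snps["a2"].to_numpy(),
    )


def simulate_expression(
    genome: GenomeModel,
    k_types: int = 6,
    cells_per_type: int | tuple = 60,
    marker_fraction: float = 0.05,
    fold_change: float = 8.0,
    dispersion: float = 2.0,
    libsize_cv: float = 0.3,
    mean_umi: int = 2_000,
    n_subtypes: int = 2,
    seed: int = 0,
) -> CellTypeCounts:
    """Cell-type-structured negative-binomial UMI counts with planted markers.

    Each type receives a disjoint marker set whose mean expression is
    ``fold_change`` times the background; counts are gamma-Poisson with NB
    size ``dispersion`` and per-cell gamma library-size multipliers of mean 1
    and coefficient of variation ``libsize_cv``.  Level-2 labels split each
    type into ``n_subtypes`` subtypes (cells split evenly; no extra markers).
    """
    if k_types < 2:
        raise ParameterError("k_types must be >= 2")
    if fold_change < 1:
        raise ParameterError("fold_change must be >= 1")
    genes = list(genome.genes["gene_id"])
    n_genes = len(genes)
    n_marked = int(round(marker_fraction * n_genes))
    if n_marked < 1:
        raise ParameterError("marker_fraction * n_genes must be >= 1")
    if n_marked * k_types > n_genes:
        raise ParameterError("marker sets would exceed the gene count")
    if np.isscalar(cells_per_type):
        cells = np.full(k_types, int(cells_per_type))
    else:
        cells = np.asarray(cells_per_type, dtype=int)
        if len(cells) != k_types:
            raise ParameterError("cells_per_type length must equal k_types")
    if np.any(cells <= 0):
        raise ParameterError("every cell type needs at least one cell")

    rng = np.random.default_rng(seed)
    types = [f"T{t + 1}" for t in range(k_types)]
    marker_idx = rng.choice(n_genes, size=n_marked * k_types, replace=False)
    markers = {
        types[t]: sorted(genes[i] for i in marker_idx[t * n_marked : (t + 1) * n_marked])
        for t in range(k_types)
    }
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    mu = np.tile(base[:, None], (1, k_types))
    for t in range(k_types):
        mu[marker_idx[t * n_marked : (t + 1) * n_marked], t] *= fold_change
    mu *= mean_umi / mu.sum(axis=0, keepdims=True)

    n_cells = int(cells.sum())
    level1 = np.repeat(types, cells)
    if libsize_cv > 0:
        shape = 1.0 / libsize_cv**2
        lib = rng.gamma(shape, 1.0 / shape, size=n_cells)
    else:
        lib = np.ones(n_cells)
    counts = np.empty((n_genes, n_cells), dtype=np.int64)
    col = 0
    for t in range(k_types):
        for _ in range(cells[t]):
            rate = mu[:, t] * lib[col]
            lam = rng.gamma(dispersion, rate / dispersion)
            counts[:, col] = rng.poisson(lam)
            col += 1
    # deterministic subtype split within each type
    level2 = np.empty(n_cells, dtype=object)
    col = 0
    for t in range(k_types):
        for j in range(cells[t]):
            level2[col] = f"{types[t]}-{j * n_subtypes // cells[t] + 1}"
            col += 1
    return CellTypeCounts(
        counts=counts,
        gene_ids=genes,
        cell_ids=[f"cell{i}" for i in range(n_cells)],
        level1=level1.astype(object),
        level2=level2,
        batch=np.array([f"b{i % 2 + 1}" for i in range(n_cells)], dtype=object),
        markers=markers,
    )


def _place_truth_peaks(
    rng: np.random.Generator,
    genome: GenomeModel,
    k_types: int,
    peaks_per_type: int,
    shared_fraction: float,
    peak_width: int,
    bin_size: int,
) -> pd.DataFrame:
    """Non-overlapping, bin-aligned truth peaks; a shared tranche plus
    per-type unique tranches."""
    n_shared = int(round(shared_fraction * peaks_per_type))
    n_unique = peaks_per_type - n_shared
    total = n_shared + n_unique * k_types
    lengths = genome.chrom_lengths
    chroms = list(lengths)
    width_bins = max(1, peak_width // bin_size)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    labels = ["shared"] * n_shared + [
        f"T{t + 1}" for t in range(k_types) for _ in range(n_unique)
    ]
    attempts = 0
    for lab in labels:
        while True:
            attempts += 1
            if attempts > 100 * total:
                raise ParameterError("could not place non-overlapping truth peaks")
            chrom = chroms[rng.integers(len(chroms))]
            n_bins = lengths[chrom] // bin_size
            if n_bins <= width_bins:
                raise ParameterError("peak width must be below chromosome length")
            b0 = int(rng.integers(0, n_bins - width_bins))
            start, end = b0 * bin_size, (b0 + width_bins) * bin_size
            if all(end <= s or start >= e for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                rows.append(
                    {"chrom": chrom, "start": start, "end": end, "cell_type": lab}
                )
                break
    return pd.DataFrame(rows)


def simulate_atac(
    genome: GenomeModel,
    k_types: int = 4,
    peaks_per_type: int = 40,
    shared_fraction: float = 0.25,
    fold: float = 10.0,
    background_rate: float = 2.0,
    pseudo_cells_per_type: int = 20,
    bin_size: int = 200,
    peak_width: int = 1_000,
    n_coaccess_pairs: int = 0,
    coaccess_cv: float = 0.8,
    seed: int = 0,
) -> AtacCoverage:
    """Poisson binned coverage with planted cell-type-specific peaks.

    Bin counts are Poisson with rate ``background_rate`` outside peaks and
    ``fold * background_rate`` inside peaks active in the pseudo-cell's type
    (its own unique peaks plus the shared tranche).  Optionally,
    ``n_coaccess_pairs`` (distal peak, promoter peak) pairs are planted near
    gene TSSs with a shared per-pseudo-cell gamma latent activity of mean 1
    and CV ``coaccess_cv`` multiplying both peaks' rates, creating planted
    co-accessibility.
    """
    if not 0 <= shared_fraction <= 1:
        raise ParameterError("shared_fraction must lie in [0, 1]")
    if fold <= 1:
        raise ParameterError("fold must exceed 1")
    if background_rate <= 0 or pseudo_cells_per_type < 1:
        raise ParameterError("background_rate > 0 and pseudo cells >= 1 required")
    rng = np.random.default_rng(seed)
    truth = _place_truth_peaks(
        rng, genome, k_types, peaks_per_type, shared_fraction, peak_width, bin_size
    )

    pairs: list[tuple[int, int]] = []
    if n_coaccess_pairs > 0:
        width_bins = max(1, peak_width // bin_size)
        lengths = genome.chrom_lengths
        tss = genome.tss()
        gene_order = rng.permutation(len(tss))
        extra = []
        occupied = {
            c: list(zip(g["start"], g["end"]))
            for c, g in truth.groupby("chrom", sort=False)
        }
        for gi in gene_order:
            if len(pairs) >= n_coaccess_pairs:
                break
            gene = genome.genes.iloc[gi]
            chrom = gene["chrom"]
            n_bins = lengths[chrom] // bin_size
            prom_b0 = max(0, min(int(tss.iloc[gi]) // bin_size, n_bins - width_bins))
            prom = (prom_b0 * bin_size, (prom_b0 + width_bins) * bin_size)
            offset = int(rng.integers(20_000, 80_000))
            dist_b0 = prom_b0 + offset // bin_size
            if dist_b0 + width_bins > n_bins:
                dist_b0 = prom_b0 - offset // bin_size
            if dist_b0 < 0:
                continue
            dist = (dist_b0 * bin_size, (dist_b0 + width_bins) * bin_size)
            occ = occupied.setdefault(chrom, [])
            if any(
                not (iv[1] <= s or iv[0] >= e)
                for iv in (prom, dist)
                for s, e in occ
            ):
                continue
            occ.extend([prom, dist])
            i0 = len(truth) + len(extra)
            extra.append(
                {"chrom": chrom, "start": dist[0], "end": dist[1], "cell_type": "shared"}
            )
            extra.append(
                {"chrom": chrom, "start": prom[0], "end": prom[1], "cell_type": "shared"}
            )
            pairs.append((i0, i0 + 1))
        if len(pairs) < n_coaccess_pairs:
            raise ParameterError("could not place the requested co-accessible pairs")
        truth = pd.concat([truth, pd.DataFrame(extra)], ignore_index=True)

    lengths = genome.chrom_lengths
    bin_chrom = np.concatenate(
        [np.repeat(c, L // bin_size) for c, L in lengths.items()]
    )
    bin_start = np.concatenate(
        [np.arange(L // bin_size) * bin_size for L in lengths.values()]
    ).astype(np.int64)
    n_bins = len(bin_chrom)
    chrom_offset = {}
    off = 0
    for c, L in lengths.items():
        chrom_offset[c] = off
        off += L // bin_size

    def peak_bins(row) -> np.ndarray:
        o = chrom_offset[row["chrom"]]
        return np.arange(o + row["start"] // bin_size, o + row["end"] // bin_size)

    types = [f"T{t + 1}" for t in range(k_types)]
    n_pc = k_types * pseudo_cells_per_type
    pc_type = np.repeat(types, pseudo_cells_per_type).astype(object)
    counts = rng.poisson(background_rate, size=(n_pc, n_bins))
    latent_shape = 1.0 / coaccess_cv**2 if coaccess_cv > 0 else None
    pair_peaks = {i for ab in pairs for i in ab}
    for pi, row in truth.iterrows():
        bins = peak_bins(row)
        if pi in pair_peaks:
            continue  # filled with latent activity below
        if row["cell_type"] == "shared":
            active = np.ones(n_pc, dtype=bool)
        else:
            active = pc_type == row["cell_type"]
        counts[np.ix_(active, bins)] = rng.poisson(
            fold * background_rate, size=(int(active.sum()), len(bins))
        )
    for a, b in pairs:
        act = (
            rng.gamma(latent_shape, 1.0 / latent_shape, size=n_pc)
            if latent_shape
            else np.ones(n_pc)
        )
        for pi in (a, b):
            bins = peak_bins(truth.iloc[pi])
            rate = fold * background_rate * act[:, None]
            counts[:, bins] = rng.poisson(np.broadcast_to(rate, (n_pc, len(bins))))
    return AtacCoverage(
        counts=counts.astype(np.int64),
        bin_size=bin_size,
        bin_chrom=bin_chrom,
        bin_start=bin_start,
        pseudo_cell_ids=[f"pc{i}" for i in range(n_pc)],
        pseudo_cell_type=pc_type,
        truth_peaks=truth,
        truth_pairs=pairs,
    )


def simulate_credible_sets(
    panel: LDPanel,
    n_loci: int = 10,
    set_size_dist: int | tuple[int, int] = (1, 10),
    peak_bias: float = 0.0,
    truth_peaks: pd.DataFrame | None = None,
    seed: int = 0,
) -> list[CredibleSet]:
    """Fine-mapping credible sets of nearby SNPs with Dirichlet posteriors.

    A fraction ``peak_bias`` of loci place their lead SNP inside a truth
    peak (requires ``truth_peaks``); symmetric Dirichlet(1) posteriors are
    assigned with the largest component on the lead SNP, so each set's mass
    sums to 1 (>= 0.95 by construction).
    """
    if n_loci < 1:
        raise ParameterError("n_loci must be >= 1")
    if n_loci > panel.m:
        raise ParameterError("n_loci exceeds available SNPs")
    if not 0 <= peak_bias <= 1:
        raise ParameterError("peak_bias must lie in [0, 1]")
    if peak_bias > 0 and (truth_peaks is None or len(truth_peaks) == 0):
        raise ParameterError("peak_bias > 0 requires truth peaks")
    rng = np.random.default_rng(seed)
    snps = panel.snps
    in_peak = np.zeros(panel.m, dtype=bool)
    if truth_peaks is not None and len(truth_peaks):
        for chrom, grp in truth_peaks.groupby("chrom", sort=False):
            sel = snps["chrom"] == chrom
            pos = snps.loc[sel, "pos"].to_numpy()
            hit = np.zeros(len(pos), dtype=bool)
            for s, e in zip(grp["start"], grp["end"]):
                hit |= (pos > s) & (pos <= e)  # 1-based SNP in half-open peak
            in_peak[np.flatnonzero(sel.to_numpy())[hit]] = True
    n_biased = int(round(peak_bias * n_loci))
    peak_snps = np.flatnonzero(in_peak)
    if n_biased > 0 and len(peak_snps) == 0:
        raise ParameterError("no panel SNP lies inside a truth peak")
    leads: list[int] = []
    if n_biased:
        leads += list(
            rng.choice(peak_snps, size=n_biased, replace=n_biased > len(peak_snps))
        )
    free = np.setdiff1d(np.arange(panel.m), np.array(leads, dtype=int))
    leads += list(rng.choice(free, size=n_loci - n_biased, replace=False))

    sets = []
    order_by_dist: dict[str, np.ndarray] = {}
    for li, lead in enumerate(leads):
        if np.isscalar(set_size_dist):
            size = int(set_size_dist)
        else:
            size = int(rng.integers(set_size_dist[0], set_size_dist[1] + 1))
        chrom = snps.iloc[lead]["chrom"]
        if chrom not in order_by_dist:
            order_by_dist[chrom] = np.flatnonzero((snps["chrom"] == chrom).to_numpy())
        same = order_by_dist[chrom]
        dist = np.abs(snps.iloc[same]["pos"].to_numpy() - snps.iloc[lead]["pos"])
        members = same[np.argsort(dist, kind="stable")[: min(size, len(same))]]
        members = np.concatenate([[lead], members[members != lead]])
        post = np.sort(rng.dirichlet(np.ones(len(members))))[::-1]
        sets.append(
            CredibleSet(
                locus_id=f"locus{li}",
                snp_ids=[snps.iloc[i]["snp_id"] for i in members],
                posterior=post,
            )
        )
    return sets


def simulate_trajectory_expression(
    n_cells: int = 300,
    n_genes: int = 100,
    n_gradient_genes: int = 20,
    effect: float = 2.0,
    noise_sd: float = 1.0,
    embedding_dim: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cells along a 1-D latent trajectory embedded in ``embedding_dim`` dims.

    Returns ``(embedding, expression, is_gradient)``: expression is genes x
    cells log-scale values; the first ``n_gradient_genes`` genes vary
    smoothly (linearly, amplitude ``effect``) along the latent pseudotime,
    the rest are pure noise.
    """
    if n_gradient_genes > n_genes:
        raise ParameterError("n_gradient_genes cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, 1, size=n_cells))
    emb = np.zeros((n_cells, embedding_dim))
    emb[:, 0] = t
    if embedding_dim > 1:
        emb[:, 1:] = rng.normal(0, 0.05, size=(n_cells, embedding_dim - 1))
    expr = rng.normal(0, noise_sd, size=(n_genes, n_cells))
    grad = np.zeros(n_genes, dtype=bool)
    grad[:n_gradient_genes] = True
    expr[:n_gradient_genes] += effect * (t - t.mean())
    return emb, expr, grad
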