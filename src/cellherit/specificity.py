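"""Expression-specificity scoring of labeled single-cell counts.

The specificity of gene g for cell type c is its mean (library-normalized)
expression in c divided by the sum of its mean expression across all types,
so each gene's scores sum to 1.  Genes in the top specificity decile per
type form the gene sets that feed the competitive gene-set and partitioned
heritability tests.  Counts are normalized per cell to a fixed total
(counts-per-10k) before averaging, making the score invariant to per-cell
sequencing depth.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import (
    CellTypeCounts,
    GeneSet,
    GenomeModel,
    InputError,
    ParameterError,
    SpecificityMatrix,
)

__all__ = [
    "filter_genes",
    "remove_region",
    "specificity_scores",
    "decile_assign",
    "top_set",
    "downsample_cells",
    "SpecificityScorer",
]

CP10K = 1e4


def filter_genes(
    counts: CellTypeCounts, min_cells: int = 10, min_total: int = 50
) -> list[str]:
    """Drop uninformative (low and/or sporadically expressed) genes.

    A gene is retained iff it is expressed (count >= 1) in at least
    ``min_cells`` cells and its total count is at least ``min_total``.
    Gene order is preserved.
    """
    if min_cells < 0 or min_total < 0:
        raise ParameterError("thresholds must be non-negative")
    if counts.counts.size == 0:
        raise InputError("empty count matrix")
    expressed = (counts.counts >= 1).sum(axis=1)
    total = counts.counts.sum(axis=1)
    keep = (expressed >= min_cells) & (total >= min_total)
    return [g for g, k in zip(counts.gene_ids, keep) if k]


def remove_region(
    genes: list[str], genome: GenomeModel, region: tuple[str, int, int]
) -> list[str]:
    """Remove genes whose transcribed region overlaps a 1-based inclusive
    interval (e.g. the MHC, hg38 chr6:28,510,120-33,480,577)."""
    chrom, start, end = region
    if chrom not in set(genome.chromosomes["chrom"]):
        raise InputError(f"unknown chromosome {chrom!r}")
    tab = genome.genes.set_index("gene_id")
    out = []
    for g in genes:
        row = tab.loc[g]
        hit = row["chrom"] == chrom and row["start"] <= end and row["end"] >= start
        if not hit:
            out.append(g)
    return out


def specificity_scores(
    counts: CellTypeCounts,
    level: str = "level1",
    genes: list[str] | None = None,
    normalize: bool = True,
) -> SpecificityMatrix:
    """Per-gene, per-cell-type specificity: s(g,c) = mu(g,c) / sum_c' mu(g,c').

    ``normalize`` applies per-cell counts-per-10k before the per-type mean
    (the default; raw means are kept as a configurable alternative).  Genes
    with zero mean in every type are dropped with a warning.
    """
    labels = counts.labels(level)
    types = sorted(set(labels))
    if len(types) < 2:
        raise ParameterError("at least two cell types required")
    x = counts.counts.astype(float)
    if genes is not None:
        gidx = {g: i for i, g in enumerate(counts.gene_ids)}
        rows = [gidx[g] for g in genes]
        x = x[rows]
        gene_ids = list(genes)
    else:
        gene_ids = list(counts.gene_ids)
    if normalize:
        tot = x.sum(axis=0, keepdims=True)
        tot[tot == 0] = 1.0
        x = x / tot * CP10K
    mu = np.column_stack([x[:, labels == t].mean(axis=1) for t in types])
    row_sum = mu.sum(axis=1)
    zero = row_sum == 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} genes with zero mean expression",
            stacklevel=2,
        )
        mu, row_sum = mu[~zero], row_sum[~zero]
        gene_ids = [g for g, z in zip(gene_ids, zero) if not z]
    spec = mu / row_sum[:, None]
    mean_df = pd.DataFrame(mu, index=gene_ids, columns=types)
    return SpecificityMatrix(mean_expr=mean_df, specificity=pd.DataFrame(
        spec, index=gene_ids, columns=types))


def decile_assign(spec: SpecificityMatrix, cell_type: str) -> pd.Series:
    """Rank-based decile (1..10, 10 = most specific) per gene for one type.

    Ties are broken by stable gene order (the matrix's row order, which
    follows gene id order in this package); decile sizes differ by <= 1.
    """
    if cell_type not in spec.specificity.columns:
        raise ParameterError(f"unknown cell type {cell_type!r}")
    s = spec.specificity[cell_type].to_numpy()
    n = len(s)
    if n < 10:
        raise ParameterError("decile assignment needs at least 10 genes")
    order = np.argsort(s, kind="stable")  # ascending; stable in row order
    bounds = np.array([round(i * n / 10) for i in range(11)])
    dec = np.empty(n, dtype=int)
    for d in range(10):
        dec[order[bounds[d] : bounds[d + 1]]] = d + 1
    return pd.Series(dec, index=spec.specificity.index, name=cell_type)


def top_set(
    spec: SpecificityMatrix,
    cell_type: str,
    rule: str = "decile",
    n: int | None = None,
) -> GeneSet:
    """Top-specificity gene set for one type.

    ``rule="decile"`` returns decile-10 genes; ``rule="top_n"`` returns the
    ``n`` highest-specificity genes (ties resolved by stable gene order,
    later rows winning as in the decile ranking).
    """
    if rule == "decile":
        dec = decile_assign(spec, cell_type)
        members = tuple(dec.index[dec == 10])
        prov = f"{cell_type}:decile10"
    elif rule == "top_n":
        if n is None or n < 1:
            raise ParameterError("rule='top_n' requires n >= 1")
        if n > len(spec.genes):
            raise ParameterError("n exceeds the number of retained genes")
        s = spec.specificity[cell_type].to_numpy()
        order = np.argsort(s, kind="stable")[::-1][:n]
        members = tuple(spec.specificity.index[np.sort(order)])
        prov = f"{cell_type}:top{n}"
    else:
        raise ParameterError(f"unknown rule {rule!r}")
    return GeneSet(name=f"{cell_type}", genes=members, provenance=prov)


def downsample_cells(
    counts: CellTypeCounts, level: str = "level1", seed: int = 0
) -> CellTypeCounts:
    """Subsample every population, without replacement, to the size of the
    smallest one.  Identity when sizes are already equal."""
    labels = counts.labels(level)
    types, sizes = np.unique(labels, return_counts=True)
    if len(types) < 2:
        raise ParameterError("at least two populations required")
    if sizes.min() == 0:
        raise InputError("a population has no cells")
    target = int(sizes.min())
    if (sizes == target).all():
        return counts
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for t in types:
        idx = np.flatnonzero(labels == t)
        if len(idx) > target:
            idx = np.sort(rng.choice(idx, size=target, replace=False))
        keep.extend(idx.tolist())
    return counts.subset_cells(np.sort(np.array(keep)))


class SpecificityScorer(BaseEstimator):
    """Filter genes and compute expression-specificity scores.

    Parameters
    ----------
    level : {"level1", "level2"}
        Label granularity used for per-type means.
    min_cells, min_total : int
        Uninformative-gene filter: expressed in >= min_cells cells and
        total count >= min_total.
    exclusion_region : tuple or None
        (chrom, start, end), 1-based inclusive; overlapping genes are
        removed (the MHC filter).  Falls back to the genome's own
        ``exclusion_region`` when None.
    normalize : bool
        Counts-per-10k per cell before averaging.

    Attributes
    ----------
    specificity_ : SpecificityMatrix
    genes_ : list of retained gene ids
    """

    def __init__(
        self,
        level: str = "level1",
        min_cells: int = 10,
        min_total: int = 50,
        exclusion_region: tuple | None = None,
        normalize: bool = True,
    ):
        self.level = level
        self.min_cells = min_cells
        self.min_total = min_total
        self.exclusion_region = exclusion_region
        self.normalize = normalize

    def fit(self, counts: CellTypeCounts, genome: GenomeModel | None = None):
        genes = filter_genes(counts, self.min_cells, self.min_total)
        region = self.exclusion_region
        if region is None and genome is not None:
            region = genome.exclusion_region
        if region is not None:
            if genome is None:
                raise ParameterError("exclusion_region requires a genome")
            genes = remove_region(genes, genome, region)
        self.specificity_ = specificity_scores(
            counts, level=self.level, genes=genes, normalize=self.normalize
        )
        self.genes_ = self.specificity_.genes
        return self

    def decile_assign(self, cell_type: str) -> pd.Series:
        return decile_assign(self.specificity_, cell_type)

    def top_set(self, cell_type: str, rule: str = "decile", n=None) -> GeneSet:
        return top_set(self.specificity_, cell_type, rule=rule, n=n)

    def top_sets(self, rule: str = "decile", n=None) -> dict[str, GeneSet]:
        return {
            c: top_set(self.specificity_, c, rule=rule, n=n)
            for c in self.specificity_.cell_types
        }
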