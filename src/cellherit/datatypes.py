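"""Core data containers shared across the package.

Coordinate conventions
----------------------
* Gene bodies and SNP positions are 1-based, inclusive (GTF-like).
* Peak intervals are 0-based, half-open (BED convention): a SNP at 1-based
  position ``p`` lies in peak ``[start, end)`` iff ``start < p <= end``.
* ``upstream`` / ``downstream`` are strand-relative: for a minus-strand gene
  the upstream extension grows the higher coordinate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeModel",
    "LDPanel",
    "SummaryStats",
    "CellTypeCounts",
    "AtacCoverage",
    "CredibleSet",
    "GeneSet",
    "SpecificityMatrix",
    "PeakSet",
    "ParameterError",
    "InputError",
]


class ParameterError(ValueError):
    """A caller-supplied parameter is outside its valid range."""


class InputError(ValueError):
    """An input object violates a structural requirement."""


@dataclass(frozen=True)
class GenomeModel:
    """A small genome: chromosome sizes, gene bodies, optional excluded region.

    Parameters
    ----------
    chromosomes : pd.DataFrame
        Columns ``chrom`` (str) and ``length`` (bp).
    genes : pd.DataFrame
        Columns ``gene_id``, ``chrom``, ``start``, ``end`` (1-based inclusive)
        and ``strand`` in ``{"+", "-"}``; sorted by (chrom, start).
    exclusion_region : tuple or None
        ``(chrom, start, end)``, 1-based inclusive.  Plays the role of the MHC
        region, which is dropped from gene-set and OCR analyses because of its
        extreme LD structure.
    """

    chromosomes: pd.DataFrame
    genes: pd.DataFrame
    exclusion_region: tuple | None = None

    def __post_init__(self) -> None:
        genes = self.genes
        if genes["gene_id"].duplicated().any():
            raise InputError("gene ids must be unique")
        if not set(genes["strand"]).issubset({"+", "-"}):
            raise InputError("strand must be '+' or '-'")
        lengths = self.chromosomes.set_index("chrom")["length"]
        unknown = set(genes["chrom"]) - set(lengths.index)
        if unknown:
            raise InputError(f"genes on unknown chromosomes: {sorted(unknown)}")
        if (genes["start"] < 1).any() or (genes["start"] >= genes["end"]).any():
            raise InputError("gene coordinates must satisfy 1 <= start < end")
        if (genes["end"].to_numpy() > lengths.loc[genes["chrom"]].to_numpy()).any():
            raise InputError("gene end exceeds chromosome length")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(
            zip(self.chromosomes["chrom"], self.chromosomes["length"].astype(int))
        )

    def tss(self) -> pd.Series:
        """1-based transcription start site per gene (strand-aware)."""
        plus = self.genes["strand"].to_numpy() == "+"
        return pd.Series(
            np.where(plus, self.genes["start"], self.genes["end"]),
            index=self.genes["gene_id"],
            name="tss",
        )


@dataclass
class LDPanel:
    """A haplotype reference panel with blockwise LD.

    ``haplotypes`` is an ``n_hap x m_snp`` binary matrix (1 = alternate
    allele a1).  ``blocks`` holds half-open index ranges ``(lo, hi)``;
    haplotypes are independent across blocks by construction.
    """

    snps: pd.DataFrame  # snp_id, chrom, pos, a1, a2, maf
    haplotypes: np.ndarray
    blocks: list[tuple[int, int]]
    # population (generative-truth) correlation matrix per block, when known;
    # panels read from files carry None and fall back to empirical LD
    pop_block_r: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.haplotypes.shape[1] != len(self.snps):
            raise InputError("haplotype column count must match SNP table")
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise InputError(f"positions not strictly increasing on {chrom}")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def m(self) -> int:
        return self.haplotypes.shape[1]

    def frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass
class SummaryStats:
    """GWAS summary statistics aligned to a panel's SNP order."""

    snp_id: np.ndarray
    z: np.ndarray
    n: np.ndarray  # per-SNP sample size
    a1: np.ndarray
    a2: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.n <= 0):
            raise InputError("sample sizes must be positive")

    @property
    def chi2(self) -> np.ndarray:
        return self.z**2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": self.snp_id,
                "A1": self.a1,
                "A2": self.a2,
                "Z": self.z,
                "N": self.n,
                "CHI2": self.chi2,
            }
        )


@dataclass
class CellTypeCounts:
    """Gene x cell UMI count matrix with two label granularities.

    ``markers`` maps level-1 cell type -> planted marker gene ids (ground
    truth carried by the generator; absent for real data).
    """

    counts: np.ndarray  # genes x cells, integer
    gene_ids: list[str]
    cell_ids: list[str]
    level1: np.ndarray  # per-cell label
    level2: np.ndarray
    batch: np.ndarray
    markers: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids) or n_cells != len(self.cell_ids):
            raise InputError("counts shape does not match gene/cell ids")
        for lab in (self.level1, self.level2, self.batch):
            if len(lab) != n_cells:
                raise InputError("one label per cell required")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise InputError("counts must be integer-valued")

    def labels(self, level: str) -> np.ndarray:
        if level == "level1":
            return self.level1
        if level == "level2":
            return self.level2
        raise ParameterError(f"unknown label granularity {level!r}")

    def subset_cells(self, idx: np.ndarray) -> "CellTypeCounts":
        return dataclasses.replace(
            self,
            counts=self.counts[:, idx],
            cell_ids=[self.cell_ids[i] for i in np.asarray(idx)],
            level1=self.level1[idx],
            level2=self.level2[idx],
            batch=self.batch[idx],
        )


@dataclass
class AtacCoverage:
    """Binned ATAC fragment counts per pseudo-cell.

    Bins tile each chromosome without overlap.  ``bin_chrom`` / ``bin_start``
    give each bin's chromosome and 0-based start; bins are ``bin_size`` bp.
    ``truth_peaks`` is the generator's planted-peak table (chrom, start, end,
    cell_type with "shared" for peaks common to all types); empty for real
    data.  ``truth_pairs`` lists planted co-accessible (distal, promoter)
    truth-peak index pairs.
    """

    counts: np.ndarray  # pseudo-cells x bins, integer
    bin_size: int
    bin_chrom: np.ndarray
    bin_start: np.ndarray
    pseudo_cell_ids: list[str]
    pseudo_cell_type: np.ndarray
    truth_peaks: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "cell_type"]
        )
    )
    truth_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.pseudo_cell_ids), len(self.bin_chrom)):
            raise InputError("coverage shape mismatch")
        if np.any(self.counts < 0):
            raise InputError("fragment counts must be non-negative")


@dataclass
class CredibleSet:
    """A fine-mapping 95% credible set at one locus."""

    locus_id: str
    snp_ids: list[str]
    posterior: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.posterior, dtype=float)
        if np.any(p <= 0) or np.any(p > 1):
            raise InputError("posteriors must lie in (0, 1]")
        if p.sum() < 0.95 - 1e-12:
            raise InputError("credible set posterior mass below 0.95")

    @property
    def lead_snp(self) -> str:
        return self.snp_ids[int(np.argmax(self.posterior))]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with provenance (cell type and selection rule)."""

    name: str
    genes: tuple
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise InputError(f"duplicate members in gene set {self.name!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class SpecificityMatrix:
    """Per-gene, per-cell-type mean expression and specificity scores.

    ``specificity.loc[g, c]`` is the mean (normalized) expression of gene g
    in type c divided by its summed mean across all types; rows sum to 1.
    """

    mean_expr: pd.DataFrame  # genes x cell types
    specificity: pd.DataFrame

    @property
    def cell_types(self) -> list[str]:
        return list(self.specificity.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.specificity.index)


@dataclass
class PeakSet:
    """Sorted, merged half-open peak intervals from one cell type.

    ``df`` columns: chrom, start, end (0-based half-open), score
    (-log10 of the best bin p-value) and qvalue (Benjamini-Hochberg).
    """

    df: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        d = self.df
        if len(d) and (d["end"] <= d["start"]).any():
            raise InputError("peak end must exceed start")

    def __len__(self) -> int:
        return len(self.df)
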