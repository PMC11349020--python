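"""Readers and writers for the standard text formats the pipeline consumes
and emits.

Writers and readers round-trip bit-exactly for integer fields.  BED files
are 0-based half-open; the gene-model TSV and SNP TSV are 1-based inclusive
(GTF-like).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datatypes import CredibleSet, CellTypeCounts, GenomeModel, LDPanel, PeakSet, SummaryStats

__all__ = [
    "write_gene_bed", "write_gene_table", "read_gene_table",
    "write_snp_table", "read_snp_table", "read_panel",
    "write_sumstats", "read_sumstats",
    "write_counts_tsv", "read_counts_tsv", "write_counts_mtx", "read_counts_mtx",
    "write_bedgraph", "write_peaks_bed", "read_peaks_bed",
    "write_credible_sets", "read_credible_sets",
    "write_specificity", "write_gene_sets", "read_gene_list",
]


def write_gene_bed(genome: GenomeModel, path: str | Path) -> None:
    """BED6: 0-based half-open gene bodies with strand."""
    g = genome.genes
    bed = pd.DataFrame(
        {
            "chrom": g["chrom"],
            "start": g["start"] - 1,
            "end": g["end"],
            "name": g["gene_id"],
            "score": 0,
            "strand": g["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_gene_table(genome: GenomeModel, path: str | Path) -> None:
    """GTF-like TSV (1-based inclusive) plus chromosome sizes as a header
    comment line per chromosome."""
    with open(path, "w") as fh:
        for _, row in genome.chromosomes.iterrows():
            fh.write(f"#chrom\t{row['chrom']}\t{row['length']}\n")
        if genome.exclusion_region is not None:
            c, s, e = genome.exclusion_region
            fh.write(f"#exclude\t{c}\t{s}\t{e}\n")
        genome.genes.to_csv(fh, sep="\t", index=False)


def read_gene_table(path: str | Path) -> GenomeModel:
    chroms, exclude = [], None
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#chrom\t"):
            _, name, length = line.rstrip("\n").split("\t")
            chroms.append({"chrom": name, "length": int(length)})
        elif line.startswith("#exclude\t"):
            _, c, s, e = line.rstrip("\n").split("\t")
            exclude = (c, int(s), int(e))
        else:
            body_start = i
            break
    from io import StringIO

    genes = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    return GenomeModel(
        chromosomes=pd.DataFrame(chroms), genes=genes, exclusion_region=exclude
    )


def write_snp_table(panel: LDPanel, path: str | Path) -> None:
    panel.snps.rename(
        columns={"snp_id": "SNP", "chrom": "CHR", "pos": "BP", "a1": "A1",
                 "a2": "A2", "maf": "MAF"}
    ).to_csv(path, sep="\t", index=False)


def read_snp_table(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    return tab.rename(
        columns={"SNP": "snp_id", "CHR": "chrom", "BP": "pos", "A1": "a1",
                 "A2": "a2", "MAF": "maf"}
    )


def write_panel(panel: LDPanel, prefix: str | Path) -> None:
    """SNP TSV plus a haplotype matrix TSV (rows = haplotypes) and a block
    table; population LD (generator truth) is not serialized."""
    prefix = Path(prefix)
    write_snp_table(panel, prefix.with_suffix(".snps.tsv"))
    np.savetxt(prefix.with_suffix(".haps.tsv"), panel.haplotypes, fmt="%d",
               delimiter="\t")
    pd.DataFrame(panel.blocks, columns=["lo", "hi"]).to_csv(
        prefix.with_suffix(".blocks.tsv"), sep="\t", index=False
    )


def read_panel(prefix: str | Path) -> LDPanel:
    prefix = Path(prefix)
    snps = read_snp_table(prefix.with_suffix(".snps.tsv"))
    haps = np.loadtxt(prefix.with_suffix(".haps.tsv"), dtype=np.uint8,
                      delimiter="\t", ndmin=2)
    blocks = [
        (int(r["lo"]), int(r["hi"]))
        for _, r in pd.read_csv(prefix.with_suffix(".blocks.tsv"), sep="\t").iterrows()
    ]
    return LDPanel(snps=snps, haplotypes=haps, blocks=blocks)


def write_sumstats(stats_: SummaryStats, path: str | Path) -> None:
    """LDSC-style tab-delimited sumstats: SNP, A1, A2, Z, N."""
    stats_.to_frame()[["SNP", "A1", "A2", "Z", "N"]].to_csv(
        path, sep="\t", index=False
    )


def read_sumstats(path: str | Path) -> SummaryStats:
    tab = pd.read_csv(path, sep="\t")
    return SummaryStats(
        snp_id=tab["SNP"].to_numpy(),
        z=tab["Z"].to_numpy(dtype=float),
        n=tab["N"].to_numpy(dtype=float),
        a1=tab["A1"].to_numpy(),
        a2=tab["A2"].to_numpy(),
    )


def _labels_frame(counts: CellTypeCounts) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": counts.cell_ids,
            "level1": counts.level1,
            "level2": counts.level2,
            "batch": counts.batch,
        }
    )


def write_counts_tsv(counts: CellTypeCounts, prefix: str | Path) -> None:
    prefix = Path(prefix)
    pd.DataFrame(
        counts.counts, index=counts.gene_ids, columns=counts.cell_ids
    ).to_csv(prefix.with_suffix(".counts.tsv"), sep="\t")
    _labels_frame(counts).to_csv(prefix.with_suffix(".labels.tsv"), sep="\t",
                                 index=False)


def read_counts_tsv(prefix: str | Path) -> CellTypeCounts:
    prefix = Path(prefix)
    mat = pd.read_csv(prefix.with_suffix(".counts.tsv"), sep="\t", index_col=0)
    lab = pd.read_csv(prefix.with_suffix(".labels.tsv"), sep="\t")
    return CellTypeCounts(
        counts=mat.to_numpy(dtype=np.int64),
        gene_ids=list(mat.index),
        cell_ids=list(mat.columns),
        level1=lab["level1"].to_numpy(dtype=object),
        level2=lab["level2"].to_numpy(dtype=object),
        batch=lab["batch"].to_numpy(dtype=object),
    )


def write_counts_mtx(counts: CellTypeCounts, prefix: str | Path) -> None:
    """MatrixMarket with gene/barcode sidecars plus the labels TSV."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")),
                 sparse.csr_matrix(counts.counts))
    pd.Series(counts.gene_ids).to_csv(prefix.with_suffix(".genes.tsv"),
                                      sep="\t", index=False, header=False)
    pd.Series(counts.cell_ids).to_csv(prefix.with_suffix(".barcodes.tsv"),
                                      sep="\t", index=False, header=False)
    _labels_frame(counts).to_csv(prefix.with_suffix(".labels.tsv"), sep="\t",
                                 index=False)


def read_counts_mtx(prefix: str | Path) -> CellTypeCounts:
    prefix = Path(prefix)
    mat = spio.mmread(str(prefix.with_suffix(".mtx"))).toarray().astype(np.int64)
    genes = pd.read_csv(prefix.with_suffix(".genes.tsv"), sep="\t",
                        header=None)[0].tolist()
    cells = pd.read_csv(prefix.with_suffix(".barcodes.tsv"), sep="\t",
                        header=None)[0].tolist()
    lab = pd.read_csv(prefix.with_suffix(".labels.tsv"), sep="\t")
    return CellTypeCounts(
        counts=mat,
        gene_ids=genes,
        cell_ids=cells,
        level1=lab["level1"].to_numpy(dtype=object),
        level2=lab["level2"].to_numpy(dtype=object),
        batch=lab["batch"].to_numpy(dtype=object),
    )


def write_bedgraph(coverage, pseudo_cell: int | None, path: str | Path) -> None:
    """bedGraph of one pseudo-cell's (or, with None, the summed) bin counts."""
    vals = (
        coverage.counts.sum(axis=0)
        if pseudo_cell is None
        else coverage.counts[pseudo_cell]
    )
    with open(path, "w") as fh:
        for chrom, start, v in zip(coverage.bin_chrom, coverage.bin_start, vals):
            fh.write(f"{chrom}\t{start}\t{start + coverage.bin_size}\t{v}\n")


def write_peaks_bed(peaks: PeakSet, path: str | Path) -> None:
    d = peaks.df
    out = pd.DataFrame(
        {
            "chrom": d["chrom"],
            "start": d["start"],
            "end": d["end"],
            "name": [f"{peaks.source or 'peak'}_{i}" for i in range(len(d))],
            "score": d.get("score", pd.Series(np.zeros(len(d)))),
            "strand": ".",
            "qvalue": d.get("qvalue", pd.Series(np.zeros(len(d)))),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path: str | Path, source: str = "") -> PeakSet:
    tab = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand", "qvalue"],
        usecols=range(7),
    )
    return PeakSet(
        df=tab[["chrom", "start", "end", "score", "qvalue"]], source=source
    )


def write_credible_sets(sets: list[CredibleSet], path: str | Path) -> None:
    rows = [
        {"locus_id": cs.locus_id, "snp_id": s, "posterior": float(p)}
        for cs in sets
        for s, p in zip(cs.snp_ids, cs.posterior)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_credible_sets(path: str | Path) -> list[CredibleSet]:
    tab = pd.read_csv(path, sep="\t")
    out = []
    for locus, grp in tab.groupby("locus_id", sort=False):
        out.append(
            CredibleSet(
                locus_id=str(locus),
                snp_ids=grp["snp_id"].tolist(),
                posterior=grp["posterior"].to_numpy(dtype=float),
            )
        )
    return out


def write_specificity(spec, path: str | Path) -> None:
    spec.specificity.rename_axis("gene_id").to_csv(path, sep="\t")


def write_gene_sets(sets: dict, path: str | Path) -> None:
    """Two-column TSV: set name, gene id."""
    rows = [
        {"set": s.name, "gene_id": g} for s in sets.values() for g in s.genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
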