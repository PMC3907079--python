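"""Probe-to-gene collapsing, SNP-to-gene copy-number mapping, and matrix alignment.

The pipeline works on gene-level matrices: expression arrays are collapsed by
averaging the probes of a gene, and a gene's copy number is the mean of the
marker (SNP) copy numbers falling within a symmetric window around its
transcription region (default 5 kb flank, boundaries inclusive). The two
matrices are then restricted to their common genes and samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    GeneAnnotation,
    OmicsMatrix,
    SnpCopyNumberTable,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class MappingParams:
    """Parameters for SNP-to-gene mapping.

    window_bp : symmetric flank, in bp, added on both sides of the
        transcription region when collecting SNPs (default 5000). Strand is
        ignored. Window membership is inclusive at both boundaries.
    """

    window_bp: int = 5000

    def __post_init__(self):
        if self.window_bp < 0:
            raise ValidationError("window_bp must be >= 0")


@dataclass
class PairedDataset:
    """Aligned expression and copy-number matrices over identical genes/samples."""

    expression: OmicsMatrix
    copy_number: OmicsMatrix
    annotation: GeneAnnotation

    def __post_init__(self):
        if list(self.expression.gene_ids) != list(self.copy_number.gene_ids):
            raise ValidationError("expression and copy-number gene ids differ")
        if list(self.expression.sample_ids) != list(self.copy_number.sample_ids):
            raise ValidationError("expression and copy-number sample ids differ")
        missing = set(self.expression.gene_ids) - set(self.annotation.gene_symbols)
        if missing:
            raise ValidationError(
                f"{len(missing)} gene(s) missing from annotation "
                f"(e.g. {sorted(missing)[:3]})"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.expression.gene_ids

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples


def collapse_to_genes(matrix: OmicsMatrix, probe_to_gene) -> OmicsMatrix:
    """Collapse probe-level rows to one row per gene symbol by averaging.

    ``probe_to_gene`` maps probe id -> gene symbol (dict, Series, or 2-column
    DataFrame). A probe mapping to more than one gene is an error; probes
    without a mapping are dropped.
    """
    if isinstance(probe_to_gene, pd.DataFrame):
        if probe_to_gene.shape[1] < 2:
            raise ValidationError("probe map DataFrame needs 2 columns (probe, gene)")
        pairs = probe_to_gene.iloc[:, :2].drop_duplicates()
        counts = pairs.groupby(pairs.columns[0]).size()
        multi = counts[counts > 1]
        if len(multi):
            raise ValidationError(
                f"probe(s) map to multiple genes: {sorted(map(str, multi.index))[:5]}"
            )
        mapping = pd.Series(
            pairs.iloc[:, 1].to_numpy(), index=pairs.iloc[:, 0].to_numpy()
        )
    else:
        mapping = pd.Series(dict(probe_to_gene))

    genes = matrix.data.index.map(mapping)
    keep = genes.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("collapse_to_genes: dropped %d unmapped probe row(s)", n_dropped)
    data = matrix.data[keep].groupby(genes[keep]).mean()
    data.index.name = "gene"
    data = data.sort_index()
    return OmicsMatrix(matrix.role, data)


def snp_to_gene_copynumber(
    snps: SnpCopyNumberTable,
    annotation: GeneAnnotation,
    params: MappingParams | None = None,
) -> OmicsMatrix:
    """Average SNP copy numbers within each gene's flanked transcription window.

    Per gene and sample, the value is the mean CN over SNPs whose position
    lies in [tx_start - window_bp, tx_end + window_bp] on the gene's
    chromosome. Genes with no SNP in the window get NaN (missing) and their
    count is logged. A SNP inside two overlapping windows contributes to both
    genes. The result does not depend on SNP row order.
    """
    params = params or MappingParams()
    w = params.window_bp
    samples = snps.sample_ids
    values = np.full((len(annotation.table), len(samples)), np.nan)

    by_chrom = {}
    for chrom, idx in snps.info.groupby("chromosome").groups.items():
        sub = snps.info.loc[idx].sort_values("position")
        by_chrom[chrom] = (
            sub["position"].to_numpy(),
            snps.values.loc[sub.index].to_numpy(),
        )

    n_missing = 0
    for i, (gene, row) in enumerate(annotation.table.iterrows()):
        entry = by_chrom.get(row["chromosome"])
        if entry is None:
            n_missing += 1
            continue
        positions, cn = entry
        lo = np.searchsorted(positions, row["tx_start"] - w, side="left")
        hi = np.searchsorted(positions, row["tx_end"] + w, side="right")
        if hi > lo:
            values[i] = np.nanmean(cn[lo:hi], axis=0)
        else:
            n_missing += 1
    if n_missing:
        logger.warning(
            "snp_to_gene_copynumber: %d gene(s) have no SNP within %d bp; "
            "their copy numbers are missing",
            n_missing,
            w,
        )
    data = pd.DataFrame(values, index=annotation.table.index, columns=samples)
    data.index.name = "gene"
    return OmicsMatrix("copy_number", data)


def align_paired(
    expression: OmicsMatrix,
    copy_number: OmicsMatrix,
    annotation: GeneAnnotation,
) -> PairedDataset:
    """Restrict both matrices to shared genes (also annotated) and shared samples.

    Genes are ordered lexicographically, samples follow the expression
    matrix's order. Dropped counts are logged; an empty intersection is an
    error.
    """
    genes = sorted(
        set(expression.gene_ids)
        & set(copy_number.gene_ids)
        & set(annotation.gene_symbols)
    )
    samples = [s for s in expression.sample_ids if s in set(copy_number.sample_ids)]
    if not genes:
        raise ValidationError("no genes shared between expression, CN and annotation")
    if not samples:
        raise ValidationError("no samples shared between expression and CN matrices")
    logger.info(
        "align_paired: kept %d genes (dropped %d expr-only, %d CN-only) "
        "and %d samples",
        len(genes),
        len(set(expression.gene_ids) - set(genes)),
        len(set(copy_number.gene_ids) - set(genes)),
        len(samples),
    )
    return PairedDataset(
        expression=expression.subset(genes, samples),
        copy_number=copy_number.subset(genes, samples),
        annotation=annotation.subset(genes),
    )


def drop_missing_cn_genes(dataset: PairedDataset) -> PairedDataset:
    """Remove genes whose copy number is missing in every sample (logged)."""
    cn = dataset.copy_number.data
    keep = cn.notna().any(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d gene(s) with entirely missing copy number", n_drop)
        genes = list(cn.index[keep])
        return PairedDataset(
            expression=dataset.expression.subset(genes),
            copy_number=dataset.copy_number.subset(genes),
            annotation=dataset.annotation.subset(genes),
        )
    return dataset
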