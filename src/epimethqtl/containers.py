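"""Shared in-memory containers for the methylQTL pipeline.

Conventions used throughout the package:

* Genomic intervals are 0-based, half-open (``[start, end)``) internally.
  Conversion to/from 1-based closed (GFF3, VCF ``POS``) happens only at I/O
  boundaries.
* SNP positions are kept 1-based (as in VCF) on the SNP table; helper code
  converts when intersecting with intervals.
* Missing values are ``NaN`` in float arrays and DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")

#: gene classes emulated by the simulator: the eight ncRNA classes of the
#: Araport11 annotation plus protein-coding genes and transposable elements.
NCRNA_CLASSES = (
    "lncRNA",
    "antisense_lncRNA",
    "miRNA",
    "tRNA",
    "snoRNA",
    "snRNA",
    "rRNA",
    "antisense_RNA",
)
GENE_CLASSES = NCRNA_CLASSES + ("protein_coding", "TE")


class EpimethqtlError(Exception):
    """Base class for package errors."""


class SimulationError(EpimethqtlError):
    """Simulation could not produce a usable cohort."""


class AnnotationError(EpimethqtlError):
    """Inconsistent or incomplete annotation."""


class FormatError(EpimethqtlError):
    """Malformed input file or record."""


def trait_id(gene_id: str, context: str) -> str:
    """Canonical trait identifier for a (gene, context) pair."""
    return f"{gene_id}:{context}"


def split_trait_id(tid: str) -> tuple[str, str]:
    gene, _, context = tid.rpartition(":")
    return gene, context


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs allele-dosage matrix.

    ``dosage`` holds values in {0, 1, 2} with ``NaN`` for missing genotypes.
    ``snps`` is indexed by SNP id with columns ``chrom``, ``pos`` (1-based),
    ``ref``, ``alt``; positions are strictly increasing within a chromosome.
    """

    dosage: np.ndarray
    snps: pd.DataFrame
    accessions: list[str]

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.accessions), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.snps)} SNPs"
            )

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency, ignoring missing genotypes."""
        p = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def snp_index(self, snp_id: str) -> int:
        try:
            return int(self.snps.index.get_loc(snp_id))
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not present in genotype matrix") from None

    def take_snps(self, mask_or_idx) -> "GenotypeMatrix":
        """Subset SNPs by boolean mask or integer positions."""
        sel = np.asarray(mask_or_idx)
        dosage = self.dosage[:, sel]
        snps = self.snps.loc[sel] if sel.dtype == bool else self.snps.iloc[sel]
        return GenotypeMatrix(dosage=dosage, snps=snps, accessions=list(self.accessions))

    def take_accessions(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosage=self.dosage[idx, :],
            snps=self.snps,
            accessions=[self.accessions[i] for i in idx],
        )

    def imputed_dosage(self) -> np.ndarray:
        """Dosage with missing entries replaced by the per-SNP mean."""
        d = self.dosage.copy()
        col_mean = np.nanmean(d, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(d))
        d[nan_r, nan_c] = col_mean[nan_c]
        return d


@dataclass
class TraitMatrix:
    """(gene, context) methylation traits x accessions, in percent [0, 100].

    ``values``: DataFrame indexed by trait id (``gene:context``), columns are
    accession ids, entries percent methylation with NaN for missing.
    ``meta``: per-trait metadata (gene_id, context, n_non_missing,
    missing_rate, cv_percent, cv_defined).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    @property
    def n_traits(self) -> int:
        return len(self.values)

    @property
    def accessions(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class KinshipMatrix:
    """Symmetric PSD accession-relatedness matrix."""

    K: np.ndarray
    accessions: list[str]
    method: str = "centered_grm"

    def __post_init__(self) -> None:
        n = len(self.accessions)
        if self.K.shape != (n, n):
            raise ValueError("kinship matrix not conformable with accession list")


@dataclass
class VarianceComponents:
    """REML estimates for the single-random-effect mixed model.

    sigma_g2 / sigma_e2 are the genetic and residual variances; delta is
    their ratio sigma_e2 / sigma_g2 (the quantity profiled during REML).
    """

    sigma_g2: float
    sigma_e2: float
    delta: float
    reml_loglik: float

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else float("nan")


@dataclass
class AssociationResult:
    """Per-SNP mixed-model association statistics for one trait.

    ``table`` is indexed by SNP id with columns ``chrom pos beta se t p``;
    ``lambda_gc`` is the genomic-inflation factor of the scan and ``df`` the
    residual degrees of freedom of the per-SNP test.
    """

    trait: str
    table: pd.DataFrame
    lambda_gc: float
    n_used: int
    df: int
    vc: VarianceComponents | None = None


@dataclass
class MethylQTL:
    """One called methylQTL: a surviving cluster with its representative SNP."""

    trait: str
    gene_id: str
    context: str
    chrom: str
    start: int
    end: int
    n_snps: int
    rep_snp: str
    rep_pos: int
    p_value: float
    pve: float
    distance_bp: float
    qtl_class: str
    same_chromosome: bool
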