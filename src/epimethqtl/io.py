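"""Readers/writers for the standard formats, pipeline configuration, and the
end-to-end pipeline runner.

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
closed) and VCF positions are converted at these boundaries only.  All
derived artifacts are TSV with a provenance header (``# epimethqtl ...``)
so runs are diffable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pyranges as pr
import yaml
from cyvcf2 import VCF
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .containers import FormatError, GenotypeMatrix, TraitMatrix
from . import synthetic_data as sd
from . import methylome_traits as mt
from . import mlm_association as mlm
from . import methylqtl_calling as qc
from . import downstream_stats as ds

__all__ = [
    "read_vcf", "write_vcf",
    "read_site_table", "write_site_table",
    "read_gff3", "write_gff3",
    "read_bed", "write_bed",
    "read_table", "write_table",
    "read_trait_matrix", "write_trait_matrix",
    "PipelineConfig", "load_config", "run_pipeline",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def _config_hash(obj) -> str:
    return hashlib.sha1(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _provenance(seed=None, cfg_hash=None) -> str:
    parts = [f"# epimethqtl {__version__}"]
    if seed is not None:
        parts.append(f"# seed: {seed}")
    if cfg_hash is not None:
        parts.append(f"# config: {cfg_hash}")
    return "\n".join(parts) + "\n"


def write_table(df: pd.DataFrame, path, index: bool = False,
                seed=None, cfg_hash=None) -> None:
    """TSV writer with provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance(seed, cfg_hash))
        df.to_csv(fh, sep="\t", index=index, na_rep="NA")


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col,
                       na_values=["NA"])


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_MAP = {0: 0.0, 1: 1.0, 3: 2.0, 2: np.nan}  # cyvcf2 gt_types


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF (GT field) into a dosage matrix.

    Non-SNP and multiallelic records are skipped (counted in the log);
    ``./.`` genotypes become missing dosages.
    """
    vcf = VCF(str(path), gts012=False)
    accessions = list(vcf.samples)
    if not accessions:
        raise FormatError(f"{path}: VCF has no samples (GT field required)")
    rows, dosages, skipped = [], [], 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            skipped += 1
            continue
        rows.append((v.ID or f"{v.CHROM}_{v.POS}", v.CHROM, v.POS, v.REF, v.ALT[0]))
        dosages.append([_GT_MAP.get(int(t), np.nan) for t in v.gt_types])
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records", skipped)
    if not rows:
        raise FormatError(f"{path}: no biallelic SNP records found")
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"]
                        ).set_index("snp_id")
    dosage = np.asarray(dosages, dtype=float).T  # accessions x snps
    return GenotypeMatrix(dosage=dosage, snps=snps, accessions=accessions)


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 (GT only) for a dosage matrix."""
    gt_strings = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.accessions) + "\n")
        for j, (snp_id, row) in enumerate(G.snps.iterrows()):
            gts = "\t".join(
                gt_strings.get(d, "./.") if not np.isnan(d) else "./."
                for d in G.dosage[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{snp_id}\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# site table, GFF3, BED
# ---------------------------------------------------------------------------

def write_site_table(sites: pd.DataFrame, path, **prov) -> None:
    write_table(sites[mt.SITE_COLUMNS], path, **prov)


def read_site_table(path) -> pd.DataFrame:
    sites = read_table(path)
    missing = set(mt.SITE_COLUMNS) - set(sites.columns)
    if missing:
        raise FormatError(f"{path}: site table lacks columns {sorted(missing)}")
    bad = sites["mc_count"] > sites["total_count"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(f"{path}: record {i}: mc_count exceeds total_count")
    if (sites["pos"] < 1).any() or (sites["total_count"] < 0).any():
        raise FormatError(f"{path}: invalid position or count")
    if not sites["context"].isin(("CG", "CHG", "CHH")).all():
        bad_ctx = sorted(set(sites["context"]) - {"CG", "CHG", "CHH"})
        raise FormatError(f"{path}: unknown context label(s) {bad_ctx}")
    return sites


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write gene models (internal 0-based half-open) as GFF3 genes with an
    ``nc_class`` attribute."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID={g.gene_id};nc_class={g.nc_class}"
            fh.write(f"{g.chrom}\tepimethqtl\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")


def read_gff3(path, feature: str = "gene") -> pd.DataFrame:
    """Read gene models from GFF3 into the internal 0-based convention."""
    df = pr.read_gff3(str(path)).df
    df = df[df["Feature"] == feature]
    if df.empty:
        raise FormatError(f"{path}: no {feature!r} records")
    if (df["End"] <= df["Start"]).any():
        bad = df[df["End"] <= df["Start"]].iloc[0]
        raise FormatError(f"{path}: empty interval for record {bad.get('ID', '?')}")
    out = pd.DataFrame({
        "gene_id": df.get("ID", pd.Series(["?"] * len(df))).to_numpy(),
        "chrom": df["Chromosome"].astype(str).to_numpy(),
        "start": df["Start"].to_numpy(),
        "end": df["End"].to_numpy(),
        "strand": df["Strand"].astype(str).to_numpy() if "Strand" in df else "+",
        "nc_class": df["nc_class"].to_numpy() if "nc_class" in df else "unknown",
    })
    return out.reset_index(drop=True)


def write_bed(track: pd.DataFrame, path) -> None:
    """Write a labelled interval track as BED4 (already 0-based half-open)."""
    label = "state" if "state" in track else "feature"
    track[["chrom", "start", "end", label]].to_csv(path, sep="\t", header=False,
                                                   index=False)


def read_bed(path) -> pd.DataFrame:
    df = pr.read_bed(str(path)).df
    if (df["End"] <= df["Start"]).any():
        bad = df[df["End"] <= df["Start"]].iloc[0]
        raise FormatError(f"{path}: empty interval at {bad.Chromosome}:{bad.Start}")
    out = df.rename(columns={"Chromosome": "chrom", "Start": "start", "End": "end",
                             "Name": "state"})
    out["chrom"] = out["chrom"].astype(str)
    return out[["chrom", "start", "end", "state"]]


def write_trait_matrix(traits: TraitMatrix, path_values, path_meta=None, **prov) -> None:
    write_table(traits.values.rename_axis("trait"), path_values, index=True, **prov)
    if path_meta is not None:
        write_table(traits.meta, path_meta, index=True, **prov)


def read_trait_matrix(path_values, path_meta=None) -> TraitMatrix:
    values = read_table(path_values, index_col=0)
    if path_meta is not None:
        meta = read_table(path_meta, index_col=0)
    else:
        meta = mt._trait_metadata(values, len(values.columns))
    return TraitMatrix(values=values, meta=meta)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class _QtlSpecModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gene_id: str
    context: str
    mode: str
    target_pve: float
    enriched_state: str | None = None


class _LinkModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    trait: str
    phenotype: str
    r: float


class SimulateBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_accessions: int = 200
    n_snps: int = 3000
    n_chromosomes: int = 2
    chrom_length_bp: int = 160_000
    n_founders: int = 24
    recomb_rate_per_bp: float = 6e-5
    n_subpops: int = 2
    subpop_admixture: float = Field(0.1, ge=0, le=1)
    maf_min: float = Field(0.05, ge=0, lt=0.5)
    coverage_mean: float = 20.0
    missing_site_rate: float = Field(0.05, ge=0, le=1)
    missing_genotype_rate: float = Field(0.02, ge=0, le=1)
    genes_per_class: int = 2
    enrichment_factor: float = 1.0
    qtls: list[_QtlSpecModel] = []
    links: list[_LinkModel] = []


class TraitsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_total: int = Field(5, ge=0)
    max_missing_rate: float = Field(0.10, ge=0, le=1)
    mode: str = "site_mean"


class GwasBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    maf_min: float = Field(0.05, ge=0, le=0.5)
    snp_missing_max: float = Field(0.25, ge=0, le=1)
    prune_window: int = 50
    prune_step: int = 10
    prune_r2: float = Field(0.1, ge=0, le=1)
    kinship_method: str = "centered_grm"


class QtlBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = Field(0.01, gt=0, lt=1)
    window_bp: int = Field(16_000, gt=0)
    min_other_neighbors: int = Field(20, ge=0)
    gap_bp: int = Field(8_000, gt=0)
    max_clusters: int = Field(20, gt=0)
    dedup_r2: float = Field(0.1, ge=0, le=1)
    proximal_bp: int = Field(100_000, gt=0)


class CorrelateBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    p_max: float = Field(6.08e-5, gt=0, lt=1)
    n_min: int = Field(100, ge=0)


class EnrichBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gene_flank_bp: int = Field(2000, ge=0)
    adjust: str = "benjamini_hochberg"


class PipelineConfig(BaseModel):
    """Validated stage parameters for the full pipeline; unknown keys are
    rejected.  All published thresholds are defaults here, never hard-coded
    in stage logic."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    simulate: SimulateBlock = SimulateBlock()
    traits: TraitsBlock = TraitsBlock()
    gwas: GwasBlock = GwasBlock()
    qtl: QtlBlock = QtlBlock()
    correlate: CorrelateBlock = CorrelateBlock()
    enrich: EnrichBlock = EnrichBlock()


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _sim_config(cfg: PipelineConfig, seed: int | None = None) -> sd.SimConfig:
    s = cfg.simulate
    return sd.SimConfig(
        n_accessions=s.n_accessions, n_snps=s.n_snps,
        n_chromosomes=s.n_chromosomes, chrom_length_bp=s.chrom_length_bp,
        n_founders=s.n_founders, recomb_rate_per_bp=s.recomb_rate_per_bp,
        n_subpops=s.n_subpops, subpop_admixture=s.subpop_admixture,
        maf_min=s.maf_min, coverage_mean=s.coverage_mean,
        missing_site_rate=s.missing_site_rate,
        missing_genotype_rate=s.missing_genotype_rate,
        genes=sd.default_gene_specs(n_per_class=s.genes_per_class),
        enrichment_factor=s.enrichment_factor,
        seed=cfg.seed if seed is None else seed,
    )


def run_pipeline(cfg: PipelineConfig, out_dir) -> Path:
    """Execute simulate -> traits -> gwas -> call-qtl -> correlate -> enrich.

    Every artifact carries a provenance header; per-stage record counts are
    logged.  Returns the artifact directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = _config_hash(cfg.model_dump())
    prov = dict(seed=cfg.seed, cfg_hash=h)

    # --- simulate ---------------------------------------------------------
    sim = _sim_config(cfg)
    G = sd.simulate_genotypes(sim)
    genes = sd.simulate_genes(sim)
    qtls = [sd.QtlSpec(q.gene_id, q.context, q.mode, q.target_pve, q.enriched_state)
            for q in cfg.simulate.qtls]
    truth = sd.make_truth(G, genes, qtls, sim) if qtls else sd.empty_truth()
    sites = sd.simulate_methylome(G, genes, truth, sim)
    _, states, features = sd.simulate_annotations(sim, truth, G)
    write_vcf(G, out / "genotypes.vcf")
    write_site_table(sites, out / "sites.tsv", **prov)
    write_gff3(genes, out / "genes.gff3")
    write_bed(states, out / "chromatin_states.bed")
    write_bed(features, out / "features.bed")
    write_table(truth, out / "truth.tsv", **prov)
    logger.info("simulate: %d accessions, %d SNPs, %d genes, %d site records",
                G.n_accessions, G.n_snps, len(genes), len(sites))

    # --- traits -----------------------------------------------------------
    traits = mt.build_trait_matrix(sites, genes, max_missing_rate=cfg.traits.max_missing_rate,
                                   mode=cfg.traits.mode, accessions=G.accessions,
                                   min_total=cfg.traits.min_total)
    write_trait_matrix(traits, out / "traits.tsv", out / "trait_meta.tsv", **prov)
    logger.info("traits: %d retained", traits.n_traits)

    # --- gwas -------------------------------------------------------------
    Gq = mlm.snp_qc(G, cfg.gwas.maf_min, cfg.gwas.snp_missing_max)
    K = mlm.kinship(mlm.ld_prune(Gq, cfg.gwas.prune_window, cfg.gwas.prune_step,
                                 cfg.gwas.prune_r2), method=cfg.gwas.kinship_method)
    assoc_dir = out / "assoc"
    assoc_dir.mkdir(exist_ok=True)
    results, summary = [], []
    for tid in traits.values.index:
        res = mlm.mlm_gwas(traits.values.loc[tid], Gq, K, trait=tid)
        results.append(res)
        thr = mlm.bonferroni_threshold(cfg.qtl.alpha, len(res.table))
        n_sig = int((res.table["p"] <= thr).sum())
        summary.append((tid, res.lambda_gc, res.n_used, n_sig))
        write_table(res.table.rename_axis("snp_id"),
                    assoc_dir / f"{tid.replace(':', '_')}.tsv", index=True, **prov)
    write_table(pd.DataFrame(summary, columns=["trait", "lambda_gc", "n", "n_sig"]),
                out / "scan_summary.tsv", **prov)

    # --- call-qtl ---------------------------------------------------------
    params = qc.QtlCallParams(alpha=cfg.qtl.alpha, window_bp=cfg.qtl.window_bp,
                              min_other_neighbors=cfg.qtl.min_other_neighbors,
                              gap_bp=cfg.qtl.gap_bp, max_clusters=cfg.qtl.max_clusters,
                              dedup_r2=cfg.qtl.dedup_r2,
                              proximal_bp=cfg.qtl.proximal_bp)
    qtl, audit = qc.call_methylqtl(results, Gq, genes, params)
    write_table(qtl, out / "methylqtl.tsv", **prov)
    write_table(audit, out / "qtl_audit.tsv", **prov)
    logger.info("call-qtl: %d methylQTL", len(qtl))

    # --- correlate --------------------------------------------------------
    links = [(l.trait, l.phenotype, l.r) for l in cfg.simulate.links]
    phen = sd.simulate_phenotypes(traits, links, sim) if links else \
        pd.DataFrame(index=pd.Index(traits.accessions, name="accession"))
    edges = ds.correlate_traits(traits, phen, p_max=cfg.correlate.p_max,
                                n_min=cfg.correlate.n_min)
    nodes, etab = ds.build_network(edges)
    write_table(phen.rename_axis("accession"), out / "phenotypes.tsv", index=True, **prov)
    write_table(edges, out / "correlations.tsv", **prov)
    write_table(nodes, out / "network_nodes.tsv", **prov)
    write_table(etab, out / "network_edges.tsv", **prov)

    # --- enrich -----------------------------------------------------------
    if len(qtl):
        reps = qtl[["chrom", "rep_pos"]].rename(columns={"rep_pos": "pos"})
        enr = ds.fisher_enrichment(reps, Gq.snps[["chrom", "pos"]], states,
                                   adjust=cfg.enrich.adjust)
    else:
        enr = pd.DataFrame(columns=["feature", "a", "b", "c", "d", "odds_ratio",
                                    "p", "p_adj"])
    write_table(enr, out / "enrichment.tsv", **prov)
    logger.info("pipeline complete: %s", out)
    return out
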