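"""Synthetic cohorts with planted methylQTL for pipeline validation.

The generator emulates the data structures of a population epigenomics
study: a few hundred inbred accessions genotyped at biallelic SNPs with
realistic linkage-disequilibrium decay and subpopulation structure,
per-cytosine bisulfite read counts in the CG/CHG/CHH contexts over an
annotated gene set, quantitative phenotypes correlated with methylation,
and chromatin-state / feature interval tracks.

Genotypes follow a founder-mosaic (haplotype copying) model: each
haplotype is a piecewise copy of one of ``n_founders`` founder haplotypes,
switching founders at rate ``recomb_rate_per_bp`` per bp.  The founder
haplotypes themselves carry linkage disequilibrium (a latent Gaussian
AR(1) copula with decay ``founder_ld_rate_per_bp``, also shared by the
allele-frequency series), so population r^2 decays smoothly with
distance at a tunable length.  Subpopulations have
Balding-Nichols-diverged founder allele frequencies, inducing kinship
structure.

Methylation is generated on the logit scale: a per-accession latent
propensity (context baseline + planted SNP effects + subpopulation and
accession random effects) is combined with per-site offsets, and each
cytosine emits (methylated, total) read counts with Poisson coverage and
binomial methylated reads.  Planted effect sizes are solved from the
requested phenotypic variance explained (PVE), so recovery of the planted
PVE is a testable quantity.

All randomness flows from one master seed through named substreams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .containers import (
    CONTEXTS,
    GENE_CLASSES,
    AnnotationError,
    GenotypeMatrix,
    SimulationError,
    TraitMatrix,
    trait_id,
)

__all__ = [
    "GeneSpec",
    "QtlSpec",
    "SimConfig",
    "default_gene_specs",
    "simulate_genotypes",
    "simulate_genes",
    "make_truth",
    "simulate_methylome",
    "simulate_phenotypes",
    "simulate_chromatin_states",
    "simulate_annotations",
    "subpop_assignment",
    "solve_effect_size",
    "latent_environmental_variance",
    "realized_pve",
]

# named substreams off the master seed
_STREAMS = {"genotypes": 1, "methylome": 2, "phenotypes": 3, "annotations": 4}


@dataclass(frozen=True)
class GeneSpec:
    """One gene to simulate; ``start`` of None means auto-placement."""

    gene_id: str
    nc_class: str
    length: int = 1200
    chrom: str | None = None
    start: int | None = None
    #: additive shift of the latent methylation baseline (logit units);
    #: used to plant class-level methylation contrasts.
    baseline_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.nc_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.nc_class!r}")
        if self.length <= 0:
            raise ValueError("gene length must be positive")


@dataclass(frozen=True)
class QtlSpec:
    """Request to plant one QTL: which trait, cis or trans, how strong."""

    gene_id: str
    context: str
    mode: str  # "cis" | "trans"
    target_pve: float
    enriched_state: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("cis", "trans"):
            raise ValueError("mode must be 'cis' or 'trans'")
        if not 0.0 < self.target_pve < 1.0:
            raise ValueError("target_pve must be in (0, 1)")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults give a desk-scale cohort whose SNP density (~9.4 SNPs/kb,
    i.e. ~150 SNPs per 16 kb) and LD decay length (r^2 drops below 0.1
    around 8 kb) match the population the pipeline is designed for, with
    bisulfite coverage ~20x and two admixed subpopulations.
    """

    n_accessions: int = 200
    n_snps: int = 3000
    n_chromosomes: int = 2
    chrom_length_bp: int = 160_000
    n_founders: int = 24
    recomb_rate_per_bp: float = 6e-5
    n_subpops: int = 2
    subpop_admixture: float = 0.1
    fst: float = 0.1
    #: decay rate of LD carried by the founder haplotypes themselves
    #: (AR(1) latent correlation exp(-rate * gap)); combined with the
    #: mosaic switching this sets the population LD decay length
    founder_ld_rate_per_bp: float = 3e-5
    maf_min: float = 0.05
    genes: tuple[GeneSpec, ...] = ()
    coverage_mean: float = 20.0
    missing_site_rate: float = 0.05
    missing_genotype_rate: float = 0.02
    seed: int = 0
    # methylation noise model (logit scale)
    baseline_logit: tuple[tuple[str, float], ...] = (("CG", 0.2), ("CHG", 0.0), ("CHH", -0.4))
    accession_noise_sd: float = 0.3
    subpop_effect_sd: float = 0.15
    site_effect_sd: float = 0.3
    site_spacing_bp: tuple[tuple[str, int], ...] = (("CG", 100), ("CHG", 100), ("CHH", 40))
    # annotation tracks
    n_chromatin_states: int = 5
    state_tile_bp: int = 2000
    enrichment_factor: float = 1.0
    phenotype_missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_accessions", "n_snps", "n_chromosomes", "chrom_length_bp",
                     "n_founders", "n_subpops", "n_chromatin_states", "state_tile_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("subpop_admixture", "maf_min", "missing_site_rate",
                     "missing_genotype_rate", "phenotype_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.maf_min >= 0.5:
            raise ValueError("maf_min must be < 0.5")
        if self.recomb_rate_per_bp < 0:
            raise ValueError("recomb_rate_per_bp must be >= 0")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if self.enrichment_factor <= 0:
            raise ValueError("enrichment_factor must be > 0")

    # mapping-style accessors for the tuple-of-pairs fields (kept hashable)
    @property
    def baselines(self) -> dict[str, float]:
        return dict(self.baseline_logit)

    @property
    def site_spacing(self) -> dict[str, int]:
        return dict(self.site_spacing_bp)

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def default_gene_specs(n_per_class: int = 3, length: int = 1200,
                       class_shifts: dict[str, float] | None = None) -> tuple[GeneSpec, ...]:
    """A balanced gene panel covering all eight ncRNA classes plus
    protein-coding genes and TEs."""
    class_shifts = class_shifts or {}
    specs = []
    i = 0
    for cls in GENE_CLASSES:
        for _ in range(n_per_class):
            specs.append(GeneSpec(gene_id=f"G{i:04d}", nc_class=cls, length=length,
                                  baseline_shift=class_shifts.get(cls, 0.0)))
            i += 1
    return tuple(specs)


def null_cohort_config(seed: int, n_accessions: int = 300, n_snps: int = 3000,
                       genes: tuple[GeneSpec, ...] | None = None) -> SimConfig:
    """Cohort layout for null-calibration studies.

    SNPs are spread over many chromosomes at ~1 SNP / 10 kb — above the LD
    decay length — so the tests are close to independent and the pruned
    kinship panel retains on the order of a thousand markers.  With the
    dense default layout a few thousand SNPs collapse into a few dozen
    linkage blocks, which makes the genomic-inflation factor of a single
    scan very unstable.
    """
    genes = genes if genes is not None else (GeneSpec("GA", "lncRNA"),)
    return SimConfig(n_accessions=n_accessions, n_snps=n_snps,
                     n_chromosomes=10, chrom_length_bp=3_000_000,
                     genes=genes, seed=seed)


def qtl_cohort_config(seed: int, n_accessions: int = 500,
                      genes: tuple[GeneSpec, ...] | None = None) -> SimConfig:
    """Cohort layout for planted-QTL recovery studies.

    Keeps the default SNP density (~9.4/kb, so the density filter sees
    ~150 SNPs per 16 kb window) but sizes the genome (2 x 2.25 Mb, 42k
    SNPs) so LD pruning leaves ~500 quasi-independent markers in the
    kinship panel.  With a much smaller genome the causal linkage block is
    a large share of the kinship matrix and the EMMAX whitening absorbs
    most of the planted signal (proximal contamination); the real study's
    kinship panel of ~46k pruned SNPs has the same dilution property.
    """
    genes = genes if genes is not None else (GeneSpec("GA", "lncRNA"),)
    return SimConfig(n_accessions=n_accessions, n_snps=42_000,
                     n_chromosomes=2, chrom_length_bp=2_250_000,
                     genes=genes, seed=seed)


def subpop_assignment(n_accessions: int, n_subpops: int) -> np.ndarray:
    """Deterministic block assignment of accessions to subpopulations."""
    return (np.arange(n_accessions) * n_subpops) // n_accessions


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _snp_positions(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sorted 1-based SNP positions, split evenly across chromosomes."""
    per = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per[: config.n_snps % config.n_chromosomes] += 1
    rows = []
    for chrom, n in zip(config.chromosomes, per):
        if n > config.chrom_length_bp:
            raise SimulationError(
                f"cannot place {n} SNPs on a {config.chrom_length_bp} bp chromosome")
        pos = np.sort(rng.choice(config.chrom_length_bp, size=int(n), replace=False)) + 1
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    snps = pd.concat(rows, ignore_index=True)
    snps.index = pd.Index(snps.chrom + "_" + snps.pos.astype(str), name="snp_id")
    return snps


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate an accessions x SNPs dosage matrix under the founder-mosaic model.

    Each accession carries two haplotypes, each a mosaic of founder
    haplotypes from its subpopulation's pool (or, with probability
    ``subpop_admixture`` per segment, another subpopulation's pool).
    SNPs with realized MAF below ``maf_min`` are removed.
    """
    rng = config.rng("genotypes")
    snps = _snp_positions(config, rng)
    n_snps = len(snps)
    n_acc = config.n_accessions

    pos_for_ar = snps.pos.to_numpy()
    chrom_for_ar = pd.factorize(snps.chrom)[0]

    def ar1(n_series: int) -> np.ndarray:
        """Latent Gaussian AR(1) along the SNP positions (reset per chromosome)."""
        gaps = np.diff(pos_for_ar).astype(float)
        phi = np.exp(-config.founder_ld_rate_per_bp * gaps)
        phi[np.diff(chrom_for_ar) != 0] = 0.0
        z = np.empty((n_series, n_snps))
        z[:, 0] = rng.normal(size=n_series)
        innov = rng.normal(size=(n_series, max(n_snps - 1, 1)))
        for i in range(1, n_snps):
            z[:, i] = phi[i - 1] * z[:, i - 1] + np.sqrt(1.0 - phi[i - 1] ** 2) * innov[:, i - 1]
        return z

    # Balding-Nichols subpopulation allele frequencies around a common p0.
    # Both p0 and the subpopulation deviations are autocorrelated along the
    # chromosome (nearby SNPs share genealogy), otherwise site-to-site LD
    # would be destroyed by independent frequency noise.
    from scipy.stats import beta as beta_dist

    p0 = 0.1 + 0.4 * ndtr(ar1(1)[0])
    a = p0 * (1 - config.fst) / config.fst
    b = (1 - p0) * (1 - config.fst) / config.fst
    u_sub = ndtr(ar1(config.n_subpops))
    p_sub = beta_dist.ppf(u_sub, a[None, :], b[None, :])

    # Founder haplotypes per subpopulation pool, with internal LD: a latent
    # Gaussian AR(1) process along the chromosome (correlation
    # exp(-founder_ld_rate_per_bp * gap), reset at chromosome breaks) is
    # thresholded at the subpopulation allele frequency.  Without this the
    # mosaic alone would create kinship but no site-to-site LD.
    nf = config.n_subpops * config.n_founders
    u = ndtr(ar1(nf)).reshape(config.n_subpops, config.n_founders, n_snps)
    founders = (u < p_sub[:, None, :]).astype(np.int8)

    # switch probabilities between consecutive SNPs (chromosome break => 1)
    pos = snps.pos.to_numpy()
    chrom_codes = pd.factorize(snps.chrom)[0]
    gap = np.diff(pos).astype(float)
    p_switch = 1.0 - np.exp(-config.recomb_rate_per_bp * gap)
    p_switch[np.diff(chrom_codes) != 0] = 1.0
    p_switch = np.concatenate([[1.0], p_switch])  # first site always opens a segment

    n_hap = 2 * n_acc
    switch = rng.random((n_hap, n_snps)) < p_switch[None, :]
    switch[:, 0] = True
    seg = np.cumsum(switch, axis=1) - 1  # segment index per haplotype per site
    max_seg = int(seg.max()) + 1

    sub_of_acc = subpop_assignment(n_acc, config.n_subpops)
    sub_of_hap = np.repeat(sub_of_acc, 2)
    # per-segment pool choice (admixture) and founder choice
    pool = np.broadcast_to(sub_of_hap[:, None], (n_hap, max_seg)).copy()
    if config.n_subpops > 1 and config.subpop_admixture > 0:
        mig = rng.random((n_hap, max_seg)) < config.subpop_admixture
        shift = rng.integers(1, config.n_subpops, size=(n_hap, max_seg))
        pool[mig] = (pool[mig] + shift[mig]) % config.n_subpops
    founder_choice = rng.integers(0, config.n_founders, size=(n_hap, max_seg))

    hap_idx = np.arange(n_hap)[:, None]
    site_idx = np.arange(n_snps)[None, :]
    alleles = founders[pool[hap_idx, seg], founder_choice[hap_idx, seg], site_idx]
    dosage = (alleles[0::2] + alleles[1::2]).astype(float)

    if config.missing_genotype_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_genotype_rate
        dosage[miss] = np.nan

    accessions = [f"acc{i:04d}" for i in range(n_acc)]
    G = GenotypeMatrix(dosage=dosage, snps=snps.assign(ref="A", alt="T"),
                       accessions=accessions)
    keep = G.maf() >= config.maf_min
    if not keep.any():
        raise SimulationError(
            f"no polymorphic SNP reached MAF >= {config.maf_min}; "
            f"founder pool too small or frequencies too extreme")
    return G.take_snps(keep)


# ---------------------------------------------------------------------------
# gene models and truth
# ---------------------------------------------------------------------------

def simulate_genes(config: SimConfig) -> pd.DataFrame:
    """Place the configured genes as non-overlapping models (0-based half-open).

    Genes without explicit coordinates are distributed evenly across
    chromosomes and spaced evenly within each.
    """
    specs = config.genes
    if not specs:
        raise ValueError("SimConfig.genes is empty")
    auto = [s for s in specs if s.start is None]
    rows = []
    # round-robin chromosome assignment for auto-placed genes
    per_chrom: dict[str, list[GeneSpec]] = {c: [] for c in config.chromosomes}
    for i, s in enumerate(auto):
        chrom = s.chrom or config.chromosomes[i % config.n_chromosomes]
        per_chrom.setdefault(chrom, []).append(s)
    for chrom, group in per_chrom.items():
        if not group:
            continue
        slot = config.chrom_length_bp // (len(group) + 1)
        for j, s in enumerate(group):
            if s.length >= slot:
                raise AnnotationError(
                    f"gene {s.gene_id} (len {s.length}) does not fit its "
                    f"{slot} bp slot on {chrom}")
            start = (j + 1) * slot - s.length // 2
            rows.append((s.gene_id, chrom, start, start + s.length,
                         "+" if j % 2 == 0 else "-", s.nc_class, s.baseline_shift))
    for s in specs:
        if s.start is not None:
            if s.chrom is None:
                raise AnnotationError(f"gene {s.gene_id}: start given without chrom")
            rows.append((s.gene_id, s.chrom, s.start, s.start + s.length,
                         "+", s.nc_class, s.baseline_shift))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                        "strand", "nc_class", "baseline_shift"])
    genes = genes.sort_values(["chrom", "start"]).reset_index(drop=True)
    prev_end = genes.groupby("chrom")["end"].shift()
    if ((genes.start - prev_end) < 0).any():
        raise AnnotationError("simulated gene models overlap")
    return genes


def latent_environmental_variance(config: SimConfig, context: str,
                                  gene_length: int, baseline_shift: float = 0.0) -> float:
    """Non-genetic variance of a gene-level trait on the logit scale.

    Sum of the subpopulation and accession random-effect variances plus a
    delta-method equivalent of binomial read-sampling noise (evaluated at
    the context baseline, averaged over the gene's cytosine sites).  With
    k balanced subpopulations the subpopulation effect contributes
    sigma^2 (k - 1) / k to the across-accession variance (zero at k = 1).
    """
    k = config.n_subpops
    var_re = (config.subpop_effect_sd ** 2 * (k - 1) / k
              + config.accession_noise_sd ** 2)
    n_sites = max(1, gene_length // context_site_spacing(config, context))
    n_eff = n_sites * (1.0 - config.missing_site_rate)
    lam = config.coverage_mean
    if lam <= 0 or n_eff <= 0:
        return var_re
    # E[1/T | T > 0] for T ~ Poisson(lam)
    tmax = int(lam + 10 * np.sqrt(lam) + 10)
    t = np.arange(1, tmax + 1)
    logpmf = t * np.log(lam) - lam - np.cumsum(np.log(t))
    pmf = np.exp(logpmf)
    e_inv_t = float((pmf / t).sum() / pmf.sum())
    p_bar = 1.0 / (1.0 + np.exp(-(config.baselines[context] + baseline_shift)))
    var_read_latent = e_inv_t / (n_eff * p_bar * (1.0 - p_bar))
    return var_re + var_read_latent


def context_site_spacing(config: SimConfig, context: str) -> int:
    spacing = config.site_spacing.get(context)
    if spacing is None:
        raise ValueError(f"unknown context {context!r}")
    return spacing


def solve_effect_size(target_pve: float, dosage_var: float, env_var: float) -> float:
    """Per-dosage effect (logit scale) giving the requested PVE.

    PVE = beta^2 * Var(dosage) / (beta^2 * Var(dosage) + env_var), solved
    for beta using the empirical dosage variance of the causal SNP.
    """
    if not 0 < target_pve < 1:
        raise ValueError("target_pve must be in (0, 1)")
    if dosage_var <= 0:
        raise ValueError("causal SNP has zero dosage variance")
    return float(np.sqrt(target_pve / (1 - target_pve) * env_var / dosage_var))


def make_truth(G: GenotypeMatrix, genes: pd.DataFrame, qtls: list[QtlSpec],
               config: SimConfig, cis_window_bp: int = 10_000,
               min_causal_maf: float = 0.1) -> pd.DataFrame:
    """Choose causal SNPs for the requested QTL and solve their effect sizes.

    cis QTL use the common SNP (MAF >= ``min_causal_maf``) nearest the gene
    midpoint within the gene +/- ``cis_window_bp``; trans QTL use a common
    SNP drawn from a different chromosome.
    """
    rng = config.rng("methylome")  # same stream family as the methylome
    gene_by_id = genes.set_index("gene_id")
    maf = G.maf()
    pos = G.snps.pos.to_numpy()
    chrom = G.snps.chrom.to_numpy()
    used = np.zeros(G.n_snps, dtype=bool)  # avoid reusing one causal SNP
    rows = []
    for q in qtls:
        if q.gene_id not in gene_by_id.index:
            raise KeyError(f"truth references unknown gene {q.gene_id!r}")
        g = gene_by_id.loc[q.gene_id]
        common = (maf >= min_causal_maf) & ~used
        if q.mode == "cis":
            mid = (g.start + g.end) / 2
            # widen the window if no common SNP is that close, but stay
            # strictly below the proximal classification threshold
            cand = np.zeros(len(pos), dtype=bool)
            w = cis_window_bp
            while not cand.any() and w < 100_000:
                cand = common & (chrom == g.chrom) \
                    & (pos >= g.start + 1 - w) & (pos <= g.end + w)
                w *= 2
            if not cand.any():
                raise SimulationError(
                    f"no common SNP near gene {q.gene_id} for a cis QTL")
            idx = np.flatnonzero(cand)
            snp_i = idx[np.argmin(np.abs(pos[idx] - mid))]
        else:
            cand = common & (chrom != g.chrom)
            if not cand.any():
                raise SimulationError(
                    f"no common SNP on another chromosome for trans QTL of {q.gene_id}")
            snp_i = int(rng.choice(np.flatnonzero(cand)))
        used[snp_i] = True
        dos = G.dosage[:, snp_i]
        dvar = float(np.nanvar(dos, ddof=1))
        env = latent_environmental_variance(
            config, q.context, int(g.end - g.start), float(g.get("baseline_shift", 0.0)))
        beta = solve_effect_size(q.target_pve, dvar, env)
        rows.append((trait_id(q.gene_id, q.context), q.gene_id, q.context,
                     G.snps.index[snp_i], q.mode, beta, q.target_pve, q.enriched_state))
    return pd.DataFrame(rows, columns=["trait", "gene_id", "context", "causal_snp_id",
                                       "mode", "effect_size", "target_pve",
                                       "enriched_state"])


def empty_truth() -> pd.DataFrame:
    return pd.DataFrame(columns=["trait", "gene_id", "context", "causal_snp_id",
                                 "mode", "effect_size", "target_pve", "enriched_state"])


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def simulate_methylome(G: GenotypeMatrix, genes: pd.DataFrame, truth: pd.DataFrame,
                       config: SimConfig) -> pd.DataFrame:
    """Per-cytosine (methylated, total) read counts for every accession.

    Returns a long table with columns
    ``chrom pos strand context mc_count total_count accession`` (pos 1-based).
    """
    for snp in truth.get("causal_snp_id", pd.Series(dtype=object)):
        if snp not in G.snps.index:
            raise KeyError(f"truth causal SNP {snp!r} absent from genotype matrix")
    if config.coverage_mean <= 0:
        warnings.warn("coverage_mean is 0; emitting an empty site table")
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context",
                                     "mc_count", "total_count", "accession"])

    rng = config.rng("methylome")
    rng = np.random.default_rng(rng.integers(2**31))  # decouple from make_truth draws
    n_acc = G.n_accessions
    sub = subpop_assignment(n_acc, config.n_subpops)
    truth_by_trait: dict[str, list[tuple[int, float]]] = {}
    for _, row in truth.iterrows():
        idx = G.snp_index(row.causal_snp_id)
        truth_by_trait.setdefault(row.trait, []).append((idx, float(row.effect_size)))

    acc_arr = np.asarray(G.accessions)
    frames = []
    dosage_imp = G.imputed_dosage()
    for _, g in genes.iterrows():
        for context in CONTEXTS:
            spacing = context_site_spacing(config, context)
            site_pos = np.arange(g.start, g.end, spacing) + 1  # 1-based
            if len(site_pos) == 0:
                continue
            base = config.baselines[context] + float(g.get("baseline_shift", 0.0))
            latent = (base
                      + rng.normal(0.0, config.subpop_effect_sd, config.n_subpops)[sub]
                      + rng.normal(0.0, config.accession_noise_sd, n_acc))
            for snp_i, beta in truth_by_trait.get(trait_id(g.gene_id, context), []):
                dos = dosage_imp[:, snp_i]
                latent = latent + beta * (dos - dos.mean())
            site_eff = rng.normal(0.0, config.site_effect_sd, len(site_pos))
            p = 1.0 / (1.0 + np.exp(-(latent[:, None] + site_eff[None, :])))
            total = rng.poisson(config.coverage_mean, size=p.shape)
            mc = rng.binomial(total, p)
            observed = total > 0
            if config.missing_site_rate > 0:
                observed &= rng.random(p.shape) >= config.missing_site_rate
            acc_i, site_i = np.nonzero(observed)
            frames.append(pd.DataFrame({
                "chrom": g.chrom,
                "pos": site_pos[site_i],
                "strand": "+",
                "context": context,
                "mc_count": mc[acc_i, site_i],
                "total_count": total[acc_i, site_i],
                "accession": acc_arr[acc_i],
            }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context",
                                     "mc_count", "total_count", "accession"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "context", "accession"],
                           kind="stable").reset_index(drop=True)


def realized_pve(trait_values: pd.Series, causal_dosage: np.ndarray) -> float:
    """Fraction of trait variance explained by the causal dosage (OLS R^2).

    Brute-force variance decomposition used to check that planted PVE is
    realized in the simulated methylome.
    """
    y = trait_values.to_numpy(dtype=float)
    ok = ~np.isnan(y) & ~np.isnan(causal_dosage)
    y, x = y[ok], causal_dosage[ok]
    if len(y) < 3 or np.var(x) == 0 or np.var(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(traits: TraitMatrix, links: list[tuple[str, str, float]],
                        config: SimConfig, n_noise_phenotypes: int = 0) -> pd.DataFrame:
    """Quantitative phenotypes with specified correlation to methylation traits.

    Each linked phenotype is ``r * z(trait) + sqrt(1 - r^2) * noise`` on the
    accessions where the trait is observed; unlinked ("noise") phenotypes are
    pure standard normals.  Returns a wide table indexed by accession.
    """
    rng = config.rng("phenotypes")
    out = pd.DataFrame(index=pd.Index(traits.accessions, name="accession"))
    for tid, pid, r in links:
        if abs(r) > 1:
            raise ValueError(f"target correlation {r} outside [-1, 1]")
        if tid not in traits.values.index:
            raise KeyError(f"link references unknown trait {tid!r}")
        y = traits.values.loc[tid].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        z = np.full_like(y, np.nan)
        z[ok] = (y[ok] - y[ok].mean()) / (y[ok].std(ddof=0) or 1.0)
        noise = rng.normal(size=len(y))
        out[pid] = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * noise
    for j in range(n_noise_phenotypes):
        out[f"noise{j:04d}"] = rng.normal(size=len(out))
    if config.phenotype_missing_rate > 0 and len(out.columns):
        miss = rng.random(out.shape) < config.phenotype_missing_rate
        out = out.mask(miss)
    return out


# ---------------------------------------------------------------------------
# annotation tracks
# ---------------------------------------------------------------------------

def simulate_chromatin_states(config: SimConfig, truth: pd.DataFrame | None = None,
                              G: GenotypeMatrix | None = None) -> pd.DataFrame:
    """Chromatin-state tiles partitioning each chromosome (BED-style, 0-based).

    When ``truth`` rows carry an ``enriched_state`` label, tiles containing
    those causal SNPs are assigned that state with probability
    ``enrichment_factor x`` the state's genomic weight, planting a testable
    enrichment of causal SNPs in the state.
    """
    rng = config.rng("annotations")
    k = config.n_chromatin_states
    weights = rng.dirichlet(np.full(k, 20.0))
    states = [f"state_{i + 1}" for i in range(k)]
    rows = []
    for chrom in config.chromosomes:
        edges = np.arange(0, config.chrom_length_bp, config.state_tile_bp)
        starts = edges
        ends = np.append(edges[1:], config.chrom_length_bp)
        labels = rng.choice(k, size=len(starts), p=weights)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                                  "state": [states[i] for i in labels]}))
    track = pd.concat(rows, ignore_index=True)

    if truth is not None and G is not None and len(truth):
        planted = truth.dropna(subset=["enriched_state"]) if "enriched_state" in truth else truth.iloc[0:0]
        # one decision per tile holding causal SNPs, so several causal SNPs
        # in one tile cannot overwrite each other's assignment
        tile_targets: dict[tuple[str, int], str] = {}
        for _, row in planted.iterrows():
            target = row.enriched_state
            if target not in states:
                raise AnnotationError(f"enriched_state {target!r} not a simulated state")
            i = G.snp_index(row.causal_snp_id)
            chrom = str(G.snps.chrom.iloc[i])
            pos0 = int(G.snps.pos.iloc[i]) - 1
            tile_targets[(chrom, pos0 // config.state_tile_bp)] = target
        for (chrom, tile_i), target in sorted(tile_targets.items()):
            w = weights[states.index(target)]
            q = min(config.enrichment_factor * w, 0.95)
            tile = (track.chrom == chrom) \
                & (track.start == tile_i * config.state_tile_bp)
            if rng.random() < q:
                track.loc[tile, "state"] = target
            else:
                others = [s for s in states if s != target]
                ow = np.array([weights[states.index(s)] for s in others])
                track.loc[tile, "state"] = rng.choice(others, p=ow / ow.sum())
    _check_partition(track, config)
    return track


def _check_partition(track: pd.DataFrame, config: SimConfig) -> None:
    for chrom, grp in track.groupby("chrom"):
        grp = grp.sort_values("start")
        if grp.start.iloc[0] != 0 or grp.end.iloc[-1] != config.chrom_length_bp \
                or (grp.start.iloc[1:].to_numpy() != grp.end.iloc[:-1].to_numpy()).any():
            raise AnnotationError(f"chromatin states do not partition {chrom}")


def simulate_annotations(config: SimConfig, truth: pd.DataFrame | None = None,
                         G: GenotypeMatrix | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene models, chromatin-state tiles, and a gene-class feature track."""
    genes = simulate_genes(config)
    states = simulate_chromatin_states(config, truth, G)
    features = genes[["chrom", "start", "end", "nc_class"]].rename(
        columns={"nc_class": "state"})
    return genes, states, features
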