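"""Post-GWAS filter cascade turning significant SNPs into methylQTL calls.

The cascade runs, per trait, in this order:

1. keep SNPs at or below the Bonferroni threshold;
2. density filter: a significant SNP survives only if strictly more than
   ``min_other_neighbors`` other significant SNPs lie within a window of
   total width ``window_bp`` centered on it (default 16 kb, >20 others);
3. gap clustering: consecutive surviving SNPs on the same chromosome are
   grouped while the gap is <= ``gap_bp`` (default 8 kb);
4. trait cap: traits with more than ``max_clusters`` clusters are dropped
   entirely (diffuse signal, likely confounding);
5. representative SNP: the most significant member of each cluster;
6. LD deduplication: processing representatives from most to least
   significant, a cluster is discarded when its representative is in LD
   (r^2 >= ``dedup_r2``) with the representative of an already accepted,
   more significant cluster of the same trait;
7. classification: proximal when the representative lies on the gene's
   chromosome at < ``proximal_bp`` (default 100 kb) from the gene body
   (distance 0 inside the gene), distal otherwise (including other
   chromosomes);
8. PVE: variance explained by the representative SNP, t^2 / (t^2 + df)
   from the whitened single-SNP regression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AssociationResult, GenotypeMatrix, MethylQTL, split_trait_id
from .mlm_association import bonferroni_threshold, ld_r2

__all__ = [
    "QtlCallParams",
    "density_filter",
    "cluster_snps",
    "trait_cluster_filter",
    "pick_representative",
    "ld_dedup",
    "classify_distance",
    "estimate_pve",
    "call_methylqtl",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QtlCallParams:
    """Thresholds of the calling cascade (defaults are the published ones)."""

    alpha: float = 0.01
    window_bp: int = 16_000
    min_other_neighbors: int = 20  # survive iff count of OTHER sig SNPs > this
    gap_bp: int = 8_000
    max_clusters: int = 20
    dedup_r2: float = 0.1
    proximal_bp: int = 100_000

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("window_bp", "gap_bp", "max_clusters", "proximal_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.dedup_r2 <= 1:
            raise ValueError("dedup_r2 must be in [0, 1]")


def _sorted_sig(snps: pd.DataFrame) -> pd.DataFrame:
    if not snps[["chrom", "pos"]].reset_index(drop=True).equals(
            snps[["chrom", "pos"]].sort_values(["chrom", "pos"]).reset_index(drop=True)):
        warnings.warn("significant SNPs were not sorted by (chrom, pos); sorting")
        snps = snps.sort_values(["chrom", "pos"], kind="stable")
    return snps


def density_filter(sig_snps: pd.DataFrame, window_bp: int = 16_000,
                   min_other_neighbors: int = 20) -> pd.DataFrame:
    """Keep significant SNPs with > ``min_other_neighbors`` other significant
    SNPs within +/- ``window_bp``/2 on the same chromosome.

    ``sig_snps`` needs columns ``chrom`` and ``pos``; self is excluded from
    the neighbor count.
    """
    sig_snps = _sorted_sig(sig_snps)
    half = window_bp / 2.0
    keep_parts = []
    for _, grp in sig_snps.groupby("chrom", sort=False):
        pos = grp.pos.to_numpy(dtype=float)
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        others = hi - lo - 1
        keep_parts.append(grp[others > min_other_neighbors])
    if not keep_parts:
        return sig_snps.iloc[0:0]
    return pd.concat(keep_parts)


def cluster_snps(filtered_snps: pd.DataFrame, gap_bp: int = 8_000) -> pd.DataFrame:
    """Group SNPs into clusters: a new cluster opens when the chromosome
    changes or the gap to the previous SNP exceeds ``gap_bp``.

    Returns the input with a ``cluster`` column (0-based, per trait-call).
    """
    if gap_bp <= 0:
        raise ValueError("gap_bp must be > 0")
    snps = _sorted_sig(filtered_snps)
    if snps.empty:
        return snps.assign(cluster=pd.Series(dtype=int))
    chrom_change = snps.chrom.ne(snps.chrom.shift())
    gap = snps.pos.diff()
    new_cluster = chrom_change | (gap > gap_bp)
    return snps.assign(cluster=new_cluster.cumsum().astype(int) - 1)


def trait_cluster_filter(n_clusters: int, max_clusters: int = 20) -> bool:
    """True when a trait with ``n_clusters`` clusters is retained
    (1 <= n <= max_clusters; zero clusters means no signal)."""
    return 1 <= n_clusters <= max_clusters


def pick_representative(cluster: pd.DataFrame) -> pd.Series:
    """The most significant member of a cluster.

    Ties on p are broken by smaller position, then lexicographic SNP id.
    ``cluster`` needs columns ``pos`` and ``p`` and a SNP-id index.
    """
    if cluster["p"].isna().any():
        bad = cluster.index[cluster["p"].isna()].tolist()
        raise ValueError(f"cluster members without p-value: {bad}")
    order = cluster.assign(_id=cluster.index.astype(str)).sort_values(
        ["p", "pos", "_id"], kind="stable")
    return order.iloc[0]


def ld_dedup(representatives: pd.DataFrame, G: GenotypeMatrix,
             r2_min: float = 0.1) -> pd.DataFrame:
    """Greedy LD deduplication of cluster representatives of one trait.

    Representatives are processed in order of increasing p (ties: smaller
    position, then SNP id); one is accepted only if its r^2 with every
    already accepted representative is below ``r2_min``.
    """
    reps = representatives.assign(_id=representatives["snp_id"].astype(str)) \
        .sort_values(["p", "pos", "_id"], kind="stable")
    accepted: list[int] = []
    accepted_dosage: list[np.ndarray] = []
    for row_i, row in enumerate(reps.itertuples()):
        dos = G.dosage[:, G.snp_index(row.snp_id)]
        in_ld = any(ld_r2(dos, prev) >= r2_min for prev in accepted_dosage)
        if not in_ld:
            accepted.append(row_i)
            accepted_dosage.append(dos)
    return reps.iloc[accepted].drop(columns="_id")


def classify_distance(rep_chrom: str, rep_pos: int,
                      gene_interval: tuple[str, int, int],
                      threshold_bp: int = 100_000) -> tuple[float, str]:
    """Distance (bp) from a representative SNP to a gene and its class.

    ``rep_pos`` is 1-based; the gene interval is 0-based half-open.
    Distance is 0 inside the gene body, +inf on another chromosome.
    Proximal requires the same chromosome and distance strictly below
    ``threshold_bp``; the boundary itself is distal.
    """
    chrom, start, end = gene_interval
    if rep_chrom != chrom:
        return float("inf"), "distal"
    p0 = rep_pos - 1
    if start <= p0 < end:
        dist = 0.0
    elif p0 < start:
        dist = float(start - p0)
    else:
        dist = float(p0 - (end - 1))
    return dist, ("proximal" if dist < threshold_bp else "distal")


def estimate_pve(t_stat: float, df: int) -> float:
    """Variance explained by a single SNP: t^2 / (t^2 + df).

    This is the squared partial correlation between the SNP and the
    whitened trait in the scan's GLS regression.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    t2 = float(t_stat) ** 2
    return t2 / (t2 + df)


def call_methylqtl(results: list[AssociationResult], G: GenotypeMatrix,
                   genes: pd.DataFrame, params: QtlCallParams = QtlCallParams(),
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full cascade over per-trait association results.

    ``genes`` needs columns ``gene_id chrom start end`` (0-based half-open).
    Returns (methylQTL table, per-trait stage audit table).
    """
    gene_by_id = genes.set_index("gene_id")
    qtl_rows: list[MethylQTL] = []
    audit_rows = []
    for res in results:
        gene_id, context = split_trait_id(res.trait)
        if gene_id not in gene_by_id.index:
            raise KeyError(f"trait {res.trait!r} references unknown gene {gene_id!r}")
        g = gene_by_id.loc[gene_id]
        thr = bonferroni_threshold(params.alpha, len(res.table))
        sig = res.table[res.table["p"] <= thr].sort_values(["chrom", "pos"])
        sig = sig.rename_axis("snp_id")
        dense = density_filter(sig, params.window_bp, params.min_other_neighbors)
        clustered = cluster_snps(dense, params.gap_bp)
        n_clusters = int(clustered["cluster"].nunique())
        audit = dict(trait=res.trait, n_snps=len(res.table), n_sig=len(sig),
                     n_after_density=len(dense), n_clusters=n_clusters,
                     trait_retained=trait_cluster_filter(n_clusters, params.max_clusters),
                     n_qtl=0)
        if not audit["trait_retained"]:
            audit_rows.append(audit)
            continue
        reps = []
        for cid, members in clustered.groupby("cluster"):
            rep = pick_representative(members)
            reps.append(dict(cluster=cid, snp_id=rep.name, chrom=rep.chrom,
                             pos=int(rep.pos), p=float(rep.p), t=float(rep.t),
                             span_start=int(members.pos.min()),
                             span_end=int(members.pos.max()),
                             n_members=len(members)))
        reps = pd.DataFrame(reps)
        surviving = ld_dedup(reps, G, params.dedup_r2)
        audit["n_qtl"] = len(surviving)
        audit_rows.append(audit)
        for row in surviving.itertuples():
            dist, qcls = classify_distance(
                row.chrom, row.pos, (g.chrom, int(g.start), int(g.end)),
                params.proximal_bp)
            qtl_rows.append(MethylQTL(
                trait=res.trait, gene_id=gene_id, context=context,
                chrom=row.chrom, start=row.span_start, end=row.span_end,
                n_snps=row.n_members, rep_snp=row.snp_id, rep_pos=row.pos,
                p_value=row.p, pve=estimate_pve(row.t, res.df),
                distance_bp=dist, qtl_class=qcls,
                same_chromosome=row.chrom == g.chrom))
    qtl = pd.DataFrame([vars(q) for q in qtl_rows])
    if qtl.empty:
        qtl = pd.DataFrame(columns=["trait", "gene_id", "context", "chrom", "start",
                                    "end", "n_snps", "rep_snp", "rep_pos", "p_value",
                                    "pve", "distance_bp", "qtl_class",
                                    "same_chromosome"])
    audit = pd.DataFrame(audit_rows)
    for row in audit.itertuples():
        logger.info("trait %s: %d sig -> %d after density -> %d clusters -> %d QTL",
                    row.trait, row.n_sig, row.n_after_density, row.n_clusters,
                    row.n_qtl)
    return qtl, audit
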