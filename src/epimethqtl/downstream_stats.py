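"""Downstream statistics: trait-phenotype correlation networks, Fisher
enrichment of representative SNPs in interval tracks, and small reporting
utilities.

Correlations are Pearson r on pairwise-complete observations with the
two-sided p from t = r sqrt((n - 2) / (1 - r^2)) (the ``corr.test``
convention).  Enrichment uses the exact hypergeometric two-sided test on
a 2x2 table of representative vs background SNPs inside vs outside a
feature, with the sample (cross-product) odds ratio and a
Haldane-Anscombe +0.5 correction for zero cells.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import FormatError, TraitMatrix, split_trait_id

__all__ = [
    "correlate_traits",
    "build_network",
    "snp_feature_membership",
    "fisher_enrichment",
    "adjust_pvalues",
    "overlap_with_phenotype_gwas",
    "ddct_relative_abundance",
]

#: published per-variable-family sample-size floors for correlation edges
N_MIN_GEOGRAPHY = 720
N_MIN_PHENOTYPE = 100


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Pairwise-complete Pearson r, n, and two-sided p via the t transform."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < 3:
        return float("nan"), n, float("nan")
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return float("nan"), n, float("nan")
    r = float(np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, n, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, n, float(p)


def correlate_traits(traits: TraitMatrix, variables: pd.DataFrame,
                     p_max: float = 6.08e-5,
                     n_min: int | dict[str, int] = 0,
                     groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Significant Pearson correlations between traits and variables.

    ``variables`` is wide (index accession, one column per variable);
    ``n_min`` may be a single floor or a per-variable mapping (e.g. 720
    for latitude/longitude, 100 for phenotypes).  An edge is kept iff
    p < ``p_max`` and n > its floor.  Returns columns
    ``trait variable r n p group``.
    """
    var = variables.reindex(traits.accessions)
    tv = traits.values.to_numpy(dtype=float)  # traits x accessions
    rows = []
    for col in var.columns:
        y = var[col].to_numpy(dtype=float)
        floor = n_min[col] if isinstance(n_min, dict) else n_min
        for ti, tid in enumerate(traits.values.index):
            r, n, p = pearson_with_p(tv[ti], y)
            if np.isnan(p):
                if n < 3:
                    warnings.warn(f"variable {col!r} x trait {tid!r}: fewer than 3 "
                                  "complete pairs; skipped")
                continue
            if p < p_max and n > floor:
                rows.append((tid, col, r, n, p,
                             (groups or {}).get(col, "ungrouped")))
    return pd.DataFrame(rows, columns=["trait", "variable", "r", "n", "p", "group"])


def build_network(edges: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for a Cytoscape-style correlation network.

    Nodes are the distinct genes behind the traits plus the variables
    (labelled by their group); the edge table is directly importable
    (``source target r p group``).  Per-group edge counts are included on
    the variable nodes.
    """
    if edges.empty:
        nodes = pd.DataFrame(columns=["node", "kind", "group", "n_edges"])
        etab = pd.DataFrame(columns=["source", "target", "r", "p", "group"])
        return nodes, etab
    genes = edges["trait"].map(lambda t: split_trait_id(t)[0])
    etab = pd.DataFrame({"source": genes, "target": edges["variable"],
                         "r": edges["r"], "p": edges["p"], "group": edges["group"]})
    gene_nodes = pd.DataFrame({"node": sorted(genes.unique()), "kind": "gene",
                               "group": "gene"})
    gene_nodes["n_edges"] = gene_nodes["node"].map(etab.groupby("source").size())
    var_counts = etab.groupby(["target", "group"]).size().reset_index(name="n_edges")
    var_nodes = var_counts.rename(columns={"target": "node"}).assign(kind="variable")
    nodes = pd.concat([gene_nodes, var_nodes[["node", "kind", "group", "n_edges"]]],
                      ignore_index=True)
    return nodes, etab


def _merged_track(track: pd.DataFrame, flank_bp: int = 0,
                  flank_features: set[str] | None = None) -> dict[str, pd.DataFrame]:
    """Per-feature merged intervals (0-based half-open), optionally flanked."""
    out = {}
    for feat, grp in track.groupby("state" if "state" in track else "feature"):
        df = grp.copy()
        if flank_bp and (flank_features is None or feat in flank_features):
            df["start"] = np.maximum(df["start"] - flank_bp, 0)
            df["end"] = df["end"] + flank_bp
        p = pr.PyRanges(pd.DataFrame({"Chromosome": df["chrom"].to_numpy(),
                                      "Start": df["start"].to_numpy(),
                                      "End": df["end"].to_numpy()})).merge()
        out[feat] = p.df
    return out


def snp_feature_membership(snps: pd.DataFrame, track: pd.DataFrame,
                           gene_flank_bp: int = 0,
                           flank_features: set[str] | None = None) -> pd.DataFrame:
    """Boolean membership of SNPs (1-based ``pos``) in each feature of a track.

    ``track`` has columns ``chrom start end`` and a feature label column
    (``state`` or ``feature``), 0-based half-open.  When ``gene_flank_bp``
    is set, intervals (of the listed features, or all) are extended by that
    many bp on both sides before testing; overlapping intervals of the same
    feature are merged.
    """
    track_chroms = set(track["chrom"].unique())
    snp_chroms = set(snps["chrom"].unique())
    if snp_chroms - track_chroms and not snp_chroms & track_chroms:
        raise FormatError(
            "no chromosome name shared between SNPs and track; offenders: "
            f"{sorted(snp_chroms - track_chroms)}")
    pos0 = snps["pos"].to_numpy() - 1
    chrom = snps["chrom"].to_numpy()
    out = pd.DataFrame(index=snps.index)
    for feat, ivals in _merged_track(track, gene_flank_bp, flank_features).items():
        member = np.zeros(len(snps), dtype=bool)
        for c, grp in ivals.groupby("Chromosome", observed=True):
            starts = grp["Start"].to_numpy()
            ends = grp["End"].to_numpy()
            sel = chrom == c
            if not sel.any():
                continue
            p = pos0[sel]
            # merged intervals are disjoint and sorted: searchsorted test
            i = np.searchsorted(starts, p, side="right") - 1
            inside = (i >= 0) & (p < ends[np.clip(i, 0, len(ends) - 1)])
            member[sel] = inside
        out[feat] = member
    return out


def fisher_enrichment(rep_snps: pd.DataFrame, background_snps: pd.DataFrame,
                      track: pd.DataFrame, gene_flank_bp: int = 0,
                      flank_features: set[str] | None = None,
                      disjoint_background: bool = True,
                      adjust: str = "benjamini_hochberg") -> pd.DataFrame:
    """Fisher's exact enrichment of representative SNPs in each feature.

    The 2x2 table per feature is (representative in / out) vs (background
    in / out); with ``disjoint_background`` (default) the representative
    SNPs are removed from the background so the cells are disjoint.  The
    odds ratio is the sample (ad)/(bc) with +0.5 added to every cell when
    any cell is zero; p is the exact two-sided hypergeometric probability.
    """
    rep_ids = set(rep_snps["chrom"].astype(str) + "_" + rep_snps["pos"].astype(str))
    bg_ids = set(background_snps["chrom"].astype(str) + "_"
                 + background_snps["pos"].astype(str))
    if not rep_ids <= bg_ids:
        raise ValueError("representative SNPs must be a subset of the background")
    bg = background_snps
    if disjoint_background:
        key = bg["chrom"].astype(str) + "_" + bg["pos"].astype(str)
        bg = bg[~key.isin(rep_ids)]
    rep_member = snp_feature_membership(rep_snps, track, gene_flank_bp, flank_features)
    bg_member = snp_feature_membership(bg, track, gene_flank_bp, flank_features)
    rows = []
    for feat in rep_member.columns:
        a = int(rep_member[feat].sum())
        b = len(rep_snps) - a
        c = int(bg_member[feat].sum())
        d = len(bg) - c
        if c + a == 0:
            rows.append((feat, a, b, c, d, float("nan"), float("nan")))
            continue
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        else:
            orr = a * d / (b * c)
        rows.append((feat, a, b, c, d, float(orr), float(p)))
    out = pd.DataFrame(rows, columns=["feature", "a", "b", "c", "d",
                                      "odds_ratio", "p"])
    valid = ~out["p"].isna()
    out["p_adj"] = np.nan
    if valid.any():
        out.loc[valid, "p_adj"] = adjust_pvalues(out.loc[valid, "p"].to_numpy(),
                                                 method=adjust)
    return out


def adjust_pvalues(p, method: str = "benjamini_hochberg") -> np.ndarray:
    """Multiple-testing adjustment (BH step-up by default, Bonferroni option)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    key = {"benjamini_hochberg": "fdr_bh", "bh": "fdr_bh",
           "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def overlap_with_phenotype_gwas(methyl_sig: pd.DataFrame, pheno_sig: pd.DataFrame,
                                correlated_pairs: pd.DataFrame | None = None
                                ) -> pd.DataFrame:
    """SNPs detected by both a methylation scan and a phenotype scan.

    Inputs are long tables with columns ``trait snp_id`` (methylation) and
    ``phenotype snp_id``; when ``correlated_pairs`` (columns ``trait
    variable``) is given, only correlated (trait, phenotype) pairs are
    intersected.  Returns ``trait phenotype n_shared shared_snps``.
    """
    rows = []
    m_sets = methyl_sig.groupby("trait")["snp_id"].agg(set)
    p_sets = pheno_sig.groupby("phenotype")["snp_id"].agg(set)
    if correlated_pairs is not None:
        pairs = [(t, v) for t, v in
                 correlated_pairs[["trait", "variable"]].itertuples(index=False)]
    else:
        pairs = [(t, v) for t in m_sets.index for v in p_sets.index]
    for t, v in pairs:
        shared = sorted(m_sets.get(t, set()) & p_sets.get(v, set()))
        if shared:
            rows.append((t, v, len(shared), ",".join(map(str, shared))))
    return pd.DataFrame(rows, columns=["trait", "phenotype", "n_shared",
                                       "shared_snps"])


def ddct_relative_abundance(ct_target: float, ct_reference: float,
                            ct_target_calibrator: float,
                            ct_reference_calibrator: float) -> float:
    """Relative transcript abundance by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference) per sample; ddCt subtracts the
    calibrator's dCt; the fold level is 2^-ddCt (1.0 means equal to the
    calibrator).
    """
    for v in (ct_target, ct_reference, ct_target_calibrator, ct_reference_calibrator):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target - ct_reference) - (ct_target_calibrator - ct_reference_calibrator)
    return float(2.0 ** (-ddct))
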