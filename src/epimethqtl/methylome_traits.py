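"""Per-gene methylation traits from site-level bisulfite counts.

Site-level (methylated, total) read counts are filtered on coverage,
aggregated to per-gene per-context methylation percentages, filtered on
missing rate across the cohort, and profiled with the coefficient of
variation (CV).  Two aggregation modes are provided:

* ``site_mean`` (default): mean over in-gene sites of mc/total x 100,
  the per-site-average a BEDtools ``map -o mean`` workflow produces;
* ``weighted``: sum(mc) / sum(total) x 100, the coverage-weighted level.

Strand is ignored for level computation: the context labels already
encode the strand-resolved cytosine classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pyranges as pr

from .containers import CONTEXTS, AnnotationError, TraitMatrix, trait_id

__all__ = [
    "filter_sites",
    "gene_context_methylation",
    "build_trait_matrix",
    "coefficient_of_variation",
    "class_summary",
]

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "mc_count", "total_count", "accession"]


def filter_sites(sites: pd.DataFrame, min_total: int = 5) -> pd.DataFrame:
    """Keep cytosine sites with total coverage >= ``min_total`` reads.

    The default of 5 reads implements the "coverage greater than 4" rule:
    a site covered by exactly 4 reads is discarded.  Row order is preserved.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    return sites[sites["total_count"] >= min_total]


def _assign_sites_to_genes(sites: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Interval-join sites (1-based pos) onto gene bodies (0-based half-open).

    Returns the site table with a ``gene_id`` column; sites outside every
    gene are dropped.  A site overlapping several genes contributes to each.
    """
    if sites.empty or genes.empty:
        return sites.iloc[0:0].assign(gene_id=pd.Series(dtype=object))
    s = pd.DataFrame({
        "Chromosome": sites["chrom"].to_numpy(),
        "Start": sites["pos"].to_numpy() - 1,
        "End": sites["pos"].to_numpy(),
        "row": np.arange(len(sites)),
    })
    g = pd.DataFrame({
        "Chromosome": genes["chrom"].to_numpy(),
        "Start": genes["start"].to_numpy(),
        "End": genes["end"].to_numpy(),
        "gene_id": genes["gene_id"].to_numpy(),
    })
    joined = pr.PyRanges(s).join(pr.PyRanges(g)).df
    if joined.empty:
        return sites.iloc[0:0].assign(gene_id=pd.Series(dtype=object))
    out = sites.iloc[joined["row"].to_numpy()].copy()
    out["gene_id"] = joined["gene_id"].to_numpy()
    return out


def _aggregate(grp_mc: np.ndarray, grp_total: np.ndarray, mode: str) -> float:
    if mode == "site_mean":
        return float(np.mean(grp_mc / grp_total) * 100.0)
    if mode == "weighted":
        return float(grp_mc.sum() / grp_total.sum() * 100.0)
    raise ValueError(f"unknown aggregation mode {mode!r}")


def gene_context_methylation(sites: pd.DataFrame, gene_interval: tuple[str, int, int],
                             context: str, mode: str = "site_mean") -> pd.Series:
    """Methylation percentage of one gene in one context, per accession.

    ``gene_interval`` is (chrom, start, end), 0-based half-open.  Accessions
    with no qualifying site get NaN (absence of data, not zero methylation).
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    if mode not in ("site_mean", "weighted"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    chrom, start, end = gene_interval
    sub = sites[(sites["chrom"] == chrom) & (sites["context"] == context)
                & (sites["pos"] > start) & (sites["pos"] <= end)]
    if sub.empty:
        return pd.Series(dtype=float, name="methylation_pct")
    out = sub.groupby("accession", sort=True).apply(
        lambda d: _aggregate(d["mc_count"].to_numpy(dtype=float),
                             d["total_count"].to_numpy(dtype=float), mode),
        include_groups=False,
    )
    out.name = "methylation_pct"
    return out


def build_trait_matrix(sites: pd.DataFrame, genes: pd.DataFrame,
                       contexts: tuple[str, ...] = CONTEXTS,
                       max_missing_rate: float = 0.10,
                       mode: str = "site_mean",
                       accessions: list[str] | None = None,
                       min_total: int | None = None) -> TraitMatrix:
    """Aggregate a cohort site table into a filtered trait matrix.

    A trait (gene, context) is retained when its number of accessions with
    missing values satisfies ``missing_count <= floor(max_missing_rate * n)``
    (with n accessions and the default rate of 0.10 this is the "missing
    rate <= 10%" rule).  When ``min_total`` is given, ``filter_sites`` is
    applied first.
    """
    if not 0.0 <= max_missing_rate <= 1.0:
        raise ValueError("max_missing_rate must be in [0, 1]")
    for c in contexts:
        if c not in CONTEXTS:
            raise ValueError(f"unknown context {c!r}")
    if accessions is None:
        accessions = sorted(sites["accession"].unique())
    if len(accessions) == 0:
        raise ValueError("no accessions in site table")
    if min_total is not None:
        sites = filter_sites(sites, min_total)

    annotated = _assign_sites_to_genes(sites[sites["context"].isin(contexts)], genes)
    n_acc = len(accessions)
    if annotated.empty:
        values = pd.DataFrame(columns=accessions)
    else:
        frac = annotated["mc_count"].to_numpy(dtype=float) / annotated["total_count"].to_numpy(dtype=float)
        work = annotated.assign(frac=frac)
        grp = work.groupby(["gene_id", "context", "accession"], sort=True, observed=True)
        if mode == "site_mean":
            level = grp["frac"].mean() * 100.0
        elif mode == "weighted":
            agg = grp[["mc_count", "total_count"]].sum()
            level = agg["mc_count"] / agg["total_count"] * 100.0
        else:
            raise ValueError(f"unknown aggregation mode {mode!r}")
        values = level.unstack("accession")
        values.index = [trait_id(g, c) for g, c in values.index]
        values = values.reindex(columns=accessions)

    missing_count = values.isna().sum(axis=1) + 0  # NaN where no site at all
    max_missing = int(np.floor(max_missing_rate * n_acc))
    keep = missing_count <= max_missing
    values = values.loc[keep]

    meta = _trait_metadata(values, n_acc)
    return TraitMatrix(values=values, meta=meta)


def _trait_metadata(values: pd.DataFrame, n_accessions: int) -> pd.DataFrame:
    from .containers import split_trait_id

    rows = []
    for tid, row in values.iterrows():
        gene, context = split_trait_id(tid)
        v = row.to_numpy(dtype=float)
        n_obs = int(np.sum(~np.isnan(v)))
        cv = coefficient_of_variation(v)
        rows.append((tid, gene, context, n_obs, 1.0 - n_obs / n_accessions,
                     cv, not np.isnan(cv)))
    return pd.DataFrame(rows, columns=["trait", "gene_id", "context", "n_non_missing",
                                       "missing_rate", "cv_percent", "cv_defined"]
                        ).set_index("trait")


def coefficient_of_variation(values: np.ndarray | pd.Series) -> float:
    """CV% = sample standard deviation / mean x 100, over non-missing values.

    Returns NaN (an "undefined CV" flag, not an exception) when the mean is
    zero or fewer than two values are observed.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        return float("nan")
    m = v.mean()
    if m == 0:
        return float("nan")
    return float(v.std(ddof=1) / m * 100.0)


def class_summary(traits: TraitMatrix, gene_classes: pd.Series | dict) -> pd.DataFrame:
    """Per-accession mean methylation of each gene class in each context.

    ``gene_classes`` maps gene_id -> class label; every gene present in the
    trait matrix must be covered.  Returns a long table with columns
    ``accession nc_class context mean_methylation_pct n_genes``.
    """
    classes = pd.Series(gene_classes)
    meta = traits.meta
    missing = sorted(set(meta["gene_id"]) - set(classes.index))
    if missing:
        raise AnnotationError(f"genes without class label: {', '.join(missing)}")
    cls = meta["gene_id"].map(classes)
    rows = []
    for (c, ctx), tids in traits.meta.groupby([cls, meta["context"]], observed=True).groups.items():
        block = traits.values.loc[list(tids)]
        means = block.mean(axis=0, skipna=True)
        n_genes = block.notna().sum(axis=0)
        for acc in block.columns:
            rows.append((acc, c, ctx, means[acc], int(n_genes[acc])))
    return pd.DataFrame(rows, columns=["accession", "nc_class", "context",
                                       "mean_methylation_pct", "n_genes"])
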