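import numpy as np
import pandas as pd
import pytest

import epimethqtl as eq
from epimethqtl.containers import TraitMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """A small structured cohort shared by read-only tests."""
    cfg = eq.SimConfig(n_accessions=120, n_snps=800, seed=42,
                       genes=(eq.GeneSpec("GA", "lncRNA"),
                              eq.GeneSpec("GB", "miRNA")))
    G = eq.simulate_genotypes(cfg)
    genes = eq.simulate_genes(cfg)
    return cfg, G, genes


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with one cis QTL (PVE 0.25) shared by read-only tests."""
    cfg = eq.SimConfig(n_accessions=300, n_snps=1500, seed=7,
                       genes=(eq.GeneSpec("GA", "lncRNA"),))
    G = eq.simulate_genotypes(cfg)
    genes = eq.simulate_genes(cfg)
    truth = eq.make_truth(G, genes, [eq.QtlSpec("GA", "CG", "cis", 0.25)], cfg)
    sites = eq.simulate_methylome(G, genes, truth, cfg)
    traits = eq.build_trait_matrix(sites, genes, min_total=5)
    return cfg, G, genes, truth, sites, traits


def make_trait_matrix(values: dict[str, list[float]], accessions=None) -> TraitMatrix:
    """Build a TraitMatrix literal for unit tests.

    ``values`` maps trait id -> per-accession values (NaN for missing).
    """
    df = pd.DataFrame(values).T
    if accessions is None:
        accessions = [f"a{i}" for i in range(df.shape[1])]
    df.columns = accessions
    from epimethqtl.methylome_traits import _trait_metadata

    return TraitMatrix(values=df, meta=_trait_metadata(df, len(accessions)))


def assoc_from_pvalues(trait, chrom, pos, p, t=None, df=100):
    """AssociationResult literal for cascade unit tests."""
    idx = [f"{c}_{x}" for c, x in zip(chrom, pos)]
    n = len(pos)
    tt = t if t is not None else np.full(n, 5.0)
    table = pd.DataFrame({"chrom": chrom, "pos": pos,
                          "beta": np.ones(n), "se": np.ones(n),
                          "t": tt, "p": p},
                         index=pd.Index(idx, name="snp_id"))
    from epimethqtl.containers import AssociationResult

    return AssociationResult(trait=trait, table=table, lambda_gc=1.0,
                             n_used=df + 2, df=df)
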