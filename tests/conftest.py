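import numpy as np
import pandas as pd
import pytest

from bidipair.annotation import GeneModel, GeneRecord
from bidipair.simulate import gen_annotation, gen_counts


def make_gene(gene_id, chrom, strand, start, end, gene_type="protein_coding"):
    return GeneRecord(
        gene_id=gene_id, gene_type=gene_type, chrom=chrom, strand=strand,
        start=start, end=end,
    )


@pytest.fixture
def tiny_model():
    """Hand-placed genes covering each pair geometry on one chromosome.

    Distant placement (> 10 kb between unrelated blocks) keeps the blocks
    independent.
    """
    genes = [
        # head-to-head: minus then plus, TSS gap 300
        make_gene("BG.m", "chr1", "-", 1000, 2000),
        make_gene("BG.p", "chr1", "+", 2300, 4000),
        # tail-to-tail: plus then minus, TES gap 400
        make_gene("CG1.p", "chr1", "+", 101000, 102000),
        make_gene("CG1.m", "chr1", "-", 102400, 103000),
        # tandem: gap 2000
        make_gene("CG2.a", "chr1", "+", 201000, 202000),
        make_gene("CG2.b", "chr1", "+", 204000, 206000),
        # nested: inner fully inside outer
        make_gene("NEST.outer", "chr1", "+", 301000, 305000),
        make_gene("NEST.inner", "chr1", "-", 302000, 303000),
        # singleton
        make_gene("LONE", "chr1", "+", 401000, 403000, "lincRNA"),
    ]
    return GeneModel(genes)


@pytest.fixture(scope="session")
def planted_annotation():
    """Default planted annotation (seed 0) with its truth table."""
    gtf_text, truth = gen_annotation(seed=0)
    return gtf_text, truth


@pytest.fixture(scope="session")
def planted_counts():
    """Counts + truth with planted DE on a small planted annotation."""
    _, truth = gen_annotation(
        n_bg=40, n_cg1=0, n_cg2=0, n_nested=0, n_singleton=120, seed=3
    )
    counts, group = gen_counts(
        truth, n_tumor=20, n_normal=20, de_frac=0.25, pair_coupling=1.0,
        seed=3,
    )
    return truth, counts, group


def nb_matrix(rng, n_genes, n_tumor, n_normal, dispersion=0.1, de_frac=0.0,
              lfc=2.0, mean_log=np.log(100.0), lib_sd=0.3):
    """Independent NB count simulator used as test input (not the package's
    generator): lognormal baselines, lognormal depths, gamma-Poisson counts.

    Returns (counts DataFrame, group list, true log2fc vector).
    """
    g, n = n_genes, n_tumor + n_normal
    base = np.exp(rng.normal(mean_log, 1.5, g))
    lib = np.exp(rng.normal(0, lib_sd, n))
    log2fc = np.zeros(g)
    nde = int(round(de_frac * g))
    if nde:
        idx = rng.choice(g, nde, replace=False)
        log2fc[idx] = np.where(rng.random(nde) < 0.5, lfc, -lfc)
    mu = np.outer(base, lib)
    mu[:, :n_tumor] *= 2.0 ** log2fc[:, None]
    shape = 1.0 / dispersion
    y = rng.poisson(rng.gamma(shape, 1.0, mu.shape) * mu / shape)
    counts = pd.DataFrame(y, columns=[f"s{i}" for i in range(n)])
    counts.index = [f"g{i}" for i in range(g)]
    group = ["tumor"] * n_tumor + ["normal"] * n_normal
    return counts, group, log2fc
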