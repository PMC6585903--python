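import subprocess

import numpy as np
import pandas as pd
import pytest

from bidipair.methylation import (
    annotate_probes,
    call_dmps,
    dataset_has_enough_normals,
    meth_correlated_genes,
    meth_pair_combos,
    promoter_window,
)
from bidipair.pairs import GenePair

from conftest import make_gene


@pytest.mark.parametrize(
    "strand,tss_pos,span,expected",
    [
        ("+", 10000, (10000, 20000), (8000, 10500)),
        ("-", 10000, (5000, 10000), (9500, 12000)),
        ("+", 100, (100, 5000), (1, 600)),  # clipped at chromosome start
    ],
)
def test_promoter_window(strand, tss_pos, span, expected):
    g = make_gene("G.1", "chr1", strand, *span)
    assert g.tss == tss_pos
    assert promoter_window(g) == expected


def test_annotate_probes_boundaries_and_multimap():
    genes = [
        make_gene("G1.1", "chr1", "+", 10000, 20000),   # promoter 8000-10500
        make_gene("G2.1", "chr1", "-", 2000, 8200),     # promoter 7700-10200
    ]
    from bidipair.annotation import GeneModel

    model = GeneModel(genes)
    probes = pd.DataFrame(
        {
            "probe_id": ["p_in", "p_edge_out", "p_both", "p_chr"],
            "chrom": ["chr1", "chr1", "chr1", "chrX"],
            "pos": [9000, 7999, 10100, 9000],
        }
    )
    m = annotate_probes(probes, model)
    assert m["p_in"] == ["G2.1", "G1.1"] or set(m["p_in"]) == {"G1.1", "G2.1"}
    assert "p_edge_out" not in m or "G1.1" not in m.get("p_edge_out", [])
    assert set(m["p_both"]) == {"G1.1", "G2.1"}
    assert "p_chr" not in m


def test_annotate_probes_matches_brute_force(planted_annotation):
    _, truth = planted_annotation
    model = truth.gene_model()
    rng = np.random.default_rng(0)
    genes = list(model)[:80]
    probes = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(200)],
            "chrom": [g.chrom for g in rng.choice(genes, 200)],
            "pos": rng.integers(1, 2_000_000, 200),
        }
    )
    got = annotate_probes(probes, model)
    for r in probes.itertuples(index=False):
        expected = sorted(
            g.gene_id for g in model
            if g.chrom == r.chrom
            and promoter_window(g)[0] <= r.pos <= promoter_window(g)[1]
        )
        assert sorted(got.get(r.probe_id, [])) == expected


def _beta_fixture(seed=0, n1=10, n2=10, n_probes=300, shift_first=0):
    rng = np.random.default_rng(seed)
    mu = rng.normal(0, 1.5, n_probes)
    logits = mu[:, None] + rng.normal(0, 0.5, (n_probes, n1 + n2))
    beta = 1 / (1 + np.exp(-logits))
    if shift_first:
        beta[:shift_first, :n1] = np.clip(
            beta[:shift_first, :n1] + 0.25, 0.005, 0.995
        )
    frame = pd.DataFrame(
        beta, index=[f"p{i}" for i in range(n_probes)],
        columns=[f"s{i}" for i in range(n1 + n2)],
    )
    return frame, ["tumor"] * n1 + ["normal"] * n2


def test_call_dmps_direction_sign_consistency():
    beta, group = _beta_fixture(seed=1, shift_first=30)
    dmp = call_dmps(beta, group)
    hypo = dmp[dmp["direction"] == "hypo"]
    hyper = dmp[dmp["direction"] == "hyper"]
    assert (hypo["delta_beta"] < 0).all() and (hypo["adj_p"] <= 0.05).all()
    assert (hyper["delta_beta"] > 0).all() and (hyper["adj_p"] <= 0.05).all()
    assert (dmp.loc[[f"p{i}" for i in range(30)], "direction"] == "hyper").mean() > 0.8


def test_call_dmps_group_invariant_shift_yields_nothing():
    beta, group = _beta_fixture(seed=2)
    shifted = (beta + 0.1).clip(upper=1.0)  # same shift for every sample
    dmp = call_dmps(shifted, group)
    assert (dmp["direction"] == "ns").all()


def test_call_dmps_zero_variance_probe():
    beta, group = _beta_fixture(seed=3, n_probes=50)
    beta.iloc[0] = 0.5
    dmp = call_dmps(beta, group)
    # shrunk variance keeps the test defined; a flat probe is never called
    assert dmp.iloc[0]["direction"] == "ns"
    with pytest.raises(ValueError):
        call_dmps(beta + 1.0, group)


def test_call_dmps_tracks_limma_reference(tmp_path):
    """The moderated t analogue should closely track limma's eBayes
    moderated t on the same matrix (independent reference, loose bound)."""
    beta, group = _beta_fixture(seed=4, n1=8, n2=6, n_probes=200,
                                shift_first=10)
    path = tmp_path / "beta.tsv"
    beta.to_csv(path, sep="\t", index=False)
    script = (
        'suppressMessages(library(limma));'
        f'x <- as.matrix(read.delim("{path}"));'
        'design <- model.matrix(~factor(rep(c("t","n"),c(8,6)),'
        'levels=c("n","t")));'
        'fit <- eBayes(lmFit(x, design));'
        'cat(fit$p.value[,2], sep="\\n")'
    )
    try:
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True,
            timeout=120, check=True,
        )
    except (FileNotFoundError, subprocess.SubprocessError) as exc:
        pytest.fail(f"limma oracle unavailable: {exc}")
    limma_p = np.array([float(v) for v in res.stdout.split()])
    ours = call_dmps(beta, group)["pvalue"].to_numpy()
    assert np.allclose(ours, limma_p, atol=5e-3)


def _corr_inputs():
    de = pd.DataFrame(
        {
            "status": ["up", "up", "down", "ns"],
            "expressed": [True, True, True, True],
        },
        index=["gU1", "gU2", "gD", "gN"],
    )
    dmp = pd.DataFrame(
        {
            "direction": ["hypo", "hyper", "hyper", "hypo"],
            "delta_beta": [-0.2, 0.2, 0.2, -0.2],
        },
        index=["pA", "pB", "pC", "pD"],
    )
    probe_map = {"pA": ["gU1"], "pB": ["gU2"], "pC": ["gD"], "pD": ["gN"]}
    return de, dmp, probe_map


def test_meth_correlated_rule():
    de, dmp, probe_map = _corr_inputs()
    corr = meth_correlated_genes(de, dmp, probe_map)
    assert corr.loc["gU1", "basis"] == "up_with_hypo"
    assert corr.loc["gU2", "basis"] == "none"   # up gene, only hyper probe
    assert corr.loc["gD", "basis"] == "down_with_hyper"
    assert corr.loc["gN", "basis"] == "none"    # ns gene never correlated
    assert corr["meth_correlated"].equals(corr["basis"] != "none")


def test_meth_correlated_monotone_in_probes():
    de, dmp, probe_map = _corr_inputs()
    base = meth_correlated_genes(de, dmp, probe_map)
    richer = {**probe_map, "pD": ["gN", "gU2"]}
    dmp2 = dmp.copy()
    dmp2.loc["pB", "direction"] = "hypo"  # add a qualifying probe for gU2
    more = meth_correlated_genes(de, dmp2, richer)
    flagged_before = set(base.index[base["meth_correlated"]])
    flagged_after = set(more.index[more["meth_correlated"]])
    assert flagged_before <= flagged_after


def test_meth_pair_combos():
    corr = pd.DataFrame(
        {
            "basis": ["up_with_hypo", "up_with_hypo", "down_with_hyper",
                      "down_with_hyper", "up_with_hypo", "none", "none",
                      "none"],
        },
        index=list("abcdefgh"),
    )
    corr["meth_correlated"] = corr["basis"] != "none"
    pairs = [
        GenePair("a", "b", "BG"),   # both hypo
        GenePair("c", "d", "BG"),   # both hyper
        GenePair("e", "f", "BG"),   # one
        GenePair("g", "h", "BG"),   # none
    ]
    tbl = meth_pair_combos(pairs, corr).set_index("combo")["count"]
    assert tbl["both_hypo"] == 1
    assert tbl["both_hyper"] == 1
    assert tbl["one"] == 1
    assert tbl["none"] == 1
    assert tbl.sum() == 4


def test_methylation_normal_sample_rule():
    assert dataset_has_enough_normals(3)
    assert not dataset_has_enough_normals(2)
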