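import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bidipair.expression import (
    DEConfig,
    bh_adjust,
    cpm,
    de_test_threshold,
    eligible_dataset,
    filter_expressed,
    ruv_lite,
    run_de,
    tmm_factors,
)

from _oracles import bh_oracle
from conftest import nb_matrix


# ---------------------------------------------------------------- cpm


def test_cpm_values_and_scale_invariance():
    counts = pd.DataFrame(
        {"a": [5, 999995], "b": [10, 90]}, index=["g1", "g2"]
    )
    c = cpm(counts)
    assert c.loc["g1", "a"] == pytest.approx(5.0)
    doubled = cpm(counts * 2)
    pd.testing.assert_frame_equal(c, doubled)
    with pytest.raises(ValueError):
        cpm(pd.DataFrame({"a": [0, 0]}))


def test_filter_expressed_threshold_and_oracle():
    counts = pd.DataFrame(
        [[200, 200, 50], [0, 0, 0], [1000, 0, 0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3"],
    )
    # library sizes make CPM interpretable: g1 CPM = (0.2M-scaled)
    flags = filter_expressed(counts, n_normal=2, cpm_threshold=0.1)
    assert flags["g1"]
    assert not flags["g2"]
    assert not flags["g3"]  # above threshold in only one sample
    with pytest.raises(ValueError):
        filter_expressed(counts, n_normal=4)


def test_filter_expressed_matches_brute_force_count():
    rng = np.random.default_rng(11)
    counts, group, _ = nb_matrix(rng, 400, 5, 5)
    zero = rng.choice(400, 120, replace=False)
    counts.iloc[zero] = 0
    flags = filter_expressed(counts, n_normal=5)
    c = counts.to_numpy() / counts.sum().to_numpy() * 1e6
    expected = (c >= 0.1).sum(axis=1) >= 5
    assert (flags.to_numpy() == expected).all()
    assert not flags.iloc[zero].any()


# ---------------------------------------------------------------- TMM


def test_tmm_identity_cases():
    counts = pd.DataFrame(
        np.tile([[10], [200], [3000]], (1, 3)), columns=list("abc")
    )
    assert np.allclose(tmm_factors(counts), 1.0)
    two = pd.DataFrame({"a": [10, 200, 3000], "b": [20, 400, 6000]})
    assert np.allclose(tmm_factors(two), 1.0)


def test_tmm_log_mean_zero_and_null_simulation():
    rng = np.random.default_rng(2)
    counts, _, _ = nb_matrix(rng, 3000, 4, 4, lib_sd=0.6)
    f = tmm_factors(counts)
    assert np.mean(np.log(f)) == pytest.approx(0.0, abs=1e-12)
    assert np.all(np.abs(f - 1.0) < 0.05)  # no DE: factors near 1


def test_tmm_matches_edger_oracle(tmp_path):
    """Independent cross-check of the doubly trimmed weighted mean against
    the reference implementation in edgeR."""
    rng = np.random.default_rng(7)
    counts, _, _ = nb_matrix(rng, 400, 3, 2, lib_sd=0.5)
    path = tmp_path / "counts.tsv"
    counts.to_csv(path, sep="\t", index=False)
    script = (
        'suppressMessages(library(edgeR));'
        f'x <- as.matrix(read.delim("{path}"));'
        'cat(calcNormFactors(x, method="TMM"), sep="\\n")'
    )
    try:
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True,
            timeout=120, check=True,
        )
    except (FileNotFoundError, subprocess.SubprocessError) as exc:
        pytest.fail(f"edgeR oracle unavailable: {exc}")
    r_factors = np.array([float(v) for v in res.stdout.split()])
    assert np.allclose(tmm_factors(counts).to_numpy(), r_factors, atol=1e-6)


# ---------------------------------------------------------------- RUV


def test_ruv_lite_identity_and_errors():
    rng = np.random.default_rng(0)
    mat = pd.DataFrame(rng.normal(size=(30, 8)),
                       index=[f"g{i}" for i in range(30)])
    assert ruv_lite(mat, [], k=0).shape == (8, 0)
    with pytest.raises(KeyError):
        ruv_lite(mat, ["missing"], k=1)
    with pytest.raises(ValueError):
        ruv_lite(mat.iloc[:2], ["g0", "g1"], k=2)


def test_ruv_lite_separates_planted_batches():
    rng = np.random.default_rng(1)
    mat = rng.normal(size=(100, 12))
    batch = np.zeros(12, dtype=bool)
    batch[6:] = True
    mat[:, batch] += 2.0  # global mean shift on half the samples
    frame = pd.DataFrame(mat, index=[f"g{i}" for i in range(100)])
    scores = ruv_lite(frame, [f"g{i}" for i in range(50)], k=1)
    s = scores["ruv_1"].to_numpy()
    assert max(s[batch].min(), s[~batch].min()) > min(
        s[batch].max(), s[~batch].max()
    )  # perfect rank separation between batches


# ---------------------------------------------------------------- BH


def test_bh_hand_example_and_edge_cases():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert bh_adjust([]).size == 0
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(max_examples=150, derandomize=True)
@given(
    st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40)
)
def test_bh_matches_quadratic_oracle(pvals):
    assert np.allclose(bh_adjust(pvals), bh_oracle(pvals))


# ---------------------------------------------------------------- DE test


def test_de_no_signal_gene_is_ns():
    rng = np.random.default_rng(4)
    counts, group, _ = nb_matrix(rng, 300, 10, 10)
    de = de_test_threshold(counts, group)
    assert set(de["status"]) <= {"ns", "up", "down"}
    assert (de["status"] == "ns").mean() > 0.95


def test_de_label_swap_antisymmetry():
    rng = np.random.default_rng(5)
    counts, group, _ = nb_matrix(rng, 200, 6, 6, de_frac=0.2)
    factors = tmm_factors(counts)
    de1 = de_test_threshold(counts, group, factors)
    swapped = ["normal" if g == "tumor" else "tumor" for g in group]
    de2 = de_test_threshold(counts, swapped, factors)
    assert np.allclose(de1["log2fc"], -de2["log2fc"])
    flip = {"up": "down", "down": "up", "ns": "ns"}
    assert list(de2["status"]) == [flip[s] for s in de1["status"]]


def test_de_threshold_monotonicity():
    rng = np.random.default_rng(6)
    counts, group, _ = nb_matrix(rng, 500, 10, 10, de_frac=0.2, lfc=1.5)
    factors = tmm_factors(counts)
    n_calls = []
    for fc in (1.2, 1.5, 2.0, 3.0):
        cfg = DEConfig(fc_threshold=fc, down_threshold=1.0 / fc)
        de = de_test_threshold(counts, group, factors, cfg)
        n_calls.append(int(de["status"].isin(["up", "down"]).sum()))
    assert n_calls == sorted(n_calls, reverse=True)


def test_de_status_invariants():
    rng = np.random.default_rng(7)
    counts, group, _ = nb_matrix(rng, 400, 10, 10, de_frac=0.15)
    de = de_test_threshold(counts, group)
    up = de[de["status"] == "up"]
    down = de[de["status"] == "down"]
    assert (up["fdr"] <= 0.05).all() and (2 ** up["log2fc"] >= 1.5).all()
    assert (down["fdr"] <= 0.05).all() and (2 ** down["log2fc"] <= 0.67).all()


def test_run_de_partitions_universe():
    rng = np.random.default_rng(8)
    counts, group, _ = nb_matrix(rng, 300, 8, 8, de_frac=0.1)
    counts.iloc[rng.choice(300, 90, replace=False)] = 0
    de, tmm = run_de(counts, group)
    assert len(de) == 300
    assert (de["status"] == "non_expressed").sum() == (~de["expressed"]).sum()
    assert set(de["status"]) <= {"up", "down", "ns", "non_expressed"}
    assert de.loc[de["expressed"], "pvalue"].notna().all()
    assert tmm.shape[0] == int(de["expressed"].sum())


def test_all_zero_both_groups_p_is_one():
    rng = np.random.default_rng(9)
    counts, group, _ = nb_matrix(rng, 50, 4, 4)
    counts.iloc[0] = 0
    de = de_test_threshold(counts, group)
    assert de.iloc[0]["pvalue"] == 1.0
    assert de.iloc[0]["status"] == "ns"


def test_dataset_eligibility_rule():
    assert eligible_dataset(200, 15)
    assert not eligible_dataset(199, 15)
    assert not eligible_dataset(200, 14)
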