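import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bidipair.pair_stats import (
    chisq_compare,
    classify_pair,
    combo_table,
    compare_classes,
    multi_dataset_hist,
    multi_dataset_pair_hist,
    significance_stars,
    t_vs_random,
)
from bidipair.pairs import GenePair

from _oracles import chisq_oracle

STATUSES = ["up", "down", "ns", "non_expressed"]


@pytest.mark.parametrize(
    "s1,s2,expected",
    [
        ("up", "up", "up_up"),
        ("down", "up", "up_down"),
        ("up", "ns", "up_ns"),
        ("down", "ns", "down_ns"),
        ("ns", "ns", "ns_ns"),
        ("up", "non_expressed", "with_non_expressed"),
    ],
)
def test_classify_pair(s1, s2, expected):
    assert classify_pair(s1, s2) == expected


def test_classify_pair_symmetric_exhaustive():
    for s1, s2 in itertools.product(STATUSES, repeat=2):
        assert classify_pair(s1, s2) == classify_pair(s2, s1)
    with pytest.raises(ValueError):
        classify_pair("up", "sideways")


def _de(status_map):
    return pd.DataFrame(
        {
            "status": pd.Series(status_map),
            "expressed": pd.Series(
                {g: s != "non_expressed" for g, s in status_map.items()}
            ),
        }
    )


def test_combo_table_counts_and_percentages():
    de = _de({"a": "up", "b": "up", "c": "down", "d": "ns", "e": "ns"})
    pairs = [
        GenePair("a", "b", "BG"),
        GenePair("b", "c", "BG"),
        GenePair("d", "e", "BG"),
    ]
    tbl = combo_table(pairs, de)
    de_part = tbl[tbl["kind"] == "de"].set_index("combo")["count"]
    assert de_part["up_up"] == 1
    assert de_part["up_down"] == 1
    assert de_part["ns_ns"] == 1
    assert de_part.sum() == 3
    expr = tbl[tbl["kind"] == "expression"].set_index("combo")["count"]
    assert expr["both_expressed"] == 3
    pct = tbl.set_index(["kind", "combo"])["percent"]
    assert pct[("de", "up_up")] == pytest.approx(100 / 3)
    with pytest.raises(KeyError):
        combo_table([GenePair("a", "zz", "BG")], de)


def test_combo_table_all_non_expressed():
    de = _de({"a": "non_expressed", "b": "non_expressed"})
    tbl = combo_table([GenePair("a", "b", "BG")], de)
    sub = tbl.set_index(["kind", "combo"])["count"]
    assert sub[("de", "with_non_expressed")] == 1
    assert sub[("expression", "none_expressed")] == 1


def test_chisq_yates_example():
    stat, df, p = chisq_compare([[10, 90], [20, 80]])
    assert stat == pytest.approx(3.1765, abs=1e-4)
    assert df == 1
    assert p == pytest.approx(0.0747, abs=1e-4)


def test_chisq_identical_rows_and_df():
    stat, df, p = chisq_compare([[30, 70], [30, 70]])
    assert stat == 0 and p == pytest.approx(1.0)
    _, df3, _ = chisq_compare([[10, 20], [30, 40], [50, 60]])
    assert df3 == 2
    with pytest.raises(ValueError):
        chisq_compare([[0, 0], [1, 2]])


def test_chisq_matches_formula_oracle():
    rng = np.random.default_rng(0)
    for _ in range(300):
        shape = (2, 2) if rng.random() < 0.5 else (
            int(rng.integers(2, 5)), int(rng.integers(2, 4))
        )
        tbl = rng.integers(1, 200, size=shape)
        stat, df, p = chisq_compare(tbl)
        o_stat, o_df, o_p = chisq_oracle(tbl)
        assert stat == pytest.approx(o_stat, rel=1e-10)
        assert df == o_df
        assert p == pytest.approx(o_p, rel=1e-8)


def test_t_vs_random_values():
    assert t_vs_random(10.0, 10.0, 2.0) == pytest.approx(1.0)
    assert t_vs_random(30.0, 10.0, 2.0) < 1e-15
    expected = 2 * stats.t.sf(2.0, df=99)
    assert t_vs_random(14.0, 10.0, 2.0, n_sets=100) == pytest.approx(expected)
    assert expected == pytest.approx(0.0483, abs=5e-4)
    with pytest.warns(UserWarning):
        assert t_vs_random(5.0, 5.0, 0.0) == 1.0
    with pytest.warns(UserWarning):
        assert t_vs_random(6.0, 5.0, 0.0) == 0.0


def test_significance_stars():
    assert significance_stars(0.2) == "ns"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.0005) == "***"


def test_multi_dataset_hist_conservation():
    universe = ["a", "b", "c"]
    ds = {
        "d1": _de({"a": "up", "b": "ns", "c": "up"}),
        "d2": _de({"a": "up", "b": "down", "c": "ns"}),
    }
    hist = multi_dataset_hist(ds, universe, status="up")
    assert hist.sum() == 3
    assert hist[2] == 1  # gene a up in both
    assert hist[1] == 1  # gene c up in one
    assert hist[0] == 1
    down = multi_dataset_hist(ds, universe, status="down")
    assert down[1] == 1 and down.sum() == 3
    with pytest.raises(ValueError):
        multi_dataset_hist({}, universe)


def test_multi_dataset_pair_hist():
    ds = {
        "d1": _de({"a": "up", "b": "up", "c": "down", "d": "down"}),
        "d2": _de({"a": "up", "b": "up", "c": "ns", "d": "down"}),
    }
    pairs = [GenePair("a", "b", "BG"), GenePair("c", "d", "BG")]
    hist = multi_dataset_pair_hist(ds, pairs)
    assert hist.sum() == len(pairs)
    assert hist[2] == 1  # (a,b) up_up in both datasets
    assert hist[1] == 1  # (c,d) down_down in d1 only


def test_compare_classes_pools_categories():
    de = _de({"a": "up", "b": "up", "c": "ns", "d": "ns",
              "e": "down", "f": "down"})
    bg = combo_table([GenePair("a", "b", "BG"), GenePair("e", "f", "BG")], de)
    cg = combo_table([GenePair("c", "d", "CG2")], de)
    res = compare_classes(bg, cg, categories=("up_up", "down_down"))
    assert res["count_a"] == 2 and res["total_a"] == 2
    assert res["count_b"] == 0 and res["total_b"] == 1
    assert 0 <= res["p"] <= 1
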