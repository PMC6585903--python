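"""Pair-level combination statistics and class comparisons.

Each gene pair is classified by the DE statuses of its two genes into a
symmetric combination category; per-class category counts are then compared
between bidirectional pairs and the control/random classes with a Pearson
chi-square test, or — against the 100-set random null — with a one-sample
t test on the observed count given the null mean and standard deviation.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .expression import (
    STATUS_DOWN,
    STATUS_NON_EXPRESSED,
    STATUS_NS,
    STATUS_UP,
)
from .pairs import GenePair

DE_COMBOS = [
    "up_up",
    "down_down",
    "up_down",
    "up_ns",
    "down_ns",
    "ns_ns",
    "with_non_expressed",
]

EXPRESSION_COMBOS = ["both_expressed", "one_expressed", "none_expressed"]

_VALID_STATUSES = {STATUS_UP, STATUS_DOWN, STATUS_NS, STATUS_NON_EXPRESSED}


def classify_pair(status1: str, status2: str) -> str:
    """Symmetric DE combination category of a pair of gene statuses."""
    for s in (status1, status2):
        if s not in _VALID_STATUSES:
            raise ValueError(f"unknown DE status {s!r}")
    if STATUS_NON_EXPRESSED in (status1, status2):
        return "with_non_expressed"
    combo = frozenset((status1, status2))
    if combo == {STATUS_UP}:
        return "up_up"
    if combo == {STATUS_DOWN}:
        return "down_down"
    if combo == {STATUS_UP, STATUS_DOWN}:
        return "up_down"
    if combo == {STATUS_UP, STATUS_NS}:
        return "up_ns"
    if combo == {STATUS_DOWN, STATUS_NS}:
        return "down_ns"
    return "ns_ns"


def classify_expression(expressed1: bool, expressed2: bool) -> str:
    n = int(bool(expressed1)) + int(bool(expressed2))
    return EXPRESSION_COMBOS[2 - n]


def combo_table(
    pairs: Iterable[GenePair], de_result: pd.DataFrame
) -> pd.DataFrame:
    """Counts and percentages of DE/expression combos over a pair list.

    ``de_result`` is a DE table indexed by gene_id with ``expressed`` and
    ``status`` columns.  Genes absent from the table raise a KeyError; the
    percentage denominator is the number of pairs.
    """
    de_counts = dict.fromkeys(DE_COMBOS, 0)
    expr_counts = dict.fromkeys(EXPRESSION_COMBOS, 0)
    status = de_result["status"]
    expressed = de_result["expressed"]
    n = 0
    for p in pairs:
        for gid in p.genes():
            if gid not in status.index:
                raise KeyError(f"pair gene {gid} missing from DE results")
        de_counts[classify_pair(status[p.gene1_id], status[p.gene2_id])] += 1
        expr_counts[
            classify_expression(expressed[p.gene1_id], expressed[p.gene2_id])
        ] += 1
        n += 1
    rows = [("de", c, de_counts[c]) for c in DE_COMBOS] + [
        ("expression", c, expr_counts[c]) for c in EXPRESSION_COMBOS
    ]
    out = pd.DataFrame(rows, columns=["kind", "combo", "count"])
    out["n_pairs"] = n
    out["percent"] = np.where(n > 0, out["count"] / max(n, 1) * 100.0, 0.0)
    return out


def chisq_compare(table) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table of counts.

    Continuity (Yates) correction is applied for 2x2 tables and not
    otherwise, matching R's ``chisq.test`` defaults.  Returns
    (statistic, df, p).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    correction = obs.shape == (2, 2)
    stat, p, df, _ = stats.chi2_contingency(obs, correction=correction)
    return float(stat), int(df), float(p)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def t_vs_random(
    observed_count: float,
    random_mean: float,
    random_sd: float,
    n_sets: int = 100,
) -> float:
    """Two-sided one-sample t p-value of an observed count against the
    random-null mean and standard deviation (n_sets - 1 df)."""
    if random_sd <= 0:
        import warnings

        warnings.warn("random_sd is zero; degenerate t test", stacklevel=2)
        return 1.0 if observed_count == random_mean else 0.0
    t = (observed_count - random_mean) / random_sd
    return float(2.0 * stats.t.sf(abs(t), df=n_sets - 1))


def multi_dataset_hist(
    de_results: Mapping[str, pd.DataFrame],
    universe: Iterable[str],
    status: str = STATUS_UP,
) -> pd.Series:
    """Histogram of per-gene recurrence across datasets.

    For each gene in ``universe``, counts the datasets in which its status
    equals ``status`` (a gene untested in a dataset counts as not having
    that status there), then bins genes by that count (0..D).
    """
    if len(de_results) == 0:
        raise ValueError("need at least one dataset")
    universe = list(universe)
    counts = pd.Series(0, index=universe, dtype=int)
    for de in de_results.values():
        hits = de.index[de["status"] == status]
        hits = [g for g in hits if g in counts.index]
        counts[hits] += 1
    d = len(de_results)
    hist = counts.value_counts().reindex(range(d + 1), fill_value=0)
    hist.index.name = "n_datasets"
    return hist.sort_index()


def multi_dataset_pair_hist(
    de_results: Mapping[str, pd.DataFrame],
    pairs: Iterable[GenePair],
    combos: Iterable[str] = ("up_up", "down_down"),
) -> pd.Series:
    """Histogram of per-pair recurrence of given DE combos across datasets."""
    if len(de_results) == 0:
        raise ValueError("need at least one dataset")
    pairs = list(pairs)
    combos = set(combos)
    counts = np.zeros(len(pairs), dtype=int)
    for de in de_results.values():
        status = de["status"]
        for i, p in enumerate(pairs):
            s1 = status.get(p.gene1_id, STATUS_NON_EXPRESSED)
            s2 = status.get(p.gene2_id, STATUS_NON_EXPRESSED)
            if classify_pair(s1, s2) in combos:
                counts[i] += 1
    d = len(de_results)
    hist = (
        pd.Series(counts).value_counts().reindex(range(d + 1), fill_value=0)
    )
    hist.index.name = "n_datasets"
    return hist.sort_index()


def compare_classes(
    combo_a: pd.DataFrame,
    combo_b: pd.DataFrame,
    categories: Iterable[str],
    kind: str = "de",
) -> dict:
    """2x2 chi-square of (in-categories vs not) between two pair classes.

    ``combo_a``/``combo_b`` are :func:`combo_table` outputs; categories are
    pooled (e.g. up_up + down_down) before comparison.
    """
    categories = set(categories)

    def split(tbl):
        sub = tbl[tbl["kind"] == kind]
        hit = int(sub.loc[sub["combo"].isin(categories), "count"].sum())
        tot = int(sub["count"].sum())
        return hit, tot - hit

    a_hit, a_miss = split(combo_a)
    b_hit, b_miss = split(combo_b)
    stat, df, p = chisq_compare([[a_hit, a_miss], [b_hit, b_miss]])
    return {
        "count_a": a_hit, "total_a": a_hit + a_miss,
        "count_b": b_hit, "total_b": b_hit + b_miss,
        "statistic": stat, "df": df, "p": p,
        "stars": significance_stars(p),
    }
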