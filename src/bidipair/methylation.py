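"""Promoter methylation: probe annotation, DMP calling, correlation rule.

Probes are assigned to every gene whose promoter window (2 kb upstream to
500 bp downstream of the TSS, strand-aware) contains the probe position.
Differentially methylated probes (DMPs) are called on beta values with a
moderated two-sample t test: per-probe pooled variances are shrunk toward a
prior estimated from the variance distribution (moment matching on the log
scale, the standard empirical-Bayes recipe for array data), p-values are
BH-adjusted, and probes with adjusted p <= 0.05 are labelled hypo (tumor
lower) or hyper (tumor higher).

A gene is *methylation-correlated* when it is up-regulated with at least
one promoter hypo-DMP, or down-regulated with at least one promoter
hyper-DMP.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

from .annotation import GeneModel, GeneRecord
from .expression import STATUS_DOWN, STATUS_UP, bh_adjust

logger = logging.getLogger(__name__)

DIRECTION_HYPO = "hypo"
DIRECTION_HYPER = "hyper"
DIRECTION_NS = "ns"

BASIS_UP_HYPO = "up_with_hypo"
BASIS_DOWN_HYPER = "down_with_hyper"
BASIS_NONE = "none"

METH_PAIR_COMBOS = ["both_hypo", "both_hyper", "mixed", "one", "none"]


def promoter_window(
    gene: GeneRecord, up: int = 2000, down: int = 500
) -> tuple[int, int]:
    """Strand-aware promoter interval around the TSS, clipped at 1.

    Plus strand: [tss - up, tss + down]; minus strand: [tss - down,
    tss + up]; closed on both ends.
    """
    if gene.strand == "+":
        lo, hi = gene.tss - up, gene.tss + down
    else:
        lo, hi = gene.tss - down, gene.tss + up
    return max(lo, 1), hi


def annotate_probes(
    probes: pd.DataFrame,
    model: GeneModel,
    up: int = 2000,
    down: int = 500,
) -> dict[str, list[str]]:
    """Map probe_id -> list of genes whose promoter contains the probe.

    ``probes`` needs columns probe_id, chrom, pos.  Probes on chromosomes
    absent from the model stay unassigned (counted in a logged diagnostic).
    Multi-assignment to overlapping promoters is expected.
    """
    out: dict[str, list[str]] = {}
    known = set(model.chromosomes())
    unknown_chrom = 0
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom in known:
        wins = []
        for g in model.genes_on(chrom):
            lo, hi = promoter_window(g, up, down)
            wins.append((lo, hi, g.gene_id))
        by_chrom[chrom] = sorted(wins)

    for r in probes.itertuples(index=False):
        chrom, pos, pid = str(r.chrom), int(r.pos), str(r.probe_id)
        if chrom not in known:
            unknown_chrom += 1
            continue
        hits = [gid for lo, hi, gid in by_chrom[chrom] if lo <= pos <= hi]
        if hits:
            out[pid] = hits
    if unknown_chrom:
        logger.info("%d probes on chromosomes absent from model", unknown_chrom)
    return out


def _trigamma_inverse(x: float, tol: float = 1e-8) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to observed variances.

    Returns (prior_df, prior_var); prior_df = inf when the observed
    log-variance spread is no wider than the chi-square sampling spread.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1e-8
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
        var_prior = np.exp(
            emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0)
        )
    else:
        df_prior = np.inf
        var_prior = np.exp(emean)
    return float(df_prior), float(var_prior)


def call_dmps(
    beta: pd.DataFrame,
    group,
    adj_p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Moderated-t differential methylation on a probe x sample beta matrix.

    Returns a frame indexed by probe with delta_beta (tumor - normal mean),
    pvalue, adj_p and direction.
    """
    g = np.asarray(group)
    tumor, normal = g == "tumor", g == "normal"
    if tumor.sum() < 2 or normal.sum() < 2:
        raise ValueError("both groups need at least 2 samples")
    x = beta.to_numpy(dtype=float)
    if np.nanmin(x) < 0 or np.nanmax(x) > 1:
        raise ValueError("beta values must lie in [0, 1]")
    n1, n2 = int(tumor.sum()), int(normal.sum())
    m1 = x[:, tumor].mean(axis=1)
    m2 = x[:, normal].mean(axis=1)
    v1 = x[:, tumor].var(axis=1, ddof=1)
    v2 = x[:, normal].var(axis=1, ddof=1)
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df

    df_prior, var_prior = _fit_variance_prior(s2, df)
    if np.isfinite(df_prior):
        s2_post = (df_prior * var_prior + df * s2) / (df_prior + df)
        df_total = df + df_prior
    else:
        s2_post = np.full_like(s2, var_prior)
        df_total = np.inf
    delta = m1 - m2
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    zero_var = se <= 0
    se = np.where(zero_var, 1.0, se)
    tstat = delta / se
    if np.isfinite(df_total):
        pvalue = 2.0 * stats.t.sf(np.abs(tstat), df=df_total)
    else:
        pvalue = 2.0 * stats.norm.sf(np.abs(tstat))
    if zero_var.any():
        logger.info("%d zero-variance probes; p set to 1", int(zero_var.sum()))
        pvalue = np.where(zero_var, 1.0, pvalue)
    adj = bh_adjust(pvalue)
    direction = np.full(x.shape[0], DIRECTION_NS, dtype=object)
    direction[(adj <= adj_p_threshold) & (delta < 0)] = DIRECTION_HYPO
    direction[(adj <= adj_p_threshold) & (delta > 0)] = DIRECTION_HYPER
    return pd.DataFrame(
        {
            "delta_beta": delta,
            "pvalue": pvalue,
            "adj_p": adj,
            "direction": direction,
        },
        index=beta.index,
    )


def meth_correlated_genes(
    de_result: pd.DataFrame,
    dmp_result: pd.DataFrame,
    probe_map: Mapping[str, list[str]],
) -> pd.DataFrame:
    """Per-gene methylation-correlation flag.

    basis = up_with_hypo when the gene is up-regulated and at least one
    assigned probe is hypo-methylated; down_with_hyper symmetrically; none
    otherwise.
    """
    gene_dirs: dict[str, set[str]] = {}
    directions = dmp_result["direction"]
    for pid, genes in probe_map.items():
        if pid not in directions.index:
            continue
        d = directions[pid]
        if d == DIRECTION_NS:
            continue
        for gid in genes:
            gene_dirs.setdefault(gid, set()).add(d)

    status = de_result["status"]
    basis = []
    for gid in de_result.index:
        dirs = gene_dirs.get(gid, set())
        s = status[gid]
        if s == STATUS_UP and DIRECTION_HYPO in dirs:
            basis.append(BASIS_UP_HYPO)
        elif s == STATUS_DOWN and DIRECTION_HYPER in dirs:
            basis.append(BASIS_DOWN_HYPER)
        else:
            basis.append(BASIS_NONE)
    out = pd.DataFrame({"basis": basis}, index=de_result.index)
    out["meth_correlated"] = out["basis"] != BASIS_NONE
    return out


def meth_pair_combos(
    pairs, meth_correlation: pd.DataFrame
) -> pd.DataFrame:
    """Counts of pair-level methylation-correlation combinations.

    both_hypo / both_hyper: both genes correlated on the same basis;
    mixed: both correlated, different bases; one: exactly one correlated;
    none: neither.  The headline statistic is the both_hypo + both_hyper
    fraction.
    """
    counts = dict.fromkeys(METH_PAIR_COMBOS, 0)
    basis = meth_correlation["basis"]
    n = 0
    for p in pairs:
        b1, b2 = basis[p.gene1_id], basis[p.gene2_id]
        flags = (b1 != BASIS_NONE, b2 != BASIS_NONE)
        if all(flags):
            if b1 == b2 == BASIS_UP_HYPO:
                combo = "both_hypo"
            elif b1 == b2 == BASIS_DOWN_HYPER:
                combo = "both_hyper"
            else:
                combo = "mixed"
        elif any(flags):
            combo = "one"
        else:
            combo = "none"
        counts[combo] += 1
        n += 1
    out = pd.DataFrame(
        [(c, counts[c]) for c in METH_PAIR_COMBOS],
        columns=["combo", "count"],
    )
    out["n_pairs"] = n
    out["percent"] = out["count"] / max(n, 1) * 100.0
    return out


def dataset_has_enough_normals(n_normal_meth: int, minimum: int = 3) -> bool:
    """Methylation eligibility: skip datasets with too few normal samples."""
    return n_normal_meth >= minimum
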