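"""Expression processing: filtering, TMM normalization, and threshold DE.

The differential-expression caller tests, per gene, the null hypothesis
that the tumor/normal fold change does not exceed a threshold (default
1.5-fold in either direction) under a negative-binomial model — the same
decision rule as a fold-change-thresholded likelihood test, implemented as
a Wald test with TREAT-style two-boundary tail probabilities:

    p = P(Z > (|b| - tau)/se) + P(Z > (|b| + tau)/se)

where b is the estimated log2 fold change and tau = log2(threshold).
Per-gene negative-binomial dispersions are method-of-moments estimates
shrunk toward a mean–dispersion trend by an empirical-Bayes weighted
average with ``prior_df`` prior degrees of freedom.

Normalization follows the trimmed-mean-of-M-values (TMM) recipe: weighted
trimmed mean of per-gene log ratios against a reference sample, trimming
30% of M values and 5% of A values on each side, weights equal to the
inverse asymptotic variance of M, and factors rescaled to have zero log
mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "ns"
STATUS_NON_EXPRESSED = "non_expressed"

DE_COLUMNS = ["expressed", "log2fc", "pvalue", "fdr", "status"]


@dataclass
class DEConfig:
    """Tunable knobs of the differential-expression caller."""

    fc_threshold: float = 1.5     # H0 boundary, fold change
    down_threshold: float = 0.67  # printed down-regulation boundary
    fdr_threshold: float = 0.05
    cpm_threshold: float = 0.1
    prior_df: float = 20.0        # dispersion-shrinkage prior df
    n_trend_bins: int = 20


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million by column (sample) library size."""
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples: {bad}")
    return counts / lib * 1e6


def filter_expressed(
    counts: pd.DataFrame, n_normal: int, cpm_threshold: float = 0.1
) -> pd.Series:
    """Expressed flag per gene: CPM >= threshold in at least n_normal samples.

    Samples from either group count toward the tally.
    """
    if n_normal > counts.shape[1]:
        raise ValueError(
            f"n_normal={n_normal} exceeds total samples {counts.shape[1]}"
        )
    tally = (cpm(counts) >= cpm_threshold).sum(axis=1)
    return (tally >= n_normal).rename("expressed")


def tmm_factors(
    counts: pd.DataFrame, m_trim: float = 0.30, a_trim: float = 0.05
) -> pd.Series:
    """TMM normalization factor per sample (log-mean rescaled to 0)."""
    y = counts.to_numpy(dtype=float)
    if y.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    # reference: sample whose upper-quartile CPM is closest to the mean
    f75 = np.array([
        np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])
    ])
    ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    ref, nref = y[:, ref_j], lib[ref_j]

    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        factors[j] = _tmm_pair(y[:, j], lib[j], ref, nref, m_trim, a_trim)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(obs, nobs, ref, nref, m_trim, a_trim) -> float:
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        raise ValueError("sample shares no nonzero gene with the reference")
    obs, ref = obs[keep], ref[keep]
    p_o, p_r = obs / nobs, ref / nref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    w = (nobs - obs) / (nobs * obs) + (nref - ref) / (nref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * m_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * a_trim) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not sel.any():
        return 1.0
    f = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def ruv_lite(
    log_cpm: pd.DataFrame, control_gene_ids, k: int = 1
) -> pd.DataFrame:
    """Unwanted-variation factor scores from SVD of control genes.

    Returns a (samples x k) frame of sample coordinates on the first ``k``
    singular directions of the row-centered control-gene submatrix; meant
    as extra covariates in the DE model.  ``k=0`` returns an empty frame.
    """
    if k == 0:
        return pd.DataFrame(index=log_cpm.columns)
    missing = [g for g in control_gene_ids if g not in log_cpm.index]
    if missing:
        raise KeyError(f"control genes absent from matrix: {missing[:5]}")
    sub = log_cpm.loc[list(control_gene_ids)].to_numpy(dtype=float)
    sub = sub - sub.mean(axis=1, keepdims=True)
    rank = np.linalg.matrix_rank(sub)
    if k >= rank:
        raise ValueError(f"k={k} >= rank {rank} of control submatrix")
    _, _, vt = np.linalg.svd(sub, full_matrices=False)
    scores = vt[:k].T
    return pd.DataFrame(
        scores, index=log_cpm.columns,
        columns=[f"ruv_{i + 1}" for i in range(k)],
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


def _group_masks(group) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(group)
    tumor = g == "tumor"
    normal = g == "normal"
    if not (tumor | normal).all():
        bad = sorted(set(g) - {"tumor", "normal"})
        raise ValueError(f"unknown group labels: {bad}")
    if tumor.sum() < 2 or normal.sum() < 2:
        raise ValueError("both groups need at least 2 samples")
    return tumor, normal


def _adjust_for_ruv(y, s, tumor, ruv_scores) -> np.ndarray:
    """Divide out fitted unwanted-variation effects from the counts."""
    w = np.asarray(ruv_scores, dtype=float)
    design = np.column_stack([
        np.ones(y.shape[1]), tumor.astype(float), w
    ])
    logz = np.log((y + 0.5) / s)
    coef, *_ = np.linalg.lstsq(design, logz.T, rcond=None)
    gamma = coef[2:]  # k x genes
    return y / np.exp(w @ gamma).T


def de_test_threshold(
    counts: pd.DataFrame,
    group,
    factors: pd.Series | None = None,
    config: DEConfig | None = None,
    ruv_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Threshold Wald DE test on expressed genes.

    ``counts`` must already be restricted to expressed genes.  Returns a
    frame indexed like ``counts`` with log2fc, pvalue, fdr and status
    (up / down / ns).
    """
    cfg = config or DEConfig()
    tumor, normal = _group_masks(group)
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if factors is None:
        factors = tmm_factors(counts)
    s = lib * factors.to_numpy(dtype=float)  # effective library sizes
    if ruv_scores is not None and ruv_scores.shape[1] > 0:
        y = _adjust_for_ruv(y, s, tumor, ruv_scores)

    tau = np.log2(cfg.fc_threshold)
    n_t, n_n = tumor.sum(), normal.sum()

    sum_t = y[:, tumor].sum(axis=1)
    sum_n = y[:, normal].sum(axis=1)
    s_t, s_n = s[tumor].sum(), s[normal].sum()
    # half-read pseudocount per group total stabilizes log ratios at zero
    mu_t = (sum_t + 0.5) / s_t
    mu_n = (sum_n + 0.5) / s_n
    log2fc = np.log2(mu_t / mu_n)

    phi = _trended_dispersion(y, s, tumor, normal, mu_t, mu_n, cfg)

    # Wald variance of ln(mu_t) + ln(mu_n) by the delta method
    fit_t = np.outer(mu_t, s[tumor])
    fit_n = np.outer(mu_n, s[normal])
    var_t = (fit_t + phi[:, None] * fit_t**2).sum(axis=1) / (mu_t * s_t) ** 2
    var_n = (fit_n + phi[:, None] * fit_n**2).sum(axis=1) / (mu_n * s_n) ** 2
    se = np.sqrt(var_t + var_n) / np.log(2.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        z_near = (np.abs(log2fc) - tau) / se
        z_far = (np.abs(log2fc) + tau) / se
        pvalue = stats.norm.sf(z_near) + stats.norm.sf(z_far)
    pvalue = np.minimum(np.nan_to_num(pvalue, nan=1.0), 1.0)
    dead = (sum_t == 0) & (sum_n == 0)
    if dead.any():
        logger.info("%d genes all-zero in both groups; p set to 1", dead.sum())
        pvalue[dead] = 1.0
        log2fc[dead] = 0.0

    fdr = bh_adjust(pvalue)
    fc = 2.0 ** log2fc
    status = np.full(y.shape[0], STATUS_NS, dtype=object)
    status[(fdr <= cfg.fdr_threshold) & (fc >= cfg.fc_threshold)] = STATUS_UP
    status[(fdr <= cfg.fdr_threshold) & (fc <= cfg.down_threshold)] = STATUS_DOWN

    return pd.DataFrame(
        {
            "expressed": True,
            "log2fc": log2fc,
            "pvalue": pvalue,
            "fdr": fdr,
            "status": status,
        },
        index=counts.index,
    )


def _trended_dispersion(y, s, tumor, normal, mu_t, mu_n, cfg) -> np.ndarray:
    """Method-of-moments NB dispersion shrunk toward the mean trend."""
    n = y.shape[1]
    resid_df = max(n - 2, 1)
    fitted = np.empty_like(y)
    fitted[:, tumor] = np.outer(mu_t, s[tumor])
    fitted[:, normal] = np.outer(mu_n, s[normal])
    fitted = np.maximum(fitted, 1e-8)
    contrib = ((y - fitted) ** 2 - fitted) / fitted**2
    phi_raw = np.maximum(contrib.sum(axis=1) / resid_df, 0.0)

    # trend: median raw dispersion within quantile bins of mean expression
    mean_expr = (mu_t + mu_n) / 2.0
    order = np.argsort(mean_expr, kind="stable")
    nbins = min(cfg.n_trend_bins, max(y.shape[0] // 20, 1))
    bins = np.array_split(order, nbins)
    trend = np.empty(y.shape[0])
    for b in bins:
        trend[b] = np.median(phi_raw[b])
    w = cfg.prior_df
    return (w * trend + resid_df * phi_raw) / (w + resid_df)


def run_de(
    counts: pd.DataFrame,
    group,
    config: DEConfig | None = None,
    ruv_k: int = 0,
    control_gene_ids=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-dataset DE pass: filter, normalize, test.

    Returns ``(de_table, tmm_expr)`` where ``de_table`` covers every input
    gene (non-expressed genes get status ``non_expressed``) and ``tmm_expr``
    is the TMM-normalized CPM matrix of expressed genes, the expression
    values consumed by the survival screen.
    """
    cfg = config or DEConfig()
    g = np.asarray(group)
    n_normal = int((g == "normal").sum())
    expressed = filter_expressed(counts, n_normal, cfg.cpm_threshold)
    kept = counts.loc[expressed]
    factors = tmm_factors(kept)
    lib = kept.sum(axis=0) * factors
    tmm_expr = kept / lib * 1e6

    ruv_scores = None
    if ruv_k > 0:
        log_cpm = np.log2(tmm_expr + 0.5)
        if control_gene_ids is None:
            first = de_test_threshold(kept, group, factors, cfg)
            control_gene_ids = (
                first["pvalue"].sort_values(ascending=False).index[:1000]
            )
        ruv_scores = ruv_lite(log_cpm, control_gene_ids, k=ruv_k)

    tested = de_test_threshold(kept, group, factors, cfg, ruv_scores)
    de = pd.DataFrame(
        {
            "expressed": expressed,
            "log2fc": np.nan,
            "pvalue": np.nan,
            "fdr": np.nan,
            "status": STATUS_NON_EXPRESSED,
        },
        index=counts.index,
    )
    de.loc[tested.index, ["log2fc", "pvalue", "fdr", "status"]] = tested[
        ["log2fc", "pvalue", "fdr", "status"]
    ]
    return de, tmm_expr


def eligible_dataset(n_tumor: int, n_normal: int) -> bool:
    """Inclusion rule for a cancer dataset: >=200 tumor and >=15 normal."""
    return n_tumor >= 200 and n_normal >= 15
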