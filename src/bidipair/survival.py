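"""Cox proportional-hazards screening of genes and gene pairs.

Genes are screened with a one-covariate Cox model on TMM-normalized
expression; pairs with a two-covariate model.  The reported p-value is the
score test at beta = 0 (the "logrank p" printed by R's coxph summary),
computed here with the Efron correction for tied event times.  Coefficient
estimates come from lifelines' CoxPHFitter (Efron ties).  A gene or pair is
*prognostic* when its score-test p <= 0.05; a prognostic pair is a
*candidate* when the four-quadrant median-split group model is itself
significant (3-df score test p <= 0.05).  No multiple-testing adjustment is
applied to survival p-values by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

logger = logging.getLogger(__name__)

ENDPOINTS = ("OS", "DFI", "PFI")

QUADRANTS = ("high_high", "high_low", "low_high", "low_low")


@dataclass
class CoxFit:
    """Result of one Cox screen (gene, pair, or group model)."""

    coefficients: np.ndarray = field(default_factory=lambda: np.array([]))
    score_chi2: float = np.nan
    score_df: int = 0
    score_test_p: float = np.nan
    prognostic: bool = False
    group_model_p: float = np.nan
    candidate: bool = False
    skipped: str = ""  # non-empty when the fit was not attempted


def cox_score_test(
    X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, int, float]:
    """Score (logrank) test of H0: beta = 0, Efron correction for ties.

    ``X`` is (n_samples, p).  Returns (chi2, df, p).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape

    order = np.argsort(time, kind="stable")
    time, event, X = time[order], event[order], X[order]

    U = np.zeros(p)
    info = np.zeros((p, p))
    event_times = np.unique(time[event == 1])
    for t in event_times:
        risk = time >= t
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        xr = X[risk]
        xd = X[dead]
        n_r = xr.shape[0]
        s_r = xr.sum(axis=0)
        q_r = xr.T @ xr
        s_d = xd.sum(axis=0)
        q_d = xd.T @ xd
        U += s_d
        for el in range(d):
            frac = el / d
            denom = n_r - el
            m = (s_r - frac * s_d) / denom
            U -= m
            q = (q_r - frac * q_d) / denom
            info += q - np.outer(m, m)
    try:
        chi2 = float(U @ np.linalg.solve(info, U))
    except np.linalg.LinAlgError:
        return np.nan, p, np.nan
    if chi2 < 0:
        chi2 = 0.0
    return chi2, p, float(stats.chi2.sf(chi2, df=p))


def cox_score_screen(
    X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> np.ndarray:
    """Vectorized one-covariate score-test p-values for many genes.

    ``X`` is (n_samples, n_genes).  Assumes (effectively) distinct event
    times — the regime of continuous simulated survival times, where the
    Breslow and Efron treatments coincide.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(time)
    order = np.argsort(time, kind="stable")
    Xs, ev = X[order], event[order]
    # reverse cumulative sums: risk set of sample i (sorted) = rows >= i
    cs = np.cumsum(Xs[::-1], axis=0)[::-1]
    cs2 = np.cumsum((Xs**2)[::-1], axis=0)[::-1]
    sizes = (n - np.arange(n)).astype(float)[:, None]
    mean_r = cs / sizes
    var_r = cs2 / sizes - mean_r**2
    is_event = ev == 1
    U = (Xs[is_event] - mean_r[is_event]).sum(axis=0)
    info = var_r[is_event].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(info > 0, U**2 / info, 0.0)
    return stats.chi2.sf(chi2, df=1)


def _fit_coefficients(
    X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> np.ndarray:
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
    df["T"] = np.asarray(time, dtype=float)
    df["E"] = np.asarray(event, dtype=int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E")
    return cph.params_.to_numpy()


def cox_gene(
    expr, time, event, alpha: float = 0.05, estimate_coef: bool = True
) -> CoxFit:
    """One-covariate Cox screen of a gene's expression."""
    x = np.asarray(expr, dtype=float)
    event = np.asarray(event, dtype=int)
    if int(event.sum()) < 2:
        return CoxFit(skipped="fewer than 2 events")
    if np.ptp(x) == 0:
        return CoxFit(skipped="constant expression")
    X = x[:, None]
    chi2, df, p = cox_score_test(X, time, event)
    coef = _fit_coefficients(X, time, event) if estimate_coef else np.array([])
    return CoxFit(
        coefficients=coef, score_chi2=chi2, score_df=df, score_test_p=p,
        prognostic=bool(p <= alpha),
    )


def cox_pair(
    expr1, expr2, time, event, alpha: float = 0.05,
    estimate_coef: bool = True,
) -> CoxFit:
    """Two-covariate Cox screen of a gene pair (global 2-df score test)."""
    x1 = np.asarray(expr1, dtype=float)
    x2 = np.asarray(expr2, dtype=float)
    event = np.asarray(event, dtype=int)
    if int(event.sum()) < 2:
        return CoxFit(skipped="fewer than 2 events")
    if np.ptp(x1) == 0 or np.ptp(x2) == 0:
        return CoxFit(skipped="constant expression")
    X = np.column_stack([x1, x2])
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < 2:
        return CoxFit(skipped="collinear covariates")
    chi2, df, p = cox_score_test(X, time, event)
    coef = _fit_coefficients(X, time, event) if estimate_coef else np.array([])
    return CoxFit(
        coefficients=coef, score_chi2=chi2, score_df=df, score_test_p=p,
        prognostic=bool(p <= alpha),
    )


def quadrant_groups(
    expr1, expr2, ties_high: bool = False
) -> tuple[pd.Series, bool]:
    """Median-split quadrant label per sample and a validity flag.

    High means strictly above the median (ties go low unless
    ``ties_high``).  The flag is False when either gene's split leaves one
    side empty (e.g. >50% identical values), in which case the pair must be
    excluded from group-model fitting.
    """
    x1 = pd.Series(np.asarray(expr1, dtype=float))
    x2 = pd.Series(np.asarray(expr2, dtype=float))
    if len(x1) < 4:
        raise ValueError("need at least 4 samples for quadrant grouping")

    def split(x: pd.Series) -> pd.Series:
        med = x.median()
        return (x > med) if not ties_high else (x >= med)

    h1, h2 = split(x1), split(x2)
    labels = pd.Series(
        np.where(
            h1, np.where(h2, "high_high", "high_low"),
            np.where(h2, "low_high", "low_low"),
        )
    )
    ok = (0 < h1.sum() < len(x1)) and (0 < h2.sum() < len(x2))
    return labels, bool(ok)


def group_model_test(
    groups: pd.Series, time, event
) -> tuple[float, int, float]:
    """Score test of the four-quadrant group Cox model (dummy coding)."""
    present = [q for q in QUADRANTS if (groups == q).any()]
    if len(present) < 2:
        raise ValueError("fewer than 2 quadrant groups present")
    X = np.column_stack([
        (groups == q).to_numpy(dtype=float) for q in present[1:]
    ])
    return cox_score_test(X, time, event)


def screen_genes(
    expr: pd.DataFrame, time, event, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene Cox screen over an expression matrix (genes x samples)."""
    rows = []
    for gid in expr.index:
        fit = cox_gene(
            expr.loc[gid].to_numpy(), time, event, alpha=alpha,
            estimate_coef=False,
        )
        rows.append((gid, fit.score_chi2, fit.score_test_p, fit.prognostic,
                     fit.skipped))
    return pd.DataFrame(
        rows, columns=["gene_id", "score_chi2", "score_test_p", "prognostic",
                       "skipped"],
    ).set_index("gene_id")


def candidate_pairs(
    pairs,
    expr: pd.DataFrame,
    time,
    event,
    alpha: float = 0.05,
    protein_coding_only: bool = False,
    gene_types: pd.Series | None = None,
) -> pd.DataFrame:
    """Pair-level Cox screen and quadrant-model candidate calling.

    Only pairs passing the two-covariate screen (score p <= alpha) are
    tested for candidacy.  With ``protein_coding_only`` (needs
    ``gene_types``), pairs are restricted to two protein-coding genes, the
    headline comparison of the analysis.
    """
    if protein_coding_only and gene_types is None:
        raise ValueError("protein_coding_only requires gene_types")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    rows = []
    for p in pairs:
        g1, g2 = p.gene1_id, p.gene2_id
        if protein_coding_only:
            if (
                gene_types.get(g1) != "protein_coding"
                or gene_types.get(g2) != "protein_coding"
            ):
                continue
        if g1 not in expr.index or g2 not in expr.index:
            rows.append((g1, g2, np.nan, False, np.nan, False,
                         "gene not in expression matrix"))
            continue
        x1 = expr.loc[g1].to_numpy(dtype=float)
        x2 = expr.loc[g2].to_numpy(dtype=float)
        fit = cox_pair(x1, x2, time, event, alpha=alpha, estimate_coef=False)
        if fit.skipped:
            rows.append((g1, g2, np.nan, False, np.nan, False, fit.skipped))
            continue
        group_p, candidate, note = np.nan, False, ""
        if fit.prognostic:
            groups, ok = quadrant_groups(x1, x2)
            if not ok:
                note = "degenerate median split"
            else:
                _, _, group_p = group_model_test(groups, time, event)
                candidate = bool(group_p <= alpha)
        rows.append(
            (g1, g2, fit.score_test_p, fit.prognostic, group_p, candidate,
             note)
        )
    return pd.DataFrame(
        rows,
        columns=["gene1_id", "gene2_id", "score_test_p", "prognostic",
                 "group_model_p", "candidate", "note"],
    )
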