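"""End-to-end synthetic study: generate, discover, test, compare, write.

Runs every stage of the analysis on generated fixtures with known truth
and writes all result tables as TSV into one output directory.  The run is
a pure function of (config, seed): outputs are byte-identical across
repeated invocations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression, methylation, pair_stats, survival
from .annotation import read_gtf, write_gene_table
from .pairs import (
    find_bg_pairs,
    find_cg1_pairs,
    find_cg2_pairs,
    pairs_to_frame,
    write_pair_table,
)
from .random_null import sample_random_sets, summarize_random_statistic
from .simulate import gen_annotation, gen_beta, gen_counts, gen_survival

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


def _sub_seed(seed: int, offset: int) -> int:
    return (seed * 1009 + offset) % (2**31)


@dataclass
class StudyConfig:
    """Problem sizes of one synthetic study run."""

    n_bg: int = 30
    n_cg1: int = 20
    n_cg2: int = 25
    n_nested: int = 5
    n_singleton: int = 150
    n_datasets: int = 2
    n_tumor: int = 20
    n_normal: int = 20
    de_frac: float = 0.2
    pair_coupling: float = 0.8
    nb_dispersion: float = 0.1
    n_random_sets: int = 100
    dmp_frac: float = 0.05
    delta_beta: float = 0.25
    censor_frac: float = 0.3
    prognostic_frac: float = 0.1
    cox_beta: float = 0.5
    extra: dict = field(default_factory=dict)


def run_synthetic_study(
    outdir: str | Path, seed: int = 0, config: StudyConfig | None = None
) -> dict:
    """Run the whole pipeline on synthetic fixtures; return summary dict."""
    cfg = config or StudyConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    # --- annotation & pair discovery -----------------------------------
    gtf_path = out / "annotation.gtf"
    _, truth = gen_annotation(
        n_bg=cfg.n_bg, n_cg1=cfg.n_cg1, n_cg2=cfg.n_cg2,
        n_nested=cfg.n_nested, n_singleton=cfg.n_singleton,
        seed=_sub_seed(seed, 1), out_gtf=gtf_path,
    )
    model = read_gtf(gtf_path, feature_policy="gene_lines")
    write_gene_table(model, out / "genes.tsv")
    bg = find_bg_pairs(model)
    cg1 = find_cg1_pairs(model, bg_pairs=bg)
    cg2 = find_cg2_pairs(model, bg_pairs=bg)
    write_pair_table(bg, out / "pairs_bg.tsv", model)
    write_pair_table(cg1, out / "pairs_cg1.tsv", model)
    write_pair_table(cg2, out / "pairs_cg2.tsv", model)
    summary["n_bg"] = len(bg)
    summary["n_cg1"] = len(cg1)
    summary["n_cg2"] = len(cg2)

    rand = sample_random_sets(
        model, bg, n_sets=cfg.n_random_sets, master_seed=_sub_seed(seed, 2)
    )
    manifest = pd.DataFrame(
        {"set_index": range(len(rand.sets)), "seed": rand.seeds,
         "n_pairs": [len(s) for s in rand.sets]},
    )
    manifest.to_csv(out / "random_sets_manifest.tsv", sep="\t", index=False)
    pairs_to_frame(rand.sets[0], model).to_csv(
        out / "random_set_000.tsv", sep="\t", index=False
    )

    # --- expression ----------------------------------------------------
    de_results: dict[str, pd.DataFrame] = {}
    tmm_by_ds: dict[str, pd.DataFrame] = {}
    group_by_ds: dict[str, list[str]] = {}
    for d in range(cfg.n_datasets):
        name = f"DS{d + 1:02d}"
        counts, group = gen_counts(
            truth, n_tumor=cfg.n_tumor, n_normal=cfg.n_normal,
            nb_dispersion=cfg.nb_dispersion, de_frac=cfg.de_frac,
            pair_coupling=cfg.pair_coupling, seed=_sub_seed(seed, 10 + d),
        )
        de, tmm = expression.run_de(counts, group)
        de_results[name] = de
        tmm_by_ds[name] = tmm
        group_by_ds[name] = group
        de.to_csv(out / f"de_{name}.tsv", sep="\t", float_format=FLOAT_FMT)

    # --- pair-level statistics -----------------------------------------
    comparisons = []
    hist_rows = []
    de0 = de_results["DS01"]
    combo_bg = pair_stats.combo_table(bg, de0)
    combo_bg.to_csv(out / "combo_bg_DS01.tsv", sep="\t", index=False,
                    float_format=FLOAT_FMT)
    for label, other in (("CG1", cg1), ("CG2", cg2)):
        if not other:
            continue
        cmp = pair_stats.compare_classes(
            combo_bg, pair_stats.combo_table(other, de0),
            categories=("up_up", "down_down"),
        )
        cmp["class_b"] = label
        comparisons.append(cmp)
    per_set = [
        int(
            pair_stats.combo_table(s, de0)
            .query("kind == 'de' and combo in ('up_up', 'down_down')")["count"]
            .sum()
        )
        for s in rand.sets
    ]
    mean_r, sd_r = summarize_random_statistic(per_set)
    obs = int(
        combo_bg.query("kind == 'de' and combo in ('up_up', 'down_down')")[
            "count"
        ].sum()
    )
    p_rand = pair_stats.t_vs_random(obs, mean_r, sd_r, n_sets=len(per_set))
    comparisons.append({
        "class_b": "RANDOM", "count_a": obs, "total_a": len(bg),
        "count_b": round(mean_r, 3), "total_b": len(bg),
        "statistic": float("nan"), "df": len(per_set) - 1, "p": p_rand,
        "stars": pair_stats.significance_stars(p_rand),
    })
    pd.DataFrame(comparisons).to_csv(
        out / "pair_comparisons_DS01.tsv", sep="\t", index=False,
        float_format=FLOAT_FMT,
    )
    summary["bg_upup_downdown_count"] = obs
    summary["random_upup_downdown_mean"] = mean_r
    summary["p_bg_vs_random"] = p_rand

    universe = [g.gene_id for g in model]
    for status in ("up", "down"):
        hist = pair_stats.multi_dataset_hist(de_results, universe, status)
        for nbin, cnt in hist.items():
            hist_rows.append(("gene", status, int(nbin), int(cnt)))
    hist_pairs = pair_stats.multi_dataset_pair_hist(de_results, bg)
    for nbin, cnt in hist_pairs.items():
        hist_rows.append(("bg_pair", "up_up+down_down", int(nbin), int(cnt)))
    pd.DataFrame(
        hist_rows, columns=["level", "status", "n_datasets", "count"]
    ).to_csv(out / "multi_dataset_hist.tsv", sep="\t", index=False)

    # --- methylation ---------------------------------------------------
    beta, probes, meth_group = gen_beta(
        truth, n_tumor=cfg.n_tumor, n_normal=cfg.n_normal,
        dmp_frac=cfg.dmp_frac, delta_beta=cfg.delta_beta,
        seed=_sub_seed(seed, 30),
    )
    dmp = methylation.call_dmps(beta, meth_group)
    dmp.to_csv(out / "dmp.tsv", sep="\t", float_format=FLOAT_FMT)
    probe_map = methylation.annotate_probes(probes, model)
    corr = methylation.meth_correlated_genes(de0, dmp, probe_map)
    corr.to_csv(out / "meth_correlated.tsv", sep="\t")
    meth_combo = methylation.meth_pair_combos(bg, corr)
    meth_combo.to_csv(out / "meth_pair_combos_bg.tsv", sep="\t", index=False,
                      float_format=FLOAT_FMT)
    summary["n_dmp"] = int((dmp["direction"] != "ns").sum())
    summary["n_meth_correlated"] = int(corr["meth_correlated"].sum())

    # --- survival ------------------------------------------------------
    tmm0 = tmm_by_ds["DS01"]
    tumor_cols = [
        c for c, g in zip(tmm0.columns, group_by_ds["DS01"]) if g == "tumor"
    ]
    expr_t = np.log2(tmm0[tumor_cols] + 0.5)
    rng = np.random.default_rng(_sub_seed(seed, 40))
    n_prog = max(int(round(cfg.prognostic_frac * len(expr_t))), 1)
    prog_genes = sorted(
        rng.choice(expr_t.index.to_numpy(), size=n_prog, replace=False)
    )
    betas = pd.Series(cfg.cox_beta, index=prog_genes)
    surv = gen_survival(
        expr_t, beta_cox=betas, censor_frac=cfg.censor_frac,
        seed=_sub_seed(seed, 41), truth=truth,
    )
    surv.to_csv(out / "survival_OS.tsv", sep="\t", index=False,
                float_format=FLOAT_FMT)
    time = surv["OS.time"].to_numpy()
    event = surv["OS"].to_numpy()
    gene_screen = survival.screen_genes(expr_t, time, event)
    gene_screen.to_csv(out / "cox_genes_OS.tsv", sep="\t",
                       float_format=FLOAT_FMT)
    cand = survival.candidate_pairs(bg, expr_t, time, event)
    cand.to_csv(out / "cox_pairs_bg_OS.tsv", sep="\t", index=False,
                float_format=FLOAT_FMT)
    summary["n_prognostic_genes"] = int(gene_screen["prognostic"].sum())
    summary["n_prognostic_bg_pairs"] = int(cand["prognostic"].sum())
    summary["n_candidate_bg_pairs"] = int(cand["candidate"].sum())

    pd.Series(summary).to_csv(out / "summary.tsv", sep="\t", header=False)
    return summary
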