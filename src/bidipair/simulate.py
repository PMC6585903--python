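"""Synthetic fixtures with known truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes —
planted head-to-head / tail-to-tail / tandem / nested gene structures in a
GTF, negative-binomial counts with planted differential expression and
optional within-pair co-regulation, logit-normal promoter beta values with
planted differential methylation, and Cox-generated survival times — while
recording the ground truth alongside, so recovery can be checked exactly.

Planted structures are separated by more than 20 kb, which makes the truth
table the *unique* correct answer for pair discovery (no accidental pairs
can arise at the 10 kb maximum pairing distance).

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, GeneRecord
from .expression import (
    STATUS_DOWN,
    STATUS_NON_EXPRESSED,
    STATUS_NS,
    STATUS_UP,
)
from .methylation import promoter_window
from .pairs import GenePair

DEFAULT_TYPE_FREQS = {
    "protein_coding": 0.55,
    "lincRNA": 0.20,
    "antisense": 0.15,
    "pseudogene": 0.10,
}

STRUCTURE_SPACING = 20_001  # bp between planted structures; > max pair reach


@dataclass
class TruthTable:
    """Ground truth recorded next to every synthetic fixture."""

    genes: list[GeneRecord] = field(default_factory=list)
    bg_pairs: list[GenePair] = field(default_factory=list)
    cg1_pairs: list[GenePair] = field(default_factory=list)
    cg2_pairs: list[GenePair] = field(default_factory=list)
    nested: list[tuple[str, str]] = field(default_factory=list)  # (inner, outer)
    de: pd.DataFrame | None = None       # gene_id -> log2fc, status
    dmp: pd.DataFrame | None = None      # probe_id -> delta_beta, direction, gene_id
    survival_beta: pd.Series | None = None  # gene_id -> Cox beta
    params: dict = field(default_factory=dict)

    def gene_model(self) -> GeneModel:
        return GeneModel(self.genes)

    def pairs(self, pair_class: str) -> list[GenePair]:
        return {
            "BG": self.bg_pairs, "CG1": self.cg1_pairs, "CG2": self.cg2_pairs
        }[pair_class]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": self.params,
            "genes": [
                [g.gene_id, g.gene_type, g.chrom, g.strand, g.start, g.end]
                for g in self.genes
            ],
            "pairs": {
                cls: [[p.gene1_id, p.gene2_id, p.distance_bp] for p in ps]
                for cls, ps in (
                    ("BG", self.bg_pairs), ("CG1", self.cg1_pairs),
                    ("CG2", self.cg2_pairs),
                )
            },
            "nested": self.nested,
            "de": None if self.de is None else self.de.reset_index().to_dict(
                orient="list"
            ),
            "dmp": None if self.dmp is None else self.dmp.reset_index().to_dict(
                orient="list"
            ),
            "survival_beta": (
                None if self.survival_beta is None
                else self.survival_beta.to_dict()
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _gtf_line(chrom, feature, start, end, strand, attrs) -> str:
    attr_str = " ".join(f'{k} "{v}";' for k, v in attrs)
    return "\t".join(
        [chrom, "synthetic", feature, str(start), str(end), ".", strand, ".",
         attr_str]
    )


def gen_annotation(
    n_bg: int = 50,
    n_cg1: int = 30,
    n_cg2: int = 40,
    n_nested: int = 10,
    n_singleton: int = 200,
    type_freqs: dict[str, float] | None = None,
    seed: int = 0,
    chrom_length: int = 120_000_000,
    max_chroms: int = 23,
    out_gtf: str | Path | None = None,
) -> tuple[str, TruthTable]:
    """Plant pair structures on synthetic chromosomes; emit GTF + truth.

    Distances follow the class definitions: TSS gaps ~ U(0, 1000) for
    head-to-head structures, TES gaps ~ U(0, 1000) for tail-to-tail,
    intergenic gaps ~ U(1000, 10000) for tandem pairs.  Returns the GTF
    text (also written to ``out_gtf`` if given) and the truth table.
    """
    freqs = dict(type_freqs or DEFAULT_TYPE_FREQS)
    names = sorted(freqs)
    probs = np.array([freqs[t] for t in names], dtype=float)
    if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
        raise ValueError("type_freqs must be a probability vector")
    rng = np.random.default_rng(seed)
    truth = TruthTable(params={
        "n_bg": n_bg, "n_cg1": n_cg1, "n_cg2": n_cg2, "n_nested": n_nested,
        "n_singleton": n_singleton, "seed": seed, "type_freqs": freqs,
    })

    counter = 0
    cursor = 10_000
    chrom_i = 1

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"SYNG{counter:06d}.1"

    def gene_type() -> str:
        return names[int(rng.choice(len(names), p=probs))]

    def glen() -> int:
        return int(rng.integers(2000, 8001))

    def place(length: int) -> int:
        nonlocal cursor, chrom_i
        if cursor + length > chrom_length:
            chrom_i += 1
            cursor = 10_000
            if chrom_i > max_chroms:
                raise ValueError(
                    "chromosome capacity exceeded; increase max_chroms or "
                    "chrom_length to fit more structures"
                )
        start = cursor
        cursor += length
        return start

    def advance() -> None:
        nonlocal cursor
        cursor += STRUCTURE_SPACING + int(rng.integers(0, 5000))

    def add_gene(start: int, end: int, strand: str) -> GeneRecord:
        g = GeneRecord(
            gene_id=next_id(), gene_type=gene_type(),
            chrom=f"chrS{chrom_i}", strand=strand, start=start, end=end,
        )
        truth.genes.append(g)
        return g

    structures = (
        ["bg"] * n_bg + ["cg1"] * n_cg1 + ["cg2"] * n_cg2
        + ["nested"] * n_nested + ["singleton"] * n_singleton
    )
    for kind in structures:
        if kind == "bg":
            l1, l2 = glen(), glen()
            gap = int(rng.integers(0, 1001))
            start = place(l1 + gap + l2)
            m = add_gene(start, start + l1 - 1, "-")
            p = add_gene(start + l1 - 1 + gap, start + l1 - 1 + gap + l2, "+")
            truth.bg_pairs.append(
                GenePair(m.gene_id, p.gene_id, "BG", distance_bp=gap,
                         chrom=m.chrom)
            )
        elif kind == "cg1":
            l1, l2 = glen(), glen()
            gap = int(rng.integers(0, 1001))
            start = place(l1 + gap + l2)
            p = add_gene(start, start + l1 - 1, "+")
            m = add_gene(start + l1 - 1 + gap, start + l1 - 1 + gap + l2, "-")
            truth.cg1_pairs.append(
                GenePair(p.gene_id, m.gene_id, "CG1", distance_bp=gap,
                         chrom=p.chrom)
            )
        elif kind == "cg2":
            l1, l2 = glen(), glen()
            gap = int(rng.integers(1000, 10001))
            strand = "+" if rng.integers(2) else "-"
            start = place(l1 + gap + l2)
            a = add_gene(start, start + l1 - 1, strand)
            b = add_gene(start + l1 - 1 + gap, start + l1 - 1 + gap + l2 - 1,
                         strand)
            truth.cg2_pairs.append(
                GenePair(a.gene_id, b.gene_id, "CG2", distance_bp=gap,
                         chrom=a.chrom)
            )
        elif kind == "nested":
            lo = int(rng.integers(12_000, 20_001))
            li = int(rng.integers(1000, lo - 4000))
            start = place(lo)
            outer = add_gene(start, start + lo - 1,
                             "+" if rng.integers(2) else "-")
            inner_start = start + 2000
            inner = add_gene(inner_start, inner_start + li - 1,
                             "+" if rng.integers(2) else "-")
            truth.nested.append((inner.gene_id, outer.gene_id))
        else:
            length = glen()
            start = place(length)
            add_gene(start, start + length - 1,
                     "+" if rng.integers(2) else "-")
        advance()

    lines = ["##description: synthetic annotation (bidipair simulate)"]
    for g in sorted(truth.genes, key=lambda x: (x.chrom, x.start, x.gene_id)):
        attrs_gene = [("gene_id", g.gene_id), ("gene_type", g.gene_type)]
        attrs_tx = attrs_gene + [("transcript_id", g.gene_id + "_T1")]
        lines.append(
            _gtf_line(g.chrom, "gene", g.start, g.end, g.strand, attrs_gene)
        )
        lines.append(
            _gtf_line(g.chrom, "transcript", g.start, g.end, g.strand,
                      attrs_tx)
        )
    gtf_text = "\n".join(lines) + "\n"
    if out_gtf is not None:
        Path(out_gtf).write_text(gtf_text)
    return gtf_text, truth


def gen_counts(
    truth: TruthTable,
    n_tumor: int = 20,
    n_normal: int = 20,
    nb_dispersion: float = 0.1,
    de_frac: float = 0.1,
    lfc: float = 2.0,
    pair_coupling: float = 0.0,
    zero_frac: float = 0.3,
    mean_log: float = np.log(50.0),
    mean_sdlog: float = 1.5,
    libsize_sdlog: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Negative-binomial counts with planted DE and within-pair coupling.

    ``pair_coupling`` is the probability that a planted head-to-head pair is
    co-regulated: both genes then share one DE draw (same direction, same
    |log2fc| = ``lfc``); otherwise genes are independently DE with
    probability ``de_frac``.  ``zero_frac`` of genes are all-zero (the
    non-expressed stratum).  Updates ``truth.de`` and returns
    (counts, group labels) with tumor samples first.
    """
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    if n_tumor < 2 or n_normal < 2:
        raise ValueError("need >= 2 samples per group")
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in truth.genes]
    n_genes = len(gene_ids)
    idx = {g: i for i, g in enumerate(gene_ids)}

    zero = np.zeros(n_genes, dtype=bool)
    zero[rng.choice(n_genes, size=int(round(zero_frac * n_genes)),
                    replace=False)] = True

    log2fc = np.zeros(n_genes)
    assigned = np.zeros(n_genes, dtype=bool)
    for pair in truth.bg_pairs:
        i, j = idx[pair.gene1_id], idx[pair.gene2_id]
        if zero[i] or zero[j]:
            assigned[i] = assigned[j] = True
            continue
        if rng.random() < pair_coupling:
            if rng.random() < de_frac:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                log2fc[i] = log2fc[j] = sign * lfc
            assigned[i] = assigned[j] = True
    for i in range(n_genes):
        if assigned[i] or zero[i]:
            continue
        if rng.random() < de_frac:
            log2fc[i] = lfc if rng.random() < 0.5 else -lfc

    status = np.full(n_genes, STATUS_NS, dtype=object)
    status[log2fc > 0] = STATUS_UP
    status[log2fc < 0] = STATUS_DOWN
    status[zero] = STATUS_NON_EXPRESSED
    log2fc[zero] = 0.0
    truth.de = pd.DataFrame(
        {"log2fc": log2fc, "status": status},
        index=pd.Index(gene_ids, name="gene_id"),
    )

    base = np.exp(rng.normal(mean_log, mean_sdlog, size=n_genes))
    base[zero] = 0.0
    n = n_tumor + n_normal
    libfac = np.exp(rng.normal(0.0, libsize_sdlog, size=n))
    tumor_mask = np.zeros(n, dtype=bool)
    tumor_mask[:n_tumor] = True
    mean = np.outer(base, libfac)
    mean[:, tumor_mask] *= 2.0 ** log2fc[:, None]
    shape = 1.0 / nb_dispersion
    lam = rng.gamma(shape, 1.0, size=mean.shape) * mean / shape
    counts = rng.poisson(lam)
    counts[zero, :] = 0

    samples = [f"T{i + 1:03d}" for i in range(n_tumor)] + [
        f"N{i + 1:03d}" for i in range(n_normal)
    ]
    group = ["tumor"] * n_tumor + ["normal"] * n_normal
    frame = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples
    )
    return frame, group


def gen_beta(
    truth: TruthTable,
    n_tumor: int = 20,
    n_normal: int = 20,
    dmp_frac: float = 0.05,
    delta_beta: float = 0.2,
    meth_coupling: float = 1.0,
    probes_per_promoter: int = 2,
    background_probes_per_gene: int = 1,
    probe_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Logit-normal beta values with planted promoter DMPs.

    With probability ``meth_coupling`` each planted up-regulated gene gets a
    hypo-methylated promoter probe (down-regulated: hyper), shifted by
    ``delta_beta`` in tumors.  Additional unlinked DMPs are planted on
    promoter probes of *non-DE* genes and on background probes until about
    ``dmp_frac`` of probes are differential, keeping the set of genes whose
    promoters hold a direction-matched DMP exactly the planted one.
    Requires ``truth.de`` (run gen_counts first) unless every gene is
    treated as non-DE.  Returns (beta, probe manifest, group labels) and
    updates ``truth.dmp``.
    """
    if not (0 < delta_beta < 1):
        raise ValueError("delta_beta must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    de = truth.de
    status = (
        de["status"] if de is not None
        else pd.Series(STATUS_NS, index=[g.gene_id for g in truth.genes])
    )

    probe_rows = []  # (probe_id, chrom, pos, gene_id, in_promoter)
    pid = 0
    for g in sorted(truth.genes, key=lambda x: (x.chrom, x.start, x.gene_id)):
        lo, hi = promoter_window(g)
        for _ in range(probes_per_promoter):
            pid += 1
            pos = int(rng.integers(lo, hi + 1))
            probe_rows.append((f"cgS{pid:07d}", g.chrom, pos, g.gene_id, True))
        for _ in range(background_probes_per_gene):
            pid += 1
            pos = g.end + 5000 + int(rng.integers(0, 5000))
            probe_rows.append((f"cgS{pid:07d}", g.chrom, pos, g.gene_id, False))
    manifest = pd.DataFrame(
        probe_rows, columns=["probe_id", "chrom", "pos", "gene_id",
                             "in_promoter"],
    )

    n_probes = len(manifest)
    shift = np.zeros(n_probes)
    # matched DMPs: first promoter probe of each DE gene
    first_prom = (
        manifest[manifest["in_promoter"]]
        .groupby("gene_id", sort=True)
        .head(1)
        .set_index("gene_id")
    )
    planted_genes: list[str] = []
    for gid, row in first_prom.iterrows():
        s = status.get(gid, STATUS_NS)
        if s not in (STATUS_UP, STATUS_DOWN):
            continue
        if rng.random() >= meth_coupling:
            continue
        i = manifest.index[manifest["probe_id"] == row["probe_id"]][0]
        shift[i] = -delta_beta if s == STATUS_UP else delta_beta
        planted_genes.append(gid)

    # unlinked DMPs: only probes that cannot create a spurious matched gene
    target = int(round(dmp_frac * n_probes))
    extra_needed = max(target - int((shift != 0).sum()), 0)
    de_genes = set(status.index[status.isin([STATUS_UP, STATUS_DOWN])])
    eligible = manifest.index[
        (shift == 0)
        & (~manifest["in_promoter"] | ~manifest["gene_id"].isin(de_genes))
    ].to_numpy()
    if extra_needed and eligible.size:
        pick = rng.choice(
            eligible, size=min(extra_needed, eligible.size), replace=False
        )
        signs = np.where(rng.random(pick.size) < 0.5, -1.0, 1.0)
        shift[pick] = signs * delta_beta

    mu = rng.normal(0.0, 1.5, size=n_probes)
    n = n_tumor + n_normal
    logits = mu[:, None] + rng.normal(0.0, probe_sd, size=(n_probes, n))
    beta = 1.0 / (1.0 + np.exp(-logits))
    beta[:, :n_tumor] = np.clip(
        beta[:, :n_tumor] + shift[:, None], 0.005, 0.995
    )

    direction = np.full(n_probes, "ns", dtype=object)
    direction[shift < 0] = "hypo"
    direction[shift > 0] = "hyper"
    truth.dmp = pd.DataFrame(
        {
            "delta_beta": shift,
            "direction": direction,
            "gene_id": manifest["gene_id"].to_numpy(),
            "in_promoter": manifest["in_promoter"].to_numpy(),
        },
        index=pd.Index(manifest["probe_id"], name="probe_id"),
    )
    samples = [f"T{i + 1:03d}" for i in range(n_tumor)] + [
        f"N{i + 1:03d}" for i in range(n_normal)
    ]
    group = ["tumor"] * n_tumor + ["normal"] * n_normal
    beta_frame = pd.DataFrame(
        beta, index=pd.Index(manifest["probe_id"], name="probe_id"),
        columns=samples,
    )
    return beta_frame, manifest.drop(columns=["gene_id", "in_promoter"]), group


def gen_survival(
    expr: pd.DataFrame,
    beta_cox: pd.Series | dict | None = None,
    censor_frac: float = 0.3,
    baseline_hazard: float = 0.002,
    frailty_sd: float = 0.5,
    frailty_rho: float = 0.5,
    seed: int = 0,
    truth: TruthTable | None = None,
) -> pd.DataFrame:
    """Cox-model survival times for the patients (columns) of ``expr``.

    Event times are exponential with hazard
    ``baseline_hazard * exp(sum_g beta_g z_g)`` over the prognostic genes in
    ``beta_cox`` (z = expression standardized across patients), plus a
    log-normal frailty shared across the OS/DFI/PFI endpoints with
    correlation ``frailty_rho``.  Censoring is independent uniform,
    calibrated so about ``censor_frac`` of records are censored.
    """
    if not (0 <= censor_frac < 1):
        raise ValueError("censor_frac must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    patients = list(expr.columns)
    n = len(patients)
    eta = np.zeros(n)
    betas = pd.Series(beta_cox if beta_cox is not None else {}, dtype=float)
    for gid, b in betas.items():
        x = expr.loc[gid].to_numpy(dtype=float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
        eta = eta + b * z
    if truth is not None:
        truth.survival_beta = betas

    shared = rng.normal(0.0, 1.0, size=n)
    data: dict[str, np.ndarray] = {}
    for endpoint in ENDPOINT_ORDER:
        own = rng.normal(0.0, 1.0, size=n)
        frail = frailty_sd * (
            np.sqrt(frailty_rho) * shared + np.sqrt(1 - frailty_rho) * own
        )
        rate = baseline_hazard * np.exp(eta + frail)
        t = rng.exponential(1.0 / rate)
        if censor_frac > 0:
            cmax = _calibrate_censoring(t, censor_frac)
            c = rng.uniform(0, cmax, size=n)
            event = (t <= c).astype(int)
            time = np.minimum(t, c)
        else:
            event = np.ones(n, dtype=int)
            time = t
        data[f"{endpoint}.time"] = np.round(time, 3)
        data[endpoint] = event
    out = pd.DataFrame(data, index=pd.Index(patients, name="patient_id"))
    return out.reset_index()


ENDPOINT_ORDER = ("OS", "DFI", "PFI")


def _calibrate_censoring(t: np.ndarray, frac: float) -> float:
    """Choose a uniform-censoring horizon giving ~frac censored records.

    With C ~ U(0, c), P(censored) = E[min(T/c, 1)]; monotone decreasing in
    c, solved by bisection on the observed event-time sample.
    """
    lo, hi = float(np.min(t)) * 1e-3 + 1e-9, float(np.max(t)) * 10
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        p_cens = float(np.mean(np.minimum(t / mid, 1.0)))
        if p_cens > frac:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
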