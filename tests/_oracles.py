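"""Brute-force reference implementations used only to check the package."""

import itertools

import numpy as np
from scipy import stats


def bh_oracle(pvalues):
    """O(n^2) Benjamini–Hochberg: q_i = min over j with p_j >= p_i of
    p_j * n / rank(j), clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    q = np.empty(n)
    for i in range(n):
        candidates = [
            p[j] * n / ranks[j] for j in range(n) if ranks[j] >= ranks[i]
        ]
        q[i] = min(min(candidates), 1.0)
    return q


def chisq_oracle(table):
    """Pearson chi-square by direct formula; Yates clipping for 2x2."""
    obs = np.asarray(table, dtype=float)
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    diff = np.abs(obs - expected)
    if obs.shape == (2, 2):
        diff = diff - np.minimum(0.5, diff)
    stat = (diff**2 / expected).sum()
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df, stats.chi2.sf(stat, df)


def _nested(a, b):
    return (a.start >= b.start and a.end <= b.end) or (
        b.start >= a.start and b.end <= a.end
    )


def brute_force_pairs(model, pair_class, cutoff_low=1000, cutoff_high=10000):
    """All-pairs scan applying the pair definitions literally."""
    found = set()
    for a, b in itertools.combinations(list(model), 2):
        if a.chrom != b.chrom:
            continue
        if pair_class in ("BG", "CG1"):
            if a.strand == b.strand:
                continue
            minus, plus = (a, b) if a.strand == "-" else (b, a)
            if pair_class == "BG":
                d = abs(minus.end - plus.start)  # TSS distance
                oriented = minus.start <= plus.start and minus.end <= plus.end
            else:
                d = abs(minus.start - plus.end)  # TES distance
                oriented = plus.start <= minus.start and plus.end <= minus.end
            if d <= cutoff_low and oriented and not _nested(a, b):
                found.add(tuple(sorted((a.gene_id, b.gene_id))))
        else:  # CG2
            if a.strand != b.strand:
                continue
            up, down = (a, b) if a.end <= b.end else (b, a)
            gap = down.start - up.end
            if cutoff_low <= gap <= cutoff_high and not _nested(a, b):
                found.add(tuple(sorted((a.gene_id, b.gene_id))))
    if pair_class in ("CG1", "CG2"):
        bg_members = set()
        for g1, g2 in brute_force_pairs(model, "BG"):
            bg_members.update((g1, g2))
        found = {
            pair for pair in found
            if pair[0] not in bg_members and pair[1] not in bg_members
        }
    return found
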