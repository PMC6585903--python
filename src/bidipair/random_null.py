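"""Composition-matched random-pair null sets.

For each bidirectional pair with gene-type combination (t1, t2), one random
pair is drawn with one gene sampled uniformly from the type-t1 pool and one
from the type-t2 pool, so every random set reproduces the BG sets' size and
gene-type composition exactly.  Repeating the draw (default 100 times)
yields the null distribution against which pair-level statistics are
compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .annotation import GeneModel
from .pairs import GenePair, pair_type_composition

logger = logging.getLogger(__name__)


class TypePoolError(ValueError):
    """A gene-type pool is too small for without-replacement sampling."""


@dataclass
class RandomPairSets:
    sets: list[list[GenePair]]
    seeds: list[int]
    composition: dict[tuple[str, str], int]
    collisions_with: dict[int, int] = field(default_factory=dict)


def _per_set_seed(master_seed: int, index: int) -> int:
    # documented derivation; kept additive so sets are auditable one by one
    return int(master_seed) + index


def sample_random_sets(
    model: GeneModel,
    bg_pairs: list[GenePair],
    n_sets: int = 100,
    master_seed: int = 0,
    with_replacement: bool = False,
    exclude_bg_genes: bool = False,
) -> RandomPairSets:
    """Draw ``n_sets`` random pair sets matching the BG type composition.

    Within one set genes are drawn without replacement by default (a gene
    appears at most once per set); sets are independent.  Output is
    deterministic for a fixed ``master_seed`` (per-set seed = master_seed +
    set index).  Random pairs that coincide with a real BG pair are kept but
    counted in ``collisions_with``.
    """
    composition = pair_type_composition(bg_pairs, model)
    n_pairs = sum(composition.values())

    excluded: set[str] = set()
    if exclude_bg_genes:
        for p in bg_pairs:
            excluded.update(p.genes())
    pools: dict[str, list[str]] = {}
    for g in model:
        if g.gene_id in excluded:
            continue
        pools.setdefault(g.gene_type, []).append(g.gene_id)

    # total draws needed per type in one set
    needed: dict[str, int] = {}
    for (t1, t2), k in composition.items():
        needed[t1] = needed.get(t1, 0) + k
        needed[t2] = needed.get(t2, 0) + k
    if not with_replacement:
        for t, k in sorted(needed.items()):
            have = len(pools.get(t, []))
            if have < k:
                raise TypePoolError(
                    f"gene type {t!r}: need {k} distinct genes per set but "
                    f"pool has {have} (deficit {k - have})"
                )

    bg_keys = {p.key for p in bg_pairs}
    combos = sorted(composition.items())  # deterministic order
    sets: list[list[GenePair]] = []
    seeds: list[int] = []
    collisions: dict[int, int] = {}
    for i in range(n_sets):
        seed = _per_set_seed(master_seed, i)
        rng = np.random.default_rng(seed)
        if with_replacement:
            pair_set = _draw_with_replacement(pools, combos, rng)
        else:
            pair_set = _draw_without_replacement(pools, combos, needed, rng)
        ncoll = sum(1 for p in pair_set if p.key in bg_keys)
        if ncoll:
            collisions[i] = ncoll
        sets.append(sorted(pair_set, key=lambda p: p.key))
        seeds.append(seed)
    logger.info(
        "drew %d random sets of %d pairs (%d collisions with BG pairs)",
        n_sets, n_pairs, sum(collisions.values()),
    )
    return RandomPairSets(
        sets=sets, seeds=seeds, composition=composition,
        collisions_with=collisions,
    )


def _draw_without_replacement(pools, combos, needed, rng) -> list[GenePair]:
    # pre-draw each type's distinct genes once, then deal them out per combo
    dealt: dict[str, list[str]] = {}
    for t in sorted(needed):
        pool = pools[t]
        idx = rng.choice(len(pool), size=needed[t], replace=False)
        dealt[t] = [pool[j] for j in idx]
    cursor = {t: 0 for t in dealt}
    out = []
    for (t1, t2), k in combos:
        for _ in range(k):
            g1 = dealt[t1][cursor[t1]]
            cursor[t1] += 1
            g2 = dealt[t2][cursor[t2]]
            cursor[t2] += 1
            out.append(GenePair(g1, g2, "RANDOM"))
    return out


def _draw_with_replacement(pools, combos, rng) -> list[GenePair]:
    out = []
    for (t1, t2), k in combos:
        p1, p2 = pools[t1], pools[t2]
        for _ in range(k):
            while True:
                g1 = p1[int(rng.integers(len(p1)))]
                g2 = p2[int(rng.integers(len(p2)))]
                if g1 != g2:
                    break
            out.append(GenePair(g1, g2, "RANDOM"))
    return out


def summarize_random_statistic(per_set_values) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation over per-set statistics."""
    values = np.asarray(per_set_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 per-set values to summarize")
    return float(values.mean()), float(values.std(ddof=1))
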