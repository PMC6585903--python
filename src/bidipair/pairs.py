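"""Discovery of bidirectional and positional-control gene pairs.

Three pair classes are extracted from a gene model:

* **BG** (bidirectional): two genes on opposite strands transcribed
  divergently (head-to-head) whose TSSs are within ``max_tss_dist`` bp.
* **CG1** (convergent control): opposite strands, tail-to-tail, TES
  distance within ``max_tes_dist`` bp.
* **CG2** (tandem control): same strand, non-overlapping, intergenic gap
  between ``min_gap`` and ``max_gap`` bp.

Nested pairs (one gene's span entirely inside the other's, identical spans
included) are never reported, and control pairs containing any gene that
participates in a BG pair are purged.

Orientation rules: with a minus-strand gene M=[m1,m2] (TSS=m2, TES=m1) and
a plus-strand gene P=[p1,p2] (TSS=p1, TES=p2), the pair is head-to-head iff
m1 <= p1 and m2 <= p2 (divergent with a gap, or 5'-overlapping), and
tail-to-tail iff p1 <= m1 and p2 <= m2.  This excludes convergent short-gene
pairs whose *outer* TSSs happen to fall within the distance cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .annotation import GeneModel, GeneRecord

PairClass = Literal["BG", "CG1", "CG2", "RANDOM"]

PAIR_TABLE_COLUMNS = [
    "gene1_id",
    "gene2_id",
    "pair_class",
    "chrom",
    "distance_bp",
    "type1",
    "type2",
]


@dataclass(frozen=True)
class GenePair:
    """Unordered pair of genes; gene1_id < gene2_id canonically.

    ``distance_bp`` is the class-defining distance: |dTSS| for BG, |dTES|
    for CG1, intergenic gap for CG2; unset (-1) for RANDOM pairs.
    """

    gene1_id: str
    gene2_id: str
    pair_class: PairClass
    distance_bp: int = -1
    chrom: str = ""

    def __post_init__(self) -> None:
        if self.gene1_id >= self.gene2_id:
            g1, g2 = self.gene2_id, self.gene1_id
            object.__setattr__(self, "gene1_id", g1)
            object.__setattr__(self, "gene2_id", g2)
        if self.gene1_id == self.gene2_id:
            raise ValueError(f"pair of a gene with itself: {self.gene1_id}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene1_id, self.gene2_id)

    def genes(self) -> tuple[str, str]:
        return (self.gene1_id, self.gene2_id)


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def is_nested(a: GeneRecord, b: GeneRecord) -> bool:
    """True iff one gene's span lies entirely within the other's.

    Identical spans count as nested.  Both genes must share a chromosome.
    """
    if a.chrom != b.chrom:
        raise ValueError(
            f"is_nested requires genes on one chromosome "
            f"({a.gene_id}@{a.chrom} vs {b.gene_id}@{b.chrom})"
        )
    return (a.start >= b.start and a.end <= b.end) or (
        b.start >= a.start and b.end <= a.end
    )


def _within(dist: int, cutoff: int, inclusive: bool) -> bool:
    return dist <= cutoff if inclusive else dist < cutoff


def _is_head_to_head(minus: GeneRecord, plus: GeneRecord) -> bool:
    return minus.start <= plus.start and minus.end <= plus.end


def _is_tail_to_tail(minus: GeneRecord, plus: GeneRecord) -> bool:
    return plus.start <= minus.start and plus.end <= minus.end


def _scan_chrom(
    genes: Sequence[GeneRecord], window: int
):
    """Yield candidate gene pairs (i earlier start) within ``window`` bp.

    ``window`` bounds the largest coordinate difference any pair class can
    span; candidates are generated by a sort-and-look-ahead sweep, so the
    cost is O(n log n + pairs) instead of O(n^2).
    """
    n = len(genes)
    for i in range(n):
        gi = genes[i]
        for j in range(i + 1, n):
            gj = genes[j]
            if gj.start - gi.end > window:
                break
            yield gi, gj


def find_bg_pairs(
    model: GeneModel,
    max_tss_dist: int = 1000,
    inclusive: bool = True,
) -> list[GenePair]:
    """Bidirectional (head-to-head) pairs with TSS distance within cutoff."""
    pairs: list[GenePair] = []
    for chrom in model.chromosomes():
        genes = model.genes_on(chrom)
        for gi, gj in _scan_chrom(genes, max_tss_dist):
            if gi.strand == gj.strand:
                continue
            minus, plus = (gi, gj) if gi.strand == "-" else (gj, gi)
            d = abs(minus.tss - plus.tss)
            if not _within(d, max_tss_dist, inclusive):
                continue
            if not _is_head_to_head(minus, plus):
                continue
            if is_nested(gi, gj):
                continue
            g1, g2 = _canonical(gi.gene_id, gj.gene_id)
            pairs.append(GenePair(g1, g2, "BG", distance_bp=d, chrom=chrom))
    return sorted(pairs, key=lambda p: (p.chrom, p.gene1_id, p.gene2_id))


def find_cg1_pairs(
    model: GeneModel,
    max_tes_dist: int = 1000,
    inclusive: bool = True,
    bg_pairs: Iterable[GenePair] | None = None,
) -> list[GenePair]:
    """Convergent (tail-to-tail) control pairs with TES distance within cutoff.

    Pairs containing any gene that occurs in a BG pair are removed; by
    default BG pairs are recomputed from ``model`` with matching bounds.
    """
    if bg_pairs is None:
        bg_pairs = find_bg_pairs(model, inclusive=inclusive)
    pairs: list[GenePair] = []
    for chrom in model.chromosomes():
        genes = model.genes_on(chrom)
        for gi, gj in _scan_chrom(genes, max_tes_dist):
            if gi.strand == gj.strand:
                continue
            minus, plus = (gi, gj) if gi.strand == "-" else (gj, gi)
            d = abs(minus.tes - plus.tes)
            if not _within(d, max_tes_dist, inclusive):
                continue
            if not _is_tail_to_tail(minus, plus):
                continue
            if is_nested(gi, gj):
                continue
            g1, g2 = _canonical(gi.gene_id, gj.gene_id)
            pairs.append(GenePair(g1, g2, "CG1", distance_bp=d, chrom=chrom))
    pairs = purge_pairs_with_genes(pairs, bg_genes(bg_pairs))
    return sorted(pairs, key=lambda p: (p.chrom, p.gene1_id, p.gene2_id))


def find_cg2_pairs(
    model: GeneModel,
    min_gap: int = 1000,
    max_gap: int = 10000,
    inclusive: bool = True,
    bg_pairs: Iterable[GenePair] | None = None,
) -> list[GenePair]:
    """Tandem (same-strand) control pairs with intergenic gap in range.

    The gap is start(downstream) - end(upstream); overlapping genes yield no
    pair.  Intervening genes are allowed.  BG-containing pairs are removed.
    """
    if bg_pairs is None:
        bg_pairs = find_bg_pairs(model, inclusive=inclusive)
    pairs: list[GenePair] = []
    for chrom in model.chromosomes():
        genes = model.genes_on(chrom)
        for gi, gj in _scan_chrom(genes, max_gap):
            if gi.strand != gj.strand:
                continue
            up, down = (gi, gj) if gi.end <= gj.end else (gj, gi)
            gap = down.start - up.end
            if gap < 0:
                continue  # overlapping
            lo_ok = gap >= min_gap if inclusive else gap > min_gap
            hi_ok = gap <= max_gap if inclusive else gap < max_gap
            if not (lo_ok and hi_ok):
                continue
            if is_nested(gi, gj):
                continue
            g1, g2 = _canonical(gi.gene_id, gj.gene_id)
            pairs.append(GenePair(g1, g2, "CG2", distance_bp=gap, chrom=chrom))
    pairs = purge_pairs_with_genes(pairs, bg_genes(bg_pairs))
    return sorted(pairs, key=lambda p: (p.chrom, p.gene1_id, p.gene2_id))


def bg_genes(bg_pairs: Iterable[GenePair]) -> set[str]:
    """All gene ids participating in at least one bidirectional pair."""
    out: set[str] = set()
    for p in bg_pairs:
        out.update(p.genes())
    return out


def purge_pairs_with_genes(
    pairs: Iterable[GenePair], genes: set[str]
) -> list[GenePair]:
    return [
        p for p in pairs
        if p.gene1_id not in genes and p.gene2_id not in genes
    ]


def pair_type_composition(
    pairs: Iterable[GenePair], model: GeneModel
) -> dict[tuple[str, str], int]:
    """Counts of unordered gene-type combinations across pairs."""
    counts: dict[tuple[str, str], int] = {}
    for p in pairs:
        for gid in p.genes():
            if gid not in model:
                raise KeyError(f"pair gene {gid} not in gene model")
        t1 = model[p.gene1_id].gene_type
        t2 = model[p.gene2_id].gene_type
        combo = tuple(sorted((t1, t2)))
        counts[combo] = counts.get(combo, 0) + 1
    return counts


def pairs_to_frame(
    pairs: Iterable[GenePair], model: GeneModel | None = None
) -> pd.DataFrame:
    rows = []
    for p in pairs:
        t1 = model[p.gene1_id].gene_type if model is not None else ""
        t2 = model[p.gene2_id].gene_type if model is not None else ""
        rows.append(
            (p.gene1_id, p.gene2_id, p.pair_class, p.chrom, p.distance_bp,
             t1, t2)
        )
    return pd.DataFrame(rows, columns=PAIR_TABLE_COLUMNS)


def write_pair_table(
    pairs: Iterable[GenePair], path: str | Path,
    model: GeneModel | None = None,
) -> None:
    pairs_to_frame(pairs, model).to_csv(path, sep="\t", index=False)


def read_pair_table(path: str | Path) -> list[GenePair]:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GenePair(
            str(r.gene1_id), str(r.gene2_id), r.pair_class,
            distance_bp=int(r.distance_bp),
            chrom="" if pd.isna(r.chrom) else str(r.chrom),
        )
        for r in frame.itertuples(index=False)
    ]
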