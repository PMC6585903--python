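"""Gene-level annotation model built from GTF.

Every downstream step in this package works on gene *spans*: for each gene
the 5'-most and 3'-most boundary over its transcripts, from which the
transcription start site (TSS) and transcription end site (TES) follow by
strand.  Coordinates are GTF convention throughout: 1-based, inclusive on
both ends.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Literal

import pandas as pd

logger = logging.getLogger(__name__)

FeaturePolicy = Literal["gene_lines", "transcript_union"]

GENE_TABLE_COLUMNS = [
    "gene_id",
    "gene_type",
    "chrom",
    "strand",
    "start",
    "end",
    "tss",
    "tes",
]

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be interpreted as required."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene with derived TSS/TES.

    ``start``/``end`` are the 5'-most and 3'-most boundaries on the
    chromosome (start <= end regardless of strand); ``tss``/``tes`` are the
    strand-resolved start and end of transcription.
    """

    gene_id: str
    gene_type: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GeneModel:
    """Collection of :class:`GeneRecord` with deterministic ordering.

    Iteration order is (chrom, start, gene_id); lookup by gene_id is O(1).
    """

    def __init__(self, genes: Iterable[GeneRecord]):
        ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
        self._genes: list[GeneRecord] = ordered
        self._by_id: dict[str, GeneRecord] = {}
        for g in ordered:
            if g.gene_id in self._by_id:
                prev = self._by_id[g.gene_id]
                raise GtfParseError(
                    f"duplicate gene_id {g.gene_id} with conflicting records "
                    f"({prev.chrom}:{prev.start}-{prev.end} vs "
                    f"{g.chrom}:{g.start}-{g.end})"
                )
            self._by_id[g.gene_id] = g

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneModel):
            return NotImplemented
        return self._genes == other._genes

    def chromosomes(self) -> list[str]:
        return sorted({g.chrom for g in self._genes})

    def genes_on(self, chrom: str) -> list[GeneRecord]:
        """Genes on one chromosome, sorted by (start, gene_id)."""
        return [g for g in self._genes if g.chrom == chrom]

    def gene_types(self) -> pd.Series:
        """gene_id -> gene_type mapping."""
        return pd.Series(
            {g.gene_id: g.gene_type for g in self._genes}, name="gene_type"
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with one row per gene (deterministic row order)."""
        return pd.DataFrame(
            [
                (g.gene_id, g.gene_type, g.chrom, g.strand, g.start, g.end,
                 g.tss, g.tes)
                for g in self._genes
            ],
            columns=GENE_TABLE_COLUMNS,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneModel":
        return cls(
            GeneRecord(
                gene_id=str(r.gene_id),
                gene_type=str(r.gene_type),
                chrom=str(r.chrom),
                strand=str(r.strand),
                start=int(r.start),
                end=int(r.end),
            )
            for r in frame.itertuples(index=False)
        )


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(
    path: str | Path, feature_policy: FeaturePolicy = "gene_lines"
) -> GeneModel:
    """Parse a GENCODE-dialect GTF into a :class:`GeneModel`.

    Parameters
    ----------
    path
        GTF file, optionally gzip-compressed.  Attribute column must carry
        ``gene_id`` and (ideally) ``gene_type`` keys.
    feature_policy
        ``gene_lines``: take each gene's span from its ``gene`` feature row,
        falling back to the union of its ``transcript`` rows for genes that
        have no gene row.  ``transcript_union``: always use
        [min transcript start, max transcript end].

    Strand values other than ``+``/``-`` cause the record to be skipped with
    a logged warning; a feature row without ``gene_id`` is a parse error.
    """
    if feature_policy not in ("gene_lines", "transcript_union"):
        raise ValueError(f"unknown feature_policy {feature_policy!r}")

    # per gene: [chrom, strand, gene_type, gene_span|None, tx_span|None]
    acc: dict[str, list] = {}
    wanted = {"gene", "transcript"}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            feature = fields[2]
            if feature not in wanted:
                continue
            attrs = _parse_attributes(fields[8])
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise GtfParseError(f"line {lineno}: missing gene_id attribute")
            chrom, strand = fields[0], fields[6]
            if strand not in ("+", "-"):
                logger.warning(
                    "line %d: gene %s has strand %r; record skipped",
                    lineno, gene_id, strand,
                )
                continue
            start, end = int(fields[3]), int(fields[4])
            gene_type = attrs.get("gene_type", "")

            entry = acc.get(gene_id)
            if entry is None:
                entry = acc[gene_id] = [chrom, strand, gene_type, None, None]
            elif entry[0] != chrom or entry[1] != strand:
                raise GtfParseError(
                    f"line {lineno}: gene {gene_id} appears on conflicting "
                    f"chromosome/strand"
                )
            if feature == "gene":
                if entry[3] is not None and entry[3] != (start, end):
                    raise GtfParseError(
                        f"line {lineno}: duplicate gene row for {gene_id} "
                        f"with conflicting coordinates"
                    )
                entry[3] = (start, end)
            else:
                tx = entry[4]
                entry[4] = (
                    (start, end) if tx is None
                    else (min(tx[0], start), max(tx[1], end))
                )
            if gene_type and not entry[2]:
                entry[2] = gene_type

    records = []
    for gid, (chrom, strand, gtype, gene_span, tx_span) in acc.items():
        if feature_policy == "gene_lines":
            span = gene_span if gene_span is not None else tx_span
        else:
            span = tx_span if tx_span is not None else gene_span
        records.append(
            GeneRecord(
                gene_id=gid, gene_type=gtype, chrom=chrom, strand=strand,
                start=span[0], end=span[1],
            )
        )
    model = GeneModel(records)
    logger.info("read %d genes from %s (%s)", len(model), path, feature_policy)
    return model


def write_gene_table(model: GeneModel, path: str | Path) -> None:
    """Write the gene model as a TSV that round-trips via read_gene_table."""
    if len(model) == 0:
        logger.warning("writing header-only gene table (empty model): %s", path)
    model.to_frame().to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path) -> GeneModel:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    missing = set(GENE_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"gene table {path} missing columns: {sorted(missing)}")
    return GeneModel.from_frame(frame)
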