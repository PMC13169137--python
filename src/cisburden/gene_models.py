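"""Gene annotation loading (GFF3/BED) and interval-indexed overlap queries.

Internally everything is 1-based with closed intervals, matching GFF3
and GWAS-Catalog position semantics; BED's 0-based half-open
coordinates are converted at the I/O boundary.  Only ``gene`` features
are read from GFF3; the gene extent is the gene body span, which
contains the transcription start site, so gene-body overlap subsumes
TSS overlap for cis-window queries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
from intervaltree import IntervalTree

from .errors import ConfigurationError, InputDataError
from .gwas_io import normalize_chrom

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """One gene interval (1-based, closed)."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"  # "+", "-" or "unknown"
    biotype: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid gene interval [{self.start}, {self.end}]")

    @property
    def tss(self) -> int:
        """Transcription start site: 5' end on the gene's strand."""
        return self.end if self.strand == "-" else self.start


def _dedupe(genes: list[GeneModel]) -> list[GeneModel]:
    seen: set[str] = set()
    out: list[GeneModel] = []
    for g in genes:
        if g.gene_id in seen:
            logger.warning("duplicate gene_id %s: keeping first occurrence", g.gene_id)
            continue
        seen.add(g.gene_id)
        out.append(g)
    return out


def _read_gff3(path: Path, biotype_filter: set[str]) -> tuple[list[GeneModel], int]:
    # Pre-screen rows so a malformed line drops with a warning instead of
    # aborting the whole parse.
    kept_lines: list[str] = []
    n_bad = 0
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            kept_lines.append(line)
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            n_bad += 1
            continue
        try:
            start, end = int(fields[3]), int(fields[4])
            if start < 1 or end < start:
                raise ValueError
        except ValueError:
            n_bad += 1
            continue
        kept_lines.append(line)
    if n_bad:
        logger.warning("%s: dropped %d malformed GFF3 rows", path, n_bad)

    db = gffutils.create_db(
        "\n".join(kept_lines),
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        chrom = normalize_chrom(feat.seqid)
        if chrom is None:
            n_bad += 1
            continue

        def attr(*names: str, default: str = "") -> str:
            for n in names:
                values = feat.attributes.get(n)
                if values:
                    return values[0]
            return default

        gene_id = attr("gene_id", "ID", default=feat.id)
        biotype = attr("gene_biotype", "gene_type", "biotype")
        if biotype_filter and biotype not in biotype_filter:
            continue
        genes.append(
            GeneModel(
                gene_id=gene_id,
                symbol=attr("gene_name", "Name", default=gene_id),
                chrom=chrom,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "unknown",
                biotype=biotype,
            )
        )
    return genes, n_bad


def _read_bed(path: Path, biotype_filter: set[str]) -> tuple[list[GeneModel], int]:
    genes: list[GeneModel] = []
    n_bad = 0
    for i, line in enumerate(path.read_text().splitlines()):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 3:
            n_bad += 1
            continue
        chrom = normalize_chrom(fields[0])
        try:
            start0, end0 = int(fields[1]), int(fields[2])
            if chrom is None or start0 < 0 or end0 <= start0:
                raise ValueError
        except ValueError:
            n_bad += 1
            continue
        name = fields[3] if len(fields) > 3 else f"bed_gene_{i}"
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "unknown"
        biotype = fields[6] if len(fields) > 6 else ""
        if biotype_filter and biotype not in biotype_filter:
            continue
        # BED half-open [start0, end0) -> 1-based closed [start0+1, end0]
        genes.append(GeneModel(name, name, chrom, start0 + 1, end0, strand, biotype))
    if n_bad:
        logger.warning("%s: dropped %d malformed BED rows", path, n_bad)
    return genes, n_bad


def read_gene_models(
    path: str | Path,
    format: str | None = None,
    biotype_filter: set[str] | frozenset[str] = frozenset(),
) -> list[GeneModel]:
    """Load gene models from GFF3 or BED.

    ``format`` is ``"gff3"`` or ``"bed"``; when None it is inferred from
    the file extension.  Malformed rows are dropped with a counted
    warning; duplicate gene ids keep the first occurrence.  Loading zero
    genes is fatal.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "bed" if suffix == ".bed" else "gff3"
    if format not in ("gff3", "bed"):
        raise ConfigurationError(f"unknown gene-model format {format!r}")
    reader = _read_gff3 if format == "gff3" else _read_bed
    genes, _ = reader(path, set(biotype_filter))
    genes = _dedupe(genes)
    if not genes:
        raise InputDataError(f"no gene models loaded from {path}")
    return genes


def write_bed(genes: list[GeneModel], path: str | Path) -> None:
    """Write genes as BED6+1 (name, placeholder score, strand, biotype)."""
    with open(path, "w") as fh:
        for g in genes:
            strand = g.strand if g.strand in ("+", "-") else "."
            fh.write(
                f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{strand}\t{g.biotype}\n"
            )


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write genes as GFF3 ``gene`` features with GENCODE-style attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            strand = g.strand if g.strand in ("+", "-") else "."
            attrs = (
                f"ID={g.gene_id};gene_id={g.gene_id};gene_name={g.symbol};"
                f"gene_biotype={g.biotype}"
            )
            fh.write(
                f"{g.chrom}\tcisburden\tgene\t{g.start}\t{g.end}\t.\t{strand}\t.\t{attrs}\n"
            )


class GeneIndex:
    """Per-chromosome interval index over gene models.

    ``query(chrom, a, b)`` returns exactly the genes overlapping the
    closed interval [a, b], i.e. those with
    ``max(start, a) <= min(end, b)`` — identical to a linear scan.
    """

    def __init__(self, genes: list[GeneModel]):
        if not genes:
            raise InputDataError("cannot build an index over zero genes")
        self._trees: dict[str, IntervalTree] = {}
        self.n_genes = len(genes)
        for g in genes:
            # closed [start, end] -> half-open [start, end + 1)
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)

    def query(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None or end < start:
            return []
        hits = [iv.data for iv in tree.overlap(start, end + 1)]
        return sorted(hits, key=lambda g: (g.start, g.end, g.gene_id))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._trees)


def build_index(genes: list[GeneModel]) -> GeneIndex:
    """Build a :class:`GeneIndex` over the given genes."""
    return GeneIndex(genes)
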