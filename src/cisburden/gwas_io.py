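"""Read, harmonize, filter and QC GWAS-Catalog-style association tables.

The functions here turn a raw tab-separated association export into a
clean list of :class:`Variant` records ready for cis-window mapping:

1. :func:`read_associations` — parse and harmonize rows (chromosome
   naming, positions, mantissa–exponent p-values), dropping and counting
   anything unparseable;
2. :func:`filter_traits` — ontology-term / keyword trait selection;
3. :func:`filter_significant` — genome-wide significance (p < 5e-8 by
   default, strict);
4. :func:`deduplicate` — one record per (variant id, trait), keeping the
   smallest p-value;
5. :func:`qc_rsid` — flag rsID vs non-rsID identifiers (records are
   never removed by this step).

All coordinates are 1-based; chromosomes are stored without a ``chr``
prefix and restricted to ``1..22, X, Y, MT``.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

#: Canonical chromosome names used internally (no "chr" prefix).
VALID_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X", "Y", "MT"])

_RSID_RE = re.compile(r"^rs\d+$")

#: Column mapping for a GWAS-Catalog association export.  Keys are the
#: internal field names, values the column headers expected in the file.
DEFAULT_DIALECT: dict[str, str] = {
    "variant_id": "SNPS",
    "chrom": "CHR_ID",
    "pos": "CHR_POS",
    "pvalue": "P-VALUE",
    "trait_label": "DISEASE/TRAIT",
    "ontology_term": "MAPPED_TRAIT_URI",
    "consequence": "CONTEXT",
    "effect_size": "OR or BETA",
    "stderr": "SE",
    # optional; when present with more than one distinct value the file
    # mixes genome builds and is rejected
    "genome_build": "GENOME_BUILD",
}

#: Fields that must be resolvable for a row to become a Variant.
MANDATORY_FIELDS = ("variant_id", "chrom", "pos", "pvalue", "trait_label")


@dataclass
class Variant:
    """One genome-wide association record."""

    variant_id: str
    chrom: str
    pos: int
    pvalue: float
    trait_label: str
    ontology_term: str = ""
    consequence: str = ""
    effect_size: float | None = None
    stderr: float | None = None
    is_rsid: bool = False

    def __post_init__(self) -> None:
        self.is_rsid = bool(_RSID_RE.match(self.variant_id))


@dataclass
class ReadReport:
    """Row-level bookkeeping from :func:`read_associations`."""

    n_rows: int = 0
    n_variants: int = 0
    n_dropped: int = 0
    dropped_by_reason: dict[str, int] = field(default_factory=dict)


@dataclass
class FilterReport:
    """Counts tracked through the trait → significance → dedup chain."""

    n_input: int = 0
    n_after_trait_filter: int = 0
    n_after_significance: int = 0
    n_duplicates_removed: int = 0
    n_rsid: int = 0
    n_non_rsid: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_after_significance - self.n_duplicates_removed

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def load_dialect(path: str | Path) -> dict[str, str]:
    """Load a column-mapping dialect from a YAML file.

    The file maps internal field names to column headers; unknown field
    names are rejected so typos fail loudly.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"dialect file {path} must map field names to column names")
    unknown = set(raw) - set(DEFAULT_DIALECT)
    if unknown:
        raise ConfigurationError(f"dialect file {path} names unknown fields: {sorted(unknown)}")
    return dict(raw)


def normalize_chrom(raw: str) -> str | None:
    """Harmonize a chromosome label to ``1..22, X, Y, MT`` or None."""
    c = raw.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper()
    if c == "M":
        c = "MT"
    return c if c in VALID_CHROMS else None


def _normalize_ontology_term(raw: str) -> str:
    """Reduce an EFO URI like ``.../EFO_0004698`` to ``EFO:0004698``.

    Plain accessions pass through unchanged; multiple comma-separated
    URIs keep only the first (the Catalog's primary mapped trait).
    """
    term = raw.strip().split(",")[0].strip()
    if not term:
        return ""
    tail = term.rstrip("/").rsplit("/", 1)[-1]
    return tail.replace("_", ":", 1) if "_" in tail else tail


def _split_variant_ids(raw: str) -> list[str]:
    """Split multi-SNP entries (haplotypes, interactions) into rsIDs.

    Catalog ``SNPS`` fields may list several identifiers separated by
    ``;``, ``,`` or `` x ``; one record is emitted per identifier.
    """
    parts = re.split(r";|,|\sx\s", raw)
    return [p.strip() for p in parts if p.strip()]


def read_associations(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> tuple[list[Variant], ReadReport]:
    """Parse a tab-separated association table into Variant records.

    Rows whose chromosome, position or p-value cannot be parsed (or fall
    outside valid ranges) are dropped and counted per reason in the
    returned :class:`ReadReport`.

    Raises
    ------
    ConfigurationError
        If a mandatory column named by the dialect is absent, or if a
        genome-build column is present with more than one distinct value
        (mixed-build input).
    """
    dialect = dict(dialect or DEFAULT_DIALECT)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    report = ReadReport(n_rows=len(df))

    missing = [
        f for f in MANDATORY_FIELDS
        if f not in dialect or dialect[f] not in df.columns
    ]
    if missing:
        raise ConfigurationError(
            f"association table {path} lacks mandatory columns for fields {missing} "
            f"under the active dialect"
        )
    if len(df) == 0:
        logger.warning("association table %s is empty", path)
        return [], report

    build_col = dialect.get("genome_build")
    if build_col and build_col in df.columns:
        builds = {b for b in df[build_col].str.strip() if b}
        if len(builds) > 1:
            raise ConfigurationError(
                f"association table {path} mixes genome builds: {sorted(builds)}"
            )

    def col(field_name: str, row) -> str:
        name = dialect.get(field_name)
        return str(row[name]).strip() if name and name in df.columns else ""

    variants: list[Variant] = []
    drops = report.dropped_by_reason
    for _, row in df.iterrows():
        chrom = normalize_chrom(col("chrom", row))
        if chrom is None:
            drops["bad_chromosome"] = drops.get("bad_chromosome", 0) + 1
            continue
        try:
            pos = int(float(col("pos", row)))
            if pos < 1:
                raise ValueError
        except ValueError:
            drops["bad_position"] = drops.get("bad_position", 0) + 1
            continue
        try:
            pvalue = float(col("pvalue", row))
            if not (0.0 < pvalue <= 1.0):
                raise ValueError
        except ValueError:
            drops["bad_pvalue"] = drops.get("bad_pvalue", 0) + 1
            continue
        ids = _split_variant_ids(col("variant_id", row))
        if not ids:
            drops["missing_variant_id"] = drops.get("missing_variant_id", 0) + 1
            continue

        def _opt_float(s: str) -> float | None:
            try:
                return float(s)
            except ValueError:
                return None

        for vid in ids:
            variants.append(
                Variant(
                    variant_id=vid,
                    chrom=chrom,
                    pos=pos,
                    pvalue=pvalue,
                    trait_label=col("trait_label", row),
                    ontology_term=_normalize_ontology_term(col("ontology_term", row)),
                    consequence=col("consequence", row),
                    effect_size=_opt_float(col("effect_size", row)),
                    stderr=_opt_float(col("stderr", row)),
                )
            )
    report.n_variants = len(variants)
    report.n_dropped = sum(drops.values())
    return variants, report


def filter_traits(
    variants: Sequence[Variant],
    include_terms: Iterable[str] = (),
    include_keywords: Iterable[str] = (),
) -> list[Variant]:
    """Keep variants whose ontology term or trait label matches a selector.

    A variant is retained iff its ontology term is in ``include_terms``
    OR its lower-cased trait label contains any lower-cased keyword.
    Order is preserved.  Passing two empty selector sets is a
    configuration error: silent pass-through is forbidden.
    """
    terms = set(include_terms)
    keywords = {k.lower() for k in include_keywords}
    if not terms and not keywords:
        raise ConfigurationError(
            "trait filtering requires at least one ontology term or keyword"
        )

    def keep(v: Variant) -> bool:
        if v.ontology_term and v.ontology_term in terms:
            return True
        label = v.trait_label.lower()
        return any(k in label for k in keywords)

    return [v for v in variants if keep(v)]


def filter_significant(variants: Sequence[Variant], alpha: float = 5e-8) -> list[Variant]:
    """Keep variants reaching genome-wide significance: p strictly < alpha."""
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"significance threshold must be in (0, 1), got {alpha}")
    return [v for v in variants if v.pvalue < alpha]


def deduplicate(variants: Sequence[Variant]) -> tuple[list[Variant], int]:
    """Collapse duplicate (variant_id, trait_label) records.

    Among duplicates the record with the smallest p-value wins, ties
    broken by first occurrence; a variant reported under two distinct
    traits yields two records.  Returns (deduplicated list, number of
    records removed), with first-occurrence key order preserved.
    """
    best: dict[tuple[str, str], Variant] = {}
    for v in variants:
        key = (v.variant_id, v.trait_label)
        cur = best.get(key)
        if cur is None or v.pvalue < cur.pvalue:
            best[key] = v
    return list(best.values()), len(variants) - len(best)


def qc_rsid(variants: Sequence[Variant], report: FilterReport | None = None) -> FilterReport:
    """Flag each variant as rsID / non-rsID and tally the split.

    Non-rsID identifiers (e.g. ``7:99921777_C_T``) are flagged but never
    removed.  Counts are written into ``report`` when given, else a
    fresh :class:`FilterReport` is returned.
    """
    report = report or FilterReport()
    n_rs = 0
    for v in variants:
        v.is_rsid = bool(_RSID_RE.match(v.variant_id))
        n_rs += v.is_rsid
    report.n_rsid = n_rs
    report.n_non_rsid = len(variants) - n_rs
    return report


_VARIANT_COLUMNS = [
    "variant_id", "chrom", "pos", "pvalue", "trait_label",
    "ontology_term", "consequence", "effect_size", "stderr", "is_rsid",
]


def write_variants_tsv(variants: Sequence[Variant], path: str | Path) -> None:
    """Write the cleaned variant table as TSV."""
    df = pd.DataFrame([asdict(v) for v in variants], columns=_VARIANT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
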