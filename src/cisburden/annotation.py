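"""Consequence classification and genome-wide landscape summaries.

Variant consequence strings (Sequence-Ontology style, e.g.
``missense_variant``) are classified into a two-level taxonomy:

* top level: coding / noncoding / unknown;
* coding subclasses: missense, stop_gained, frameshift, splice_related,
  other_coding;
* regulatory (noncoding) subclasses: utr, regulatory_region,
  splice_region, tfbs, intronic, intergenic, other_noncoding.

The mapping ships as an editable YAML vocabulary
(``data/consequence_vocabulary.yaml``).  Splice terms are split between
the two branches: splice acceptor/donor variants disrupt the transcript
and are treated as coding ``splice_related``, while
``splice_region_variant`` is a noncoding ``splice_region`` annotation.
Multi-term strings resolve to the most severe term under a configured
severity order.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigurationError
from .gwas_io import Variant

__all__ = [
    "TopLevel", "CodingSubclass", "RegulatorySubclass", "ConsequenceClass",
    "LandscapeSummary", "default_vocabulary", "load_vocabulary",
    "classify_consequence", "summarize_landscape", "KARYOTYPE_ORDER",
]


class TopLevel(str, Enum):
    CODING = "coding"
    NONCODING = "noncoding"
    UNKNOWN = "unknown"


class CodingSubclass(str, Enum):
    MISSENSE = "missense"
    STOP_GAINED = "stop_gained"
    FRAMESHIFT = "frameshift"
    SPLICE_RELATED = "splice_related"
    OTHER_CODING = "other_coding"
    NONE = "none"


class RegulatorySubclass(str, Enum):
    UTR = "utr"
    REGULATORY_REGION = "regulatory_region"
    SPLICE_REGION = "splice_region"
    TFBS = "tfbs"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    OTHER_NONCODING = "other_noncoding"
    NONE = "none"


@dataclass(frozen=True)
class ConsequenceClass:
    """Classification of one raw consequence string."""

    raw_term: str
    top_level: TopLevel
    coding_subclass: CodingSubclass = CodingSubclass.NONE
    regulatory_subclass: RegulatorySubclass = RegulatorySubclass.NONE

    def __post_init__(self) -> None:
        if self.top_level is TopLevel.CODING and self.regulatory_subclass is not RegulatorySubclass.NONE:
            raise ValueError("coding class cannot carry a regulatory subclass")
        if self.top_level is TopLevel.NONCODING and self.coding_subclass is not CodingSubclass.NONE:
            raise ValueError("noncoding class cannot carry a coding subclass")


#: Most-severe-first order over subclasses, used to resolve multi-term
#: consequence strings.  other_coding ranks below the named coding
#: classes; other_noncoding below the named regulatory classes.
SEVERITY_ORDER: list[tuple[TopLevel, str]] = [
    (TopLevel.CODING, CodingSubclass.STOP_GAINED.value),
    (TopLevel.CODING, CodingSubclass.FRAMESHIFT.value),
    (TopLevel.CODING, CodingSubclass.SPLICE_RELATED.value),
    (TopLevel.CODING, CodingSubclass.MISSENSE.value),
    (TopLevel.CODING, CodingSubclass.OTHER_CODING.value),
    (TopLevel.NONCODING, RegulatorySubclass.UTR.value),
    (TopLevel.NONCODING, RegulatorySubclass.SPLICE_REGION.value),
    (TopLevel.NONCODING, RegulatorySubclass.TFBS.value),
    (TopLevel.NONCODING, RegulatorySubclass.REGULATORY_REGION.value),
    (TopLevel.NONCODING, RegulatorySubclass.INTRONIC.value),
    (TopLevel.NONCODING, RegulatorySubclass.INTERGENIC.value),
    (TopLevel.NONCODING, RegulatorySubclass.OTHER_NONCODING.value),
]

_SEVERITY_RANK = {pair: i for i, pair in enumerate(SEVERITY_ORDER)}

Vocabulary = Mapping[str, tuple[TopLevel, str]]

_default_vocabulary_cache: dict[str, tuple[TopLevel, str]] | None = None


def _parse_vocabulary(raw: Mapping) -> dict[str, tuple[TopLevel, str]]:
    vocab: dict[str, tuple[TopLevel, str]] = {}
    for term, entry in raw.items():
        try:
            top = TopLevel(entry["top_level"])
            sub = entry["subclass"]
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"bad vocabulary entry for {term!r}: {entry!r}") from exc
        if top is TopLevel.CODING:
            CodingSubclass(sub)
        elif top is TopLevel.NONCODING:
            RegulatorySubclass(sub)
        else:
            raise ConfigurationError(f"vocabulary entry {term!r} may not map to 'unknown'")
        vocab[term.lower()] = (top, sub)
    return vocab


def default_vocabulary() -> dict[str, tuple[TopLevel, str]]:
    """The packaged Sequence-Ontology term mapping (read once, cached)."""
    global _default_vocabulary_cache
    if _default_vocabulary_cache is None:
        text = resources.files("cisburden.data").joinpath("consequence_vocabulary.yaml").read_text()
        _default_vocabulary_cache = _parse_vocabulary(yaml.safe_load(text))
    return _default_vocabulary_cache


def load_vocabulary(path: str | Path) -> dict[str, tuple[TopLevel, str]]:
    """Load a user-edited vocabulary YAML (same layout as the packaged one)."""
    return _parse_vocabulary(yaml.safe_load(Path(path).read_text()))


def _class_from_entry(raw_term: str, top: TopLevel, sub: str) -> ConsequenceClass:
    if top is TopLevel.CODING:
        return ConsequenceClass(raw_term, top, coding_subclass=CodingSubclass(sub))
    return ConsequenceClass(raw_term, top, regulatory_subclass=RegulatorySubclass(sub))


def classify_consequence(
    raw_term: str,
    vocabulary: Vocabulary | None = None,
    unknown_counter: Counter | None = None,
) -> ConsequenceClass:
    """Classify one consequence string via deterministic vocabulary lookup.

    Comma- or ampersand-separated multi-term strings resolve to the most
    severe recognized term.  Terms absent from the vocabulary count into
    ``unknown_counter`` when given; a string with no recognized term
    (or an empty string) classifies as unknown.
    """
    vocabulary = vocabulary if vocabulary is not None else default_vocabulary()
    terms = [t.strip() for t in re.split(r"[,&;]", raw_term) if t.strip()]
    best: tuple[int, TopLevel, str] | None = None
    for term in terms:
        entry = vocabulary.get(term.lower())
        if entry is None:
            if unknown_counter is not None:
                unknown_counter[term] += 1
            continue
        rank = _SEVERITY_RANK[(entry[0], entry[1])]
        if best is None or rank < best[0]:
            best = (rank, entry[0], entry[1])
    if best is None:
        return ConsequenceClass(raw_term, TopLevel.UNKNOWN)
    return _class_from_entry(raw_term, best[1], best[2])


KARYOTYPE_ORDER = [str(i) for i in range(1, 23)] + ["X", "Y", "MT"]
_KARYOTYPE_RANK = {c: i for i, c in enumerate(KARYOTYPE_ORDER)}


@dataclass
class LandscapeSummary:
    """Chromosome-wise counts, cumulative density profile and class tallies."""

    per_chrom_counts: dict[str, int] = field(default_factory=dict)
    #: (chrom, pos, cumulative count within that chromosome), ordered by
    #: karyotype then position.
    cumulative_profile: list[tuple[str, int, int]] = field(default_factory=list)
    top_level_counts: dict[str, int] = field(default_factory=dict)
    coding_subclass_counts: dict[str, int] = field(default_factory=dict)
    regulatory_subclass_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return sum(self.per_chrom_counts.values())


def summarize_landscape(
    variants: Sequence[Variant],
    classes: Sequence[ConsequenceClass],
) -> LandscapeSummary:
    """Summarize the genomic and functional landscape of retained variants.

    ``classes`` must align one-to-one with ``variants``.  The cumulative
    profile orders variants by (karyotype order, position) and counts
    within each chromosome, so the last entry per chromosome equals that
    chromosome's total.
    """
    if len(variants) != len(classes):
        raise ValueError("variants and classes must align one-to-one")

    per_chrom = Counter(v.chrom for v in variants)
    ordered = sorted(variants, key=lambda v: (_KARYOTYPE_RANK[v.chrom], v.pos))
    profile: list[tuple[str, int, int]] = []
    running: Counter = Counter()
    for v in ordered:
        running[v.chrom] += 1
        profile.append((v.chrom, v.pos, running[v.chrom]))

    top = Counter(c.top_level.value for c in classes)
    coding = Counter(
        c.coding_subclass.value for c in classes if c.coding_subclass is not CodingSubclass.NONE
    )
    regulatory = Counter(
        c.regulatory_subclass.value
        for c in classes
        if c.regulatory_subclass is not RegulatorySubclass.NONE
    )
    return LandscapeSummary(
        per_chrom_counts=dict(per_chrom),
        cumulative_profile=profile,
        top_level_counts=dict(top),
        coding_subclass_counts=dict(coding),
        regulatory_subclass_counts=dict(regulatory),
    )
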