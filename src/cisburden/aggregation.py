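"""Gene-level SNP burden aggregation and candidate prioritization.

Mapped SNPs are aggregated per gene into a burden — the number of
distinct independent variants whose cis window intersects the gene.
Independence means distinct reported lead variants (distinct variant
ids); no LD pruning is applied.  A variant supporting the same gene
under several traits counts once (set semantics on variant id).
Candidate genes are prioritized by requiring a minimum burden
(default >= 2 independent SNPs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .cismap import SnpGeneLink
from .errors import ConfigurationError


@dataclass
class GeneBurden:
    """Per-gene count of distinct supporting variants."""

    gene_id: str
    symbol: str
    variant_ids: frozenset[str]

    @property
    def snp_count(self) -> int:
        return len(self.variant_ids)


def aggregate_burden(links: Sequence[SnpGeneLink]) -> list[GeneBurden]:
    """One burden record per gene with at least one link.

    Output ordered by descending burden, ties broken alphabetically by
    symbol then gene id, so top-ranked gene reports are deterministic.
    The result is invariant to link ordering and duplicated link rows.
    """
    per_gene: dict[str, set[str]] = {}
    symbols: dict[str, str] = {}
    for link in links:
        per_gene.setdefault(link.gene_id, set()).add(link.variant_id)
        symbols.setdefault(link.gene_id, link.symbol)
    burdens = [
        GeneBurden(gene_id=gid, symbol=symbols[gid], variant_ids=frozenset(vids))
        for gid, vids in per_gene.items()
    ]
    burdens.sort(key=lambda b: (-b.snp_count, b.symbol, b.gene_id))
    return burdens


def threshold_curve(
    burdens: Sequence[GeneBurden],
    ks: Sequence[int] = (1, 2, 3),
) -> list[tuple[int, int]]:
    """Number of genes with burden >= k for each threshold k.

    ``ks`` must be ascending with every k >= 1; the counts are
    non-increasing in k and the k=1 count equals the number of genes
    with any link.
    """
    if any(k < 1 for k in ks) or list(ks) != sorted(ks):
        raise ConfigurationError(f"thresholds must be ascending and >= 1, got {list(ks)}")
    counts = [b.snp_count for b in burdens]
    return [(k, sum(c >= k for c in counts)) for k in ks]


def prioritize(burdens: Sequence[GeneBurden], min_snps: int = 2) -> set[str]:
    """Gene ids supported by at least ``min_snps`` independent variants."""
    if min_snps < 1:
        raise ConfigurationError(f"min_snps must be >= 1, got {min_snps}")
    return {b.gene_id for b in burdens if b.snp_count >= min_snps}


def write_burden_tsv(burdens: Sequence[GeneBurden], path: str | Path) -> None:
    pd.DataFrame(
        [
            (b.gene_id, b.symbol, b.snp_count, ",".join(sorted(b.variant_ids)))
            for b in burdens
        ],
        columns=["gene_id", "symbol", "snp_count", "variant_ids"],
    ).to_csv(path, sep="\t", index=False)


def write_threshold_curve_tsv(curve: Sequence[tuple[int, int]], path: str | Path) -> None:
    pd.DataFrame(curve, columns=["min_snps", "n_genes"]).to_csv(path, sep="\t", index=False)
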