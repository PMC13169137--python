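"""Cis-window SNP-to-gene mapping and multiplicity profiling.

Each genome-wide significant variant is linked to every gene whose body
overlaps the symmetric cis-regulatory window ``[pos - W, pos + W]``
(default W = 50 kb, closed interval: a gene edge exactly W away is
linked).  Per-SNP gene counts quantify regulatory multiplicity — how
many candidate target genes a single association signal touches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ConfigurationError
from .gene_models import GeneIndex, GeneModel
from .gwas_io import Variant


@dataclass(frozen=True)
class SnpGeneLink:
    """One variant-to-gene cis-window assignment."""

    variant_id: str
    trait_label: str
    gene_id: str
    symbol: str
    #: 0 if the SNP lies inside the gene body, else the gap to the
    #: nearest gene edge (always <= the window half-width).
    distance: int
    #: Signed distance to the TSS on the gene's strand; negative =
    #: upstream of the TSS.
    signed_tss_distance: int


def _link(variant: Variant, gene: GeneModel) -> SnpGeneLink:
    if gene.start <= variant.pos <= gene.end:
        distance = 0
    else:
        distance = min(abs(variant.pos - gene.start), abs(variant.pos - gene.end))
    if gene.strand == "-":
        signed = gene.tss - variant.pos
    else:
        signed = variant.pos - gene.tss
    return SnpGeneLink(
        variant_id=variant.variant_id,
        trait_label=variant.trait_label,
        gene_id=gene.gene_id,
        symbol=gene.symbol,
        distance=distance,
        signed_tss_distance=signed,
    )


def map_snps_to_genes(
    variants: Sequence[Variant],
    index: GeneIndex,
    window_bp: int = 50_000,
) -> list[SnpGeneLink]:
    """Link every variant to all genes within its +/- ``window_bp`` window.

    The window is clamped at position 1 on the left.  Variants on
    contigs absent from the annotation simply produce no links; they
    are counted as unmapped by :func:`multiplicity_profile`, never
    treated as errors.
    """
    if window_bp < 0:
        raise ConfigurationError(f"window_bp must be >= 0, got {window_bp}")
    links: list[SnpGeneLink] = []
    for v in variants:
        lo = max(1, v.pos - window_bp)
        hi = v.pos + window_bp
        for gene in index.query(v.chrom, lo, hi):
            links.append(_link(v, gene))
    return links


@dataclass
class MultiplicityProfile:
    """Distribution of genes-per-SNP over mapped variants."""

    genes_per_snp: dict[str, int] = field(default_factory=dict)
    #: gene count k -> number of SNPs mapped to exactly k genes
    histogram: dict[int, int] = field(default_factory=dict)
    #: (k, fraction of mapped SNPs with <= k genes), non-decreasing,
    #: ending at 1.0
    cumulative: list[tuple[int, float]] = field(default_factory=list)
    n_unmapped: int = 0


def multiplicity_profile(
    links: Sequence[SnpGeneLink],
    all_variants: Sequence[Variant],
) -> MultiplicityProfile:
    """Tally distinct genes per variant and the unmapped remainder.

    A variant reported under several traits contributes once: gene
    counts are over distinct (variant_id, gene_id) pairs, and the
    unmapped count is over distinct variant ids with no link at all.
    """
    genes_by_snp: dict[str, set[str]] = {}
    for link in links:
        genes_by_snp.setdefault(link.variant_id, set()).add(link.gene_id)
    genes_per_snp = {vid: len(gs) for vid, gs in genes_by_snp.items()}

    histogram: dict[int, int] = {}
    for count in genes_per_snp.values():
        histogram[count] = histogram.get(count, 0) + 1

    n_mapped = len(genes_per_snp)
    cumulative: list[tuple[int, float]] = []
    running = 0
    for k in sorted(histogram):
        running += histogram[k]
        cumulative.append((k, running / n_mapped))

    all_ids = {v.variant_id for v in all_variants}
    n_unmapped = len(all_ids - set(genes_per_snp))
    return MultiplicityProfile(
        genes_per_snp=genes_per_snp,
        histogram=histogram,
        cumulative=cumulative,
        n_unmapped=n_unmapped,
    )


def write_links_tsv(links: Sequence[SnpGeneLink], path: str | Path) -> None:
    pd.DataFrame(
        [
            (l.variant_id, l.trait_label, l.gene_id, l.symbol, l.distance, l.signed_tss_distance)
            for l in links
        ],
        columns=["variant_id", "trait_label", "gene_id", "symbol", "distance", "signed_tss_distance"],
    ).to_csv(path, sep="\t", index=False)


def write_multiplicity_tsv(profile: MultiplicityProfile, path: str | Path) -> None:
    rows = [(k, profile.histogram[k]) for k in sorted(profile.histogram)]
    df = pd.DataFrame(rows, columns=["genes_per_snp", "n_snps"])
    cum = dict(profile.cumulative)
    df["cumulative_fraction"] = [cum[k] for k in df["genes_per_snp"]]
    df.to_csv(path, sep="\t", index=False)
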