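"""Hypergeometric over-representation analysis with BH correction and
Jaccard term clustering.

Given a prioritized query gene set, a GMT gene-set collection and a
background universe, each set is scored with the upper-tail
hypergeometric probability

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

where N is the universe size, K the set's genes inside the universe,
n the query size and k the observed overlap.  Raw p-values are adjusted
with the Benjamini–Hochberg step-up, significant terms are selected at
adjusted p < alpha (strict), and related terms are grouped by
single-linkage connected components over pairwise Jaccard similarity of
their gene membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ConfigurationError, InputDataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    genes: frozenset[str]
    collection: str = "custom"  # go_bp | kegg | custom


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    name: str
    k_overlap: int
    n_query: int
    K_set: int
    N_universe: int
    p_value: float
    overlap_genes: frozenset[str]
    p_adjusted: float | None = None


@dataclass(frozen=True)
class TermSimilarityCluster:
    cluster_id: int
    member_set_ids: tuple[str, ...]
    representative_set_id: str


def read_gmt(path: str | Path, collection: str = "custom") -> list[GeneSet]:
    """Read a GMT file: one set per line as ``id<TAB>description<TAB>genes...``.

    Duplicate genes within a line collapse; lines with fewer than three
    fields are skipped with a warning; an empty collection is fatal.
    """
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            logger.warning("%s line %d: fewer than 3 fields, skipped", path, lineno)
            continue
        set_id, name = fields[0], fields[1]
        genes = frozenset(g for g in fields[2:] if g)
        if genes:
            sets.append(GeneSet(set_id=set_id, name=name, genes=genes, collection=collection))
    if not sets:
        raise InputDataError(f"no gene sets loaded from {path}")
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.genes)]) + "\n")


def hypergeom_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Population N with K successes, n draws, k observed successes; the
    degenerate case k = 0 returns exactly 1.
    """
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_ora(
    query: Iterable[str],
    sets: Sequence[GeneSet],
    universe: Iterable[str],
    min_set_size: int = 3,
    max_set_size: int = 500,
) -> list[EnrichmentResult]:
    """Score every gene set against the query by hypergeometric tail.

    Query genes outside the universe are dropped with a logged count;
    an empty query after intersection is fatal.  Sets are restricted to
    their universe intersection and skipped when that intersection is
    outside [min_set_size, max_set_size].  Sets with zero overlap are
    reported with p = 1.
    """
    universe = set(universe)
    if not universe:
        raise InputDataError("enrichment universe is empty")
    query = set(query)
    dropped = query - universe
    if dropped:
        logger.warning("%d query genes outside the universe were dropped", len(dropped))
    query &= universe
    if not query:
        raise InputDataError("no query genes remain after universe intersection")

    N, n = len(universe), len(query)
    results: list[EnrichmentResult] = []
    for s in sets:
        members = s.genes & universe
        K = len(members)
        if not min_set_size <= K <= max_set_size:
            continue
        overlap = members & query
        k = len(overlap)
        results.append(
            EnrichmentResult(
                set_id=s.set_id,
                name=s.name,
                k_overlap=k,
                n_query=n,
                K_set=K,
                N_universe=N,
                p_value=hypergeom_pvalue(k, N, K, n),
                overlap_genes=frozenset(overlap),
            )
        )
    return results


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment.

    Sort p ascending; adjusted(i) = min over j >= i of p(j) * m / j,
    capped at 1.  Stable under ties and monotone in the raw p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def adjust_pvalues(
    results: Sequence[EnrichmentResult], method: str = "bh"
) -> list[EnrichmentResult]:
    """Fill ``p_adjusted`` on every result (order preserved)."""
    if method != "bh":
        raise ConfigurationError(f"unsupported adjustment method {method!r}")
    adjusted = bh_adjust([r.p_value for r in results])
    return [replace(r, p_adjusted=float(a)) for r, a in zip(results, adjusted)]


def significant(
    results: Sequence[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Terms with adjusted p strictly below alpha."""
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    if any(r.p_adjusted is None for r in results):
        raise ConfigurationError("adjust_pvalues must run before significance selection")
    return [r for r in results if r.p_adjusted < alpha]


def jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def cluster_terms(
    results: Sequence[EnrichmentResult],
    sets: Sequence[GeneSet],
    tau: float = 0.5,
    universe: Iterable[str] | None = None,
) -> list[TermSimilarityCluster]:
    """Group significant terms by membership similarity.

    Pairwise Jaccard similarity is computed on gene membership
    (intersected with the universe when given); single-linkage clusters
    are the connected components over edges with similarity >= tau.
    Each cluster's representative is its member with the smallest
    adjusted p (ties: smallest set id); clusters are numbered from 1 in
    order of representative significance.
    """
    by_id = {s.set_id: s for s in sets}
    uni = set(universe) if universe is not None else None
    membership: dict[str, frozenset[str]] = {}
    for r in results:
        genes = by_id[r.set_id].genes
        membership[r.set_id] = frozenset(genes & uni) if uni is not None else genes

    graph = nx.Graph()
    graph.add_nodes_from(membership)
    ids = sorted(membership)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if jaccard(membership[a], membership[b]) >= tau:
                graph.add_edge(a, b)

    padj = {r.set_id: r.p_adjusted for r in results}
    clusters = []
    for component in nx.connected_components(graph):
        members = sorted(component)
        rep = min(members, key=lambda sid: (padj[sid], sid))
        clusters.append((rep, members))
    clusters.sort(key=lambda c: (padj[c[0]], c[0]))
    return [
        TermSimilarityCluster(
            cluster_id=i + 1,
            member_set_ids=tuple(members),
            representative_set_id=rep,
        )
        for i, (rep, members) in enumerate(clusters)
    ]


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            (
                r.set_id, r.name, r.k_overlap, r.K_set, r.n_query, r.N_universe,
                r.p_value, r.p_adjusted, ",".join(sorted(r.overlap_genes)),
            )
            for r in results
        ],
        columns=[
            "set_id", "name", "k_overlap", "K_set", "n_query", "N_universe",
            "p_value", "p_adjusted", "overlap_genes",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_clusters_tsv(clusters: Sequence[TermSimilarityCluster], path: str | Path) -> None:
    pd.DataFrame(
        [
            (c.cluster_id, c.representative_set_id, ",".join(c.member_set_ids))
            for c in clusters
        ],
        columns=["cluster_id", "representative_set_id", "member_set_ids"],
    ).to_csv(path, sep="\t", index=False)
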