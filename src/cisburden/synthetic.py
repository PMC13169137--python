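"""Synthetic GWAS-style datasets with known ground truth.

The generator emulates the statistical structure of a curated
GWAS-Catalog slice so every pipeline stage is testable without
downloads: variant positions clustered in loci around genes, p-values
spanning the genome-wide significance threshold, a realistic
noncoding-dominated consequence mix, mostly-rsID identifiers, planted
exact duplicates and malformed rows for QC, gene models emitted as both
GFF3 and BED, and GMT gene sets with enrichment planted in the
prioritized subset.

Class fractions use exact allocation (rounded counts assigned by seeded
permutation) rather than Bernoulli draws, so generator bookkeeping is
deterministic and assertable without tolerance bands.  Ground-truth
SNP–gene links are finalized by a brute-force all-pairs scan at
generation time, so incidental overlaps (a background variant landing
near a gene by chance) are part of the truth, not an error source.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InputDataError
from .gene_models import GeneModel, write_bed, write_gff3
from .enrichment import GeneSet, hypergeom_pvalue, write_gmt
from .network import MODULE_LABELS

GENOME_WIDE_ALPHA = 5e-8

_NONCODING_TERMS = [
    ("intron_variant", 0.45),
    ("intergenic_variant", 0.20),
    ("regulatory_region_variant", 0.10),
    ("3_prime_UTR_variant", 0.08),
    ("5_prime_UTR_variant", 0.05),
    ("splice_region_variant", 0.05),
    ("TF_binding_site_variant", 0.04),
    ("upstream_gene_variant", 0.02),
    ("downstream_gene_variant", 0.01),
]
_CODING_TERMS = [
    ("missense_variant", 0.70),
    ("stop_gained", 0.10),
    ("splice_acceptor_variant", 0.06),
    ("splice_donor_variant", 0.06),
    ("frameshift_variant", 0.05),
    ("synonymous_variant", 0.03),
]

_DECOY_TRAITS = [
    ("height", "EFO:0004339"),
    ("body mass index", "EFO:0004340"),
    ("type 2 diabetes", "MONDO:0005148"),
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated conditions."""

    seed: int = 0
    n_chromosomes: int = 8
    chrom_length_bp: int = 15_000_000
    n_genes: int = 500
    gene_length_range: tuple[int, int] = (5_000, 50_000)
    n_variants: int = 1000
    frac_significant: float = 0.25
    frac_noncoding: float = 0.9
    frac_rsid: float = 0.88
    #: fraction of significant variants placed inside the cis window of a
    #: randomly chosen gene (regional clustering of association signals)
    cluster_rate: float = 0.3
    window_bp: int = 50_000
    min_snps: int = 2
    n_gene_sets: int = 50
    planted_sets: int = 5
    planted_overlap: int = 10
    set_size_range: tuple[int, int] = (10, 60)
    min_set_size: int = 3
    max_set_size: int = 500
    n_duplicate_rows: int = 5
    n_malformed_rows: int = 2
    n_decoy_trait_rows: int = 50
    trait_label: str = "25-hydroxyvitamin D levels"
    ontology_term: str = "EFO:0004698"

    def validate(self) -> None:
        for name in ("frac_significant", "frac_noncoding", "frac_rsid", "cluster_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if not 1 <= self.n_chromosomes <= 22:
            raise ConfigurationError("n_chromosomes must be in 1..22")
        lo, hi = self.gene_length_range
        if not 1 <= lo <= hi:
            raise ConfigurationError(f"bad gene_length_range {self.gene_length_range}")
        if self.n_genes < 1 or self.n_variants < 1:
            raise ConfigurationError("need at least one gene and one variant")
        if self.min_snps < 1:
            raise ConfigurationError("min_snps must be >= 1")
        if self.window_bp < 0:
            raise ConfigurationError("window_bp must be >= 0")
        if self.planted_sets > self.n_gene_sets:
            raise ConfigurationError("planted_sets cannot exceed n_gene_sets")
        if self.planted_sets > 0 and self.planted_overlap < 1:
            raise ConfigurationError("planted_overlap must be >= 1 when sets are planted")


@dataclass
class GroundTruth:
    """What the pipeline must recover from a simulated dataset."""

    expected_links: set[tuple[str, str]] = field(default_factory=set)
    expected_burden: dict[str, int] = field(default_factory=dict)
    expected_prioritized: set[str] = field(default_factory=set)
    expected_prioritized_symbols: set[str] = field(default_factory=set)
    n_variants: int = 0
    n_significant: int = 0
    n_noncoding_total: int = 0
    n_noncoding_significant: int = 0
    n_rsid_total: int = 0
    n_rsid_significant: int = 0
    n_duplicate_rows: int = 0
    n_malformed_rows: int = 0
    n_decoy_rows: int = 0
    planted_set_ids: list[str] = field(default_factory=list)
    #: generation-time closed-form hypergeometric tail per planted set
    planted_p: dict[str, float] = field(default_factory=dict)
    #: BH-adjusted (across the whole tested collection) at generation time
    planted_p_adjusted: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["expected_links"] = sorted(self.expected_links)
        payload["expected_prioritized"] = sorted(self.expected_prioritized)
        payload["expected_prioritized_symbols"] = sorted(self.expected_prioritized_symbols)
        payload["expected_burden"] = dict(sorted(self.expected_burden.items()))
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        raw["expected_links"] = {tuple(pair) for pair in raw["expected_links"]}
        raw["expected_prioritized"] = set(raw["expected_prioritized"])
        raw["expected_prioritized_symbols"] = set(raw["expected_prioritized_symbols"])
        return cls(**raw)


def _exact_allocation_mask(rng: np.random.Generator, n: int, count: int) -> np.ndarray:
    """Boolean mask with exactly ``count`` True entries, placed uniformly."""
    mask = np.zeros(n, dtype=bool)
    mask[rng.permutation(n)[:count]] = True
    return mask


def _weighted_terms(rng: np.random.Generator, table, size: int) -> list[str]:
    terms = [t for t, _ in table]
    weights = np.array([w for _, w in table])
    return list(rng.choice(terms, size=size, p=weights / weights.sum()))


def simulate_genome(config: SimulationConfig) -> list[GeneModel]:
    """Place non-overlapping genes uniformly along each chromosome.

    Gene counts split as evenly as possible across chromosomes; gaps
    between genes follow a seeded stars-and-bars draw.  Packing that
    cannot fit the requested genes is fatal.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.gene_length_range
    base, rem = divmod(config.n_genes, config.n_chromosomes)
    genes: list[GeneModel] = []
    idx = 0
    for ci in range(config.n_chromosomes):
        chrom = str(ci + 1)
        k = base + (1 if ci < rem else 0)
        if k == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=k)
        free = config.chrom_length_bp - int(lengths.sum())
        if free < 0:
            raise InputDataError(
                f"cannot pack {k} genes totalling {int(lengths.sum())} bp "
                f"into a {config.chrom_length_bp} bp chromosome"
            )
        cuts = np.sort(rng.integers(0, free + 1, size=k))
        prev_end = 0
        prev_cut = 0
        for j in range(k):
            gap = int(cuts[j] - prev_cut)
            prev_cut = int(cuts[j])
            start = prev_end + gap + 1
            end = start + int(lengths[j]) - 1
            idx += 1
            genes.append(
                GeneModel(
                    gene_id=f"SIMG{idx:05d}",
                    symbol=f"GENE{idx:04d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=str(rng.choice(["+", "-"])),
                    biotype="protein_coding",
                )
            )
            prev_end = end
    return genes


def _oracle_links(
    variants: list[tuple[str, str, int]],
    genes: list[GeneModel],
    window_bp: int,
) -> set[tuple[str, str]]:
    """Brute-force all-pairs cis-window check: the generation-time truth."""
    links: set[tuple[str, str]] = set()
    for vid, chrom, pos in variants:
        for g in genes:
            if g.chrom != chrom:
                continue
            if max(g.start, pos - window_bp) <= min(g.end, pos + window_bp):
                links.add((vid, g.gene_id))
    return links


def simulate_variants(
    config: SimulationConfig, genes: list[GeneModel]
) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit a GWAS-Catalog-style association table plus its ground truth.

    Significant variants draw p log-uniformly in [1e-30, 5e-8), the rest
    in [5e-8, 1]; ``cluster_rate`` of the significant variants land
    inside the cis window of a random gene.  Exact duplicate rows
    (copies of significant records), malformed rows and decoy-trait rows
    are appended for QC testing, then the table is shuffled.
    """
    config.validate()
    if not genes:
        raise InputDataError("simulate_variants needs a non-empty gene list")
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_variants
    n_sig = round(n * config.frac_significant)
    n_clustered = round(n_sig * config.cluster_rate)
    L = config.chrom_length_bp
    chrom_names = [str(i + 1) for i in range(config.n_chromosomes)]

    sig_mask = _exact_allocation_mask(rng, n, n_sig)
    noncoding_mask = _exact_allocation_mask(rng, n, round(n * config.frac_noncoding))
    rsid_mask = _exact_allocation_mask(rng, n, round(n * config.frac_rsid))

    # positions: clustered significant variants sit near a random gene
    sig_indices = np.flatnonzero(sig_mask)
    clustered = set(sig_indices[rng.permutation(n_sig)[:n_clustered]].tolist())
    chroms: list[str] = [""] * n
    positions: list[int] = [0] * n
    for i in range(n):
        if i in clustered:
            g = genes[int(rng.integers(0, len(genes)))]
            lo = max(1, g.start - config.window_bp)
            hi = min(L, g.end + config.window_bp)
            chroms[i] = g.chrom
            positions[i] = int(rng.integers(lo, hi + 1))
        else:
            chroms[i] = chrom_names[int(rng.integers(0, len(chrom_names)))]
            positions[i] = int(rng.integers(1, L + 1))

    # p-values (written with full-precision repr so text round-trips exactly)
    pvals = np.empty(n)
    exp_sig = rng.uniform(np.log10(1e-30), np.log10(GENOME_WIDE_ALPHA), size=n)
    exp_null = rng.uniform(np.log10(GENOME_WIDE_ALPHA), 0.0, size=n)
    pvals[sig_mask] = 10.0 ** exp_sig[sig_mask]
    pvals[~sig_mask] = 10.0 ** exp_null[~sig_mask]
    pvals[sig_mask] = np.minimum(pvals[sig_mask], GENOME_WIDE_ALPHA * 0.999999)
    pvals[~sig_mask] = np.maximum(pvals[~sig_mask], GENOME_WIDE_ALPHA)

    consequences = [""] * n
    nc_idx = np.flatnonzero(noncoding_mask)
    cd_idx = np.flatnonzero(~noncoding_mask)
    for idx_arr, table in ((nc_idx, _NONCODING_TERMS), (cd_idx, _CODING_TERMS)):
        for i, term in zip(idx_arr, _weighted_terms(rng, table, len(idx_arr))):
            consequences[int(i)] = term

    ids: list[str] = [""] * n
    used: set[str] = set()
    rs_numbers = 10_000_000 + rng.permutation(10 * n)[:n]
    for i in range(n):
        if rsid_mask[i]:
            vid = f"rs{int(rs_numbers[i])}"
        else:
            while True:
                vid = f"{chroms[i]}:{positions[i]}_A_G"
                if vid not in used:
                    break
                positions[i] = positions[i] % L + 1
        used.add(vid)
        ids[i] = vid

    sig_records = [
        (ids[i], chroms[i], positions[i]) for i in range(n) if sig_mask[i]
    ]
    links = _oracle_links(sig_records, genes, config.window_bp)
    burden: dict[str, int] = {}
    for _, gid in links:
        burden[gid] = burden.get(gid, 0) + 1
    prioritized = {gid for gid, c in burden.items() if c >= config.min_snps}
    symbol_of = {g.gene_id: g.symbol for g in genes}

    truth = GroundTruth(
        expected_links=links,
        expected_burden=burden,
        expected_prioritized=prioritized,
        expected_prioritized_symbols={symbol_of[g] for g in prioritized},
        n_variants=n,
        n_significant=n_sig,
        n_noncoding_total=int(noncoding_mask.sum()),
        n_noncoding_significant=int((noncoding_mask & sig_mask).sum()),
        n_rsid_total=int(rsid_mask.sum()),
        n_rsid_significant=int((rsid_mask & sig_mask).sum()),
        n_duplicate_rows=config.n_duplicate_rows,
        n_malformed_rows=config.n_malformed_rows,
        n_decoy_rows=config.n_decoy_trait_rows,
    )

    trait_uri = "http://www.ebi.ac.uk/efo/" + config.ontology_term.replace(":", "_")
    betas = rng.normal(0.0, 0.05, size=n)
    ses = rng.uniform(0.002, 0.02, size=n)
    chr_prefix = rng.random(n) < 0.3  # exercise "chr"-prefix stripping

    def row(i: int) -> dict[str, str]:
        return {
            "DISEASE/TRAIT": config.trait_label,
            "MAPPED_TRAIT_URI": trait_uri,
            "SNPS": ids[i],
            "CHR_ID": ("chr" + chroms[i]) if chr_prefix[i] else chroms[i],
            "CHR_POS": str(positions[i]),
            "P-VALUE": repr(float(pvals[i])),
            "CONTEXT": consequences[i],
            "OR or BETA": repr(round(float(betas[i]), 4)),
            "SE": repr(round(float(ses[i]), 4)),
        }

    rows = [row(i) for i in range(n)]

    # exact duplicates of significant records (removed again by dedup)
    dup_sources = rng.choice(np.flatnonzero(sig_mask), size=config.n_duplicate_rows)
    rows.extend(row(int(i)) for i in dup_sources)

    # malformed rows: unparseable position / chromosome / p-value
    malform_kinds = ["pos", "chrom", "pval"]
    for j in range(config.n_malformed_rows):
        bad = row(int(rng.integers(0, n)))
        kind = malform_kinds[j % len(malform_kinds)]
        if kind == "pos":
            bad["CHR_POS"] = "NA"
        elif kind == "chrom":
            bad["CHR_ID"] = "chrUn_gl000220"
        else:
            bad["P-VALUE"] = "."
        rows.append(bad)

    # decoy traits: removed by ontology/keyword trait selection
    for j in range(config.n_decoy_trait_rows):
        label, term = _DECOY_TRAITS[j % len(_DECOY_TRAITS)]
        rows.append(
            {
                "DISEASE/TRAIT": label,
                "MAPPED_TRAIT_URI": "http://www.ebi.ac.uk/efo/" + term.replace(":", "_"),
                "SNPS": f"rs{5_000_000 + j}",
                "CHR_ID": chrom_names[int(rng.integers(0, len(chrom_names)))],
                "CHR_POS": str(int(rng.integers(1, L + 1))),
                "P-VALUE": repr(float(10.0 ** rng.uniform(-30, -8))),
                "CONTEXT": "intron_variant",
                "OR or BETA": repr(round(float(rng.normal(0.0, 0.05)), 4)),
                "SE": repr(round(float(rng.uniform(0.002, 0.02)), 4)),
            }
        )

    order = rng.permutation(len(rows))
    df = pd.DataFrame([rows[int(i)] for i in order])
    return df, truth


def simulate_gene_sets(
    config: SimulationConfig,
    genes: list[GeneModel],
    truth: GroundTruth,
) -> tuple[list[GeneSet], dict[str, str]]:
    """Build a GMT collection with enrichment planted in prioritized genes.

    Planted sets receive ``planted_overlap`` prioritized-gene symbols
    plus random fill; null sets draw uniformly from all gene symbols.
    Each set's closed-form hypergeometric tail (and its BH-adjusted
    value across the whole tested collection) is computed at generation
    time against the burden-gene universe and stored in the truth, so
    recovery tests compare against numbers, not intent.  Also returns a
    category map assigning planted sets round-robin to the four module
    labels and covering every other null set.
    """
    config.validate()
    if config.planted_sets > 0 and not truth.expected_prioritized_symbols:
        raise InputDataError("cannot plant enrichment: the prioritized truth set is empty")
    if config.planted_sets > 0 and config.planted_overlap > len(truth.expected_prioritized_symbols):
        raise ConfigurationError(
            f"planted_overlap={config.planted_overlap} exceeds the "
            f"{len(truth.expected_prioritized_symbols)} prioritized genes"
        )
    rng = np.random.default_rng([config.seed, 2])
    all_symbols = sorted(g.symbol for g in genes)
    symbol_of = {g.gene_id: g.symbol for g in genes}
    universe = sorted(symbol_of[gid] for gid in truth.expected_burden)
    query = sorted(truth.expected_prioritized_symbols)
    smin, smax = config.set_size_range

    sets: list[GeneSet] = []
    for i in range(config.n_gene_sets):
        set_id = f"SET{i + 1:04d}"
        size = int(rng.integers(smin, smax + 1))
        if i < config.planted_sets:
            core = list(rng.choice(query, size=config.planted_overlap, replace=False))
            size = max(size, config.planted_overlap + 2)
            pool = [s for s in all_symbols if s not in set(core)]
            fill = list(rng.choice(pool, size=size - len(core), replace=False))
            members = frozenset(core + fill)
            name = f"synthetic planted pathway {i + 1}"
        else:
            members = frozenset(rng.choice(all_symbols, size=size, replace=False))
            name = f"synthetic null pathway {i + 1}"
        sets.append(GeneSet(set_id=set_id, name=name, genes=members, collection="kegg"))

    # generation-time closed-form enrichment truth on the burden universe
    uni = set(universe)
    qry = set(query)
    tested: list[tuple[str, float]] = []
    for s in sets:
        K = len(s.genes & uni)
        if not config.min_set_size <= K <= config.max_set_size:
            continue
        k = len(s.genes & qry)
        tested.append((s.set_id, hypergeom_pvalue(k, len(uni), K, len(qry))))
    if tested:
        adjusted = multipletests([p for _, p in tested], method="fdr_bh")[1]
    else:
        adjusted = []
    adj_by_id = {sid: float(a) for (sid, _), a in zip(tested, adjusted)}
    raw_by_id = dict(tested)

    truth.planted_set_ids = [s.set_id for s in sets[: config.planted_sets]]
    truth.planted_p = {
        sid: raw_by_id[sid] for sid in truth.planted_set_ids if sid in raw_by_id
    }
    truth.planted_p_adjusted = {
        sid: adj_by_id[sid] for sid in truth.planted_set_ids if sid in adj_by_id
    }

    category_map: dict[str, str] = {}
    for i, s in enumerate(sets):
        if i < config.planted_sets or (i - config.planted_sets) % 2 == 0:
            category_map[s.set_id] = MODULE_LABELS[i % len(MODULE_LABELS)]
    return sets, category_map


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Generate a complete runnable dataset directory.

    Writes ``associations.tsv`` (GWAS-Catalog dialect), ``genes.gff3``
    and ``genes.bed``, ``gene_sets.gmt``, ``category_map.yaml``,
    ``ground_truth.json`` and a ready-to-run ``pipeline_config.yaml``
    with paths relative to the directory.  Identical config and seed
    produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = simulate_genome(config)
    table, truth = simulate_variants(config, genes)
    sets, category_map = simulate_gene_sets(config, genes, truth)

    table.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    write_gff3(genes, outdir / "genes.gff3")
    write_bed(genes, outdir / "genes.bed")
    write_gmt(sets, outdir / "gene_sets.gmt")
    (outdir / "category_map.yaml").write_text(
        yaml.safe_dump(category_map, sort_keys=True)
    )
    truth.to_json(outdir / "ground_truth.json")

    pipeline_cfg = {
        "associations": "associations.tsv",
        "gene_models": "genes.gff3",
        "gmt": "gene_sets.gmt",
        "category_map": "category_map.yaml",
        "out_dir": "results",
        "include_terms": [config.ontology_term],
        "include_keywords": ["vitamin d"],
        "alpha_gwas": GENOME_WIDE_ALPHA,
        "window_bp": config.window_bp,
        "min_snps": config.min_snps,
        "alpha_enrich": 0.05,
        "min_set_size": config.min_set_size,
        "max_set_size": config.max_set_size,
        "seed": config.seed,
    }
    (outdir / "pipeline_config.yaml").write_text(
        yaml.safe_dump(pipeline_cfg, sort_keys=True)
    )
    return truth
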