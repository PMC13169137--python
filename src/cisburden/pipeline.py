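"""End-to-end pipeline: associations -> variants -> links -> burdens ->
enrichment -> network, with a machine-readable run manifest.

Stage order is fixed: read/harmonize, trait selection, genome-wide
significance, deduplication, rsID QC, consequence classification and
landscape summary, gene loading and indexing, cis-window mapping,
burden aggregation and prioritization, over-representation testing with
BH correction, term clustering, bipartite network construction, module
assignment, hub identification and layout export.  Every intermediate
table is written to the output directory and the manifest records
parameter values, input checksums and per-stage row counts, so an
identical config on identical inputs reproduces identical counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from . import aggregation, annotation, cismap, enrichment, gene_models, gwas_io, network
from .errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    associations: str = ""
    gene_models: str = ""
    gmt: str = ""
    category_map: str = ""
    out_dir: str = "results"
    gene_models_format: str | None = None
    biotype_filter: list[str] = field(default_factory=list)
    include_terms: list[str] = field(default_factory=list)
    include_keywords: list[str] = field(default_factory=list)
    alpha_gwas: float = 5e-8
    window_bp: int = 50_000
    min_snps: int = 2
    alpha_enrich: float = 0.05
    similarity_tau: float = 0.5
    universe_mode: str = "burden"  # "burden" or "annotated"
    min_set_size: int = 3
    max_set_size: int = 500
    thresholds: list[int] = field(default_factory=lambda: [1, 2, 3])
    hub_top_n: int = 5
    seed: int = 0
    dialect: str | None = None
    vocabulary: str | None = None

    def validate(self) -> None:
        if not 0.0 < self.alpha_gwas < 1.0:
            raise ConfigurationError(f"alpha_gwas must be in (0, 1), got {self.alpha_gwas}")
        if not 0.0 < self.alpha_enrich < 1.0:
            raise ConfigurationError(f"alpha_enrich must be in (0, 1), got {self.alpha_enrich}")
        if self.window_bp < 0:
            raise ConfigurationError(f"window_bp must be >= 0, got {self.window_bp}")
        if self.min_snps < 1:
            raise ConfigurationError(f"min_snps must be >= 1, got {self.min_snps}")
        if not 0.0 <= self.similarity_tau <= 1.0:
            raise ConfigurationError(f"similarity_tau must be in [0, 1], got {self.similarity_tau}")
        if self.universe_mode not in ("burden", "annotated"):
            raise ConfigurationError(f"unknown universe_mode {self.universe_mode!r}")
        if not self.associations or not self.gene_models:
            raise ConfigurationError("associations and gene_models paths are required")
        if not self.include_terms and not self.include_keywords:
            raise ConfigurationError("trait selection needs include_terms or include_keywords")
        if not 1 <= self.min_set_size <= self.max_set_size:
            raise ConfigurationError("need 1 <= min_set_size <= max_set_size")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config; relative paths resolve against the YAML's directory."""
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys in {path}: {sorted(unknown)}")
        cfg = cls(**raw)
        base = path.parent
        for attr in ("associations", "gene_models", "gmt", "category_map",
                     "out_dir", "dialect", "vocabulary"):
            value = getattr(cfg, attr)
            if value and not Path(value).is_absolute():
                setattr(cfg, attr, str(base / value))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, write outputs and return the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "cisburden",
        "version": __version__,
        "parameters": asdict(config),
        "inputs": {},
        "counts": {},
        "stages": [],
    }
    counts = manifest["counts"]

    def stage(name: str) -> None:
        logger.info("[%s] starting", name)
        manifest["stages"].append(name)

    for key in ("associations", "gene_models", "gmt", "category_map"):
        p = getattr(config, key)
        if p:
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

    # --- variant QC chain -------------------------------------------------
    stage("read_associations")
    dialect = gwas_io.load_dialect(config.dialect) if config.dialect else None
    variants, read_report = gwas_io.read_associations(config.associations, dialect)
    counts["n_input_rows"] = read_report.n_rows
    counts["n_parsed_variants"] = read_report.n_variants
    counts["n_unparseable_rows"] = read_report.n_dropped

    stage("filter_traits")
    report = gwas_io.FilterReport(n_input=len(variants))
    variants = gwas_io.filter_traits(variants, config.include_terms, config.include_keywords)
    report.n_after_trait_filter = len(variants)

    stage("filter_significant")
    variants = gwas_io.filter_significant(variants, config.alpha_gwas)
    report.n_after_significance = len(variants)

    stage("deduplicate")
    variants, n_removed = gwas_io.deduplicate(variants)
    report.n_duplicates_removed = n_removed

    stage("qc_rsid")
    gwas_io.qc_rsid(variants, report)
    report.to_json(out / "filter_report.json")
    gwas_io.write_variants_tsv(variants, out / "variants.tsv")
    counts.update(
        n_after_trait_filter=report.n_after_trait_filter,
        n_after_significance=report.n_after_significance,
        n_duplicates_removed=report.n_duplicates_removed,
        n_retained=report.n_retained,
        n_rsid=report.n_rsid,
        n_non_rsid=report.n_non_rsid,
    )

    # --- annotation landscape --------------------------------------------
    stage("annotation")
    vocabulary = (
        annotation.load_vocabulary(config.vocabulary) if config.vocabulary else None
    )
    classes = [annotation.classify_consequence(v.consequence, vocabulary) for v in variants]
    landscape = annotation.summarize_landscape(variants, classes)
    (out / "landscape.json").write_text(
        json.dumps(
            {
                "per_chrom_counts": landscape.per_chrom_counts,
                "top_level_counts": landscape.top_level_counts,
                "coding_subclass_counts": landscape.coding_subclass_counts,
                "regulatory_subclass_counts": landscape.regulatory_subclass_counts,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    counts["n_noncoding"] = landscape.top_level_counts.get("noncoding", 0)
    counts["n_coding"] = landscape.top_level_counts.get("coding", 0)

    # --- gene models and cis mapping --------------------------------------
    stage("gene_models")
    genes = gene_models.read_gene_models(
        config.gene_models, config.gene_models_format, frozenset(config.biotype_filter)
    )
    index = gene_models.build_index(genes)
    counts["n_genes_loaded"] = len(genes)

    stage("cismap")
    links = cismap.map_snps_to_genes(variants, index, config.window_bp)
    profile = cismap.multiplicity_profile(links, variants)
    cismap.write_links_tsv(links, out / "links.tsv")
    cismap.write_multiplicity_tsv(profile, out / "multiplicity.tsv")
    counts["n_links"] = len(links)
    counts["n_mapped_snps"] = len(profile.genes_per_snp)
    counts["n_unmapped_snps"] = profile.n_unmapped

    stage("aggregation")
    burdens = aggregation.aggregate_burden(links)
    curve = aggregation.threshold_curve(burdens, config.thresholds)
    prioritized_ids = aggregation.prioritize(burdens, config.min_snps)
    aggregation.write_burden_tsv(burdens, out / "burden.tsv")
    aggregation.write_threshold_curve_tsv(curve, out / "threshold_curve.tsv")
    symbol_of = {b.gene_id: b.symbol for b in burdens}
    prioritized_symbols = {symbol_of[g] for g in prioritized_ids}
    (out / "prioritized_genes.txt").write_text(
        "".join(f"{gid}\t{symbol_of[gid]}\n" for gid in sorted(prioritized_ids))
    )
    counts["n_genes_any_link"] = len(burdens)
    counts["threshold_curve"] = {str(k): v for k, v in curve}
    counts["n_prioritized"] = len(prioritized_ids)

    # --- enrichment -------------------------------------------------------
    sig_results: list[enrichment.EnrichmentResult] = []
    sets: list[enrichment.GeneSet] = []
    if config.gmt and prioritized_ids:
        stage("enrichment")
        sets = enrichment.read_gmt(config.gmt)
        if config.universe_mode == "burden":
            universe = {b.symbol for b in burdens}
        else:
            universe = {g.symbol for g in genes}
        results = enrichment.hypergeom_ora(
            prioritized_symbols, sets, universe,
            config.min_set_size, config.max_set_size,
        )
        results = enrichment.adjust_pvalues(results)
        sig_results = enrichment.significant(results, config.alpha_enrich)
        clusters = enrichment.cluster_terms(
            sig_results, sets, config.similarity_tau, universe
        )
        enrichment.write_enrichment_tsv(results, out / "enrichment.tsv")
        enrichment.write_clusters_tsv(clusters, out / "term_clusters.tsv")
        counts["n_sets_loaded"] = len(sets)
        counts["n_sets_tested"] = len(results)
        counts["n_significant_sets"] = len(sig_results)
        counts["n_term_clusters"] = len(clusters)
    elif config.gmt:
        logger.warning("no prioritized genes: enrichment and network stages skipped")

    # --- network ----------------------------------------------------------
    if config.gmt and prioritized_ids:
        stage("network")
        net = network.build_network(sig_results, sets, prioritized_symbols)
        cat_map = (
            network.load_category_map(config.category_map) if config.category_map else {}
        )
        modules = network.assign_modules(net, cat_map)
        hubs = network.find_hubs(net, modules, config.hub_top_n)
        layout = network.export_layout(net, modules, config.seed)
        network.write_edge_list_tsv(net, out / "network_edges.tsv")
        network.write_node_attributes_tsv(net, modules, out / "network_nodes.tsv")
        network.write_hubs_tsv(hubs, out / "hubs.tsv")
        layout.to_csv(out / "layout.tsv", sep="\t", index=False)
        counts["n_network_genes"] = len(net.gene_nodes)
        counts["n_network_pathways"] = len(net.pathway_nodes)
        counts["n_network_edges"] = len(net.edges)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %s", manifest_path)
    return manifest
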