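# Methods

## The interpretation chain

`cisburden` treats post-GWAS gene prioritization as a deterministic chain of
set operations on published lead variants, not as a statistical model fitted
to the data. The only probability calculation is the enrichment test; every
other stage is counting under explicit conventions, which is why the package
is organized as pipeline stages with exact, oracle-checked tests rather than
as an estimator with standard errors.

**Variant QC.** Association rows are harmonized to 1-based positions on
chromosomes 1–22/X/Y/MT (any `chr` prefix stripped; unknown contigs dropped
and counted). Rows with unparseable chromosome, position or p-value are
dropped and counted per reason. Multi-variant `SNPS` fields (haplotype or
interaction entries) are split on `;`, `,` and ` x ` into one record per
identifier; the source databases do not document a canonical treatment, and
one-record-per-rsID keeps each physical signal addressable. Trait selection
retains a record iff its ontology accession is in the configured term list
or its lower-cased trait label contains a configured keyword; configuring
neither is an error, because silent pass-through would turn a curation step
into a no-op. Significance is strict: *p* < 5×10⁻⁸. Deduplication is per
(variant id, trait) keeping the smallest p-value (first occurrence on ties);
the same variant under two traits is two records, but never inflates
gene-level burden (see below). rsID QC (`rs\d+`) flags records without
removing them.

**Consequence classes.** Classification is a vocabulary lookup over ~28
Sequence-Ontology terms shipped as editable YAML. Multi-term strings resolve
to the most severe term under the order stop_gained > frameshift >
splice_related > missense > other_coding > UTR > splice_region > TFBS >
regulatory_region > intronic > intergenic > other_noncoding. One deliberate
ambiguity resolution: splice acceptor/donor variants are *coding*
("splice_related") because they disrupt the mature transcript, while
`splice_region_variant` is *noncoding* ("splice_region"); both conventions
appear in the annotation literature, so the mapping is configuration, not
code.

**Cis-window mapping.** The window is symmetric, unsigned and closed:
variant *x* links to gene *g* iff max(*g.start*, *x*−*W*) ≤ min(*g.end*,
*x*+*W*), *W* = 50,000 bp by default, clamped at position 1. A gene edge
exactly *W* away is linked; *W*+1 is not — the boundary is pinned by a
dedicated test pair. Gene extent is the gene body (GFF3 `gene` feature span,
BED interval converted from half-open 0-based to closed 1-based); since the
TSS lies inside the gene body, body overlap subsumes TSS overlap. Strand is
ignored for windowing (the window is symmetric) but retained to report the
signed variant-to-TSS distance (negative = upstream). The interval index
(per-chromosome interval tree) is contractually identical to a linear scan
and is tested against one on randomized instances.

**Burden and prioritization.** A gene's burden is the number of *distinct*
variant ids linked to it — set semantics, so a variant reported under
several traits counts once, and no LD pruning is applied (the inputs are
published lead variants). Prioritization keeps genes with burden ≥ 2
(configurable); threshold curves at ≥1/≥2/≥3 quantify the
stringency/coverage trade-off and are nested by construction.

**Enrichment.** Over-representation uses the upper-tail hypergeometric
probability P(X ≥ k) with population N (universe), K successes (set ∩
universe), n draws (query); k = 0 reports p = 1 exactly. The default
universe is the *burden universe* — genes with at least one mapped SNP —
which is the conservative background when the query itself was derived from
mapping; `universe_mode: annotated` switches to all loaded genes for
sensitivity analysis. Sets are filtered to 3 ≤ |set ∩ universe| ≤ 500
(configurable). BH step-up adjustment is implemented directly (sort
ascending, p·m/rank, right-to-left cumulative minimum, cap at 1) and is
cross-checked against the statsmodels implementation to 1e-12 in tests.
Significance is strict: adjusted p < 0.05. Significant terms are grouped by
single-linkage connected components over pairwise membership Jaccard ≥ τ
(default 0.5); the cluster representative is the member with the smallest
adjusted p. Membership Jaccard was chosen over information-content semantic
similarity because it needs no ontology graph and behaves identically for GO
and KEGG inputs.

**Network, modules, hubs.** Edges connect prioritized genes to the
significant pathways containing them; zero-degree genes are excluded.
Modules are *curation*: a YAML map from set ids (or case-insensitive name
substrings) to one of immune / metabolic / endocrine /
signal_transduction_cellular_regulation; unmapped pathways are
`unassigned`. A gene inherits the union of its neighbors' modules, so
modules overlap by design. Hub ranking within a module counts only
same-module pathway neighbors (otherwise "within module" would be
meaningless), breaking ties by overall degree then gene id. Layout export
uses a seeded Fruchterman–Reingold placement; coordinates are data, so any
renderer reproduces the figure.

## The synthetic study

The generator emulates the structure the pipeline assumes about a curated
GWAS-Catalog slice. Default conditions (one `SimulationConfig`):

| parameter | default | meaning |
|---|---|---|
| n_chromosomes × chrom_length_bp | 8 × 15 Mb | genome extent (120 Mb) |
| n_genes | 500 | non-overlapping gene bodies, 5–50 kb |
| n_variants | 1000 | association rows for the target trait |
| frac_significant | 0.25 | exact fraction with p < 5×10⁻⁸ |
| cluster_rate | 0.3 | significant variants placed inside a random gene's ±50 kb window |
| frac_noncoding / frac_rsid | 0.90 / 0.88 | consequence and identifier mix |
| n_gene_sets / planted_sets / planted_overlap | 50 / 5 / 10 | GMT collection with planted enrichment |
| n_duplicate_rows / n_malformed_rows / n_decoy_trait_rows | 5 / 2 / 50 | QC fodder |

Gene density (≈4.2/Mb against a 100-kb window) and a moderate cluster rate
were chosen so the burden distribution reproduces the qualitative behaviour
the method is designed around: many genes with a single supporting SNP
(~160 of 500), a markedly smaller ≥2-SNP prioritized set (~25–35), and very
few ≥3-SNP genes — giving the prioritized set enough selectivity
(~20 % of the burden universe) for planted enrichment to be detectable.
Significant p-values are log-uniform on [10⁻³⁰, 5×10⁻⁸), null p-values
log-uniform on [5×10⁻⁸, 1], written with full-precision `repr` so the text
round-trips exactly across the parser.

Class fractions use exact allocation (rounded counts assigned by seeded
permutation), not Bernoulli draws, so generated counts are assertable
without tolerance bands. Ground-truth links are finalized by a brute-force
all-pairs window scan at generation time: incidental overlaps (a background
variant landing near a gene) are part of the truth. Planted gene sets seed
`planted_overlap` prioritized-gene symbols plus random fill; each tested
set's closed-form hypergeometric tail and its BH-adjusted value (computed
with statsmodels, independently of the package's own BH code) are stored in
the truth file, so recovery tests compare the pipeline against stored
numbers, never against intent.

**What the synthetic study does not emulate:** linkage disequilibrium and
allele frequencies (the pipeline consumes published lead variants and never
uses them), overlapping genes and isoform structure, realistic chromosome
size and gene-density heterogeneity, ontology structure among gene sets, and
any relationship between effect sizes and positions. Passing tests therefore
demonstrate the *bookkeeping* is exact under the stated conventions — not
that ±50 kb proximity recovers biologically causal genes, which no desk
check can establish.

## Numerical and degenerate-case choices

- All thresholds are strict inequalities (p < 5×10⁻⁸, adjusted p < 0.05),
  and the window boundary is inclusive; each is pinned by a boundary test.
- BH with ties: stable argsort gives tied raw p-values identical adjusted
  values via the cumulative minimum.
- Zero-overlap enrichment reports p = 1 rather than being dropped, keeping
  the tested-set count m stable for adjustment.
- Empty significant-pathway lists produce an empty network and no-op
  downstream stages (warning, not error); empty queries after universe
  intersection are fatal, because a silent empty enrichment is misleading.
- All randomness flows from single integer seeds (per-stage child seeds
  derived as `default_rng([seed, stage])`); identical seeds give
  byte-identical generated files and identical run manifests.
- Problem sizes in the test suite (e.g. 100 mapping fixtures of ≤500 SNPs ×
  ≤200 genes, 20 full-pipeline seeds, 250 null-calibration sets over a
  1000-gene universe) are the package's own choice of desk-scale instances
  that exercise every code path while keeping the suite in seconds.

## Known limitations

- Proximity-only mapping: no LD expansion, eQTL colocalization or chromatin
  interaction evidence; a fixed window misattributes genes under long-range
  regulation by construction.
- No genome-build liftover: inputs must share one build; a build column with
  conflicting values is rejected, but silently mixed coordinates without
  such a column cannot be detected.
- Burden is a count of reported lead variants, not a gene-based association
  test; it inherits every ascertainment bias of the source catalog.
- Module themes are user curation; the shipped KEGG-style starting map is a
  convenience, not a claim about pathway taxonomy.
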