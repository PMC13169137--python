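import numpy as np
import pytest
from hypothesis import settings

from cisburden.gene_models import GeneModel
from cisburden.gwas_io import Variant

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_variant(vid="rs1", chrom="1", pos=100, pvalue=1e-9, trait="25-hydroxyvitamin D levels",
                 term="EFO:0004698", consequence="intron_variant"):
    return Variant(variant_id=vid, chrom=chrom, pos=pos, pvalue=pvalue,
                   trait_label=trait, ontology_term=term, consequence=consequence)


def random_genes(rng: np.random.Generator, n: int, n_chroms: int = 3,
                 chrom_len: int = 2_000_000) -> list[GeneModel]:
    """Random (possibly overlapping) gene intervals for oracle tests."""
    genes = []
    for i in range(n):
        chrom = str(rng.integers(1, n_chroms + 1))
        start = int(rng.integers(1, chrom_len))
        length = int(rng.integers(1, 60_000))
        genes.append(GeneModel(f"G{i:04d}", f"SYM{i:04d}", chrom, start, start + length - 1,
                               strand="+" if rng.random() < 0.5 else "-"))
    return genes


def random_variants(rng: np.random.Generator, n: int, n_chroms: int = 3,
                    chrom_len: int = 2_000_000) -> list[Variant]:
    return [
        make_variant(vid=f"rs{i}", chrom=str(rng.integers(1, n_chroms + 1)),
                     pos=int(rng.integers(1, chrom_len)))
        for i in range(n)
    ]


def bruteforce_links(variants, genes, window_bp):
    """Independent all-pairs cis-window oracle used against map_snps_to_genes."""
    out = set()
    for v in variants:
        for g in genes:
            if g.chrom == v.chrom and max(g.start, v.pos - window_bp) <= min(g.end, v.pos + window_bp):
                out.add((v.variant_id, g.gene_id))
    return out


@pytest.fixture(scope="session")
def demo_dataset(tmp_path_factory):
    """One default-condition synthetic dataset shared across tests."""
    from cisburden.synthetic import SimulationConfig, simulate_dataset

    outdir = tmp_path_factory.mktemp("demo_dataset")
    truth = simulate_dataset(SimulationConfig(seed=11), outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def demo_run(demo_dataset, tmp_path_factory):
    """Pipeline results for the shared demo dataset."""
    from cisburden.pipeline import PipelineConfig, run_pipeline

    outdir, truth = demo_dataset
    cfg = PipelineConfig.from_yaml(outdir / "pipeline_config.yaml")
    cfg.out_dir = str(tmp_path_factory.mktemp("demo_run"))
    manifest = run_pipeline(cfg)
    return cfg, manifest, truth
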