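import pandas as pd
import pytest

from cnp import simulate as sim


@pytest.fixture(scope="session")
def small_pangenome():
    """3 subgroups x 6 genomes, 40 families, one strong planted expansion."""
    cfg = sim.PangenomeSimConfig(
        n_subgroups=3, genomes_per_subgroup=6, n_families=40,
        background_copy_mean=2.0,
        expansions=[("SG03", "FAM0005", 25.0)],
        n_single_copy_families=10, seed=11,
    )
    genomes, annotations, truth = sim.generate_pangenome(cfg)
    return cfg, genomes, annotations, truth


@pytest.fixture(scope="session")
def family_counts(small_pangenome):
    _, _, annotations, _ = small_pangenome
    return annotations.groupby(["genome_id", "family_id"]).size().unstack(fill_value=0)


@pytest.fixture(scope="session")
def small_community(small_pangenome, family_counts):
    """Shallow / mid / deep Gaussian niches over a 10-sample depth grid."""
    _, genomes, _, _ = small_pangenome
    curves = {
        "SG01": sim.NicheCurve(center=100, width=200, peak=0.25),
        "SG02": sim.NicheCurve(center=800, width=400, peak=0.25),
        "SG03": sim.NicheCurve(center=3500, width=900, peak=0.25),
    }
    cfg = sim.CommunitySimConfig(
        depth_grid=list(pd.Series([50, 150, 300, 600, 900, 1500, 2200, 3000, 4000, 5000],
                                  dtype=float)),
        niche_curves=curves, reads_per_sample=2000, read_length=100,
        genes_per_sample=2000, seed=12,
    )
    samples, alignments, gene_taxon = sim.generate_community(cfg, genomes, family_counts)
    return cfg, samples, alignments, gene_taxon
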