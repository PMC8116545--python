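import numpy as np
import pandas as pd
import pytest

from methconsist.simulate import (
    ConversionConfig,
    DepthConfig,
    EffectConfig,
    GenomeConfig,
    GenomeModel,
    SiteCounts,
    TrueMethylome,
    build_genome,
    draw_true_methylome,
)


@pytest.fixture(scope="session")
def genome():
    """Default-scale synthetic genome shared across tests."""
    return build_genome(GenomeConfig(), seed=5)


@pytest.fixture(scope="session")
def truth(genome):
    """4v4 ground truth with the default hypo-dominant effect registry."""
    return draw_true_methylome(genome, 4, 4, EffectConfig(50, 5, 0.3), seed=17)


@pytest.fixture(scope="session")
def small_genome():
    return build_genome(
        GenomeConfig(
            n_chroms=1, chrom_length=120_000, n_genes=20, gene_length=(800, 1_500),
            island_rate=6e-5, panel_size=20, probe_fraction=0.3,
        ),
        seed=3,
    )


def manual_genome(site_positions, gene_intervals, chrom="chr1", length=100_000):
    """Hand-built single-chromosome GenomeModel for exact-value tests."""
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": site_positions, "island": False}
    )
    sites.index.name = "site_id"
    genes = pd.DataFrame(
        [(f"g{i}", chrom, s, e, "+") for i, (s, e) in enumerate(gene_intervals)],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
    return GenomeModel(
        chrom_lengths={chrom: length},
        sites=sites,
        ccgg=pd.DataFrame(columns=["chrom", "pos"]),
        genes=genes,
        islands=pd.DataFrame(columns=["chrom", "start", "end"]),
        panel=frozenset(),
        probes=np.array([], dtype=int),
        control_sites=np.array([], dtype=int),
    )


def manual_counts(records, samples=None, assay="WGBS"):
    """SiteCounts from (site_id, sample_id, C, T) tuples."""
    df = pd.DataFrame(records, columns=["site_id", "sample_id", "C", "T"])
    sample_ids = samples or sorted(df["sample_id"].unique())
    groups = ["tumor" if "t" in s else "normal" for s in sample_ids]
    return SiteCounts(
        assay=assay,
        samples=pd.DataFrame({"sample_id": sample_ids, "group": groups}),
        counts=df,
    )


def constant_truth(genome, m, n_tumor=1, n_normal=1):
    """TrueMethylome with every site's methylation fixed to ``m``."""
    ids = [f"tumor_{i}" for i in range(n_tumor)] + [
        f"normal_{i}" for i in range(n_normal)
    ]
    groups = ["tumor"] * n_tumor + ["normal"] * n_normal
    m0 = np.full(genome.n_sites, float(m))
    truth = pd.DataFrame(
        {sid: m0 for sid in ids}, index=genome.sites.index
    )
    return TrueMethylome(
        samples=pd.DataFrame({"sample_id": ids, "group": groups}),
        truth=truth,
        effects={},
        baseline=m0,
        island_beta=(0.5, 5.0),
        background_beta=(5.0, 0.5),
    )
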