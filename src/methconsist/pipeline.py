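"""End-to-end orchestration: simulate -> score -> differential -> consistency -> functional.

A :class:`RunConfig` captures every parameter of a run (genome, ground
truth, assay roster, filters, thresholds, seeds) and round-trips through
YAML.  :func:`run_all` executes the full pipeline into an output directory,
emitting every intermediate table plus a ``manifest.yaml`` recording
parameters, derived seeds and per-stage row counts; identical configs
reproduce identical output trees.

The dataset roster mirrors a multi-assay study design: each dataset draws
its own samples from one shared ground-truth methylome and is measured by
its own assay, then the datasets are compared on the genes they all measure.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consistency import build_report, overlap_significance, shared_universe
from .differential import aggregate_genes, call_dmg
from .functional import (
    cross_dataset_edges,
    enrich,
    geneset_similarity,
    make_toy_annotation,
    make_toy_network,
    null_similarity,
)
from .readwrite import (
    write_counts,
    write_genes_bed,
    write_matrix,
    write_network,
    write_sites_bed,
    write_tsv,
)
from .scoring import qc_report, score_sites
from .simulate import (
    ConversionConfig,
    DepthConfig,
    EffectConfig,
    GenomeConfig,
    DEFAULT_DEPTH,
    build_genome,
    draw_true_methylome,
    simulate_counts,
)

__all__ = ["DatasetSpec", "RunConfig", "run_all", "make_fixtures", "measured_genes"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DatasetSpec:
    """One dataset of the roster: a named assay with its own cohort."""

    name: str
    assay: str
    n_tumor: int
    n_normal: int
    mean_depth: float | None = None  # None -> assay default
    dispersion: float = 0.2


@dataclass(frozen=True)
class RunConfig:
    """All parameters of a pipeline run; YAML-serializable."""

    genome: GenomeConfig = field(default_factory=GenomeConfig)
    effects: EffectConfig = field(default_factory=EffectConfig)
    conversion: ConversionConfig = field(default_factory=ConversionConfig)
    datasets: tuple[DatasetSpec, ...] = (
        DatasetSpec("wgbs", "WGBS", 3, 3),
        DatasetSpec("rrbs", "RRBS", 4, 6),
        DatasetSpec("targeted", "targetedBS", 8, 8),
        DatasetSpec("array450k", "array", 20, 10),
    )
    min_cov: int = 4
    min_sites: int = 1
    tau: float = 0.15
    island_beta: tuple[float, float] = (0.5, 5.0)
    background_beta: tuple[float, float] = (5.0, 0.5)
    array_sigma: float = 0.05
    null_draws: int = 200
    sim_weight: float = 0.8
    seed: int = 0

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, (tuple, list)):
                return [clean(o) for o in obj]
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return clean(dataclasses.asdict(obj))
            return obj

        return clean(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        g = dict(d.pop("genome", {}))
        for k in ("gene_length", "island_length"):
            if k in g:
                g[k] = tuple(g[k])
        e = dict(d.pop("effects", {}))
        c = dict(d.pop("conversion", {}))
        ds = tuple(DatasetSpec(**x) for x in d.pop("datasets", []))
        for k in ("island_beta", "background_beta"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(genome=GenomeConfig(**g), effects=EffectConfig(**e),
                   conversion=ConversionConfig(**c), datasets=ds, **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def measured_genes(gene_scores: pd.DataFrame, groups: dict[str, str]) -> set:
    """Genes with a non-missing score in at least one sample of each group."""
    tumor = [s for s in gene_scores.columns if groups.get(s) == "tumor"]
    normal = [s for s in gene_scores.columns if groups.get(s) == "normal"]
    ok = gene_scores[tumor].notna().any(axis=1) & gene_scores[normal].notna().any(axis=1)
    return set(gene_scores.index[ok])


def run_all(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    Raises on the first failing stage; the manifest names every derived seed
    so any stage can be replayed in isolation.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "seeds": {},
        "rows": {},
    }
    stage = "build_genome"
    try:
        genome_seed = config.seed
        truth_seed = config.seed + 1
        manifest["seeds"]["genome"] = genome_seed
        manifest["seeds"]["truth"] = truth_seed
        genome = build_genome(config.genome, seed=genome_seed)
        write_sites_bed(genome, out / "sites.bed")
        write_genes_bed(genome, out / "genes.bed")
        manifest["rows"]["sites"] = genome.n_sites
        manifest["rows"]["genes"] = len(genome.genes)

        stage = "draw_true_methylome"
        n_t = max(ds.n_tumor for ds in config.datasets)
        n_n = max(ds.n_normal for ds in config.datasets)
        truth = draw_true_methylome(
            genome, n_t, n_n, config.effects, seed=truth_seed,
            island_beta=config.island_beta, background_beta=config.background_beta,
        )
        write_tsv(truth.truth, out / "truth.tsv")
        effects = pd.DataFrame(
            sorted(truth.effects.items()), columns=["gene_id", "delta"]
        )
        write_tsv(effects, out / "effects.tsv", index=False)

        gene_sets_measured: dict[str, set] = {}
        gmats, groups_by_ds = {}, {}
        for i, ds in enumerate(config.datasets):
            stage = f"simulate[{ds.name}]"
            ds_seed = config.seed + 101 + i
            manifest["seeds"][f"counts_{ds.name}"] = ds_seed
            tr = truth.subset(ds.n_tumor, ds.n_normal, prefix=f"{ds.name}_")
            depth = DepthConfig(
                mean_depth=ds.mean_depth
                if ds.mean_depth is not None
                else DEFAULT_DEPTH.get(ds.assay, 30.0),
                dispersion=ds.dispersion,
            )
            counts = simulate_counts(
                tr, genome, ds.assay, depth_config=depth,
                conv_config=config.conversion, seed=ds_seed,
                array_sigma=config.array_sigma,
            )
            write_counts(counts, out / f"counts_{ds.name}.tsv")
            write_tsv(counts.samples, out / f"groups_{ds.name}.tsv", index=False)

            stage = f"score[{ds.name}]"
            mm = score_sites(counts, min_cov=config.min_cov)
            write_matrix(mm, out / f"levels_{ds.name}.tsv")
            if ds.assay != "array":
                qc = qc_report(counts, control_sites=genome.control_sites)
                write_tsv(qc.per_sample, out / f"qc_{ds.name}.tsv")

            stage = f"aggregate[{ds.name}]"
            gmat = aggregate_genes(mm, genome, min_sites=config.min_sites)
            write_tsv(gmat.scores, out / f"gene_scores_{ds.name}.tsv")
            gmats[ds.name] = gmat
            groups_by_ds[ds.name] = tr.groups
            gene_sets_measured[ds.name] = measured_genes(gmat.scores, tr.groups)
            manifest["rows"][f"counts_{ds.name}"] = (
                len(counts.counts) if counts.counts is not None else len(counts.levels)
            )
            manifest["rows"][f"genes_measured_{ds.name}"] = len(
                gene_sets_measured[ds.name]
            )

        stage = "shared_universe"
        universe = shared_universe(list(gene_sets_measured.values()))
        manifest["rows"]["genes_shared"] = len(universe)
        (out / "universe.txt").write_text("\n".join(sorted(universe)) + "\n")

        stage = "call_dmg"
        dmg_tables = {}
        for name, gmat in gmats.items():
            restricted = dataclasses.replace(
                gmat,
                scores=gmat.scores.loc[sorted(universe & set(gmat.scores.index))],
                n_sites=gmat.n_sites.loc[sorted(universe & set(gmat.n_sites.index))],
            )
            dmg = call_dmg(restricted, groups_by_ds[name], tau=config.tau)
            write_tsv(dmg, out / f"dmg_{name}.tsv")
            dmg_tables[name] = dmg
            manifest["rows"][f"dmg_{name}"] = int(dmg["is_dmg"].sum())

        stage = "consistency"
        report = build_report(dmg_tables, universe)
        write_tsv(report.to_frame(), out / "consistency_report.tsv", index=False)
        write_tsv(report.intersection_counts(), out / "venn_counts.tsv", index=False)
        (out / "common_genes.txt").write_text(
            "\n".join(sorted(report.common)) + ("\n" if report.common else "")
        )
        for name in report.datasets:
            (out / f"exclusive_{name}.txt").write_text(
                "\n".join(sorted(report.exclusive[name]))
                + ("\n" if report.exclusive[name] else "")
            )
        manifest["rows"]["common_dmgs"] = len(report.common)
        if report.common:
            n_hypo_common = sum(
                1 for g in report.common
                if all(report.directions[d].get(g) == "hypo"
                       for d in report.datasets)
            )
            manifest["common_hypo_fraction"] = n_hypo_common / len(report.common)
        else:
            manifest["common_hypo_fraction"] = None
        manifest["sign_concordance"] = (
            None if np.isnan(report.sign_concordance)
            else float(report.sign_concordance)
        )

        stage = "functional"
        ann_seed = config.seed + 301
        net_seed = config.seed + 302
        null_seed = config.seed + 303
        manifest["seeds"].update(
            {"annotation": ann_seed, "network": net_seed, "null_similarity": null_seed}
        )
        genes_u = sorted(universe)
        # true effect genes share function: hypo effects in branch 0, hyper in 1
        branch_of = {g: (0 if d < 0 else 1) for g, d in truth.effects.items()
                     if g in universe}
        dag = make_toy_annotation(
            genes_u, weight=config.sim_weight, branch_of=branch_of, seed=ann_seed
        )
        network = make_toy_network(genes_u, community_of=branch_of, seed=net_seed)
        write_network(network, out / "network.tsv")

        if report.common:
            enr = enrich(report.common, dag, universe)
            write_tsv(enr, out / "enrichment_common.tsv", index=False)
            topo = pd.DataFrame()
            from .functional import topology

            topo = topology(network, report.common)
            write_tsv(topo, out / "topology.tsv")

        names = report.datasets
        sim = pd.DataFrame(np.nan, index=names, columns=names)
        for a in names:
            for b in names:
                if report.dmg_sets[a] and report.dmg_sets[b]:
                    sim.loc[a, b] = geneset_similarity(
                        report.dmg_sets[a], report.dmg_sets[b], dag
                    )
        write_tsv(sim, out / "semsim_matrix.tsv")

        null = null_similarity(dag, universe, n_draws=config.null_draws,
                               seed=null_seed)
        write_tsv(
            pd.DataFrame([{"mean": null.mean, "n_draws": null.n_draws,
                           **null.quantiles}]),
            out / "null_similarity.tsv", index=False,
        )

        edges = cross_dataset_edges(network, dict(report.dmg_sets))
        write_tsv(edges, out / "cross_edges.tsv")

        overlaps = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                overlaps.append(
                    {"dataset_a": a, "dataset_b": b,
                     "n_overlap": len(report.dmg_sets[a] & report.dmg_sets[b]),
                     "p_value": overlap_significance(
                         report.dmg_sets[a], report.dmg_sets[b], universe)}
                )
        write_tsv(pd.DataFrame(overlaps), out / "overlap_significance.tsv",
                  index=False)
    except Exception:
        logger.error("pipeline failed at stage %s", stage)
        raise

    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest


FIXTURE_SCALES = {
    "tiny": RunConfig(
        genome=GenomeConfig(
            n_chroms=1, chrom_length=40_000, n_genes=10,
            gene_length=(800, 1_500), island_rate=1e-4, island_length=(300, 800),
            ccgg_rate_island=0.015, ccgg_rate_background=0.003,
            panel_size=10, probe_fraction=0.3,
        ),
        effects=EffectConfig(n_hypo=3, n_hyper=1, delta=0.3),
        datasets=(
            DatasetSpec("wgbs", "WGBS", 2, 2),
            DatasetSpec("rrbs", "RRBS", 2, 2),
            DatasetSpec("targeted", "targetedBS", 2, 2),
            DatasetSpec("array450k", "array", 2, 2),
        ),
        null_draws=50,
    ),
    "small": RunConfig(
        genome=GenomeConfig(
            n_chroms=1, chrom_length=200_000, n_genes=40,
            gene_length=(800, 2_000), island_rate=6e-5, island_length=(300, 1_000),
            ccgg_rate_island=0.01, ccgg_rate_background=0.002,
            panel_size=40, probe_fraction=0.25,
        ),
        effects=EffectConfig(n_hypo=8, n_hyper=2, delta=0.3),
        datasets=(
            DatasetSpec("wgbs", "WGBS", 3, 3),
            DatasetSpec("rrbs", "RRBS", 3, 3),
            DatasetSpec("targeted", "targetedBS", 3, 3),
            DatasetSpec("array450k", "array", 3, 3),
        ),
        null_draws=100,
    ),
}


def make_fixtures(scale: str, seed: int = 0, outdir=None) -> Path:
    """Run a scaled-down end-to-end fixture and return its directory.

    ``tiny`` (1 chromosome, ~200 CpG sites, 10 genes, 2v2 samples) finishes
    in seconds and exercises every stage; ``small`` is a step up.
    """
    if scale not in FIXTURE_SCALES:
        raise ValueError(f"scale must be one of {sorted(FIXTURE_SCALES)}")
    config = dataclasses.replace(FIXTURE_SCALES[scale], seed=seed)
    out = Path(outdir) if outdir is not None else Path(f"fixture_{scale}")
    run_all(config, out)
    config.to_yaml(out / "config.yaml")
    return out
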