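"""Synthetic genome and multi-assay bisulfite methylome generator.

This module produces the raw material the rest of the package analyses: a
toy genome model (CpG sites, CpG islands, CCGG restriction motifs, gene
intervals, a capture panel and an array probe set), a ground-truth
tumor-vs-normal methylome with known effect genes, and per-site
methylated/unmethylated read counts for four assay types:

* ``WGBS``       — whole-genome bisulfite sequencing; every CpG site covered.
* ``RRBS``       — reduced-representation: MspI digestion at CCGG motifs
                   followed by 40–220 bp fragment size selection, so coverage
                   is restricted to retained fragments and enriched in
                   CpG islands (where CCGG motifs are denser).
* ``targetedBS`` — capture-panel bisulfite sequencing; coverage restricted to
                   a panel of gene intervals.
* ``array``      — probe-based assay reporting a noisy methylation level per
                   probe site, with no read counts.

The simulator works at the level of per-site read counts: bisulfite
chemistry is modelled through the probability that a read reports cytosine,

    p_C = m * (1 - e_over) + (1 - m) * (1 - conv),

where ``m`` is the true methylation probability, ``conv`` the bisulfite
conversion rate of unmethylated cytosines and ``e_over`` the inappropriate
conversion rate of methylated cytosines; a final symmetric ``seq_err`` flip
models sequencing error.  No read sequences or alignment are simulated.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ASSAYS",
    "GenomeCapacityError",
    "GenomeConfig",
    "GenomeModel",
    "EffectConfig",
    "TrueMethylome",
    "DepthConfig",
    "ConversionConfig",
    "SiteCounts",
    "build_genome",
    "draw_true_methylome",
    "simulate_counts",
    "rrbs_fragments",
    "DEFAULT_DEPTH",
]

ASSAYS = ("WGBS", "RRBS", "targetedBS", "array")

#: default negative-binomial mean depth per assay (reads per covered site);
#: reduced-representation and capture assays concentrate reads on fewer sites
#: and therefore run deeper.
DEFAULT_DEPTH = {"WGBS": 30.0, "RRBS": 60.0, "targetedBS": 100.0}


class GenomeCapacityError(ValueError):
    """Raised when the requested non-overlapping genes cannot be placed."""


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeConfig:
    """Parameters of the synthetic genome.

    Densities are per-bp rates of homogeneous Poisson processes; CpG and CCGG
    rates are piecewise constant, higher inside islands.
    """

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 100
    gene_length: tuple[int, int] = (1_000, 3_000)
    island_rate: float = 3e-5          # islands per bp
    island_length: tuple[int, int] = (500, 2_000)
    cpg_rate_island: float = 0.02      # CpG sites per bp inside islands
    cpg_rate_background: float = 0.005
    ccgg_rate_island: float = 0.0125   # CCGG motifs per bp inside islands
    ccgg_rate_background: float = 0.0025
    panel_size: int = 60               # genes captured by the targeted assay
    probe_fraction: float = 0.15       # fraction of CpG sites with array probes
    control_fraction: float = 0.02     # fraction of non-gene sites reserved as
                                       # unmethylated spike-in controls


@dataclass
class GenomeModel:
    """A synthetic genome: sites, motifs, intervals and assay footprints.

    ``sites`` is indexed by integer site id (global, ordered by chromosome
    then position) with columns ``chrom``, ``pos``, ``island``.  ``genes``
    has columns ``gene_id``, ``chrom``, ``start``, ``end``, ``strand``;
    gene intervals are non-overlapping.  ``control_sites`` are non-gene site
    ids whose true methylation is pinned to zero for conversion-rate QC.
    """

    chrom_lengths: dict[str, int]
    sites: pd.DataFrame
    ccgg: pd.DataFrame
    genes: pd.DataFrame
    islands: pd.DataFrame
    panel: frozenset[str]
    probes: np.ndarray
    control_sites: np.ndarray
    config: GenomeConfig | None = None
    seed: int | None = None
    _gene_sites: dict[str, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def gene_sites(self) -> dict[str, np.ndarray]:
        """Map gene_id -> array of site ids whose position lies in [start, end)."""
        if self._gene_sites is None:
            out: dict[str, np.ndarray] = {}
            for chrom, chrom_sites in self.sites.groupby("chrom", sort=False):
                pos = chrom_sites["pos"].to_numpy()
                ids = chrom_sites.index.to_numpy()
                sub = self.genes[self.genes["chrom"] == chrom]
                lo = np.searchsorted(pos, sub["start"].to_numpy(), side="left")
                hi = np.searchsorted(pos, sub["end"].to_numpy(), side="left")
                for gid, a, b in zip(sub["gene_id"], lo, hi):
                    out[gid] = ids[a:b]
            for gid in self.genes["gene_id"]:
                out.setdefault(gid, np.array([], dtype=int))
            object.__setattr__(self, "_gene_sites", out)
        return self._gene_sites

    def validate(self) -> None:
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if len(p) and not np.all(np.diff(p) > 0):
                raise ValueError(f"site positions not strictly increasing on {chrom}")
        for _, g in self.genes.iterrows():
            L = self.chrom_lengths[g["chrom"]]
            if not (0 <= g["start"] < g["end"] <= L):
                raise ValueError(f"gene {g['gene_id']} interval out of bounds")
        known = set(self.genes["gene_id"])
        if not self.panel <= known:
            raise ValueError("panel contains unknown gene ids")


def _poisson_positions(
    rng: np.random.Generator,
    length: int,
    islands: np.ndarray,
    rate_island: float,
    rate_background: float,
) -> np.ndarray:
    """Sample positions of a piecewise-homogeneous Poisson process on [0, length).

    ``islands`` is an (n, 2) array of merged, sorted half-open intervals.
    """
    bounds = [0]
    rates = []
    cursor = 0
    for s, e in islands:
        if s > cursor:
            rates.append(rate_background)
            bounds.append(s)
        rates.append(rate_island)
        bounds.append(e)
        cursor = e
    if cursor < length:
        rates.append(rate_background)
        bounds.append(length)
    pos_chunks = []
    for (s, e), r in zip(zip(bounds[:-1], bounds[1:]), rates):
        n = rng.poisson(r * (e - s))
        if n:
            pos_chunks.append(rng.integers(s, e, size=n))
    if not pos_chunks:
        return np.array([], dtype=int)
    return np.unique(np.concatenate(pos_chunks))


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    if len(iv) == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0])]
    merged = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=int)


def build_genome(config: GenomeConfig | None = None, seed: int = 0) -> GenomeModel:
    """Generate a :class:`GenomeModel`; deterministic given ``(config, seed)``.

    Genes are placed by rejection sampling so that they never overlap; a
    :class:`GenomeCapacityError` is raised when the requested number cannot
    be placed.
    """
    config = config or GenomeConfig()
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_lengths = {c: int(config.chrom_length) for c in chroms}

    # crude capacity check before the rejection loop
    total_len = sum(chrom_lengths.values())
    if config.n_genes * config.gene_length[0] > total_len:
        raise GenomeCapacityError(
            f"{config.n_genes} genes of >= {config.gene_length[0]} bp cannot fit "
            f"into {total_len} bp of genome"
        )

    islands_by_chrom: dict[str, np.ndarray] = {}
    site_rows, ccgg_rows, island_rows = [], [], []
    for chrom in chroms:
        L = chrom_lengths[chrom]
        n_isl = rng.poisson(config.island_rate * L)
        if n_isl:
            lens = rng.integers(*config.island_length, size=n_isl)
            starts = rng.integers(0, L, size=n_isl)
            iv = np.column_stack([starts, np.minimum(starts + lens, L)])
            iv = _merge_intervals(iv)
        else:
            iv = np.empty((0, 2), dtype=int)
        islands_by_chrom[chrom] = iv
        for s, e in iv:
            island_rows.append((chrom, int(s), int(e)))
        cpg = _poisson_positions(
            rng, L, iv, config.cpg_rate_island, config.cpg_rate_background
        )
        ccgg = _poisson_positions(
            rng, L, iv, config.ccgg_rate_island, config.ccgg_rate_background
        )
        in_island = np.zeros(len(cpg), dtype=bool)
        for s, e in iv:
            in_island |= (cpg >= s) & (cpg < e)
        site_rows.append(
            pd.DataFrame({"chrom": chrom, "pos": cpg, "island": in_island})
        )
        ccgg_rows.append(pd.DataFrame({"chrom": chrom, "pos": ccgg}))

    sites = pd.concat(site_rows, ignore_index=True)
    sites.index.name = "site_id"
    ccgg_df = pd.concat(ccgg_rows, ignore_index=True)
    islands_df = pd.DataFrame(island_rows, columns=["chrom", "start", "end"])

    # non-overlapping gene placement by rejection
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    gene_rows = []
    max_attempts = max(1_000, 200 * config.n_genes)
    attempts = 0
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    while len(gene_rows) < config.n_genes:
        if attempts >= max_attempts:
            raise GenomeCapacityError(
                f"could not place {config.n_genes} non-overlapping genes "
                f"(placed {len(gene_rows)} after {attempts} attempts)"
            )
        attempts += 1
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        glen = int(rng.integers(*config.gene_length))
        L = chrom_lengths[chrom]
        if glen >= L:
            continue
        start = int(rng.integers(0, L - glen))
        end = start + glen
        if any(start < e and s < end for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        gene_rows.append((f"g{len(gene_rows):04d}", chrom, start, end,
                          "+" if rng.random() < 0.5 else "-"))
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    ).sort_values(["chrom", "start"], ignore_index=True)

    gene_ids = genes["gene_id"].to_numpy()
    panel_size = min(config.panel_size, len(gene_ids))
    panel = frozenset(rng.choice(gene_ids, size=panel_size, replace=False)) if panel_size else frozenset()

    n_probes = int(round(config.probe_fraction * len(sites)))
    probes = np.sort(rng.choice(len(sites), size=n_probes, replace=False)) if n_probes else np.array([], dtype=int)

    # control sites: sampled from sites outside every gene interval
    in_gene = np.zeros(len(sites), dtype=bool)
    model_tmp = GenomeModel(
        chrom_lengths, sites, ccgg_df, genes, islands_df,
        frozenset(), np.array([], dtype=int), np.array([], dtype=int),
    )
    for idx in model_tmp.gene_sites().values():
        in_gene[idx] = True
    free = np.flatnonzero(~in_gene)
    n_ctrl = int(round(config.control_fraction * len(free)))
    control = np.sort(rng.choice(free, size=n_ctrl, replace=False)) if n_ctrl else np.array([], dtype=int)

    model = GenomeModel(
        chrom_lengths=chrom_lengths,
        sites=sites,
        ccgg=ccgg_df,
        genes=genes,
        islands=islands_df,
        panel=panel,
        probes=probes,
        control_sites=control,
        config=config,
        seed=seed,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# ground-truth methylome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectConfig:
    """Differential-methylation ground truth: counts and magnitude of effect genes.

    ``delta`` is the per-site shift of the tumor-group mean; hypomethylated
    effect genes shift down, hypermethylated up, clipped to [0, 1].
    """

    n_hypo: int = 50
    n_hyper: int = 5
    delta: float = 0.3


@dataclass
class TrueMethylome:
    """Ground-truth methylation probabilities per site and sample.

    ``samples`` has columns ``sample_id``, ``group`` (tumor/normal); ``truth``
    is a sites x samples DataFrame of probabilities; ``effects`` maps effect
    gene ids to their signed shift (negative = hypomethylated in tumor).
    """

    samples: pd.DataFrame
    truth: pd.DataFrame
    effects: dict[str, float]
    baseline: np.ndarray
    island_beta: tuple[float, float]
    background_beta: tuple[float, float]
    seed: int | None = None

    @property
    def groups(self) -> dict[str, str]:
        return dict(zip(self.samples["sample_id"], self.samples["group"]))

    def subset(self, n_tumor: int, n_normal: int, prefix: str = "") -> "TrueMethylome":
        """A view with the first ``n_tumor``/``n_normal`` samples, re-labelled.

        True methylation is shared within a group, so subsetting and
        re-labelling columns yields the cohort a smaller study would draw
        from the same underlying truth.
        """
        g = self.samples["group"].to_numpy()
        t_ids = self.samples["sample_id"].to_numpy()[g == "tumor"][:n_tumor]
        n_ids = self.samples["sample_id"].to_numpy()[g == "normal"][:n_normal]
        if len(t_ids) < n_tumor or len(n_ids) < n_normal:
            raise ValueError("not enough samples in truth to subset")
        new_ids = [f"{prefix}tumor_{i}" for i in range(n_tumor)] + [
            f"{prefix}normal_{i}" for i in range(n_normal)
        ]
        truth = self.truth[list(t_ids) + list(n_ids)].copy()
        truth.columns = new_ids
        samples = pd.DataFrame(
            {"sample_id": new_ids, "group": ["tumor"] * n_tumor + ["normal"] * n_normal}
        )
        return replace(self, samples=samples, truth=truth)


def draw_true_methylome(
    genome: GenomeModel,
    n_tumor: int,
    n_normal: int,
    effect_config: EffectConfig | None = None,
    seed: int = 0,
    island_beta: tuple[float, float] = (0.5, 5.0),
    background_beta: tuple[float, float] = (5.0, 0.5),
) -> TrueMethylome:
    """Draw baseline methylation and plant tumor-vs-normal effect genes.

    Baseline per-site methylation follows a bimodal beta mixture: island
    sites are drawn from ``beta(*island_beta)`` (low mode) and non-island
    sites from ``beta(*background_beta)`` (high mode), shared across samples.
    Spike-in control sites are pinned to 0.  Effect genes shift every site's
    tumor-group mean by the signed delta, clipped to [0, 1]; a warning is
    emitted for any effect gene whose realized shift is destroyed by
    clipping.
    """
    ec = effect_config or EffectConfig()
    if not (0.0 <= ec.delta <= 1.0):
        raise ValueError("delta must lie in [0, 1]")
    n_effect = ec.n_hypo + ec.n_hyper
    if n_effect > len(genome.genes):
        raise ValueError("n_hypo + n_hyper exceeds the number of genes")

    rng = np.random.default_rng(seed)
    island = genome.sites["island"].to_numpy()
    m0 = np.where(
        island,
        rng.beta(*island_beta, size=genome.n_sites),
        rng.beta(*background_beta, size=genome.n_sites),
    )
    m0[genome.control_sites] = 0.0

    gene_ids = genome.genes["gene_id"].to_numpy()
    chosen = rng.choice(gene_ids, size=n_effect, replace=False) if n_effect else np.array([], dtype=object)
    effects = {g: -ec.delta for g in chosen[: ec.n_hypo]}
    effects.update({g: ec.delta for g in chosen[ec.n_hypo:]})

    shift = np.zeros(genome.n_sites)
    gsites = genome.gene_sites()
    for g, d in effects.items():
        shift[gsites[g]] = d

    tumor_m = np.clip(m0 + shift, 0.0, 1.0)
    for g, d in effects.items():
        idx = gsites[g]
        if len(idx) == 0 or d == 0:
            continue
        realized = abs(tumor_m[idx].mean() - m0[idx].mean())
        if realized < 0.05 * abs(d):
            warnings.warn(
                f"effect on gene {g} is unrecoverable: clipping reduced the "
                f"realized shift to {realized:.3g} (requested {abs(d):.3g})",
                stacklevel=2,
            )

    sample_ids = [f"tumor_{i}" for i in range(n_tumor)] + [
        f"normal_{i}" for i in range(n_normal)
    ]
    groups = ["tumor"] * n_tumor + ["normal"] * n_normal
    cols = {
        sid: (tumor_m if grp == "tumor" else m0)
        for sid, grp in zip(sample_ids, groups)
    }
    truth = pd.DataFrame(cols, index=genome.sites.index)
    return TrueMethylome(
        samples=pd.DataFrame({"sample_id": sample_ids, "group": groups}),
        truth=truth,
        effects=effects,
        baseline=m0,
        island_beta=island_beta,
        background_beta=background_beta,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# read-count simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DepthConfig:
    """Negative-binomial read depth: mean and dispersion (var = mu + phi*mu^2)."""

    mean_depth: float = 30.0
    dispersion: float = 0.2


@dataclass(frozen=True)
class ConversionConfig:
    """Bisulfite chemistry error model.

    conv    — conversion rate of unmethylated C (reads T when converted);
    e_over  — inappropriate conversion rate of methylated C;
    seq_err — symmetric per-read base-call flip probability;
    bb_phi  — optional per-(site, sample) beta overdispersion of the read-level
              methylation probability (0 = pure binomial reads).
    """

    conv: float = 0.995
    e_over: float = 0.005
    seq_err: float = 0.001
    bb_phi: float = 0.0


@dataclass
class SiteCounts:
    """Per-site assay output: read counts (sequencing) or levels (array).

    ``counts`` is long form with columns ``site_id``, ``sample_id``, ``C``,
    ``T`` (None for array assays); ``levels`` is long form with columns
    ``site_id``, ``sample_id``, ``level`` (array only).
    """

    assay: str
    samples: pd.DataFrame
    counts: pd.DataFrame | None = None
    levels: pd.DataFrame | None = None
    conv: ConversionConfig | None = None
    depth: DepthConfig | None = None
    seed: int | None = None

    @property
    def groups(self) -> dict[str, str]:
        return dict(zip(self.samples["sample_id"], self.samples["group"]))

    def validate(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.counts is not None:
            if (self.counts[["C", "T"]].to_numpy() < 0).any():
                raise ValueError("negative read counts")


def rrbs_fragments(genome: GenomeModel, size_range: tuple[int, int] = (40, 220)) -> pd.DataFrame:
    """MspI fragments retained by size selection.

    Fragments run between consecutive CCGG cut positions on a chromosome and
    are retained when their length falls within ``size_range`` (inclusive),
    emulating the 40–220 bp selection step of reduced-representation
    protocols.
    """
    rows = []
    for chrom, grp in genome.ccgg.groupby("chrom", sort=False):
        p = np.sort(grp["pos"].to_numpy())
        if len(p) < 2:
            continue
        lengths = np.diff(p)
        keep = (lengths >= size_range[0]) & (lengths <= size_range[1])
        for s, e in zip(p[:-1][keep], p[1:][keep]):
            rows.append((chrom, int(s), int(e)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _footprint(genome: GenomeModel, assay: str) -> np.ndarray:
    """Site ids covered by an assay's footprint."""
    if assay == "WGBS":
        return genome.sites.index.to_numpy()
    if assay == "RRBS":
        frags = rrbs_fragments(genome)
        keep = np.zeros(genome.n_sites, dtype=bool)
        for chrom, grp in genome.sites.groupby("chrom", sort=False):
            sub = frags[frags["chrom"] == chrom]
            if sub.empty:
                continue
            pos = grp["pos"].to_numpy()
            ids = grp.index.to_numpy()
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            # fragments are disjoint and sorted; locate each site's fragment
            j = np.searchsorted(starts, pos, side="right") - 1
            ok = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
            keep[ids[ok]] = True
        return np.flatnonzero(keep)
    if assay == "targetedBS":
        gsites = genome.gene_sites()
        idx = [gsites[g] for g in sorted(genome.panel)]
        if not idx:
            return np.array([], dtype=int)
        return np.unique(np.concatenate(idx))
    if assay == "array":
        return np.asarray(genome.probes, dtype=int)
    raise ValueError(f"unknown assay {assay!r}")


def simulate_counts(
    truth: TrueMethylome,
    genome: GenomeModel,
    assay: str,
    depth_config: DepthConfig | None = None,
    conv_config: ConversionConfig | None = None,
    seed: int = 0,
    array_sigma: float = 0.05,
) -> SiteCounts:
    """Simulate per-site counts (or array levels) for one assay.

    Coverage per covered site and sample is negative-binomial; each read
    reports methylated with probability
    ``p = m(1-e_over) + (1-m)(1-conv)`` and is then flipped with probability
    ``seq_err``.  The array assay instead reports ``truth + N(0, array_sigma)``
    clipped to [0, 1] at probe sites, without counts.
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    conv = conv_config or ConversionConfig()
    rng = np.random.default_rng(seed)
    fp = _footprint(genome, assay)
    sample_ids = truth.samples["sample_id"].to_list()
    m = truth.truth.loc[fp, sample_ids].to_numpy()

    if assay == "array":
        noisy = np.clip(m + rng.normal(0.0, array_sigma, size=m.shape), 0.0, 1.0)
        levels = pd.DataFrame(
            {
                "site_id": np.repeat(fp, len(sample_ids)),
                "sample_id": np.tile(sample_ids, len(fp)),
                "level": noisy.ravel(),
            }
        )
        return SiteCounts(
            assay=assay, samples=truth.samples.copy(), levels=levels,
            conv=conv, depth=None, seed=seed,
        )

    dc = depth_config or DepthConfig(mean_depth=DEFAULT_DEPTH[assay])
    if dc.mean_depth < 0:
        raise ValueError("mean depth must be non-negative")
    if dc.dispersion > 0:
        n_param = 1.0 / dc.dispersion
        p_param = n_param / (n_param + dc.mean_depth)
        depth = rng.negative_binomial(n_param, p_param, size=m.shape)
    else:
        depth = rng.poisson(dc.mean_depth, size=m.shape)

    if conv.bb_phi > 0:
        # per-cell beta jitter of the true methylation probability
        conc = 1.0 / conv.bb_phi
        eps = 1e-9
        mm = np.clip(m, eps, 1 - eps)
        m_cell = rng.beta(mm * conc, (1 - mm) * conc)
    else:
        m_cell = m
    p = m_cell * (1.0 - conv.e_over) + (1.0 - m_cell) * (1.0 - conv.conv)
    p = p * (1.0 - conv.seq_err) + (1.0 - p) * conv.seq_err
    C = rng.binomial(depth, p)
    T = depth - C

    covered = depth > 0
    rows, cols = np.nonzero(covered)
    counts = pd.DataFrame(
        {
            "site_id": fp[rows],
            "sample_id": np.asarray(sample_ids, dtype=object)[cols],
            "C": C[rows, cols],
            "T": T[rows, cols],
        }
    )
    out = SiteCounts(
        assay=assay, samples=truth.samples.copy(), counts=counts,
        conv=conv, depth=dc, seed=seed,
    )
    out.validate()
    return out
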