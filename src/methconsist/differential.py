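"""Gene-level aggregation, fold-change DMG calling and DMR hypothesis tests.

A gene's methylation score in a sample is the unweighted mean of the
non-missing site levels inside the gene interval.  Differentially methylated
genes (DMGs) are called by fold change — the absolute difference between the
tumor and normal group means of the gene score — at a threshold tau
(default 0.15 on the fraction scale, i.e. a 15-percentage-point shift).

Region-level differential tests come in two families:

* count-based — Fisher's exact test, Pearson chi-square, and a Poisson–Wald
  test on the log methylated-read rate; read counts are pooled over the
  sites and samples of each group (methylKit-style), or optionally tallied
  as methylated/unmethylated samples with ``count_unit='sample'``.
* ratio-based — Welch's two-sample t on per-sample scores, or one-way ANOVA
  for more than two groups.

p-values from a scan over many regions are adjusted with the
Benjamini–Hochberg step-up false-discovery-rate procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scoring import MethylationMatrix
from .simulate import GenomeModel, SiteCounts

__all__ = [
    "GeneMethylationMatrix",
    "DMRTestResult",
    "aggregate_genes",
    "call_dmg",
    "pool_region_counts",
    "fisher_region_test",
    "fisher_test",
    "chisq_test",
    "poisson_wald_test",
    "ratio_tests",
    "bh_adjust",
    "dmr_scan_counts",
    "dmr_scan_ratio",
    "ZeroExpectedError",
]

logger = logging.getLogger(__name__)


class ZeroExpectedError(ValueError):
    """Chi-square expected cell count is zero; use Fisher's exact test instead."""


@dataclass
class GeneMethylationMatrix:
    """Genes x samples methylation scores with per-cell usable-site counts."""

    scores: pd.DataFrame
    n_sites: pd.DataFrame
    min_sites: int = 1


@dataclass
class DMRTestResult:
    """One region-level test: statistic, p, and method-specific extras."""

    method: str
    statistic: float
    p_value: float
    q_value: float | None = None
    df: float | None = None
    table: np.ndarray | None = None
    group_means: tuple[float, ...] | None = None
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# gene aggregation and DMG calling
# ---------------------------------------------------------------------------


def aggregate_genes(
    levels: MethylationMatrix, genome: GenomeModel, min_sites: int = 1
) -> GeneMethylationMatrix:
    """Average site levels within each gene interval, per sample.

    The mean is unweighted over non-missing site levels at positions in
    ``[start, end)``; a cell is missing when fewer than ``min_sites`` sites
    are usable.
    """
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    gsites = genome.gene_sites()
    samples = levels.levels.columns
    score_rows, n_rows, index = [], [], []
    lv = levels.levels
    for gid in genome.genes["gene_id"]:
        sub = lv.reindex(gsites[gid])
        n_used = sub.notna().sum(axis=0)
        with np.errstate(invalid="ignore"):
            score = sub.mean(axis=0, skipna=True)
        score = score.where(n_used >= min_sites)
        score_rows.append(score.to_numpy())
        n_rows.append(n_used.to_numpy())
        index.append(gid)
    scores = pd.DataFrame(score_rows, index=index, columns=samples)
    n_sites = pd.DataFrame(n_rows, index=index, columns=samples)
    scores.index.name = n_sites.index.name = "gene_id"
    return GeneMethylationMatrix(scores=scores, n_sites=n_sites, min_sites=min_sites)


def call_dmg(
    genes: GeneMethylationMatrix,
    groups: dict[str, str] | pd.Series,
    tau: float = 0.15,
) -> pd.DataFrame:
    """Fold-change DMG table.

    fold_change = |mean_tumor - mean_normal| of the per-sample gene scores;
    direction is ``hypo`` when the tumor mean is lower.  Genes with an
    entirely missing group are dropped (count logged).  Returns a DataFrame
    indexed by gene_id with columns mean_tumor, mean_normal, fold_change,
    direction, is_dmg.
    """
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie in (0, 1)")
    groups = dict(groups)
    tumor = [s for s in genes.scores.columns if groups.get(s) == "tumor"]
    normal = [s for s in genes.scores.columns if groups.get(s) == "normal"]
    if not tumor or not normal:
        raise ValueError("need at least one sample per group")
    mt = genes.scores[tumor].mean(axis=1, skipna=True)
    mn = genes.scores[normal].mean(axis=1, skipna=True)
    ok = mt.notna() & mn.notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("call_dmg: dropped %d genes with an all-missing group", n_dropped)
    mt, mn = mt[ok], mn[ok]
    fc = (mt - mn).abs()
    direction = pd.Series(pd.NA, index=fc.index, dtype="object")
    direction[mt < mn] = "hypo"
    direction[mt > mn] = "hyper"
    return pd.DataFrame(
        {
            "mean_tumor": mt,
            "mean_normal": mn,
            "fold_change": fc,
            "direction": direction,
            "is_dmg": fc > tau,
        }
    )


# ---------------------------------------------------------------------------
# count-based tests
# ---------------------------------------------------------------------------


def pool_region_counts(
    counts: SiteCounts,
    site_ids: np.ndarray,
    groups: dict[str, str] | None = None,
    count_unit: str = "read",
    sample_level_threshold: float = 0.5,
) -> tuple[np.ndarray, list[str]]:
    """Build the per-group (methylated, unmethylated) table for a region.

    ``count_unit='read'`` pools C and T reads over all sites and samples of
    each group; ``count_unit='sample'`` instead counts samples whose pooled
    region level exceeds ``sample_level_threshold`` as methylated.
    Returns (groups x 2 array, group labels).
    """
    groups = dict(groups) if groups is not None else counts.groups
    df = counts.counts
    sub = df[df["site_id"].isin(set(np.asarray(site_ids).tolist()))]
    labels = sorted(set(groups.values()))
    table = []
    for lab in labels:
        sids = [s for s, g in groups.items() if g == lab]
        grp = sub[sub["sample_id"].isin(sids)]
        if count_unit == "read":
            table.append([int(grp["C"].sum()), int(grp["T"].sum())])
        elif count_unit == "sample":
            per = grp.groupby("sample_id")[["C", "T"]].sum()
            lv = per["C"] / (per["C"] + per["T"])
            meth = int((lv > sample_level_threshold).sum())
            table.append([meth, len(per) - meth])
        else:
            raise ValueError("count_unit must be 'read' or 'sample'")
    return np.array(table, dtype=int), labels


def fisher_test(table: np.ndarray) -> DMRTestResult:
    """Two-sided Fisher exact test on a 2x2 (methylated, unmethylated) table.

    The two-sided p sums the probabilities of all tables with the same
    margins whose hypergeometric probability does not exceed the observed
    table's.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise ValueError("fisher_test requires a 2x2 table")
    flags: tuple[str, ...] = ()
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return DMRTestResult("fisher", np.nan, np.nan, table=table,
                             flags=("empty_margin",))
    res = stats.fisher_exact(table, alternative="two-sided")
    return DMRTestResult("fisher", float(res.statistic), float(res.pvalue),
                         table=table, flags=flags)


def fisher_region_test(
    counts: SiteCounts,
    region: tuple[str, int, int],
    genome: GenomeModel,
    groups: dict[str, str] | None = None,
    count_unit: str = "read",
) -> DMRTestResult:
    """Fisher exact test on the pooled counts of one genomic region."""
    chrom, start, end = region
    sites = genome.sites
    mask = (sites["chrom"] == chrom) & (sites["pos"] >= start) & (sites["pos"] < end)
    site_ids = sites.index.to_numpy()[mask.to_numpy()]
    table, labels = pool_region_counts(counts, site_ids, groups, count_unit)
    if table.shape[0] != 2:
        raise ValueError("fisher_region_test requires exactly two groups")
    if (table.sum(axis=1) == 0).any():
        return DMRTestResult("fisher", np.nan, np.nan, table=table,
                             flags=("uncovered_group",))
    return fisher_test(table)


def chisq_test(table: np.ndarray) -> DMRTestResult:
    """Pearson chi-square on a groups x 2 table (no continuity correction).

    Handles any number of groups (rows).  Raises :class:`ZeroExpectedError`
    when an expected cell count is zero, pointing users at Fisher's exact
    test.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("chisq_test requires an r x c table with r, c >= 2")
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if (expected == 0).any():
        raise ZeroExpectedError(
            "zero expected cell count; use Fisher's exact test for sparse tables"
        )
    stat = float(((table - expected) ** 2 / expected).sum())
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = float(stats.chi2.sf(stat, dof))
    return DMRTestResult("chisq", stat, p, df=float(dof), table=table.astype(int))


def poisson_wald_test(
    meth: tuple[int, int] | np.ndarray, total: tuple[int, int] | np.ndarray
) -> DMRTestResult:
    """Wald test for equality of two Poisson rates of methylated reads.

    The per-group rate is methylated count / total reads; the Wald statistic
    compares log rates, ``z = (ln r1 - ln r2) / sqrt(1/C1 + 1/C2)``, with a
    two-sided normal p.  Groups with zero methylated reads receive a +0.5
    continuity correction (flagged).
    """
    C = np.asarray(meth, dtype=float)
    N = np.asarray(total, dtype=float)
    if C.shape != (2,) or N.shape != (2,):
        raise ValueError("poisson_wald_test compares exactly two groups")
    if (N <= 0).any():
        raise ValueError("total reads (exposure) must be positive in both groups")
    flags: tuple[str, ...] = ()
    if (C == 0).any():
        C = C + 0.5
        N = N + 0.5
        flags = ("continuity_correction",)
    r = C / N
    z = float((np.log(r[0]) - np.log(r[1])) / np.sqrt(1.0 / C[0] + 1.0 / C[1]))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DMRTestResult("poisson_wald", z, p, group_means=tuple(r), flags=flags)


# ---------------------------------------------------------------------------
# ratio-based tests
# ---------------------------------------------------------------------------


def ratio_tests(
    values_by_group: list[np.ndarray], method: str = "welch_t"
) -> DMRTestResult:
    """Welch two-sample t or one-way ANOVA on per-sample region scores.

    Degenerate zero-variance inputs are resolved by the limit argument:
    equal means give p = 1, unequal means p = 0 (flagged ``degenerate``).
    """
    vals = [np.asarray(v, dtype=float) for v in values_by_group]
    vals = [v[~np.isnan(v)] for v in vals]
    if any(len(v) < 2 for v in vals):
        raise ValueError("need >= 2 non-missing samples per group")
    variances = [v.var(ddof=1) for v in vals]
    means = tuple(float(v.mean()) for v in vals)
    if all(s == 0 for s in variances):
        if len(set(means)) == 1:
            return DMRTestResult(method, 0.0, 1.0, group_means=means,
                                 flags=("degenerate",))
        return DMRTestResult(method, np.inf, 0.0, group_means=means,
                             flags=("degenerate",))
    if method == "welch_t":
        if len(vals) != 2:
            raise ValueError("welch_t compares exactly two groups")
        res = stats.ttest_ind(vals[0], vals[1], equal_var=False)
        return DMRTestResult("welch_t", float(res.statistic), float(res.pvalue),
                             df=float(res.df), group_means=means)
    if method == "anova":
        stat, p = stats.f_oneway(*vals)
        return DMRTestResult("anova", float(stat), float(p), group_means=means)
    raise ValueError("method must be 'welch_t' or 'anova'")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; empty input gives empty output."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# gene-wise scans
# ---------------------------------------------------------------------------


def dmr_scan_counts(
    counts: SiteCounts,
    genome: GenomeModel,
    method: str = "fisher",
    groups: dict[str, str] | None = None,
    count_unit: str = "read",
) -> pd.DataFrame:
    """Run a count-based test gene by gene and BH-adjust across genes.

    ``method`` is one of ``fisher``, ``chisq``, ``poisson``.  Genes whose
    pooled table has an uncovered group are skipped.  Returns a DataFrame
    indexed by gene_id with statistic, p_value, q_value and the pooled
    per-group counts.
    """
    groups = dict(groups) if groups is not None else counts.groups
    gsites = genome.gene_sites()
    # pool counts per (gene, group) in one pass
    df = counts.counts
    site_to_gene: dict[int, str] = {}
    for gid, idx in gsites.items():
        for s in idx:
            site_to_gene[int(s)] = gid
    sub = df[df["site_id"].isin(site_to_gene.keys())].copy()
    sub["gene_id"] = sub["site_id"].map(site_to_gene)
    sub["group"] = sub["sample_id"].map(groups)
    labels = sorted(set(groups.values()))
    pooled = sub.groupby(["gene_id", "group"])[["C", "T"]].sum()

    rows = []
    for gid in genome.genes["gene_id"]:
        try:
            tab = np.array(
                [pooled.loc[(gid, lab)].to_numpy() for lab in labels], dtype=int
            )
        except KeyError:
            continue
        if (tab.sum(axis=1) == 0).any():
            continue
        if method == "fisher":
            res = fisher_test(tab)
        elif method == "chisq":
            try:
                res = chisq_test(tab)
            except ZeroExpectedError:
                continue
        elif method == "poisson":
            res = poisson_wald_test(tab[:, 0], tab.sum(axis=1))
        else:
            raise ValueError("method must be 'fisher', 'chisq' or 'poisson'")
        row = {"gene_id": gid, "method": res.method, "statistic": res.statistic,
               "p_value": res.p_value}
        for lab, (c, t) in zip(labels, tab):
            row[f"C_{lab}"], row[f"T_{lab}"] = int(c), int(t)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["method", "statistic", "p_value"]
    )
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def dmr_scan_ratio(
    genes: GeneMethylationMatrix,
    groups: dict[str, str] | pd.Series,
    method: str = "welch_t",
) -> pd.DataFrame:
    """Run a ratio-based test on per-sample gene scores, gene by gene."""
    groups = dict(groups)
    labels = sorted(set(groups.values()))
    cols = {lab: [s for s in genes.scores.columns if groups.get(s) == lab]
            for lab in labels}
    rows = []
    for gid, sc in genes.scores.iterrows():
        vals = [sc[cols[lab]].to_numpy(dtype=float) for lab in labels]
        vals = [v[~np.isnan(v)] for v in vals]
        if any(len(v) < 2 for v in vals):
            continue
        res = ratio_tests(vals, method=method)
        rows.append({"gene_id": gid, "method": res.method,
                     "statistic": res.statistic, "p_value": res.p_value,
                     **{f"mean_{lab}": m for lab, m in zip(labels, res.group_means)}})
    out = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["method", "statistic", "p_value"]
    )
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out
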