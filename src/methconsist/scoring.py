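"""Per-site methylation level scoring and quality-control metrics.

The methylation level of a site in a sample is the fraction of reads
reporting cytosine, ``C / (C + T)``, conventionally printed as a percentage.
Levels are stored as fractions in [0, 1]; cells whose coverage ``C + T``
falls below ``min_cov`` are marked missing.  The bisulfite conversion rate is
estimated from unmethylated spike-in control sites as the fraction of their
reads that were successfully converted (read as T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SiteCounts

__all__ = ["MethylationMatrix", "QCReport", "score_sites", "qc_report"]

COVERAGE_THRESHOLDS = (1, 4, 10, 30)


@dataclass
class MethylationMatrix:
    """Sites x samples methylation levels in [0, 1] with missingness.

    ``levels`` holds NaN where a cell is unobserved or under-covered;
    ``coverage`` holds per-cell read totals (None for array assays, which
    report levels without counts).
    """

    levels: pd.DataFrame
    coverage: pd.DataFrame | None
    assay: str
    min_cov: int | None = None


@dataclass
class QCReport:
    """Per-sample quality metrics.

    ``per_sample`` columns: n_covered_sites, coverage quantiles
    (cov_min/q25/median/q75/max), frac_cov_ge_{1,4,10,30}, conversion_rate
    (NaN when no control sites are available).  ``level_histogram`` is a
    20-bin histogram of per-cell methylation levels per sample.
    """

    per_sample: pd.DataFrame
    level_histogram: pd.DataFrame


def score_sites(counts: SiteCounts, min_cov: int = 4) -> MethylationMatrix:
    """Compute the site x sample level matrix ``C/(C+T)`` with a coverage filter.

    Cells with ``C + T < min_cov`` are missing.  Array assays carry no read
    counts, so their levels pass through unchanged and ``coverage`` is None.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if counts.assay == "array":
        lv = counts.levels.pivot(index="site_id", columns="sample_id", values="level")
        lv = lv.reindex(columns=counts.samples["sample_id"].to_list())
        return MethylationMatrix(levels=lv, coverage=None, assay=counts.assay,
                                 min_cov=None)
    df = counts.counts
    if (df[["C", "T"]].to_numpy() < 0).any():
        raise ValueError("negative read counts")
    cov_long = df["C"] + df["T"]
    level_long = np.where(cov_long > 0, df["C"] / cov_long.replace(0, np.nan), np.nan)
    tmp = df.assign(_cov=cov_long, _lv=level_long)
    cov = tmp.pivot(index="site_id", columns="sample_id", values="_cov")
    lv = tmp.pivot(index="site_id", columns="sample_id", values="_lv")
    lv = lv.where(cov >= min_cov)
    order = [s for s in counts.samples["sample_id"] if s in lv.columns]
    return MethylationMatrix(
        levels=lv[order], coverage=cov[order].fillna(0).astype(int),
        assay=counts.assay, min_cov=min_cov,
    )


def qc_report(counts: SiteCounts, control_sites: np.ndarray | None = None) -> QCReport:
    """Per-sample coverage, level-distribution and conversion-rate metrics.

    The conversion rate is estimated over control sites (true methylation 0)
    as ``sum(T) / sum(C + T)``: every converted read at such a site appears
    as T, so any residual C reflects failed conversion (plus sequencing
    error).  When ``control_sites`` is empty or absent the estimate is NaN.
    """
    if counts.assay == "array":
        raise ValueError("qc_report requires read counts; array assays have none")
    df = counts.counts
    if df is None or df.empty:
        raise ValueError("empty counts")
    df = df.assign(cov=df["C"] + df["T"])

    rows = []
    hist_rows = {}
    edges = np.linspace(0.0, 1.0, 21)
    ctrl = set(np.asarray(control_sites).tolist()) if control_sites is not None else set()
    for sid, grp in df.groupby("sample_id", sort=False):
        cov = grp["cov"].to_numpy()
        q = np.quantile(cov, [0.0, 0.25, 0.5, 0.75, 1.0])
        lv = (grp["C"] / grp["cov"]).to_numpy()
        hist_rows[sid], _ = np.histogram(lv, bins=edges)
        if ctrl:
            sub = grp[grp["site_id"].isin(ctrl)]
            tot = int(sub["cov"].sum())
            conv = float(sub["T"].sum() / tot) if tot else np.nan
        else:
            conv = np.nan
        row = {
            "sample_id": sid,
            "n_covered_sites": int((cov > 0).sum()),
            "cov_min": q[0], "cov_q25": q[1], "cov_median": q[2],
            "cov_q75": q[3], "cov_max": q[4],
            "conversion_rate": conv,
        }
        for k in COVERAGE_THRESHOLDS:
            row[f"frac_cov_ge_{k}"] = float((cov >= k).mean())
        rows.append(row)
    per_sample = pd.DataFrame(rows).set_index("sample_id")
    hist = pd.DataFrame(hist_rows, index=pd.IntervalIndex.from_breaks(edges))
    hist.index.name = "level_bin"
    return QCReport(per_sample=per_sample, level_histogram=hist)
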