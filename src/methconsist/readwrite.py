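"""Plain-text readers and writers for the pipeline's tabular formats.

All tables are tab-separated with a header row; missing values are written
as ``NA``.  BED outputs use 0-based half-open coordinates.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .functional import AnnotationDAG
from .simulate import GenomeModel, SiteCounts
from .scoring import MethylationMatrix

FLOAT_FMT = "%.6g"

#: conventional Wang edge weights by relation type
RELATION_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", float_format=FLOAT_FMT, index=index)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], index_col=index_col)


def write_sites_bed(genome: GenomeModel, path) -> None:
    """BED of CpG sites: chrom, start, end (=start+1), site_id, island flag."""
    df = genome.sites.reset_index()
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"] + 1,
            "name": "s" + df["site_id"].astype(str),
            "score": df["island"].astype(int),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_genes_bed(genome: GenomeModel, path) -> None:
    df = genome.genes
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": df["gene_id"],
            "score": 0,
            "strand": df["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_counts(counts: SiteCounts, path) -> None:
    if counts.assay == "array":
        write_tsv(counts.levels, path, index=False)
    else:
        write_tsv(counts.counts, path, index=False)


def read_counts(path, assay: str, groups: dict[str, str] | None = None) -> SiteCounts:
    """Read a counts TSV (site_id, sample_id, C, T) or array levels TSV.

    ``groups`` maps sample ids to tumor/normal; unlisted samples get group
    ``NA``.
    """
    df = read_tsv(path)
    sample_ids = sorted(df["sample_id"].unique())
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": [groups.get(s, "NA") if groups else "NA" for s in sample_ids],
        }
    )
    if assay == "array":
        return SiteCounts(assay=assay, samples=samples, levels=df)
    return SiteCounts(assay=assay, samples=samples, counts=df)


def read_groups(path) -> dict[str, str]:
    df = read_tsv(path)
    return dict(zip(df["sample_id"], df["group"]))


def write_matrix(mm: MethylationMatrix | pd.DataFrame, path) -> None:
    df = mm.levels if isinstance(mm, MethylationMatrix) else mm
    write_tsv(df, path)


def read_matrix(path) -> pd.DataFrame:
    return read_tsv(path, index_col=0)


def read_annotation(path) -> dict[str, set]:
    """Flat gene->terms annotation from a two-column (gene_id, term_id) TSV."""
    df = read_tsv(path)
    out: dict[str, set] = {}
    for g, t in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(g), set()).add(str(t))
    return out


def read_dag(path, annotation: dict[str, set] | None = None) -> AnnotationDAG:
    """Term DAG from a (child, parent[, relation]) edge-list TSV.

    Relations map to Wang weights via :data:`RELATION_WEIGHTS` (unknown
    relations default to is-a weight).  Roots are terms with no parents.
    """
    df = read_tsv(path)
    parents: dict[str, list[tuple[str, float]]] = {}
    all_terms: set[str] = set()
    for _, row in df.iterrows():
        child, parent = str(row.iloc[0]), str(row.iloc[1])
        rel = str(row.iloc[2]) if df.shape[1] > 2 else "is_a"
        w = RELATION_WEIGHTS.get(rel, RELATION_WEIGHTS["is_a"])
        parents.setdefault(child, []).append((parent, w))
        all_terms.update((child, parent))
    roots = all_terms - set(parents)
    dag = AnnotationDAG(parents=parents, gene2terms=annotation or {}, roots=roots)
    dag.validate()
    return dag


def read_network(path) -> nx.Graph:
    """Undirected simple graph from a two-column edge-list TSV."""
    df = read_tsv(path)
    g = nx.Graph()
    for u, v in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if str(u) != str(v):
            g.add_edge(str(u), str(v))
    return g


def write_network(g: nx.Graph, path) -> None:
    rows = sorted((min(u, v), max(u, v)) for u, v in g.edges)
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)
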