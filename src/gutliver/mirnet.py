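"""Stage-wise signed miRNA-mRNA interaction networks.

Predicted miRNA targets (externally supplied, miRWalk-style) are overlapped
with the differentially expressed miRNAs and mRNAs of each stage; surviving
pairs are signed by the Pearson correlation of their expression profiles
over the four time points and optionally restricted to immune-library
targets.  Networks export to SIF / GraphML / attribute TSVs for Cytoscape.

Because mRNA and miRNA libraries carry different replicate numbers (3 vs
2), correlations pair per-time-point means of log2(normalised count + 1):
four paired points per (miRNA, gene) pair.  No p-value is attached to r at
four points, and no |r| threshold is applied by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import TIMEPOINTS, CountMatrix
from .diffexpr import StageDEResult, size_factors
from .immune_library import ImmuneGeneLibrary

log = logging.getLogger(__name__)


@dataclass
class TargetMap:
    """Predicted miRNA -> target-gene relation (deduplicated pairs)."""

    edges: set[tuple[str, str]]
    source: str = ""

    def __post_init__(self) -> None:
        for m, g in self.edges:
            if not m or not g:
                raise ValueError("TargetMap ids must be non-empty")

    @classmethod
    def from_tsv(cls, path) -> "TargetMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"mirna_id", "gene_id"} <= set(df.columns):
            raise ValueError("target map needs columns mirna_id, gene_id")
        return cls(set(zip(df["mirna_id"], df["gene_id"])), source=str(path))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            sorted(self.edges), columns=["mirna_id", "gene_id"]
        ).to_csv(path, sep="\t", index=False)

    def targets_of(self, mirna_id: str) -> set[str]:
        return {g for m, g in self.edges if m == mirna_id}


def _timepoint_means(cm: CountMatrix) -> pd.DataFrame:
    """log2(normalised count + 1) averaged per time point (features x 4)."""
    sf = size_factors(cm.counts.to_numpy(), pseudo_reference=True)
    logexpr = np.log2(cm.counts.to_numpy(dtype=float) / sf + 1.0)
    df = pd.DataFrame(logexpr, index=cm.feature_ids, columns=cm.counts.columns)
    cols = {}
    for tp in cm.timepoints_present:
        cols[tp] = df[cm.samples_at(tp)].mean(axis=1)
    return pd.DataFrame(cols)


def pair_correlations(
    mir_expr: CountMatrix, mrna_expr: CountMatrix, targets: TargetMap
) -> pd.DataFrame:
    """Pearson r per predicted (miRNA, gene) pair over shared time points.

    Pairs whose miRNA or gene is absent from the matrices, or whose
    profile has zero variance on either side (r undefined), are dropped
    with a log entry.  Requires >=3 shared time points.
    """
    shared = [t for t in TIMEPOINTS
              if t in mir_expr.timepoints_present and t in mrna_expr.timepoints_present]
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared time points; got {shared}")
    mir_prof = _timepoint_means(mir_expr)[shared]
    mrna_prof = _timepoint_means(mrna_expr)[shared]
    rows, n_missing, n_degenerate = [], 0, 0
    for m, g in sorted(targets.edges):
        if m not in mir_prof.index or g not in mrna_prof.index:
            n_missing += 1
            continue
        x = mir_prof.loc[m].to_numpy()
        y = mrna_prof.loc[g].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            n_degenerate += 1
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"mirna_id": m, "gene_id": g, "r": r, "n_points": len(shared)})
    if n_missing:
        log.info("skipped %d target pairs absent from the matrices", n_missing)
    if n_degenerate:
        log.info("dropped %d pairs with zero-variance profiles (r undefined)", n_degenerate)
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "r", "n_points"])


def stage_network(
    correlations: pd.DataFrame,
    mirna_de: StageDEResult,
    mrna_de: StageDEResult,
    stage: str,
    library: ImmuneGeneLibrary | None = None,
    r_threshold: float | None = None,
) -> pd.DataFrame:
    """Signed interaction edges for one stage.

    Edges are the target-map pairs whose miRNA and gene are both called
    differentially expressed in the stage; each edge carries the DE
    directions, the correlation sign, and an immune flag when a library is
    given.  ``r_threshold`` optionally drops edges with |r| below it
    (off by default).
    """
    mir_dir = {m: "up" for m in mirna_de.up_set}
    mir_dir.update({m: "down" for m in mirna_de.down_set})
    gene_dir = {g: "up" for g in mrna_de.up_set}
    gene_dir.update({g: "down" for g in mrna_de.down_set})
    immune_genes = library.genes if library is not None else set()
    rows = []
    for rec in correlations.itertuples(index=False):
        if rec.mirna_id not in mir_dir or rec.gene_id not in gene_dir:
            continue
        if r_threshold is not None and abs(rec.r) < r_threshold:
            continue
        rows.append(
            {
                "mirna_id": rec.mirna_id,
                "gene_id": rec.gene_id,
                "r": rec.r,
                "n_points": rec.n_points,
                "stage": stage,
                "mirna_dir": mir_dir[rec.mirna_id],
                "gene_dir": gene_dir[rec.gene_id],
                "sign": "positive" if rec.r > 0 else "negative",
                "immune": rec.gene_id in immune_genes,
            }
        )
    edges = pd.DataFrame(
        rows,
        columns=["mirna_id", "gene_id", "r", "n_points", "stage",
                 "mirna_dir", "gene_dir", "sign", "immune"],
    )
    if len(edges):
        tally = edges.groupby(["mirna_dir", "gene_dir", "sign"]).size()
        log.info("stage %s: %d edges; direction/sign cells:\n%s", stage, len(edges), tally)
    return edges


def immune_subnetwork(edges: pd.DataFrame, library: ImmuneGeneLibrary) -> pd.DataFrame:
    """Edges whose target gene is in the immune library."""
    if not len(edges):
        return edges.copy()
    out = edges[edges["gene_id"].isin(library.genes)].copy()
    out["immune"] = True
    return out.reset_index(drop=True)


def summarize_by_process(edges: pd.DataFrame, library: ImmuneGeneLibrary) -> pd.DataFrame:
    """Per-stage, per-direction immune-process tally of network targets.

    Mirrors the published per-stage pair listing: for each (stage,
    mirna_dir, gene_dir, immune process) the distinct target genes, their
    count, and the miRNAs with their targets in parentheses.
    """
    member: dict[str, list[tuple[str, str]]] = {}
    for g, p, c in library.records:
        member.setdefault(g, []).append((p, c))
    rows = []
    if not len(edges):
        return pd.DataFrame(
            columns=["stage", "mirna_dir", "gene_dir", "process",
                     "gene_no", "categories", "pairs"]
        )
    for (stage, mdir, gdir), grp in edges.groupby(["stage", "mirna_dir", "gene_dir"]):
        by_proc: dict[str, dict[str, set]] = {}
        for rec in grp.itertuples(index=False):
            for proc, cat in member.get(rec.gene_id, []):
                d = by_proc.setdefault(proc, {"genes": set(), "cats": set(), "pairs": set()})
                d["genes"].add(rec.gene_id)
                d["cats"].add(cat)
                d["pairs"].add(f"{rec.mirna_id} ({rec.gene_id})")
        for proc, d in sorted(by_proc.items()):
            rows.append(
                {
                    "stage": stage,
                    "mirna_dir": mdir,
                    "gene_dir": gdir,
                    "process": proc,
                    "gene_no": len(d["genes"]),
                    "categories": "; ".join(sorted(d["cats"])),
                    "pairs": "; ".join(sorted(d["pairs"])),
                }
            )
    return pd.DataFrame(rows)


def to_graph(edges: pd.DataFrame) -> nx.Graph:
    """networkx graph with node class/regulation and edge sign attributes."""
    g = nx.Graph()
    for rec in edges.itertuples(index=False):
        g.add_node(rec.mirna_id, kind="mirna", regulation=rec.mirna_dir)
        g.add_node(rec.gene_id, kind="mrna", regulation=rec.gene_dir)
        g.add_edge(
            rec.mirna_id,
            rec.gene_id,
            r=float(rec.r),
            sign=rec.sign,
            stage=rec.stage,
            immune=bool(rec.immune),
        )
    return g


def export_network(edges: pd.DataFrame, outdir, prefix: str = "network") -> dict[str, Path]:
    """Write SIF, GraphML and node/edge attribute TSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sif": outdir / f"{prefix}.sif",
        "graphml": outdir / f"{prefix}.graphml",
        "edges": outdir / f"{prefix}.edges.tsv",
        "nodes": outdir / f"{prefix}.nodes.tsv",
    }
    with open(paths["sif"], "w") as fh:
        for rec in edges.itertuples(index=False):
            fh.write(f"{rec.mirna_id}\ttargets\t{rec.gene_id}\n")
    g = to_graph(edges)
    nx.write_graphml(g, paths["graphml"])
    edges.to_csv(paths["edges"], sep="\t", index=False)
    nodes = pd.DataFrame(
        [{"node_id": n, **attrs} for n, attrs in sorted(g.nodes(data=True))],
        columns=["node_id", "kind", "regulation"],
    )
    nodes.to_csv(paths["nodes"], sep="\t", index=False)
    return paths


def read_network(path) -> pd.DataFrame:
    """Re-import an edge attribute TSV written by :func:`export_network`."""
    return pd.read_csv(path, sep="\t")
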