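"""End-to-end orchestration: simulate -> DE -> classify -> enrich ->
checkpoints -> network -> phenotype -> report.

``run_all`` executes every analysis stage into a run directory and writes
a manifest recording seeds, thresholds and per-stage tallies; ``make_report``
assembles the publication-style summary tables (stage x process x category
gene lists, the checkpoint table, the stage-wise miRNA-target pair table)
from a completed run.  Outputs are deterministic for a fixed config and
seed (no timestamps inside result files).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import checkpoints as ckpt
from . import mirnet, phenotype
from .containers import STAGES, CountMatrix
from .diffexpr import StageDEModel
from .enrichment import GeneSetCollection, enrich
from .immune_library import IMMUNE_PROCESSES, ImmuneGeneLibrary, classify_genes, load_library
from .synthetic import SimConfig, growth_records, simulate_phenotype, write_inputs

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Run-level configuration: inputs, thresholds, seed, output directory."""

    out_dir: str
    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None  # used when simulate=False; expects the
    # layout written by write_inputs under <input_dir>/gut and /liver
    alpha_de: float = 0.05
    alpha_q: float = 0.05
    alpha_checkpoint: float = 0.05
    alpha_growth: float = 0.05
    alpha_morphology: float = 0.01
    enrichment_filter: str = "after"  # immune filter before or after testing
    sim_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha_de", "alpha_q", "alpha_checkpoint",
                     "alpha_growth", "alpha_morphology"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must be in (0, 1); got {a}")
        if self.enrichment_filter not in ("before", "after"):
            raise ValueError("enrichment_filter must be 'before' or 'after'")


def _load_tissue_inputs(d: Path):
    mrna = CountMatrix.from_tsv(d / "mrna_counts.tsv", d / "mrna_samples.tsv")
    mirna = None
    if (d / "mir_counts.tsv").exists():
        mirna = CountMatrix.from_tsv(d / "mir_counts.tsv", d / "mir_samples.tsv")
    library = load_library(d / "immune_library.tsv")
    targets = None
    if (d / "targets.tsv").exists():
        targets = mirnet.TargetMap.from_tsv(d / "targets.tsv")
    return mrna, mirna, library, targets


def _figure6_tally(de_results, library: ImmuneGeneLibrary) -> pd.DataFrame:
    """Per-stage immune-process gene tallies; down counts are negative."""
    rows = []
    for stage, res in de_results.items():
        for direction, genes in (("up", res.up_set), ("down", res.down_set)):
            partition, _ = classify_genes(genes, library)
            per_proc: dict[str, set] = {}
            for (proc, _cat), gs in partition.items():
                per_proc.setdefault(proc, set()).update(gs)
            for proc in IMMUNE_PROCESSES:
                n = len(per_proc.get(proc, ()))
                rows.append(
                    {"stage": stage, "process": proc, "direction": direction,
                     "count": n if direction == "up" else -n}
                )
    return pd.DataFrame(rows)


def _classification_table(de_results, library: ImmuneGeneLibrary) -> pd.DataFrame:
    """Stage x direction x process x category gene lists (Table-3 style)."""
    rows = []
    for stage, res in de_results.items():
        for direction, genes in (("up", res.up_set), ("down", res.down_set)):
            partition, _ = classify_genes(genes, library)
            for (proc, cat), gs in sorted(partition.items()):
                rows.append(
                    {"stage": stage, "direction": direction, "process": proc,
                     "category": cat, "gene_no": len(gs), "genes": ",".join(gs)}
                )
    return pd.DataFrame(
        rows, columns=["stage", "direction", "process", "category", "gene_no", "genes"]
    )


def run_all(cfg: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    logging.getLogger("gutliver").addHandler(handler)
    manifest: dict = {
        "seed": cfg.seed,
        "thresholds": {
            "de_padj": cfg.alpha_de, "enrichment_q": cfg.alpha_q,
            "checkpoint_padj": cfg.alpha_checkpoint,
            "growth_p": cfg.alpha_growth, "morphology_p": cfg.alpha_morphology,
        },
        "stages": {k: f"{v[1]} vs {v[0]}" for k, v in STAGES.items()},
        "completed": [],
    }
    try:
        # --- inputs -------------------------------------------------------
        if cfg.simulate:
            inputs = out / "inputs"
            for tissue, seed_off in (("gut", 0), ("liver", 1)):
                sim = SimConfig(
                    seed=(cfg.seed + seed_off) % 2**31, tissue=tissue,
                    **cfg.sim_overrides,
                )
                write_inputs(sim, inputs / tissue)
            manifest["completed"].append("simulate")
        else:
            if not cfg.input_dir:
                raise ValueError("input_dir required when simulate=False")
            inputs = Path(cfg.input_dir)

        data = {}
        for tissue in ("gut", "liver"):
            if (inputs / tissue).exists():
                data[tissue] = _load_tissue_inputs(inputs / tissue)
        if not data:
            raise FileNotFoundError(f"no tissue input directories under {inputs}")

        # --- differential expression -------------------------------------
        de: dict[str, dict] = {}
        mir_de = None
        for tissue, (mrna, mirna_cm, library, _t) in data.items():
            res = StageDEModel(mrna, alpha=cfg.alpha_de).fit()
            res.to_tsv_dir(out / "de" / tissue)
            res.summary().to_csv(out / "de" / tissue / "summary.tsv", sep="\t", index=False)
            de[tissue] = res.results
            if mirna_cm is not None:
                mres = StageDEModel(mirna_cm, alpha=cfg.alpha_de).fit()
                mres.to_tsv_dir(out / "de" / f"{tissue}_mirna")
                mir_de = mres.results
        manifest["completed"].append("de")
        manifest["de_tallies"] = {
            t: {s: {"up": len(r.up_set), "down": len(r.down_set)}
                for s, r in res.items()}
            for t, res in de.items()
        }

        # --- immune classification (Figure-6 / Table-3 style) ------------
        for tissue, (mrna, _m, library, _t) in data.items():
            tally = _figure6_tally(de[tissue], library)
            tally.to_csv(out / f"classification_tally_{tissue}.tsv", sep="\t", index=False)
            table3 = _classification_table(de[tissue], library)
            table3.to_csv(out / f"classification_{tissue}.tsv", sep="\t", index=False)
        manifest["completed"].append("classify")

        # --- enrichment ---------------------------------------------------
        for tissue, (mrna, _m, library, _t) in data.items():
            gmt = inputs / tissue / "gene_sets.gmt"
            if not gmt.exists():
                continue
            for stage, res in de[tissue].items():
                universe = res.table.index.tolist()
                collection = GeneSetCollection.from_gmt(gmt, universe)
                for direction, genes in (("up", res.up_set), ("down", res.down_set)):
                    if cfg.enrichment_filter == "before":
                        genes = [g for g in genes if g in library.genes]
                    table = enrich(genes, collection, cfg.alpha_q)
                    if cfg.enrichment_filter == "after" and len(table):
                        imm = {g for g in genes if g in library.genes}
                        table["n_immune_de"] = [
                            len(imm & set(collection.sets[s][1]))
                            for s in table["set_id"]
                        ]
                    d = out / "enrichment" / tissue
                    d.mkdir(parents=True, exist_ok=True)
                    table.to_csv(d / f"{stage}_{direction}.tsv", sep="\t", index=False)
        manifest["completed"].append("enrich")

        # --- checkpoints --------------------------------------------------
        ckpt_tables = []
        for tissue, (mrna, _m, library, _t) in data.items():
            table = ckpt.checkpoint_table(mrna, library, tissue, cfg.alpha_checkpoint)
            ckpt_tables.append(table)
        ckpt_all = pd.concat(ckpt_tables, ignore_index=True)
        ckpt_all.to_csv(out / "checkpoints.tsv", sep="\t", index=False)
        manifest["completed"].append("checkpoints")
        manifest["checkpoints_selected"] = int(ckpt_all["selected"].sum())

        # --- miRNA-mRNA network (gut) ------------------------------------
        if "gut" in data and mir_de is not None and data["gut"][3] is not None:
            mrna, mirna_cm, library, targets = data["gut"]
            corr = mirnet.pair_correlations(mirna_cm, mrna, targets)
            all_edges = []
            for stage in STAGES:
                edges = mirnet.stage_network(
                    corr, mir_de[stage], de["gut"][stage], stage, library
                )
                mirnet.export_network(edges, out / "network", prefix=f"network_{stage}")
                imm = mirnet.immune_subnetwork(edges, library)
                mirnet.export_network(imm, out / "network", prefix=f"immune_{stage}")
                all_edges.append(edges)
            edges_all = pd.concat(all_edges, ignore_index=True)
            summary = mirnet.summarize_by_process(
                mirnet.immune_subnetwork(edges_all, library), library
            )
            summary.to_csv(out / "network" / "immune_pairs_by_process.tsv",
                           sep="\t", index=False)
            manifest["network_edges"] = int(len(edges_all))
            manifest["completed"].append("network")

        # --- phenotype ----------------------------------------------------
        growth_path = inputs / "gut" / "growth.tsv"
        if growth_path.exists():
            growth = pd.read_csv(growth_path, sep="\t")
        else:
            growth, _d, _m = simulate_phenotype(SimConfig(seed=cfg.seed))
        rows = []
        for group, cage, rec in growth_records(growth):
            rows.append({"group": group, "cage": cage,
                         **phenotype.growth_metrics(rec)})
        per_cage = pd.DataFrame(rows)
        metrics = [c for c in per_cage.columns if c not in ("group", "cage")]
        srows = []
        ref_group = "FM" if "FM" in set(per_cage["group"]) else per_cage["group"].iloc[0]
        for group, grp in per_cage.groupby("group"):
            for m in metrics:
                vals = grp[m].to_numpy()
                row = {"group": group, "metric": m, "mean": vals.mean(),
                       "sd": vals.std(ddof=1), "n": len(vals)}
                if group != ref_group:
                    cmpres = phenotype.group_compare(
                        per_cage.loc[per_cage["group"] == ref_group, m],
                        vals, cfg.alpha_growth,
                    )
                    row["p_vs_ref"] = cmpres["p"]
                    row["significant"] = cmpres["significant"]
                srows.append(row)
        pd.DataFrame(srows).to_csv(out / "growth_summary.tsv", sep="\t", index=False)
        manifest["completed"].append("phenotype")

        manifest["immune_processes"] = list(IMMUNE_PROCESSES)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    except Exception as err:
        stage_name = manifest["completed"][-1] if manifest["completed"] else "inputs"
        raise RuntimeError(
            f"pipeline failed after stage {stage_name!r}: {err}"
        ) from err
    finally:
        logging.getLogger("gutliver").removeHandler(handler)
        handler.close()
    return out


def make_report(run_dir) -> Path:
    """Assemble publication-style summary tables from a completed run."""
    run_dir = Path(run_dir)
    required = ["manifest.json", "checkpoints.tsv"]
    missing = [f for f in required if not (run_dir / f).exists()]
    classif = sorted(run_dir.glob("classification_*.tsv"))
    if not classif:
        missing.append("classification_<tissue>.tsv")
    if missing:
        raise FileNotFoundError(f"incomplete run; missing artifacts: {missing}")
    report = run_dir / "report"
    report.mkdir(exist_ok=True)

    # Table-3 style: per tissue, stage x process gene counts and lists
    for path in classif:
        if "tally" in path.name:
            continue
        tissue = path.stem.replace("classification_", "")
        df = pd.read_csv(path, sep="\t")
        if len(df):
            grouped = (
                df.groupby(["stage", "direction", "process"], sort=True)
                .agg(gene_no=("gene_no", "sum"),
                     categories=("category", lambda s: "; ".join(s)))
                .reset_index()
            )
        else:
            grouped = pd.DataFrame(
                columns=["stage", "direction", "process", "gene_no", "categories"]
            )
        grouped.to_csv(report / f"table3_{tissue}.tsv", sep="\t", index=False)

    # Table-4 style: selected checkpoints
    ckpt_all = pd.read_csv(run_dir / "checkpoints.tsv", sep="\t")
    sel = ckpt_all[ckpt_all["selected"]].copy() if len(ckpt_all) else ckpt_all
    cols = [c for c in ("tissue", "process", "category", "member_gene_ids",
                        "rule_trace") if c in sel.columns]
    sel[cols].to_csv(report / "table4_checkpoints.tsv", sep="\t", index=False)

    # Table-5 style: immune miRNA-target pairs per stage and process
    pairs = run_dir / "network" / "immune_pairs_by_process.tsv"
    if pairs.exists():
        df = pd.read_csv(pairs, sep="\t")
        if len(df):
            df["process_gene_no"] = df.apply(
                lambda r: f"{r['process']} ({r['gene_no']})", axis=1
            )
        else:
            df["process_gene_no"] = pd.Series(dtype=str)
        df.to_csv(report / "table5_pairs.tsv", sep="\t", index=False)
    return report
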