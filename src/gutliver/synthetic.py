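"""Seeded synthetic-data generator with planted ground truth.

Emulates the feeding-trial design the pipeline consumes: NB-distributed
mRNA and miRNA counts over four time points (0d, 3w, 5w, 7w; 3 mRNA and
2 miRNA replicates per time point), a two-level immune gene library over
the nine canonical immune processes, gene-set collections, a predicted
miRNA->target map, growth records and morphometry inputs — together with
the planted truth needed for recovery testing:

* stage-wise differential expression: a planted log2 fold change switches
  on at the stage's later time point and persists, so each effect is
  differential in exactly one consecutive-stage contrast;
* immune checkpoints: planted categories have every member gene shifted
  at 3w and 5w and restored at 7w (gut) or shifted from 3w onward (liver);
* miRNA->target couplings: a planted target's mean is
  baseline * 2^(s * beta * z(t)) with z the realized per-time-point
  z-profile of its miRNA and s = -1 (negative pairs) or +1 (positive).

Stage-DE effects are never planted inside pair-target genes (their
dynamics come from the coupling alone) nor inside checkpoint-planted
categories (so checkpoint truth is unambiguous).  Everything is a pure
function of the config, whose seed is mandatory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import STAGES, TIMEPOINTS, CountMatrix
from .enrichment import GeneSetCollection
from .immune_library import IMMUNE_PROCESSES, ImmuneGeneLibrary
from .mirnet import TargetMap
from .phenotype import GrowthRecord

#: time point at which each stage's planted effect switches on
STAGE_ONSET = {"early": "3w", "middle": "5w", "late": "7w"}


def _default_pheno_groups() -> dict:
    # FM / 40SBM / 70SBM group means in the magnitude range typical of a
    # 7-week juvenile grass carp trial (g, g/fish, cm)
    return {
        "FM": dict(initial_weight=13.94, final_weight=51.0, feed_per_fish=59.7,
                   fish_n_start=40, fish_n_end=40, days=49, body_weight=51.0,
                   body_length=13.0, hepatopancreas_weight=1.62,
                   intestine_weight=2.42, intestine_length=25.6),
        "40SBM": dict(initial_weight=13.83, final_weight=42.8, feed_per_fish=53.7,
                      fish_n_start=40, fish_n_end=40, days=49, body_weight=42.8,
                      body_length=12.4, hepatopancreas_weight=1.03,
                      intestine_weight=1.62, intestine_length=23.5),
        "70SBM": dict(initial_weight=14.06, final_weight=26.7, feed_per_fish=34.9,
                      fish_n_start=40, fish_n_end=38, days=49, body_weight=26.7,
                      body_length=10.8, hepatopancreas_weight=0.57,
                      intestine_weight=0.85, intestine_length=21.9),
    }


@dataclass
class SimConfig:
    """Generator configuration; ``seed`` is mandatory and drives everything."""

    seed: int
    tissue: str = "gut"
    n_genes: int = 2000
    n_mirnas: int = 200
    mrna_reps: int = 3
    mir_reps: int = 2
    baseline_meanlog: float = 5.0   # lognormal log-mean of baseline counts
    baseline_sdlog: float = 1.0
    dispersion: float = 0.1         # NB dispersion alpha (var = mu + alpha mu^2)
    # planted stage-wise DE (half up, half down per stage)
    de_per_stage: int = 50
    de_log2fc: float = 2.0
    mir_de_per_stage: int = 15
    mir_de_log2fc: float = 2.0
    # immune library and planted checkpoints
    n_categories: int = 40
    genes_per_category: int = 8
    n_checkpoint_categories: int = 5
    checkpoint_effect: float = 1.5  # log2 units
    # miRNA->target couplings
    n_pairs_negative: int = 20
    n_pairs_positive: int = 10
    coupling_beta: float = 1.0
    n_decoy_targets: int = 200
    # gene sets: one planted pathway per stage plus decoys
    pathway_size: int = 10
    pathway_de_members: int = 8
    n_decoy_sets: int = 20
    decoy_set_size: int = 15
    # phenotype
    pheno_groups: dict = field(default_factory=_default_pheno_groups)
    pheno_cages: int = 3
    pheno_cv: float = 0.02
    image_size: int = 16
    signal_value: float = 10.0
    background_value: float = 2.0
    mask_coverage: float = 0.125

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_checkpoint_categories > self.n_categories:
            raise ValueError("more checkpoint categories than categories")
        n_immune = self.n_categories * self.genes_per_category
        n_targets = self.n_pairs_negative + self.n_pairs_positive
        if n_immune + n_targets + 3 * self.de_per_stage > self.n_genes:
            raise ValueError("n_genes too small for the planted structure")
        if 3 * self.mir_de_per_stage > self.n_mirnas:
            raise ValueError("n_mirnas too small for planted miRNA DE")
        if n_targets > 3 * self.mir_de_per_stage * 4:
            raise ValueError("not enough DE miRNAs to host the planted pairs")


@dataclass
class SyntheticTruth:
    """Planted ground truth written alongside the generated data."""

    de_truth: dict            # stage -> {gene_id: log2FC}
    mir_de_truth: dict        # stage -> {mirna_id: log2FC}
    checkpoint_truth: list    # planted (process, category) pairs for cfg.tissue
    checkpoint_expected: list # categories expected selected under the tissue rule
    pair_truth: list          # dicts: mirna_id, gene_id, beta, sign, stage
    pathway_truth: dict       # stage -> planted set_id

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["checkpoint_truth"] = [tuple(x) for x in d["checkpoint_truth"]]
        d["checkpoint_expected"] = [tuple(x) for x in d["checkpoint_expected"]]
        return cls(**d)


# --------------------------------------------------------------------------
# deterministic plan shared by all generator operations


def _plan(cfg: SimConfig) -> dict:
    rng = np.random.default_rng([cfg.seed % (2**31), 11])
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    mirnas = [f"mir{i:04d}" for i in range(cfg.n_mirnas)]

    pool = list(genes)
    rng.shuffle(pool)
    pos = 0

    def take(n):
        nonlocal pos
        out = pool[pos:pos + n]
        pos += n
        return out

    # immune library: spread cfg.n_categories over the nine processes
    per_proc = np.full(len(IMMUNE_PROCESSES), cfg.n_categories // len(IMMUNE_PROCESSES))
    per_proc[: cfg.n_categories % len(IMMUNE_PROCESSES)] += 1
    records, categories = [], []
    c = 0
    for proc, k in zip(IMMUNE_PROCESSES, per_proc):
        for _ in range(k):
            cat = f"category_{c:03d}"
            for g in take(cfg.genes_per_category):
                records.append((g, proc, cat))
            categories.append((proc, cat))
            c += 1
    member = {}
    for g, p, cat in records:
        member.setdefault((p, cat), []).append(g)

    ckpt_idx = rng.choice(len(categories), cfg.n_checkpoint_categories, replace=False)
    checkpoints = [categories[i] for i in sorted(ckpt_idx)]
    ckpt_genes = {g for key in checkpoints for g in member[key]}

    # pair targets: genes outside checkpoint categories, half immune
    n_pairs = cfg.n_pairs_negative + cfg.n_pairs_positive
    immune_free = [g for g, _, _ in records if g not in ckpt_genes]
    rng.shuffle(immune_free)
    n_imm_targets = min(n_pairs // 2, len(immune_free))
    pair_targets = immune_free[:n_imm_targets] + take(n_pairs - n_imm_targets)

    # stage DE genes: non-immune, non-target remainder of the pool
    immune_all = {g for g, _, _ in records}
    de_truth = {}
    for stage in STAGES:
        chosen = []
        while len(chosen) < cfg.de_per_stage:
            g = take(1)[0]
            if g not in immune_all and g not in pair_targets:
                chosen.append(g)
        signs = np.where(np.arange(cfg.de_per_stage) % 2 == 0, 1.0, -1.0)
        de_truth[stage] = {g: float(s * cfg.de_log2fc) for g, s in zip(chosen, signs)}

    # miRNA stage DE and planted pairs
    mpool = list(mirnas)
    rng.shuffle(mpool)
    mir_de_truth, mpos = {}, 0
    for stage in STAGES:
        chosen = mpool[mpos:mpos + cfg.mir_de_per_stage]
        mpos += cfg.mir_de_per_stage
        signs = np.where(np.arange(cfg.mir_de_per_stage) % 2 == 0, 1.0, -1.0)
        mir_de_truth[stage] = {m: float(s * cfg.mir_de_log2fc) for m, s in zip(chosen, signs)}
    de_mirs = [(m, stage) for stage in STAGES for m in mir_de_truth[stage]]
    pair_truth = []
    for i, g in enumerate(pair_targets):
        m, stage = de_mirs[i % len(de_mirs)]
        sign = "negative" if i < cfg.n_pairs_negative else "positive"
        pair_truth.append(
            {"mirna_id": m, "gene_id": g, "beta": cfg.coupling_beta,
             "sign": sign, "stage": stage}
        )

    # target map: planted pairs plus decoys
    tmap = {(p["mirna_id"], p["gene_id"]) for p in pair_truth}
    while len(tmap) < len(pair_truth) + cfg.n_decoy_targets:
        m = mirnas[rng.integers(cfg.n_mirnas)]
        g = genes[rng.integers(cfg.n_genes)]
        if g not in pair_targets:
            tmap.add((m, g))

    # gene sets: one planted pathway per stage (members drawn from that
    # stage's up-regulated planted genes) plus random decoy sets
    sets, pathway_truth = {}, {}
    for stage in STAGES:
        ups = [g for g, fc in de_truth[stage].items() if fc > 0]
        members = ups[: cfg.pathway_de_members]
        extra = [g for g in genes if g not in de_truth[stage] and g not in pair_targets]
        members = members + [extra[i] for i in
                             rng.choice(len(extra), cfg.pathway_size - len(members),
                                        replace=False)]
        sid = f"pathway_{stage}"
        sets[sid] = (f"planted {stage}-stage pathway", sorted(members))
        pathway_truth[stage] = sid
    for i in range(cfg.n_decoy_sets):
        idx = rng.choice(cfg.n_genes, cfg.decoy_set_size, replace=False)
        sets[f"decoy_{i:03d}"] = (f"decoy set {i}", sorted(genes[j] for j in idx))

    # checkpoint-expected under the tissue rule: for the gut, planted
    # categories only (restored-at-7w pattern); for the liver, planted
    # categories are shifted from 3w onward and are the expected set too
    expected = list(checkpoints)

    # baselines
    base_g = rng.lognormal(cfg.baseline_meanlog, cfg.baseline_sdlog, cfg.n_genes)
    base_m = rng.lognormal(cfg.baseline_meanlog, cfg.baseline_sdlog, cfg.n_mirnas)

    return {
        "genes": genes, "mirnas": mirnas, "records": records,
        "member": member, "checkpoints": checkpoints,
        "de_truth": de_truth, "mir_de_truth": mir_de_truth,
        "pair_truth": pair_truth, "target_map": tmap,
        "sets": sets, "pathway_truth": pathway_truth,
        "expected": expected,
        "base_g": base_g, "base_m": base_m,
    }


# --------------------------------------------------------------------------


def _nb_draw(rng, mean, dispersion):
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-8:
        return rng.poisson(mean)
    lam = rng.gamma(1.0 / dispersion, mean * dispersion)
    return rng.poisson(lam)


def _log2_multipliers(planted: dict, n_features: int, id_index: dict,
                      stage_list=STAGES) -> np.ndarray:
    """log2 mean multiplier per feature x time point for persistent effects."""
    mult = np.zeros((n_features, len(TIMEPOINTS)))
    for stage, effects in planted.items():
        onset = TIMEPOINTS.index(STAGE_ONSET[stage])
        for fid, lfc in effects.items():
            mult[id_index[fid], onset:] += lfc
    return mult


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, CountMatrix, SyntheticTruth]:
    """Generate the mRNA and miRNA count matrices and their planted truth."""
    plan = _plan(cfg)
    rng = np.random.default_rng([cfg.seed % (2**31), 23])
    genes, mirnas = plan["genes"], plan["mirnas"]
    gidx = {g: i for i, g in enumerate(genes)}
    midx = {m: i for i, m in enumerate(mirnas)}

    # --- miRNA means and counts first (targets couple to the realization)
    m_mult = _log2_multipliers(plan["mir_de_truth"], cfg.n_mirnas, midx)
    m_mean = plan["base_m"][:, None] * 2.0 ** m_mult
    mir_cols, mir_counts = [], []
    for t, tp in enumerate(TIMEPOINTS):
        for r in range(cfg.mir_reps):
            mir_cols.append((f"{cfg.tissue}_mir_{tp}_r{r + 1}", tp, r + 1))
            mir_counts.append(_nb_draw(rng, m_mean[:, t], cfg.dispersion))
    mir_arr = np.array(mir_counts).T

    # realized per-time-point z-profile of each pair miRNA
    rep_cols = np.arange(len(mir_cols)).reshape(len(TIMEPOINTS), cfg.mir_reps)
    mir_tp_log2 = np.stack(
        [np.log2(mir_arr[:, cols] + 1.0).mean(axis=1) for cols in rep_cols], axis=1
    )
    zprof = {}
    for p in plan["pair_truth"]:
        x = mir_tp_log2[midx[p["mirna_id"]]]
        sd = x.std()
        zprof[p["mirna_id"]] = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    # --- mRNA means: persistent stage effects + checkpoint dynamics + coupling
    g_mult = _log2_multipliers(plan["de_truth"], cfg.n_genes, gidx)
    ckpt_tps = ("3w", "5w") if cfg.tissue == "gut" else ("3w", "5w", "7w")
    for key in plan["checkpoints"]:
        for g in plan["member"][key]:
            for tp in ckpt_tps:
                g_mult[gidx[g], TIMEPOINTS.index(tp)] += cfg.checkpoint_effect
    for p in plan["pair_truth"]:
        s = -1.0 if p["sign"] == "negative" else 1.0
        g_mult[gidx[p["gene_id"]], :] += s * p["beta"] * zprof[p["mirna_id"]]
    g_mean = plan["base_g"][:, None] * 2.0 ** g_mult

    mrna_cols, mrna_counts = [], []
    for t, tp in enumerate(TIMEPOINTS):
        for r in range(cfg.mrna_reps):
            mrna_cols.append((f"{cfg.tissue}_{tp}_r{r + 1}", tp, r + 1))
            mrna_counts.append(_nb_draw(rng, g_mean[:, t], cfg.dispersion))
    mrna_arr = np.array(mrna_counts).T

    def _cm(arr, cols, index):
        sheet = pd.DataFrame(
            [{"sample_id": sid, "tissue": cfg.tissue, "timepoint": tp, "replicate": r}
             for sid, tp, r in cols]
        )
        counts = pd.DataFrame(arr, index=index, columns=[c[0] for c in cols])
        return CountMatrix(counts, sheet)

    truth = SyntheticTruth(
        de_truth=plan["de_truth"],
        mir_de_truth=plan["mir_de_truth"],
        checkpoint_truth=plan["checkpoints"],
        checkpoint_expected=plan["expected"],
        pair_truth=plan["pair_truth"],
        pathway_truth=plan["pathway_truth"],
    )
    return _cm(mrna_arr, mrna_cols, genes), _cm(mir_arr, mir_cols, mirnas), truth


def simulate_library_and_sets(
    cfg: SimConfig,
) -> tuple[ImmuneGeneLibrary, GeneSetCollection, TargetMap]:
    """Immune library, gene-set collection and target map for the same plan."""
    plan = _plan(cfg)
    library = ImmuneGeneLibrary(plan["records"])
    collection = GeneSetCollection(dict(plan["sets"]), list(plan["genes"]))
    targets = TargetMap(set(plan["target_map"]), source=f"synthetic:seed={cfg.seed}")
    return library, collection, targets


def simulate_phenotype(cfg: SimConfig):
    """Growth records per group/cage plus toy morphometry inputs.

    Returns ``(growth, density_images, masks)``: growth is a DataFrame of
    per-cage records; density_images maps group -> dict with the intensity
    matrix, signal mask and background ROI needed by the mean-density
    statistic; masks maps group -> boolean stained-area matrix with the
    configured coverage.
    """
    rng = np.random.default_rng([cfg.seed % (2**31), 37])
    rows = []
    for group, means in cfg.pheno_groups.items():
        for cage in range(1, cfg.pheno_cages + 1):
            rec = {"group": group, "cage": cage}
            for k, v in means.items():
                if k in ("fish_n_start", "fish_n_end", "days"):
                    rec[k] = int(v)
                else:
                    noise = rng.normal(0.0, cfg.pheno_cv) if cfg.pheno_cv > 0 else 0.0
                    rec[k] = float(v) * (1.0 + noise)
            rec["feed_consumed"] = rec.pop("feed_per_fish") * rec["fish_n_start"]
            rows.append(rec)
    growth = pd.DataFrame(rows)

    n = cfg.image_size
    k = int(round(cfg.mask_coverage * n * n))
    flat_mask = np.zeros(n * n, dtype=bool)
    flat_mask[:k] = True
    mask = flat_mask.reshape(n, n)
    density_images, masks = {}, {}
    for group in cfg.pheno_groups:
        intensity = np.full((n, n), cfg.background_value)
        intensity[mask] = cfg.signal_value
        bg_roi = np.zeros((n, n), dtype=bool)
        bg_roi[-1, :] = True  # last row is always background by construction
        density_images[group] = {
            "intensity": intensity, "signal_mask": mask, "background_rois": [bg_roi]
        }
        masks[group] = mask.copy()
    return growth, density_images, masks


def growth_records(growth: pd.DataFrame) -> list[tuple[str, int, GrowthRecord]]:
    """Convert the growth DataFrame into per-cage GrowthRecord objects."""
    out = []
    for row in growth.itertuples(index=False):
        rec = GrowthRecord(
            initial_weight=row.initial_weight,
            final_weight=row.final_weight,
            feed_consumed=row.feed_consumed,
            fish_n_start=int(row.fish_n_start),
            fish_n_end=int(row.fish_n_end),
            days=int(row.days),
            body_weight=row.body_weight,
            body_length=row.body_length,
            hepatopancreas_weight=row.hepatopancreas_weight,
            intestine_weight=row.intestine_weight,
            intestine_length=row.intestine_length,
        )
        out.append((row.group, int(row.cage), rec))
    return out


def write_inputs(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Write every input format the pipeline reads, plus the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mrna, mirna, truth = simulate_counts(cfg)
    library, sets, targets = simulate_library_and_sets(cfg)
    growth, density, masks = simulate_phenotype(cfg)
    paths = {
        "mrna_counts": outdir / "mrna_counts.tsv",
        "mrna_samples": outdir / "mrna_samples.tsv",
        "mir_counts": outdir / "mir_counts.tsv",
        "mir_samples": outdir / "mir_samples.tsv",
        "library": outdir / "immune_library.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "targets": outdir / "targets.tsv",
        "growth": outdir / "growth.tsv",
        "truth": outdir / "truth.json",
    }
    mrna.to_tsv(paths["mrna_counts"], paths["mrna_samples"])
    mirna.to_tsv(paths["mir_counts"], paths["mir_samples"])
    library.to_tsv(paths["library"])
    sets.to_gmt(paths["gene_sets"])
    targets.to_tsv(paths["targets"])
    growth.to_csv(paths["growth"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    for group, mask in masks.items():
        p = outdir / f"mask_{group}.tsv"
        np.savetxt(p, mask.astype(int), fmt="%d", delimiter="\t")
        paths[f"mask_{group}"] = p
    return paths
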