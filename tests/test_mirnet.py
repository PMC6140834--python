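import numpy as np
import pandas as pd
import pytest

from gutliver.containers import CountMatrix
from gutliver.diffexpr import StageDEModel, StageDEResult
from gutliver.mirnet import (
    TargetMap,
    export_network,
    immune_subnetwork,
    pair_correlations,
    read_network,
    stage_network,
    summarize_by_process,
    to_graph,
)
from gutliver.immune_library import ImmuneGeneLibrary
from gutliver.synthetic import SimConfig, simulate_counts, simulate_library_and_sets

from conftest import make_count_matrix


# profiles are chosen in log2(count+1) space: count 2^x - 1 gives log2 profile x
def _counts_for_log2(profile):
    return [int(2**x - 1) for x in profile]


def _mir_cm(profiles):
    return make_count_matrix(
        {m: _counts_for_log2(p) for m, p in profiles.items()}, n_reps=2
    )


def _mrna_cm(profiles):
    return make_count_matrix(
        {g: _counts_for_log2(p) for g, p in profiles.items()}, n_reps=3
    )


def test_pair_correlations_exact_cases():
    mir = _mir_cm({"m1": [1, 2, 3, 4], "m2": [1, 2, 3, 4]})
    mrna = _mrna_cm(
        {
            "gsame": [1, 2, 3, 4],       # identical profile -> r = 1
            "ganti": [5, 4, 3, 2],       # gene = a - b*mir  -> r = -1
            "gswap": [2, 1, 4, 3],       # hand Pearson: r = 0.6
        }
    )
    targets = TargetMap({("m1", "gsame"), ("m1", "ganti"), ("m2", "gswap")})
    corr = pair_correlations(mir, mrna, targets).set_index(["mirna_id", "gene_id"])
    assert corr.loc[("m1", "gsame"), "r"] == pytest.approx(1.0)
    assert corr.loc[("m1", "ganti"), "r"] == pytest.approx(-1.0)
    assert corr.loc[("m2", "gswap"), "r"] == pytest.approx(0.6)
    assert (corr["n_points"] == 4).all()


def test_pair_correlations_drops_flat_profiles():
    mir = _mir_cm({"m1": [3, 3, 3, 3]})
    mrna = _mrna_cm({"g1": [1, 2, 3, 4]})
    corr = pair_correlations(mir, mrna, TargetMap({("m1", "g1")}))
    assert len(corr) == 0


def test_pair_correlations_needs_three_timepoints():
    mir = _mir_cm({"m1": [1, 2, 3, 4]})
    mrna = _mrna_cm({"g1": [1, 2, 3, 4]})
    keep = mir.samples["timepoint"].isin(["0d", "3w"])
    sheet = mir.samples[keep].reset_index(drop=True)
    sub = CountMatrix(mir.counts[sheet["sample_id"].tolist()], sheet)
    with pytest.raises(ValueError, match="3 shared time points"):
        pair_correlations(sub, mrna, TargetMap({("m1", "g1")}))


def test_pair_correlations_affine_invariance():
    # g2's log2 profile is 2*g1 + 1: exactly representable integer counts
    mir = _mir_cm({"m1": [2, 1, 4, 3]})
    mrna = _mrna_cm({"g1": [1, 2, 3, 4], "g2": [3, 5, 7, 9]})
    corr = pair_correlations(
        mir, mrna, TargetMap({("m1", "g1"), ("m1", "g2")})
    ).set_index("gene_id")
    assert corr.loc["g1", "r"] == pytest.approx(corr.loc["g2", "r"], abs=1e-12)
    assert np.all(np.abs(corr["r"]) <= 1.0 + 1e-12)


def _de_result(up, down, label="early"):
    feats = list(up) + list(down)
    table = pd.DataFrame(
        {
            "log2FC": [1.0] * len(up) + [-1.0] * len(down),
            "SE": 0.1, "p": 0.001, "padj": 0.001,
            "call": ["up"] * len(up) + ["down"] * len(down),
        },
        index=feats,
    )
    return StageDEResult(label, "0d", "3w", table, alpha=0.05)


def test_stage_network_toy_enumeration():
    corr = pd.DataFrame(
        {
            "mirna_id": ["m_up", "m_up", "m_down", "m_down"],
            "gene_id": ["gA", "gB", "gC", "gZ"],
            "r": [-0.9, 0.8, -0.7, 0.5],
            "n_points": 4,
        }
    )
    mir_de = _de_result(up=["m_up"], down=["m_down"])
    mrna_de = _de_result(up=["gA"], down=["gB", "gC"])
    edges = stage_network(corr, mir_de, mrna_de, "early")
    assert len(edges) == 3  # gZ is not DE
    e = edges.set_index("gene_id")
    assert e.loc["gA", "mirna_dir"] == "up" and e.loc["gA", "gene_dir"] == "up"
    assert e.loc["gB", "mirna_dir"] == "up" and e.loc["gB", "gene_dir"] == "down"
    assert e.loc["gA", "sign"] == "negative" and e.loc["gB", "sign"] == "positive"


def test_stage_network_empty_de_sets():
    corr = pd.DataFrame(
        {"mirna_id": ["m1"], "gene_id": ["g1"], "r": [0.5], "n_points": [4]}
    )
    edges = stage_network(corr, _de_result([], []), _de_result([], []), "early")
    assert len(edges) == 0


def test_no_hallucinated_edges():
    cfg = SimConfig(seed=3)
    mrna, mirna, _ = simulate_counts(cfg)
    lib, _, targets = simulate_library_and_sets(cfg)
    corr = pair_correlations(mirna, mrna, targets)
    mir_de = StageDEModel(mirna).fit()["middle"]
    mrna_de = StageDEModel(mrna).fit()["middle"]
    edges = stage_network(corr, mir_de, mrna_de, "middle", lib)
    for rec in edges.itertuples(index=False):
        assert (rec.mirna_id, rec.gene_id) in targets.edges


def test_immune_subnetwork_filter():
    lib = ImmuneGeneLibrary([("gImm", "complement system", "C3")])
    edges = pd.DataFrame(
        {
            "mirna_id": ["m1", "m1", "m2"],
            "gene_id": ["gImm", "gX", "gY"],
            "r": [-0.9, 0.8, 0.1], "n_points": 4, "stage": "early",
            "mirna_dir": "up", "gene_dir": "down", "sign": "negative",
            "immune": False,
        }
    )
    imm = immune_subnetwork(edges, lib)
    assert imm["gene_id"].tolist() == ["gImm"]
    assert imm["immune"].all()
    empty = immune_subnetwork(edges[edges.gene_id == "gX"].reset_index(drop=True), lib)
    assert len(empty) == 0


def test_summarize_by_process_gene_counts():
    lib = ImmuneGeneLibrary(
        [("gImm", "complement system", "C3"), ("gImm2", "complement system", "C1q")]
    )
    edges = pd.DataFrame(
        {
            "mirna_id": ["m1", "m2"], "gene_id": ["gImm", "gImm2"],
            "r": [-0.9, -0.8], "n_points": 4, "stage": "early",
            "mirna_dir": ["up", "up"], "gene_dir": ["down", "down"],
            "sign": "negative", "immune": True,
        }
    )
    summary = summarize_by_process(edges, lib)
    row = summary.iloc[0]
    assert row["process"] == "complement system"
    assert row["gene_no"] == 2
    assert "m1 (gImm)" in row["pairs"]


def test_export_roundtrip_and_counts(tmp_path):
    edges = pd.DataFrame(
        {
            "mirna_id": ["m1", "m1", "m2"], "gene_id": ["gA", "gB", "gA"],
            "r": [-0.9, 0.8, -0.5], "n_points": 4, "stage": "early",
            "mirna_dir": ["up", "up", "down"], "gene_dir": ["down", "up", "down"],
            "sign": ["negative", "positive", "negative"], "immune": False,
        }
    )
    paths = export_network(edges, tmp_path, prefix="toy")
    sif = paths["sif"].read_text().strip().splitlines()
    assert len(sif) == 3
    g = to_graph(edges)
    assert g.number_of_nodes() == 4  # m1, m2, gA, gB
    nodes = pd.read_csv(paths["nodes"], sep="\t").set_index("node_id")
    assert set(nodes["regulation"]) <= {"up", "down"}
    assert nodes.loc["m1", "kind"] == "mirna"
    reloaded = read_network(paths["edges"])
    assert reloaded["gene_id"].tolist() == edges["gene_id"].tolist()
    # empty network still exports valid files
    empty_paths = export_network(edges.iloc[0:0], tmp_path, prefix="empty")
    assert empty_paths["sif"].read_text() == ""


def test_planted_negative_couplings_recover_sign():
    cfg = SimConfig(seed=1)
    mrna, mirna, truth = simulate_counts(cfg)
    lib, _, targets = simulate_library_and_sets(cfg)
    corr = pair_correlations(mirna, mrna, targets)
    mir_res = StageDEModel(mirna, alpha=0.1).fit()
    mrna_res = StageDEModel(mrna, alpha=0.1).fit()
    frames = [
        stage_network(corr, mir_res[s], mrna_res[s], s, lib)
        for s in ("early", "middle", "late")
    ]
    edges = pd.concat(frames, ignore_index=True)
    planted = {
        (p["mirna_id"], p["gene_id"]): p["sign"]
        for p in truth.pair_truth if p["sign"] == "negative"
    }
    hits = edges[[(m, g) in planted for m, g in zip(edges.mirna_id, edges.gene_id)]]
    hits = hits.drop_duplicates(["mirna_id", "gene_id"])
    assert len(hits) > 0
    agreement = (hits["sign"] == "negative").mean()
    assert agreement >= 0.9
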