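import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gutliver.containers import CountMatrix
from gutliver.diffexpr import (
    DISPERSION_FLOOR,
    StageDEModel,
    bh_adjust,
    dispersion_trend,
    estimate_dispersion,
    nb_wald,
    size_factors,
    stage_de,
)
from gutliver.synthetic import SimConfig, simulate_counts

from conftest import nb_sample


def bh_brute(p):
    """Textbook step-up BH with running-minimum monotonicity (oracle)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


# --- size factors ----------------------------------------------------------


def test_size_factors_identical_columns():
    m = np.array([[10, 10], [3, 3], [50, 50]])
    assert size_factors(m) == pytest.approx([1.0, 1.0])


def test_size_factors_doubled_column():
    rng = np.random.default_rng(0)
    a = rng.integers(1, 100, size=20).astype(float)
    m = np.stack([a, 2 * a], axis=1)
    sf = size_factors(m)
    assert sf[1] / sf[0] == pytest.approx(2.0)


def test_size_factors_brute_force_oracle():
    # odd feature count keeps the linear- and log-space medians identical
    m = np.array(
        [[4.0, 8.0, 12.0], [10.0, 10.0, 40.0], [1.0, 2.0, 3.0],
         [9.0, 3.0, 27.0], [6.0, 5.0, 4.0]]
    )
    ref = stats.gmean(m, axis=1)
    raw = np.median(m / ref[:, None], axis=0)
    expected = raw / stats.gmean(raw)
    assert size_factors(m) == pytest.approx(expected)


def test_size_factors_feature_permutation_invariant():
    rng = np.random.default_rng(1)
    m = rng.integers(1, 200, size=(30, 4)).astype(float)
    perm = rng.permutation(30)
    assert size_factors(m[perm]) == pytest.approx(size_factors(m))


def test_size_factors_column_scaling_equivariant():
    rng = np.random.default_rng(2)
    m = rng.integers(1, 200, size=(30, 4)).astype(float)
    scale = np.array([1.0, 2.0, 0.5, 3.0])
    sf0, sf1 = size_factors(m), size_factors(m * scale)
    ratio = sf1 / sf0
    # equivariant up to the geometric-mean-1 renormalisation
    assert ratio / stats.gmean(ratio) == pytest.approx(scale / stats.gmean(scale))


def test_size_factors_zero_free_requirement():
    m = np.array([[0, 5], [5, 0]])
    with pytest.raises(ValueError, match="pseudo_reference"):
        size_factors(m)
    sf = size_factors(m, pseudo_reference=True)
    assert np.all(sf > 0)


# --- dispersion ------------------------------------------------------------


def test_dispersion_constant_feature_hits_floor():
    m = np.full((1, 6), 7.0)
    alpha = estimate_dispersion(m, [np.arange(3), np.arange(3, 6)])
    assert alpha[0] == DISPERSION_FLOOR


def test_dispersion_poisson_simulation():
    rng = np.random.default_rng(3)
    m = rng.poisson(50, size=(300, 200)).astype(float)
    alpha = estimate_dispersion(m, [np.arange(100), np.arange(100, 200)])
    assert np.median(alpha) <= 0.02


def test_dispersion_nb_simulation():
    rng = np.random.default_rng(4)
    m = nb_sample(rng, np.full((300, 200), 100.0), 0.5)
    alpha = estimate_dispersion(m, [np.arange(100), np.arange(100, 200)])
    frac_close = np.mean(np.abs(alpha - 0.5) <= 0.1)
    assert frac_close >= 0.8


def test_dispersion_trend_recovers_constant_alpha():
    rng = np.random.default_rng(5)
    mu = rng.lognormal(5, 1, 2000)
    m = nb_sample(rng, np.tile(mu[:, None], (1, 6)), 0.1)
    mom = estimate_dispersion(m, [np.arange(3), np.arange(3, 6)])
    trend = dispersion_trend(mom, m.mean(axis=1))
    assert np.median(trend) == pytest.approx(0.1, rel=0.3)


# --- Wald test -------------------------------------------------------------


def test_nb_wald_null_large_n():
    rng = np.random.default_rng(6)
    mu = np.full(500, 100.0)
    a = nb_sample(rng, np.tile(mu[:, None], (1, 50)), 0.05)
    b = nb_sample(rng, np.tile(mu[:, None], (1, 50)), 0.05)
    res = nb_wald(a, b, np.ones(50), np.ones(50), np.full(500, 0.05))
    assert np.abs(res["log2FC"]).median() <= 0.1
    # p roughly uniform: quartiles not collapsed
    assert 0.15 < np.quantile(res["p"], 0.25) < 0.40


def test_nb_wald_planted_fourfold():
    rng = np.random.default_rng(7)
    a = nb_sample(rng, np.full((500, 3), 100.0), 0.05)
    b = nb_sample(rng, np.full((500, 3), 400.0), 0.05)
    res = nb_wald(a, b, np.ones(3), np.ones(3), np.full(500, 0.05))
    assert abs(np.median(res["log2FC"]) - 2.0) <= 0.3


def test_nb_wald_null_type_one_error_known_dispersion():
    rng = np.random.default_rng(8)
    mu = rng.lognormal(5, 1, 2000)
    a = nb_sample(rng, np.tile(mu[:, None], (1, 3)), 0.1)
    b = nb_sample(rng, np.tile(mu[:, None], (1, 3)), 0.1)
    res = nb_wald(a, b, np.ones(3), np.ones(3), np.full(2000, 0.1))
    assert 0.03 <= (res["p"] < 0.05).mean() <= 0.08


def test_nb_wald_symmetry():
    rng = np.random.default_rng(9)
    a = nb_sample(rng, np.full((100, 3), 80.0), 0.1)
    b = nb_sample(rng, np.full((100, 3), 160.0), 0.1)
    disp = np.full(100, 0.1)
    fwd = nb_wald(a, b, np.ones(3), np.ones(3), disp)
    rev = nb_wald(b, a, np.ones(3), np.ones(3), disp)
    assert rev["log2FC"].to_numpy() == pytest.approx(-fwd["log2FC"].to_numpy())
    assert rev["p"].to_numpy() == pytest.approx(fwd["p"].to_numpy())


def test_nb_wald_all_zero_feature_flagged():
    a = np.zeros((1, 3))
    b = np.zeros((1, 3))
    res = nb_wald(a, b, np.ones(3), np.ones(3), np.array([0.1]))
    assert res.loc[0, "log2FC"] == 0.0
    assert res.loc[0, "p"] == 1.0
    assert bool(res.loc[0, "all_zero"])


# --- BH adjustment ---------------------------------------------------------


@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.01], [0.01]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
    ],
)
def test_bh_hand_examples(p, expected):
    assert bh_adjust(p) == pytest.approx(expected)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


def test_bh_matches_brute_force_many_vectors():
    rng = np.random.default_rng(10)
    for _ in range(200):
        n = rng.integers(1, 60)
        p = rng.uniform(size=n)
        assert bh_adjust(p) == pytest.approx(bh_brute(p), abs=1e-12)


@settings(derandomize=True, max_examples=60)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_bounds_property(p):
    adj = bh_adjust(p)
    assert np.all(adj >= np.asarray(p) - 1e-15)
    assert np.all(adj <= 1.0 + 1e-15)


# --- stage-wise pipeline ---------------------------------------------------


def _null_cfg(seed):
    return SimConfig(seed=seed, de_per_stage=0, mir_de_per_stage=0,
                     n_checkpoint_categories=0, n_pairs_negative=0,
                     n_pairs_positive=0)


def test_stage_de_null_calls_bounded():
    mrna, _, _ = simulate_counts(_null_cfg(1))
    res = stage_de(mrna, alpha=0.05)
    for stage, r in res.items():
        assert (r.table["call"] != "ns").mean() <= 0.05


def test_stage_de_planted_recovery():
    cfg = SimConfig(seed=1, de_per_stage=100, n_checkpoint_categories=0,
                    n_pairs_negative=0, n_pairs_positive=0)
    mrna, _, truth = simulate_counts(cfg)
    res = StageDEModel(mrna, alpha=0.1).fit()
    planted = set(truth.de_truth["early"])
    called = set(res["early"].up_set) | set(res["early"].down_set)
    assert len(called & planted) / len(planted) >= 0.8
    assert len(called - planted) / max(1, len(called)) <= 0.15


def test_stage_de_missing_timepoint_errors():
    cfg = _null_cfg(2)
    mrna, _, _ = simulate_counts(cfg)
    keep = mrna.samples["timepoint"] != "7w"
    sub_sheet = mrna.samples[keep].reset_index(drop=True)
    sub = CountMatrix(mrna.counts[sub_sheet["sample_id"].tolist()], sub_sheet)
    with pytest.raises(ValueError, match="7w"):
        stage_de(sub)


def test_stage_de_result_invariants():
    cfg = SimConfig(seed=3, de_per_stage=30, n_checkpoint_categories=0,
                    n_pairs_negative=0, n_pairs_positive=0)
    mrna, _, _ = simulate_counts(cfg)
    res = stage_de(mrna, alpha=0.05)
    for r in res.values():
        t = r.table
        assert np.all(t["padj"] >= t["p"] - 1e-12)
        assert not (set(r.up_set) & set(r.down_set))
        called = t[t["padj"] < r.alpha]
        assert set(called.index) == set(r.up_set) | set(r.down_set)


def test_mirna_two_replicates_warns():
    cfg = _null_cfg(4)
    _, mirna, _ = simulate_counts(cfg)
    with pytest.warns(UserWarning, match="2 replicates"):
        stage_de(mirna)
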