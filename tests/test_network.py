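"""Signed co-expression network: bicor, adjacency, scale-free fit, TOM,
UPGMA, tree cut, eigengenes, kME, merging and resampling robustness."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

from oracles import bicor_oracle, tom_oracle, upgma_cophenetic_oracle

import nephronet as nn
from nephronet.network import (DEEP_SPLIT_QUANTILE, NetworkParams,
                               bicor_matrix, cut_dynamic_hybrid,
                               detect_modules, hclust_average,
                               module_eigengene, robustness_consensus,
                               signed_adjacency, tom)
from nephronet.simulate import GREY


# ------------------------------------------------------------------ bicor

def test_bicor_self_and_antisymmetry(rng):
    x = rng.normal(0, 1, 20)
    assert nn.bicor(x, x) == pytest.approx(1.0)
    assert nn.bicor(x, -x) == pytest.approx(-1.0)


def test_bicor_downweights_outlier_and_matches_formula_oracle():
    x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    val = nn.bicor(x, y)
    assert val == pytest.approx(bicor_oracle(x, y), abs=1e-12)
    assert abs(val) > abs(np.corrcoef(x, y)[0, 1])


def test_bicor_matrix_matches_scalar_oracle_on_random_instances(rng):
    X = rng.normal(0, 1, size=(8, 12))
    C = bicor_matrix(X)
    for i in range(8):
        for j in range(8):
            assert C[i, j] == pytest.approx(bicor_oracle(X[i], X[j]),
                                            abs=1e-12)


def test_bicor_length_mismatch_and_constant_vector():
    with pytest.raises(ValueError):
        nn.bicor(np.arange(4.0), np.arange(5.0))
    with pytest.warns(UserWarning):
        val = nn.bicor(np.ones(6), np.arange(6.0))
    assert np.isfinite(val)


# -------------------------------------------------------------- adjacency

def test_signed_adjacency_endpoints_and_beta_nine():
    C = np.array([[1.0, 1.0, -1.0, 0.0]] * 4)
    np.fill_diagonal(C, 1.0)
    A = signed_adjacency(C, beta=9)
    assert A[0, 1] == pytest.approx(1.0)
    assert A[0, 2] == pytest.approx(0.0)
    assert A[0, 3] == pytest.approx(1.0 / 512.0)
    with pytest.raises(ValueError):
        signed_adjacency(np.array([[0.0, 1.5], [1.5, 0.0]]), beta=9)


def test_signed_adjacency_monotone_in_correlation(rng):
    c = np.sort(rng.uniform(-1, 1, 50))
    a = ((1 + c) / 2) ** 9
    assert np.all(np.diff(a) > 0)


# ----------------------------------------------------------- scale-free fit

def power_law_adjacency(n=300, gamma=2.5, seed=0):
    rng = np.random.default_rng(seed)
    # degrees from a discrete power law; expected-degree (Chung-Lu) weights
    k = (rng.pareto(gamma - 1, n) + 1.0) * 2.0
    k = np.clip(k, 2.0, n / 4)
    A = np.outer(k, k) / k.sum()
    np.fill_diagonal(A, 0.0)
    return np.clip(A, 0.0, 1.0)


def test_power_law_network_scores_high_signed_r2():
    r2, mean_k = nn.scale_free_fit(power_law_adjacency())
    assert r2 > 0.9
    assert mean_k > 0


def test_equal_connectivity_gives_zero_r2():
    A = np.full((60, 60), 0.3)
    np.fill_diagonal(A, 0.0)
    r2, _ = nn.scale_free_fit(A)
    assert r2 == 0.0


def test_increasing_degree_distribution_scores_negative():
    # connectivities concentrated at high k with rising frequency
    rng = np.random.default_rng(1)
    k = 10.0 - (rng.pareto(1.5, 400) + 1.0)
    k = np.clip(k, 1.0, 10.0)
    A = np.outer(k, k) / k.sum()
    np.fill_diagonal(A, 0.0)
    r2, _ = nn.scale_free_fit(np.clip(A, 0, 1))
    assert r2 < 0


def test_pick_soft_threshold_modular_data_and_trivial_target(default_bundle):
    X = default_bundle.expression.to_numpy()[:300]
    beta = nn.pick_soft_threshold(X, r2_target=-1.0)
    assert beta == 1
    beta2 = nn.pick_soft_threshold(X, r2_target=0.8)
    assert 1 <= beta2 <= 20


def test_pick_soft_threshold_falls_back_to_default_nine(rng):
    noise = rng.normal(0, 1, size=(60, 10))
    with pytest.warns(UserWarning):
        beta = nn.pick_soft_threshold(noise, beta_grid=[1],
                                      r2_target=0.999)
    assert beta == 9


# --------------------------------------------------------------------- TOM

def test_tom_diagonal_and_uniform_triangle():
    a = 0.37
    A = np.full((3, 3), a)
    np.fill_diagonal(A, 0.0)
    T = tom(A)
    assert np.allclose(np.diag(T), 1.0)
    off = ~np.eye(3, dtype=bool)
    assert np.allclose(T[off], a, atol=1e-12)


def test_tom_matches_bruteforce_on_random_networks(rng):
    for _ in range(5):
        A = rng.uniform(0, 1, size=(6, 6))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        assert np.allclose(tom(A), tom_oracle(A), atol=1e-12)


def test_tom_rejects_asymmetric_input():
    A = np.array([[0.0, 0.5], [0.4, 0.0]])
    with pytest.raises(ValueError):
        tom(A)


# ------------------------------------------------------------------- UPGMA

def test_upgma_two_blocks_merge_heights():
    D = np.array([
        [0.0, 0.1, 0.9, 0.9],
        [0.1, 0.0, 0.9, 0.9],
        [0.9, 0.9, 0.0, 0.1],
        [0.9, 0.9, 0.1, 0.0],
    ])
    Z = hclust_average(D)
    heights = Z[:, 2]
    assert heights[-1] == pytest.approx(0.9)
    assert heights[-2] <= 0.1 + 1e-12


def test_upgma_heights_nondecreasing_and_two_item_merge(rng):
    D = rng.uniform(0.1, 1, size=(10, 10))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    Z = hclust_average(D)
    assert np.all(np.diff(Z[:, 2]) >= -1e-12)
    two = hclust_average(np.array([[0.0, 0.42], [0.42, 0.0]]))
    assert two[0, 2] == pytest.approx(0.42)


def test_upgma_matches_naive_oracle_via_cophenetic_distances(rng):
    for _ in range(3):
        D = rng.uniform(0.05, 1, size=(8, 8))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        Z = hclust_average(D)
        coph = squareform(cophenet(Z))
        assert np.allclose(coph, upgma_cophenetic_oracle(D), atol=1e-12)


def test_upgma_rejects_nan():
    D = np.array([[0.0, np.nan], [np.nan, 0.0]])
    with pytest.raises(ValueError):
        hclust_average(D)


# ---------------------------------------------------------------- tree cut

def test_two_planted_blocks_recovered_with_background_grey():
    b = nn.simulate_expression_study(
        n_genes=500, n_samples=100, module_sizes=[150, 150],
        hub_weight_range=(0.75, 0.95), seed=21)
    part = detect_modules(b.expression, NetworkParams(seed=21))
    truth = b.truth.module_assignment
    assert len(part.modules) == 2
    for planted in ("turquoise", "blue"):
        members = truth.index[truth == planted]
        got = part.labels[members]
        top = got.value_counts().index[0]
        assert top != GREY
        assert (got == top).mean() >= 0.95
    grey_bg = (part.labels[truth == GREY] == GREY).mean()
    assert grey_bg >= 0.9


def test_undersized_block_goes_entirely_grey():
    b = nn.simulate_expression_study(n_genes=250, n_samples=60,
                                     module_sizes=[50],
                                     hub_weight_range=(0.8, 0.95), seed=5)
    part = detect_modules(b.expression,
                          NetworkParams(min_module_size=100, seed=5))
    assert part.modules == []
    assert (part.labels == GREY).all()


def test_deeper_split_never_finds_fewer_modules(default_bundle):
    X = default_bundle.expression
    D = nn.tom_dissimilarity(signed_adjacency(bicor_matrix(X.to_numpy()), 9))
    Z = hclust_average(D)
    counts = {ds: len(cut_dynamic_hybrid(Z, X.index, 100, ds).modules)
              for ds in (0, 4)}
    assert counts[4] >= counts[0]


def test_min_module_size_below_two_rejected():
    Z = hclust_average(np.array([[0.0, 0.5], [0.5, 0.0]]))
    with pytest.raises(ValueError):
        cut_dynamic_hybrid(Z, ["a", "b"], min_module_size=1)


# -------------------------------------------------------------- eigengenes

def test_identical_members_give_zscored_eigengene(rng):
    v = rng.normal(5, 2, 30)
    X = pd.DataFrame([v, v, v], index=["a", "b", "c"],
                     columns=[f"s{i}" for i in range(30)])
    me = module_eigengene(X, ["a", "b", "c"])
    z = (v - v.mean()) / v.std(ddof=1)
    assert np.allclose(me.to_numpy(), z, atol=1e-10)
    K = nn.kme(X, pd.DataFrame({"m": me}).T.set_axis(X.columns, axis=1))
    assert np.allclose(K["m"], 1.0)


def test_sign_orientation_with_anticorrelated_members(rng):
    v = rng.normal(0, 1, 40)
    X = pd.DataFrame([v, -v], index=["a", "b"],
                     columns=[f"s{i}" for i in range(40)])
    me = module_eigengene(X, ["a", "b"])
    r = np.corrcoef(np.vstack([X.to_numpy(), me.to_numpy()]))[-1, :-1]
    assert r.mean() >= 0
    assert np.allclose(np.abs(r), 1.0, atol=1e-10)


def test_eigengene_recovers_planted_latent_factor(default_bundle,
                                                  default_partition):
    b = default_bundle
    truth = b.truth.module_assignment
    for planted in ("turquoise", "blue", "brown"):
        members = truth.index[truth == planted]
        me = module_eigengene(b.expression, members)
        latent = b.truth.latent_factors.loc[planted].to_numpy(dtype=float)
        assert abs(np.corrcoef(me, latent)[0, 1]) >= 0.95


def test_pure_noise_genes_have_low_kme(default_bundle, default_network):
    ME, K = default_network
    truth = default_bundle.truth.module_assignment
    noise_genes = truth.index[truth == GREY]
    frac_low = (K.loc[noise_genes].abs() < 0.5).to_numpy().mean()
    assert frac_low >= 0.99


def test_planted_hubs_have_high_own_module_kme(default_bundle,
                                               default_partition,
                                               default_network):
    ME, K = default_network
    truth = default_bundle.truth
    hubs = truth.hub_weights.index[truth.hub_weights >= 0.9]
    labels = default_partition.labels
    own = [K.loc[g, labels[g]] for g in hubs if labels[g] != GREY]
    assert len(own) >= 0.9 * len(hubs)
    assert min(own) >= 0.8


# ------------------------------------------------------------------ merging

def test_modules_from_same_latent_factor_are_merged():
    rng = np.random.default_rng(17)
    n = 80
    E = rng.normal(0, 1, n)
    X = pd.DataFrame(
        0.9 * E + 0.3 * rng.normal(0, 1, (240, n)),
        index=[f"g{i}" for i in range(240)],
        columns=[f"s{j}" for j in range(n)])
    labels = pd.Series(["turquoise"] * 120 + ["blue"] * 120, index=X.index)
    part = nn.ModulePartition(labels=labels)
    merged, ME = nn.merge_close_modules(X, part, merge_cut_height=0.1)
    assert len(merged.modules) == 1


def test_orthogonal_modules_not_merged(default_bundle):
    truth = default_bundle.truth.module_assignment
    part = nn.ModulePartition(labels=truth.copy())
    merged, _ = nn.merge_close_modules(default_bundle.expression, part,
                                       merge_cut_height=0.1)
    assert len(merged.modules) == 3


def test_zero_cut_height_changes_nothing(default_bundle):
    truth = default_bundle.truth.module_assignment
    part = nn.ModulePartition(labels=truth.copy())
    merged, _ = nn.merge_close_modules(default_bundle.expression, part,
                                       merge_cut_height=0.0)
    # same grouping (labels may be renamed by size)
    assert nn.adjusted_rand_index(merged.labels, truth) == pytest.approx(1.0)


# -------------------------------------------------------------- robustness

def test_full_sample_single_resample_is_identity(default_bundle,
                                                 default_partition):
    params = NetworkParams(n_resamples=1, resample_fraction=1.0,
                           seed=3)
    stability, part = robustness_consensus(default_bundle.expression, params,
                                           default_partition)
    assert (stability == 1.0).all()
    assert part.labels.equals(default_partition.labels)


def test_resampling_too_small_rejected(default_bundle):
    params = NetworkParams(resample_fraction=0.04, seed=0)
    with pytest.raises(ValueError):
        robustness_consensus(default_bundle.expression.iloc[:, :60], params)


def test_strong_modules_are_stable_under_resampling():
    b = nn.simulate_expression_study(
        n_genes=420, n_samples=80, module_sizes=[140, 140],
        hub_weight_range=(0.8, 0.95), seed=33)
    params = NetworkParams(n_resamples=20, seed=33)
    stability, part = robustness_consensus(b.expression, params)
    truth = b.truth.module_assignment
    member_stab = stability[truth != GREY]
    assert (member_stab >= 0.9).mean() >= 0.9


def test_pure_noise_partition_is_mostly_grey():
    rng = np.random.default_rng(29)
    X = pd.DataFrame(rng.normal(0, 1, size=(400, 60)),
                     index=[f"g{i}" for i in range(400)],
                     columns=[f"s{j}" for j in range(60)])
    params = NetworkParams(min_module_size=50, n_resamples=10, seed=29)
    full = detect_modules(X, params)
    if full.modules:
        _, part = robustness_consensus(X, params, full)
    else:
        part = full
    assert part.grey_fraction() >= 0.95


# ------------------------------------------------------------- determinism

def test_detection_is_deterministic(default_bundle):
    X = default_bundle.expression.iloc[:300, :50]
    params = NetworkParams(min_module_size=50, seed=4)
    p1 = detect_modules(X, params)
    p2 = detect_modules(X, params)
    assert p1.labels.equals(p2.labels)
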