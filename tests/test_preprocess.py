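"""QC and normalization: quantile normalization, connectivity outliers,
covariate balance, empirical-Bayes batch adjustment, probe collapsing."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import fisher_greater_oracle

import nephronet as nn
from nephronet.preprocess import (adjust_batch_empirical_bayes, check_balance,
                                  collapse_probes, intersect_genes,
                                  log2_transform, quantile_normalize,
                                  remove_outliers, sample_connectivity_z)


def frame(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


# ---------------------------------------------------------------- log2

def test_log2_examples_and_flag():
    m = frame([[8.0, 1.0]])
    out = log2_transform(m, offset=0.0)
    assert out.iloc[0, 0] == pytest.approx(3.0)
    zero = log2_transform(frame([[0.0]]), offset=1.0)
    assert zero.iloc[0, 0] == pytest.approx(0.0)
    assert log2_transform(m, already_log2=True) is m
    with pytest.raises(ValueError, match="g0"):
        log2_transform(frame([[0.0]]), offset=0.0)


# ---------------------------------------------------- quantile normalization

def test_quantile_normalize_toy_columns():
    m = frame(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
    out = quantile_normalize(m)
    for col in out.columns:
        assert sorted(out[col]) == pytest.approx([2.5, 3.5, 4.5])


def test_quantile_normalize_identity_and_idempotence(rng):
    m = frame(rng.normal(8, 2, size=(40, 6)))
    same = pd.concat([m.iloc[:, [0]]] * 4, axis=1)
    same.columns = list("abcd")
    assert np.allclose(quantile_normalize(same).to_numpy(), same.to_numpy())
    once = quantile_normalize(m)
    twice = quantile_normalize(once)
    assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)


def test_quantile_normalize_equalizes_column_multisets(rng):
    m = frame(rng.normal(0, 1, size=(30, 5)))
    out = quantile_normalize(m)
    ref = np.sort(out.iloc[:, 0].to_numpy())
    for j in range(1, 5):
        assert np.allclose(np.sort(out.iloc[:, j].to_numpy()), ref)


def test_quantile_normalize_ties_get_mean_of_tied_quantiles():
    m = frame(np.array([[1.0, 1.0], [1.0, 2.0], [5.0, 3.0]]))
    out = quantile_normalize(m)
    target = np.sort(m.to_numpy(), axis=0).mean(axis=1)
    # column 0 has a tie at value 1 across ranks 1 and 2
    assert out.iloc[0, 0] == pytest.approx((target[0] + target[1]) / 2)
    assert out.iloc[1, 0] == pytest.approx((target[0] + target[1]) / 2)
    assert out.iloc[2, 0] == pytest.approx(target[2])


# ------------------------------------------------------- connectivity Z

def test_identical_samples_all_z_zero():
    col = np.arange(10.0)
    m = frame(np.tile(col[:, None], (1, 5)))
    z = sample_connectivity_z(m)
    assert np.allclose(z.to_numpy(), 0.0)


def outlier_fixture():
    """10 concordant samples plus one equal to the negated mean profile."""
    rng = np.random.default_rng(42)
    base = rng.normal(0, 1, size=60)
    cols = [base + rng.normal(0, 0.3, size=60) for _ in range(10)]
    mean_profile = np.mean(cols, axis=0)
    cols.append(-mean_profile)
    m = frame(np.column_stack(cols))
    meta = pd.DataFrame(
        {"diagnosis": ["case"] * 5 + ["control"] * 6},
        index=m.columns)
    return m, meta


def test_negated_sample_is_extreme_outlier():
    m, _ = outlier_fixture()
    z = sample_connectivity_z(m)
    assert z.idxmin() == m.columns[-1]
    assert z.iloc[-1] < -2


def test_z_scores_sum_to_zero():
    m = frame(np.random.default_rng(1).normal(0, 1, size=(20, 3)))
    assert abs(sample_connectivity_z(m).sum()) < 1e-10


def test_remove_outliers_removes_exactly_the_planted_one():
    m, meta = outlier_fixture()
    out, meta_out, report = remove_outliers(m, meta, max_iterations=1)
    removed = [s for _, s, _ in report.removed_samples]
    assert m.columns[-1] in removed
    assert all(z < -2 for _, _, z in report.removed_samples)


def test_infinite_threshold_removes_nothing():
    m, meta = outlier_fixture()
    out, meta_out, report = remove_outliers(m, meta, z_threshold=-np.inf)
    assert report.removed_samples == []
    pd.testing.assert_frame_equal(out, m)


def test_removal_refuses_to_empty_a_diagnosis_group():
    m, _ = outlier_fixture()
    meta = pd.DataFrame({"diagnosis": ["case"] * 10 + ["control"]},
                        index=m.columns)
    with pytest.raises(ValueError, match="control"):
        remove_outliers(m, meta)


# --------------------------------------------------------- balance check

def test_balanced_batch_gives_chi_square_p_one():
    meta = pd.DataFrame({
        "diagnosis": ["case"] * 10 + ["control"] * 10,
        "batch": (["b1"] * 5 + ["b2"] * 5) * 2,
    }, index=[f"s{i}" for i in range(20)])
    table = check_balance(meta)
    row = table[table["covariate"] == "batch"].iloc[0]
    assert row["p"] == pytest.approx(1.0)
    assert not row["flagged"]


def test_fisher_branch_matches_hypergeometric_oracle():
    meta = pd.DataFrame({
        "diagnosis": ["case"] * 10 + ["control"] * 10,
        "batch": ["b1"] * 8 + ["b2"] * 2 + ["b1"] * 2 + ["b2"] * 8,
    }, index=[f"s{i}" for i in range(20)])
    table = check_balance(meta)
    row = table[table["covariate"] == "batch"].iloc[0]
    # two-sided Fisher p for table (8,2 / 2,8): sum over tables at least as
    # extreme in either direction under the hypergeometric null
    p_greater = fisher_greater_oracle(8, 2, 2, 8)
    p_less = fisher_greater_oracle(2, 8, 8, 2)
    expected = stats.fisher_exact([[8, 2], [2, 8]])[1]
    assert row["test"] == "fisher_exact"
    assert row["p"] == pytest.approx(expected)
    # one-sided oracle brackets the two-sided value
    assert p_greater <= row["p"] <= p_greater + p_less + 1e-12


def test_null_continuous_covariate_flag_rate_is_nominal():
    rng = np.random.default_rng(11)
    flags = 0
    n_reps = 400
    for _ in range(n_reps):
        meta = pd.DataFrame({
            "diagnosis": ["case"] * 15 + ["control"] * 15,
            "rin": rng.normal(8, 1, 30),
        }, index=[f"s{i}" for i in range(30)])
        t = check_balance(meta, covariates=["rin"])
        flags += int(t.iloc[0]["flagged"])
    rate = flags / n_reps
    # binomial 99% CI around 0.05 at 400 replicates
    assert 0.05 - 2.576 * np.sqrt(0.05 * 0.95 / n_reps) <= rate \
        <= 0.05 + 2.576 * np.sqrt(0.05 * 0.95 / n_reps)


def test_constant_covariate_skipped():
    meta = pd.DataFrame({
        "diagnosis": ["case"] * 5 + ["control"] * 5,
        "rin": [7.0] * 10,
    }, index=[f"s{i}" for i in range(10)])
    t = check_balance(meta, covariates=["rin"])
    assert "skipped" in t.iloc[0]["test"]


# ------------------------------------------------------ batch adjustment

def two_batch_fixture(noise=0.0, effect=0.0, seed=0, n_per_batch=50):
    rng = np.random.default_rng(seed)
    n_genes = 30
    n = 2 * n_per_batch
    batch = ["b1"] * n_per_batch + ["b2"] * n_per_batch
    diagnosis = (["case", "control"] * (n_per_batch // 2 + 1))[:n_per_batch] * 2
    base = rng.normal(8, 1, n_genes)
    X = np.tile(base[:, None], (1, n))
    if noise:
        X = X + rng.normal(0, noise, X.shape)
    X[:, n_per_batch:] += 2.0
    if effect:
        case_cols = np.asarray(diagnosis) == "case"
        X[:, case_cols] += effect
    m = frame(X, samples=[f"s{i}" for i in range(n)])
    meta = pd.DataFrame({"diagnosis": diagnosis, "batch": batch},
                        index=m.columns)
    return m, meta


def test_single_batch_is_identity():
    m, meta = two_batch_fixture(noise=0.5)
    meta["batch"] = "b1"
    assert adjust_batch_empirical_bayes(m, meta) is m


def test_noiseless_constant_offset_is_removed_exactly():
    m, meta = two_batch_fixture(noise=0.0)
    adj = adjust_batch_empirical_bayes(m, meta)
    b1 = adj.loc[:, (meta["batch"] == "b1").to_numpy()].mean(axis=1)
    b2 = adj.loc[:, (meta["batch"] == "b2").to_numpy()].mean(axis=1)
    assert np.abs(b1 - b2).max() < 1e-6


def test_preserved_diagnosis_effect_survives_adjustment():
    m, meta = two_batch_fixture(noise=1.0, effect=1.0, seed=3)
    adj = adjust_batch_empirical_bayes(m, meta, preserve=["diagnosis"])
    case = (meta["diagnosis"] == "case").to_numpy()
    diff = adj.loc[:, case].mean(axis=1) - adj.loc[:, ~case].mean(axis=1)
    assert diff.mean() == pytest.approx(1.0, abs=0.1)


def test_grand_gene_means_preserved_on_balanced_design():
    # EB shrinkage perturbs per-gene means only at the order of the
    # shrinkage residue, far below the batch offset (+2) being removed
    m, meta = two_batch_fixture(noise=0.8, seed=5)
    adj = adjust_batch_empirical_bayes(m, meta)
    assert np.abs(adj.mean(axis=1) - m.mean(axis=1)).max() < 5e-3


def test_single_sample_batch_rejected():
    m, meta = two_batch_fixture(noise=0.5)
    meta.iloc[0, meta.columns.get_loc("batch")] = "b3"
    with pytest.raises(ValueError, match="single sample"):
        adjust_batch_empirical_bayes(m, meta)


def test_batch_confounded_with_diagnosis_rejected():
    m, meta = two_batch_fixture(noise=0.5)
    meta["diagnosis"] = np.where(meta["batch"] == "b1", "case", "control")
    with pytest.raises(ValueError, match="confounded"):
        adjust_batch_empirical_bayes(m, meta)


def test_matches_bioconductor_sva_combat(tmp_path):
    """Independent cross-check against sva::ComBat on a small fixture."""
    rng = np.random.default_rng(5)
    n_g, n_s = 30, 24
    batch = ["b1"] * 12 + ["b2"] * 12
    diagnosis = (["case", "control"] * 6) * 2
    X = rng.normal(8, 1, (n_g, 1)) + rng.normal(0, 1, (n_g, n_s))
    X[:, 12:] += rng.normal(1.0, 0.5, n_g)[:, None]
    m = frame(X, samples=[f"s{i}" for i in range(n_s)])
    meta = pd.DataFrame({"diagnosis": diagnosis, "batch": batch},
                        index=m.columns)
    mine = adjust_batch_empirical_bayes(m, meta)
    m.to_csv(tmp_path / "expr.tsv", sep="\t")
    meta.to_csv(tmp_path / "meta.tsv", sep="\t")
    script = tmp_path / "run.R"
    script.write_text(f"""
suppressMessages(library(sva))
x <- as.matrix(read.delim("{tmp_path}/expr.tsv", row.names=1))
m <- read.delim("{tmp_path}/meta.tsv", row.names=1)
mod <- model.matrix(~ diagnosis, data=m)
out <- ComBat(dat=x, batch=m$batch, mod=mod, par.prior=TRUE)
write.table(out, "{tmp_path}/r_out.tsv", sep="\\t", quote=FALSE)
""")
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    theirs = pd.read_csv(tmp_path / "r_out.tsv", sep="\t")
    assert np.abs(mine.to_numpy() - theirs.to_numpy()).max() < 1e-4


# ------------------------------------------------------- probe collapsing

def test_collapse_keeps_highest_mean_probe_row():
    probes = frame(np.array([[5.0, 5.0], [7.0, 7.0]]),
                   genes=["gA_p1", "gA_p2"])
    pmap = pd.DataFrame({"probe_id": ["gA_p1", "gA_p2"],
                         "gene_id": ["gA", "gA"]})
    out = collapse_probes(probes, pmap)
    assert list(out.loc["gA"]) == [7.0, 7.0]


def test_collapse_tie_breaks_to_smaller_probe_id():
    probes = frame(np.array([[3.0, 5.0], [5.0, 3.0]]),
                   genes=["gA_p2", "gA_p1"])
    pmap = pd.DataFrame({"probe_id": ["gA_p1", "gA_p2"],
                         "gene_id": ["gA", "gA"]})
    out = collapse_probes(probes, pmap)
    assert list(out.loc["gA"]) == [5.0, 3.0]  # gA_p1 wins the tie


def test_collapse_rejects_unmapped_probe():
    probes = frame(np.array([[1.0, 2.0]]), genes=["mystery"])
    pmap = pd.DataFrame({"probe_id": ["other"], "gene_id": ["gA"]})
    with pytest.raises(ValueError, match="mystery"):
        collapse_probes(probes, pmap)


def test_collapse_rows_are_copies_never_averages(rng):
    b = nn.simulate_expression_study(n_genes=30, n_samples=12,
                                     module_sizes=[10], seed=2)
    probes, pmap = nn.simulate_probe_table(b.expression, 3, 0.3, seed=3)
    out = collapse_probes(probes, pmap)
    probe_rows = {tuple(r) for r in probes.to_numpy()}
    for row in out.to_numpy():
        assert tuple(row) in probe_rows


# ------------------------------------------------------ gene intersection

def test_intersection_examples():
    a = frame(np.zeros((3, 2)), genes=["A", "B", "C"])
    b = frame(np.zeros((3, 2)), genes=["B", "C", "D"], samples=["x", "y"])
    common, mats = intersect_genes([a, b])
    assert common == ["B", "C"]
    assert list(mats[0].index) == ["B", "C"]
    common_rev, _ = intersect_genes([b, a])
    assert common_rev == common
    with pytest.raises(ValueError, match="empty"):
        intersect_genes([a, frame(np.zeros((1, 2)), genes=["Z"])])
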