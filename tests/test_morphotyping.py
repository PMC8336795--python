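import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage

import oracles
from stiffmorph import morphotyping


def _blobs(k, n_per=40, sep=10.0, dim=4, seed=0):
    rng = np.random.default_rng(seed)
    parts, labels = [], []
    for i in range(k):
        center = np.zeros(dim)
        center[i % dim] = sep * (1 + i // dim)
        parts.append(rng.normal(0, 1, size=(n_per, dim)) + center)
        labels += [i] * n_per
    X = np.vstack(parts)
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(dim)])
    return df, np.array(labels)


def test_zscore_hand_example_and_constant_removal():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
    z = morphotyping.zscore(df)
    np.testing.assert_allclose(z["a"], [-1.0, 0.0, 1.0])  # sample-SD convention
    assert "b" not in z.columns
    with pytest.raises(ValueError):
        morphotyping.zscore(pd.DataFrame({"b": [5.0, 5.0]}))


def test_zscore_output_means_below_1e9(paper_run):
    z = morphotyping.zscore(
        paper_run.morphology_table[~paper_run.morphology_table["clumped"]].reset_index(
            drop=True
        )
    )
    feats = morphotyping.feature_matrix(z)
    assert (feats.mean().abs() < 1e-9).all()
    np.testing.assert_allclose(feats.std(ddof=1), 1.0, rtol=1e-9)


@pytest.mark.parametrize("k_true", [2, 3])
def test_estimate_k_recovers_separated_clouds(k_true):
    df, _ = _blobs(k_true, n_per=60, sep=12.0)
    chosen, traces = morphotyping.estimate_k(df, seed=4, n_reps=10)
    assert chosen == k_true
    assert len(traces) == 10 * 5  # n_reps x |k_range|


def test_estimate_k_reproducible_and_validity_vs_oracle():
    df, _ = _blobs(3, n_per=20, sep=9.0, seed=2)
    c1, t1 = morphotyping.estimate_k(df, seed=7, n_reps=5)
    c2, t2 = morphotyping.estimate_k(df, seed=7, n_reps=5)
    assert c1 == c2
    pd.testing.assert_frame_equal(t1, t2)
    # silhouette / Davies-Bouldin agree with the brute-force formulas
    X = df.to_numpy()[:45]
    labels = fcluster(linkage(X, method="ward"), t=3, criterion="maxclust")
    from sklearn.metrics import davies_bouldin_score, silhouette_score

    assert math.isclose(
        silhouette_score(X, labels), oracles.silhouette_oracle(X, labels), abs_tol=1e-9
    )
    assert math.isclose(
        davies_bouldin_score(X, labels),
        oracles.davies_bouldin_oracle(X, labels),
        abs_tol=1e-9,
    )
    assert -1.0 <= silhouette_score(X, labels) <= 1.0
    assert davies_bouldin_score(X, labels) > 0


def test_estimate_k_input_guards():
    df, _ = _blobs(2, n_per=10)
    with pytest.raises(ValueError):
        morphotyping.estimate_k(df.iloc[:8], seed=0)
    with pytest.raises(ValueError):
        morphotyping.estimate_k(df, k_range=range(2, 50), seed=0)


def test_ward_merge_order_matches_exhaustive_objective():
    rng = np.random.default_rng(3)
    X = rng.random((6, 2)) * 10
    Z = linkage(X, method="ward")
    ref = oracles.ward_merge_order(X)
    # replay scipy's merge history as sets of original indices
    clusters = {i: frozenset([i]) for i in range(6)}
    for step, (a, b, _, _) in enumerate(Z):
        got = {clusters[int(a)], clusters[int(b)]}
        assert got == {ref[step][0], ref[step][1]}
        clusters[6 + step] = clusters.pop(int(a)) | clusters.pop(int(b))


def test_ward_objective_nondecreasing_along_merges():
    rng = np.random.default_rng(1)
    X = rng.random((40, 5))
    Z = linkage(X, method="ward")
    assert (np.diff(Z[:, 2]) >= -1e-12).all()


def test_cluster_morphs_coclusters_duplicates():
    df, labels = _blobs(3, n_per=15, sep=10.0)
    dup = pd.concat([df, df], ignore_index=True)
    a = morphotyping.cluster_morphs(dup, 3)
    half = len(df)
    assert (a.labels.iloc[:half].to_numpy() == a.labels.iloc[half:].to_numpy()).all()
    with pytest.raises(ValueError):
        morphotyping.cluster_morphs(df, len(df) + 1)


def test_medoid_examples_and_permutation_invariance():
    df = pd.DataFrame({"x": [0.0, 1.0, 10.0]})
    a = morphotyping.MorphAssignment(
        labels=pd.Series([1, 1, 1]), chosen_k=1, linkage_record=np.empty((0, 4))
    )
    assert morphotyping.medoids(df, a) == {1: 1}  # member 1 minimises mean distance
    single = pd.DataFrame({"x": [3.0]})
    s = morphotyping.MorphAssignment(
        labels=pd.Series([1]), chosen_k=1, linkage_record=np.empty((0, 4))
    )
    assert morphotyping.medoids(single, s) == {1: 0}
    df2, labels = _blobs(2, n_per=10, dim=3, seed=5)
    a2 = morphotyping.MorphAssignment(
        labels=pd.Series(labels + 1), chosen_k=2, linkage_record=np.empty((0, 4))
    )
    m1 = morphotyping.medoids(df2, a2)
    m2 = morphotyping.medoids(df2[list(reversed(df2.columns))], a2)
    assert m1 == m2


def test_mutual_information_ranking():
    rng = np.random.default_rng(0)
    labels = np.repeat([1, 2, 3], 60)
    df = pd.DataFrame(
        {
            "signal": labels + rng.normal(0, 0.05, size=len(labels)),
            "noise": rng.normal(0, 1, size=len(labels)),
            "constantish": np.ones(len(labels)) + rng.normal(0, 1e-9, len(labels)),
        }
    )
    mi = morphotyping.feature_importance_mi(df, labels, seed=0)
    assert mi.index[0] == "signal"
    assert mi["constantish"] < 0.02
    assert (mi >= 0).all()
    # plug-in histogram MI on the discretised copy agrees the signal is ~log(3)
    counts = np.full((3, 3), 1e-12)
    for lab, v in zip(labels, df["signal"].round().astype(int)):
        counts[lab - 1, v - 1] += 1
    p = counts / counts.sum()
    px, py = p.sum(1), p.sum(0)
    hist_mi = float((p * np.log(p / np.outer(px, py))).sum())
    assert abs(mi["signal"] - hist_mi) < 0.2


def test_composition_hand_examples():
    meta = pd.DataFrame(
        {
            "scene_id": ["s1"] * 5 + ["s2"] * 5,
            "stiffness_kpa": [2.0] * 10,
        }
    )
    labels = [1, 1, 2, 2, 2, 1, 1, 1, 2, 2]  # scene props: 0.4/0.6 then 0.6/0.4
    comp = morphotyping.composition_by_condition(labels, meta)
    row = comp[(comp["morph"] == 1)].iloc[0]
    assert math.isclose(row["proportion"], 0.5)
    # closed-form t(1) interval: mean +/- t_{0.975,1} * sd/sqrt(2)
    from scipy.stats import t as tdist

    sd = np.std([0.4, 0.6], ddof=1)
    half = tdist.ppf(0.975, 1) * sd / np.sqrt(2)
    assert math.isclose(row["ci_high"] - row["proportion"], half, rel_tol=1e-9)

    uni = morphotyping.composition_by_condition(
        [1, 1, 1, 1], pd.DataFrame({"scene_id": ["a", "a", "b", "b"], "stiffness_kpa": [2.0] * 4})
    )
    assert math.isclose(uni["proportion"].iloc[0], 1.0)
    assert math.isclose(uni["ci_high"].iloc[0] - uni["ci_low"].iloc[0], 0.0, abs_tol=1e-12)
    lone = morphotyping.composition_by_condition(
        [1, 2], pd.DataFrame({"scene_id": ["a", "a"], "stiffness_kpa": [2.0, 2.0]})
    )
    assert lone["ci_low"].isna().all()  # single scene: CI unavailable
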