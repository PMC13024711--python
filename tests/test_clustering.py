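"""Tests for DTW, PAM K-medoids and the cluster-quality indices."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from procfx.clustering import (
    ch_index,
    compare_cluster_features,
    dtw_distance,
    dtw_matrix,
    pam_cluster,
    scan_k,
    silhouette_mean,
    unigram_frequency_features,
)


# ---------------------------------------------------------------------------
# DTW


def _dtw_path_oracle(x, y):
    """Exhaustive enumeration of all monotone warping paths (tiny series only)."""
    n, m = len(x), len(y)
    best = [math.inf]

    def walk(i, j, cost):
        cost += abs(x[i] - y[j])
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < n and j + dj < m:
                walk(i + di, j + dj, cost)

    walk(0, 0, 0.0)
    return best[0]


def test_dtw_of_identical_series_is_zero():
    x = [3.0, 1.0, 4.0, 1.0, 5.0]
    assert dtw_distance(x, x) == 0.0


def test_single_element_series():
    assert dtw_distance([1], [2]) == 1.0


def test_warping_absorbs_an_inserted_element():
    assert dtw_distance([1, 3], [1, 2, 3]) == 1.0


def test_dtw_matches_exhaustive_path_oracle_on_all_short_series():
    values = [0.0, 1.0, 3.0]
    series = [
        list(s)
        for length in (1, 2, 3)
        for s in itertools.product(values, repeat=length)
    ]
    for x in series:
        for y in series:
            assert dtw_distance(x, y) == pytest.approx(_dtw_path_oracle(x, y))


def test_dtw_matches_oracle_on_random_length4_series():
    rng = np.random.default_rng(4)
    for _ in range(200):
        x = rng.integers(0, 6, size=4).astype(float)
        y = rng.integers(0, 6, size=rng.integers(1, 5)).astype(float)
        assert dtw_distance(x, y) == pytest.approx(_dtw_path_oracle(list(x), list(y)))


@settings(derandomize=True, max_examples=100)
@given(
    x=st.lists(st.integers(0, 9), min_size=1, max_size=6),
    y=st.lists(st.integers(0, 9), min_size=1, max_size=6),
)
def test_dtw_is_symmetric_and_nonnegative(x, y):
    d = dtw_distance(x, y)
    assert d >= 0
    assert d == pytest.approx(dtw_distance(y, x))


def test_symmetric2_weights_the_diagonal():
    # single-cell alignment: the diagonal step costs twice the local distance
    assert dtw_distance([1], [5], step_pattern="symmetric2") == 8.0
    assert dtw_distance([2, 2], [2, 2], step_pattern="symmetric2") == 0.0


def test_empty_series_raise():
    with pytest.raises(ValueError):
        dtw_distance([], [1])


def test_dtw_matrix_properties():
    seqs = [[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]]
    D = dtw_matrix(seqs)
    assert np.allclose(D, 0.0)
    seqs = [[0.0, 1.0], [5.0], [2.0, 2.0, 2.0]]
    D = dtw_matrix(seqs)
    assert np.allclose(D, D.T)
    assert np.allclose(np.diag(D), 0.0)
    # order independence
    perm = [2, 0, 1]
    D2 = dtw_matrix([seqs[i] for i in perm])
    assert np.allclose(D2, D[np.ix_(perm, perm)])


# ---------------------------------------------------------------------------
# PAM


def _pairs_instance():
    # two tight pairs far apart
    pts = np.array([0.0, 0.1, 10.0, 10.1])
    return np.abs(pts[:, None] - pts[None, :])


def test_pam_recovers_two_tight_pairs():
    D = _pairs_instance()
    res = pam_cluster(D, 2)
    assert res.assignment[0] == res.assignment[1]
    assert res.assignment[2] == res.assignment[3]
    assert res.assignment[0] != res.assignment[2]


def test_pam_objective_zero_when_k_covers_distinct_points():
    pts = np.array([0.0, 0.0, 5.0, 9.0])
    D = np.abs(pts[:, None] - pts[None, :])
    res = pam_cluster(D, 3)
    assert res.objective == pytest.approx(0.0)


def test_pam_is_deterministic():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(30, 2))
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    r1 = pam_cluster(D, 3)
    r2 = pam_cluster(D, 3)
    assert r1.medoids == r2.medoids
    assert np.array_equal(r1.assignment, r2.assignment)


def test_pam_k_out_of_range():
    D = _pairs_instance()
    for k in (1, 4, 5):
        with pytest.raises(ValueError):
            pam_cluster(D, k)


def _is_one_swap_optimal(D, medoids, objective):
    n = D.shape[0]
    for mi in range(len(medoids)):
        for h in range(n):
            if h in medoids:
                continue
            cand = list(medoids)
            cand[mi] = h
            if D[:, cand].min(axis=1).sum() < objective - 1e-12:
                return False
    return True


def test_pam_is_globally_or_one_swap_optimal_on_small_instances():
    """BUILD+SWAP is a local search: it must match the exhaustive global
    optimum on most tiny instances, and any miss must itself be a verified
    1-swap-optimal solution (the same behaviour the reference BUILD+SWAP
    implementations show)."""
    rng = np.random.default_rng(21)
    misses = trials = 0
    for _ in range(50):
        n = int(rng.integers(5, 9))
        pts = rng.uniform(0, 10, size=(n, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        for k in (2, 3):
            trials += 1
            res = pam_cluster(D, k)
            best = min(
                D[:, list(med)].min(axis=1).sum()
                for med in itertools.combinations(range(n), k)
            )
            assert res.objective >= best - 1e-12
            if res.objective > best + 1e-9:
                misses += 1
                assert _is_one_swap_optimal(D, res.medoids, res.objective)
    assert misses < trials / 4  # global optimum on the large majority


# ---------------------------------------------------------------------------
# quality indices


def test_silhouette_hand_value_for_two_tight_pairs():
    # a = 1 within, b = 10 between -> s = (10 - 1)/10 = 0.9 for every point
    D = np.array(
        [
            [0.0, 1.0, 10.0, 10.0],
            [1.0, 0.0, 10.0, 10.0],
            [10.0, 10.0, 0.0, 1.0],
            [10.0, 10.0, 1.0, 0.0],
        ]
    )
    labels = np.array([0, 0, 1, 1])
    mean_s, samples = silhouette_mean(D, labels)
    assert samples == pytest.approx([0.9, 0.9, 0.9, 0.9])
    assert mean_s == pytest.approx(0.9)


def test_silhouette_requires_two_clusters():
    D = _pairs_instance()
    with pytest.raises(ValueError):
        silhouette_mean(D, [0, 0, 0, 0])


def test_random_labels_have_near_zero_silhouette():
    rng = np.random.default_rng(11)
    pts = rng.uniform(size=60)
    D = np.abs(pts[:, None] - pts[None, :])
    means = []
    for _ in range(20):
        labels = rng.integers(0, 2, size=60)
        if len(np.unique(labels)) < 2:
            continue
        means.append(silhouette_mean(D, labels)[0])
    assert abs(np.mean(means)) < 0.15


def test_ch_prefers_true_split_over_random_split():
    D = _pairs_instance()
    good = ch_index(D, [0, 0, 1, 1], [0, 2])
    bad = ch_index(D, [0, 1, 0, 1], [0, 1])
    assert good > bad


def test_ch_hand_computed_toy_value():
    # points on a line at 0, 1, 10, 11; medoids 0 and 10; global medoid is
    # index 1 (point 1).  W = 1^2 + 1^2 = 2; B = 2*1 + 2*81 = 164;
    # CH = (164/1)/(2/2) = 164.
    pts = np.array([0.0, 1.0, 10.0, 11.0])
    D = np.abs(pts[:, None] - pts[None, :])
    assert ch_index(D, [0, 0, 1, 1], [0, 2]) == pytest.approx(164.0)


def test_ch_invariant_to_cluster_relabeling():
    rng = np.random.default_rng(2)
    pts = np.concatenate([rng.normal(0, 1, 10), rng.normal(8, 1, 10)])
    D = np.abs(pts[:, None] - pts[None, :])
    res = pam_cluster(D, 2)
    swapped = 1 - res.assignment
    assert ch_index(D, res.assignment, res.medoids) == pytest.approx(
        ch_index(D, swapped, res.medoids[::-1])
    )


def test_ch_infinite_when_degenerate():
    D = np.zeros((4, 4))
    with pytest.warns(UserWarning, match="zero within-cluster"):
        assert math.isinf(ch_index(D, [0, 0, 1, 1], [0, 2]))


# ---------------------------------------------------------------------------
# k scan


def test_scan_k_finds_the_planted_two_population_structure():
    rng = np.random.default_rng(31)
    seqs = [rng.normal(0, 0.3, size=rng.integers(8, 13)) for _ in range(15)]
    seqs += [rng.normal(5, 0.3, size=rng.integers(8, 13)) for _ in range(15)]
    D = dtw_matrix(seqs)
    table = scan_k(D, range(2, 6))
    assert int(table.loc[table["silhouette"].idxmax(), "k"]) == 2


def test_scan_k_single_value_range():
    D = _pairs_instance()
    table = scan_k(D, [2])
    assert len(table) == 1
    assert table.loc[0, "best_silhouette"] and table.loc[0, "best_ch"]


# ---------------------------------------------------------------------------
# cluster interpretation


def test_identical_groups_give_zero_t_and_d():
    feats = pd.DataFrame({"f": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
    out = compare_cluster_features(feats, [0, 0, 0, 1, 1, 1])
    assert out.loc[0, "t"] == pytest.approx(0.0)
    assert out.loc[0, "cohens_d"] == pytest.approx(0.0)


def test_unit_separation_gives_cohens_d_of_one():
    # groups [0,1,2] and [1,2,3]: pooled SD exactly 1, mean gap exactly 1
    feats = pd.DataFrame({"f": [0.0, 1.0, 2.0, 1.0, 2.0, 3.0]})
    out = compare_cluster_features(feats, [0, 0, 0, 1, 1, 1])
    assert out.loc[0, "cohens_d"] == pytest.approx(-1.0)
    assert out.loc[0, "df"] == 4


def test_zero_variance_feature_is_skipped_with_warning():
    feats = pd.DataFrame({"const": [1.0] * 6, "ok": [0, 1, 2, 3, 4, 5.0]})
    with pytest.warns(UserWarning, match="zero pooled variance"):
        out = compare_cluster_features(feats, [0, 0, 0, 1, 1, 1])
    assert list(out["feature"]) == ["ok"]


def test_more_than_two_clusters_rejected():
    feats = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError):
        compare_cluster_features(feats, [0, 1, 2])


def test_unigram_features_merge_roles(eff, planted_corpora):
    corpus = planted_corpora["state-pair"]
    feats = unigram_frequency_features(corpus, merge_roles=True)
    assert len(feats) == len(corpus)
    assert not any(str(c).startswith(("A: ", "B: ")) for c in feats.columns)
    # merged counts preserve the total number of actions
    assert feats.to_numpy().sum() == sum(len(s.tokens) for s in corpus)
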