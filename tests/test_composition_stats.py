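"""JSD distances, merge-height rule, PERMANOVA oracle, metadata screens."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gradimmune import (
    DistanceMatrix,
    cluster_count_by_height,
    equal_frequency_bins,
    jensen_shannon_divergence,
    jensen_shannon_matrix,
    merge_heights,
    metadata_association,
    permanova,
)
from gradimmune.composition_stats import _permanova_stats
from gradimmune.data_model import AbundanceTable, SubjectMetadata


# ---------------------------------------------------------------------------
# Jensen-Shannon divergence

def test_jsd_identical_zero():
    assert jensen_shannon_divergence([0.3, 0.7], [0.3, 0.7]) == pytest.approx(0.0)


def test_jsd_disjoint_supports_ln2():
    assert jensen_shannon_divergence([1, 0], [0, 1]) == pytest.approx(np.log(2))


def test_jsd_closed_form_example():
    assert jensen_shannon_divergence([1, 0], [0.5, 0.5]) == pytest.approx(
        0.215762, abs=1e-6)


def test_jsd_matrix_matches_scipy():
    from scipy.spatial.distance import jensenshannon

    rng = np.random.default_rng(2)
    raw = rng.random((6, 8))
    vals = raw / raw.sum(axis=1, keepdims=True)
    tab = AbundanceTable([f"s{i}" for i in range(6)], [f"t{j}" for j in range(8)], vals)
    D = jensen_shannon_matrix(tab)
    for i, j in itertools.combinations(range(6), 2):
        # scipy returns sqrt(JSD) in the given log base
        ref = jensenshannon(vals[i], vals[j], base=np.e) ** 2
        assert D.values[i, j] == pytest.approx(ref, abs=1e-10)


def test_jsd_all_zero_sample_rejected():
    tab = AbundanceTable(["a", "b"], ["x", "y"], [[0.0, 0.0], [0.5, 0.5]])
    with pytest.raises(ValueError, match="a"):
        jensen_shannon_matrix(tab)


def test_sqrt_jsd_triangle_inequality():
    rng = np.random.default_rng(4)
    raw = rng.random((12, 10))
    tab = AbundanceTable([f"s{i}" for i in range(12)], [f"t{j}" for j in range(10)],
                         raw / raw.sum(axis=1, keepdims=True))
    R = np.sqrt(jensen_shannon_matrix(tab).values)
    for i, j, k in itertools.combinations(range(12), 3):
        assert R[i, k] <= R[i, j] + R[j, k] + 1e-12


# ---------------------------------------------------------------------------
# merge-height rule

@pytest.mark.parametrize("heights,n,expected", [
    ([10, 4, 3.5, 2, 1], 6, 3),
    ([27, 9, 3], 4, 4),
    ([5, 5, 5, 5], 5, 2),
])
def test_cluster_count_examples(heights, n, expected):
    assert cluster_count_by_height(heights, n) == expected


def test_cluster_count_scale_invariant():
    h = [12.0, 5.0, 4.0, 1.0]
    assert cluster_count_by_height(h, 5) == cluster_count_by_height(
        [x * 37.0 for x in h], 5)


def test_cluster_count_rejects_nonpositive():
    with pytest.raises(ValueError):
        cluster_count_by_height([3.0, 0.0], 3)


def test_merge_heights_shape(small_cohort):
    _, cohort = small_cohort
    tab = cohort["abundance"]
    D = jensen_shannon_matrix(tab)
    h = merge_heights(D)
    assert len(h) == len(tab.sample_ids) - 1
    assert np.all(np.diff(h) <= 1e-12)


# ---------------------------------------------------------------------------
# PERMANOVA

def euclid_dm(points):
    pts = np.asarray(points, float)
    D = np.abs(pts[:, None] - pts[None, :])
    return DistanceMatrix([f"s{i}" for i in range(len(pts))], D)


def brute_force_permanova(dist, labels):
    """Independent oracle: full enumeration over all label permutations."""
    labels = np.asarray(labels)
    d2 = dist.values ** 2
    F_obs, r2 = _brute_stats(d2, labels)
    seen = set()
    ge = total = 0
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        F_p, _ = _brute_stats(d2, np.asarray(perm))
        ge += F_p >= F_obs - 1e-12
        total += 1
    return F_obs, r2, ge / total


def _brute_stats(d2, labels):
    n = len(labels)
    groups = sorted(set(labels))
    sst = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ssw = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ssw += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
    ssb = sst - ssw
    a = len(groups)
    F = (ssb / (a - 1)) / (ssw / (n - a)) if ssw > 0 else np.inf
    return F, ssb / sst


def test_permanova_worked_four_point_example():
    dm = euclid_dm([0, 1, 10, 11])
    res = permanova(dm, ["g1", "g1", "g2", "g2"])
    assert res.r_squared == pytest.approx(100 / 101, abs=1e-10)
    assert res.pseudo_F == pytest.approx(200.0, abs=1e-8)
    assert res.p_perm == pytest.approx(1 / 3, abs=1e-12)
    assert "exact" in res.method_note


@pytest.mark.parametrize("seed", range(5))
def test_permanova_matches_brute_force_small_n(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(5, 8)
    pts = rng.normal(size=n)
    labels = rng.choice(["a", "b"], size=n)
    if len(set(labels)) < 2:
        labels[0] = "a" if labels[1] == "b" else "b"
    dm = euclid_dm(pts)
    res = permanova(dm, labels)
    F, r2, p = brute_force_permanova(dm, labels)
    assert res.pseudo_F == pytest.approx(F, abs=1e-10)
    assert res.r_squared == pytest.approx(r2, abs=1e-10)
    assert res.p_perm == pytest.approx(p, abs=1e-10)


def test_permanova_matches_skbio():
    from skbio.stats.distance import DistanceMatrix as SkDM
    from skbio.stats.distance import permanova as sk_permanova

    rng = np.random.default_rng(9)
    pts = rng.normal(size=(20, 3))
    labels = ["a"] * 10 + ["b"] * 10
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    dm = DistanceMatrix([f"s{i}" for i in range(20)], D)
    res = permanova(dm, labels, n_perm=999, seed=0)
    ref = sk_permanova(SkDM(D, [f"s{i}" for i in range(20)]),
                       grouping=labels, permutations=999)
    assert res.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-8)


def test_permanova_identical_groups_near_zero_r2():
    pts = [0.0, 1.0, 2.0, 0.0, 1.0, 2.0]
    res = permanova(euclid_dm(pts), ["a", "a", "a", "b", "b", "b"])
    assert res.r_squared < 0.05


def test_permanova_null_p_roughly_uniform():
    rng = np.random.default_rng(0)
    ps = []
    for seed in range(40):
        pts = rng.normal(size=12)
        labels = ["a"] * 6 + ["b"] * 6
        res = permanova(euclid_dm(pts), labels, n_perm=99, seed=seed)
        ps.append(res.p_perm)
    assert 0.3 < np.mean(ps) < 0.7
    assert np.mean(np.asarray(ps) <= 0.05) < 0.2


# ---------------------------------------------------------------------------
# metadata associations

def test_equal_frequency_bins_sizes():
    rng = np.random.default_rng(1)
    bins = equal_frequency_bins(rng.normal(size=299), 3)
    assert sorted(np.bincount(bins).tolist()) == [99, 100, 100]


def test_fungi_residency_association():
    """Presence/absence counts from a 70/253 rural-urban split with 11/11
    positives give the chi-square p = 0.002."""
    residency = np.array(["rural"] * 70 + ["urban"] * 253)
    fungi = np.zeros(323, int)
    fungi[:11] = 1          # 11 rural positives
    fungi[70:81] = 1        # 11 urban positives
    meta = SubjectMetadata(pd.DataFrame(
        {"age": np.full(323, 30.0), "sex": np.zeros(323, int), "fungi": fungi},
        index=[f"s{i}" for i in range(323)]))
    res = metadata_association(residency, meta, variables=["fungi"])
    assert round(res["fungi"].p_value, 3) == 0.002


def test_null_categorical_calibration():
    rng = np.random.default_rng(0)
    groups = np.array(["a", "b", "c"] * 40)
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        var = rng.integers(0, 3, 120)
        meta = SubjectMetadata(pd.DataFrame(
            {"age": np.full(120, 30.0), "sex": np.zeros(120, int), "v": var},
            index=[f"s{i}" for i in range(120)]))
        res = metadata_association(groups, meta, variables=["v"])
        hits += res["v"].p_value < 0.05
    assert 0.02 <= hits / n_rep <= 0.09


def test_ordinal_variable_uses_kruskal():
    rng = np.random.default_rng(3)
    groups = np.array(["a"] * 30 + ["b"] * 30)
    weekly = np.concatenate([rng.integers(0, 3, 30), rng.integers(4, 7, 30)])
    meta = SubjectMetadata(pd.DataFrame(
        {"age": np.full(60, 30.0), "sex": np.zeros(60, int), "weekly": weekly},
        index=[f"s{i}" for i in range(60)]))
    res = metadata_association(groups, meta, variables=["weekly"],
                               ordinal={"weekly"})
    assert "tie-corrected" in res["weekly"].method_note
    assert res["weekly"].p_value < 1e-6


def test_single_level_variable_skipped():
    meta = SubjectMetadata(pd.DataFrame(
        {"age": [30.0, 40.0], "sex": [0, 1], "const": ["x", "x"]},
        index=["a", "b"]))
    res = metadata_association(np.array(["g1", "g2"]), meta, variables=["const"])
    assert "const" not in res
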