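import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgecrafting.blob_detection import DetectorConfig, detect_blobs
from edgecrafting.binning import bin_edge, compute_bin_grid, normalize_image
from edgecrafting.edge_scoring import (
    discretize_for_mi,
    edge_nmi,
    entropy,
    mi_result,
    mutual_information,
    normalized_mi,
    silhouette,
)

from oracles import entropy_direct, mi_double_sum, silhouette_direct


def test_mi_two_equal_modules_is_ln2():
    u = np.repeat([0, 1], 50)
    assert mutual_information(u, u) == pytest.approx(math.log(2), abs=1e-12)


def test_mi_constant_partition_is_zero():
    u = np.zeros(60)
    v = np.repeat([0, 1, 2], 20)
    assert mutual_information(u, v) == pytest.approx(0.0, abs=1e-12)


def test_mi_small_contingency_matches_double_sum():
    # contingency table [[2, 1], [1, 2]] over N = 6
    u = [0, 0, 0, 1, 1, 1]
    v = [0, 0, 1, 0, 1, 1]
    assert mutual_information(u, v) == pytest.approx(mi_double_sum(u, v),
                                                     abs=1e-12)


def test_mi_matches_double_sum_exhaustively_small_n():
    """Literal formula equivalence over every pair of <=3-module labelings."""
    for n in (2, 3, 4):
        labelings = list(itertools.product(range(3), repeat=n))
        for u in labelings:
            for v in labelings:
                assert mutual_information(u, v) == pytest.approx(
                    mi_double_sum(u, v), abs=1e-12)


def test_mi_matches_double_sum_and_sklearn_at_n12():
    from sklearn.metrics import mutual_info_score

    rng = np.random.default_rng(12)
    for _ in range(300):
        u = rng.integers(0, 3, 12)
        v = rng.integers(0, 3, 12)
        mi = mutual_information(u, v)
        assert mi == pytest.approx(mi_double_sum(u, v), abs=1e-12)
        assert mi == pytest.approx(mutual_info_score(u, v), abs=1e-9)


def test_entropy_matches_direct():
    rng = np.random.default_rng(2)
    labels = rng.integers(0, 5, 200)
    assert entropy(labels) == pytest.approx(entropy_direct(labels), abs=1e-12)


def test_nmi_identical_nontrivial_labelings_is_one():
    u = np.repeat(np.arange(4), 25)
    assert normalized_mi(u, u) == 1.0


def test_nmi_zero_entropy_convention():
    u = np.zeros(100)
    v = np.repeat(np.arange(4), 25)
    assert normalized_mi(u, v) == 0.0
    assert normalized_mi(v, u) == 0.0


def test_nmi_independent_labels_near_zero():
    rng = np.random.default_rng(99)
    u = rng.integers(0, 4, 10_000)
    v = rng.integers(0, 4, 10_000)
    assert normalized_mi(u, v) < 0.01


@pytest.mark.parametrize("norm", ["arithmetic", "geometric", "min", "max"])
def test_nmi_agrees_with_sklearn(norm):
    from sklearn.metrics import normalized_mutual_info_score

    rng = np.random.default_rng(7)
    for _ in range(50):
        u = rng.integers(0, 4, 60)
        v = (u + rng.integers(0, 2, 60)) % 4  # partially dependent
        ours = normalized_mi(u, v, norm=norm)
        theirs = normalized_mutual_info_score(u, v, average_method=norm)
        assert ours == pytest.approx(theirs, abs=1e-9)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.integers(2, 50))
def test_mi_symmetry_bound_and_permutation_invariance(seed, n):
    rng = np.random.default_rng(seed)
    u = rng.integers(0, 4, n)
    v = rng.integers(0, 4, n)
    mi = mutual_information(u, v)
    assert mi == pytest.approx(mutual_information(v, u), abs=1e-12)
    assert mi <= min(entropy(u), entropy(v)) + 1e-12
    assert 0.0 <= normalized_mi(u, v) <= 1.0
    # relabeling modules changes nothing
    perm = rng.permutation(4)
    assert mutual_information(perm[u], v) == pytest.approx(mi, abs=1e-12)


def test_discretize_for_mi(grid38):
    assert len(set(discretize_for_mi(np.full(20, 0.2), grid38))) == 1
    labels = discretize_for_mi(np.array([0.1, 0.6]), grid38)
    assert labels.tolist() == [0, 1]
    rng = np.random.default_rng(0)
    expr = rng.uniform(0, 18.89, 500)
    labels = discretize_for_mi(expr, grid38)
    assert labels.size == 500


def test_edge_nmi_identical_columns_is_one(grid38):
    rng = np.random.default_rng(1)
    expr = np.concatenate([rng.normal(3, 0.5, 100), rng.normal(14, 0.5, 100)])
    expr = np.clip(expr, 0, 18.89)
    assert edge_nmi(expr, expr, grid38) == 1.0


def test_edge_nmi_constant_partner_is_zero(grid38):
    rng = np.random.default_rng(1)
    a = rng.uniform(0, 18.89, 100)
    b = np.full(100, 5.1)
    assert edge_nmi(a, b, grid38) == 0.0


def test_edge_nmi_two_cluster_constructions(grid38):
    """Two planted clusters: the score hinges on within-cluster coupling.

    With the within-cluster deviation shared by both genes the binned
    partitions determine each other and NMI is 1.  With independent
    per-gene noise of the same s.d. the within-cluster bins are
    uninformative and the NMI collapses to the cluster-indicator MI
    over the full bin entropy (~0.35 here) — far below the 0.97 edge
    threshold.  Frozen regression values.
    """
    rng = np.random.default_rng(42)
    a = np.concatenate([rng.normal(3, 0.5, 200), rng.normal(14, 0.5, 200)])
    b = np.concatenate([rng.normal(3, 0.5, 200), rng.normal(14, 0.5, 200)])
    independent = edge_nmi(a, b, grid38)
    assert independent == pytest.approx(0.3516518, abs=1e-6)

    latent = rng.normal(0, 0.5, 400)
    mu = np.repeat([3.0, 14.0], 200)
    shared = edge_nmi(mu + latent, mu + latent, grid38)
    assert shared == 1.0
    assert shared >= 0.97


def test_edge_nmi_swap_symmetry(grid38):
    rng = np.random.default_rng(3)
    a = rng.uniform(0, 18.89, 300)
    b = np.clip(a + rng.normal(0, 1, 300), 0, 18.89)
    assert edge_nmi(a, b, grid38) == pytest.approx(
        edge_nmi(b, a, grid38), abs=1e-12)


def test_edge_nmi_per_blob_mode(grid38):
    """Per-blob averaging scores each subpopulation separately."""
    rng = np.random.default_rng(8)
    latent = rng.normal(0, 0.5, 400)
    mu = np.repeat([3.0, 14.0], 200)
    expr = np.clip(mu + latent, 0, 18.89)
    img = normalize_image(bin_edge(expr, expr, grid38), log_compress=True)
    blobs = detect_blobs(img, "LoG")
    assert len(blobs) >= 2
    score = edge_nmi(expr, expr, grid38, mode="per_blob", blobs=blobs)
    assert 0.0 <= score <= 1.0
    # identical genes stay perfectly informative inside every blob
    assert score == pytest.approx(1.0)


def test_edge_nmi_per_blob_fallback_warns(grid38):
    from edgecrafting.blob_detection import Blob, BlobSet

    rng = np.random.default_rng(9)
    a = rng.uniform(0, 18.89, 50)
    empty = BlobSet("LoG", [Blob(row=0.0, col=0.0, sigma=0.5)])
    with pytest.warns(UserWarning, match="falling back"):
        score = edge_nmi(a, a, grid38, mode="per_blob", blobs=empty)
    assert score == edge_nmi(a, a, grid38)


def test_edge_nmi_input_validation(grid38):
    with pytest.raises(ValueError):
        edge_nmi(np.array([]), np.array([]), grid38)
    with pytest.raises(ValueError):
        edge_nmi(np.ones(3), np.ones(4), grid38)
    with pytest.raises(ValueError):
        edge_nmi(np.ones(10), np.ones(10), grid38, mode="per_blob")


def test_silhouette_two_tight_clusters():
    pts = np.array([[0.0], [0.1], [10.0], [10.1]])
    labels = [0, 0, 1, 1]
    s = silhouette(pts, labels)
    assert s == pytest.approx(0.98999975, abs=1e-8)
    assert s == pytest.approx(silhouette_direct(pts, labels), abs=1e-12)


def test_silhouette_coincident_clusters_is_zero():
    pts = np.array([[1.0, 1.0]] * 6)
    labels = [0, 0, 0, 1, 1, 1]
    assert silhouette(pts, labels) == 0.0


def test_silhouette_single_cluster_rejected():
    with pytest.raises(ValueError):
        silhouette(np.array([[0.0], [1.0]]), [0, 0])


def test_silhouette_matches_sklearn_and_stays_bounded():
    from sklearn.metrics import silhouette_score

    rng = np.random.default_rng(4)
    for _ in range(20):
        pts = rng.normal(size=(30, 2))
        labels = rng.integers(0, 3, 30)
        if len(set(labels.tolist())) < 2:
            continue
        s = silhouette(pts, labels)
        assert -1.0 <= s <= 1.0
        assert s == pytest.approx(silhouette_score(pts, labels), abs=1e-9)
        assert s == pytest.approx(silhouette_direct(pts, labels), abs=1e-9)


def test_mi_result_fields(grid38):
    u = np.repeat([0, 1], 30)
    res = mi_result(u, u)
    assert res.mi_raw == pytest.approx(math.log(2), abs=1e-12)
    assert res.h_u == res.h_v == pytest.approx(math.log(2), abs=1e-12)
    assert res.nmi == 1.0
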