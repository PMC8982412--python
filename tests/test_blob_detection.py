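import numpy as np
import pytest

from edgecrafting.blob_detection import (
    METHODS,
    DetectorConfig,
    count_multimodal_methods,
    detect_all_methods,
    detect_blobs,
    passes_blob_criterion,
    response_stack,
)

from conftest import gaussian_bump
from oracles import blob_maxima


@pytest.mark.parametrize("method", METHODS)
def test_zero_image_yields_no_blobs(method):
    assert len(detect_blobs(np.zeros((38, 38)), method)) == 0


def test_single_bump_recovered_by_log():
    img = gaussian_bump(38, [(19, 19)], sigma=3.0)
    blobs = detect_blobs(img, "LoG").blobs
    assert len(blobs) == 1
    assert abs(blobs[0].row - 19) <= 1 and abs(blobs[0].col - 19) <= 1


@pytest.mark.parametrize("method", ["LoG", "DoG"])
def test_two_bumps_recovered(method):
    img = gaussian_bump(38, [(9, 9), (28, 28)], sigma=2.5)
    blobs = detect_blobs(img, method).blobs
    assert len(blobs) == 2
    centers = sorted((b.row, b.col) for b in blobs)
    for found, true in zip(centers, [(9, 9), (28, 28)]):
        assert abs(found[0] - true[0]) <= 1 and abs(found[1] - true[1]) <= 1


@pytest.mark.parametrize("method", METHODS)
@pytest.mark.parametrize("image_id", ["one_bump", "two_bumps", "random"])
def test_scale_space_maxima_match_exhaustive_scan(method, image_id):
    """Detected (row, col, sigma) maxima equal a brute-force response scan.

    overlap=1.0 disables pruning so the raw candidate set is compared.
    """
    if image_id == "one_bump":
        img = gaussian_bump(40, [(20, 20)], sigma=3.0)
    elif image_id == "two_bumps":
        img = gaussian_bump(40, [(10, 10), (29, 29)], sigma=2.5)
    else:
        rng = np.random.default_rng(5)
        img = gaussian_bump(40, [(13, 26)], sigma=4.0)
        img += 0.2 * rng.random((40, 40))
        img /= img.max()
    cfg = DetectorConfig(min_sigma=1.5, max_sigma=6.0, num_sigma=5,
                         sigma_ratio=1.6, response_threshold=0.03,
                         overlap=1.0)
    found = {(b.row, b.col, b.sigma)
             for b in detect_blobs(img, method, cfg).blobs}
    _, sigmas = response_stack(img, method, cfg)
    if method == "DoG":
        # oracle needs the full smoothing ladder including the top sigma
        from edgecrafting.blob_detection import _dog_sigmas
        sigmas = _dog_sigmas(cfg, img.shape[0])
    expected = blob_maxima(img, method, np.asarray(sigmas), cfg.sigma_ratio,
                           cfg.response_threshold)
    assert len(found) == len(expected)
    for f in found:
        assert any(
            all(abs(x - y) < 1e-6 for x, y in zip(f, e)) for e in expected
        ), f"maximum {f} absent from brute-force scan"


@pytest.mark.parametrize("method", METHODS)
def test_orientation_invariance_of_detection(method):
    """Transposing the image transposes the blob list, so counts match."""
    rng = np.random.default_rng(7)
    img = gaussian_bump(38, [(8, 25), (27, 6)], sigma=2.5)
    img += 0.1 * rng.random((38, 38))
    img /= img.max()
    fwd = detect_blobs(img, method).blobs
    rev = detect_blobs(img.T, method).blobs
    assert len(fwd) == len(rev)
    assert sorted((b.row, b.col, b.sigma) for b in fwd) == sorted(
        (b.col, b.row, b.sigma) for b in rev)


def test_amplitude_monotonicity():
    """Dimming the image never adds blobs at a fixed absolute threshold."""
    img = gaussian_bump(38, [(9, 9), (28, 28)], sigma=2.5)
    counts = [
        len(detect_blobs(c * img, "LoG"))
        for c in (1.0, 0.7, 0.4, 0.2, 0.05)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_non_square_or_non_finite_rejected():
    with pytest.raises(ValueError):
        detect_blobs(np.zeros((10, 12)), "LoG")
    bad = np.zeros((10, 10))
    bad[3, 3] = np.nan
    with pytest.raises(ValueError):
        detect_blobs(bad, "LoG")
    with pytest.raises(ValueError):
        detect_blobs(np.zeros((10, 10)), "XYZ")


def test_detector_config_validation():
    with pytest.raises(ValueError):
        DetectorConfig(min_sigma=5, max_sigma=2)
    with pytest.raises(ValueError):
        DetectorConfig(num_sigma=1)
    with pytest.raises(ValueError):
        DetectorConfig(sigma_ratio=0.9)


def test_overlap_pruning_keeps_stronger_response():
    """Two nearby bumps of unequal height collapse to the taller one."""
    img = gaussian_bump(38, [(18, 18)], sigma=3.0, amplitude=1.0)
    img += gaussian_bump(38, [(21, 21)], sigma=3.0, amplitude=0.5)
    blobs = detect_blobs(img / img.max(), "LoG").blobs
    assert len(blobs) == 1
    assert abs(blobs[0].row - 18) <= 1.5 and abs(blobs[0].col - 18) <= 1.5


def _sets(counts):
    from edgecrafting.blob_detection import Blob, BlobSet

    return {
        m: BlobSet(m, [Blob(0, 0, 1.0)] * c)
        for m, c in zip(METHODS, counts)
    }


@pytest.mark.parametrize("counts, expected_n, passes", [
    ((2, 2, 1), 2, True),
    ((2, 1, 1), 1, False),
    ((0, 0, 0), 0, False),
    ((3, 2, 2), 3, True),
])
def test_multimodal_method_counting(counts, expected_n, passes):
    per_method, n_multi = count_multimodal_methods(_sets(counts))
    assert per_method == dict(zip(METHODS, counts))
    assert n_multi == expected_n
    assert passes_blob_criterion(n_multi) is passes


def test_missing_method_rejected():
    sets = _sets((2, 2, 2))
    del sets["DoH"]
    with pytest.raises(ValueError, match="missing"):
        count_multimodal_methods(sets)


def test_blob_criterion_monotone():
    assert passes_blob_criterion(3, 2)
    assert passes_blob_criterion(2, 2)
    assert not passes_blob_criterion(1, 2)
    with pytest.raises(ValueError):
        passes_blob_criterion(4, 2)


def test_cross_check_against_skimage():
    """skimage's LoG/DoG detectors agree on clean two-bump images."""
    skimage_feature = pytest.importorskip("skimage.feature")
    img = gaussian_bump(38, [(9, 9), (28, 28)], sigma=2.5)
    ours = detect_blobs(img, "LoG").blobs
    theirs = skimage_feature.blob_log(img, min_sigma=1, max_sigma=9.5,
                                      num_sigma=10, threshold=0.05)
    assert len(ours) == len(theirs) == 2
    ours_centers = sorted((b.row, b.col) for b in ours)
    their_centers = sorted((r, c) for r, c, _ in theirs)
    for (r1, c1), (r2, c2) in zip(ours_centers, their_centers):
        assert abs(r1 - r2) <= 1 and abs(c1 - c2) <= 1
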