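"""Fuzzy C-means correctness: closed forms, invariants, external oracle."""

import shutil
import subprocess

import numpy as np
import pytest

from gliograd.fuzzy import (
    FcmConfig,
    fcm_fit,
    fit_phase1,
    load_model,
    save_model,
    transform,
)
from gliograd.hog import HogConfig, extract_subject
from gliograd.preprocess import zscore_normalize
from gliograd.synthetic import CohortSpec, PhantomSpec, generate_cohort


def _two_gaussians(rng, n=20, dim=8, sep=10.0):
    a = rng.normal(0.0, 0.5, size=(n, dim))
    b = rng.normal(0.0, 0.5, size=(n, dim))
    b[:, 0] += sep
    return np.vstack([a, b])


def test_two_point_exact_fit():
    points = np.array([[0.0, 0.0], [4.0, 0.0]])
    res = fcm_fit(points, FcmConfig(K=2, seed=0))
    # centroids converge to the points themselves; coincidence rule applies
    order = np.argsort(res.centroids[:, 0])
    assert np.allclose(res.centroids[order], points, atol=1e-6)
    assert np.allclose(np.sort(res.memberships, axis=1)[:, 1], 1.0)
    assert res.objective == pytest.approx(0.0, abs=1e-9)


def test_equidistant_query_membership_is_half():
    from gliograd.fuzzy import _membership_from_d2

    rng = np.random.default_rng(0)
    points = _two_gaussians(rng, n=15, dim=2, sep=8.0)
    res = fcm_fit(points, FcmConfig(K=2, seed=1))
    mid = res.centroids.mean(axis=0)  # exactly equidistant from both
    d2 = np.sum((mid - res.centroids) ** 2, axis=1)
    u = _membership_from_d2(d2[None], fuzzifier=2.0)[0]
    assert np.allclose(u, [0.5, 0.5], atol=1e-9)


def test_memberships_match_closed_form_from_returned_centroids(rng):
    """u_ik = 1 / sum_j (d_ik/d_jk)^(2/(m-1)) recomputed independently."""
    points = _two_gaussians(rng, n=20, dim=8, sep=10.0)
    res = fcm_fit(points, FcmConfig(K=2, fuzzifier=2.0, tol=1e-9, seed=2))
    d = np.linalg.norm(points[:, None, :] - res.centroids[None], axis=2)
    oracle = 1.0 / np.sum((d[:, :, None] / d[:, None, :]) ** 2, axis=2)
    assert np.allclose(res.memberships, oracle, atol=1e-6)
    # hardened assignments recover the generating partition exactly
    hard = np.argmax(res.memberships, axis=1)
    truth = np.array([0] * 20 + [1] * 20)
    assert (hard == truth).all() or (hard == 1 - truth).all()


def test_objective_non_increasing_and_row_stochastic_on_20_problems():
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n, dim = rng.integers(6, 30), rng.integers(2, 10)
        points = rng.normal(size=(int(n), int(dim)))
        res = fcm_fit(points, FcmConfig(K=2, seed=seed, n_init=1))
        hist = np.array(res.objective_history)
        assert np.all(np.diff(hist) <= 1e-9), f"objective rose (seed {seed})"
        assert np.allclose(res.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert res.memberships.min() >= 0 and res.memberships.max() <= 1


def test_fewer_points_than_clusters_rejected():
    with pytest.raises(ValueError, match="K=2"):
        fcm_fit(np.zeros((1, 3)), FcmConfig(K=2))


def test_identical_points_flagged_degenerate():
    res = fcm_fit(np.ones((5, 3)), FcmConfig(K=2, seed=0))
    assert res.degenerate


def test_fixed_seed_reproducible(rng):
    points = rng.normal(size=(25, 6))
    a = fcm_fit(points, FcmConfig(seed=42))
    b = fcm_fit(points, FcmConfig(seed=42))
    assert np.array_equal(a.centroids, b.centroids)
    assert np.array_equal(a.memberships, b.memberships)


def test_low_fuzzifier_limit_agrees_with_kmeans(rng):
    """As the fuzzifier approaches 1, hardened FCM matches k-means."""
    from sklearn.cluster import KMeans

    points = _two_gaussians(rng, n=25, dim=4, sep=12.0)
    res = fcm_fit(points, FcmConfig(K=2, fuzzifier=1.05, seed=3))
    hard = np.argmax(res.memberships, axis=1)
    km = KMeans(n_clusters=2, n_init=5, random_state=0).fit(points)
    agree = np.mean(hard == km.labels_)
    assert agree in (0.0, 1.0)  # identical up to label swap


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not found")
def test_against_e1071_cmeans_oracle(tmp_path, rng):
    """Independent FCM implementation (R e1071) agrees on separated data."""
    points = _two_gaussians(rng, n=15, dim=3, sep=9.0)
    np.savetxt(tmp_path / "x.csv", points, delimiter=",")
    script = tmp_path / "fcm.R"
    script.write_text(
        'x <- as.matrix(read.csv("%s", header=FALSE))\n'
        "set.seed(1)\n"
        'fit <- e1071::cmeans(x, centers=2, m=2, iter.max=500, method="cmeans")\n'
        'write.csv(fit$centers, "%s", row.names=FALSE)\n'
        % (tmp_path / "x.csv", tmp_path / "centers.csv")
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    r_centers = np.loadtxt(tmp_path / "centers.csv", delimiter=",", skiprows=1)
    res = fcm_fit(points, FcmConfig(K=2, fuzzifier=2.0, tol=1e-9, seed=0))
    # align clusters by first coordinate; optima coincide on separated data
    ours = res.centroids[np.argsort(res.centroids[:, 0])]
    theirs = r_centers[np.argsort(r_centers[:, 0])]
    assert np.allclose(ours, theirs, atol=1e-3)


# ---------------------------------------------------------------- phase 1


def test_phase1_holds_one_centroid_set_per_position(detection_descriptors):
    descs, _ = detection_descriptors
    model = fit_phase1(descs, FcmConfig(seed=0))
    assert model.centroids.shape == (descs[0].n_positions, 2, 8)
    assert model.degenerate.shape == (descs[0].n_positions,)


def test_degenerate_position_gets_constant_half(detection_descriptors):
    import dataclasses

    descs, _ = detection_descriptors
    # force a position whose descriptor is identical in every subject
    forced = []
    for d in descs:
        h = d.histograms.copy()
        h[0] = np.arange(h.shape[1], dtype=float)
        forced.append(dataclasses.replace(d, histograms=h))
    model = fit_phase1(forced, FcmConfig(seed=0))
    assert model.degenerate[0]
    vec = transform(model, forced[0])
    assert vec.values[0] == 0.5


def test_transform_reproduces_training_memberships(detection_descriptors):
    """Soft transform of a training subject equals its training membership."""
    descs, _ = detection_descriptors
    config = FcmConfig(seed=0, tol=1e-9)
    model = fit_phase1(descs, config)
    subject = descs[2]
    vec = transform(model, subject, mode="soft")
    # recompute from frozen centroids with the membership formula
    diff = subject.histograms[:, None, :] - model.centroids
    d2 = np.sum(diff**2, axis=2)
    with np.errstate(divide="ignore"):
        inv = d2 ** (-1.0)
    co = d2 < 1e-24
    inv = np.where(co.any(axis=1, keepdims=True), co.astype(float), inv)
    expected = (inv / inv.sum(axis=1, keepdims=True))[:, 0]
    expected[model.degenerate] = 0.5
    assert np.allclose(vec.values, expected, atol=1e-6)


def test_transform_exact_centroid_membership_one(detection_descriptors):
    descs, _ = detection_descriptors
    model = fit_phase1(descs, FcmConfig(seed=0))
    p = int(np.flatnonzero(~model.degenerate)[0])
    fake = descs[0].histograms.copy()
    fake[p] = model.centroids[p, 0]
    import dataclasses

    subject = dataclasses.replace(descs[0], histograms=fake)
    soft = transform(model, subject, mode="soft")
    hard = transform(model, subject, mode="hard")
    assert soft.values[p] == pytest.approx(1.0)
    assert hard.values[p] == 1.0


def test_transform_grid_mismatch_rejected(detection_cohort):
    volumes, _, _ = detection_cohort
    big = [extract_subject(zscore_normalize(v), HogConfig(cell_size=10))
           for v in volumes]
    small = extract_subject(zscore_normalize(volumes[0]), HogConfig(cell_size=20))
    model = fit_phase1(big, FcmConfig(seed=0))
    with pytest.raises(ValueError):
        transform(model, small)


def test_lesion_covered_position_separates_classes():
    """Hardened memberships at a lesion-center cell track the true labels."""
    base = PhantomSpec(lesion_present=True)
    cohort = CohortSpec(
        n_per_class=10, task="detection", base_spec=base, seed=17,
        center_jitter=0.0, radius_jitter=0.0,  # fixed lesion position
    )
    volumes, specs = generate_cohort(cohort)
    config = HogConfig(cell_size=10)
    descs = [extract_subject(zscore_normalize(v), config) for v in volumes]
    labels = np.array([v.label for v in volumes])
    model = fit_phase1(descs, FcmConfig(seed=1))
    # position of the cell at the lesion center: slice 5, row 2, col 2
    p = np.ravel_multi_index((5, 2, 2), descs[0].grid)
    values = np.array([transform(model, d).values[p] for d in descs])
    hard = (values > 0.5).astype(int)
    agreement = max(np.mean(hard == labels), np.mean(hard == 1 - labels))
    assert agreement >= 0.9


def test_model_roundtrip_serialization(tmp_path, detection_descriptors):
    descs, _ = detection_descriptors
    model = fit_phase1(descs, FcmConfig(seed=0))
    path = tmp_path / "phase1.npz"
    save_model(model, path)
    loaded = load_model(path)
    assert np.array_equal(loaded.centroids, model.centroids)
    assert np.array_equal(loaded.degenerate, model.degenerate)
    assert loaded.fcm_config == model.fcm_config
    assert loaded.grid == model.grid
    vec_a = transform(model, descs[0])
    vec_b = transform(loaded, descs[0])
    assert np.array_equal(vec_a.values, vec_b.values)
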