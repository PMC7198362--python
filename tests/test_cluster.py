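"""k-means first pass, centroid matching, silhouettes."""

import itertools

import numpy as np
import pytest
from sklearn.cluster import KMeans

from bstemseg.cluster import (
    ClusterModel,
    kmeans_firstpass,
    labels_to_binary_maps,
    match_centroids,
    silhouette_values,
)
from bstemseg.extract import ChannelStack, standardize
from bstemseg.image import VolumetricImage


def _stack_from_values(values):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    side = int(np.ceil(n ** (1 / 3))) + 1
    idx = np.array(list(np.ndindex(side, side, side))[:n])
    mask = np.zeros((side, side, side))
    mask[tuple(idx.T)] = 1.0
    grid = VolumetricImage(mask)
    return standardize(
        ChannelStack(idx, values, None, grid, tuple(f"c{i}" for i in range(values.shape[1])))
    )


def _blobs(k, n_per, sep, sd=1.0, seed=0, dim=3):
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, 1, (k, dim))
    centers = sep * centers / np.linalg.norm(centers, axis=1, keepdims=True)
    x = np.concatenate([c + sd * rng.normal(0, 1, (n_per, dim)) for c in centers])
    labels = np.repeat(np.arange(1, k + 1), n_per)
    return x, labels


def test_single_cluster_centroid_is_channel_mean():
    x, _ = _blobs(1, 60, 0.0, seed=1)
    stack = _stack_from_values(x)
    model = kmeans_firstpass(stack, k=1, replicates=2, seed=0)
    assert set(model.labels) == {1}
    assert np.allclose(model.centroids[0], stack.zscores.mean(axis=0), atol=1e-9)


def test_well_separated_blobs_recovered_exactly_and_deterministically():
    x, truth = _blobs(6, 60, sep=10.0, sd=0.1, seed=2)
    stack = _stack_from_values(x)
    a = kmeans_firstpass(stack, replicates=5, seed=42)
    b = kmeans_firstpass(stack, replicates=5, seed=42)
    assert np.array_equal(a.labels, b.labels)
    assert np.allclose(a.centroids, b.centroids)
    # recovery up to permutation: every predicted cluster is pure
    for c in range(1, 7):
        members = truth[a.labels == c]
        assert members.size > 0 and np.unique(members).size == 1
    assert a.cluster_sizes().min() > 0
    assert np.all(a.distances >= 0)


def test_lloyd_inertia_never_increases_across_iterations():
    x, _ = _blobs(4, 120, sep=2.0, sd=1.0, seed=3)
    stack = _stack_from_values(x)
    init = stack.zscores[:4].copy()
    inertias = []
    for max_iter in range(1, 8):
        km = KMeans(4, init=init, n_init=1, max_iter=max_iter, tol=0.0, algorithm="lloyd").fit(
            stack.zscores
        )
        inertias.append(km.inertia_)
    assert all(a >= b - 1e-9 for a, b in zip(inertias, inertias[1:]))


def test_match_centroids_recovers_constructed_permutation():
    x, _ = _blobs(6, 50, sep=8.0, sd=0.2, seed=4)
    stack = _stack_from_values(x)
    ref = kmeans_firstpass(stack, replicates=3, seed=0)
    # subject = reference -> identity
    same = match_centroids(ref, ref)
    assert np.array_equal(same.labels, ref.labels)
    # permuted reference centroids are un-permuted
    perm = np.array([2, 0, 1, 5, 3, 4])
    subject = ClusterModel(
        k=6,
        centroids=ref.centroids[perm],
        labels=np.argsort(perm)[ref.labels - 1] + 1,
        distances=ref.distances.copy(),
        inertia=ref.inertia,
    )
    matched = match_centroids(subject, ref)
    assert np.allclose(matched.centroids, ref.centroids)
    assert np.array_equal(matched.labels, ref.labels)
    # stability: small centroid noise does not change the assignment
    noisy = ClusterModel(
        k=6,
        centroids=ref.centroids[perm] + 0.01,
        labels=subject.labels,
        distances=ref.distances.copy(),
        inertia=ref.inertia,
    )
    assert np.allclose(match_centroids(noisy, ref).centroids, ref.centroids, atol=0.02)


def test_match_centroids_beats_every_other_permutation():
    rng = np.random.default_rng(5)
    ref_c = rng.normal(0, 1, (6, 3))
    sub_c = ref_c[rng.permutation(6)] + rng.normal(0, 0.05, (6, 3))
    ref = ClusterModel(6, ref_c, np.arange(1, 7), np.zeros(6), 0.0)
    sub = ClusterModel(6, sub_c, np.arange(1, 7), np.zeros(6), 0.0)
    matched = match_centroids(sub, ref)
    best = np.linalg.norm(matched.centroids - ref_c, axis=1).sum()
    for perm in itertools.permutations(range(6)):  # exhaustive: 720 cases
        cost = np.linalg.norm(sub_c[list(perm)] - ref_c, axis=1).sum()
        assert best <= cost + 1e-9


def test_binary_maps_partition_the_tissue_mask():
    x, _ = _blobs(6, 50, sep=6.0, sd=0.3, seed=6)
    stack = _stack_from_values(x)
    model = kmeans_firstpass(stack, replicates=3, seed=1)
    maps = labels_to_binary_maps(model, stack)
    total = sum(m.data for m in maps)
    assert np.array_equal(total > 0, stack.grid.data > 0)
    counts = [int(m.data.sum()) for m in maps]
    assert counts == list(np.bincount(model.labels, minlength=7)[1:])


def test_silhouettes_match_direct_oracle_and_bounds():
    x, _ = _blobs(3, 80, sep=4.0, sd=0.8, seed=7)
    stack = _stack_from_values(x)
    model = kmeans_firstpass(stack, k=3, replicates=3, seed=2)
    s = silhouette_values(stack, model)
    assert np.all(s >= -1) and np.all(s <= 1)
    # direct O(n^2) oracle
    z = stack.zscores
    d = np.linalg.norm(z[:, None, :] - z[None, :, :], axis=2)
    oracle = np.empty(len(stack))
    for i in range(len(stack)):
        own = model.labels == model.labels[i]
        a = d[i, own].sum() / max(own.sum() - 1, 1)
        b = min(
            d[i, model.labels == c].mean()
            for c in range(1, 4)
            if c != model.labels[i]
        )
        oracle[i] = (b - a) / max(a, b)
    assert np.allclose(s, oracle, atol=1e-9)


def test_silhouette_separation_extremes():
    x, _ = _blobs(2, 100, sep=30.0, sd=0.3, seed=8)
    stack = _stack_from_values(x)
    model = kmeans_firstpass(stack, k=2, replicates=3, seed=3)
    assert silhouette_values(stack, model).min() > 0.9
    # one blob split arbitrarily into two labels -> mean near or below 0
    rng = np.random.default_rng(9)
    one = rng.normal(0, 1, (200, 3))
    stack1 = _stack_from_values(one)
    labels = np.where(rng.random(200) < 0.5, 1, 2).astype(np.int16)
    model1 = ClusterModel(
        2,
        np.stack([stack1.zscores[labels == c].mean(axis=0) for c in (1, 2)]),
        labels,
        np.zeros(200),
        0.0,
    )
    assert silhouette_values(stack1, model1).mean() < 0.1
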