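"""Correlation-distance K-means segmentation of pooled cohort pixels.

Spectra are row-standardised (zero mean, unit norm), under which squared
Euclidean distance equals twice the correlation distance, so Lloyd's
algorithm on standardised rows minimises total correlation distance.
Pixels from all patients are pooled before clustering so subpopulation
labels are comparable across the cohort.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from msihetero.types import ClusterComposition, PatientDatacube, SegmentationResult

logger = logging.getLogger(__name__)

__all__ = [
    "correlation_distance",
    "kmeans_correlation",
    "segment_cohort",
    "composition",
    "compositions",
]


def correlation_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - Pearson correlation of two intensity vectors; range [0, 2]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("vectors must have length >= 3")
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    ac = a - a.mean()
    bc = b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0 or nb == 0:
        raise ValueError("correlation distance undefined for constant vectors")
    return float(1.0 - (ac @ bc) / (na * nb))


def standardize_rows(X: np.ndarray) -> np.ndarray:
    """Centre each row to mean 0 and scale to unit Euclidean norm."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    if np.any(norms == 0):
        raise ValueError("rows with zero variance cannot be standardised")
    return Xc / norms[:, None]


def _corr_dist_to_centroids(Xs: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Correlation distance of each standardised row to each centroid."""
    C = centroids - centroids.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(C, axis=1)
    norms[norms == 0] = np.inf  # degenerate centroid: infinitely far
    return 1.0 - (Xs @ C.T) / norms[None, :]


def _lloyd(Xs: np.ndarray, k: int, rng: np.random.Generator, max_iter: int):
    n = Xs.shape[0]
    centroids = Xs[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d = _corr_dist_to_centroids(Xs, centroids)
        new_labels = np.argmin(d, axis=1)
        # repair empty clusters by reseeding from the farthest point
        for c in range(k):
            if not np.any(new_labels == c):
                far = int(np.argmax(d[np.arange(n), new_labels]))
                centroids[c] = Xs[far]
                new_labels[far] = c
                d[:, c] = _corr_dist_to_centroids(Xs, centroids[c : c + 1])[:, 0]
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = Xs[labels == c].mean(axis=0)
    inertia = float(_corr_dist_to_centroids(Xs, centroids)[np.arange(n), labels].sum())
    return labels, centroids, inertia


def kmeans_correlation(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float]:
    """K-means under correlation distance.

    Returns ``(labels, centroids, inertia)``: 1-based labels renumbered by
    descending cluster size, centroids (in standardised space) in that
    order, and the summed correlation distance to assigned centroids.
    Deterministic given ``seed``; best of ``n_init`` random initialisations.
    """
    X = np.asarray(X, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {X.shape[0]}")
    Xs = standardize_rows(X)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        labels, centroids, inertia = _lloyd(Xs, k, rng, max_iter)
        if best is None or inertia < best[2]:
            best = (labels, centroids, inertia)
    labels, centroids, inertia = best
    # renumber by descending global size for reproducible reporting
    sizes = np.bincount(labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[labels] + 1, centroids[order], inertia


def _pool(cubes: Sequence[PatientDatacube]):
    """Pool pixel spectra across patients, dropping zero-variance pixels.

    Patients are sorted by id so the pooled matrix (and hence the
    clustering) is invariant to input order.
    """
    cubes = sorted(cubes, key=lambda c: c.patient_id)
    blocks, keeps = [], {}
    n_dropped = 0
    for c in cubes:
        var_ok = c.intensities.std(axis=1) > 0
        n_dropped += int((~var_ok).sum())
        keeps[c.patient_id] = var_ok
        blocks.append(c.intensities[var_ok])
    if n_dropped:
        logger.info("dropped %d zero-variance pixel(s) before clustering", n_dropped)
    X = np.vstack(blocks)
    sizes = [b.shape[0] for b in blocks]
    return cubes, X, sizes, keeps, n_dropped


def segment_cohort(
    cubes: Sequence[PatientDatacube],
    k_range: Iterable[int] = range(2, 11),
    seed: int = 0,
    n_init: int = 10,
) -> dict[int, SegmentationResult]:
    """Cluster the pooled cohort once per K in ``k_range``."""
    ch = cubes[0].channels if len(cubes) else None
    for c in cubes:
        if not np.allclose(c.channels, ch):
            raise ValueError("all datacubes must share identical channels")
    cubes_sorted, X, sizes, keeps, n_dropped = _pool(cubes)
    results: dict[int, SegmentationResult] = {}
    for k in k_range:
        labels, centroids, inertia = kmeans_correlation(X, k, seed=seed, n_init=n_init)
        per_patient: dict[str, np.ndarray] = {}
        start = 0
        for c, n in zip(cubes_sorted, sizes):
            lab = np.zeros(c.n_pixels, dtype=int)
            lab[keeps[c.patient_id]] = labels[start : start + n]
            if not keeps[c.patient_id].all():
                # dropped pixels inherit the patient's modal label
                vals, counts = np.unique(labels[start : start + n], return_counts=True)
                lab[~keeps[c.patient_id]] = vals[np.argmax(counts)]
            per_patient[c.patient_id] = lab
            start += n
        results[k] = SegmentationResult(
            k=k,
            labels=per_patient,
            centroids=centroids,
            inertia=inertia,
            n_dropped_pixels=n_dropped,
        )
    return results


def composition(seg: SegmentationResult, patient_id: str) -> ClusterComposition:
    """Fraction of a patient's pixels in each subpopulation."""
    if patient_id not in seg.labels:
        raise KeyError(f"patient {patient_id!r} not present in segmentation")
    lab = seg.labels[patient_id]
    counts = np.bincount(lab - 1, minlength=seg.k)
    return ClusterComposition(patient_id, counts / lab.size, int(lab.size))


def compositions(seg: SegmentationResult) -> list[ClusterComposition]:
    return [composition(seg, pid) for pid in sorted(seg.labels)]
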