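"""Unsupervised validation of SNP panels: distances, MDS, k-means.

A panel that separates the subspecies should place plains and wood animals
in distinct clusters of the genotype (allele-count) space.  This module
computes Euclidean dosage distances with an explicit missing-data policy,
embeds them with classical (Torgerson) multidimensional scaling, partitions
samples with seeded multi-start k-means, and cross-tabulates clusters
against subspecies labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SampleRecord


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.values < 0).any() or not np.allclose(np.diag(self.values), 0):
            raise ValueError("distances must be non-negative with zero diagonal")


@dataclass
class ClusterAssignment:
    sample_ids: list[str]
    labels: np.ndarray  # cluster labels in 1..k
    wss: float
    k: int


def _impute_column_means(dos: np.ndarray) -> np.ndarray:
    X = dos.astype(float)
    mask = dos == MISSING
    if mask.any():
        means = np.where(mask, np.nan, X).mean(axis=0, where=~mask)
        means = np.nan_to_num(means, nan=0.0)
        X = np.where(mask, means[None, :], X)
    return X


def genotype_distance(
    gm: GenotypeMatrix,
    missing_policy: Literal["pairwise_scaled", "mean_impute"] = "pairwise_scaled",
) -> DistanceMatrix:
    """Euclidean distance between samples on dosage vectors.

    ``pairwise_scaled`` computes squared distance over co-called loci and
    rescales by ``m / m_co_called`` before the square root, so samples with
    different missingness stay comparable; ``mean_impute`` fills missing
    dosages with the locus mean first.  A pair with no co-called loci is an
    error naming the pair.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    m = gm.n_loci
    if missing_policy == "mean_impute":
        X = _impute_column_means(gm.dosages)
        sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2) if gm.n_samples <= 64 else None
        if sq is None:
            from scipy.spatial.distance import squareform, pdist

            return DistanceMatrix(list(gm.sample_ids), squareform(pdist(X)))
        return DistanceMatrix(list(gm.sample_ids), np.sqrt(sq))

    if missing_policy != "pairwise_scaled":
        raise ValueError(f"unknown missing_policy: {missing_policy!r}")

    W = (gm.dosages != MISSING).astype(float)
    X = np.where(W > 0, gm.dosages, 0).astype(float)
    # sum over co-called loci of (xi - xj)^2, via the cross-term expansion
    X2 = X * X
    sq = X2 @ W.T + W @ X2.T - 2.0 * (X @ X.T)
    m_co = W @ W.T
    if (m_co == 0).any():
        i, j = np.argwhere((m_co == 0) & ~np.eye(gm.n_samples, dtype=bool))[0]
        raise ValueError(
            f"no co-called loci for pair ({gm.sample_ids[i]}, {gm.sample_ids[j]})"
        )
    sq_scaled = sq * (m / m_co)
    np.fill_diagonal(sq_scaled, 0.0)
    return DistanceMatrix(list(gm.sample_ids), np.sqrt(np.maximum(sq_scaled, 0.0)))


class MDSResult(NamedTuple):
    coordinates: np.ndarray  # samples x k
    eigenvalues: np.ndarray  # all eigenvalues, descending


def classical_mds(D: DistanceMatrix, k: int = 2) -> MDSResult:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centres ``-D^2 / 2``, eigendecomposes, and returns the top-``k``
    coordinate axes scaled by the square root of their eigenvalues.  Axes
    are defined up to sign; for reproducibility the first nonzero loading of
    each axis is forced positive.  If fewer than ``k`` eigenvalues are
    positive the embedding is truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    A = -0.5 * D.values**2
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(n, 1) * np.finfo(float).eps * max(abs(evals[0]), 1.0)
    n_pos = int((evals > tol).sum())
    if k > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating embedding from {k}",
            stacklevel=2,
        )
        k = max(n_pos, 1)
    coords = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    return MDSResult(coordinates=coords, eigenvalues=evals)


def kmeans_cluster(
    data: np.ndarray | GenotypeMatrix,
    k: int = 2,
    n_starts: int = 25,
    seed: int | None = None,
    sample_ids: Sequence[str] | None = None,
) -> ClusterAssignment:
    """Multi-start k-means partition minimising within-cluster SS.

    Accepts MDS coordinates (or any numeric matrix) or a
    :class:`GenotypeMatrix` (missing dosages mean-imputed).  The best of
    ``n_starts`` seeded runs by within-cluster sum of squares is returned;
    labels are 1-based."""
    if isinstance(data, GenotypeMatrix):
        sample_ids = list(data.sample_ids)
        X = _impute_column_means(data.dosages)
    else:
        X = np.asarray(data, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        sample_ids = list(sample_ids) if sample_ids is not None else [
            f"s{i}" for i in range(X.shape[0])
        ]
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    if k == 1:
        centroid = X.mean(axis=0)
        wss = float(((X - centroid) ** 2).sum())
        return ClusterAssignment(sample_ids, np.ones(n, dtype=int), wss, 1)

    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
    labels = km.fit_predict(X) + 1
    return ClusterAssignment(sample_ids, labels, float(km.inertia_), k)


class ConcordanceResult(NamedTuple):
    table: pd.DataFrame  # cluster x subspecies_label counts
    composition: pd.DataFrame  # per-cluster label fractions


def label_concordance(
    assignment: ClusterAssignment,
    sample_metadata: Sequence[SampleRecord],
    min_confidence: int = 2,
) -> ConcordanceResult:
    """Cross-tabulate clusters against subspecies labels.

    Restricted to samples whose label confidence is at or better than
    ``min_confidence`` (1 = absolutely confident, 4 = none)."""
    meta = {r.sample_id: r for r in sample_metadata}
    rows = [
        (int(lab), meta[sid].subspecies_label)
        for sid, lab in zip(assignment.sample_ids, assignment.labels)
        if sid in meta and meta[sid].confidence_level <= min_confidence
    ]
    if not rows:
        raise ValueError("no labelled samples at the required confidence")
    df = pd.DataFrame(rows, columns=["cluster", "subspecies_label"])
    table = pd.crosstab(df["cluster"], df["subspecies_label"])
    composition = table.div(table.sum(axis=1), axis=0)
    return ConcordanceResult(table=table, composition=composition)
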