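"""Nearest-centroid (Voronoi) analyte classifier in 2D principal-component space.

The classifier is the labeled set of k-means cluster centers together
with the PCA transform fitted on the surviving sensors. Decision regions
are the Voronoi cells of the centers (boundaries are perpendicular
bisectors). Classifier quality is summarized by the mean intercluster
distance ⟨D⟩ and by the classification error: the probability mass of
each cluster's fitted 2D Gaussian falling outside its own cell,
averaged over clusters with equal priors, estimated by Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import ClusterModel, PCAModel, project
from .errors import ValidationError

__all__ = [
    "VoronoiClassifier",
    "ClassificationResult",
    "build_classifier",
    "intercluster_distance",
    "classification_error",
    "classify_sample",
]


def intercluster_distance(centers: np.ndarray) -> tuple[np.ndarray, float]:
    """Pairwise Euclidean distances between cluster centers and their
    unordered-pair mean ⟨D⟩."""
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 2 or centers.shape[0] < 2:
        raise ValidationError("need at least 2 centers")
    condensed = pdist(centers)
    return squareform(condensed), float(condensed.mean())


@dataclass
class VoronoiClassifier:
    """Labeled centers + attached PCA transform.

    Centers are stored in analyte-name order so that index order doubles
    as the deterministic tie-break.
    """

    centers: np.ndarray  # (k, 2), analyte-name order
    labels: tuple[str, ...]
    pca: PCAModel
    sensor_ids: tuple[str, ...]
    gaussian_means: np.ndarray  # (k, 2)
    gaussian_covs: np.ndarray  # (k, 2, 2)
    distance_matrix: np.ndarray = field(init=False)
    mean_intercluster_distance: float = field(init=False)
    classification_error: float | None = None
    error_se: float | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        D, Dmean = intercluster_distance(self.centers)
        dup = [
            (self.labels[i], self.labels[j])
            for i in range(len(self.labels))
            for j in range(i + 1, len(self.labels))
            if D[i, j] == 0.0
        ]
        if dup:
            raise ValidationError(f"coincident cluster centers for analytes: {dup}")
        self.distance_matrix = D
        self.mean_intercluster_distance = Dmean

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    def assign(self, points: np.ndarray) -> np.ndarray:
        """Index of the nearest center; ties go to the lower index
        (alphabetically first analyte)."""
        pts = np.atleast_2d(np.asarray(points, float))
        d2 = ((pts[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


def build_classifier(
    clusters: ClusterModel, pca: PCAModel, sensor_ids: Sequence[str]
) -> VoronoiClassifier:
    """Assemble the Voronoi classifier from a label-matched cluster model."""
    if clusters.label_map is None:
        raise ValidationError("cluster labels must be matched before building")
    if clusters.gaussian_means is None or clusters.gaussian_covs is None:
        raise ValidationError("cluster Gaussians must be fitted before building")
    order = sorted(range(clusters.k), key=lambda i: clusters.label_map[i])
    labels = tuple(clusters.label_map[i] for i in order)
    return VoronoiClassifier(
        centers=clusters.centers[order],
        labels=labels,
        pca=pca,
        sensor_ids=tuple(sensor_ids),
        gaussian_means=clusters.gaussian_means[order],
        gaussian_covs=clusters.gaussian_covs[order],
    )


def classification_error(
    classifier: VoronoiClassifier,
    gaussians: tuple[np.ndarray, np.ndarray] | None = None,
    n_mc: int = 1_000_000,
    seed: int = 0,
    jitter: float = 1e-10,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the Gaussian/Voronoi overlap error.

    For each cluster, ``n_mc`` draws from its fitted Gaussian are assigned
    to the nearest center; the error is the unweighted mean (equal analyte
    priors) of the per-cluster fractions landing in a foreign cell.
    Singular covariances are regularized by adding ``jitter``·I.

    Returns ``(error, standard_error)``.
    """
    if gaussians is not None:
        means, covs = gaussians
    else:
        means, covs = classifier.gaussian_means, classifier.gaussian_covs
    means = np.asarray(means, float)
    covs = np.asarray(covs, float)
    rng = np.random.default_rng(seed)
    k = classifier.k
    errs = np.zeros(k)
    var_sum = 0.0
    for i in range(k):
        cov = covs[i]
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            L = np.linalg.cholesky(cov + jitter * np.eye(2))
        draws = means[i] + rng.standard_normal((n_mc, 2)) @ L.T
        p = float(np.mean(classifier.assign(draws) != i))
        errs[i] = p
        var_sum += p * (1.0 - p) / n_mc
    error = float(errs.mean())
    se = float(np.sqrt(var_sum) / k)
    return error, se


@dataclass(frozen=True)
class ClassificationResult:
    label: str
    coords: np.ndarray
    distances: dict[str, float]
    tie: bool


def classify_sample(
    classifier: VoronoiClassifier,
    response_vector: Mapping[str, float] | Sequence[float],
) -> ClassificationResult:
    """Classify one unknown sample from its raw sensor responses.

    The vector (a mapping sensor id → response, or a sequence in the
    classifier's sensor order) is projected through the attached PCA
    transform; the nearest center's analyte is returned together with
    the distances to all centers. Exact ties are broken by analyte name
    order and flagged.
    """
    if isinstance(response_vector, Mapping):
        missing = [s for s in classifier.sensor_ids if s not in response_vector]
        if missing:
            raise ValidationError(f"missing sensor responses: {missing}")
        row = np.array([float(response_vector[s]) for s in classifier.sensor_ids])
    else:
        row = np.asarray(response_vector, dtype=float)
        if row.shape != (len(classifier.sensor_ids),):
            raise ValidationError(
                f"expected {len(classifier.sensor_ids)} responses, got {row.shape}"
            )
    coords = project(classifier.pca, row)
    d = np.sqrt(((classifier.centers - coords) ** 2).sum(axis=1))
    best = int(d.argmin())
    tie = bool(np.sum(np.isclose(d, d[best], rtol=0, atol=1e-12)) > 1)
    distances = {lab: float(di) for lab, di in zip(classifier.labels, d)}
    return ClassificationResult(label=classifier.labels[best],
                                coords=np.atleast_1d(coords), distances=distances,
                                tie=tie)
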