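"""Core of the analyte classification and feature selection algorithm (ACFSA).

A fluorescence sensor array screen yields a table of relative responses
(ΔI/I₀) of many sensors to a panel of analytes, measured in replicates.
The ACFSA iteratively shrinks the sensor set: at every iteration the
surviving responses are reduced to two principal components, partitioned
by k-means into one cluster per analyte, matched to analyte names by the
Kuhn-Munkres assignment, scored with the adjusted Rand index, and the
sensor whose discretized responses associate least with the cluster
labels (Pearson chi-squared on a 10-bin contingency table) is dropped.
Each surviving set also receives a nearest-centroid (Voronoi) classifier
whose expected misclassification rate is estimated from per-cluster
Gaussian fits; see :mod:`acfsa.classifier`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import chi2 as chi2_dist
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .errors import ValidationError

__all__ = [
    "ResponseTable",
    "PCAModel",
    "ClusterModel",
    "Ellipse",
    "StoppingCondition",
    "ACFSAConfig",
    "IterationRecord",
    "EliminationTrace",
    "fit_pca",
    "project",
    "kmeans_cluster",
    "fit_cluster_gaussians",
    "match_cluster_labels",
    "adjusted_rand_index",
    "confidence_ellipse",
    "chi_squared_scores",
    "eliminate_lowest",
    "binarize_responses",
    "run_acfsa",
]


# ---------------------------------------------------------------------------
# Response table


@dataclass(frozen=True)
class ResponseTable:
    """Samples × sensors matrix of relative fluorescence responses ΔI/I₀.

    ``data`` is a wide DataFrame: one row per (analyte, replicate) sample
    (a two-level index) and one column per sensor id.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.nlevels != 2:
            raise ValidationError(
                "ResponseTable rows must be indexed by (analyte, replicate)"
            )
        if df.columns.has_duplicates:
            dups = sorted(df.columns[df.columns.duplicated()].unique())
            raise ValidationError(f"duplicate sensor ids: {dups}")
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate (analyte, replicate) rows: {dups}")
        vals = df.to_numpy(dtype=float)
        if vals.size and not np.isfinite(vals).all():
            raise ValidationError("responses must be finite numbers")

    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        sensor_ids: Sequence[str],
        analytes: Sequence[str],
        replicates: Sequence[int],
    ) -> "ResponseTable":
        idx = pd.MultiIndex.from_arrays(
            [list(analytes), list(replicates)], names=["analyte", "replicate"]
        )
        df = pd.DataFrame(np.asarray(values, dtype=float), index=idx,
                          columns=list(sensor_ids))
        return cls(df)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def sensor_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def analyte_labels(self) -> np.ndarray:
        """Per-row ground-truth analyte label."""
        return self.data.index.get_level_values("analyte").to_numpy()

    @property
    def replicate_index(self) -> np.ndarray:
        return self.data.index.get_level_values("replicate").to_numpy()

    @property
    def analytes(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.analyte_labels:
            seen.setdefault(str(a))
        return list(seen)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    def select_sensors(self, sensor_ids: Sequence[str]) -> "ResponseTable":
        missing = [s for s in sensor_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown sensor ids: {missing}")
        return ResponseTable(self.data.loc[:, list(sensor_ids)])

    def check_complete(self) -> None:
        """Require every (analyte, replicate) cell for every sensor."""
        analytes = self.analytes
        reps = sorted(set(self.replicate_index.tolist()))
        expected = {(a, r) for a in analytes for r in reps}
        present = set(self.data.index.tolist())
        missing = sorted(expected - present)
        if missing:
            raise ValidationError(f"missing (analyte, replicate) cells: {missing}")


def binarize_responses(table: ResponseTable, dead_band: float = 0.0) -> ResponseTable:
    """Map responses to ±1: turn-on (+1) vs turn-off (−1).

    Responses with ``|value| < dead_band`` count as no significant change
    and map to +1; exactly zero maps to +1 under the default dead band.
    """
    v = table.values
    signs = np.where((v <= -dead_band) & (v < 0), -1.0, 1.0)
    return ResponseTable(pd.DataFrame(signs, index=table.data.index,
                                      columns=table.data.columns))


# ---------------------------------------------------------------------------
# PCA


@dataclass(frozen=True)
class PCAModel:
    """Two-component PCA of a response table.

    ``loadings`` has shape (2, n_sensors). For a single-sensor table the
    second component is a zero (zero-variance) axis so that downstream 2D
    geometry still applies; ``degenerate`` flags that case.
    """

    mean: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    degenerate: bool = False

    @property
    def n_sensors(self) -> int:
        return self.mean.shape[0]


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    # deterministic sign: largest-|.| coefficient of each component positive
    out = loadings.copy()
    for i in range(out.shape[0]):
        row = out[i]
        if row.any():
            j = int(np.argmax(np.abs(row)))
            if row[j] < 0:
                out[i] = -row
    return out


def fit_pca(table: ResponseTable | np.ndarray, standardize: bool = False) -> PCAModel:
    """Mean-centered PCA retaining the top two components.

    ``standardize=True`` additionally scales each sensor to unit variance
    before the decomposition (off by default: responses share the same
    dimensionless ΔI/I₀ scale).
    """
    X = table.values if isinstance(table, ResponseTable) else np.asarray(table, float)
    if X.ndim != 2:
        raise ValidationError("expected a 2D samples × sensors array")
    n, p = X.shape
    if n < 3:
        raise ValidationError(f"PCA needs at least 3 samples, got {n}")
    mean = X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        scale = np.where(sd > 0, sd, 1.0)
    else:
        scale = np.ones(p)
    Z = (X - mean) / scale

    if p == 1:
        var = float(np.var(Z[:, 0], ddof=1))
        return PCAModel(
            mean=mean,
            scale=scale,
            loadings=np.array([[1.0], [0.0]]),
            explained_variance=np.array([var, 0.0]),
            explained_variance_ratio=np.array([1.0 if var > 0 else 0.0, 0.0]),
            degenerate=True,
        )

    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(Z)
    return PCAModel(
        mean=mean,
        scale=scale,
        loadings=_fix_signs(pca.components_),
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def project(model: PCAModel, rows: np.ndarray) -> np.ndarray:
    """Project raw response rows into the 2D principal-component space.

    Applies unchanged to unknown samples: (row − training mean) · loadings.
    """
    rows = np.asarray(rows, dtype=float)
    single = rows.ndim == 1
    rows = np.atleast_2d(rows)
    if rows.shape[1] != model.n_sensors:
        raise ValidationError(
            f"row length {rows.shape[1]} != model sensors {model.n_sensors}"
        )
    coords = ((rows - model.mean) / model.scale) @ model.loadings.T
    return coords[0] if single else coords


# ---------------------------------------------------------------------------
# Clustering and label matching


@dataclass(frozen=True)
class Ellipse:
    """Gaussian confidence ellipse: semi-axes along covariance eigenvectors."""

    center: np.ndarray
    semi_axes: np.ndarray  # (major, minor)
    angle_rad: float  # orientation of the major axis w.r.t. x
    level: float
    degenerate: bool

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership test via the ellipse quadratic form in axis coordinates."""
        pts = np.atleast_2d(np.asarray(points, float)) - self.center
        c, s = np.cos(self.angle_rad), np.sin(self.angle_rad)
        u = pts @ np.array([c, s])  # coordinate along the major axis
        v = pts @ np.array([-s, c])
        a, b = self.semi_axes
        if a <= 0:
            return (np.abs(u) <= 1e-12) & (np.abs(v) <= 1e-12)
        q = (u / a) ** 2
        if b > 0:
            q = q + (v / b) ** 2
        else:
            q = np.where(np.abs(v) > 1e-12, np.inf, q)
        return q <= 1.0


@dataclass
class ClusterModel:
    """k-means partition of the 2D PC coordinates plus per-cluster Gaussians."""

    centers: np.ndarray  # (k, 2)
    assignments: np.ndarray  # (n_samples,)
    inertia: float
    label_map: dict[int, str] | None = None
    gaussian_means: np.ndarray | None = None  # (k, 2)
    gaussian_covs: np.ndarray | None = None  # (k, 2, 2)
    ellipses: list[Ellipse] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    def matched_labels(self) -> np.ndarray:
        if self.label_map is None:
            raise ValidationError("cluster labels have not been matched yet")
        return np.array([self.label_map[int(c)] for c in self.assignments])


def kmeans_cluster(
    coords: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10
) -> ClusterModel:
    """k-means (k-means++ init, ``n_restarts`` seeded runs, best inertia)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2:
        raise ValidationError("coords must be 2D (n_samples × n_dims)")
    if k > coords.shape[0]:
        raise ValidationError(f"k={k} exceeds n_samples={coords.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed)
    assignments = km.fit_predict(coords)
    return ClusterModel(centers=km.cluster_centers_.copy(),
                        assignments=assignments.astype(int),
                        inertia=float(km.inertia_))


def fit_cluster_gaussians(model: ClusterModel, coords: np.ndarray,
                          level: float = 0.95) -> ClusterModel:
    """Fit a 2D Gaussian (sample mean, covariance) and confidence ellipse
    to every cluster's points in place."""
    coords = np.asarray(coords, dtype=float)
    means = np.zeros((model.k, 2))
    covs = np.zeros((model.k, 2, 2))
    ellipses: list[Ellipse] = []
    for i in range(model.k):
        pts = coords[model.assignments == i]
        means[i] = pts.mean(axis=0)
        if pts.shape[0] >= 2:
            covs[i] = np.cov(pts.T, ddof=1).reshape(2, 2)
        ellipses.append(confidence_ellipse(pts, level=level)
                        if pts.shape[0] >= 3 else
                        Ellipse(means[i], np.zeros(2), 0.0, level, True))
    model.gaussian_means = means
    model.gaussian_covs = covs
    model.ellipses = ellipses
    return model


def match_cluster_labels(
    assignments: Sequence[int], truth_labels: Sequence[str]
) -> dict[int, str]:
    """Bijection cluster index → analyte maximizing correctly labeled samples.

    Solved as a linear assignment (Kuhn-Munkres) on the negated
    contingency table between cluster indices and true labels.
    """
    assignments = np.asarray(assignments)
    truth = np.asarray(truth_labels)
    if assignments.shape[0] != truth.shape[0]:
        raise ValidationError("assignments and truth labels differ in length")
    clusters = np.unique(assignments)
    analytes = sorted(set(str(t) for t in truth))
    if len(clusters) != len(analytes):
        raise ValidationError(
            f"{len(clusters)} clusters cannot be matched to {len(analytes)} analytes"
        )
    cont = np.zeros((len(clusters), len(analytes)))
    aidx = {a: j for j, a in enumerate(analytes)}
    cidx = {int(c): i for i, c in enumerate(clusters)}
    for c, t in zip(assignments, truth):
        cont[cidx[int(c)], aidx[str(t)]] += 1
    rows, cols = linear_sum_assignment(-cont)
    return {int(clusters[r]): analytes[c] for r, c in zip(rows, cols)}


def adjusted_rand_index(a: Sequence, b: Sequence) -> float:
    """Chance-corrected pair-counting similarity of two partitions (ARI)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape[0] != b.shape[0]:
        raise ValidationError("partitions differ in length")
    if a.shape[0] < 2:
        raise ValidationError("ARI needs at least 2 samples")
    return float(adjusted_rand_score(a, b))


def confidence_ellipse(points: np.ndarray, level: float = 0.95) -> Ellipse:
    """Gaussian confidence ellipse of 2D points.

    Axes lie along the eigenvectors of the sample covariance; each
    semi-axis is sqrt(χ²₂(level) · eigenvalue), i.e. ≈ 2.4477·σ per axis
    at the 95% level for isotropic data.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be n × 2")
    if pts.shape[0] < 3:
        raise ValidationError("confidence ellipse needs at least 3 points")
    center = pts.mean(axis=0)
    cov = np.cov(pts.T, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    q = chi2_dist.ppf(level, df=2)
    semi = np.sqrt(q * evals)
    major = evecs[:, 0]
    angle = float(np.arctan2(major[1], major[0]))
    tol = 1e-12 * max(evals[0], 1.0)
    return Ellipse(center=center, semi_axes=semi, angle_rad=angle,
                   level=level, degenerate=bool(evals[1] <= tol))


# ---------------------------------------------------------------------------
# Chi-squared sensor ranking


def chi_squared_scores(
    table: ResponseTable, labels: Sequence[str], n_bins: int = 10
) -> dict[str, float]:
    """Per-sensor Pearson chi-squared association between discretized
    responses and the (cluster) labels.

    Each sensor's responses are uniformly discretized into ``n_bins``
    values over its own [min, max]; the statistic is computed on the
    bins × labels contingency table with unoccupied bins dropped.
    A constant sensor carries no association and scores 0 (with a warning).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != table.n_samples:
        raise ValidationError("labels length must equal n_samples")
    if n_bins < 2:
        raise ValidationError("n_bins must be ≥ 2")
    scores: dict[str, float] = {}
    for sensor in table.sensor_ids:
        vals = table.data[sensor].to_numpy(dtype=float)
        lo, hi = vals.min(), vals.max()
        if hi <= lo:
            warnings.warn(f"sensor {sensor!r} is constant; chi² score set to 0",
                          stacklevel=2)
            scores[sensor] = 0.0
            continue
        edges = np.linspace(lo, hi, n_bins + 1)
        bins = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, n_bins - 1)
        cont = pd.crosstab(bins, labels).to_numpy()
        if cont.shape[0] < 2:
            scores[sensor] = 0.0
            continue
        stat = chi2_contingency(cont, correction=False)[0]
        scores[sensor] = float(stat)
    return scores


def eliminate_lowest(scores: Mapping[str, float]) -> str:
    """Sensor with the minimal score; ties broken by lexicographic id."""
    if len(scores) < 2:
        raise ValidationError("cannot eliminate: fewer than 2 surviving sensors")
    return min(scores, key=lambda s: (scores[s], s))


# ---------------------------------------------------------------------------
# The elimination loop


@dataclass(frozen=True)
class StoppingCondition:
    """When to stop eliminating sensors.

    ``min_sensors`` stops once that many sensors survive. ``min_ari`` /
    ``max_error`` are performance floors: elimination continues while
    they hold and the smallest surviving set still satisfying them is
    selected once the loop finishes.
    """

    min_sensors: int | None = None
    min_ari: float | None = None
    max_error: float | None = None

    def __post_init__(self) -> None:
        if self.min_sensors is None and self.min_ari is None and self.max_error is None:
            raise ValidationError("at least one stopping threshold must be set")
        if self.min_sensors is not None and self.min_sensors < 1:
            raise ValidationError("min_sensors must be ≥ 1")
        if self.min_ari is not None and not -1.0 < self.min_ari <= 1.0:
            raise ValidationError("min_ari must lie in (−1, 1]")
        if self.max_error is not None and not 0.0 <= self.max_error <= 1.0:
            raise ValidationError("max_error must lie in [0, 1]")

    @property
    def floor(self) -> int:
        return self.min_sensors if self.min_sensors is not None else 1

    def satisfied_by(self, ari: float, error: float) -> bool:
        ok = True
        if self.min_ari is not None:
            ok &= ari >= self.min_ari - 1e-12
        if self.max_error is not None:
            ok &= error <= self.max_error + 1e-12
        return ok

    @property
    def has_performance_terms(self) -> bool:
        return self.min_ari is not None or self.max_error is not None


@dataclass(frozen=True)
class ACFSAConfig:
    """Tunables of one elimination run; all randomness is seeded here."""

    kmeans_seed: int = 0
    n_restarts: int = 10
    n_bins: int = 10
    strategy: str = "chi2"  # "chi2" | "random"
    random_seed: int = 0  # used only by the random baseline
    standardize: bool = False
    n_mc: int = 1_000_000  # Monte-Carlo draws per cluster for the error
    mc_seed: int = 0
    dead_band: float = 0.0
    jitter: float = 1e-10

    def __post_init__(self) -> None:
        if self.strategy not in ("chi2", "random"):
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        if self.n_restarts < 1 or self.n_bins < 2 or self.n_mc < 1:
            raise ValidationError("n_restarts ≥ 1, n_bins ≥ 2, n_mc ≥ 1 required")


@dataclass
class IterationRecord:
    """Everything evaluated for one surviving sensor set."""

    iteration: int
    sensors: tuple[str, ...]
    chi2_scores: dict[str, float]
    eliminated: str | None
    ari: float
    mean_intercluster_distance: float
    error: float
    error_se: float
    pca_model: "PCAModel"
    cluster_model: ClusterModel
    classifier: object  # VoronoiClassifier; typed loosely to avoid a cycle

    @property
    def n_sensors(self) -> int:
        return len(self.sensors)


@dataclass
class EliminationTrace:
    """Ordered record of a full ACFSA run plus the selected sensor set."""

    records: list[IterationRecord]
    status: str  # "min_sensors" | "performance" | "exhausted"
    selected_index: int | None
    config: ACFSAConfig
    stopping: StoppingCondition

    @property
    def selected(self) -> IterationRecord | None:
        return None if self.selected_index is None else self.records[self.selected_index]

    @property
    def final_classifier(self):
        rec = self.selected if self.selected is not None else self.records[-1]
        return rec.classifier

    @property
    def n_eliminations(self) -> int:
        return sum(1 for r in self.records if r.eliminated is not None)


def run_acfsa(
    table: ResponseTable,
    stopping: StoppingCondition,
    config: ACFSAConfig | None = None,
    labels: Sequence[str] | None = None,
) -> EliminationTrace:
    """Run the full iterative sensor-elimination loop.

    Per iteration the surviving columns are refit from scratch: PCA to two
    components → k-means with k = number of analytes → Kuhn-Munkres label
    matching → ARI against ground truth → Voronoi classifier with mean
    intercluster distance and Gaussian-overlap error → chi-squared ranking
    of the raw surviving responses against the matched cluster labels →
    elimination of the lowest-ranked sensor. ``strategy="random"``
    replaces the ranking with a seeded uniform draw (baseline).
    """
    from .classifier import build_classifier, classification_error

    config = config or ACFSAConfig()
    table.check_complete()
    truth = np.asarray(labels) if labels is not None else table.analyte_labels
    if truth.shape[0] != table.n_samples:
        raise ValidationError("labels length must equal n_samples")
    k = len(set(truth.tolist()))
    floor = stopping.floor
    if floor > table.n_sensors:
        raise ValidationError("min_sensors exceeds the number of sensors")

    rng_random = np.random.default_rng(config.random_seed)
    survivors = list(table.sensor_ids)
    records: list[IterationRecord] = []
    iteration = 0
    while True:
        sub = table.select_sensors(survivors)
        pca = fit_pca(sub, standardize=config.standardize)
        coords = project(pca, sub.values)
        clusters = kmeans_cluster(coords, k, seed=config.kmeans_seed,
                                  n_restarts=config.n_restarts)
        clusters.label_map = match_cluster_labels(clusters.assignments, truth)
        fit_cluster_gaussians(clusters, coords)
        ari = adjusted_rand_index(truth, clusters.assignments)
        clf = build_classifier(clusters, pca, sensor_ids=survivors)
        err, err_se = classification_error(
            clf, n_mc=config.n_mc,
            seed=config.mc_seed + iteration, jitter=config.jitter)
        clf.classification_error = err
        clf.error_se = err_se
        scores = chi_squared_scores(sub, clusters.matched_labels(),
                                    n_bins=config.n_bins)

        eliminated: str | None = None
        if len(survivors) > max(floor, 1):
            if config.strategy == "chi2":
                eliminated = eliminate_lowest(scores)
            else:
                eliminated = survivors[int(rng_random.integers(len(survivors)))]

        records.append(IterationRecord(
            iteration=iteration, sensors=tuple(survivors),
            chi2_scores=scores, eliminated=eliminated, ari=ari,
            mean_intercluster_distance=clf.mean_intercluster_distance,
            error=err, error_se=err_se, pca_model=pca,
            cluster_model=clusters, classifier=clf))

        if eliminated is None:
            break
        survivors.remove(eliminated)
        iteration += 1

    if stopping.has_performance_terms:
        selected = None
        for i in range(len(records) - 1, -1, -1):  # smallest set first
            if stopping.satisfied_by(records[i].ari, records[i].error):
                selected = i
                break
        status = "performance" if selected is not None else "exhausted"
        return EliminationTrace(records, status, selected, config, stopping)

    return EliminationTrace(records, "min_sensors", len(records) - 1,
                            config, stopping)
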