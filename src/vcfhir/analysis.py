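"""Joint analyses on the merged clinical + genomic table.

Three applications run off the merged table: columnar export (handled by
:mod:`vcfhir.fhir_flatten`'s writers), exploratory patient clustering
(k-means++, DBSCAN, spectral clustering, evaluated with the
Davies-Bouldin, Calinski-Harabasz and Silhouette indices and an
elbow-method choice of k), and a pharmacogenomic study testing each
(variant-carrier x drug) cell's survival against the 50% untreated
baseline with a one-sided proportion z-test.

Inertia here is the MEAN squared distance from each point to its
assigned centroid; the common sum-based definition differs only by the
factor n, so cluster assignments and the elbow choice are unaffected.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.cluster import DBSCAN as _SkDBSCAN
from sklearn.cluster import KMeans as _SkKMeans
from sklearn.cluster import SpectralClustering as _SkSpectral

from .variant_matrix import PatientGenomicMatrix

logger = logging.getLogger(__name__)


class MergeKeyError(ValueError):
    """Duplicate MRN in one of the inputs to merge."""


class FeatureConfigError(ValueError):
    """A configured feature column is absent or not encodable."""


# ---------------------------------------------------------------------------
# Merge
# ---------------------------------------------------------------------------

@dataclass
class DropReport:
    clinical_only: list[str]
    genomic_only: list[str]

    @property
    def n_dropped(self) -> int:
        return len(self.clinical_only) + len(self.genomic_only)


def merge_tables(
    clinical: pd.DataFrame, genomic: PatientGenomicMatrix | pd.DataFrame
) -> tuple[pd.DataFrame, DropReport]:
    """Inner-join the clinical table and the genomic matrix on MRN.

    Patients present on only one side are listed in the drop report;
    column-name collisions are resolved with a source prefix.
    """
    gdf = genomic.data if isinstance(genomic, PatientGenomicMatrix) else genomic
    if clinical["mrn"].duplicated().any():
        raise MergeKeyError("duplicate MRN in clinical table")
    if gdf.index.duplicated().any():
        raise MergeKeyError("duplicate patient id in genomic matrix")
    ckeys = set(clinical["mrn"])
    gkeys = set(gdf.index)
    report = DropReport(
        clinical_only=sorted(ckeys - gkeys),
        genomic_only=sorted(gkeys - ckeys),
    )
    gren = gdf.rename(
        columns={c: f"genomic_{c}" for c in gdf.columns if c in set(clinical.columns)}
    )
    merged = clinical.merge(
        gren, left_on="mrn", right_index=True, how="inner", validate="one_to_one"
    ).reset_index(drop=True)
    if report.n_dropped:
        logger.info(
            "merge dropped %d clinical-only and %d genomic-only patients",
            len(report.clinical_only), len(report.genomic_only),
        )
    return merged, report


# ---------------------------------------------------------------------------
# Feature encoding
# ---------------------------------------------------------------------------

@dataclass
class FeatureConfig:
    genotype_columns: list[str] = field(default_factory=list)  # "0/1" strings -> dosage
    categorical_columns: list[str] = field(default_factory=list)  # one-hot
    numeric_columns: list[str] = field(default_factory=list)  # z-scored


def _gt_dosage(gt: str) -> int:
    return sum(1 for a in str(gt).split("/") if a not in (".", "") and int(a) >= 1)


def encode_features(merged: pd.DataFrame, config: FeatureConfig) -> pd.DataFrame:
    """Encode configured columns into a dense numeric feature matrix.

    Genotypes become alt-allele dosage 0/1/2; categoricals one-hot;
    numerics are z-score standardized. Constant columns are dropped
    (logged), and the output contains no missing values.
    """
    for col in (
        config.genotype_columns + config.categorical_columns + config.numeric_columns
    ):
        if col not in merged.columns:
            raise FeatureConfigError(f"configured column {col!r} not in merged table")
    parts: list[pd.DataFrame] = []
    for col in config.genotype_columns:
        parts.append(merged[col].map(_gt_dosage).astype(float).to_frame(col))
    for col in config.categorical_columns:
        onehot = pd.get_dummies(merged[col].astype(str), prefix=col).astype(float)
        parts.append(onehot)
    for col in config.numeric_columns:
        vals = pd.to_numeric(merged[col], errors="raise").astype(float)
        if vals.isna().any():
            raise FeatureConfigError(f"numeric column {col!r} has missing values")
        sd = vals.std(ddof=0)
        parts.append(((vals - vals.mean()) / sd if sd > 0 else vals).to_frame(col))
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=merged.index)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        logger.info("dropping %d constant feature column(s): %s", len(constant), constant)
        X = X.drop(columns=constant)
    return X


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

NOISE = -1


@dataclass
class Clustering:
    """Cluster labels (-1 = noise) with mean-squared-distance inertia."""

    labels: np.ndarray
    inertia: float | None = None

    @property
    def k(self) -> int:
        return len(set(self.labels[self.labels != NOISE]))

    @property
    def noise_fraction(self) -> float:
        return float(np.mean(self.labels == NOISE))


def kmeanspp(
    X: np.ndarray, k: int, n_init: int = 10, max_iter: int = 300,
    tol: float = 1e-4, seed: int = 0,
) -> Clustering:
    """k-means with k-means++ seeding, best of ``n_init`` restarts.

    Inertia is reported as the mean squared distance to the assigned
    centroid (sum-based inertia divided by n).
    """
    X = np.asarray(X, dtype=float)
    if k > len(X):
        raise ValueError("k cannot exceed the number of points")
    km = _SkKMeans(
        n_clusters=k, init="k-means++", n_init=n_init, max_iter=max_iter,
        tol=tol, random_state=seed,
    ).fit(X)
    return Clustering(labels=km.labels_.astype(int), inertia=float(km.inertia_) / len(X))


def dbscan(X: np.ndarray, eps: float, min_samples: int) -> Clustering:
    """Density-based clustering; unreachable points are labeled noise (-1)."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    X = np.asarray(X, dtype=float)
    db = _SkDBSCAN(eps=eps, min_samples=min_samples).fit(X)
    labels = db.labels_.astype(int)
    clust = Clustering(labels=labels)
    non_noise = labels != NOISE
    if clust.k >= 1 and non_noise.any():
        cents = {c: X[labels == c].mean(axis=0) for c in set(labels[non_noise])}
        sq = [
            float(np.sum((x - cents[c]) ** 2))
            for x, c in zip(X[non_noise], labels[non_noise])
        ]
        clust.inertia = float(np.mean(sq))
    return clust


def spectral(X: np.ndarray, k: int, gamma: float = 1.0, seed: int = 0) -> Clustering:
    """Spectral clustering on an RBF affinity matrix.

    Embeds rows via the leading eigenvectors of the normalized graph
    Laplacian of ``W_ij = exp(-gamma * ||x_i - x_j||^2)``, then clusters
    the embedding with k-means.
    """
    X = np.asarray(X, dtype=float)
    if k > len(X):
        raise ValueError("k cannot exceed the number of points")
    if k == 1:
        labels = np.zeros(len(X), dtype=int)
    else:
        try:
            sc = _SkSpectral(
                n_clusters=k, affinity="rbf", gamma=gamma,
                assign_labels="kmeans", random_state=seed,
            ).fit(X)
        except np.linalg.LinAlgError as exc:
            W = np.exp(-gamma * np.sum((X[:, None] - X[None, :]) ** 2, axis=-1))
            raise RuntimeError(
                f"eigen-solver failure (affinity condition number "
                f"{np.linalg.cond(W):.3g}): {exc}"
            ) from exc
        labels = sc.labels_.astype(int)
    cents = {c: X[labels == c].mean(axis=0) for c in set(labels)}
    sq = [float(np.sum((x - cents[c]) ** 2)) for x, c in zip(X, labels)]
    return Clustering(labels=labels, inertia=float(np.mean(sq)))


class NoElbowWarning(UserWarning):
    pass


def select_elbow(ks: list[int], inertias: list[float]) -> int:
    """Pick the k maximizing the discrete second difference of inertia.

    ``inertia(k-1) - 2*inertia(k) + inertia(k+1)`` is largest where the
    curve bends hardest toward the horizontal. A flat curve (no positive
    curvature anywhere) triggers :class:`NoElbowWarning`.
    """
    if len(ks) < 3:
        raise ValueError("need at least 3 k values")
    second = [
        inertias[i - 1] - 2 * inertias[i] + inertias[i + 1]
        for i in range(1, len(ks) - 1)
    ]
    best = int(np.argmax(second))
    if max(second) <= 1e-12:
        warnings.warn("no pronounced elbow in the inertia curve", NoElbowWarning)
    return ks[best + 1]


def elbow_select(
    X: np.ndarray, k_range: list[int], seed: int = 0, n_init: int = 10
) -> tuple[int, list[float]]:
    """Inertia curve over ``k_range`` (via k-means++) and the elbow k."""
    ks = list(k_range)
    if ks != sorted(ks) or len(ks) < 3:
        raise ValueError("k_range must be ascending with length >= 3")
    inertias = [kmeanspp(X, k, n_init=n_init, seed=seed).inertia for k in ks]
    return select_elbow(ks, inertias), inertias


# ---------------------------------------------------------------------------
# Validity indices
# ---------------------------------------------------------------------------

def _check_labels(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, list]:
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if NOISE in labels:
        raise ValueError("validity indices are undefined for noise labels; filter first")
    clusters = sorted(set(labels.tolist()))
    return X, labels, clusters


def davies_bouldin(X: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index (lower is better).

    DB = (1/k) * sum_i max_{j!=i} (S_i + S_j) / M_ij, with S the mean
    Euclidean distance of a cluster's points to its centroid and M the
    distance between centroids.
    """
    X, labels, clusters = _check_labels(X, labels)
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    cents = np.array([X[labels == c].mean(axis=0) for c in clusters])
    scatter = np.array([
        np.mean(np.linalg.norm(X[labels == c] - cents[i], axis=1))
        for i, c in enumerate(clusters)
    ])
    total = 0.0
    for i in range(len(clusters)):
        worst = -np.inf
        for j in range(len(clusters)):
            if i == j:
                continue
            m = np.linalg.norm(cents[i] - cents[j])
            if m == 0.0:
                raise ValueError(
                    f"clusters {clusters[i]} and {clusters[j]} share a centroid"
                )
            worst = max(worst, (scatter[i] + scatter[j]) / m)
        total += worst
    return total / len(clusters)


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz index: [BSS/(k-1)] / [WSS/(n-k)] (higher is better).

    Zero within-group scatter returns ``inf`` (flagged via log) rather
    than raising.
    """
    X, labels, clusters = _check_labels(X, labels)
    n, k = len(X), len(clusters)
    if not 2 <= k < n:
        raise ValueError("need 2 <= k < n")
    grand = X.mean(axis=0)
    bss = sum(
        (labels == c).sum() * float(np.sum((X[labels == c].mean(axis=0) - grand) ** 2))
        for c in clusters
    )
    wss = sum(
        float(np.sum((X[labels == c] - X[labels == c].mean(axis=0)) ** 2))
        for c in clusters
    )
    if wss == 0.0:
        logger.warning("zero within-group scatter: Calinski-Harabasz is infinite")
        return float("inf")
    return (bss / (k - 1)) / (wss / (n - k))


def silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient, in [-1, 1].

    Per point, s = (b - a) / max(a, b): a is the mean distance to the
    point's own cluster (excluding itself), b the lowest mean distance to
    any other cluster. Points in singleton clusters score 0.
    """
    X, labels, clusters = _check_labels(X, labels)
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    scores = np.zeros(len(X))
    for i in range(len(X)):
        own = labels == labels[i]
        if own.sum() == 1:
            scores[i] = 0.0
            continue
        a = D[i, own].sum() / (own.sum() - 1)
        b = min(D[i, labels == c].mean() for c in clusters if c != labels[i])
        scores[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(scores.mean())


# ---------------------------------------------------------------------------
# Pharmacogenomic study
# ---------------------------------------------------------------------------

class NormalApproximationWarning(UserWarning):
    pass


def ztest_survival(
    survivors: int, n: int, p0: float = 0.5, alternative: str = "greater"
) -> tuple[float, float]:
    """One-sample proportion z-test, upper tail, no continuity correction.

    z = (p_hat - p0) / sqrt(p0 (1 - p0) / n); p is the upper-tail
    standard-normal probability. Warns (but still answers) when the
    normal approximation is shaky (n*p0 < 5 or n*(1-p0) < 5).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0,1)")
    if not 0 <= survivors <= n:
        raise ValueError("survivors must be in [0, n]")
    if alternative != "greater":
        raise ValueError("only the upper-tail alternative is supported")
    if n * p0 < 5 or n * (1 - p0) < 5:
        warnings.warn(
            f"normal approximation questionable for n={n}, p0={p0}",
            NormalApproximationWarning,
        )
    z = (survivors / n - p0) / np.sqrt(p0 * (1 - p0) / n)
    return float(z), float(norm.sf(z))


@dataclass
class GroupTestResult:
    carrier: bool
    drug: str
    n: int
    survivors: int
    z: float | None
    p: float | None
    significant: bool
    testable: bool = True


def pgx_study(
    merged: pd.DataFrame,
    pgx_column: str,
    alpha: float = 0.01,
    p0: float = 0.5,
    drug_column: str = "medication_1",
    survived_column: str = "survived",
) -> tuple[list[GroupTestResult], pd.DataFrame]:
    """Test each (carrier x drug) cell's survival against the untreated rate.

    Carrier status is derived from the genomic PGx genotype column
    (dosage >= 1), not from any clinical field. Returns four one-sided
    test results (alpha default 0.01) plus a contingency summary table of
    counts — the tabular equivalent of a treatment/outcome flow diagram.
    """
    for col in (pgx_column, drug_column, survived_column):
        if col not in merged.columns:
            raise FeatureConfigError(f"column {col!r} not in merged table")
    carrier = merged[pgx_column].map(_gt_dosage) >= 1
    drugs = sorted(merged[drug_column].dropna().unique())
    survived = merged[survived_column].astype(bool)

    results: list[GroupTestResult] = []
    rows = []
    for is_carrier in (False, True):
        for drug in drugs:
            mask = (carrier == is_carrier) & (merged[drug_column] == drug)
            n = int(mask.sum())
            surv = int(survived[mask].sum())
            if n == 0:
                results.append(GroupTestResult(is_carrier, drug, 0, 0, None, None, False, testable=False))
            else:
                z, p = ztest_survival(surv, n, p0=p0)
                results.append(GroupTestResult(is_carrier, drug, n, surv, z, p, bool(p < alpha)))
            rows.append(
                {"carrier": is_carrier, "drug": drug, "n": n,
                 "survived": surv, "died": n - surv,
                 "survival_rate": surv / n if n else float("nan")}
            )
    return results, pd.DataFrame(rows)
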