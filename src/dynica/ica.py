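"""Robust ensemble ICA: FastICA restarts, DBSCAN clustering, repeat filtering.

The fold-change matrix X (promoters x conditions) is decomposed as
X_centered ~= M @ A, with independent sources in the gene dimension (columns
of M, the promoter coefficients) and mixing in the condition dimension (rows
of A, the activity coefficients).  FastICA is restarted ``n_runs`` times from
random seeds, the pooled components are clustered with DBSCAN under the
distance d(u, v) = 1 - |pearson r(u, v)|, and cluster centroids become the
robust components.  The whole ensemble-plus-clustering step is repeated
``n_repeats`` times with fresh seeds and only components re-identified in
every repeat are retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IcaConfig:
    """Ensemble and clustering parameters.

    Defaults follow the published pipeline: 100 FastICA runs at tolerance
    1e-6, dimension from the 99%-variance PCA elbow, DBSCAN distance 0.1,
    minimum cluster fraction 0.5 of the runs, and 100 repeat computations of
    the clustered components.  ``fast()`` returns a 10-run/10-repeat variant
    for desk-scale work.
    """

    n_runs: int = 100
    tolerance: float = 1e-6
    variance_fraction: float = 0.99
    cluster_distance: float = 0.1
    min_frac: float = 0.5
    n_repeats: int = 100
    max_iter: int = 10000
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.variance_fraction <= 1:
            raise ValueError("variance_fraction must be in (0, 1]")
        if not 0 < self.cluster_distance < 2:
            raise ValueError("cluster_distance must be in (0, 2)")
        if not 0 < self.min_frac <= 1:
            raise ValueError("min_frac must be in (0, 1]")
        if self.n_runs < 1 or self.n_repeats < 1:
            raise ValueError("n_runs and n_repeats must be positive")

    @classmethod
    def fast(cls, base_seed: int = 0, **kwargs) -> "IcaConfig":
        """Fast-test mode: n_runs = n_repeats = 10, with a looser per-run
        tolerance and iteration cap (the cross-run clustering, not per-run
        convergence, is what stabilizes the retained components)."""
        kwargs.setdefault("tolerance", 1e-5)
        kwargs.setdefault("max_iter", 1000)
        return cls(n_runs=10, n_repeats=10, base_seed=base_seed, **kwargs)


@dataclass
class IcaDecomposition:
    """Robust components: X ~= M @ A + column means.

    Each column of M has unit L2 norm and its largest-magnitude entry is
    positive; A rows carry the scale.  ``column_means`` holds the per-condition
    means removed before ICA, so the original matrix is M @ A + 1 * mu^T.
    """

    M: pd.DataFrame  # promoters x k_robust
    A: pd.DataFrame  # k_robust x conditions
    column_means: pd.Series
    cluster_sizes: list[int] = field(default_factory=list)
    run_frequency: list[float] = field(default_factory=list)

    @property
    def k_robust(self) -> int:
        return self.M.shape[1]

    def reconstruction(self) -> pd.DataFrame:
        rec = self.M.to_numpy() @ self.A.to_numpy()
        rec = rec + self.column_means.to_numpy()[None, :]
        return pd.DataFrame(rec, index=self.M.index, columns=self.A.columns)


def _as_array(X) -> np.ndarray:
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(
        X, dtype=float
    )
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 rows and columns")
    if not np.all(np.isfinite(arr)):
        raise ValueError("X contains non-finite entries")
    return arr


def center_columns(X) -> tuple[np.ndarray, np.ndarray]:
    """Mean-center each condition column (no variance scaling: fold changes
    share units and scaling would distort weight comparability)."""
    arr = _as_array(X)
    mu = arr.mean(axis=0)
    return arr - mu, mu


def select_dimension(X, variance_fraction: float = 0.99) -> int:
    """Smallest number of principal components whose cumulative explained
    variance reaches ``variance_fraction``."""
    arr, _ = center_columns(X)
    total = float(np.sum(arr**2))
    if total == 0:
        raise ValueError("X has zero variance; cannot select a dimension")
    pca = PCA(n_components=min(arr.shape), svd_solver="full")
    pca.fit(arr)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    return min(max(k, 1), min(arr.shape))


def _orient(m: np.ndarray, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-normalize m, push scale into a, and make the largest-magnitude
    entry of m positive (ties broken by the lower row index)."""
    norm = float(np.linalg.norm(m))
    if norm == 0:
        return m, a
    m = m / norm
    a = a * norm
    i = int(np.argmax(np.abs(m)))  # argmax takes the lowest index on ties
    if m[i] < 0:
        m, a = -m, -a
    return m, a


def _single_run(Xc: np.ndarray, k: int, config: IcaConfig, seed: int):
    """One FastICA restart.  A run fails only when the solver errors or
    returns non-finite output; merely reaching the iteration cap is fine —
    unstable directions are filtered later by the cross-run clustering."""
    ica = FastICA(
        n_components=k,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        tol=config.tolerance,
        max_iter=config.max_iter,
        random_state=seed,
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            S = ica.fit_transform(Xc)  # promoters x k sources
    except Exception:
        return [], False
    A = ica.mixing_.T  # k x conditions
    if not (np.all(np.isfinite(S)) and np.all(np.isfinite(A))):
        return [], False
    comps = []
    for j in range(k):
        m, a = _orient(S[:, j].copy(), A[j].copy())
        comps.append((m, a))
    return comps, True


def run_ica_ensemble(
    X, k: int, config: IcaConfig | None = None
) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """``n_runs`` FastICA decompositions from seeds derived from base_seed.

    Each run is a list of (gene-space component, activity vector) pairs, the
    component unit-normalized and sign-oriented.  A run that fails to converge
    is retried once with a fresh derived seed, then skipped with a log entry.
    """
    config = config or IcaConfig()
    Xc, _ = center_columns(X)
    runs = []
    for r in range(config.n_runs):
        seed = (config.base_seed + r) % (2**31)
        comps, ok = _single_run(Xc, k, config, seed)
        if not ok:
            retry_seed = (config.base_seed + 7919 * (r + 1)) % (2**31)
            comps, ok = _single_run(Xc, k, config, retry_seed)
            if not ok:
                logger.info("ICA run %d did not converge after retry; skipped", r)
                continue
        runs.append(comps)
    return runs


def _correlation_distance_matrix(vectors: np.ndarray) -> np.ndarray:
    """d(u, v) = 1 - |pearson r(u, v)| for every pair of row vectors."""
    centered = vectors - vectors.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = centered / norms
    corr = np.clip(np.abs(unit @ unit.T), 0.0, 1.0)
    return 1.0 - corr


def _abs_corr(u: np.ndarray, v: np.ndarray) -> float:
    uc = u - u.mean()
    vc = v - v.mean()
    denom = np.linalg.norm(uc) * np.linalg.norm(vc)
    if denom == 0:
        return 0.0
    return float(abs(uc @ vc) / denom)


def cluster_components(
    ensemble: list[list[tuple[np.ndarray, np.ndarray]]],
    cluster_distance: float = 0.1,
    min_frac: float = 0.5,
) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Group pooled run components by DBSCAN density clustering.

    Neighborhood radius is ``cluster_distance`` under the 1 - |r| distance;
    the minimum cluster size is ceil(min_frac * n_runs), i.e. a valid
    component must reappear in at least half the runs by default.  Noise
    points are discarded.  Clusters are returned largest first.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    n_runs = len(ensemble)
    pooled = [comp for run in ensemble for comp in run]
    if not pooled:
        return []
    vectors = np.stack([m for m, _ in pooled])
    dist = _correlation_distance_matrix(vectors)
    min_samples = int(np.ceil(min_frac * n_runs))
    labels = DBSCAN(
        eps=cluster_distance, min_samples=min_samples, metric="precomputed"
    ).fit_predict(dist)
    clusters = []
    for lab in sorted(set(labels) - {-1}):
        idx = np.where(labels == lab)[0]
        clusters.append([pooled[i] for i in idx])
    clusters.sort(key=len, reverse=True)
    return clusters


def _cluster_centroid(
    cluster: list[tuple[np.ndarray, np.ndarray]]
) -> tuple[np.ndarray, np.ndarray]:
    """Sign-aligned mean of cluster members, renormalized so the M part has
    unit norm while the centroid product M*A preserves the cluster mean."""
    ref = cluster[0][0]
    ms, As = [], []
    for m, a in cluster:
        flip = -1.0 if float(m @ ref) < 0 else 1.0
        ms.append(flip * m)
        As.append(flip * a)
    m_mean = np.mean(ms, axis=0)
    a_mean = np.mean(As, axis=0)
    norm = float(np.linalg.norm(m_mean))
    if norm > 0:
        m_mean = m_mean / norm
        a_mean = a_mean * norm
    return _orient(m_mean, a_mean)


def _centroids(
    ensemble, config: IcaConfig
) -> list[tuple[np.ndarray, np.ndarray, int]]:
    clusters = cluster_components(
        ensemble, config.cluster_distance, config.min_frac
    )
    return [(*_cluster_centroid(c), len(c)) for c in clusters]


def robust_components(
    ensemble,
    config: IcaConfig | None = None,
    X=None,
    k: int | None = None,
) -> IcaDecomposition:
    """Cluster the ensemble and keep components re-identified in every repeat.

    When ``X`` (and the dimension ``k``) are given and ``n_repeats > 1``, the
    ensemble-plus-clustering computation is redone ``n_repeats - 1`` more
    times with fresh base seeds; a candidate centroid is retained only if each
    repeat contains a cluster centroid with |pearson r| > 1 - cluster_distance
    to it (greedy matching by descending |r|).  Zero retained components is a
    valid result, not an error.
    """
    config = config or IcaConfig()
    candidates = _centroids(ensemble, config)

    if X is not None and config.n_repeats > 1 and candidates:
        if k is None:
            k = len(ensemble[0]) if ensemble else 0
        keep = np.ones(len(candidates), dtype=bool)
        for rep in range(1, config.n_repeats):
            rep_seed = (config.base_seed + 100_003 * rep) % (2**31)
            rep_config = replace(config, base_seed=rep_seed)
            rep_ens = run_ica_ensemble(X, k, rep_config)
            if not rep_ens:
                keep[:] = False
                break
            rep_centroids = _centroids(rep_ens, config)
            keep &= _match_every(candidates, rep_centroids,
                                 1.0 - config.cluster_distance)
            if not keep.any():
                break
        candidates = [c for c, kf in zip(candidates, keep) if kf]

    index = X.index if isinstance(X, pd.DataFrame) else None
    columns = X.columns if isinstance(X, pd.DataFrame) else None
    mu = (
        center_columns(X)[1]
        if X is not None
        else np.zeros(candidates[0][1].size if candidates else 0)
    )
    return _build_decomposition(candidates, len(ensemble), index, columns, mu)


def _match_every(candidates, rep_centroids, r_min: float) -> np.ndarray:
    """Greedy one-to-one matching of candidates to repeat centroids by
    descending |r|; True where a match above r_min was found."""
    matched = np.zeros(len(candidates), dtype=bool)
    if not rep_centroids:
        return matched
    pairs = []
    for i, (m, _, _) in enumerate(candidates):
        for j, (mr, _, _) in enumerate(rep_centroids):
            r = _abs_corr(m, mr)
            if r > r_min:
                pairs.append((r, i, j))
    pairs.sort(reverse=True)
    used_j: set[int] = set()
    for r, i, j in pairs:
        if matched[i] or j in used_j:
            continue
        matched[i] = True
        used_j.add(j)
    return matched


def _build_decomposition(
    candidates, n_runs: int, index, columns, mu: np.ndarray
) -> IcaDecomposition:
    ids = [f"im_{i}" for i in range(len(candidates))]
    if candidates:
        M = np.column_stack([m for m, _, _ in candidates])
        A = np.stack([a for _, a, _ in candidates])
        sizes = [int(s) for _, _, s in candidates]
    else:
        n_rows = len(index) if index is not None else 0
        n_cols = len(columns) if columns is not None else mu.size
        M = np.zeros((n_rows, 0))
        A = np.zeros((0, n_cols))
        sizes = []
    freq = [s / n_runs if n_runs else 0.0 for s in sizes]
    return IcaDecomposition(
        M=pd.DataFrame(M, index=index, columns=ids),
        A=pd.DataFrame(A, index=ids, columns=columns),
        column_means=pd.Series(mu, index=columns),
        cluster_sizes=sizes,
        run_frequency=freq,
    )


def robust_ica(X, config: IcaConfig | None = None) -> IcaDecomposition:
    """End to end: dimension selection, ensemble, clustering, repeat filter."""
    config = config or IcaConfig()
    k = select_dimension(X, config.variance_fraction)
    ensemble = run_ica_ensemble(X, k, config)
    if not ensemble:
        logger.warning("no ICA run converged; returning no robust components")
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        _, mu = center_columns(Xdf)
        return _build_decomposition([], 0, Xdf.index, Xdf.columns, mu)
    return robust_components(ensemble, config, X=X, k=k)
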