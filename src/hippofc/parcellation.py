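"""Data-driven functional segmentation of the hippocampus.

Both hippocampi enter one joint analysis: the pooled (voxel x time) matrix of
all subjects is decomposed by group spatial ICA, each component's spatial map
is converted to an "active-voxel" probability map by a two-component Gaussian
mixture, and the per-voxel probability profiles are clustered by k-means.
The cluster count is selected automatically from the elbow (knee) of the
cluster validity index — the ratio of within-cluster to between-cluster
distances — over a scan of k.  Components whose time courses look like
high-frequency noise (or whose FC maps track an exclusion mask such as a CSF
proxy) are dropped by an automated QC screen before feature building.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import skew
from sklearn.cluster import KMeans
from sklearn.decomposition import FastICA
from sklearn.mixture import GaussianMixture

from .containers import BoldSeries, ParcellationVolume
from .synthetic import order_parcels_anterior_posterior

__all__ = [
    "ComponentMaps",
    "ValidityCurve",
    "group_ica",
    "probability_from_map",
    "kmeans_cluster",
    "cluster_validity_index",
    "select_cluster_number",
    "qc_screen",
    "overlap_table",
    "pool_subjects",
    "parcellate",
    "order_parcels_anterior_posterior",
]


@dataclass
class ComponentMaps:
    """Spatial ICA output: K maps over voxels plus pooled time courses."""

    spatial_maps: np.ndarray  # (k, n_voxels), zero mean / unit variance per map
    time_courses: np.ndarray  # (k, total_timepoints)
    probability_maps: np.ndarray | None = None  # (k, n_voxels) in [0, 1]
    probability_fallback: np.ndarray | None = None  # per-component fallback flag

    @property
    def k(self) -> int:
        return self.spatial_maps.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.spatial_maps.shape[1]


@dataclass
class ValidityCurve:
    """Cluster validity index over a scan of k, with the selected elbow."""

    k_values: list[int]
    cvi: list[float]
    selected_k: int

    def __post_init__(self) -> None:
        if self.selected_k not in self.k_values:
            raise ValueError("selected_k must be one of the scanned k values")


def pool_subjects(series_list: list[BoldSeries]) -> np.ndarray:
    """Concatenate subjects' (voxel x time) matrices along time.

    All subjects must cover the same voxels in the same order.
    """
    ref = series_list[0].location_ids
    for s in series_list[1:]:
        if not np.array_equal(s.location_ids, ref):
            raise ValueError("subjects must share identical voxel ordering")
    return np.hstack([s.values for s in series_list])


def group_ica(pooled: np.ndarray, k: int, rng_seed: int = 0) -> ComponentMaps:
    """Group spatial ICA of a pooled (voxels x total-time) matrix.

    SVD reduces the data to ``k`` dimensions and fixed-point negentropy ICA
    (FastICA) unmixes them into spatially independent maps; the associated
    time courses are the mixing columns.  Each map is standardised to zero
    mean and unit variance over voxels, and its sign is fixed so the map's
    skewness is nonnegative (the time course flips with it).  If the data
    rank is below ``k`` the component count is reduced with a warning.
    """
    pooled = np.asarray(pooled, dtype=float)
    n_voxels, n_time = pooled.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_voxels < k or n_time < k:
        raise ValueError(f"pooled matrix {pooled.shape} cannot support k={k}")
    # temporal demeaning per voxel, then SVD reduction: spatial structure
    # lives in the left singular vectors (voxel space)
    centered = pooled - pooled.mean(axis=1, keepdims=True)
    u, sv, vt = np.linalg.svd(centered, full_matrices=False)
    tol = max(centered.shape) * np.finfo(float).eps * (sv[0] if len(sv) else 0.0)
    rank = int((sv > tol).sum())
    if rank < k:
        warnings.warn(
            f"pooled data rank {rank} < requested k={k}; using k={rank}",
            UserWarning,
            stacklevel=2,
        )
        k = rank
    # whitened spatial data, scaled to unit variance per dimension so the
    # negentropy nonlinearity operates away from its linear regime
    z = u[:, :k] * np.sqrt(n_voxels)
    ica = FastICA(
        n_components=k,
        random_state=np.random.RandomState(rng_seed),
        whiten=False,
        max_iter=1000,
        tol=1e-6,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        # z is already reduced to k columns, so n_components is redundant
        warnings.filterwarnings("ignore", message=".*Ignoring n_components.*")
        maps = ica.fit_transform(z)  # (voxels, k) spatial sources
    maps = maps.T.astype(float)
    # time courses by least squares: centered ~ maps.T @ courses
    courses, *_ = np.linalg.lstsq(maps.T, centered, rcond=None)
    # standardise maps; keep map and time course consistent
    mean = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    maps = (maps - mean) / sd
    flip = np.where(skew(maps, axis=1) < 0, -1.0, 1.0)
    maps *= flip[:, None]
    courses = courses * flip[:, None]
    return ComponentMaps(spatial_maps=maps, time_courses=courses)


def probability_from_map(spatial_map: np.ndarray) -> tuple[np.ndarray, bool]:
    """Posterior probability of the "active" class per voxel of an ICA map.

    A two-component Gaussian mixture with shared variance (null + active) is
    fitted to the map values by EM; the active class is the component with
    the larger mean and the returned value is its posterior probability,
    which with a shared variance is monotone non-decreasing in the map
    value.  When the fit degenerates (components collapse onto each other or
    one empties out) the fallback is a logistic transform of the
    standardised map value; the second return value flags that path.
    """
    x = np.asarray(spatial_map, dtype=float).ravel()
    if x.size < 10:
        raise ValueError("need at least 10 voxels to fit the mixture")
    sd = x.std()
    if sd < 1e-12:
        return np.full(x.size, 0.5), True
    gm = GaussianMixture(
        n_components=2, covariance_type="tied", random_state=0, n_init=3,
        reg_covar=1e-6,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore")
        gm.fit(x[:, None])
    means = gm.means_.ravel()
    weights = gm.weights_
    degenerate = (
        abs(means[0] - means[1]) < 1e-6 * max(sd, 1e-12)
        or weights.min() < 1e-6
        or not np.all(np.isfinite(gm.covariances_))
    )
    if degenerate:
        z = (x - x.mean()) / sd
        return 1.0 / (1.0 + np.exp(-z)), True
    active = int(np.argmax(means))
    post = gm.predict_proba(x[:, None])[:, active]
    return post, False


def kmeans_cluster(features: np.ndarray, k: int, rng_seed: int = 0, n_init: int = 10) -> np.ndarray:
    """Euclidean k-means over per-voxel feature profiles (V x K).

    Runs ``n_init`` restarts and keeps the lowest within-cluster sum of
    squares; deterministic given ``rng_seed``.  Returns 0-based labels.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    v = features.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > v:
        raise ValueError(f"k={k} exceeds the number of points {v}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=rng_seed)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore")  # duplicate-point / convergence chatter
        labels = km.fit_predict(features)
    return labels


def cluster_validity_index(features: np.ndarray, labels: np.ndarray) -> float:
    """Ratio of within-cluster to between-cluster distances.

    Numerator: mean Euclidean distance of every point to its own centroid.
    Denominator: mean pairwise distance between cluster centroids.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValueError("the validity index needs at least 2 clusters")
    centroids = np.vstack([features[labels == c].mean(axis=0) for c in ids])
    own = centroids[np.searchsorted(ids, labels)]
    within = float(np.linalg.norm(features - own, axis=1).mean())
    diffs = centroids[:, None, :] - centroids[None, :, :]
    dists = np.linalg.norm(diffs, axis=2)
    iu = np.triu_indices(len(ids), k=1)
    between = float(dists[iu].mean())
    if between == 0:
        raise ValueError("coincident centroids: between-cluster distance is zero")
    return within / between


def select_cluster_number(
    features: np.ndarray,
    k_min: int = 2,
    k_max: int = 24,
    rng_seed: int = 0,
    n_init: int = 10,
) -> ValidityCurve:
    """Scan k, compute the validity index, and pick the elbow of the curve.

    The elbow (knee) is the k maximising the perpendicular distance from the
    point ``(k, CVI(k))`` to the chord joining the curve's endpoints, after
    min-max normalisation of both axes.  Ties — including a perfectly linear
    curve, where every distance is zero — resolve toward the smaller k.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    v = features.shape[0]
    if not 2 <= k_min < k_max <= v - 1:
        raise ValueError(f"need 2 <= k_min < k_max <= V-1 (V={v})")
    k_values = list(range(k_min, k_max + 1))
    cvi = []
    for i, k in enumerate(k_values):
        labels = kmeans_cluster(features, k, rng_seed=rng_seed + i, n_init=n_init)
        cvi.append(cluster_validity_index(features, labels))
    selected = _knee(np.array(k_values, dtype=float), np.array(cvi))
    return ValidityCurve(k_values=k_values, cvi=cvi, selected_k=int(selected))


def _knee(k_values: np.ndarray, cvi: np.ndarray) -> int:
    """Maximum chord-distance knee after min-max normalising both axes."""
    kx = (k_values - k_values.min()) / (k_values.max() - k_values.min())
    span = cvi.max() - cvi.min()
    if span == 0:
        warnings.warn("flat validity curve; selecting k_min", UserWarning, stacklevel=3)
        return int(k_values[0])
    cy = (cvi - cvi.min()) / span
    x0, y0 = kx[0], cy[0]
    x1, y1 = kx[-1], cy[-1]
    # distance from (x, y) to the chord through (x0, y0)-(x1, y1)
    norm = np.hypot(x1 - x0, y1 - y0)
    dist = np.abs((y1 - y0) * kx - (x1 - x0) * cy + x1 * y0 - y1 * x0) / norm
    best = float(dist.max())
    if best < 1e-12:
        warnings.warn("no interior knee in the validity curve; selecting k_min",
                      UserWarning, stacklevel=3)
        return int(k_values[0])
    return int(k_values[int(np.argmax(dist))])  # argmax takes the first (smallest k) tie


def qc_screen(
    time_courses: np.ndarray,
    tr_seconds: float,
    fc_maps: np.ndarray | None = None,
    exclusion_mask: np.ndarray | None = None,
    high_hz: float = 0.1,
    max_high_power_fraction: float = 0.25,
    max_exclusion_correlation: float = 0.5,
) -> tuple[np.ndarray, dict]:
    """Automated component QC: spectral and exclusion-mask criteria.

    A component fails when more than ``max_high_power_fraction`` of its time
    course's spectral power lies above ``high_hz`` (high-frequency,
    noise-like fluctuation), or — if an exclusion mask such as a CSF proxy
    is supplied together with component FC maps — when the map's correlation
    with the mask exceeds ``max_exclusion_correlation``.  Returns pass flags
    and a report with the measured quantities.
    """
    tc = np.atleast_2d(np.asarray(time_courses, dtype=float))
    n = tc.shape[1]
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    power = np.abs(np.fft.rfft(tc - tc.mean(axis=1, keepdims=True), axis=1)) ** 2
    total = power.sum(axis=1)
    total[total == 0] = 1.0
    high_frac = power[:, freqs > high_hz].sum(axis=1) / total
    passes = high_frac <= max_high_power_fraction
    report: dict = {
        "high_frequency_power_fraction": high_frac.tolist(),
        "spectral_pass": passes.tolist(),
        "exclusion_correlation": None,
    }
    if exclusion_mask is not None:
        if fc_maps is None:
            raise ValueError("exclusion screening needs component FC maps")
        mask = np.asarray(exclusion_mask, dtype=float).ravel()
        corrs = np.array([
            _safe_corr(np.asarray(m, dtype=float).ravel(), mask) for m in fc_maps
        ])
        passes = passes & (np.abs(corrs) <= max_exclusion_correlation)
        report["exclusion_correlation"] = corrs.tolist()
    report["pass"] = passes.tolist()
    return passes, report


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def overlap_table(a: ParcellationVolume, b: ParcellationVolume) -> np.ndarray:
    """Percent of each parcel of B that falls inside each parcel of A.

    Entry (i, j) = 100 * |A_i intersect B_j| / |B_j| for the i-th parcel id
    of A and j-th of B.  Columns sum to 100 exactly when A's parcels cover
    B's support.
    """
    if not a.same_mask(b):
        raise ValueError("parcellations must share the same voxel mask")
    ids_a = a.parcel_ids
    ids_b = b.parcel_ids
    table = np.zeros((len(ids_a), len(ids_b)))
    la = a.labels.ravel()
    lb = b.labels.ravel()
    for j, pb in enumerate(ids_b):
        in_b = lb == pb
        denom = in_b.sum()
        for i, pa in enumerate(ids_a):
            table[i, j] = 100.0 * np.count_nonzero(la[in_b] == pa) / denom
    return table


@dataclass
class ParcellationResult:
    parcellation: ParcellationVolume
    components: ComponentMaps
    validity: ValidityCurve | None
    qc_report: dict
    kept_components: np.ndarray  # indices into the original component list


def parcellate(
    series_list: list[BoldSeries],
    volume_shape: tuple[int, int, int],
    ica_k: int = 24,
    k_scan: tuple[int, int] | None = (2, 24),
    fixed_k: int | None = None,
    rng_seed: int = 0,
    exclusion_mask: np.ndarray | None = None,
    fc_maps_for_qc: np.ndarray | None = None,
) -> ParcellationResult:
    """Full functional segmentation of pooled hippocampal series.

    Steps: pool subjects along time -> group ICA with ``ica_k`` components
    -> QC screen (failed components are dropped before feature building) ->
    Gaussian-mixture probability maps as per-voxel features -> k-means with
    the cluster count either fixed (``fixed_k``) or selected by the elbow of
    the validity index over ``k_scan`` -> anterior->posterior relabelling.
    """
    pooled = pool_subjects(series_list)
    comps = group_ica(pooled, ica_k, rng_seed=rng_seed)
    tr = series_list[0].tr_seconds
    passes, qc_report = qc_screen(
        comps.time_courses, tr, fc_maps=fc_maps_for_qc, exclusion_mask=exclusion_mask
    )
    kept = np.flatnonzero(passes)
    if len(kept) == 0:
        raise RuntimeError("QC screen rejected every component")
    spatial = comps.spatial_maps[kept]
    prob = np.empty_like(spatial)
    fallback = np.zeros(len(kept), dtype=bool)
    for i, m in enumerate(spatial):
        prob[i], fallback[i] = probability_from_map(m)
    qc_report["probability_fallback"] = fallback.tolist()
    comps.probability_maps = np.full((comps.k, comps.n_voxels), np.nan)
    comps.probability_maps[kept] = prob
    comps.probability_fallback = fallback

    features = prob.T  # voxels x kept-components
    validity = None
    if fixed_k is not None:
        k = fixed_k
    else:
        k_min, k_max = k_scan
        k_max = min(k_max, features.shape[0] - 1)
        validity = select_cluster_number(features, k_min, k_max, rng_seed=rng_seed)
        k = validity.selected_k
    labels0 = kmeans_cluster(features, k, rng_seed=rng_seed)

    volume = np.zeros(volume_shape, dtype=np.int32)
    volume.ravel()[series_list[0].location_ids] = labels0 + 1
    parc, _ = order_parcels_anterior_posterior(ParcellationVolume(volume))
    return ParcellationResult(
        parcellation=parc,
        components=comps,
        validity=validity,
        qc_report=qc_report,
        kept_components=kept,
    )
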