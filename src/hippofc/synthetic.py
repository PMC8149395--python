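"""Synthetic multi-subject resting-state cohort with planted ground truth.

The generator emulates the study conditions the pipeline is built for: a
cohort of ~16 subjects scanned for 180 timepoints at TR = 2 s, hippocampal
voxels organised into contiguous parcels along the longitudinal axis (a
configurable fraction mirrored across hemispheres, the rest unilateral), a
lamellar anatomical labelling that is bilaterally symmetric by construction,
seven cortical resting-state networks as contiguous vertex patches, and a
parcel -> network connectivity matrix that plants the ground-truth intrinsic
FC the downstream statistics must recover.

Signal model
------------
Each parcel j carries a band-limited (0.01-0.1 Hz) latent u_j(t) with zero
mean and unit variance, drawn independently per subject.  A hippocampal voxel
in parcel j observes ``u_j(t) + e(t)/snr`` with i.i.d. standard-normal noise
e.  A cortical vertex in network m observes the unit-variance normalisation of
``sum_j C[j, m] * u_j(t)`` plus noise of the same scale, where C is the
connectivity matrix.  Noise is white on purpose: it keeps the sign-flip
permutation null exact and the recovery targets interpretable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import BoldSeries, NetworkAtlas, ParcellationVolume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "SubjectData",
    "Cohort",
    "make_phantom",
    "band_limited_signal",
    "simulate_cohort",
]

#: canonical seven cortical resting-state network names
DEFAULT_NETWORK_NAMES = (
    "visual",
    "sensorimotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)

MIN_PARCEL_VOXELS = 8


@dataclass
class PhantomSpec:
    """Parameters of the synthetic cohort.

    Defaults follow the acquisition the pipeline targets (16 subjects,
    180 timepoints at TR = 2 s, seven networks) with a desk-scale voxel
    grid.  ``bilateral_fraction`` defaults to 0.35, i.e. roughly one third
    of parcels mirrored across hemispheres and the rest unilateral.
    ``snr`` (signal sd / noise sd) is a free parameter of the phantom.
    """

    grid_dims_per_hemisphere: tuple[int, int, int] = (12, 4, 4)
    n_true_parcels: int = 6
    bilateral_fraction: float = 0.35
    n_anatomical_labels: int = 4
    n_networks: int = 7
    n_vertices_per_network: int = 100
    n_subjects: int = 16
    n_timepoints: int = 180
    tr_seconds: float = 2.0
    snr: float = 2.0
    connectivity_matrix: np.ndarray | None = None
    rng_seed: int = 0
    low_hz: float = 0.01
    high_hz: float = 0.1

    def __post_init__(self) -> None:
        self.grid_dims_per_hemisphere = tuple(int(d) for d in self.grid_dims_per_hemisphere)
        if len(self.grid_dims_per_hemisphere) != 3 or min(self.grid_dims_per_hemisphere) < 1:
            raise ValueError("grid_dims_per_hemisphere must be 3 positive integers")
        if self.n_true_parcels < 2:
            raise ValueError("need at least 2 true parcels")
        if not 0.0 <= self.bilateral_fraction <= 1.0:
            raise ValueError("bilateral_fraction must lie in [0, 1]")
        if self.n_anatomical_labels < 1:
            raise ValueError("need at least one anatomical label")
        if self.n_networks < 2:
            raise ValueError("need at least 2 networks")
        if self.n_vertices_per_network < 1:
            raise ValueError("each network needs at least one vertex")
        if self.n_subjects < 1 or self.n_timepoints < 2:
            raise ValueError("need >= 1 subject and >= 2 timepoints")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if self.connectivity_matrix is not None:
            c = np.asarray(self.connectivity_matrix, dtype=float)
            if c.shape != (self.n_true_parcels, self.n_networks):
                raise ValueError("connectivity_matrix must be n_true_parcels x n_networks")
            if c.min() < 0:
                raise ValueError("connectivity weights must be nonnegative")
            if np.any(c.sum(axis=1) == 0):
                # a parcel without cortical targets is a legitimate null
                # condition (its seed should show no significant iFC)
                warnings.warn(
                    "connectivity_matrix has all-zero rows: the corresponding "
                    "parcels have no cortical targets",
                    UserWarning,
                    stacklevel=2,
                )
            self.connectivity_matrix = c
        # the 0.01 Hz band edge must be resolvable within the scan duration
        if self.n_timepoints * self.tr_seconds <= 1.0 / self.low_hz:
            warnings.warn(
                "scan duration does not resolve the lower band edge "
                f"({self.n_timepoints * self.tr_seconds:.0f} s <= {1.0 / self.low_hz:.0f} s)",
                UserWarning,
                stacklevel=2,
            )

    @property
    def hemisphere_voxels(self) -> int:
        a, b, c = self.grid_dims_per_hemisphere
        return a * b * c

    def default_connectivity(self) -> np.ndarray:
        """One-hot parcel -> network assignment, cycling through networks.

        Parcel j projects to network ``j mod n_networks`` with unit weight;
        every row therefore has exactly one nonzero entry, giving each seed a
        fully specific cortical target (non-uniformity 1 in the ground truth).
        """
        c = np.zeros((self.n_true_parcels, self.n_networks))
        c[np.arange(self.n_true_parcels), np.arange(self.n_true_parcels) % self.n_networks] = 1.0
        return c

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["connectivity_matrix"] is not None:
            d["connectivity_matrix"] = np.asarray(d["connectivity_matrix"]).tolist()
        d["grid_dims_per_hemisphere"] = list(d["grid_dims_per_hemisphere"])
        return d


@dataclass
class GroundTruth:
    """Planted truth of one phantom: labels, atlas, latents, connectivity."""

    true_parcel_labels: ParcellationVolume
    anatomical_labels: ParcellationVolume
    network_atlas: NetworkAtlas
    parcel_latents: np.ndarray  # (n_subjects, n_parcels, n_timepoints)
    network_latents: np.ndarray  # (n_subjects, n_networks, n_timepoints)
    connectivity_matrix: np.ndarray
    parcel_hemispheres: dict[int, str] = field(default_factory=dict)  # 'left'/'right'/'bilateral'

    @property
    def n_parcels(self) -> int:
        return self.true_parcel_labels.n_parcels


@dataclass
class SubjectData:
    """One subject's simulated data: hippocampal voxels plus cortical vertices."""

    hippocampus: BoldSeries
    cortex: BoldSeries
    tsnr: float
    gender: int


@dataclass
class Cohort:
    subjects: list[SubjectData]
    truth: GroundTruth
    spec: PhantomSpec

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def covariate_table(self) -> np.ndarray:
        """(n_subjects, 2) array of [seed tSNR, gender]."""
        return np.array([[s.tsnr, float(s.gender)] for s in self.subjects])


def _slab_edges(extent: int, n_slabs: int) -> np.ndarray:
    """Split 0..extent into n_slabs contiguous integer slabs, sizes within 1."""
    return np.round(np.linspace(0, extent, n_slabs + 1)).astype(int)


def make_phantom(spec: PhantomSpec) -> GroundTruth:
    """Build ground-truth geometry, atlas and latent signals for a phantom.

    The volume holds two hemisphere grids side by side along axis 1 with a
    one-voxel background gap.  True parcels are contiguous slabs along the
    longitudinal axis (axis 0): bilateral parcels occupy the same slab in
    both hemispheres under one label; the remaining longitudinal extent is
    tiled by unilateral slabs, split between hemispheres as evenly as the
    parcel count allows.  Anatomical labels are lamellar shells along the
    dorsal-ventral axis spanning the full longitudinal extent, mirrored
    across hemispheres.  Parcel labels are sorted anterior -> posterior by
    centroid; ties (a left/right pair of the same slab) put left first.
    """
    rng = np.random.default_rng(spec.rng_seed)
    L, M, D = spec.grid_dims_per_hemisphere
    n = spec.n_true_parcels

    n_bilateral = int(round(spec.bilateral_fraction * n))
    n_unilateral = n - n_bilateral
    # a slab of one hemisphere not covered by a bilateral parcel must be
    # covered by a unilateral one on each side, so the unilateral count
    # splits into left/right groups tiling the same leftover extent
    n_uni_left = (n_unilateral + 1) // 2
    n_uni_right = n_unilateral // 2
    if n_unilateral == 1:
        raise ValueError(
            "a single unilateral parcel cannot tile both hemispheres; "
            "choose bilateral_fraction so that the unilateral count is 0 or >= 2"
        )

    # longitudinal budget: bilateral slabs first (anterior), then the
    # unilateral region, tiled independently per hemisphere
    slabs_needed = n_bilateral + max(n_uni_left, n_uni_right, 1 if n_unilateral else 0)
    min_thickness = int(np.ceil(MIN_PARCEL_VOXELS / (M * D)))
    if slabs_needed * min_thickness > L:
        raise ValueError(
            f"grid too small: {slabs_needed} longitudinal slabs of >= "
            f"{min_thickness} voxels needed but axis 0 has only {L}"
        )

    width = 2 * M + 1  # hemispheres separated by a background column
    labels = np.zeros((L, width, D), dtype=np.int32)
    left = slice(0, M)
    right = slice(M + 1, width)

    if n_unilateral:
        # bilateral region thickness proportional to its parcel share
        l_bilateral = int(round(L * n_bilateral / (n_bilateral + max(n_uni_left, n_uni_right))))
        l_bilateral = max(l_bilateral, n_bilateral * min_thickness)
        l_bilateral = min(l_bilateral, L - max(n_uni_left, n_uni_right) * min_thickness)
    else:
        l_bilateral = L

    hemis: dict[int, str] = {}
    label = 0
    if n_bilateral:
        edges = _slab_edges(l_bilateral, n_bilateral)
        for s in range(n_bilateral):
            label += 1
            labels[edges[s]:edges[s + 1], left, :] = label
            labels[edges[s]:edges[s + 1], right, :] = label
            hemis[label] = "bilateral"
    for side, n_side in ((left, n_uni_left), (right, n_uni_right)):
        if n_side == 0:
            continue
        edges = _slab_edges(L - l_bilateral, n_side) + l_bilateral
        for s in range(n_side):
            label += 1
            labels[edges[s]:edges[s + 1], side, :] = label
            hemis[label] = "left" if side is left else "right"

    counts = np.bincount(labels.ravel())[1:]
    if len(counts) != n or counts.min() < MIN_PARCEL_VOXELS:
        raise ValueError(
            f"grid too small to host {n} parcels with >= {MIN_PARCEL_VOXELS} voxels each"
        )

    parcels = ParcellationVolume(labels)
    parcels, order = order_parcels_anterior_posterior(parcels)
    hemis = {int(new): hemis[int(old)] for new, old in enumerate(order, start=1)}

    # lamellar anatomical shells: layers along the dorsal-ventral axis,
    # spanning the full longitudinal extent, identical in both hemispheres
    anat = np.zeros_like(labels)
    shell_edges = _slab_edges(D, spec.n_anatomical_labels)
    for s in range(spec.n_anatomical_labels):
        anat[:, left, shell_edges[s]:shell_edges[s + 1]] = s + 1
        anat[:, right, shell_edges[s]:shell_edges[s + 1]] = s + 1
    anatomical = ParcellationVolume(anat)

    # network atlas: contiguous equal-size vertex patches
    atlas_labels = np.repeat(np.arange(1, spec.n_networks + 1), spec.n_vertices_per_network)
    names = [
        DEFAULT_NETWORK_NAMES[i] if i < len(DEFAULT_NETWORK_NAMES) else f"network_{i + 1}"
        for i in range(spec.n_networks)
    ]
    atlas = NetworkAtlas(atlas_labels, names)

    C = (
        np.asarray(spec.connectivity_matrix, dtype=float)
        if spec.connectivity_matrix is not None
        else spec.default_connectivity()
    )

    parcel_latents = np.empty((spec.n_subjects, n, spec.n_timepoints))
    for s in range(spec.n_subjects):
        for j in range(n):
            parcel_latents[s, j] = band_limited_signal(
                spec.n_timepoints, spec.tr_seconds, spec.low_hz, spec.high_hz, rng
            )
    # network latents: connectivity-weighted sums of parcel latents,
    # standardised to unit variance (zero networks stay zero)
    network_latents = np.einsum("jm,sjt->smt", C, parcel_latents)
    sd = network_latents.std(axis=2, keepdims=True)
    np.divide(network_latents, sd, out=network_latents, where=sd > 0)
    network_latents -= network_latents.mean(axis=2, keepdims=True)

    return GroundTruth(
        true_parcel_labels=parcels,
        anatomical_labels=anatomical,
        network_atlas=atlas,
        parcel_latents=parcel_latents,
        network_latents=network_latents,
        connectivity_matrix=C,
        parcel_hemispheres=hemis,
    )


def band_limited_signal(
    n_timepoints: int,
    tr_seconds: float,
    low_hz: float,
    high_hz: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Zero-mean unit-variance series with power confined to [low_hz, high_hz].

    The series is synthesised in the frequency domain: independent complex
    Gaussian coefficients on the in-band rFFT bins, zeros elsewhere, then an
    inverse transform and exact standardisation (which only rescales, so the
    spectrum stays in-band).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz={high_hz} must lie below Nyquist={nyquist}")
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
    in_band = (freqs >= low_hz) & (freqs <= high_hz)
    in_band[0] = False  # never excite DC
    n_bins = int(in_band.sum())
    if n_bins == 0:
        raise ValueError(
            "no FFT bin falls inside the requested band; series too short "
            "for the lower band edge"
        )
    coeff = np.zeros(len(freqs), dtype=complex)
    coeff[in_band] = rng.standard_normal(n_bins) + 1j * rng.standard_normal(n_bins)
    x = np.fft.irfft(coeff, n=n_timepoints)
    x -= x.mean()
    x /= x.std()
    return x


def simulate_cohort(truth: GroundTruth, spec: PhantomSpec) -> Cohort:
    """Assemble per-subject voxel and vertex series plus covariates.

    Everything is a pure function of (spec, truth); the noise stream is
    seeded from ``spec.rng_seed`` independently of the latent stream used in
    :func:`make_phantom`.
    """
    if truth.parcel_latents.shape != (spec.n_subjects, spec.n_true_parcels, spec.n_timepoints):
        raise ValueError("ground truth inconsistent with spec")
    rng = np.random.default_rng(np.random.SeedSequence((spec.rng_seed, 1)))
    labels = truth.true_parcel_labels.labels
    voxel_ids = np.flatnonzero(labels.ravel() > 0)
    voxel_parcels = labels.ravel()[voxel_ids]  # 1-based parcel per voxel row
    atlas = truth.network_atlas
    noise_sd = 1.0 / spec.snr

    subjects: list[SubjectData] = []
    for s in range(spec.n_subjects):
        hippo = truth.parcel_latents[s][voxel_parcels - 1]
        hippo = hippo + noise_sd * rng.standard_normal(hippo.shape)
        cortex = truth.network_latents[s][atlas.labels - 1]
        cortex = cortex + noise_sd * rng.standard_normal(cortex.shape)
        hippo_series = BoldSeries(hippo, voxel_ids, spec.tr_seconds)
        cortex_series = BoldSeries(cortex, np.arange(atlas.n_vertices), spec.tr_seconds)
        # tSNR proxy: baseline-to-fluctuation ratio of the whole-hippocampus
        # mean series (baseline 100 a.u., as for raw BOLD) plus jitter
        seed_mean = hippo.mean(axis=0)
        tsnr = 100.0 / seed_mean.std() + rng.normal(0.0, 1.0)
        subjects.append(
            SubjectData(
                hippocampus=hippo_series,
                cortex=cortex_series,
                tsnr=float(tsnr),
                gender=s % 2,
            )
        )
    return Cohort(subjects=subjects, truth=truth, spec=spec)


def order_parcels_anterior_posterior(
    parcels: ParcellationVolume,
) -> tuple[ParcellationVolume, np.ndarray]:
    """Relabel parcels so the label increases anterior -> posterior.

    Returns the relabelled volume and the old labels in their new order
    (``order[i]`` is the old label that became ``i+1``).  Ties on the
    longitudinal centroid are broken by the medial-lateral centroid (left
    hemisphere first), then by old label.
    """
    labels = parcels.labels
    ids = parcels.parcel_ids
    cent_long = np.empty(len(ids))
    cent_ml = np.empty(len(ids))
    for i, pid in enumerate(ids):
        where = np.argwhere(labels == pid)
        cent_long[i] = where[:, 0].mean()
        cent_ml[i] = where[:, 1].mean()
    order = ids[np.lexsort((ids, cent_ml, cent_long))]
    new = np.zeros_like(labels)
    for new_id, old_id in enumerate(order, start=1):
        new[labels == old_id] = new_id
    return ParcellationVolume(new), order
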