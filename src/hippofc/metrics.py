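"""Network-level summaries of significant iFC maps.

Given binary significance maps over cortical vertices and a resting-state
network atlas, this module computes per-network coverage percentages, the
non-uniformity statistic nu quantifying how selectively a hippocampal seed
connects to the networks, specificity tertiles, merged-map coverages,
per-vertex hippocampal-coverage maps, and two-map overlap partitions with
the dice coefficient.

Non-uniformity
--------------
For a coverage vector c (percent of each of n networks significantly
connected to a seed), let c' = c / sum(c).  Then

    nu = (||c'||_2 * sqrt(n) - 1) / (sqrt(n) - 1)

which is 0 when the seed covers every network equally (||c'||_2 = 1/sqrt(n))
and 1 when all mass sits in a single network (||c'||_2 = 1).  nu is
invariant to positive rescaling of c, so it does not matter whether c is
stored in percent or as fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import NetworkAtlas, VertexMap

__all__ = [
    "CoverageVector",
    "OverlapPartition",
    "coverage_vector",
    "nonuniformity",
    "specificity_tertiles",
    "merged_map",
    "hippocampal_coverage_map",
    "overlap_partition",
    "dice",
]


@dataclass
class CoverageVector:
    """Per-network coverage percentages with derived normalisation and nu."""

    c: np.ndarray  # percent per network
    names: list[str]

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if self.c.ndim != 1:
            raise ValueError("coverage must be a vector")
        if self.c.min(initial=0) < 0:
            raise ValueError("coverage percentages are nonnegative")
        if len(self.names) != len(self.c):
            raise ValueError("one name per network required")

    @property
    def n(self) -> int:
        return len(self.c)

    @property
    def c_prime(self) -> np.ndarray:
        total = self.c.sum()
        if total == 0:
            raise ValueError("c' is undefined for an all-zero coverage vector")
        return self.c / total

    @property
    def nu(self) -> float:
        return nonuniformity(self.c)


def coverage_vector(significance: VertexMap, atlas: NetworkAtlas) -> CoverageVector:
    """Percent of each network's vertices inside the significance mask."""
    if significance.n_vertices != atlas.n_vertices:
        raise ValueError("significance map and atlas must share the vertex set")
    mask = significance.binary()
    sizes = atlas.network_sizes()
    hits = np.bincount(atlas.labels[mask], minlength=atlas.n + 1)[1:]
    return CoverageVector(100.0 * hits / sizes, list(atlas.names))


def nonuniformity(c: np.ndarray | CoverageVector) -> float:
    """Non-uniformity nu of a nonnegative coverage vector (see module docs).

    Raises on an all-zero vector, where the statistic is undefined.
    """
    if isinstance(c, CoverageVector):
        c = c.c
    c = np.asarray(c, dtype=float)
    if c.ndim != 1 or len(c) < 2:
        raise ValueError("need a coverage vector with n >= 2 networks")
    if c.min() < 0:
        raise ValueError("coverage entries must be nonnegative")
    total = c.sum()
    if total == 0:
        raise ValueError(
            "non-uniformity is undefined for an all-zero coverage vector "
            "(the seed shows no significant connectivity in any network)"
        )
    c_prime = c / total
    n = len(c)
    sqrt_n = np.sqrt(n)
    nu = (np.linalg.norm(c_prime) * sqrt_n - 1.0) / (sqrt_n - 1.0)
    # norm of a simplex vector lies in [1/sqrt(n), 1]; clip rounding spill
    return float(np.clip(nu, 0.0, 1.0))


def specificity_tertiles(
    nu_values: list[float], seed_ids: list[int] | None = None
) -> tuple[list[int], list[int], list[int]]:
    """Split seeds into high / medium / low specificity thirds by nu.

    Seeds are sorted by descending nu (ties broken by ascending seed id) and
    split into three groups; when the count is not divisible by 3 the extra
    members go to the earlier (higher-specificity) groups.  Returns the seed
    ids of the (high, medium, low) groups.
    """
    nu_values = list(nu_values)
    if len(nu_values) < 3:
        raise ValueError("need at least 3 seeds to form tertiles")
    if seed_ids is None:
        seed_ids = list(range(1, len(nu_values) + 1))
    if len(seed_ids) != len(nu_values):
        raise ValueError("one seed id per nu value required")
    order = sorted(range(len(nu_values)), key=lambda i: (-nu_values[i], seed_ids[i]))
    m = len(order)
    base, extra = divmod(m, 3)
    sizes = [base + (1 if g < extra else 0) for g in range(3)]
    groups: list[list[int]] = []
    start = 0
    for size in sizes:
        groups.append([seed_ids[i] for i in order[start:start + size]])
        start += size
    return tuple(groups)  # type: ignore[return-value]


def merged_map(
    significance_maps: list[VertexMap], atlas: NetworkAtlas | None = None
) -> tuple[VertexMap, float, CoverageVector | None]:
    """Vertex-wise union of significance maps with coverage summaries.

    Returns the union map, the percent of the cortical surface it covers,
    and (when an atlas is given) the per-network coverage of the union.
    """
    if not significance_maps:
        raise ValueError("need at least one significance map to merge")
    v = significance_maps[0].n_vertices
    union = np.zeros(v, dtype=bool)
    for m in significance_maps:
        if m.n_vertices != v:
            raise ValueError("all maps must share the vertex set")
        union |= m.binary()
    union_map = VertexMap(union.astype(float), kind="significance")
    cortical_percent = 100.0 * union.sum() / v
    per_network = coverage_vector(union_map, atlas) if atlas is not None else None
    return union_map, float(cortical_percent), per_network


def hippocampal_coverage_map(
    significance_maps: dict[int, VertexMap], seed_voxel_counts: dict[int, int]
) -> VertexMap:
    """Volumetric fraction of the hippocampus significantly connected per vertex.

    For every cortical vertex, sums the voxel counts of the seeds whose
    significance map includes that vertex and divides by the total
    hippocampal voxel count (the seeds partition the hippocampus).
    """
    if set(significance_maps) != set(seed_voxel_counts):
        raise ValueError("significance maps and seed volumes must cover the same seeds")
    if any(v <= 0 for v in seed_voxel_counts.values()):
        raise ValueError("seed volumes must be positive")
    total = sum(seed_voxel_counts.values())
    seeds = sorted(significance_maps)
    v = significance_maps[seeds[0]].n_vertices
    acc = np.zeros(v)
    for s in seeds:
        m = significance_maps[s]
        if m.n_vertices != v:
            raise ValueError("all maps must share the vertex set")
        acc += seed_voxel_counts[s] * m.binary()
    return VertexMap(acc / total, kind="coverage")


@dataclass
class OverlapPartition:
    """Four-way vertex classification of two binary maps, with dice."""

    classes: np.ndarray  # per-vertex string code: both / a_only / b_only / neither
    dice: float | None  # None when both maps are empty
    per_network_percent: dict[str, dict[str, float]] | None = None

    @property
    def counts(self) -> dict[str, int]:
        keys, counts = np.unique(self.classes, return_counts=True)
        out = {k: 0 for k in ("both", "a_only", "b_only", "neither")}
        out.update(dict(zip(keys.tolist(), counts.tolist())))
        return out


def dice(a: np.ndarray, b: np.ndarray) -> float | None:
    """Dice coefficient 2|A.B| / (|A| + |B|); None when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return None
    return float(2.0 * (a & b).sum() / denom)


def overlap_partition(
    binary_a: VertexMap, binary_b: VertexMap, atlas: NetworkAtlas | None = None
) -> OverlapPartition:
    """Classify vertices into both / a_only / b_only / neither, with dice.

    When an atlas is supplied, also reports the percentages of the both,
    a_only and b_only classes within each network (relative to the
    network's vertex count).
    """
    if binary_a.n_vertices != binary_b.n_vertices:
        raise ValueError("maps must share the vertex set")
    a = binary_a.binary()
    b = binary_b.binary()
    classes = np.full(a.shape, "neither", dtype=object)
    classes[a & b] = "both"
    classes[a & ~b] = "a_only"
    classes[~a & b] = "b_only"
    d = dice(a, b)
    per_network = None
    if atlas is not None:
        if atlas.n_vertices != binary_a.n_vertices:
            raise ValueError("atlas must share the vertex set")
        per_network = {}
        sizes = atlas.network_sizes()
        for i, name in enumerate(atlas.names):
            in_net = atlas.labels == i + 1
            per_network[name] = {
                cls: 100.0 * float(np.sum((classes == cls) & in_net)) / sizes[i]
                for cls in ("both", "a_only", "b_only")
            }
    return OverlapPartition(classes=classes, dice=d, per_network_percent=per_network)
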