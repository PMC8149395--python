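"""Toy triangulated surface meshes for synthetic cortical data.

Real analyses run on a template cortical surface; the synthetic cohort uses a
regular planar grid mesh whose vertex ordering matches the network atlas
(vertices of one network form a contiguous index block, i.e. a contiguous
band of grid rows).
"""

from __future__ import annotations

import numpy as np

from .containers import SurfaceMesh

__all__ = ["make_grid_mesh", "make_cortex_mesh"]


def make_grid_mesh(n_rows: int, n_cols: int, spacing_mm: float = 1.5) -> SurfaceMesh:
    """Planar rectangular grid of n_rows x n_cols vertices, triangulated.

    Vertex index = row * n_cols + col; each grid cell is split into two
    triangles.  ``spacing_mm`` is the horizontal/vertical edge length.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("grid mesh needs at least 2 rows and 2 columns")
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    positions = np.column_stack(
        [cc.ravel() * spacing_mm, rr.ravel() * spacing_mm, np.zeros(n_rows * n_cols)]
    )
    tris = []
    for r in range(n_rows - 1):
        for c in range(n_cols - 1):
            v00 = r * n_cols + c
            v01 = v00 + 1
            v10 = v00 + n_cols
            v11 = v10 + 1
            tris.append((v00, v01, v11))
            tris.append((v00, v11, v10))
    return SurfaceMesh(positions, np.array(tris, dtype=int))


def _patch_columns(n_vertices_per_network: int) -> int:
    """Largest divisor of the patch size not exceeding its square root."""
    best = 1
    d = 1
    while d * d <= n_vertices_per_network:
        if n_vertices_per_network % d == 0:
            best = d
        d += 1
    return best


def make_cortex_mesh(
    n_networks: int, n_vertices_per_network: int, spacing_mm: float = 1.5
) -> SurfaceMesh:
    """Grid mesh whose rows tile into ``n_networks`` equal contiguous patches.

    With vertex index = row * n_cols + col, network ``i`` (labels
    ``1 + i``) owns vertices ``i * n_vertices_per_network`` to
    ``(i + 1) * n_vertices_per_network - 1``, matching the synthetic atlas.
    """
    n_cols = max(_patch_columns(n_vertices_per_network), 2)
    if n_vertices_per_network % n_cols != 0:
        raise ValueError("n_vertices_per_network must factor into a grid patch")
    rows_per_network = n_vertices_per_network // n_cols
    return make_grid_mesh(n_networks * rows_per_network, n_cols, spacing_mm)
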