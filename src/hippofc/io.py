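"""File round-trips for pipeline artifacts.

Volumes (masks, label maps) travel as NIfTI with an isotropic affine;
per-vertex fields and tables as TSV; meshes as GIFTI; cohort matrices as a
documented ``.npz`` container (arrays ``hippocampus`` (S x V x T), ``cortex``
(S x W x T), ``voxel_ids``, ``tr_seconds``, ``covariates`` (S x 2: seed tSNR,
gender)); configs as YAML and manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .containers import NetworkAtlas, ParcellationVolume, SurfaceMesh, VertexMap

__all__ = [
    "save_labels_nifti",
    "load_labels_nifti",
    "save_vertex_map_tsv",
    "load_vertex_map_tsv",
    "save_atlas_tsv",
    "load_atlas_tsv",
    "save_mesh_gifti",
    "load_mesh_gifti",
    "save_json",
    "load_json",
    "save_yaml",
    "load_yaml",
]


def save_labels_nifti(
    parc: ParcellationVolume, path: str | Path, voxel_size_mm: float = 0.94
) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(parc.labels.astype(np.int32), affine)
    img.header.set_data_dtype(np.int32)
    nib.save(img, str(path))


def load_labels_nifti(path: str | Path) -> ParcellationVolume:
    img = nib.load(str(path))
    return ParcellationVolume(np.asarray(img.dataobj).astype(np.int32))


def save_vertex_map_tsv(vmap: VertexMap, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "vertex_id": np.arange(vmap.n_vertices),
            "value": vmap.values,
            "kind": vmap.kind,
            "flag": vmap.flags if vmap.flags is not None else np.zeros(vmap.n_vertices, bool),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_vertex_map_tsv(path: str | Path) -> VertexMap:
    df = pd.read_csv(path, sep="\t")
    return VertexMap(
        df["value"].to_numpy(float),
        kind=str(df["kind"].iloc[0]),
        flags=df["flag"].to_numpy(bool),
    )


def save_atlas_tsv(atlas: NetworkAtlas, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "vertex_id": np.arange(atlas.n_vertices),
            "network": atlas.labels,
            "network_name": [atlas.names[i - 1] for i in atlas.labels],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_atlas_tsv(path: str | Path) -> NetworkAtlas:
    df = pd.read_csv(path, sep="\t")
    labels = df["network"].to_numpy(int)
    names_by_label: dict[int, str] = {}
    for lab, name in zip(labels, df["network_name"]):
        names_by_label[int(lab)] = str(name)
    names = [names_by_label[i] for i in sorted(names_by_label)]
    return NetworkAtlas(labels, names)


def save_mesh_gifti(mesh: SurfaceMesh, path: str | Path) -> None:
    coords = nib.gifti.GiftiDataArray(
        mesh.vertex_positions.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
    )
    tris = nib.gifti.GiftiDataArray(
        mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[coords, tris]), str(path))


def load_mesh_gifti(path: str | Path) -> SurfaceMesh:
    img = nib.load(str(path))
    coords, tris = img.darrays[0].data, img.darrays[1].data
    return SurfaceMesh(np.asarray(coords, float), np.asarray(tris, int))


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def save_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
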