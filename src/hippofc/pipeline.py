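"""End-to-end orchestration: simulate -> preprocess -> parcellate -> map FC -> score.

Each stage reads and writes declared file artifacts inside a run directory,
so stages can be re-run independently; a JSON manifest records the exact
configuration, per-stage derived seeds and package versions.  Re-running
with an identical configuration reproduces label volumes bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import BoldSeries, NetworkAtlas, ParcellationVolume, VertexMap
from .ifc import GroupModel, fisher_z, correlation_map, permutation_correct, seed_timecourse
from .io import (
    load_atlas_tsv,
    load_json,
    load_labels_nifti,
    save_atlas_tsv,
    save_json,
    save_labels_nifti,
    save_mesh_gifti,
    save_vertex_map_tsv,
    save_yaml,
)
from .meshes import make_cortex_mesh
from .metrics import (
    coverage_vector,
    hippocampal_coverage_map,
    merged_map,
    nonuniformity,
    overlap_partition,
    specificity_tertiles,
)
from .parcellation import overlap_table, parcellate
from .preprocessing import bandpass_filter, surface_smooth
from .synthetic import Cohort, PhantomSpec, make_phantom, simulate_cohort

logger = logging.getLogger("hippofc")

STAGES = ("simulate", "parcellate", "connect", "score")


@dataclass
class RunConfig:
    """All pipeline settings, with the study's default numeric values.

    Defaults: band-pass 0.01-0.1 Hz, surface smoothing FWHM 3 mm, group ICA
    with 24 components, cluster-count scan 2..24, 4000 permutations with
    vertex- and cluster-wise thresholds of 0.05.  ``n_perm`` is reducible
    for desk-scale synthetic runs; whatever value is used is recorded in the
    manifest.
    """

    mode: str = "synthetic"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    ica_k: int = 24
    k_scan: tuple[int, int] = (2, 24)
    fixed_k: int | None = None
    low_hz: float = 0.01
    high_hz: float = 0.1
    fwhm_mm: float = 3.0
    n_perm: int = 4000
    vertex_alpha: float = 0.05
    cluster_alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        if not 0 < self.vertex_alpha < 1:
            raise ValueError(f"vertex_alpha={self.vertex_alpha} must lie in (0, 1)")
        if not 0 < self.cluster_alpha < 1:
            raise ValueError(f"cluster_alpha={self.cluster_alpha} must lie in (0, 1)")
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.ica_k < 1:
            raise ValueError("ica_k must be >= 1")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        k_min, k_max = self.k_scan
        if not 2 <= k_min < k_max:
            raise ValueError("k_scan must be an increasing range starting at >= 2")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be nonnegative")

    def stage_seed(self, stage: str) -> int:
        """Per-stage reproducible seed derived from the top-level rng_seed."""
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence((int(self.rng_seed), idx))
        return int(ss.generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"] = self.phantom.to_dict()
        d["k_scan"] = list(self.k_scan)
        return d

    def config_hash(self) -> str:
        import json

        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _timer(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            logger.info("stage %s: %.1f s", stage, time.perf_counter() - self.t0)

    return _T()


def _npz_path(run_dir: Path) -> Path:
    return run_dir / "cohort.npz"


def stage_simulate(config: RunConfig, run_dir: str | Path) -> Cohort:
    """Generate the phantom and cohort and write the stage artifacts."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    if config.mode != "synthetic":
        raise NotImplementedError("only synthetic mode generates data")
    with _timer("simulate"):
        spec = dataclasses.replace(config.phantom)
        truth = make_phantom(spec)
        cohort = simulate_cohort(truth, spec)
        save_yaml(config.to_dict(), run_dir / "config.yaml")
        save_labels_nifti(truth.true_parcel_labels, run_dir / "true_labels.nii.gz")
        save_labels_nifti(truth.anatomical_labels, run_dir / "anatomical_labels.nii.gz")
        save_atlas_tsv(truth.network_atlas, run_dir / "atlas.tsv")
        mesh = make_cortex_mesh(spec.n_networks, spec.n_vertices_per_network)
        save_mesh_gifti(mesh, run_dir / "cortex_mesh.surf.gii")
        pd.DataFrame(
            cohort.covariate_table(), columns=["seed_tsnr", "gender"]
        ).rename_axis("subject").to_csv(run_dir / "covariates.tsv", sep="\t")
        np.savez_compressed(
            _npz_path(run_dir),
            hippocampus=np.stack([s.hippocampus.values for s in cohort.subjects]),
            cortex=np.stack([s.cortex.values for s in cohort.subjects]),
            voxel_ids=cohort.subjects[0].hippocampus.location_ids,
            tr_seconds=np.array(spec.tr_seconds),
            covariates=cohort.covariate_table(),
        )
        _write_manifest(config, run_dir, "simulate")
    return cohort


def _load_cohort_arrays(run_dir: Path) -> dict:
    with np.load(_npz_path(run_dir)) as z:
        return {k: z[k] for k in z.files}


def _preprocessed_series(config: RunConfig, run_dir: Path) -> tuple[list[BoldSeries], list[BoldSeries], np.ndarray]:
    """Band-pass filtered hippocampal and cortical series per subject."""
    arrays = _load_cohort_arrays(run_dir)
    tr = float(arrays["tr_seconds"])
    hip, cor = [], []
    n_vertices = arrays["cortex"].shape[1]
    for s in range(arrays["hippocampus"].shape[0]):
        hs = BoldSeries(arrays["hippocampus"][s], arrays["voxel_ids"], tr)
        cs = BoldSeries(arrays["cortex"][s], np.arange(n_vertices), tr)
        hip.append(bandpass_filter(hs, config.low_hz, config.high_hz))
        cor.append(bandpass_filter(cs, config.low_hz, config.high_hz))
    return hip, cor, arrays["covariates"]


def stage_parcellate(config: RunConfig, run_dir: str | Path):
    """Functional segmentation of the pooled, filtered hippocampal series."""
    run_dir = Path(run_dir)
    with _timer("parcellate"):
        hip, _, _ = _preprocessed_series(config, run_dir)
        shape = load_labels_nifti(run_dir / "true_labels.nii.gz").labels.shape
        result = parcellate(
            hip,
            shape,
            ica_k=config.ica_k,
            k_scan=config.k_scan,
            fixed_k=config.fixed_k,
            rng_seed=config.stage_seed("parcellate"),
        )
        save_labels_nifti(result.parcellation, run_dir / "functional_labels.nii.gz")
        save_json(result.qc_report, run_dir / "qc_report.json")
        if result.validity is not None:
            pd.DataFrame(
                {"k": result.validity.k_values, "cvi": result.validity.cvi}
            ).to_csv(run_dir / "validity_curve.tsv", sep="\t", index=False)
            save_json(
                {"selected_k": result.validity.selected_k},
                run_dir / "selected_k.json",
            )
        _write_manifest(config, run_dir, "parcellate")
    return result


def _seed_significance(
    config: RunConfig,
    hip: list[BoldSeries],
    cor: list[BoldSeries],
    covariates: np.ndarray,
    labels: ParcellationVolume,
    mesh,
    seed_id: int,
    perm_seed: int,
) -> tuple[VertexMap, VertexMap]:
    """One seed's group significance map: r -> z -> smooth -> GLM -> permutation."""
    z_maps = []
    for hs, cs in zip(hip, cor):
        tc = seed_timecourse(hs, labels, seed_id)
        r = correlation_map(tc, cs.values)
        z = fisher_z(r)
        z = surface_smooth(z, mesh, config.fwhm_mm)
        z_maps.append(z.values)
    model = GroupModel(np.vstack(z_maps), covariates=covariates)
    result = permutation_correct(
        model,
        mesh,
        n_perm=config.n_perm,
        vertex_alpha=config.vertex_alpha,
        cluster_alpha=config.cluster_alpha,
        rng_seed=perm_seed,
    )
    return result.significance, result.corrected_z


def stage_connect(config: RunConfig, run_dir: str | Path) -> None:
    """Seed-based iFC maps for every functional and anatomical seed."""
    run_dir = Path(run_dir)
    with _timer("connect"):
        hip, cor, covariates = _preprocessed_series(config, run_dir)
        mesh = make_cortex_mesh(
            config.phantom.n_networks, config.phantom.n_vertices_per_network
        )
        fc_dir = run_dir / "fc"
        fc_dir.mkdir(exist_ok=True)
        base_seed = config.stage_seed("connect")
        for tag, labels_file in (
            ("functional", "functional_labels.nii.gz"),
            ("anatomical", "anatomical_labels.nii.gz"),
        ):
            labels = load_labels_nifti(run_dir / labels_file)
            for i, seed_id in enumerate(labels.parcel_ids):
                sig, cz = _seed_significance(
                    config, hip, cor, covariates, labels, mesh,
                    int(seed_id), perm_seed=base_seed + 1000 * (tag == "anatomical") + i,
                )
                save_vertex_map_tsv(sig, fc_dir / f"{tag}_seed{seed_id:02d}_significance.tsv")
                save_vertex_map_tsv(cz, fc_dir / f"{tag}_seed{seed_id:02d}_corrected_z.tsv")
        save_json(
            {
                "n_perm": config.n_perm,
                "vertex_alpha": config.vertex_alpha,
                "cluster_alpha": config.cluster_alpha,
                "fwhm_mm": config.fwhm_mm,
                "rng_seed": config.rng_seed,
            },
            fc_dir / "fc_manifest.json",
        )
        _write_manifest(config, run_dir, "connect")


def _load_seed_maps(run_dir: Path, tag: str) -> dict[int, VertexMap]:
    from .io import load_vertex_map_tsv

    maps = {}
    for f in sorted((run_dir / "fc").glob(f"{tag}_seed*_significance.tsv")):
        seed_id = int(f.name.split("seed")[1].split("_")[0])
        maps[seed_id] = load_vertex_map_tsv(f)
    return maps


def stage_score(config: RunConfig, run_dir: str | Path) -> dict:
    """Network metrics: coverage, nu, tertiles, merged maps, partition, dice."""
    run_dir = Path(run_dir)
    with _timer("score"):
        atlas = load_atlas_tsv(run_dir / "atlas.tsv")
        report: dict = {"networks": atlas.names}
        seed_maps = {tag: _load_seed_maps(run_dir, tag) for tag in ("functional", "anatomical")}
        if not seed_maps["functional"]:
            raise RuntimeError("score: no per-seed FC outputs found; run connect first")
        for tag in ("functional", "anatomical"):
            labels = load_labels_nifti(run_dir / f"{tag}_labels.nii.gz")
            maps = seed_maps[tag]
            rows = []
            nus = {}
            for seed_id, vmap in maps.items():
                cov = coverage_vector(vmap, atlas)
                nu = nonuniformity(cov) if cov.c.sum() > 0 else np.nan
                nus[seed_id] = nu
                rows.append({"seed": seed_id, "nu": nu, **dict(zip(atlas.names, cov.c))})
            pd.DataFrame(rows).to_csv(run_dir / f"coverage_{tag}.tsv", sep="\t", index=False)
            valid = {k: v for k, v in nus.items() if np.isfinite(v)}
            if len(valid) >= 3:
                high, mid, low = specificity_tertiles(
                    list(valid.values()), list(valid.keys())
                )
                report[f"{tag}_tertiles"] = {"high": high, "medium": mid, "low": low}
            union, cortical, per_net = merged_map(list(maps.values()), atlas)
            save_vertex_map_tsv(union, run_dir / f"merged_{tag}.tsv")
            report[f"{tag}_merged_cortical_coverage_percent"] = cortical
            report[f"{tag}_merged_network_coverage_percent"] = dict(
                zip(atlas.names, per_net.c)
            )
            counts = labels.voxel_counts()
            hcm = hippocampal_coverage_map(maps, {int(k): counts[int(k)] for k in maps})
            save_vertex_map_tsv(hcm, run_dir / f"hippocampal_coverage_{tag}.tsv")

        union_f, _, _ = merged_map(list(seed_maps["functional"].values()))
        union_a, _, _ = merged_map(list(seed_maps["anatomical"].values()))
        part = overlap_partition(union_a, union_f, atlas)
        report["dice_merged_anat_vs_func"] = part.dice
        report["partition_counts"] = part.counts
        report["partition_per_network_percent"] = part.per_network_percent

        func = load_labels_nifti(run_dir / "functional_labels.nii.gz")
        anat = load_labels_nifti(run_dir / "anatomical_labels.nii.gz")
        table = overlap_table(anat, func)
        pd.DataFrame(
            table,
            index=[f"anat_{i}" for i in anat.parcel_ids],
            columns=[f"func_{j}" for j in func.parcel_ids],
        ).to_csv(run_dir / "overlap_table.tsv", sep="\t")
        save_json(_jsonable(report), run_dir / "score_report.json")
        _write_manifest(config, run_dir, "score")
    return report


def run_pipeline(config: RunConfig, run_dir: str | Path) -> dict:
    """Run every stage in order and return the final score report."""
    stage_simulate(config, run_dir)
    stage_parcellate(config, run_dir)
    stage_connect(config, run_dir)
    return stage_score(config, run_dir)


def compare_parcellations(run_dir: str | Path) -> dict:
    """Bundle comparing the anatomical and functional segmentations of a run.

    Requires per-seed FC outputs for both segmentations (stage ``connect``)
    and emits the overlap table, both merged-map coverages, both
    hippocampal-coverage maps, the three-way partition and dice — i.e. the
    contents of ``score_report.json`` plus the overlap table file.
    """
    run_dir = Path(run_dir)
    report_path = run_dir / "score_report.json"
    if not report_path.exists():
        raise RuntimeError("compare: run the score stage first")
    report = load_json(report_path)
    missing = [
        tag
        for tag in ("functional", "anatomical")
        if not list((run_dir / "fc").glob(f"{tag}_seed*_significance.tsv"))
    ]
    if missing:
        raise RuntimeError(f"compare: missing per-seed FC outputs for {missing}")
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    return obj


def _write_manifest(config: RunConfig, run_dir: Path, stage: str) -> None:
    path = run_dir / "manifest.json"
    manifest = load_json(path) if path.exists() else {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": {},
    }
    # no timestamps: identical configs must yield bit-identical manifests
    manifest["stages"][stage] = {
        "seed": config.stage_seed(stage) if stage in STAGES else None,
        "completed": True,
    }
    save_json(manifest, path)
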