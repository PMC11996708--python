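"""Orchestration, configuration, file formats and handedness handling.

Ties the stages together: simulate (or load) → segment → frames →
kinematics → stats.  Every run writes a JSON-lines log with the exact
parameters and seed, sufficient to re-execute it byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import stats as stats_mod
from . import synthetic
from .frames import Landmarks
from .kinematics import MOTION_COLUMNS, SpecimenScans, run_kinematics


@dataclass
class PipelineConfig:
    out_dir: str = "wristkin_run"
    simulate: bool = True
    n_specimens: int = 4
    seed: int = 0
    subdivision: int = 3
    voxelize: bool = False
    spacing_mm: float = 0.5          # CT-like slice thickness
    hu_min: float = 300.0
    hu_max: float = float("inf")
    smooth_iterations: int = 10
    crop_distance_mm: float = 60.0
    euler_convention: str = "XZY"    # intrinsic; fixed, recorded for the log
    alpha: float = 0.05
    paired: bool = False
    vertex_noise_sd: float = 0.05
    overwrite: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**{k: v for k, v in d.items()
                      if k in {f.name for f in dataclasses.fields(cls)}})


def mirror_left_hand(meshes: dict[str, trimesh.Trimesh],
                     landmarks: Landmarks | dict,
                     ) -> tuple[dict[str, trimesh.Trimesh], Landmarks]:
    """Reflect a left hand through the YZ-plane into right-hand convention.

    Vertices get x → −x and face winding is flipped so the meshes stay
    outward-oriented.
    """
    out = {}
    for bone, mesh in meshes.items():
        verts = mesh.vertices.view(np.ndarray).copy()
        verts[:, 0] *= -1.0
        faces = mesh.faces.view(np.ndarray)[:, ::-1]
        out[bone] = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if not isinstance(landmarks, Landmarks):
        landmarks = Landmarks.from_dict(landmarks)
    def flip(p):
        q = np.array(p, dtype=float)
        q[0] *= -1.0
        return q
    lm = Landmarks(flip(landmarks.ulnar_notch_palmar),
                   flip(landmarks.ulnar_notch_dorsal),
                   flip(landmarks.radial_styloid_tip))
    return out, lm


def load_effects(path: str | Path) -> synthetic.EffectConfig:
    d = json.loads(Path(path).read_text())
    incs = tuple(synthetic.EffectIncrement(**i) for i in d.get("increments", ()))
    kwargs = {k: d[k] for k in ("between_specimen_sd_rot",
                                "between_specimen_sd_trans",
                                "vertex_noise_sd") if k in d}
    return synthetic.EffectConfig(incs, **kwargs)


def load_scan_dir(scan_dir: str | Path) -> tuple[dict[str, trimesh.Trimesh], Landmarks]:
    """Read one scan's bone meshes (STL/PLY) and landmark file."""
    scan_dir = Path(scan_dir)
    meshes = {}
    for path in sorted(scan_dir.iterdir()):
        if path.suffix.lower() in (".stl", ".ply"):
            # process=True merges the per-facet duplicated STL vertices so
            # the mesh is watertight again
            meshes[path.stem] = trimesh.load_mesh(path, process=True)
    lm_path = scan_dir / "landmarks.json"
    if not lm_path.exists():
        raise FileNotFoundError(f"missing landmarks file {lm_path}")
    d = json.loads(lm_path.read_text())
    lm = Landmarks.from_dict(d)
    return meshes, lm


def load_manifest_specimens(manifest: synthetic.StudyManifest,
                            ) -> list[SpecimenScans]:
    """Materialize SpecimenScans from an on-disk manifest."""
    handedness = {s["id"]: s.get("handedness", "right")
                  for s in manifest.specimens}
    by_spec: dict[str, SpecimenScans] = {}
    for entry in manifest.entries:
        sid = entry["specimen"]
        if entry.get("mesh_dir") is None:
            raise FileNotFoundError(
                f"manifest entry for {sid}/{entry['pose']}/{entry['condition']} "
                "has no mesh directory (manifest was not materialized)")
        meshes, lm = load_scan_dir(entry["mesh_dir"])
        if handedness[sid] == "left":
            meshes, lm = mirror_left_hand(meshes, lm)
        spec = by_spec.setdefault(sid, SpecimenScans(sid, {}, {},
                                                     handedness[sid]))
        spec.meshes[(entry["pose"], entry["condition"])] = meshes
        spec.landmarks[(entry["pose"], entry["condition"])] = lm
    return list(by_spec.values())


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False, columns=MOTION_COLUMNS,
                  float_format="%.9g")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_stats(results: list[stats_mod.StatResult], out_dir: str | Path,
                ) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = stats_mod.results_to_frame(results)
    csv_path = out_dir / "stats_condition_contrasts.csv"
    frame.to_csv(csv_path, index=False, float_format="%.9g")
    json_path = out_dir / "stats_full.json"
    json_path.write_text(json.dumps(
        [dataclasses.asdict(r) for r in results], indent=1, default=float))
    return csv_path, json_path


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        path.write_text("")

    def record(self, stage: str, **params) -> None:
        with self.path.open("a") as fh:
            fh.write(json.dumps({"stage": stage, **params}, default=str) + "\n")


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the artifact paths."""
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.overwrite:
        raise FileExistsError(f"{out} exists and is not empty")
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run_log.jsonl")
    log.record("config", params=config.to_dict())
    t0 = time.perf_counter()
    if not config.simulate:
        raise NotImplementedError(
            "real-data ingestion runs stage-by-stage via the CLI "
            "(segment / frames / kinematics / stats)")
    effects = synthetic.default_effects()
    effects.vertex_noise_sd = config.vertex_noise_sd
    manifest, specimens = synthetic.generate_cohort(
        config.n_specimens, effects=effects, seed=config.seed,
        out_dir=out / "cohort", overwrite=True,
        write_volumes=config.voxelize, spacing=config.spacing_mm,
        subdivision=config.subdivision)
    log.record("simulate", n=config.n_specimens, seed=config.seed,
               elapsed_s=round(time.perf_counter() - t0, 3))
    scans = [SpecimenScans(s.specimen_id, s.meshes, s.landmarks, s.handedness)
             for s in specimens.values()]
    t1 = time.perf_counter()
    cohort = run_kinematics(scans, crop_distance=config.crop_distance_mm)
    cohort_path = out / "cohort.csv"
    write_cohort_csv(cohort, cohort_path)
    log.record("kinematics", records=len(cohort),
               elapsed_s=round(time.perf_counter() - t1, 3))
    t2 = time.perf_counter()
    results = stats_mod.compare_conditions(cohort, alpha=config.alpha,
                                           paired=config.paired)
    csv_path, json_path = write_stats(results, out / "stats")
    log.record("stats", results=len(results),
               elapsed_s=round(time.perf_counter() - t2, 3))
    return {"manifest": out / "cohort" / "manifest.json",
            "cohort": cohort_path, "stats_csv": csv_path,
            "stats_json": json_path, "log": log.path}
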