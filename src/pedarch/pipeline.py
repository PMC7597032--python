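"""End-to-end orchestration: meshes -> skeletal variables, pressure trials
-> LOAD/FUNC variables, clinical records -> scores and groups, and the
correlation screen, with reproducible CSV outputs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import ClinicalRecord, score_cohort
from .errors import PedarchError
from .mesh import (
    FootFrame,
    TriangleMesh,
    compute_foot_frame,
    fit_ground_plane,
    pca_bone_frame,
    read_stl,
    realign,
)
from .pressure import (
    DEFAULT_CONTACT_THRESHOLD,
    DEFAULT_SECTOR_FRACTIONS,
    PressureFrameSequence,
    foot_load_and_func,
)
from .screen import CorrelationScreen
from .skeletal import FOREFOOT_BONES, foot_3d_variables
from .synthetic import (
    SyntheticCohortSpec,
    default_foot_spec,
    default_gait_spec,
    make_cohort,
    make_foot,
    make_pressure_trials,
)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (YAML-serialisable)."""

    out_dir: str = "pedarch_out"
    seed: int = 0
    alpha: float = 0.05
    contact_threshold: float = DEFAULT_CONTACT_THRESHOLD
    sector_fractions: tuple[float, float, float] = DEFAULT_SECTOR_FRACTIONS
    pti_convention: str = "peak_curve"
    multiple_testing: str = "none"
    n_n: int = 7
    n_d: int = 8
    n_lada: int = 1
    mesh_dir: str | None = None  # optional: real STL input instead of synthetic

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise PedarchError(f"alpha must lie in (0, 1), got {self.alpha}")
        fr = tuple(self.sector_fractions)
        if len(fr) != 3 or any(f <= 0 for f in fr) or not np.isclose(sum(fr), 1.0):
            raise PedarchError(
                f"sector fractions must be 3 positive values summing to 1, got {fr}"
            )
        self.sector_fractions = fr

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stage helpers


def load_foot_dir(path: str | Path) -> dict[str, TriangleMesh]:
    """Read every ``*.stl`` in a directory, labelling by file stem."""
    meshes = {}
    for f in sorted(Path(path).glob("*.stl")):
        m = read_stl(f)
        meshes[m.label] = m
    if "GROUND" not in meshes:
        raise PedarchError(f"{path}: no ground.stl found")
    return meshes


def process_foot_meshes(
    meshes: dict[str, TriangleMesh],
) -> tuple[pd.Series, FootFrame]:
    """Meshes (incl. GROUND) in scanner coordinates -> 84 skeletal variables.

    Fits the ground plane, builds the foot anatomical frame, realigns all
    bones, derives PCA bone frames and assembles the variable vector.
    """
    bones = {k: m for k, m in meshes.items() if k != "GROUND"}
    ground = fit_ground_plane(meshes["GROUND"], toward=list(bones.values()))
    frame = compute_foot_frame(bones["CAL"], bones["M2"], ground)
    aligned = realign(bones, frame)
    bone_frames = {b: pca_bone_frame(aligned[b]) for b in FOREFOOT_BONES}
    series = foot_3d_variables(bone_frames, aligned, frame.foot_length)
    return series, frame


def frame_to_dict(frame: FootFrame) -> dict:
    return {
        "origin": list(frame.origin),
        "ap_axis": list(frame.ap_axis),
        "ml_axis": list(frame.ml_axis),
        "vert_axis": list(frame.vert_axis),
        "foot_length": frame.foot_length,
    }


def save_trials(trials: list[PressureFrameSequence], path: str | Path) -> None:
    """Store trials as an ``.npz`` stack with a JSON sidecar (pitch, dt,
    markers)."""
    path = Path(path)
    np.savez_compressed(path, **{f"trial_{i}": t.frames for i, t in enumerate(trials)})
    sidecar = {
        "pitch": trials[0].pitch,
        "dt": trials[0].dt,
        "markers": [
            {k: list(v) for k, v in t.markers.items()} for t in trials
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_trials(path: str | Path) -> list[PressureFrameSequence]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path)
    trials = []
    for i in range(len([k for k in data.files if k.startswith("trial_")])):
        trials.append(
            PressureFrameSequence(
                data[f"trial_{i}"],
                pitch=sidecar["pitch"],
                dt=sidecar["dt"],
                markers={k: tuple(v) for k, v in sidecar["markers"][i].items()},
            )
        )
    return trials


def records_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def records_from_frame(df: pd.DataFrame) -> list[ClinicalRecord]:
    return [ClinicalRecord(**row) for row in df.to_dict(orient="records")]


# ---------------------------------------------------------------------------
# Full run


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle.

    Outputs (under ``config.out_dir``): the per-foot 84-variable CSV and
    foot-frame JSON, the LOAD/FUNC CSV, the clinical CSV with NS-VPT and
    group labels, the long-format correlation CSV, the family summary CSV,
    and a run log carrying the config, its hash and library versions.
    Reruns with the same config and seed are byte-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # geometry stage: real meshes if given, else one synthetic foot
    if config.mesh_dir is not None:
        meshes = load_foot_dir(config.mesh_dir)
    else:
        meshes = make_foot(default_foot_spec(seed=config.seed)).meshes
    variables, frame = process_foot_meshes(meshes)
    df = variables.rename("value").to_frame()
    df["units"] = ["deg" if n[0] in "IR" else ("mm" if n.startswith("Hg_") else "-")
                  for n in df.index]
    paths["foot_3d_variables"] = out / "foot_3d_variables.csv"
    df.to_csv(paths["foot_3d_variables"], index_label="variable")
    paths["foot_frame"] = out / "foot_frame.json"
    paths["foot_frame"].write_text(json.dumps(frame_to_dict(frame), indent=1))

    # pressure stage on synthetic trials
    trials, _ = make_pressure_trials(default_gait_spec(seed=config.seed))
    load, ct, ai = foot_load_and_func(
        trials,
        contact_threshold=config.contact_threshold,
        fractions=config.sector_fractions,
        pti_convention=config.pti_convention,
    )
    lf = load.rename("value").to_frame()
    lf.loc["CT"] = ct
    lf.loc["AI"] = ai
    paths["load_func"] = out / "load_func_variables.csv"
    lf.to_csv(paths["load_func"], index_label="variable")

    # cohort: clinical scoring and the correlation screen
    cohort_spec = SyntheticCohortSpec(
        n_n=config.n_n, n_d=config.n_d, n_lada=config.n_lada, seed=config.seed
    )
    table, records, _ = make_cohort(cohort_spec)
    clin = records_to_frame(records)
    clin = pd.concat([clin, score_cohort(records)[["NS_VPT", "group"]]], axis=1)
    paths["clinical"] = out / "clinical.csv"
    clin.to_csv(paths["clinical"], index_label="patient")

    screen = CorrelationScreen(
        table,
        alpha=config.alpha,
        multiple_testing=config.multiple_testing,
    )
    results = screen.fit()
    paths["correlations"] = out / "correlations.csv"
    results.frame.to_csv(paths["correlations"], index=False)
    paths["family_summary"] = out / "family_summary.csv"
    results.family_summary().to_csv(paths["family_summary"], index=False)
    paths["significant"] = out / "significant_inter.csv"
    results.significant_pairs("inter").to_csv(paths["significant"], index=False)

    log = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "versions": {
            "pedarch": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    paths["run_log"] = out / "run_log.json"
    paths["run_log"].write_text(json.dumps(log, indent=1, sort_keys=True))
    return paths
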