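"""Synthetic inputs with exact ground truth for every pipeline stage.

Three families of generators mirror the three input families the pipeline
consumes:

* :func:`make_foot` - ellipsoidal bone meshes with planted poses, a ground
  mesh and footprint-plane markers, plus the analytically known 84-entry
  skeletal variable vector.  Bones are scalene ellipsoids because their
  principal axes and ground-tangent heights are known in closed form; the
  surface sampling is closed under reflection through the three principal
  planes, so PCA recovers the planted axes exactly (up to sign).
* :func:`make_pressure_trials` - walking trials as half-sine-in-time,
  Gaussian-blob-in-space pressure evolutions per plantar region, with
  per-trial rigid jitter, plus analytic PP/PTI/CT ground truth.
* :func:`make_cohort` - a patient cohort with clinical records consistent
  with the two-of-three neuropathy grouping rule and planted linear
  angle-to-load relations of controlled R^2.

All generators are deterministic given their seed; ground truth is
computed from the planted construction, never from the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .clinical import ClinicalRecord
from .errors import PedarchError
from .mesh import TriangleMesh
from .pressure import PressureFrameSequence
from .skeletal import (
    FOREFOOT_BONES,
    HEIGHT_BONES,
    MTP_PAIRS,
    VARIABLE_NAMES_3D,
)

# ---------------------------------------------------------------------------
# Bone meshes


def rotation_from_angles(
    elevation: float, azimuth: float, roll: float = 0.0
) -> np.ndarray:
    """Rotation matrix whose first column (the bone's long axis) has the
    given elevation above the ground plane and azimuth in it (degrees)."""
    el, az, ro = np.radians([elevation, azimuth, roll])
    cz, sz = np.cos(az), np.sin(az)
    cy, sy = np.cos(-el), np.sin(-el)
    cx, sx = np.cos(ro), np.sin(ro)
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1.0]])
    Ry = np.array([[cy, 0, sy], [0, 1.0, 0], [-sy, 0, cy]])
    Rx = np.array([[1.0, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return Rz @ Ry @ Rx


def _fibonacci_sphere(n: int, offset: float = 0.5) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-angle spiral)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + offset) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _symmetric_sphere(n_octant: int, rng: np.random.Generator | None) -> np.ndarray:
    """Sphere sampling closed under reflection through the coordinate planes.

    A quasi-uniform set is folded into the positive octant (|x|, |y|, |z|)
    and unfolded through all eight sign combinations, so the second-moment
    matrix of the set is exactly diagonal.
    """
    offset = 0.5 if rng is None else float(rng.uniform(0.2, 0.8))
    base = np.abs(_fibonacci_sphere(n_octant, offset))
    base = np.clip(base, 1e-6, None)  # keep points off the principal planes
    base /= np.linalg.norm(base, axis=1, keepdims=True)
    signs = np.array(
        [[sx, sy, sz] for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)],
        dtype=float,
    )
    return (base[:, None, :] * signs[None, :, :]).reshape(-1, 3)


def make_bone_mesh(
    semi_axes,
    rotation,
    translation,
    n_vertices: int = 520,
    label: str = "M1",
    rng: np.random.Generator | None = None,
) -> tuple[TriangleMesh, dict]:
    """Ellipsoid bone mesh with a planted pose.

    Parameters
    ----------
    semi_axes : three strictly descending semi-axes (mm).
    rotation : 3x3 rotation matrix, or an (elevation, azimuth, roll)
        triple in degrees (see :func:`rotation_from_angles`).
    translation : world position of the ellipsoid centre (mm).
    n_vertices : approximate vertex count (rounded up to a multiple of 8).

    Returns the mesh and the ground truth: the pose matrix (columns are
    the longitudinal, medio-lateral and dorsi-plantar body axes in world
    coordinates), the centre and the semi-axes.
    """
    a = np.asarray(semi_axes, dtype=float)
    if not (a[0] > a[1] > a[2] > 0):
        raise PedarchError(
            f"semi-axes must be strictly descending and positive, got {tuple(a)}"
        )
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3):
        R = rotation_from_angles(*np.asarray(rotation, dtype=float))
    t = np.asarray(translation, dtype=float)
    n8 = max(1, int(np.ceil(n_vertices / 8)))
    unit = _symmetric_sphere(n8, rng)
    body = unit * a
    world = body @ R.T + t
    faces = ConvexHull(body).simplices
    mesh = TriangleMesh(world, faces, label)
    return mesh, {"axes": R, "center": t.copy(), "semi_axes": a.copy()}


# ---------------------------------------------------------------------------
# Whole synthetic foot


@dataclass
class BonePose:
    """Planted pose of one ellipsoid bone: semi-axes (mm), centre (mm) and
    long-axis elevation/azimuth plus roll about it (degrees)."""

    semi_axes: tuple[float, float, float]
    center: tuple[float, float, float]
    elevation: float = 0.0
    azimuth: float = 0.0
    roll: float = 0.0


def default_foot_spec(seed: int = 0, **pose_overrides) -> "SyntheticFootSpec":
    """A neutral adult-scale foot: metatarsals declining ~20 deg to their
    heads, near-horizontal phalanges, arch bones raised.  Keyword overrides
    replace the pose of individual bones (e.g. ``P2=BonePose(...)``)."""
    bones = {
        "CAL": BonePose((38, 22, 18), (38, 0, 22), elevation=20.0),
        "M1": BonePose((32, 9, 8), (105, 24, 16), elevation=-18.0, azimuth=8.0),
        "M2": BonePose((34, 8.5, 7.5), (108, 12, 15), elevation=-20.0, azimuth=2.0),
        "M3": BonePose((32, 8, 7), (106, 0, 14), elevation=-21.0, azimuth=-2.0),
        "M4": BonePose((30, 7.5, 6.5), (103, -11, 14), elevation=-22.0, azimuth=-6.0),
        "M5": BonePose((28, 7.5, 6.5), (99, -22, 13.5), elevation=-23.0, azimuth=-9.0),
        "P1": BonePose((16, 7, 5), (138, 27, 10), elevation=-10.0, azimuth=8.0),
        "P2": BonePose((13, 5, 4), (140, 13, 9), elevation=5.0, azimuth=2.0),
        "P3": BonePose((12.5, 5, 4), (137, 0, 9), elevation=5.0, azimuth=-2.0),
        "P4": BonePose((12, 4.8, 3.8), (133, -12, 9), elevation=5.0, azimuth=-6.0),
        "P5": BonePose((11, 4.5, 3.5), (128, -23, 9), elevation=8.0, azimuth=-9.0),
        "CUB": BonePose((22, 13, 10), (70, -14, 14), elevation=-5.0, azimuth=-5.0),
        "NAV": BonePose((19, 13, 9), (78, 12, 20), elevation=0.0, azimuth=25.0),
    }
    for label, pose in pose_overrides.items():
        if label not in bones:
            raise PedarchError(f"unknown bone {label!r}")
        bones[label] = pose
    return SyntheticFootSpec(bones=bones, seed=seed)


@dataclass
class SyntheticFootSpec:
    bones: dict[str, BonePose]
    n_vertices: int = 520
    seed: int = 0


@dataclass
class SyntheticFoot:
    """A generated foot: scanner-frame meshes (incl. GROUND) for the
    pipeline, plus planted ground truth in the anatomical frame."""

    meshes: dict[str, TriangleMesh]
    truth: pd.Series  # the 84 skeletal variables
    markers: dict[str, tuple[float, float]]
    foot_length: float
    scanner_rotation: np.ndarray
    scanner_translation: np.ndarray


def _angles_of_axis(u) -> dict[str, float]:
    """I3/IL/IF/IT of a unit axis, scalar trigonometry (generator-side
    oracle, independent of the pipeline's vector implementation)."""
    ux, uy, uz = (float(v) for v in u)
    out = {"I3": math.degrees(math.asin(max(-1.0, min(1.0, uz))))}
    out["IL"] = math.degrees(math.atan2(uz, ux)) if math.hypot(ux, uz) > 1e-9 else float("nan")
    out["IT"] = math.degrees(math.atan2(uy, ux)) if math.hypot(ux, uy) > 1e-9 else float("nan")
    out["IF"] = math.degrees(math.atan2(uz, uy)) if math.hypot(uy, uz) > 1e-9 else float("nan")
    return out


def _wrap(a: float) -> float:
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _ground_mesh(x_range=(-60.0, 220.0), y_range=(-80.0, 80.0), n: int = 6) -> TriangleMesh:
    xs = np.linspace(*x_range, n)
    ys = np.linspace(*y_range, n)
    gx, gy = np.meshgrid(xs, ys)
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    faces = []
    for r in range(n - 1):
        for c in range(n - 1):
            i = r * n + c
            faces.append([i, i + 1, i + n])
            faces.append([i + 1, i + n + 1, i + n])
    return TriangleMesh(verts, np.asarray(faces), "GROUND")


def make_foot(
    spec: SyntheticFootSpec | None = None,
    seed: int | None = None,
    scanner_pose: bool = True,
) -> SyntheticFoot:
    """Generate a synthetic foot and its exact skeletal ground truth.

    The planted scene is first aligned so that the anatomical frame the
    pipeline will reconstruct (ground normal vertical, calcaneus-to-M2
    plantar segment along +x) is exactly the identity; ground truth angles
    and heights are read off the planted poses there.  A random rigid
    scanner pose is then applied to every mesh including the ground.
    """
    if spec is None:
        spec = default_foot_spec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    meshes: dict[str, TriangleMesh] = {}
    axes: dict[str, np.ndarray] = {}
    for label, pose in spec.bones.items():
        R = rotation_from_angles(pose.elevation, pose.azimuth, pose.roll)
        mesh, truth = make_bone_mesh(
            pose.semi_axes, R, pose.center, spec.n_vertices, label, rng
        )
        if mesh.vertices[:, 2].min() < 0:
            raise PedarchError(f"bone {label} extends below the ground")
        meshes[label] = mesh
        axes[label] = truth["axes"]

    # align the scene so the anatomical frame is exactly canonical; the
    # plantar points are picked with the pipeline's medio-lateral tie-break
    # so reflection-twin vertices resolve identically in any frame
    from .mesh import _pick_plantar

    u_m2 = axes["M2"][:, 0]
    hp = np.array([u_m2[0], u_m2[1], 0.0])
    hp /= np.linalg.norm(hp)
    ml_hint = np.cross(np.array([0.0, 0.0, 1.0]), hp)
    cal = meshes["CAL"]
    p_cal = _pick_plantar(cal.vertices, cal.vertices[:, 2], ml_hint)
    m2 = meshes["M2"]
    tvals = (m2.vertices - m2.vertices.mean(axis=0)) @ u_m2
    head = m2.vertices[tvals >= tvals.min() + 0.7 * (tvals.max() - tvals.min())]
    p_m2 = _pick_plantar(head, head[:, 2], ml_hint)
    d = p_m2[:2] - p_cal[:2]
    foot_length = float(np.linalg.norm(d))
    if foot_length < 1e-9:
        raise PedarchError("degenerate foot: plantar points coincide")
    delta = -math.atan2(d[1], d[0])
    cz, sz = math.cos(delta), math.sin(delta)
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1.0]])
    shift = np.array([p_cal[0], p_cal[1], 0.0])
    for label in meshes:
        meshes[label] = meshes[label].transformed(Rz, -Rz @ shift)
    axes = {label: Rz @ A for label, A in axes.items()}

    # ground truth from the planted poses in the canonical frame
    values: dict[str, float] = {}
    for b in FOREFOOT_BONES:
        for k, v in _angles_of_axis(axes[b][:, 0]).items():
            values[f"{k}_{b}"] = v
    for prox, dist in MTP_PAIRS:
        up, ud = axes[prox][:, 0], axes[dist][:, 0]
        values[f"R3_{prox}{dist}"] = math.degrees(
            math.acos(max(-1.0, min(1.0, float(up @ ud))))
        )
        ap = _angles_of_axis(up)
        ad = _angles_of_axis(ud)
        for plane in "LFT":
            values[f"R{plane}_{prox}{dist}"] = _wrap(ad[f"I{plane}"] - ap[f"I{plane}"])
    for b in HEIGHT_BONES:
        h = max(float(meshes[b].vertices[:, 2].min()), 0.0)
        values[f"Hg_{b}"] = h
        values[f"Hgr_{b}"] = h / foot_length
    truth_series = pd.Series(
        [values[n] for n in VARIABLE_NAMES_3D], index=list(VARIABLE_NAMES_3D)
    )

    # footprint-plane marker positions (anatomical frame)
    def _tip(label: str) -> tuple[float, float]:
        m = meshes[label]
        tip = m.vertices.mean(axis=0) + spec.bones[label].semi_axes[0] * axes[label][:, 0]
        return float(tip[0]), float(tip[1])

    markers = {
        "CAL": (float(meshes["CAL"].vertices[:, 0].min()), 0.0),
        "M1": _tip("M1"),
        "M2": _tip("M2"),
        "M5": _tip("M5"),
        "HLX": _tip("P1"),
    }

    scene = dict(meshes)
    scene["GROUND"] = _ground_mesh()
    if scanner_pose:
        Rs = _random_rotation(rng)
        ts = rng.uniform(-100.0, 100.0, size=3)
    else:
        Rs = np.eye(3)
        ts = np.zeros(3)
    scene = {k: m.transformed(Rs, ts) for k, m in scene.items()}
    return SyntheticFoot(
        meshes=scene,
        truth=truth_series,
        markers=markers,
        foot_length=foot_length,
        scanner_rotation=Rs,
        scanner_translation=ts,
    )


# ---------------------------------------------------------------------------
# Pressure trials


@dataclass
class RegionBlob:
    """One plantar contact area: Gaussian in space (compact support at
    2.5 sigma), half-sine in time."""

    center: tuple[float, float]  # mm
    sigma: float  # mm
    amplitude: float  # kPa
    t0: float  # ms
    duration: float  # ms


def default_gait_spec(seed: int = 0) -> "SyntheticGaitSpec":
    """A heel-to-toe stance of 680 ms on a 64 x 32 grid of 5 mm sensors.

    Blob centres sit on the sensor lattice and half-sine peaks on the
    mid-frame sampling instants, so planted peak pressures are recovered
    exactly in the jitter-free case.  Amplitudes follow the scale of
    adult barefoot walking (metatarsal peaks ~200-450 kPa).
    """
    blobs = {
        "HINDFOOT": RegionBlob((75, 40), 10.0, 300.0, 0.0, 410.0),
        "MIDFOOT": RegionBlob((60, 110), 9.0, 120.0, 100.0, 410.0),
        "I_MET": RegionBlob((115, 210), 5.5, 280.0, 250.0, 410.0),
        "II_IV_MET": RegionBlob((80, 210), 7.0, 420.0, 250.0, 410.0),
        "V_MET": RegionBlob((40, 210), 4.0, 220.0, 250.0, 410.0),
        "HLX": RegionBlob((120, 265), 5.0, 360.0, 370.0, 310.0),
    }
    return SyntheticGaitSpec(blobs=blobs, seed=seed)


@dataclass
class SyntheticGaitSpec:
    blobs: dict[str, RegionBlob]
    shape: tuple[int, int] = (64, 32)  # rows (anterior), cols
    pitch: float = 5.0  # mm
    dt: float = 10.0  # ms
    stance_ms: float = 680.0
    jitter_translation_mm: float = 2.0
    jitter_rotation_deg: float = 1.5
    amplitude_cv: float = 0.05
    n_trials: int = 5
    threshold: float = 10.0  # kPa, used for the ground-truth contact count
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stance_ms <= 0:
            raise PedarchError("stance duration must be positive")
        for name, b in self.blobs.items():
            if not 0.0 <= b.amplitude <= 1270.0:
                raise PedarchError(
                    f"blob {name}: amplitude {b.amplitude} outside [0, 1270] kPa"
                )


def make_pressure_trials(
    spec: SyntheticGaitSpec | None = None, seed: int | None = None
) -> tuple[list[PressureFrameSequence], dict]:
    """Generate jittered walking trials plus analytic ground truth.

    Ground truth (per trial): per-region planted PP (amplitude times the
    largest spatial kernel value on the jittered grid times the largest
    sampled half-sine value), the discrete and the continuous half-sine
    PTI (``2 A T / pi``), the whole-foot contact time, and a per-pixel
    region label map (pixels inside each blob's support).
    """
    if spec is None:
        spec = default_gait_spec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    H, W = spec.shape
    ys = np.arange(H) * spec.pitch
    xs = np.arange(W) * spec.pitch
    gx, gy = np.meshgrid(xs, ys)
    n_frames = int(round(spec.stance_ms / spec.dt))
    tk = (np.arange(n_frames) + 0.5) * spec.dt
    pivot = np.array([xs.mean(), ys.mean()])

    trials: list[PressureFrameSequence] = []
    truth: dict = {"per_trial": [], "labels": [], "CT": [], "n_frames": n_frames}
    base_markers = {
        "CAL": spec.blobs["HINDFOOT"].center,
        "M1": spec.blobs["I_MET"].center,
        "M2": spec.blobs["II_IV_MET"].center,
        "M5": spec.blobs["V_MET"].center,
        "HLX": (spec.blobs["HLX"].center[0], spec.blobs["HLX"].center[1] - 20.0),
    }
    from .pressure import LABEL_CODES  # local import to avoid cycle at module load

    for _ in range(spec.n_trials):
        th = math.radians(rng.normal(0.0, spec.jitter_rotation_deg)) if spec.jitter_rotation_deg else 0.0
        tau = (
            rng.normal(0.0, spec.jitter_translation_mm, size=2)
            if spec.jitter_translation_mm
            else np.zeros(2)
        )
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])

        def _move(p) -> np.ndarray:
            return rot @ (np.asarray(p, float) - pivot) + pivot + tau

        frames = np.zeros((n_frames, H, W))
        trial_truth: dict[str, dict[str, float]] = {}
        labels = np.zeros((H, W), dtype=np.int8)
        kernel_peak = np.zeros((H, W))
        for name, blob in spec.blobs.items():
            scale = (
                max(0.0, 1.0 + spec.amplitude_cv * rng.normal())
                if spec.amplitude_cv
                else 1.0
            )
            amp = min(blob.amplitude * scale, 1260.0)
            cx, cy = _move(blob.center)
            d2 = (gx - cx) ** 2 + (gy - cy) ** 2
            kern = np.exp(-d2 / (2.0 * blob.sigma**2))
            kern[d2 > (2.5 * blob.sigma) ** 2] = 0.0
            env = np.sin(np.pi * (tk - blob.t0) / blob.duration)
            env[(tk < blob.t0) | (tk > blob.t0 + blob.duration)] = 0.0
            env = np.clip(env, 0.0, None)
            frames += amp * env[:, None, None] * kern[None, :, :]
            code = LABEL_CODES.get(name, 0)
            newly = (kern > kernel_peak) & (kern > 0)
            labels[newly] = code
            kernel_peak = np.maximum(kernel_peak, kern)
            kmax = float(kern.max())
            emax = float(env.max())
            dur_s = blob.duration / 1000.0
            trial_truth[name] = {
                "PP": amp * kmax * emax,
                "PTI_discrete": amp * kmax * float(env.sum()) * spec.dt / 1000.0,
                "PTI_halfsine": 2.0 * amp * kmax * dur_s / math.pi,
                "amplitude": amp,
            }
        frames = np.clip(frames, 0.0, 1270.0)
        ct = float((frames.max(axis=(1, 2)) > spec.threshold).sum() * spec.dt)
        markers = {k: tuple(_move(v)) for k, v in base_markers.items()}
        trials.append(
            PressureFrameSequence(frames, pitch=spec.pitch, dt=spec.dt, markers=markers)
        )
        truth["per_trial"].append(trial_truth)
        truth["labels"].append(labels)
        truth["CT"].append(ct)
    return trials, truth


# ---------------------------------------------------------------------------
# Cohorts with planted correlations


@dataclass
class PlantedLink:
    """A planted linear relation between a skeletal and a LOAD variable."""

    var_3d: str
    var_load: str
    slope: float
    target_r2: float
    group: str = "ALL"

    def __post_init__(self) -> None:
        if not 0.0 < self.target_r2 <= 1.0:
            raise PedarchError(f"target R^2 must lie in (0, 1], got {self.target_r2}")


@dataclass
class SyntheticCohortSpec:
    """Cohort sizes mirror the study population: 7 neuropathic (N),
    8 non-neuropathic (D), 1 LADA."""

    n_n: int = 7
    n_d: int = 8
    n_lada: int = 1
    links: list[PlantedLink] = field(
        default_factory=lambda: [PlantedLink("I3_P2", "PTI_II_IV_MET", 3.0, 0.77)]
    )
    seed: int = 0


# means and standard deviations for the unlinked background variables
_ANGLE_I3_MEANS = {"P1": -10.8, "P2": 5.7, "P3": 4.6, "P4": 5.3, "P5": 7.5}
_RL_MEANS = {"M1P1": 12.2, "M2P2": 32.1, "M3P3": 26.8, "M4P4": 20.4, "M5P5": 16.1}
_LOAD_MEANS = {
    "HLX": (363.0, 74.0, 82.0),
    "I_MET": (279.0, 71.0, 77.0),
    "II_IV_MET": (418.0, 106.0, 118.0),
    "V_MET": (220.0, 70.0, 76.0),
}
_LOAD_SDS = {
    "HLX": (133.0, 35.0, 39.0),
    "I_MET": (120.0, 38.0, 35.0),
    "II_IV_MET": (178.0, 43.0, 52.0),
    "V_MET": (160.0, 53.0, 54.0),
}


def _background_moments() -> dict[str, tuple[float, float]]:
    """Mean/sd for every one of the 102 variables (before planting)."""
    out: dict[str, tuple[float, float]] = {}
    for name in VARIABLE_NAMES_3D:
        measure, rest = name.split("_", 1)
        if measure in ("I3", "IL"):
            mu = _ANGLE_I3_MEANS.get(rest, -20.0) if rest.startswith("P") else -21.0
            out[name] = (mu, 8.0 if rest.startswith("P") else 4.0)
        elif measure == "IT":
            out[name] = (0.0, 5.0)
        elif measure == "IF":
            out[name] = (45.0, 25.0)
        elif measure in ("R3", "RL"):
            out[name] = (_RL_MEANS.get(rest, 20.0), 8.0)
        elif measure in ("RF", "RT"):
            out[name] = (0.0, 10.0)
        elif measure == "Hg":
            base = {"CUB": 12.0, "NAV": 18.0}.get(rest, 15.0 if rest.startswith("M") else 8.0)
            out[name] = (base, 3.0)
        else:  # Hgr
            base = {"CUB": 12.0, "NAV": 18.0}.get(rest, 15.0 if rest.startswith("M") else 8.0)
            out[name] = (base / 180.0, 3.0 / 180.0)
    for region, mus in _LOAD_MEANS.items():
        sds = _LOAD_SDS[region]
        for metric, mu, sd in zip(("PP", "PTI", "PTI_N"), mus, sds):
            out[f"{metric}_{region}"] = (mu, sd)
    out["CT"] = (680.0, 86.0)
    out["AI"] = (0.22, 0.05)
    return out


def _make_record(group: str, rng: np.random.Generator) -> ClinicalRecord:
    if group == "N":
        # satisfy at least two of the three neuropathy criteria
        fail = rng.integers(0, 3) if rng.random() < 0.4 else -1
        mnsi_p = rng.uniform(0.0, 2.0) if fail == 0 else rng.uniform(3.0, 8.0)
        mdns = rng.uniform(0.0, 7.0) if fail == 1 else rng.uniform(8.0, 20.0)
        vpt_h = rng.uniform(5.0, 25.0) if fail == 2 else rng.uniform(26.0, 40.0)
        mnsi_h = rng.uniform(4.0, 12.0)
        age, bmi, yod = 58.1, 25.7, 35.0
        sds = (15.6, 2.0, 11.5)
        diagnosis = "type1"
    elif group == "D":
        # satisfy at most one criterion
        hit = rng.integers(0, 3) if rng.random() < 0.3 else -1
        mnsi_p = rng.uniform(3.0, 8.0) if hit == 0 else rng.uniform(0.0, 2.0)
        mdns = rng.uniform(8.0, 15.0) if hit == 1 else rng.uniform(0.0, 7.0)
        vpt_h = rng.uniform(26.0, 40.0) if hit == 2 else rng.uniform(2.0, 25.0)
        mnsi_h = rng.uniform(0.0, 5.0)
        age, bmi, yod = 46.2, 22.6, 30.8
        sds = (17.2, 2.5, 15.8)
        diagnosis = "type1"
    else:  # LADA
        mnsi_p, mdns, vpt_h, mnsi_h = 2.5, 6.0, 20.0, 6.0
        age, bmi, yod = 51.3, 23.7, 9.3
        sds = (0.0, 0.0, 0.0)
        diagnosis = "LADA"
    return ClinicalRecord(
        mnsi_history=float(np.clip(mnsi_h, 0, 15)),
        mnsi_physical=float(np.clip(mnsi_p, 0, 10)),
        mdns=float(mdns),
        vpt_hallux=float(np.clip(vpt_h, 0, 40)),
        vpt_malleolus=float(np.clip(vpt_h + rng.normal(0, 3), 0, 40)),
        age=float(np.clip(age + sds[0] * rng.normal(), 20, 90)),
        bmi=float(np.clip(bmi + sds[1] * rng.normal(), 17, 38)),
        yod=float(np.clip(yod + sds[2] * rng.normal(), 1, 60)),
        diagnosis=diagnosis,
    )


def make_cohort(
    spec: SyntheticCohortSpec | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, list[ClinicalRecord], dict]:
    """Generate a cohort table with planted angle-to-load correlations.

    All 102 variables are drawn as independent normals at realistic scales;
    each planted link then overwrites its LOAD variable within the linked
    group as ``intercept + slope * angle + noise``.  The noise variance is
    calibrated against the realized sample variance of the drawn angle
    values, so the planted R^2 is matched by the generated sample itself
    (``target_r2 = 1`` plants an exactly linear relation).

    Returns the wide variable table (with a ``group`` column), the
    clinical records, and the ground-truth planting description.
    """
    from .clinical import classify_group, ns_vpt  # deferred: avoid cycle

    if spec is None:
        spec = SyntheticCohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    groups = ["N"] * spec.n_n + ["D"] * spec.n_d + ["LADA"] * spec.n_lada
    records = [_make_record(g, rng) for g in groups]
    labels = [classify_group(r) for r in records]
    if labels != groups:
        raise PedarchError("generated clinical records violate the grouping rule")

    moments = _background_moments()
    n = len(groups)
    data = {
        name: mu + sd * rng.normal(size=n) for name, (mu, sd) in moments.items()
    }
    table = pd.DataFrame(data)
    table["AGE"] = [r.age for r in records]
    table["BMI"] = [r.bmi for r in records]
    table["YOD"] = [r.yod for r in records]
    table["NS_VPT"] = [ns_vpt(r) for r in records]
    table["group"] = labels

    for link in spec.links:
        rows = (
            table.index
            if link.group == "ALL"
            else table.index[table["group"] == link.group]
        )
        if len(rows) < 3:
            raise PedarchError(f"link {link}: fewer than 3 rows in group {link.group}")
        x = table.loc[rows, link.var_3d].to_numpy()
        sx = x.std(ddof=1)
        if sx <= 0:
            raise PedarchError(f"link {link}: zero variance in {link.var_3d}")
        if link.target_r2 >= 1.0:
            noise = np.zeros(len(rows))
        else:
            se = abs(link.slope) * sx * math.sqrt(
                (1.0 - link.target_r2) / link.target_r2
            )
            noise = se * rng.normal(size=len(rows))
        mu_load = moments.get(link.var_load, (0.0, 1.0))[0]
        intercept = mu_load - link.slope * x.mean()
        table.loc[rows, link.var_load] = intercept + link.slope * x + noise

    truth = {
        "links": list(spec.links),
        "groups": {g: groups.count(g) for g in ("N", "D", "LADA")},
    }
    return table, records, truth
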