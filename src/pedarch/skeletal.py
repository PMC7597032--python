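"""The 84 per-foot skeletal ("3D") variables.

Absolute inclination angles (I) of a single bone's longitudinal axis and
relative orientation angles (R) between the metatarsal and phalanx of each
ray, each evaluated in 3D and as projections into the lateral, frontal and
transverse anatomical planes; plus minimum bone heights above the ground,
absolute (mm) and relative to foot length.

Angle conventions (degrees, foot coordinates x=ap, y=ml, z=vertical):

* ``I3``  signed elevation of the axis above the ground plane, positive
  dorsal (tip up), range [-90, 90].
* ``IL``  axis projected into the lateral plane (x, z), angle from the ap
  axis, dorsal-positive: ``atan2(u_z, u_x)``.
* ``IT``  projection into the transverse plane (x, y), angle from the ap
  axis, positive toward +ml: ``atan2(u_y, u_x)``.
* ``IF``  projection into the frontal plane (y, z), angle from the ml axis,
  dorsal-positive: ``atan2(u_z, u_y)``.
* ``R3``  unsigned 3D angle between the two longitudinal axes.
* ``RL/RF/RT``  planar relative angles as the difference of the projected
  absolute inclinations, distal minus proximal, so positive = distal
  dorsiflexed relative to proximal (plantarflexion is negative
  dorsiflexion); wrapped to (-180, 180].

A projection shorter than :data:`PROJECTION_TOL` leaves that planar angle
undefined; undefined values propagate as NaN.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import GeometryError
from .mesh import BoneFrame, FootFrame, GroundPlane, TriangleMesh

PROJECTION_TOL = 1e-9

FOREFOOT_BONES = tuple(f"M{i}" for i in range(1, 6)) + tuple(
    f"P{i}" for i in range(1, 6)
)
MTP_PAIRS = tuple((f"M{i}", f"P{i}") for i in range(1, 6))
HEIGHT_BONES = FOREFOOT_BONES + ("CUB", "NAV")

ANGLE_MEASURES = ("I3", "IL", "IF", "IT")
REL_MEASURES = ("R3", "RL", "RF", "RT")

#: Canonical names and order of the 84 skeletal variables.
VARIABLE_NAMES_3D: tuple[str, ...] = (
    tuple(f"{m}_{b}" for b in FOREFOOT_BONES for m in ANGLE_MEASURES)
    + tuple(f"{m}_{p}{d}" for (p, d) in MTP_PAIRS for m in REL_MEASURES)
    + tuple(f"{m}_{b}" for b in HEIGHT_BONES for m in ("Hg", "Hgr"))
)
assert len(VARIABLE_NAMES_3D) == 84

ANGLE_VARIABLES = tuple(n for n in VARIABLE_NAMES_3D if n[0] in "IR")
HEIGHT_VARIABLES = tuple(n for n in VARIABLE_NAMES_3D if n.startswith("Hg"))


def _wrap_deg(a: float) -> float:
    """Wrap to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def _axis_in_foot(bone: BoneFrame, foot: FootFrame | None) -> np.ndarray:
    u = np.asarray(bone.longitudinal_axis, dtype=float)
    if foot is not None:
        u = foot.rotation @ u
    return u / np.linalg.norm(u)


def absolute_inclination(
    bone: BoneFrame, foot: FootFrame | None = None
) -> dict[str, float]:
    """I3/IL/IF/IT of one bone's longitudinal axis (degrees).

    ``foot=None`` means the bone frame is already expressed in foot
    coordinates.  A planar angle whose projection is shorter than
    :data:`PROJECTION_TOL` is returned as NaN.
    """
    u = _axis_in_foot(bone, foot)
    out = {"I3": float(np.degrees(np.arcsin(np.clip(u[2], -1.0, 1.0))))}
    for name, (i, j) in (("IL", (0, 2)), ("IT", (0, 1)), ("IF", (1, 2))):
        if np.hypot(u[i], u[j]) < PROJECTION_TOL:
            out[name] = np.nan
        else:
            out[name] = float(np.degrees(np.arctan2(u[j], u[i])))
    return out


def relative_orientation(
    proximal: BoneFrame, distal: BoneFrame, foot: FootFrame | None = None
) -> dict[str, float]:
    """R3/RL/RF/RT between a metatarsal (proximal) and its phalanx (distal).

    R3 is the unsigned 3D angle; the planar angles are differences of the
    projected absolute inclinations (distal minus proximal), so they negate
    under argument swap while R3 is symmetric.
    """
    up = _axis_in_foot(proximal, foot)
    ud = _axis_in_foot(distal, foot)
    ip = absolute_inclination(proximal, foot)
    idist = absolute_inclination(distal, foot)
    out = {"R3": float(np.degrees(np.arccos(np.clip(up @ ud, -1.0, 1.0))))}
    for plane in ("L", "F", "T"):
        a, b = idist[f"I{plane}"], ip[f"I{plane}"]
        out[f"R{plane}"] = np.nan if (np.isnan(a) or np.isnan(b)) else _wrap_deg(a - b)
    return out


def min_height(bone: TriangleMesh, ground: GroundPlane | None = None) -> float:
    """Minimum distance (mm) of the bone surface from the ground, >= 0.

    With ``ground=None`` the bone is assumed realigned (ground at z = 0)
    and the minimum vertex z is used.
    """
    if ground is None:
        h = float(bone.vertices[:, 2].min())
    else:
        h = float(ground.signed_distance(bone.vertices).min())
    return max(h, 0.0)


def relative_height(bone_height: float, foot_length: float) -> float:
    """Height normalised by foot length (calcaneus-to-M2 plantar distance)."""
    if not foot_length > 0:
        raise GeometryError(f"foot length must be positive, got {foot_length}")
    return bone_height / foot_length


def assemble_3d_variables(
    angles: Mapping[str, float], heights: Mapping[str, float]
) -> pd.Series:
    """Assemble the 84-entry skeletal variable vector.

    Parameters
    ----------
    angles : mapping with the 60 angle entries (``I*_M1`` ... ``RT_M5P5``)
    heights : mapping with the 24 height entries (``Hg_M1`` ... ``Hgr_NAV``)

    Undefined (NaN) entries are carried as missing.  A missing bone raises
    an error naming the first absent variable's bone.
    """
    merged = {**dict(angles), **dict(heights)}
    values = []
    for name in VARIABLE_NAMES_3D:
        if name not in merged:
            bone = name.split("_", 1)[1]
            raise KeyError(f"{bone} required: variable {name} missing")
        values.append(float(merged[name]))
    return pd.Series(values, index=list(VARIABLE_NAMES_3D), name="3D", dtype=float)


def foot_3d_variables(
    bone_frames: Mapping[str, BoneFrame],
    realigned_meshes: Mapping[str, TriangleMesh],
    foot_length: float,
    foot: FootFrame | None = None,
) -> pd.Series:
    """Compute the full 84-vector from realigned meshes and their frames.

    ``bone_frames`` must contain the 10 forefoot bones; ``realigned_meshes``
    additionally CUB and NAV for the midfoot heights.
    """
    angles: dict[str, float] = {}
    for b in FOREFOOT_BONES:
        if b not in bone_frames:
            raise KeyError(f"{b} required")
        angles.update(
            {f"{k}_{b}": v for k, v in absolute_inclination(bone_frames[b], foot).items()}
        )
    for prox, dist in MTP_PAIRS:
        rel = relative_orientation(bone_frames[prox], bone_frames[dist], foot)
        angles.update({f"{k}_{prox}{dist}": v for k, v in rel.items()})

    heights: dict[str, float] = {}
    for b in HEIGHT_BONES:
        if b not in realigned_meshes:
            raise KeyError(f"{b} required")
        h = min_height(realigned_meshes[b])
        heights[f"Hg_{b}"] = h
        heights[f"Hgr_{b}"] = relative_height(h, foot_length)
    return assemble_3d_variables(angles, heights)
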