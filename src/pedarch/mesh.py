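"""Bone-mesh geometry: STL I/O, ground-plane fit, the foot anatomical
reference frame, rigid realignment, and PCA-based bone-embedded frames.

Coordinates are millimetres throughout.  After realignment the convention
is right-handed z-up: x = antero/posterior (ap), y = medio-lateral (ml),
z = vertical.  The three anatomical planes follow from the frame axes:
lateral = span(ap, vert), transverse = span(ap, ml), frontal = span(ml, vert).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

from .errors import (
    DegeneracyWarning,
    GeometryError,
    MeshParseError,
    MeshValidationError,
    PlaneFitError,
)

#: Controlled vocabulary of segment labels.
BONE_LABELS = frozenset(
    ["CAL", "TAL", "NAV", "CUB", "CN1", "CN2", "CN3"]
    + [f"M{i}" for i in range(1, 6)]
    + [f"P{i}" for i in range(1, 6)]
    + ["GROUND"]
)

#: Ratio of the two largest PCA eigenvalues below which a bone is
#: considered to have no dominant longitudinal axis.
EIGEN_TIE_RATIO = 1.05


@dataclass
class TriangleMesh:
    """Triangulated surface of one bone (or the ground segment).

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices
    label : segment name from :data:`BONE_LABELS`
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError(f"{self.label}: vertices must be (n, 3)")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshValidationError(f"{self.label}: face index out of range")
        if self.label != "GROUND":
            if len(self.vertices) < 4:
                raise MeshValidationError(
                    f"{self.label}: a bone needs >= 4 vertices"
                )
            if _coplanar(self.vertices):
                raise MeshValidationError(f"{self.label}: vertices are coplanar")

    @property
    def centroid(self) -> np.ndarray:
        """Arithmetic mean of the unique vertices."""
        return np.unique(self.vertices, axis=0).mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        """Return a rigidly moved copy: ``v -> rotation @ v + translation``."""
        verts = self.vertices @ np.asarray(rotation).T + np.asarray(translation)
        return TriangleMesh(verts, self.faces.copy(), self.label)


def _coplanar(verts: np.ndarray, tol: float = 1e-9) -> bool:
    pts = np.unique(verts, axis=0)
    if len(pts) < 4:
        return True
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[2] <= tol * max(s[0], 1.0)


@dataclass
class GroundPlane:
    """Plane ``normal . x = offset`` with unit normal pointing toward the bones."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if not np.isfinite(n) or n == 0:
            raise PlaneFitError("ground normal has zero length")
        self.offset = float(self.offset) / n
        self.normal = self.normal / n

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distances, positive on the bone side."""
        return np.asarray(points, dtype=float) @ self.normal - self.offset

    def project(self, points: np.ndarray) -> np.ndarray:
        """Orthogonal projection of ``points`` onto the plane."""
        d = self.signed_distance(points)
        return np.asarray(points, dtype=float) - np.outer(np.atleast_1d(d), self.normal).reshape(
            np.shape(points)
        )


@dataclass
class FootFrame:
    """Foot anatomical reference frame.

    ``vert_axis`` is the ground normal; ``ap_axis`` runs on the ground plane
    from the calcaneus plantar point toward the second metatarsal head;
    ``ml_axis = vert x ap`` closes the right-handed triad
    (``ap x ml = vert``).  ``foot_length`` is the on-ground distance between
    the two plantar-point projections that define ``ap_axis``.
    """

    origin: np.ndarray
    ap_axis: np.ndarray
    ml_axis: np.ndarray
    vert_axis: np.ndarray
    foot_length: float = field(default=np.nan)

    def __post_init__(self) -> None:
        for name in ("origin", "ap_axis", "ml_axis", "vert_axis"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise GeometryError("foot frame axes are not orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("foot frame is left-handed")

    @property
    def rotation(self) -> np.ndarray:
        """World-to-foot rotation; rows are ap, ml, vert."""
        return np.vstack([self.ap_axis, self.ml_axis, self.vert_axis])

    def to_foot(self, points: np.ndarray) -> np.ndarray:
        """Express world-frame points in foot coordinates."""
        return (np.asarray(points, dtype=float) - self.origin) @ self.rotation.T

    @classmethod
    def identity(cls) -> "FootFrame":
        return cls(np.zeros(3), np.r_[1.0, 0, 0], np.r_[0, 1.0, 0], np.r_[0, 0, 1.0])


@dataclass
class BoneFrame:
    """PCA-derived bone-embedded frame.

    Axes are ordered by descending variance of the surface-point cloud;
    the first is the longitudinal (near antero/posterior) direction.  Signs
    follow the anatomical convention resolved against the foot frame:
    longitudinal points anteriorly, dp dorsally, and
    ``longitudinal x ml = dp``.
    """

    centroid: np.ndarray
    longitudinal_axis: np.ndarray
    ml_axis: np.ndarray
    dp_axis: np.ndarray
    variances: np.ndarray
    degenerate: bool = False


# ---------------------------------------------------------------------------
# STL I/O


def read_stl(path: str | Path, label: str | None = None) -> TriangleMesh:
    """Read a binary or ASCII STL file into a :class:`TriangleMesh`.

    Vertices are deduplicated by exact coordinate match.  The segment label
    defaults to the upper-cased file stem, validated against
    :data:`BONE_LABELS`.
    """
    path = Path(path)
    if label is None:
        label = path.stem.upper()
    if label not in BONE_LABELS:
        raise MeshValidationError(
            f"file stem {path.stem!r} is not a recognised segment label"
        )
    try:
        raw = _trimesh.load_mesh(path, file_type="stl", process=False)
    except Exception as exc:  # trimesh raises various types on bad input
        raise MeshParseError(f"cannot parse STL {path}: {exc}") from exc
    verts = np.asarray(raw.vertices, dtype=float)
    faces = np.asarray(raw.faces, dtype=int)
    if verts.size == 0 or faces.size == 0:
        raise MeshParseError(f"{path}: empty mesh")
    uniq, inverse = np.unique(verts, axis=0, return_inverse=True)
    return TriangleMesh(uniq, inverse[faces], label)


def write_stl(mesh: TriangleMesh, path: str | Path) -> None:
    """Write a mesh to binary STL (vertex coordinates preserved exactly
    up to the format's float32 storage)."""
    tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(Path(path), file_type="stl")


# ---------------------------------------------------------------------------
# Ground plane and foot frame


def fit_ground_plane(ground: TriangleMesh, toward=None) -> GroundPlane:
    """Total-least-squares plane through the ground-segment vertices.

    Parameters
    ----------
    ground : ground-segment mesh
    toward : optional 3-point or iterable of bone meshes used to orient the
        normal toward the bone cloud; with neither, the normal keeps a
        positive component on its largest axis.
    """
    pts = np.unique(ground.vertices, axis=0)
    if len(pts) < 3:
        raise PlaneFitError("ground mesh has fewer than 3 unique vertices")
    center = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - center)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise PlaneFitError("ground vertices are collinear")
    normal = vt[2]
    if toward is not None:
        if hasattr(toward, "__iter__") and not isinstance(toward, np.ndarray):
            toward = np.mean([m.centroid for m in toward], axis=0)
        if np.dot(np.asarray(toward, dtype=float) - center, normal) < 0:
            normal = -normal
    elif normal[np.argmax(np.abs(normal))] < 0:
        normal = -normal
    return GroundPlane(normal, float(normal @ center))


#: Plantar-point tie tolerance (mm): vertices this close to the minimum
#: ground distance are tied and resolved by the medio-lateral tie-break.
PLANTAR_TIE_TOL = 1e-3


def _pick_plantar(verts: np.ndarray, d: np.ndarray, tiebreak: np.ndarray | None) -> np.ndarray:
    """Lowest vertex; near-ties resolved by the largest projection onto a
    frame-invariant direction (the provisional medio-lateral axis), so the
    choice does not depend on the arbitrary scanner pose."""
    cand = np.flatnonzero(d <= d.min() + PLANTAR_TIE_TOL)
    if len(cand) > 1 and tiebreak is not None:
        cand = cand[np.argsort(verts[cand] @ tiebreak)]
        return verts[cand[-1]]
    return verts[int(cand[np.argmin(d[cand])])]


def _most_plantar(
    mesh: TriangleMesh, ground: GroundPlane, tiebreak: np.ndarray | None = None
) -> np.ndarray:
    d = ground.signed_distance(mesh.vertices)
    return _pick_plantar(mesh.vertices, d, tiebreak)


def _m2_head_plantar(
    m2: TriangleMesh,
    ground: GroundPlane,
    anterior_hint: np.ndarray,
    distal_fraction: float = 0.30,
    tiebreak: np.ndarray | None = None,
) -> np.ndarray:
    """Most plantar vertex within the distal (head) region of M2.

    The head region is the distal ``distal_fraction`` of the bone's extent
    along its first principal axis, the axis sign being resolved against
    ``anterior_hint``.
    """
    verts = np.unique(m2.vertices, axis=0)
    centered = verts - verts.mean(axis=0)
    cov = centered.T @ centered / len(verts)
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    if axis @ anterior_hint < 0:
        axis = -axis
    t = centered @ axis
    cut = t.min() + (1.0 - distal_fraction) * (t.max() - t.min())
    head = verts[t >= cut]
    d = ground.signed_distance(head)
    return _pick_plantar(head, d, tiebreak)


def compute_foot_frame(
    calcaneus: TriangleMesh,
    m2: TriangleMesh,
    ground: GroundPlane,
) -> FootFrame:
    """Construct the foot anatomical frame in the scanner coordinates.

    The vertical axis is the ground normal; the antero/posterior axis is
    the on-ground segment from the projection of the calcaneus's most
    plantar point to the projection of the most plantar point of the second
    metatarsal head.  The head is located in a first pass with the bone's
    provisional principal axis and refined once with the resulting frame's
    ap direction.
    """
    hint = m2.centroid - calcaneus.centroid
    for _ in range(2):  # provisional pass, then one refinement
        hp = hint - (hint @ ground.normal) * ground.normal
        nh = np.linalg.norm(hp)
        if nh < 1e-9:
            raise GeometryError("anterior direction is vertical; frame undefined")
        ml_hint = np.cross(ground.normal, hp / nh)
        p_cal = _most_plantar(calcaneus, ground, tiebreak=ml_hint)
        p_m2 = _m2_head_plantar(m2, ground, hint, tiebreak=ml_hint)
        ap_vec = ground.project(p_m2) - ground.project(p_cal)
        length = np.linalg.norm(ap_vec)
        if length < 1e-9:
            raise GeometryError(
                "calcaneus and M2 plantar points coincide in ground projection"
            )
        hint = ap_vec / length
    ap = ap_vec / length
    vert = ground.normal
    ml = np.cross(vert, ap)
    return FootFrame(
        origin=ground.project(p_cal),
        ap_axis=ap,
        ml_axis=ml / np.linalg.norm(ml),
        vert_axis=vert,
        foot_length=float(length),
    )


def realign(
    meshes: dict[str, TriangleMesh] | list[TriangleMesh],
    frame: FootFrame,
) -> dict[str, TriangleMesh] | list[TriangleMesh]:
    """Rigidly express meshes in the foot frame (ap -> x, ml -> y, vert -> z,
    origin -> (0, 0, 0)).  Pairwise distances are preserved exactly."""
    R = frame.rotation

    def _move(m: TriangleMesh) -> TriangleMesh:
        return TriangleMesh((m.vertices - frame.origin) @ R.T, m.faces.copy(), m.label)

    if isinstance(meshes, dict):
        return {k: _move(m) for k, m in meshes.items()}
    return [_move(m) for m in meshes]


# ---------------------------------------------------------------------------
# PCA bone frames


def pca_bone_frame(bone: TriangleMesh, foot: FootFrame | None = None) -> BoneFrame:
    """Bone-embedded frame from PCA of the unique surface vertices.

    The bone must already be expressed in the foot frame (or ``foot`` given
    as the frame to interpret the axes against; identity by default).
    Eigenvectors are ordered by descending variance; signs are resolved
    anatomically: the longitudinal axis gets a non-negative dot product
    with the foot ap axis, of the remaining two the one closer to vertical
    becomes the dorsi-plantar axis (flipped dorsal-positive), and the
    medio-lateral axis is flipped to make the triad right-handed
    (``longitudinal x ml = dp``).
    """
    if foot is None:
        foot = FootFrame.identity()
    verts = np.unique(bone.vertices, axis=0)
    centroid = verts.mean(axis=0)
    centered = verts - centroid
    cov = centered.T @ centered / len(verts)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]
    if w[2] <= 0 or not np.all(np.isfinite(w)):
        raise GeometryError(f"{bone.label}: degenerate vertex covariance")

    degenerate = w[0] / w[1] < EIGEN_TIE_RATIO
    if degenerate:
        warnings.warn(
            f"{bone.label}: no dominant longitudinal axis "
            f"(eigenvalue ratio {w[0] / w[1]:.4f} < {EIGEN_TIE_RATIO})",
            DegeneracyWarning,
            stacklevel=2,
        )
    # deterministic sign fix before the anatomical flips
    for k in range(3):
        if v[np.argmax(np.abs(v[:, k])), k] < 0:
            v[:, k] = -v[:, k]

    longitudinal = v[:, 0]
    if longitudinal @ foot.ap_axis < 0:
        longitudinal = -longitudinal
    a, b = v[:, 1], v[:, 2]
    if abs(a @ foot.vert_axis) >= abs(b @ foot.vert_axis):
        dp, ml = a, b
    else:
        dp, ml = b, a
    if dp @ foot.vert_axis < 0:
        dp = -dp
    if np.cross(longitudinal, ml) @ dp < 0:
        ml = -ml
    return BoneFrame(
        centroid=centroid,
        longitudinal_axis=longitudinal,
        ml_axis=ml,
        dp_axis=dp,
        variances=w,
        degenerate=bool(degenerate),
    )
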