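"""Dynamic plantar-pressure processing.

Turns time-ordered pressure grids from barefoot walking trials into the 12
regional LOAD variables (peak pressure PP, pressure-time integral PTI and
PTI normalised to contact time PTI_N, in the hallux, first, central and
fifth metatarsal regions) and the two FUNC variables (contact time CT and
arch index AI).

Grid convention: a frame is an (H, W) array of pressures in kPa sampled on
a square sensor grid of pitch ``pitch`` mm (default 5 mm, i.e. 4 sensors
per cm^2) every ``dt`` ms (default 10 ms, 100 Hz).  A pixel at row r,
column c sits at x = c * pitch (medio-lateral), y = r * pitch (posterior
to anterior).  Marker positions are given in these (x, y) millimetres.

The forefoot is subdivided by fanning rays from the footprint apex (the
most posterior contact point): the whole-foot plantar angle gamma between
the medial and lateral tangents of the footprint is split into sectors of
30, 51 and 19 % of gamma, medial to lateral, defining the first, central
(II-IV) and fifth metatarsal regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .errors import MaskingError, PedarchError

PRESSURE_RANGE_KPA = (0.0, 1270.0)  # capacitive platform measurement range
DEFAULT_CONTACT_THRESHOLD = 10.0  # kPa
DEFAULT_SECTOR_FRACTIONS = (0.30, 0.51, 0.19)
#: Posterior offset (mm) of the forefoot band's rear edge from the
#: metatarsal-head marker line, so the band covers the heads themselves.
DEFAULT_MET_OFFSET = -25.0
DEFAULT_TOE_OFFSET = 0.0

MARKER_NAMES = ("CAL", "M1", "M2", "M5", "HLX")

REGIONS_FOREFOOT = ("HLX", "I_MET", "II_IV_MET", "V_MET")
LABEL_CODES = {
    "NONE": 0,
    "HLX": 1,
    "I_MET": 2,
    "II_IV_MET": 3,
    "V_MET": 4,
    "MIDFOOT": 5,
    "HINDFOOT": 6,
}

LOAD_METRICS = ("PP", "PTI", "PTI_N")
#: Canonical order of the 12 LOAD variables.
LOAD_VARIABLES = tuple(
    f"{m}_{r}" for r in REGIONS_FOREFOOT for m in LOAD_METRICS
)


@dataclass
class PressureFrameSequence:
    """One walking trial: time-ordered pressure grids plus marker positions."""

    frames: np.ndarray  # (T, H, W) kPa
    pitch: float = 5.0  # mm
    dt: float = 10.0  # ms
    markers: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise PedarchError("frames must be a non-empty (T, H, W) stack")
        lo, hi = PRESSURE_RANGE_KPA
        if self.frames.min() < lo or self.frames.max() > hi:
            raise PedarchError(
                f"pressures outside the platform range {PRESSURE_RANGE_KPA} kPa"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class Footprint:
    """Per-sensor maximum pressure over time and the derived contact mask."""

    peak_image: np.ndarray  # (H, W) kPa
    contact_mask: np.ndarray  # (H, W) bool
    pitch: float = 5.0
    threshold: float = DEFAULT_CONTACT_THRESHOLD
    transforms: list | None = None  # set by register_and_average
    residuals: list | None = None


@dataclass
class RegionMask:
    """Labelled footprint grid plus the masking geometry that produced it."""

    labels: np.ndarray  # (H, W) int codes per LABEL_CODES
    gamma: float  # whole-foot plantar angle, degrees
    boundaries: tuple[float, float]  # interior ray angles from the medial tangent
    axis: np.ndarray  # unit foot axis (x, y), anterior-positive
    apex: np.ndarray  # apex position (x, y) mm
    toe_s: float  # toe-line position along the axis, mm from apex
    met_s: float  # forefoot band rear edge along the axis, mm from apex
    pitch: float = 5.0

    def region(self, name: str) -> np.ndarray:
        """Boolean mask of one labelled region."""
        return self.labels == LABEL_CODES[name]


def peak_pressure_image(
    seq: PressureFrameSequence,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
) -> Footprint:
    """Per-sensor maximum over time; contact where the peak exceeds
    ``threshold``."""
    peak = seq.frames.max(axis=0)
    mask = peak > threshold
    if not mask.any():
        raise MaskingError("empty footprint: no sensor above contact threshold")
    return Footprint(peak, mask, pitch=seq.pitch, threshold=threshold)


def contact_time(
    seq: PressureFrameSequence,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
) -> float:
    """Contact time in ms: frames with any sensor above threshold, times dt."""
    active = (seq.frames > threshold).any(axis=(1, 2))
    return float(active.sum() * seq.dt)


# ---------------------------------------------------------------------------
# Registration and averaging of footprints


def _mask_pose(mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Centroid (row, col) and principal-axis orientation of a boolean mask.

    The orientation is the angle of the largest-variance direction in the
    (row, col) plane, normalised to [0, pi).
    """
    rc = np.argwhere(mask).astype(float)
    c = rc.mean(axis=0)
    cov = np.cov((rc - c).T)
    w, v = np.linalg.eigh(cov)
    e = v[:, np.argmax(w)]
    theta = np.arctan2(e[1], e[0]) % np.pi
    return c, theta


def register_and_average(footprints: list[Footprint], residual_bound: float = 0.5) -> Footprint:
    """Rigidly register footprints to the first and average the peak images.

    Each footprint is aligned to the first by matching the contact-mask
    centroid and principal-axis orientation (rotation resolved to the
    nearest half-turn).  The aligned peak images are averaged pixelwise.
    Recovered (drow, dcol, dtheta) transforms and mask-overlap residuals
    (1 - Jaccard index) are attached to the result; a residual above
    ``residual_bound`` raises a warning.
    """
    if len(footprints) < 2:
        raise PedarchError("need at least 2 footprints to register and average")
    ref = footprints[0]
    c_ref, th_ref = _mask_pose(ref.contact_mask)
    aligned = [ref.peak_image.astype(float)]
    transforms: list[tuple[float, float, float]] = [(0.0, 0.0, 0.0)]
    residuals: list[float] = [0.0]
    for fp in footprints[1:]:
        c, th = _mask_pose(fp.contact_mask)
        d = th_ref - th
        d = (d + np.pi / 2) % np.pi - np.pi / 2  # nearest half-turn
        rot = np.array([[np.cos(d), -np.sin(d)], [np.sin(d), np.cos(d)]])
        # output[p] = input[rot^-1 (p - c_ref) + c]
        matrix = rot.T
        offset = c - matrix @ c_ref
        img = ndimage.affine_transform(
            fp.peak_image, matrix, offset=offset, order=1, mode="constant", cval=0.0
        )
        aligned.append(img)
        msk = img > ref.threshold
        inter = np.logical_and(msk, ref.contact_mask).sum()
        union = np.logical_or(msk, ref.contact_mask).sum()
        res = 1.0 - inter / union if union else 1.0
        if res > residual_bound:
            warnings.warn(
                f"footprint registration residual {res:.2f} above {residual_bound}",
                stacklevel=2,
            )
        transforms.append((c_ref[0] - c[0], c_ref[1] - c[1], float(d)))
        residuals.append(float(res))
    mean_img = np.mean(aligned, axis=0)
    out = Footprint(
        mean_img, mean_img > ref.threshold, pitch=ref.pitch, threshold=ref.threshold
    )
    out.transforms = transforms
    out.residuals = residuals
    return out


# ---------------------------------------------------------------------------
# Anatomical masking


def _contact_xy(fp: Footprint) -> np.ndarray:
    rc = np.argwhere(fp.contact_mask).astype(float)
    return rc[:, ::-1] * fp.pitch  # (x, y) mm


def _side_tangents(
    hull_pts: np.ndarray, e1: np.ndarray, e2: np.ndarray, medial_sign: float
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Medial and lateral supporting bitangent lines of the footprint hull.

    Each side tangent is the hull edge that spans from the posterior
    (heel) bulge to the anterior (forefoot) bulge of the footprint; as a
    hull edge it is automatically a supporting line of the whole contact
    area.  Returns ((point, direction), ...) for the medial then lateral
    line, directions oriented anteriorly.
    """
    s = hull_pts @ e1
    lo, span = s.min(), s.max() - s.min()
    if span <= 0:
        raise MaskingError("degenerate hull: no extent along the foot axis")
    edges = list(zip(hull_pts, np.roll(hull_pts, -1, axis=0)))
    sides: dict[float, list[tuple[float, np.ndarray, np.ndarray]]] = {1.0: [], -1.0: []}
    for p1, p2 in edges:
        s1, s2 = p1 @ e1, p2 @ e1
        if min(s1, s2) < lo + 0.45 * span and max(s1, s2) > lo + 0.55 * span:
            side = np.sign((0.5 * (p1 + p2)) @ e2)
            if side != 0:
                sides[side].append((float(np.linalg.norm(p2 - p1)), p1, p2))
    out = []
    for sign in (medial_sign, -medial_sign):
        cands = sides.get(sign, [])
        if not cands:
            raise MaskingError(
                "cannot find a side tangent: footprint has no heel-to-forefoot "
                "hull edge on one side"
            )
        _, p1, p2 = max(cands, key=lambda c: c[0])
        d = p2 - p1
        if d @ e1 < 0:
            d = -d
        out.append((p1, d / np.linalg.norm(d)))
    return out[0], out[1]


def plantar_angle_masks(
    fp: Footprint,
    markers: dict[str, tuple[float, float]],
    fractions: tuple[float, float, float] = DEFAULT_SECTOR_FRACTIONS,
    met_offset: float = DEFAULT_MET_OFFSET,
    toe_offset: float = DEFAULT_TOE_OFFSET,
) -> RegionMask:
    """Marker-based anatomical masking of a footprint.

    The foot axis is the principal axis of the contact mask, pointed
    anteriorly using the CAL -> M2 marker direction.  The medial and
    lateral tangents of the footprint (supporting lines of the contact
    convex hull running from the heel bulge to the forefoot bulge) span
    the whole-foot plantar angle gamma at their intersection behind the
    heel; gamma is split medial-to-lateral into ``fractions`` (default
    30/51/19 %) by rays fanning from that apex, defining the first,
    central (II-IV) and fifth metatarsal sectors.  Parallel tangents
    (gamma = 0, e.g. a rectangular footprint) degrade gracefully to
    partitioning the strip width in the same proportions.

    The forefoot band lies between the metatarsal-head marker line
    (offset by ``met_offset`` mm along the axis) and the toe line through
    the hallux marker (offset ``toe_offset``); the hallux region is the
    contact anterior to the toe line and medial of the first sector
    boundary.  The toe-free footprint is banded into three equal-length
    thirds along the axis to label MIDFOOT and HINDFOOT.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise MaskingError(f"sector fractions must sum to 1, got {fractions}")
    for name in MARKER_NAMES:
        if name not in markers:
            raise MaskingError(f"marker {name} missing")
    xy = _contact_xy(fp)
    if len(xy) < 3:
        raise MaskingError("too few contact pixels for masking")

    # anterior-positive foot axis
    c = xy.mean(axis=0)
    cov = np.cov((xy - c).T)
    w, v = np.linalg.eigh(cov)
    e1 = v[:, np.argmax(w)]
    ant = np.asarray(markers["M2"], float) - np.asarray(markers["CAL"], float)
    if e1 @ ant < 0:
        e1 = -e1
    e2 = np.array([-e1[1], e1[0]])

    try:
        hull = ConvexHull(xy)
        hull_pts = xy[hull.vertices]  # counterclockwise
    except QhullError as exc:
        raise MaskingError(f"degenerate contact hull: {exc}") from exc

    medial_sign = float(np.sign((np.asarray(markers["M1"], float) - c) @ e2))
    if medial_sign == 0:
        raise MaskingError("M1 marker lies on the foot axis; medial side unknown")
    (p_med, d_med), (p_lat, d_lat) = _side_tangents(hull_pts - c, e1, e2, medial_sign)
    p_med, p_lat = p_med + c, p_lat + c

    phi_med = np.degrees(np.arctan2(d_med @ e2, d_med @ e1))
    phi_lat = np.degrees(np.arctan2(d_lat @ e2, d_lat @ e1))
    gamma = float(abs(phi_med - phi_lat))
    cum1, cum2 = fractions[0], fractions[0] + fractions[1]
    b1, b2 = cum1 * gamma, cum2 * gamma

    if gamma < 0.05:
        # parallel tangents: fan apex at infinity; use the strip width
        smin_idx = int(np.argmin(xy @ e1))
        apex = xy[smin_idx]
        n_med = np.array([-d_med[1], d_med[0]])
        if n_med @ (p_lat - p_med) < 0:
            n_med = -n_med
        width = float(n_med @ (p_lat - p_med))
        if width <= 0:
            raise MaskingError("degenerate footprint: zero tangent separation")
        u = ((xy - p_med) @ n_med) / width
    else:
        # apex: intersection of the two tangent lines (behind the heel)
        A = np.column_stack([d_med, -d_lat])
        ts = np.linalg.solve(A, p_lat - p_med)
        apex = p_med + ts[0] * d_med
        rel = xy - apex
        phi_px = np.degrees(np.arctan2(rel @ e2, rel @ e1))
        u = (phi_med - phi_px) / (phi_med - phi_lat)
    u = np.clip(u, 0.0, 1.0)

    # positions along the axis, measured from the apex
    s_px = (xy - apex) @ e1
    s_markers = {k: (np.asarray(p, float) - apex) @ e1 for k, p in markers.items()}
    met_s = float(np.mean([s_markers["M1"], s_markers["M2"], s_markers["M5"]])) + met_offset
    toe_s = float(s_markers["HLX"]) + toe_offset

    labels_flat = np.zeros(len(xy), dtype=np.int8)
    sector = np.where(u < cum1, LABEL_CODES["I_MET"],
                      np.where(u < cum2, LABEL_CODES["II_IV_MET"], LABEL_CODES["V_MET"]))
    fore = (s_px >= met_s) & (s_px < toe_s)
    labels_flat[fore] = sector[fore]
    toe = s_px >= toe_s
    labels_flat[toe & (u < cum1)] = LABEL_CODES["HLX"]

    # equal-length thirds of the toe-free footprint for MIDFOOT / HINDFOOT
    toe_free = ~toe
    if toe_free.any():
        lo, hi = s_px[toe_free].min(), s_px[toe_free].max()
        t1, t2 = lo + (hi - lo) / 3.0, lo + 2.0 * (hi - lo) / 3.0
        rear = toe_free & (labels_flat == 0)
        labels_flat[rear & (s_px < t1)] = LABEL_CODES["HINDFOOT"]
        labels_flat[rear & (s_px >= t1) & (s_px < t2)] = LABEL_CODES["MIDFOOT"]

    labels = np.zeros(fp.contact_mask.shape, dtype=np.int8)
    labels[fp.contact_mask] = labels_flat
    return RegionMask(
        labels=labels,
        gamma=gamma,
        boundaries=(b1, b2),
        axis=e1,
        apex=apex,
        toe_s=toe_s,
        met_s=met_s,
        pitch=fp.pitch,
    )


# ---------------------------------------------------------------------------
# Regional LOAD metrics and FUNC variables


def regional_metrics(
    seq: PressureFrameSequence,
    mask: RegionMask,
    region: str,
    contact_threshold: float = DEFAULT_CONTACT_THRESHOLD,
    pti_convention: str = "peak_curve",
) -> tuple[dict[str, float], bool]:
    """PP (kPa), PTI (kPa s) and PTI_N (kPa) for one region of one trial.

    ``pti_convention='peak_curve'`` integrates the regional peak-pressure
    curve (the per-frame maximum over the region's sensors);
    ``'per_sensor'`` takes the maximum over sensors of the per-sensor
    time integral.  PTI_N divides PTI by the whole-foot contact time in
    seconds.  Returns the metrics and an empty-region flag (metrics are
    zero when the region never makes contact).
    """
    sel = mask.region(region)
    if not sel.any():
        return {"PP": 0.0, "PTI": 0.0, "PTI_N": 0.0}, True
    sub = seq.frames[:, sel]  # (T, n_px)
    peak_curve = sub.max(axis=1)
    if peak_curve.max() <= contact_threshold:
        return {"PP": 0.0, "PTI": 0.0, "PTI_N": 0.0}, True
    pp = float(peak_curve.max())
    dt_s = seq.dt / 1000.0
    if pti_convention == "peak_curve":
        pti = float(peak_curve.sum() * dt_s)
    elif pti_convention == "per_sensor":
        pti = float((sub.sum(axis=0) * dt_s).max())
    else:
        raise PedarchError(f"unknown PTI convention {pti_convention!r}")
    ct_s = contact_time(seq, contact_threshold) / 1000.0
    pti_n = pti / ct_s if ct_s > 0 else 0.0
    return {"PP": pp, "PTI": pti, "PTI_N": pti_n}, False


def arch_index(fp: Footprint, mask: RegionMask) -> float:
    """Midfoot contact area over total toe-free contact area.

    The toe-free footprint is split into three equal-length bands along the
    foot axis; the arch index is the middle band's share of the contact
    area.
    """
    xy = _contact_xy(fp)
    s = (xy - mask.apex) @ mask.axis
    toe_free = s < mask.toe_s
    if not toe_free.any():
        raise MaskingError("empty toe-free footprint")
    sf = s[toe_free]
    lo, hi = sf.min(), sf.max()
    if hi <= lo:
        raise MaskingError("degenerate toe-free footprint extent")
    t1, t2 = lo + (hi - lo) / 3.0, lo + 2.0 * (hi - lo) / 3.0
    middle = (sf >= t1) & (sf < t2)
    return float(middle.sum() / toe_free.sum())


def trial_load_variables(
    seq: PressureFrameSequence,
    contact_threshold: float = DEFAULT_CONTACT_THRESHOLD,
    fractions: tuple[float, float, float] = DEFAULT_SECTOR_FRACTIONS,
    pti_convention: str = "peak_curve",
    met_offset: float = DEFAULT_MET_OFFSET,
    toe_offset: float = DEFAULT_TOE_OFFSET,
) -> pd.Series:
    """The 12 LOAD variables of a single trial."""
    fp = peak_pressure_image(seq, contact_threshold)
    mask = plantar_angle_masks(
        fp, seq.markers, fractions, met_offset=met_offset, toe_offset=toe_offset
    )
    out: dict[str, float] = {}
    for region in REGIONS_FOREFOOT:
        metrics, _ = regional_metrics(
            seq, mask, region, contact_threshold, pti_convention
        )
        for m in LOAD_METRICS:
            out[f"{m}_{region}"] = metrics[m]
    return pd.Series(out, index=list(LOAD_VARIABLES), dtype=float)


def foot_load_and_func(
    trials: list[PressureFrameSequence],
    contact_threshold: float = DEFAULT_CONTACT_THRESHOLD,
    fractions: tuple[float, float, float] = DEFAULT_SECTOR_FRACTIONS,
    pti_convention: str = "peak_curve",
    met_offset: float = DEFAULT_MET_OFFSET,
    toe_offset: float = DEFAULT_TOE_OFFSET,
) -> tuple[pd.Series, float, float]:
    """LOAD variables averaged over trials, plus CT (ms) and AI.

    Regional metrics are computed per trial and then averaged; the arch
    index is computed on the registered-and-averaged footprint (a single
    footprint is used as is), with the reference trial's masking geometry.
    """
    if not trials:
        raise PedarchError("no trials given")
    per_trial = [
        trial_load_variables(
            t, contact_threshold, fractions, pti_convention, met_offset, toe_offset
        )
        for t in trials
    ]
    load = pd.concat(per_trial, axis=1).mean(axis=1)
    load.name = "LOAD"
    ct = float(np.mean([contact_time(t, contact_threshold) for t in trials]))
    fps = [peak_pressure_image(t, contact_threshold) for t in trials]
    avg_fp = register_and_average(fps) if len(fps) > 1 else fps[0]
    ref_mask = plantar_angle_masks(
        avg_fp, trials[0].markers, fractions, met_offset=met_offset, toe_offset=toe_offset
    )
    ai = arch_index(avg_fp, ref_mask)
    return load, ct, ai
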