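"""Partition continuous traces into immobility bouts and single movements.

A *single movement* (primitive) is one discrete change of the angular
relation between a trunk segment and its next heavy neighbour — one
notational expression.  Because the body-relative angles already factor
out carried-along motion, a genuine movement shows up as a body-relative
angular excursion of exactly the segment that moved; carried-along lighter
segments stay flat and are never reported as movers.

Forward transport (translation without angular change) is detected from
joint translation: a transport bout is attributed to the heaviest segment
whose proximal joint translated, since every lighter joint is carried
along with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .linkage import (
    BodyRelativeAngles,
    HeavyLightOrder,
    KeypointSeries,
    LinkageSpec,
    quantize_direction,
)

__all__ = [
    "SegmentationParams",
    "ImmobilityBout",
    "Primitive",
    "Arena",
    "Plane",
    "detect_immobility",
    "segment_single_movements",
    "classify_movement_type",
    "detect_snout_contact",
]

MOVEMENT_TYPES = ("plane_horizontal", "plane_vertical", "conical", "forward_transport")


@dataclass
class SegmentationParams:
    """Tunables for movement segmentation.

    ``min_amplitude_deg`` defaults to a quarter of the 45-degree quantum:
    small enough to keep genuine low-amplitude "buds" of movement, large
    enough to suppress tracker jitter.  The hysteresis keeps bout detection
    stable around the speed threshold; the floor fraction controls how far
    bout boundaries are expanded toward the true rest points so amplitudes
    are read where the trace is flat.
    """

    quantum: float = 45.0
    min_amplitude_deg: float = 11.25
    speed_threshold_deg_s: float = 10.0
    hysteresis: float = 0.2
    floor_fraction: float = 0.05
    smooth_window_s: float = 0.25
    smooth_polyorder: int = 3
    plane_tolerance_deg: float = 22.5
    cone_residual_deg: float = 8.0
    transport_speed_threshold: float = 0.005  # length units / s
    min_transport_distance: float = 0.005  # length units
    contact_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.hysteresis < 1:
            raise ValueError("hysteresis must be in (0, 1)")
        if self.min_amplitude_deg <= 0 or self.speed_threshold_deg_s <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ImmobilityBout:
    """Maximal run of frames with all tracked speeds below threshold."""

    start: int  # frame, inclusive
    end: int  # frame, exclusive
    duration_s: float
    mean_position: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("bout must have end > start")


@dataclass
class Primitive:
    """One single movement attributed to the heaviest part that moved."""

    segment: str
    movement_type: str
    sign: str
    start: int
    end: int  # half-open
    amplitude_deg: float | None = None
    amplitude_units: int | None = None
    distance: float | None = None
    chord_members: tuple[str, ...] = ()
    snout_contact: bool | None = None
    support_base: str = "hindquarters"
    mixed: bool = False
    module: str | None = None

    def __post_init__(self) -> None:
        if self.movement_type not in MOVEMENT_TYPES:
            raise ValueError(f"unknown movement type {self.movement_type!r}")
        if self.end <= self.start:
            raise ValueError("primitive must have end > start")
        if self.movement_type == "forward_transport":
            if self.distance is None:
                raise ValueError("forward_transport needs a translation distance")
        elif self.amplitude_deg is None:
            raise ValueError("angular primitive needs amplitude_deg")

    def symbol(self) -> tuple[str, str, str]:
        return (self.segment, self.movement_type, self.sign)


# ---------------------------------------------------------------------------
# smoothing / bout helpers
# ---------------------------------------------------------------------------


def _smooth(x: np.ndarray, frame_rate: float, window_s: float, poly: int) -> np.ndarray:
    """Symmetric low-pass (Savitzky-Golay) along axis 0; a non-positive
    window disables smoothing (exact boundaries on noise-free input)."""
    if window_s <= 0:
        return x.copy()
    n = x.shape[0]
    w = int(round(window_s * frame_rate))
    if w % 2 == 0:
        w += 1
    w = max(w, poly + 1 + ((poly + 1) % 2 == 0))
    w = max(w, 5)
    if w >= n:
        return x.copy()
    return savgol_filter(x, w, poly, axis=0)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    if mask.size == 0:
        return []
    m = np.asarray(mask, dtype=bool)
    d = np.diff(m.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if m[0]:
        starts = [0] + starts
    if m[-1]:
        ends = ends + [m.size]
    return list(zip(starts, ends))


def _hysteresis_bouts(
    speed: np.ndarray, hi: float, lo: float, floor: float
) -> list[tuple[int, int]]:
    """Bouts seeded where speed >= hi, grown while > lo, then expanded
    outward while speed stays above ``floor`` (to reach the rest points)."""
    finite = np.isfinite(speed)
    seeds = finite & (speed >= hi)
    if not seeds.any():
        return []
    above_lo = finite & (speed > lo)
    bouts = []
    for s, e in _runs(above_lo):
        if seeds[s:e].any():
            bouts.append((s, e))
    above_floor = finite & (speed > floor)
    out: list[tuple[int, int]] = []
    for s, e in bouts:
        while s > 0 and above_floor[s - 1]:
            s -= 1
        n = speed.size
        while e < n and above_floor[e]:
            e += 1
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# immobility
# ---------------------------------------------------------------------------


def keypoint_speeds(
    kps: KeypointSeries, smooth_window_s: float = 0.25, polyorder: int = 3
) -> np.ndarray:
    """Per-frame per-keypoint speeds from smoothed first differences."""
    pos = np.where(kps.valid_mask[..., None], kps.positions, np.nan)
    # fill NaN by nearest valid for smoothing stability; speeds at invalid
    # frames are masked afterwards.
    filled = pos.copy()
    for k in range(pos.shape[1]):
        v = kps.valid_mask[:, k]
        if v.any() and not v.all():
            good = np.flatnonzero(v)
            t = np.arange(pos.shape[0])
            for d in range(pos.shape[2]):
                filled[:, k, d] = np.interp(t, good, pos[good, k, d])
        elif not v.any():
            filled[:, k, :] = 0.0
    sm = _smooth(filled, kps.frame_rate, smooth_window_s, polyorder)
    vel = np.gradient(sm, kps.times, axis=0)
    speed = np.linalg.norm(vel, axis=2)
    speed[~kps.valid_mask] = np.nan
    return speed


def detect_immobility(
    kps: KeypointSeries,
    speed_threshold: float,
    min_duration_s: float,
    reference_keypoint: str | None = None,
    smooth_window_s: float = 0.25,
) -> list[ImmobilityBout]:
    """Maximal non-overlapping bouts with all tracked speeds below threshold.

    Sub-threshold runs shorter than ``min_duration_s`` are ignored.
    """
    fps = kps.frame_rate
    min_frames = int(round(min_duration_s * fps))
    if min_frames < 2:
        raise ValueError("min_duration must span at least 2 frames")
    speed = keypoint_speeds(kps, smooth_window_s)
    with np.errstate(invalid="ignore"):
        quiet = np.all(np.where(np.isnan(speed), np.inf, speed) < speed_threshold, axis=1)
    quiet &= kps.valid_mask.any(axis=1)
    ref = reference_keypoint or kps.keypoint_names[0]
    ref_pos = kps.get(ref)
    bouts = []
    for s, e in _runs(quiet):
        if e - s >= min_frames:
            bouts.append(
                ImmobilityBout(
                    start=s,
                    end=e,
                    duration_s=(e - s) / fps,
                    mean_position=ref_pos[s:e].mean(axis=0),
                )
            )
    return bouts


# ---------------------------------------------------------------------------
# movement classification
# ---------------------------------------------------------------------------


def _unwrap_deg(theta: np.ndarray) -> np.ndarray:
    return np.degrees(np.unwrap(np.radians(theta), axis=0))


def classify_movement_type(
    theta_rel: np.ndarray,
    phi_rel: np.ndarray,
    params: SegmentationParams,
    base_displacement: float = 0.0,
    zero_dot: float = 0.0,
):
    """Classify one segmented bout of (theta_rel, phi_rel) plus root motion.

    Returns ``(movement_type, sign, amplitude_deg, distance, mixed)`` or
    ``None`` when neither the angular nor the translational criterion is
    met.  Plane movements keep one spherical coordinate approximately
    constant; a conical movement keeps a roughly constant half-angle to a
    fixed axis (a small circle on the direction sphere).  When both the
    angular and the translational criteria are met, the angular
    classification takes precedence and the bout is flagged mixed.
    """
    th = np.asarray(theta_rel, dtype=float)
    ph = np.asarray(phi_rel, dtype=float)
    dtheta = th[-1] - th[0]
    dphi = ph[-1] - ph[0]
    rtheta = np.ptp(th)
    rphi = np.ptp(ph)
    tol = params.plane_tolerance_deg
    amin = params.min_amplitude_deg
    angular = max(rtheta, rphi) >= amin
    translational = base_displacement >= params.min_transport_distance
    if not angular and not translational:
        return None
    if not angular:
        sign = "forward" if zero_dot >= 0 else "backward"
        return ("forward_transport", sign, None, float(base_displacement), False)

    mixed = translational
    h_sign = "left" if dtheta >= 0 else "right"
    v_sign = "up" if dphi >= 0 else "down"
    if rphi <= tol and rtheta >= amin:
        if np.max(np.abs(ph)) <= tol:
            return ("plane_horizontal", h_sign, abs(dtheta), None, mixed)
        # constant elevation off the horizontal plane: a cone about vertical
        return ("conical", h_sign, abs(dtheta), None, mixed)
    if rtheta <= tol and rphi >= amin:
        return ("plane_vertical", v_sign, abs(dphi), None, mixed)
    # both coordinates vary: small-circle (cone) fit on the sphere
    from .linkage import direction_from_angles

    u = direction_from_angles(th, ph)
    cov = np.cov(u.T)
    w, v = np.linalg.eigh(cov)
    axis = v[:, 0]
    dots = u @ axis
    resid_deg = np.degrees(np.std(np.arcsin(np.clip(dots, -1, 1))))
    rho = np.degrees(np.arccos(np.clip(abs(dots.mean()), 0, 1)))
    if resid_deg <= params.cone_residual_deg and abs(rho - 90.0) > tol / 2:
        amp = max(rtheta, rphi)
        sign = h_sign if rtheta >= rphi else v_sign
        return ("conical", sign, amp, None, mixed)
    if rtheta >= rphi:
        return ("plane_horizontal", h_sign, abs(dtheta), None, True)
    return ("plane_vertical", v_sign, abs(dphi), None, True)


# ---------------------------------------------------------------------------
# single-movement segmentation
# ---------------------------------------------------------------------------


def segment_single_movements(
    angles: BodyRelativeAngles,
    order: HeavyLightOrder,
    spec: LinkageSpec,
    params: SegmentationParams | None = None,
    kps: KeypointSeries | None = None,
    contact: np.ndarray | None = None,
    discard_log: list | None = None,
) -> list[Primitive]:
    """Detect single movements on body-relative angle traces.

    Angular bouts are bounded by angular-speed threshold crossings with
    hysteresis and expanded to the surrounding rest points; each bout is a
    primitive of the segment whose own body-relative angles changed.
    Lighter segments with overlapping own-movement bouts are cross-linked
    as chord members.  If ``kps`` is given, forward-transport bouts are
    detected from proximal-joint translation on frames without angular
    activity.  Sub-amplitude flicker is suppressed and counted in
    ``discard_log`` when provided.
    """
    params = params or SegmentationParams()
    T, S = angles.theta_rel.shape
    fps = angles.frame_rate
    times = angles.times

    th = _unwrap_deg(angles.theta_rel)
    ph = angles.phi_rel.astype(float)
    th_s = _smooth(th, fps, params.smooth_window_s, params.smooth_polyorder)
    ph_s = _smooth(ph, fps, params.smooth_window_s, params.smooth_polyorder)
    dth = np.gradient(th_s, times, axis=0)
    dph = np.gradient(ph_s, times, axis=0)
    ang_speed = np.hypot(dth, dph)
    ang_speed[~angles.valid] = np.nan

    hi = params.speed_threshold_deg_s
    lo = hi * (1 - params.hysteresis)
    floor = hi * params.floor_fraction

    seg_bouts: list[list[tuple[int, int]]] = []
    for s in range(S):
        seg_bouts.append(_hysteresis_bouts(ang_speed[:, s], hi, lo, floor))

    primitives: list[Primitive] = []
    per_seg_prims: list[list[tuple[int, int]]] = [[] for _ in range(S)]
    for s in range(S):
        name = angles.segment_names[s]
        for b0, b1 in seg_bouts[s]:
            sl = slice(b0, min(b1 + 1, T))
            res = classify_movement_type(th_s[sl, s], ph_s[sl, s], params)
            if res is None:
                if discard_log is not None:
                    discard_log.append(
                        {"segment": name, "start": b0, "end": b1, "reason": "sub-amplitude"}
                    )
                continue
            mtype, sign, amp, dist, mixed = res
            if mtype == "forward_transport":
                continue  # pure-angular pass; transport handled below
            snout = None
            if contact is not None:
                snout = bool(np.mean(contact[b0:b1]) >= params.contact_fraction)
            units = None
            if amp is not None:
                units = int(
                    quantize_direction(np.array([amp]), np.array([0.0]), params.quantum)[0][0]
                )
            primitives.append(
                Primitive(
                    segment=name,
                    movement_type=mtype,
                    sign=sign,
                    start=b0,
                    end=b1,
                    amplitude_deg=amp,
                    amplitude_units=units,
                    distance=None,
                    snout_contact=snout,
                    support_base=str(order.base[b0]),
                    mixed=mixed,
                )
            )
            per_seg_prims[s].append((b0, b1))

    # chord members: lighter segments with overlapping own-movement bouts
    for p in primitives:
        s = spec.segment_index(p.segment)
        members = []
        for s2 in range(S):
            if s2 == s:
                continue
            # lighter than s at onset?
            perm = list(order.order[p.start])
            if perm.index(s2) <= perm.index(s):
                continue
            for b0, b1 in per_seg_prims[s2]:
                if b0 < p.end and p.start < b1:
                    members.append(angles.segment_names[s2])
                    break
        p.chord_members = tuple(members)

    # forward transport from joint translation, outside angular activity
    if kps is not None:
        any_ang = np.zeros(T, dtype=bool)
        with np.errstate(invalid="ignore"):
            any_ang |= np.nanmax(np.where(np.isnan(ang_speed), 0, ang_speed), axis=1) > lo
        joint_pos = np.stack([kps.get(n) for n in spec.joint_names], axis=1)
        if joint_pos.shape[2] == 2:
            joint_pos = np.concatenate(
                [joint_pos, np.zeros(joint_pos.shape[:2] + (1,))], axis=2
            )
        jp_s = _smooth(joint_pos, fps, params.smooth_window_s, params.smooth_polyorder)
        jvel = np.gradient(jp_s, times, axis=0)
        jspeed = np.linalg.norm(jvel, axis=2)
        jspeed[any_ang, :] = np.nan
        thi = params.transport_speed_threshold
        tlo = thi * (1 - params.hysteresis)
        tfloor = thi * params.floor_fraction
        z0 = spec.zero()
        kept: list[tuple[int, int, int]] = []  # (joint, start, end)
        # proximal joint of segment i (hindquarters rooting) is joint i;
        # process root-most first so carried-along joints are skipped.
        for j in range(S):
            for b0, b1 in _hysteresis_bouts(jspeed[:, j], thi, tlo, tfloor):
                if any(k0 < b1 and b0 < k1 for _, k0, k1 in kept):
                    continue
                kept.append((j, b0, b1))
        for j, b0, b1 in kept:
            e = min(b1, T - 1)
            disp = joint_pos[e, j] - joint_pos[b0, j]
            dist = float(np.linalg.norm(disp))
            if dist < params.min_transport_distance:
                if discard_log is not None:
                    discard_log.append(
                        {
                            "segment": angles.segment_names[j],
                            "start": b0,
                            "end": b1,
                            "reason": "sub-distance transport",
                        }
                    )
                continue
            sign = "forward" if float(disp @ z0) >= 0 else "backward"
            snout = None
            if contact is not None:
                snout = bool(np.mean(contact[b0:b1]) >= params.contact_fraction)
            primitives.append(
                Primitive(
                    segment=angles.segment_names[j],
                    movement_type="forward_transport",
                    sign=sign,
                    start=b0,
                    end=b1,
                    distance=dist,
                    snout_contact=snout,
                    support_base=str(order.base[b0]),
                )
            )

    primitives.sort(key=lambda p: (p.start, spec.segment_index(p.segment)))
    return primitives


# ---------------------------------------------------------------------------
# snout contact
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Plane:
    """Infinite plane given by a point and a (unit) normal."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def distance(self, p: np.ndarray) -> np.ndarray:
        n = np.asarray(self.normal, dtype=float)
        n = n / np.linalg.norm(n)
        d = (p - np.asarray(self.point, dtype=float)) @ n
        return np.abs(d)


@dataclass
class Arena:
    """Arena geometry: planes (walls/floor) and optional 2-D polylines."""

    planes: list[Plane] = field(default_factory=list)
    polylines: list[np.ndarray] = field(default_factory=list)

    def distance(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        if p.shape[1] == 2:
            p3 = np.concatenate([p, np.zeros((p.shape[0], 1))], axis=1)
        else:
            p3 = p
        dists = [pl.distance(p3) for pl in self.planes]
        if self.polylines:
            from shapely.geometry import LineString, Point

            for line in self.polylines:
                ls = LineString(np.asarray(line, dtype=float))
                dists.append(
                    np.array([ls.distance(Point(xy)) for xy in p[:, :2]])
                )
        if not dists:
            raise ValueError("arena has no surfaces")
        return np.min(np.stack(dists, axis=0), axis=0)


def detect_snout_contact(
    kps: KeypointSeries,
    arena: Arena,
    threshold: float,
    min_dwell_s: float = 0.0,
    snout_keypoint: str = "snout",
) -> np.ndarray | None:
    """Per-frame contact booleans: snout within ``threshold`` of a surface.

    Contact runs shorter than ``min_dwell_s`` are debounced away.  Returns
    ``None`` (contact unknown) when the snout keypoint is absent.
    """
    if snout_keypoint not in kps.keypoint_names:
        import warnings

        warnings.warn(
            f"no {snout_keypoint!r} keypoint: snout contact unknown; "
            "vertical modules with/without contact cannot be split",
            stacklevel=2,
        )
        return None
    d = arena.distance(kps.get(snout_keypoint))
    contact = d <= threshold
    contact &= kps.valid_mask[:, kps.index(snout_keypoint)]
    min_frames = int(round(min_dwell_s * kps.frame_rate))
    if min_frames > 1:
        for s, e in _runs(contact):
            if e - s < min_frames:
                contact[s:e] = False
    return contact
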