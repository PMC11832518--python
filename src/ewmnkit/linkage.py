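"""Kinematic linkage in absolute and carried-along spherical frames.

The trunk is modelled as a chain of rigid segments ordered along the
antero-posterior (AP) axis.  Every segment carries an individual spherical
system of reference that stays axis-parallel to the *general* system of
reference at all times: the vertical axis is set by gravity and the
horizontal reference direction is fixed in the environment.  A segment's
orientation is therefore a pair of spherical angles

* ``theta`` — horizontal angle, degrees in ``[0, 360)``, measured
  counter-clockwise (viewed from above) from the configured reference
  direction;
* ``phi`` — vertical angle, degrees in ``[-90, +90]``, positive upward.

The mechanical hierarchy between segments (the law of heavy and light
limbs) is induced by the base of support: the closer a segment is to the
supporting girdle the "heavier" it is, and moving a heavy segment carries
along all lighter segments.  The motion of a light segment is described in
the frame carried along on its heavy neighbour, as if the heavy neighbour
had not moved — this module converts between the absolute and the
carried-along (body-relative) description, and renders body-relative
angles back to joint coordinates (forward kinematics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "KeypointSeries",
    "SegmentDef",
    "LinkageSpec",
    "SupportState",
    "HeavyLightOrder",
    "SegmentPose",
    "BodyRelativeAngles",
    "compute_segment_directions",
    "derive_heavy_light_order",
    "to_body_relative",
    "forward_kinematics",
    "quantize_direction",
    "dequantize_direction",
    "direction_from_angles",
    "angles_from_direction",
]

_EPS = 1e-12

BASE_LABELS = ("hindquarters", "forequarters", "both", "none")


class ConfigurationError(ValueError):
    """Raised when a linkage/support configuration is inconsistent."""


# ---------------------------------------------------------------------------
# carriers
# ---------------------------------------------------------------------------


@dataclass
class KeypointSeries:
    """Tracked keypoint coordinates over time.

    Parameters
    ----------
    times
        Strictly increasing sample times in seconds, shape ``(T,)``.
    positions
        Coordinates, shape ``(T, K, D)`` with ``D`` 2 or 3, in length units.
    keypoint_names
        ``K`` identifiers.
    valid_mask
        Boolean ``(T, K)``; ``False`` marks missing/unreliable samples.
    frame_rate
        Nominal sampling rate in Hz.
    """

    times: np.ndarray
    positions: np.ndarray
    keypoint_names: list[str]
    valid_mask: np.ndarray | None = None
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.keypoint_names = list(self.keypoint_names)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("KeypointSeries needs at least 2 frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.positions.ndim != 3:
            raise ValueError("positions must have shape (T, K, D)")
        T, K, D = self.positions.shape
        if T != self.times.size:
            raise ValueError("positions and times disagree on frame count")
        if K != len(self.keypoint_names):
            raise ValueError("positions and keypoint_names disagree on K")
        if D not in (2, 3):
            raise ValueError("coordinates must be 2-D or 3-D")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.positions).all(axis=2)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != (T, K):
                raise ValueError("valid_mask must have shape (T, K)")
        if self.frame_rate is None:
            self.frame_rate = float(1.0 / np.median(np.diff(self.times)))
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        bad = ~np.isfinite(self.positions).all(axis=2) & self.valid_mask
        if np.any(bad):
            raise ValueError("positions must be finite wherever valid_mask is set")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def ndim(self) -> int:
        return self.positions.shape[2]

    def index(self, name: str) -> int:
        try:
            return self.keypoint_names.index(name)
        except ValueError:
            raise KeyError(f"keypoint {name!r} not present (have {self.keypoint_names})")

    def get(self, name: str) -> np.ndarray:
        return self.positions[:, self.index(name), :]


@dataclass(frozen=True)
class SegmentDef:
    """One rigid segment of the axial chain."""

    name: str
    proximal: str
    distal: str
    rest_length: float

    def __post_init__(self) -> None:
        if self.rest_length <= 0:
            raise ConfigurationError(f"segment {self.name!r}: rest_length must be > 0")


@dataclass(frozen=True)
class LinkageSpec:
    """The axial chain and its spatial conventions.

    ``segments`` are ordered from the posterior end (tail side) to the
    anterior end (head side); the distal keypoint of segment *k* is the
    proximal keypoint of segment *k + 1*.  ``zero_direction`` is the AP axis
    of the prone reference posture ("zero position"), perpendicular to the
    vertical ``up`` axis.
    """

    segments: tuple[SegmentDef, ...]
    appendage_sets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    appendage_order: tuple[str, ...] = ()  # posterior -> anterior
    zero_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    up: tuple[float, float, float] = (0.0, 0.0, 1.0)
    snout_keypoint: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ConfigurationError("linkage needs at least one segment")
        for a, b in zip(self.segments[:-1], self.segments[1:]):
            if a.distal != b.proximal:
                raise ConfigurationError(
                    f"chain broken between {a.name!r} and {b.name!r}: "
                    f"{a.distal!r} != {b.proximal!r}"
                )
        z = np.asarray(self.zero_direction, dtype=float)
        u = np.asarray(self.up, dtype=float)
        if abs(np.linalg.norm(z) - 1) > 1e-6 or abs(np.linalg.norm(u) - 1) > 1e-6:
            raise ConfigurationError("zero_direction and up must be unit vectors")
        if abs(float(z @ u)) > 1e-6:
            raise ConfigurationError("zero_direction must be perpendicular to up")
        for name in self.appendage_order:
            if name not in self.appendage_sets:
                raise ConfigurationError(f"appendage_order names unknown set {name!r}")

    @property
    def segment_names(self) -> list[str]:
        return [s.name for s in self.segments]

    @property
    def joint_names(self) -> list[str]:
        return [self.segments[0].proximal] + [s.distal for s in self.segments]

    @property
    def rest_lengths(self) -> np.ndarray:
        return np.array([s.rest_length for s in self.segments])

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def zero(self) -> np.ndarray:
        return np.asarray(self.zero_direction, dtype=float)

    def up_axis(self) -> np.ndarray:
        return np.asarray(self.up, dtype=float)

    def segment_index(self, name: str) -> int:
        try:
            return self.segment_names.index(name)
        except ValueError:
            raise KeyError(f"unknown segment {name!r}")

    def anterior_rank(self, name: str) -> int:
        """0 for the most anterior (head-end) segment, increasing caudally."""
        return self.n_segments - 1 - self.segment_index(name)

    def caudal_rank(self, name: str) -> int:
        """0 for the most anterior segment; alias kept for clarity at call sites."""
        return self.segment_index(name)


@dataclass
class SupportState:
    """Per-frame support flags and the derived base-of-support label."""

    hind: np.ndarray
    fore: np.ndarray
    ventral: np.ndarray | None = None
    base: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hind = np.asarray(self.hind, dtype=bool)
        self.fore = np.asarray(self.fore, dtype=bool)
        if self.ventral is None:
            self.ventral = np.zeros_like(self.hind)
        else:
            self.ventral = np.asarray(self.ventral, dtype=bool)
        if self.base is None:
            self.base = self.derive_base(self.hind, self.fore, self.ventral)
        else:
            self.base = np.asarray(self.base, dtype=object)

    @staticmethod
    def derive_base(hind: np.ndarray, fore: np.ndarray, ventral: np.ndarray) -> np.ndarray:
        base = np.empty(hind.shape, dtype=object)
        base[:] = "none"
        base[ventral] = "both"
        base[fore & ~hind] = "forequarters"
        base[hind & ~fore] = "hindquarters"
        base[hind & fore] = "both"
        return base

    @classmethod
    def constant(cls, n_frames: int, label: str = "hindquarters") -> "SupportState":
        if label not in BASE_LABELS:
            raise ValueError(f"unknown base label {label!r}")
        hind = np.full(n_frames, label in ("hindquarters", "both"))
        fore = np.full(n_frames, label in ("forequarters", "both"))
        return cls(hind=hind, fore=fore)

    @property
    def n_frames(self) -> int:
        return self.hind.size


@dataclass
class HeavyLightOrder:
    """Per-frame heavy-to-light permutation of segments and root joint."""

    order: np.ndarray  # (T, S) segment indices, heaviest first
    base: np.ndarray  # (T,) effective base labels after 'both'/'none' resolution
    root_joint: np.ndarray  # (T,) joint names
    airborne: np.ndarray  # (T,) bool

    @property
    def n_frames(self) -> int:
        return self.order.shape[0]

    def hind_rooted(self) -> np.ndarray:
        return self.base == "hindquarters"


@dataclass
class SegmentPose:
    """Per-frame per-segment directions in the general frame of reference."""

    directions: np.ndarray  # (T, S, 3) unit vectors
    theta: np.ndarray  # (T, S) deg in [0, 360)
    phi: np.ndarray  # (T, S) deg in [-90, 90]
    valid: np.ndarray  # (T, S) bool
    times: np.ndarray
    frame_rate: float
    segment_names: list[str]
    quantum: float
    theta_sectors: np.ndarray
    phi_sectors: np.ndarray
    is_2d: bool = False

    @property
    def n_frames(self) -> int:
        return self.theta.shape[0]


@dataclass
class BodyRelativeAngles:
    """Segment angles read in the carried-along frame of the heavy neighbour.

    In zero position body-relative equals absolute; a light segment rigidly
    carried along by its heavy neighbour keeps constant body-relative
    coordinates, so genuine single movements show up as body-relative
    angular change of exactly one segment.
    """

    theta_rel: np.ndarray  # (T, S) deg, [0, 360)
    phi_rel: np.ndarray  # (T, S) deg
    directions_rel: np.ndarray  # (T, S, 3)
    valid: np.ndarray  # (T, S)
    antiparallel: np.ndarray  # (T, S) tie-break applied for this segment's heavy neighbour
    times: np.ndarray
    frame_rate: float
    segment_names: list[str]
    quantum: float

    @property
    def n_frames(self) -> int:
        return self.theta_rel.shape[0]


# ---------------------------------------------------------------------------
# angle helpers
# ---------------------------------------------------------------------------


def direction_from_angles(theta_deg, phi_deg) -> np.ndarray:
    """Unit vector for spherical angles (theta CCW from +x, phi up)."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    ph = np.deg2rad(np.asarray(phi_deg, dtype=float))
    return np.stack(
        [np.cos(ph) * np.cos(th), np.cos(ph) * np.sin(th), np.sin(ph)], axis=-1
    )


def angles_from_direction(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spherical angles in degrees for unit vectors ``(..., 3)``."""
    u = np.asarray(u, dtype=float)
    theta = np.degrees(np.arctan2(u[..., 1], u[..., 0])) % 360.0
    phi = np.degrees(np.arcsin(np.clip(u[..., 2], -1.0, 1.0)))
    return theta, phi


def _round_half_toward_zero(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.ceil(np.abs(x) - 0.5)


def quantize_direction(theta_deg, phi_deg, quantum: float = 45.0):
    """Quantize an angle pair to sector indices in units of ``quantum``.

    Nearest-multiple rounding with ties toward zero; theta sectors wrap
    modulo ``360 / quantum``, phi sectors do not wrap.
    """
    if quantum <= 0:
        raise ValueError("quantum must be positive")
    n = 360.0 / quantum
    if abs(n - round(n)) > 1e-9:
        raise ValueError("quantum must divide 360 evenly")
    n = int(round(n))
    t = _round_half_toward_zero(np.asarray(theta_deg, dtype=float) / quantum)
    p = _round_half_toward_zero(np.asarray(phi_deg, dtype=float) / quantum)
    t = np.mod(t, n)
    return t.astype(int), p.astype(int)


def dequantize_direction(theta_sectors, phi_sectors, quantum: float = 45.0):
    """Sector-centre angles for sector indices (inverse of quantization)."""
    if quantum <= 0:
        raise ValueError("quantum must be positive")
    t = (np.asarray(theta_sectors, dtype=float) * quantum) % 360.0
    p = np.asarray(phi_sectors, dtype=float) * quantum
    return t, p


# ---------------------------------------------------------------------------
# rotations
# ---------------------------------------------------------------------------


def _minimal_rotation(a: np.ndarray, b: np.ndarray, up: np.ndarray):
    """Rotation matrices taking unit vector(s) ``a`` onto ``b`` by the
    smallest angle.

    When ``a`` and ``b`` are antiparallel the minimal rotation is
    ill-defined; the tie-break is a half-turn about the vertical axis
    (preserving horizontal-plane semantics), and those frames are flagged.

    Parameters are broadcast to ``(T, 3)``; returns ``(R, flagged)`` with
    ``R`` of shape ``(T, 3, 3)``.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    a, b = np.broadcast_arrays(a, b)
    T = a.shape[0]
    v = np.cross(a, b)
    c = np.einsum("ti,ti->t", a, b)
    s = np.linalg.norm(v, axis=1)

    R = np.tile(np.eye(3), (T, 1, 1))
    flagged = np.zeros(T, dtype=bool)

    ok = s > 1e-12
    if np.any(ok):
        k = v[ok] / s[ok, None]
        K = np.zeros((k.shape[0], 3, 3))
        K[:, 0, 1] = -k[:, 2]
        K[:, 0, 2] = k[:, 1]
        K[:, 1, 0] = k[:, 2]
        K[:, 1, 2] = -k[:, 0]
        K[:, 2, 0] = -k[:, 1]
        K[:, 2, 1] = k[:, 0]
        sin_t = s[ok]
        cos_t = c[ok]
        KK = np.einsum("tij,tjk->tik", K, K)
        R[ok] = np.eye(3) + sin_t[:, None, None] * K + (1 - cos_t)[:, None, None] * KK

    anti = (~ok) & (c < 0)
    if np.any(anti):
        u = np.asarray(up, dtype=float)
        K = np.array(
            [[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]], dtype=float
        )
        R_pi = np.eye(3) + 2.0 * (K @ K)  # Rodrigues with angle pi
        R[anti] = R_pi
        flagged[anti] = True
    return R, flagged


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _interpolate_gaps(pos: np.ndarray, valid: np.ndarray, max_gap: int):
    """Linearly fill invalid runs of length <= max_gap (per keypoint).

    Longer gaps stay invalid so downstream segmentation treats them as
    record boundaries rather than inventing motion across them.
    """
    pos = pos.copy()
    valid = valid.copy()
    T = pos.shape[0]
    for k in range(pos.shape[1]):
        v = valid[:, k]
        if v.all() or not v.any():
            continue
        idx = np.flatnonzero(~v)
        # group consecutive invalid indices
        splits = np.flatnonzero(np.diff(idx) > 1)
        runs = np.split(idx, splits + 1)
        t_all = np.arange(T)
        good = np.flatnonzero(v)
        for run in runs:
            interior = run[0] > 0 and run[-1] < T - 1
            if len(run) <= max_gap and interior:
                for d in range(pos.shape[2]):
                    pos[run, k, d] = np.interp(t_all[run], good, pos[good, k, d])
                valid[run, k] = True
    return pos, valid


def compute_segment_directions(
    kps: KeypointSeries,
    spec: LinkageSpec,
    quantum: float = 45.0,
    max_gap_frames: int = 5,
) -> SegmentPose:
    """Per-frame unit direction and spherical angles for every segment.

    2-D input is treated as the horizontal plane (phi identically zero).
    Zero-length segments flag the frame invalid rather than dropping it.
    """
    missing = [
        name
        for name in spec.joint_names
        if name not in kps.keypoint_names
    ]
    if missing:
        raise ConfigurationError(
            f"chain keypoints missing from series: {missing} "
            f"(series has {kps.keypoint_names})"
        )
    joint_idx = [kps.index(n) for n in spec.joint_names]
    pos = kps.positions[:, joint_idx, :]
    val = kps.valid_mask[:, joint_idx]
    is_2d = kps.ndim == 2
    if is_2d:
        pos = np.concatenate([pos, np.zeros(pos.shape[:2] + (1,))], axis=2)
    pos, val = _interpolate_gaps(pos, val, max_gap_frames)

    T, S = kps.n_frames, spec.n_segments
    d = pos[:, 1:, :] - pos[:, :-1, :]
    norms = np.linalg.norm(d, axis=2)
    valid = val[:, 1:] & val[:, :-1] & (norms > _EPS)
    u = np.zeros((T, S, 3))
    np.divide(d, np.where(norms[..., None] > _EPS, norms[..., None], 1.0), out=u)
    # park invalid frames at zero direction so downstream math stays finite
    u[~valid] = spec.zero()
    theta, phi = angles_from_direction(u)
    if is_2d:
        phi = np.zeros_like(phi)
    ts, ps = quantize_direction(theta, phi, quantum)
    return SegmentPose(
        directions=u,
        theta=theta,
        phi=phi,
        valid=valid,
        times=kps.times,
        frame_rate=float(kps.frame_rate),
        segment_names=spec.segment_names,
        quantum=quantum,
        theta_sectors=ts,
        phi_sectors=ps,
        is_2d=is_2d,
    )


def derive_heavy_light_order(
    support: SupportState,
    spec: LinkageSpec,
    both_policy: str = "hindquarters",
    initial_base: str | None = None,
) -> HeavyLightOrder:
    """Per-frame heavy-to-light segment permutation from the base of support.

    ``both`` resolves to ``both_policy`` (hindquarters by default — the
    early-emerging modules pivot on the hind legs).  ``none`` (airborne)
    retains the last grounded base and flags the frame; on the first frame
    it requires an explicit ``initial_base``.
    """
    if both_policy not in ("hindquarters", "forequarters"):
        raise ValueError("both_policy must be 'hindquarters' or 'forequarters'")
    T, S = support.n_frames, spec.n_segments
    hind_perm = np.arange(S)
    fore_perm = hind_perm[::-1]
    order = np.zeros((T, S), dtype=int)
    base = np.empty(T, dtype=object)
    root = np.empty(T, dtype=object)
    airborne = np.zeros(T, dtype=bool)
    joints = spec.joint_names
    last = initial_base
    for t in range(T):
        lab = support.base[t]
        if lab == "both":
            eff = both_policy
        elif lab == "none":
            if last is None:
                raise ConfigurationError(
                    "support is 'none' on the first frame; pass initial_base "
                    "to state which girdle the hierarchy is rooted on"
                )
            eff = last
            airborne[t] = True
        else:
            eff = lab
        last = eff
        base[t] = eff
        if eff == "hindquarters":
            order[t] = hind_perm
            root[t] = joints[0]
        else:
            order[t] = fore_perm
            root[t] = joints[-1]
    return HeavyLightOrder(order=order, base=base, root_joint=root, airborne=airborne)


def _heavy_neighbor_index(i: int, S: int, hind: bool) -> int | None:
    if hind:
        return i - 1 if i > 0 else None
    return i + 1 if i < S - 1 else None


def to_body_relative(
    pose: SegmentPose, order: HeavyLightOrder, spec: LinkageSpec
) -> BodyRelativeAngles:
    """Undo the heavy neighbour's rotation from zero position.

    For each segment the minimal rotation taking the zero direction onto
    the heavy neighbour's current direction is inverted before reading the
    spherical coordinates.  The heaviest segment's body-relative
    coordinates equal its absolute coordinates.
    """
    if pose.n_frames != order.n_frames:
        raise ValueError("pose and order must share frames")
    T, S = pose.theta.shape
    z0 = spec.zero()
    up = spec.up_axis()
    u_abs = pose.directions
    u_rel = u_abs.copy()
    anti = np.zeros((T, S), dtype=bool)
    hind = order.hind_rooted()
    for group, mask in (("hind", hind), ("fore", ~hind)):
        if not np.any(mask):
            continue
        idx = np.flatnonzero(mask)
        for i in range(S):
            j = _heavy_neighbor_index(i, S, group == "hind")
            if j is None:
                continue  # heaviest: relative == absolute
            R, flg = _minimal_rotation(z0[None, :], u_abs[idx, j], up)
            u_rel[idx, i] = np.einsum("tji,tj->ti", R, u_abs[idx, i])
            anti[idx, i] = flg
    theta_rel, phi_rel = angles_from_direction(u_rel)
    valid = pose.valid.copy()
    return BodyRelativeAngles(
        theta_rel=theta_rel,
        phi_rel=phi_rel,
        directions_rel=u_rel,
        valid=valid,
        antiparallel=anti,
        times=pose.times,
        frame_rate=pose.frame_rate,
        segment_names=pose.segment_names,
        quantum=pose.quantum,
    )


def forward_kinematics(
    base_point: np.ndarray,
    angles: BodyRelativeAngles,
    order: HeavyLightOrder,
    spec: LinkageSpec,
    extensions: np.ndarray | None = None,
) -> KeypointSeries:
    """Place chain joints from body-relative angles (renderer / oracle).

    Joints are chained from the root joint outward toward the light end:
    ``p_next = p + (L + ext) * u``.  ``extensions`` (``(T, S)``, length
    units, default zero) lengthen individual segments and model forward
    transport of a sub-chain (soft-tissue extension between metameres).
    """
    T, S = angles.theta_rel.shape
    if order.n_frames != T:
        raise ValueError("angles and order must share frames")
    base_point = np.asarray(base_point, dtype=float)
    if base_point.ndim == 1:
        base_point = np.broadcast_to(base_point, (T, base_point.size)).copy()
    if base_point.shape != (T, 3):
        raise ValueError("base_point must be (3,) or (T, 3)")
    if extensions is None:
        extensions = np.zeros((T, S))
    else:
        extensions = np.asarray(extensions, dtype=float)
        if extensions.shape != (T, S):
            raise ValueError("extensions must have shape (T, S)")
    z0 = spec.zero()
    up = spec.up_axis()
    L = spec.rest_lengths
    u_rel = direction_from_angles(angles.theta_rel, angles.phi_rel)
    u_abs = np.zeros_like(u_rel)
    hind = order.hind_rooted()
    roots = set(np.unique(order.root_joint))
    if not roots <= set(spec.joint_names):
        raise ConfigurationError(f"unknown root joint(s) {roots - set(spec.joint_names)}")
    for group, mask in (("hind", hind), ("fore", ~hind)):
        if not np.any(mask):
            continue
        idx = np.flatnonzero(mask)
        seq = range(S) if group == "hind" else range(S - 1, -1, -1)
        for i in seq:
            j = _heavy_neighbor_index(i, S, group == "hind")
            if j is None:
                u_abs[idx, i] = u_rel[idx, i]
            else:
                R, _ = _minimal_rotation(z0[None, :], u_abs[idx, j], up)
                u_abs[idx, i] = np.einsum("tij,tj->ti", R, u_rel[idx, i])
    joints = np.zeros((T, S + 1, 3))
    if np.any(hind):
        idx = np.flatnonzero(hind)
        joints[idx, 0] = base_point[idx]
        for i in range(S):
            step = (L[i] + extensions[idx, i])[:, None] * u_abs[idx, i]
            joints[idx, i + 1] = joints[idx, i] + step
    if np.any(~hind):
        idx = np.flatnonzero(~hind)
        joints[idx, S] = base_point[idx]
        for i in range(S - 1, -1, -1):
            step = (L[i] + extensions[idx, i])[:, None] * u_abs[idx, i]
            joints[idx, i] = joints[idx, i + 1] - step
    return KeypointSeries(
        times=angles.times,
        positions=joints,
        keypoint_names=spec.joint_names,
        valid_mask=np.ones((T, S + 1), dtype=bool),
        frame_rate=angles.frame_rate,
    )


def make_body_relative(
    theta_rel: np.ndarray,
    phi_rel: np.ndarray,
    times: np.ndarray,
    frame_rate: float,
    spec: LinkageSpec,
    quantum: float = 45.0,
) -> BodyRelativeAngles:
    """Convenience constructor from raw angle arrays (used by simulators)."""
    theta_rel = np.asarray(theta_rel, dtype=float) % 360.0
    phi_rel = np.asarray(phi_rel, dtype=float)
    T, S = theta_rel.shape
    return BodyRelativeAngles(
        theta_rel=theta_rel,
        phi_rel=phi_rel,
        directions_rel=direction_from_angles(theta_rel, phi_rel),
        valid=np.ones((T, S), dtype=bool),
        antiparallel=np.zeros((T, S), dtype=bool),
        times=np.asarray(times, dtype=float),
        frame_rate=float(frame_rate),
        segment_names=spec.segment_names,
        quantum=quantum,
    )
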