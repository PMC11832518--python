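"""Synthetic ground-truth generators for every pipeline stage.

Three simulators emulate the study conditions the toolkit targets:

* ``simulate_warmup`` — grammar-compliant warm-up sequences (immobility,
  then side-to-side horizontal head movements budding into full AP
  recruitment along the first four spatial modules), rendered to noisy
  keypoints through the forward-kinematics engine with minimum-jerk
  profiles between quantized targets;
* ``simulate_fly_session`` — a rigid-trunk (fly-like) centroid + heading
  session with the narrowing → complete immobility → build-up structure
  (fast straight runs, increasingly curved paths spiralling onto the
  immobility spot, pivoting in place, a long complete-immobility bout,
  then the mirror-image build-up);
* ``simulate_traveling_wave`` — antero-posterior traveling waves of
  lateral bending with scripted wavelength.

``inject_violations`` mutates a compliant sequence with minimal edits,
each creating exactly one violation of a chosen rule, for closed-loop
benchmarking of the grammar checkers.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .grammar import (
    DEFAULT_TAXONOMY,
    M1,
    M2,
    M3,
    M4,
    ModuleTaxonomy,
    _recruitment_order,
)
from .linkage import (
    KeypointSeries,
    LinkageSpec,
    SupportState,
    derive_heavy_light_order,
    forward_kinematics,
    make_body_relative,
)
from .segmentation import Arena, ImmobilityBout, Plane, Primitive

__all__ = [
    "GrammarSimConfig",
    "FlySimConfig",
    "WarmupSimResult",
    "FlySimResult",
    "simulate_warmup",
    "simulate_fly_session",
    "simulate_traveling_wave",
    "inject_violations",
]


def _minjerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1]."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


# ---------------------------------------------------------------------------
# warm-up grammar simulator
# ---------------------------------------------------------------------------


@dataclass
class GrammarSimConfig:
    """Conditions for the warm-up generator.

    ``stage`` is the fraction of the bauplan unlocked: it maps monotonically
    to the highest module reached (one module per quarter stage, capped at
    the fourth) and, within each module, to how many trunk segments are
    recruited and how large the amplitudes grow (linearly from one quantum
    toward the module maximum).
    """

    stage: float = 1.0
    reps: int = 2  # repetitions per (segment, module) recruitment step
    quantum: float = 45.0
    max_quanta: dict = field(
        default_factory=lambda: {M1: 2, M3: 1, M4: 2}
    )
    transport_distance: float = 0.02  # base forward-step length (length units)
    transport_growth: float = 0.04
    move_duration_s: float = 0.5
    transport_duration_s: float = 0.6
    pause_mean_s: float = 0.7
    pause_sigma: float = 0.3
    pause_min_s: float = 0.45
    immobility_s: float = 10.0
    frame_rate: float = 50.0
    noise_sigma: float = 0.0  # keypoint noise, length units
    violation_rate: float = 0.0  # violations are injected downstream, not here
    contact_threshold: float = 0.02
    trunk_height: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.stage <= 1.0:
            raise ValueError("stage must lie in [0, 1]")
        if self.noise_sigma < 0 or self.violation_rate < 0:
            raise ValueError("rates and noise must be non-negative")
        if self.reps < 1 or self.frame_rate <= 0:
            raise ValueError("reps and frame_rate must be positive")


@dataclass
class WarmupSimResult:
    primitives: list[Primitive]  # ground truth, module-labeled, frames filled
    keypoints: KeypointSeries
    support: SupportState
    arena: Arena
    contact: np.ndarray  # ground-truth per-frame snout contact
    immobility: ImmobilityBout
    config: GrammarSimConfig


def _stage_plan(cfg: GrammarSimConfig, spec: LinkageSpec):
    """Symbol plan: ordered (segment, module, kind, amplitude/distance)."""
    S = spec.n_segments
    n_modules = min(4, 1 + int(math.floor(cfg.stage * 4)))
    modules = (M1, M2, M3, M4)[:n_modules]
    plan = []
    progresses = {}
    for j, m in enumerate(modules):
        progress = float(np.clip(cfg.stage * 4 - j, 0.0, 1.0))
        progresses[m] = progress
        n_seg = max(1, int(math.ceil(progress * S)))
        rec = _recruitment_order(spec, m)[:n_seg]
        if m == M2:
            dist = cfg.transport_distance + cfg.transport_growth * progress
            for seg in rec:
                for _ in range(cfg.reps):
                    plan.append(("transport", seg, m, dist, "forward"))
        else:
            maxq = cfg.max_quanta.get(m, 2)
            quanta = 1 + int(round(progress * (maxq - 1)))
            amp = cfg.quantum * quanta
            for seg in rec:
                for r in range(cfg.reps):
                    if m == M1:
                        out = "left" if r % 2 == 0 else "right"
                        back = "right" if r % 2 == 0 else "left"
                        plan.append(("angular", seg, m, amp, out))
                        plan.append(("angular", seg, m, amp, back))
                    else:
                        plan.append(("angular", seg, m, amp, "up"))
                        plan.append(("angular", seg, m, amp, "down"))
        if m == M3 and M4 in modules:
            # approach before contact work happened implicitly; retreat from
            # the wall before free-vertical work (a legal forward-module event)
            plan.append(("transport", _recruitment_order(spec, M2)[0], M2, 0.08, "backward"))
        if m == M2 and M3 in modules:
            plan.append(("transport", _recruitment_order(spec, M2)[0], M2, 0.08, "forward"))
    return plan


def simulate_warmup(
    cfg: GrammarSimConfig, spec: LinkageSpec | None = None
) -> WarmupSimResult:
    """Generate a warm-up sequence and render it to keypoints.

    The grammar automaton honours AP-within-module recruitment and the
    fixed module order up to ``cfg.stage``.  Rendering starts from the
    prone zero position after an immobility prelude, interpolates each
    single movement with a minimum-jerk profile between quantized targets,
    models forward transport of a sub-chain as axial extension at its
    heavy joint, and adds Gaussian keypoint noise.  A wall plane is placed
    where the snout sits at the onset of contact-vertical work, so the
    rendered session reproduces the contact/no-contact split of the two
    vertical modules.
    """
    spec = spec or _default_spec()
    rng = np.random.default_rng(cfg.seed)
    fps = cfg.frame_rate
    plan = _stage_plan(cfg, spec)

    # schedule: (event, start_s, end_s)
    t = cfg.immobility_s
    schedule = []
    for ev in plan:
        pause = float(
            np.clip(
                rng.lognormal(np.log(cfg.pause_mean_s), cfg.pause_sigma),
                cfg.pause_min_s,
                3.0,
            )
        )
        t += pause
        dur = cfg.transport_duration_s if ev[0] == "transport" else cfg.move_duration_s
        schedule.append((ev, t, t + dur))
        t += dur
    t += cfg.pause_min_s
    T = int(round(t * fps)) + 1
    times = np.arange(T) / fps

    S = spec.n_segments
    theta = np.zeros((T, S))
    phi = np.zeros((T, S))
    ext = np.zeros((T, S))
    base = np.zeros((T, 3))
    base[:, 2] = cfg.trunk_height

    primitives: list[Primitive] = []
    seg_idx = {n: i for i, n in enumerate(spec.segment_names)}
    for ev, t0, t1 in schedule:
        kind, seg, module, size, sign = ev
        f0, f1 = int(round(t0 * fps)), int(round(t1 * fps))
        f1 = min(max(f1, f0 + 2), T)
        tau = np.linspace(0.0, 1.0, f1 - f0)
        prof = _minjerk(tau)
        si = seg_idx[seg]
        if kind == "angular":
            if module == M1:
                cur = theta[f0, si]
                target = cur + size if sign == "left" else cur - size
                theta[f0:f1, si] = cur + (target - cur) * prof
                theta[f1:, si] = target
            else:
                cur = phi[f0, si]
                target = cur + size if sign == "up" else cur - size
                phi[f0:f1, si] = cur + (target - cur) * prof
                phi[f1:, si] = target
            primitives.append(
                Primitive(
                    segment=seg,
                    movement_type="plane_horizontal" if module == M1 else "plane_vertical",
                    sign=sign,
                    start=f0,
                    end=f1,
                    amplitude_deg=float(size),
                    amplitude_units=int(round(size / cfg.quantum)),
                    support_base="hindquarters",
                    module=module,
                )
            )
        else:  # transport
            delta = size if sign == "forward" else -size
            if si == 0:
                cur = base[f0, 0]
                base[f0:f1, 0] = cur + delta * prof
                base[f1:, 0] = cur + delta
            else:
                j = si - 1  # extend the heavy neighbour's axial length
                cur = ext[f0, j]
                ext[f0:f1, j] = cur + delta * prof
                ext[f1:, j] = cur + delta
            primitives.append(
                Primitive(
                    segment=seg,
                    movement_type="forward_transport",
                    sign=sign,
                    start=f0,
                    end=f1,
                    distance=float(size),
                    support_base="hindquarters",
                    module=M2,
                )
            )

    support = SupportState.constant(T, "hindquarters")
    order = derive_heavy_light_order(support, spec)
    angles = make_body_relative(theta, phi, times, fps, spec, cfg.quantum)
    kps = forward_kinematics(base, angles, order, spec, extensions=ext)
    if cfg.noise_sigma > 0:
        kps.positions = kps.positions + rng.normal(
            0.0, cfg.noise_sigma, size=kps.positions.shape
        )

    # arena: floor plus (when contact work exists) a wall at the snout's
    # position at the onset of the first contact-vertical movement
    planes = [Plane(point=(0.0, 0.0, 0.0), normal=(0.0, 0.0, 1.0))]
    first_m3 = next((p for p in primitives if p.module == M3), None)
    snout = kps.get(spec.joint_names[-1])
    if first_m3 is not None:
        wall_x = float(snout[first_m3.start, 0]) + 0.004
        planes.append(Plane(point=(wall_x, 0.0, 0.0), normal=(1.0, 0.0, 0.0)))
    arena = Arena(planes=planes)
    contact = arena.distance(snout) <= cfg.contact_threshold
    for p in primitives:
        frac = float(np.mean(contact[p.start : p.end]))
        p.snout_contact = frac >= 0.5
    imm = ImmobilityBout(
        start=0,
        end=int(round(cfg.immobility_s * fps)),
        duration_s=cfg.immobility_s,
        mean_position=snout[0].copy(),
    )
    return WarmupSimResult(
        primitives=primitives,
        keypoints=kps,
        support=support,
        arena=arena,
        contact=contact,
        immobility=imm,
        config=cfg,
    )


def _default_spec() -> LinkageSpec:
    from .config import default_rat_linkage

    return default_rat_linkage()


# ---------------------------------------------------------------------------
# fly session simulator
# ---------------------------------------------------------------------------


@dataclass
class FlySimConfig:
    """Phase schedule of a narrowing -> immobility -> build-up session.

    Defaults reproduce the canonical cocaine-fly scenario: fast straight
    runs, increasingly curved paths spiralling onto the immobility spot,
    pivoting in place, a ten-minute bout of complete immobility, then the
    mirror-image build-up.  Lengths in mm, rates in Hz / deg/s.
    """

    straight_s: float = 300.0
    narrowing_s: float = 240.0
    pivot_s: float = 60.0
    immobility_s: float = 600.0
    buildup_s: float = 240.0
    straight_out_s: float = 300.0
    speed_straight: float = 20.0  # mm/s
    pivot_rate_deg_s: float = 90.0
    wind_rate_start: float = 0.3  # rad/s at the spiral's outer end
    wind_rate_end: float = 1.8  # rad/s near the immobility spot
    hp_offset_deg: float = 35.0  # heading-progression inflation in spirals
    arena_radius: float = 30.0  # mm
    body_length: float = 3.0  # mm
    frame_rate: float = 30.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "straight_s",
            "narrowing_s",
            "pivot_s",
            "immobility_s",
            "buildup_s",
            "straight_out_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.speed_straight / self.frame_rate > self.arena_radius / 4:
            raise ValueError("arena too small for this speed and frame rate")


@dataclass
class FlySimResult:
    keypoints: KeypointSeries  # head/tail keypoint pair
    times: np.ndarray
    centroid: np.ndarray
    heading_deg: np.ndarray
    phase: np.ndarray  # per-frame phase labels
    spot: np.ndarray  # scripted immobility spot
    config: FlySimConfig


def _straight_bounce(rng, p0, h0, n, dt, v, R):
    pos = np.zeros((n, 2))
    ang = np.zeros(n)
    p = np.array(p0, dtype=float)
    d = np.array([math.cos(h0), math.sin(h0)])
    for i in range(n):
        p = p + v * dt * d
        r = np.linalg.norm(p)
        if r > R:
            nrm = p / r
            d = d - 2 * (d @ nrm) * nrm
            p = nrm * R
        pos[i] = p
        ang[i] = math.atan2(d[1], d[0])
    return pos, ang


def simulate_fly_session(cfg: FlySimConfig) -> FlySimResult:
    """Centroid + heading series with the scripted phase structure.

    The transition into immobility is a spiral of shrinking radius (so the
    distance to the immobility spot decreases monotonically while path
    curvature grows), ending in pivoting in place; immobility is exactly
    the configured duration with all keypoints frozen; the build-up
    mirrors the narrowing.  The heading–progression interval is inflated
    during the spiral phases.
    """
    rng = np.random.default_rng(cfg.seed)
    fps = cfg.frame_rate
    dt = 1.0 / fps
    spot = np.zeros(2)

    segments: list[tuple[str, np.ndarray, np.ndarray]] = []  # (label, pos, heading_rad)

    # 1 baseline straight runs
    n1 = int(round(cfg.straight_s * fps))
    start = 0.6 * cfg.arena_radius * np.array(
        [math.cos(rng.uniform(0, 2 * math.pi)), math.sin(rng.uniform(0, 2 * math.pi))]
    )
    pos1, prog1 = _straight_bounce(
        rng, start, rng.uniform(0, 2 * math.pi), n1, dt, cfg.speed_straight, cfg.arena_radius
    )
    segments.append(("straight_in", pos1, prog1))

    # 2 narrowing spiral onto the spot
    n2 = int(round(cfg.narrowing_s * fps))
    p0 = pos1[-1]
    r0 = max(np.linalg.norm(p0), 1e-6)
    a0 = math.atan2(p0[1], p0[0])
    tau = np.linspace(0.0, 1.0, n2, endpoint=False) + 1.0 / n2
    r = r0 * (1 - tau) ** 2
    wind = cfg.wind_rate_start + (cfg.wind_rate_end - cfg.wind_rate_start) * tau
    alpha = a0 + np.cumsum(wind) * dt
    pos2 = np.stack([r * np.cos(alpha), r * np.sin(alpha)], axis=1)
    vel2 = np.gradient(pos2, dt, axis=0)
    prog2 = np.arctan2(vel2[:, 1], vel2[:, 0])
    off2 = np.radians(cfg.hp_offset_deg) * tau
    segments.append(("narrowing", pos2, prog2 + off2))

    # 3 pivot in place at the spot
    n3 = int(round(cfg.pivot_s * fps))
    h_start = segments[-1][2][-1]
    heading3 = h_start + np.radians(cfg.pivot_rate_deg_s) * dt * np.arange(1, n3 + 1)
    segments.append(("pivot_in", np.tile(spot, (n3, 1)), heading3))

    # 4 complete immobility
    n4 = int(round(cfg.immobility_s * fps))
    segments.append(("immobility", np.tile(spot, (n4, 1)), np.full(n4, heading3[-1])))

    # 5 pivot out
    n5 = int(round(cfg.pivot_s * fps))
    heading5 = heading3[-1] + np.radians(cfg.pivot_rate_deg_s) * dt * np.arange(1, n5 + 1)
    segments.append(("pivot_out", np.tile(spot, (n5, 1)), heading5))

    # 6 build-up spiral away from the spot
    n6 = int(round(cfg.buildup_s * fps))
    tau6 = np.linspace(0.0, 1.0, n6, endpoint=False) + 1.0 / n6
    r6 = 0.6 * cfg.arena_radius * tau6**2
    wind6 = cfg.wind_rate_end + (cfg.wind_rate_start - cfg.wind_rate_end) * tau6
    alpha6 = heading5[-1] + np.cumsum(wind6) * dt
    pos6 = np.stack([r6 * np.cos(alpha6), r6 * np.sin(alpha6)], axis=1)
    vel6 = np.gradient(pos6, dt, axis=0)
    prog6 = np.arctan2(vel6[:, 1], vel6[:, 0])
    off6 = np.radians(cfg.hp_offset_deg) * (1 - tau6)
    segments.append(("buildup", pos6, prog6 + off6))

    # 7 straight out
    n7 = int(round(cfg.straight_out_s * fps))
    pos7, prog7 = _straight_bounce(
        rng, pos6[-1], prog6[-1], n7, dt, cfg.speed_straight, cfg.arena_radius
    )
    segments.append(("straight_out", pos7, prog7))

    pos = np.concatenate([s[1] for s in segments], axis=0)
    heading = np.concatenate([s[2] for s in segments])
    phase = np.concatenate(
        [np.full(s[1].shape[0], s[0], dtype=object) for s in segments]
    )
    T = pos.shape[0]
    times = np.arange(T) * dt
    half = cfg.body_length / 2.0
    d = np.stack([np.cos(heading), np.sin(heading)], axis=1)
    head = pos + half * d
    tail = pos - half * d
    pts = np.stack([head, tail], axis=1)
    if cfg.noise_sigma > 0:
        pts = pts + rng.normal(0.0, cfg.noise_sigma, size=pts.shape)
    kps = KeypointSeries(
        times=times,
        positions=pts,
        keypoint_names=["head", "tail"],
        frame_rate=fps,
    )
    return FlySimResult(
        keypoints=kps,
        times=times,
        centroid=pos,
        heading_deg=np.degrees(heading),
        phase=phase,
        spot=spot,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# traveling wave simulator
# ---------------------------------------------------------------------------


def simulate_traveling_wave(
    n_segments: int,
    wavelength_bl: float,
    frequency_hz: float,
    duration_s: float,
    frame_rate: float,
    noise: float = 0.0,
    amplitude_deg: float = 20.0,
    seed: int = 0,
):
    """AP traveling wave of lateral bending.

    Segment ``k`` bends as ``A sin(2 pi f t - 2 pi k / (n * wavelength))``
    plus optional Gaussian noise (fraction of the amplitude).  Returns
    ``(times, bending, script)`` where ``script`` records the exact
    generating parameters (adjacent phase lag in degrees included).
    """
    if n_segments < 3:
        raise ValueError("need at least 3 segments")
    if wavelength_bl == 0:
        raise ValueError("wavelength must be non-zero")
    rng = np.random.default_rng(seed)
    T = int(round(duration_s * frame_rate))
    times = np.arange(T) / frame_rate
    k = np.arange(n_segments)
    phase_offsets = 2 * np.pi * k / (n_segments * wavelength_bl)
    bending = amplitude_deg * np.sin(
        2 * np.pi * frequency_hz * times[:, None] - phase_offsets[None, :]
    )
    if noise > 0:
        bending = bending + rng.normal(0.0, noise * amplitude_deg, size=bending.shape)
    script = {
        "n_segments": n_segments,
        "wavelength_bl": wavelength_bl,
        "frequency_hz": frequency_hz,
        "amplitude_deg": amplitude_deg,
        "adjacent_lag_deg": 360.0 / (n_segments * wavelength_bl),
    }
    return times, bending, script


# ---------------------------------------------------------------------------
# violation injection
# ---------------------------------------------------------------------------


def inject_violations(
    primitives: Sequence[Primitive],
    n: int,
    rule_id: str,
    seed: int = 0,
    spec: LinkageSpec | None = None,
    taxonomy: ModuleTaxonomy = DEFAULT_TAXONOMY,
):
    """Mutate a compliant sequence with ``n`` minimal rule-breaking edits.

    Each edit creates exactly one violation of ``rule_id``:

    * ``AP_within_module`` — a caudal segment's first movement in a module
      is moved ahead of its anterior neighbour's first movement there;
    * ``module_order`` — the most anterior segment's first movement in a
      module is moved ahead of its first movement in the previous module;
    * ``LIFO_narrowing`` — expects a narrowing (LIFO-compliant) sequence,
      e.g. a time-reversed build-up, and re-appends a copy of a
      higher-module primitive after the lower modules' last occurrences.

    Returns ``(mutated, truth)`` where ``truth`` is a list of
    ``(index, rule_id)`` pairs in the mutated sequence.
    """
    spec = spec or _default_spec()
    rng = np.random.default_rng(seed)
    seq = [replace(p) for p in primitives]
    if n == 0:
        return seq, []

    def first_index(seg, mod):
        return next(
            (i for i, p in enumerate(seq) if p.segment == seg and p.module == mod), None
        )

    marked: list[Primitive] = []

    if rule_id == "AP_within_module":
        candidates = []
        for m in {p.module for p in seq if taxonomy.is_spatial(p.module)}:
            order = _recruitment_order(spec, m)
            present = [s for s in order if first_index(s, m) is not None]
            for a, b in zip(order[:-1], order[1:]):
                if a in present and b in present:
                    candidates.append((m, a, b))
                    break  # at most one edit per module to keep edits independent
        if n > len(candidates):
            raise ValueError(
                f"at most {len(candidates)} AP_within_module edits are feasible here"
            )
        chosen = [candidates[i] for i in rng.choice(len(candidates), n, replace=False)]
        for m, a, b in chosen:
            i, j = first_index(a, m), first_index(b, m)
            moved = seq.pop(j)
            seq.insert(i, moved)
            marked.append(moved)
    elif rule_id == "module_order":
        head = _recruitment_order(spec, M1)[0]
        candidates = []
        for m in {p.module for p in seq if taxonomy.is_spatial(p.module)}:
            r = taxonomy.rank(m)
            if r <= 1:
                continue
            prev = [pm for pm in taxonomy.modules_of_rank(r - 1) if first_index(head, pm) is not None]
            if prev and first_index(head, m) is not None:
                candidates.append((m, prev[0]))
        if n > len(candidates):
            raise ValueError(
                f"at most {len(candidates)} module_order edits are feasible here"
            )
        chosen = [candidates[i] for i in rng.choice(len(candidates), n, replace=False)]
        # apply lowest-rank module first so earlier edits don't displace the
        # anchors of later ones
        for m, mprev in sorted(chosen, key=lambda c: taxonomy.rank(c[0])):
            j = first_index(head, m)
            i = first_index(head, mprev)
            moved = seq.pop(j)
            seq.insert(i, moved)
            marked.append(moved)
    elif rule_id == "LIFO_narrowing":
        present = sorted(
            {p.module for p in seq if taxonomy.is_spatial(p.module)},
            key=taxonomy.rank,
        )
        candidates = [m for m in present if taxonomy.rank(m) > taxonomy.rank(present[0])]
        if n > len(candidates):
            raise ValueError(
                f"at most {len(candidates)} LIFO_narrowing edits are feasible here"
            )
        chosen = [candidates[i] for i in rng.choice(len(candidates), n, replace=False)]
        for m in sorted(chosen, key=lambda mm: -taxonomy.rank(mm)):
            src = next(p for p in seq if p.module == m)
            dup = replace(src)
            seq.append(dup)
            marked.append(dup)
    else:
        raise ValueError(f"cannot inject violations of rule {rule_id!r}")

    # repeated primitives compare equal by value, so locate by identity
    ids = {id(p) for p in marked}
    truth = sorted((i, rule_id) for i, p in enumerate(seq) if id(p) in ids)
    return seq, truth
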