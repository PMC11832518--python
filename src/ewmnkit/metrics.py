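"""Mobility-gradient metrics.

Quantifies the momentary narrowing or build-up of the repertoire:

* the **stereotypy triplet** — number of spatial modules active, the AP
  extent of recruitment in the most advanced module, and the
  predictability of the (segment, module) symbol sequence;
* **recruitment delays** — the cumulative amplitude a trunk part performs
  in a module before the next caudal part is first recruited there;
* **attended space** — the spread of the snout path over time windows;
* rigid-trunk **path kinematics** for animals (flies) whose trunk cannot
  articulate: speed, path curvature, body rotation, and the
  heading–progression interval (the rigid-trunk analogue of delayed caudal
  recruitment);
* traces **aligned on immobility** on- and offsets;
* **traveling-wave phase** structure of lateral bending along the body.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import hilbert, savgol_filter
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import kendalltau

from .grammar import DEFAULT_TAXONOMY, ModuleTaxonomy, _recruitment_order
from .linkage import LinkageSpec
from .segmentation import ImmobilityBout, Primitive, _smooth

__all__ = [
    "StereotypyTriplet",
    "RecruitmentDelays",
    "PathMetrics",
    "SpreadSeries",
    "AlignedTraces",
    "WavePhases",
    "stereotypy_triplet",
    "recruitment_delays",
    "attended_space",
    "fly_path_metrics",
    "align_to_immobility",
    "traveling_wave_phase",
]


# ---------------------------------------------------------------------------
# stereotypy
# ---------------------------------------------------------------------------


@dataclass
class StereotypyTriplet:
    n_modules_active: int
    ap_extent: int
    predictability: float
    most_advanced_module: str | None = None
    degenerate: bool = False
    low_confidence: bool = False
    n_symbols: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.predictability <= 1.0:
            raise ValueError("predictability must lie in [0, 1]")


def markov_predictability(symbols: Sequence, alpha: float = 1.0) -> float:
    """1 minus the normalized first-order Markov entropy rate.

    Transition counts are Laplace-smoothed with ``alpha``; the entropy rate
    (stationary weights from the empirical symbol frequencies) is
    normalized by ``log2`` of the observed alphabet size, so the score is
    invariant to symbol relabeling.  A single-symbol alphabet is perfectly
    predictable by convention.
    """
    symbols = list(symbols)
    alphabet = sorted(set(symbols), key=repr)
    K = len(alphabet)
    if K <= 1 or len(symbols) < 2:
        return 1.0
    idx = {a: i for i, a in enumerate(alphabet)}
    counts = np.full((K, K), alpha, dtype=float)
    for a, b in zip(symbols[:-1], symbols[1:]):
        counts[idx[a], idx[b]] += 1.0
    P = counts / counts.sum(axis=1, keepdims=True)
    pi = np.bincount([idx[s] for s in symbols[:-1]], minlength=K).astype(float)
    pi /= pi.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        H = -np.sum(pi[:, None] * P * np.log2(P))
    return float(np.clip(1.0 - H / np.log2(K), 0.0, 1.0))


def stereotypy_triplet(
    primitives: Sequence[Primitive],
    spec: LinkageSpec,
    taxonomy: ModuleTaxonomy = DEFAULT_TAXONOMY,
    min_symbols: int = 20,
) -> StereotypyTriplet:
    """Stereotypy triplet of a window of module-labeled primitives."""
    spatial = [p for p in primitives if taxonomy.is_spatial(p.module)]
    if not spatial:
        return StereotypyTriplet(0, 0, 1.0, degenerate=True)
    modules = {p.module for p in spatial}
    advanced = max(modules, key=taxonomy.rank)
    recruited = {p.segment for p in spatial if p.module == advanced}
    symbols = [(p.segment, p.module) for p in spatial]
    pred = markov_predictability(symbols)
    degenerate = len(set(symbols)) <= 1
    if degenerate:
        pred = 1.0
    return StereotypyTriplet(
        n_modules_active=len(modules),
        ap_extent=len(recruited),
        predictability=pred,
        most_advanced_module=advanced,
        degenerate=degenerate,
        low_confidence=len(symbols) < min_symbols,
        n_symbols=len(symbols),
    )


# ---------------------------------------------------------------------------
# recruitment delays
# ---------------------------------------------------------------------------


@dataclass
class DelayEntry:
    value: float  # cumulative amplitude (deg, or length units for forward)
    censored: bool = False  # next segment never recruited: value is a lower bound


@dataclass
class RecruitmentDelays:
    """D(segment_i -> segment_{i+1}, module): amplitude before recruitment."""

    entries: dict  # (module, seg_i, seg_next) -> DelayEntry

    def get(self, module: str, seg_i: str, seg_next: str) -> DelayEntry | None:
        return self.entries.get((module, seg_i, seg_next))


def _amplitude_of(p: Primitive) -> float:
    if p.movement_type == "forward_transport":
        return float(p.distance or 0.0)
    return float(p.amplitude_deg or 0.0)


def recruitment_delays(
    primitives: Sequence[Primitive],
    spec: LinkageSpec,
    taxonomy: ModuleTaxonomy = DEFAULT_TAXONOMY,
) -> RecruitmentDelays:
    """Cumulative pre-recruitment amplitude per module and AP segment pair.

    For each module and each adjacent pair along the recruitment direction,
    sums the amplitudes performed by the anterior segment before the
    posterior segment's first primitive in that module.  If the posterior
    segment never appears the entry is censored at the accumulated total.
    """
    entries: dict = {}
    prims = sorted(
        (p for p in primitives if taxonomy.is_spatial(p.module)), key=lambda p: p.start
    )
    modules = {p.module for p in prims}
    for m in modules:
        order = _recruitment_order(spec, m)
        in_m = [p for p in prims if p.module == m]
        for a, b in zip(order[:-1], order[1:]):
            first_b = next((k for k, p in enumerate(in_m) if p.segment == b), None)
            if first_b is None:
                if any(p.segment == a for p in in_m):
                    total = sum(_amplitude_of(p) for p in in_m if p.segment == a)
                    entries[(m, a, b)] = DelayEntry(value=total, censored=True)
                continue
            amt = sum(_amplitude_of(p) for p in in_m[:first_b] if p.segment == a)
            entries[(m, a, b)] = DelayEntry(value=amt, censored=False)
    return RecruitmentDelays(entries=entries)


# ---------------------------------------------------------------------------
# attended space
# ---------------------------------------------------------------------------


@dataclass
class SpreadSeries:
    window_s: float
    radius_of_gyration: np.ndarray
    hull_area: np.ndarray
    degenerate: np.ndarray  # windows with < 3 distinct points
    tau: float
    tau_p: float


def attended_space(
    path: np.ndarray, times: np.ndarray, window_s: float
) -> SpreadSeries:
    """Per-window spread (radius of gyration, convex-hull area) of a path,
    with a Kendall-tau trend statistic over windows."""
    if window_s < 1.0:
        raise ValueError("window must be at least 1 s")
    path = np.asarray(path, dtype=float)[:, :2]
    times = np.asarray(times, dtype=float)
    dt = np.median(np.diff(times))
    w = max(2, int(round(window_s / dt)))
    n_win = path.shape[0] // w
    if n_win < 1:
        raise ValueError("path shorter than one window")
    rg = np.zeros(n_win)
    area = np.zeros(n_win)
    degen = np.zeros(n_win, dtype=bool)
    for i in range(n_win):
        seg = path[i * w : (i + 1) * w]
        c = seg.mean(axis=0)
        rg[i] = np.sqrt(np.mean(np.sum((seg - c) ** 2, axis=1)))
        uniq = np.unique(seg, axis=0)
        if uniq.shape[0] < 3:
            degen[i] = True
            area[i] = 0.0
        else:
            try:
                area[i] = ConvexHull(uniq).volume  # 2-D: volume is the area
            except QhullError:
                degen[i] = True
                area[i] = 0.0
    if n_win >= 2 and np.ptp(rg) > 0:
        tau, p = kendalltau(np.arange(n_win), rg)
    else:
        tau, p = 0.0, 1.0
    return SpreadSeries(
        window_s=window_s,
        radius_of_gyration=rg,
        hull_area=area,
        degenerate=degen,
        tau=float(tau),
        tau_p=float(p),
    )


# ---------------------------------------------------------------------------
# rigid-body path metrics (fly)
# ---------------------------------------------------------------------------


@dataclass
class PathMetrics:
    times: np.ndarray
    speed: np.ndarray  # length/s, >= 0
    curvature: np.ndarray  # 1/length; NaN below the speed floor
    heading_deg: np.ndarray  # trunk orientation
    rotation_rate: np.ndarray  # deg/s, signed
    hp_interval_deg: np.ndarray  # heading-progression interval, [0, 180]; NaN below floor
    speed_floor: float
    centroid: np.ndarray

    def distance_to(self, spot: np.ndarray) -> np.ndarray:
        return np.linalg.norm(self.centroid - np.asarray(spot, dtype=float), axis=1)


def fly_path_metrics(
    times: np.ndarray,
    centroid: np.ndarray,
    heading_deg: np.ndarray,
    smooth_window_s: float = 0.25,
    speed_floor: float | None = None,
) -> PathMetrics:
    """Per-frame kinematics of a rigid planar trunk.

    Curvature is the turning of the direction of progression per unit arc
    length, computed on an arc-length-resampled path (step = median
    per-frame displacement) to avoid speed–curvature coupling; it is
    masked, together with the heading–progression interval, below the
    speed floor (default: 10% of the session median speed), where the
    direction of progression is noise.  Pivoting (body rotation) comes
    from the heading alone and stays defined at zero speed.
    """
    times = np.asarray(times, dtype=float)
    centroid = np.asarray(centroid, dtype=float)[:, :2]
    heading = np.asarray(heading_deg, dtype=float)
    fps = 1.0 / np.median(np.diff(times))
    sm = _smooth(centroid, fps, smooth_window_s, 3)
    vel = np.gradient(sm, times, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    if speed_floor is None:
        speed_floor = 0.1 * float(np.median(speed))
    moving = speed > speed_floor

    # progression direction and heading-progression interval
    prog = np.degrees(np.arctan2(vel[:, 1], vel[:, 0]))
    hp = np.abs(((heading - prog) + 180.0) % 360.0 - 180.0)
    hp = np.where(moving, hp, np.nan)

    hu = np.degrees(np.unwrap(np.radians(heading)))
    rot = np.gradient(hu, times)

    # arc-length resampled curvature
    curv = np.full(times.size, np.nan)
    disp = np.linalg.norm(np.diff(sm, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(disp)])
    pos_disp = disp[disp > 0]
    if pos_disp.size > 10:
        step = float(np.median(pos_disp))
        grid = np.arange(0.0, arclen[-1], step)
        if grid.size > 4:
            xr = np.interp(grid, arclen, sm[:, 0])
            yr = np.interp(grid, arclen, sm[:, 1])
            seg_ang = np.unwrap(np.arctan2(np.diff(yr), np.diff(xr)))
            kappa = np.abs(np.diff(seg_ang)) / step  # at grid[1:-1]
            curv_resampled = np.interp(arclen, grid[1:-1], kappa)
            curv = np.where(moving, curv_resampled, np.nan)
    return PathMetrics(
        times=times,
        speed=speed,
        curvature=curv,
        heading_deg=heading,
        rotation_rate=rot,
        hp_interval_deg=hp,
        speed_floor=float(speed_floor),
        centroid=centroid,
    )


# ---------------------------------------------------------------------------
# immobility-aligned traces
# ---------------------------------------------------------------------------


@dataclass
class AlignedTraces:
    """Distance-to-immobility-spot traces aligned on bout on/offsets."""

    grid: np.ndarray  # rescaled time in [0, 1] (or seconds if not rescaled)
    into_traces: list[np.ndarray]
    out_traces: list[np.ndarray]
    into_mean: np.ndarray | None
    into_dispersion: np.ndarray | None
    out_mean: np.ndarray | None
    out_dispersion: np.ndarray | None
    into_taus: list[float]
    out_taus: list[float]
    status: str = "ok"


def _resample(x: np.ndarray, grid: np.ndarray) -> np.ndarray:
    t = np.linspace(0.0, 1.0, x.size)
    return np.interp(grid, t, x)


def align_to_immobility(
    sessions: Sequence[tuple[np.ndarray, np.ndarray, Sequence[ImmobilityBout]]],
    rescale: bool = True,
    n_grid: int = 101,
) -> AlignedTraces:
    """Align distance-to-immobility-spot traces on bout onset and offset.

    Each session is ``(times, centroid, bouts)``; the immobility spot is
    the mean centroid within the bout.  The into-immobility trace runs
    from the previous bout end (or session start) to the bout onset; the
    out-of-immobility trace from the offset to the next bout (or session
    end).  With ``rescale`` every trace is mapped to [0, 1] before
    averaging.  Kendall taus quantify the monotone trend of each trace.
    """
    grid = np.linspace(0.0, 1.0, n_grid)
    into, out = [], []
    into_taus, out_taus = [], []
    for times, centroid, bouts in sessions:
        centroid = np.asarray(centroid, dtype=float)[:, :2]
        bouts = sorted(bouts, key=lambda b: b.start)
        for k, b in enumerate(bouts):
            spot = centroid[b.start : b.end].mean(axis=0)
            d = np.linalg.norm(centroid - spot, axis=1)
            s0 = bouts[k - 1].end if k > 0 else 0
            e1 = bouts[k + 1].start if k + 1 < len(bouts) else centroid.shape[0]
            seg_in = d[s0 : b.start]
            seg_out = d[b.end : e1]
            if seg_in.size >= 3:
                into.append(_resample(seg_in, grid) if rescale else seg_in)
                tau, _ = kendalltau(np.arange(seg_in.size), seg_in)
                into_taus.append(float(tau))
            if seg_out.size >= 3:
                out.append(_resample(seg_out, grid) if rescale else seg_out)
                tau, _ = kendalltau(np.arange(seg_out.size), seg_out)
                out_taus.append(float(tau))
    if not into and not out:
        return AlignedTraces(
            grid=grid,
            into_traces=[],
            out_traces=[],
            into_mean=None,
            into_dispersion=None,
            out_mean=None,
            out_dispersion=None,
            into_taus=[],
            out_taus=[],
            status="no qualifying immobility bout",
        )

    def agg(traces):
        if not traces or not rescale:
            return None, None
        arr = np.stack(traces)
        return arr.mean(axis=0), arr.std(axis=0) / np.sqrt(arr.shape[0])

    im, idisp = agg(into)
    om, odisp = agg(out)
    return AlignedTraces(
        grid=grid,
        into_traces=into,
        out_traces=out,
        into_mean=im,
        into_dispersion=idisp,
        out_mean=om,
        out_dispersion=odisp,
        into_taus=into_taus,
        out_taus=out_taus,
    )


# ---------------------------------------------------------------------------
# traveling wave
# ---------------------------------------------------------------------------


@dataclass
class WavePhases:
    phases: np.ndarray  # (T, S) instantaneous phase, radians; NaN for excluded
    relative_phases_deg: np.ndarray  # (S-1,) circular-mean adjacent lags
    mean_lag_deg: float  # mean AP phase lag between adjacent segments
    wavelength_bl: float  # body lengths; inf for a standing wave
    standing: bool
    excluded: list[int]


def traveling_wave_phase(
    bending: np.ndarray,
    frame_rate: float,
    min_variance_ratio: float = 1e-4,
    standing_threshold_deg: float = 2.0,
    edge_trim: float = 0.05,
) -> WavePhases:
    """Phase structure of lateral bending along the AP axis.

    Instantaneous phases come from the analytic signal (Hilbert transform)
    of each zero-meaned bending trace, so neither periodicity nor symmetry
    of the movement is required.  The relative phase between adjacent
    segments is the circular mean of their instantaneous phase difference;
    with ``S`` segments spanning one body length, a mean adjacent lag of
    ``delta`` corresponds to a wavelength of ``360 / (S * delta)`` body
    lengths.  Segments with near-zero bending variance are excluded.
    """
    bending = np.asarray(bending, dtype=float)
    if bending.ndim != 2 or bending.shape[1] < 3:
        raise ValueError("need a (T, S) bending array with at least 3 segments")
    T, S = bending.shape
    var = bending.var(axis=0)
    keep = var > min_variance_ratio * max(var.max(), 1e-30)
    excluded = [int(i) for i in np.flatnonzero(~keep)]
    centered = bending - bending.mean(axis=0)
    phases = np.full((T, S), np.nan)
    analytic = hilbert(centered[:, keep], axis=0)
    phases[:, keep] = np.angle(analytic)
    trim = int(edge_trim * T)
    sl = slice(trim, T - trim if trim else T)
    rel = np.full(S - 1, np.nan)
    kept_idx = np.flatnonzero(keep)
    for a, b in zip(kept_idx[:-1], kept_idx[1:]):
        if b != a + 1:
            continue
        dphi = phases[sl, a] - phases[sl, b]
        rel[a] = np.degrees(np.angle(np.mean(np.exp(1j * dphi))))
    lags = rel[np.isfinite(rel)]
    if lags.size == 0:
        raise ValueError("no adjacent segment pairs with usable bending signal")
    mean_lag = float(np.degrees(np.angle(np.mean(np.exp(1j * np.radians(lags))))))
    standing = abs(mean_lag) < standing_threshold_deg
    wavelength = np.inf if standing else 360.0 / (S * abs(mean_lag))
    return WavePhases(
        phases=phases,
        relative_phases_deg=rel,
        mean_lag_deg=mean_lag,
        wavelength_bl=float(wavelength),
        standing=standing,
        excluded=excluded,
    )
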