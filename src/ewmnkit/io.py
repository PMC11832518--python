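"""Readers/writers for keypoint tables and event tables, and the compact
notation-like text export of primitive sequences.

Supported keypoint dialects
---------------------------
``dlc_csv`` / ``dlc_h5``
    The three-level pose-estimation table layout (scorer / bodyparts /
    coords with per-part x, y, likelihood columns); likelihood below the
    configured threshold masks the sample invalid.
``generic_csv``
    A wide table with a ``time`` column and ``<part>_x``, ``<part>_y``
    (optionally ``<part>_z``) columns; NaN marks invalid samples.

Readers reject malformed structure with explicit errors rather than
guessing; writers are deterministic given identical inputs.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .linkage import KeypointSeries
from .segmentation import Primitive

__all__ = [
    "read_keypoints",
    "write_keypoints",
    "events_frame",
    "write_events",
    "read_events",
    "export_notation",
    "parse_notation",
]

EVENTS_SCHEMA = "ewmnkit/events-v1"

EVENT_COLUMNS = [
    "segment",
    "module",
    "movement_type",
    "sign",
    "amplitude_deg",
    "amplitude_units",
    "distance",
    "start_frame",
    "end_frame",
    "start_s",
    "end_s",
    "snout_contact",
    "support_base",
    "chord_members",
    "mixed",
]

EVENT_UNITS = {
    "amplitude_deg": "deg",
    "amplitude_units": "quanta",
    "distance": "length",
    "start_frame": "frame",
    "end_frame": "frame",
    "start_s": "s",
    "end_s": "s",
}


class DialectError(ValueError):
    """Raised when a file does not match the requested dialect."""


# ---------------------------------------------------------------------------
# keypoints
# ---------------------------------------------------------------------------


def _from_dlc_frame(df: pd.DataFrame, likelihood_threshold: float, frame_rate: float):
    if not isinstance(df.columns, pd.MultiIndex) or df.columns.nlevels != 3:
        raise DialectError(
            "expected a three-level header (scorer / bodyparts / coords)"
        )
    coords_level = df.columns.get_level_values(2)
    if not {"x", "y"} <= set(coords_level):
        raise DialectError("coords level must contain x and y columns")
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    scorer = df.columns.get_level_values(0)[0]
    T = len(df)
    K = len(bodyparts)
    pos = np.full((T, K, 2), np.nan)
    valid = np.ones((T, K), dtype=bool)
    for k, bp in enumerate(bodyparts):
        pos[:, k, 0] = df[(scorer, bp, "x")].to_numpy(dtype=float)
        pos[:, k, 1] = df[(scorer, bp, "y")].to_numpy(dtype=float)
        if (scorer, bp, "likelihood") in df.columns:
            lik = df[(scorer, bp, "likelihood")].to_numpy(dtype=float)
            valid[:, k] = lik >= likelihood_threshold
    valid &= np.isfinite(pos).all(axis=2)
    pos[~valid] = 0.0
    times = np.arange(T) / frame_rate
    return KeypointSeries(
        times=times,
        positions=pos,
        keypoint_names=bodyparts,
        valid_mask=valid,
        frame_rate=frame_rate,
    )


def read_keypoints(
    path: str | Path,
    dialect: str,
    frame_rate: float | None = None,
    likelihood_threshold: float = 0.6,
) -> KeypointSeries:
    """Read a keypoint table in one of the supported dialects."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "dlc_csv":
        if frame_rate is None:
            raise ValueError("dlc_csv carries no time column: pass frame_rate")
        try:
            df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        except Exception as exc:
            raise DialectError(
                f"{path}: not a pose CSV with scorer/bodyparts/coords header rows ({exc})"
            ) from exc
        return _from_dlc_frame(df, likelihood_threshold, frame_rate)
    if dialect == "dlc_h5":
        if frame_rate is None:
            raise ValueError("dlc_h5 carries no time column: pass frame_rate")
        try:
            df = pd.read_hdf(path)
        except Exception as exc:
            raise DialectError(f"{path}: unreadable HDF5 table ({exc})") from exc
        return _from_dlc_frame(df, likelihood_threshold, frame_rate)
    if dialect == "generic_csv":
        df = pd.read_csv(path)
        if "time" not in df.columns:
            raise DialectError("generic_csv requires a 'time' column")
        suffixes = ("_x", "_y", "_z")
        parts: list[str] = []
        for c in df.columns:
            for suf in suffixes:
                if c.endswith(suf):
                    p = c[: -len(suf)]
                    if p not in parts:
                        parts.append(p)
        if not parts:
            raise DialectError("generic_csv has no <part>_x/_y columns")
        has_z = all(f"{p}_z" in df.columns for p in parts)
        dims = ["x", "y", "z"] if has_z else ["x", "y"]
        for p in parts:
            for d in dims:
                if f"{p}_{d}" not in df.columns:
                    raise DialectError(f"generic_csv missing column {p}_{d}")
        T, K, D = len(df), len(parts), len(dims)
        pos = np.zeros((T, K, D))
        for k, p in enumerate(parts):
            for d_i, d in enumerate(dims):
                pos[:, k, d_i] = df[f"{p}_{d}"].to_numpy(dtype=float)
        valid = np.isfinite(pos).all(axis=2)
        pos[~valid] = 0.0
        return KeypointSeries(
            times=df["time"].to_numpy(dtype=float),
            positions=pos,
            keypoint_names=parts,
            valid_mask=valid,
            frame_rate=frame_rate,
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def write_keypoints(kps: KeypointSeries, path: str | Path, dialect: str = "generic_csv") -> None:
    """Write a keypoint series (invalid samples become NaN)."""
    path = Path(path)
    if dialect == "generic_csv":
        dims = ["x", "y", "z"][: kps.ndim]
        data = {"time": kps.times}
        for k, name in enumerate(kps.keypoint_names):
            for d_i, d in enumerate(dims):
                col = kps.positions[:, k, d_i].astype(float).copy()
                col[~kps.valid_mask[:, k]] = np.nan
                data[f"{name}_{d}"] = col
        pd.DataFrame(data).to_csv(path, index=False)
        return
    if dialect in ("dlc_csv", "dlc_h5"):
        if kps.ndim != 2:
            raise ValueError("pose-table dialects are 2-D; use generic_csv for 3-D")
        scorer = "ewmnkit"
        cols = pd.MultiIndex.from_product(
            [[scorer], kps.keypoint_names, ["x", "y", "likelihood"]],
            names=["scorer", "bodyparts", "coords"],
        )
        T = kps.n_frames
        arr = np.zeros((T, len(kps.keypoint_names) * 3))
        for k in range(len(kps.keypoint_names)):
            arr[:, 3 * k] = kps.positions[:, k, 0]
            arr[:, 3 * k + 1] = kps.positions[:, k, 1]
            arr[:, 3 * k + 2] = kps.valid_mask[:, k].astype(float)
        df = pd.DataFrame(arr, columns=cols)
        if dialect == "dlc_csv":
            df.to_csv(path)
        else:
            df.to_hdf(path, key="df_with_missing", mode="w")
        return
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------


def events_frame(primitives: Sequence[Primitive], frame_rate: float) -> pd.DataFrame:
    """Primitive event table with stable column order and both timestamps."""
    rows = []
    for p in primitives:
        rows.append(
            {
                "segment": p.segment,
                "module": p.module,
                "movement_type": p.movement_type,
                "sign": p.sign,
                "amplitude_deg": p.amplitude_deg,
                "amplitude_units": p.amplitude_units,
                "distance": p.distance,
                "start_frame": p.start,
                "end_frame": p.end,
                "start_s": p.start / frame_rate,
                "end_s": p.end / frame_rate,
                "snout_contact": p.snout_contact,
                "support_base": p.support_base,
                "chord_members": ";".join(p.chord_members),
                "mixed": p.mixed,
            }
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def _none_if_nan(x):
    if x is None:
        return None
    if isinstance(x, float) and math.isnan(x):
        return None
    return x


def write_events(table: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    """Write an event table; censored/undefined values serialize as NaN in
    CSV and ``null`` in JSON."""
    path = Path(path)
    if format == "csv":
        table.to_csv(path, index=False)
    elif format == "json":
        rows = [
            {k: _none_if_nan(v) for k, v in rec.items()}
            for rec in table.to_dict(orient="records")
        ]
        payload = {
            "schema": EVENTS_SCHEMA,
            "units": EVENT_UNITS,
            "events": rows,
        }
        path.write_text(json.dumps(payload, indent=1, default=_json_default))
    else:
        raise ValueError(f"unknown format {format!r}")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_events(path: str | Path, format: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "csv"
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "json":
        payload = json.loads(path.read_text())
        if payload.get("schema") != EVENTS_SCHEMA:
            raise ValueError(f"unexpected event schema {payload.get('schema')!r}")
        df = pd.DataFrame(payload["events"], columns=EVENT_COLUMNS)
    else:
        raise ValueError(f"unknown format {format!r}")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    return df[EVENT_COLUMNS]


def events_to_primitives(df: pd.DataFrame) -> list[Primitive]:
    """Rebuild primitives from an event table."""
    out = []
    for rec in df.to_dict(orient="records"):
        chord = rec.get("chord_members")
        if chord is None or (isinstance(chord, float) and math.isnan(chord)):
            chord = ""
        amp = _none_if_nan(rec["amplitude_deg"])
        units = _none_if_nan(rec["amplitude_units"])
        contact = _none_if_nan(rec["snout_contact"])
        module = _none_if_nan(rec["module"])
        out.append(
            Primitive(
                segment=rec["segment"],
                movement_type=rec["movement_type"],
                sign=rec["sign"],
                start=int(rec["start_frame"]),
                end=int(rec["end_frame"]),
                amplitude_deg=None if amp is None else float(amp),
                amplitude_units=None if units is None else int(units),
                distance=_none_if_nan(rec["distance"]),
                chord_members=tuple(c for c in str(chord).split(";") if c),
                snout_contact=None if contact is None else bool(contact),
                support_base=rec["support_base"],
                mixed=bool(rec["mixed"]),
                module=module,
            )
        )
    return out


# ---------------------------------------------------------------------------
# notation export
# ---------------------------------------------------------------------------

_TYPE_CODES = {
    "plane_horizontal": "H",
    "forward_transport": "F",
    "conical": "C",
}
_SIGN_CODES = {"left": "+", "up": "+", "forward": "+", "right": "-", "down": "-", "backward": "-"}
_SIGN_BACK = {
    "H": {"+": "left", "-": "right"},
    "V": {"+": "up", "-": "down"},
    "Vc": {"+": "up", "-": "down"},
    "C": {"+": "left", "-": "right"},
    "F": {"+": "forward", "-": "backward"},
}


def _vertical_code(p: Primitive) -> str:
    return "Vc" if p.snout_contact else "V"


def export_notation(
    primitives: Sequence[Primitive], abbreviations: dict[str, str] | None = None
) -> str:
    """ASCII rendering of a primitive sequence, one phrase per primitive.

    Each phrase is ``<segment>:<type><sign><amplitude>`` with H horizontal,
    F forward transport, Vc/V vertical with/without snout contact, C
    conical; angular amplitude in quanta, transport distance in length
    units.  ``parse_notation`` inverts it losslessly at the symbol level.
    """
    phrases = []
    for p in primitives:
        abbr = (abbreviations or {}).get(p.segment, p.segment[0])
        if p.movement_type == "plane_vertical":
            code = _vertical_code(p)
        else:
            try:
                code = _TYPE_CODES[p.movement_type]
            except KeyError:
                raise ValueError(f"unknown movement label {p.movement_type!r}")
        try:
            sign = _SIGN_CODES[p.sign]
        except KeyError:
            raise ValueError(f"unknown sign {p.sign!r}")
        if p.movement_type == "forward_transport":
            amp = repr(float(p.distance))
        else:
            amp = str(int(p.amplitude_units or 0))
        phrases.append(f"{abbr}:{code}{sign}{amp}")
    return " | ".join(phrases)


def parse_notation(
    text: str,
    segment_names: Sequence[str],
    quantum: float = 45.0,
) -> list[Primitive]:
    """Parse an exported notation line back into (synthetic-frame) primitives.

    Frame spans are synthesized (one unit per phrase) since the text form
    carries symbols, not timestamps.
    """
    abbr_map = {}
    for name in segment_names:
        a = name[0]
        if a in abbr_map:
            raise ValueError("segment abbreviations collide; pass unique names")
        abbr_map[a] = name
    out: list[Primitive] = []
    if not text.strip():
        return out
    for k, phrase in enumerate(text.split("|")):
        phrase = phrase.strip()
        try:
            abbr, rest = phrase.split(":", 1)
        except ValueError:
            raise ValueError(f"malformed phrase {phrase!r}")
        if abbr not in abbr_map:
            raise ValueError(f"unknown segment abbreviation {abbr!r}")
        code = rest[:2] if rest[:2] == "Vc" else rest[:1]
        body = rest[len(code):]
        if not body or body[0] not in "+-":
            raise ValueError(f"malformed phrase {phrase!r}: missing sign")
        sign_ch, amp_str = body[0], body[1:]
        if code not in _SIGN_BACK:
            raise ValueError(f"unknown movement code {code!r}")
        sign = _SIGN_BACK[code][sign_ch]
        if code == "F":
            out.append(
                Primitive(
                    segment=abbr_map[abbr],
                    movement_type="forward_transport",
                    sign=sign,
                    start=k,
                    end=k + 1,
                    distance=float(amp_str),
                )
            )
        else:
            units = int(amp_str)
            mtype = {
                "H": "plane_horizontal",
                "V": "plane_vertical",
                "Vc": "plane_vertical",
                "C": "conical",
            }[code]
            out.append(
                Primitive(
                    segment=abbr_map[abbr],
                    movement_type=mtype,
                    sign=sign,
                    start=k,
                    end=k + 1,
                    amplitude_deg=units * quantum,
                    amplitude_units=units,
                    snout_contact=(code == "Vc") if code in ("V", "Vc") else None,
                )
            )
    return out
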