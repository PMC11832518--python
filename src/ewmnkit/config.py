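"""Linkage/support configuration: defaults and YAML loading.

The YAML schema mirrors :class:`~ewmnkit.linkage.LinkageSpec` plus a free
``params`` mapping for thresholds::

    linkage:
      zero_direction: [1, 0, 0]
      up: [0, 0, 1]
      snout_keypoint: snout
      segments:
        - {name: pelvis, proximal: tail_base, distal: mid_spine, rest_length: 0.04}
        - {name: torso,  proximal: mid_spine, distal: neck_base, rest_length: 0.05}
        - {name: head,   proximal: neck_base, distal: snout,     rest_length: 0.03}
      appendages:
        order_posterior_to_anterior: [hind_feet, fore_feet]
        sets:
          hind_feet: [left_hind_foot, right_hind_foot]
          fore_feet: [left_fore_foot, right_fore_foot]
    params:
      quantum: 45.0
      likelihood_threshold: 0.6

Validation is strict: a malformed file raises ``ConfigurationError`` with
a message naming the offending field.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .linkage import ConfigurationError, LinkageSpec, SegmentDef

__all__ = ["default_rat_linkage", "load_config", "DEFAULT_PARAMS"]

DEFAULT_PARAMS = {
    "quantum": 45.0,
    "likelihood_threshold": 0.6,
    "min_amplitude_deg": 11.25,
    "speed_threshold_deg_s": 10.0,
    "plane_tolerance_deg": 22.5,
    "contact_threshold": 0.02,
    "max_gap_frames": 5,
    "immobility_speed_threshold": 0.002,
    "immobility_min_duration_s": 2.0,
    "warmup_reset_s": 5.0,
}


def default_rat_linkage() -> LinkageSpec:
    """Three-segment axial chain of an infant rat (lengths in metres)."""
    return LinkageSpec(
        segments=(
            SegmentDef("pelvis", "tail_base", "mid_spine", 0.04),
            SegmentDef("torso", "mid_spine", "neck_base", 0.05),
            SegmentDef("head", "neck_base", "snout", 0.03),
        ),
        appendage_sets={
            "hind_feet": ("left_hind_foot", "right_hind_foot"),
            "fore_feet": ("left_fore_foot", "right_fore_foot"),
        },
        appendage_order=("hind_feet", "fore_feet"),
        snout_keypoint="snout",
    )


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ConfigurationError(f"{context}: missing required key {key!r}")
    return mapping[key]


def load_config(path: str | Path) -> tuple[LinkageSpec, dict]:
    """Load and validate a linkage/params YAML file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: invalid YAML ({exc})") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    link = _require(raw, "linkage", str(path))
    seg_raw = _require(link, "segments", "linkage")
    if not isinstance(seg_raw, list) or not seg_raw:
        raise ConfigurationError("linkage.segments must be a non-empty list")
    segments = []
    for k, s in enumerate(seg_raw):
        ctx = f"linkage.segments[{k}]"
        if not isinstance(s, dict):
            raise ConfigurationError(f"{ctx}: must be a mapping")
        try:
            segments.append(
                SegmentDef(
                    name=str(_require(s, "name", ctx)),
                    proximal=str(_require(s, "proximal", ctx)),
                    distal=str(_require(s, "distal", ctx)),
                    rest_length=float(_require(s, "rest_length", ctx)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"{ctx}: {exc}") from exc
    app = link.get("appendages", {}) or {}
    sets = {
        str(k): tuple(map(str, v)) for k, v in (app.get("sets", {}) or {}).items()
    }
    order = tuple(map(str, app.get("order_posterior_to_anterior", ()) or ()))
    try:
        spec = LinkageSpec(
            segments=tuple(segments),
            appendage_sets=sets,
            appendage_order=order,
            zero_direction=tuple(link.get("zero_direction", (1.0, 0.0, 0.0))),
            up=tuple(link.get("up", (0.0, 0.0, 1.0))),
            snout_keypoint=link.get("snout_keypoint"),
        )
    except ConfigurationError:
        raise
    except Exception as exc:
        raise ConfigurationError(f"{path}: invalid linkage ({exc})") from exc
    params = dict(DEFAULT_PARAMS)
    user = raw.get("params", {}) or {}
    if not isinstance(user, dict):
        raise ConfigurationError("params must be a mapping")
    params.update(user)
    return spec, params
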