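"""The six-module spatial taxonomy and the generative rules of warm-up.

Locomotor behavior unfolds along six spatial modules that emerge in a
fixed order: horizontal movement on the hind legs, forward transport,
vertical movement with snout contact, vertical movement in the air, and —
concurrently — horizontal and vertical movement rooted on the forelegs.
Within each module, trunk segments are recruited linearly in
antero-posterior (AP) order.  The build-up rule: a trunk part moves along
a dimension only after the part anterior to it has moved along that
dimension, and only after the part itself has moved along the previously
prescribed dimension in the current sequence.  Under stress the modules
are eliminated "last in first out", and the support module folds in a
tail-to-head (PA) order.  This module labels primitives with their
modules, extracts warm-up sequences from immobility, and checks the rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .linkage import LinkageSpec
from .segmentation import ImmobilityBout, Primitive

__all__ = [
    "M1",
    "M2",
    "M3",
    "M4",
    "M5",
    "M6",
    "SUPPORT",
    "VERTICAL_UNRESOLVED",
    "ModuleTaxonomy",
    "DEFAULT_TAXONOMY",
    "Violation",
    "ComplianceReport",
    "WarmUpSequence",
    "assign_module",
    "label_modules",
    "extract_warmup",
    "check_buildup_rule",
    "check_narrowing_rule",
    "support_inactivation_events",
    "ontogenetic_matrix",
]

M1 = "horizontal_on_hindlegs"
M2 = "forward"
M3 = "vertical_snout_contact"
M4 = "vertical_free"
M5 = "horizontal_on_forelegs"
M6 = "vertical_on_forelegs"
SUPPORT = "support"
VERTICAL_UNRESOLVED = "vertical_unresolved"

RULE_IDS = ("AP_within_module", "module_order", "LIFO_narrowing", "PA_support")


@dataclass(frozen=True)
class ModuleTaxonomy:
    """Ordered spatial modules plus the separate support module.

    The last two modules form a concurrent tier: they share a rank and are
    mutually unordered, but both require the fourth module to precede them.
    """

    modules: tuple[str, ...] = (M1, M2, M3, M4, M5, M6)
    tier: frozenset = frozenset({M5, M6})
    support_label: str = SUPPORT

    def __post_init__(self) -> None:
        if len(self.modules) != 6:
            raise ValueError("the taxonomy has exactly six spatial modules")

    def rank(self, module: str) -> int:
        """1-based rank; tier members share the top rank."""
        if module in self.tier:
            return 5
        return self.modules.index(module) + 1

    def is_spatial(self, module: str | None) -> bool:
        return module in self.modules

    def predecessor_rank(self, module: str) -> int:
        return self.rank(module) - 1

    def modules_of_rank(self, rank: int) -> tuple[str, ...]:
        return tuple(m for m in self.modules if self.rank(m) == rank)


DEFAULT_TAXONOMY = ModuleTaxonomy()


def assign_module(p: Primitive, taxonomy: ModuleTaxonomy = DEFAULT_TAXONOMY) -> str:
    """Module label for a classified primitive.

    Horizontal movement maps to the hindleg or foreleg horizontal module by
    the support base at onset; vertical movement splits on snout contact
    (or maps to the foreleg vertical module when rooted on the
    forequarters); forward transport is its own module regardless of base.
    Conical movement maps to the nearest plane module and is flagged mixed.
    Unknown contact yields a merged, unresolved vertical label.
    """
    mt = p.movement_type
    fore = p.support_base == "forequarters"
    if mt == "forward_transport":
        return M2
    if mt == "plane_horizontal":
        return M5 if fore else M1
    if mt == "plane_vertical":
        if fore:
            return M6
        if p.snout_contact is None:
            return VERTICAL_UNRESOLVED
        return M3 if p.snout_contact else M4
    if mt == "conical":
        # nearest plane module, by which plane the sign came from
        p.mixed = True
        if p.sign in ("up", "down"):
            proxy = Primitive(
                segment=p.segment,
                movement_type="plane_vertical",
                sign=p.sign,
                start=p.start,
                end=p.end,
                amplitude_deg=p.amplitude_deg,
                snout_contact=p.snout_contact,
                support_base=p.support_base,
            )
        else:
            proxy = Primitive(
                segment=p.segment,
                movement_type="plane_horizontal",
                sign=p.sign,
                start=p.start,
                end=p.end,
                amplitude_deg=p.amplitude_deg,
                snout_contact=p.snout_contact,
                support_base=p.support_base,
            )
        return assign_module(proxy, taxonomy)
    raise ValueError(f"cannot assign module for movement type {mt!r}")


def label_modules(
    primitives: Sequence[Primitive], taxonomy: ModuleTaxonomy = DEFAULT_TAXONOMY
) -> list[Primitive]:
    for p in primitives:
        p.module = assign_module(p, taxonomy)
    return list(primitives)


# ---------------------------------------------------------------------------
# compliance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    rule_id: str
    index: int  # primitive index (or support-event index for PA_support)
    explanation: str

    def __post_init__(self) -> None:
        if self.rule_id not in RULE_IDS:
            raise ValueError(f"unknown rule id {self.rule_id!r}")


@dataclass
class ComplianceReport:
    violations: list[Violation] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def compliant(self) -> bool:
        return not self.violations

    @property
    def counts(self) -> dict[str, int]:
        c = {r: 0 for r in RULE_IDS}
        for v in self.violations:
            c[v.rule_id] += 1
        return c

    def to_dict(self) -> dict:
        return {
            "compliant": self.compliant,
            "counts": self.counts,
            "violations": [
                {"rule_id": v.rule_id, "index": v.index, "explanation": v.explanation}
                for v in self.violations
            ],
            "notes": list(self.notes),
        }


def _recruitment_order(spec: LinkageSpec, module: str) -> list[str]:
    """Segment recruitment order within a module: anterior (head) first.

    Recruitment proceeds antero-posteriorly in every module; on the
    forelegs the mechanical hierarchy is reversed but recruitment still
    runs along the AP axis from the supporting forequarters backwards.
    """
    return list(reversed(spec.segment_names))


def check_buildup_rule(
    seq: "WarmUpSequence | Sequence[Primitive]",
    spec: LinkageSpec,
    taxonomy: ModuleTaxonomy = DEFAULT_TAXONOMY,
) -> ComplianceReport:
    """Check AP-within-module recruitment and the fixed module order.

    A primitive of segment *s* in module *m* violates AP recruitment when
    the segment anterior to *s* has not yet appeared in *m*; it violates
    the module order when it is *s*'s first appearance in *m* but *s* has
    not yet appeared in the previously prescribed module (the tier of the
    two foreleg modules is unordered internally, both requiring the free
    vertical module).
    """
    primitives = seq.primitives if isinstance(seq, WarmUpSequence) else list(seq)
    report = ComplianceReport()
    seen: dict[tuple[str, str], bool] = {}  # (segment, module) appeared
    skipped = 0
    for i, p in enumerate(primitives):
        m = p.module
        if m is None:
            raise ValueError("primitives must be module-labeled (assign_module)")
        if not taxonomy.is_spatial(m):
            if m == VERTICAL_UNRESOLVED:
                skipped += 1
            continue
        s = p.segment
        order = _recruitment_order(spec, m)
        pos = order.index(s)
        if pos > 0:
            anterior = order[pos - 1]
            if not seen.get((anterior, m), False):
                report.violations.append(
                    Violation(
                        "AP_within_module",
                        i,
                        f"{s} moved in {m} before its anterior neighbour {anterior}",
                    )
                )
        if not seen.get((s, m), False):
            r = taxonomy.rank(m)
            if r > 1:
                prev_modules = taxonomy.modules_of_rank(r - 1)
                if not any(seen.get((s, pm), False) for pm in prev_modules):
                    report.violations.append(
                        Violation(
                            "module_order",
                            i,
                            f"first {s} movement in {m} precedes any {s} movement "
                            f"in {' / '.join(prev_modules)}",
                        )
                    )
        seen[(s, m)] = True
    if skipped:
        report.notes.append(
            f"{skipped} primitive(s) with unresolved vertical label excluded"
        )
    return report


def check_narrowing_rule(
    seq: "WarmUpSequence | Sequence[Primitive]",
    taxonomy: ModuleTaxonomy = DEFAULT_TAXONOMY,
    support_events: Sequence[tuple[int, str]] | None = None,
    spec: LinkageSpec | None = None,
) -> ComplianceReport:
    """Check last-in-first-out narrowing and PA support folding.

    Higher modules must disappear from the sequence before lower ones: a
    module's last occurrence after the last occurrence of a lower-ranked
    module is a violation.  Support inactivation events (appendage-set
    stance losses, as ``(event_index-ordered (frame, set_name)`` pairs)
    must run tail-to-head; an anterior set folding before a posterior one
    is a violation.
    """
    primitives = seq.primitives if isinstance(seq, WarmUpSequence) else list(seq)
    report = ComplianceReport()
    last: dict[str, int] = {}
    for i, p in enumerate(primitives):
        if taxonomy.is_spatial(p.module):
            last[p.module] = i
    for m_hi, i_hi in last.items():
        r_hi = taxonomy.rank(m_hi)
        offenders = [
            m_lo
            for m_lo, i_lo in last.items()
            if taxonomy.rank(m_lo) < r_hi and i_lo < i_hi
        ]
        if offenders:
            report.violations.append(
                Violation(
                    "LIFO_narrowing",
                    i_hi,
                    f"last {m_hi} occurs after the last occurrence of "
                    f"{', '.join(sorted(offenders))}",
                )
            )
    if support_events:
        if spec is None or not spec.appendage_order:
            report.notes.append(
                "support events supplied without an appendage AP order; PA rule skipped"
            )
        else:
            ap_rank = {name: k for k, name in enumerate(spec.appendage_order)}
            # posterior first (rank 0) must inactivate before anterior
            for j, (fr_j, name_j) in enumerate(support_events):
                for i2 in range(j):
                    _, name_i = support_events[i2]
                    if ap_rank[name_i] > ap_rank[name_j]:
                        report.violations.append(
                            Violation(
                                "PA_support",
                                i2,
                                f"{name_i} support folded before the more posterior "
                                f"{name_j}",
                            )
                        )
                        break
    return report


def support_inactivation_events(
    flags: dict[str, np.ndarray]
) -> list[tuple[int, str]]:
    """(frame, appendage_set) pairs where a support flag turns off."""
    events = []
    for name, arr in flags.items():
        arr = np.asarray(arr, dtype=bool)
        offs = np.flatnonzero(arr[:-1] & ~arr[1:]) + 1
        events.extend((int(f), name) for f in offs)
    events.sort()
    return events


# ---------------------------------------------------------------------------
# warm-up extraction and ontogeny
# ---------------------------------------------------------------------------


@dataclass
class WarmUpSequence:
    """Module-labeled primitives from one immobility offset."""

    primitives: list[Primitive]
    start: int
    end: int
    session_id: str | None = None
    no_reset: bool = False
    peak: Primitive | None = None

    def __len__(self) -> int:
        return len(self.primitives)


def peak_key(
    p: Primitive, spec: LinkageSpec, taxonomy: ModuleTaxonomy = DEFAULT_TAXONOMY
) -> tuple[int, int]:
    """Total order on primitives: module rank, then caudal recruitment depth."""
    if not taxonomy.is_spatial(p.module):
        return (0, 0)
    order = _recruitment_order(spec, p.module)
    return (taxonomy.rank(p.module), order.index(p.segment))


def extract_warmup(
    primitives: Sequence[Primitive],
    bouts: Sequence[ImmobilityBout],
    reset_duration_s: float,
    spec: LinkageSpec,
    taxonomy: ModuleTaxonomy = DEFAULT_TAXONOMY,
    session_end: int | None = None,
    session_id: str | None = None,
) -> list[WarmUpSequence]:
    """One warm-up sequence per qualifying immobility bout.

    A bout qualifies when its duration reaches ``reset_duration_s``; the
    sequence runs from the bout's offset until the next qualifying bout
    starts.  A session with no qualifying bout yields a single sequence
    spanning the session, flagged ``no_reset``.
    """
    primitives = sorted(primitives, key=lambda p: p.start)
    if session_end is None:
        session_end = max([p.end for p in primitives], default=0)
        session_end = max(session_end, max([b.end for b in bouts], default=0))
    resets = sorted(
        (b for b in bouts if b.duration_s >= reset_duration_s), key=lambda b: b.start
    )
    sequences: list[WarmUpSequence] = []
    if not resets:
        seq = WarmUpSequence(
            primitives=list(primitives),
            start=0,
            end=session_end,
            session_id=session_id,
            no_reset=True,
        )
        sequences.append(seq)
    else:
        for k, b in enumerate(resets):
            span_start = b.end
            span_end = resets[k + 1].start if k + 1 < len(resets) else session_end
            sel = [p for p in primitives if span_start <= p.start < span_end]
            sequences.append(
                WarmUpSequence(
                    primitives=sel,
                    start=span_start,
                    end=span_end,
                    session_id=session_id,
                )
            )
    for seq in sequences:
        spatial = [p for p in seq.primitives if taxonomy.is_spatial(p.module)]
        if spatial:
            seq.peak = max(spatial, key=lambda p: peak_key(p, spec, taxonomy))
    return sequences


@dataclass
class OntogenyReport:
    """Daily peak primitives and terminal-addition (collinearity) check."""

    days: list
    peaks: list[tuple[str, str] | None]  # (module, segment) per day
    keys: list[tuple[int, int] | None]
    collinear: bool
    regressions: list  # days whose peak fell below the previous defined peak
    gaps: list  # missing day identifiers (for integer day labels)


def ontogenetic_matrix(
    daily_sequences: Sequence[tuple[object, WarmUpSequence]],
    spec: LinkageSpec,
    taxonomy: ModuleTaxonomy = DEFAULT_TAXONOMY,
) -> OntogenyReport:
    """Daily peak series and collinearity (terminal addition) report.

    Collinearity holds when the (module rank, caudal recruitment) key of
    the daily peaks is non-decreasing across days: new movement types are
    added terminally, never losing previously acquired ones.
    """
    if len(daily_sequences) < 2:
        raise ValueError("ontogenetic matrix needs at least 2 days")
    days = [d for d, _ in daily_sequences]
    peaks: list[tuple[str, str] | None] = []
    keys: list[tuple[int, int] | None] = []
    for _, seq in daily_sequences:
        if seq.peak is None:
            peaks.append(None)
            keys.append(None)
        else:
            peaks.append((seq.peak.module, seq.peak.segment))
            keys.append(peak_key(seq.peak, spec, taxonomy))
    regressions = []
    prev = None
    for day, key in zip(days, keys):
        if key is None:
            continue
        if prev is not None and key < prev:
            regressions.append(day)
        prev = key
    gaps: list = []
    if all(isinstance(d, (int, np.integer)) for d in days):
        full = range(int(min(days)), int(max(days)) + 1)
        gaps = [d for d in full if d not in set(int(x) for x in days)]
    return OntogenyReport(
        days=list(days),
        peaks=peaks,
        keys=keys,
        collinear=not regressions,
        regressions=regressions,
        gaps=gaps,
    )
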