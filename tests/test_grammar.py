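"""Module taxonomy, build-up and narrowing rules, warm-up extraction."""

import itertools

import numpy as np
import pytest

import ewmnkit as ek
from ewmnkit.grammar import (
    DEFAULT_TAXONOMY,
    M1,
    M2,
    M3,
    M4,
    M5,
    M6,
    VERTICAL_UNRESOLVED,
    ModuleTaxonomy,
    assign_module,
    check_buildup_rule,
    check_narrowing_rule,
    extract_warmup,
    label_modules,
    ontogenetic_matrix,
    peak_key,
    support_inactivation_events,
)
from ewmnkit.segmentation import ImmobilityBout, Primitive
from ewmnkit.simulate import GrammarSimConfig, simulate_warmup


def prim(seg, module=None, mtype="plane_horizontal", sign="left", start=0, end=1, **kw):
    defaults = dict(amplitude_deg=45.0, amplitude_units=1)
    if mtype == "forward_transport":
        defaults = dict(distance=0.02)
        sign = kw.pop("sign", "forward") if "sign" in kw else "forward"
    defaults.update(kw)
    p = Primitive(
        segment=seg, movement_type=mtype, sign=sign, start=start, end=end, **defaults
    )
    p.module = module
    return p


def seq_from_symbols(symbols):
    """[(segment, module), ...] -> primitives with consistent types."""
    mtypes = {
        M1: ("plane_horizontal", "left"),
        M2: ("forward_transport", "forward"),
        M3: ("plane_vertical", "up"),
        M4: ("plane_vertical", "up"),
        M5: ("plane_horizontal", "left"),
        M6: ("plane_vertical", "up"),
    }
    out = []
    for k, (seg, m) in enumerate(symbols):
        mtype, sign = mtypes[m]
        kw = {}
        if m == M3:
            kw["snout_contact"] = True
        if m == M4:
            kw["snout_contact"] = False
        if m in (M5, M6):
            kw["support_base"] = "forequarters"
        out.append(prim(seg, m, mtype, sign, start=k, end=k + 1, **kw))
    return out


class TestTaxonomy:
    def test_exactly_six_spatial_modules(self):
        assert len(DEFAULT_TAXONOMY.modules) == 6
        with pytest.raises(ValueError):
            ModuleTaxonomy(modules=(M1, M2, M3))

    def test_module_ordering_with_concurrent_tier(self):
        ranks = [DEFAULT_TAXONOMY.rank(m) for m in DEFAULT_TAXONOMY.modules]
        assert ranks == [1, 2, 3, 4, 5, 5]


class TestAssignModule:
    def test_exhaustive_truth_table(self):
        """(type x base x contact) against an enumerated oracle."""
        oracle = {}
        for base in ("hindquarters", "forequarters"):
            for contact in (True, False, None):
                oracle[("forward_transport", base, contact)] = M2
                oracle[("plane_horizontal", base, contact)] = M5 if base == "forequarters" else M1
                if base == "forequarters":
                    oracle[("plane_vertical", base, contact)] = M6
                elif contact is None:
                    oracle[("plane_vertical", base, contact)] = VERTICAL_UNRESOLVED
                else:
                    oracle[("plane_vertical", base, contact)] = M3 if contact else M4
        for (mtype, base, contact), want in oracle.items():
            p = prim(
                "head",
                mtype=mtype,
                sign="forward" if mtype == "forward_transport" else ("up" if "vertical" in mtype else "left"),
                snout_contact=contact,
                support_base=base,
            )
            assert assign_module(p) == want, (mtype, base, contact)

    def test_conical_maps_to_nearest_plane_with_mixed_flag(self):
        p = prim("head", mtype="conical", sign="up", snout_contact=False)
        assert assign_module(p) == M4
        assert p.mixed
        p2 = prim("head", mtype="conical", sign="left")
        assert assign_module(p2) == M1


class TestBuildUp:
    def test_fig_style_ap_then_module_progression_compliant(self, spec):
        symbols = [
            ("head", M1), ("torso", M1), ("pelvis", M1),
            ("head", M2), ("torso", M2), ("pelvis", M2),
            ("head", M3), ("torso", M3),
            ("head", M4),
        ]
        rep = check_buildup_rule(seq_from_symbols(symbols), spec)
        assert rep.compliant

    def test_caudal_before_anterior_is_one_ap_violation(self, spec):
        symbols = [("pelvis", M1), ("torso", M1)]
        rep = check_buildup_rule(seq_from_symbols(symbols), spec)
        ap = [v for v in rep.violations if v.rule_id == "AP_within_module"]
        assert len(ap) == 2  # pelvis lacks torso; torso lacks head
        assert ap[0].index == 0

    def test_constructed_counterexample_single_violation(self, spec):
        symbols = [("head", M1), ("pelvis", M1), ("torso", M1)]
        rep = check_buildup_rule(seq_from_symbols(symbols), spec)
        assert [v.rule_id for v in rep.violations] == ["AP_within_module"]
        assert rep.violations[0].index == 1

    def test_module_order_requires_previous_dimension(self, spec):
        symbols = [("head", M2)]
        rep = check_buildup_rule(seq_from_symbols(symbols), spec)
        assert rep.counts["module_order"] == 1

    def test_tier_modules_unordered_internally(self, spec):
        base = [("head", m) for m in (M1, M2, M3, M4)]
        for first, second in ((M5, M6), (M6, M5)):
            symbols = base + [("head", first), ("head", second)]
            rep = check_buildup_rule(seq_from_symbols(symbols), spec)
            assert rep.compliant, (first, second)

    def test_exhaustive_two_segment_two_module_alphabet(self, spec):
        """All 4^4 short sequences over {head, torso} x {M1, M2} match an
        independent brute-force rule evaluator."""
        alphabet = [(s, m) for s in ("head", "torso") for m in (M1, M2)]

        def brute_force(symbols):
            viol = 0
            seen = set()
            for (s, m) in symbols:
                if s == "torso" and ("head", m) not in seen:
                    viol += 1
                if (s, m) not in seen and m == M2 and (s, M1) not in seen:
                    viol += 1
                seen.add((s, m))
            return viol

        for symbols in itertools.product(alphabet, repeat=4):
            rep = check_buildup_rule(seq_from_symbols(list(symbols)), spec)
            assert len(rep.violations) == brute_force(symbols), symbols

    def test_unresolved_vertical_excluded_and_noted(self, spec):
        symbols = [("head", M1)]
        prims = seq_from_symbols(symbols)
        p = prim("head", VERTICAL_UNRESOLVED, mtype="plane_vertical", sign="up")
        rep = check_buildup_rule(prims + [p], spec)
        assert rep.compliant and rep.notes


class TestNarrowing:
    def test_lifo_compliant_last_occurrences(self, spec):
        symbols = [
            ("head", M4), ("head", M3), ("head", M2), ("head", M1),
        ]
        # prefix so every module occurred before its last occurrence
        rep = check_narrowing_rule(seq_from_symbols(symbols))
        assert rep.compliant

    def test_low_module_disappearing_before_high_is_violation(self, spec):
        symbols = [("head", M1), ("head", M3)]
        rep = check_narrowing_rule(seq_from_symbols(symbols))
        assert rep.counts["LIFO_narrowing"] == 1
        assert rep.violations[0].index == 1

    def test_single_module_trivially_compliant(self, spec):
        rep = check_narrowing_rule(seq_from_symbols([("head", M1), ("torso", M1)]))
        assert rep.compliant

    def test_reversed_buildup_passes_lifo(self, spec):
        """Reversal duality: any build-up-compliant sequence, time-reversed,
        is LIFO-compliant on module labels."""
        for seed in range(20):
            res = simulate_warmup(GrammarSimConfig(stage=1.0, seed=seed))
            assert check_buildup_rule(res.primitives, spec).compliant
            rev = list(reversed(res.primitives))
            assert check_narrowing_rule(rev).compliant

    def test_pa_support_folding_order(self, spec):
        flags_ok = {
            "hind_feet": np.array([True, True, False, False]),
            "fore_feet": np.array([True, True, True, False]),
        }
        ev = support_inactivation_events(flags_ok)
        rep = check_narrowing_rule([], support_events=ev, spec=spec)
        assert rep.compliant
        flags_bad = {
            "hind_feet": np.array([True, True, True, False]),
            "fore_feet": np.array([True, False, False, False]),
        }
        ev = support_inactivation_events(flags_bad)
        rep = check_narrowing_rule([], support_events=ev, spec=spec)
        assert rep.counts["PA_support"] == 1


class TestWarmupExtraction:
    def bout(self, start, end, fps=50.0):
        return ImmobilityBout(start=start, end=end, duration_s=(end - start) / fps)

    def test_two_long_bouts_give_two_sequences(self, spec):
        prims = [prim("head", M1, start=s, end=s + 5) for s in (300, 320, 900, 950)]
        bouts = [self.bout(0, 250), self.bout(600, 860)]
        seqs = extract_warmup(prims, bouts, reset_duration_s=4.0, spec=spec, session_end=1000)
        assert len(seqs) == 2
        assert [len(s) for s in seqs] == [2, 2]
        assert (seqs[0].start, seqs[0].end) == (250, 600)
        assert (seqs[1].start, seqs[1].end) == (860, 1000)

    def test_no_qualifying_bout_flags_no_reset(self, spec):
        prims = [prim("head", M1, start=10, end=20)]
        seqs = extract_warmup(prims, [self.bout(0, 5)], 60.0, spec=spec, session_end=100)
        assert len(seqs) == 1 and seqs[0].no_reset

    def test_random_interleavings_match_interval_partition_oracle(self, spec, rng):
        for _ in range(25):
            n_b = rng.integers(1, 4)
            starts = np.sort(rng.choice(np.arange(0, 2000, 100), n_b, replace=False))
            bouts = [self.bout(int(s), int(s) + 80) for s in starts]
            prims = [
                prim("head", M1, start=int(f), end=int(f) + 3)
                for f in np.sort(rng.integers(0, 2200, 30))
            ]
            seqs = extract_warmup(prims, bouts, 1.0, spec=spec, session_end=2300)
            # oracle: a primitive belongs to the interval after the latest
            # bout end <= start; primitives before the first bout or starting
            # inside a bout belong to no sequence
            edges = [b.end for b in bouts]
            for p in prims:
                k = int(np.searchsorted(edges, p.start, side="right")) - 1
                inside = any(b.start <= p.start < b.end for b in bouts)
                if k < 0 or inside:
                    assert all(p not in s.primitives for s in seqs)
                else:
                    assert p in seqs[k].primitives

    def test_peak_is_most_caudal_of_highest_module(self, spec):
        symbols = [("head", M1), ("torso", M1), ("head", M2), ("torso", M2), ("head", M3)]
        prims = seq_from_symbols(symbols)
        seqs = extract_warmup(prims, [self.bout(0, 100)], 1.0, spec=spec, session_end=200)
        # frames in seq_from_symbols are 0..n; shift starts after the bout
        for k, p in enumerate(prims):
            p.start, p.end = 100 + k, 101 + k
        seqs = extract_warmup(prims, [self.bout(0, 100)], 1.0, spec=spec, session_end=200)
        assert seqs[0].peak.module == M3 and seqs[0].peak.segment == "head"


class TestOntogeny:
    def day(self, symbols, spec):
        prims = seq_from_symbols(symbols)
        seq = ek.WarmUpSequence(primitives=prims, start=0, end=len(prims))
        spatial = [p for p in prims if DEFAULT_TAXONOMY.is_spatial(p.module)]
        seq.peak = max(spatial, key=lambda p: peak_key(p, spec))
        return seq

    def test_advancing_peaks_are_collinear(self, spec):
        days = [
            (1, self.day([("head", M1)], spec)),
            (2, self.day([("head", M1), ("torso", M1)], spec)),
            (3, self.day([("head", M1), ("torso", M1), ("pelvis", M1)], spec)),
            (5, self.day([("head", M1), ("torso", M1), ("head", M2)], spec)),
        ]
        rep = ontogenetic_matrix(days, spec)
        assert rep.collinear and rep.regressions == []
        assert rep.gaps == [4]

    def test_regressing_day_is_flagged(self, spec):
        days = [
            (1, self.day([("head", M1), ("head", M2)], spec)),
            (2, self.day([("head", M1)], spec)),
        ]
        rep = ontogenetic_matrix(days, spec)
        assert not rep.collinear and rep.regressions == [2]

    def test_simulator_stage_sweep_is_collinear(self, spec):
        """Days with a monotone stage parameter always yield collinear peaks."""
        for seed in range(30):
            days = []
            for d, stage in enumerate((0.1, 0.4, 0.7, 1.0)):
                res = simulate_warmup(GrammarSimConfig(stage=stage, seed=seed + 100 * d))
                seqs = extract_warmup(
                    res.primitives,
                    [res.immobility],
                    reset_duration_s=5.0,
                    spec=spec,
                    session_end=res.keypoints.n_frames,
                )
                days.append((d, seqs[0]))
            rep = ontogenetic_matrix(days, spec)
            assert rep.collinear, (seed, rep.peaks)

    def test_needs_two_days(self, spec):
        with pytest.raises(ValueError):
            ontogenetic_matrix([(1, self.day([("head", M1)], spec))], spec)
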