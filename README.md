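# ewmnkit

Kinematic movement primitives, movement-grammar checking, and
mobility-gradient metrics for pose-tracked behavior.

## The problem

Marker-less pose estimation yields per-frame coordinates of skeletal
keypoints, but the coordinates themselves say little about the *structure*
of behavior. In the movement-notation (EWMN) tradition of kinematic
analysis, the trunk is a chain of rigid segments; each segment owns a
spherical system of reference that stays axis-parallel to an absolute
frame whose vertical axis is set by gravity. The base of support induces a
mechanical hierarchy on the chain — the **law of heavy and light limbs**:
the closer a segment is to the supporting girdle, the "heavier" it is, and
a heavy segment's movement carries all lighter segments along. A light
segment's motion is read in the frame *carried along* on its heavy
neighbour, as if the neighbour had not moved.

On this geometry the primitive of behavior is a **single movement**: one
discrete change of the angular relation between a trunk segment and its
next heavy neighbour. Primitives organize into six spatial **modules**
(horizontal on the hind legs, forward transport, vertical with snout
contact, vertical in the air, and — concurrently — horizontal and vertical
rooted on the forelegs), which emerge out of immobility in a fixed order
("warm-up"): within each module, trunk segments are recruited
antero-posteriorly; a segment moves along a dimension only after the
segment anterior to it has, and after it has itself moved along the
previously prescribed dimension. Under stress or dopaminergic challenge
the repertoire narrows in reverse — last in, first out — while the support
module folds tail-to-head.

`ewmnkit` implements this formalism end to end:

- **linkage** — segment directions in absolute and carried-along spherical
  frames, the heavy/light hierarchy from support, quantization to the
  45-degree notation grid, and a forward-kinematics renderer/oracle;
- **segmentation** — immobility bouts, single-movement detection on
  body-relative angle traces, movement-type classification (plane
  horizontal/vertical, conical, forward transport), snout-contact
  detection against arena geometry;
- **grammar** — module labeling, warm-up extraction with peak primitives,
  the build-up (AP-recruitment and module-order), last-in-first-out
  narrowing, and posterior-to-anterior support-folding checkers, plus an
  ontogenetic (day-by-day peak) collinearity report;
- **metrics** — the stereotypy triplet (active modules, AP extent,
  sequence predictability), recruitment delays, attended-space spread,
  rigid-trunk path kinematics for flies (speed, curvature, pivoting,
  heading–progression interval), immobility-aligned traces, and
  traveling-wave phase structure of lateral bending;
- **simulate** — seeded generators for grammar-compliant warm-ups rendered
  to keypoints, fly-like narrowing→immobility→build-up sessions, and AP
  traveling waves, plus a violation injector for benchmarking;
- **io / CLI** — pose-table dialects (three-row-header CSV/HDF5 with
  likelihood masking, generic wide CSV), typed event tables, YAML linkage
  configuration, an ASCII notation export, and the `ewmnkit` command.

## Worked example

Simulate a half-unlocked warm-up, measure it back from the rendered
keypoints, and quantify it:

```python
import ewmnkit as ek
from ewmnkit.simulate import GrammarSimConfig, simulate_warmup
from ewmnkit.segmentation import detect_snout_contact, segment_single_movements
from ewmnkit.grammar import label_modules, check_buildup_rule
from ewmnkit.metrics import stereotypy_triplet, recruitment_delays
from ewmnkit.io import export_notation

spec = ek.default_rat_linkage()
sim = simulate_warmup(GrammarSimConfig(stage=0.5, seed=7))

pose = ek.compute_segment_directions(sim.keypoints, spec)
order = ek.derive_heavy_light_order(sim.support, spec)
angles = ek.to_body_relative(pose, order, spec)
contact = detect_snout_contact(sim.keypoints, sim.arena, threshold=0.02)
prims = segment_single_movements(angles, order, spec, kps=sim.keypoints,
                                 contact=contact)
label_modules(prims)

print("n primitives:", len(prims))
print("notation:", export_notation(prims[:8]), "...")
print("compliant:", check_buildup_rule(prims, spec).compliant)
trip = stereotypy_triplet(prims, spec)
print(f"modules active: {trip.n_modules_active}, AP extent: {trip.ap_extent}, "
      f"predictability: {trip.predictability:.2f}")
d = recruitment_delays(prims, spec).get("horizontal_on_hindlegs", "head", "torso")
print(f"head->torso horizontal recruitment delay: {d.value:.0f} deg")
```

prints

```
n primitives: 23
notation: h:H+2 | h:H-2 | h:H-2 | h:H+2 | t:H+2 | t:H-2 | t:H-2 | t:H+2 ...
compliant: True
modules active: 3, AP extent: 1, predictability: 0.07
head->torso horizontal recruitment delay: 360 deg
```

Reading: the sequence opens with side-to-side horizontal head movements of
two 45-degree units (`h:H±2`), recruits the torso only afterwards, is
fully lawful under the build-up rule, spans three spatial modules with the
head alone recruited in the most advanced one, and the head performed 360
degrees of horizontal movement before the torso's first horizontal
primitive — the recruitment delay.

The same pipeline is available from the shell:

```bash
ewmnkit simulate --kind warmup --stage 0.5 --seed 7 --out-prefix /tmp/demo
ewmnkit segment --input /tmp/demo.csv --out /tmp/events.csv
ewmnkit compliance --events /tmp/events.csv   # exit code = compliance
ewmnkit export --events /tmp/events.csv
```

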