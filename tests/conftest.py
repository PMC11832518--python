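import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ewmnkit as ek

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def spec():
    return ek.default_rat_linkage()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_angles(theta, phi, spec, fps=50.0):
    """Body-relative angle container from raw arrays."""
    from ewmnkit.linkage import make_body_relative

    theta = np.asarray(theta, dtype=float)
    T = theta.shape[0]
    return make_body_relative(theta, phi, np.arange(T) / fps, fps, spec)


def render(theta, phi, spec, fps=50.0, base=(0.0, 0.0, 0.0), support="hindquarters"):
    """Forward-render raw body-relative angles to keypoints."""
    angles = make_angles(theta, phi, spec, fps)
    sup = ek.SupportState.constant(theta.shape[0], support)
    order = ek.derive_heavy_light_order(sup, spec)
    return ek.forward_kinematics(np.asarray(base, dtype=float), angles, order, spec), order


def run_pipeline(sim_result, spec, params=None):
    """Measure-and-segment a rendered warm-up simulation."""
    from ewmnkit.segmentation import detect_snout_contact, segment_single_movements

    kps = sim_result.keypoints
    pose = ek.compute_segment_directions(kps, spec)
    order = ek.derive_heavy_light_order(sim_result.support, spec)
    rel = ek.to_body_relative(pose, order, spec)
    contact = detect_snout_contact(kps, sim_result.arena, sim_result.config.contact_threshold)
    prims = segment_single_movements(rel, order, spec, params, kps=kps, contact=contact)
    from ewmnkit.grammar import label_modules

    label_modules(prims)
    return prims
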