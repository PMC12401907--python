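import dataclasses

import numpy as np
import pytest

from octbias import geometry as g
from octbias import synthetic


def circle_vertices(radius=1.0, center=(0.0, 0.0), n=512):
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.c_[center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]


def ellipse_vertices(a, b, center=(0.0, 0.0), n=1024, phi=0.0):
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    x = a * np.cos(th)
    y = b * np.sin(th)
    c, s = np.cos(phi), np.sin(phi)
    return np.c_[center[0] + c * x - s * y, center[1] + s * x + c * y]


def star_vertices(rng, n=12, r_lo=0.5, r_hi=1.5, center=(0.0, 0.0)):
    """Random simple (star-shaped) polygon."""
    th = np.sort(rng.uniform(0.0, 2.0 * np.pi, n))
    # enforce distinct angles
    while np.any(np.diff(th) < 1e-3):
        th = np.sort(rng.uniform(0.0, 2.0 * np.pi, n))
    r = rng.uniform(r_lo, r_hi, n)
    return np.c_[center[0] + r * np.cos(th), center[1] + r * np.sin(th)]


def make_cross_section(lumen_r=2.0, catheter_xy=(0.5, 0.0), media_r=None,
                       eem_r=None, frame_id=0, z=0.0, n=512, **kwargs):
    media = None if media_r is None else g.Contour(
        circle_vertices(media_r, n=n), g.ContourRole.MEDIA)
    eem = None if eem_r is None else g.Contour(
        circle_vertices(eem_r, n=n), g.ContourRole.EEM)
    return g.CrossSection(
        frame_id=frame_id, z=z,
        intima=g.Contour(circle_vertices(lumen_r, n=n)),
        media=media, eem=eem,
        catheter=g.CatheterPose(center=catheter_xy), **kwargs)


@pytest.fixture(scope="session")
def default_study():
    """Default threshold-mode study, seed 1 (shared; ~400 frames)."""
    return synthetic.generate_study(synthetic.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_study():
    """Tiny study for fast structural tests."""
    cfg = synthetic.GeneratorConfig(seed=7, n_patients=3,
                                    frames_per_patient=(6, 8))
    return synthetic.generate_study(cfg)


@pytest.fixture(scope="session")
def paired_default(default_study):
    from octbias import pipeline
    paired, pairs = pipeline.run_pair(default_study.pre_pullbacks,
                                      default_study.post_pullbacks)
    return paired, pairs


def severe_bias_config(seed=7, n_patients=4, frames=(8, 10)):
    """Config with the catheter pushed close to the wall (many events)."""
    return synthetic.GeneratorConfig(
        seed=seed, n_patients=n_patients, frames_per_patient=frames,
        bias=dataclasses.replace(synthetic.BiasModel(),
                                 clearance_min_mm=0.30, clearance_scale_mm=0.4))
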