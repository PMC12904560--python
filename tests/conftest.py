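import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nvflow as nv

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def meta():
    return nv.ScanMetadata()


@pytest.fixture(scope="session")
def clean_dyc(meta):
    """Noise-free B-scan series: one vessel at 0.5*pi phase shift, galvo ramp
    and depth-dependent phase bias active."""
    dphi = 0.5 * np.pi
    alpha = 0.67
    v_long = dphi * meta.phase_to_axial_velocity / np.cos(alpha)
    nz, nx, nt = 64, 96, 12
    vessel = nv.straight_vessel(
        metadata=meta, dims=(nz, nx), angle_alpha=alpha, radius=14e-6,
        center=(26, 48), speed_profile=v_long, backscatter_baseline=2.0,
        half_length=50e-6, label="v1",
    )
    scene = nv.SyntheticScene(
        metadata=meta, dims=(nz, nx, nt), rpe_depth_index=52, vessels=[vessel],
        galvo_ramp=0.15, depth_phase_bias=0.002 * np.arange(nz),
        noise_sigma=0.0, seed=3,
    )
    volume, truth = nv.simulate_dyc_series(scene)
    return scene, volume, truth, dphi


@pytest.fixture(scope="session")
def noisy_dyc(meta):
    """Same geometry at 20 dB amplitude SNR."""
    dphi = 0.5 * np.pi
    alpha = 0.67
    v_long = dphi * meta.phase_to_axial_velocity / np.cos(alpha)
    nz, nx, nt = 64, 96, 40
    vessel = nv.straight_vessel(
        metadata=meta, dims=(nz, nx), angle_alpha=alpha, radius=14e-6,
        center=(26, 48), speed_profile=v_long, backscatter_baseline=2.0,
        half_length=50e-6, label="v1",
    )
    scene = nv.SyntheticScene(
        metadata=meta, dims=(nz, nx, nt), rpe_depth_index=52, vessels=[vessel],
        galvo_ramp=0.15, depth_phase_bias=0.002 * np.arange(nz),
        noise_sigma=0.2, seed=11,
    )
    volume, truth = nv.simulate_dyc_series(scene)
    return scene, volume, truth, dphi


@pytest.fixture(scope="session")
def angio_tube(meta):
    """Small 3D angiography scene with one tilted tube."""
    vessel = nv.straight_vessel(
        metadata=meta, dims=(48, 96, 64), angle_alpha=0.3, azimuth=0.4,
        radius=14e-6, center=(22, 48, 32), speed_profile=1.5e-3,
        backscatter_baseline=2.0, label="tube",
    )
    scene = nv.SyntheticScene(
        metadata=meta, dims=(48, 96, 64), rpe_depth_index=40,
        vessels=[vessel], galvo_ramp=0.1, noise_sigma=0.1, seed=7,
        choroid_amp=1.5,
    )
    volume, truth = nv.simulate_angio_volume(scene)
    return scene, volume, truth
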