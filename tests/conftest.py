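"""Shared fixtures: a miniature acquisition geometry and phantom scene that
keep unit tests fast while exercising the full pipeline."""

from __future__ import annotations

import numpy as np
import pytest

from paatlas.atlas_estimator import EstimatorConfig
from paatlas.core_io import AcquisitionGeometry, ChannelFrame, ChannelFrameSet
from paatlas.synthetic_phantom import PhantomScene, simulate_trial


@pytest.fixture(scope="session")
def tiny_geom() -> AcquisitionGeometry:
    return AcquisitionGeometry(n_elements=32, sampling_frequency_mhz=8.0)


@pytest.fixture(scope="session")
def tiny_scene() -> PhantomScene:
    return PhantomScene(
        chamber_center_mm=(10.0, None),
        chamber_diameter_mm=5.0,
        n_sources=60,
        noise_sd=0.05,
    )


@pytest.fixture(scope="session")
def tiny_cfg() -> EstimatorConfig:
    return EstimatorConfig(M=8, kernel_mm=1.2, n_draws=100, stride=1)


def make_tiny_trial(scene, geom, c, seed, n_frames=2, noise_sd=None):
    sc = scene
    if noise_sd is not None or c != scene.mb_fraction:
        from dataclasses import replace

        kw = {"mb_fraction": c}
        if noise_sd is not None:
            kw["noise_sd"] = noise_sd
        sc = replace(scene, **kw)
    return simulate_trial(sc, geom, n_frames_per_wavelength=n_frames, seed=seed)


@pytest.fixture(scope="session")
def tiny_pure_trials(tiny_scene, tiny_geom):
    """(pure-MB, pure-Hb) trials of the miniature phantom."""
    mb = make_tiny_trial(tiny_scene, tiny_geom, 1.0, seed=11)
    hb = make_tiny_trial(tiny_scene, tiny_geom, 0.0, seed=12)
    return mb, hb


@pytest.fixture(scope="session")
def tiny_atlas(tiny_pure_trials, tiny_cfg):
    from paatlas.atlas_estimator import build_atlas

    mb, hb = tiny_pure_trials
    return build_atlas(mb, hb, tiny_cfg)


def single_point_frame(
    geom: AcquisitionGeometry,
    z_mm: float,
    x_mm: float,
    *,
    f_c_mhz: float = 2.0,
    sigma_us: float = 0.25,
    n_samples: int = 160,
    wavelength: int = 710,
    amplitude: float = 1.0,
) -> ChannelFrame:
    """Channel data of an ideal point source built directly from the forward
    delay model (the independent oracle for DAS/SLSC localization tests)."""
    t_us = np.arange(n_samples) / geom.sampling_frequency_mhz
    elem = geom.element_positions_mm()
    d_mm = np.hypot(z_mm, x_mm - elem)  # (n_el,)
    tau = d_mm * 1e3 / geom.speed_of_sound_m_s  # us
    arg = t_us[:, None] - tau[None, :]
    rf = amplitude * np.exp(-(arg**2) / (2 * sigma_us**2)) * np.cos(
        2 * np.pi * f_c_mhz * arg
    )
    return ChannelFrame(rf=rf, optical_wavelength=wavelength)


def frame_set(frames, geom, gt=None) -> ChannelFrameSet:
    return ChannelFrameSet(frames=frames, geometry=geom, ground_truth_fraction=gt)
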