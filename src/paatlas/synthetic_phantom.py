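"""Synthetic phantom study generator.

Emulates the physical experiment the estimator targets: a ~15-mm circular
chamber filled with a methylene blue (MB) / hemoglobin (Hb) mixture about
20 mm from a 128-element linear array, illuminated through an optical fiber
whose tip sits inside the chamber.  Point absorbers scattered in the chamber
receive a fluence that decays radially from the fiber tip,
``E * exp(-mu_eff r) / max(r, r0)^2``, with the effective optical absorption
a volume-weighted blend of the two chromophores,
``mu_eff(c, lambda) = c mu_MB(lambda) + (1 - c) mu_Hb(lambda)``.

Each absorber emits a Gaussian-envelope acoustic pulse whose center
frequency interpolates between the chromophore pulse models with weight c
and is additionally shifted upward with mu_eff (stronger absorption excites
a smaller volume, hence a shorter, higher-frequency pulse — the stylized
fluence-driven mechanism that makes the acoustic spectrum carry the mixture
fraction).  Channel signals are the superposition over absorbers, delayed by
the one-way travel time and weighted by fluence x absorption / propagation
distance.  Per-frame laser energy is drawn from a truncated normal
(3.13 +- 0.4 mJ), and white noise is added relative to the frame's peak
amplitude.

The chromophore absorption values and pulse frequencies are *synthetic*,
stylized defaults: MB dominates the 710-nm response and Hb the 870-nm
response, and pulse center frequencies lie in the 1-4 MHz band.  They are
configuration, not claims about real optical spectra.  The default study is
11 mixture fractions (0..100% MB in 10% steps) x 5 trials x 10 frames per
wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    VALID_WAVELENGTHS,
    AcquisitionGeometry,
    ChannelFrame,
    ChannelFrameSet,
)

__all__ = [
    "ChromophoreModel",
    "PhantomScene",
    "default_models",
    "mixture_volumes",
    "effective_absorption",
    "sample_energies",
    "simulate_trial",
    "generate_study",
    "DEFAULT_CONCENTRATIONS",
]

#: Mixture fractions of the default study: 0..100% MB in 10% steps.
DEFAULT_CONCENTRATIONS: tuple[float, ...] = tuple(np.round(np.arange(11) * 0.1, 1))


@dataclass(frozen=True)
class ChromophoreModel:
    """Synthetic acousto-optic signature of one chromophore.

    ``absorption_per_mm`` gives the effective optical absorption (mm^-1) at
    each laser wavelength; ``pulse_center_frequency_mhz`` the center
    frequency of the emitted acoustic pulse at each wavelength;
    ``pulse_bandwidth`` its fractional FWHM bandwidth.
    """

    name: str
    absorption_per_mm: Mapping[int, float]
    pulse_center_frequency_mhz: Mapping[int, float]
    pulse_bandwidth: float = 0.6

    def __post_init__(self) -> None:
        for wl in VALID_WAVELENGTHS:
            if self.absorption_per_mm.get(wl, 0.0) <= 0.0:
                raise ValueError(f"{self.name}: absorption at {wl} nm must be > 0")
            if self.pulse_center_frequency_mhz.get(wl, 0.0) <= 0.0:
                raise ValueError(
                    f"{self.name}: pulse center frequency at {wl} nm must be > 0"
                )


def default_models() -> tuple[ChromophoreModel, ChromophoreModel]:
    """Default (MB, Hb) templates.

    MB absorbs more strongly at 710 nm, Hb at 870 nm, so the relative
    710-vs-870 amplitude is monotone in the MB fraction; the pulse center
    frequencies differ per class so the spectral shape carries additional
    contrast.
    """
    mb = ChromophoreModel(
        name="MB",
        absorption_per_mm={710: 0.15, 870: 0.04},
        pulse_center_frequency_mhz={710: 2.6, 870: 2.1},
    )
    hb = ChromophoreModel(
        name="Hb",
        absorption_per_mm={710: 0.06, 870: 0.135},
        pulse_center_frequency_mhz={710: 1.7, 870: 2.4},
    )
    return mb, hb


@dataclass(frozen=True)
class PhantomScene:
    """Geometry and statistics of one simulated trial.

    ``chamber_center_mm`` is (axial, lateral); ``None`` lateral centers the
    chamber on the aperture.  The fiber tip defaults to the chamber center
    (~20 mm depth).  ``noise_sd`` is the white-noise standard deviation
    relative to the frame's peak signal amplitude.
    """

    mb_fraction: float = 0.0
    chamber_center_mm: tuple[float, float | None] = (20.0, None)
    chamber_diameter_mm: float = 15.0
    fiber_tip_mm: tuple[float, float] | None = None
    n_sources: int = 160
    energy_mean_mj: float = 3.13
    energy_sd_mj: float = 0.4
    noise_sd: float = 0.05
    r0_mm: float = 0.5
    frequency_shift_exponent: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.mb_fraction <= 1.0:
            raise ValueError("mb_fraction must lie in [0, 1]")
        if self.chamber_diameter_mm <= 0 or self.n_sources < 1:
            raise ValueError("chamber_diameter_mm and n_sources must be positive")

    def resolved_center(self, geom: AcquisitionGeometry) -> tuple[float, float]:
        ax, lat = self.chamber_center_mm
        if lat is None:
            lat = geom.aperture_mm / 2.0
        return float(ax), float(lat)

    def resolved_fiber_tip(self, geom: AcquisitionGeometry) -> tuple[float, float]:
        if self.fiber_tip_mm is not None:
            return tuple(map(float, self.fiber_tip_mm))
        return self.resolved_center(geom)


def mixture_volumes(total_ml: float, mb_fraction: float) -> tuple[float, float]:
    """Volumes (MB mL, Hb mL) of a mixture with the given MB volume fraction;
    e.g. a 60% MB mixture of 2 mL is 1.2 mL MB + 0.8 mL Hb."""
    if total_ml <= 0:
        raise ValueError("total_ml must be positive")
    if not 0.0 <= mb_fraction <= 1.0:
        raise ValueError("mb_fraction must lie in [0, 1]")
    return total_ml * mb_fraction, total_ml * (1.0 - mb_fraction)


def effective_absorption(
    models: tuple[ChromophoreModel, ChromophoreModel], c: float, wavelength: int
) -> float:
    """Volume-weighted effective absorption
    mu_eff(c, lambda) = c mu_MB + (1 - c) mu_Hb, in mm^-1."""
    mb, hb = models
    return c * mb.absorption_per_mm[wavelength] + (1.0 - c) * hb.absorption_per_mm[
        wavelength
    ]


def sample_energies(
    rng: np.random.Generator, n: int, mean_mj: float = 3.13, sd_mj: float = 0.4
) -> np.ndarray:
    """Per-frame laser energies: Normal(mean, sd) truncated to > 0."""
    e = rng.normal(mean_mj, sd_mj, size=n)
    bad = e <= 0
    while np.any(bad):
        e[bad] = rng.normal(mean_mj, sd_mj, size=int(bad.sum()))
        bad = e <= 0
    return e


def _pulse_parameters(
    models: tuple[ChromophoreModel, ChromophoreModel],
    c: float,
    wavelength: int,
    shift_exponent: float,
) -> tuple[float, float]:
    """(center frequency MHz, envelope std in us) of the mixture pulse."""
    mb, hb = models
    f0 = c * mb.pulse_center_frequency_mhz[wavelength] + (
        1.0 - c
    ) * hb.pulse_center_frequency_mhz[wavelength]
    bw = c * mb.pulse_bandwidth + (1.0 - c) * hb.pulse_bandwidth
    mu = effective_absorption(models, c, wavelength)
    mu_ref = 0.5 * (
        mb.absorption_per_mm[wavelength] + hb.absorption_per_mm[wavelength]
    )
    f_c = f0 * (mu / mu_ref) ** shift_exponent
    sigma_f = bw * f_c / 2.355  # fractional FWHM -> Gaussian std (MHz)
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)  # us
    return f_c, sigma_t


def _default_n_samples(
    scene: PhantomScene, geom: AcquisitionGeometry, margin_mm: float = 4.0
) -> int:
    ax, lat = scene.resolved_center(geom)
    depth_mm = ax + scene.chamber_diameter_mm / 2.0 + margin_mm
    # farthest element from the deepest chamber point bounds the arrival time
    far_mm = np.hypot(depth_mm, geom.aperture_mm)
    t_us = far_mm * 1e3 / geom.speed_of_sound_m_s
    return int(np.ceil(t_us * geom.sampling_frequency_mhz)) + 1


def simulate_trial(
    scene: PhantomScene,
    geom: AcquisitionGeometry | None = None,
    models: tuple[ChromophoreModel, ChromophoreModel] | None = None,
    n_frames_per_wavelength: int = 10,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    *,
    n_samples: int | None = None,
    trial_id: int = 0,
) -> ChannelFrameSet:
    """Simulate one trial: ``n_frames_per_wavelength`` frames at each of
    710 and 870 nm, with per-frame absorber positions, laser energy and
    noise.  Deterministic for a given seed."""
    if geom is None:
        geom = AcquisitionGeometry()
    if models is None:
        models = default_models()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_samples is None:
        n_samples = _default_n_samples(scene, geom)
    c = scene.mb_fraction
    center_ax, center_lat = scene.resolved_center(geom)
    radius = scene.chamber_diameter_mm / 2.0
    if center_ax - radius < 0 or center_ax + radius > (
        (n_samples - 1)
        * geom.speed_of_sound_m_s
        / (geom.sampling_frequency_mhz * 1e6)
        * 1e3
    ):
        raise ValueError("chamber does not fit inside the imaging depth")
    fiber_ax, fiber_lat = scene.resolved_fiber_tip(geom)
    elem_lat = geom.element_positions_mm()  # (n_el,)
    t_us = np.arange(n_samples) / geom.sampling_frequency_mhz  # (n_samp,)
    c_mm_per_us = geom.speed_of_sound_m_s * 1e-3  # mm / us

    # The laser alternates wavelengths between consecutive shots, so the
    # k-th 710-nm frame and the k-th 870-nm frame image (nearly) the same
    # absorber distribution: positions are drawn once per shot pair and the
    # mixture is re-stirred (redrawn) between pairs.  Energy and noise are
    # independent per shot.
    frames: list[ChannelFrame] = []
    for k in range(n_frames_per_wavelength):
        u = rng.random(scene.n_sources)
        theta = rng.random(scene.n_sources) * 2.0 * np.pi
        r = radius * np.sqrt(u)
        src_ax = center_ax + r * np.sin(theta)
        src_lat = center_lat + r * np.cos(theta)
        r_fiber = np.hypot(src_ax - fiber_ax, src_lat - fiber_lat)
        d = np.hypot(
            src_ax[:, None], src_lat[:, None] - elem_lat[None, :]
        )  # (n_src, n_el) mm
        tau = d / c_mm_per_us  # (n_src, n_el) us
        arg = t_us[None, None, :] - tau[:, :, None]
        for wavelength in VALID_WAVELENGTHS:
            mu = effective_absorption(models, c, wavelength)
            f_c, sigma_t = _pulse_parameters(
                models, c, wavelength, scene.frequency_shift_exponent
            )
            energy = sample_energies(
                rng, 1, scene.energy_mean_mj, scene.energy_sd_mj
            )[0]
            fluence = (
                energy
                * np.exp(-mu * r_fiber)
                / np.maximum(r_fiber, scene.r0_mm) ** 2
            )
            amp = (fluence * mu)[:, None] / np.maximum(d, scene.r0_mm)
            pulse = np.exp(-(arg**2) / (2.0 * sigma_t**2)) * np.cos(
                2.0 * np.pi * f_c * arg
            )
            rf = (amp[:, :, None] * pulse).sum(axis=0).T  # (n_samp, n_el)
            if scene.noise_sd > 0 and np.any(rf):
                rf = rf + rng.normal(
                    0.0, scene.noise_sd * np.abs(rf).max(), size=rf.shape
                )
            frames.append(
                ChannelFrame(
                    rf=rf,
                    optical_wavelength=wavelength,
                    trial_id=trial_id,
                    frame_id=k,
                    laser_energy_mj=energy,
                )
            )
    return ChannelFrameSet(
        frames=frames, geometry=geom, ground_truth_fraction=c
    )


def generate_study(
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    n_trials: int = 5,
    *,
    scene: PhantomScene | None = None,
    geom: AcquisitionGeometry | None = None,
    models: tuple[ChromophoreModel, ChromophoreModel] | None = None,
    n_frames_per_wavelength: int = 10,
    n_samples: int | None = None,
    seed: int = 0,
) -> list[ChannelFrameSet]:
    """Simulate a full study: one frameset per (concentration, trial).

    Per-trial seeds are spawned deterministically from the master seed, so
    two different master seeds give different data and the same master seed
    reproduces the study bit-exactly.
    """
    concentrations = list(concentrations)
    if not concentrations:
        raise ValueError("no concentrations given")
    if scene is None:
        scene = PhantomScene()
    children = np.random.SeedSequence(seed).spawn(len(concentrations) * n_trials)
    sets: list[ChannelFrameSet] = []
    i = 0
    for c in concentrations:
        for trial in range(n_trials):
            sets.append(
                simulate_trial(
                    replace(scene, mb_fraction=float(c)),
                    geom=geom,
                    models=models,
                    n_frames_per_wavelength=n_frames_per_wavelength,
                    seed=np.random.default_rng(children[i]),
                    n_samples=n_samples,
                    trial_id=trial,
                )
            )
            i += 1
    return sets
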