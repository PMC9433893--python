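"""Domain types and array-container I/O for dual-wavelength photoacoustic data.

The package operates on raw radiofrequency (RF) channel data recorded by a
linear ultrasound array after pulsed-laser excitation at two optical
wavelengths (710 and 870 nm).  A :class:`ChannelFrameSet` bundles the
per-frame channel data of one acquisition trial with the acquisition
geometry and an optional ground-truth methylene-blue volume fraction, and is
persisted in a single self-describing HDF5 container so that multi-frame,
multi-wavelength sets travel as one file.

Conventions
-----------
* axial index 0 is the transducer face; depth increases with row index;
* all indices are 0-based, ranges half-open;
* the image grid places axial rows at the RF-sample spacing
  ``c / (2 fs)`` and lateral columns at the element pitch.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np

__all__ = [
    "VALID_WAVELENGTHS",
    "FormatError",
    "AcquisitionGeometry",
    "ChannelFrame",
    "ChannelFrameSet",
    "BeamformedImage",
    "read_frameset",
    "write_frameset",
    "validate_container",
]

#: Optical wavelengths (nm) supported by the two-wavelength method.
VALID_WAVELENGTHS = (710, 870)

_FORMAT_NAME = "paatlas-frameset"
_FORMAT_VERSION = 1

_GEOMETRY_FIELDS = (
    "n_elements",
    "element_pitch_mm",
    "sampling_frequency_mhz",
    "speed_of_sound_m_s",
    "transducer_center_frequency_mhz",
    "axial_spacing_mm",
    "lateral_spacing_mm",
)

_FRAME_ATTRS = ("optical_wavelength", "trial_id", "frame_id", "laser_energy_mj")


class FormatError(ValueError):
    """Raised when an on-disk container is missing required structure."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Linear-array acquisition geometry and derived image-grid spacings.

    Defaults describe a 128-element, 0.3-mm-pitch linear probe with a
    5.5-MHz center frequency sampled at 40 MHz in 1540 m/s medium.  When
    ``axial_spacing_mm`` is omitted it is derived from the RF sampling as
    ``c / (2 fs)``; ``lateral_spacing_mm`` defaults to the element pitch.
    """

    n_elements: int = 128
    element_pitch_mm: float = 0.3
    sampling_frequency_mhz: float = 40.0
    speed_of_sound_m_s: float = 1540.0
    transducer_center_frequency_mhz: float = 5.5
    axial_spacing_mm: float = None  # type: ignore[assignment]
    lateral_spacing_mm: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if int(self.n_elements) <= 0:
            raise ValueError("n_elements must be positive")
        object.__setattr__(self, "n_elements", int(self.n_elements))
        for name in _GEOMETRY_FIELDS[1:5]:
            if float(getattr(self, name)) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")
        if self.axial_spacing_mm is None:
            object.__setattr__(
                self, "axial_spacing_mm", self.rf_derived_axial_spacing_mm
            )
        if self.lateral_spacing_mm is None:
            object.__setattr__(self, "lateral_spacing_mm", self.element_pitch_mm)
        for name in ("axial_spacing_mm", "lateral_spacing_mm"):
            if float(getattr(self, name)) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def rf_derived_axial_spacing_mm(self) -> float:
        """Axial pixel spacing implied by the RF sampling, c / (2 fs), in mm."""
        return self.speed_of_sound_m_s / (2.0 * self.sampling_frequency_mhz) * 1e-3

    @property
    def has_rf_derived_axial_spacing(self) -> bool:
        return bool(
            np.isclose(self.axial_spacing_mm, self.rf_derived_axial_spacing_mm)
        )

    @property
    def aperture_mm(self) -> float:
        return (self.n_elements - 1) * self.element_pitch_mm

    @property
    def image_sampling_mhz(self) -> float:
        """One-way temporal sampling rate along image rows (c / axial spacing)."""
        return self.speed_of_sound_m_s / (self.axial_spacing_mm * 1e-3) * 1e-6

    def element_positions_mm(self) -> np.ndarray:
        return np.arange(self.n_elements) * self.element_pitch_mm

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in _GEOMETRY_FIELDS}


@dataclass
class ChannelFrame:
    """One RF frame: [axial sample x element] data for a single laser shot."""

    rf: np.ndarray
    optical_wavelength: int
    trial_id: int = 0
    frame_id: int = 0
    laser_energy_mj: float = 3.0

    def __post_init__(self) -> None:
        self.rf = np.asarray(self.rf, dtype=np.float64)
        if self.rf.ndim != 2:
            raise ValueError("rf must be a 2-D [axial sample x element] array")
        self.optical_wavelength = int(self.optical_wavelength)
        if self.optical_wavelength not in VALID_WAVELENGTHS:
            raise ValueError(
                f"optical_wavelength must be one of {VALID_WAVELENGTHS}, "
                f"got {self.optical_wavelength}"
            )

    @property
    def n_samples(self) -> int:
        return self.rf.shape[0]

    @property
    def n_elements(self) -> int:
        return self.rf.shape[1]


@dataclass
class ChannelFrameSet:
    """All frames of one trial plus geometry and an optional ground-truth label.

    ``ground_truth_fraction`` is the methylene-blue volume fraction of the
    imaged mixture (k/100 for a k% MB mixture), or ``None`` when unknown.
    """

    frames: Sequence[ChannelFrame]
    geometry: AcquisitionGeometry
    ground_truth_fraction: float | None = None

    def __post_init__(self) -> None:
        self.frames = tuple(self.frames)
        for fr in self.frames:
            if fr.n_elements != self.geometry.n_elements:
                raise ValueError(
                    f"frame has {fr.n_elements} elements, geometry declares "
                    f"{self.geometry.n_elements}"
                )
        if self.ground_truth_fraction is not None:
            gt = float(self.ground_truth_fraction)
            if not 0.0 <= gt <= 1.0:
                raise ValueError("ground_truth_fraction must lie in [0, 1]")
            self.ground_truth_fraction = gt

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def wavelengths(self) -> tuple[int, ...]:
        return tuple(sorted({fr.optical_wavelength for fr in self.frames}))

    def frames_at(self, wavelength: int) -> list[ChannelFrame]:
        """Frames of one optical wavelength, ordered by frame id."""
        sel = [fr for fr in self.frames if fr.optical_wavelength == wavelength]
        return sorted(sel, key=lambda fr: fr.frame_id)

    def require_both_wavelengths(self) -> None:
        present = self.wavelengths()
        if set(present) != set(VALID_WAVELENGTHS):
            raise ValueError(
                f"frameset must contain both wavelengths {VALID_WAVELENGTHS}, "
                f"found {present}"
            )


@dataclass
class BeamformedImage:
    """A beamformed image on the axial x lateral pixel grid.

    ``kind`` is ``"amplitude"`` for envelope-detected delay-and-sum images and
    ``"coherence"`` for (M-weighted) short-lag spatial coherence images, whose
    normalized values lie in [-1, 1].
    """

    pixels: np.ndarray
    kind: str
    axial_spacing_mm: float
    lateral_spacing_mm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D [axial x lateral] array")
        if self.kind not in ("amplitude", "coherence"):
            raise ValueError("kind must be 'amplitude' or 'coherence'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def write_frameset(
    fs: ChannelFrameSet, path: str | Path, *, overwrite: bool = False
) -> None:
    """Write a frameset to a self-describing HDF5 container.

    Refuses to clobber an existing file unless ``overwrite`` is set.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = _FORMAT_NAME
        h5.attrs["format_version"] = _FORMAT_VERSION
        if fs.ground_truth_fraction is not None:
            h5.attrs["ground_truth_fraction"] = fs.ground_truth_fraction
        geo = h5.create_group("geometry")
        for name, value in fs.geometry.to_dict().items():
            geo.attrs[name] = value
        frames = h5.create_group("frames")
        for i, fr in enumerate(fs.frames):
            grp = frames.create_group(f"{i:05d}")
            grp.create_dataset("rf", data=fr.rf)
            grp.attrs["optical_wavelength"] = fr.optical_wavelength
            grp.attrs["trial_id"] = fr.trial_id
            grp.attrs["frame_id"] = fr.frame_id
            grp.attrs["laser_energy_mj"] = fr.laser_energy_mj


def read_frameset(path: str | Path) -> ChannelFrameSet:
    """Read a container written by :func:`write_frameset`.

    Round-trips metadata bit-exactly and RF arrays at full precision; raises
    :class:`FormatError` naming the first missing field.
    """
    path = Path(path)
    with h5py.File(path, "r") as h5:
        if "geometry" not in h5:
            raise FormatError(f"{path}: missing 'geometry' group")
        geo_attrs = h5["geometry"].attrs
        geo_kwargs = {}
        for name in _GEOMETRY_FIELDS:
            if name not in geo_attrs:
                raise FormatError(f"{path}: geometry attribute '{name}' missing")
            geo_kwargs[name] = geo_attrs[name]
        geometry = AcquisitionGeometry(**geo_kwargs)
        if "frames" not in h5 or len(h5["frames"]) == 0:
            raise FormatError(f"{path}: no frames")
        frames = []
        for key in sorted(h5["frames"], key=int):
            grp = h5["frames"][key]
            if "rf" not in grp:
                raise FormatError(f"{path}: frame {key} has no 'rf' dataset")
            for attr in _FRAME_ATTRS:
                if attr not in grp.attrs:
                    raise FormatError(
                        f"{path}: frame {key} attribute '{attr}' missing"
                    )
            frames.append(
                ChannelFrame(
                    rf=grp["rf"][()],
                    optical_wavelength=int(grp.attrs["optical_wavelength"]),
                    trial_id=int(grp.attrs["trial_id"]),
                    frame_id=int(grp.attrs["frame_id"]),
                    laser_energy_mj=float(grp.attrs["laser_energy_mj"]),
                )
            )
        gt = h5.attrs.get("ground_truth_fraction")
        return ChannelFrameSet(
            frames=frames,
            geometry=geometry,
            ground_truth_fraction=None if gt is None else float(gt),
        )


def validate_container(path: str | Path) -> dict:
    """Validate a container and return a small summary (for the CLI)."""
    fs = read_frameset(path)
    return {
        "path": str(path),
        "n_frames": fs.n_frames,
        "wavelengths": list(fs.wavelengths()),
        "n_elements": fs.geometry.n_elements,
        "n_samples": fs.frames[0].n_samples if fs.frames else 0,
        "ground_truth_fraction": fs.ground_truth_fraction,
    }
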