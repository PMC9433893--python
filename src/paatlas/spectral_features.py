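"""Acoustic-spectrum feature extraction.

The mixture estimator discriminates chromophores through the *acoustic*
frequency content of their photoacoustic response: the fiber-tip fluence
decays radially, so different absorbers excite differently sized volumes and
emit pulses with different spectra.  Features are built per pixel by

1. IQ-demodulating the beamformed RF image (mix down at 2.75 MHz, low-pass
   at 85% fractional bandwidth — the band where the photoacoustic content
   resides, well below the 5.5-MHz transducer center frequency);
2. taking windowed power spectra of a sliding axial kernel centered on each
   coherence-masked pixel;
3. concatenating the 710-nm and 870-nm spectra of the same pixel along the
   frequency axis, normalizing the concatenated row to its own maximum and
   log-compressing to a fixed dynamic range;
4. reducing dimensionality with mean-centered PCA fitted once on the pooled
   pure-class training rows.

Normalization is applied to the concatenated dual-wavelength row (not per
wavelength block) so that the relative 710-vs-870 amplitude, which carries
the optical-absorption contrast between methylene blue and hemoglobin,
survives compression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import filtfilt, firwin
from sklearn.decomposition import PCA

from .beamforming import CoherenceMask

__all__ = [
    "SpectraStack",
    "FeatureMatrix",
    "iq_demodulate",
    "kernel_spectra",
    "stack_and_compress",
    "fit_pca",
    "project",
]


@dataclass
class SpectraStack:
    """Log-compressed dual-wavelength power spectra, one row per (pixel,
    frame pair).

    ``values`` has ``2 x n_bins_per_wavelength`` columns: the 710-nm block
    followed by the 870-nm block.  Every value lies in
    ``[-dynamic_range_db, 0]`` (each row is normalized to its own maximum).
    """

    values: np.ndarray
    dynamic_range_db: float
    kernel_mm: float | None = None
    pixel_index: np.ndarray | None = None  # (n, 2) [axial, lateral]
    frame_id: np.ndarray | None = None  # (n,)
    wavelength_order: tuple[int, int] = (710, 870)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D [row x stacked frequency bin]")
        if self.dynamic_range_db <= 0:
            raise ValueError("dynamic_range_db must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureMatrix:
    """PCA feature space: orthonormal loading basis, training mean and the
    projected training rows."""

    basis: np.ndarray  # (n_bins, p), orthonormal columns
    mean_spectrum: np.ndarray  # (n_bins,)
    projected: np.ndarray  # (n_rows, p)
    p: int

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=np.float64)
        self.mean_spectrum = np.asarray(self.mean_spectrum, dtype=np.float64)
        self.projected = np.asarray(self.projected, dtype=np.float64)
        if self.basis.shape[1] != self.p or self.p < 1:
            raise ValueError("basis must have p >= 1 columns")
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(self.p), atol=1e-8):
            raise ValueError("basis columns must be orthonormal")


def iq_demodulate(
    rf: np.ndarray,
    fs_mhz: float,
    f_mod_mhz: float = 2.75,
    bandwidth_fraction: float = 0.85,
    *,
    axis: int = 0,
    numtaps: int | None = None,
) -> np.ndarray:
    """Complex baseband (IQ) conversion of real RF data.

    Mixes down by ``f_mod_mhz`` and low-passes at
    ``bandwidth_fraction * f_mod / 2`` with a zero-phase FIR filter; the
    sample count is preserved (no decimation).
    """
    rf = np.asarray(rf, dtype=np.float64)
    if not 0.0 < f_mod_mhz < fs_mhz / 2.0:
        raise ValueError(
            f"modulation frequency {f_mod_mhz} MHz must lie in (0, Nyquist "
            f"= {fs_mhz / 2.0} MHz)"
        )
    if not 0.0 < bandwidth_fraction <= 2.0:
        raise ValueError("bandwidth_fraction must lie in (0, 2]")
    n = rf.shape[axis]
    if numtaps is None:
        # filtfilt needs > 3*numtaps samples for its default edge padding
        numtaps = min(101, max(9, ((n - 2) // 3) | 1))
    t_us = np.arange(n) / fs_mhz
    mixer = np.exp(-2j * np.pi * f_mod_mhz * t_us)
    shape = [1] * rf.ndim
    shape[axis] = n
    mixed = rf * mixer.reshape(shape)
    cutoff = bandwidth_fraction * f_mod_mhz / 2.0
    taps = firwin(numtaps, cutoff, fs=fs_mhz)
    return 2.0 * filtfilt(taps, 1.0, mixed, axis=axis)


def kernel_mm_to_samples(kernel_mm: float, axial_spacing_mm: float) -> int:
    """Axial kernel length in image rows (minimum 4)."""
    return max(4, int(round(kernel_mm / axial_spacing_mm)))


def kernel_spectra(
    iq: np.ndarray,
    mask: CoherenceMask | np.ndarray,
    kernel_mm: float,
    axial_spacing_mm: float,
    stride: int = 1,
    *,
    n_bins: int = 128,
) -> tuple[np.ndarray, np.ndarray]:
    """Power spectra of sliding axial kernels centered on masked pixels.

    For each masked pixel whose full kernel fits inside the image (and whose
    row index is a multiple of ``stride``), the centered axial segment of IQ
    data is Hann-windowed and its power spectrum (squared DFT magnitude,
    zero-padded to ``n_bins`` and fftshifted) forms one row.

    Returns ``(power, pixel_index)`` with shapes ``(n, n_bins)`` and
    ``(n, 2)``.
    """
    iq = np.asarray(iq)
    if iq.ndim != 2:
        raise ValueError("iq must be a 2-D [axial x lateral] image")
    m = mask.mask if isinstance(mask, CoherenceMask) else np.asarray(mask, bool)
    if m.shape != iq.shape:
        raise ValueError("mask shape does not match image")
    K = kernel_mm_to_samples(kernel_mm, axial_spacing_mm)
    half = K // 2
    n_rows = iq.shape[0]
    lo, hi = half, n_rows - (K - half)  # centers with a full in-image kernel
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if not m.any():
        return (
            np.empty((0, n_bins), dtype=np.float64),
            np.empty((0, 2), dtype=np.intp),
        )
    eligible = np.zeros_like(m)
    eligible[lo : hi + 1 : stride] = True
    rows, cols = np.nonzero(m & eligible)
    if rows.size == 0:
        raise ValueError(
            f"the {K}-sample kernel extends beyond the image for every "
            "masked pixel"
        )
    window = np.hanning(K)
    sw = np.lib.stride_tricks.sliding_window_view(iq, K, axis=0)
    segments = sw[rows - half, cols]  # (n, K)
    spectra = np.fft.fftshift(np.fft.fft(segments * window, n=n_bins, axis=1),
                              axes=1)
    power = np.abs(spectra) ** 2
    return power, np.column_stack([rows, cols]).astype(np.intp)


def stack_and_compress(
    spec710: np.ndarray,
    spec870: np.ndarray,
    dynamic_range_db: float = 60.0,
    *,
    kernel_mm: float | None = None,
    pixel_index: np.ndarray | None = None,
    frame_id: np.ndarray | None = None,
) -> SpectraStack:
    """Concatenate per-wavelength power-spectrum rows (710 block then 870
    block), normalize each concatenated row to its own maximum, log-compress
    (10 log10) and floor at ``-dynamic_range_db``."""
    spec710 = np.atleast_2d(np.asarray(spec710, dtype=np.float64))
    spec870 = np.atleast_2d(np.asarray(spec870, dtype=np.float64))
    if spec710.shape != spec870.shape:
        raise ValueError("per-wavelength spectra must have matching shapes")
    stacked = np.concatenate([spec710, spec870], axis=1)
    row_max = stacked.max(axis=1)
    if np.any(row_max <= 0):
        raise ValueError("all-zero spectrum row: no normalizer")
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(stacked / row_max[:, None])
    db = np.maximum(db, -float(dynamic_range_db))
    return SpectraStack(
        values=db,
        dynamic_range_db=float(dynamic_range_db),
        kernel_mm=kernel_mm,
        pixel_index=pixel_index,
        frame_id=frame_id,
    )


def _as_values(x: SpectraStack | np.ndarray) -> np.ndarray:
    if isinstance(x, SpectraStack):
        return x.values
    return np.atleast_2d(np.asarray(x, dtype=np.float64))


def fit_pca(training: SpectraStack | np.ndarray, p: int = 1) -> FeatureMatrix:
    """Mean-centered PCA of the training rows.

    The basis holds the top-``p`` loading vectors by explained variance with
    a deterministic sign convention (the largest-magnitude element of each
    loading is positive); the projected rows are the centered training data
    in that basis.
    """
    X = _as_values(training)
    n, d = X.shape
    if p < 1:
        raise ValueError("p must be >= 1")
    if n < p + 1:
        raise ValueError(f"need at least p + 1 = {p + 1} rows, got {n}")
    if p > d:
        raise ValueError("p exceeds the number of frequency bins")
    pca = PCA(n_components=p, svd_solver="full")
    scores = pca.fit_transform(X)
    ev = pca.explained_variance_
    scale = max(ev[0], 1e-30)
    if ev[p - 1] <= 1e-12 * scale:
        raise ValueError(f"p = {p} exceeds the rank of the training data")
    basis = pca.components_.T.copy()  # (d, p)
    for k in range(p):
        i = np.argmax(np.abs(basis[:, k]))
        if basis[i, k] < 0:
            basis[:, k] *= -1.0
            scores[:, k] *= -1.0
    return FeatureMatrix(
        basis=basis,
        mean_spectrum=pca.mean_.copy(),
        projected=scores,
        p=p,
    )


def project(x: SpectraStack | np.ndarray, fm: FeatureMatrix) -> np.ndarray:
    """Project rows into the PCA feature space: (x - mean) @ basis."""
    X = _as_values(x)
    if X.shape[1] != fm.basis.shape[0]:
        raise ValueError(
            f"row length {X.shape[1]} does not match basis with "
            f"{fm.basis.shape[0]} bins"
        )
    return (X - fm.mean_spectrum) @ fm.basis
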