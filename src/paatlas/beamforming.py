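"""Beamforming and coherence masking.

Photoacoustic reconstruction here is receive-only: a source at depth ``z``
arrives at an element after the one-way travel time ``d / c``, so
delay-and-sum (DAS) aligns channels with one-way delays before summation and
envelope detection.  Short-lag spatial coherence (SLSC) replaces the sum by
the normalized cross-correlation of delayed channel pairs, averaged over all
pairs at each element separation (lag) m and summed over lags 1..M; the
M-weighted variant down-weights higher lags so that the short lags, which
carry most of the coherent-target information, dominate and the resulting
binary masks are less disjointed.

Coherence images thresholded either relative to their own maximum (dB mode,
-3 dB default) or at an absolute coherence value segment the coherent
photoacoustic signal; per-trial masks are the inclusive OR over all frames
and both optical wavelengths, and masks are compared with the Dice
coefficient.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert

from .core_io import AcquisitionGeometry, BeamformedImage, ChannelFrame

__all__ = [
    "CoherenceMask",
    "aligned_channel_cube",
    "das_rf_image",
    "das_image",
    "lag_coherence_images",
    "combine_lag_images",
    "triangular_lag_weights",
    "slsc_image",
    "mweighted_slsc_image",
    "default_correlation_kernel",
    "make_mask",
    "merge_masks",
    "dice",
    "select_M",
]


@dataclass
class CoherenceMask:
    """Binary segmentation obtained by thresholding a coherence image."""

    mask: np.ndarray
    threshold_mode: str  # "db" | "absolute"
    threshold_value: float
    source_frames: int = 1

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.threshold_mode not in ("db", "absolute"):
            raise ValueError("threshold_mode must be 'db' or 'absolute'")

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


# ---------------------------------------------------------------------------
# Channel alignment and DAS
# ---------------------------------------------------------------------------

def _delay_table(
    geom: AcquisitionGeometry, n_rows: int, n_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """One-way delay (in RF samples, nearest-neighbour) per row and lateral
    element offset.  Returns ``(index, valid)`` arrays of shape
    ``(n_rows, n_elements)`` where offset k means |column - element| = k.
    """
    z = np.arange(n_rows) * geom.axial_spacing_mm  # mm
    dx = np.arange(geom.n_elements) * geom.element_pitch_mm  # mm
    dist_mm = np.sqrt(z[:, None] ** 2 + dx[None, :] ** 2)
    samples = dist_mm * 1e-3 / geom.speed_of_sound_m_s * geom.sampling_frequency_mhz * 1e6
    idx = np.rint(samples).astype(np.intp)
    valid = idx < n_samples
    idx[~valid] = 0
    return idx, valid


def _default_n_rows(geom: AcquisitionGeometry, n_samples: int) -> int:
    # Deepest on-axis pixel that maps inside the recording: depth i * dz needs
    # RF sample i * dz * fs / c, which is i/2 on the RF-derived grid.
    depth_mm = (n_samples - 1) * geom.speed_of_sound_m_s / (
        geom.sampling_frequency_mhz * 1e6
    ) * 1e3
    return int(depth_mm / geom.axial_spacing_mm) + 1


def aligned_channel_cube(
    frame: ChannelFrame,
    geom: AcquisitionGeometry,
    n_rows: int | None = None,
) -> np.ndarray:
    """Delay-align channel data to every pixel of the image grid.

    Returns a float32 cube of shape ``(n_rows, n_columns, n_elements)`` where
    entry (i, j, e) is the RF sample of element e at the one-way arrival time
    of pixel (i, j).  Out-of-recording delays are zero-filled.  Lateral
    columns coincide with element positions.
    """
    if frame.rf.size == 0:
        raise ValueError("rf is empty")
    n_samples, n_el = frame.rf.shape
    if n_el != geom.n_elements:
        raise ValueError("frame element count does not match geometry")
    max_rows = _default_n_rows(geom, n_samples)
    if n_rows is None:
        n_rows = max_rows
    elif n_rows > max_rows:
        raise ValueError(
            f"pixel grid of {n_rows} rows is deeper than the {n_samples} "
            "recorded samples"
        )
    idx, valid = _delay_table(geom, n_rows, n_samples)
    rf32 = frame.rf.astype(np.float32)
    elements = np.arange(n_el)
    cube = np.empty((n_rows, n_el, n_el), dtype=np.float32)
    for j in range(n_el):
        k = np.abs(j - elements)
        col_idx = idx[:, k]  # (n_rows, n_el)
        a = np.take_along_axis(rf32, col_idx, axis=0)
        a[~valid[:, k]] = 0.0
        cube[:, j, :] = a
    return cube


def das_rf_image(
    frame: ChannelFrame,
    geom: AcquisitionGeometry,
    n_rows: int | None = None,
    cube: np.ndarray | None = None,
) -> np.ndarray:
    """Delayed-and-summed RF image (before envelope detection), float64."""
    if cube is None:
        cube = aligned_channel_cube(frame, geom, n_rows)
    return cube.sum(axis=2, dtype=np.float64)


def das_image(
    frame: ChannelFrame,
    geom: AcquisitionGeometry,
    n_rows: int | None = None,
    cube: np.ndarray | None = None,
) -> BeamformedImage:
    """Conventional DAS amplitude image: envelope of the summed channels."""
    rf_img = das_rf_image(frame, geom, n_rows, cube)
    if np.any(rf_img):
        env = np.abs(hilbert(rf_img, axis=0))
    else:
        env = np.zeros_like(rf_img)
    return BeamformedImage(
        pixels=env,
        kind="amplitude",
        axial_spacing_mm=geom.axial_spacing_mm,
        lateral_spacing_mm=geom.lateral_spacing_mm,
    )


# ---------------------------------------------------------------------------
# Spatial coherence
# ---------------------------------------------------------------------------

def default_correlation_kernel(geom: AcquisitionGeometry) -> int:
    """Axial correlation kernel: one acoustic wavelength at the transducer
    center frequency, expressed in image rows (minimum 4)."""
    wavelength_mm = geom.speed_of_sound_m_s / (
        geom.transducer_center_frequency_mhz * 1e6
    ) * 1e3
    return max(4, int(round(wavelength_mm / geom.axial_spacing_mm)))


def _lag_coherence_numpy(cube: np.ndarray, M: int, corr_kernel: int) -> np.ndarray:
    """Reference (pure numpy) per-lag coherence; see lag_coherence_images."""
    n_rows, n_cols, n_el = cube.shape
    energy = uniform_filter1d(cube * cube, corr_kernel, axis=0, mode="constant")
    out = np.empty((M, n_rows, n_cols), dtype=np.float64)
    tiny = np.finfo(np.float32).tiny
    for m in range(1, M + 1):
        prod = uniform_filter1d(
            cube[:, :, :-m] * cube[:, :, m:], corr_kernel, axis=0, mode="constant"
        )
        denom = np.sqrt(energy[:, :, :-m] * energy[:, :, m:])
        ratio = np.divide(
            prod, denom, out=np.zeros_like(prod), where=denom > tiny
        )
        out[m - 1] = ratio.mean(axis=2, dtype=np.float64)
    return out


try:  # compiled fast path; the numpy path is the behavioural reference
    import numba as _nb

    @_nb.njit(cache=True, fastmath=True)
    def _lag_coherence_jit(cube_t, M, K):  # pragma: no cover - exercised via wrapper
        C, E, R = cube_t.shape
        out = np.zeros((M, C, R), dtype=np.float64)
        half = K // 2
        cs_ab = np.empty(R + 1, dtype=np.float64)
        cs_e = np.empty((E, R + 1), dtype=np.float64)
        for c in range(C):
            for e in range(E):
                s = 0.0
                cs_e[e, 0] = 0.0
                for r in range(R):
                    v = cube_t[c, e, r]
                    s += v * v
                    cs_e[e, r + 1] = s
            for m in range(1, M + 1):
                for e in range(E - m):
                    a = cube_t[c, e]
                    b = cube_t[c, e + m]
                    s = 0.0
                    cs_ab[0] = 0.0
                    for r in range(R):
                        s += a[r] * b[r]
                        cs_ab[r + 1] = s
                    for r in range(R):
                        lo = r - half
                        hi = lo + K
                        if lo < 0:
                            lo = 0
                        if hi > R:
                            hi = R
                        num = cs_ab[hi] - cs_ab[lo]
                        den = (cs_e[e, hi] - cs_e[e, lo]) * (
                            cs_e[e + m, hi] - cs_e[e + m, lo]
                        )
                        if den > 1e-30:
                            out[m - 1, c, r] += num / np.sqrt(den)
                out[m - 1, c] /= E - m
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def lag_coherence_images(
    cube: np.ndarray, M: int, corr_kernel: int, *, engine: str = "auto"
) -> np.ndarray:
    """Per-lag normalized correlation images c_hat(m), m = 1..M.

    For each pixel and lag m, the normalized cross-correlation of every
    delayed channel pair (e, e+m) is computed over a centered axial window of
    ``corr_kernel`` rows (border windows are clipped) and averaged over the
    available pairs.  Returns an array of shape ``(M, n_rows, n_columns)``.

    ``engine`` is "auto" (compiled kernel when available), "numba" or
    "numpy"; both engines produce the same values to float32 accuracy.
    """
    n_rows, n_cols, n_el = cube.shape
    if not 1 <= M < n_el:
        raise ValueError(f"M must satisfy 1 <= M < n_elements ({n_el})")
    if corr_kernel < 2:
        raise ValueError("corr_kernel must be >= 2")
    use_numba = _HAVE_NUMBA if engine == "auto" else engine == "numba"
    if use_numba:
        cube_t = np.ascontiguousarray(np.transpose(cube, (1, 2, 0)))
        out = _lag_coherence_jit(cube_t.astype(np.float32), M, int(corr_kernel))
        return np.transpose(out, (0, 2, 1)).copy()
    return _lag_coherence_numpy(np.asarray(cube, dtype=np.float32), M, corr_kernel)


def combine_lag_images(
    lag_images: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Weighted mean over the lag axis; uniform weights when ``weights`` is
    None (which equals the normalized plain-SLSC sum)."""
    lag_images = np.asarray(lag_images, dtype=np.float64)
    M = lag_images.shape[0]
    if weights is None:
        weights = np.ones(M)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (M,):
        raise ValueError("weights must have one entry per lag")
    if weights.sum() <= 0:
        raise ValueError("weights must sum to a positive value")
    return np.tensordot(weights, lag_images, axes=(0, 0)) / weights.sum()


def triangular_lag_weights(M: int) -> np.ndarray:
    """Linearly decreasing lag weights w_m = M - m + 1, m = 1..M."""
    return np.arange(M, 0, -1, dtype=np.float64)


def _coherence_image(
    pixels: np.ndarray, geom: AcquisitionGeometry
) -> BeamformedImage:
    return BeamformedImage(
        pixels=pixels,
        kind="coherence",
        axial_spacing_mm=geom.axial_spacing_mm,
        lateral_spacing_mm=geom.lateral_spacing_mm,
    )


def slsc_image(
    frame: ChannelFrame,
    geom: AcquisitionGeometry,
    M: int = 5,
    corr_kernel: int | None = None,
    *,
    normalize: bool = True,
    n_rows: int | None = None,
    cube: np.ndarray | None = None,
) -> BeamformedImage:
    """Short-lag spatial coherence image: sum of c_hat(m) over m = 1..M.

    With ``normalize`` (default) the sum is divided by M so values lie in
    [-1, 1]; negative correlations are kept in the sum.
    """
    if corr_kernel is None:
        corr_kernel = default_correlation_kernel(geom)
    if cube is None:
        cube = aligned_channel_cube(frame, geom, n_rows)
    lags = lag_coherence_images(cube, M, corr_kernel)
    pixels = lags.sum(axis=0)
    if normalize:
        pixels = pixels / M
    return _coherence_image(pixels, geom)


def mweighted_slsc_image(
    frame: ChannelFrame,
    geom: AcquisitionGeometry,
    M: int = 20,
    corr_kernel: int | None = None,
    *,
    weights: np.ndarray | None = None,
    n_rows: int | None = None,
    cube: np.ndarray | None = None,
) -> BeamformedImage:
    """M-weighted SLSC image: weighted mean of c_hat(m) with decreasing lag
    weights (triangular by default), so low lags dominate.  Values lie in
    [-1, 1]."""
    if corr_kernel is None:
        corr_kernel = default_correlation_kernel(geom)
    if cube is None:
        cube = aligned_channel_cube(frame, geom, n_rows)
    lags = lag_coherence_images(cube, M, corr_kernel)
    if weights is None:
        weights = triangular_lag_weights(M)
    pixels = combine_lag_images(lags, weights)
    return _coherence_image(pixels, geom)


# ---------------------------------------------------------------------------
# Masks and Dice
# ---------------------------------------------------------------------------

def make_mask(
    coh: BeamformedImage, mode: str = "db", value: float = -3.0
) -> CoherenceMask:
    """Threshold a coherence image into a binary mask.

    dB mode keeps pixels within ``value`` dB of the image's own maximum
    (20 log10 of the ratio, -3 dB default); absolute mode keeps pixels with
    coherence >= ``value`` for value in (0, 1], so negative coherence never
    passes.
    """
    if coh.kind != "coherence":
        raise ValueError("make_mask requires a coherence image")
    pixels = coh.pixels
    if mode == "db":
        mx = pixels.max(initial=-np.inf)
        if mx <= 0:
            mask = np.zeros(pixels.shape, dtype=bool)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                db = 20.0 * np.log10(
                    np.divide(pixels, mx, out=np.zeros_like(pixels, dtype=float),
                              where=pixels > 0),
                )
            db[pixels <= 0] = -np.inf
            mask = db >= value
    elif mode == "absolute":
        if not 0.0 < value <= 1.0:
            raise ValueError("absolute threshold must lie in (0, 1]")
        mask = pixels >= value
    else:
        raise ValueError("mode must be 'db' or 'absolute'")
    return CoherenceMask(mask=mask, threshold_mode=mode, threshold_value=value)


def merge_masks(masks: Sequence[CoherenceMask]) -> CoherenceMask:
    """Per-pixel inclusive OR of masks (the per-trial mask over all frames
    and both wavelengths)."""
    masks = list(masks)
    if not masks:
        raise ValueError("no masks to merge")
    shape = masks[0].shape
    merged = np.zeros(shape, dtype=bool)
    total = 0
    for m in masks:
        if m.shape != shape:
            raise ValueError(f"mask shape {m.shape} != {shape}")
        merged |= m.mask
        total += m.source_frames
    first = masks[0]
    return CoherenceMask(
        mask=merged,
        threshold_mode=first.threshold_mode,
        threshold_value=first.threshold_value,
        source_frames=total,
    )


def dice(a: CoherenceMask, b: CoherenceMask) -> float:
    """Dice similarity between two masks, in percent:
    2 |a AND b| / (|a| + |b|) x 100."""
    if a.shape != b.shape:
        raise ValueError("masks must have identical dimensions")
    na, nb = a.area, b.area
    if na + nb == 0:
        raise ValueError("Dice undefined: both masks are empty")
    overlap = int(np.logical_and(a.mask, b.mask).sum())
    return 200.0 * overlap / (na + nb)


def _select_best(
    candidates: Sequence[int], means: Sequence[float], sds: Sequence[float]
) -> int:
    """Highest mean Dice; ties broken by smaller SD, then smaller M."""
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-means[i], sds[i], candidates[i]),
    )
    return int(candidates[order[0]])


def select_M(
    frames: Sequence[ChannelFrame],
    geom: AcquisitionGeometry,
    M_candidates: Sequence[int] = tuple(range(10, 31)),
    *,
    reference_M: int = 5,
    corr_kernel: int | None = None,
    db_threshold: float = -3.0,
    n_rows: int | None = None,
) -> int:
    """Choose the M-weighted SLSC cumulative lag by Dice agreement with
    plain-SLSC reference masks (reference M = 5, -3 dB masks).

    Returns the candidate with the highest mean Dice over the frames; ties
    are broken by smaller standard deviation, then smaller M.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame collection")
    candidates = list(M_candidates)
    if not candidates:
        raise ValueError("no candidate M values")
    if corr_kernel is None:
        corr_kernel = default_correlation_kernel(geom)
    max_lag = max(max(candidates), reference_M)
    scores: dict[int, list[float]] = {M: [] for M in candidates}
    for frame in frames:
        cube = aligned_channel_cube(frame, geom, n_rows)
        lags = lag_coherence_images(cube, max_lag, corr_kernel)
        ref = make_mask(
            _coherence_image(combine_lag_images(lags[:reference_M]), geom),
            "db",
            db_threshold,
        )
        for M in candidates:
            cand = make_mask(
                _coherence_image(
                    combine_lag_images(lags[:M], triangular_lag_weights(M)), geom
                ),
                "db",
                db_threshold,
            )
            scores[M].append(dice(ref, cand))
    means = [float(np.mean(scores[M])) for M in candidates]
    sds = [float(np.std(scores[M])) for M in candidates]
    return _select_best(candidates, means, sds)
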