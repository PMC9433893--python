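"""Atlas construction and per-pixel mixture estimation.

The dual-wavelength atlas consists of PCA feature samples of *pure*
concentrations: one trial of 100% Hb and one of 100% MB, pushed through the
same beamform -> coherence mask -> dual-wavelength spectra -> PCA pipeline.
A test feature x is regressed against randomly drawn atlas pairs
(MB_i, Hb_i):

    C'_i = 1/2 + (||x - Hb_i||_1 - ||x - MB_i||_1) / (2 ||Hb_i - MB_i||_1)

clamped to [0, 1], under the assumption that mixture spectra are linear
combinations of the pure-class spectra.  The N-draw distribution C' is
reduced by a histogram filter (mean of the most populated of 10 equal-width
bins on [0, 1]), repeated for every masked pixel and frame, and the
resulting concentration tensor is reduced to a 2-D map by a median filter
of 0.64 mm x 0.70 mm x 30 frames (a frame kernel at least as large as the
frame count collapses the frame axis entirely).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .beamforming import (
    CoherenceMask,
    aligned_channel_cube,
    das_rf_image,
    make_mask,
    merge_masks,
    mweighted_slsc_image,
)
from .core_io import AcquisitionGeometry, BeamformedImage, ChannelFrameSet
from .metrics import mae, r_squared_one_to_one
from .spectral_features import (
    FeatureMatrix,
    SpectraStack,
    fit_pca,
    iq_demodulate,
    kernel_spectra,
    project,
    stack_and_compress,
)

__all__ = [
    "EstimatorConfig",
    "Atlas",
    "ConcentrationMap",
    "TrialComputation",
    "beamform_trial",
    "trial_mask",
    "build_atlas",
    "concentration_distribution",
    "histogram_filter",
    "estimate_map",
    "median_filter_tensor",
    "parameter_sweep",
    "threshold_sweep",
    "save_atlas",
    "load_atlas",
]

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class EstimatorConfig:
    """All tunable parameters of the atlas pipeline.

    Defaults follow the method's reference configuration: M-weighted SLSC
    with cumulative lag 20, absolute coherence threshold 0.7, IQ
    demodulation at 2.75 MHz with 85% bandwidth, 1.8-mm axial spectral
    kernel, 60-dB log-compression dynamic range, a single principal
    component, N = 1000 atlas draws, 10 histogram bins and a
    0.64 x 0.70 mm x 30-frame median kernel.
    """

    M: int = 20
    mask_mode: str = "absolute"  # "absolute" | "db"
    mask_threshold: float = 0.7
    slsc_corr_kernel: int | None = None  # None -> one wavelength at f_center
    f_mod_mhz: float = 2.75
    bandwidth_fraction: float = 0.85
    kernel_mm: float = 1.8
    dynamic_range_db: float = 60.0
    n_components: int = 1
    n_draws: int = 1000
    n_bins: int = 10
    median_axial_mm: float = 0.64
    median_lateral_mm: float = 0.70
    median_frames: int = 30
    stride: int = 1
    n_bins_spectrum: int = 128
    n_rows: int | None = None  # image rows; None -> full recorded depth

    def to_dict(self) -> dict:
        return {
            k: v for k, v in self.__dict__.items()
        }


@dataclass
class Atlas:
    """PCA basis plus projected pure-class feature samples."""

    fm: FeatureMatrix
    mb_rows: np.ndarray  # (n_MB, p)
    hb_rows: np.ndarray  # (n_Hb, p)
    config: EstimatorConfig

    def __post_init__(self) -> None:
        self.mb_rows = np.atleast_2d(np.asarray(self.mb_rows, dtype=np.float64))
        self.hb_rows = np.atleast_2d(np.asarray(self.hb_rows, dtype=np.float64))
        if self.mb_rows.shape[1] != self.hb_rows.shape[1]:
            raise ValueError("MB and Hb rows must share the feature dimension")

    @property
    def class_separation(self) -> float:
        """L1 distance between the class means in feature space."""
        return float(
            np.abs(self.mb_rows.mean(axis=0) - self.hb_rows.mean(axis=0)).sum()
        )


@dataclass
class ConcentrationMap:
    """Per-pixel estimated MB fraction; absent (unmasked) pixels are NaN."""

    c: np.ndarray  # (rows, cols) with NaN outside the mask
    ground_truth: float | None
    axial_spacing_mm: float
    lateral_spacing_mm: float
    tensor: np.ndarray | None = None  # optional (rows, cols, frames) C''

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=np.float64)
        present = self.present_values
        if present.size and (present.min() < 0 or present.max() > 1):
            raise ValueError("concentrations must lie in [0, 1]")

    @property
    def present_values(self) -> np.ndarray:
        return self.c[np.isfinite(self.c)]


# ---------------------------------------------------------------------------
# Per-trial beamforming / feature caches
# ---------------------------------------------------------------------------

@dataclass
class TrialComputation:
    """Cached beamforming products of one trial: per frame the DAS RF image,
    the M-weighted SLSC coherence image and the IQ-demodulated image.
    Frames are ordered (all 710-nm frames by frame id, then all 870-nm)."""

    fset: ChannelFrameSet
    wavelengths: list[int]
    frame_ids: list[int]
    coherence: list[BeamformedImage]
    iq: list[np.ndarray]


def beamform_trial(fset: ChannelFrameSet, cfg: EstimatorConfig) -> TrialComputation:
    """Beamform every frame of a trial once; reused by masks, features and
    the threshold sweep."""
    fset.require_both_wavelengths()
    geom = fset.geometry
    wavelengths, frame_ids, coherence, iqs = [], [], [], []
    image_fs = geom.image_sampling_mhz
    for wl in (710, 870):
        for frame in fset.frames_at(wl):
            cube = aligned_channel_cube(frame, geom, cfg.n_rows)
            coh = mweighted_slsc_image(
                frame, geom, cfg.M, cfg.slsc_corr_kernel, cube=cube
            )
            rf_img = das_rf_image(frame, geom, cube=cube)
            iq = iq_demodulate(
                rf_img, image_fs, cfg.f_mod_mhz, cfg.bandwidth_fraction
            )
            wavelengths.append(wl)
            frame_ids.append(frame.frame_id)
            coherence.append(coh)
            iqs.append(iq)
    return TrialComputation(
        fset=fset,
        wavelengths=wavelengths,
        frame_ids=frame_ids,
        coherence=coherence,
        iq=iqs,
    )


def trial_mask(
    tc: TrialComputation, mode: str, value: float
) -> CoherenceMask:
    """Per-trial mask: inclusive OR of the per-frame masks over all frames
    and both wavelengths."""
    masks = [make_mask(coh, mode, value) for coh in tc.coherence]
    return merge_masks(masks)


def _paired_frames(tc: TrialComputation) -> list[tuple[int, int]]:
    """Indices pairing the q-th 710-nm frame with the q-th 870-nm frame."""
    i710 = [i for i, wl in enumerate(tc.wavelengths) if wl == 710]
    i870 = [i for i, wl in enumerate(tc.wavelengths) if wl == 870]
    return list(zip(i710, i870))


def features_for_trial(
    tc: TrialComputation, mask: CoherenceMask, cfg: EstimatorConfig
) -> SpectraStack:
    """Dual-wavelength spectra stack of a trial under a given mask."""
    geom = tc.fset.geometry
    values, pix, fids = [], [], []
    for q, (a, b) in enumerate(_paired_frames(tc)):
        p710, idx = kernel_spectra(
            tc.iq[a], mask, cfg.kernel_mm, geom.axial_spacing_mm, cfg.stride,
            n_bins=cfg.n_bins_spectrum,
        )
        p870, _ = kernel_spectra(
            tc.iq[b], mask, cfg.kernel_mm, geom.axial_spacing_mm, cfg.stride,
            n_bins=cfg.n_bins_spectrum,
        )
        if p710.shape[0] == 0:
            continue
        stack = stack_and_compress(
            p710, p870, cfg.dynamic_range_db, kernel_mm=cfg.kernel_mm
        )
        values.append(stack.values)
        pix.append(idx)
        fids.append(np.full(idx.shape[0], q, dtype=np.intp))
    if not values:
        raise ValueError("no coherent signal: empty feature stack")
    return SpectraStack(
        values=np.vstack(values),
        dynamic_range_db=cfg.dynamic_range_db,
        kernel_mm=cfg.kernel_mm,
        pixel_index=np.vstack(pix),
        frame_id=np.concatenate(fids),
    )


# ---------------------------------------------------------------------------
# Atlas construction
# ---------------------------------------------------------------------------

def _atlas_from_caches(
    tc_mb: TrialComputation, tc_hb: TrialComputation, cfg: EstimatorConfig
) -> Atlas:
    mask_mb = trial_mask(tc_mb, cfg.mask_mode, cfg.mask_threshold)
    mask_hb = trial_mask(tc_hb, cfg.mask_mode, cfg.mask_threshold)
    if mask_mb.area == 0 or mask_hb.area == 0:
        raise ValueError("no coherent signal: empty coherence mask")
    stack_mb = features_for_trial(tc_mb, mask_mb, cfg)
    stack_hb = features_for_trial(tc_hb, mask_hb, cfg)
    pooled = np.vstack([stack_mb.values, stack_hb.values])
    fm = fit_pca(pooled, cfg.n_components)
    mb_rows = project(stack_mb.values, fm)
    hb_rows = project(stack_hb.values, fm)
    atlas = Atlas(fm=fm, mb_rows=mb_rows, hb_rows=hb_rows, config=cfg)
    spread = 0.5 * (
        np.abs(mb_rows - mb_rows.mean(0)).sum(1).mean()
        + np.abs(hb_rows - hb_rows.mean(0)).sum(1).mean()
    )
    if atlas.class_separation <= 1e-9 * max(spread, 1e-12):
        warnings.warn(
            "degenerate atlas: MB and Hb class means coincide in feature space",
            stacklevel=2,
        )
    return atlas


def build_atlas(
    pure_mb_trial: ChannelFrameSet,
    pure_hb_trial: ChannelFrameSet,
    cfg: EstimatorConfig | None = None,
) -> Atlas:
    """Construct the dual-wavelength atlas from one pure-MB (100%) and one
    pure-Hb (0% MB) trial."""
    if cfg is None:
        cfg = EstimatorConfig()
    tc_mb = beamform_trial(pure_mb_trial, cfg)
    tc_hb = beamform_trial(pure_hb_trial, cfg)
    return _atlas_from_caches(tc_mb, tc_hb, cfg)


# ---------------------------------------------------------------------------
# Mixture estimation
# ---------------------------------------------------------------------------

def _cprime_batch(
    X: np.ndarray,
    mb: np.ndarray,
    hb: np.ndarray,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized C' distributions for many test features.

    ``X`` is (n, p); returns (n, n_draws) clamped to [0, 1].  One MB and one
    Hb atlas row are drawn independently (uniformly, with replacement) per
    entry; degenerate pairs (zero L1 distance) are redrawn up to
    ``_MAX_REDRAWS`` times.
    """
    n = X.shape[0]
    imb = rng.integers(0, mb.shape[0], size=(n, n_draws))
    ihb = rng.integers(0, hb.shape[0], size=(n, n_draws))
    a = mb[imb]  # (n, N, p)
    b = hb[ihb]
    d = np.abs(a - b).sum(axis=2)
    for _ in range(_MAX_REDRAWS):
        bad = d == 0
        if not np.any(bad):
            break
        k = int(bad.sum())
        imb_new = rng.integers(0, mb.shape[0], size=k)
        ihb_new = rng.integers(0, hb.shape[0], size=k)
        a[bad] = mb[imb_new]
        b[bad] = hb[ihb_new]
        d[bad] = np.abs(a[bad] - b[bad]).sum(axis=1)
    if np.any(d == 0):
        raise ValueError(
            "degenerate atlas pairs: ||Hb_i - MB_i||_1 = 0 for every redraw"
        )
    dist_hb = np.abs(X[:, None, :] - b).sum(axis=2)
    dist_mb = np.abs(X[:, None, :] - a).sum(axis=2)
    cprime = 0.5 + (dist_hb - dist_mb) / (2.0 * d)
    return np.clip(cprime, 0.0, 1.0)


def concentration_distribution(
    x: np.ndarray,
    atlas: Atlas,
    n_draws: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """The C' distribution of a single projected test feature: ``n_draws``
    evaluations of the pairwise mixture estimator, each clamped to [0, 1]."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    return _cprime_batch(x[None, :], atlas.mb_rows, atlas.hb_rows, n_draws, rng)[0]


def _histogram_filter_batch(C: np.ndarray, n_bins: int) -> np.ndarray:
    """Row-wise histogram filter: mean of the values in the most populated
    of ``n_bins`` equal-width bins on [0, 1] (ties -> lowest bin index)."""
    n, _ = C.shape
    b = np.minimum((C * n_bins).astype(np.intp), n_bins - 1)
    counts = np.bincount(
        (np.arange(n)[:, None] * n_bins + b).ravel(), minlength=n * n_bins
    ).reshape(n, n_bins)
    best = counts.argmax(axis=1)  # argmax returns the first (lowest) maximum
    sel = b == best[:, None]
    return (C * sel).sum(axis=1) / sel.sum(axis=1)


def histogram_filter(cprime: np.ndarray, n_bins: int = 10) -> float:
    """Reduce a C' vector to the scalar C'': the mean of the most populated
    histogram bin (fixed equal-width bins on [0, 1]; last bin right-closed;
    ties broken toward the lowest bin)."""
    c = np.asarray(cprime, dtype=np.float64).ravel()
    if c.size == 0:
        raise ValueError("empty C' vector")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    return float(_histogram_filter_batch(c[None, :], n_bins)[0])


def _to_odd_pixels(length_mm: float, spacing_mm: float) -> int:
    """mm -> nearest odd pixel count, minimum 1."""
    px = length_mm / spacing_mm
    odd = 2 * int(round((px - 1.0) / 2.0)) + 1
    return max(1, odd)


def median_filter_tensor(
    tensor: np.ndarray, ka: int, kl: int, kf: int
) -> np.ndarray:
    """Reduce a (rows, cols, frames) concentration tensor to a 2-D map by a
    median filter with shrinking (border-clipped) windows; NaN entries are
    ignored.

    The window spans ``ka`` axial pixels, ``kl`` lateral pixels and
    ``min(kf, frames)`` frames centered on the frame axis; a frame kernel at
    least as large as the frame count therefore collapses the frame axis
    completely, which is how the reference configuration (30-frame kernel,
    20 frames) reduces the tensor.  Output pixels whose window holds no
    finite value are NaN.
    """
    t = np.asarray(tensor, dtype=np.float64)
    if t.ndim == 2:
        t = t[:, :, None]
    R, C, F = t.shape
    ka, kl = int(ka) | 1, int(kl) | 1
    kf = min(int(kf), F)
    f0 = (F - kf) // 2
    t = t[:, :, f0 : f0 + kf]
    pad_a, pad_l = ka // 2, kl // 2
    padded = np.pad(
        t, ((pad_a, pad_a), (pad_l, pad_l), (0, 0)), constant_values=np.nan
    )
    out = np.empty((R, C))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        for j in range(C):
            block = padded[:, j : j + kl, :]  # (R + 2 pad_a, kl, kf)
            sw = np.lib.stride_tricks.sliding_window_view(
                block, ka, axis=0
            )  # (R, kl, kf, ka)
            out[:, j] = np.nanmedian(sw.reshape(R, -1), axis=1)
    return out


def _estimate_from_cache(
    tc: TrialComputation,
    atlas: Atlas,
    cfg: EstimatorConfig,
    rng: np.random.Generator,
    *,
    keep_tensor: bool = False,
) -> ConcentrationMap:
    geom = tc.fset.geometry
    mask = trial_mask(tc, cfg.mask_mode, cfg.mask_threshold)
    shape = tc.coherence[0].shape
    if mask.area == 0:
        warnings.warn("empty coherence mask: returning an empty map", stacklevel=2)
        return ConcentrationMap(
            c=np.full(shape, np.nan),
            ground_truth=tc.fset.ground_truth_fraction,
            axial_spacing_mm=geom.axial_spacing_mm,
            lateral_spacing_mm=geom.lateral_spacing_mm,
        )
    stack = features_for_trial(tc, mask, cfg)
    proj = project(stack.values, atlas.fm)
    n_pairs = int(stack.frame_id.max()) + 1
    tensor = np.full(shape + (n_pairs,), np.nan)
    chunk = max(1, int(5e6) // max(cfg.n_draws, 1))
    for q in range(n_pairs):
        rows_q = np.nonzero(stack.frame_id == q)[0]
        if rows_q.size == 0:
            continue
        Xq = proj[rows_q]
        cpp = np.empty(rows_q.size)
        for s in range(0, rows_q.size, chunk):
            sl = slice(s, min(s + chunk, rows_q.size))
            cp = _cprime_batch(
                Xq[sl], atlas.mb_rows, atlas.hb_rows, cfg.n_draws, rng
            )
            cpp[sl] = _histogram_filter_batch(cp, cfg.n_bins)
        idx = stack.pixel_index[rows_q]
        tensor[idx[:, 0], idx[:, 1], q] = cpp
    ka = _to_odd_pixels(cfg.median_axial_mm, geom.axial_spacing_mm)
    kl = _to_odd_pixels(cfg.median_lateral_mm, geom.lateral_spacing_mm)
    # restrict the median filter to the mask bounding box for speed
    rr, cc = np.nonzero(mask.mask)
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    sub = median_filter_tensor(
        tensor[r0:r1, c0:c1, :], ka, kl, cfg.median_frames
    )
    cmap = np.full(shape, np.nan)
    cmap[r0:r1, c0:c1] = sub
    cmap[~mask.mask] = np.nan  # present-pixel set equals the trial mask
    return ConcentrationMap(
        c=cmap,
        ground_truth=tc.fset.ground_truth_fraction,
        axial_spacing_mm=geom.axial_spacing_mm,
        lateral_spacing_mm=geom.lateral_spacing_mm,
        tensor=tensor if keep_tensor else None,
    )


def estimate_map(
    test: ChannelFrameSet,
    atlas: Atlas,
    cfg: EstimatorConfig | None = None,
    seed: int | np.random.Generator = 0,
    *,
    keep_tensor: bool = False,
) -> ConcentrationMap:
    """Estimate the per-pixel MB fraction map of a test trial.

    The configuration must match the one the atlas was built with; the
    random atlas draws of the pairwise estimator are seeded, so identical seeds give
    identical maps.
    """
    if cfg is None:
        cfg = atlas.config
    if cfg != atlas.config:
        raise ValueError("configuration does not match the atlas configuration")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tc = beamform_trial(test, cfg)
    return _estimate_from_cache(tc, atlas, cfg, rng, keep_tensor=keep_tensor)


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def _split_train_test(
    datasets: Sequence[ChannelFrameSet],
) -> tuple[ChannelFrameSet, ChannelFrameSet, list[ChannelFrameSet]]:
    """First pure-MB and pure-Hb sets for training; the rest for testing."""
    mb = next((d for d in datasets if d.ground_truth_fraction == 1.0), None)
    hb = next((d for d in datasets if d.ground_truth_fraction == 0.0), None)
    if mb is None or hb is None:
        raise ValueError(
            "datasets must include pure trials (fractions 0.0 and 1.0)"
        )
    test = [d for d in datasets if d is not mb and d is not hb]
    return mb, hb, test


def parameter_sweep(
    datasets: Sequence[ChannelFrameSet],
    grid: Mapping[str, Sequence],
    base_cfg: EstimatorConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Full-factorial sweep over estimator parameters, scored by the R^2 of
    the 1:1 fit of estimated versus true concentrations.

    ``grid`` maps :class:`EstimatorConfig` field names (e.g. ``kernel_mm``,
    ``dynamic_range_db``, ``n_components``) to candidate values.  Returns
    the results table and the maximizing setting (ties -> first in grid
    order).
    """
    if base_cfg is None:
        base_cfg = EstimatorConfig()
    grid = dict(grid)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty parameter grid")
    labels = {d.ground_truth_fraction for d in datasets}
    if len(labels) < 2:
        raise ValueError("need at least 2 distinct ground-truth labels")
    mb, hb, test = _split_train_test(datasets)
    keys = list(grid)
    records = []
    ss = np.random.SeedSequence(seed)
    for values in product(*(grid[k] for k in keys)):
        cfg = replace(base_cfg, **dict(zip(keys, values)))
        rng = np.random.default_rng(ss.spawn(1)[0])
        atlas = build_atlas(mb, hb, cfg)
        est, lab = [], []
        for d in test:
            m = estimate_map(d, atlas, cfg, rng)
            v = m.present_values
            est.append(v)
            lab.append(np.full(v.size, d.ground_truth_fraction))
        r2 = r_squared_one_to_one(np.concatenate(est), np.concatenate(lab))
        records.append(dict(zip(keys, values)) | {"r_squared": r2})
    table = pd.DataFrame.from_records(records)
    best = table.loc[table["r_squared"].idxmax()]  # idxmax -> first maximum
    return table, {k: best[k] for k in keys} | {"r_squared": float(best["r_squared"])}


def threshold_sweep(
    datasets: Sequence[ChannelFrameSet],
    thresholds: Sequence[float] | None = None,
    base_cfg: EstimatorConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """MAE of the full estimator as a function of the absolute coherence
    threshold used to build the segmentation masks.

    Beamforming products are computed once per trial and reused across
    thresholds.  Thresholds whose masks are empty for the training trials
    (or for every test trial) are recorded as absent (NaN), not errors.
    Default grid: 0.3 to 0.9 in steps of 0.02.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.3, 0.9 + 1e-9, 0.02), 2)
    if base_cfg is None:
        base_cfg = EstimatorConfig()
    mb, hb, test = _split_train_test(datasets)
    tc_mb = beamform_trial(mb, base_cfg)
    tc_hb = beamform_trial(hb, base_cfg)
    tc_test = [beamform_trial(d, base_cfg) for d in test]
    ss = np.random.SeedSequence(seed)
    records = []
    for t in thresholds:
        cfg = replace(base_cfg, mask_mode="absolute", mask_threshold=float(t))
        rng = np.random.default_rng(ss.spawn(1)[0])
        row = {"threshold": float(t), "mae_percent": np.nan}
        try:
            atlas = _atlas_from_caches(tc_mb, tc_hb, cfg)
        except ValueError:
            records.append(row)
            continue
        per_label: dict[float, list[np.ndarray]] = {}
        for tc in tc_test:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = _estimate_from_cache(tc, atlas, cfg, rng)
            v = m.present_values
            if v.size:
                per_label.setdefault(tc.fset.ground_truth_fraction, []).append(v)
        if per_label:
            maes = [
                mae(np.concatenate(vals), k) for k, vals in per_label.items()
            ]
            row["mae_percent"] = float(np.mean(maes))
        records.append(row)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Atlas persistence
# ---------------------------------------------------------------------------

def save_atlas(atlas: Atlas, path: str | Path, *, overwrite: bool = False) -> None:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True")
    import json

    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "paatlas-atlas"
        h5.attrs["config"] = json.dumps(atlas.config.to_dict())
        h5.create_dataset("basis", data=atlas.fm.basis)
        h5.create_dataset("mean_spectrum", data=atlas.fm.mean_spectrum)
        h5.create_dataset("projected", data=atlas.fm.projected)
        h5.create_dataset("mb_rows", data=atlas.mb_rows)
        h5.create_dataset("hb_rows", data=atlas.hb_rows)


def load_atlas(path: str | Path) -> Atlas:
    import json

    with h5py.File(path, "r") as h5:
        cfg = EstimatorConfig(**json.loads(h5.attrs["config"]))
        fm = FeatureMatrix(
            basis=h5["basis"][()],
            mean_spectrum=h5["mean_spectrum"][()],
            projected=h5["projected"][()],
            p=h5["basis"].shape[1],
        )
        return Atlas(
            fm=fm, mb_rows=h5["mb_rows"][()], hb_rows=h5["hb_rows"][()], config=cfg
        )
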