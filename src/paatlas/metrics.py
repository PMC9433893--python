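"""Quantitative evaluation of concentration estimates.

Three summary statistics are used throughout:

* ``r_squared_one_to_one`` — coefficient of determination of the estimates
  against the 1:1 line C = k (not against a fitted regression line):
  ``R^2 = 1 - sum (C_ki - k)^2 / sum (C_ki - Cbar)^2`` with ``Cbar`` the mean
  of all estimates.  It quantifies how well estimated concentrations track
  the true ones with unit slope and zero intercept.
* ``spearman_rho`` — Spearman's rank correlation (Pearson correlation of
  mid-ranks; ties receive average ranks).  |rho| >= 0.8 is treated as a
  strong monotonic trend.
* ``mae`` — mean absolute error between estimated and true concentration,
  reported in % concentration units.

``spectral_linearity_scan`` applies the first two statistics per stacked
frequency bin to locate acoustic frequencies whose amplitude is linear /
monotonic in the mixture fraction, as a function of the log-compression
dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .spectral_features import SpectraStack

__all__ = [
    "EvaluationReport",
    "LinearityScan",
    "r_squared_one_to_one",
    "spearman_rho",
    "mae",
    "spectral_linearity_scan",
]


@dataclass
class EvaluationReport:
    """Aggregate evaluation of a set of concentration maps."""

    r_squared: float
    spearman_rho: float
    mae_per_label: dict[float, float]  # percent, keyed by ground-truth fraction
    mae_overall: float  # percent, equal weight per label

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "spearman_rho": self.spearman_rho,
            "mae_per_label_percent": {
                f"{k:g}": v for k, v in sorted(self.mae_per_label.items())
            },
            "mae_overall_percent": self.mae_overall,
        }


def r_squared_one_to_one(
    estimates: Sequence[float] | np.ndarray, labels: Sequence[float] | np.ndarray
) -> float:
    """R^2 of the estimates about the 1:1 line C = k.

    ``estimates`` and ``labels`` are aligned arrays (one label per
    estimate).  Requires at least two distinct labels and non-constant
    estimates.
    """
    c = np.asarray(estimates, dtype=np.float64).ravel()
    k = np.asarray(labels, dtype=np.float64).ravel()
    if c.shape != k.shape:
        raise ValueError("estimates and labels must be aligned")
    if np.unique(k).size < 2:
        raise ValueError("need at least 2 distinct ground-truth labels")
    ss_tot = np.sum((c - c.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("R^2 undefined: all estimates identical")
    ss_res = np.sum((c - k) ** 2)
    return float(1.0 - ss_res / ss_tot)


def spearman_rho(x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray) -> float:
    """Spearman's rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Spearman's rho undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def mae(estimates: Sequence[float] | np.ndarray, k: float) -> float:
    """Mean absolute error of the estimates for ground-truth fraction ``k``,
    in % concentration units."""
    c = np.asarray(estimates, dtype=np.float64).ravel()
    if c.size == 0:
        raise ValueError("no estimates")
    return float(np.mean(np.abs(c - float(k))) * 100.0)


def evaluation_report(
    estimates_by_label: Mapping[float, np.ndarray],
    *,
    label_means: Mapping[float, float] | None = None,
) -> EvaluationReport:
    """Build an :class:`EvaluationReport` from per-label pixel estimates.

    R^2 is computed over the pooled pixel estimates; Spearman's rho over the
    per-label mean estimates (the monotone-trend criterion); the overall MAE
    is the equal-weight mean of the per-label MAEs.
    """
    labels = sorted(estimates_by_label)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    pooled_c, pooled_k = [], []
    maes: dict[float, float] = {}
    means = []
    for k in labels:
        vals = np.asarray(estimates_by_label[k], dtype=np.float64).ravel()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"no finite estimates for label {k}")
        pooled_c.append(vals)
        pooled_k.append(np.full(vals.size, k))
        maes[float(k)] = mae(vals, k)
        means.append(vals.mean())
    c = np.concatenate(pooled_c)
    kk = np.concatenate(pooled_k)
    return EvaluationReport(
        r_squared=r_squared_one_to_one(c, kk),
        spearman_rho=spearman_rho(means, labels),
        mae_per_label=maes,
        mae_overall=float(np.mean(list(maes.values()))),
    )


@dataclass
class LinearityScan:
    """Per-frequency-bin linearity/monotonicity curves.

    ``r_squared`` and ``spearman`` have shape
    ``(len(dynamic_ranges_db), n_bins)`` where the bin axis is the stacked
    dual-wavelength frequency axis (710-nm block then 870-nm block).
    """

    dynamic_ranges_db: np.ndarray
    r_squared: np.ndarray
    spearman: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.r_squared.shape[1]


def _columnwise_pearson(y: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Pearson correlation of ``y`` against every column of ``W``; columns
    with zero variance yield 0."""
    yc = y - y.mean()
    Wc = W - W.mean(axis=0)
    num = yc @ Wc
    den = np.sqrt((yc**2).sum() * (Wc**2).sum(axis=0))
    out = np.zeros(W.shape[1])
    np.divide(num, den, out=out, where=den > 0)
    return out


def spectral_linearity_scan(
    stacks_by_label: Mapping[float, SpectraStack | np.ndarray],
    dynamic_ranges_db: Sequence[float],
) -> LinearityScan:
    """OLS R^2 and Spearman's rho of spectral amplitude versus mixture
    fraction, per stacked frequency bin and dynamic range.

    The input stacks should be compressed at (at least) the largest dynamic
    range requested; smaller ranges are obtained by re-flooring the dB
    values, which is exact because log compression is the identity above the
    floor.
    """
    labels = sorted(stacks_by_label)
    if len(labels) < 3:
        raise ValueError("need at least 3 distinct labels")
    blocks, ys = [], []
    for k in labels:
        v = stacks_by_label[k]
        v = v.values if isinstance(v, SpectraStack) else np.atleast_2d(v)
        blocks.append(np.asarray(v, dtype=np.float64))
        ys.append(np.full(v.shape[0], float(k)))
    V = np.vstack(blocks)
    y = np.concatenate(ys)
    ranges = np.asarray(sorted(dynamic_ranges_db, reverse=True), dtype=np.float64)
    y_rank = stats.rankdata(y)
    r2 = np.empty((ranges.size, V.shape[1]))
    rho = np.empty_like(r2)
    for i, T in enumerate(ranges):
        W = np.maximum(V, -T)
        r2[i] = _columnwise_pearson(y, W) ** 2
        W_rank = stats.rankdata(W, axis=0)
        rho[i] = _columnwise_pearson(y_rank, W_rank)
    return LinearityScan(dynamic_ranges_db=ranges, r_squared=r2, spearman=rho)
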