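"""Depth-integrated activation metrics.

The laminar analysis integrates (averages) all ROI voxels at a given
cortical depth, per echo and volume, and derives from the resulting
depth x echo x volume array:

* the state means S_rest and S_active and their difference
  dS = S_active - S_rest (plus the percent variant 100 * dS / S_rest);
* the profile normalisation dS / mean(dS over cortex x TE), one divisor
  per dataset so that subject-level response amplitude cancels;
* the temporal SD of the resting signal and the functional
  contrast-to-noise ratio CNR = dS / sigma_rest;
* a Welch two-sample t between active and rest per-volume means, a
  lightweight surrogate for a GLM t-map with the same monotonicities;
* the grey-matter-to-pial ratio dS(mid cortex) / dS(pial) per echo.

Voxel-level preprocessing provided here: discarding voxels whose local
cortical thickness exceeds a threshold (default 2.5 mm, guarding against
segmentation errors) and an optional high-pass drift filter with cutoff
f_c = 1 / (2.1 * volume TR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .protocol import ACTIVE, REST
from .simulate import MultiEchoTimeSeries, VoxelGrid, cortical_bins, mid_cortex_bin, pial_bin

__all__ = [
    "DepthSeries",
    "LaminarProfile",
    "filter_by_thickness",
    "highpass_cutoff",
    "cosine_drift_basis",
    "highpass_filter",
    "integrate_depth",
    "activation_metrics",
    "normalize_profiles",
    "gm_pial_ratio",
    "te_over_t2s",
    "DEFAULT_MAX_THICKNESS_MM",
]

DEFAULT_MAX_THICKNESS_MM = 2.5


# ---------------------------------------------------------------------------
# voxel filtering


def filter_by_thickness(
    grid: VoxelGrid, max_thickness: float = DEFAULT_MAX_THICKNESS_MM
) -> tuple[VoxelGrid, int]:
    """Discard voxels whose cortical thickness exceeds ``max_thickness`` mm.

    Returns the filtered grid and the number of voxels removed.
    """
    th = grid.thickness_array
    if th is None:
        raise ValueError("grid carries no thickness map")
    keep = th <= max_thickness
    n_removed = int((~keep).sum())
    if n_removed == 0:
        return grid, 0
    filtered = VoxelGrid(
        n_voxels=int(keep.sum()),
        depth_bin=tuple(grid.depth_bin_array[keep]),
        in_v1=tuple(grid.v1_array[keep]),
        in_activation_mask=tuple(grid.mask_array[keep]),
        thickness=tuple(th[keep]),
        depth_bins=grid.depth_bins,
    )
    return filtered, n_removed


# ---------------------------------------------------------------------------
# temporal high-pass


def highpass_cutoff(vol_tr: float) -> float:
    """Drift cutoff frequency f_c = 1 / (2.1 * volume TR), in Hz."""
    if vol_tr <= 0:
        raise ValueError("vol_tr must be positive")
    return 1.0 / (2.1 * vol_tr)


def cosine_drift_basis(n_volumes: int, dt: float, f_c: float) -> np.ndarray:
    """Discrete-cosine drift regressors with frequencies strictly below f_c.

    Column k (k = 1..K) is cos(pi * k * (t + 1/2) / T) with frequency
    k / (2 * T * dt) Hz; columns up to the last frequency below ``f_c``
    (at most T - 1) are returned.  Shape (T, K); K may be zero.
    """
    t = np.arange(n_volumes)
    k_max = int(np.ceil(2.0 * n_volumes * dt * f_c)) - 1
    k_max = min(max(k_max, 0), n_volumes - 1)
    ks = np.arange(1, k_max + 1)
    return np.cos(np.pi * np.outer(t + 0.5, ks) / n_volumes)


def highpass_filter(series: np.ndarray, f_c: float, dt: float, axis: int = -1) -> np.ndarray:
    """Remove drift below ``f_c`` by regressing out a cosine basis.

    The temporal mean is preserved.  Series shorter than 4 volumes are
    returned unchanged with a warning.  For very short runs whose cutoff
    sits close to the Nyquist frequency the basis approaches completeness
    and the filter removes nearly all temporal structure; a warning is
    issued in that case (see the package methods note).
    """
    x = np.moveaxis(np.asarray(series, dtype=float), axis, -1)
    n = x.shape[-1]
    if n < 4:
        warnings.warn("series shorter than 4 volumes; high-pass filter is a no-op", stacklevel=2)
        return np.asarray(series, dtype=float).copy()
    basis = cosine_drift_basis(n, dt, f_c)
    if basis.shape[1] == 0:
        return np.asarray(series, dtype=float).copy()
    if basis.shape[1] >= 0.9 * (n - 1):
        warnings.warn(
            "high-pass basis is nearly complete for this series length; "
            "the filtered series retains almost no temporal structure",
            stacklevel=2,
        )
    mean = x.mean(axis=-1, keepdims=True)
    resid = x - mean
    # project out the drift columns (orthogonal up to discretisation)
    coeff, *_ = np.linalg.lstsq(basis, resid.reshape(-1, n).T, rcond=None)
    resid = resid - (basis @ coeff).T.reshape(resid.shape)
    return np.moveaxis(resid + mean, -1, axis)


# ---------------------------------------------------------------------------
# depth integration


@dataclass(frozen=True)
class DepthSeries:
    """ROI-averaged signal per depth bin, echo and volume."""

    depth_bins: np.ndarray  # 1-based bins present, ascending
    signal: np.ndarray  # (D_present, E, T)
    n_voxels: np.ndarray  # voxels contributing per bin
    echo_times_ms: np.ndarray
    volume_tr: float
    paradigm: tuple[str, ...]
    n_depth_bins_total: int
    excluded_bins: tuple[int, ...] = ()


def integrate_depth(ts: MultiEchoTimeSeries, roi: np.ndarray | None = None) -> DepthSeries:
    """Average ROI voxels within each depth bin, per echo and volume."""
    if roi is None:
        roi = ts.grid.v1_array
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != (ts.grid.n_voxels,):
        raise ValueError("roi must be a boolean flag per voxel")
    if not roi.any():
        raise ValueError("roi is empty")
    depth = ts.grid.depth_bin_array
    present = np.unique(depth)
    kept, sigs, counts, excluded = [], [], [], []
    for b in present:
        sel = roi & (depth == b)
        if not sel.any():
            excluded.append(int(b))
            continue
        kept.append(int(b))
        counts.append(int(sel.sum()))
        sigs.append(ts.signal[sel].mean(axis=0))
    if excluded:
        warnings.warn(f"depth bins without ROI voxels excluded: {excluded}", stacklevel=2)
    return DepthSeries(
        depth_bins=np.asarray(kept),
        signal=np.stack(sigs, axis=0),
        n_voxels=np.asarray(counts),
        echo_times_ms=ts.protocol.echo_times_ms,
        volume_tr=ts.protocol.volume_tr,
        paradigm=ts.protocol.paradigm,
        n_depth_bins_total=ts.grid.depth_bins,
        excluded_bins=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# activation metrics


@dataclass
class LaminarProfile:
    """Per-(depth, TE) activation metrics.

    2-D arrays are indexed [depth, echo] following ``depth_bins`` and
    ``echo_times_ms``.  ``cnr`` is NaN (flagged, not infinite) where the
    resting SD vanishes; ``delta_s_norm`` divides dS by one grand mean
    over the cortical bins and all echoes.
    """

    depth_bins: np.ndarray
    echo_times_ms: np.ndarray
    s_rest: np.ndarray
    s_active: np.ndarray
    delta_s: np.ndarray
    delta_s_pct: np.ndarray
    delta_s_norm: np.ndarray
    sigma_rest: np.ndarray
    cnr: np.ndarray
    t_score: np.ndarray
    n_rest: int
    n_active: int
    n_depth_bins_total: int
    roi_description: str = ""

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with one row per (depth bin, echo)."""
        d, e = np.meshgrid(np.arange(len(self.depth_bins)), np.arange(len(self.echo_times_ms)), indexing="ij")
        return pd.DataFrame(
            {
                "depth_bin": self.depth_bins[d.ravel()],
                "te_ms": self.echo_times_ms[e.ravel()],
                "s_rest": self.s_rest.ravel(),
                "s_active": self.s_active.ravel(),
                "delta_s": self.delta_s.ravel(),
                "delta_s_pct": self.delta_s_pct.ravel(),
                "delta_s_norm": self.delta_s_norm.ravel(),
                "sigma_rest": self.sigma_rest.ravel(),
                "cnr": self.cnr.ravel(),
                "t": self.t_score.ravel(),
            }
        )

    def gm_pial_ratio(self) -> np.ndarray:
        return gm_pial_ratio(self.delta_s, self.depth_bins, self.n_depth_bins_total)


def _welch_t(active: np.ndarray, rest: np.ndarray) -> float:
    """Welch two-sample t; 0 when both samples are constant and equal."""
    va, vr = active.var(ddof=1), rest.var(ddof=1)
    da = active.mean() - rest.mean()
    if va == 0 and vr == 0:
        return 0.0 if da == 0 else float(np.sign(da) * np.inf)
    return float(stats.ttest_ind(active, rest, equal_var=False).statistic)


def activation_metrics(
    ds: DepthSeries, paradigm: tuple[str, ...] | None = None, roi_description: str = ""
) -> LaminarProfile:
    """Activation metrics from a depth-integrated series.

    State means, dS (active minus rest), percent signal change, resting
    temporal SD, CNR and Welch t per (depth, TE).  Requires both paradigm
    states; where sigma_rest is zero the CNR is flagged NaN.
    """
    if paradigm is None:
        paradigm = ds.paradigm
    states = np.asarray(paradigm)
    if states.shape != (ds.signal.shape[2],):
        raise ValueError("paradigm length must equal the number of volumes")
    rest = states == REST
    active = states == ACTIVE
    if rest.sum() < 2 or active.sum() < 2:
        raise ValueError("both paradigm states must occur at least twice")

    x = ds.signal  # (D, E, T)
    s_rest = x[..., rest].mean(axis=-1)
    s_active = x[..., active].mean(axis=-1)
    delta_s = s_active - s_rest
    with np.errstate(divide="ignore", invalid="ignore"):
        delta_s_pct = np.where(s_rest != 0, 100.0 * delta_s / s_rest, np.nan)
    sigma_rest = x[..., rest].std(axis=-1, ddof=1)
    cnr = np.where(sigma_rest > 0, delta_s / np.where(sigma_rest > 0, sigma_rest, 1.0), np.nan)
    if np.any(sigma_rest == 0):
        warnings.warn("zero resting SD in some (depth, TE) cells; CNR flagged NaN", stacklevel=2)

    t_score = np.empty_like(delta_s)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            t_score[i, j] = _welch_t(x[i, j, active], x[i, j, rest])

    cx = np.isin(ds.depth_bins, cortical_bins(ds.n_depth_bins_total))
    norm_pool = delta_s[cx] if cx.any() else delta_s
    grand = norm_pool.mean()
    if grand == 0:
        warnings.warn("zero grand-mean dS; normalised profiles flagged NaN", stacklevel=2)
        delta_s_norm = np.full_like(delta_s, np.nan)
    else:
        delta_s_norm = delta_s / grand

    return LaminarProfile(
        depth_bins=ds.depth_bins.copy(),
        echo_times_ms=ds.echo_times_ms.copy(),
        s_rest=s_rest,
        s_active=s_active,
        delta_s=delta_s,
        delta_s_pct=delta_s_pct,
        delta_s_norm=delta_s_norm,
        sigma_rest=sigma_rest,
        cnr=cnr,
        t_score=t_score,
        n_rest=int(rest.sum()),
        n_active=int(active.sum()),
        n_depth_bins_total=ds.n_depth_bins_total,
        roi_description=roi_description,
    )


def normalize_profiles(delta_s: np.ndarray) -> np.ndarray:
    """Divide a dS surface by its single grand mean over (depth x TE).

    Scale-invariant and idempotent; the output has grand mean 1.
    """
    x = np.asarray(delta_s, dtype=float)
    grand = x.mean()
    if grand == 0:
        raise ValueError("grand mean of delta_s is zero; profiles cannot be normalised")
    return x / grand


def gm_pial_ratio(
    delta_s: np.ndarray,
    depth_bins: np.ndarray,
    n_depth_bins_total: int = 15,
) -> np.ndarray:
    """dS(mid cortex) / dS(pial surface) per echo.

    Mid cortex is cortical layer 6 of 11 (overall bin 8 for a 15-bin
    axis); the pial surface is cortical layer 11 (bin 13).  A venous-
    weighted, ascending profile gives a ratio below 1; echoes with zero
    pial dS are flagged NaN.
    """
    depth_bins = np.asarray(depth_bins)
    mid = mid_cortex_bin(n_depth_bins_total)
    pial = pial_bin(n_depth_bins_total)
    for b in (mid, pial):
        if b not in depth_bins:
            raise ValueError(f"depth bin {b} required for the GM/pial ratio is absent")
    ds_mid = np.asarray(delta_s)[depth_bins == mid][0]
    ds_pial = np.asarray(delta_s)[depth_bins == pial][0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ds_pial != 0, ds_mid / np.where(ds_pial != 0, ds_pial, 1.0), np.nan)
    if np.any(ds_pial == 0):
        warnings.warn("zero pial dS at some echoes; ratio flagged NaN", stacklevel=2)
    return ratio


def te_over_t2s(echo_times_ms: np.ndarray, t2s_gm_ms: float) -> np.ndarray:
    """Echo times normalised by the grey-matter T2*, the between-field
    'equivalent TE' axis."""
    if t2s_gm_ms <= 0:
        raise ValueError("t2s_gm_ms must be positive")
    return np.asarray(echo_times_ms, dtype=float) / t2s_gm_ms
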