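"""Synthetic multi-echo laminar time series.

Forward model
-------------
Each voxel carries a two-compartment gradient-echo decay: a tissue
compartment with depth-dependent resting relaxation rate R2*(d) and an
activation-induced rate *decrease* dR2*(d) >= 0, plus a small venous blood
compartment with its own (shorter) T2* that lengthens upon activation.
The noiseless signal at echo time TE for depth d and state s is

    S(TE) = S0(d) * [ (1 - v(d)) * exp(-TE * R2t(d, s))
                      + v(d) * exp(-TE * R2v(s)) ]

with v(d) the venous volume fraction.  Across the 11 cortical depth bins
dR2* and v ramp up toward the pial surface, which produces the ascending
activation (dS) profile characteristic of gradient-echo BOLD, while the
tissue T2* lengthens toward the pial surface (equivalently R2* falls from
white matter to the pial surface).

Noise model
-----------
Three components, each removable by setting its SD to zero:

* thermal noise: additive Gaussian, independent per (voxel, echo, volume);
* BOLD-like physiological noise: a per-volume rate fluctuation dr(t)
  shared by all voxels, applied inside the exponent scaled by a per-depth
  weight, so its signal footprint is ~ -TE * S * dr(t) and follows the
  BOLD TE-dependence;
* non-BOLD-like physiological noise: a per-volume multiplicative
  fluctuation g(t) shared by all voxels, so its footprint scales with the
  signal itself (the cardiac/respiratory-style component).

Shared components are drawn before any per-voxel randomness so that the
shared trajectories do not depend on the voxel count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .protocol import ACTIVE, REST, AcquisitionProtocol, make_default_protocol

__all__ = [
    "TissueParams",
    "NoiseParams",
    "VoxelGrid",
    "MultiEchoTimeSeries",
    "make_default_tissue",
    "make_default_grid",
    "compartment_signal",
    "simulate_noiseless",
    "simulate_timeseries",
    "cortical_bins",
    "mid_cortex_bin",
    "pial_bin",
    "DEFAULT_DEPTH_BINS",
]

DEFAULT_DEPTH_BINS = 15  # 2 WM + 11 cortical + 2 CSF

# -- depth-axis conventions -------------------------------------------------
# Bins are 1-based: 1-2 white matter, 3..(D-2) cortex (cortical layers
# numbered WM -> pial), (D-1)-D CSF.  With D = 15 the cortex spans bins
# 3-13; "middle of the cortex" is cortical layer 6 (bin 8) and the pial
# surface is cortical layer 11 (bin 13).


def cortical_bins(depth_bins: int = DEFAULT_DEPTH_BINS) -> np.ndarray:
    """1-based overall bin indices of the cortical layers."""
    if depth_bins < 5:
        raise ValueError("need at least 5 depth bins (2 WM + >=1 cortex + 2 CSF)")
    return np.arange(3, depth_bins - 1)


def mid_cortex_bin(depth_bins: int = DEFAULT_DEPTH_BINS) -> int:
    """Overall bin index of the middle of the cortex (layer 6 of 11 for D=15)."""
    n_cortex = depth_bins - 4
    return 2 + (n_cortex + 1) // 2


def pial_bin(depth_bins: int = DEFAULT_DEPTH_BINS) -> int:
    """Overall bin index of the pial surface (last cortical layer)."""
    return depth_bins - 2


# -- parameter containers ----------------------------------------------------


@dataclass(frozen=True)
class TissueParams:
    """Depth-resolved relaxation parameters of the two-compartment model.

    All per-depth arrays have length ``depth_bins`` and are indexed by the
    0-based bin (bin 1 of the depth axis is element 0).  Times are in ms,
    rates in 1/s, signals in arbitrary units.
    """

    depth_bins: int
    t2s_tissue_rest: tuple[float, ...]  # ms per depth
    delta_r2s_tissue: tuple[float, ...]  # 1/s per depth, rest minus active, >= 0
    s0: tuple[float, ...]  # a.u. per depth
    venous_fraction: tuple[float, ...]  # unitless per depth
    t2s_venous_rest: float  # ms
    t2s_venous_active: float  # ms
    t2s_csf: float  # ms

    def __post_init__(self) -> None:
        d = self.depth_bins
        for name in ("t2s_tissue_rest", "delta_r2s_tissue", "s0", "venous_fraction"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (d,):
                raise ValueError(f"{name} must have length depth_bins={d}")
        t2s = np.asarray(self.t2s_tissue_rest)
        if np.any(t2s <= 0) or self.t2s_venous_rest <= 0 or self.t2s_venous_active <= 0 or self.t2s_csf <= 0:
            raise ValueError("all relaxation times must be positive")
        vf = np.asarray(self.venous_fraction)
        if np.any(vf < 0) or np.any(vf >= 1):
            raise ValueError("venous_fraction must satisfy 0 <= v < 1")
        dr = np.asarray(self.delta_r2s_tissue)
        if np.any(dr < 0):
            raise ValueError("delta_r2s_tissue must be non-negative")
        cx = cortical_bins(d) - 1
        if np.any(np.diff(dr[cx]) < -1e-12):
            raise ValueError("delta_r2s_tissue must be non-decreasing toward pial within cortex")
        if np.any(np.diff(vf[cx]) < -1e-12):
            raise ValueError("venous_fraction must be non-decreasing toward pial within cortex")
        # T2* lengthens toward the pial surface (R2* falls from WM to pial)
        if np.any(np.diff(t2s[cx]) < -1e-12):
            raise ValueError("t2s_tissue_rest must be non-decreasing toward pial within cortex")

    def as_arrays(self) -> dict[str, np.ndarray]:
        return {
            "t2s_tissue_rest": np.asarray(self.t2s_tissue_rest, dtype=float),
            "delta_r2s_tissue": np.asarray(self.delta_r2s_tissue, dtype=float),
            "s0": np.asarray(self.s0, dtype=float),
            "venous_fraction": np.asarray(self.venous_fraction, dtype=float),
        }


@dataclass(frozen=True)
class NoiseParams:
    """Noise standard deviations; any SD set to zero removes that component.

    ``bold_weight`` scales the sensitivity of each depth to the shared
    BOLD-like rate fluctuation.  ``None`` selects the default: proportional
    to the venous fraction, normalised to mean 1 over the cortical bins, so
    that ``sigma_delta_r2s`` is the rate-fluctuation SD of an average
    cortical depth in 1/s.
    """

    sigma_thermal: float = 0.0  # a.u., independent per (voxel, echo, volume)
    sigma_delta_r2s: float = 0.0  # 1/s, shared BOLD-like rate fluctuation
    sigma_nonbold: float = 0.0  # unitless, shared multiplicative fluctuation
    bold_weight: tuple[float, ...] | None = None  # per depth
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_thermal, self.sigma_delta_r2s, self.sigma_nonbold) < 0:
            raise ValueError("noise SDs must be non-negative")

    def resolve_bold_weight(self, tissue: TissueParams) -> np.ndarray:
        if self.bold_weight is not None:
            bw = np.asarray(self.bold_weight, dtype=float)
            if bw.shape != (tissue.depth_bins,):
                raise ValueError("bold_weight must have length depth_bins")
            return bw
        vf = np.asarray(tissue.venous_fraction, dtype=float)
        cx = cortical_bins(tissue.depth_bins) - 1
        mean_cx = vf[cx].mean()
        if mean_cx == 0:
            return np.ones_like(vf)
        return vf / mean_cx


@dataclass(frozen=True)
class VoxelGrid:
    """Flat voxel population with depth labels and ROI flags."""

    n_voxels: int
    depth_bin: tuple[int, ...]  # 1..D per voxel
    in_v1: tuple[bool, ...]
    in_activation_mask: tuple[bool, ...]
    thickness: tuple[float, ...] | None = None  # mm per voxel, optional
    depth_bins: int = DEFAULT_DEPTH_BINS

    def __post_init__(self) -> None:
        db = np.asarray(self.depth_bin)
        if db.shape != (self.n_voxels,):
            raise ValueError("depth_bin must have length n_voxels")
        if np.any(db < 1) or np.any(db > self.depth_bins):
            raise ValueError(f"depth_bin values must lie in 1..{self.depth_bins}")
        v1 = np.asarray(self.in_v1, dtype=bool)
        mask = np.asarray(self.in_activation_mask, dtype=bool)
        if v1.shape != (self.n_voxels,) or mask.shape != (self.n_voxels,):
            raise ValueError("flag arrays must have length n_voxels")
        if np.any(mask & ~v1):
            raise ValueError("activation mask must be a subset of the V1 flags")
        if self.thickness is not None and len(self.thickness) != self.n_voxels:
            raise ValueError("thickness must have length n_voxels")

    @property
    def depth_bin_array(self) -> np.ndarray:
        return np.asarray(self.depth_bin, dtype=int)

    @property
    def v1_array(self) -> np.ndarray:
        return np.asarray(self.in_v1, dtype=bool)

    @property
    def mask_array(self) -> np.ndarray:
        return np.asarray(self.in_activation_mask, dtype=bool)

    @property
    def thickness_array(self) -> np.ndarray | None:
        if self.thickness is None:
            return None
        return np.asarray(self.thickness, dtype=float)


@dataclass(frozen=True)
class MultiEchoTimeSeries:
    """Magnitude signal indexed [voxel, echo, volume] plus its provenance."""

    signal: np.ndarray
    protocol: AcquisitionProtocol
    grid: VoxelGrid

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        expected = (self.grid.n_voxels, self.protocol.n_echoes, self.protocol.n_volumes)
        if sig.shape != expected:
            raise ValueError(f"signal shape {sig.shape} != (voxel, echo, volume) {expected}")
        if not np.all(np.isfinite(sig)):
            raise ValueError("signal contains non-finite values")
        object.__setattr__(self, "signal", sig)

    @property
    def n_voxels(self) -> int:
        return self.grid.n_voxels


# -- defaults ----------------------------------------------------------------

#: Grey-matter resting T2* in the middle of the cortex per field (ms).
T2S_GM_MS = {1.5: 68.8, 3.0: 55.2, 7.0: 27.9}

# Modelling constants for the per-depth ramps (plausibility choices,
# overridable; never used as oracles).  Relative to the mid-cortex T2*:
_T2S_CORTEX_SPAN = 0.16  # pial T2* minus WM-boundary T2*, fraction of mid value
_T2S_WM_FACTOR = 0.85  # WM T2* relative to mid-cortex
#: Activation rate decrease at the pial surface per field (1/s); the ramp
#: starts at 10% of this value at the WM boundary.
_DELTA_R2S_PIAL = {1.5: 0.35, 3.0: 0.7, 7.0: 1.4}
_VENOUS_FRACTION_WM = 0.005
_VENOUS_FRACTION_RAMP = (0.01, 0.05)  # WM boundary -> pial within cortex
#: Venous-blood T2* at rest (~0.35 x tissue T2*) and its lengthening upon
#: activation; CSF T2* per field (ms).
_T2S_VENOUS_REST = {1.5: 24.0, 3.0: 19.0, 7.0: 10.0}
_VENOUS_ACTIVE_FACTOR = 1.25
_T2S_CSF = {1.5: 300.0, 3.0: 250.0, 7.0: 120.0}
_S0_DEFAULT = 1000.0


def make_default_tissue(field: float, depth_bins: int = DEFAULT_DEPTH_BINS) -> TissueParams:
    """Default depth-resolved tissue parameters for a supported field.

    The mid-cortex resting T2* equals the per-field grey-matter value
    (68.8 / 55.2 / 27.9 ms at 1.5 / 3 / 7 T); T2* ramps linearly across the
    cortical layers so that it lengthens toward the pial surface; dR2*
    ramps linearly from 10% of its pial value at the WM boundary to the
    pial maximum; the venous fraction ramps 0.01 -> 0.05 across cortex.
    """
    key = float(field)
    if key not in T2S_GM_MS:
        raise ValueError(f"unsupported field strength {field}; supported: {sorted(T2S_GM_MS)}")
    if depth_bins < 5:
        raise ValueError("depth_bins must be >= 5")

    d = depth_bins
    cx = cortical_bins(d) - 1  # 0-based cortical indices
    n_cx = cx.size
    mid = mid_cortex_bin(d) - 1

    t2s_mid = T2S_GM_MS[key]
    ramp = np.linspace(-0.5, 0.5, n_cx)  # centred on the middle layer
    t2s = np.empty(d)
    t2s[:2] = _T2S_WM_FACTOR * t2s_mid
    t2s[cx] = t2s_mid * (1.0 + _T2S_CORTEX_SPAN * ramp)
    t2s[d - 2 :] = _T2S_CSF[key]
    # exactness of the mid-cortex value (the centred ramp passes through 0
    # only for an odd number of layers)
    t2s[mid] = t2s_mid

    dr_pial = _DELTA_R2S_PIAL[key]
    dr = np.empty(d)
    dr[:2] = 0.05 * dr_pial
    dr[cx] = np.linspace(0.1 * dr_pial, dr_pial, n_cx)
    dr[d - 2 :] = dr_pial

    vf = np.empty(d)
    vf[:2] = _VENOUS_FRACTION_WM
    vf[cx] = np.linspace(*_VENOUS_FRACTION_RAMP, n_cx)
    vf[d - 2 :] = _VENOUS_FRACTION_RAMP[1]

    return TissueParams(
        depth_bins=d,
        t2s_tissue_rest=tuple(t2s),
        delta_r2s_tissue=tuple(dr),
        s0=tuple(np.full(d, _S0_DEFAULT)),
        venous_fraction=tuple(vf),
        t2s_venous_rest=_T2S_VENOUS_REST[key],
        t2s_venous_active=_T2S_VENOUS_REST[key] * _VENOUS_ACTIVE_FACTOR,
        t2s_csf=_T2S_CSF[key],
    )


def make_default_grid(
    n_voxels: int = 600,
    depth_bins: int = DEFAULT_DEPTH_BINS,
    activation_fraction: float = 0.4,
    all_bins: bool = False,
    thickness_mm: float | None = 2.0,
) -> VoxelGrid:
    """Default V1 voxel population.

    Voxels are assigned round-robin to the cortical bins (or to all bins
    when ``all_bins`` is set), all flagged as V1; within each bin the first
    ``activation_fraction`` of voxels form the activation mask, mirroring
    the ~40% of V1 that responds to a full-field stimulus.
    """
    bins = np.arange(1, depth_bins + 1) if all_bins else cortical_bins(depth_bins)
    depth = np.tile(bins, n_voxels // bins.size + 1)[:n_voxels]
    depth.sort()
    mask = np.zeros(n_voxels, dtype=bool)
    for b in bins:
        idx = np.flatnonzero(depth == b)
        mask[idx[: max(1, int(round(activation_fraction * idx.size)))]] = True
    thickness = None if thickness_mm is None else tuple([thickness_mm] * n_voxels)
    return VoxelGrid(
        n_voxels=n_voxels,
        depth_bin=tuple(int(b) for b in depth),
        in_v1=tuple([True] * n_voxels),
        in_activation_mask=tuple(bool(m) for m in mask),
        thickness=thickness,
        depth_bins=depth_bins,
    )


# -- forward model -----------------------------------------------------------


def _rates_per_s(tissue: TissueParams, state: str) -> tuple[np.ndarray, float]:
    """Tissue rate per depth and venous rate (both 1/s) for a paradigm state."""
    t2s = np.asarray(tissue.t2s_tissue_rest, dtype=float)
    r2t = 1000.0 / t2s
    if state == ACTIVE:
        r2t = r2t - np.asarray(tissue.delta_r2s_tissue, dtype=float)
        r2v = 1000.0 / tissue.t2s_venous_active
    elif state == REST:
        r2v = 1000.0 / tissue.t2s_venous_rest
    else:
        raise ValueError(f"state must be '{REST}' or '{ACTIVE}', got {state!r}")
    if np.any(r2t <= 0):
        raise ValueError("activation dR2* exceeds the resting rate; active R2* must stay positive")
    return r2t, r2v


def compartment_signal(
    echo_times_ms: np.ndarray | float,
    tissue: TissueParams,
    depth: int,
    state: str = REST,
) -> np.ndarray:
    """Noiseless two-compartment signal at arbitrary echo times (ms).

    ``depth`` is the 1-based depth bin.  TE = 0 returns S0 for any state.
    """
    if not 1 <= depth <= tissue.depth_bins:
        raise ValueError(f"depth must lie in 1..{tissue.depth_bins}")
    te = np.asarray(echo_times_ms, dtype=float) / 1000.0  # s
    r2t, r2v = _rates_per_s(tissue, state)
    i = depth - 1
    v = tissue.venous_fraction[i]
    s0 = tissue.s0[i]
    return s0 * ((1.0 - v) * np.exp(-te * r2t[i]) + v * np.exp(-te * r2v))


def simulate_noiseless(
    protocol: AcquisitionProtocol,
    tissue: TissueParams,
    depth: int,
    state: str = REST,
) -> np.ndarray:
    """Noiseless signal on the protocol's echo grid for one depth/state."""
    return compartment_signal(protocol.echo_times_ms, tissue, depth, state)


def simulate_timeseries(
    protocol: AcquisitionProtocol,
    tissue: TissueParams,
    noise: NoiseParams,
    grid: VoxelGrid,
) -> MultiEchoTimeSeries:
    """Simulate a full [voxel, echo, volume] magnitude time series.

    Shared physiological components (one BOLD-like rate fluctuation and one
    multiplicative fluctuation per volume) are drawn first from a single
    seeded generator, then independent thermal noise per sample, so the
    output is bit-reproducible given the seed and the shared trajectories
    are unchanged by the voxel count.  Negative magnitudes are clipped at
    zero; a clip fraction above 1% triggers a warning.
    """
    if grid.depth_bins != tissue.depth_bins:
        raise ValueError("grid and tissue disagree on the number of depth bins")
    rng = np.random.default_rng(noise.seed)
    n_vox, n_echo, n_vol = grid.n_voxels, protocol.n_echoes, protocol.n_volumes

    delta_r = rng.normal(0.0, noise.sigma_delta_r2s, size=n_vol) if noise.sigma_delta_r2s > 0 else np.zeros(n_vol)
    g = rng.normal(0.0, noise.sigma_nonbold, size=n_vol) if noise.sigma_nonbold > 0 else np.zeros(n_vol)
    eps = (
        rng.normal(0.0, noise.sigma_thermal, size=(n_vox, n_echo, n_vol))
        if noise.sigma_thermal > 0
        else 0.0
    )

    d0 = grid.depth_bin_array - 1
    params = tissue.as_arrays()
    s0 = params["s0"][d0]  # (V,)
    vf = params["venous_fraction"][d0]
    bw = noise.resolve_bold_weight(tissue)[d0]

    r2t_rest, r2v_rest = _rates_per_s(tissue, REST)
    r2t_act, r2v_act = _rates_per_s(tissue, ACTIVE)
    active = protocol.active_mask  # (T,)

    # per-voxel, per-volume tissue rate including the shared BOLD-like term
    r2t_vt = np.where(active[None, :], r2t_act[d0][:, None], r2t_rest[d0][:, None])
    r2t_vt = r2t_vt + bw[:, None] * delta_r[None, :]
    r2v_t = np.where(active, r2v_act, r2v_rest)  # (T,)

    te_s = protocol.echo_times_ms / 1000.0  # (E,)
    tissue_decay = np.exp(-te_s[None, :, None] * r2t_vt[:, None, :])  # (V,E,T)
    venous_decay = np.exp(-te_s[:, None] * r2v_t[None, :])  # (E,T)

    signal = (
        s0[:, None, None]
        * ((1.0 - vf)[:, None, None] * tissue_decay + vf[:, None, None] * venous_decay[None])
        * (1.0 + g)[None, None, :]
        + eps
    )

    n_clipped = int(np.count_nonzero(signal < 0))
    if n_clipped:
        frac = n_clipped / signal.size
        np.clip(signal, 0.0, None, out=signal)
        if frac > 0.01:
            warnings.warn(
                f"clipped {frac:.1%} of samples at zero magnitude; "
                "noise settings are implausibly large for this S0",
                stacklevel=2,
            )
    return MultiEchoTimeSeries(signal=signal, protocol=protocol, grid=grid)


def make_default_dataset(
    field: float = 7.0,
    n_voxels: int = 600,
    n_volumes: int | None = None,
    sigma_thermal: float = 10.0,
    sigma_delta_r2s: float = 0.15,
    sigma_nonbold: float = 0.0005,
    seed: int = 0,
) -> MultiEchoTimeSeries:
    """One-call synthetic dataset with the per-field defaults.

    The default noise mix places single voxels in the thermal-dominated
    regime (1% thermal noise on S0) while the shared noise is dominated by
    the BOLD-like component, the regime reported for depth-integrated
    grey-matter signal.
    """
    protocol = make_default_protocol(field, n_volumes=n_volumes)
    tissue = make_default_tissue(field)
    grid = make_default_grid(n_voxels=n_voxels)
    noise = NoiseParams(
        sigma_thermal=sigma_thermal,
        sigma_delta_r2s=sigma_delta_r2s,
        sigma_nonbold=sigma_nonbold,
        seed=seed,
    )
    return simulate_timeseries(protocol, tissue, noise, grid)
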