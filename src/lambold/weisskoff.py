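"""Incremental-ROI noise analysis (Weisskoff test) and the noise regime.

For a region of N voxels, voxels are taken in one seeded random order and
the running mean over the first i voxels is formed per volume.  The
temporal SD of that mean over resting volumes, divided by one shared
denominator — the mean resting signal of all N voxels at the reference
echo (the acquired TE closest to the grey-matter T2*) — gives the
normalised noise curve

    sigma_n(i, TE) = std_t[ mean_{v<=i} S(v, TE, t) ] / avg(S_{N, TE_ref})

With independent thermal noise only, sigma_n(i) falls as 1/sqrt(i); noise
shared across voxels (physiological) puts a floor under the curve.  The
ROI size at which the curve settles onto that plateau marks the entry
into the physiological-noise-dominated regime.

Plateau detection is automated: the plateau level is the median of the
last ``tail_fraction`` of the curve, and the detection point n_phys is
the smallest i from which the whole remaining curve stays within a
(1 + epsilon) band of that level.  For a mixed noise model
sigma(i) = sqrt(sigma_p^2 + sigma_t^2 / i) the band crossing has the
closed form i* = sigma_t^2 / (sigma_p^2 * ((1 + epsilon)^2 - 1)), used as
the oracle in the test suite.

The TE-dependence of the plateau classifies the dominant physiological
component: non-BOLD-like (multiplicative) noise scales with the signal
S(TE) itself, while BOLD-like (rate-fluctuation) noise follows the BOLD
TE-weighting ~ TE * S(TE) and therefore does not track S(TE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .relaxometry import fit_monoexponential
from .simulate import MultiEchoTimeSeries

__all__ = [
    "WeisskoffResult",
    "NoiseRegime",
    "weisskoff_curve",
    "weisskoff_curve_from_array",
    "detect_plateau",
    "noise_vs_te",
    "roi_arithmetic",
    "voxels_for_volume",
    "DEFAULT_EPSILON",
    "DEFAULT_TAIL_FRACTION",
]

DEFAULT_EPSILON = 0.05
DEFAULT_TAIL_FRACTION = 0.2


@dataclass
class WeisskoffResult:
    """Normalised noise curves sigma_n[i, TE] and their provenance.

    ``sigma_n`` has shape (N, E) with row i-1 holding the i-voxel curve
    value.  ``s_ref`` is the single shared denominator (mean resting
    signal over all N voxels at the reference echo); ``s_te`` the mean
    resting signal per echo (used for the noise-regime regression).
    ``voxel_order`` and ``seed`` reproduce the curve exactly.
    """

    sigma_n: np.ndarray  # (N, E)
    echo_times_ms: np.ndarray  # (E,)
    reference_te_index: int
    s_ref: float
    s_te: np.ndarray  # (E,)
    voxel_order: np.ndarray  # permutation of 0..N-1
    seed: int
    n_rest_volumes: int
    t2s_ref_ms: float | None = None  # fitted T2* used to pick the reference echo

    @property
    def n_voxels(self) -> int:
        return self.sigma_n.shape[0]

    @property
    def thermal_ref(self) -> np.ndarray:
        """The thermal-only expectation sigma_n(1) / sqrt(i), per TE."""
        i = np.arange(1, self.n_voxels + 1)[:, None]
        return self.sigma_n[0][None, :] / np.sqrt(i)

    def to_frame(self) -> pd.DataFrame:
        n, e = self.sigma_n.shape
        i, j = np.meshgrid(np.arange(1, n + 1), np.arange(e), indexing="ij")
        return pd.DataFrame(
            {
                "te_ms": self.echo_times_ms[j.ravel()],
                "i": i.ravel(),
                "sigma_n": self.sigma_n.ravel(),
            }
        )


def weisskoff_curve_from_array(
    signal: np.ndarray,
    echo_times_ms: np.ndarray,
    rest_mask: np.ndarray | None = None,
    seed: int = 0,
    reference_index: int | None = None,
    t2s_ref_ms: float | None = None,
) -> WeisskoffResult:
    """Weisskoff curves from a raw [voxel, echo, volume] array.

    ``rest_mask`` selects the volumes the temporal SD is computed over
    (all volumes when None).  The reference echo is given explicitly or
    chosen as the TE nearest ``t2s_ref_ms`` (fitted from the mean resting
    decay when that is None); a reference further than 25% from the target
    T2* triggers a warning but the nearest echo is still used.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 3:
        raise ValueError("signal must be [voxel, echo, volume]")
    te = np.asarray(echo_times_ms, dtype=float)
    n_vox, n_echo, n_vol = x.shape
    if te.shape != (n_echo,):
        raise ValueError("echo_times_ms length must match the echo axis")
    if n_vox < 2:
        raise ValueError("need at least 2 voxels")
    if rest_mask is None:
        rest_mask = np.ones(n_vol, dtype=bool)
    rest_mask = np.asarray(rest_mask, dtype=bool)
    if rest_mask.sum() < 4:
        raise ValueError("need at least 4 resting volumes")

    rest = x[:, :, rest_mask]  # (V, E, Tr)

    if reference_index is None:
        if t2s_ref_ms is None:
            decay = rest.mean(axis=(0, 2))  # mean resting decay over voxels/volumes
            if n_echo >= 3:
                t2s_ref_ms = fit_monoexponential(te, decay).t2s_ms
            else:
                t2s_ref_ms = float(te[-1])
        reference_index = int(np.argmin(np.abs(te - t2s_ref_ms)))
        if abs(te[reference_index] - t2s_ref_ms) > 0.25 * t2s_ref_ms:
            warnings.warn(
                f"no echo within 25% of T2*={t2s_ref_ms:.1f} ms; "
                f"using nearest TE={te[reference_index]:.1f} ms",
                stacklevel=2,
            )

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_vox)

    csum = np.cumsum(rest[order], axis=0)
    running_mean = csum / np.arange(1, n_vox + 1)[:, None, None]
    sigma = running_mean.std(axis=-1, ddof=1)  # (N, E)

    s_ref = float(rest[:, reference_index, :].mean())
    if s_ref == 0:
        raise ValueError("reference signal is zero; curves cannot be normalised")
    return WeisskoffResult(
        sigma_n=sigma / s_ref,
        echo_times_ms=te,
        reference_te_index=reference_index,
        s_ref=s_ref,
        s_te=rest.mean(axis=(0, 2)),
        voxel_order=order,
        seed=seed,
        n_rest_volumes=int(rest_mask.sum()),
        t2s_ref_ms=t2s_ref_ms,
    )


def weisskoff_curve(
    ts: MultiEchoTimeSeries,
    roi: np.ndarray | None = None,
    seed: int = 0,
    reference_index: int | None = None,
) -> WeisskoffResult:
    """Weisskoff curves over an ROI of a multi-echo time series.

    The curve is computed on the resting volumes of the paradigm, for
    every echo, with the single shared denominator taken at the reference
    echo (TE nearest the fitted mid-decay T2*).
    """
    if roi is None:
        roi = ts.grid.v1_array
    roi = np.asarray(roi, dtype=bool)
    if roi.sum() < 2:
        raise ValueError("roi must contain at least 2 voxels")
    return weisskoff_curve_from_array(
        ts.signal[roi],
        ts.protocol.echo_times_ms,
        rest_mask=ts.protocol.rest_mask,
        seed=seed,
        reference_index=reference_index,
    )


def _detect_plateau_1d(
    sigma: np.ndarray, tail_fraction: float, epsilon: float
) -> tuple[int | None, float]:
    n = sigma.size
    if n < 10:
        raise ValueError("curve must have length >= 10")
    if not 0 < tail_fraction < 1:
        raise ValueError("tail_fraction must lie in (0, 1)")
    tail_start = int(np.floor(n * (1.0 - tail_fraction)))  # 0-based
    tail = sigma[tail_start:]
    plateau = float(np.nanmedian(tail)) if np.isfinite(tail).any() else float("nan")
    if not np.isfinite(plateau):
        return None, plateau
    # validity guard: a genuine plateau must stand clear of the thermal
    # 1/sqrt(i) extrapolation of the single-voxel noise at the tail;
    # otherwise the curve is indistinguishable from pure thermal decay
    # and any band entry near the tail boundary is spurious.
    i_tail_med = (tail_start + n) // 2 + 1  # 1-based median tail index
    if np.isfinite(sigma[0]) and plateau < 2.0 * sigma[0] / np.sqrt(i_tail_med):
        return None, plateau
    ok = np.isfinite(sigma) & (sigma <= (1.0 + epsilon) * plateau)
    suffix_ok = np.flip(np.logical_and.accumulate(np.flip(ok)))
    if not suffix_ok.any():
        return None, plateau
    first = int(np.argmax(suffix_ok))  # 0-based index of earliest all-ok suffix
    if first >= tail_start:
        return None, plateau  # the band is only reached inside the tail
    return first + 1, plateau


def detect_plateau(
    result: WeisskoffResult,
    te_index: int | None = None,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[int | None, float]:
    """Plateau level and detection point n_phys for one echo's curve.

    Returns ``(n_phys, plateau_level)``; ``n_phys`` is None (undetected)
    when the curve only enters the (1 + epsilon) band inside the tail that
    defines the plateau, as for a pure 1/sqrt(i) decay.  Pathological
    curves yield undetected, never an exception.
    """
    if te_index is None:
        te_index = result.reference_te_index
    return _detect_plateau_1d(result.sigma_n[:, te_index], tail_fraction, epsilon)


@dataclass
class NoiseRegime:
    """Plateau magnitude per TE and the dominant-noise classification."""

    table: pd.DataFrame  # te_ms, s_te, plateau_level, n_phys
    classification: str | None  # 'BOLD-like dominated' | 'non-BOLD-like dominated' | None
    slope: float | None
    p_value_one_sided: float | None
    flatness: float | None  # (max - min) / mean of the plateau levels


def noise_vs_te(
    result: WeisskoffResult,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
    epsilon: float = DEFAULT_EPSILON,
    alpha: float = 0.05,
) -> NoiseRegime:
    """Plateau level per TE and a slope-based noise-regime classification.

    Echoes without a detected plateau are excluded.  The plateau levels of
    the usable echoes are regressed on the mean resting signal S(TE); a
    significantly positive slope (one-sided p < alpha) indicates noise
    scaling with the signal, i.e. non-BOLD-like dominance, otherwise the
    regime is classified BOLD-like.  With fewer than 3 usable echoes the
    classification is withheld (None).
    """
    rows = []
    for j, te in enumerate(result.echo_times_ms):
        n_phys, plateau = detect_plateau(result, j, tail_fraction, epsilon)
        rows.append(
            {
                "te_ms": float(te),
                "s_te": float(result.s_te[j]),
                "plateau_level": plateau,
                "n_phys": n_phys,
            }
        )
    table = pd.DataFrame(rows)
    usable = table[table["n_phys"].notna()]
    if len(usable) < 3:
        return NoiseRegime(table=table, classification=None, slope=None, p_value_one_sided=None, flatness=None)
    reg = stats.linregress(usable["s_te"], usable["plateau_level"])
    p_one = reg.pvalue / 2.0 if reg.slope > 0 else 1.0 - reg.pvalue / 2.0
    classification = "non-BOLD-like dominated" if p_one < alpha else "BOLD-like dominated"
    levels = usable["plateau_level"].to_numpy()
    flatness = float((levels.max() - levels.min()) / levels.mean()) if levels.mean() else None
    return NoiseRegime(
        table=table,
        classification=classification,
        slope=float(reg.slope),
        p_value_one_sided=float(p_one),
        flatness=flatness,
    )


def roi_arithmetic(n_voxels: int, voxel_size: float = 0.75) -> dict[str, float]:
    """Voxel-count <-> geometry conversions for a one-voxel-thick patch.

    volume = n * voxel_size^3; area = volume / voxel_size (the cortical
    patch area when the patch is one voxel thick); length = sqrt(area)
    (the side of the equivalent square patch).  E.g. 100 mm^3 of 0.75 mm
    voxels -> 133 mm^2, 11.5 mm.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    volume = n_voxels * voxel_size**3
    area = volume / voxel_size
    return {"volume_mm3": volume, "area_mm2": area, "length_mm": float(np.sqrt(area))}


def voxels_for_volume(volume_mm3: float, voxel_size: float = 0.75) -> int:
    """Rounded voxel count occupying a given volume."""
    if volume_mm3 <= 0 or voxel_size <= 0:
        raise ValueError("volume and voxel size must be positive")
    return int(round(volume_mm3 / voxel_size**3))
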