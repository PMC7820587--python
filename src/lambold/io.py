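"""File formats and run configuration.

Volumes are NIfTI-1 (one 4D file per echo, x-y-z-volume), depth labels
and masks are integer NIfTI volumes in the same grid (label 0 = outside
the sampled cortex), tables are TSV, summaries JSON and configurations
YAML.  A flat TSV dialect (voxel, echo, volume, signal) is provided for
desk-scale text fixtures.

The synthetic writer lays the flat voxel population out as a small slab
so that the NIfTI pathway round-trips bit-exactly through the reader.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .protocol import AcquisitionProtocol
from .simulate import MultiEchoTimeSeries, VoxelGrid

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
    "write_dataset",
    "read_inputs",
    "timeseries_to_tsv",
    "timeseries_from_tsv",
    "write_table",
]


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``simulate`` (generator settings) or the input paths
    (``echoes``/``depth_labels``/``mask``) must be provided.
    """

    out_dir: str = "lambold_out"
    # real-data pathway
    echoes: list[str] | None = None
    depth_labels: str | None = None
    mask: str | None = None
    thickness: str | None = None
    protocol: str | None = None  # JSON sidecar path
    paradigm: list[str] | None = None  # overrides the sidecar paradigm
    # synthetic pathway
    simulate: dict | None = None  # kwargs of simulate.make_default_dataset
    # analysis options
    seed: int = 0
    epsilon: float = 0.05
    tail_fraction: float = 0.2
    highpass: bool = False
    max_thickness_mm: float = 2.5
    depth_bins: int = 15

    def validate(self) -> None:
        if self.simulate is None:
            missing = [
                name
                for name in ("echoes", "depth_labels", "mask")
                if getattr(self, name) is None
            ]
            if missing:
                raise ValueError(
                    f"config must set either 'simulate' or the input paths; missing: {missing}"
                )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the analytic part of a config.

    The output directory is excluded: it identifies where results go, not
    what is computed, so re-running the same analysis elsewhere yields
    identical tables.
    """
    payload = asdict(cfg)
    payload.pop("out_dir", None)
    canonical = yaml.safe_dump(payload, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# NIfTI dataset


def _slab_shape(n_voxels: int, n_slices: int = 8) -> tuple[int, int, int]:
    per_slice = math.ceil(n_voxels / n_slices)
    nx = math.ceil(math.sqrt(per_slice))
    ny = math.ceil(per_slice / nx)
    return nx, ny, n_slices


def write_dataset(ts: MultiEchoTimeSeries, out_dir: str | Path) -> dict[str, list[str] | str]:
    """Write a time series as per-echo 4D NIfTIs + labels, mask and sidecar.

    Voxels are packed in C order into a small slab; unoccupied positions
    carry depth label 0 and are ignored by the reader.  Returns the paths
    written (keys: echoes, depth_labels, mask, thickness?, protocol).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = ts.grid
    shape = _slab_shape(grid.n_voxels)
    n_slab = int(np.prod(shape))
    affine = np.diag([ts.protocol.voxel_size] * 3 + [1.0])

    def to_volume(values: np.ndarray, fill, dtype) -> np.ndarray:
        flat = np.full(n_slab, fill, dtype=dtype)
        flat[: grid.n_voxels] = values
        return flat.reshape(shape)

    echo_paths = []
    for e in range(ts.protocol.n_echoes):
        vol4d = np.zeros(shape + (ts.protocol.n_volumes,), dtype=np.float64)
        flat = vol4d.reshape(n_slab, ts.protocol.n_volumes)
        flat[: grid.n_voxels] = ts.signal[:, e, :]
        p = out / f"echo-{e + 1:02d}.nii.gz"
        nib.save(nib.Nifti1Image(vol4d, affine), p)
        echo_paths.append(str(p))

    labels_path = out / "depth_labels.nii.gz"
    nib.save(
        nib.Nifti1Image(to_volume(grid.depth_bin_array, 0, np.int16), affine), labels_path
    )
    mask_path = out / "mask.nii.gz"
    nib.save(
        nib.Nifti1Image(to_volume(grid.mask_array.astype(np.int16), 0, np.int16), affine),
        mask_path,
    )
    paths: dict[str, list[str] | str] = {
        "echoes": echo_paths,
        "depth_labels": str(labels_path),
        "mask": str(mask_path),
    }
    if grid.thickness is not None:
        th_path = out / "thickness.nii.gz"
        nib.save(
            nib.Nifti1Image(to_volume(grid.thickness_array, np.nan, np.float64), affine),
            th_path,
        )
        paths["thickness"] = str(th_path)

    sidecar = out / "protocol.json"
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "field_strength": ts.protocol.field_strength,
                "echo_times_ms": list(ts.protocol.echo_times),
                "volume_tr_s": ts.protocol.volume_tr,
                "n_volumes": ts.protocol.n_volumes,
                "paradigm": list(ts.protocol.paradigm),
                "voxel_size_mm": ts.protocol.voxel_size,
                "flip_angle_deg": ts.protocol.flip_angle,
                "depth_bins": grid.depth_bins,
            },
            fh,
            indent=2,
        )
    paths["protocol"] = str(sidecar)
    return paths


def read_protocol_sidecar(path: str | Path, paradigm: list[str] | None = None) -> AcquisitionProtocol:
    with open(path) as fh:
        meta = json.load(fh)
    return AcquisitionProtocol(
        field_strength=meta["field_strength"],
        echo_times=tuple(meta["echo_times_ms"]),
        volume_tr=meta["volume_tr_s"],
        n_volumes=meta["n_volumes"],
        paradigm=tuple(paradigm if paradigm is not None else meta["paradigm"]),
        voxel_size=meta.get("voxel_size_mm", 0.75),
        flip_angle=meta.get("flip_angle_deg"),
    )


def _load_checked(path: str, reference_shape, reference_affine) -> np.ndarray:
    if not Path(path).exists():
        raise FileNotFoundError(f"input volume not found: {path}")
    img = nib.load(path)
    if img.shape[:3] != reference_shape:
        raise ValueError(
            f"shape mismatch in {path}: {img.shape[:3]} != {reference_shape}"
        )
    if reference_affine is not None and not np.allclose(img.affine, reference_affine, atol=1e-4):
        raise ValueError(f"affine mismatch in {path}")
    return np.asarray(img.dataobj)


def read_inputs(cfg: RunConfig) -> tuple[MultiEchoTimeSeries, VoxelGrid]:
    """Assemble the in-memory series from the NIfTI inputs of a config.

    Voxels with depth label 0 are excluded; labels above ``depth_bins``
    are an error.  All volumes must share shape and affine.
    """
    cfg.validate()
    if cfg.simulate is not None:
        raise ValueError("read_inputs expects file inputs, not a synthetic config")
    if cfg.protocol is None:
        raise ValueError("config must name a protocol sidecar for file inputs")
    protocol = read_protocol_sidecar(cfg.protocol, cfg.paradigm)

    first = nib.load(cfg.echoes[0]) if Path(cfg.echoes[0]).exists() else None
    if first is None:
        raise FileNotFoundError(f"input volume not found: {cfg.echoes[0]}")
    shape, affine = first.shape[:3], first.affine

    labels = _load_checked(cfg.depth_labels, shape, affine)
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.allclose(labels, np.round(labels)):
            raise ValueError("depth labels must be integer-valued")
        labels = np.round(labels).astype(int)
    if labels.max() > cfg.depth_bins:
        raise ValueError(
            f"depth label {int(labels.max())} exceeds depth_bins={cfg.depth_bins}"
        )
    mask = _load_checked(cfg.mask, shape, affine) > 0

    inside = labels.reshape(-1) > 0
    if not inside.any():
        raise ValueError("no voxels with a non-zero depth label")
    if not (mask.reshape(-1) & inside).any():
        raise ValueError("activation mask has no overlap with the depth labels")

    n_voxels = int(inside.sum())
    echo_data = []
    for path in cfg.echoes:
        img4d = _load_checked(path, shape, affine)
        if img4d.ndim != 4 or img4d.shape[3] != protocol.n_volumes:
            raise ValueError(f"echo volume {path} is not 4D with {protocol.n_volumes} volumes")
        echo_data.append(img4d.reshape(-1, protocol.n_volumes)[inside])
    if len(echo_data) != protocol.n_echoes:
        raise ValueError(
            f"{len(echo_data)} echo files for a protocol with {protocol.n_echoes} echoes"
        )
    signal = np.stack(echo_data, axis=1)  # (V, E, T)

    thickness = None
    if cfg.thickness is not None:
        th = _load_checked(cfg.thickness, shape, affine).reshape(-1)[inside]
        thickness = tuple(float(x) for x in th)

    grid = VoxelGrid(
        n_voxels=n_voxels,
        depth_bin=tuple(int(x) for x in labels.reshape(-1)[inside]),
        in_v1=tuple([True] * n_voxels),
        in_activation_mask=tuple(bool(x) for x in mask.reshape(-1)[inside]),
        thickness=thickness,
        depth_bins=cfg.depth_bins,
    )
    return MultiEchoTimeSeries(signal=signal, protocol=protocol, grid=grid), grid


# ---------------------------------------------------------------------------
# flat TSV dialect


def timeseries_to_tsv(ts: MultiEchoTimeSeries, signal_path: str | Path, grid_path: str | Path) -> None:
    """Write the long (voxel, echo, volume, signal) table plus the grid table."""
    v, e, t = np.meshgrid(
        np.arange(ts.grid.n_voxels),
        np.arange(ts.protocol.n_echoes),
        np.arange(ts.protocol.n_volumes),
        indexing="ij",
    )
    pd.DataFrame(
        {"voxel": v.ravel(), "echo": e.ravel(), "volume": t.ravel(), "signal": ts.signal.ravel()}
    ).to_csv(signal_path, sep="\t", index=False)
    grid_df = pd.DataFrame(
        {
            "voxel": np.arange(ts.grid.n_voxels),
            "depth_bin": ts.grid.depth_bin_array,
            "in_v1": ts.grid.v1_array.astype(int),
            "in_activation_mask": ts.grid.mask_array.astype(int),
        }
    )
    if ts.grid.thickness is not None:
        grid_df["thickness"] = ts.grid.thickness_array
    grid_df.to_csv(grid_path, sep="\t", index=False)


def timeseries_from_tsv(
    signal_path: str | Path, grid_path: str | Path, protocol: AcquisitionProtocol
) -> MultiEchoTimeSeries:
    sig = pd.read_csv(signal_path, sep="\t")
    grid_df = pd.read_csv(grid_path, sep="\t")
    n_voxels = len(grid_df)
    signal = np.zeros((n_voxels, protocol.n_echoes, protocol.n_volumes))
    signal[sig["voxel"], sig["echo"], sig["volume"]] = sig["signal"]
    grid = VoxelGrid(
        n_voxels=n_voxels,
        depth_bin=tuple(int(x) for x in grid_df["depth_bin"]),
        in_v1=tuple(bool(x) for x in grid_df["in_v1"]),
        in_activation_mask=tuple(bool(x) for x in grid_df["in_activation_mask"]),
        thickness=tuple(grid_df["thickness"]) if "thickness" in grid_df else None,
    )
    return MultiEchoTimeSeries(signal=signal, protocol=protocol, grid=grid)


def write_table(df: pd.DataFrame, path: str | Path, header_meta: dict | None = None) -> None:
    """Write a TSV, optionally prefixed with ``# key=value`` metadata lines."""
    with open(path, "w") as fh:
        if header_meta:
            for k, v in header_meta.items():
                fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)
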