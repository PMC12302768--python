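"""NIfTI and tabular I/O plus run manifests."""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import os
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["read_volume", "write_volume", "write_maps", "RunManifest", "sha256_of"]

MAP_ORDER = ("f", "dn", "de", "rn", "tex", "p2", "loss")


def read_volume(path: str | os.PathLike):
    """Load a NIfTI volume.

    Returns (data, affine, voxel_sizes).  Data is float64 for intensity
    volumes; callers binarize masks themselves.  Unreadable files raise.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim not in (2, 3, 4):
        raise IOError(f"{path}: expected a 2D/3D/4D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[: min(3, data.ndim)]
    return data, img.affine, tuple(float(z) for z in zooms)


def write_volume(data: np.ndarray, affine: np.ndarray, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    # fix scaling so repeated runs produce byte-identical files
    img.header.set_slope_inter(1.0, 0.0)
    nib.save(img, str(path))


def write_maps(
    result,
    affine: np.ndarray,
    out_dir: str | os.PathLike,
    mask: np.ndarray | None = None,
    manifest: "RunManifest | None" = None,
    prefix: str = "nexi",
) -> list[Path]:
    """Write one NIfTI per fitted parameter (NaN outside the mask) + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    maps = result.as_dict() if hasattr(result, "as_dict") else dict(result)
    if hasattr(result, "loss") and np.ndim(getattr(result, "loss")) > 0:
        maps = {**maps, "loss": np.asarray(result.loss, dtype=float)}
    written = []
    ref_shape = None
    for name in [n for n in MAP_ORDER if n in maps] + sorted(set(maps) - set(MAP_ORDER)):
        data = np.asarray(maps[name], dtype=float)
        if ref_shape is None:
            ref_shape = data.shape
        elif data.shape != ref_shape:
            raise ValueError(f"map {name!r} shape {data.shape} != {ref_shape}")
        if mask is not None:
            if mask.shape != data.shape:
                raise ValueError("mask shape does not match the parameter maps")
            data = np.where(mask, data, np.nan)
        path = out_dir / f"{prefix}_{name}.nii.gz"
        write_volume(data, affine, path)
        written.append(path)
    if manifest is not None:
        manifest.save(out_dir / f"{prefix}_manifest.json")
    return written


def sha256_of(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Everything needed to re-execute a run bit-identically.

    Records the command line, the fully resolved configuration (flags after
    config-file merging), every seed, input checksums and timestamps.
    """

    command: str
    config: dict
    seeds: dict
    inputs: dict = dataclasses.field(default_factory=dict)
    version: str = ""
    started: str = ""
    finished: str = ""
    logs: list = dataclasses.field(default_factory=list)

    @classmethod
    def begin(cls, command: str, config: dict, seeds: dict, inputs: dict | None = None):
        from . import __version__

        checksums = {}
        for name, path in (inputs or {}).items():
            if path is not None and Path(str(path)).is_file():
                checksums[name] = {"path": str(path), "sha256": sha256_of(path)}
        return cls(
            command=command,
            config={k: v for k, v in config.items()},
            seeds=seeds,
            inputs=checksums,
            version=__version__,
            started=datetime.datetime.now().isoformat(timespec="seconds"),
        )

    def finish(self) -> "RunManifest":
        self.finished = datetime.datetime.now().isoformat(timespec="seconds")
        return self

    def save(self, path: str | os.PathLike) -> None:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, Path):
                return str(o)
            return str(o)

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=default)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
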