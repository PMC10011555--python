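"""3D volume container with physical voxel size metadata.

Arrays follow the microscopy stack convention: axis 0 is z (depth),
axis 1 is y, axis 2 is x. Voxel sizes are carried in micrometres and
flow through every processing stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid with per-axis voxel size.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Intensity values. Integer inputs are converted to float32 on
        construction; processing is carried out in 32-bit floats.
    voxel_size_um : tuple of float
        Physical voxel size as ``(dz, dy, dx)`` in micrometres.
    channel : str
        Free-form channel label (e.g. ``"fibers"``, ``"soma"``).
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel: str = "fibers"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {arr.shape}")
        if arr.dtype != np.float32:
            arr = arr.astype(np.float32)
        self.data = arr
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_um must be 3 positive floats, got {vs}")
        self.voxel_size_um = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        dz, dy, dx = self.voxel_size_um
        return np.isclose(dz, dy) and np.isclose(dy, dx)

    def copy(self) -> "VolumeImage":
        return VolumeImage(self.data.copy(), self.voxel_size_um, self.channel)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(vol: VolumeImage, path: str | Path, dtype=None) -> Path:
    """Write a volume as multi-page TIFF or HDF5 plus a JSON metadata sidecar.

    The container is chosen from the file suffix (``.tif``/``.tiff`` or
    ``.h5``/``.hdf5``). Voxel size and channel are stored in a sidecar
    (TIFF) or as dataset attributes (HDF5).
    """
    path = Path(path)
    data = vol.data if dtype is None else np.asarray(vol.data, dtype=dtype)
    meta = {"voxel_size_um": list(vol.voxel_size_um), "channel": vol.channel,
            "axes": "zyx"}
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("volume", data=data)
            ds.attrs["voxel_size_um"] = vol.voxel_size_um
            ds.attrs["channel"] = vol.channel
    else:
        raise ValueError(f"unsupported volume container: {path.suffix}")
    return path


def read_volume(path: str | Path,
                voxel_size_um: tuple[float, float, float] | None = None,
                channel: str | None = None) -> VolumeImage:
    """Read a TIFF or HDF5 volume; voxel size comes from the sidecar,
    HDF5 attributes, or the explicit ``voxel_size_um`` override."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
        meta = {}
        sc = _sidecar_path(path)
        if sc.exists():
            meta = json.loads(sc.read_text())
        vs = voxel_size_um or meta.get("voxel_size_um")
        ch = channel or meta.get("channel", "fibers")
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ds = f["volume"]
            data = ds[()]
            vs = voxel_size_um or tuple(ds.attrs.get("voxel_size_um", ()))
            ch = channel or str(ds.attrs.get("channel", "fibers"))
    else:
        raise ValueError(f"unsupported volume container: {path.suffix}")
    if not vs:
        raise ValueError(f"no voxel size metadata for {path}; pass voxel_size_um")
    return VolumeImage(np.asarray(data), tuple(vs), ch)
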