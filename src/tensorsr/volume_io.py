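"""Volume readers and writers.

Supported on-disk formats, selected by extension:

* ``.nii`` / ``.nii.gz`` — NIfTI via nibabel (the standard MRI/CT container);
  the affine and header are carried through as opaque metadata.
* ``.npy`` — portable numpy array.
* ``.bin`` — flat binary (C order) with a ``.json`` sidecar recording shape,
  dtype and the intensity scaling; a lightweight fixture-friendly format.

Intensities are affinely normalized to [0, 1] at read time (the solver's
defaults assume unit range); the original (min, max) is recorded in the
returned metadata and re-applied at write time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["VolumeMeta", "read_volume", "write_volume"]


@dataclass
class VolumeMeta:
    """Provenance of a loaded volume: intensity scaling plus format extras."""

    vmin: float = 0.0
    vmax: float = 1.0
    affine: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def denormalize(self, data: np.ndarray) -> np.ndarray:
        if self.vmax > self.vmin:
            return data * (self.vmax - self.vmin) + self.vmin
        return np.full_like(data, self.vmin)


def _normalize(data: np.ndarray) -> tuple[np.ndarray, float, float]:
    vmin, vmax = float(np.min(data)), float(np.max(data))
    if vmax > vmin:
        return (data - vmin) / (vmax - vmin), vmin, vmax
    return np.zeros_like(data, dtype=float), vmin, vmax


def read_volume(path) -> tuple[np.ndarray, VolumeMeta]:
    """Load a 3D volume, normalized to [0, 1], plus its metadata.

    A 4D payload with a singleton trailing dimension is squeezed (and noted
    in the metadata); any other dimensionality is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    suffixes = "".join(path.suffixes)
    affine = None
    extra: dict = {}
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        affine = img.affine
        extra["format"] = "nifti"
    elif path.suffix == ".npy":
        data = np.load(path).astype(float)
        extra["format"] = "npy"
    elif path.suffix == ".bin":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"sidecar not found for flat binary: {sidecar}")
        header = json.loads(sidecar.read_text())
        data = np.fromfile(path, dtype=np.dtype(header["dtype"])).reshape(
            header["shape"]
        ).astype(float)
        extra["format"] = "bin"
        if "vmin" in header:
            extra["stored_range"] = (header["vmin"], header["vmax"])
    else:
        raise ValueError(f"unrecognized volume format: {path.name}")

    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
        extra["squeezed_trailing_dim"] = True
    if data.ndim != 3:
        raise ValueError(f"expected a 3D payload, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite values in {path}")
    norm, vmin, vmax = _normalize(data)
    return norm, VolumeMeta(vmin=vmin, vmax=vmax, affine=affine, extra=extra)


def write_volume(path, data: np.ndarray, meta: VolumeMeta | None = None) -> None:
    """Write a normalized volume, restoring the original intensity range.

    The stored payload is float32; NIfTI output carries the affine from
    ``meta`` (identity if absent), flat-binary output records the scaling in
    its JSON sidecar.
    """
    path = Path(path)
    meta = meta or VolumeMeta(vmin=float(np.min(data)), vmax=1.0)
    out = meta.denormalize(np.asarray(data, dtype=float)).astype(np.float32)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = meta.affine if meta.affine is not None else np.eye(4)
        nib.save(nib.Nifti1Image(out, affine), str(path))
    elif path.suffix == ".npy":
        np.save(path, out)
    elif path.suffix == ".bin":
        out.tofile(path)
        path.with_suffix(".json").write_text(
            json.dumps(
                {
                    "shape": list(out.shape),
                    "dtype": "float32",
                    "order": "C",
                    "vmin": meta.vmin,
                    "vmax": meta.vmax,
                }
            )
        )
    else:
        raise ValueError(f"unrecognized volume format: {path.name}")
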