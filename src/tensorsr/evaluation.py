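"""Volumetric image-quality metrics (PSNR, SSIM) and the nearest-neighbour
upsampling baseline.

PSNR uses a caller-supplied peak (default 1.0, matching the package-wide
normalized intensity convention).  SSIM is computed on each axial slice with
the standard 11x11 Gaussian window (sigma 1.5, K1=0.01, K2=0.03) and averaged
over slices; a volume-native 3D SSIM is deliberately not defined here since
slicewise averaging is the convention in the 3D super-resolution literature.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["QualityReport", "psnr", "ssim", "ssim_slice", "nn_upsample", "quality_report"]

_SSIM_SIGMA = 1.5
_SSIM_RADIUS = 5  # 11x11 window
_K1, _K2 = 0.01, 0.03


def psnr(x: np.ndarray, ref: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` when the volumes coincide."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {ref.shape}")
    if peak <= 0:
        raise ValueError("peak must be > 0")
    mse = float(np.mean((x - ref) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak**2 / mse)


def _filt(img: np.ndarray) -> np.ndarray:
    return gaussian_filter(img, _SSIM_SIGMA, mode="reflect", radius=_SSIM_RADIUS)


def ssim_slice(x: np.ndarray, ref: np.ndarray, data_range: float = 1.0) -> float:
    """Mean SSIM of one 2D slice pair (Gaussian-weighted local statistics).

    Local means/variances/covariance come from an 11x11 Gaussian window
    (sigma 1.5); the mean is taken over the interior where the window fits,
    so boundary padding does not influence the score.
    """
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {ref.shape}")
    if min(x.shape) < 2 * _SSIM_RADIUS + 1:
        raise ValueError("slice smaller than the 11x11 SSIM window")
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2
    ux, uy = _filt(x), _filt(ref)
    vx = _filt(x * x) - ux * ux
    vy = _filt(ref * ref) - uy * uy
    cov = _filt(x * ref) - ux * uy
    s = ((2 * ux * uy + c1) * (2 * cov + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    r = _SSIM_RADIUS
    return float(s[r:-r, r:-r].mean())


def ssim(x: np.ndarray, ref: np.ndarray, data_range: float = 1.0, axis: int = 2) -> float:
    """Mean slicewise SSIM of two volumes along ``axis`` (default axial)."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {ref.shape}")
    vals = [
        ssim_slice(np.take(x, i, axis=axis), np.take(ref, i, axis=axis), data_range)
        for i in range(x.shape[axis])
    ]
    return float(np.mean(vals))


def nn_upsample(y: np.ndarray, factors, out_shape: tuple | None = None) -> np.ndarray:
    """Nearest-neighbour upsampling: replicate each voxel ``factor`` times per axis.

    ``out_shape`` crops the replicated volume (needed when the HR extent is
    not a multiple of the factor).
    """
    y = np.asarray(y, dtype=float)
    if np.isscalar(factors):
        factors = (factors,) * y.ndim
    out = y
    for axis, f in enumerate(factors):
        if int(f) != f or f < 1:
            raise ValueError("factors must be positive integers")
        out = np.repeat(out, int(f), axis=axis)
    if out_shape is not None:
        out = out[tuple(slice(0, s) for s in out_shape)]
    return out


@dataclass
class QualityReport:
    """Volumetric and per-slice PSNR/SSIM along one axis."""

    psnr_db: float
    ssim: float
    per_slice_psnr: list = field(default_factory=list)
    per_slice_ssim: list = field(default_factory=list)
    axis: int = 2

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["slice", "psnr_db", "ssim"])
            for i, (p, s) in enumerate(zip(self.per_slice_psnr, self.per_slice_ssim)):
                writer.writerow([i, f"{p:.6f}", f"{s:.6f}"])


def quality_report(
    x: np.ndarray, ref: np.ndarray, peak: float = 1.0, axis: int = 2
) -> QualityReport:
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    per_p = []
    per_s = []
    for i in range(x.shape[axis]):
        xs = np.take(x, i, axis=axis)
        rs = np.take(ref, i, axis=axis)
        mse = float(np.mean((xs - rs) ** 2))
        per_p.append(float("inf") if mse == 0 else 10.0 * np.log10(peak**2 / mse))
        per_s.append(ssim_slice(xs, rs, data_range=peak))
    return QualityReport(
        psnr_db=psnr(x, ref, peak),
        ssim=float(np.mean(per_s)),
        per_slice_psnr=per_p,
        per_slice_ssim=per_s,
        axis=axis,
    )
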