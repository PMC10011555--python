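"""PSF anisotropy compensation and isotropic resampling.

Point-scanning fluorescence microscopes resolve far better laterally
than axially; left uncorrected, this bias propagates into the Hessian
and skews every 3D orientation estimate. The remedy used here blurs
each XY plane with the 2D Gaussian whose variance tops the lateral PSF
up to the axial one (sigma_x^2 = sigma_PSFz^2 - sigma_PSFx^2, and
likewise for y), then downsamples laterally to an isotropic voxel size
(1 um by default) before any Hessian analysis. Both steps are optional
and may be skipped on deconvolved or already-isotropic data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import VolumeImage

#: FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian profile
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: lateral / axial PSF FWHM of the reference two-photon setup, um
DEFAULT_PSF_FWHM_UM = (0.692, 0.692, 2.612)


@dataclass(frozen=True)
class PSFModel:
    """Gaussian PSF model given by its FWHM along x, y and z (um).

    The axial FWHM must not be smaller than the lateral ones, otherwise
    the compensating blur would need a negative variance.
    """

    fwhm_x: float
    fwhm_y: float
    fwhm_z: float

    def __post_init__(self) -> None:
        if min(self.fwhm_x, self.fwhm_y, self.fwhm_z) <= 0:
            raise ValueError("PSF FWHM values must be positive")

    @property
    def sigmas(self) -> tuple[float, float, float]:
        return (self.fwhm_x / FWHM_TO_SIGMA, self.fwhm_y / FWHM_TO_SIGMA,
                self.fwhm_z / FWHM_TO_SIGMA)


def anisotropy_sigmas(psf: PSFModel) -> tuple[float, float]:
    """Standard deviations (um) of the in-plane Gaussian blur that
    equalizes lateral and axial resolution.

    sigma_i = sqrt(sigma_PSFz^2 - sigma_PSFi^2) for i in {x, y}; an
    isotropic PSF yields (0, 0), i.e. no blur.
    """
    sx, sy, sz = psf.sigmas
    if sz < sx or sz < sy:
        raise ValueError(
            "axial FWHM smaller than lateral: the compensating variance "
            f"would be negative (FWHM x/y/z = {psf.fwhm_x}/{psf.fwhm_y}/"
            f"{psf.fwhm_z} um)")
    return (float(np.sqrt(sz**2 - sx**2)), float(np.sqrt(sz**2 - sy**2)))


def lateral_blur(vol: VolumeImage,
                 sigmas_um: tuple[float, float]) -> VolumeImage:
    """Convolve every XY plane with a 2D Gaussian of the given standard
    deviations (um, converted to voxels via the volume metadata); z is
    untouched."""
    sx, sy = sigmas_um
    if sx < 0 or sy < 0:
        raise ValueError("blur sigmas must be non-negative")
    if sx == 0 and sy == 0:
        return vol.copy()
    dz, dy, dx = vol.voxel_size_um
    out = ndimage.gaussian_filter(vol.data, (0.0, sy / dy, sx / dx),
                                  mode="reflect", output=np.float32)
    return VolumeImage(out, vol.voxel_size_um, vol.channel)


def isotropize(vol: VolumeImage, target_um: float = 1.0) -> VolumeImage:
    """Downsample to an isotropic ``target_um`` voxel size with linear
    interpolation (axes already at the target are left untouched).

    Only downsampling is supported: the target must not be finer than
    any native voxel dimension.
    """
    if target_um <= 0:
        raise ValueError("target voxel size must be positive")
    native = np.asarray(vol.voxel_size_um)
    if np.any(target_um < native - 1e-9):
        raise ValueError(
            f"target {target_um} um would upsample native voxel size "
            f"{vol.voxel_size_um}")
    factors = native / target_um
    if np.allclose(factors, 1.0):
        return VolumeImage(vol.data.copy(), (target_um,) * 3, vol.channel)
    # sample the input exactly at target_um spacing (an affine map with
    # the exact scale; zoom() would quietly round the scale to an
    # integer-shape ratio and distort the voxel size on small volumes)
    step = target_um / native
    shape = tuple(int(np.floor((n - 1) / s)) + 1
                  for n, s in zip(vol.shape, step))
    out = ndimage.affine_transform(vol.data, np.diag(step), order=1,
                                   output_shape=shape, mode="nearest",
                                   output=np.float32)
    return VolumeImage(out, (target_um,) * 3, vol.channel)


def preprocess(vol: VolumeImage, psf: PSFModel | None = None,
               target_um: float = 1.0, blur: bool = True,
               resample: bool = True) -> VolumeImage:
    """Standard preprocessing chain: anisotropy-compensating lateral
    blur followed by isotropic resampling; either stage can be skipped."""
    out = vol
    if blur and psf is not None:
        out = lateral_blur(out, anisotropy_sigmas(psf))
    if resample:
        out = isotropize(out, target_um)
    return out
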