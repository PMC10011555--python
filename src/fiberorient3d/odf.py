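"""Orientation distribution functions on super-voxel grids.

Masked voxel-wise fiber orientations are aggregated into per-compartment
ODFs through the analytical spherical-harmonics route: each orientation
is treated as a Dirac delta on the unit sphere, so the expansion
coefficients of the compartment's distribution are simply the mean of
the basis functions over the K orientations,

    c_lm = (1/K) sum_k Y_lm(theta_k, phi_k),

with no intermediate directional histogram. Orientations are axial
(v and -v identical), hence only even orders carry information; the
expansion is truncated at lmax = 6 (28 real coefficients) and stored in
the real symmetric basis with MRtrix-compatible ordering (ascending
even l, m from -l to l), which serializes straight into a 4D NIfTI
viewable in MRtrix3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.special import sph_harm_y

from .masking import OrientationField

DEFAULT_LMAX = 6


def even_orders(lmax: int) -> list[tuple[int, int]]:
    """(l, m) pairs of the real even-order basis, storage order."""
    if lmax < 0 or lmax % 2:
        raise ValueError("lmax must be a non-negative even integer")
    return [(l, m) for l in range(0, lmax + 1, 2) for m in range(-l, l + 1)]


def n_coefficients(lmax: int) -> int:
    """Number of real even-order coefficients: (lmax+1)(lmax+2)/2."""
    return (lmax + 1) * (lmax + 2) // 2


def real_sh(l: int, m: int, theta, phi):
    """Real symmetric spherical-harmonic basis value.

    ``theta`` is the polar angle from +z and ``phi`` the azimuth, in
    radians. The complex exponential of the standard basis is replaced
    by cos(m phi) (m > 0), sin(|m| phi) (m < 0) or 1 (m = 0), keeping
    the orthonormal normalization.
    """
    if abs(m) > l:
        raise ValueError(f"|m| = {abs(m)} exceeds l = {l}")
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    y = sph_harm_y(l, abs(m), theta, phi)
    if m == 0:
        out = y.real
    elif m > 0:
        out = np.sqrt(2.0) * (-1.0) ** m * y.real
    else:
        out = np.sqrt(2.0) * (-1.0) ** m * y.imag
    return out if out.ndim else float(out)


def _basis_matrix(theta: np.ndarray, phi: np.ndarray, lmax: int) -> np.ndarray:
    """(N, n_coefficients) matrix of basis evaluations."""
    cols = [real_sh(l, m, theta, phi) for l, m in even_orders(lmax)]
    return np.stack(cols, axis=-1)


def sh_coefficients(theta: np.ndarray, phi: np.ndarray,
                    lmax: int = DEFAULT_LMAX) -> np.ndarray:
    """Analytical even-order SH coefficients of K delta orientations.

    ``theta``/``phi`` are the polar/azimuth angles (radians) of the K
    orientations; the result is their basis-function mean. Axial
    symmetry makes the coefficients invariant to sign flips of any
    orientation. K = 0 is the caller's empty-compartment case, not an
    error here at the math layer.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    if theta.size == 0:
        raise ValueError("need at least one orientation")
    return _basis_matrix(theta, phi, lmax).mean(axis=0)


def synthesize(coefficients: np.ndarray, theta: np.ndarray,
               phi: np.ndarray, lmax: int | None = None) -> np.ndarray:
    """Evaluate the truncated expansion sum_lm c_lm Y_lm at the given
    sphere points (used for lobe finding and plotting)."""
    coefficients = np.asarray(coefficients, dtype=float)
    if lmax is None:
        # invert n = (l+1)(l+2)/2 for even l
        lmax = int(round((np.sqrt(8 * coefficients.size + 1) - 3) / 2))
    if n_coefficients(lmax) != coefficients.size:
        raise ValueError("coefficient count does not match lmax")
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    return _basis_matrix(theta, phi, lmax) @ coefficients


def vectors_to_sphere_angles(vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Polar and azimuth angles (radians) of unit vectors given as
    (..., 3) arrays of (x, y, z) components."""
    v = np.asarray(vectors, dtype=float)
    theta = np.arccos(np.clip(v[..., 2], -1.0, 1.0))
    phi = np.arctan2(v[..., 1], v[..., 0])
    return theta, phi


@dataclass
class ODFField:
    """Grid of super-voxel ODF coefficient sets.

    ``coefficients`` has shape (gz, gy, gx, n_coefficients(lmax));
    ``counts`` holds K, the number of orientations aggregated into each
    super-voxel. Super-voxels with K = 0 are flagged empty and carry
    all-zero coefficients; wherever K >= 1, c_00 = 1/(2 sqrt(pi))
    exactly (the l = 0 basis value is constant).
    """

    coefficients: np.ndarray
    counts: np.ndarray
    sv_size_um: float
    lmax: int = DEFAULT_LMAX

    @property
    def empty(self) -> np.ndarray:
        return self.counts == 0

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.counts.shape


def supervoxel_odfs(field: OrientationField, sv_size_um: float,
                    voxel_size_um: tuple[float, float, float] = (1, 1, 1),
                    lmax: int = DEFAULT_LMAX) -> ODFField:
    """Partition the orientation field into axis-aligned cubes of side
    ``sv_size_um`` and compute each compartment's analytical ODF from
    the masked orientations inside it.

    Edge super-voxels may cover the volume only partially; they are
    retained (their K makes them filterable downstream).
    """
    dz, dy, dx = voxel_size_um
    if sv_size_um < max(voxel_size_um):
        raise ValueError("super-voxel size must be at least one voxel")
    nz, ny, nx = field.mask.shape
    sv_vox = (max(1, int(round(sv_size_um / dz))),
              max(1, int(round(sv_size_um / dy))),
              max(1, int(round(sv_size_um / dx))))
    grid = tuple(int(np.ceil(n / s)) for n, s in zip((nz, ny, nx), sv_vox))
    ncoef = n_coefficients(lmax)
    coeffs = np.zeros(grid + (ncoef,), dtype=np.float32)
    counts = np.zeros(grid, dtype=np.int64)
    zi, yi, xi = np.nonzero(field.mask)
    if zi.size:
        sv_index = np.ravel_multi_index(
            (zi // sv_vox[0], yi // sv_vox[1], xi // sv_vox[2]), grid)
        vecs = field.vectors[zi, yi, xi]
        theta, phi = vectors_to_sphere_angles(vecs)
        basis = _basis_matrix(theta, phi, lmax)
        nsv = int(np.prod(grid))
        counts = np.bincount(sv_index, minlength=nsv)
        sums = np.zeros((nsv, ncoef))
        for j in range(ncoef):
            sums[:, j] = np.bincount(sv_index, weights=basis[:, j],
                                     minlength=nsv)
        with np.errstate(invalid="ignore"):
            mean = np.where(counts[:, None] > 0, sums / counts[:, None], 0.0)
        coeffs = mean.reshape(grid + (ncoef,)).astype(np.float32)
        counts = counts.reshape(grid)
    return ODFField(coeffs, counts.astype(np.int64), float(sv_size_um), lmax)


def write_odf(odf: ODFField, path: str | Path) -> Path:
    """Write the coefficient grid as a 4D NIfTI (x, y, z, coefficient)
    with the super-voxel size as voxel spacing, plus a JSON sidecar
    (lmax, sv size, empty-compartment count) and the K map as a 16-bit
    NIfTI alongside."""
    path = Path(path)
    s = odf.sv_size_um
    affine = np.diag([s, s, s, 1.0])
    # grid arrays are (z, y, x, c); NIfTI wants (x, y, z, c)
    data = np.transpose(odf.coefficients, (2, 1, 0, 3)).astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), path)
    k_path = path.with_name(path.name.replace(".nii", "_k.nii"))
    k = np.transpose(np.minimum(odf.counts, np.iinfo(np.uint16).max),
                     (2, 1, 0)).astype(np.uint16)
    nib.save(nib.Nifti1Image(k, affine), k_path)
    sidecar = {"lmax": odf.lmax, "sv_size_um": odf.sv_size_um,
               "n_coefficients": int(odf.coefficients.shape[-1]),
               "k_map": k_path.name, "n_empty": int(odf.empty.sum())}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))
    return path


def read_odf(path: str | Path) -> ODFField:
    """Round-trip reader for :func:`write_odf` output."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    img = nib.load(path)
    coeffs = np.transpose(np.asarray(img.dataobj, dtype=np.float32),
                          (2, 1, 0, 3))
    k_img = nib.load(path.with_name(sidecar["k_map"]))
    counts = np.transpose(np.asarray(k_img.dataobj), (2, 1, 0)).astype(np.int64)
    return ODFField(coeffs, counts, float(sidecar["sv_size_um"]),
                    int(sidecar["lmax"]))
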