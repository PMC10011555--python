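"""Scale-to-radius characterization of the tubular enhancement.

Reproduces the classic calibration experiment: a noiseless cylinder of
known radius is filtered at a sweep of scale-to-radius ratios and the
cross-sectional vesselness profile at the axis midpoint is scored for
intensity and size preservation. Too small a scale turns the smoothing
kernel into a near-delta and the response into a spurious ridge at the
fiber edge; too large a scale blurs the structure and inflates its
apparent calibre. The scale that best preserves the original intensity
and cross-sectional size sits at half the fiber radius, which yields
the working mapping scale = diameter / 4 (1, 1.25 and 1.5 um scales
for 4, 5 and 6 um fibers).

Preservation is measured on the *raw* curvature response (the Hessian
with the sigma^2 scale-compensation factor divided out): compensation
is what makes responses comparable *across* scales inside the
multiscale maximum, but preservation of the original image contrast is
a fixed-unit question, answered by the curvature amplitude the
smoothed image actually retains. At small scale-to-radius ratios the
global profile maximum is the spurious edge ridge, so responses are
read at the axis midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import frangi3d
from .phantoms import make_cylinder
from .volume import VolumeImage

DEFAULT_RATIOS = np.arange(0.1, 1.51, 0.1)

#: smallest representable filter scale, in voxels: below this the sampled
#: Gaussian-derivative kernels degenerate into noisy finite differences
MIN_SIGMA_VOX = 0.7


@dataclass
class SweepPoint:
    """One entry of a scale or diameter sweep."""

    scale_um: float
    radius_um: float
    s_axis: float              # raw structureness at the axis midpoint
    axis_response: float       # vesselness at the axis (sweep-wide gamma)
    fwhm_um: float             # contiguous FWHM of the profile at the axis
    profile: np.ndarray        # 1D cross-sectional vesselness profile

    @property
    def ratio(self) -> float:
        return self.scale_um / self.radius_um

    @property
    def fwhm_norm(self) -> float:
        return self.fwhm_um / (2.0 * self.radius_um)


def _fwhm_around_center(profile: np.ndarray, dx: float) -> float:
    """FWHM of the lobe containing the profile center, with linear
    interpolation at the half-crossings."""
    n = len(profile)
    c = n // 2
    ref = profile[c]
    if ref <= 0:
        return 0.0
    half = ref / 2.0
    li = c
    while li > 0 and profile[li - 1] >= half:
        li -= 1
    ri = c
    while ri < n - 1 and profile[ri + 1] >= half:
        ri += 1
    left = float(li)
    if li > 0 and profile[li] > profile[li - 1]:
        left = li - (profile[li] - half) / (profile[li] - profile[li - 1])
    right = float(ri)
    if ri < n - 1 and profile[ri] > profile[ri + 1]:
        right = ri + (profile[ri] - half) / (profile[ri] - profile[ri + 1])
    return (right - left) * dx


def _raw_hessian(vol: VolumeImage, sigma_um: float) -> frangi3d.HessianField:
    """Hessian at scale sigma with the sigma^2 compensation divided out."""
    h = frangi3d.scale_space_hessian(vol, sigma_um)
    norm = np.float32(h.sigma_vox**2)
    for k in h.components:
        h.components[k] = h.components[k] / norm
    return h


def _axis_raw_structureness(vol: VolumeImage, sigma_um: float) -> float:
    h = _raw_hessian(vol, sigma_um)
    nz, ny, nx = h.shape
    return float(h.structureness()[nz // 2, ny // 2, nx // 2])


def _sweep_points(volumes: list[tuple[VolumeImage, float]],
                  scales_um: list[float],
                  alpha: float, beta: float) -> list[SweepPoint]:
    """Raw-response sweep over (volume, radius) / scale pairs under a
    single sweep-wide auto gamma (half the largest axis structureness)."""
    hessians = [_raw_hessian(vol, s) for (vol, _), s in zip(volumes, scales_um)]
    s_axes = []
    for h in hessians:
        nz, ny, nx = h.shape
        s_axes.append(float(h.structureness()[nz // 2, ny // 2, nx // 2]))
    gamma = frangi3d.auto_gamma(np.asarray(s_axes))
    points = []
    for h, (vol, radius), sigma, s_axis in zip(hessians, volumes, scales_um,
                                               s_axes):
        nz, ny, nx = h.shape
        # only the central cross-sectional slice feeds the 1D profile
        sel = np.zeros(h.shape, dtype=bool)
        sel[nz // 2] = True
        e = frangi3d.eigen_decompose(h, where=sel)
        f = frangi3d.frangi_features(e)
        v = frangi3d.vesselness(f, e.eigenvalues, alpha, beta,
                                gamma).reshape(ny, nx)
        profile = v[ny // 2, :]
        fwhm = _fwhm_around_center(profile, vol.voxel_size_um[2])
        points.append(SweepPoint(float(sigma), float(radius), s_axis,
                                 float(profile[nx // 2]), fwhm, profile))
    return points


def scale_sweep(radius_um: float = 1.0,
                ratios: np.ndarray | None = None,
                px_per_um: float = 10.0, aspect_ratio: float = 12.0,
                alpha: float = frangi3d.DEFAULT_ALPHA,
                beta: float = frangi3d.DEFAULT_BETA) -> list[SweepPoint]:
    """Sweep scale-to-radius ratios (default 10%..150% in 10% steps) on
    one noiseless cylinder and return the per-ratio responses."""
    if ratios is None:
        ratios = DEFAULT_RATIOS
    ratios = np.asarray(ratios, dtype=float)
    pad = float(4.0 * ratios.max() * radius_um)
    ph = make_cylinder(radius_um, aspect_ratio, px_per_um, pad_um=pad)
    volumes = [(ph.volume, radius_um)] * len(ratios)
    return _sweep_points(volumes, list(ratios * radius_um), alpha, beta)


def optimal_ratio(points: list[SweepPoint]) -> float:
    """Scale-to-radius ratio maximizing the preserved axis response
    (the profile FWHM stays near the true diameter there; both numbers
    are available on the sweep points)."""
    best = max(points, key=lambda p: p.s_axis)
    return best.ratio


def diameter_sweep(scale_um: float = 1.25,
                   diameters_um: tuple[float, ...] = (3, 4, 5, 6, 7),
                   px_per_um: float = 2.0, aspect_ratio: float = 12.0,
                   ratios: np.ndarray | None = None,
                   alpha: float = frangi3d.DEFAULT_ALPHA,
                   beta: float = frangi3d.DEFAULT_BETA
                   ) -> tuple[list[SweepPoint], list[float]]:
    """Fix the filter scale and sweep cylinder diameters.

    For each diameter the preserved fraction is the axis response at
    the fixed scale relative to the best response attainable for that
    calibre over a full scale sweep (amplitudes of different calibres
    are not directly comparable: thinner tubes always carry larger raw
    curvature). The per-diameter ceiling search only visits scales of
    at least ``MIN_SIGMA_VOX`` voxels. Returns the per-diameter sweep
    points at ``scale_um`` plus the preserved fractions.
    """
    if ratios is None:
        ratios = DEFAULT_RATIOS
    pad = max(6.0, 4.0 * float(scale_um))
    points, preserved = [], []
    for d in diameters_um:
        r = d / 2.0
        pad_d = max(pad, 4.0 * float(np.max(ratios)) * r)
        ph = make_cylinder(r, aspect_ratio, px_per_um, pad_um=pad_d)
        pt = _sweep_points([(ph.volume, r)], [scale_um], alpha, beta)[0]
        sigmas = [float(u) * r for u in ratios
                  if float(u) * r * px_per_um >= MIN_SIGMA_VOX]
        best = max(_axis_raw_structureness(ph.volume, s) for s in sigmas)
        points.append(pt)
        preserved.append(pt.s_axis / best if best > 0 else 0.0)
    return points, preserved


def optimal_diameter(points: list[SweepPoint],
                     preserved: list[float]) -> float:
    """Fiber diameter whose response is best preserved at the fixed scale."""
    i = int(np.argmax(preserved))
    return 2.0 * points[i].radius_um
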