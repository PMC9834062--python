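"""Preprocessing: depth-dependent z-distortion correction and NPC site
segmentation.

Astigmatic 3D SMLM suffers from a depth-dependent axial distortion: the
apparent z spacing of structures shrinks or stretches with imaging depth.
Nuclear pore complexes provide an internal ruler — the Nup96 ring
separation has a known average value E(s) = 49.3 nm — so the measured
vertical separations s_z of many NPCs across depth calibrate a smooth
rescaling of the z axis.  Per NPC the tilt from the optical axis is
ψ = atan2(√(1 − R₃₃²), R₃₃) (R the fitted rotation matrix), the vertical
separation s_z = s·cos ψ, and the local scaling factor
s_f(z) = E(s)·cos ψ / s_z ≈ ∂E(z)/∂z.  A quadratic fit s_z(z) yields a
smooth s_f; integrating it gives the corrected coordinate
z' = E(z) − E(0), anchored so the focal plane stays at zero.

Segmentation renders the 2D localization histogram, convolves it with a
ring-of-Gaussians kernel matched to the approximate NPC radius, keeps
local maxima above a threshold, and cleans candidates with circle-fit and
localization-fraction filters.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .locdata import LocalizationSet, Site, crop_site

__all__ = [
    "EXPECTED_SEPARATION",
    "DistortionModel",
    "tilt_angle",
    "fit_distortion",
    "apply_distortion_correction",
    "fit_circle",
    "fit_circle_fixed_radius",
    "segment_npc_sites",
]

#: previously determined average Nup96 ring separation, nm
EXPECTED_SEPARATION = 49.3


def tilt_angle(R: np.ndarray) -> float:
    """Tilt ψ of a fitted structure's symmetry axis from the z axis,
    from the (3,3) element of the rotation matrix."""
    r33 = float(R[2, 2])
    return math.atan2(math.sqrt(max(0.0, 1.0 - r33**2)), r33)


@dataclass
class DistortionModel:
    """Quadratic model of the measured vertical ring separation vs depth.

    ``s_f(z) = amplitude / (c1·z² + c2·z + c3)`` is the local axial
    scaling factor, equal to 1 at ``z0``; ``amplitude = E(s)·⟨cos ψ⟩``.
    """

    c1: float
    c2: float
    c3: float
    z0: float
    amplitude: float
    expected_separation: float = EXPECTED_SEPARATION
    z_range: tuple = (-500.0, 500.0)

    def separation_at(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return self.c1 * z**2 + self.c2 * z + self.c3

    def scale_factor(self, z) -> np.ndarray:
        """s_f(z) = E(s)·⟨cos ψ⟩ / s_z(z)."""
        return self.amplitude / self.separation_at(z)

    def corrected_z(self, z) -> np.ndarray:
        """E(z) = ∫ s_f dz with E(z0) = z0, evaluated by quadrature on a
        1-nm grid, then shifted so the focal plane maps to zero:
        z' = E(z) − E(0)."""
        z = np.asarray(z, dtype=float)
        lo = min(float(z.min(initial=self.z0)), self.z0, 0.0) - 1.0
        hi = max(float(z.max(initial=self.z0)), self.z0, 0.0) + 1.0
        grid = np.arange(lo, hi + 1.0, 1.0)
        sf = self.scale_factor(grid)
        if np.any(sf <= 0):
            raise ValueError("scaling factor must stay positive in range")
        integral = np.concatenate(
            [[0.0], np.cumsum((sf[1:] + sf[:-1]) / 2 * np.diff(grid))])
        ez = np.interp(z, grid, integral)
        ez0 = np.interp(self.z0, grid, integral)
        e0 = np.interp(0.0, grid, integral)
        # anchor: E(z0) = z0, then report E(z) − E(0)
        return (ez - ez0 + self.z0) - (e0 - ez0 + self.z0)


def fit_distortion(z: np.ndarray, separation: np.ndarray,
                   rotations: np.ndarray | None = None,
                   expected_separation: float = EXPECTED_SEPARATION
                   ) -> DistortionModel:
    """Fit the quadratic depth model of the vertical ring separation.

    Parameters: per-site depth ``z`` (nm), fitted separation ``s`` (nm)
    and optional per-site 3×3 rotation matrices (for the tilt correction
    s_z = s·cos ψ; untilted sites are assumed when omitted).  Needs at
    least 10 sites with a non-degenerate z spread.
    """
    z = np.asarray(z, dtype=float)
    s = np.asarray(separation, dtype=float)
    if len(z) < 10:
        raise ValueError("need at least 10 sites")
    if np.ptp(z) < 1e-9:
        raise ValueError("degenerate z spread")
    if rotations is not None:
        cospsi = np.array([math.cos(tilt_angle(R)) for R in rotations])
    else:
        cospsi = np.ones_like(z)
    s_z = s * cospsi
    c1, c2, c3 = np.polyfit(z, s_z, 2)
    amplitude = expected_separation * float(cospsi.mean())
    # z0 solves s_f(z0) = 1, i.e. the quadratic equals the amplitude;
    # pick the root closest to the focal plane
    roots = np.roots([c1, c2, c3 - amplitude])
    real = roots[np.abs(roots.imag) < 1e-9].real
    z0 = float(real[np.argmin(np.abs(real))]) if real.size else 0.0
    return DistortionModel(float(c1), float(c2), float(c3), z0, amplitude,
                           expected_separation,
                           z_range=(float(z.min()), float(z.max())))


def apply_distortion_correction(locs: LocalizationSet,
                                model: DistortionModel,
                                rescale_sigma_z: bool = True) -> LocalizationSet:
    """Replace each z by E(z) − E(0); x, y (and their precisions) are
    untouched.  Values outside the fitted z range are extrapolated (flag
    it upstream if that matters).

    Because the correction is a remap of the z axis, first-order error
    propagation rescales the axial precision by the local factor,
    σ_z' = s_f(z)·σ_z (disable with ``rescale_sigma_z=False``).
    """
    if locs.ndim != 3:
        raise ValueError("z correction needs 3D localizations")
    coords = locs.coords.copy()
    z = coords[:, 2].copy()
    coords[:, 2] = model.corrected_z(z)
    out = locs.with_coords(coords)
    if rescale_sigma_z:
        prec = out.precisions.copy()
        prec[:, 2] *= model.scale_factor(z)
        out = dataclasses.replace(out, precisions=prec)
    return out


# ---------------------------------------------------------------------------
# circle fits (segmentation sub-oracle)
# ---------------------------------------------------------------------------

def fit_circle(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kåsa) least-squares circle fit followed by one
    Gauss-Newton refinement of Σ(|x − c| − R)².  Returns (center, radius)."""
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones(len(x))])
    b = x**2 + y**2
    (cx, cy, c0), *_ = np.linalg.lstsq(A, b, rcond=None)
    r = math.sqrt(max(c0 + cx**2 + cy**2, 0.0))
    center = np.array([cx, cy])
    # one Gauss-Newton step on (cx, cy, r)
    d = np.linalg.norm(xy - center, axis=1)
    ok = d > 1e-12
    if ok.sum() >= 3:
        # residual g_i = d_i − r, Jacobian [∂g/∂c, ∂g/∂r] = [u_i, −1]
        u = (center - xy[ok]) / d[ok, None]
        Jm = np.column_stack([u, -np.ones(ok.sum())])
        g = d[ok] - r
        try:
            delta, *_ = np.linalg.lstsq(Jm, -g, rcond=None)
            center = center + delta[:2]
            r = r + delta[2]
        except np.linalg.LinAlgError:
            pass
    return center, float(r)


def fit_circle_fixed_radius(xy: np.ndarray, radius: float,
                            init: np.ndarray | None = None,
                            n_iter: int = 10) -> np.ndarray:
    """Gauss-Newton center fit with the radius held fixed."""
    center = np.asarray(init, float) if init is not None else xy.mean(axis=0)
    for _ in range(n_iter):
        d = np.linalg.norm(xy - center, axis=1)
        ok = d > 1e-12
        if ok.sum() < 2:
            break
        u = (center - xy[ok]) / d[ok, None]
        g = d[ok] - radius
        delta, *_ = np.linalg.lstsq(u, -g, rcond=None)
        center = center + delta
        if np.linalg.norm(delta) < 1e-9:
            break
    return center


def _ring_kernel(ring_radius: float, gauss_sd: float,
                 pixel: float) -> np.ndarray:
    """Ring of radius ``ring_radius`` convolved with a Gaussian of SD
    ``gauss_sd`` (both nm), sampled at ``pixel`` nm."""
    half = int(math.ceil((ring_radius + 4 * gauss_sd) / pixel))
    ax = np.arange(-half, half + 1) * pixel
    X, Y = np.meshgrid(ax, ax)
    r = np.hypot(X, Y)
    kern = np.exp(-0.5 * ((r - ring_radius) / gauss_sd) ** 2)
    # unit peak: the convolved score reads as a ring-weighted count
    return kern / kern.max()


def segment_npc_sites(locs: LocalizationSet, render_pixel: float = 5.0,
                      threshold: float = 5.0, ring_radius: float = 55.0,
                      gauss_sd: float = 10.0, site_size: float = 300.0,
                      radius_bounds: tuple = (40.0, 70.0),
                      fixed_radius: float = 53.4,
                      min_locs: int = 30) -> list[Site]:
    """Detect candidate NPC sites in a 2D projection and clean them up.

    Pipeline: render the x-y localization histogram at ``render_pixel``
    nm; convolve with a ring⊗Gaussian kernel; local maxima above
    ``threshold`` become candidates.  Each candidate is then (1) circle
    fitted with a free radius and rejected outside ``radius_bounds``
    ([40, 70] nm); (2) refitted with the fixed radius to pin the center
    and rejected if more than 25% of its localizations lie closer than
    40 nm to the center or more than 40% lie further than 70 nm; and
    (3) rejected with fewer than ``min_locs`` (30) localizations.
    """
    xy = locs.coords[:, :2]
    if not len(xy):
        return []
    lo = xy.min(axis=0) - 2 * ring_radius
    hi = xy.max(axis=0) + 2 * ring_radius
    nx = int(math.ceil((hi[0] - lo[0]) / render_pixel))
    ny = int(math.ceil((hi[1] - lo[1]) / render_pixel))
    hist, xe, ye = np.histogram2d(xy[:, 0], xy[:, 1], bins=(nx, ny),
                                  range=[[lo[0], hi[0]], [lo[1], hi[1]]])
    kern = _ring_kernel(ring_radius, gauss_sd, render_pixel)
    score = signal.fftconvolve(hist, kern, mode="same")
    # suppress secondary maxima within roughly one NPC diameter
    win = 2 * int(math.ceil(ring_radius / render_pixel)) + 1
    local_max = (score == ndimage.maximum_filter(score, size=win))
    cand = np.argwhere(local_max & (score > threshold))
    cand = cand[np.argsort(-score[cand[:, 0], cand[:, 1]], kind="stable")]
    inner_r, outer_r = 40.0, 70.0
    sites = []
    accepted_centers = []
    for (ix, iy) in cand:
        center = np.array([(xe[ix] + xe[ix + 1]) / 2,
                           (ye[iy] + ye[iy + 1]) / 2])
        near = xy[np.abs(xy - center).max(axis=1) <= site_size / 2]
        if len(near) < 3:
            continue
        c_free, r_free = fit_circle(near)
        if not (radius_bounds[0] <= r_free <= radius_bounds[1]):
            continue
        c_fix = fit_circle_fixed_radius(near, fixed_radius, init=c_free)
        d = np.linalg.norm(near - c_fix, axis=1)
        if (d < inner_r).mean() > 0.25 or (d > outer_r).mean() > 0.40:
            continue
        if len(near) < min_locs:
            continue
        if any(np.linalg.norm(c_fix - c0) < ring_radius
               for c0 in accepted_centers):
            continue  # duplicate detection of an accepted structure
        full_center = np.zeros(locs.ndim)
        full_center[:2] = c_fix
        site = crop_site(locs, full_center, site_size)
        if site.n_locs < min_locs:
            continue
        site.meta["detection_score"] = float(score[ix, iy])
        accepted_centers.append(c_fix)
        sites.append(site)
    return sites
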