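"""Probability-density construction and likelihood evaluation.

The fitting objective treats the localizations of a site as independent
draws from a model PDF ``M(x, σ | p)``.  For a model given as (possibly
discretized) fluorophore positions ``v_j`` with weights ``q_j``, the PDF is
the Gaussian mixture

    M(x, σ | p) = (Σ_j q_j)⁻¹ Σ_j q_j (2π)^(−D/2) det(Σ)^(−1/2)
                  · exp(−½ (x − v_j)ᵀ Σ⁻¹ (x − v_j)),

with the per-localization covariance Σ = diag(σ_x² + ε², σ_y² + ε²[, σ_z² + ε²]);
the extra uncertainty ε absorbs blur beyond the localization precision
(linkage error, drift, unmodeled deformation).  A uniform background PDF
``M_bg = d^(−D)`` over the site of side ``d`` is mixed in with weight
``w_bg``.  The log-likelihood of a site is the sum of log densities,
optionally weighted per color channel.

Poses (extrinsic parameters) are applied either by reverse-transforming
the data into the model frame, ``x' = R⁻¹ S⁻¹ (x − x0)`` (used for
continuous models, where the blur is applied in the model frame), or by
transforming the model points into the data frame, ``v' = S R v + x0``
(used for discrete models, keeping the anisotropic Gaussians axis-aligned
in the data frame).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .locdata import LocalizationSet, Site
from .models import GeometricModel, ModelPoints

__all__ = [
    "Pose",
    "DiscretizedModel",
    "DensityImage",
    "Component",
    "CompositeSpec",
    "rotation_matrix",
    "angles_from_matrix",
    "apply_pose",
    "compose_poses",
    "discretize",
    "pdf_discrete",
    "pdf_image",
    "rasterize",
    "mix_background",
    "background_stats",
    "composite_pdf",
    "log_likelihood",
    "cross_correlation_score",
    "DENSITY_FLOOR",
]

#: densities are clamped here before taking logs, so that a vanishing
#: density yields a large negative but finite log-likelihood (flagged).
DENSITY_FLOOR = 1e-300

SPACING_FACTOR = 0.75  # max spacing δ < 0.75 × min localization precision
MAX_MODEL_POINTS = 2_000_000


class ResourceError(RuntimeError):
    """Discretization would exceed the point budget; raise sigma_min."""


# ---------------------------------------------------------------------------
# poses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pose:
    """Extrinsic parameters: translation x0 (nm), z-y-x rotation angles
    (α, β, γ) in radians about the x, y, z axes, per-axis scale, extra
    uncertainty ε (nm) and background weight w_bg in [0, 1].

    For 2D data only the γ (in-plane) rotation applies.
    """

    x0: tuple = (0.0, 0.0, 0.0)
    angles: tuple = (0.0, 0.0, 0.0)
    scale: tuple = (1.0, 1.0, 1.0)
    extra_sigma: float = 0.0
    bg_weight: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "x0", tuple(float(v) for v in self.x0))
        object.__setattr__(self, "angles", tuple(float(v) for v in self.angles))
        object.__setattr__(self, "scale", tuple(float(v) for v in self.scale))
        if len(self.angles) != 3:
            raise ValueError("angles must be (alpha, beta, gamma)")
        if any(s <= 0 for s in self.scale):
            raise ValueError("scales must be > 0")
        if not (0.0 <= self.bg_weight <= 1.0):
            raise ValueError("bg_weight must be in [0, 1]")
        if self.extra_sigma < 0:
            raise ValueError("extra_sigma must be >= 0")

    @property
    def ndim(self) -> int:
        return len(self.x0)

    def matrix(self) -> np.ndarray:
        """Rotation matrix for this pose's dimensionality."""
        a, b, g = self.angles
        R = rotation_matrix(a, b, g)
        if self.ndim == 2:
            return R[:2, :2]
        return R


def rotation_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """3×3 rotation matrix for z-y-x intrinsic rotation order,
    R = Rx(α) · Ry(β) · Rz(γ): the rotations are applied about the z, y
    and x axes subsequently."""
    ca, sa = math.cos(alpha), math.sin(alpha)
    cb, sb = math.cos(beta), math.sin(beta)
    cg, sg = math.cos(gamma), math.sin(gamma)
    return np.array([
        [cb * cg, -cb * sg, sb],
        [ca * sg + cg * sa * sb, ca * cg - sa * sb * sg, -cb * sa],
        [sa * sg - ca * cg * sb, cg * sa + ca * sb * sg, ca * cb],
    ])


def angles_from_matrix(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`rotation_matrix` (β taken in [−π/2, π/2])."""
    beta = math.asin(np.clip(R[0, 2], -1.0, 1.0))
    if abs(math.cos(beta)) > 1e-12:
        alpha = math.atan2(-R[1, 2], R[2, 2])
        gamma = math.atan2(-R[0, 1], R[0, 0])
    else:  # gimbal lock: fold everything into α
        alpha = math.atan2(R[1, 0], R[1, 1])
        gamma = 0.0
    return alpha, beta, gamma


def compose_poses(outer: Pose, inner: Pose) -> Pose:
    """Rigid composition: applying ``inner`` then ``outer`` (model-to-data)
    equals applying the returned pose once.  Requires unit scales."""
    if any(s != 1.0 for s in outer.scale + inner.scale):
        raise ValueError("compose_poses requires unit scales")
    Ro, Ri = rotation_matrix(*outer.angles), rotation_matrix(*inner.angles)
    x0o = np.array(outer.x0 + (0.0,) * (3 - len(outer.x0)))
    x0i = np.array(inner.x0 + (0.0,) * (3 - len(inner.x0)))
    R = Ro @ Ri
    t = Ro @ x0i + x0o
    d = outer.ndim
    return Pose(x0=tuple(t[:d]), angles=angles_from_matrix(R),
                extra_sigma=math.hypot(outer.extra_sigma, inner.extra_sigma),
                bg_weight=outer.bg_weight)


def invert_pose(pose: Pose) -> Pose:
    """Inverse rigid pose (unit scales): maps data frame back to model frame
    under model-to-data application."""
    if any(s != 1.0 for s in pose.scale):
        raise ValueError("invert_pose requires unit scales")
    R = rotation_matrix(*pose.angles)
    x0 = np.array(pose.x0 + (0.0,) * (3 - len(pose.x0)))
    t = -R.T @ x0
    return Pose(x0=tuple(t[: pose.ndim]), angles=angles_from_matrix(R.T),
                extra_sigma=pose.extra_sigma, bg_weight=pose.bg_weight)


def _transform(coords: np.ndarray, pose: Pose, direction: str) -> np.ndarray:
    D = coords.shape[1]
    R = rotation_matrix(*pose.angles)
    if D == 2:
        R = R[:2, :2]
    S = np.asarray(pose.scale[:D], dtype=float)
    x0 = np.asarray(pose.x0[:D], dtype=float)
    if direction == "data-to-model":
        return (coords - x0) / S @ R  # R⁻¹ S⁻¹ (x − x0); (v/S)·R == R.T @ (v/S)
    elif direction == "model-to-data":
        return (coords @ R.T) * S + x0  # S R v + x0
    raise ValueError("direction must be 'data-to-model' or 'model-to-data'")


def apply_pose(target, pose: Pose, direction: str):
    """Apply a pose to a :class:`LocalizationSet` (coordinates only;
    precisions untouched) or a :class:`DiscretizedModel`.

    ``data-to-model`` reverse-transforms coordinates,
    ``x' = R⁻¹ S⁻¹ (x − x0)``; ``model-to-data`` forward-transforms,
    ``v' = S R v + x0``.  The two are exact inverses of one another.
    """
    if isinstance(target, LocalizationSet):
        return target.with_coords(_transform(target.coords, pose, direction))
    if isinstance(target, DiscretizedModel):
        return replace(target, points=_transform(target.points, pose, direction))
    raise TypeError(f"cannot apply pose to {type(target).__name__}")


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass
class DiscretizedModel:
    """Model points v_j with weights q_j at spacing δ (nm)."""

    points: np.ndarray
    weights: np.ndarray
    spacing: float
    sigma_min: float = 0.0
    channels: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.sum() <= 0:
            raise ValueError("sum of model weights must be > 0")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def in_channel(self, c: int) -> "DiscretizedModel":
        if self.channels is None:
            return self
        m = self.channels == c
        return DiscretizedModel(self.points[m], self.weights[m], self.spacing,
                                self.sigma_min)


def clamp_precisions(locs: LocalizationSet, sigma_min: float) -> np.ndarray:
    """Per-axis precisions with everything below sigma_min raised to it."""
    return np.maximum(locs.precisions, sigma_min)


def max_spacing(locs: LocalizationSet, sigma_min: float = 0.0) -> float:
    """The spacing bound δ < 0.75 · min over all clamped precision
    components."""
    return SPACING_FACTOR * float(clamp_precisions(locs, sigma_min).min())


def discretize(model: GeometricModel, locs: LocalizationSet,
               sigma_min: float = 0.0,
               values: dict | None = None) -> DiscretizedModel:
    """Discretize a continuous model at spacing δ strictly below
    0.75 × the minimum (clamped) localization precision of ``locs``.

    Raising ``sigma_min`` coarsens the sampling and shrinks the model; a
    model that would need more than ~2e6 points raises
    :class:`ResourceError` advising a larger sigma_min.
    """
    # request 99% of the bound so the achieved spacing is strictly below it
    bound = 0.99 * max_spacing(locs, sigma_min)
    mp = model.evaluate(values, spacing=bound)
    if len(mp.points) > MAX_MODEL_POINTS:
        raise ResourceError(
            f"model requires {len(mp.points)} points at spacing {bound:.3g} nm;"
            " increase sigma_min to coarsen the discretization")
    return DiscretizedModel(mp.points, mp.weights, spacing=bound,
                            sigma_min=sigma_min, channels=mp.channels)


# ---------------------------------------------------------------------------
# PDFs
# ---------------------------------------------------------------------------

def pdf_discrete(locs: LocalizationSet, model: DiscretizedModel,
                 extra_sigma: float = 0.0,
                 sigma_min: float | None = None) -> np.ndarray:
    """Gaussian-mixture density of each localization under the model points.

    Each localization uses its own per-axis precision, inflated in
    quadrature by ``extra_sigma``; weights q_j are normalized to sum to 1.
    The normalizing constant is (2π)^(−D/2) det(Σ)^(−1/2) so that the PDF
    integrates to 1 in either dimensionality.
    """
    if model.n_points == 0:
        raise ValueError("empty model")
    if sigma_min is None:
        sigma_min = model.sigma_min
    D = locs.ndim
    if model.points.shape[1] != D:
        raise ValueError("model/data dimensionality mismatch")
    sig = clamp_precisions(locs, sigma_min)
    var = sig**2 + extra_sigma**2  # (K, D)
    norm = (2 * math.pi) ** (-D / 2) / np.sqrt(var.prod(axis=1))  # (K,)
    q = model.weights / model.weights.sum()
    K, J = len(locs.coords), model.n_points
    out = np.zeros(K)
    # chunk over model points to bound the (K, J, D) intermediate
    chunk = max(1, int(4e6 // max(K, 1)))
    inv2var = 0.5 / var  # (K, D)
    for j0 in range(0, J, chunk):
        v = model.points[j0:j0 + chunk]  # (j, D)
        d2 = np.zeros((K, len(v)))
        for ax in range(D):
            diff = locs.coords[:, ax, None] - v[None, :, ax]
            d2 += diff * diff * inv2var[:, ax, None]
        out += np.exp(-d2) @ q[j0:j0 + chunk]
    return norm * out


@dataclass
class DensityImage:
    """Fluorophore density sampled on a cell-centered grid.

    ``origin`` is the coordinate of the center of cell (0, ..., 0);
    ``cell`` the grid spacing in nm (isotropic).
    """

    values: np.ndarray
    origin: np.ndarray
    cell: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def ndim(self) -> int:
        return self.values.ndim


def rasterize(model: GeometricModel, site: Site, cell: float,
              values: dict | None = None,
              spacing: float | None = None) -> DensityImage:
    """Render a model into a density image covering the site box (model
    frame)."""
    D = model.dim if model.dim else site.ndim
    half = site.side_length / 2
    n = int(math.ceil(site.side_length / cell))
    mp = model.evaluate(values, spacing=spacing or cell / 2)
    edges = [np.linspace(-half, half, n + 1)] * D
    hist, _ = np.histogramdd(mp.points[:, :D], bins=edges, weights=mp.weights)
    origin = np.full(D, -half + cell_center_offset(half, n))
    return DensityImage(hist, origin, (2 * half) / n)


def cell_center_offset(half: float, n: int) -> float:
    return (2 * half) / n / 2


def pdf_image(locs: LocalizationSet, image: DensityImage,
              mean_sigma, extra_sigma: float = 0.0) -> np.ndarray:
    """Density of each localization under a density-image model.

    The image is normalized over its support, convolved with a Gaussian of
    per-axis SD sqrt(⟨σ⟩² + ε²) (the blur uses the *mean* localization
    precision rather than per-localization values), renormalized so the
    numerical integral over the covered box is 1, and evaluated at the
    localization coordinates by multilinear interpolation.
    """
    if not np.any(image.values):
        raise ValueError("all-zero density image")
    D = image.ndim
    mean_sigma = np.broadcast_to(np.asarray(mean_sigma, dtype=float), (D,))
    sd = np.sqrt(mean_sigma**2 + extra_sigma**2) / image.cell
    # edge replication keeps a uniform density exactly uniform under blur
    blurred = ndimage.gaussian_filter(image.values, sigma=sd, mode="nearest")
    total = blurred.sum() * image.cell**D
    blurred = blurred / total
    idx = [(locs.coords[:, ax] - image.origin[ax]) / image.cell
           for ax in range(D)]
    return np.clip(
        ndimage.map_coordinates(blurred, np.vstack(idx), order=1,
                                mode="constant", cval=0.0),
        0.0, None)


def background_stats(n_locs: int, bg_weight: float, side_length: float) -> dict:
    """Background bookkeeping: expected background count K_bg = K·w_bg,
    its area density ρ_bg = K_bg/d² and the model-described count
    K_m = K − K_bg."""
    k_bg = n_locs * bg_weight
    return {"K_bg": k_bg, "rho_bg": k_bg / side_length**2,
            "K_m": n_locs - k_bg}


def mix_background(model_pdf: np.ndarray, bg_weight: float,
                   site: Site) -> np.ndarray:
    """Mix the model PDF with the uniform site background:
    (1 − w_bg)·M + w_bg·d^(−D)."""
    if not (0.0 <= bg_weight <= 1.0):
        raise ValueError("bg_weight must be in [0, 1]")
    m_bg = 1.0 / site.volume
    return (1.0 - bg_weight) * model_pdf + bg_weight * m_bg


# ---------------------------------------------------------------------------
# composite models and likelihood
# ---------------------------------------------------------------------------

@dataclass
class Component:
    """One sub-model of a composite: a model, its intrinsic parameter
    values, its pose, a mixture weight and a color channel.

    The pose of component m > 1 is expressed *relative to* component 1:
    the first component's transformation is applied to all components,
    followed by the component's own."""

    model: GeometricModel
    values: dict = field(default_factory=dict)
    pose: Pose = field(default_factory=Pose)
    weight: float = 1.0
    channel: int = 0
    #: for models that emit several point channels (e.g. the endocytic
    #: dome + ring), restrict this component to one of them
    model_channel: int | None = None


@dataclass
class CompositeSpec:
    """A linear combination of sub-models sharing one background.

    Per channel c the density is Σ_m w_m·M_m + w_bg·M_bg over the
    components (and localizations) of that channel; the weights of each
    channel's components plus the shared w_bg must sum to 1.

    ``color_weights='unit'`` uses w_c = 1 for every channel (default);
    ``'ratio'`` uses w_c = K_c⁻¹·Σ_c K_c to balance unequal counts.
    """

    components: list
    bg_weight: float = 0.0
    color_weights: str = "unit"
    sigma_min: float = 0.0

    def __post_init__(self):
        if not self.components:
            raise ValueError("need at least one component")
        for c in self.channels():
            w = sum(comp.weight for comp in self.components if comp.channel == c)
            if abs(w + self.bg_weight - 1.0) > 1e-9:
                raise ValueError(
                    f"channel {c}: component weights ({w}) + bg_weight "
                    f"({self.bg_weight}) must sum to 1")

    def channels(self) -> list[int]:
        return sorted({comp.channel for comp in self.components})


def _component_density(locs: LocalizationSet, comp: Component,
                       base_pose: Pose, sigma_min: float,
                       is_first: bool) -> np.ndarray:
    """Density of one component at the given localizations.

    Continuous and image models reverse-transform the data
    (x' = R⁻¹S⁻¹(x − x0)); discrete models forward-transform their points
    (v' = SRv + x0).
    """
    eps = math.hypot(base_pose.extra_sigma,
                     0.0 if is_first else comp.pose.extra_sigma)
    model = comp.model
    if model.kind == "discrete-points":
        mp = model.evaluate(comp.values)
        dm = DiscretizedModel(mp.points[:, :locs.ndim], mp.weights,
                              spacing=0.0, sigma_min=sigma_min,
                              channels=mp.channels)
        if comp.model_channel is not None:
            dm = dm.in_channel(comp.model_channel)
        dm = apply_pose(dm, comp.pose if not is_first else base_pose,
                        "model-to-data")
        if not is_first:
            dm = apply_pose(dm, base_pose, "model-to-data")
        return pdf_discrete(locs, dm, extra_sigma=eps)
    # continuous kinds: move the data into the component's model frame
    data = apply_pose(locs, base_pose, "data-to-model")
    if not is_first:
        data = apply_pose(data, comp.pose, "data-to-model")
    dm = discretize(model, locs, sigma_min=sigma_min, values=comp.values)
    if comp.model_channel is not None:
        dm = dm.in_channel(comp.model_channel)
    if model.dim and locs.ndim < dm.points.shape[1]:
        dm = replace(dm, points=dm.points[:, :locs.ndim])
    return pdf_discrete(data, dm, extra_sigma=eps)


def composite_pdf(locs: LocalizationSet, spec: CompositeSpec,
                  site: Site) -> np.ndarray:
    """Per-localization density of the composite model (channel-wise)."""
    base = spec.components[0].pose
    out = np.zeros(len(locs.coords))
    for c in spec.channels():
        mask = locs.channel == c
        if not mask.any():
            continue
        sub = locs.select(mask)
        dens = np.zeros(len(sub.coords))
        for i, comp in enumerate(spec.components):
            if comp.channel != c:
                continue
            dens += comp.weight * _component_density(
                sub, comp, base, spec.sigma_min, is_first=(i == 0))
        # shared uniform background completes the per-channel mixture
        dens += spec.bg_weight / site.volume
        out[mask] = dens
    # localizations in channels without a model see background only
    unmodeled = ~np.isin(locs.channel, spec.channels())
    if unmodeled.any():
        out[unmodeled] = spec.bg_weight / site.volume
    return out


def _color_weights(locs: LocalizationSet, spec: CompositeSpec) -> dict:
    chans = list(np.unique(locs.channel))
    if spec.color_weights == "unit":
        return {c: 1.0 for c in chans}
    counts = {c: int((locs.channel == c).sum()) for c in chans}
    total = sum(counts.values())
    return {c: total / counts[c] for c in chans}


def log_likelihood(locs: LocalizationSet, spec: CompositeSpec,
                   site: Site) -> tuple[float, dict]:
    """Channel-weighted log-likelihood LL = Σ_c w_c Σ_{k∈c} ln M_c.

    Returns ``(LL, info)``; ``info['floored']`` flags localizations whose
    density hit the numerical floor (these would otherwise be −inf).
    """
    dens = composite_pdf(locs, spec, site)
    floored = dens < DENSITY_FLOOR
    logd = np.log(np.maximum(dens, DENSITY_FLOOR))
    wc = _color_weights(locs, spec)
    ll = 0.0
    per_channel = {}
    for c, w in wc.items():
        mask = locs.channel == c
        term = float(logd[mask].sum())
        per_channel[c] = term
        ll += w * term
    info = {"per_channel": per_channel, "color_weights": wc,
            "floored": int(floored.sum())}
    return ll, info


def cross_correlation_score(locs: LocalizationSet, spec: CompositeSpec,
                            site: Site) -> float:
    """Cross-correlation objective: the *sum* (instead of product) of the
    per-localization densities, L_cc = Σ_k M(x_k, σ_k | p)."""
    return float(composite_pdf(locs, spec, site).sum())
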