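"""Library of parameterized geometric models.

A :class:`GeometricModel` is a deterministic generator of expected
fluorophore geometry.  Depending on its ``kind`` it describes

* ``continuous-line`` / ``continuous-surface`` — a parametric curve or
  surface carrying a constant fluorophore density.  Evaluation discretizes
  it into points ``v_j`` with weights ``q_j`` at a requested maximum
  spacing;
* ``discrete-points`` — exact expected fluorophore positions (e.g. the 32
  Nup96 positions of the nuclear pore complex);
* ``density-image`` — a fluorophore density sampled on a grid (see
  :func:`smlmfit.pdfcore.rasterize` for turning any model into this form).

All lengths are nm and all angles radians.  Built-in models are registered
by name in :data:`MODEL_REGISTRY`; a user plug-in is simply another
:class:`GeometricModel` instance registered with :func:`register_model`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "Parameter",
    "ModelPoints",
    "GeometricModel",
    "MODEL_REGISTRY",
    "register_model",
    "get_model",
    "npc_dual_ring",
    "npc_discrete",
    "npc_elliptical",
    "mt_spline",
    "mt_tube",
    "endocytic_model",
    "line_segments",
]


class ParameterError(ValueError):
    """A model parameter violates its bounds or a structural precondition."""


@dataclass(frozen=True)
class Parameter:
    """One named intrinsic parameter with finite bounds.

    ``unit`` is 'nm' for lengths, 'rad' for angles, '' for unitless.
    """

    name: str
    default: float
    lower: float
    upper: float
    unit: str = "nm"


class ModelPoints(NamedTuple):
    """Discretized model output: points ``v_j`` (J, D), strictly positive
    weights ``q_j`` (J,) and an integer channel label per point."""

    points: np.ndarray
    weights: np.ndarray
    channels: np.ndarray


def _model_points(points, weights=None, channels=None) -> ModelPoints:
    points = np.asarray(points, dtype=float)
    if weights is None:
        weights = np.ones(len(points))
    if channels is None:
        channels = np.zeros(len(points), dtype=int)
    return ModelPoints(points, np.asarray(weights, float),
                       np.asarray(channels, int))


@dataclass
class GeometricModel:
    """A named, parameterized fluorophore-geometry generator.

    ``evaluate(values, spacing)`` must be deterministic for fixed parameter
    values; for continuous kinds the returned point spacing never exceeds
    the requested ``spacing``.
    """

    name: str
    kind: str  # continuous-line | continuous-surface | discrete-points | density-image
    dim: int
    params: tuple[Parameter, ...]
    _evaluate: Callable[..., ModelPoints]
    meta: dict = field(default_factory=dict)

    def param_names(self) -> list[str]:
        return [p.name for p in self.params]

    def defaults(self) -> dict[str, float]:
        return {p.name: p.default for p in self.params}

    def bounds(self) -> dict[str, tuple[float, float]]:
        return {p.name: (p.lower, p.upper) for p in self.params}

    def validate(self, values: dict[str, float]) -> dict[str, float]:
        full = self.defaults()
        unknown = set(values) - set(full)
        if unknown:
            raise ParameterError(f"{self.name}: unknown parameter(s) {sorted(unknown)}")
        full.update(values)
        for p in self.params:
            v = full[p.name]
            if not (p.lower <= v <= p.upper):
                raise ParameterError(
                    f"{self.name}: parameter {p.name}={v} outside "
                    f"[{p.lower}, {p.upper}] {p.unit}")
        return full

    def evaluate(self, values: dict[str, float] | None = None,
                 spacing: float | None = None) -> ModelPoints:
        """Return the model point set for the given intrinsic parameters.

        ``spacing`` is the maximum allowed distance between adjacent points
        for continuous kinds; ignored for ``discrete-points``.
        """
        full = self.validate(values or {})
        return self._evaluate(full, spacing)

    @property
    def is_continuous(self) -> bool:
        return self.kind in ("continuous-line", "continuous-surface")


MODEL_REGISTRY: dict[str, Callable[..., GeometricModel]] = {}


def register_model(name: str, factory: Callable[..., GeometricModel]) -> None:
    """Register a model factory addressable by name from config and CLI."""
    MODEL_REGISTRY[name] = factory


def get_model(name: str, **kwargs) -> GeometricModel:
    """Instantiate a registered model by name."""
    try:
        factory = MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        ) from None
    return factory(**kwargs)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

_DEFAULT_SPACING = 2.0  # nm, used when no localization-driven spacing is given


def _n_steps(length: float, spacing: float) -> int:
    """Number of equal subdivisions of ``length`` with step < ``spacing``."""
    return int(math.floor(length / spacing)) + 1


def _ring_points(radius: float, spacing: float, z: float,
                 phase: float = 0.0) -> np.ndarray:
    """Evenly sample a circle of ``radius`` in the plane ``z`` with arc
    spacing strictly below ``spacing``."""
    n = max(8, _n_steps(2 * math.pi * radius, spacing))
    ang = phase + 2 * math.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.full(n, z)])


# ---------------------------------------------------------------------------
# NPC models
# ---------------------------------------------------------------------------

def npc_dual_ring(radius: float = 53.4, separation: float = 50.2) -> GeometricModel:
    """Two identical parallel continuous rings of radius ``r`` in the planes
    z = ±s/2 (the model origin is the NPC center).

    This is the smooth dual-ring description of the Nup96 scaffold of the
    nuclear pore complex used for robust pose/size estimation before a
    discrete-corner fit.
    """
    if not radius > 0:
        raise ParameterError("radius must be > 0")
    if separation < 0:
        raise ParameterError("separation must be >= 0")
    params = (
        Parameter("r", radius, 5.0, 200.0, "nm"),
        Parameter("s", separation, 0.0, 200.0, "nm"),
    )

    def _eval(v, spacing):
        sp = spacing or _DEFAULT_SPACING
        lower = _ring_points(v["r"], sp, -v["s"] / 2)
        upper = _ring_points(v["r"], sp, +v["s"] / 2)
        return _model_points(np.vstack([lower, upper]))

    return GeometricModel("npc_dual_ring", "continuous-line", 3, params, _eval)


def npc_discrete(radius: float = 53.4, separation: float = 50.2,
                 twist: float = math.radians(8.8), symmetry: int = 8,
                 copies_per_unit: int = 2,
                 unit_angle: float = math.radians(14.0)) -> GeometricModel:
    """Discrete-corner NPC model: ``symmetry``-fold rotationally symmetric
    units of ``copies_per_unit`` fluorophores on two rings at z = ±s/2.

    With the defaults (n = 8, two copies per unit) each ring carries 16
    positions, 32 in total.  The two copies of a unit sit at ±unit_angle/2
    about the corner angle at identical radius.  The upper ring is rotated
    by the twist angle θ relative to the lower ring.  Angles in radians.
    """
    if symmetry < 3:
        raise ParameterError("symmetry must be >= 3")
    if not radius > 0:
        raise ParameterError("radius must be > 0")
    if copies_per_unit < 1:
        raise ParameterError("copies_per_unit must be >= 1")
    params = (
        Parameter("r", radius, 5.0, 200.0, "nm"),
        Parameter("s", separation, 0.0, 200.0, "nm"),
        Parameter("theta", twist, -math.pi, math.pi, "rad"),
    )
    n, cp, ua = symmetry, copies_per_unit, unit_angle

    def _corner_angles(phase):
        corners = phase + 2 * math.pi * np.arange(n) / n
        if cp == 1:
            return corners
        offsets = (np.arange(cp) - (cp - 1) / 2) * (ua / max(cp - 1, 1))
        return (corners[:, None] + offsets[None, :]).ravel()

    def _eval(v, spacing):
        pts = []
        for z, phase in ((-v["s"] / 2, 0.0), (+v["s"] / 2, v["theta"])):
            ang = _corner_angles(phase)
            pts.append(np.column_stack([
                v["r"] * np.cos(ang), v["r"] * np.sin(ang),
                np.full(ang.size, z)]))
        return _model_points(np.vstack(pts))

    m = GeometricModel("npc_discrete", "discrete-points", 3, params, _eval)
    m.meta.update(symmetry=n, copies_per_unit=cp, unit_angle=ua)
    return m


def npc_elliptical(mean_radius: float = 53.4, ellipticity: float = 0.0,
                   internal_rotation: float = 0.0,
                   separation: float = 50.2,
                   twist: float = math.radians(8.8), symmetry: int = 8,
                   copies_per_unit: int = 2,
                   unit_angle: float = math.radians(14.0)) -> GeometricModel:
    """Elliptical variant of :func:`npc_discrete`.

    The semi-axes a >= b solve e = 1 - b/a and r = (a + b)/2, i.e.
    a = 2r/(2 - e) and b = a(1 - e).  The internal rotation Φ orients the
    long axis relative to the first corner; at e = 0 the point set reduces
    exactly to the circular model.
    """
    if not (0 <= ellipticity < 1):
        raise ParameterError("ellipticity must satisfy 0 <= e < 1")
    base = npc_discrete(mean_radius, separation, twist, symmetry,
                        copies_per_unit, unit_angle)
    params = base.params + (
        Parameter("e", ellipticity, 0.0, 0.999, ""),
        Parameter("phi", internal_rotation, -math.pi, math.pi, "rad"),
    )

    def _eval(v, spacing):
        circ = base._evaluate({k: v[k] for k in ("r", "s", "theta")}, spacing)
        e, phi = v["e"], v["phi"]
        a = 2 * v["r"] / (2 - e)
        b = a * (1 - e)
        x, y, z = circ.points.T
        ang = np.arctan2(y, x) - phi
        ex = a * np.cos(ang)
        ey = b * np.sin(ang)
        c, s = math.cos(phi), math.sin(phi)
        pts = np.column_stack([c * ex - s * ey, s * ex + c * ey, z])
        return _model_points(pts)

    m = GeometricModel("npc_elliptical", "discrete-points", 3, params, _eval)
    m.meta.update(base.meta)
    return m


# ---------------------------------------------------------------------------
# microtubule models
# ---------------------------------------------------------------------------

def control_points(x_mid, h: float, azimuths, elevations, N: int) -> np.ndarray:
    """Build N control points outward from the middle point.

    The middle point (index ``(N+1)/2`` in 1-based order) sits at ``x_mid``.
    The remaining points are placed in two chains, first from the middle
    down to index 1 and then from the middle up to index N; each point lies
    at distance ``h`` from its predecessor in the direction given by its
    azimuth θ and elevation φ (radians, spherical convention
    ``(cosφ·cosθ, cosφ·sinθ, sinφ)``).  ``azimuths``/``elevations`` have
    N - 1 entries ordered by build order (down-chain first).
    """
    x_mid = np.asarray(x_mid, dtype=float)
    az = np.asarray(azimuths, dtype=float)
    el = np.asarray(elevations, dtype=float)
    if az.shape != (N - 1,) or el.shape != (N - 1,):
        raise ParameterError(
            f"need {N - 1} azimuth/elevation angles for N={N} points")
    q0 = (N + 1) // 2  # 1-based middle index
    pts = np.zeros((N, 3))
    pts[q0 - 1] = x_mid
    k = 0
    for q in range(q0 - 1, 0, -1):  # down chain, 1-based q
        d = np.array([math.cos(el[k]) * math.cos(az[k]),
                      math.cos(el[k]) * math.sin(az[k]),
                      math.sin(el[k])])
        pts[q - 1] = pts[q] - h * d  # outward = opposite build direction
        k += 1
    for q in range(q0 + 1, N + 1):
        d = np.array([math.cos(el[k]) * math.cos(az[k]),
                      math.cos(el[k]) * math.sin(az[k]),
                      math.sin(el[k])])
        pts[q - 1] = pts[q - 2] + h * d
        k += 1
    return pts


def _control_param_table(N: int, h: float) -> tuple[Parameter, ...]:
    pars = [
        Parameter("x_mid", 0.0, -5e4, 5e4, "nm"),
        Parameter("y_mid", 0.0, -5e4, 5e4, "nm"),
        Parameter("z_mid", 0.0, -5e4, 5e4, "nm"),
        Parameter("h", h, 1.0, 5e3, "nm"),
    ]
    for i in range(N - 1):
        pars.append(Parameter(f"az{i}", 0.0, -math.pi, math.pi, "rad"))
        pars.append(Parameter(f"el{i}", 0.0, -math.pi / 2, math.pi / 2, "rad"))
    return tuple(pars)


def _controls_from_values(v: dict, N: int) -> np.ndarray:
    az = [v[f"az{i}"] for i in range(N - 1)]
    el = [v[f"el{i}"] for i in range(N - 1)]
    return control_points([v["x_mid"], v["y_mid"], v["z_mid"]], v["h"],
                          az, el, N)


def _spline_through(pts: np.ndarray) -> CubicSpline:
    """Natural cubic spline through the control points with chord-length
    parameterization."""
    chord = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    return CubicSpline(chord, pts, bc_type="natural")


def _equidistant_on_spline(cs: CubicSpline, spacing: float,
                           oversample: int = 8):
    """Sample the spline at (approximately) equal arc-length steps strictly
    below ``spacing``; returns (points, tangents)."""
    t_max = cs.x[-1]
    n_dense = max(64, _n_steps(t_max, spacing / oversample))
    td = np.linspace(0.0, t_max, n_dense + 1)
    pd = cs(td)
    seg = np.linalg.norm(np.diff(pd, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(2, _n_steps(total, spacing))
    targets = np.linspace(0.0, total, n + 1)
    ts = np.interp(targets, arc, td)
    pts = cs(ts)
    tangents = cs(ts, 1)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return pts, tangents


def mt_spline(N: int = 5, h: float = 250.0, x_mid=(0.0, 0.0, 0.0),
              azimuths=None, elevations=None) -> GeometricModel:
    """Curved-filament backbone: a natural cubic spline through an odd
    number N of control points spaced ``h`` nm apart (default N = 5,
    h = 250 nm; micrometer-scale microtubule segments).

    Evaluation returns equidistant samples along the spline with equal
    weights.
    """
    if N % 2 == 0:
        raise ParameterError("N must be odd")
    if N < 3:
        raise ParameterError("N must be >= 3")
    if not h > 0:
        raise ParameterError("h must be > 0")
    params = _control_param_table(N, h)
    defaults = {}
    if azimuths is not None:
        defaults.update({f"az{i}": a for i, a in enumerate(azimuths)})
    if elevations is not None:
        defaults.update({f"el{i}": e for i, e in enumerate(elevations)})
    defaults.update(zip(("x_mid", "y_mid", "z_mid"), np.asarray(x_mid, float)))
    params = tuple(
        Parameter(p.name, defaults.get(p.name, p.default), p.lower, p.upper,
                  p.unit) for p in params)

    def _eval(v, spacing):
        sp = spacing or _DEFAULT_SPACING
        ctrl = _controls_from_values(v, N)
        cs = _spline_through(ctrl)
        pts, _ = _equidistant_on_spline(cs, sp)
        return _model_points(pts)

    m = GeometricModel("mt_spline", "continuous-line", 3, params, _eval)
    m.meta.update(N=N)
    return m


def mt_tube(N: int = 5, h: float = 250.0, radius: float = 12.5,
            x_mid=(0.0, 0.0, 0.0), azimuths=None,
            elevations=None) -> GeometricModel:
    """Curved tube: rings of radius r centered at equidistant points on the
    backbone spline of :func:`mt_spline`, each ring lying in the plane
    perpendicular to the local tangent."""
    if not radius > 0:
        raise ParameterError("radius must be > 0")
    backbone = mt_spline(N, h, x_mid, azimuths, elevations)
    params = backbone.params + (Parameter("r", radius, 1.0, 500.0, "nm"),)

    def _eval(v, spacing):
        sp = spacing or _DEFAULT_SPACING
        ctrl = _controls_from_values(v, N)
        cs = _spline_through(ctrl)
        centers, tangents = _equidistant_on_spline(cs, sp)
        r = v["r"]
        n_ring = max(8, _n_steps(2 * math.pi * r, sp))
        ang = 2 * math.pi * np.arange(n_ring) / n_ring
        circ = np.column_stack([np.cos(ang), np.sin(ang)])
        # parallel-transport-free frame: stable reference-vector construction
        ref = np.where(np.abs(tangents[:, 2:3]) < 0.9,
                       np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
        n1 = np.cross(tangents, ref)
        n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
        n2 = np.cross(tangents, n1)
        pts = (centers[:, None, :]
               + r * (circ[None, :, 0, None] * n1[:, None, :]
                      + circ[None, :, 1, None] * n2[:, None, :]))
        return _model_points(pts.reshape(-1, 3))

    m = GeometricModel("mt_tube", "continuous-surface", 3, params, _eval)
    m.meta.update(N=N)
    return m


# ---------------------------------------------------------------------------
# endocytic two-channel model (2D)
# ---------------------------------------------------------------------------

def endocytic_model(a: float = 100.0, b: float = 80.0, t: float = 30.0,
                    r_in: float = 60.0, r_out: float = 110.0) -> GeometricModel:
    """Two-component 2D model of a yeast endocytic site.

    Channel 0: the projection onto the imaging plane of a hemiellipsoid
    surface with half-axis ``a`` along the invagination axis (+y) and
    lateral half-axis ``b`` (the Abp1-decorated actin dome).  Channel 1:
    the projection of a thick ring (annulus of inner radius ``r_in``, outer
    radius ``r_out``, thickness ``t`` along y; the Las17 ring at the plasma
    membrane).  The ring mid-plane is y = 0; the hemiellipsoid base sits at
    y = base_offset >= 0, i.e. at or above the ring.

    The ring projection uses the closed-form chord-length marginalization
    over the optical axis; the hemiellipsoid projection integrates the
    surface area element numerically on a parameter grid.
    """
    if not (a > 0 and b > 0 and t > 0):
        raise ParameterError("a, b, t must be > 0")
    if not (0 < r_in < r_out):
        raise ParameterError("need 0 < r_in < r_out")
    params = (
        Parameter("a", a, 1.0, 500.0, "nm"),
        Parameter("b", b, 1.0, 500.0, "nm"),
        Parameter("t", t, 1.0, 200.0, "nm"),
        Parameter("r_in", r_in, 1.0, 500.0, "nm"),
        Parameter("r_out", r_out, 2.0, 600.0, "nm"),
        Parameter("base_offset", 0.0, 0.0, 300.0, "nm"),
    )

    def _ring_projection(v, sp):
        ri, ro, th = v["r_in"], v["r_out"], v["t"]
        nx = max(8, _n_steps(2 * ro, sp))
        x = np.linspace(-ro, ro, nx + 1)
        outer = np.sqrt(np.clip(ro**2 - x**2, 0.0, None))
        inner = np.sqrt(np.clip(ri**2 - x**2, 0.0, None))
        w = 2 * (outer - inner)
        ny = max(2, _n_steps(th, sp))
        y = np.linspace(-th / 2, th / 2, ny + 1)
        pts = np.column_stack([np.repeat(x, y.size), np.tile(y, x.size)])
        wts = np.repeat(w, y.size)
        keep = wts > 0
        return pts[keep], wts[keep]

    def _dome_projection(v, sp):
        av, bv = v["a"], v["b"]
        # surface (x, z) = b sinφ (cos u, sin u), y = base + a cosφ
        nphi = max(8, _n_steps(math.pi / 2 * max(av, bv), sp))
        nu = max(8, _n_steps(2 * math.pi * bv, sp))
        phi = (np.arange(nphi) + 0.5) * (math.pi / 2) / nphi
        u = 2 * math.pi * np.arange(nu) / nu
        sphi, cphi = np.sin(phi), np.cos(phi)
        # area element: b sinφ sqrt(a² sin²φ + b² cos²φ) dφ du
        area = bv * sphi * np.sqrt(av**2 * sphi**2 + bv**2 * cphi**2)
        x = bv * sphi[:, None] * np.cos(u)[None, :]
        y = v["base_offset"] + av * cphi[:, None] * np.ones_like(u)[None, :]
        pts = np.column_stack([x.ravel(), y.ravel()])
        wts = np.repeat(area, nu)
        return pts, wts

    def _eval(v, spacing):
        if not v["r_in"] < v["r_out"]:
            raise ParameterError("need r_in < r_out")
        sp = spacing or _DEFAULT_SPACING
        dome_p, dome_w = _dome_projection(v, sp)
        ring_p, ring_w = _ring_projection(v, sp)
        pts = np.vstack([dome_p, ring_p])
        wts = np.concatenate([dome_w, ring_w])
        ch = np.concatenate([np.zeros(len(dome_p), int),
                             np.ones(len(ring_p), int)])
        return ModelPoints(pts, wts, ch)

    return GeometricModel("endocytic", "continuous-surface", 2, params, _eval)


# ---------------------------------------------------------------------------
# line segments
# ---------------------------------------------------------------------------

def line_segments(N: int = 3, h: float = 100.0, x_mid=(0.0, 0.0, 0.0),
                  azimuths=None, elevations=None) -> GeometricModel:
    """Discrete model whose points are the N vertices of connected line
    segments; vertex positions are defined like the spline control points
    (middle vertex + per-vertex distance/azimuth/elevation)."""
    if N < 2:
        raise ParameterError("N must be >= 2")
    params = _control_param_table(N, h)
    defaults = {}
    if azimuths is not None:
        defaults.update({f"az{i}": a for i, a in enumerate(azimuths)})
    if elevations is not None:
        defaults.update({f"el{i}": e for i, e in enumerate(elevations)})
    defaults.update(zip(("x_mid", "y_mid", "z_mid"), np.asarray(x_mid, float)))
    params = tuple(
        Parameter(p.name, defaults.get(p.name, p.default), p.lower, p.upper,
                  p.unit) for p in params)

    def _eval(v, spacing):
        # N=2 has no middle vertex in the odd sense; anchor at x_mid and
        # chain upward only
        if N % 2 == 1:
            pts = _controls_from_values(v, N)
        else:
            az = [v[f"az{i}"] for i in range(N - 1)]
            el = [v[f"el{i}"] for i in range(N - 1)]
            pts = np.zeros((N, 3))
            pts[0] = [v["x_mid"], v["y_mid"], v["z_mid"]]
            for i in range(1, N):
                d = np.array([
                    math.cos(el[i - 1]) * math.cos(az[i - 1]),
                    math.cos(el[i - 1]) * math.sin(az[i - 1]),
                    math.sin(el[i - 1])])
                pts[i] = pts[i - 1] + v["h"] * d
        return _model_points(pts)

    m = GeometricModel("line_segments", "discrete-points", 3, params, _eval)
    m.meta.update(N=N)
    return m


for _name, _factory in [
    ("npc_dual_ring", npc_dual_ring),
    ("npc_discrete", npc_discrete),
    ("npc_elliptical", npc_elliptical),
    ("mt_spline", mt_spline),
    ("mt_tube", mt_tube),
    ("endocytic", endocytic_model),
    ("line_segments", line_segments),
]:
    register_model(_name, _factory)
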