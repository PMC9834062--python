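"""Particle averaging: reference-based, pseudotime, and model-free fusion.

Model-free averaging treats the localization coordinates of one particle
as the fluorophore positions of a discrete point model and fits it to
another particle by maximizing the same Gaussian-mixture log-likelihood
used everywhere else; the maximum log-likelihood doubles as a similarity
score.  The fusion workflow is:

1.  all-against-all pairwise registration of an n-particle subset fills a
    similarity matrix M[i, j] (max LL of fitting particle i to particle j);
2.  particles are ranked by row sum; the top-ranked particle seeds the
    initial template and the others are fused onto it cumulatively in rank
    order;
3.  the template registers the full k-particle dataset; the union of the
    registered particles becomes the next template; iterations continue
    while the summed registration log-likelihood improves and stop after J
    consecutive non-improvements.

Because registration carries no parametric shape model, the result is free
of template bias.  An optional pre-alignment with a continuous dual-ring
fit narrows the rotational search range for ring-like particles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .locdata import LocalizationSet, Site
from .models import GeometricModel, Parameter, _model_points
from .fitting import FitStep, fit_step
from .pdfcore import (Pose, apply_pose, compose_poses, invert_pose,
                      rotation_matrix)

__all__ = [
    "Template",
    "particle_model",
    "register_pair",
    "prealign_poses",
    "build_initial_template",
    "iterative_average",
    "model_free_average",
    "reference_average",
    "pseudotime_reconstruct",
    "azimuthal_harmonics",
]

_POSE_FREE_3D = ("x0", "y0", "z0", "alpha", "beta", "gamma")
_POSE_FREE_2D = ("x0", "y0", "gamma")


@dataclass
class Template:
    """A fused particle: the union of pose-corrected member particles.

    ``score`` is the summed registration log-likelihood of the accepted
    iteration; it is non-decreasing over accepted iterations.
    """

    localizations: LocalizationSet
    score: float = -math.inf
    n_iterations: int = 0
    unimproved: int = 0
    max_unimproved: int = 3
    history: list = field(default_factory=list)
    similarity: np.ndarray | None = None   # all-vs-all LL matrix (subset)
    rank_order: np.ndarray | None = None   # fusion order of the subset
    prealign_poses: list | None = None


def particle_model(locs: LocalizationSet, name: str = "particle") -> GeometricModel:
    """Wrap a particle's localization coordinates as a discrete point
    model (no intrinsic parameters)."""
    pts = locs.coords.copy()
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])

    def _eval(v, spacing):
        return _model_points(pts)

    return GeometricModel(name, "discrete-points", locs.ndim, (), _eval)


def _as_locs(obj) -> LocalizationSet:
    if isinstance(obj, Template):
        return obj.localizations
    if isinstance(obj, Site):
        return obj.localizations
    return obj


def _subsample(locs: LocalizationSet, cap: int,
               rng: np.random.Generator) -> LocalizationSet:
    if len(locs) <= cap:
        return locs
    idx = rng.choice(len(locs), size=cap, replace=False)
    return locs.select(np.sort(idx))


try:
    from numba import njit as _njit

    @_njit(fastmath=True)
    def _mixture_ll_kernel(v, coords, inv2var, lognorm):  # pragma: no cover
        K = coords.shape[0]
        J = v.shape[0]
        out = 0.0
        for k in range(K):
            s = 0.0
            x, y, z = coords[k, 0], coords[k, 1], coords[k, 2]
            w0, w1, w2 = inv2var[k, 0], inv2var[k, 1], inv2var[k, 2]
            for j in range(J):
                d0 = x - v[j, 0]
                d1 = y - v[j, 1]
                d2 = z - v[j, 2]
                q = d0 * d0 * w0 + d1 * d1 * w1 + d2 * d2 * w2
                # contributions below exp(-34) ~ 1.7e-15 are negligible
                if q < 34.0:
                    s += math.exp(-q)
            m = s / J
            if m < 1e-300:
                m = 1e-300
            out += math.log(m) + lognorm[k]
        return out

    _HAVE_NUMBA = True
except ImportError:  # pure-numpy fallback
    _HAVE_NUMBA = False


def _registration_loglik(pts: np.ndarray, coords: np.ndarray,
                         inv2var: np.ndarray, lognorm: np.ndarray):
    """LL of the data (coords, inv2var) under the point model ``pts``
    placed by a pose vector (x0, y0, z0, α, β, γ): the K×J Gaussian
    mixture of the fitting core, specialized for the pose-only search of
    registration (far-field terms truncated)."""
    K = len(coords)
    chunk = max(1, int(4e6) // max(K, 1))

    def ll(x):
        R = rotation_matrix(x[3], x[4], x[5])
        v = pts @ R.T + x[:3]
        if _HAVE_NUMBA:
            return float(_mixture_ll_kernel(v, coords, inv2var, lognorm))
        m = np.zeros(K)
        for j0 in range(0, len(v), chunk):
            d2 = ((coords[:, None, :] - v[None, j0:j0 + chunk, :]) ** 2
                  * inv2var[:, None, :]).sum(axis=2)
            m += np.exp(-d2).sum(axis=1)
        m /= len(v)
        return float((np.log(np.maximum(m, 1e-300)) + lognorm).sum())

    return ll


def register_pair(moving, target, seed: int = 0, init_pose: Pose | None = None,
                  restarts: int = 5, n_gamma: int = 12,
                  symmetry_sector: float = 2 * math.pi,
                  max_target_points: int = 100_000,
                  maxfev: int = 250, extra_sigma: float = 0.0) -> dict:
    """Rigid registration of ``moving`` onto ``target``.

    The target's localizations become a discrete point model (equal
    weights) whose pose (translation + z-y-x rotation) is optimized
    against the moving particle's localizations, each with its own
    precision.  A coarse grid of ``n_gamma`` in-plane rotations over
    ``symmetry_sector`` around the initial pose is scored first; the best
    ``restarts`` candidates are refined by seeded simplex runs and the
    best log-likelihood wins.

    Returns ``{"pose", "loglik", "moving_to_target"}``: ``pose`` maps
    target (model) coordinates into the moving particle's frame;
    ``moving_to_target`` is its inverse, the transform that registers the
    moving particle into the target frame.  Registration is generally
    asymmetric: LL(A→B) ≠ LL(B→A).
    """
    from scipy.optimize import minimize

    rng = np.random.default_rng(seed)
    moving_locs = _as_locs(moving)
    target_locs = _subsample(_as_locs(target), max_target_points, rng)
    if not len(moving_locs) or not len(target_locs):
        raise ValueError("both particles must be non-empty")
    D = moving_locs.ndim
    pts = target_locs.coords
    coords = moving_locs.coords
    if D == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
        coords = np.column_stack([coords, np.zeros(len(coords))])
        var = np.column_stack([
            moving_locs.precisions ** 2 + extra_sigma**2,
            np.full(len(coords), 0.5)])
    else:
        # optional extra blur smooths the rotational likelihood surface
        # and damps cluster locking ("hot spots")
        var = moving_locs.precisions ** 2 + extra_sigma**2
    inv2var = 0.5 / var
    lognorm = (-(D / 2) * math.log(2 * math.pi)
               - 0.5 * np.log(var[:, :D].prod(axis=1)))
    ll = _registration_loglik(pts, coords, inv2var, lognorm)

    base = init_pose or Pose(x0=(0.0, 0.0, 0.0))
    bx = base.x0 + (0.0,) * (3 - len(base.x0))
    a, b, g = base.angles
    offsets = g + symmetry_sector * np.arange(n_gamma) / max(1, n_gamma)
    scored = sorted(
        ((ll([bx[0], bx[1], bx[2], a, b, gg]), gg) for gg in offsets),
        reverse=True)
    best_x, best_ll = None, -math.inf
    for ll0, gg in scored[:max(1, restarts)]:
        if D == 2:  # in-plane: optimize x0, y0, γ only
            obj = lambda y: -ll([y[0], y[1], 0.0, 0.0, 0.0, y[2]])
            start = np.array([bx[0], bx[1], gg])
            steps = np.array([10.0, 10.0, 0.2])
        else:
            obj = lambda y: -ll(y)
            start = np.array([bx[0], bx[1], bx[2], a, b, gg])
            steps = np.array([10.0, 10.0, 10.0, 0.15, 0.15, 0.2])
        # explicit nm/radian-scale initial simplex: the default one is
        # degenerate for parameters starting at zero
        simplex = np.vstack([start, start + np.diag(steps)])
        res = minimize(obj, start, method="Nelder-Mead",
                       options={"maxfev": maxfev, "xatol": 1e-3,
                                "fatol": 1e-6, "initial_simplex": simplex})
        if -res.fun > best_ll:
            best_ll, best_x = -res.fun, res.x
    if D == 2:
        pose = Pose(x0=tuple(best_x[:2]), angles=(0.0, 0.0, best_x[2]))
    else:
        pose = Pose(x0=tuple(best_x[:3]), angles=tuple(best_x[3:6]))
    return {"pose": pose, "loglik": best_ll,
            "moving_to_target": invert_pose(pose)}


def prealign_poses(particles, seed: int = 0, radius: float = 53.4,
                   separation: float = 50.2) -> list[Pose]:
    """Approximate pose of each (ring-like) particle from a continuous
    dual-ring fit; used to narrow the rotational search in pairwise
    registration."""
    from .models import npc_dual_ring

    poses = []
    for i, p in enumerate(particles):
        site = p if isinstance(p, Site) else Site(
            _as_locs(p), 2 * float(np.abs(_as_locs(p).coords).max() + 1),
            center=np.zeros(_as_locs(p).ndim))
        model = npc_dual_ring(radius, separation)
        step = FitStep(
            model=model, free=("x0", "y0", "z0", "alpha", "beta", "r", "s"),
            fixed={"epsilon": 8.0, "w_bg": 0.01},
            optimizer="global-evolutionary",
            options={"maxiter": 25, "popsize": 9, "tol": 0.01},
            sigma_min=6.0, name="prealign")
        res = fit_step(site, step, seed=seed + i)
        e = res.estimates
        poses.append(Pose(x0=(e["x0"], e["y0"], e["z0"]),
                          angles=(e["alpha"], e["beta"], 0.0)))
    return poses


def _pair_init(pose_model: Pose, pose_data: Pose) -> Pose:
    """Initial registration pose from per-particle pre-alignment poses:
    maps the model particle's frame into the data particle's frame."""
    return compose_poses(pose_data, invert_pose(pose_model))


def build_initial_template(subset, seed: int = 0, prealign: bool = True,
                           restarts: int = 5,
                           symmetry_sector: float = 2 * math.pi,
                           max_target_points: int = 100_000,
                           extra_sigma: float = 0.0,
                           n_gamma: int = 12) -> Template:
    """All-against-all registration of the subset, ranking by total
    similarity, and cumulative fusion in rank order (rank ties break by
    lower particle index).

    ``M[i, j]`` holds the maximum log-likelihood of fitting particle i (as
    a point model) to particle j; the diagonal is zero.
    """
    n = len(subset)
    if n < 2:
        raise ValueError("need at least two particles")
    poses = prealign_poses(subset, seed=seed) if prealign else None
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # M[i, j]: fit particle i (model) to particle j (data);
            # the pre-alignment init maps i's frame into j's frame
            init = _pair_init(poses[i], poses[j]) if poses else None
            reg = register_pair(subset[j], subset[i], seed=seed + 97 * i + j,
                                init_pose=init, restarts=restarts,
                                symmetry_sector=symmetry_sector,
                                max_target_points=max_target_points,
                                extra_sigma=extra_sigma, n_gamma=n_gamma)
            M[i, j] = reg["loglik"]
    rowsum = M.sum(axis=1)
    order = np.argsort(-rowsum, kind="stable")  # rank 1 first
    fused = _as_locs(subset[order[0]]).copy()
    template = Template(fused)
    for idx in order[1:]:
        part = subset[idx]
        init = _pair_init(poses[order[0]], poses[idx]) if poses else None
        reg = register_pair(part, template, seed=seed + 1000 + int(idx),
                            init_pose=init, restarts=restarts,
                            symmetry_sector=symmetry_sector,
                            max_target_points=max_target_points,
                            extra_sigma=extra_sigma, n_gamma=n_gamma)
        moved = apply_pose(_as_locs(part), reg["pose"], "data-to-model")
        template.localizations = LocalizationSet.concatenate(
            [template.localizations, moved])
    template.history.append(("initial", n))
    template.similarity = M
    template.rank_order = order
    template.prealign_poses = poses
    return template


def iterative_average(particles, template: Template, J: int = 3,
                      seed: int = 0, restarts: int = 3,
                      symmetry_sector: float = 2 * math.pi,
                      max_target_points: int = 100_000,
                      max_iterations: int = 20,
                      extra_sigma: float = 0.0,
                      n_gamma: int = 12) -> Template:
    """Iterative refinement: register all particles to the current
    template, take the union of the registered particles as the candidate,
    accept it when the summed registration log-likelihood improves, and
    stop after ``J`` consecutive non-improving iterations."""
    best = template
    current = template.localizations
    score = template.score
    j = 0
    # warm starts: the template-to-particle pose found in one iteration
    # initializes the next; first iteration falls back to pre-alignment
    inits: list = [None] * len(particles)
    for it in range(max_iterations):
        regs = []
        for i, p in enumerate(particles):
            reg = register_pair(p, current, seed=seed + 7919 * it + i,
                                init_pose=inits[i],
                                restarts=(restarts if it == 0 else 1),
                                symmetry_sector=symmetry_sector,
                                max_target_points=max_target_points,
                                extra_sigma=extra_sigma, n_gamma=n_gamma)
            inits[i] = reg["pose"]
            regs.append(reg)
        s_new = sum(r["loglik"] for r in regs)
        moved = [apply_pose(_as_locs(p), r["pose"], "data-to-model")
                 for p, r in zip(particles, regs)]
        candidate = LocalizationSet.concatenate(moved)
        best.history.append(("iterate", it, s_new))
        if s_new > score:
            best = Template(candidate, score=s_new, n_iterations=it + 1,
                            unimproved=0, max_unimproved=J,
                            history=best.history)
            score = s_new
            j = 0
        else:
            j += 1
            if j >= J:
                break
        current = candidate  # next round registers against the new union
    best.unimproved = j
    return best


def model_free_average(particles, n_subset: int = 50, J: int = 3,
                       seed: int = 0, prealign: bool = True,
                       restarts: int = 5,
                       symmetry_sector: float = 2 * math.pi,
                       max_target_points: int = 100_000,
                       extra_sigma: float = 0.0,
                       n_gamma: int = 12) -> Template:
    """Complete model-free fusion pipeline: initial template from an
    n-particle subset, then iterative registration of the full dataset."""
    subset = list(particles[:n_subset])
    template = build_initial_template(
        subset, seed=seed, prealign=prealign, restarts=restarts,
        symmetry_sector=symmetry_sector, max_target_points=max_target_points,
        extra_sigma=extra_sigma, n_gamma=n_gamma)
    return iterative_average(
        list(particles), template, J=J, seed=seed + 1,
        restarts=max(1, restarts // 2), symmetry_sector=symmetry_sector,
        max_target_points=max_target_points, extra_sigma=extra_sigma,
        n_gamma=n_gamma)


# ---------------------------------------------------------------------------
# reference-based averaging and pseudotime
# ---------------------------------------------------------------------------

def _pose_of(result, ndim: int) -> Pose:
    e = result.estimates if hasattr(result, "estimates") else result
    x0 = (e.get("x0", 0.0), e.get("y0", 0.0))
    if ndim == 3:
        x0 = x0 + (e.get("z0", 0.0),)
    return Pose(x0=x0, angles=(e.get("alpha", 0.0), e.get("beta", 0.0),
                               e.get("gamma", 0.0)))


def reference_average(sites, fit_results, target_channel: int = 1,
                      skip_flags: tuple = ("converged",)) -> LocalizationSet:
    """Pool the target-channel localizations of all sites after
    transforming every site into the fitted reference-model frame
    (x' = R⁻¹S⁻¹(x − x0) with the site's fitted pose).

    Sites whose fit carries a failure flag are skipped.
    """
    pooled = []
    for site, res in zip(sites, fit_results):
        flags = getattr(res, "flags", {})
        if any(flags.get(f) is False for f in ("converged",)) or \
           flags.get("all_background"):
            continue
        pose = _pose_of(res, site.ndim)
        moved = apply_pose(site.localizations, pose, "data-to-model")
        pooled.append(moved.in_channel(target_channel))
    if not pooled:
        raise ValueError("no converged sites to average")
    return LocalizationSet.concatenate(pooled)


def pseudotime_reconstruct(sites, fit_results, sort_key: str,
                           bin_size: int = 21, window: int | None = None,
                           step: int = 1) -> list[dict]:
    """Order sites by a monotonically progressing fitted parameter and pool
    pose-aligned localizations per pseudotime bin.

    Fixed bins of ``bin_size`` drop the remainder; when ``window`` is given
    a moving average over the sorted sites is returned instead (frames of
    ``window`` sites advancing by ``step``, n − window + 1 frames for
    step 1, remainder kept).
    """
    import warnings

    values = []
    for res in fit_results:
        e = res.estimates if hasattr(res, "estimates") else res
        if sort_key not in e:
            raise KeyError(f"sort key {sort_key!r} missing from a fit result")
        values.append(e[sort_key])
    order = np.argsort(values, kind="stable")
    aligned = []
    for idx in order:
        pose = _pose_of(fit_results[idx], sites[idx].ndim)
        aligned.append(apply_pose(sites[idx].localizations, pose,
                                  "data-to-model"))
    n = len(aligned)
    out = []
    if window is not None:
        for start in range(0, n - window + 1, step):
            members = aligned[start:start + window]
            out.append({
                "start": start,
                "sort_value": float(np.mean(
                    [values[order[i]] for i in range(start, start + window)])),
                "localizations": LocalizationSet.concatenate(members)})
        return out
    if bin_size > n:
        warnings.warn("bin_size exceeds the number of sites; single bin")
        return [{"start": 0, "sort_value": float(np.mean(values)),
                 "localizations": LocalizationSet.concatenate(aligned)}]
    for b in range(n // bin_size):
        members = aligned[b * bin_size:(b + 1) * bin_size]
        vals = [values[order[i]]
                for i in range(b * bin_size, (b + 1) * bin_size)]
        out.append({"start": b * bin_size, "sort_value": float(np.mean(vals)),
                    "localizations": LocalizationSet.concatenate(members)})
    return out


def azimuthal_harmonics(coords: np.ndarray, n_bins: int = 360,
                        max_order: int = 16) -> np.ndarray:
    """Magnitude spectrum of the azimuthal density about the z axis.

    Returns magnitudes for harmonic orders 0..max_order; an n-fold
    symmetric point distribution peaks at order n.
    """
    ang = np.arctan2(coords[:, 1], coords[:, 0])
    hist, _ = np.histogram(ang, bins=n_bins, range=(-math.pi, math.pi))
    spec = np.abs(np.fft.rfft(hist - hist.mean()))
    return spec[:max_order + 1]
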