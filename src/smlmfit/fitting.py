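"""Maximum-likelihood fitting, confidence intervals and model selection.

A :class:`FitStep` bundles a model (or a composite-spec builder), the split
into free and fixed parameters, bounds, initial values and the optimizer
choice.  :func:`fit_step` maximizes the log-likelihood (or the
cross-correlation score) over the free parameters; :func:`chain_fit` runs a
sequence of steps, passing estimates from one step to the next as initial
values — the usual smooth-to-detailed strategy that avoids local optima.

Parameter naming
----------------
Intrinsic parameters keep their model names (``r``, ``s``, ``theta``, ...).
Extrinsic (pose) parameters are ``x0, y0, z0`` (nm), ``alpha, beta, gamma``
(rad, rotations about x/y/z), ``sx, sy, sz`` (scale), ``epsilon`` (extra
uncertainty, nm) and ``w_bg`` (background weight).

Model comparison uses the sample-size-corrected Akaike information
criterion, AIC = 2P − 2 ln L̂ and AICc = AIC + (2P² + 2P)/(K − P − 1) with
K the number of localizations; the smallest AICc marks the preferred model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .locdata import Site
from .models import GeometricModel
from .pdfcore import (Component, CompositeSpec, Pose, background_stats,
                      cross_correlation_score, log_likelihood)

__all__ = [
    "EXTRINSIC_NAMES",
    "FitStep",
    "FitResult",
    "fit_step",
    "chain_fit",
    "estimate_ci",
    "aicc",
    "select_model",
]

EXTRINSIC_NAMES = ("x0", "y0", "z0", "alpha", "beta", "gamma",
                   "sx", "sy", "sz", "epsilon", "w_bg")

_EXTRINSIC_DEFAULTS = {"x0": 0.0, "y0": 0.0, "z0": 0.0,
                       "alpha": 0.0, "beta": 0.0, "gamma": 0.0,
                       "sx": 1.0, "sy": 1.0, "sz": 1.0,
                       "epsilon": 0.0, "w_bg": 0.0}


class DegenerateSiteError(ValueError):
    """Fewer localizations than free parameters + 2; the fit is refused."""


def _pose_from_params(p: dict, ndim: int) -> Pose:
    x0 = (p["x0"], p["y0"]) if ndim == 2 else (p["x0"], p["y0"], p["z0"])
    scale = (p["sx"], p["sy"]) if ndim == 2 else (p["sx"], p["sy"], p["sz"])
    return Pose(x0=x0, angles=(p["alpha"], p["beta"], p["gamma"]),
                scale=scale, extra_sigma=p["epsilon"], bg_weight=p["w_bg"])


def single_model_builder(model: GeometricModel,
                         ndim: int) -> Callable[[dict], CompositeSpec]:
    """Builder for a one-component spec; multi-channel models (per-point
    channel labels) are split into one component per emitted channel, all
    sharing the same intrinsic values and pose."""
    probe = model.evaluate()
    emitted = sorted(set(np.unique(probe.channels)))

    def build(p: dict, sigma_min: float = 0.0) -> CompositeSpec:
        values = {k: v for k, v in p.items() if k in model.defaults()}
        pose = _pose_from_params(p, ndim)
        w = 1.0 - p["w_bg"]
        comps = [Component(model, values=values, pose=pose, weight=w,
                           channel=c, model_channel=(c if len(emitted) > 1
                                                     else None))
                 for c in emitted]
        return CompositeSpec(comps, bg_weight=p["w_bg"],
                             sigma_min=sigma_min)

    return build


@dataclass
class FitStep:
    """One fitting step.

    ``model`` is a registered :class:`GeometricModel`; alternatively pass a
    ``builder`` mapping a full parameter dict to a :class:`CompositeSpec`
    together with ``param_names``.  ``free`` names the fitted parameters;
    everything else is fixed (``fixed`` overrides defaults).  ``init``
    entries may be numbers or the string ``"inherit"`` (take the value from
    the previous step in a chain); ``inherit_map`` renames inherited
    parameters (this-step name -> previous-step name).
    """

    model: GeometricModel | None = None
    builder: Callable | None = None
    param_names: Sequence[str] | None = None
    free: Sequence[str] = ()
    fixed: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=dict)
    init: dict = field(default_factory=dict)
    inherit_map: dict = field(default_factory=dict)
    optimizer: str = "global-evolutionary"  # | simplex | gradient
    objective: str = "mle"  # | cc
    sigma_min: float = 0.0
    compute_ci: bool = False
    name: str = ""
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.builder is None:
            if self.model is None:
                raise ValueError("FitStep needs a model or a builder")
            self.param_names = (tuple(self.model.param_names())
                                + EXTRINSIC_NAMES)
        if not self.name:
            self.name = self.model.name if self.model else "custom"

    def all_defaults(self, ndim: int) -> dict:
        d = dict(_EXTRINSIC_DEFAULTS)
        if self.model is not None:
            d.update(self.model.defaults())
        else:
            d.update({n: 0.0 for n in self.param_names
                      if n not in _EXTRINSIC_DEFAULTS})
            d.update(_EXTRINSIC_DEFAULTS)
        return d

    def default_bounds(self, site: Site) -> dict:
        half = site.side_length / 2
        b = {"x0": (-half, half), "y0": (-half, half), "z0": (-half, half),
             "alpha": (-math.pi / 2, math.pi / 2),
             "beta": (-math.pi / 2, math.pi / 2),
             "gamma": (-math.pi, math.pi),
             "sx": (0.2, 5.0), "sy": (0.2, 5.0), "sz": (0.2, 5.0),
             "epsilon": (0.0, 50.0), "w_bg": (0.0, 0.9)}
        if self.model is not None:
            b.update(self.model.bounds())
            n = self.model.meta.get("symmetry")
            if n:  # n-fold rotational ambiguity: restrict γ to one sector
                b["gamma"] = (0.0, 2 * math.pi / n)
        b.update(self.bounds)
        return b


@dataclass
class FitResult:
    """Estimates and diagnostics of one fitting step."""

    estimates: dict
    max_loglik: float
    n_params: int
    n_locs: int
    free_names: tuple
    aic: float | None = None
    aicc: float | None = None
    aicc_per_loc: float | None = None
    hessian: np.ndarray | None = None
    variances: dict | None = None
    ci95: dict | None = None
    quadratic_const: float | None = None
    derived: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    step_name: str = ""
    objective: str = "mle"

    def to_dict(self) -> dict:
        out = {
            "step": self.step_name,
            "objective": self.objective,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "max_loglik": self.max_loglik,
            "n_params": self.n_params,
            "n_locs": self.n_locs,
            "aic": self.aic,
            "aicc": self.aicc,
            "aicc_per_loc": self.aicc_per_loc,
            "derived": self.derived,
            "flags": self.flags,
        }
        if self.ci95 is not None:
            out["ci95"] = {k: [float(a), float(b)]
                           for k, (a, b) in self.ci95.items()}
            out["variances"] = {k: float(v) for k, v in self.variances.items()}
        return out


def aicc(loglik: float, n_params: int, n_locs: int) -> dict:
    """AIC = 2P − 2 ln L̂ and its small-sample correction
    AICc = AIC + (2P² + 2P)/(K − P − 1); also returns AICc/K."""
    P, K = n_params, n_locs
    if K <= P + 1:
        raise ValueError(f"AICc undefined for K={K} <= P+1={P + 1}")
    aic = 2 * P - 2 * loglik
    corr = (2 * P**2 + 2 * P) / (K - P - 1)
    return {"aic": aic, "aicc": aic + corr, "aicc_per_loc": (aic + corr) / K}


def _resolve_step(step: FitStep, site: Site, prev: dict | None):
    """Return (free names, init vector, bounds array, full fixed dict)."""
    defaults = step.all_defaults(site.ndim)
    bounds = step.default_bounds(site)

    def inherited(name):
        src = step.inherit_map.get(name, name)
        if prev is None or src not in prev:
            raise KeyError(
                f"step {step.name!r}: cannot inherit {name!r} (prev has "
                f"{sorted(prev) if prev else 'nothing'})")
        return prev[src]

    fixed = dict(defaults)
    for k, v in step.fixed.items():
        fixed[k] = inherited(k) if v == "inherit" else v
    free = list(step.free)
    x0 = []
    for name in free:
        if name in step.init:
            v = step.init[name]
            v = inherited(name) if v == "inherit" else v
        elif prev is not None and (name in prev or name in step.inherit_map):
            try:
                v = inherited(name)
            except KeyError:
                v = fixed.get(name, defaults[name])
        else:
            v = fixed.get(name, defaults[name])
        lo, hi = bounds[name]
        x0.append(min(max(v, lo), hi))
    barr = [bounds[n] for n in free]
    return free, np.array(x0, float), barr, fixed


def _make_objective(step: FitStep, site: Site, free, fixed):
    locs = site.localizations
    builder = (step.builder if step.builder is not None
               else single_model_builder(step.model, site.ndim))
    sign = -1.0

    def params_of(x):
        p = dict(fixed)
        p.update(zip(free, x))
        return p

    def neg_objective(x):
        spec = builder(params_of(x), sigma_min=step.sigma_min)
        if step.objective == "cc":
            return sign * cross_correlation_score(locs, spec, site)
        ll, _ = log_likelihood(locs, spec, site)
        return sign * ll

    return neg_objective, params_of


def _wrap_symmetric_gamma(step: FitStep, estimates: dict) -> None:
    """For an n-fold symmetric model both the in-plane rotation γ and the
    ring twist θ are only identifiable modulo 2π/n; report them in the
    canonical sector ([0, 2π/n) for γ, centered for θ)."""
    n = step.model.meta.get("symmetry") if step.model is not None else None
    if not n:
        return
    sector = 2 * math.pi / n
    if "gamma" in estimates:
        estimates["gamma"] = float(estimates["gamma"] % sector)
    if "theta" in estimates:
        estimates["theta"] = float(
            (estimates["theta"] + sector / 2) % sector - sector / 2)


def fit_step(site: Site, step: FitStep, seed: int = 0,
             _prev: dict | None = None) -> FitResult:
    """Maximize the objective of one step over its free parameters.

    Deterministic for fixed (site, step, seed).  A site with fewer than
    P + 2 localizations is refused.  Non-convergence returns the best
    point found, flagged; a background weight at its upper bound flags a
    degenerate all-background fit.
    """
    locs = site.localizations
    free, x0, bounds, fixed = _resolve_step(step, site, _prev)
    P, K = len(free), locs.n_locs
    if K < P + 2:
        raise DegenerateSiteError(
            f"site has K={K} localizations but the step frees P={P} "
            "parameters; need K >= P + 2")
    neg_obj, params_of = _make_objective(step, site, free, fixed)

    flags = {}
    if P == 0:
        xbest, success, nfev = x0, True, 1
    elif step.optimizer == "global-evolutionary":
        opts = {"maxiter": 60, "popsize": 12, "tol": 0.005,
                "mutation": (0.4, 1.0), "recombination": 0.8}
        opts.update(step.options)
        res = optimize.differential_evolution(
            neg_obj, bounds, x0=x0, seed=int(seed) % (2**31),
            polish=True, **opts)
        xbest, success, nfev = res.x, bool(res.success), res.nfev
    elif step.optimizer == "simplex":
        opts = {"maxfev": 400 * max(P, 1), "xatol": 1e-4, "fatol": 1e-7}
        opts.update(step.options)
        if "initial_simplex" not in opts:
            # bound-scaled initial simplex: the default one degenerates
            # for parameters whose initial value is zero
            steps = np.array([0.02 * (hi - lo) for lo, hi in bounds])
            verts = np.vstack([x0, x0 + np.diag(steps)])
            hi_arr = np.array([hi for _, hi in bounds])
            lo_arr = np.array([lo for lo, _ in bounds])
            over = verts > hi_arr  # reflect vertices that leave the box
            verts = np.where(over, verts - 2 * np.vstack(
                [np.zeros(P), np.diag(steps)]), verts)
            verts = np.clip(verts, lo_arr, hi_arr)
            opts["initial_simplex"] = verts
        res = optimize.minimize(neg_obj, x0, method="Nelder-Mead",
                                bounds=bounds, options=opts)
        xbest, success, nfev = res.x, bool(res.success), res.nfev
    elif step.optimizer == "gradient":
        opts = dict(step.options)
        res = optimize.minimize(neg_obj, x0, method="L-BFGS-B",
                                bounds=bounds, options=opts)
        xbest, success, nfev = res.x, bool(res.success), res.nfev
    else:
        raise ValueError(f"unknown optimizer {step.optimizer!r}")

    max_ll = -neg_obj(xbest)
    if not success:
        flags["converged"] = False
    estimates = params_of(xbest)
    _wrap_symmetric_gamma(step, estimates)
    w_bg = estimates.get("w_bg", 0.0)
    if P and "w_bg" in free:
        hi = bounds[free.index("w_bg")][1]
        if w_bg >= hi - 1e-6:
            flags["all_background"] = True

    try:
        crit = aicc(max_ll, P, K)
    except ValueError:
        crit = {"aic": None, "aicc": None, "aicc_per_loc": None}

    result = FitResult(
        estimates=estimates, max_loglik=max_ll, n_params=P, n_locs=K,
        free_names=tuple(free), derived=background_stats(K, w_bg,
                                                         site.side_length),
        flags=flags, step_name=step.name, objective=step.objective,
        **crit,
    )
    result.flags["nfev"] = nfev
    if step.compute_ci and P:
        ci = estimate_ci(neg_obj, xbest, bounds, seed=seed)
        result.hessian = ci["hessian"]
        result.quadratic_const = ci["a0"]
        result.variances = dict(zip(free, ci["variances"]))
        result.ci95 = {
            n: (estimates[n] - hw, estimates[n] + hw)
            for n, hw in zip(free, ci["ci95_halfwidth"])}
        if ci["flagged"]:
            result.flags["ci_unreliable"] = True
    return result


def estimate_ci(neg_loglik: Callable, p_hat: np.ndarray, bounds,
                seed: int = 0, n_samples: int | None = None,
                radius_frac: float = 0.02) -> dict:
    """Hessian-based 95% confidence intervals.

    The log-likelihood is sampled at random parameter vectors near p̂
    (uniform within ±radius_frac of each bound range) and least-squares
    fitted with the quadratic form
    LL_q(p) = ½ (p − p̂)ᵀ H (p − p̂) + a0, so that H estimates the Hessian
    of the log-likelihood and [(−H)⁻¹]_bb is the b-th parameter variance
    (matching the Fisher-information limit for a Gaussian-location
    problem); CI(p̂_b) = p̂_b ± 1.96·√var.  If −H is not positive definite
    the result is flagged and a pseudo-inverse is used.
    """
    p_hat = np.asarray(p_hat, float)
    P = len(p_hat)
    if n_samples is None:
        n_samples = 20 * P * (P + 3) // 2
    rng = np.random.default_rng(seed)
    ranges = np.array([hi - lo for lo, hi in bounds])
    lows = np.array([lo for lo, _ in bounds])
    highs = np.array([hi for _, hi in bounds])
    deltas = rng.uniform(-1.0, 1.0, size=(n_samples, P)) * radius_frac * ranges
    samples = np.clip(p_hat + deltas, lows, highs)
    deltas = samples - p_hat
    ll = np.array([-neg_loglik(s) for s in samples])

    # design: constant + upper-triangle quadratic monomials of the form
    # ½ H_aa Δa² + H_ab Δa Δb, so the coefficients are Hessian entries
    cols = [np.ones(n_samples)]
    index = []
    for a in range(P):
        for b in range(a, P):
            col = deltas[:, a] * deltas[:, b]
            cols.append(0.5 * col if a == b else col)
            index.append((a, b))
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, ll, rcond=None)
    a0 = coef[0]
    H = np.zeros((P, P))
    for c, (a, b) in zip(coef[1:], index):
        H[a, b] = H[b, a] = c
    negH = -H
    flagged = False
    try:
        eigvals = np.linalg.eigvalsh(negH)
        if eigvals.min() <= 0:
            raise np.linalg.LinAlgError
        cov = np.linalg.inv(negH)
    except np.linalg.LinAlgError:
        flagged = True
        cov = np.linalg.pinv(negH)
    var = np.abs(np.diag(cov))
    return {"hessian": H, "a0": float(a0), "variances": var,
            "ci95_halfwidth": 1.96 * np.sqrt(var), "flagged": flagged}


def chain_fit(site: Site, steps: Sequence[FitStep],
              seed: int = 0) -> list[FitResult]:
    """Run fitting steps in order; each step's ``"inherit"`` initial values
    resolve from the previous step's estimates (via ``inherit_map`` when
    names differ)."""
    results: list[FitResult] = []
    prev: dict | None = None
    for i, step in enumerate(steps):
        res = fit_step(site, step, seed=seed + i, _prev=prev)
        results.append(res)
        prev = res.estimates
    return results


def npc_chain_steps(radius_init: float = 53.4,
                    fast: bool = False) -> list[FitStep]:
    """The standard three-step nuclear-pore chain.

    1. smooth continuous dual-ring, fixed radius, strong extra blur,
       global evolutionary search of position/tilt/separation;
    2. continuous dual-ring refinement (radius, separation, ε, w_bg free)
       with a simplex;
    3. discrete 32-point model adding in-plane rotation γ and ring twist θ
       (γ restricted to one 45° symmetry sector).

    :func:`fit_npc_chain` inserts a coarse (γ, θ) grid scan between steps
    2 and 3, since neither is observable by the rotationally symmetric
    ring models.
    """
    from .models import npc_discrete, npc_dual_ring

    ring = npc_dual_ring(radius=radius_init)
    disc = npc_discrete(radius=radius_init)
    de_opts = ({"maxiter": 25, "popsize": 8, "tol": 0.01} if fast
               else {"maxiter": 40, "popsize": 10, "tol": 0.005})
    inherit = {k: "inherit" for k in ("x0", "y0", "z0", "alpha", "beta", "s")}
    # physiological parameter windows: r/s keep the rare site with one
    # sparsely labeled ring from collapsing onto a single-ring solution;
    # the tilt bounds encode that envelope-bound pores stand near-vertical
    # (a tilt/separation degeneracy otherwise skews ŝ low)
    npc_bounds = {"r": (30.0, 80.0), "s": (20.0, 100.0),
                  "alpha": (-0.35, 0.35), "beta": (-0.35, 0.35)}
    return [
        FitStep(model=ring, free=("x0", "y0", "z0", "alpha", "beta", "s"),
                fixed={"epsilon": 10.0, "w_bg": 0.02, "r": radius_init},
                bounds=npc_bounds,
                optimizer="global-evolutionary", sigma_min=6.0,
                options=de_opts, name="ring-global"),
        FitStep(model=ring,
                free=("x0", "y0", "z0", "alpha", "beta", "r", "s",
                      "epsilon", "w_bg"),
                init={**inherit, "epsilon": 6.0, "w_bg": 0.02},
                bounds=npc_bounds,
                optimizer="simplex", sigma_min=4.0,
                options={"maxfev": 1500}, name="ring-refine"),
        FitStep(model=disc, bounds=npc_bounds,
                free=("x0", "y0", "z0", "alpha", "beta", "gamma", "r", "s",
                      "theta", "epsilon", "w_bg"),
                init={k: "inherit" for k in
                      ("x0", "y0", "z0", "alpha", "beta", "r", "s",
                       "epsilon", "w_bg")},
                optimizer="simplex", options={"maxfev": 2500},
                name="npc-discrete"),
    ]


def fit_npc_chain(site: Site, seed: int = 0, radius_init: float = 53.4,
                  fast: bool = False,
                  compute_ci: bool = False) -> list[FitResult]:
    """Chained NPC fit (smooth → refined ring → discrete corners) with a
    coarse grid over the rotation/twist pair to initialize the final step."""
    steps = npc_chain_steps(radius_init, fast=fast)
    steps[-1].compute_ci = compute_ci
    r1 = fit_step(site, steps[0], seed=seed)
    r2 = fit_step(site, steps[1], seed=seed + 1, _prev=r1.estimates)
    # γ/θ are invisible to the ring models: coarse joint scan before the
    # discrete fit
    disc = steps[2].model
    builder = single_model_builder(disc, site.ndim)
    base = dict(r2.estimates)
    defaults = steps[2].all_defaults(site.ndim)
    best = None
    for g in np.linspace(0.0, math.pi / 4, 6, endpoint=False):
        for th in np.linspace(-math.radians(20), math.radians(20), 5):
            p = dict(defaults)
            p.update(base)
            p["gamma"], p["theta"] = g, th
            ll, _ = log_likelihood(site.localizations,
                                   builder(p, sigma_min=steps[2].sigma_min),
                                   site)
            if best is None or ll > best[0]:
                best = (ll, g, th)
    steps[2].init = dict(steps[2].init)
    steps[2].init.update(gamma=best[1], theta=best[2])
    r3 = fit_step(site, steps[2], seed=seed + 2, _prev=r2.estimates)
    return [r1, r2, r3]


def npc_symmetry_selection(site: Site, symmetries=(6, 7, 8, 9, 10),
                           seed: int = 0, fast: bool = True) -> list[dict]:
    """Fit rotationally symmetric NPC models of the given symmetries to
    one site and rank them by AICc.

    The two continuous ring steps (symmetry-blind) run once and their
    estimates seed every discrete candidate; per candidate a coarse
    (γ, θ) scan inside its own symmetry sector initializes a simplex
    refinement.  Returns rows sorted ascending by AICc.
    """
    from .models import npc_discrete

    steps = npc_chain_steps(fast=fast)
    r1 = fit_step(site, steps[0], seed=seed)
    r2 = fit_step(site, steps[1], seed=seed + 1, _prev=r1.estimates)
    rows = []
    for idx, n in enumerate(symmetries):
        disc = npc_discrete(symmetry=n)
        builder = single_model_builder(disc, site.ndim)
        step = FitStep(model=disc,
                       free=("x0", "y0", "z0", "alpha", "beta", "gamma",
                             "r", "s", "theta", "epsilon", "w_bg"),
                       init={k: "inherit" for k in
                             ("x0", "y0", "z0", "alpha", "beta", "r", "s",
                              "epsilon", "w_bg")},
                       bounds={"r": (30.0, 80.0), "s": (20.0, 100.0)},
                       optimizer="simplex", options={"maxfev": 2500},
                       name=f"npc-{n}fold")
        defaults = step.all_defaults(site.ndim)
        sector = 2 * math.pi / n
        best = None
        for g in np.linspace(0.0, sector, 6, endpoint=False):
            for th in np.linspace(-sector / 2.2, sector / 2.2, 5):
                p = dict(defaults)
                p.update(r2.estimates)
                p["gamma"], p["theta"] = g, th
                ll, _ = log_likelihood(site.localizations, builder(p), site)
                if best is None or ll > best[0]:
                    best = (ll, g, th)
        step.init = dict(step.init)
        step.init.update(gamma=best[1], theta=best[2])
        res = fit_step(site, step, seed=seed + 2 + idx, _prev=r2.estimates)
        rows.append({"name": step.name, "symmetry": n, "result": res,
                     "aicc": res.aicc, "aicc_per_loc": res.aicc_per_loc})
    return sorted(rows, key=lambda r: r["aicc"])


def select_model(site: Site, candidates, seed: int = 0) -> list[dict]:
    """Fit every candidate (a FitStep or a chain of them) to the same site
    and rank ascending by AICc (the smallest AICc indicates the preferred
    model; stable order breaks ties)."""
    rows = []
    for i, cand in enumerate(candidates):
        steps = cand if isinstance(cand, (list, tuple)) else [cand]
        results = chain_fit(site, steps, seed=seed)
        final = results[-1]
        rows.append({"name": steps[-1].name or f"candidate{i}",
                     "index": i, "result": final, "aicc": final.aicc,
                     "aicc_per_loc": final.aicc_per_loc})
    return sorted(rows, key=lambda r: (r["aicc"], r["index"]))
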