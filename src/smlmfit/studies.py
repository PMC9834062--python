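"""Simulation-based validation studies.

Each study simulates localization data at defined conditions, runs the
corresponding analysis end to end and reports summary numbers.  They are
the package's validation loop — fitting synthetic structures and comparing
the estimates with the generating ground truth — and are shared by the
test suite and the acceptance script.

Study conditions (chosen once; see docs/methods.md):

* parameter recovery — NPCs at the experimental mean geometry
  (r = 53.4 nm, s = 50.2 nm, θ = 8.8°), ~10 nm lateral precision,
  6.4 nm label displacement, 80% labeling;
* symmetry selection — the same geometry imaged at experimental-grade
  conditions (~4.5 nm lateral precision after quality filtering, 3 nm
  label displacement, fewer re-blinks), where the corner signal is
  resolvable;
* model-free averaging — 60% labeling, ~10 nm precision, n = 50 subset
  for the initial template;
* z-distortion correction — NPCs spread over ±400 nm of depth with a
  synthetic quadratic axial compression.
"""

from __future__ import annotations

import math

import numpy as np

from . import averaging as av
from .fitting import (FitStep, fit_npc_chain, fit_step, npc_chain_steps,
                      npc_symmetry_selection)
from .locdata import LocalizationSet, Site
from .models import npc_dual_ring
from .pdfcore import rotation_matrix
from .preprocess import apply_distortion_correction, fit_distortion
from .simulator import simulate_npc_study

__all__ = [
    "SELECTION_CONDITIONS",
    "wrap_sector",
    "recovery_study",
    "selection_study",
    "averaging_study",
    "zcorrection_study",
]

#: imaging conditions of the symmetry-selection study (experimental-grade
#: precision after quality filtering; small-tag label displacement)
SELECTION_CONDITIONS = dict(brightness=1e5, extra_displacement_sd=3.0,
                            reactivation_prob=0.3)


def wrap_sector(angle: float, sector: float = math.pi / 4) -> float:
    """Fold an angular error into the centered symmetry sector."""
    return (angle + sector / 2) % sector - sector / 2


def recovery_study(n_sites: int = 200, seed: int = 0,
                   fast: bool = False) -> dict:
    """Chained NPC fits on simulated pores: mean estimates and mean errors
    of ring radius, separation and twist."""
    truth = dict(r=53.4, s=50.2, theta=math.radians(8.8))
    sites = simulate_npc_study(n_sites, seed=seed)
    rows = []
    for i, site in enumerate(sites):
        res = fit_npc_chain(site, seed=seed + 13 * i + 1, fast=fast)[-1]
        e = res.estimates
        rows.append((e["r"], e["s"],
                     math.degrees(wrap_sector(e["theta"] - truth["theta"]))
                     + 8.8, e["epsilon"]))
    arr = np.array(rows)
    out = {
        "n_sites": len(arr),
        "mean_r": float(arr[:, 0].mean()),
        "mean_s": float(arr[:, 1].mean()),
        "mean_theta_deg": float(arr[:, 2].mean()),
        "mean_epsilon": float(arr[:, 3].mean()),
        "bias_r": float(arr[:, 0].mean() - truth["r"]),
        "bias_s": float(arr[:, 1].mean() - truth["s"]),
        "bias_theta_deg": float(arr[:, 2].mean() - 8.8),
        "sd_r": float(arr[:, 0].std()),
        "sd_s": float(arr[:, 1].std()),
        "sd_theta_deg": float(arr[:, 2].std()),
    }
    return out


def selection_study(n_sites: int = 100, seed: int = 0,
                    symmetries=(6, 7, 8, 9, 10)) -> dict:
    """Fit competing rotational symmetries to simulated 8-fold pores and
    report how often the 8-fold model attains the lowest AICc."""
    sites = simulate_npc_study(n_sites, seed=seed, **SELECTION_CONDITIONS)
    winners = []
    per_loc = {n: [] for n in symmetries}
    for i, site in enumerate(sites):
        rows = npc_symmetry_selection(site, symmetries=symmetries,
                                      seed=seed + 101 * i)
        winners.append(rows[0]["symmetry"])
        for r in rows:
            per_loc[r["symmetry"]].append(r["aicc_per_loc"])
    winners = np.array(winners)
    return {
        "n_sites": len(winners),
        "fraction_correct": float((winners == 8).mean()),
        "percent_correct": float(100.0 * (winners == 8).mean()),
        "winner_counts": {int(n): int((winners == n).sum())
                          for n in symmetries},
        "median_aicc_per_loc": {int(n): float(np.median(v))
                                for n, v in per_loc.items()},
    }


def _refit_ring_radius(locs: LocalizationSet, seed: int = 0,
                       cap: int = 4000) -> dict:
    rng = np.random.default_rng(seed)
    sub = av._subsample(locs, cap, rng)
    side = 2 * float(np.abs(sub.coords).max() + 1)
    site = Site(sub, side_length=side, center=np.zeros(3))
    step = FitStep(model=npc_dual_ring(),
                   free=("x0", "y0", "z0", "alpha", "beta", "r", "s"),
                   fixed={"epsilon": 8.0, "w_bg": 0.02},
                   bounds={"r": (30.0, 80.0), "s": (20.0, 100.0)},
                   optimizer="global-evolutionary", sigma_min=6.0,
                   options={"maxiter": 40, "popsize": 10}, name="refit")
    res = fit_step(site, step, seed=seed)
    return res.estimates


def averaging_study(n_particles: int = 150, seed: int = 0,
                    n_subset: int = 50, J: int = 3,
                    template_cap: int = 2500,
                    max_iterations: int = 6,
                    reg_extra_sigma: float = 3.0,
                    n_gamma: int = 48) -> dict:
    """Model-free fusion of simulated NPC particles at 60% labeling.

    Imaging conditions follow the experimental-grade
    :data:`SELECTION_CONDITIONS` (merged/filtered-equivalent precision):
    registration of sparse particles needs the corner signal to be
    resolvable.  No parametric model of the pore enters the fusion; the
    fused particle is afterwards aligned to its own symmetry frame by a
    dual-ring refit and its azimuthal harmonic spectrum and refit radius
    quantify how well the 8-fold geometry is recovered.
    """
    from .pdfcore import Pose, apply_pose

    sites = simulate_npc_study(n_particles, seed=seed, labeling_prob=0.6,
                               **SELECTION_CONDITIONS)
    template = av.build_initial_template(
        sites[:n_subset], seed=seed + 1, prealign=False, restarts=3,
        n_gamma=n_gamma, max_target_points=template_cap,
        extra_sigma=reg_extra_sigma)
    final = av.iterative_average(
        sites, template, J=J, seed=seed + 2, restarts=3, n_gamma=n_gamma,
        max_target_points=template_cap, max_iterations=max_iterations,
        extra_sigma=reg_extra_sigma)
    refit = _refit_ring_radius(final.localizations, seed=seed + 3)
    axis_pose = Pose(x0=(refit["x0"], refit["y0"], refit["z0"]),
                     angles=(refit["alpha"], refit["beta"], 0.0))
    aligned = apply_pose(final.localizations, axis_pose, "data-to-model")
    spec = av.azimuthal_harmonics(aligned.coords)
    return {
        "n_particles": len(sites),
        "n_fused_locs": len(final.localizations),
        "score": final.score,
        "harmonics": spec.tolist(),
        "peak_harmonic": int(np.argmax(spec[1:]) + 1),
        "refit_radius": float(refit["r"]),
        "refit_separation": float(refit["s"]),
        "template": final,
    }


def _npc_fit(site: Site, seed: int) -> dict:
    """Full chained NPC fit; the discrete-corner step supplies the
    unbiased separation estimate."""
    return fit_npc_chain(site, seed=seed, fast=True)[-1].estimates


def zcorrection_study(n_sites: int = 36, seed: int = 0,
                      base_factor: float = 0.93,
                      quad_coeff: float = 8e-8) -> dict:
    """End-to-end depth-distortion correction on simulated NPCs.

    Pores with the calibration-standard separation E(s) = 49.3 nm are
    placed across ±400 nm of depth; a synthetic axial compression
    z → ∫ (base_factor + quad_coeff·u²) du distorts all z coordinates.
    Ring fits of the distorted sites feed the quadratic distortion model;
    the correction is applied and the sites refitted.
    """
    true_s = 49.3
    depths = np.linspace(-400.0, 400.0, n_sites)

    def local_rate(z):
        return base_factor + quad_coeff * z**2

    def distort(z):  # antiderivative of the local compression rate
        return base_factor * z + quad_coeff * z**3 / 3.0

    sites, dist_sites, fits = [], [], []
    for i, zd in enumerate(depths):
        site = simulate_npc_study(1, seed=seed + 500 + i,
                                  separation=true_s)[0]
        coords = site.localizations.coords.copy()
        z_abs = coords[:, 2] + zd
        coords[:, 2] = distort(z_abs) - distort(zd)  # local distorted frame
        # the distortion remaps the measured z axis, so the apparent
        # axial scatter — and with it the reported precision — compresses
        # by the same local rate
        locs = site.localizations.with_coords(coords)
        prec = locs.precisions.copy()
        prec[:, 2] *= local_rate(zd)
        locs = LocalizationSet(locs.coords, prec, channel=locs.channel,
                               frame=locs.frame, photons=locs.photons)
        dist = Site(locs, side_length=site.side_length, center=site.center)
        sites.append(site)
        dist_sites.append(dist)
        fits.append(_npc_fit(dist, seed=seed + i))
    s_meas = np.array([f["s"] for f in fits])
    depth_meas = np.array([distort(zd) + f["z0"]
                           for zd, f in zip(depths, fits)])
    rots = [rotation_matrix(f["alpha"], f["beta"], 0.0) for f in fits]
    model = fit_distortion(depth_meas, s_meas, rotations=rots,
                           expected_separation=true_s)

    s_corr = []
    for zd, dist, f in zip(depths, dist_sites, fits):
        locs = dist.localizations
        abs_coords = locs.coords.copy()
        abs_coords[:, 2] += distort(zd)  # back to absolute distorted depth
        corrected = apply_distortion_correction(
            locs.with_coords(abs_coords), model)
        rel = corrected.coords.copy()
        rel[:, 2] -= np.median(rel[:, 2])  # re-center the site
        side = max(dist.side_length, 2 * float(np.abs(rel).max()) + 1)
        cor_site = Site(corrected.with_coords(rel), side_length=side,
                        center=dist.center)
        s_corr.append(_npc_fit(cor_site, seed=seed + 7000)["s"])
    s_corr = np.array(s_corr)
    return {
        "n_sites": n_sites,
        "true_separation": true_s,
        "mean_s_distorted": float(s_meas.mean()),
        "mean_s_corrected": float(s_corr.mean()),
        "bias_s_corrected": float(s_corr.mean() - true_s),
        "distortion_model": model,
    }
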