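"""Frozen study configurations for the headline computational results.

Each function runs one of the package's reference computations end to end
and returns plain numbers: the Boolean fixture enumeration, the reference
landscape topology, the small-noise stability profile, the exit-time
(Kramers/Freidlin–Wentzell) scaling check on a calibrated double well, the
mountain-pass localization of crossing points, and the two noise-induced
polarization itinerary scenarios.  The study conditions (noise magnitudes,
horizons, replicate counts, integrator steps) are part of the package's
reference protocol; randomness is controlled by the single seed argument.
"""
from __future__ import annotations

import numpy as np

from .boolnet import find_attractors
from .fixtures import make_double_well, make_reference_landscape, make_toy_network
from .landscape import cluster_centers, find_passes
from .mollify import MollifiedLandscape, MollifierConfig
from .sde import SDEConfig, simulate_sde
from .transitions import (
    detect_transitions,
    ensemble_itineraries,
    exit_time_study,
    occupancy,
    pass_localization,
)

__all__ = [
    "boolean_fixture_study",
    "reference_topology_study",
    "stability_study",
    "kramers_study",
    "pass_localization_study",
    "itinerary_study_m1",
    "itinerary_study_m0",
    "REFERENCE_MOLLIFIER_RADIUS",
]

#: kernel radius used for all reference-landscape dynamics (landscape units)
REFERENCE_MOLLIFIER_RADIUS = 0.05

#: noise magnitudes of the small-noise stability scan (Fig. 3-style)
STABILITY_SIGMAS = (0.05, 0.10, 0.15, 0.20)
STABILITY_HORIZON = 150.0
STABILITY_REPLICATES = 200

#: double-well exit-time scaling: sigma grid chosen inside the small-noise
#: regime where mean exits stay computable at 200 replicates
KRAMERS_SIGMAS = (0.30, 0.34, 0.38, 0.42)
KRAMERS_REPLICATES = 200
KRAMERS_HORIZON = 6000.0
KRAMERS_DT = 0.008

#: pass-localization sigma grid (largest to smallest)
LOCALIZATION_SIGMAS = (0.65, 0.50, 0.40)

#: polarization itinerary scenarios (noise magnitude, horizon)
M1_SCENARIO = {"sigma": 0.27, "t_max": 600.0, "replicates": 50}
M0_SCENARIO = {"sigma": 0.20, "t_max": 400.0, "replicates": 50}


def boolean_fixture_study(seed: int = 0) -> dict:
    """Exhaustive vs sampled enumeration of the 3-node fixture network."""
    net = make_toy_network("pair-reporter")
    exact = find_attractors(net, mode="exhaustive")
    sampled = find_attractors(net, mode="sampled", n_samples=10_000, seed=seed)
    exact_frac = {a.states: a.basin_fraction for a in exact}
    worst = max(
        abs(a.basin_fraction - exact_frac[a.states]) for a in sampled
    )
    return {
        "n_attractors": len(exact),
        "basin_sizes": sorted(a.basin_size for a in exact),
        "sampled_max_abs_error": worst,
    }


def reference_topology_study(seed: int = 0) -> dict:
    """Phenotype and spatial-cluster counts of the reference landscape."""
    ls = make_reference_landscape(seed=seed)
    assign = cluster_centers(ls)
    return {"n_phenotypes": ls.n, "n_clusters": int(len(set(assign)))}


def _reference_mollifier() -> MollifiedLandscape:
    ls = make_reference_landscape()
    return MollifiedLandscape(ls, MollifierConfig(radius=REFERENCE_MOLLIFIER_RADIUS))


def stability_study(seed: int = 0) -> list[dict]:
    """Exit probability from the M1 basin within a fixed horizon, per sigma.

    200 replicates of the 0-D reduction per noise magnitude; the probability
    of leaving the M1 basin within the horizon shrinks rapidly as sigma
    decreases, and at the smallest sigma the macrophage stays in its basin
    essentially always.
    """
    moll = _reference_mollifier()
    out = []
    summaries = exit_time_study(
        moll.landscape,
        moll,
        start="M1",
        sigmas=list(STABILITY_SIGMAS),
        replicates=STABILITY_REPLICATES,
        t_max=STABILITY_HORIZON,
        dt=0.01,
        seed=seed,
    )
    for s in summaries:
        out.append({"sigma": s.sigma, "exit_probability": s.exit_probability})
    return out


def kramers_study(seed: int = 0) -> dict:
    """log(mean exit time) vs 1/sigma^2 on the calibrated double well.

    For the gradient SDE the mean exit time obeys tau ~ C exp(2 dF / sigma^2)
    with dF the mountain-pass height, so the regression slope should match
    2 dF.  Well steepness (1, 1), separation 1, kernel radius 0.01.
    """
    dw = make_double_well(a=(1.0, 1.0), separation=1.0)
    moll = MollifiedLandscape(dw, MollifierConfig(radius=0.01))
    (mp,) = find_passes(dw)
    summaries = exit_time_study(
        dw, moll, start="left",
        sigmas=list(KRAMERS_SIGMAS),
        replicates=KRAMERS_REPLICATES,
        t_max=KRAMERS_HORIZON,
        dt=KRAMERS_DT,
        seed=seed,
    )
    means = np.array([s.mean for s in summaries])
    x = 1.0 / np.asarray(KRAMERS_SIGMAS) ** 2
    slope = float(np.polyfit(x, np.log(means), 1)[0])
    return {
        "pass_height": mp.height,
        "slope": slope,
        "slope_over_2dF": slope / (2.0 * mp.height),
        "mean_exit_times": means.tolist(),
        "n_censored": [s.n_censored for s in summaries],
    }


def pass_localization_study(seed: int = 0) -> list[dict]:
    """Median distance of crossing points to the mountain pass, per sigma.

    One long double-well trajectory per noise magnitude; as sigma decreases
    the basin-to-basin crossings concentrate at the saddle.
    """
    dw = make_double_well(a=(1.0, 1.0), separation=1.0)
    moll = MollifiedLandscape(dw, MollifierConfig(radius=0.01))
    passes = find_passes(dw)
    out = []
    for i, sigma in enumerate(LOCALIZATION_SIGMAS):
        cfg = SDEConfig(
            sigma=sigma, dt=0.005, t_end=400.0, x0="left",
            seed=seed + 1000 * i, save_every=2,
        )
        traj = simulate_sde(dw, moll, cfg)
        events = detect_transitions(occupancy(traj, dw))
        _, annotated = pass_localization(events, passes, tolerance=10.0)
        dists = [e.pass_distance for e in annotated if e.pass_distance is not None]
        out.append(
            {
                "sigma": sigma,
                "n_events": len(events),
                "median_pass_distance": float(np.median(dists)) if dists else float("nan"),
            }
        )
    return out


def itinerary_study_m1(seed: int = 0) -> dict:
    """Noise-induced polarization from M1 at sigma 0.27 (Fig. 4 pattern).

    Majority behavior over 50 replicates: the first polarization event is
    the hop into the wound-healing hybrid M1M2d, and the pro-tumoral
    M2aM2d basin is visited before the horizon.
    """
    moll = _reference_mollifier()
    summary = ensemble_itineraries(
        moll, start="M1", sigma=M1_SCENARIO["sigma"],
        replicates=M1_SCENARIO["replicates"], t_max=M1_SCENARIO["t_max"],
        dt=0.01, seed=seed,
    )
    return {
        "sigma": summary.sigma,
        "fraction_first_event_M1M2d": summary.fraction_first("M1M2d"),
        "fraction_reached_M2aM2d": summary.fraction_reached("M2aM2d"),
    }


def itinerary_study_m0(seed: int = 0) -> dict:
    """Monocyte polarization from M0 at sigma 0.20 (Fig. 6 pattern).

    Majority behavior over 50 replicates: the itinerary ends in the deep
    pro-tumoral M2bM2d basin at the horizon; en route the monocyte first
    polarizes within its own valley (M2d / M2cM2d).
    """
    moll = _reference_mollifier()
    summary = ensemble_itineraries(
        moll, start="M0", sigma=M0_SCENARIO["sigma"],
        replicates=M0_SCENARIO["replicates"], t_max=M0_SCENARIO["t_max"],
        dt=0.01, seed=seed,
    )
    first_in_c = sum(t in ("M2d", "M2cM2d") for t in summary.first_target) / len(
        summary.first_target
    )
    return {
        "sigma": summary.sigma,
        "fraction_final_M2bM2d": summary.fraction_final("M2bM2d"),
        "fraction_reached_M2bM2d": summary.fraction_reached("M2bM2d"),
        "fraction_first_event_in_monocyte_valley": first_in_c,
    }
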