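"""Observables of noise-induced polarization.

Trajectories of the stochastic model are reduced to basin occupancy over
time; changes of the dominant basin are polarization events, whose crossing
points can be compared with the mountain passes of the landscape; first
exit times from the starting basin quantify how the transition time depends
(inversely) on the noise magnitude sigma.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .landscape import Landscape, MountainPass, classify_point, passes_by_labels
from .mollify import MollifiedLandscape
from .sde import FieldTrajectory, Trajectory, _check_stability

__all__ = [
    "OccupancyProfile",
    "TransitionEvent",
    "ExitTimeSummary",
    "ItinerarySummary",
    "occupancy",
    "detect_transitions",
    "polarization_sequence",
    "exit_time_study",
    "ensemble_itineraries",
    "pass_localization",
]


@dataclass(frozen=True)
class OccupancyProfile:
    """Per-snapshot fraction of the spatial grid in each basin.

    For the 0-D reduction the "fraction" is the indicator of the current
    basin.  ``mean_xy`` is the spatial mean field, used as the crossing
    point when dominance flips.
    """

    times: np.ndarray  # (K,)
    fractions: np.ndarray  # (K, n_basins)
    mean_xy: np.ndarray  # (K, 2)
    labels: tuple[str, ...]

    def dominant(self, threshold: float = 0.5) -> np.ndarray:
        """Dominant basin index per snapshot; -1 marks a mixed state."""
        idx = np.argmax(self.fractions, axis=1)
        top = self.fractions[np.arange(len(idx)), idx]
        return np.where(top > threshold, idx, -1)


@dataclass(frozen=True)
class TransitionEvent:
    """A change of the dominant basin (a polarization event)."""

    time: float
    source: str
    target: str
    crossing: np.ndarray  # (2,) spatial mean field at the flip
    pass_distance: float | None = None


@dataclass(frozen=True)
class ExitTimeSummary:
    """First-exit statistics from the starting basin at one noise level."""

    sigma: float
    n_replicates: int
    exit_times: np.ndarray  # uncensored first exits
    n_censored: int
    t_max: float
    start: str

    @property
    def n_exited(self) -> int:
        return len(self.exit_times)

    @property
    def exit_probability(self) -> float:
        return self.n_exited / self.n_replicates

    @property
    def mean(self) -> float:
        return float(np.mean(self.exit_times)) if self.n_exited else float("nan")

    @property
    def median(self) -> float:
        return float(np.median(self.exit_times)) if self.n_exited else float("nan")

    @property
    def se(self) -> float:
        if self.n_exited < 2:
            return float("nan")
        return float(np.std(self.exit_times, ddof=1) / np.sqrt(self.n_exited))

    @property
    def all_censored(self) -> bool:
        return self.n_exited == 0


# ---------------------------------------------------------------------------


def occupancy(
    trajectory: Trajectory | FieldTrajectory, landscape: Landscape
) -> OccupancyProfile:
    """Classify every grid point of every snapshot into its basin."""
    if isinstance(trajectory, FieldTrajectory):
        K, N = trajectory.u.shape
        pts = np.stack([trajectory.u, trajectory.v], axis=-1).reshape(K * N, 2)
        idx = classify_point(landscape, pts).reshape(K, N)
        fractions = np.stack(
            [(idx == b).mean(axis=1) for b in range(landscape.n)], axis=1
        )
        mean_xy = np.stack(
            [trajectory.u.mean(axis=1), trajectory.v.mean(axis=1)], axis=1
        )
    else:
        idx = classify_point(landscape, trajectory.xy)
        fractions = np.zeros((len(idx), landscape.n))
        fractions[np.arange(len(idx)), idx] = 1.0
        mean_xy = np.asarray(trajectory.xy)
    return OccupancyProfile(
        times=np.asarray(trajectory.times),
        fractions=fractions,
        mean_xy=mean_xy,
        labels=landscape.labels,
    )


def detect_transitions(
    profile: OccupancyProfile, dominance: float = 0.5
) -> list[TransitionEvent]:
    """Events where the dominant basin changes between consecutive dominant states.

    Snapshots without a basin above the dominance threshold are "mixed" and
    never emit events; the comparison is between successive *dominant*
    snapshots, which debounces boundary flicker.
    """
    if not (0 < dominance <= 1):
        raise ValueError("dominance threshold must lie in (0, 1]")
    dom = profile.dominant(dominance)
    events: list[TransitionEvent] = []
    prev = -1
    for k, b in enumerate(dom):
        if b < 0:
            continue
        if prev >= 0 and b != prev:
            events.append(
                TransitionEvent(
                    time=float(profile.times[k]),
                    source=profile.labels[prev],
                    target=profile.labels[b],
                    crossing=np.asarray(profile.mean_xy[k], dtype=float),
                )
            )
        prev = b
    return events


def polarization_sequence(
    events: Sequence[TransitionEvent], start: str | None = None
) -> list[str]:
    """Ordered itinerary of dominant basins (no events -> just the start)."""
    if not events:
        return [start] if start is not None else []
    seq = [events[0].source if start is None else start]
    for e in events:
        if e.target != seq[-1]:
            seq.append(e.target)
    return seq


# ---------------------------------------------------------------------------
# exit times
# ---------------------------------------------------------------------------


def first_exit_times(
    mollifier: MollifiedLandscape,
    start: str,
    sigma: float,
    replicates: int,
    t_max: float,
    dt: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Vectorized first-exit sampler for the 0-D reduction.

    Runs ``replicates`` independent gradient-SDE paths from the center of
    ``start`` and records the first time each path's basin (argmin of the
    raw landscape) differs from the starting basin; paths that never leave
    within ``t_max`` are censored.  Returns (uncensored exits, n_censored).
    """
    landscape = mollifier.landscape
    _check_stability(dt, landscape)
    start_idx = landscape.index(start)
    x = np.tile(landscape.center(start), (replicates, 1)).astype(float)
    alive = np.ones(replicates, dtype=bool)
    exits = np.full(replicates, np.nan)
    n_steps = int(round(t_max / dt))
    sqdt = np.sqrt(dt)
    for k in range(1, n_steps + 1):
        idx_alive = np.flatnonzero(alive)
        if idx_alive.size == 0:
            break
        sub = x[idx_alive]
        drift, basin = mollifier.drift(sub, return_basin=True)
        sub = sub + drift * dt
        if sigma > 0:
            sub = sub + sigma * sqdt * rng.standard_normal(sub.shape)
        x[idx_alive] = sub
        left = basin != start_idx
        if np.any(left):
            who = idx_alive[left]
            exits[who] = (k - 1) * dt  # basin evaluated before this step's move
            alive[who] = False
    # check basin of final positions for paths that moved out on the last step
    idx_alive = np.flatnonzero(alive)
    if idx_alive.size:
        final_basin = classify_point(landscape, x[idx_alive])
        left = final_basin != start_idx
        exits[idx_alive[left]] = n_steps * dt
        alive[idx_alive[left]] = False
    out = exits[~np.isnan(exits)]
    return out, int(np.sum(alive))


def exit_time_study(
    landscape: Landscape,
    mollifier: MollifiedLandscape | None,
    start: str,
    sigmas: Sequence[float],
    replicates: int,
    t_max: float,
    dt: float,
    seed: int = 0,
) -> list[ExitTimeSummary]:
    """First-exit-time ensembles over a grid of noise magnitudes.

    Uses the 0-D reduction of the stochastic model; censored replicates are
    excluded from the mean/median and reported separately.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    moll = mollifier if mollifier is not None else MollifiedLandscape(landscape)
    rng = np.random.default_rng(seed)
    out = []
    for sigma in sigmas:
        times, n_cens = first_exit_times(
            moll, start, sigma, replicates, t_max, dt, rng
        )
        out.append(
            ExitTimeSummary(
                sigma=float(sigma),
                n_replicates=replicates,
                exit_times=np.sort(times),
                n_censored=n_cens,
                t_max=t_max,
                start=start,
            )
        )
    return out


# ---------------------------------------------------------------------------
# replicated itineraries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ItinerarySummary:
    """Ensemble view of polarization itineraries in the 0-D reduction.

    ``first_target[r]`` is the label of replicate r's first polarization
    event (None if it never left the start basin), ``reached[r, b]`` marks
    basins visited at any time, and ``final[r]`` is the dominant basin at
    the horizon - i.e. the last entry of each replicate's itinerary.
    """

    start: str
    sigma: float
    t_max: float
    labels: tuple[str, ...]
    first_target: tuple[str | None, ...]
    reached: np.ndarray  # (R, n) bool
    final: tuple[str, ...]

    def fraction_first(self, label: str) -> float:
        return sum(t == label for t in self.first_target) / len(self.first_target)

    def fraction_reached(self, label: str) -> float:
        return float(self.reached[:, self.labels.index(label)].mean())

    def fraction_final(self, label: str) -> float:
        return sum(t == label for t in self.final) / len(self.final)


def ensemble_itineraries(
    mollifier: MollifiedLandscape,
    start: str,
    sigma: float,
    replicates: int,
    t_max: float,
    dt: float,
    seed: int = 0,
) -> ItinerarySummary:
    """Run ``replicates`` 0-D paths and summarize their itineraries.

    Vectorized equivalent of simulating each replicate and applying
    ``detect_transitions``: in the 0-D reduction the occupancy profile is
    the indicator of the current basin, so events are exactly the changes
    of the instantaneous basin, the first event's target is the first basin
    the path crosses into, and the itinerary's last entry is the basin at
    the final time.
    """
    landscape = mollifier.landscape
    _check_stability(dt, landscape)
    rng = np.random.default_rng(seed)
    i0 = landscape.index(start)
    R = replicates
    x = np.tile(landscape.center(start), (R, 1)).astype(float)
    first = np.full(R, -1)
    reached = np.zeros((R, landscape.n), dtype=bool)
    reached[:, i0] = True
    n_steps = int(round(t_max / dt))
    sqdt = np.sqrt(dt)
    rows = np.arange(R)
    basin = np.full(R, i0)
    for _ in range(n_steps):
        drift, basin = mollifier.drift(x, return_basin=True)
        fe = (first < 0) & (basin != i0)
        first[fe] = basin[fe]
        reached[rows, basin] = True
        x += drift * dt
        if sigma > 0:
            x += sigma * sqdt * rng.standard_normal(x.shape)
    final = classify_point(landscape, x)
    reached[rows, final] = True
    labels = landscape.labels
    return ItinerarySummary(
        start=start,
        sigma=sigma,
        t_max=t_max,
        labels=labels,
        first_target=tuple(None if f < 0 else labels[f] for f in first),
        reached=reached,
        final=tuple(labels[f] for f in final),
    )


# ---------------------------------------------------------------------------
# mountain-pass localization
# ---------------------------------------------------------------------------


def pass_localization(
    events: Sequence[TransitionEvent],
    passes: Sequence[MountainPass],
    tolerance: float,
) -> tuple[float | None, list[TransitionEvent]]:
    """Fraction of events whose crossing point lies near its mountain pass.

    Each event's crossing point is matched against the pass of its
    (source, target) pair; events between basins with no shared boundary
    count as unmatched.  Returns (matched fraction or None if there are no
    events, events annotated with their pass distance).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if not events:
        return None, []
    by_pair = passes_by_labels(passes)
    annotated: list[TransitionEvent] = []
    matched = 0
    for e in events:
        mp = by_pair.get(frozenset((e.source, e.target)))
        if mp is None:
            annotated.append(e)
            continue
        dist = float(np.linalg.norm(e.crossing - mp.location))
        if dist <= tolerance:
            matched += 1
        annotated.append(
            TransitionEvent(
                time=e.time,
                source=e.source,
                target=e.target,
                crossing=e.crossing,
                pass_distance=dist,
            )
        )
    return matched / len(events), annotated
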