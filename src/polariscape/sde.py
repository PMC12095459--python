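"""Stochastic dynamics on the mollified epigenetic landscape.

Two integrators of the reaction–diffusion model

    dx = (A x + a(x)) dt + dW,     x(t, xi) = (u(t, xi), v(t, xi)),

where A applies diffusion d1, d2 along the 1-D spatial coordinate xi in
[0, L], the reaction a(x) = -grad F_eps(u, v) is the mollified-landscape
drift applied pointwise, and W carries independent Wiener noise of
magnitude sigma per component (white in space, or colored via a truncated
Fourier spectrum).  Diffusion is treated implicitly (tridiagonal solve per
step), drift and noise explicitly (semi-implicit Euler–Maruyama).  The
zero-dimensional reduction (one grid point, no diffusion) is the plain
gradient SDE  d(u, v) = -grad F_eps dt + sigma dW  used for fast
exit-time studies.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.linalg import solve_banded

from .landscape import Landscape
from .mollify import MollifiedLandscape

__all__ = [
    "SDEConfig",
    "SPDEConfig",
    "Trajectory",
    "FieldTrajectory",
    "simulate_sde",
    "simulate_spde",
    "noise_increment",
    "evolve_ensemble",
]


class SimulationBlowupError(RuntimeError):
    """Raised when the integrator produces non-finite values."""


def _check_stability(dt: float, landscape: Landscape):
    # explicit drift substep: dt * max curvature of the wells (2 a_max) <= 1/2
    a_max = float(np.max(landscape.steepness))
    if dt * 2.0 * a_max > 0.5:
        raise ValueError(
            f"dt={dt} violates the drift stability bound dt <= {0.25 / a_max:.3g} "
            f"(max well curvature 2*a = {2 * a_max:.3g})"
        )


@dataclass(frozen=True)
class SDEConfig:
    """Zero-dimensional (well-mixed) simulation settings.

    ``x0`` is either a phenotype label (start at that basin center) or an
    explicit (u, v) pair.  ``sigma`` is the noise magnitude; time units are
    dimensionless.
    """

    sigma: float
    dt: float
    t_end: float
    x0: str | tuple[float, float]
    seed: int = 0
    save_every: int = 1

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be > 0")
        if self.save_every < 1:
            raise ValueError("save_every must be >= 1")


@dataclass(frozen=True)
class SPDEConfig(SDEConfig):
    """Spatially extended simulation settings (1-D domain [0, L])."""

    length: float = 1.0
    n_grid: int = 64
    d1: float = 1e-3
    d2: float = 1e-3
    noise_kind: str = "white"
    boundary: str = "neumann"
    # colored noise: weight per cosine/Fourier mode (mode 0 = constant)
    mode_weights: tuple[float, ...] = ()
    sigma1: float | None = None
    sigma2: float | None = None

    def __post_init__(self):
        super().__post_init__()
        if self.n_grid < 1:
            raise ValueError("n_grid must be >= 1")
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if self.d1 < 0 or self.d2 < 0:
            raise ValueError("diffusivities must be >= 0")
        if self.noise_kind not in ("white", "colored"):
            raise ValueError("noise_kind must be 'white' or 'colored'")
        if self.boundary not in ("neumann", "periodic"):
            raise ValueError("boundary must be 'neumann' or 'periodic'")
        if self.noise_kind == "colored" and not self.mode_weights:
            raise ValueError("colored noise requires a non-empty mode_weights spectrum")

    @property
    def dxi(self) -> float:
        return self.length / self.n_grid

    @property
    def sigmas(self) -> tuple[float, float]:
        s1 = self.sigma if self.sigma1 is None else self.sigma1
        s2 = self.sigma if self.sigma2 is None else self.sigma2
        return s1, s2


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed (u, v) path of the 0-D reduction."""

    times: np.ndarray  # (K,)
    xy: np.ndarray  # (K, 2)
    config: Mapping = field(default_factory=dict)


@dataclass(frozen=True)
class FieldTrajectory:
    """Time-indexed two-component field snapshots (u(t, xi), v(t, xi))."""

    times: np.ndarray  # (K,)
    u: np.ndarray  # (K, N)
    v: np.ndarray  # (K, N)
    config: Mapping = field(default_factory=dict)


def _resolve_x0(landscape: Landscape, x0) -> np.ndarray:
    if isinstance(x0, str):
        return np.array(landscape.center(x0), dtype=float)
    arr = np.asarray(x0, dtype=float)
    if arr.shape != (2,):
        raise ValueError("x0 must be a phenotype label or a (u, v) pair")
    return arr


# ---------------------------------------------------------------------------
# 0-D reduction
# ---------------------------------------------------------------------------


def evolve_ensemble(
    mollifier: MollifiedLandscape,
    x: np.ndarray,
    n_steps: int,
    dt: float,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance an (R, 2) ensemble by Euler–Maruyama steps, in place."""
    sqdt = np.sqrt(dt)
    for _ in range(n_steps):
        drift = mollifier.drift(x)
        x += drift * dt
        if sigma > 0:
            x += sigma * sqdt * rng.standard_normal(x.shape)
    return x


def simulate_sde(
    landscape: Landscape,
    mollifier: MollifiedLandscape | None,
    cfg: SDEConfig,
) -> Trajectory:
    """Euler–Maruyama integration of d(u,v) = -grad F_eps dt + sigma dW."""
    _check_stability(cfg.dt, landscape)
    moll = mollifier if mollifier is not None else MollifiedLandscape(landscape)
    rng = np.random.default_rng(cfg.seed)
    x = _resolve_x0(landscape, cfg.x0)
    n_steps = int(round(cfg.t_end / cfg.dt))
    times = [0.0]
    path = [x.copy()]
    sqdt = np.sqrt(cfg.dt)
    for k in range(1, n_steps + 1):
        _, g = moll.value_grad(x)
        x = x - g * cfg.dt
        if cfg.sigma > 0:
            x = x + cfg.sigma * sqdt * rng.standard_normal(2)
        if not np.all(np.isfinite(x)):
            raise SimulationBlowupError(f"non-finite state at step {k} (t={k * cfg.dt:.4g})")
        if k % cfg.save_every == 0 or k == n_steps:
            times.append(k * cfg.dt)
            path.append(x.copy())
    return Trajectory(
        times=np.asarray(times),
        xy=np.asarray(path),
        config=_sde_provenance(cfg),
    )


def _sde_provenance(cfg: SDEConfig) -> dict:
    d = {
        "sigma": cfg.sigma,
        "dt": cfg.dt,
        "t_end": cfg.t_end,
        "x0": list(cfg.x0) if not isinstance(cfg.x0, str) else cfg.x0,
        "seed": cfg.seed,
        "save_every": cfg.save_every,
    }
    if isinstance(cfg, SPDEConfig):
        d.update(
            length=cfg.length,
            n_grid=cfg.n_grid,
            d1=cfg.d1,
            d2=cfg.d2,
            noise_kind=cfg.noise_kind,
            boundary=cfg.boundary,
            mode_weights=list(cfg.mode_weights),
        )
    return d


# ---------------------------------------------------------------------------
# noise increments
# ---------------------------------------------------------------------------


def _colored_modes(cfg: SPDEConfig) -> np.ndarray:
    """Orthonormal spatial modes on [0, L]: cosines (Neumann) or Fourier."""
    N, L = cfg.n_grid, cfg.length
    xi = (np.arange(N) + 0.5) * cfg.dxi
    modes = []
    for k in range(len(cfg.mode_weights)):
        if cfg.boundary == "neumann":
            phi = (
                np.full(N, 1.0 / np.sqrt(L))
                if k == 0
                else np.sqrt(2.0 / L) * np.cos(k * np.pi * xi / L)
            )
        else:
            if k == 0:
                phi = np.full(N, 1.0 / np.sqrt(L))
            elif k % 2 == 1:
                phi = np.sqrt(2.0 / L) * np.cos(((k + 1) // 2) * 2 * np.pi * xi / L)
            else:
                phi = np.sqrt(2.0 / L) * np.sin((k // 2) * 2 * np.pi * xi / L)
        modes.append(phi)
    return np.asarray(modes)  # (n_modes, N)


def noise_increment(cfg: SPDEConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One Wiener increment per grid point for the u- and v-channels.

    White noise: i.i.d. Normal(0, sigma^2 dt / dxi) per point (the standard
    grid scaling of space-time white noise).  Colored noise: a truncated
    expansion  sigma * sqrt(dt) * sum_k w_k eta_k phi_k(xi)  with orthonormal
    modes phi_k and independent standard normals eta_k per channel.
    """
    s1, s2 = cfg.sigmas
    if cfg.noise_kind == "white":
        std = np.sqrt(cfg.dt / cfg.dxi)
        du = s1 * std * rng.standard_normal(cfg.n_grid)
        dv = s2 * std * rng.standard_normal(cfg.n_grid)
        return du, dv
    modes = _colored_modes(cfg)
    w = np.asarray(cfg.mode_weights, dtype=float)
    eta_u = rng.standard_normal(len(w))
    eta_v = rng.standard_normal(len(w))
    du = s1 * np.sqrt(cfg.dt) * ((w * eta_u) @ modes)
    dv = s2 * np.sqrt(cfg.dt) * ((w * eta_v) @ modes)
    return du, dv


# ---------------------------------------------------------------------------
# SPDE integrator
# ---------------------------------------------------------------------------


def _implicit_diffusion_banded(N: int, c: float, boundary: str):
    """Banded form of (I - c * Lap_h) for solve_banded, or None if c == 0."""
    if c == 0 or N == 1:
        return None
    if boundary == "periodic":
        # dense fallback via circulant solve in Fourier space
        k = np.arange(N)
        lam = -4.0 * np.sin(np.pi * k / N) ** 2  # eigenvalues of Lap_h * dxi^2
        return ("periodic", 1.0 - c * lam)
    ab = np.zeros((3, N))
    ab[0, 1:] = -c  # upper diagonal
    ab[2, :-1] = -c  # lower diagonal
    ab[1, :] = 1.0 + 2.0 * c
    ab[1, 0] = 1.0 + c  # zero-flux ends
    ab[1, -1] = 1.0 + c
    return ("banded", ab)


def _diffuse(solver, x: np.ndarray) -> np.ndarray:
    if solver is None:
        return x
    kind, data = solver
    if kind == "banded":
        return solve_banded((1, 1), data, x)
    spec = np.fft.fft(x)
    return np.real(np.fft.ifft(spec / data))


def simulate_spde(
    landscape: Landscape,
    mollifier: MollifiedLandscape | None,
    cfg: SPDEConfig,
) -> FieldTrajectory:
    """Semi-implicit Euler–Maruyama for the stochastic reaction–diffusion model.

    Each step: explicit drift at every grid point, additive noise increment,
    then an implicit diffusion solve (unconditionally stable) per component.
    Constant-in-xi initial data at a basin center reproduces the 0-D
    gradient flow when sigma = 0 and stays spatially uniform.
    """
    _check_stability(cfg.dt, landscape)
    moll = mollifier if mollifier is not None else MollifiedLandscape(landscape)
    rng = np.random.default_rng(cfg.seed)
    N = cfg.n_grid
    if isinstance(cfg.x0, str) or np.asarray(cfg.x0, dtype=float).shape == (2,):
        c0 = _resolve_x0(landscape, cfg.x0)
        u = np.full(N, c0[0])
        v = np.full(N, c0[1])
    else:
        arr = np.asarray(cfg.x0, dtype=float)
        if arr.shape != (2, N):
            raise ValueError(f"explicit x0 field must have shape (2, {N})")
        u, v = arr[0].copy(), arr[1].copy()

    r1 = cfg.d1 * cfg.dt / cfg.dxi**2
    r2 = cfg.d2 * cfg.dt / cfg.dxi**2
    sol1 = _implicit_diffusion_banded(N, r1, cfg.boundary)
    sol2 = _implicit_diffusion_banded(N, r2, cfg.boundary)

    n_steps = int(round(cfg.t_end / cfg.dt))
    times = [0.0]
    us = [u.copy()]
    vs = [v.copy()]
    for k in range(1, n_steps + 1):
        pts = np.column_stack([u, v])
        drift = moll.drift(pts)
        u = u + drift[:, 0] * cfg.dt
        v = v + drift[:, 1] * cfg.dt
        if cfg.sigma > 0 or cfg.sigma1 or cfg.sigma2:
            du, dv = noise_increment(cfg, rng)
            u = u + du
            v = v + dv
        u = _diffuse(sol1, u)
        v = _diffuse(sol2, v)
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise SimulationBlowupError(
                f"non-finite field at step {k} (t={k * cfg.dt:.4g})"
            )
        if k % cfg.save_every == 0 or k == n_steps:
            times.append(k * cfg.dt)
            us.append(u.copy())
            vs.append(v.copy())
    return FieldTrajectory(
        times=np.asarray(times),
        u=np.asarray(us),
        v=np.asarray(vs),
        config=_sde_provenance(cfg),
    )
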