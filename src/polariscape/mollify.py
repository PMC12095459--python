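"""Smoothing of the min-of-paraboloids potential.

The raw landscape F is continuous but has gradient kinks on basin
boundaries, so the drift of the stochastic model uses a mollified potential
F_eps = F * k_eps (convolution with a kernel of radius eps).  Three
evaluation routes are combined, all agreeing on their overlaps:

* closed form — wherever the kernel's support around the query point lies
  inside a single basin, the convolution of the local paraboloid is exact:
  for the gaussian kernel  F_eps(p) = a |p - c|^2 + 2 a eps^2  and
  grad F_eps = grad F = 2 a (p - c);
* grid — F sampled on a regular grid, convolved with the kernel, and
  interpolated with a bicubic spline (C^2, so the drift is continuous
  across boundaries); used for points near basin boundaries;
* quadrature — Gauss–Hermite average of F over the kernel, used as a
  mesh-free fallback for points outside the precomputed grid.

The drift of the stochastic model is (f, g) = -grad F_eps.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage
from scipy.integrate import quad
from scipy.interpolate import RectBivariateSpline

from .landscape import Landscape, _sq_dists

__all__ = ["MollifierConfig", "MollifiedLandscape", "mollified_potential"]


@dataclass(frozen=True)
class MollifierConfig:
    """Kernel choice and resolution for smoothing the potential.

    ``radius`` is the kernel scale eps in landscape units (gaussian: the
    standard deviation per axis; bump: the support radius).  ``grid_spacing``
    defaults to eps/4 so the convolution grid resolves the kernel.
    """

    kernel: str = "gaussian"
    radius: float = 0.1
    grid_spacing: float | None = None
    cutoff: float = 6.0  # gaussian support truncation, in units of eps
    gh_order: int = 12  # Gauss–Hermite nodes per axis for the fallback

    def __post_init__(self):
        if self.kernel not in ("gaussian", "bump"):
            raise ValueError("kernel must be 'gaussian' or 'bump'")
        if self.radius <= 0:
            raise ValueError("mollifier radius must be > 0")
        h = self.grid_spacing
        if h is None:
            object.__setattr__(self, "grid_spacing", self.radius / 4.0)
        elif h <= 0 or h > self.radius / 4.0 + 1e-15:
            raise ValueError("grid_spacing must satisfy 0 < h <= radius/4")

    @property
    def support_radius(self) -> float:
        """Radius beyond which the kernel mass is negligible."""
        return self.radius if self.kernel == "bump" else self.cutoff * self.radius

    @property
    def second_moment(self) -> float:
        """E|Z|^2 of the kernel: the constant lift of a mollified paraboloid."""
        if self.kernel == "gaussian":
            return 2.0 * self.radius**2
        return _bump_second_moment() * self.radius**2


def default_mollifier(landscape: Landscape, radius_factor: float = 0.05) -> MollifierConfig:
    """Kernel radius = ``radius_factor`` x bounding-box diagonal."""
    lo, hi = landscape.bounding_box()
    diag = float(np.linalg.norm(hi - lo))
    return MollifierConfig(radius=radius_factor * diag)


@lru_cache(maxsize=1)
def _bump_second_moment() -> float:
    """E|Z|^2 (units of eps^2) for the 2-D bump kernel exp(-1/(1-r^2))."""
    mass = quad(lambda r: np.exp(-1.0 / (1.0 - r * r)) * r, 0.0, 1.0)[0]
    m2 = quad(lambda r: np.exp(-1.0 / (1.0 - r * r)) * r**3, 0.0, 1.0)[0]
    return m2 / mass


class MollifiedLandscape:
    """Evaluator of the smoothed potential and its gradient.

    The spline backend over the convolution grid is built lazily the first
    time a query lands near a basin boundary.
    """

    def __init__(self, landscape: Landscape, cfg: MollifierConfig | None = None):
        self.landscape = landscape
        self.cfg = cfg if cfg is not None else default_mollifier(landscape)
        self._splines: tuple | None = None
        self._grid_box: tuple[np.ndarray, np.ndarray] | None = None
        self._gh = None

    # -- region tests -------------------------------------------------------

    def _interior_mask(self, d2: np.ndarray, idx: np.ndarray) -> np.ndarray:
        """True where the kernel ball around the point stays in one basin.

        Sufficient condition: for every other well j,
        a_j (d_j - R)^2 >= a_i (d_i + R)^2 with R the kernel support radius.
        """
        a = self.landscape.steepness
        R = self.cfg.support_radius
        d = np.sqrt(d2)
        m = d.shape[0]
        di = d[np.arange(m), idx]
        own = a[idx] * (di + R) ** 2
        other = a[None, :] * np.maximum(d - R, 0.0) ** 2
        other[np.arange(m), idx] = np.inf
        return other.min(axis=1) >= own

    # -- grid backend -------------------------------------------------------

    def _build_grid(self):
        # grid covers the centers' box plus a margin; queries beyond it are
        # served by the quadrature fallback, so a tight box keeps the spline
        # cheap without losing correctness far afield
        eps, h = self.cfg.radius, self.cfg.grid_spacing
        lo = self.landscape.centers.min(axis=0)
        hi = self.landscape.centers.max(axis=0)
        span = float(np.max(hi - lo))
        margin = max(4.0 * self.cfg.support_radius, 0.25 * span, 0.5)
        lo = lo - margin
        hi = hi + margin
        xs = np.arange(lo[0], hi[0] + h, h)
        ys = np.arange(lo[1], hi[1] + h, h)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel()])
        F = (
            (_sq_dists(pts, self.landscape.centers) * self.landscape.steepness)
            .min(axis=1)
            .reshape(X.shape)
        )
        if self.cfg.kernel == "gaussian":
            Fs = ndimage.gaussian_filter(
                F, sigma=eps / h, mode="nearest", truncate=self.cfg.cutoff
            )
        else:
            r = int(np.ceil(eps / h))
            ax = np.arange(-r, r + 1) * h / eps
            RX, RY = np.meshgrid(ax, ax, indexing="ij")
            rho2 = RX**2 + RY**2
            K = np.where(rho2 < 1.0, np.exp(-1.0 / np.maximum(1.0 - rho2, 1e-300)), 0.0)
            K /= K.sum()
            pad = r
            Fp = np.pad(F, pad, mode="edge")
            from scipy.signal import fftconvolve

            Fs = fftconvolve(Fp, K, mode="same")[pad:-pad, pad:-pad]
        spline = RectBivariateSpline(xs, ys, Fs, kx=3, ky=3, s=0)
        self._splines = (spline,)
        self._grid_box = (np.array([xs[0], ys[0]]), np.array([xs[-1], ys[-1]]))

    def _in_grid(self, pts: np.ndarray) -> np.ndarray:
        if self._grid_box is None:
            self._build_grid()
        lo, hi = self._grid_box
        return np.all((pts >= lo) & (pts <= hi), axis=1)

    def _eval_spline(self, pts: np.ndarray):
        (spline,) = self._splines
        x, y = pts[:, 0], pts[:, 1]
        F = spline.ev(x, y)
        Gx = spline.ev(x, y, dx=1)
        Gy = spline.ev(x, y, dy=1)
        return F, np.column_stack([Gx, Gy])

    # -- quadrature fallback ------------------------------------------------

    def _gh_nodes(self):
        if self._gh is None:
            if self.cfg.kernel != "gaussian":
                raise ValueError("quadrature fallback supports the gaussian kernel only")
            z, w = np.polynomial.hermite_e.hermegauss(self.cfg.gh_order)
            ZX, ZY = np.meshgrid(z, z, indexing="ij")
            W = np.outer(w, w).ravel()
            W /= W.sum()
            self._gh = (
                np.column_stack([ZX.ravel(), ZY.ravel()]) * self.cfg.radius,
                W,
            )
        return self._gh

    def _eval_quadrature(self, pts: np.ndarray):
        offsets, W = self._gh_nodes()
        a = self.landscape.steepness
        C = self.landscape.centers
        m, q = len(pts), len(W)
        shifted = (pts[:, None, :] + offsets[None, :, :]).reshape(m * q, 2)
        d2 = _sq_dists(shifted, C) * a
        idx = np.argmin(d2, axis=1)
        Fv = d2[np.arange(m * q), idx].reshape(m, q)
        G = 2.0 * a[idx, None] * (shifted - C[idx])
        F = Fv @ W
        Gm = np.tensordot(G.reshape(m, q, 2), W, axes=(1, 0))
        return F, Gm

    # -- public API ---------------------------------------------------------

    def value_grad(self, points, return_basin: bool = False):
        """Mollified potential and gradient at one point or an (m, 2) array.

        Returns ``(F, grad)`` with shapes ``(m,)`` and ``(m, 2)``
        (scalars/one row for a single point); with ``return_basin=True``
        also returns the raw-landscape basin index of each point.
        """
        pts = np.asarray(points, dtype=float)
        scalar = pts.ndim == 1
        pts = np.atleast_2d(pts)
        a = self.landscape.steepness
        d2 = _sq_dists(pts, self.landscape.centers)
        idx = np.argmin(d2 * a, axis=1)
        F = np.empty(len(pts))
        G = np.empty((len(pts), 2))

        interior = self._interior_mask(d2, idx)
        if np.any(interior):
            ii = idx[interior]
            F[interior] = a[ii] * d2[interior, ii] + a[ii] * self.cfg.second_moment
            G[interior] = 2.0 * a[ii, None] * (
                pts[interior] - self.landscape.centers[ii]
            )
        rest = ~interior
        if np.any(rest):
            sub = pts[rest]
            in_grid = self._in_grid(sub)
            if np.any(in_grid):
                Fg, Gg = self._eval_spline(sub[in_grid])
                tmp_idx = np.flatnonzero(rest)[in_grid]
                F[tmp_idx] = Fg
                G[tmp_idx] = Gg
            if np.any(~in_grid):
                Fq, Gq = self._eval_quadrature(sub[~in_grid])
                tmp_idx = np.flatnonzero(rest)[~in_grid]
                F[tmp_idx] = Fq
                G[tmp_idx] = Gq

        if scalar:
            out = (float(F[0]), G[0])
            return out + ((int(idx[0]),) if return_basin else ())
        return (F, G, idx) if return_basin else (F, G)

    def drift(self, points, return_basin: bool = False):
        """Drift (f, g) = -grad F_eps; optionally with basin indices."""
        res = self.value_grad(points, return_basin=return_basin)
        if return_basin:
            return -res[1], res[2]
        return -res[1]


def mollified_potential(
    landscape: Landscape, cfg: MollifierConfig, point
) -> tuple[float | np.ndarray, np.ndarray]:
    """Functional form of :meth:`MollifiedLandscape.value_grad`."""
    return MollifiedLandscape(landscape, cfg).value_grad(point)
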