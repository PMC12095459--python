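"""Epigenetic (Waddington) landscape built from Boolean attractors.

The potential on the phenotype plane is a minimum of paraboloids,

    F(u, v) = min_i  a_i [ (u - u_i)^2 + (v - v_i)^2 ],

one well per macrophage phenotype.  Centers (u_i, v_i) come from a 2-D
stochastic neighbor embedding of the attractor states and the steepness a_i
is derived from the basin of attraction of each phenotype, so the landscape
encodes both the geometry (which phenotypes are epigenetically close) and
the stability (how large each basin is) of the Boolean model.  The induced
partition of the plane (argmin of the paraboloids) is a multiplicatively
weighted Voronoi diagram; the lowest point of the boundary between two
cells is the "mountain pass" through which small-noise transitions occur.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize_scalar

from .boolnet import Attractor

__all__ = [
    "Landscape",
    "EmbeddingConfig",
    "MountainPass",
    "embed_attractors",
    "build_landscape",
    "potential",
    "classify_point",
    "find_passes",
    "cluster_centers",
    "DEPTH_RULES",
]


@dataclass(frozen=True)
class Landscape:
    """Minimum-of-paraboloids potential with one well per phenotype."""

    labels: tuple[str, ...]
    centers: np.ndarray  # (n, 2)
    steepness: np.ndarray  # (n,)
    depth_rule: str = "proportional"
    scale: float = 1.0
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self):
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        steep = np.atleast_1d(np.asarray(self.steepness, dtype=float))
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "steepness", steep)
        n = len(self.labels)
        if n < 1:
            raise ValueError("landscape needs at least one basin")
        if centers.shape != (n, 2):
            raise ValueError(f"centers must have shape ({n}, 2), got {centers.shape}")
        if steep.shape != (n,):
            raise ValueError(f"steepness must have shape ({n},)")
        if not np.all(steep > 0):
            raise ValueError("all steepness values must be > 0")
        if len(set(self.labels)) != n:
            raise ValueError("phenotype labels must be unique")
        d2 = _sq_dists(centers, centers)
        np.fill_diagonal(d2, np.inf)
        if np.min(d2) == 0.0:
            raise ValueError("basin centers must be pairwise distinct")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown phenotype {label!r}") from None

    def center(self, label: str) -> np.ndarray:
        return self.centers[self.index(label)]

    # convenience wrappers
    def potential(self, points) -> np.ndarray:
        return potential(self, points)

    def classify(self, points) -> np.ndarray:
        return classify_point(self, points)

    def bounding_box(self, pad_factor: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned box: centers padded by ``pad_factor`` x max basin radius.

        The basin radius of well i is taken as the largest half-distance to
        another center (single-well landscapes use 1.0).
        """
        lo = self.centers.min(axis=0)
        hi = self.centers.max(axis=0)
        if self.n > 1:
            d = np.sqrt(_sq_dists(self.centers, self.centers))
            np.fill_diagonal(d, 0.0)
            radius = d.max() / 2.0
        else:
            radius = 1.0
        pad = pad_factor * radius
        return lo - pad, hi + pad


def _sq_dists(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - centers[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _as_points(points) -> tuple[np.ndarray, bool]:
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], True
    return arr, False


def potential(landscape: Landscape, points) -> np.ndarray | float:
    """Evaluate F(u, v) = min_i a_i |p - c_i|^2 (>= 0, zero at centers)."""
    pts, scalar = _as_points(points)
    vals = (_sq_dists(pts, landscape.centers) * landscape.steepness).min(axis=1)
    return float(vals[0]) if scalar else vals


def classify_point(landscape: Landscape, points) -> np.ndarray | int:
    """Basin index attaining the minimum; ties resolve to the lowest index."""
    pts, scalar = _as_points(points)
    idx = np.argmin(_sq_dists(pts, landscape.centers) * landscape.steepness, axis=1)
    return int(idx[0]) if scalar else idx


# ---------------------------------------------------------------------------
# embedding & construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmbeddingConfig:
    """t-SNE settings for placing attractors on the phenotype plane."""

    perplexity: float = 5.0
    iterations: int = 1000
    seed: int = 0
    center_rule: str = "centroid"


def embed_attractors(
    attractors: Sequence[Attractor], cfg: EmbeddingConfig = EmbeddingConfig()
) -> np.ndarray:
    """2-D stochastic neighbor embedding of attractor states.

    Cyclic attractors are represented by their mean bit vector so each
    attractor contributes one point.  Deterministic given ``cfg.seed``.
    """
    from sklearn.manifold import TSNE

    if len(attractors) < 2:
        raise ValueError("need at least 2 attractors to embed")
    if cfg.perplexity >= len(attractors):
        raise ValueError(
            f"perplexity ({cfg.perplexity}) must be < number of attractors "
            f"({len(attractors)})"
        )
    X = np.array([np.mean(a.states, axis=0) for a in attractors], dtype=float)
    tsne = TSNE(
        n_components=2,
        perplexity=cfg.perplexity,
        max_iter=cfg.iterations,
        random_state=cfg.seed,
        init="pca",
    )
    return tsne.fit_transform(X)


DEPTH_RULES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    # larger basin -> steeper well -> higher escape barriers
    "proportional": lambda f: f,
    # larger basin -> shallower well (alternative hypothesis)
    "inverse": lambda f: np.min(f) / f,
    # compressive map of fractions onto (0, 1]
    "log": lambda f: np.log1p(9.0 * f) / np.log(10.0),
}


def build_landscape(
    attractors: Sequence[Attractor],
    coords: np.ndarray,
    depth_rule: str = "proportional",
    scale: float = 1.0,
    center_rule: str = "centroid",
    provenance: Mapping | None = None,
) -> Landscape:
    """Aggregate labeled, embedded attractors into one well per phenotype.

    The center of a phenotype's well is the centroid of its attractors'
    embedding coordinates; its steepness is ``scale * depth_rule(fraction)``
    where ``fraction`` is the phenotype's total basin fraction.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if depth_rule not in DEPTH_RULES:
        raise ValueError(f"unknown depth rule {depth_rule!r}; options: {list(DEPTH_RULES)}")
    if center_rule != "centroid":
        raise ValueError("only the 'centroid' center rule is implemented")
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(attractors), 2):
        raise ValueError("coords must be (n_attractors, 2)")
    labels: list[str] = []
    centers: list[np.ndarray] = []
    fracs: list[float] = []
    by_label: dict[str, list[int]] = {}
    for i, a in enumerate(attractors):
        if a.phenotype is None:
            raise ValueError("attractors must be phenotype-labeled before building")
        by_label.setdefault(a.phenotype, []).append(i)
    for lab, idx in by_label.items():
        frac = sum(attractors[i].basin_fraction for i in idx)
        if frac <= 0:
            raise ValueError(f"phenotype {lab!r} has zero basin fraction; cannot size well")
        labels.append(lab)
        centers.append(coords[idx].mean(axis=0))
        fracs.append(frac)
    steep = scale * DEPTH_RULES[depth_rule](np.asarray(fracs))
    return Landscape(
        labels=tuple(labels),
        centers=np.asarray(centers),
        steepness=steep,
        depth_rule=depth_rule,
        scale=scale,
        provenance=dict(provenance or {}),
    )


# ---------------------------------------------------------------------------
# mountain passes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MountainPass:
    """Lowest point of the boundary between two basins of attraction."""

    pair: tuple[int, int]
    labels: tuple[str, str]
    location: np.ndarray  # (2,)
    height: float


def _boundary_param(landscape: Landscape, i: int, j: int):
    """Parametrization of {p : a_i |p-c_i|^2 = a_j |p-c_j|^2}.

    Equal weights give the perpendicular bisector (parameter t along the
    line); unequal weights give an Apollonius-type circle (parameter theta).
    Returns (point_fn, param_grid).
    """
    ci, cj = landscape.centers[i], landscape.centers[j]
    ai, aj = landscape.steepness[i], landscape.steepness[j]
    D = np.linalg.norm(cj - ci)
    if np.isclose(ai, aj):
        mid = 0.5 * (ci + cj)
        tangent = np.array([-(cj - ci)[1], (cj - ci)[0]]) / D
        lo, hi = landscape.bounding_box()
        reach = np.linalg.norm(hi - lo)

        def point(t):
            return mid + np.multiply.outer(np.asarray(t), tangent)

        grid = np.linspace(-reach, reach, 4001)
    else:
        q = (ai * ci - aj * cj) / (ai - aj)
        r = np.sqrt(ai * aj) * D / abs(ai - aj)

        def point(theta):
            th = np.asarray(theta)
            return q + r * np.stack([np.cos(th), np.sin(th)], axis=-1)

        grid = np.linspace(0.0, 2.0 * np.pi, 4001, endpoint=False)
    return point, grid


def find_passes(landscape: Landscape, rel_tol: float = 1e-9) -> list[MountainPass]:
    """Mountain pass of every adjacent basin pair.

    For each pair (i, j) the pairwise boundary curve is parametrized
    analytically, densely sampled, restricted to the region where wells i
    and j are jointly minimal, and the minimizer of F is refined by a local
    1-D search.  Pairs whose boundary is everywhere dominated by a third
    well are not adjacent and yield no pass.
    """
    if landscape.n < 2:
        raise ValueError("need at least two basins to have passes")
    a = landscape.steepness
    passes: list[MountainPass] = []
    for i in range(landscape.n):
        for j in range(i + 1, landscape.n):
            point_fn, grid = _boundary_param(landscape, i, j)
            pts = point_fn(grid)
            vals = _sq_dists(pts, landscape.centers) * a
            fij = 0.5 * (vals[:, i] + vals[:, j])  # equal on the curve up to fp noise
            others = np.delete(vals, [i, j], axis=1)
            tol = rel_tol * (1.0 + np.abs(fij))
            ok = (
                others.min(axis=1) >= fij - tol
                if others.size
                else np.ones(len(grid), dtype=bool)
            )
            if not np.any(ok):
                continue  # no shared boundary: not adjacent
            k = int(np.argmin(np.where(ok, fij, np.inf)))

            def f_on_curve(t):
                p = point_fn(t)
                return float(a[i] * np.sum((p - landscape.centers[i]) ** 2))

            def feasible_min(ts):
                # constrained zoom: minimum of F over curve samples where
                # wells i and j stay jointly minimal
                p = point_fn(ts)
                v = _sq_dists(p, landscape.centers) * a
                f = 0.5 * (v[:, i] + v[:, j])
                oth = np.delete(v, [i, j], axis=1)
                good = (
                    oth.min(axis=1) >= f - rel_tol * (1.0 + np.abs(f))
                    if oth.size
                    else np.ones(len(ts), dtype=bool)
                )
                if not np.any(good):
                    return None, None
                kk = int(np.argmin(np.where(good, f, np.inf)))
                return ts[kk], f[kk]

            dg = grid[1] - grid[0]
            cand_t, cand_f = grid[k], fij[k]
            width = dg
            for _ in range(4):  # successive 10x zooms around the best point
                ts = np.linspace(cand_t - width, cand_t + width, 201)
                t_new, f_new = feasible_min(ts)
                if t_new is not None and f_new < cand_f:
                    cand_t, cand_f = t_new, f_new
                width /= 10.0
            # an interior optimum can also be polished unconstrained
            res = minimize_scalar(
                f_on_curve, bounds=(cand_t - dg, cand_t + dg), method="bounded"
            )
            p = point_fn(res.x)
            vals_c = (_sq_dists(p[None, :], landscape.centers) * a)[0]
            third = np.delete(vals_c, [i, j]).min() if landscape.n > 2 else np.inf
            if res.fun < cand_f and third >= res.fun - rel_tol * (1.0 + res.fun):
                cand_t, cand_f = res.x, res.fun
            p = point_fn(cand_t)
            passes.append(
                MountainPass(
                    pair=(i, j),
                    labels=(landscape.labels[i], landscape.labels[j]),
                    location=np.asarray(p, dtype=float),
                    height=float(cand_f),
                )
            )
    return passes


def passes_by_labels(passes: Sequence[MountainPass]) -> dict[frozenset, MountainPass]:
    return {frozenset(p.labels): p for p in passes}


# ---------------------------------------------------------------------------
# spatial clustering of basin centers
# ---------------------------------------------------------------------------


def cluster_centers(
    landscape: Landscape,
    method: str = "single",
    n_clusters: int | None = None,
    tol: float = 1e-9,
) -> np.ndarray:
    """Group basin centers by spatial proximity.

    Default: single-linkage agglomeration cut at the largest gap in the
    merge-height sequence, which recovers well-separated clusters without a
    preset count.  Pass ``n_clusters`` to force a specific cut.  Returns a
    0-based cluster label per basin.
    """
    n = landscape.n
    if n == 1:
        return np.zeros(1, dtype=int)
    Z = linkage(landscape.centers, method=method)
    heights = Z[:, 2]
    if heights.max() < tol:  # all centers (numerically) identical
        return np.zeros(n, dtype=int)
    if n_clusters is not None:
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        h = np.sort(heights)
        if len(h) == 1:
            labels = fcluster(Z, t=2, criterion="maxclust")
        else:
            gaps = np.diff(h)
            k = int(np.argmax(gaps))  # cut between h[k] and h[k+1]
            thresh = 0.5 * (h[k] + h[k + 1])
            labels = fcluster(Z, t=thresh, criterion="distance")
    # renumber to 0-based, stable in basin order
    out = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for b, lab in enumerate(labels):
        out[b] = seen.setdefault(int(lab), len(seen))
    return out


def cluster_composition(
    landscape: Landscape, assignment: np.ndarray
) -> dict[int, tuple[str, ...]]:
    """Phenotype labels per cluster."""
    comp: dict[int, list[str]] = {}
    for lab, c in zip(landscape.labels, assignment):
        comp.setdefault(int(c), []).append(lab)
    return {c: tuple(v) for c, v in comp.items()}
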