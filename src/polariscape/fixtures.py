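"""Synthetic fixtures: toy Boolean networks and a reference landscape.

The toy networks have exactly known attractors and basins, so every stage
of the pipeline can be exercised and checked against hand enumeration.
The reference landscape is a synthetic 13-phenotype Waddington landscape
reproducing the topology of the macrophage polarization system: five
spatial clusters, of which exactly one (M1 with its wound-healing hybrid
M1M2d) is anti-tumoral and four contain only tumor-supportive phenotypes;
pro-tumoral wells carry the largest basins.  Its geometry is a package
design artifact, not the authors' (unpublished) coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boolnet import BooleanNetwork
from .landscape import Landscape, cluster_centers, cluster_composition

__all__ = [
    "make_toy_network",
    "make_reference_landscape",
    "make_double_well",
    "REFERENCE_PHENOTYPES",
    "ANTI_TUMORAL",
    "PRO_TUMORAL",
]


# ---------------------------------------------------------------------------
# toy Boolean networks
# ---------------------------------------------------------------------------


def make_toy_network(kind: str = "pair-reporter", n: int = 8, k: int = 2,
                     seed: int = 0) -> BooleanNetwork:
    """Generate a small Boolean network with known structure.

    kinds
    -----
    ``pair-reporter``
        Mutual-activation pair A<->B plus a reporter C = NOT A.  Under
        synchronous update it has fixed points (0,0,1) and (1,1,0) with
        basins of 2 states each, and the 2-cycle {(0,1,0),(1,0,1)} with
        basin 4.
    ``ring``
        A ring of ``n`` nodes, each activated by its predecessor, with one
        inhibiting link (negative feedback loop).  The synchronous map is a
        bijection, so the state space decomposes into disjoint cycles and
        there are no fixed points.
    ``random``
        Each node regulated by ``k`` random nodes through a random
        AND/OR chain of (possibly negated) literals; reproducible by seed.
    """
    if kind == "pair-reporter":
        return BooleanNetwork(
            nodes=("A", "B", "C"),
            rules={"A": "B", "B": "A", "C": "NOT A"},
        )
    if kind == "ring":
        if n < 2:
            raise ValueError("ring needs n >= 2")
        names = tuple(f"N{i}" for i in range(n))
        rules = {names[i]: names[(i - 1) % n] for i in range(n)}
        rules[names[0]] = f"NOT {names[-1]}"  # the single inhibiting link
        return BooleanNetwork(nodes=names, rules=rules)
    if kind == "random":
        rng = np.random.default_rng(seed)
        names = tuple(f"N{i}" for i in range(n))
        rules = {}
        for i in range(n):
            regs = rng.choice(n, size=min(k, n), replace=False)
            lits = []
            for r in regs:
                neg = "NOT " if rng.random() < 0.5 else ""
                lits.append(f"{neg}{names[r]}")
            expr = lits[0]
            for lit in lits[1:]:
                op = "AND" if rng.random() < 0.5 else "OR"
                expr = f"({expr}) {op} ({lit})"
            rules[names[i]] = expr
        return BooleanNetwork(nodes=names, rules=rules)
    raise ValueError(f"unknown toy network kind {kind!r}")


# ---------------------------------------------------------------------------
# reference landscape
# ---------------------------------------------------------------------------

#: label, (u, v) center, basin fraction -- grouped into 5 spatial clusters:
#: A = anti-tumoral (M1, M1M2d); B, C, D, E = tumor-supportive.  The two
#: hybrids the source system leaves unnamed are taken as M2cM2d and M2bM2c.
#: M2bM2d, the terminal pro-tumoral sink, carries the largest basin.
REFERENCE_PHENOTYPES: tuple[tuple[str, tuple[float, float], float], ...] = (
    # cluster A - anti-tumoral
    ("M1", (0.0, 0.0), 0.03),
    ("M1M2d", (1.1, 0.3), 0.05),
    # cluster B - adjacent to A (M2aM2d reached from M1M2d)
    ("M2aM2d", (3.15, 0.1), 0.14),
    ("M2aM2bM2d", (3.9, 0.45), 0.09),
    # cluster C - monocyte entry point (M0 beside M2d)
    ("M0", (0.2, 2.9), 0.02),
    ("M2d", (1.05, 3.2), 0.03),
    ("M2cM2d", (0.35, 3.8), 0.02),
    # cluster D - the deep pro-tumoral sink, alone in its valley
    ("M2bM2d", (2.85, 3.5), 0.32),
    # cluster E - far pro-tumoral group
    ("M2a", (5.9, 1.6), 0.08),
    ("M2c", (6.6, 2.1), 0.08),
    ("M1M2bM2cM2d", (6.1, 2.7), 0.08),
    ("M2bM2c", (5.5, 3.3), 0.03),
    ("M2b", (6.4, 3.6), 0.03),
)

ANTI_TUMORAL = frozenset({"M1", "M1M2d"})
PRO_TUMORAL = frozenset(
    lab for lab, _, _ in REFERENCE_PHENOTYPES if lab not in ("M1", "M1M2d", "M0")
)


@dataclass(frozen=True)
class ReferenceLandscapeSpec:
    """Parameters of the synthetic 13-basin reference landscape."""

    scale: float = 0.25
    jitter: float = 0.0  # sd of a seeded perturbation of the centers
    phenotypes: tuple = REFERENCE_PHENOTYPES


def make_reference_landscape(
    spec: ReferenceLandscapeSpec | None = None, seed: int = 0
) -> Landscape:
    """Build the 13-basin reference landscape and validate its topology.

    Steepness follows the inverse depth rule, a_i = scale * min_f / f_i:
    the largest basins (the pro-tumoral sinks) are the widest, shallowest
    wells and therefore hold trajectories longest, while the small
    anti-tumoral wells are steep and narrow.  Deterministic given ``seed``.
    """
    spec = spec or ReferenceLandscapeSpec()
    labels = tuple(lab for lab, _, _ in spec.phenotypes)
    centers = np.array([c for _, c, _ in spec.phenotypes], dtype=float)
    fracs = np.array([f for _, _, f in spec.phenotypes], dtype=float)
    if not np.isclose(fracs.sum(), 1.0):
        raise ValueError("reference basin fractions must sum to 1")
    if spec.jitter > 0:
        rng = np.random.default_rng(seed)
        centers = centers + rng.normal(0.0, spec.jitter, size=centers.shape)
    ls = Landscape(
        labels=labels,
        centers=centers,
        steepness=spec.scale * fracs.min() / fracs,
        depth_rule="inverse",
        scale=spec.scale,
        provenance={"fixture": "reference-13", "seed": seed, "jitter": spec.jitter,
                    "basin_fractions": fracs.tolist()},
    )
    _validate_reference(ls)
    return ls


def _validate_reference(ls: Landscape):
    if ls.n != 13:
        raise ValueError(f"reference landscape must have 13 basins, got {ls.n}")
    comp = cluster_composition(ls, cluster_centers(ls))
    if len(comp) != 5:
        raise ValueError(f"reference landscape must form 5 clusters, got {len(comp)}")
    anti = [c for c, labs in comp.items() if "M1" in labs and "M1M2d" in labs]
    if len(anti) != 1 or set(comp[anti[0]]) != {"M1", "M1M2d"}:
        raise ValueError("exactly one cluster must be the anti-tumoral pair {M1, M1M2d}")
    for c, labs in comp.items():
        if c == anti[0]:
            continue
        if any(lab in ("M1", "M1M2d") for lab in labs):
            raise ValueError("pro-tumoral clusters must not contain M1 or M1M2d")


# ---------------------------------------------------------------------------
# analytic double well
# ---------------------------------------------------------------------------


def make_double_well(
    a: tuple[float, float] = (1.0, 1.0), separation: float = 1.0
) -> Landscape:
    """Two-well landscape on the u-axis; the pass height is known in closed
    form, which makes it the calibration target for exit-time scaling."""
    return Landscape(
        labels=("left", "right"),
        centers=np.array([[0.0, 0.0], [separation, 0.0]]),
        steepness=np.asarray(a, dtype=float),
        provenance={"fixture": "double-well"},
    )
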