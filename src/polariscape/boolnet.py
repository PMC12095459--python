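"""Synchronous Boolean network dynamics for macrophage-polarization models.

A regulatory network is given as one logical update rule per node, written
over node identifiers with ``AND``/``OR``/``NOT`` and parentheses.  All nodes
update simultaneously (synchronous scheme), so the dynamics is a deterministic
map on the finite state space ``{0,1}^n`` and every trajectory ends in a fixed
point or a cycle.  Attractors, their basins of attraction, and the effect of
clamping nodes ON (overexpression) or OFF (knockout) are computed here; basin
sizes later set the depth of the wells of the epigenetic landscape.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NetworkDefinitionError",
    "BooleanNetwork",
    "Attractor",
    "PhenotypeRules",
    "ScanReport",
    "DEFAULT_PHENOTYPE_RULES",
    "step",
    "find_attractors",
    "classify_phenotype",
    "perturb",
    "perturbation_scan",
]

EXHAUSTIVE_NODE_CAP = 24

COMPARTMENT_ORDER = ("M1", "M2a", "M2b", "M2c", "M2d")


class NetworkDefinitionError(ValueError):
    """Raised when a network or rule definition is malformed."""


# ---------------------------------------------------------------------------
# rule expressions
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z_][A-Za-z0-9_]*|[01])")


def _tokenize(expr: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            if expr[pos:].strip() == "":
                break
            raise NetworkDefinitionError(
                f"unexpected character {expr[pos]!r} in rule {expr!r}"
            )
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _RuleParser:
    """Recursive-descent parser for AND/OR/NOT expressions.

    Grammar:  expr := term (OR term)* ; term := factor (AND factor)* ;
    factor := NOT factor | '(' expr ')' | identifier | 0 | 1.
    Produces a nested-tuple AST: ("or", a, b) / ("and", a, b) /
    ("not", a) / ("var", name) / ("const", 0|1).
    """

    def __init__(self, expr: str):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.pos = 0

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            raise NetworkDefinitionError(f"unexpected end of rule {self.expr!r}")
        self.pos += 1
        return tok

    def parse(self):
        node = self._expr()
        if self._peek() is not None:
            raise NetworkDefinitionError(
                f"trailing token {self._peek()!r} in rule {self.expr!r}"
            )
        return node

    def _expr(self):
        node = self._term()
        while self._peek() is not None and self._peek().upper() == "OR":
            self._next()
            node = ("or", node, self._term())
        return node

    def _term(self):
        node = self._factor()
        while self._peek() is not None and self._peek().upper() == "AND":
            self._next()
            node = ("and", node, self._factor())
        return node

    def _factor(self):
        tok = self._next()
        up = tok.upper()
        if up == "NOT":
            return ("not", self._factor())
        if tok == "(":
            node = self._expr()
            if self._next() != ")":
                raise NetworkDefinitionError(f"unbalanced parentheses in {self.expr!r}")
            return node
        if tok in ("0", "1"):
            return ("const", int(tok))
        if up in ("TRUE", "FALSE"):
            return ("const", 1 if up == "TRUE" else 0)
        if up in ("AND", "OR", ")"):
            raise NetworkDefinitionError(f"misplaced {tok!r} in rule {self.expr!r}")
        return ("var", tok)


def parse_rule(expr: str):
    """Parse a logical rule into an AST; raises NetworkDefinitionError."""
    return _RuleParser(expr).parse()


def rule_variables(ast) -> set[str]:
    kind = ast[0]
    if kind == "var":
        return {ast[1]}
    if kind == "const":
        return set()
    if kind == "not":
        return rule_variables(ast[1])
    return rule_variables(ast[1]) | rule_variables(ast[2])


def eval_rule(ast, values: Mapping[str, int]) -> int:
    kind = ast[0]
    if kind == "var":
        return int(values[ast[1]])
    if kind == "const":
        return ast[1]
    if kind == "not":
        return 1 - eval_rule(ast[1], values)
    if kind == "and":
        return eval_rule(ast[1], values) & eval_rule(ast[2], values)
    return eval_rule(ast[1], values) | eval_rule(ast[2], values)


def _ast_to_bitexpr(ast, index: Mapping[str, int]) -> str:
    # compiles to an expression over the packed state integer `s`
    kind = ast[0]
    if kind == "var":
        return f"((s>>{index[ast[1]]})&1)"
    if kind == "const":
        return str(ast[1])
    if kind == "not":
        return f"(1-{_ast_to_bitexpr(ast[1], index)})"
    op = "&" if kind == "and" else "|"
    return f"({_ast_to_bitexpr(ast[1], index)}{op}{_ast_to_bitexpr(ast[2], index)})"


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BooleanNetwork:
    """A synchronous Boolean network with optional node clamps.

    Parameters
    ----------
    nodes
        Ordered node identifiers; the order defines the bit order of states.
    rules
        Map node -> logical expression string over node identifiers.
    clamps
        Map node -> {0, 1}; a clamped node ignores its rule at every step
        (overexpression = clamp 1, knockout = clamp 0).
    """

    nodes: tuple[str, ...]
    rules: Mapping[str, str]
    clamps: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "rules", dict(self.rules))
        object.__setattr__(self, "clamps", dict(self.clamps))
        if len(set(self.nodes)) != len(self.nodes):
            raise NetworkDefinitionError("duplicate node names")
        missing = set(self.nodes) - set(self.rules)
        if missing:
            raise NetworkDefinitionError(f"no rule for node(s): {sorted(missing)}")
        extra = set(self.rules) - set(self.nodes)
        if extra:
            raise NetworkDefinitionError(f"rule for undeclared node(s): {sorted(extra)}")
        index = {name: i for i, name in enumerate(self.nodes)}
        asts = {}
        for name in self.nodes:
            ast = parse_rule(self.rules[name])
            unknown = rule_variables(ast) - set(self.nodes)
            if unknown:
                raise NetworkDefinitionError(
                    f"rule for {name!r} references unknown node(s): {sorted(unknown)}"
                )
            asts[name] = ast
        for name, val in self.clamps.items():
            if name not in index:
                raise NetworkDefinitionError(f"clamp on unknown node {name!r}")
            if val not in (0, 1):
                raise NetworkDefinitionError(f"clamp value for {name!r} must be 0 or 1")
        object.__setattr__(self, "_index", index)
        object.__setattr__(self, "_asts", asts)
        object.__setattr__(self, "_step_int", self._compile_step())

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def free_nodes(self) -> tuple[str, ...]:
        return tuple(nm for nm in self.nodes if nm not in self.clamps)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown node {name!r}") from None

    def _compile_step(self):
        parts = []
        for i, name in enumerate(self.nodes):
            if name in self.clamps:
                bit = str(self.clamps[name])
            else:
                bit = _ast_to_bitexpr(self._asts[name], self._index)
            parts.append(f"(({bit})<<{i})")
        src = "lambda s: " + "|".join(parts)
        return eval(src, {"__builtins__": {}})  # noqa: S307 - generated from validated AST

    # -- state helpers ------------------------------------------------------

    def pack(self, state: Sequence[int]) -> int:
        if len(state) != self.n:
            raise ValueError(f"state length {len(state)} != node count {self.n}")
        return sum((int(b) & 1) << i for i, b in enumerate(state))

    def unpack(self, s: int) -> tuple[int, ...]:
        return tuple((s >> i) & 1 for i in range(self.n))

    def apply_clamps(self, s: int) -> int:
        for name, val in self.clamps.items():
            i = self._index[name]
            s = (s | (1 << i)) if val else (s & ~(1 << i))
        return s

    def step_int(self, s: int) -> int:
        return self._step_int(s)

    def with_clamp(self, node: str, value: int) -> "BooleanNetwork":
        if node not in self._index:
            raise KeyError(f"unknown node {node!r}")
        clamps = dict(self.clamps)
        clamps[node] = int(value)
        return BooleanNetwork(self.nodes, self.rules, clamps)


def step(network: BooleanNetwork, state: Sequence[int]) -> tuple[int, ...]:
    """One synchronous update; clamped nodes take their clamp value."""
    return network.unpack(network.step_int(network.apply_clamps(network.pack(state))))


def perturb(network: BooleanNetwork, node: str, clamp: int) -> BooleanNetwork:
    """Copy of the network with ``node`` clamped to ``clamp`` (0 or 1)."""
    return network.with_clamp(node, clamp)


# ---------------------------------------------------------------------------
# attractors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Attractor:
    """A fixed point (length-1) or cycle of the synchronous dynamics.

    ``states`` is in canonical form: the cycle is rotated so that its
    lexicographically smallest state comes first, which makes attractor
    identity stable across runs.  ``basin_size`` counts initial states that
    converge here (exact in exhaustive mode, sampled counts otherwise).
    """

    states: tuple[tuple[int, ...], ...]
    basin_size: int
    basin_fraction: float
    nodes: tuple[str, ...]
    phenotype: str | None = None

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    def activity(self, mode: str = "all") -> dict[str, int]:
        """Node activity over the cycle: ON in *all* states or in *any*."""
        if mode not in ("all", "any"):
            raise ValueError("activity mode must be 'all' or 'any'")
        arr = np.asarray(self.states)
        agg = arr.min(axis=0) if mode == "all" else arr.max(axis=0)
        return {name: int(v) for name, v in zip(self.nodes, agg)}

    def labeled(self, phenotype: str) -> "Attractor":
        return replace(self, phenotype=phenotype)


def _canonical_cycle(cycle: list[int], network: BooleanNetwork) -> tuple[int, ...]:
    # rotate so the lexicographically smallest state (by bit tuple) is first
    keys = [network.unpack(s) for s in cycle]
    k = min(range(len(cycle)), key=lambda i: keys[i])
    return tuple(cycle[k:] + cycle[:k])


def _free_to_full(network: BooleanNetwork, free_bits: int) -> int:
    """Expand an integer over free nodes into a full clamped state."""
    s = 0
    j = 0
    for i, name in enumerate(network.nodes):
        if name in network.clamps:
            if network.clamps[name]:
                s |= 1 << i
        else:
            if (free_bits >> j) & 1:
                s |= 1 << i
            j += 1
    return s


def _iterate_to_attractor(network, s, attr_of, attractors_int):
    """Follow the trajectory from s; returns the attractor index."""
    path = []
    path_pos = {}
    while True:
        if s in attr_of:
            aid = attr_of[s]
            break
        if s in path_pos:
            cycle = path[path_pos[s]:]
            canon = _canonical_cycle(cycle, network)
            aid = len(attractors_int)
            attractors_int.append(canon)
            break
        path_pos[s] = len(path)
        path.append(s)
        s = network.step_int(s)
    for t in path:
        attr_of[t] = aid
    return aid


def find_attractors(
    network: BooleanNetwork,
    mode: str = "exhaustive",
    n_samples: int | None = None,
    seed: int | None = None,
    cap: int = EXHAUSTIVE_NODE_CAP,
) -> list[Attractor]:
    """Enumerate attractors and basin sizes.

    ``exhaustive`` iterates every state of the free (non-clamped) nodes, so
    basin sizes are exact and sum to ``2**n_free``.  ``sampled`` follows
    ``n_samples`` random initial states (seeded) and reports sample
    proportions as basin fractions; attractors themselves are still exact
    cycles of the dynamics.
    """
    n_free = len(network.free_nodes)
    attr_of: dict[int, int] = {}
    attractors_int: list[tuple[int, ...]] = []
    counts: dict[int, int] = {}

    if mode == "exhaustive":
        if n_free > cap:
            raise ValueError(
                f"exhaustive enumeration over {n_free} free nodes exceeds cap {cap}; "
                "use mode='sampled'"
            )
        total = 1 << n_free
        for fb in range(total):
            aid = _iterate_to_attractor(
                network, _free_to_full(network, fb), attr_of, attractors_int
            )
            counts[aid] = counts.get(aid, 0) + 1
    elif mode == "sampled":
        if not n_samples or n_samples < 1:
            raise ValueError("sampled mode requires n_samples >= 1")
        rng = np.random.default_rng(seed)
        total = n_samples
        draws = rng.integers(0, 1 << n_free, size=n_samples, dtype=np.uint64)
        for fb in draws:
            aid = _iterate_to_attractor(
                network, _free_to_full(network, int(fb)), attr_of, attractors_int
            )
            counts[aid] = counts.get(aid, 0) + 1
    else:
        raise ValueError("mode must be 'exhaustive' or 'sampled'")

    out = []
    for aid, cycle in enumerate(attractors_int):
        size = counts.get(aid, 0)
        out.append(
            Attractor(
                states=tuple(network.unpack(s) for s in cycle),
                basin_size=size,
                basin_fraction=size / total,
                nodes=network.nodes,
            )
        )
    # stable order: largest basin first, ties by canonical first state
    out.sort(key=lambda a: (-a.basin_size, a.states[0]))
    return out


# ---------------------------------------------------------------------------
# phenotype labeling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenotypeRules:
    """Logical conditions naming the macrophage compartments.

    ``compartments`` maps each label in M1, M2a, M2b, M2c, M2d to a rule
    expression over node activities.  An attractor's label is the
    concatenation of all compartments whose condition holds, in fixed
    compartment order; if none holds the label is "M0" (unpolarized).
    """

    compartments: Mapping[str, str]

    def __post_init__(self):
        object.__setattr__(self, "compartments", dict(self.compartments))
        asts = {}
        for label, expr in self.compartments.items():
            asts[label] = parse_rule(expr)
        object.__setattr__(self, "_asts", asts)

    def variables(self) -> set[str]:
        out: set[str] = set()
        for ast in self._asts.values():
            out |= rule_variables(ast)
        return out

    def label(self, activity: Mapping[str, int]) -> str:
        order = [c for c in COMPARTMENT_ORDER if c in self._asts]
        order += [c for c in self._asts if c not in COMPARTMENT_ORDER]
        active = [c for c in order if eval_rule(self._asts[c], activity)]
        return "".join(active) if active else "M0"


#: Table-1-style default conditions for networks using the canonical node
#: names of the macrophage polarization literature.
DEFAULT_PHENOTYPE_RULES = PhenotypeRules(
    {
        "M1": "NFKB OR STAT1 OR (TNFA AND AP1)",
        "M2a": "IL4 AND STAT6",
        "M2b": "AP1 OR ERK",
        "M2c": "IL10 AND STAT3",
        "M2d": "(TLR4 AND A2A) OR HIF1A",
    }
)


def classify_phenotype(
    attractor: Attractor, rules: PhenotypeRules, activity: str = "all"
) -> str:
    """Label an attractor with its macrophage phenotype.

    For cyclic attractors a node counts as activated under ``activity='all'``
    iff it is ON in every cycle state (default), or in at least one state
    under ``'any'``.  Total function: unmatched attractors get "M0".
    """
    unknown = rules.variables() - set(attractor.nodes)
    if unknown:
        raise NetworkDefinitionError(
            f"phenotype rules reference unknown node(s): {sorted(unknown)}"
        )
    return rules.label(attractor.activity(activity))


def label_attractors(
    attractors: Iterable[Attractor], rules: PhenotypeRules, activity: str = "all"
) -> list[Attractor]:
    return [a.labeled(classify_phenotype(a, rules, activity)) for a in attractors]


# ---------------------------------------------------------------------------
# perturbation scans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanReport:
    """Fig.-1-style table of basin-size changes under clamping perturbations.

    One row per (perturbation, phenotype) pair, with wild-type and perturbed
    basin fractions, percent change, and a category: increased / decreased /
    minimal (|change| below threshold) / disappeared (present in WT only) /
    novel (appears only under the perturbation).  Aggregates pool the basin
    fractions of the anti-tumoral and pro-tumoral label sets.
    """

    rows: pd.DataFrame
    aggregates: pd.DataFrame
    minimal_threshold: float

    def for_perturbation(self, name: str) -> pd.DataFrame:
        return self.rows[self.rows["perturbation"] == name]


SCAN_COLUMNS = [
    "perturbation",
    "phenotype",
    "wt_fraction",
    "pert_fraction",
    "pct_change",
    "category",
    "wt_attractors",
    "pert_attractors",
]


def _fractions_by_label(attractors: Sequence[Attractor]) -> tuple[dict, dict]:
    frac: dict[str, float] = {}
    count: dict[str, int] = {}
    for a in attractors:
        frac[a.phenotype] = frac.get(a.phenotype, 0.0) + a.basin_fraction
        count[a.phenotype] = count.get(a.phenotype, 0) + 1
    return frac, count


def _categorize(wt: float, pert: float, threshold: float) -> tuple[float | None, str]:
    if wt > 0 and pert == 0:
        return -100.0, "disappeared"
    if wt == 0 and pert > 0:
        return None, "novel"
    pct = 100.0 * (pert - wt) / wt
    if abs(pct) < threshold:
        return pct, "minimal"
    return pct, "increased" if pct > 0 else "decreased"


def perturbation_scan(
    network: BooleanNetwork,
    perturbations: Sequence[tuple[str, int]],
    rules: PhenotypeRules,
    antitumoral_classes: Iterable[str] = (),
    protumoral_classes: Iterable[str] = (),
    minimal_threshold: float = 5.0,
    mode: str = "exhaustive",
    n_samples: int | None = None,
    seed: int | None = None,
    activity: str = "all",
) -> ScanReport:
    """Recompute attractors under each clamp and tabulate basin-size shifts."""
    anti = set(antitumoral_classes)
    pro = set(protumoral_classes)
    if anti & pro:
        raise ValueError("anti- and pro-tumoral class sets must be disjoint")
    if perturbations and not (anti or pro):
        raise ValueError("class sets must be provided for a non-empty scan")

    wt = label_attractors(
        find_attractors(network, mode=mode, n_samples=n_samples, seed=seed),
        rules,
        activity,
    )
    wt_frac, wt_count = _fractions_by_label(wt)

    rows = []
    agg_rows = []
    for node, clamp in perturbations:
        pname = f"{node}={clamp}"
        pert_net = perturb(network, node, clamp)
        pert = label_attractors(
            find_attractors(pert_net, mode=mode, n_samples=n_samples, seed=seed),
            rules,
            activity,
        )
        p_frac, p_count = _fractions_by_label(pert)
        labels = sorted(set(wt_frac) | set(p_frac))
        for lab in labels:
            w, p = wt_frac.get(lab, 0.0), p_frac.get(lab, 0.0)
            pct, cat = _categorize(w, p, minimal_threshold)
            rows.append(
                (pname, lab, w, p, pct, cat, wt_count.get(lab, 0), p_count.get(lab, 0))
            )
        for group, classes in (("anti_tumoral", anti), ("pro_tumoral", pro)):
            w = sum(wt_frac.get(c, 0.0) for c in classes)
            p = sum(p_frac.get(c, 0.0) for c in classes)
            pct = 100.0 * (p - w) / w if w > 0 else None
            agg_rows.append((pname, group, w, p, pct))

    rows_df = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    agg_df = pd.DataFrame(
        agg_rows,
        columns=["perturbation", "group", "wt_fraction", "pert_fraction", "pct_change"],
    )
    return ScanReport(rows=rows_df, aggregates=agg_df, minimal_threshold=minimal_threshold)
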