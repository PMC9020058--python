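"""Maximum-average-score connected subgraph optimization.

The model selects a node set ``V*`` of a directed network together with a
single root node such that every selected node is reachable from the root by
a directed path inside ``V*``, the root is a receptor (when receptors are
given), every selected sink is a terminal (when terminals are given), and
``k_min <= |V*| <= k_max``.  The objective is the *average* node score
``s(V*)/|V*|``, a fractional objective solved by a Dinkelbach-type scheme:
iteratively maximize the parametric linear objective ``s^T x - lambda e^T x``
and update ``lambda`` to the incumbent ratio until the parametric optimum is
(numerically) zero.

Connectivity is enforced through two constraint families:

* every selected non-root node has a selected in-neighbor, and
* every strongly connected node set ``S`` (|S| > 1) that is selected entirely
  must contain the root or receive an edge from a selected node outside ``S``.

The second family is exponential and is separated lazily: solve, find
violating strongly connected components of the incumbent, add their rows,
re-solve, until no violation remains.

The MILP subproblems are solved with HiGHS through :func:`scipy.optimize.milp`.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .network import DirectedNetwork, align_scores

logger = logging.getLogger(__name__)

__all__ = [
    "SubgraphInstance",
    "SubgraphSolution",
    "SolverSettings",
    "InfeasibleInstance",
    "SolverTimeout",
    "check_feasible",
    "separate_scc_violations",
    "solve_parametric",
    "solve",
    "solve_fixed_size",
    "solve_union_over_sizes",
    "solve_suboptimal",
    "union_summary",
    "UnionSummary",
    "enumerate_feasible_sets",
    "brute_force_optimal",
    "write_solution",
]


class InfeasibleInstance(Exception):
    """The constraint system admits no feasible subgraph."""


class SolverTimeout(Exception):
    """Per-solve time limit exceeded; carries the best incumbent if any."""

    def __init__(self, message: str, incumbent: "SubgraphSolution | None" = None):
        super().__init__(message)
        self.incumbent = incumbent


@dataclass(frozen=True)
class SolverSettings:
    """Numerical controls for the Dinkelbach loop and the MILP backend.

    gap_tolerance: termination threshold on the parametric optimum.
    time_limit: seconds per parametric MILP solve (None = unlimited).
    maximal_optimum: after convergence, among optimal-average subgraphs
        return one of maximum cardinality (secondary MILP); keeps reported
        subgraphs from collapsing to the smallest tied optimum.
    """

    gap_tolerance: float = 1e-6
    max_iterations: int = 50
    time_limit: float | None = None
    random_seed: int = 0
    suboptimal_strategy: str = "nogood-cut"
    backend: str = "highs"
    maximal_optimum: bool = True

    def __post_init__(self) -> None:
        if self.gap_tolerance <= 0:
            raise ValueError("gap_tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class SubgraphInstance:
    """A network, node scores, role sets and size bounds (one problem)."""

    network: DirectedNetwork
    score: Mapping[str, float]
    receptors: frozenset[str] = frozenset()
    terminals: frozenset[str] = frozenset()
    include: frozenset[str] = frozenset()
    exclude: frozenset[str] = frozenset()
    k_min: int = 10
    k_max: int = 50
    sense: str = "maximize"
    absolute: bool = False
    mode: str = "forward"

    def __post_init__(self) -> None:
        object.__setattr__(self, "receptors", frozenset(self.receptors))
        object.__setattr__(self, "terminals", frozenset(self.terminals))
        object.__setattr__(self, "include", frozenset(self.include))
        object.__setattr__(self, "exclude", frozenset(self.exclude))
        n = len(self.network)
        if not (1 <= self.k_min <= self.k_max <= n):
            raise ValueError(f"need 1 <= k_min <= k_max <= |V|={n}")
        nodes = self.network.node_set
        for name, S in (
            ("receptors", self.receptors),
            ("terminals", self.terminals),
            ("include", self.include),
            ("exclude", self.exclude),
        ):
            if not S <= nodes:
                raise ValueError(f"{name} not a subset of network nodes")
        if self.include & self.exclude:
            raise ValueError("include and exclude sets overlap")
        if len(self.include) > self.k_max:
            raise ValueError("|include| exceeds k_max")
        if self.sense not in ("maximize", "minimize"):
            raise ValueError("sense must be 'maximize' or 'minimize'")
        if self.mode not in ("forward", "reverse"):
            raise ValueError("mode must be 'forward' or 'reverse'")

    def effective(self) -> "SubgraphInstance":
        """Forward-orientation equivalent: reverse mode flips the network
        and swaps the receptor/terminal roles; node sets are unchanged."""
        if self.mode == "forward":
            return self
        return replace(
            self,
            network=self.network.reverse(),
            receptors=self.terminals,
            terminals=self.receptors,
            mode="forward",
        )

    def used_score(self) -> dict[str, float]:
        """Score actually optimized: aligned with the network, absolute
        value applied when requested (sense is handled by the solver)."""
        s = align_scores(self.network, self.score)
        if self.absolute:
            s = {k: abs(v) for k, v in s.items()}
        return s


@dataclass(frozen=True)
class SubgraphSolution:
    """A feasible subgraph: node set, root, and its average-score objective."""

    node_set: frozenset[str]
    root: str
    objective: float
    total_score: float
    rank: int = 0
    converged: bool = True
    lambda_sequence: tuple[float, ...] = ()
    n_parametric_solves: int = 0

    @property
    def size(self) -> int:
        return len(self.node_set)


# ---------------------------------------------------------------------------
# feasibility checking (reference semantics, used for post-hoc verification)
# ---------------------------------------------------------------------------


def check_feasible(
    instance: SubgraphInstance, node_set: Iterable[str], root: str
) -> tuple[bool, list[str]]:
    """Verify a (node set, root) pair against every constraint of the model.

    Returns ``(ok, tags)`` where ``tags`` names each violated constraint
    family: root selection (1b), size bounds (1d), in-neighbor cover (1e),
    strongly-connected-set cover (1f), receptor root (1g), terminal sinks
    (1h), include (1i), exclude (1j), plus a defensive ``reachability`` tag.
    """
    inst = instance.effective()
    net = inst.network
    V = net.node_set
    Vstar = frozenset(node_set)
    if root not in V:
        raise ValueError(f"root {root!r} not a network node")
    if not Vstar <= V:
        raise ValueError("node set not a subset of network nodes")

    tags: list[str] = []
    if root not in Vstar:
        tags.append("1b")
    if not (inst.k_min <= len(Vstar) <= inst.k_max):
        tags.append("1d")
    # (1e): every selected non-root node has a selected in-neighbor
    for v in sorted(Vstar):
        if v == root:
            continue
        if not (net.in_neighbors(v) & Vstar):
            tags.append("1e")
            break
    if separate_scc_violations(instance, Vstar, root):
        tags.append("1f")
    if inst.receptors and root not in inst.receptors:
        tags.append("1g")
    if inst.terminals:
        for v in sorted(Vstar - inst.terminals):
            if not (net.out_neighbors(v) & Vstar):
                tags.append("1h")
                break
    if not inst.include <= Vstar:
        tags.append("1i")
    if inst.exclude & Vstar:
        tags.append("1j")
    # (1e) + all (1f) rows are equivalent to root-reachability; flag any
    # residual discrepancy explicitly rather than trusting the equivalence.
    if root in Vstar and not ("1e" in tags or "1f" in tags):
        if net.reachable_from(root, Vstar) != Vstar:
            tags.append("reachability")
    return (not tags, tags)


def separate_scc_violations(
    instance: SubgraphInstance, node_set: Iterable[str], root: str
) -> list[frozenset[str]]:
    """Strongly connected components of the selected subgraph that violate
    the rooted-connectivity cover: |S| > 1, root not in S, and no selected
    node outside S has an edge into S."""
    inst = instance.effective()
    net = inst.network
    Vstar = frozenset(node_set)
    violations = []
    for S in net.strongly_connected_components(Vstar):
        if len(S) <= 1 or root in S:
            continue
        if not (net.in_neighbors(S) & Vstar):
            violations.append(S)
    return violations


# ---------------------------------------------------------------------------
# MILP model
# ---------------------------------------------------------------------------


class _Model:
    """MILP over variables [x; y]: x_v selects node v, y_v flags the root.

    Builds the static constraint rows once; lazily separated rows and
    caller-supplied cuts are appended per solve.
    """

    def __init__(
        self,
        network: DirectedNetwork,
        score: Mapping[str, float],
        receptors: frozenset[str],
        terminals: frozenset[str],
        include: frozenset[str],
        exclude: frozenset[str],
        k_min: int,
        k_max: int,
    ) -> None:
        self.net = network
        self.nodes = network.nodes
        self.index = {v: i for i, v in enumerate(self.nodes)}
        n = len(self.nodes)
        self.n = n
        self.s = np.array([score[v] for v in self.nodes], dtype=float)
        self.receptors = receptors
        self.terminals = terminals

        rows: list[dict[int, float]] = []
        lbs: list[float] = []
        ubs: list[float] = []

        def add(coeffs: dict[int, float], lb: float, ub: float) -> None:
            rows.append(coeffs)
            lbs.append(lb)
            ubs.append(ub)

        # root must be selected: y_v - x_v <= 0
        for i in range(n):
            add({i: -1.0, n + i: 1.0}, -np.inf, 0.0)
        # exactly one root
        add({n + i: 1.0 for i in range(n)}, 1.0, 1.0)
        # size bounds
        add({i: 1.0 for i in range(n)}, float(k_min), float(k_max))
        # in-neighbor cover: x_v - y_v - sum_{u in delta-(v)} x_u <= 0
        g = network.as_nx()
        for v in self.nodes:
            i = self.index[v]
            coeffs = {i: 1.0, n + i: -1.0}
            for u in g.predecessors(v):
                coeffs[self.index[u]] = coeffs.get(self.index[u], 0.0) - 1.0
            add(coeffs, -np.inf, 0.0)
        # terminal guard: selected non-terminals need a selected out-neighbor
        if terminals:
            for v in self.nodes:
                if v in terminals:
                    continue
                i = self.index[v]
                coeffs = {i: 1.0}
                for u in g.successors(v):
                    coeffs[self.index[u]] = coeffs.get(self.index[u], 0.0) - 1.0
                add(coeffs, -np.inf, 0.0)

        self._A_static = self._to_sparse(rows)
        self._lb_static = np.array(lbs)
        self._ub_static = np.array(ubs)

        # variable bounds encode receptor, include and exclude roles
        lb = np.zeros(2 * n)
        ub = np.ones(2 * n)
        if receptors:
            for v in self.nodes:
                if v not in receptors:
                    ub[n + self.index[v]] = 0.0
        for v in include:
            lb[self.index[v]] = 1.0
        for v in exclude:
            ub[self.index[v]] = 0.0
            ub[n + self.index[v]] = 0.0
        self.bounds = Bounds(lb, ub)

        # lazily separated strongly-connected-set rows, kept across solves
        self.lazy_rows: list[dict[int, float]] = []
        self.lazy_lbs: list[float] = []
        self.lazy_ubs: list[float] = []
        self._seen_sccs: set[frozenset[str]] = set()

    def _to_sparse(self, rows: list[dict[int, float]]) -> sparse.csr_matrix:
        data, ri, ci = [], [], []
        for r, coeffs in enumerate(rows):
            for c, val in coeffs.items():
                ri.append(r)
                ci.append(c)
                data.append(val)
        return sparse.csr_matrix(
            (data, (ri, ci)), shape=(len(rows), 2 * self.n)
        )

    def add_scc_row(self, S: frozenset[str]) -> bool:
        """Row: sum_{v in S}(x_v - y_v) - sum_{u in delta-(S)} x_u <= |S|-1."""
        if S in self._seen_sccs:
            return False
        self._seen_sccs.add(S)
        coeffs: dict[int, float] = {}
        for v in S:
            i = self.index[v]
            coeffs[i] = coeffs.get(i, 0.0) + 1.0
            coeffs[self.n + i] = -1.0
        for u in self.net.in_neighbors(S):
            i = self.index[u]
            coeffs[i] = coeffs.get(i, 0.0) - 1.0
        self.lazy_rows.append(coeffs)
        self.lazy_lbs.append(-np.inf)
        self.lazy_ubs.append(float(len(S)) - 1.0)
        return True

    def _constraints(
        self, extra: list[tuple[dict[int, float], float, float]]
    ) -> LinearConstraint:
        rows = self.lazy_rows + [r for r, _, _ in extra]
        A = self._A_static
        lb = self._lb_static
        ub = self._ub_static
        if rows:
            A = sparse.vstack([A, self._to_sparse(rows)], format="csr")
            lb = np.concatenate([lb, self.lazy_lbs, [l for _, l, _ in extra]])
            ub = np.concatenate([ub, self.lazy_ubs, [u for _, _, u in extra]])
        return LinearConstraint(A, lb, ub)

    def solve_milp(
        self,
        c_x: np.ndarray,
        settings: SolverSettings,
        extra: list[tuple[dict[int, float], float, float]],
        maximize: bool = True,
    ) -> tuple[np.ndarray, np.ndarray, float]:
        """One MILP solve; returns (x, y, objective value in 'maximize' sense)."""
        c = np.concatenate([c_x, np.zeros(self.n)])
        if maximize:
            c = -c
        options: dict = {"mip_rel_gap": 0.0}
        if settings.time_limit is not None:
            options["time_limit"] = float(settings.time_limit)
        res = milp(
            c,
            constraints=[self._constraints(extra)],
            integrality=np.ones(2 * self.n),
            bounds=self.bounds,
            options=options,
        )
        if res.status == 2:
            raise InfeasibleInstance("no feasible subgraph under the constraints")
        if res.x is None:
            raise SolverTimeout(f"MILP solve failed or timed out (status {res.status})")
        x = np.round(res.x[: self.n]).astype(int)
        y = np.round(res.x[self.n :]).astype(int)
        return x, y, float(c_x @ x)

    def selected(self, x: np.ndarray, y: np.ndarray) -> tuple[frozenset[str], str]:
        node_set = frozenset(v for v, i in self.index.items() if x[i] == 1)
        roots = [v for v, i in self.index.items() if y[i] == 1]
        if len(roots) != 1:
            raise RuntimeError("backend returned an invalid root flagging")
        return node_set, roots[0]

    def solve_with_separation(
        self,
        c_x: np.ndarray,
        settings: SolverSettings,
        extra: list[tuple[dict[int, float], float, float]],
        max_rounds: int = 1000,
    ) -> tuple[frozenset[str], str, float]:
        """Solve -> separate violated strongly-connected-set rows -> re-solve
        until the incumbent satisfies the full exponential family."""
        for _ in range(max_rounds):
            x, y, val = self.solve_milp(c_x, settings, extra)
            node_set, root = self.selected(x, y)
            violated = self._separate(node_set, root)
            if not violated:
                return node_set, root, val
            for S in violated:
                self.add_scc_row(S)
        raise RuntimeError("lazy separation did not converge")

    def _separate(self, node_set: frozenset[str], root: str) -> list[frozenset[str]]:
        violations = []
        for S in self.net.strongly_connected_components(node_set):
            if len(S) <= 1 or root in S:
                continue
            if not (self.net.in_neighbors(S) & node_set):
                violations.append(S)
        return violations


def _build_model(inst: SubgraphInstance, sign: float = 1.0) -> _Model:
    score = inst.used_score()
    if sign < 0:
        score = {k: -v for k, v in score.items()}
    return _Model(
        inst.network,
        score,
        inst.receptors,
        inst.terminals,
        inst.include,
        inst.exclude,
        inst.k_min,
        inst.k_max,
    )


Cut = tuple[dict[str, float], float, float]
"""Extra linear cut over x variables: ({node: coeff}, lb, ub)."""


def _translate_cuts(model: _Model, cuts: Sequence[Cut]) -> list[tuple[dict[int, float], float, float]]:
    out = []
    for coeffs, lb, ub in cuts:
        out.append(({model.index[v]: c for v, c in coeffs.items()}, lb, ub))
    return out


def solve_parametric(
    instance: SubgraphInstance,
    lam: float,
    settings: SolverSettings | None = None,
    extra_cuts: Sequence[Cut] = (),
    _model: _Model | None = None,
) -> tuple[frozenset[str], str, float]:
    """Maximize ``s^T x - lam * e^T x`` over the feasible subgraphs.

    Connectivity rows are enforced lazily.  Returns the selected node set,
    the root, and the parametric objective value.  ``sense='minimize'`` is
    handled by negating the score, so the returned value is always in the
    maximization sense of the (possibly negated) score.
    """
    settings = settings or SolverSettings()
    inst = instance.effective()
    model = _model or _build_model(inst, -1.0 if inst.sense == "minimize" else 1.0)
    c_x = model.s - lam
    return model.solve_with_separation(
        c_x, settings, _translate_cuts(model, extra_cuts)
    )


def _greedy_feasible(inst: SubgraphInstance, model: _Model) -> frozenset[str] | None:
    """BFS from the best-scoring admissible root up to k_min nodes; used only
    to initialize lambda, so failures return None."""
    net = inst.network
    score = {v: model.s[model.index[v]] for v in net.nodes}
    roots = sorted(inst.receptors or net.node_set, key=lambda v: (-score[v], v))
    for root in roots[:10]:
        if root in inst.exclude:
            continue
        selected = {root}
        frontier = [root]
        while len(selected) < inst.k_min and frontier:
            v = frontier.pop(0)
            for u in sorted(net.out_neighbors(v), key=lambda u: (-score[u], u)):
                if u in selected or u in inst.exclude:
                    continue
                selected.add(u)
                frontier.append(u)
                if len(selected) >= inst.k_min:
                    break
        cand = frozenset(selected)
        ok, _ = check_feasible(inst, cand, root)
        if ok:
            return cand
    return None


def _maximal_tied_optimum(
    model: _Model,
    settings: SolverSettings,
    extra: list[tuple[dict[int, float], float, float]],
    node_set: frozenset[str],
    root: str,
) -> tuple[frozenset[str], str]:
    """Among subgraphs whose average (signed) score ties the optimum, return
    one of maximum cardinality; falls back to the incumbent on any numerical
    degradation."""
    k = len(node_set)
    total = float(sum(model.s[model.index[v]] for v in node_set))
    lam_star = total / k
    # s^T x - lam* e^T x >= -tol  <=>  average >= lam* (up to tol/size)
    tol = 1e-9 * max(1.0, abs(lam_star))
    tie_row = ({i: float(model.s[i]) - lam_star for i in range(model.n)}, -tol, np.inf)
    try:
        cand_set, cand_root, _ = model.solve_with_separation(
            np.ones(model.n), settings, extra + [tie_row]
        )
    except (InfeasibleInstance, SolverTimeout):
        return node_set, root
    cand_total = float(sum(model.s[model.index[v]] for v in cand_set))
    if cand_total / len(cand_set) + 1e-12 >= lam_star:
        return cand_set, cand_root
    return node_set, root


def solve(
    instance: SubgraphInstance, settings: SolverSettings | None = None,
    extra_cuts: Sequence[Cut] = (),
) -> SubgraphSolution:
    """Find a subgraph maximizing (or minimizing) the average node score.

    Dinkelbach loop: start from the average score of a greedy feasible
    subgraph (or the worst single-node score if greedy construction fails),
    repeatedly solve the parametric problem and update lambda to the
    incumbent's average until the parametric optimum is within the gap
    tolerance of zero.
    """
    settings = settings or SolverSettings()
    inst = instance.effective()
    sign = -1.0 if inst.sense == "minimize" else 1.0
    model = _build_model(inst, sign)
    extra = _translate_cuts(model, extra_cuts)

    greedy = _greedy_feasible(inst, model)
    if greedy is not None:
        lam = float(sum(model.s[model.index[v]] for v in greedy)) / len(greedy)
    else:
        lam = float(model.s.min())

    lambdas = [lam]
    node_set: frozenset[str] | None = None
    root = ""
    converged = False
    n_solves = 0
    for _ in range(settings.max_iterations):
        cur_set, cur_root, value = model.solve_with_separation(
            model.s - lam, settings, extra
        )
        n_solves += 1
        node_set, root = cur_set, cur_root
        ratio = float(sum(model.s[model.index[v]] for v in node_set)) / len(node_set)
        if abs(value) <= settings.gap_tolerance:
            converged = True
            lam = max(lam, ratio)
            break
        lam = ratio
        lambdas.append(lam)
    if node_set is None:
        raise RuntimeError("Dinkelbach loop made no iterations")
    if not converged:
        logger.warning("Dinkelbach loop hit max_iterations; returning incumbent")

    if settings.maximal_optimum and converged:
        node_set, root = _maximal_tied_optimum(model, settings, extra, node_set, root)

    used = instance.used_score()
    total = float(sum(used[v] for v in node_set))
    solution = SubgraphSolution(
        node_set=node_set,
        root=root,
        objective=total / len(node_set),
        total_score=total,
        rank=0,
        converged=converged,
        lambda_sequence=tuple(lambdas),
        n_parametric_solves=n_solves,
    )
    ok, tags = check_feasible(instance, node_set, root)
    if not ok:
        raise RuntimeError(f"solver emitted an infeasible subgraph: {tags}")
    return solution


def solve_fixed_size(
    network: DirectedNetwork,
    score: Mapping[str, float],
    k: int,
    receptors: frozenset[str] = frozenset(),
    terminals: frozenset[str] = frozenset(),
    settings: SolverSettings | None = None,
) -> SubgraphSolution:
    """Fixed-cardinality comparator: maximize the *total* score ``s^T x``
    over rooted-connected subgraphs of exactly ``k`` nodes.

    This is the a-priori-size model the average-score formulation is
    benchmarked against; with empty receptor/terminal sets the root is free
    and no sink constraint applies.
    """
    settings = settings or SolverSettings()
    if k > len(network):
        raise ValueError("k exceeds the number of nodes")
    inst = SubgraphInstance(
        network=network,
        score=score,
        receptors=frozenset(receptors),
        terminals=frozenset(terminals),
        k_min=k,
        k_max=k,
    )
    model = _build_model(inst)
    node_set, root, total = model.solve_with_separation(model.s, settings, [])
    solution = SubgraphSolution(
        node_set=node_set,
        root=root,
        objective=total / k,
        total_score=float(total),
        converged=True,
    )
    ok, tags = check_feasible(inst, node_set, root)
    if not ok:
        raise RuntimeError(f"solver emitted an infeasible subgraph: {tags}")
    return solution


def solve_union_over_sizes(
    network: DirectedNetwork,
    score: Mapping[str, float],
    k_min: int,
    k_max: int,
    receptors: frozenset[str] = frozenset(),
    terminals: frozenset[str] = frozenset(),
    settings: SolverSettings | None = None,
) -> frozenset[str]:
    """Run the fixed-size comparator for every size in ``[k_min, k_max]`` and
    return the union of the node sets; infeasible or timed-out sizes are
    skipped with a log entry."""
    if k_min > k_max:
        raise ValueError("k_min > k_max")
    union: set[str] = set()
    any_ok = False
    for k in range(k_min, k_max + 1):
        try:
            sol = solve_fixed_size(network, score, k, receptors, terminals, settings)
        except (InfeasibleInstance, SolverTimeout) as exc:
            logger.info("fixed-size k=%d skipped: %s", k, exc)
            continue
        union.update(sol.node_set)
        any_ok = True
    if not any_ok:
        raise InfeasibleInstance("every size in the range was infeasible")
    return frozenset(union)


def solve_suboptimal(
    instance: SubgraphInstance,
    n: int,
    settings: SolverSettings | None = None,
) -> list[SubgraphSolution]:
    """Optimal plus up to ``n`` next-best solutions with distinct node sets.

    After each solution the no-good cut
    ``sum_{v in V*} x_v - sum_{v not in V*} x_v <= |V*| - 1`` is appended and
    the fractional problem is re-solved; the cut excludes exactly the
    previous node set (supersets and subsets stay admissible).  Enumeration
    stops early when the cut pool exhausts the feasible region.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    settings = settings or SolverSettings()
    solutions: list[SubgraphSolution] = []
    cuts: list[Cut] = []
    for rank in range(n + 1):
        try:
            sol = solve(instance, settings, extra_cuts=tuple(cuts))
        except InfeasibleInstance:
            if rank == 0:
                raise
            break
        sol = replace(sol, rank=rank)
        ok, tags = check_feasible(instance, sol.node_set, sol.root)
        if not ok:
            raise RuntimeError(f"suboptimal emission infeasible: {tags}")
        solutions.append(sol)
        coeffs = {
            v: (1.0 if v in sol.node_set else -1.0)
            for v in instance.network.nodes
        }
        cuts.append((coeffs, -np.inf, float(len(sol.node_set) - 1)))
    return solutions


@dataclass(frozen=True)
class UnionSummary:
    """Union of solution node sets with induced edges and per-node counts."""

    network: DirectedNetwork
    frequency: Mapping[str, int]


def union_summary(
    solutions: Sequence[SubgraphSolution], network: DirectedNetwork
) -> UnionSummary:
    """Summarize optimal and suboptimal solutions as one induced subgraph
    annotated with how often each node occurs across solutions."""
    if not solutions:
        raise ValueError("no solutions to summarize")
    union: set[str] = set()
    freq: dict[str, int] = {}
    for sol in solutions:
        union.update(sol.node_set)
        for v in sol.node_set:
            freq[v] = freq.get(v, 0) + 1
    return UnionSummary(network=network.induced(union), frequency=freq)


def enumerate_feasible_sets(
    instance: SubgraphInstance, max_nodes: int = 15
) -> list[tuple[frozenset[str], str]]:
    """Exhaustively enumerate every feasible (node set, smallest root) pair.

    Feasibility is decided by reachability semantics directly — breadth-first
    search from each admissible root inside the candidate set, plus the sink,
    include and exclude conditions — independently of the MILP constraint
    rows, so this doubles as the reference oracle for the solver path.
    Only for networks of at most ``max_nodes`` nodes.
    """
    n = len(instance.network)
    if n > max_nodes:
        raise ValueError(f"enumeration capped at {max_nodes} nodes, got {n}")
    inst = instance.effective()
    nodes = inst.network.nodes
    g = inst.network.as_nx()
    succ = {v: frozenset(g.successors(v)) for v in nodes}
    root_pool = inst.receptors or inst.network.node_set
    terminals = inst.terminals

    out: list[tuple[frozenset[str], str]] = []
    for k in range(inst.k_min, inst.k_max + 1):
        for subset in itertools.combinations(nodes, k):
            sset = frozenset(subset)
            if not inst.include <= sset or (inst.exclude & sset):
                continue
            if terminals and any(
                not (succ[v] & sset) for v in sset - terminals
            ):
                continue
            for root in subset:  # sorted order from sorted `nodes`
                if root not in root_pool:
                    continue
                seen = {root}
                stack = [root]
                while stack:
                    for u in succ[stack.pop()] & sset:
                        if u not in seen:
                            seen.add(u)
                            stack.append(u)
                if len(seen) == k:
                    out.append((sset, root))
                    break
    return out


def brute_force_optimal(
    instance: SubgraphInstance, max_nodes: int = 15
) -> SubgraphSolution:
    """Exhaustive oracle: enumerate every feasible (node set, root) pair
    within the size bounds and return the best average score.  Ties break
    toward the lexicographically smallest sorted node set."""
    feasible = enumerate_feasible_sets(instance, max_nodes)
    if not feasible:
        raise InfeasibleInstance("no feasible subgraph in the enumeration")
    used = instance.used_score()
    sign = -1.0 if instance.sense == "minimize" else 1.0

    def signed_avg(item: tuple[frozenset[str], str]) -> float:
        return sign * sum(used[v] for v in item[0]) / len(item[0])

    best_val = max(signed_avg(item) for item in feasible)
    ties = [item for item in feasible if signed_avg(item) == best_val]
    sset, root = min(ties, key=lambda item: tuple(sorted(item[0])))
    avg = sum(used[v] for v in sset) / len(sset)
    return SubgraphSolution(
        node_set=sset,
        root=root,
        objective=avg,
        total_score=avg * len(sset),
        converged=True,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_solution(
    solution: SubgraphSolution,
    instance: SubgraphInstance,
    basename: str | Path,
    frequency: Mapping[str, int] | None = None,
) -> tuple[Path, Path]:
    """Write a solution as GraphML (induced subgraph, node attributes score /
    is_root / frequency) plus a JSON sidecar; returns the two paths."""
    basename = Path(basename)
    used = instance.used_score()
    sub = instance.network.induced(solution.node_set)
    attrs: dict[str, Mapping] = {
        "score": {v: used[v] for v in solution.node_set},
        "is_root": {v: int(v == solution.root) for v in solution.node_set},
    }
    if frequency is not None:
        attrs["frequency"] = {v: frequency.get(v, 0) for v in solution.node_set}
    graphml = basename.with_suffix(".graphml")
    sub.write_graphml(graphml, attrs)
    sidecar = basename.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "nodes": sorted(solution.node_set),
                "root": solution.root,
                "objective": solution.objective,
                "total_score": solution.total_score,
                "rank": solution.rank,
                "converged": solution.converged,
                "k_min": instance.k_min,
                "k_max": instance.k_max,
                "sense": instance.sense,
            },
            fh,
            indent=2,
        )
    return graphml, sidecar
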