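"""Constant-sign analysis: from ODE dynamics to signed gene regulatory graphs.

An ODE model over observables (mRNAs, indices ``1..n``), unobservables
(proteins and derived species, ``n+1..n+m``) and exogenous signals
(``n+m+1..n+m+l``) induces a signed directed graph on the genes.  Two
notions of the induced edge sign are implemented:

* **sum-product monotonicity** — the sign of the sum, over all shortest
  *unobserved paths* from regulator to target (paths whose interior visits
  only unobservables), of the products of first-order partial derivatives
  of the dynamics along each path;
* **infinitesimal monotonicity** — the sign of the short-time response of
  the target mRNA to a small offset of the regulator mRNA in the *clamped*
  system, where every observable except the target and every signal is
  frozen at its current value.

For smooth dynamics the two verdicts agree wherever the sum-product sign is
determinate, which this package exploits by using the cheap sum-product
route for graph induction and the numeric probe as an independent
cross-check.  The *constant sign property* (CSP) holds over a set of
(state, parameter) pairs when no regulator-target pair accumulates both
signs across the set; a model with global CSP corresponds to a single
signed graph.  Module-based models with linear (untruncated) production
rates have this property, and their induced graph is the generating graph.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .gnw import GnwModel, module_activation_partials
from .graphs import SignedDigraph
from .simulate import compile_rhs

__all__ = [
    "EMPTY", "PLUS", "MINUS", "BOTH",
    "OdeSystem",
    "MolecularGraph",
    "GeneRegulatoryGraph",
    "ProbeGrid",
    "molecular_graph",
    "unobserved_paths",
    "molecular_distance",
    "sum_product_delta",
    "b_sum",
    "b_inf",
    "gene_regulatory_graph",
    "gnw_to_ode_system",
    "check_dependency",
]

# The four possible monotonicity verdicts for a regulator-target pair.
EMPTY: frozenset[int] = frozenset()
PLUS: frozenset[int] = frozenset({1})
MINUS: frozenset[int] = frozenset({-1})
BOTH: frozenset[int] = frozenset({1, -1})

#: Relative half-width of the band around 0 inside which the sum-product
#: statistic is classified as "exactly zero" (hence indeterminate sign).
#: The band is relative to the sum of |path products|: a single path keeps
#: its exact sign however small its magnitude; only near-total cancellation
#: between paths is indeterminate.
ZERO_BAND = 1e-9


@dataclass(frozen=True)
class OdeSystem:
    """A general ODE model with declared variable classes and sparsity.

    ``rhs(state, params)`` returns the ``n_obs + n_unobs`` derivatives of
    the internal classes; signal components (the trailing ``n_sig`` state
    entries) are exogenous and never integrated.  ``partials(k, l, state,
    params)`` is the first-order partial of the l-th derivative with respect
    to the k-th state component (1-based); when omitted, central finite
    differences are used.  ``dependency`` declares which components each
    derivative actually depends on, as pairs ``(k, l)``; it must be a
    superset of the true dependence (declared, not inferred, because
    "actually depends on" is not decidable from point samples).
    """

    n_obs: int
    n_unobs: int
    rhs: Callable[[np.ndarray, np.ndarray | None], np.ndarray]
    dependency: frozenset[tuple[int, int]]
    n_sig: int = 0
    partials: Callable[[int, int, np.ndarray, np.ndarray | None], float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "dependency", frozenset(self.dependency))
        n_int = self.n_obs + self.n_unobs
        for (k, l) in self.dependency:
            if not (1 <= l <= n_int) or not (1 <= k <= n_int + self.n_sig):
                raise ValueError(f"dependency pair ({k}, {l}) out of range")

    @property
    def n_internal(self) -> int:
        return self.n_obs + self.n_unobs

    def partial(self, k: int, l: int, state: np.ndarray, params=None) -> float:
        """``d f_l / d x_k`` at (state, params), analytic or finite-difference."""
        if self.partials is not None:
            return self.partials(k, l, state, params)
        state = np.asarray(state, dtype=float)
        step = 1e-6 * (1.0 + abs(state[k - 1]))
        up = state.copy(); up[k - 1] += step
        dn = state.copy(); dn[k - 1] -= step
        return float((self.rhs(up, params)[l - 1] - self.rhs(dn, params)[l - 1]) / (2 * step))


@dataclass(frozen=True)
class MolecularGraph:
    """Directed graph over the internal molecular classes ``1..n_obs+n_unobs``."""

    n_vertices: int
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", frozenset(self.edges))
        for (i, j) in self.edges:
            if not (1 <= i <= self.n_vertices and 1 <= j <= self.n_vertices):
                raise ValueError(f"edge ({i}, {j}) outside [1, {self.n_vertices}]^2")

    def successors(self, v: int) -> set[int]:
        return {j for (i, j) in self.edges if i == v}


def molecular_graph(sys: OdeSystem) -> MolecularGraph:
    """Restrict the declared dependency pattern to the internal classes."""
    n_int = sys.n_internal
    return MolecularGraph(
        n_vertices=n_int,
        edges=frozenset((k, l) for (k, l) in sys.dependency if k <= n_int and l <= n_int),
    )


# ---------------------------------------------------------------------------
# Paths through unobservables
# ---------------------------------------------------------------------------

def unobserved_paths(
    mg: MolecularGraph, n_obs: int, i: int, j: int, q: int
) -> list[tuple[int, ...]]:
    """All length-*q* paths from mRNA *i* to mRNA *j* avoiding other mRNAs.

    A path is a tuple ``(r_0, ..., r_q)`` with ``r_q = i``, ``r_0 = j``,
    every interior vertex unobservable, and ``(r_k, r_{k-1})`` an edge of
    the molecular graph for each step.  Paths need not be simple, but
    self-loop edges (degradation terms, where a derivative depends on its
    own variable) are never traversed: they carry no regulator-to-target
    influence, and skipping them is what makes a translation/production
    two-layer model's molecular graph effectively bipartite with no
    unobserved path longer than 2.  Self-effects (``i == j``) are out of
    scope.
    """
    if i == j:
        raise ValueError("self-effects are out of scope for monotonicity")
    if not (1 <= i <= n_obs and 1 <= j <= n_obs):
        raise ValueError("endpoints must be observables")
    if q < 1:
        raise ValueError("path length must be >= 1")
    unobs = range(n_obs + 1, mg.n_vertices + 1)
    paths: list[tuple[int, ...]] = []

    def extend(prefix: list[int]) -> None:
        # prefix runs from r_q = i downward; position len(prefix) - 1 filled
        pos = q - len(prefix)  # index of next vertex r_pos to choose
        cur = prefix[-1]
        if pos == 0:
            if (cur, j) in mg.edges:
                paths.append(tuple(reversed(prefix + [j])))
            return
        for nxt in sorted(mg.successors(cur)):
            if nxt in unobs and nxt != cur:
                extend(prefix + [nxt])

    extend([i])
    return paths


def molecular_distance(mg: MolecularGraph, n_obs: int, i: int, j: int) -> float:
    """Smallest unobserved-path length from *i* to *j*; ``inf`` if none.

    The search is bounded by ``n_unobs + 1`` (an interior visiting each
    unobservable at most once); a shortest path never revisits a vertex, so
    the bound is exact for the minimum even though longer, non-simple paths
    exist when the unobservable subgraph has cycles.
    """
    n_unobs = mg.n_vertices - n_obs
    for q in range(1, n_unobs + 2):
        if unobserved_paths(mg, n_obs, i, j, q):
            return q
    return math.inf


def sum_product_delta(
    sys: OdeSystem, i: int, j: int, state: np.ndarray, params=None
) -> float:
    """Sum over shortest unobserved paths of products of partials along each.

    Raises when no unobserved path exists (callers wanting a sign verdict
    should use :func:`b_sum`, which maps that case to the empty sign set).
    """
    mg = molecular_graph(sys)
    q = molecular_distance(mg, sys.n_obs, i, j)
    if math.isinf(q):
        raise ValueError(f"no unobserved path from {i} to {j}")
    total = 0.0
    for path in unobserved_paths(mg, sys.n_obs, i, j, int(q)):
        prod = 1.0
        for step in range(1, len(path)):
            prod *= sys.partial(path[step], path[step - 1], state, params)
        total += prod
    return total


def _delta_scale(sys: OdeSystem, i: int, j: int, state, params) -> float:
    """Sum of |products| over shortest paths — the natural scale for the zero band."""
    mg = molecular_graph(sys)
    q = molecular_distance(mg, sys.n_obs, i, j)
    scale = 0.0
    for path in unobserved_paths(mg, sys.n_obs, i, j, int(q)):
        prod = 1.0
        for step in range(1, len(path)):
            prod *= sys.partial(path[step], path[step - 1], state, params)
        scale += abs(prod)
    return scale


def b_sum(sys: OdeSystem, i: int, j: int, state, params=None) -> frozenset[int]:
    """Sum-product monotonicity verdict for regulator *i* on target *j*.

    Empty when *i* has no unobserved path to *j*; ``{1}``/``{-1}`` by the
    sign of the sum-product statistic; ``{1, -1}`` when the statistic
    cancels to within ``ZERO_BAND`` of the summed path-product magnitudes
    (exact zeros form a measure-zero boundary where the sign flips, so
    relative cancellation that deep is classified as indeterminate; with
    finite-difference partials, supply analytic partials if behaviour at
    such boundaries matters).
    """
    mg = molecular_graph(sys)
    if math.isinf(molecular_distance(mg, sys.n_obs, i, j)):
        return EMPTY
    state = np.asarray(state, dtype=float)
    delta = sum_product_delta(sys, i, j, state, params)
    scale = _delta_scale(sys, i, j, state, params)
    if abs(delta) <= ZERO_BAND * scale:
        return BOTH
    return PLUS if delta > 0 else MINUS


# ---------------------------------------------------------------------------
# Numeric infinitesimal probe
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeGrid:
    """Finite surrogate for the "for all small t and h" quantifier.

    The exact definition quantifies over all sufficiently small times and
    offsets; the probe evaluates difference quotients on a fixed grid near
    zero and requires a consistent sign across every informative grid
    point.  Differences below ``noise_floor`` (solver accuracy territory)
    are uninformative; if all points are uninformative the verdict is the
    empty set.
    """

    h_values: tuple[float, ...] = (-1e-2, -1e-3, 1e-3, 1e-2)
    t_values: tuple[float, ...] = (1e-3, 1e-2, 1e-1)
    noise_floor: float = 1e-12
    rtol: float = 1e-11
    atol: float = 1e-13


def _clamped_solution(
    sys: OdeSystem, j: int, state0: np.ndarray, params, t_values: Sequence[float],
    rtol: float, atol: float,
) -> np.ndarray:
    """Solve the clamped system (only target j and unobservables evolve);
    return the target's trajectory sampled at t_values."""
    n_int = sys.n_internal
    free = np.zeros(len(state0))
    free[j - 1] = 1.0
    free[sys.n_obs: n_int] = 1.0

    def rhs(t, s):
        d = np.zeros(len(s))
        d[:n_int] = sys.rhs(s, params)
        return d * free

    sol = solve_ivp(
        rhs, (0.0, float(max(t_values))), np.asarray(state0, dtype=float),
        t_eval=np.asarray(t_values, dtype=float), method="DOP853",
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"clamped-system solver failed: {sol.message}")
    return sol.y[j - 1]


def b_inf(
    sys: OdeSystem, i: int, j: int, state, params=None,
    probe: ProbeGrid | None = None,
) -> frozenset[int]:
    """Infinitesimal monotonicity of *i* on *j*, probed numerically.

    Integrates the clamped dynamics (all observables except *j* and all
    signals frozen) from the given state with the regulator offset by each
    probe ``h``, and classifies the sign of the difference quotient
    ``(eta_j(t, h) - eta_j(t, 0)) / h`` across the probe grid: consistently
    positive -> ``{1}``, consistently negative -> ``{-1}``, every
    difference below the noise floor -> empty, anything else -> ``{1, -1}``.
    """
    if i == j:
        raise ValueError("self-effects are out of scope for monotonicity")
    probe = probe or ProbeGrid()
    state = np.asarray(state, dtype=float)
    base = _clamped_solution(sys, j, state, params, probe.t_values, probe.rtol, probe.atol)
    signs: set[int] = set()
    informative = False
    for h in probe.h_values:
        shifted = state.copy()
        shifted[i - 1] += h
        eta = _clamped_solution(sys, j, shifted, params, probe.t_values, probe.rtol, probe.atol)
        for diff in eta - base:
            if abs(diff) <= probe.noise_floor:
                continue
            informative = True
            signs.add(1 if diff / h > 0 else -1)
    if not informative:
        return EMPTY
    return frozenset(signs)


# ---------------------------------------------------------------------------
# Induced gene regulatory graphs and CSP verdicts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRegulatoryGraph:
    """Signed graph over genes induced from an ODE model on a sample of
    (state, params) pairs, with its constant-sign verdict.

    ``edge_signs`` maps each pair with a nonempty accumulated sign set to
    that set; ``csp`` is true iff no pair accumulated both signs.
    """

    n_genes: int
    edge_signs: Mapping[tuple[int, int], frozenset[int]]
    sample_size: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "edge_signs", dict(self.edge_signs))
        if any(not s for s in self.edge_signs.values()):
            raise ValueError("edge sign sets must be nonempty")

    @property
    def csp(self) -> bool:
        return all(s != BOTH for s in self.edge_signs.values())

    def to_signed_digraph(self) -> SignedDigraph:
        """Collapse to a plain signed graph; requires the CSP to hold."""
        if not self.csp:
            raise ValueError("graph has indeterminate edges; CSP does not hold")
        return SignedDigraph(
            n_vertices=self.n_genes,
            sign={e: (1 if s == PLUS else -1) for e, s in self.edge_signs.items()},
        )

    def report(self) -> dict:
        """JSON-ready summary: per-pair sign sets, sample size, CSP verdict."""
        return {
            "n_genes": self.n_genes,
            "sample_size": self.sample_size,
            "csp": self.csp,
            "edges": [
                {"source": i, "target": j, "signs": sorted(s)}
                for (i, j), s in sorted(self.edge_signs.items())
            ],
        }


def gene_regulatory_graph(
    sys: OdeSystem,
    sample: Iterable[tuple[np.ndarray, np.ndarray | None]],
    method: str = "sum",
    probe: ProbeGrid | None = None,
) -> GeneRegulatoryGraph:
    """Union per-pair monotonicity verdicts over a sample of conditions.

    ``method="sum"`` uses the sum-product route (cheap, derivative-based);
    ``method="inf"`` uses the numeric infinitesimal probe.  Enlarging the
    sample can only grow each pair's sign set, never shrink it.
    """
    sample = list(sample)
    if not sample:
        raise ValueError("sample must be nonempty")
    if method not in ("sum", "inf"):
        raise ValueError(f"unknown method {method!r}")
    accum: dict[tuple[int, int], frozenset[int]] = {}
    for (state, params) in sample:
        for i in range(1, sys.n_obs + 1):
            for j in range(1, sys.n_obs + 1):
                if i == j:
                    continue
                if method == "sum":
                    s = b_sum(sys, i, j, state, params)
                else:
                    s = b_inf(sys, i, j, state, params, probe=probe)
                if s:
                    accum[(i, j)] = accum.get((i, j), EMPTY) | s
    return GeneRegulatoryGraph(
        n_genes=sys.n_obs, edge_signs=accum, sample_size=len(sample)
    )


def check_dependency(
    sys: OdeSystem,
    states: Iterable[np.ndarray],
    params=None,
    tol: float = 1e-12,
) -> set[tuple[int, int]]:
    """Warn about declared dependency pairs that are numerically inactive.

    Evaluates the partial of each declared pair at every sampled state and
    returns (and warns about) pairs whose partial never exceeds *tol* —
    usually a sign that the declared sparsity pattern is wider than the
    dynamics.  The converse (undeclared active pairs) is an error in the
    declaration and is not checked here.
    """
    states = [np.asarray(s, dtype=float) for s in states]
    never_active = set()
    for (k, l) in sorted(sys.dependency):
        if l > sys.n_internal:
            continue
        if all(abs(sys.partial(k, l, s, params)) <= tol for s in states):
            never_active.add((k, l))
    if never_active:
        warnings.warn(
            f"declared dependencies never active on the sampled states: "
            f"{sorted(never_active)}",
            stacklevel=2,
        )
    return never_active


# ---------------------------------------------------------------------------
# Module-model bridge
# ---------------------------------------------------------------------------

def gnw_to_ode_system(model: GnwModel) -> OdeSystem:
    """View a module-based model as a general ODE system.

    State layout: molecular classes ``1..n`` are the mRNAs, ``n+1..2n`` the
    proteins; there are no exogenous signals and the molecular graph is
    bipartite (protein i -> mRNA j for every graph edge, mRNA i -> protein
    i, plus degradation self-loops), so every regulator-target pair is at
    molecular distance 2.  Partials are analytic for linear production;
    truncated and clipped production fall back to finite differences of the
    production term.
    """
    n = model.n_genes
    rhs_flat = compile_rhs(model)

    def rhs(state, params=None):
        return rhs_flat(0.0, np.asarray(state, dtype=float))

    dependency = set()
    for j in range(1, n + 1):
        dependency.add((j, j))            # degradation
        dependency.add((j, n + j))        # translation
        dependency.add((n + j, n + j))    # protein degradation
    for (i, j) in model.graph.edges:
        dependency.add((n + i, j))        # module regulation

    linear = model.production == "linear"

    def partials(k, l, state, params=None):
        state = np.asarray(state, dtype=float)
        x, y = state[:n], state[n: 2 * n]
        if l <= n:
            j = l
            if k == j:
                return -model.delta_m[j]
            if k <= n:
                return 0.0
            i = k - n
            if (i, j) not in model.graph.edges:
                return 0.0
            if not linear:
                return _production_fd(model, j, y, i)
            m = next(mm for mm in model.modules[j] if i in mm.inputs)
            nu = model.nu(j, y)
            dM = module_activation_partials(m, nu)[i]
            kij, hij = model.k[(i, j)], model.h[(i, j)]
            yi = y[i - 1]
            if yi == 0.0:
                dnu = 1.0 / kij if hij == 1 else 0.0
            else:
                dnu = hij * nu[i] / yi
            return m.c * m.beta * dM * dnu
        ii = l - n
        if k == ii:
            return model.rho[ii]
        if k == n + ii:
            return -model.rho[ii]
        return 0.0

    return OdeSystem(
        n_obs=n, n_unobs=n, rhs=rhs,
        dependency=frozenset(dependency), partials=partials,
    )


def _production_fd(model: GnwModel, j: int, y: np.ndarray, i: int) -> float:
    from .gnw import production_rate

    step = 1e-6 * (1.0 + abs(y[i - 1]))
    up = y.copy(); up[i - 1] += step
    dn = y.copy(); dn[i - 1] = max(dn[i - 1] - step, 0.0)
    return float(
        (production_rate(model, j, up) - production_rate(model, j, dn))
        / (up[i - 1] - dn[i - 1])
    )
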