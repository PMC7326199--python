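"""Module-based thermodynamic ODE models of transcriptional regulation.

The model follows the generative scheme of the GeneNetWeaver simulator
(version 3).  Transcription factors (TFs) regulate a target gene through
*cis*-regulatory modules: each module has a nonempty set of activator
inputs, possibly some deactivator inputs, a type (``+1`` enhancer or ``-1``
silencer), and a binding mode (independent or synergistic/complex).  The
input sets of the modules of a target gene partition its regulator set, so
each TF acts on a given target through exactly one module.

For an edge ``(i, j)`` the normalized expression of the TF protein is the
Hill term ``nu_ij = (y_i / k_ij) ** h_ij``.  The activation probability of a
module is a Shea-Ackers-type function of its inputs' ``nu`` values (three
types, below), and the mRNA production rate of a gene is the basal rate plus
a signed, module-effect-weighted combination of module activations.  mRNA
and protein dynamics are first-order:

    dx_j/dt = f_j(y) - delta_j * x_j
    dy_i/dt = rho_i * (x_i - y_i)

after choosing protein units so the translation rate equals the protein
degradation rate.  Nondimensionalizing (``delta_j = alpha_basal_j + sum of
beta`` over modules of *j*) puts steady states in [0, 1].
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np

from .graphs import SignedDigraph

__all__ = [
    "RegModule",
    "ModuleStructure",
    "GnwModel",
    "ParamRanges",
    "normalized_expression",
    "module_activation",
    "module_activation_partials",
    "production_rate",
    "derivative_field",
    "nondimensionalize",
    "set_partitions",
    "enumerate_module_structures",
    "count_partitions",
    "sample_model",
    "count_parameters",
    "model_to_json",
    "model_from_json",
]

SCHEMA_VERSION = 1

#: Production-rate conventions.
#: ``linear``     -- basal + sum of c*beta*M (no truncation).
#: ``truncated``  -- expectation over module on/off configurations with each
#:                   configuration rate clipped to [0, 1] (the GeneNetWeaver
#:                   source-code behaviour).
#: ``clip``       -- single outer clip max(basal + sum c*beta*M, 0), the
#:                   convention used by the five-gene case-study equations.
PRODUCTION_MODES = ("linear", "truncated", "clip")


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModuleStructure:
    """Discrete part of a module: inputs, roles, type and mode (no effect size)."""

    inputs: frozenset[int]
    activators: frozenset[int]
    deactivators: frozenset[int]
    c: int  # +1 enhancer, -1 silencer
    r: int  # 0 independent, 1 synergistic

    def __post_init__(self) -> None:
        A, D, K = self.activators, self.deactivators, self.inputs
        if not K:
            raise ValueError("module must have at least one input")
        if A | D != K or A & D:
            raise ValueError("activators and deactivators must partition the inputs")
        if not A:
            raise ValueError("module must have at least one activator")
        if self.c not in (1, -1):
            raise ValueError(f"module type must be +1 or -1, got {self.c}")
        if self.r not in (0, 1):
            raise ValueError(f"binding mode must be 0 or 1, got {self.r}")
        if len(K) == 1 and (self.r != 0 or D):
            raise ValueError("single-input modules must be independent single-activator")

    @property
    def module_type(self) -> int:
        """1 (independent), 2 (complex, all activators) or 3 (complex with deactivators)."""
        if self.r == 0:
            return 1
        return 2 if not self.deactivators else 3

    def sign_consistent(self, g: SignedDigraph, target: int) -> bool:
        """Check b_ij == c * (1[i in A] - 1[i in D]) for every input i."""
        for i in self.inputs:
            b = g.sign.get((i, target))
            if b is None:
                return False
            role = 1 if i in self.activators else -1
            if b != self.c * role:
                return False
        return True


@dataclass(frozen=True)
class RegModule:
    """A *cis*-regulatory module acting on one target gene.

    ``structure`` carries the discrete configuration; ``beta`` is the
    absolute effect of the module on the target's mRNA production rate.
    """

    target: int
    structure: ModuleStructure
    beta: float

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("module effect beta must be nonnegative")

    @property
    def inputs(self) -> frozenset[int]:
        return self.structure.inputs

    @property
    def activators(self) -> frozenset[int]:
        return self.structure.activators

    @property
    def deactivators(self) -> frozenset[int]:
        return self.structure.deactivators

    @property
    def c(self) -> int:
        return self.structure.c

    @property
    def r(self) -> int:
        return self.structure.r

    @property
    def module_type(self) -> int:
        return self.structure.module_type

    def sign_consistent(self, g: SignedDigraph, target: int) -> bool:
        return self.structure.sign_consistent(g, target)


def normalized_expression(y_i: float, k_ij: float, h_ij: int) -> float:
    """Hill term ``nu_ij = (y_i / k_ij) ** h_ij``.

    ``k_ij`` is the Michaelis-Menten normalizing constant (protein units) and
    ``h_ij`` a small positive integer, the Hill constant (number of TF copies
    that must bind to activate the promoter).
    """
    if y_i < 0:
        raise ValueError("protein concentration must be nonnegative")
    if k_ij <= 0:
        raise ValueError("Michaelis-Menten constant must be positive")
    if h_ij < 1:
        raise ValueError("Hill constant must be a positive integer")
    return (y_i / k_ij) ** h_ij


def module_activation(
    m: ModuleStructure | RegModule,
    nu: Mapping[int, float],
    module_type: int | None = None,
) -> float:
    """Activation probability ``M`` of a module given input Hill terms.

    Type 1 (independent): product over activators of ``nu/(1+nu)`` times
    product over deactivators of ``1/(1+nu)``.  Type 2 (activator complex):
    ``P_A/(1+P_A)`` with ``P_A`` the product of activator ``nu``'s.  Type 3
    (complex with deactivators): ``P_A/(1 + P_A + P_A*P_D)``.

    ``module_type`` may be passed to assert the expected type; forcing type 3
    on a module with no deactivators is rejected (a historically buggy
    reduction: with the empty product over deactivators read as 1 instead of
    0, type-3 formulas silently corrupt type-2 modules).
    """
    s = m.structure if isinstance(m, RegModule) else m
    for i in s.inputs:
        if i not in nu:
            raise ValueError(f"missing Hill term for module input {i}")
        if nu[i] < 0:
            raise ValueError(f"negative Hill term for input {i}")
    if module_type is not None:
        if module_type == 3 and not s.deactivators:
            raise ValueError("type-3 module with no deactivators")
        if module_type != s.module_type:
            raise ValueError(
                f"module is type {s.module_type}, not type {module_type}"
            )
    if s.r == 0:
        m_act = 1.0
        for i in s.activators:
            m_act *= nu[i] / (1.0 + nu[i])
        for i in s.deactivators:
            m_act *= 1.0 / (1.0 + nu[i])
        return m_act
    p_a = math.prod(nu[i] for i in s.activators)
    if not s.deactivators:  # type 2
        return p_a / (1.0 + p_a)
    p_d = math.prod(nu[i] for i in s.deactivators)  # type 3
    return p_a / (1.0 + p_a + p_a * p_d)


def module_activation_partials(
    m: ModuleStructure | RegModule, nu: Mapping[int, float]
) -> dict[int, float]:
    """Analytic partial derivatives ``dM/dnu_i`` for every input *i*.

    Positive for activators and negative for deactivators whenever all
    ``nu`` are positive, for every module type.
    """
    s = m.structure if isinstance(m, RegModule) else m
    out: dict[int, float] = {}
    if s.r == 0:
        for i in s.inputs:
            rest = 1.0
            for a in s.activators:
                if a != i:
                    rest *= nu[a] / (1.0 + nu[a])
            for d in s.deactivators:
                if d != i:
                    rest *= 1.0 / (1.0 + nu[d])
            # d/dnu [nu/(1+nu)] = 1/(1+nu)^2; d/dnu [1/(1+nu)] = -1/(1+nu)^2
            grad = rest / (1.0 + nu[i]) ** 2
            out[i] = grad if i in s.activators else -grad
        return out
    p_a = math.prod(nu[i] for i in s.activators)
    if not s.deactivators:  # type 2
        denom = (1.0 + p_a) ** 2
        for i in s.activators:
            p_rest = math.prod(nu[a] for a in s.activators if a != i)
            out[i] = p_rest / denom
        return out
    p_d = math.prod(nu[i] for i in s.deactivators)  # type 3
    denom = (1.0 + p_a + p_a * p_d) ** 2
    for i in s.activators:
        p_rest = math.prod(nu[a] for a in s.activators if a != i)
        out[i] = p_rest * (1.0 + 0.0) / denom  # d/dPa [Pa/(1+Pa(1+Pd))] = 1/denom
    for i in s.deactivators:
        p_rest = math.prod(nu[d] for d in s.deactivators if d != i)
        out[i] = -(p_a ** 2) * p_rest / denom
    return out


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GnwModel:
    """A module-based ODE model over a signed directed graph.

    Parameters are keyed by 1-based gene index (``alpha_basal``, ``rho``,
    ``delta_m``) or by edge ``(i, j)`` (``k``, ``h``).  ``modules`` maps each
    regulated gene to its modules, whose input sets partition the gene's
    regulator set.  ``production`` selects the production-rate convention
    (see :data:`PRODUCTION_MODES`).
    """

    graph: SignedDigraph
    modules: Mapping[int, tuple[RegModule, ...]]
    alpha_basal: Mapping[int, float]
    k: Mapping[tuple[int, int], float]
    h: Mapping[tuple[int, int], int]
    rho: Mapping[int, float]
    delta_m: Mapping[int, float]
    production: str = "linear"

    def __post_init__(self) -> None:
        object.__setattr__(self, "modules", {j: tuple(ms) for j, ms in self.modules.items()})
        object.__setattr__(self, "alpha_basal", dict(self.alpha_basal))
        object.__setattr__(self, "k", dict(self.k))
        object.__setattr__(self, "h", dict(self.h))
        object.__setattr__(self, "rho", dict(self.rho))
        object.__setattr__(self, "delta_m", dict(self.delta_m))
        if self.production not in PRODUCTION_MODES:
            raise ValueError(f"unknown production mode {self.production!r}")
        g = self.graph
        n = g.n_vertices
        for j in range(1, n + 1):
            regs = g.regulators(j)
            mods = self.modules.get(j, ())
            covered: set[int] = set()
            for m in mods:
                if m.target != j:
                    raise ValueError(f"module targeting {m.target} listed under gene {j}")
                if covered & m.inputs:
                    raise ValueError(f"gene {j}: a regulator appears in two modules")
                covered |= m.inputs
                if not m.structure.sign_consistent(g, j):
                    raise ValueError(f"gene {j}: module roles inconsistent with edge signs")
            if covered != regs:
                raise ValueError(
                    f"gene {j}: module inputs {sorted(covered)} do not partition "
                    f"regulators {sorted(regs)}"
                )
            for key in ("alpha_basal", "rho", "delta_m"):
                if j not in getattr(self, key):
                    raise ValueError(f"missing {key} for gene {j}")
        for (i, j) in g.edges:
            if (i, j) not in self.k or (i, j) not in self.h:
                raise ValueError(f"missing k or h for edge ({i}, {j})")

    @property
    def n_genes(self) -> int:
        return self.graph.n_vertices

    def nu(self, j: int, y: Sequence[float]) -> dict[int, float]:
        """Hill terms of all regulators of gene *j* at protein vector *y* (0-based array)."""
        return {
            i: normalized_expression(y[i - 1], self.k[(i, j)], self.h[(i, j)])
            for i in self.graph.regulators(j)
        }


def production_rate(model: GnwModel, j: int, y: Sequence[float]) -> float:
    """mRNA production rate ``f_j(y)`` of gene *j*.

    In ``linear`` mode this is ``alpha_basal + sum_K c_K * beta_K * M_K``
    (the expectation of the per-configuration promoter activity under
    independent Bernoulli(M_K) module states, when activities combine
    linearly).  In ``truncated`` mode every per-configuration activity is
    first clipped to [0, 1] and the expectation is taken explicitly over the
    ``2**n_modules`` on/off configurations.  In ``clip`` mode the linear rate
    gets a single outer ``max(. , 0)``.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("protein concentrations must be nonnegative")
    alpha = model.alpha_basal[j]
    mods = model.modules.get(j, ())
    if not mods:
        return alpha
    nu = model.nu(j, y)
    acts = [module_activation(m, nu) for m in mods]
    if model.production == "truncated":
        total = 0.0
        for states in itertools.product((0, 1), repeat=len(mods)):
            a_s = alpha + sum(m.c * m.beta for m, s in zip(mods, states) if s)
            a_s = min(max(a_s, 0.0), 1.0)
            p = math.prod(M if s else 1.0 - M for M, s in zip(acts, states))
            total += a_s * p
        return total
    rate = alpha + sum(m.c * m.beta * M for m, M in zip(mods, acts))
    if model.production == "clip":
        return max(rate, 0.0)
    return rate


def derivative_field(model: GnwModel) -> Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Return ``field(x, y) -> (dx, dy)`` for the model's dynamics.

    ``dx_j = f_j(y) - delta_j x_j`` and ``dy_i = rho_i (x_i - y_i)``; a fixed
    point ``x_j = f_j(y)/delta_j, y = x`` maps to the zero vector.
    """
    n = model.n_genes
    delta = np.array([model.delta_m[j] for j in range(1, n + 1)])
    rho = np.array([model.rho[j] for j in range(1, n + 1)])

    def field(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.any(x < 0) or np.any(y < 0):
            raise ValueError("state components must be nonnegative")
        f = np.array([production_rate(model, j, y) for j in range(1, n + 1)])
        return f - delta * x, rho * (x - y)

    return field


def nondimensionalize(model: GnwModel) -> GnwModel:
    """Set ``delta_j = alpha_basal_j + sum of beta`` over the modules of *j*.

    With this choice the maximal production rate equals the degradation
    rate, so steady-state expression levels lie in [0, 1].  Idempotent.
    """
    delta = {}
    for j in range(1, model.n_genes + 1):
        d = model.alpha_basal[j] + sum(m.beta for m in model.modules.get(j, ()))
        if d <= 0:
            raise ValueError(f"gene {j}: basal rate and module effects are all zero")
        delta[j] = d
    return replace(model, delta_m=delta)


# ---------------------------------------------------------------------------
# Combinatorics of module configurations
# ---------------------------------------------------------------------------

def count_partitions(K: int) -> int:
    """Kth Bell number (number of set partitions of K items), exactly.

    Uses the Bell-triangle recurrence with integer arithmetic.
    """
    if K < 1:
        raise ValueError("K must be a positive integer")
    row = [1]  # triangle row 1; the last entry of row K is B(K)
    for _ in range(K - 1):
        nxt = [row[-1]]
        for v in row:
            nxt.append(nxt[-1] + v)
        row = nxt
    return row[-1]


def set_partitions(items: Sequence[int]) -> Iterator[list[list[int]]]:
    """All set partitions of *items*, each as a sorted list of sorted blocks."""
    items = sorted(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield [sorted([first] + part[i])] + [b for j, b in enumerate(part) if j != i]
        yield [[first]] + part


def _block_options(g: SignedDigraph, j: int, block: Sequence[int]) -> list[ModuleStructure]:
    """Sign-consistent (roles, type, mode) choices for one input block.

    Ordered: independent binding before synergistic, enhancer before
    silencer — matching the conventional listing of the case-study
    configurations.
    """
    opts: list[ModuleStructure] = []
    modes = (0,) if len(block) == 1 else (0, 1)
    for r in modes:
        for c in (1, -1):
            A = frozenset(i for i in block if g.sign[(i, j)] == c)
            D = frozenset(block) - A
            if not A:
                continue
            if len(block) == 1 and D:
                continue
            opts.append(ModuleStructure(frozenset(block), A, D, c, r))
    return opts


def enumerate_module_structures(
    g: SignedDigraph, j: int
) -> list[tuple[ModuleStructure, ...]]:
    """All module structures (partition + roles + types + modes) for gene *j*.

    Returns every way to partition the regulators of *j* into modules and
    assign sign-consistent roles, types and binding modes, as a
    canonically-ordered, duplicate-free list.  Partitions with fewer blocks
    come first (then lexicographically by sorted blocks); within a
    partition, per-block options vary independent-before-synergistic then
    enhancer-before-silencer.  Single-input modules admit only the
    independent single-activator form, so the binding mode does not
    multiply them.  Unregulated genes yield an empty list.
    """
    regs = sorted(g.regulators(j))
    if not regs:
        return []
    parts = sorted(set_partitions(regs), key=lambda p: (len(p), [tuple(b) for b in p]))
    out: list[tuple[ModuleStructure, ...]] = []
    for part in parts:
        per_block = [_block_options(g, j, block) for block in part]
        if any(not opts for opts in per_block):
            continue
        for combo in itertools.product(*per_block):
            out.append(tuple(combo))
    return out


# ---------------------------------------------------------------------------
# Random model sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamRanges:
    """Sampling ranges for the continuous and discrete model parameters.

    These are documented knobs of this package's generator (uniform over
    the stated ranges); the structural constraints — sign consistency, one
    module per TF-target pair, effective silencing via the basal-rate
    offset — are model requirements, the numeric ranges are not.
    """

    k: tuple[float, float] = (0.01, 1.0)
    h_choices: tuple[int, ...] = (1, 2, 3, 4)
    beta: tuple[float, float] = (0.2, 1.0)
    alpha_basal: tuple[float, float] = (0.0, 0.2)
    rho: tuple[float, float] = (0.5, 2.0)


def sample_model(
    g: SignedDigraph,
    seed: int | np.random.Generator,
    ranges: ParamRanges | None = None,
    production: str = "linear",
) -> GnwModel:
    """Draw a random, nondimensionalized model consistent with graph *g*.

    The regulator set of each gene is partitioned uniformly over set
    partitions (enumerated; regulator in-degrees above 10 are rejected),
    each block's type is drawn uniformly among its sign-consistent options
    with mode Bernoulli(1/2) for multi-input blocks, and continuous
    parameters are drawn uniformly from *ranges*.  For genes with silencer
    modules the basal rate is offset by the summed silencer effects so that
    silencing can actually lower expression.  The same seed always yields
    the identical model.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ranges = ranges or ParamRanges()
    n = g.n_vertices

    modules: dict[int, tuple[RegModule, ...]] = {}
    for j in range(1, n + 1):
        regs = sorted(g.regulators(j))
        if not regs:
            modules[j] = ()
            continue
        if len(regs) > 10:
            raise ValueError("uniform partition sampling supports in-degree <= 10")
        parts = sorted(set_partitions(regs), key=lambda p: (len(p), [tuple(b) for b in p]))
        part = parts[rng.integers(len(parts))]
        mods = []
        for block in part:
            opts = _block_options(g, j, block)
            if len(block) > 1:
                # choose type uniformly among consistent c's, mode ~ Bernoulli(1/2)
                r = int(rng.integers(2))
                cs = sorted({o.c for o in opts}, reverse=True)
                c = cs[rng.integers(len(cs))]
                opt = next(o for o in opts if o.c == c and o.r == r)
            else:
                opt = opts[0]
            beta = rng.uniform(*ranges.beta)
            mods.append(RegModule(target=j, structure=opt, beta=beta))
        modules[j] = tuple(mods)

    alpha, rho_p, kk, hh = {}, {}, {}, {}
    for j in range(1, n + 1):
        sil = sum(m.beta for m in modules[j] if m.c == -1)
        alpha[j] = sil + rng.uniform(*ranges.alpha_basal)
        rho_p[j] = rng.uniform(*ranges.rho)
    for (i, j) in sorted(g.edges):
        kk[(i, j)] = rng.uniform(*ranges.k)
        hh[(i, j)] = int(rng.choice(ranges.h_choices))

    model = GnwModel(
        graph=g, modules=modules, alpha_basal=alpha, k=kk, h=hh,
        rho=rho_p, delta_m={j: 1.0 for j in range(1, n + 1)},
        production=production,
    )
    return nondimensionalize(model)


# ---------------------------------------------------------------------------
# Parameter accounting for the case-study classes
# ---------------------------------------------------------------------------

def _parse_class_id(model_class: str) -> tuple[str, int | None, int | None]:
    mc = model_class.replace(" ", "")
    if mc == "R":
        return "R", None, None
    # F[i,j]+ or F[i,j]-
    if mc.startswith("F[") and mc[-1] in "+-" and mc[-2] == "]":
        try:
            i_s, j_s = mc[2:-2].split(",")
            return "F" + mc[-1], int(i_s), int(j_s)
        except ValueError:
            pass
    raise ValueError(f"unknown model class {model_class!r}")


def count_parameters(model_class: str, S: int) -> int:
    """Free-parameter count of a case-study class when fitting *S* trajectory sets.

    Uses the per-edge accounting convention ``2*n_genes + 2*n_edges +
    sum_j max(n_modules_j - 1, 0)`` for the continuous dynamics parameters
    (basal rates and translation rates per gene; Michaelis-Menten constants
    and module effects per edge; one increment per extra module), plus 10
    initial conditions (5 mRNA + 5 protein) per trajectory set.  Class ids:
    ``"F[i,j]+"``, ``"F[i,j]-"`` (flowering configurations) and ``"R"``
    (repressilator).
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    kind, i, j = _parse_class_id(model_class)
    if kind == "R":
        n_genes, n_edges, extra = 5, 5, 0
    else:
        if not (1 <= i <= 3 and 1 <= j <= 5):
            raise ValueError(f"invalid flowering configuration [{i},{j}]")
        n_genes, n_edges = 5, 7
        # configuration 3 for gene 3 and configuration 5 for gene 5 are the
        # two-module forms; each adds one module beyond one-per-gene
        extra = int(i == 3) + int(j == 5)
    return 2 * n_genes + 2 * n_edges + extra + 10 * S


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def _edge_key(e: tuple[int, int]) -> str:
    return f"{e[0]}->{e[1]}"


def _parse_edge(s: str) -> tuple[int, int]:
    i, j = s.split("->")
    return int(i), int(j)


def model_to_json(model: GnwModel, seed: int | None = None) -> str:
    """Serialize a model (graph, modules, parameters) to a JSON string."""
    g = model.graph
    doc = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "production": model.production,
        "graph": {
            "n_vertices": g.n_vertices,
            "edges": [
                {"source": i, "target": j, "sign": g.sign[(i, j)]}
                for (i, j) in sorted(g.edges)
            ],
            "labels": {str(i): name for i, name in sorted(g.labels.items())},
        },
        "modules": [
            {
                "target": m.target,
                "inputs": sorted(m.inputs),
                "activators": sorted(m.activators),
                "deactivators": sorted(m.deactivators),
                "c": m.c,
                "r": m.r,
                "beta": m.beta,
            }
            for j in sorted(model.modules)
            for m in model.modules[j]
        ],
        "alpha_basal": {str(j): model.alpha_basal[j] for j in sorted(model.alpha_basal)},
        "rho": {str(j): model.rho[j] for j in sorted(model.rho)},
        "delta_m": {str(j): model.delta_m[j] for j in sorted(model.delta_m)},
        "k": {_edge_key(e): model.k[e] for e in sorted(model.k)},
        "h": {_edge_key(e): model.h[e] for e in sorted(model.h)},
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def model_from_json(text: str) -> GnwModel:
    """Inverse of :func:`model_to_json`."""
    doc = json.loads(text)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {doc.get('schema_version')!r}")
    gdoc = doc["graph"]
    g = SignedDigraph(
        n_vertices=gdoc["n_vertices"],
        sign={(e["source"], e["target"]): e["sign"] for e in gdoc["edges"]},
        labels={int(i): name for i, name in gdoc.get("labels", {}).items()},
    )
    modules: dict[int, list[RegModule]] = {j: [] for j in range(1, g.n_vertices + 1)}
    for md in doc["modules"]:
        s = ModuleStructure(
            inputs=frozenset(md["inputs"]),
            activators=frozenset(md["activators"]),
            deactivators=frozenset(md["deactivators"]),
            c=md["c"], r=md["r"],
        )
        modules[md["target"]].append(RegModule(md["target"], s, md["beta"]))
    return GnwModel(
        graph=g,
        modules={j: tuple(ms) for j, ms in modules.items()},
        alpha_basal={int(j): v for j, v in doc["alpha_basal"].items()},
        rho={int(j): v for j, v in doc["rho"].items()},
        delta_m={int(j): v for j, v in doc["delta_m"].items()},
        k={_parse_edge(s): v for s, v in doc["k"].items()},
        h={_parse_edge(s): int(v) for s, v in doc["h"].items()},
        production=doc.get("production", "linear"),
    )
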