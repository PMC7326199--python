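"""The five-gene flowering-network case study.

Three signed graphs over the genes (E1, COL1a, FT4, FT2a, AP1a):

* ``F[i,j]+`` — the core flowering network with COL1a *activating* E1;
  gene 3 (FT4) admits 3 module configurations and gene 5 (AP1a) admits 5,
  indexed ``[i, j]`` in the canonical enumeration order, giving 15 ODE
  classes per graph.
* ``F[i,j]-`` — identical except COL1a *represses* E1.
* ``R`` — an arbitrary five-gene repressilator (every gene silenced by one
  other), for comparison.

All case-study classes use the as-printed outer clip ``max(rate, 0)`` on
the production term (production mode ``"clip"``), Hill constants fixed at a
known small integer, and derived degradation rates (nondimensionalization),
so steady-state expression sits in [0, 1] and the free continuous
parameters are the basal rates, translation rates, Michaelis-Menten
constants, module effects, and per-set initial conditions.

The cross-model experiment generates multi-shot data from one class (or
from reflected Brownian motion) and fits another class to it by
basin-hopping least squares; classes sharing the data-generating graph fit
markedly better once the problem is overdetermined.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Mapping, Sequence

import numpy as np

from . import _kernel, fitting
from .gnw import (
    GnwModel, ModuleStructure, RegModule, enumerate_module_structures,
    model_from_json, nondimensionalize,
)
from .graphs import (
    SignedDigraph, flowering_graph, flowering_graph_minus, repressilator_graph,
)
from .simulate import (
    DEFAULT_TIMES, ExpressionDataset, brownian_dataset, generate_dataset,
    integrate_sets,
)

__all__ = [
    "CaseStudyClass",
    "case_study_class",
    "normalize_class_id",
    "build_case_model",
    "true_model",
    "generate_case_dataset",
    "run_fit_experiment",
]

DEFAULT_HILL = 2
#: Bounds for the continuous dynamics parameters (nondimensionalized scale)
#: and the per-set initial conditions.
DYN_BOUNDS = (1e-6, 10.0)
IC_BOUNDS = (0.0, 1.0)

_ALIASES = {
    "F11P": "F[1,1]+", "F11M": "F[1,1]-", "F35P": "F[3,5]+", "F35M": "F[3,5]-",
    "B": "B", "R": "R",
}


def normalize_class_id(class_id: str) -> str:
    """Accept both ``F[1,1]+`` and the CLI shorthand ``F11p`` spellings."""
    cid = class_id.strip()
    up = cid.upper().replace("-", "M").replace("+", "P") if "[" not in cid else cid
    if "[" in cid:
        return cid.replace(" ", "")
    if up in _ALIASES:
        return _ALIASES[up]
    raise ValueError(f"unknown class id {class_id!r}")


def _class_graph(class_id: str) -> SignedDigraph:
    if class_id == "R":
        return repressilator_graph()
    if class_id.endswith("+"):
        return flowering_graph()
    if class_id.endswith("-"):
        return flowering_graph_minus()
    raise ValueError(f"unknown class id {class_id!r}")


@dataclass(frozen=True)
class CaseStudyClass:
    """One ODE model class of the case study: a graph plus a module
    configuration for every regulated gene, with fixed Hill constants."""

    class_id: str
    graph: SignedDigraph
    structures: Mapping[int, tuple[ModuleStructure, ...]]
    hill: int = DEFAULT_HILL
    times: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "structures", dict(self.structures))
        if self.times is None:
            object.__setattr__(self, "times", DEFAULT_TIMES.copy())

    @property
    def n_genes(self) -> int:
        return self.graph.n_vertices

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(self.graph.edges)

    @property
    def module_index(self) -> list[tuple[int, ModuleStructure]]:
        """Modules in canonical order: genes ascending, blocks in structure order."""
        return [
            (j, s)
            for j in sorted(self.structures)
            for s in self.structures[j]
        ]

    def parameter_names(self, S: int) -> list[str]:
        """Names of the free parameters: per-gene basal and translation
        rates, per-edge Michaelis-Menten constants, per-module effects,
        then 2n initial conditions per trajectory set."""
        n = self.n_genes
        names = [f"alpha_{j}" for j in range(1, n + 1)]
        names += [f"rho_{j}" for j in range(1, n + 1)]
        names += [f"k_{i}->{j}" for (i, j) in self.edges]
        names += [
            f"beta_{'.'.join(map(str, sorted(s.inputs)))}:{j}"
            for (j, s) in self.module_index
        ]
        for s_idx in range(1, S + 1):
            names += [f"x0_{s_idx}_{g}" for g in range(1, n + 1)]
            names += [f"y0_{s_idx}_{g}" for g in range(1, n + 1)]
        return names

    @property
    def n_dynamics_parameters(self) -> int:
        return 2 * self.n_genes + len(self.edges) + len(self.module_index)

    def n_parameters(self, S: int) -> int:
        return self.n_dynamics_parameters + 2 * self.n_genes * S

    def bounds(self, S: int) -> tuple[np.ndarray, np.ndarray]:
        nd, nic = self.n_dynamics_parameters, 2 * self.n_genes * S
        lo = np.concatenate([np.full(nd, DYN_BOUNDS[0]), np.full(nic, IC_BOUNDS[0])])
        hi = np.concatenate([np.full(nd, DYN_BOUNDS[1]), np.full(nic, IC_BOUNDS[1])])
        return lo, hi

    def ic_mask(self, S: int) -> np.ndarray:
        nd, nic = self.n_dynamics_parameters, 2 * self.n_genes * S
        return np.concatenate([np.zeros(nd, dtype=bool), np.ones(nic, dtype=bool)])

    # -- model construction -------------------------------------------------

    def build_model(self, theta_dyn: np.ndarray) -> GnwModel:
        """Assemble the (nondimensionalized, clipped-production) model from
        the dynamics part of a parameter vector."""
        n = self.n_genes
        theta_dyn = np.asarray(theta_dyn, dtype=float)
        if len(theta_dyn) != self.n_dynamics_parameters:
            raise ValueError(
                f"expected {self.n_dynamics_parameters} dynamics parameters, "
                f"got {len(theta_dyn)}"
            )
        alpha = {j: float(theta_dyn[j - 1]) for j in range(1, n + 1)}
        rho = {j: float(theta_dyn[n + j - 1]) for j in range(1, n + 1)}
        k = {
            e: float(theta_dyn[2 * n + idx]) for idx, e in enumerate(self.edges)
        }
        off = 2 * n + len(self.edges)
        modules: dict[int, list[RegModule]] = {j: [] for j in range(1, n + 1)}
        for idx, (j, s) in enumerate(self.module_index):
            modules[j].append(RegModule(j, s, float(theta_dyn[off + idx])))
        model = GnwModel(
            graph=self.graph,
            modules={j: tuple(ms) for j, ms in modules.items()},
            alpha_basal=alpha,
            k=k,
            h={e: self.hill for e in self.edges},
            rho=rho,
            delta_m={j: 1.0 for j in range(1, n + 1)},
            production="clip",
        )
        return nondimensionalize(model)

    def theta_from_model(self, model: GnwModel) -> np.ndarray:
        """Dynamics parameter vector of a model with this class's structure."""
        n = self.n_genes
        theta = [model.alpha_basal[j] for j in range(1, n + 1)]
        theta += [model.rho[j] for j in range(1, n + 1)]
        theta += [model.k[e] for e in self.edges]
        for (j, s) in self.module_index:
            m = next(mm for mm in model.modules[j] if mm.structure == s)
            theta.append(m.beta)
        return np.asarray(theta, dtype=float)

    # -- fast trajectory predictor ------------------------------------------

    def _module_arrays(self) -> dict[str, np.ndarray]:
        """Padded positional encoding of the module layout for the kernel."""
        edges = self.edges
        edge_pos = {e: idx for idx, e in enumerate(edges)}
        mods = self.module_index
        M = len(mods)
        P = max(max((len(s.activators), len(s.deactivators))) for _, s in mods)
        arr = {
            "mt": np.empty(M, dtype=np.int64),
            "mc": np.empty(M, dtype=np.int64),
            "mr": np.empty(M, dtype=np.int64),
            "mb": np.arange(M, dtype=np.int64),
            "a_idx": np.zeros((M, P), dtype=np.int64),
            "a_edge": np.zeros((M, P), dtype=np.int64),
            "a_n": np.empty(M, dtype=np.int64),
            "d_idx": np.zeros((M, P), dtype=np.int64),
            "d_edge": np.zeros((M, P), dtype=np.int64),
            "d_n": np.empty(M, dtype=np.int64),
        }
        for m_idx, (j, s) in enumerate(mods):
            arr["mt"][m_idx] = j - 1
            arr["mc"][m_idx] = s.c
            arr["mr"][m_idx] = s.r
            a = sorted(s.activators)
            d = sorted(s.deactivators)
            arr["a_n"][m_idx] = len(a)
            arr["d_n"][m_idx] = len(d)
            for p, i in enumerate(a):
                arr["a_idx"][m_idx, p] = i - 1
                arr["a_edge"][m_idx, p] = edge_pos[(i, j)]
            for p, i in enumerate(d):
                arr["d_idx"][m_idx, p] = i - 1
                arr["d_edge"][m_idx, p] = edge_pos[(i, j)]
        return arr

    def make_predictor(
        self,
        S: int,
        times: Sequence[float] | None = None,
        rk4_step: float = 0.02,
        use_kernel: bool | None = None,
    ) -> Callable[[np.ndarray], np.ndarray]:
        """Compile ``theta -> S x T x n`` predicted mRNA tensor.

        Bypasses model-object construction: the module structure is fixed,
        so only parameter arrays change between objective evaluations.
        Trajectories come from fixed-step classical RK4 stacked over all
        trajectory sets (global error ~ step**4, far below fitting-loss
        scales), through the numba kernel when available or an equivalent
        numpy path otherwise (``use_kernel`` forces the choice; the test
        suite asserts both paths agree).
        """
        n = self.n_genes
        times = np.asarray(DEFAULT_TIMES if times is None else times, dtype=float)
        n_edges = len(self.edges)
        hill = float(self.hill)
        nd = self.n_dynamics_parameters
        arr = self._module_arrays()
        n_steps_per_unit = int(np.ceil(1.0 / rk4_step))
        if use_kernel is None:
            use_kernel = _kernel.HAVE_NUMBA

        def predict(theta: np.ndarray) -> np.ndarray:
            theta = np.asarray(theta, dtype=float)
            alpha = theta[:n].copy()
            rho = theta[n: 2 * n].copy()
            kvals = theta[2 * n: 2 * n + n_edges].copy()
            betas = theta[2 * n + n_edges: nd].copy()
            ics = theta[nd:].reshape(S, 2 * n).copy()
            if use_kernel:
                return _kernel.simulate_rk4(
                    ics, times, n_steps_per_unit, alpha, rho, kvals, betas,
                    hill, arr["mt"], arr["mc"], arr["mr"], arr["mb"],
                    arr["a_idx"], arr["a_edge"], arr["a_n"],
                    arr["d_idx"], arr["d_edge"], arr["d_n"],
                )
            return self._predict_numpy(
                ics, times, n_steps_per_unit, alpha, rho, kvals, betas, hill, arr
            )

        return predict

    def _predict_numpy(
        self, ics, times, n_steps_per_unit, alpha, rho, kvals, betas, hill, arr
    ) -> np.ndarray:
        n = self.n_genes
        S = ics.shape[0]
        delta = alpha.copy()
        np.add.at(delta, arr["mt"], betas[arr["mb"]])
        M_count = len(arr["mt"])

        def rhs(st: np.ndarray) -> np.ndarray:
            st = np.maximum(st, 0.0)
            x, y = st[:, :n], st[:, n:]
            rate = np.tile(alpha, (S, 1))
            for m in range(M_count):
                an, dn = arr["a_n"][m], arr["d_n"][m]
                ai, ae = arr["a_idx"][m, :an], arr["a_edge"][m, :an]
                di, de = arr["d_idx"][m, :dn], arr["d_edge"][m, :dn]
                nu_a = (y[:, ai] / kvals[ae]) ** hill
                if arr["mr"][m] == 0:
                    M = np.prod(nu_a / (1.0 + nu_a), axis=1)
                    if dn:
                        nu_d = (y[:, di] / kvals[de]) ** hill
                        M *= np.prod(1.0 / (1.0 + nu_d), axis=1)
                else:
                    p_a = np.prod(nu_a, axis=1)
                    if dn:
                        p_d = np.prod((y[:, di] / kvals[de]) ** hill, axis=1)
                        M = p_a / (1.0 + p_a + p_a * p_d)
                    else:
                        M = p_a / (1.0 + p_a)
                rate[:, arr["mt"][m]] += arr["mc"][m] * betas[arr["mb"][m]] * M
            rate = np.maximum(rate, 0.0)
            return np.hstack([rate - delta * x, rho * (x - y)])

        state = ics.copy()
        out = np.empty((len(times), S, n))
        out[0] = np.maximum(state[:, :n], 0.0)
        t = times[0]
        for t_idx in range(1, len(times)):
            span = times[t_idx] - t
            n_sub = max(1, int(np.ceil(span * n_steps_per_unit)))
            h = span / n_sub
            for _ in range(n_sub):
                k1 = rhs(state)
                k2 = rhs(state + (h / 2) * k1)
                k3 = rhs(state + (h / 2) * k2)
                k4 = rhs(state + h * k3)
                state = state + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
            t = times[t_idx]
            out[t_idx] = np.maximum(state[:, :n], 0.0)
        return out.transpose(1, 0, 2)


@lru_cache(maxsize=None)
def case_study_class(class_id: str, hill: int = DEFAULT_HILL) -> CaseStudyClass:
    """Build a case-study class from its id (``F[i,j]+``, ``F[i,j]-``, ``R``)."""
    cid = normalize_class_id(class_id)
    if cid == "B":
        raise ValueError("'B' names the Brownian data generator, not an ODE class")
    g = _class_graph(cid)
    structures: dict[int, tuple[ModuleStructure, ...]] = {}
    if cid == "R":
        for j in range(1, 6):
            structures[j] = enumerate_module_structures(g, j)[0]
    else:
        i_cfg, j_cfg = (int(c) for c in cid[2:-2].split(","))
        options3 = enumerate_module_structures(g, 3)
        options5 = enumerate_module_structures(g, 5)
        if not (1 <= i_cfg <= len(options3) and 1 <= j_cfg <= len(options5)):
            raise ValueError(f"invalid configuration [{i_cfg},{j_cfg}]")
        for j in (1, 2, 4):
            structures[j] = enumerate_module_structures(g, j)[0]
        structures[3] = options3[i_cfg - 1]
        structures[5] = options5[j_cfg - 1]
    return CaseStudyClass(class_id=cid, graph=g, structures=structures, hill=hill)


def build_case_model(class_id: str, params: np.ndarray | Mapping[str, float]) -> GnwModel:
    """Assemble a case-study model from a dynamics parameter vector or a
    name->value mapping over :meth:`CaseStudyClass.parameter_names`."""
    cls = case_study_class(class_id)
    if isinstance(params, Mapping):
        names = cls.parameter_names(S=0)
        theta = np.array([params[nm] for nm in names])
    else:
        theta = np.asarray(params, dtype=float)
    return cls.build_model(theta)


# ---------------------------------------------------------------------------
# Canonical data-generating model
# ---------------------------------------------------------------------------

def true_model() -> GnwModel:
    """The fixed ``F[1,1]+`` model used to generate the synthetic datasets.

    A single documented draw of the random parameter generator restricted
    to the ``[1,1]`` configuration with Hill constants fixed at 2, shipped
    as a JSON fixture so every experiment reuses the identical dynamics.
    """
    text = (
        importlib.resources.files("grnode.data")
        .joinpath("f11p_true_model.json")
        .read_text()
    )
    return model_from_json(text)


def generate_case_dataset(
    data_class: str,
    S: int,
    seed: int,
    times: Sequence[float] | None = None,
) -> ExpressionDataset:
    """Synthetic data from the canonical model (``F[1,1]+``) or the
    reflected-Brownian null (``B``)."""
    cid = normalize_class_id(data_class)
    if cid == "B":
        return brownian_dataset(S, times=times, n=5, seed=seed)
    if cid != "F[1,1]+":
        raise ValueError("datasets are generated from F[1,1]+ or B only")
    return generate_dataset(true_model(), S, times=times, seed=seed,
                            provenance="F[1,1]+")


# ---------------------------------------------------------------------------
# Cross-model fitting experiment
# ---------------------------------------------------------------------------

def fit_class_to_dataset(
    fit_class: str,
    dataset: ExpressionDataset,
    seed: int,
    budget: int = 8,
    rk4_step: float = 0.02,
    max_nfev: int | None = 3000,
    x0: np.ndarray | None = None,
) -> fitting.FitResult:
    """Fit one case-study class to a dataset by basin-hopping least squares.

    Dynamics parameters are shared across trajectory sets; each set
    contributes 2n free initial conditions.
    """
    cls = case_study_class(fit_class)
    S = dataset.n_sets
    predict = cls.make_predictor(S, times=dataset.times, rk4_step=rk4_step)
    return fitting.fit(
        predict, dataset.values, cls.bounds(S), seed=seed, budget=budget,
        ic_mask=cls.ic_mask(S), x0=x0, max_nfev=max_nfev,
    )


def run_fit_experiment(
    data_class: str,
    fit_class: str,
    S: int,
    seeds: Sequence[int],
    budget: int = 8,
    rk4_step: float = 0.02,
    max_nfev: int | None = None,
) -> dict:
    """One cell of the cross-model fitting tables.

    For each seed, generates a fresh dataset (new initial conditions; the
    dynamics of the generating model are always the same) and runs a
    seeded fit; reports the mean loss and mean pooled R^2 over seeds.
    """
    data_cid = normalize_class_id(data_class)
    fit_cid = normalize_class_id(fit_class)
    per_seed = []
    for s in seeds:
        ds = generate_case_dataset(data_cid, S, seed=s)
        res = fit_class_to_dataset(
            fit_cid, ds, seed=s + 1, budget=budget,
            rk4_step=rk4_step, max_nfev=max_nfev,
        )
        per_seed.append(res)
    return {
        "data_class": data_cid,
        "fit_class": fit_cid,
        "S": S,
        "seeds": list(seeds),
        "loss": float(np.mean([r.loss for r in per_seed])),
        "r_squared": float(np.mean([r.r_squared for r in per_seed])),
        "per_seed": per_seed,
    }
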