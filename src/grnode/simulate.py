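"""Trajectory simulation and synthetic expression datasets.

Datasets are *multi-shot*: every time point of a trajectory set comes from
the same simulated individual (one initial condition), and only the mRNA
variables are recorded — protein concentrations are hidden state.  Distinct
individuals (trajectory sets) share the dynamics parameters and differ only
in their initial conditions, drawn uniformly from [0, 1].

A reflected-Brownian-motion generator provides structureless null datasets
on the same grid, for calibrating how well a mechanistic model can fit
arbitrary bounded curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .gnw import GnwModel, production_rate

__all__ = [
    "ExpressionDataset",
    "compile_rhs",
    "integrate",
    "generate_dataset",
    "one_shot_dataset",
    "brownian_dataset",
    "write_dataset_csv",
    "read_dataset_csv",
]


@dataclass(frozen=True)
class ExpressionDataset:
    """Observed mRNA levels: an ``S x T x n`` tensor with its sampling grid.

    ``initial_conditions`` holds one length-``2n`` vector ``(x(0), y(0))``
    per set; ``provenance`` names the generating model (or ``"brownian"``).
    """

    values: np.ndarray
    times: np.ndarray
    initial_conditions: np.ndarray
    seed: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        times = np.asarray(self.times, dtype=float)
        ics = np.asarray(self.initial_conditions, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "initial_conditions", ics)
        if values.ndim != 3:
            raise ValueError("values must be an S x T x n tensor")
        S, T, n = values.shape
        if times.shape != (T,):
            raise ValueError("times length must match the tensor's T axis")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if ics.shape != (S, 2 * n):
            raise ValueError("need one length-2n initial-condition vector per set")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("values must be finite and nonnegative")

    @property
    def n_sets(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def n_genes(self) -> int:
        return self.values.shape[2]


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def compile_rhs(model: GnwModel) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build a vectorized right-hand side for stacked states.

    The returned callable accepts a flat state of ``n_sets * 2n`` entries
    (``n_sets`` independent copies of the dynamics, concatenated
    ``(x, y)`` blocks) and is pure numpy, so the same compiled field serves
    single trajectories and batched multi-set objective evaluations.
    Production modes ``linear`` and ``clip`` are vectorized; ``truncated``
    falls back to the scalar expectation formula per gene and set.

    State components are clamped at 0 before evaluating production terms:
    trajectories are physically nonnegative and adaptive solvers may
    momentarily probe tiny negative values.
    """
    n = model.n_genes
    alpha = np.array([model.alpha_basal[j] for j in range(1, n + 1)])
    delta = np.array([model.delta_m[j] for j in range(1, n + 1)])
    rho = np.array([model.rho[j] for j in range(1, n + 1)])
    # per-module arrays: (target_index0, act_idx0, act_k, act_h, deact_idx0,
    #                     deact_k, deact_h, c*beta, mode)
    mods = []
    for j in range(1, n + 1):
        for m in model.modules.get(j, ()):
            a = sorted(m.activators)
            d = sorted(m.deactivators)
            mods.append((
                j - 1,
                np.array(a, dtype=int) - 1,
                np.array([model.k[(i, j)] for i in a]),
                np.array([model.h[(i, j)] for i in a], dtype=float),
                np.array(d, dtype=int) - 1,
                np.array([model.k[(i, j)] for i in d]),
                np.array([model.h[(i, j)] for i in d], dtype=float),
                m.c * m.beta,
                m.r,
            ))
    truncated = model.production == "truncated"
    clip = model.production == "clip"

    def production_batch(y: np.ndarray) -> np.ndarray:
        # y: (n_sets, n) -> (n_sets, n)
        rate = np.tile(alpha, (y.shape[0], 1))
        for (t0, ai, ak, ah, di, dk, dh, cbeta, r) in mods:
            nu_a = (y[:, ai] / ak) ** ah
            nu_d = (y[:, di] / dk) ** dh if len(di) else None
            if r == 0:
                M = np.prod(nu_a / (1.0 + nu_a), axis=1)
                if nu_d is not None:
                    M *= np.prod(1.0 / (1.0 + nu_d), axis=1)
            else:
                p_a = np.prod(nu_a, axis=1)
                if nu_d is None:
                    M = p_a / (1.0 + p_a)
                else:
                    p_d = np.prod(nu_d, axis=1)
                    M = p_a / (1.0 + p_a + p_a * p_d)
            rate[:, t0] += cbeta * M
        return np.maximum(rate, 0.0) if clip else rate

    def rhs(t: float, state: np.ndarray) -> np.ndarray:
        st = np.maximum(state.reshape(-1, 2 * n), 0.0)
        x, y = st[:, :n], st[:, n:]
        if truncated:
            f = np.array([
                [production_rate(model, j, yi) for j in range(1, n + 1)]
                for yi in y
            ])
        else:
            f = production_batch(y)
        dx = f - delta * x
        dy = rho * (x - y)
        return np.concatenate([dx, dy], axis=1).ravel()

    return rhs


def integrate(
    model: GnwModel,
    x0: Sequence[float],
    y0: Sequence[float],
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> np.ndarray:
    """Solve the initial value problem and sample the solution at *times*.

    Returns a ``T x 2n`` array with columns ``(x_1..x_n, y_1..y_n)``.
    Solver failures raise ``RuntimeError`` with the solver's diagnostics.
    """
    x0 = np.asarray(x0, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(x0 < 0) or np.any(y0 < 0):
        raise ValueError("initial conditions must be nonnegative")
    if times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing and start at 0")
    rhs = compile_rhs(model)
    sol = solve_ivp(
        rhs, (0.0, float(times[-1])), np.concatenate([x0, y0]),
        t_eval=times, method=method, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    return sol.y.T


def integrate_sets(
    model: GnwModel,
    ics: np.ndarray,
    times: Sequence[float],
    rk4_step: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate several trajectory sets at once; returns ``S x T x 2n``.

    All sets share the dynamics, so they are stacked into one system and
    solved in a single call.  With ``rk4_step`` set, a fixed-step classical
    Runge-Kutta scheme replaces the adaptive solver — used in fitting
    objectives where millions of cheap, smooth solves matter more than
    adaptive error control (global error ~ step**4, far below fitting loss
    scales for step <= 0.05).
    """
    ics = np.asarray(ics, dtype=float)
    times = np.asarray(times, dtype=float)
    S = ics.shape[0]
    rhs = compile_rhs(model)
    state0 = ics.ravel()
    if rk4_step is None:
        sol = solve_ivp(
            rhs, (0.0, float(times[-1])), state0,
            t_eval=times, method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed: {sol.message}")
        traj = sol.y.T  # (T, S*2n)
    else:
        traj = _rk4(rhs, state0, times, rk4_step)
    n2 = ics.shape[1]
    return traj.reshape(len(times), S, n2).transpose(1, 0, 2)


def _rk4(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    state0: np.ndarray,
    times: np.ndarray,
    step: float,
) -> np.ndarray:
    out = np.empty((len(times), len(state0)))
    out[0] = state0
    state = state0.astype(float)
    t = times[0]
    for idx in range(1, len(times)):
        t_next = times[idx]
        n_sub = max(1, int(np.ceil((t_next - t) / step)))
        h = (t_next - t) / n_sub
        for _ in range(n_sub):
            k1 = rhs(t, state)
            k2 = rhs(t + h / 2, state + h / 2 * k1)
            k3 = rhs(t + h / 2, state + h / 2 * k2)
            k4 = rhs(t + h, state + h * k3)
            state = state + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        t = t_next
        out[idx] = state
    return out


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

DEFAULT_TIMES = np.arange(7.0)  # t = 0, 1, ..., 6


def generate_dataset(
    model: GnwModel,
    S: int,
    times: Sequence[float] | None = None,
    seed: int | np.random.Generator = 0,
    provenance: str = "model",
) -> ExpressionDataset:
    """Multi-shot synthetic data: *S* independent Uniform(0,1) initial
    conditions, shared dynamics, mRNA sampled at *times*.

    With the default 7-point grid and 5 genes each set contributes
    ``7 * 5 = 35`` observed values.
    """
    if S < 1:
        raise ValueError("need at least one trajectory set")
    times = DEFAULT_TIMES if times is None else np.asarray(times, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)
    n = model.n_genes
    ics = rng.uniform(0.0, 1.0, size=(S, 2 * n))
    traj = integrate_sets(model, ics, times)
    x_obs = np.clip(traj[:, :, :n], 0.0, None)  # solver roundoff guard
    return ExpressionDataset(
        values=x_obs, times=times, initial_conditions=ics,
        seed=seed_val, provenance=provenance,
    )


def one_shot_dataset(
    model: GnwModel,
    S: int,
    times: Sequence[float] | None = None,
    seed: int | np.random.Generator = 0,
    provenance: str = "model-oneshot",
) -> ExpressionDataset:
    """One-shot sampling: every observation comes from a distinct individual.

    For each set ``s`` and time index ``t`` an independent Uniform(0,1)
    initial condition is drawn and only that individual's mRNA at
    ``times[t]`` is recorded, mimicking destructive sampling where each
    individual is measured once.  The dataset shape matches the multi-shot
    design (``S x T x n``) so the two designs are directly comparable; the
    stored initial conditions are those of each set's *first* individual.
    The case-study experiments use multi-shot data only.
    """
    if S < 1:
        raise ValueError("need at least one trajectory set")
    times = DEFAULT_TIMES if times is None else np.asarray(times, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)
    n = model.n_genes
    T = len(times)
    ics = rng.uniform(0.0, 1.0, size=(S, T, 2 * n))
    traj = integrate_sets(model, ics.reshape(S * T, 2 * n), times)
    traj = traj.reshape(S, T, T, 2 * n)
    # individual (s, t) contributes its state at times[t] only
    values = np.clip(
        np.stack([traj[:, t, t, :n] for t in range(T)], axis=1), 0.0, None
    )
    return ExpressionDataset(
        values=values, times=times, initial_conditions=ics[:, 0, :],
        seed=seed_val, provenance=provenance,
    )


def _fold01(z: np.ndarray) -> np.ndarray:
    """Reflect real values into [0, 1] by folding at both boundaries."""
    return 1.0 - np.abs(1.0 - np.mod(z, 2.0))


def brownian_dataset(
    S: int,
    times: Sequence[float] | None = None,
    n: int = 5,
    variance_rate: float = 0.05,
    seed: int | np.random.Generator = 0,
    return_unreflected: bool = False,
) -> ExpressionDataset | tuple[ExpressionDataset, np.ndarray]:
    """Reflected Brownian motion null data on the sampling grid.

    Per set and gene, a discretized Brownian path started at Uniform(0,1)
    with increment variance ``variance_rate * dt``, reflected into [0, 1]
    by folding.  ``return_unreflected=True`` additionally returns the raw
    (unreflected) paths so increment statistics can be verified.
    """
    if variance_rate <= 0:
        raise ValueError("variance_rate must be positive")
    times = DEFAULT_TIMES if times is None else np.asarray(times, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)
    T = len(times)
    start = rng.uniform(0.0, 1.0, size=(S, 1, n))
    dt = np.diff(times).reshape(1, T - 1, 1)
    incr = rng.normal(0.0, 1.0, size=(S, T - 1, n)) * np.sqrt(variance_rate * dt)
    raw = np.concatenate([start, start + np.cumsum(incr, axis=1)], axis=1)
    values = _fold01(raw)
    ics = np.concatenate([values[:, 0, :], np.zeros((S, n))], axis=1)
    ds = ExpressionDataset(
        values=values, times=times, initial_conditions=ics,
        seed=seed_val, provenance="brownian",
    )
    return (ds, raw) if return_unreflected else ds


# ---------------------------------------------------------------------------
# Tidy CSV round-trip
# ---------------------------------------------------------------------------

def write_dataset_csv(ds: ExpressionDataset, path: str | Path) -> None:
    """Write ``set,time,gene,value`` rows plus a JSON sidecar (``<path>.json``)
    holding the grid, seed, provenance and initial conditions."""
    path = Path(path)
    S, T, n = ds.values.shape
    sets, t_idx, genes = np.meshgrid(
        np.arange(1, S + 1), np.arange(T), np.arange(1, n + 1), indexing="ij"
    )
    frame = pd.DataFrame({
        "set": sets.ravel(),
        "time": ds.times[t_idx.ravel()],
        "gene": genes.ravel(),
        "value": ds.values.ravel(),
    })
    frame.to_csv(path, index=False)
    sidecar = {
        "times": ds.times.tolist(),
        "seed": ds.seed,
        "provenance": ds.provenance,
        "initial_conditions": ds.initial_conditions.tolist(),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_dataset_csv(path: str | Path) -> ExpressionDataset:
    """Inverse of :func:`write_dataset_csv`."""
    path = Path(path)
    frame = pd.read_csv(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    times = np.asarray(sidecar["times"], dtype=float)
    sets = np.sort(frame["set"].unique())
    genes = np.sort(frame["gene"].unique())
    S, T, n = len(sets), len(times), len(genes)
    cube = (
        frame.sort_values(["set", "time", "gene"])["value"]
        .to_numpy()
        .reshape(S, T, n)
    )
    return ExpressionDataset(
        values=cube, times=times,
        initial_conditions=np.asarray(sidecar["initial_conditions"], dtype=float),
        seed=sidecar.get("seed"), provenance=sidecar.get("provenance", ""),
    )
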