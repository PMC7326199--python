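"""Shared fixtures: hand-built ODE systems with known monotonicity
structure, and a seeded random-graph helper for ensemble properties."""

from __future__ import annotations

import numpy as np
import pytest

from grnode.csp import OdeSystem
from grnode.graphs import SignedDigraph


@pytest.fixture
def example1_system() -> OdeSystem:
    """Four-gene system whose gene-3 -> gene-4 effect switches sign.

    Genes 1 and 3 form an activating complex on gene 4 while genes 2 and 3
    form a repressing one:

        dx4/dt = x1*x3 / (l1 + x1*x3) * l2 / (l2 + x2*x3)

    (mRNA and protein identified, so all four genes are observables).  The
    partial of this rate in x3 is proportional to ``l1*l2 - x1*x2*x3**2``,
    so gene 3 activates gene 4 below the boundary surface and represses it
    above — no globally constant sign.
    """

    def rhs(state, params):
        l1, l2 = params
        x1, x2, x3 = state[0], state[1], state[2]
        f4 = (x1 * x3) / (l1 + x1 * x3) * l2 / (l2 + x2 * x3)
        return np.array([0.0, 0.0, 0.0, f4])

    def partials(k, l, state, params):
        l1, l2 = params
        x1, x2, x3 = state[0], state[1], state[2]
        if l != 4:
            return 0.0
        da = l1 + x1 * x3
        db = l2 + x2 * x3
        if k == 1:
            return (l1 * x3 / da ** 2) * (l2 / db)
        if k == 2:
            return (x1 * x3 / da) * (-l2 * x3 / db ** 2)
        if k == 3:
            return x1 * l2 * (l1 * l2 - x1 * x2 * x3 ** 2) / (da ** 2 * db ** 2)
        return 0.0

    return OdeSystem(
        n_obs=4, n_unobs=0, rhs=rhs,
        dependency=frozenset({(1, 4), (2, 4), (3, 4)}),
        partials=partials,
    )


@pytest.fixture
def example2_system() -> OdeSystem:
    """Two observed mRNAs linked through a three-protein complex layer.

    mRNA 1 is translated into protein 3, which both joins complex 5
    directly (3 hops from mRNA 1 to mRNA 2) and represses protein 4, the
    complex's other component (a 4-hop path of opposite sign).  The
    complex activates mRNA 2.  Internal classes: 1, 2 observables;
    3, 4, 5 unobservables.
    """

    def rhs(state, params):
        x1, x2, u3, u4, u5 = state[:5]
        return np.array([
            0.3 - x1,
            u5 / (1.0 + u5) - x2,
            x1 - u3,
            1.0 / (1.0 + u3 ** 2) - u4,
            u3 * u4 - u5,
        ])

    dependency = {
        (1, 1), (5, 2), (2, 2),
        (1, 3), (3, 3),
        (3, 4), (4, 4),
        (3, 5), (4, 5), (5, 5),
    }
    return OdeSystem(n_obs=2, n_unobs=3, rhs=rhs, dependency=frozenset(dependency))


def random_signed_digraph(rng: np.random.Generator, n_max: int = 8,
                          p_edge: float = 0.3) -> SignedDigraph:
    """A random signed digraph with at least one edge (test ensembles)."""
    while True:
        n = int(rng.integers(2, n_max + 1))
        sign = {}
        for i in range(1, n + 1):
            for j in range(1, n + 1):
                if i != j and rng.random() < p_edge:
                    sign[(i, j)] = 1 if rng.random() < 0.5 else -1
        if sign:
            return SignedDigraph(n_vertices=n, sign=sign)
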