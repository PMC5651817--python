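"""Generalized Lotka-Volterra (gLV) community dynamics.

The model is the standard pairwise interaction ODE

    y'(t) = diag(y(t)) (r + A y(t))

where ``y`` holds the abundances of ``n`` taxa, ``r`` their intrinsic
growth rates, and ``A`` the interaction matrix: entry ``a_ij`` is the
per-capita influence of taxon ``j`` on the growth of taxon ``i``
(positive = facilitation, negative = inhibition).

Abundances are treated as relative proportions throughout the package;
the gLV form is agnostic to the normalisation, and fitting it to
compositional data is an approximation documented in the methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "CommunityModel",
    "Trajectory",
    "GlvDivergenceError",
    "glv_rhs",
    "simulate",
    "equilibrium_residual",
    "growth_rates_for_equilibrium",
]

#: Trajectories whose any component exceeds this magnitude abort the solve.
OVERFLOW_GUARD = 1e6

#: Negative excursions smaller than this are treated as integrator noise
#: (an order of magnitude above the absolute solver tolerance).
NEGATIVITY_TOL = 1e-8


class GlvDivergenceError(RuntimeError):
    """Raised when a trajectory exceeds the overflow guard.

    Attributes
    ----------
    failure_time : float
        The integration time at which the guard was tripped.
    """

    def __init__(self, failure_time: float):
        self.failure_time = float(failure_time)
        super().__init__(
            f"gLV trajectory exceeded |y| > {OVERFLOW_GUARD:g} at t = "
            f"{failure_time:.6g}; the parameterization is divergent"
        )


@dataclass(frozen=True)
class CommunityModel:
    """A gLV community: taxon labels, growth rates ``r`` and interactions ``A``.

    Parameters
    ----------
    taxa : sequence of str
        Unique taxon labels, ordering fixes the meaning of ``r`` and ``A``.
    r : array-like, shape (n,)
        Intrinsic growth rates (1/time).
    A : array-like, shape (n, n)
        Interaction matrix; ``A[i, j]`` is the influence of taxon ``j``
        on the growth of taxon ``i`` (1/(abundance * time)).
    """

    taxa: tuple[str, ...]
    r: np.ndarray
    A: np.ndarray

    def __init__(self, taxa: Sequence[str], r, A):
        taxa = tuple(str(t) for t in taxa)
        if len(set(taxa)) != len(taxa):
            raise ValueError("taxon labels must be unique")
        r = np.asarray(r, dtype=float).reshape(-1)
        A = np.asarray(A, dtype=float)
        n = len(taxa)
        if r.shape != (n,):
            raise ValueError(f"r has shape {r.shape}, expected ({n},)")
        if A.shape != (n, n):
            raise ValueError(f"A has shape {A.shape}, expected ({n}, {n})")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(A))):
            raise ValueError("r and A must be finite")
        object.__setattr__(self, "taxa", taxa)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "A", A)

    @property
    def n(self) -> int:
        return len(self.taxa)

    def to_json(self) -> str:
        return json.dumps(
            {"taxa": list(self.taxa), "r": self.r.tolist(), "A": self.A.tolist()},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CommunityModel":
        doc = json.loads(text)
        return cls(doc["taxa"], doc["r"], doc["A"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "CommunityModel":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class Trajectory:
    """A simulated abundance time course on a fixed grid."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), n), nonnegative
    taxa: tuple[str, ...] = field(default=())

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float).reshape(-1)
        states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if states.shape[0] != times.shape[0]:
            raise ValueError("states row count must equal len(times)")
        if np.any(states < -NEGATIVITY_TOL):
            raise ValueError("states must be nonnegative (beyond solver tolerance)")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)

    def to_tsv(self, path: str | Path) -> None:
        """Write time column plus one abundance column per taxon."""
        import pandas as pd

        cols = list(self.taxa) if self.taxa else [
            f"taxon_{i}" for i in range(self.states.shape[1])
        ]
        df = pd.DataFrame(self.states, columns=cols)
        df.insert(0, "time", self.times)
        df.to_csv(path, sep="\t", index=False)


def _check_dim(y: np.ndarray, n: int, what: str = "y") -> np.ndarray:
    y = np.asarray(y, dtype=float).reshape(-1)
    if y.shape != (n,):
        raise ValueError(f"{what} has length {y.size}, expected n = {n}")
    return y


def glv_rhs(y, model: CommunityModel) -> np.ndarray:
    """Right-hand side ``diag(y)(r + A y)`` of the gLV system.

    Exact algebraic evaluation; no clipping is applied here.
    """
    y = _check_dim(y, model.n)
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    return y * (model.r + model.A @ y)


def equilibrium_residual(model: CommunityModel, y_bar) -> np.ndarray:
    """Residual ``diag(ȳ)(r + A ȳ)`` of the equilibrium condition.

    Zero iff ``ȳ`` is a fixed point of the dynamics.
    """
    y_bar = _check_dim(y_bar, model.n, "y_bar")
    return y_bar * (model.r + model.A @ y_bar)


def growth_rates_for_equilibrium(A, y_bar) -> np.ndarray:
    """The unique ``r = -A ȳ`` making an interior ``ȳ`` an equilibrium.

    For strictly positive ``ȳ``, ``diag(ȳ)(r + Aȳ) = 0`` forces
    ``r + Aȳ = 0`` componentwise; this eliminates ``r`` from the inverse
    problem.
    """
    A = np.asarray(A, dtype=float)
    y_bar = np.asarray(y_bar, dtype=float).reshape(-1)
    if A.shape != (y_bar.size, y_bar.size):
        raise ValueError(
            f"A has shape {A.shape}, expected ({y_bar.size}, {y_bar.size})"
        )
    if np.any(y_bar <= 0):
        raise ValueError(
            "y_bar must be strictly positive (interior equilibrium required)"
        )
    return -(A @ y_bar)


def simulate(
    model: CommunityModel,
    y0,
    times,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the gLV ODE on a time grid.

    Uses an adaptive stiff-capable solver (LSODA). Small negative
    excursions (< 1e-10 in magnitude, floating-point noise: analytically
    the positive orthant is invariant) are clipped to zero. Any component
    exceeding the overflow guard aborts with :class:`GlvDivergenceError`.
    """
    y0 = _check_dim(y0, model.n, "y0")
    if np.any(y0 < 0):
        raise ValueError("y0 must be nonnegative")
    times = np.asarray(times, dtype=float).reshape(-1)
    if times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing grid of >= 2 points")

    r, A = model.r, model.A

    def rhs(t, y):
        return y * (r + A @ y)

    def overflow(t, y):
        return OVERFLOW_GUARD - np.max(np.abs(y))

    overflow.terminal = True
    overflow.direction = -1

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        y0,
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        events=overflow,
    )
    if sol.status == 1:  # terminated by the overflow event
        raise GlvDivergenceError(sol.t_events[0][0])
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")

    states = sol.y.T.copy()
    if np.any(states < -NEGATIVITY_TOL):
        worst = float(states.min())
        raise RuntimeError(
            f"trajectory went negative beyond tolerance (min = {worst:.3g})"
        )
    np.clip(states, 0.0, None, out=states)
    return Trajectory(times=times, states=states, taxa=model.taxa)
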