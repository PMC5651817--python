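"""Equilibrium- and stability-constrained interaction-matrix inference.

The inverse problem: given a data-determined equilibrium ``ȳ`` (and,
optionally, the longitudinal trajectories it was estimated from), find
interaction matrices ``A`` — with growth rates implied as ``r = -Aȳ`` —
such that ``ȳ`` is an asymptotically stable equilibrium of the gLV
system. The problem is nonconvex and badly underdetermined: many
network configurations admit the same stable equilibrium. It is
therefore solved by *repeated Monte-Carlo-sampled direct search*:
many random starting matrices, each refined by derivative-free compass
search, yielding an ensemble of admissible solutions that is distilled
into a consensus signed network.

The scalar merit function minimised per restart is

    fit_weight * collocation misfit        (only when trajectories given)
    + max(0, spectral_abscissa + margin)^2 (squared stability hinge)
    + sparsity_weight * sum_{i!=j} |a_ij|  (l1, interpretable networks)

Eliminating ``r`` analytically makes the equilibrium constraint exact,
so accepted solutions satisfy it to machine precision. The collocation
misfit matches per-capita growth rates, ``d log y_i / dt = (A(y-ȳ))_i``,
against spline-smoothed finite differences of the observed series; it
is what ties the inferred network to the temporal data rather than to
the equilibrium alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .glv import Trajectory, growth_rates_for_equilibrium
from .networks import SignedEdge, SignedNetwork

__all__ = [
    "SearchConfig",
    "Solution",
    "SolutionEnsemble",
    "NoAdmissibleNetworkError",
    "sample_initial_matrix",
    "collocation_arrays",
    "objective",
    "direct_search",
    "infer_ensemble",
    "consensus_network",
]

#: Max-norm bound on the equilibrium residual of an accepted solution.
RESIDUAL_TOL = 1e-8


@dataclass(frozen=True)
class SearchConfig:
    """Tunables of the repeated Monte-Carlo direct search.

    ``max_iters`` caps the number of objective evaluations per restart;
    ``init_scale`` sets the uniform sampling range of starting matrices;
    the step-size schedule (``step_init``, ``step_contract``,
    ``step_tol``) drives the compass search; ``fit_weight`` scales the
    trajectory-misfit term (ignored when no trajectories are supplied).
    """

    n_restarts: int = 200
    init_scale: float = 0.5
    step_init: float = 0.25
    step_contract: float = 0.5
    step_tol: float = 1e-3
    max_iters: int = 20000
    stability_margin: float = 1e-6
    sparsity_weight: float = 1.0
    fit_weight: float = 1.0
    diag_constraint: bool = True
    accept_tol: float = float("inf")
    subsample_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if not 0.0 < self.step_contract < 1.0:
            raise ValueError("step_contract must lie in (0, 1)")
        if not self.step_tol < self.step_init:
            raise ValueError("step_tol must be smaller than step_init")
        if self.sparsity_weight < 0:
            raise ValueError("sparsity_weight must be nonnegative")
        if self.fit_weight < 0:
            raise ValueError("fit_weight must be nonnegative")
        if self.stability_margin < 0:
            raise ValueError("stability_margin must be nonnegative")
        if self.init_scale <= 0:
            raise ValueError("init_scale must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Solution:
    """One direct-search outcome: a candidate (A, r) with diagnostics."""

    A: np.ndarray
    r: np.ndarray
    objective: float
    spectral_abscissa: float
    accepted: bool
    restart_index: int


@dataclass(frozen=True)
class SolutionEnsemble:
    """All restart outcomes for one equilibrium, admissible or not."""

    solutions: tuple[Solution, ...]
    y_bar: np.ndarray
    taxa: tuple[str, ...]
    config: SearchConfig

    @property
    def accepted(self) -> tuple[Solution, ...]:
        return tuple(s for s in self.solutions if s.accepted)

    def to_json(self) -> str:
        return json.dumps(
            {
                "taxa": list(self.taxa),
                "y_bar": self.y_bar.tolist(),
                "config": self.config.to_dict(),
                "solutions": [
                    {
                        "A": s.A.tolist(),
                        "r": s.r.tolist(),
                        "objective": s.objective,
                        "spectral_abscissa": s.spectral_abscissa,
                        "accepted": s.accepted,
                        "restart_index": s.restart_index,
                    }
                    for s in self.solutions
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SolutionEnsemble":
        doc = json.loads(text)
        return cls(
            solutions=tuple(
                Solution(
                    A=np.asarray(s["A"], dtype=float),
                    r=np.asarray(s["r"], dtype=float),
                    objective=float(s["objective"]),
                    spectral_abscissa=float(s["spectral_abscissa"]),
                    accepted=bool(s["accepted"]),
                    restart_index=int(s["restart_index"]),
                )
                for s in doc["solutions"]
            ),
            y_bar=np.asarray(doc["y_bar"], dtype=float),
            taxa=tuple(doc["taxa"]),
            config=SearchConfig(**doc["config"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "SolutionEnsemble":
        return cls.from_json(Path(path).read_text())


class NoAdmissibleNetworkError(RuntimeError):
    """No restart produced an admissible (stable, equilibrium) solution."""

    def __init__(self, best_objective: float):
        self.best_objective = float(best_objective)
        super().__init__(
            "no admissible network found: every restart violated the "
            f"stability constraint (best objective {best_objective:.6g})"
        )


# ---------------------------------------------------------------------------
# Monte Carlo sampling of starting matrices
# ---------------------------------------------------------------------------

def sample_initial_matrix(rng: np.random.Generator, n: int,
                          init_scale: float) -> np.ndarray:
    """Random starting matrix: off-diagonals uniform on ±init_scale,
    diagonals uniform on [-init_scale, 0] (self-limitation bias — random
    matrices with unconstrained diagonals are almost never stable as the
    community grows)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    A = rng.uniform(-init_scale, init_scale, size=(n, n))
    diag = rng.uniform(-init_scale, 0.0, size=n)
    A[np.diag_indices(n)] = diag
    return A


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def collocation_arrays(
    trajectories: Sequence[Trajectory] | Sequence[tuple],
    floor: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool observed states and per-capita growth estimates for fitting.

    Per trajectory the per-capita growth over each sampling interval,
    ``(log y(t_{k+1}) - log y(t_k)) / (t_{k+1} - t_k)``, is paired with
    the state observed at the interval's *left* endpoint: an abrupt
    community shift inside the interval then enters the growth target
    but never the regressor, so process noise acts as unbiased equation
    error rather than errors-in-variables. The first-order
    discretisation mismatch (the interval-average state differs from
    the left endpoint) is corrected model-consistently inside the
    misfit via a half-step along the candidate model's own flow; see
    :func:`objective`. Returns ``(Y, G, dt)``: states, growth targets
    (each (n_taxa, pooled intervals)) and per-interval durations.
    """
    ys, gs, dts = [], [], []
    for traj in trajectories:
        if isinstance(traj, Trajectory):
            t, states = traj.times, traj.states
        else:
            t, states = traj
            t = np.asarray(t, dtype=float)
            states = np.asarray(states, dtype=float)
        if t.size < 2:
            raise ValueError(
                "collocation needs >= 2 time points per trajectory"
            )
        logy = np.log(np.clip(states, floor, None))  # (m, n)
        dt = np.diff(t)
        g = np.diff(logy, axis=0) / dt[:, None]
        ys.append(states[:-1])
        gs.append(g)
        dts.append(dt)
    Y = np.vstack(ys).T
    G = np.vstack(gs).T
    return Y, G, np.concatenate(dts)


def _taxon_precision_weights(G: np.ndarray) -> np.ndarray:
    """Inverse-variance weights per taxon from the pooled growth targets.

    Rare taxa carry noisier log-derivatives (counting noise); weighting
    rows by the reciprocal pooled variance of their growth target keeps
    them from dominating the misfit. Normalised to mean 1.
    """
    var = G.var(axis=1)
    w = 1.0 / np.maximum(var, 1e-12)
    return w / w.mean()


def _misfit(
    A: np.ndarray,
    P: np.ndarray,
    G: np.ndarray,
    dt: np.ndarray,
    y_bar: np.ndarray,
    weights: np.ndarray | None,
) -> float:
    """Weighted mean squared one-step prediction error of log-composition.

    For every sampling interval the candidate model's simplex-restricted
    gLV flow is integrated forward from the observed left-endpoint
    composition (one classical RK4 step — weekly intervals and growth
    rates below ~1/week keep its truncation error far below the noise),
    and the predicted interval log-slope is compared with the observed
    one. Predicting from the left endpoint only means abrupt in-interval
    community shifts (process noise) enter the target but never the
    predictor, so they act as unbiased equation error.

    Residuals are double-centered before squaring: the per-sample
    precision-weighted mean across taxa absorbs the common compositional
    offset (renormalisation adds the same ``-d log(total)/dt`` to every
    taxon), and the per-taxon mean across samples acts as a free
    intercept absorbing the constant error left by imperfect equilibrium
    estimation (``r = -A ȳ_est`` rather than ``-A ȳ_true``).
    """
    yb = y_bar[:, None]

    def flow(Q):
        growth = Q * (A @ (Q - yb))
        return growth - Q * growth.sum(axis=0)

    half = 0.5 * dt
    k1 = flow(P)
    k2 = flow(np.clip(P + half * k1, 1e-12, None))
    k3 = flow(np.clip(P + half * k2, 1e-12, None))
    k4 = flow(np.clip(P + dt * k3, 1e-12, None))
    P_next = P + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    P_next = np.clip(P_next, 1e-12, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = G - np.log(P_next / P) / dt
    if not np.all(np.isfinite(resid)):
        return float("inf")
    if weights is None:
        resid = resid - resid.mean(axis=0, keepdims=True)
        resid = resid - resid.mean(axis=1, keepdims=True)
        return float(np.mean(np.sum(resid * resid, axis=0)))
    # precision-weighted estimate of the common per-sample offset: the
    # offset is constant across taxa, so any weighted mean removes it
    # exactly, and weighting keeps noisy rare-taxon rows (detection-floor
    # spikes) from leaking into every other taxon's residual
    w = weights[:, None]
    resid = resid - (w * resid).sum(axis=0, keepdims=True) / weights.sum()
    resid = resid - resid.mean(axis=1, keepdims=True)
    resid = resid * np.sqrt(w)
    return float(np.mean(np.sum(resid * resid, axis=0)))


def _weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    """Weighted median: minimiser of ``sum_i w_i |x_i - u|``."""
    order = np.argsort(x)
    x, w = np.asarray(x, float)[order], np.asarray(w, float)[order]
    cum = np.cumsum(w)
    return float(x[np.searchsorted(cum, 0.5 * cum[-1])])


def _adaptive_penalty_scales(
    blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    y_bar: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    """Per-entry l1 scales: each coefficient's soft-threshold tracks its
    own sampling-noise level (adaptive lasso).

    A leave-one-subject-out jackknife of an unpenalised least-squares
    fit yields a standard error for every entry of ``A``; multiplying
    by the local misfit curvature ``2 w_i E[x_j^2]`` converts it into
    the l1 scale that places the soft-threshold for entry (i, j) at
    ``sparsity_weight`` times that standard error — so
    ``sparsity_weight`` acts as a dimensionless significance multiple,
    uniform across entries. Columns driven by slowly-mixing or
    weakly-excited taxa (few effective observations per subject)
    thereby get proportionally stronger shrinkage, which keeps spurious
    edges from such taxa out of the consensus network. The diagonal is
    never penalised.
    """
    n = y_bar.size
    S = len(blocks)
    X_full = np.hstack([b[0] for b in blocks]) - y_bar[:, None]
    ex2 = np.mean(X_full * X_full, axis=1)

    def x_eff(A: np.ndarray, P: np.ndarray, dt: np.ndarray) -> np.ndarray:
        # third-order Taylor advance of the regressor along the pilot's
        # own flow: the growth target responds to the interval-average
        # state, and ignoring that biases the pilot on fast transients
        X = P - y_bar[:, None]
        W = A @ X
        phi = np.sum(P * W, axis=0)
        F = P * (W - phi)
        AF = A @ F
        phid = np.sum(F * W + P * AF, axis=0)
        Fd = F * (W - phi) + P * (AF - phid)
        return X + (0.5 * dt) * F + (dt * dt / 6.0) * Fd

    def ls_fit(idx: list[int]) -> np.ndarray:
        P = np.hstack([blocks[s][0] for s in idx])
        G = np.hstack([blocks[s][1] for s in idx])
        dt = np.concatenate([blocks[s][2] for s in idx])
        w = weights[:, None]
        Gd = G - (w * G).sum(axis=0, keepdims=True) / weights.sum()
        Gd = Gd - Gd.mean(axis=1, keepdims=True)
        A = np.zeros((n, n))
        for _ in range(3):
            Xd = x_eff(A, P, dt)
            Xd = Xd - Xd.mean(axis=1, keepdims=True)
            A = Gd @ Xd.T @ np.linalg.pinv(Xd @ Xd.T, rcond=1e-8,
                                           hermitian=True)
        return A

    if S < 3:
        return np.ones((n, n)) - np.eye(n)
    reps = np.stack([ls_fit([s for s in range(S) if s != k])
                     for k in range(S)])
    beta = reps.mean(axis=0)
    se = np.sqrt((S - 1) / S * np.sum((reps - beta) ** 2, axis=0))
    # Removing the observable common growth mode leaves every *column*
    # of A identifiable only up to an additive constant, and the pilot
    # (fit row-by-row against taxon-centered targets) absorbs that
    # constant as the precision-weighted column mean of the true matrix
    # — a substantial offset dominated by each taxon's self-limitation.
    # Remove it by a weighted-median polish down the columns before
    # judging which entries are genuinely nonzero. (Row shifts — the
    # closure null direction — are left alone: the minimum-norm row
    # shift is tiny because the diagonal offsets the edge sum, and
    # estimating it from few off-diagonal entries is far riskier than
    # the residual it would remove.)
    off = ~np.eye(n, dtype=bool)
    if n >= 5:
        # plain median down each column: true edges are a minority of
        # any column and weighting by precision would let a tight
        # strong edge drag the shift estimate
        v = np.array([
            float(np.median(beta[off[:, j], j])) for j in range(n)
        ])
        pilot = beta - v[None, :]
        # adaptive relaxation: entries whose null-space-resolved pilot
        # clearly exceeds their own noise level (|pilot| > 2 SE) get
        # proportionally lighter shrinkage, so the flat directions
        # resolve toward keeping strong edges rather than
        # redistributing them onto weakly-excited columns
        relax = np.minimum(1.0, 2.0 * se / np.maximum(np.abs(pilot), 1e-12))
    else:
        # too few off-diagonal entries per column to resolve the shift;
        # use one uniform penalty scale (the mean significance scale) so
        # tie-breaking between shift-equivalent sparse patterns is not
        # systematically biased against any row or column, and let the
        # ensemble median centre the sign-preserving ambiguity
        flat = 2.0 * weights[:, None] * ex2[None, :] * se
        scale = np.full((n, n), float(flat[off].mean()))
        scale[np.eye(n, dtype=bool)] = 0.0
        return scale
    scale = 2.0 * weights[:, None] * ex2[None, :] * se * relax
    scale[np.eye(n, dtype=bool)] = 0.0
    return scale


def objective(
    A,
    y_bar,
    config: SearchConfig,
    data: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Scalar merit of a candidate interaction matrix at equilibrium ȳ.

    With ``r`` eliminated as ``-Aȳ`` the equilibrium residual is
    identically zero; what remains is the squared hinge on the spectral
    abscissa of the interior Jacobian ``diag(ȳ)A`` (plus margin), the l1
    sparsity penalty on off-diagonals, and — when collocation ``data``
    from :func:`collocation_arrays` is supplied — the mean squared
    per-capita growth misfit weighted by ``fit_weight``.
    """
    A = np.asarray(A, dtype=float)
    y_bar = np.asarray(y_bar, dtype=float).reshape(-1)
    if np.any(y_bar <= 0):
        raise ValueError("y_bar must be interior (all components > 0)")
    n = y_bar.size
    if A.shape != (n, n):
        raise ValueError(f"A has shape {A.shape}, expected ({n}, {n})")

    alpha = float(np.max(np.linalg.eigvals(y_bar[:, None] * A).real))
    hinge = max(0.0, alpha + config.stability_margin)
    off = A - np.diag(np.diag(A))
    val = hinge * hinge + config.sparsity_weight * float(np.abs(off).sum())
    if data is not None and config.fit_weight > 0:
        Y, G, dt = data
        val += config.fit_weight * _misfit(
            A, Y, G, dt, y_bar, _taxon_precision_weights(G)
        )
    return val


# ---------------------------------------------------------------------------
# Compass direct search
# ---------------------------------------------------------------------------

def direct_search(
    f: Callable[[np.ndarray], float],
    A0,
    config: SearchConfig,
    return_trace: bool = False,
):
    """Derivative-free compass search over the entries of a matrix.

    Polls ``±step`` along each matrix entry in row-major order (``+``
    before ``-``), accepts the first improvement, contracts the step by
    ``step_contract`` after a full unsuccessful sweep, and stops when
    the step falls below ``step_tol`` or ``max_iters`` objective
    evaluations are spent. Non-finite polls are rejected and the search
    continues. The incumbent objective never increases.
    """
    A = np.array(A0, dtype=float, copy=True)
    f_best = float(f(A))
    if not np.isfinite(f_best):
        raise ValueError("objective must be finite at the starting point A0")
    trace = [f_best]
    step = config.step_init
    evals = 1
    n_rows, n_cols = A.shape

    while step >= config.step_tol and evals < config.max_iters:
        improved = False
        for i in range(n_rows):
            for j in range(n_cols):
                for delta in (step, -step):
                    if evals >= config.max_iters:
                        break
                    old = A[i, j]
                    A[i, j] = old + delta
                    f_trial = f(A)
                    evals += 1
                    if np.isfinite(f_trial) and f_trial < f_best:
                        f_best = float(f_trial)
                        trace.append(f_best)
                        improved = True
                        break  # keep the move, go to next coordinate
                    A[i, j] = old
                else:
                    continue
        if not improved:
            step *= config.step_contract
    if return_trace:
        return A, f_best, trace
    return A, f_best


# ---------------------------------------------------------------------------
# Repeated Monte Carlo restarts and consensus
# ---------------------------------------------------------------------------

def infer_ensemble(
    y_bar,
    config: SearchConfig,
    trajectories: Sequence[Trajectory] | None = None,
    taxa: Sequence[str] | None = None,
) -> SolutionEnsemble:
    """Repeated Monte-Carlo-sampled direct search for admissible networks.

    Each restart samples a starting matrix, refines it by compass
    search, recovers ``r = -Aȳ`` and accepts the solution iff the
    equilibrium residual is < 1e-8 in max-norm and the spectral
    abscissa clears the stability margin (and the total objective is
    within ``accept_tol``). Bit-for-bit reproducible for a fixed
    ``config.seed``. Pass the longitudinal ``trajectories`` the
    equilibrium was estimated from to anchor the ensemble to the
    observed dynamics; without them the ensemble characterises the full
    (sign-symmetric) admissible set of the equilibrium alone.
    """
    y_bar = np.asarray(y_bar, dtype=float).reshape(-1)
    if np.any(y_bar <= 0):
        raise ValueError("y_bar must be interior (all components > 0)")
    n = y_bar.size
    if taxa is None:
        taxa = tuple(f"taxon_{i+1}" for i in range(n))
    else:
        taxa = tuple(taxa)
        if len(taxa) != n:
            raise ValueError("taxa length must match y_bar")

    if trajectories is not None:
        # per-trajectory (subject) collocation blocks; each restart fits a
        # random subject subsample, so ensemble support doubles as a
        # stability-selection frequency that filters noise-driven edges
        blocks = [collocation_arrays([traj]) for traj in trajectories]
        G_all = np.hstack([b[1] for b in blocks])
        weights = _taxon_precision_weights(G_all)
        penalty = _adaptive_penalty_scales(blocks, y_bar, weights)
        n_sub = len(blocks)
        k_sub = max(2, int(round(config.subsample_fraction * n_sub)))
        k_sub = min(k_sub, n_sub)
    else:
        blocks = weights = None
        penalty = np.ones((n, n)) - np.eye(n)

    # Stability is a constraint, not a preference: while a candidate is
    # unstable the merit is a large offset plus the squared hinge (drive
    # toward feasibility); once inside the stable region only the data
    # misfit and the sparsity penalty are minimised and unstable polls
    # are never re-entered (extreme barrier). Any stable matrix
    # therefore beats every unstable one, and accepted solutions satisfy
    # the spectral constraint exactly rather than approximately.
    BARRIER = 1e6

    def make_merit(P, G, dt):
        def merit(A: np.ndarray) -> float:
            if config.diag_constraint and np.any(np.diag(A) > 0):
                return float("inf")
            alpha = float(np.max(np.linalg.eigvals(y_bar[:, None] * A).real))
            hinge = alpha + config.stability_margin
            if hinge >= 0:
                return BARRIER + hinge * hinge
            # feasible: the spectral hinge is zero by construction
            val = config.sparsity_weight * float(
                np.sum(penalty * np.abs(A))
            )
            if P is not None and config.fit_weight > 0:
                val += config.fit_weight * _misfit(A, P, G, dt, y_bar, weights)
            return val

        return merit

    children = np.random.SeedSequence(config.seed).spawn(config.n_restarts)
    solutions = []
    best_obj = float("inf")
    for k in range(config.n_restarts):
        rng = np.random.default_rng(children[k])
        if blocks is not None:
            chosen = rng.choice(len(blocks), size=k_sub, replace=False)
            Y_k = np.hstack([blocks[c][0] for c in sorted(chosen)])
            G_k = np.hstack([blocks[c][1] for c in sorted(chosen)])
            dt_k = np.concatenate([blocks[c][2] for c in sorted(chosen)])
            merit = make_merit(Y_k, G_k, dt_k)
        else:
            merit = make_merit(None, None, None)
        A0 = sample_initial_matrix(rng, n, config.init_scale)
        A_star, f_star = direct_search(merit, A0, config)
        r_star = growth_rates_for_equilibrium(A_star, y_bar)
        residual = float(np.max(np.abs(y_bar * (r_star + A_star @ y_bar))))
        alpha = float(np.max(np.linalg.eigvals(y_bar[:, None] * A_star).real))
        accepted = (
            alpha < -config.stability_margin
            and residual < RESIDUAL_TOL
            and f_star <= config.accept_tol
        )
        best_obj = min(best_obj, f_star)
        solutions.append(
            Solution(
                A=A_star,
                r=r_star,
                objective=f_star,
                spectral_abscissa=alpha,
                accepted=accepted,
                restart_index=k,
            )
        )
    ensemble = SolutionEnsemble(
        solutions=tuple(solutions), y_bar=y_bar, taxa=taxa, config=config
    )
    if not ensemble.accepted:
        raise NoAdmissibleNetworkError(best_obj)
    return ensemble


def consensus_network(
    ensemble: SolutionEnsemble,
    sign_support: float = 0.8,
    strength_floor: float = 0.05,
) -> SignedNetwork:
    """Distill an ensemble into a consensus signed network.

    For each ordered taxon pair the consensus strength is the median of
    ``a_ij`` over accepted solutions; a directed edge ``j -> i`` is kept
    iff ``|median| >= strength_floor`` and the fraction of solutions
    agreeing with the median's sign is ``>= sign_support``. Diagonal
    terms are reported per taxon as self-limitation, not as self-loops.
    """
    accepted = ensemble.accepted
    if not accepted:
        raise ValueError("ensemble has no accepted solutions")
    stack = np.stack([s.A for s in accepted])  # (k, n, n)
    med = np.median(stack, axis=0)
    n = med.shape[0]
    taxa = ensemble.taxa
    edges = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            m = med[i, j]
            if abs(m) < strength_floor:
                continue
            agree = float(np.mean(np.sign(stack[:, i, j]) == np.sign(m)))
            if agree < sign_support:
                continue
            edges.append(
                SignedEdge(
                    source=taxa[j],
                    target=taxa[i],
                    sign=int(np.sign(m)),
                    weight=float(abs(m)),
                    support=agree,
                )
            )
    self_lim = {taxa[i]: float(med[i, i]) for i in range(n)}
    return SignedNetwork(nodes=taxa, edges=tuple(edges), self_limitation=self_lim)
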