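"""Ground-truth-known synthetic longitudinal microbiome datasets.

Emulates the study design the package targets: seven gut phyla sampled
weekly (3–15 weeks of age) in two mouse cohorts — an untreated control
group and a vancomycin-treated group — whose communities follow gLV
dynamics with *different* known interaction networks. Each subject
starts from a randomly perturbed composition, relaxes toward the
group's stable equilibrium, and is observed through multiplicative
lognormal process noise followed by multinomial read sampling at a
fixed sequencing depth, the standard stand-in for compositional 16S
noise.

The two presets differ by construction in the edges the downstream
comparison should detect: the control network has a Proteobacteria hub
influencing Bacteroidetes, Actinobacteria and Verrucomicrobia; the
vancomycin network lacks those edges and instead gains a positive
Firmicutes → Verrucomicrobia influence; the positive Bacteroidetes →
Verrucomicrobia edge is common to both. Preset magnitudes are
illustrative fixtures chosen once for comfortable stability, not
estimates of any real community.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from scipy.integrate import solve_ivp

from .abundance import AbundanceTable, SampleMetadata
from .glv import CommunityModel, growth_rates_for_equilibrium
from .stability import assess_stability

__all__ = [
    "PHYLA",
    "ScenarioSpec",
    "make_scenario",
    "make_three_taxon_scenario",
    "generate_dataset",
]

#: The seven phyla of the two-condition design, in node order.
PHYLA = (
    "Actinobacteria",
    "Bacteroidetes",
    "Cyanobacteria",
    "Firmicutes",
    "Proteobacteria",
    "Tenericutes",
    "Verrucomicrobia",
)

_IDX = {p: i for i, p in enumerate(PHYLA)}

# Self-limitation (diagonal) strengths shared by both presets.
_DIAG = np.array([-1.0, -1.2, -0.8, -1.3, -1.1, -0.9, -1.4])

# Shared off-diagonal edge (source -> target: value), kept under both
# conditions ("some relationships remain the same").
_SHARED_EDGES = {
    ("Bacteroidetes", "Verrucomicrobia"): +0.60,
}

# Control-only: the Proteobacteria hub.
_CONTROL_EDGES = {
    ("Proteobacteria", "Bacteroidetes"): -0.60,
    ("Proteobacteria", "Actinobacteria"): +0.60,
    ("Proteobacteria", "Verrucomicrobia"): -0.60,
}

# Vancomycin-only gain.
_VANCOMYCIN_EDGES = {
    ("Firmicutes", "Verrucomicrobia"): +0.60,
}

# Equilibrium compositions: Firmicutes + Bacteroidetes dominant in the
# control; Bacteroidetes depleted and Verrucomicrobia expanded under
# vancomycin. Illustrative only.
_YBAR_CONTROL = np.array([0.05, 0.30, 0.02, 0.40, 0.10, 0.03, 0.10])
_YBAR_VANCOMYCIN = np.array([0.04, 0.08, 0.02, 0.40, 0.10, 0.06, 0.30])


def _build_matrix(edges: Mapping[tuple[str, str], float]) -> np.ndarray:
    A = np.diag(_DIAG.copy())
    for (src, tgt), val in edges.items():
        A[_IDX[tgt], _IDX[src]] = val
    return A


@dataclass(frozen=True)
class ScenarioSpec:
    """Fully specified, stability-verified ground-truth scenario."""

    name: str
    taxa: tuple[str, ...]
    A_true: np.ndarray
    y_bar_true: np.ndarray
    weeks: np.ndarray = field(default_factory=lambda: np.arange(3.0, 16.0))
    n_subjects: int = 12
    depth: int = 10_000
    process_noise: float = 0.1
    init_sigma: float = 1.2
    seed: int = 0

    def __post_init__(self):
        A = np.asarray(self.A_true, dtype=float)
        y = np.asarray(self.y_bar_true, dtype=float).reshape(-1)
        weeks = np.asarray(self.weeks, dtype=float).reshape(-1)
        if np.any(y <= 0):
            raise ValueError("y_bar_true must be interior (all > 0)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        object.__setattr__(self, "A_true", A)
        object.__setattr__(self, "y_bar_true", y)
        object.__setattr__(self, "weeks", weeks)
        report = assess_stability(self.model, y, margin=1e-6)
        if not report.stable:
            raise ValueError(
                f"scenario {self.name!r} is not asymptotically stable: "
                f"spectral abscissa {report.spectral_abscissa:.6g}"
            )

    @property
    def r_true(self) -> np.ndarray:
        return growth_rates_for_equilibrium(self.A_true, self.y_bar_true)

    @property
    def model(self) -> CommunityModel:
        return CommunityModel(self.taxa, self.r_true, self.A_true)

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "taxa": list(self.taxa),
                "A_true": self.A_true.tolist(),
                "r_true": self.r_true.tolist(),
                "y_bar_true": self.y_bar_true.tolist(),
                "weeks": self.weeks.tolist(),
                "n_subjects": self.n_subjects,
                "depth": self.depth,
                "process_noise": self.process_noise,
                "init_sigma": self.init_sigma,
                "seed": self.seed,
            },
            indent=2,
        )


def make_scenario(name: str, overrides: Mapping | None = None) -> ScenarioSpec:
    """Build a named preset (``control`` | ``vancomycin``) or a custom spec.

    Overrides replace ScenarioSpec fields; for ``custom`` they must at
    least supply ``taxa``, ``A_true`` and ``y_bar_true``. Construction
    verifies asymptotic stability and raises with the offending spectral
    abscissa otherwise.
    """
    overrides = dict(overrides or {})
    if name == "control":
        base = ScenarioSpec(
            name="control",
            taxa=PHYLA,
            A_true=_build_matrix({**_SHARED_EDGES, **_CONTROL_EDGES}),
            y_bar_true=_YBAR_CONTROL,
        )
    elif name == "vancomycin":
        base = ScenarioSpec(
            name="vancomycin",
            taxa=PHYLA,
            A_true=_build_matrix({**_SHARED_EDGES, **_VANCOMYCIN_EDGES}),
            y_bar_true=_YBAR_VANCOMYCIN,
        )
    elif name == "custom":
        for key in ("taxa", "A_true", "y_bar_true"):
            if key not in overrides:
                raise ValueError(f"custom scenario requires override {key!r}")
        return ScenarioSpec(name=overrides.pop("name", "custom"),
                            **overrides)
    else:
        raise ValueError(
            f"unknown scenario {name!r}; expected control, vancomycin or custom"
        )
    if overrides:
        base = replace(base, **overrides)
    return base


def make_three_taxon_scenario(**overrides) -> ScenarioSpec:
    """Small three-phylum community used for fast recovery checks.

    Every row and column pairs a facilitation with an inhibition: with
    only three taxa, compositional shifts are resolvable from sparsity
    alone only in degenerate ways, but alternating signs keep every
    edge's sign identifiable regardless of how the shift is resolved.
    """
    taxa = ("Bacteroidetes", "Firmicutes", "Verrucomicrobia")
    A = np.array(
        [
            [-1.3, +0.50, -0.45],
            [-0.50, -1.1, +0.45],
            [+0.55, -0.50, -1.2],
        ]
    )
    y_bar = np.array([0.40, 0.50, 0.10])
    return make_scenario(
        "custom",
        {"name": "three_taxon", "taxa": taxa, "A_true": A,
         "y_bar_true": y_bar, **overrides},
    )


def _advance_composition(
    model: CommunityModel, p0: np.ndarray, t0: float, t1: float
) -> np.ndarray:
    """Advance a composition under the gLV field restricted to the simplex.

    Only relative abundances are observable, so the latent state is a
    composition and evolves under the simplex projection of the gLV
    field: ``p' = diag(p)(r + Ap) - p * phi`` with
    ``phi = sum_i p_i (r + Ap)_i``. The projection subtracts the common
    (total-abundance) mode, which carries no compositional information;
    the interaction matrix and the interior equilibrium are unchanged.
    """
    r, A = model.r, model.A

    def rhs(t, p):
        growth = p * (r + A @ p)
        return growth - p * growth.sum()

    sol = solve_ivp(rhs, (t0, t1), p0, method="LSODA", rtol=1e-7, atol=1e-9)
    if not sol.success:
        raise RuntimeError(
            f"composition simulation failed on [{t0}, {t1}]: {sol.message}"
        )
    p = np.clip(sol.y[:, -1], 0.0, None)
    return p / p.sum()


def generate_dataset(spec: ScenarioSpec) -> tuple[AbundanceTable, SampleMetadata]:
    """Forward-simulate a cohort and return (counts table, metadata).

    Per subject: the latent composition starts at the equilibrium
    perturbed by i.i.d. lognormal factors (sigma ``init_sigma``), evolves
    under the scenario's gLV model, and is read out weekly through
    lognormal process noise (sigma ``process_noise``) and a multinomial
    draw of ``depth`` reads. Deterministic for a fixed ``spec.seed``;
    every sample column sums exactly to ``depth``.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    n = len(spec.taxa)
    model = spec.model
    lineages = tuple(f"k__Bacteria;p__{p}" for p in spec.taxa)

    columns, sample_ids, meta_rows = [], [], []
    for s in range(spec.n_subjects):
        subject = f"{spec.name}_m{s + 1}"
        y0 = spec.y_bar_true * np.exp(
            rng.normal(0.0, spec.init_sigma, size=n)
        )
        latent = y0 / y0.sum()  # a perturbed composition is still a composition
        for k, week in enumerate(spec.weeks):
            if k > 0:
                latent = _advance_composition(
                    model, latent, spec.weeks[k - 1], spec.weeks[k]
                )
            latent = np.clip(latent, 1e-12, None)
            p = latent / latent.sum()
            counts = rng.multinomial(spec.depth, p)
            sid = f"{subject}_w{int(week) if float(week).is_integer() else week}"
            columns.append(counts)
            sample_ids.append(sid)
            meta_rows.append((sid, subject, float(week), spec.name))
            if spec.process_noise > 0:
                # logistic-normal process (not readout) noise, applied
                # after the weekly observation: lognormal kicks
                # renormalised back to a composition, persisting in the
                # subsequent dynamics
                latent = p * np.exp(
                    rng.normal(0.0, spec.process_noise, size=n)
                )
                latent = latent / latent.sum()

    values = np.column_stack(columns).astype(float)
    table = AbundanceTable(
        taxa=spec.taxa,
        lineages=lineages,
        samples=tuple(sample_ids),
        values=values,
        is_relative=False,
    )
    meta = SampleMetadata(
        frame=pd.DataFrame(
            [(sub, wk, grp) for _, sub, wk, grp in meta_rows],
            index=pd.Index([sid for sid, *_ in meta_rows], name="sample"),
            columns=["subject", "week", "group"],
        )
    )
    return table, meta
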