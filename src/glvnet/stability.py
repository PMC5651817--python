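"""Local stability analysis of gLV equilibria.

Linearising ``y' = diag(y)(r + Ay)`` at a state ``ȳ`` gives the Jacobian

    J = diag(r + A ȳ) + diag(ȳ) A

whose spectrum governs behaviour near ``ȳ``: the equilibrium is
asymptotically stable iff every eigenvalue has strictly negative real
part, i.e. the spectral abscissa ``max_j Re(λ_j)`` is negative. At an
interior equilibrium the first term vanishes (``r + Aȳ = 0``) and
``J = diag(ȳ)A``; the term is kept so boundary states (some ``ȳ_i = 0``)
are handled correctly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .glv import CommunityModel, _check_dim

__all__ = [
    "StabilityReport",
    "stability_matrix",
    "spectral_abscissa",
    "assess_stability",
    "DEFAULT_MARGIN",
]

#: Default stability margin: eigenvalues with real part in (-margin, 0) are
#: treated as unstable because floating-point spectra near zero are
#: sign-unreliable.
DEFAULT_MARGIN = 1e-6


@dataclass(frozen=True)
class StabilityReport:
    """Spectrum-based stability assessment at a candidate equilibrium."""

    J: np.ndarray
    eigenvalues: np.ndarray
    spectral_abscissa: float
    stable: bool
    margin: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "J": self.J.tolist(),
                "eigenvalues": [
                    {"re": float(ev.real), "im": float(ev.imag)}
                    for ev in self.eigenvalues
                ],
                "spectral_abscissa": self.spectral_abscissa,
                "stable": self.stable,
                "margin": self.margin,
            },
            indent=2,
        )


def stability_matrix(model: CommunityModel, y_bar) -> np.ndarray:
    """Jacobian ``diag(r + Aȳ) + diag(ȳ)A`` of the gLV flow at ``ȳ``."""
    y_bar = _check_dim(y_bar, model.n, "y_bar")
    return np.diag(model.r + model.A @ y_bar) + y_bar[:, None] * model.A


def spectral_abscissa(J) -> float:
    """Maximum real part of the spectrum of a square matrix."""
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError(f"J must be square, got shape {J.shape}")
    if not np.all(np.isfinite(J)):
        raise ValueError("J must be finite")
    return float(np.max(np.linalg.eigvals(J).real))


def assess_stability(
    model: CommunityModel, y_bar, margin: float = DEFAULT_MARGIN
) -> StabilityReport:
    """Full stability report; ``stable`` iff spectral abscissa < -margin."""
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    J = stability_matrix(model, y_bar)
    eig = np.linalg.eigvals(J)
    alpha = float(np.max(eig.real))
    return StabilityReport(
        J=J,
        eigenvalues=eig,
        spectral_abscissa=alpha,
        stable=bool(alpha < -margin),
        margin=float(margin),
    )
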