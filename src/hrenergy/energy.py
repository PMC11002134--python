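"""Helmholtz decomposition and Hamiltonian energy of the reduced HR neuron.

Any smooth autonomous field F(X) can be written F = (G1 + G2) grad H with G1
skew-symmetric and G2 symmetric; the products F1 = G1 grad H (conservative,
orthogonal to grad H) and F2 = G2 grad H (dissipative) split the dynamics
into an energy-preserving rotation and an energy-exchanging part.  For the
mean-field reduced HR system with aggregate coupling D = d1*k and neighbour
level x0, writing u = y - z + D (x0 - x), the published split is

    F1 = ( u,          -d x^2,   r s x )
    F2 = ( -a x^3 + b x^2 + I_ext [- k x],   c - y,   -r s x_r - r z )

with Hamiltonian energy

    H = u^2 + (2/3) d x^3 + r s x^2

and energy rate Hdot = grad H . F2.  Two deliberate variants are exposed:

* ``consistent`` -- F2's x-component is -a x^3 + b x^2 + I_ext so that
  F1 + F2 reproduces the reduced vector field exactly;
* ``as_printed`` -- F2's x-component additionally carries -k x (no d1
  factor), reproducing the published component list and the published
  polynomial expansion of Hdot verbatim; the sum then differs from the
  vector field by exactly (-k x, 0, 0).

Likewise two gradient conventions: ``partial`` treats the coupling drive
D (x0 - x) inside u as an external input when differentiating with respect
to x (the unique reading under which grad H . F1 vanishes identically);
``full`` differentiates everything, picking up an extra -2 D u in the first
component, so grad H . F1 = -2 D u^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .model import CouplingSpec, HRParams

__all__ = [
    "HelmholtzSplit",
    "EnergyRecord",
    "EnergySummary",
    "hamiltonian",
    "grad_hamiltonian",
    "helmholtz_split",
    "orthogonality_residual",
    "hdot_formula",
    "hdot_printed_polynomial",
    "energy_series",
    "energy_summary",
]

VARIANTS = ("consistent", "as_printed")
CONVENTIONS = ("partial", "full")


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")


def _check_convention(convention: str) -> None:
    if convention not in CONVENTIONS:
        raise ValueError(
            f"gradient convention must be one of {CONVENTIONS}, got {convention!r}")


def _unpack(state, coupling: CouplingSpec):
    state = np.asarray(state, dtype=float)
    x, y, z = state[..., 0], state[..., 1], state[..., 2]
    D = np.asarray(coupling.D, dtype=float)
    x0 = np.asarray(coupling.x0, dtype=float)
    u = y - z + D * (x0 - x)
    return x, y, z, D, x0, u


@dataclass(frozen=True)
class HelmholtzSplit:
    """Conservative/dissipative field pair at one (batch of) state(s)."""

    F1: np.ndarray
    F2: np.ndarray
    variant: str


@dataclass
class EnergyRecord:
    """H(t) and Hdot(t) along a trajectory."""

    times: np.ndarray
    H: np.ndarray
    Hdot: np.ndarray
    variant: str
    scaled: bool

    def __post_init__(self) -> None:
        if len(self.times) != len(self.H) or len(self.H) != len(self.Hdot):
            raise ValueError("times, H and Hdot must have equal length")


@dataclass(frozen=True)
class EnergySummary:
    """Windowed summaries: H1 (time-average of H), H2 = (max, min) of Hdot."""

    H1: float
    H2: Tuple[float, float]
    deltaH: float
    deltaHdot: float
    t0: float
    T: float


def hamiltonian(state, params: HRParams, coupling: CouplingSpec,
                scaled: bool = False):
    """H = (y - z + D(x0 - x))^2 + (2/3) d x^3 + r s x^2, optionally /100."""
    x, _, _, _, _, u = _unpack(state, coupling)
    H = u**2 + (2.0 / 3.0) * params.d * x**3 + params.r * params.s * x**2
    return H / 100.0 if scaled else H


def grad_hamiltonian(state, params: HRParams, coupling: CouplingSpec,
                     convention: str = "partial") -> np.ndarray:
    """Gradient of H; ``partial`` holds the coupling drive fixed in d/dx."""
    _check_convention(convention)
    x, _, _, D, _, u = _unpack(state, coupling)
    gx = 2.0 * params.d * x**2 + 2.0 * params.r * params.s * x
    if convention == "full":
        gx = gx - 2.0 * D * u
    return np.stack(np.broadcast_arrays(gx, 2.0 * u, -2.0 * u), axis=-1)


def helmholtz_split(state, params: HRParams, coupling: CouplingSpec,
                    variant: str = "consistent") -> HelmholtzSplit:
    """F1/F2 pair; ``consistent`` satisfies F1 + F2 = reduced vector field."""
    _check_variant(variant)
    x, y, z, _, _, u = _unpack(state, coupling)
    p = params
    F1 = np.stack(np.broadcast_arrays(
        u, -p.d * x**2, p.r * p.s * x), axis=-1)
    f2x = -p.a * x**3 + p.b * x**2 + p.I_ext
    if variant == "as_printed":
        f2x = f2x - np.asarray(coupling.k, float) * x
    F2 = np.stack(np.broadcast_arrays(
        f2x, p.c - y, -p.r * p.s * p.x_r - p.r * z), axis=-1)
    return HelmholtzSplit(F1=F1, F2=F2, variant=variant)


def orthogonality_residual(state, params: HRParams, coupling: CouplingSpec,
                           convention: str = "partial"):
    """grad H . F1: identically 0 (partial) or -2 D u^2 (full)."""
    grad = grad_hamiltonian(state, params, coupling, convention)
    F1 = helmholtz_split(state, params, coupling, "consistent").F1
    return np.einsum("...i,...i->...", grad, F1)


def hdot_formula(state, params: HRParams, coupling: CouplingSpec,
                 variant: str = "consistent"):
    """Energy rate Hdot = grad H . F2 under the partial-gradient convention."""
    grad = grad_hamiltonian(state, params, coupling, "partial")
    F2 = helmholtz_split(state, params, coupling, variant).F2
    return np.einsum("...i,...i->...", grad, F2)


def hdot_printed_polynomial(state, params: HRParams, coupling: CouplingSpec):
    """The published polynomial expansion of Hdot, transcribed term by term.

    Independent of :func:`hdot_formula` (which evaluates the dot product
    grad H . F2); the two must agree for the ``as_printed`` variant.  The
    degree ``k`` enters through D = d1*k and through the bare -k x term.
    """
    x, y, z, D, x0, _ = _unpack(state, coupling)
    p = params
    k = np.asarray(coupling.k, dtype=float)
    rs = p.r * p.s
    return (
        (2 * rs * p.x_r + 2 * p.r * z + 2 * p.c - 2 * y) * D * (x0 - x)
        - 2 * p.a * p.d * x**5
        + (-2 * p.a * rs + 2 * p.b * p.d) * x**4
        + (2 * p.b * rs - 2 * p.d * k) * x**3
        + (-2 * k * rs + 2 * p.I_ext * p.d) * x**2
        + 2 * p.I_ext * rs * x
        + 2 * rs * p.x_r * y - 2 * rs * p.x_r * z
        + 2 * p.r * y * z - 2 * p.r * z**2
        + 2 * p.c * y - 2 * p.c * z
        - 2 * y**2 + 2 * y * z
    )


def energy_series(trajectory, params: HRParams, coupling: CouplingSpec,
                  variant: str = "consistent", scaled: bool = True) -> EnergyRecord:
    """Evaluate H and Hdot at every recorded step of a trajectory.

    ``scaled`` applies the reporting scale H/100 (and Hdot/100, for
    dimensional consistency) used for all experiment outputs.
    """
    _check_variant(variant)
    states = np.asarray(trajectory.states, dtype=float)
    H = hamiltonian(states, params, coupling, scaled=False)
    Hdot = hdot_formula(states, params, coupling, variant)
    if scaled:
        H = H / 100.0
        Hdot = Hdot / 100.0
    return EnergyRecord(times=np.asarray(trajectory.times), H=H, Hdot=Hdot,
                        variant=variant, scaled=scaled)


def energy_summary(record: EnergyRecord, t0: float,
                   T: float = 5000.0) -> EnergySummary:
    """Windowed summaries over [t0, t0 + T].

    H1 is the trapezoidal time-average of H; H2 the (max, min) pair of
    Hdot; deltaH / deltaHdot the max-minus-min ranges.  The window must lie
    inside the record.
    """
    t = np.asarray(record.times)
    eps = 1e-9 * max(1.0, abs(t0) + T)
    if t0 < t[0] - eps or t0 + T > t[-1] + eps:
        raise ValueError(
            f"window [{t0}, {t0 + T}] outside record [{t[0]}, {t[-1]}]")
    mask = (t >= t0 - eps) & (t <= t0 + T + eps)
    if mask.sum() < 2:
        raise ValueError("window contains fewer than 2 samples")
    tw = t[mask]
    H = np.asarray(record.H)[mask]
    Hdot = np.asarray(record.Hdot)[mask]
    H1 = float(np.trapezoid(H, tw, axis=0) / (tw[-1] - tw[0]))
    h2 = (float(Hdot.max()), float(Hdot.min()))
    return EnergySummary(
        H1=H1, H2=h2,
        deltaH=float(H.max() - H.min()),
        deltaHdot=h2[0] - h2[1],
        t0=float(t0), T=float(T),
    )
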