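"""Hindmarsh-Rose vector fields and equilibria.

The three-variable Hindmarsh-Rose (HR) neuron couples a fast membrane
potential ``x``, a fast recovery current ``y`` and a slow adaptation
current ``z``:

    dx/dt = y - a x^3 + b x^2 + I_ext - z
    dy/dt = c - d x^2 - y
    dz/dt = r (s (x - x_r) - z)

Three levels of coupling are provided:

* :func:`rhs_single` -- the isolated neuron;
* :func:`rhs_reduced` -- the mean-field reduction, where a neuron of degree
  ``k`` sees its neighbours frozen at the network-free equilibrium and
  receives the drive ``D (x0 - x)`` with aggregate coupling ``D = d1 k``;
* :func:`rhs_network` -- ``n`` neurons diffusively coupled through the graph
  Laplacian ``L = A - diag(k)``, with per-node drive ``d1 * sum_j L_ij x_j``.

States are ``numpy`` arrays whose last axis holds ``(x, y, z)``; all
operations broadcast over leading axes, so a batch of neurons (or a whole
parameter grid) integrates in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

__all__ = [
    "HRParams",
    "CouplingSpec",
    "Equilibrium",
    "neuron_state",
    "rhs_single",
    "rhs_reduced",
    "rhs_network",
    "equilibrium_uncoupled",
    "equilibrium_reduced",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class HRParams:
    """Scalar constants of the HR model.

    Defaults are the standard spiking-regime values a=1, b=3, c=1, d=5,
    r=0.01, s=4.  The resting offset ``x_r = -1.6`` makes the constant term
    of the slow equation r*s*(-x_r) equal 0.064.

    ``z_decay`` selects the coefficient multiplying ``z`` in the slow
    equation.  The canonical form uses ``r`` (slow decay, default,
    ``z_decay=None``); setting ``z_decay=1.0`` reproduces the alternative
    reading in which the slow current relaxes at unit rate.
    """

    a: float = 1.0
    b: float = 3.0
    c: float = 1.0
    d: float = 5.0
    r: float = 0.01
    s: float = 4.0
    x_r: float = -1.6
    I_ext: float = 1.0
    z_decay: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.r > 0 and self.s > 0 and self.d > 0 and self.a > 0):
            raise ValueError("HRParams requires r > 0, s > 0, d > 0, a > 0")
        vals = [self.a, self.b, self.c, self.d, self.r, self.s, self.x_r, self.I_ext]
        if self.z_decay is not None:
            if self.z_decay <= 0:
                raise ValueError("z_decay must be positive")
            vals.append(self.z_decay)
        if not np.all(np.isfinite(vals)):
            raise ValueError("HRParams fields must be finite")

    @property
    def g_z(self) -> float:
        """Effective decay coefficient of z in the slow equation."""
        return self.r if self.z_decay is None else self.z_decay

    def replace(self, **kw) -> "HRParams":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


@dataclass(frozen=True)
class CouplingSpec:
    """Mean-field coupling: aggregate strength D = d1 * k and drive level x0.

    ``x0`` is the membrane-potential level at which the neighbours are held
    (the network-free equilibrium in the mean-field reduction, but usable as
    a free external-stimulus parameter).  ``d1`` may be an array to scan a
    coupling grid in one batched integration.
    """

    d1: ArrayLike = 0.0
    k: ArrayLike = 0.0
    x0: ArrayLike = 0.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.d1) < 0):
            raise ValueError("coupling strength d1 must be >= 0")
        if np.any(np.asarray(self.k) < 0):
            raise ValueError("degree k must be >= 0")

    @classmethod
    def from_aggregate(cls, D: ArrayLike, x0: ArrayLike = 0.0) -> "CouplingSpec":
        """Build a spec directly from the aggregate D = d1*k (k set to 1)."""
        return cls(d1=D, k=1.0, x0=x0)

    @property
    def D(self) -> ArrayLike:
        return np.asarray(self.d1) * np.asarray(self.k)


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point together with the real-root census of its cubic."""

    state: np.ndarray  # (x0, y0, z0)
    n_real_roots: int
    real_roots: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def x(self) -> float:
        return float(self.state[0])

    @property
    def y(self) -> float:
        return float(self.state[1])

    @property
    def z(self) -> float:
        return float(self.state[2])


def neuron_state(x: ArrayLike, y: ArrayLike, z: ArrayLike) -> np.ndarray:
    """Pack components into a state array with (x, y, z) on the last axis."""
    return np.stack(np.broadcast_arrays(
        np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
    ), axis=-1)


def _check_state(state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape[-1] != 3:
        raise ValueError("state must have (x, y, z) on the last axis")
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state passed to HR vector field")
    return state


def rhs_single(state: np.ndarray, params: HRParams) -> np.ndarray:
    """Time derivative of the isolated HR neuron. Broadcasts over batches."""
    state = _check_state(state)
    x, y, z = state[..., 0], state[..., 1], state[..., 2]
    p = params
    dx = y - p.a * x**3 + p.b * x**2 + p.I_ext - z
    dy = p.c - p.d * x**2 - y
    dz = p.r * p.s * (x - p.x_r) - p.g_z * z
    return np.stack([dx, dy, dz], axis=-1)


def rhs_reduced(state: np.ndarray, params: HRParams,
                coupling: CouplingSpec) -> np.ndarray:
    """Mean-field reduced system: rhs_single plus D (x0 - x) on dx/dt."""
    deriv = rhs_single(state, params)
    x = np.asarray(state, float)[..., 0]
    deriv[..., 0] += np.asarray(coupling.D) * (np.asarray(coupling.x0) - x)
    return deriv


def rhs_network(state: np.ndarray, params: HRParams, network,
                d1: float) -> np.ndarray:
    """Network system: per-node rhs_single plus d1 * L @ x on dx/dt.

    ``network`` is a :class:`hrenergy.network.Network`; the Laplacian rows
    sum to zero, so the coupling vanishes identically on the synchronized
    manifold.
    """
    state = np.asarray(state, float)
    if state.shape[0] != network.n:
        raise ValueError(
            f"state has {state.shape[0]} nodes but network has {network.n}")
    deriv = rhs_single(state, params)
    # sum_j L_ij x_j = sum_j A_ij (x_j - x_i): the pairwise form makes the
    # coupling vanish exactly (not just to rounding) on the sync manifold
    x = state[..., 0]
    diffs = x[np.newaxis, :] - x[:, np.newaxis]
    deriv[..., 0] += d1 * np.einsum("ij,ij->i", network.adjacency, diffs)
    return deriv


def _equilibrium_cubic(params: HRParams, D: float = 0.0,
                       x0: float = 0.0) -> np.ndarray:
    """Coefficients (highest first) of the fixed-point cubic in x.

    Setting the three derivatives to zero and eliminating y, z gives

        a x^3 + (d - b) x^2 + (s_eff + D) x - (c + I_ext + s_eff x_r + D x0) = 0

    with s_eff = r*s/g_z (equal to s for the canonical z decay).
    """
    p = params
    s_eff = p.r * p.s / p.g_z
    return np.array([
        p.a,
        p.d - p.b,
        s_eff + D,
        -(p.c + p.I_ext + s_eff * p.x_r + D * x0),
    ])


def _solve_cubic(coeffs: np.ndarray, tol: float = 1e-9):
    """Real roots of a cubic via the companion matrix, bisection-polished.

    Near-coincident real roots (within ``tol``) are merged so multiplicity
    does not inflate the census.  Returns (chosen_root, n_distinct_real,
    distinct_real_roots).
    """
    roots = np.roots(coeffs)
    scale = max(1.0, np.abs(roots).max())
    real = np.sort(roots[np.abs(roots.imag) < 1e-9 * scale].real)
    # merge near-degenerate roots
    distinct = [real[0]]
    for v in real[1:]:
        if v - distinct[-1] > tol * max(1.0, abs(v)):
            distinct.append(v)
    distinct = np.array(distinct)

    poly = np.poly1d(coeffs)
    chosen = distinct[-1] if len(distinct) > 1 else distinct[0]
    # bisection polish when a sign-change bracket exists around the root
    from scipy.optimize import brentq

    h = 1e-3 * max(1.0, abs(chosen))
    lo, hi = chosen - h, chosen + h
    if poly(lo) * poly(hi) < 0:
        chosen = brentq(poly, lo, hi, xtol=1e-14, rtol=1e-15)
    return float(chosen), len(distinct), distinct


def _equilibrium_from_x(params: HRParams, x: float) -> np.ndarray:
    p = params
    y = p.c - p.d * x**2
    z = p.r * p.s * (x - p.x_r) / p.g_z
    return np.array([x, y, z])


def equilibrium_uncoupled(params: HRParams) -> Equilibrium:
    """Fixed point of the isolated neuron, with the real-root count.

    For the default parameters the cubic's derivative 3x^2 + 4x + 4 has a
    negative discriminant, so the cubic is strictly monotone and the real
    root is unique for every I_ext.
    """
    x, n_real, roots = _solve_cubic(_equilibrium_cubic(params))
    return Equilibrium(_equilibrium_from_x(params, x), n_real, roots)


def equilibrium_reduced(params: HRParams, coupling: CouplingSpec) -> Equilibrium:
    """Fixed point of the mean-field reduced system (D >= 0).

    The coupling steepens the cubic (derivative gains +D x-coefficient), so
    uniqueness persists for all D >= 0 at the default parameters.
    """
    D = float(np.asarray(coupling.D))
    x0 = float(np.asarray(coupling.x0))
    x, n_real, roots = _solve_cubic(_equilibrium_cubic(params, D, x0))
    return Equilibrium(_equilibrium_from_x(params, x), n_real, roots)
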