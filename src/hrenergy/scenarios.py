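"""Seeded scenario bundles reproducing the study's experimental setups.

Each scenario packs the model parameters, the coupling (a small-world
network spec or a mean-field coupling), the integrator configuration and
the scan grids for one experiment family, so every stage of the pipeline
is runnable without external data:

* ``fig2`` -- pattern formation vs coupling strength d1 on W(100, 8, 0.01)
  at I_ext = 4, d1 grid {0.01, 0.05, 0.3, 1};
* ``fig3`` -- pattern formation vs ring degree K at d1 = 1, K grid
  {0, 2, 4, 6};
* ``fig4`` -- single-neuron regimes at I_ext = 1, x0 = 1, Di spot values
  {0.1, 1, 1.5};
* ``fig5`` -- Di bifurcation + energy scan, Di in [0, 2] step 0.02;
* ``fig6`` -- x0 spot values {1, 5, 10, 20, 200} at Di = 0.1, I_ext = 1;
* ``fig7`` -- x0 bifurcation + energy scan at Di = 1, x0 in [0, 30]
  step 0.25;
* ``toy`` -- 3-node ring, 200 time units, end-to-end in well under a second.

Initial conditions are the relevant equilibrium plus a seeded uniform
perturbation of amplitude 0.1 per component, small relative to the
attractor so basin selection is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .model import CouplingSpec, HRParams
from .network import SmallWorldSpec
from .simulate import IntegratorConfig

__all__ = ["Scenario", "SCENARIO_NAMES", "make_scenario", "initial_conditions"]

DEFAULT_PERTURBATION = 0.1


@dataclass
class Scenario:
    """A complete runnable experiment bundle."""

    name: str
    params: HRParams
    config: IntegratorConfig
    network_spec: Optional[SmallWorldSpec] = None
    coupling: Optional[CouplingSpec] = None
    grids: Dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0


SCENARIO_NAMES = ("fig2", "fig3", "fig4", "fig5", "fig6", "fig7", "toy")


def make_scenario(name: str, seed: int = 0, overrides: Optional[dict] = None) -> Scenario:
    """Build a named scenario; ``overrides`` replaces bundle fields last.

    Override keys: any HRParams field, any IntegratorConfig field, plus
    ``n``, ``K``, ``p`` (network), ``d1``, ``k``, ``x0`` (coupling) and
    ``grids`` (dict of grid-name -> array).
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}")
    overrides = dict(overrides or {})

    long_run = IntegratorConfig(dt=0.01, total_time=7000.0, burn_in=2000.0,
                                seed=seed)
    if name == "fig2":
        sc = Scenario(
            name=name, params=HRParams(I_ext=4.0),
            config=IntegratorConfig(dt=0.01, total_time=4000.0, burn_in=2000.0,
                                    record_stride=10, seed=seed),
            network_spec=SmallWorldSpec(n=100, K=8, p=0.01, seed=seed),
            grids={"d1": np.array([0.01, 0.05, 0.3, 1.0])}, seed=seed)
    elif name == "fig3":
        sc = Scenario(
            name=name, params=HRParams(I_ext=4.0),
            config=IntegratorConfig(dt=0.01, total_time=4000.0, burn_in=2000.0,
                                    record_stride=10, seed=seed),
            network_spec=SmallWorldSpec(n=100, K=8, p=0.01, seed=seed),
            coupling=CouplingSpec(d1=1.0, k=8, x0=0.0),
            grids={"K": np.array([0.0, 2.0, 4.0, 6.0])}, seed=seed)
    elif name == "fig4":
        sc = Scenario(
            name=name, params=HRParams(I_ext=1.0), config=long_run,
            coupling=CouplingSpec.from_aggregate(D=0.1, x0=1.0),
            grids={"Di": np.array([0.1, 1.0, 1.5])}, seed=seed)
    elif name == "fig5":
        sc = Scenario(
            name=name, params=HRParams(I_ext=1.0), config=long_run,
            coupling=CouplingSpec.from_aggregate(D=0.0, x0=1.0),
            grids={"Di": np.round(np.arange(0.0, 2.0 + 1e-9, 0.02), 10)},
            seed=seed)
    elif name == "fig6":
        sc = Scenario(
            name=name, params=HRParams(I_ext=1.0), config=long_run,
            coupling=CouplingSpec.from_aggregate(D=0.1, x0=1.0),
            grids={"x0": np.array([1.0, 5.0, 10.0, 20.0, 200.0])}, seed=seed)
    elif name == "fig7":
        sc = Scenario(
            name=name, params=HRParams(I_ext=1.0), config=long_run,
            coupling=CouplingSpec.from_aggregate(D=1.0, x0=0.0),
            grids={"x0": np.round(np.arange(0.0, 30.0 + 1e-9, 0.25), 10)},
            seed=seed)
    else:  # toy
        sc = Scenario(
            name=name, params=HRParams(I_ext=1.0),
            config=IntegratorConfig(dt=0.01, total_time=200.0, burn_in=50.0,
                                    seed=seed),
            network_spec=SmallWorldSpec(n=3, K=2, p=0.0, seed=seed),
            coupling=CouplingSpec.from_aggregate(D=1.0, x0=1.0),
            grids={"d1": np.array([0.1, 1.0])}, seed=seed)

    if "grids" in overrides:
        sc.grids = {k: np.asarray(v, float) for k, v in overrides.pop("grids").items()}
    param_kw = {k: overrides.pop(k) for k in list(overrides)
                if k in HRParams.__dataclass_fields__}
    if param_kw:
        sc.params = sc.params.replace(**param_kw)
    config_kw = {k: overrides.pop(k) for k in list(overrides)
                 if k in IntegratorConfig.__dataclass_fields__}
    if config_kw:
        from dataclasses import replace
        if "total_time" in config_kw and "burn_in" not in config_kw:
            # keep the bundle's burn-in fraction sane under a shorter horizon
            config_kw["burn_in"] = min(sc.config.burn_in,
                                       0.4 * float(config_kw["total_time"]))
        sc.config = replace(sc.config, **config_kw)
    net_kw = {k: overrides.pop(k) for k in list(overrides) if k in ("n", "K", "p")}
    if net_kw:
        from dataclasses import replace
        base = sc.network_spec or SmallWorldSpec(n=100, K=8, p=0.01, seed=seed)
        sc.network_spec = replace(base, **net_kw)
    coup_kw = {k: overrides.pop(k) for k in list(overrides)
               if k in ("d1", "k", "x0")}
    if coup_kw:
        from dataclasses import replace
        base = sc.coupling or CouplingSpec()
        sc.coupling = replace(base, **coup_kw)
    if overrides:
        raise ValueError(f"unknown override keys: {sorted(overrides)}")
    return sc


def initial_conditions(n: int, equilibrium: np.ndarray,
                       amplitude: float = DEFAULT_PERTURBATION,
                       seed: int = 0) -> np.ndarray:
    """Equilibrium plus independent uniform perturbations in [-amp, amp].

    Returns an (n, 3) state array; deterministic given the seed.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    eq = np.asarray(equilibrium, dtype=float).reshape(1, 3)
    rng = np.random.default_rng(seed)
    return eq + rng.uniform(-amplitude, amplitude, size=(n, 3))
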