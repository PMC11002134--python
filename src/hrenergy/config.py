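"""YAML run configuration shared by the CLI subcommands.

A config file has optional sections ``model``, ``coupling``, ``integration``,
``scan``, ``output`` plus a top-level ``seed``; every key is validated
against the owning dataclass's invariants before any computation and
unknown keys are rejected by name.  Defaults are the standard parameter
set (a=1, b=3, c=1, d=5, r=0.01, s=4, x_r=-1.6, dt=0.01) with a 5,000
time-unit analysis window after a 2,000 time-unit burn-in.  The effective
post-default config is echoed into the output directory so runs are
self-describing.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .model import CouplingSpec, HRParams
from .network import SmallWorldSpec
from .simulate import IntegratorConfig

__all__ = ["RunConfig", "load_config", "echo_config"]

_MODEL_KEYS = set(HRParams.__dataclass_fields__)
_INTEGRATION_KEYS = set(IntegratorConfig.__dataclass_fields__)
_COUPLING_KEYS = {"d1", "k", "x0", "network_file", "n", "K", "p"}
_SCAN_KEYS = {"parameter", "grid", "start", "stop", "step", "values"}
_OUTPUT_KEYS = {"directory", "stride", "scaled", "variant"}
_TOP_KEYS = {"model", "coupling", "integration", "scan", "output", "seed"}


@dataclass
class ScanSection:
    parameter: Optional[str] = None
    grid: Optional[np.ndarray] = None


@dataclass
class OutputSection:
    directory: str = "hrenergy-out"
    stride: int = 1
    scaled: bool = True
    variant: str = "consistent"


@dataclass
class RunConfig:
    params: HRParams
    coupling: CouplingSpec
    integration: IntegratorConfig
    scan: ScanSection
    output: OutputSection
    seed: int = 0
    network_spec: Optional[SmallWorldSpec] = None
    network_file: Optional[str] = None


def _reject_unknown(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


def load_config(source: Union[str, Path, dict, None]) -> RunConfig:
    """Parse and validate a YAML file (or pre-parsed dict) into a RunConfig."""
    if source is None:
        raw: dict = {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        raw = yaml.safe_load(Path(source).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of sections")
    _reject_unknown(raw, _TOP_KEYS, "config")

    model = dict(raw.get("model") or {})
    _reject_unknown(model, _MODEL_KEYS, "model section")
    params = HRParams(**model)  # dataclass __post_init__ enforces invariants

    integ = dict(raw.get("integration") or {})
    _reject_unknown(integ, _INTEGRATION_KEYS, "integration section")
    integ.setdefault("total_time", 7000.0)
    # 2,000 tu of transient shedding by default, shrunk for short runs
    integ.setdefault("burn_in", min(2000.0, 0.4 * float(integ["total_time"])))
    integration = IntegratorConfig(**integ)

    coup = dict(raw.get("coupling") or {})
    _reject_unknown(coup, _COUPLING_KEYS, "coupling section")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ValueError("seed must be an integer")
    network_spec = None
    if any(k in coup for k in ("n", "K", "p")):
        network_spec = SmallWorldSpec(n=int(coup.get("n", 100)),
                                      K=int(coup.get("K", 8)),
                                      p=float(coup.get("p", 0.01)),
                                      seed=seed)
    coupling = CouplingSpec(d1=float(coup.get("d1", 0.0)),
                            k=float(coup.get("k", 0.0)),
                            x0=float(coup.get("x0", 0.0)))

    scan_raw = dict(raw.get("scan") or {})
    _reject_unknown(scan_raw, _SCAN_KEYS, "scan section")
    grid = None
    if scan_raw.get("values") is not None or scan_raw.get("grid") is not None:
        vals = scan_raw.get("values")
        grid = np.asarray(vals if vals is not None else scan_raw["grid"], float)
    elif {"start", "stop", "step"} <= set(scan_raw):
        grid = np.arange(scan_raw["start"], scan_raw["stop"] + 1e-12,
                         scan_raw["step"])
    scan = ScanSection(parameter=scan_raw.get("parameter"), grid=grid)

    out_raw = dict(raw.get("output") or {})
    _reject_unknown(out_raw, _OUTPUT_KEYS, "output section")
    output = OutputSection(**out_raw)
    if output.stride < 1:
        raise ValueError("output stride must be >= 1")
    if output.variant not in ("consistent", "as_printed"):
        raise ValueError("output variant must be 'consistent' or 'as_printed'")

    return RunConfig(params=params, coupling=coupling, integration=integration,
                     scan=scan, output=output, seed=seed,
                     network_spec=network_spec,
                     network_file=coup.get("network_file"))


def echo_config(config: RunConfig, path: Union[str, Path]) -> None:
    """Write the effective (post-default) config back out as YAML."""
    doc = {
        "model": asdict(config.params),
        "coupling": {"d1": config.coupling.d1, "k": config.coupling.k,
                     "x0": config.coupling.x0},
        "integration": asdict(config.integration),
        "scan": {"parameter": config.scan.parameter,
                 "grid": None if config.scan.grid is None
                 else [float(v) for v in config.scan.grid]},
        "output": asdict(config.output),
        "seed": config.seed,
    }
    if config.network_spec is not None:
        doc["coupling"].update(n=config.network_spec.n, K=config.network_spec.K,
                               p=config.network_spec.p)
    if config.network_file:
        doc["coupling"]["network_file"] = config.network_file
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
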