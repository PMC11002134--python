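"""Parameter-scan experiments: synchronization, regimes, bifurcation, energy.

Three experiment families are covered:

* coupling-strength and degree scans of the full small-world network,
  scored by a synchronization error (time-averaged cross-node standard
  deviation of the membrane potential) and exported as space-time pattern
  matrices;
* regime classification of single-neuron (mean-field reduced) runs into
  resting / periodic / irregular, via post-transient amplitude, spike
  counts and the interspike-interval coefficient of variation;
* bifurcation scans sweeping one of {Di, d1, x0, Iext}, recording
  post-transient local extrema of x alongside the windowed energy
  summaries (H1, H2 ranges) for each grid value.

All scans integrate the whole grid as one batched Euler run, so a
50-point sweep costs one trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .energy import EnergyRecord, EnergySummary, energy_summary, hamiltonian, hdot_formula
from .model import (CouplingSpec, HRParams, equilibrium_reduced,
                    equilibrium_uncoupled, rhs_network, rhs_reduced)
from .network import SmallWorldSpec, generate_small_world
from .simulate import (BlowUpError, IntegratorConfig, Trajectory, integrate,
                       settle_window)

__all__ = [
    "SyncResult",
    "RegimeLabel",
    "SpikeStats",
    "BifurcationResult",
    "sync_error",
    "regime_classify",
    "spike_stats",
    "local_extrema",
    "cluster_extrema",
    "bifurcation_scan",
    "pattern_scan",
    "count_sync_clusters",
]

SCAN_PARAMETERS = ("Di", "d1", "x0", "Iext")

# label thresholds, scale-free relative to the HR attractor amplitude (~2-4)
SYNC_THRESHOLD = 1e-3
PARTIAL_SYNC_THRESHOLD = 0.5
RESTING_AMPLITUDE_TOL = 0.01
PERIODIC_CV_TOL = 0.05
SPIKE_THRESHOLD = 1.0
SPIKE_REFRACTORY = 1.0


@dataclass
class SyncResult:
    """One grid value of a pattern scan over d1 or K."""

    parameter: float
    sync_error: float
    pattern: np.ndarray  # nodes x recorded steps, membrane potential
    label: str
    n_clusters: Optional[int] = None


@dataclass(frozen=True)
class RegimeLabel:
    """resting / periodic / irregular with the diagnostics behind the call."""

    label: str
    amplitude: float
    n_spikes: int
    isi_cv: float


@dataclass(frozen=True)
class SpikeStats:
    times: np.ndarray
    count: int
    frequency: float
    isi_cv: float


@dataclass
class BifurcationResult:
    """Per-grid-value extrema, energy summaries and regime labels."""

    parameter: str
    grid: np.ndarray
    extrema: List[np.ndarray]        # local max/min values of x per grid point
    n_branches: np.ndarray           # distinct extremum values (clustered)
    summaries: List[Optional[EnergySummary]]
    labels: List[Optional[RegimeLabel]]
    blown_up: np.ndarray             # bool flag per grid point

    @property
    def H1(self) -> np.ndarray:
        return np.array([s.H1 if s else np.nan for s in self.summaries])

    @property
    def deltaH(self) -> np.ndarray:
        return np.array([s.deltaH if s else np.nan for s in self.summaries])

    @property
    def deltaHdot(self) -> np.ndarray:
        return np.array([s.deltaHdot if s else np.nan for s in self.summaries])

    @property
    def regimes(self) -> List[str]:
        return [lab.label if lab else "blow_up" for lab in self.labels]


def sync_error(trajectory: Trajectory, burn_in: Optional[float] = None) -> float:
    """Time-averaged cross-node standard deviation of x after burn-in."""
    x = trajectory.x
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("sync_error needs a network trajectory with n >= 2 nodes")
    if burn_in is None:
        burn_in = trajectory.config.burn_in
    post = trajectory.after(burn_in)
    return float(post.x.std(axis=1).mean())


def _sync_label(err: float) -> str:
    if err < SYNC_THRESHOLD:
        return "synchronized"
    if err < PARTIAL_SYNC_THRESHOLD:
        return "partial_sync"
    return "asynchronous"


def spike_stats(trajectory: Trajectory, burn_in: Optional[float] = None,
                threshold: float = SPIKE_THRESHOLD,
                refractory: float = SPIKE_REFRACTORY) -> SpikeStats:
    """Spikes as upward threshold crossings with a refractory gap.

    HR action potentials overshoot x = 1 while subthreshold wobble stays
    below it, so a plain upward crossing of 1.0 with a >= 1 time-unit
    refractory gap counts spikes robustly.  Zero spikes is a valid result.
    """
    if burn_in is None:
        burn_in = trajectory.config.burn_in
    post = trajectory.after(burn_in)
    x = post.x
    if x.ndim != 1:
        raise ValueError("spike_stats expects a single-node trajectory")
    up = np.nonzero((x[:-1] < threshold) & (x[1:] >= threshold))[0]
    times = post.times[up + 1]
    if len(times):
        keep = [times[0]]
        for t in times[1:]:
            if t - keep[-1] >= refractory:
                keep.append(t)
        times = np.asarray(keep)
    window = post.times[-1] - post.times[0]
    isi = np.diff(times)
    cv = float(isi.std() / isi.mean()) if len(isi) >= 2 and isi.mean() > 0 else np.nan
    return SpikeStats(times=times, count=len(times),
                      frequency=len(times) / window if window > 0 else np.nan,
                      isi_cv=cv)


def regime_classify(trajectory: Trajectory, burn_in: Optional[float] = None,
                    amplitude_tol: float = RESTING_AMPLITUDE_TOL,
                    cv_tol: float = PERIODIC_CV_TOL) -> RegimeLabel:
    """resting / periodic / irregular from the post-transient membrane potential.

    resting: amplitude (max - min of x) below ``amplitude_tol``.  Otherwise
    oscillation cycles are counted as upward crossings of the amplitude
    midpoint — mean-field coupling can hold a perfectly periodic orbit
    entirely below the absolute action-potential threshold of 1.0, so cycle
    detection must be amplitude-aware rather than use the fixed spike
    threshold.  periodic: >= 3 cycles with inter-cycle-interval CV below
    ``cv_tol``; anything else is irregular.
    """
    if burn_in is None:
        burn_in = trajectory.config.burn_in
    post = trajectory.after(burn_in)
    if len(post.times) < 3:
        raise ValueError("trajectory shorter than burn-in")
    x = post.x
    if x.ndim != 1:
        raise ValueError("regime_classify expects a single-node trajectory")
    amplitude = float(x.max() - x.min())
    if amplitude < amplitude_tol:
        return RegimeLabel(label="resting", amplitude=amplitude,
                           n_spikes=0, isi_cv=float("nan"))
    midpoint = 0.5 * float(x.max() + x.min())
    stats = spike_stats(trajectory, burn_in, threshold=midpoint)
    if stats.count >= 3 and np.isfinite(stats.isi_cv) and stats.isi_cv < cv_tol:
        label = "periodic"
    else:
        label = "irregular"
    return RegimeLabel(label=label, amplitude=amplitude,
                       n_spikes=stats.count, isi_cv=stats.isi_cv)


def local_extrema(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Strict interior local maxima and minima of a series."""
    x = np.asarray(x)
    mid = x[1:-1]
    maxima = mid[(mid > x[:-2]) & (mid > x[2:])]
    minima = mid[(mid < x[:-2]) & (mid < x[2:])]
    return maxima, minima


def cluster_extrema(values: np.ndarray, tol: float = 1e-4) -> int:
    """Count distinct extremum branches, merging values within tol."""
    values = np.sort(np.asarray(values, float))
    if len(values) == 0:
        return 0
    return int(1 + np.sum(np.diff(values) > tol))


def _scan_arrays(parameter: str, grid: np.ndarray, params: HRParams,
                 coupling: CouplingSpec):
    """Per-grid-point (D, x0, I_ext) arrays for a scan over `parameter`."""
    m = len(grid)
    D = np.full(m, float(np.asarray(coupling.D)))
    x0 = np.full(m, float(np.asarray(coupling.x0)))
    I = np.full(m, params.I_ext)
    if parameter == "Di":
        D = grid.copy()
    elif parameter == "d1":
        k = float(np.asarray(coupling.k))
        D = grid * k
    elif parameter == "x0":
        x0 = grid.copy()
    elif parameter == "Iext":
        I = grid.copy()
    else:
        raise ValueError(f"parameter must be one of {SCAN_PARAMETERS}")
    return D, x0, I


def bifurcation_scan(parameter: str, grid: Sequence[float], params: HRParams,
                     coupling: CouplingSpec, config: IntegratorConfig,
                     seed: int = 0, perturbation: float = 0.1,
                     scaled: bool = True,
                     variant: str = "consistent") -> BifurcationResult:
    """Sweep one parameter of the reduced system; batched Euler integration.

    For each grid value the run starts at that point's own equilibrium plus
    a seeded uniform perturbation, integrates through the burn-in, then
    collects strict local extrema of x, an energy summary windowed from the
    settled cycle start, and a regime label.  A blow-up at a grid point is
    flagged and the scan continues.
    """
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-empty and strictly increasing")
    D, x0, I = _scan_arrays(parameter, grid, params, coupling)
    m = len(grid)

    rng = np.random.default_rng(seed)
    init = np.empty((m, 3))
    for j in range(m):
        eq = equilibrium_reduced(params.replace(I_ext=I[j]),
                                 CouplingSpec.from_aggregate(D[j], x0[j]))
        init[j] = eq.state
    init = init + rng.uniform(-perturbation, perturbation, size=(m, 3))

    base = params.replace(I_ext=0.0)
    vec_coupling = CouplingSpec.from_aggregate(D, x0)

    def rhs(s):
        d = rhs_reduced(s, base, vec_coupling)
        d[..., 0] += I
        return d

    cfg = config if config.record_start > 0 else replace(
        config, record_start=config.burn_in)
    blown = np.zeros(m, dtype=bool)
    try:
        traj = integrate(rhs, init, cfg)
        cols = [Trajectory(traj.times, traj.states[:, j, :], cfg) for j in range(m)]
    except BlowUpError:
        # rare: fall back to per-point runs so one divergence cannot sink the scan
        cols = []
        for j in range(m):
            cj = CouplingSpec.from_aggregate(D[j], x0[j])
            pj = params.replace(I_ext=I[j])
            try:
                cols.append(integrate(lambda s: rhs_reduced(s, pj, cj), init[j], cfg))
            except (BlowUpError, ValueError):
                blown[j] = True
                cols.append(None)

    extrema, n_branches, summaries, labels = [], [], [], []
    for j in range(m):
        tr = cols[j]
        if tr is None:
            extrema.append(np.empty(0))
            n_branches.append(0)
            summaries.append(None)
            labels.append(None)
            continue
        maxima, minima = local_extrema(tr.x)
        vals = np.concatenate([maxima, minima])
        extrema.append(vals)
        n_branches.append(cluster_extrema(vals))
        t0 = settle_window(tr)
        pj = params.replace(I_ext=I[j])
        cj = CouplingSpec.from_aggregate(D[j], x0[j])
        H = hamiltonian(tr.states, pj, cj, scaled=False)
        Hd = hdot_formula(tr.states, pj, cj, variant)
        if scaled:
            H, Hd = H / 100.0, Hd / 100.0
        rec = EnergyRecord(tr.times, H, Hd, variant, scaled)
        summaries.append(energy_summary(rec, t0, float(tr.times[-1] - t0)))
        labels.append(regime_classify(tr))
    return BifurcationResult(parameter=parameter, grid=grid, extrema=extrema,
                             n_branches=np.asarray(n_branches),
                             summaries=summaries, labels=labels,
                             blown_up=blown)


def count_sync_clusters(trajectory: Trajectory, burn_in: Optional[float] = None,
                        within_tol: float = 1e-2) -> int:
    """Number of node clusters that are internally synchronized.

    Two nodes share a cluster when the RMS difference of their post-burn-in
    membrane potentials is below ``within_tol`` (greedy single-linkage).
    Several clusters alongside a large global sync error is the signature
    of simultaneous partial synchrony ("multiple memories"); reported as a
    diagnostic, never asserted.
    """
    if burn_in is None:
        burn_in = trajectory.config.burn_in
    x = trajectory.after(burn_in).x  # steps x nodes
    n = x.shape[1]
    assigned = np.full(n, -1)
    n_clusters = 0
    for i in range(n):
        if assigned[i] >= 0:
            continue
        assigned[i] = n_clusters
        diff = np.sqrt(((x - x[:, [i]]) ** 2).mean(axis=0))
        assigned[(assigned < 0) & (diff < within_tol)] = n_clusters
        n_clusters += 1
    return n_clusters


def pattern_scan(values: Sequence[float], vary: str, spec: SmallWorldSpec,
                 params: HRParams, config: IntegratorConfig, d1: float = 1.0,
                 ic_amplitude: float = 0.1, ic_seed: int = 0,
                 report_clusters: bool = False) -> List[SyncResult]:
    """Sync/pattern scan over coupling strength d1 or ring degree K.

    The network seed and the initial-condition draw are shared across grid
    values, so the scanned parameter is the only thing varying.  Returns
    one :class:`SyncResult` (sync error, space-time matrix, label) per value.
    """
    if vary not in ("d1", "K"):
        raise ValueError("vary must be 'd1' or 'K'")
    if not len(values):
        raise ValueError("grid of scan values must be non-empty")
    from .scenarios import initial_conditions

    eq = equilibrium_uncoupled(params)
    init = initial_conditions(spec.n, eq.state, ic_amplitude, ic_seed)
    results = []
    for v in values:
        if vary == "d1":
            net = generate_small_world(spec)
            strength = float(v)
        else:
            net = generate_small_world(replace(spec, K=int(v)))
            strength = d1
        traj = integrate(lambda s: rhs_network(s, params, net, strength),
                         init, config)
        err = sync_error(traj)
        res = SyncResult(parameter=float(v), sync_error=err,
                         pattern=traj.x.T.copy(), label=_sync_label(err))
        if report_clusters:
            res.n_clusters = count_sync_clusters(traj)
        results.append(res)
    return results
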