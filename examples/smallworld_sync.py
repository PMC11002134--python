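"""Synchronization of HR neurons coupled on a small-world network.

Builds W(60, 8, 0.01), integrates the full network at two coupling
strengths (I_ext = 4, seeded initial conditions near the uncoupled
equilibrium) and scores each run with the synchronization error: the
time-averaged cross-node standard deviation of the membrane potential.
"""

from hrenergy import (HRParams, IntegratorConfig, SmallWorldSpec,
                      generate_small_world, pattern_scan)

p = HRParams(I_ext=4.0)
spec = SmallWorldSpec(n=60, K=8, p=0.01, seed=7)
net = generate_small_world(spec)
print(f"network: n={net.n}, edges={net.n_edges}, "
      f"degrees {int(net.degrees.min())}..{int(net.degrees.max())}")

cfg = IntegratorConfig(dt=0.01, total_time=1000.0, burn_in=500.0,
                       record_stride=10)
results = pattern_scan([0.01, 1.0], "d1", spec, p, cfg, ic_seed=3,
                       report_clusters=True)
for r in results:
    print(f"d1 = {r.parameter:4.2f}: sync_error = {r.sync_error:.3f} "
          f"({r.label}, {r.n_clusters} cluster(s))")
print("-> stronger coupling pulls the neurons toward a common firing")
print("   pattern; the dispersion of membrane potentials shrinks.")
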