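"""Spike frequency grows with the stimulus from neighbouring neurons.

At weak coupling (D = 0.1) the drive level x0 acts like an external
current: sweeping x0 over {5, 10, 20} raises the firing rate of the
reduced neuron, and the spikes overshoot the absolute threshold x = 1.
"""

from hrenergy import CouplingSpec, HRParams, IntegratorConfig, bifurcation_scan

p = HRParams(I_ext=1.0)
cfg = IntegratorConfig(dt=0.01, total_time=4000.0, burn_in=2000.0)
res = bifurcation_scan("x0", [5.0, 10.0, 20.0], p,
                       CouplingSpec.from_aggregate(D=0.1, x0=1.0),
                       cfg, seed=1)

window = cfg.total_time - cfg.burn_in
print(" x0   cycles  freq (1/tu)   deltaH")
for j, v in enumerate(res.grid):
    lab = res.labels[j]
    print(f"{v:4.0f}   {lab.n_spikes:5d}   {lab.n_spikes / window:8.4f}"
          f"   {res.deltaH[j]:8.4f}")
print("-> stronger neighbour stimulus means faster firing; the energy range")
print("   deltaH stays wide because every spike releases a burst of energy.")
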