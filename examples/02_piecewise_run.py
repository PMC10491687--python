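"""One full crossover trajectory: classical -> fractional -> stochastic.

Runs the baseline scenario with the power-law kernel at order 0.95
(classical on [0,10], fractional on [10,20], stochastic on [20,30] days),
audits positivity and writes the trajectory as CSV + JSON sidecar.
"""

import numpy as np

from malnut import PiecewiseSchedule, baseline_scenario, piecewise_solve, write_trajectory
from malnut.analysis import positivity_check

scenario = baseline_scenario()
schedule = PiecewiseSchedule(dz=0.01, T1=10.0, T2=20.0, T=30.0)
traj = piecewise_solve(
    scenario.params, scenario.noise, scenario.y0.as_array(),
    schedule, order=0.95, kernel="power_law", seed=1,
)

print(f"grid points: {len(traj)}  (dz = {schedule.dz} d)")
for label in ("classical", "fractional", "stochastic"):
    idx = np.flatnonzero(traj.regime == label)
    t0, t1 = traj.times[idx[0]], traj.times[idx[-1]]
    print(f"  {label:10s} regime: t in [{t0:5.2f}, {t1:5.2f}] d, {idx.size} points")

for t in (0.0, 10.0, 20.0, 30.0):
    s = traj.states[traj.index_of_time(t)]
    print(f"  state at t={t:4.0f} d: Sf={s[0]:8.4f}  Mb={s[1]:7.4f}  Mg={s[2]:7.4f}  U={s[3]:7.4f}")

report = positivity_check(traj)
print(f"positivity audit: {'clean' if report.clean else 'violated'}; "
      f"per-compartment minima {np.round(report.min_values, 4)}")

csv_path, json_path = write_trajectory(traj, "scratch/baseline_run", scenario=scenario)
print(f"wrote {csv_path} and {json_path}")
print()
print("The susceptible pool decays from 30 toward its endemic level while the")
print("malnourished and underweight compartments relax to small positive values;")
print("after t=20 d the path fluctuates under multiplicative white noise.")
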