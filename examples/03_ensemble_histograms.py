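"""Monte-Carlo ensemble of crossover runs with terminal-time histograms.

The stochastic regime's stationary behaviour is summarised by per-time
ensemble moments and by terminal histograms with moment-fitted normal
densities (the frequency-plot diagnostic for the stationary distribution).
"""

from malnut import PiecewiseSchedule, baseline_scenario
from malnut.analysis import run_ensemble, terminal_histogram

scenario = baseline_scenario()
schedule = PiecewiseSchedule(dz=0.01, T1=10.0, T2=20.0, T=30.0)
summary = run_ensemble(scenario, schedule, order=0.95, kernel="power_law",
                       n_paths=400, seed=7)

print(f"{summary.n_paths} paths, {len(summary.times)} grid points each")
print("terminal-time (t = 30 d) ensemble statistics:")
print(f"  {'comp':4s} {'mean':>9s} {'variance':>10s} {'2.5%':>9s} {'97.5%':>9s}")
for k, name in enumerate(("Sf", "Mb", "Mg", "U")):
    print(
        f"  {name:4s} {summary.mean[-1, k]:9.4f} {summary.variance[-1, k]:10.5f} "
        f"{summary.quantiles[0, -1, k]:9.4f} {summary.quantiles[2, -1, k]:9.4f}"
    )

print()
print("terminal histograms (moment-fitted normal overlays):")
for name in ("Sf", "Mb", "Mg", "U"):
    h = terminal_histogram(summary, name, n_bins=25)
    occupied = int((h.counts > 0).sum())
    print(f"  {name:4s}: N(mean={h.fitted_mean:.4f}, var={h.fitted_variance:.5f}), "
          f"{occupied}/25 bins occupied")

print()
print("Nonzero ensemble spread appears only after the stochastic onset at")
print("t = 20 d; the fitted normals summarise the terminal law the same way")
print("stationary-distribution frequency plots do.")
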