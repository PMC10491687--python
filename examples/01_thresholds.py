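"""Threshold arithmetic at the baseline design point.

Computes the deterministic basic reproduction number R0, the
next-generation-matrix spectral radius, the noise-adjusted stochastic
threshold R0^s and the Lyapunov constants, then classifies persistence.
"""

from malnut import baseline_scenario
from malnut.analysis import threshold_report

report = threshold_report(baseline_scenario())

print("Threshold report (baseline scenario)")
for key in ("R0", "ngm_spectral_radius", "R0_s", "psi1", "psi2", "psi3", "psi5"):
    print(f"  {key:20s} = {report[key]:.6f}")
print(f"  classification       = {report['classification']}")

print()
print("R0 < 1: the deterministic model's malnutrition-free state is stable,")
print("yet R0^s > 1: multiplicative noise at the stated intensities pushes the")
print("stochastic model into its ergodic persistence regime — malnutrition")
print("fluctuates around a stationary distribution instead of dying out.")
print("psi5 = 4(B+eps)[(R0^s)^{1/4} - 1] > 0 is the margin in the Lyapunov")
print("drift bound certifying that stationary law.")
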