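# Baseline malnutrition-model configuration (tabulated study values).
# Rates are per day; compartments are person-counts.
label = baseline

B = 0.01        # recruitment of new females
eps = 0.001     # vertical spread to newborns
lam_b = 0.1     # susceptible -> malnourished-boy transfer
lam_g = 0.2     # susceptible -> malnourished-girl transfer
theta = 0.1     # death rate
theta_b = 0.3   # natural restoration (boys)
gam_b = 0.01    # boy malnourished -> underweight progression
gam_g = 0.1     # girl malnourished -> underweight progression
chi_b = 0.014   # underweight -> malnourished-boy return
chi_g = 0.01    # underweight -> malnourished-girl return
del_g = 0.1     # girl recovery
theta1 = 0.0    # health-promotion evaluation (recorded, unused)
theta2 = 0.0    # treatment rate (recorded, unused)

sigma1 = 0.08   # white-noise intensities
sigma2 = 0.09
sigma3 = 0.1
sigma4 = 0.12

Sf0 = 30        # initial state
Mb0 = 2
Mg0 = 4
U0 = 1
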