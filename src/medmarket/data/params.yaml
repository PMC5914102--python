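# Baseline parameter set for the bundled four-zone example network.
params:
  mu1: 20.0          # patient waiting-time value ($/h)
  mu2: 10.0          # patient in-service-time value ($/h)
  omega1: 0.2        # patient mode-choice dispersion
  omega2: 0.2        # doctor mode-choice dispersion
  omega3: 0.5        # doctor within-mode-1 dispersion
  omega4: 0.5        # doctor within-mode-2 dispersion
  alpha1: 1.0        # meeting-rate elasticity, unserved patients
  alpha2: 1.0        # meeting-rate elasticity, idle doctors
  efficiency: 1.0    # zone matching efficiency A_j
  a_tilde: 1.0e+4     # app-channel friction constant
  pi_t: 10.0         # doctor activity cost ($/h)
  z_bar: 0.0         # extra app-mode patient wait (h)
  attractiveness: 0.0  # patient-information attractiveness y_j ($)
  lam: 1.0           # profitability index
  n_doctors: 100     # doctor-hours per unit period
network:
  fee_rate: 60.0     # F_ij = fee_rate * t_ij ($/h)
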