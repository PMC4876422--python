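# Default fitted parameter set: ex vivo beef liver, two-needle electrodes.
# Values in strict SI; unit-suffixed strings (e.g. "100 us") are also accepted.
parameters:
  sigma0: 0.065        # initial tissue conductivity, S/m
  sigmaMax: 0.1483     # final (fully porated) tissue conductivity, S/m
  Emin: 20000.0        # lower limit of the linear poration ramp, V/m
  Emax: 40000.0        # upper limit of the linear poration ramp, V/m
  tauRelax: 100.0e-6   # specific time of poration relaxation, s
  Apg: 0.35            # amplitude of the pore-growth model
  tauPg: 15.0e-6       # specific time of the pore-growth model, s
  AT: 0.125            # amplitude of the thermal model
  tauT: 1.75           # specific time of thermal diffusion, s
  alphaP: 0.0015       # amplitude of the poration damage model, m/V
  alphaT: 25.0         # amplitude of the thermal damage model, m/V
  AC: 0.0005           # amplitude of the capacitive model, 1/m^2
  R: 15.0              # resistance in the capacitive model, Ohm
  C: 1.2e-7            # capacitance in the capacitive model, F
  dtMin: 2.0e-6        # smallest adaptive simulation time step, s
  dtMax: 0.99          # largest adaptive simulation time step, s
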