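# Stand-in sampling schemes for the Monte-Carlo scans.
#
# The fixed rates below are package calibrations ("stand-in" values): they
# were chosen so that (a) the three-phosphoform model's oscillating region
# is non-trivial at Kd = 1e-4 with a ~24 h median period, and (b) the
# TTFL/PTR comparison reproduces the expected ordering and approximate
# magnitudes of the oscillating fractions.  Every entry can be overridden
# from a user config file (see circlock.param_sampling.load_ranges).
core:
  fixed:
    k2: 0.15
    k3: 0.15
    k4: 0.15
  uniform:
    k1: [0.0, 1.0]
    A_T: [0.0, 100.0]
    C_T: [0.0, 100.0]
ttfl:
  fixed:
    k1: 0.1
    k2: 0.15
    k3: 0.15
    k4: 0.15
    Kd: 1.0e-5
    V_trsp: 0.17
    V_m: 0.5
    V_d: 0.05
    K_0: 100.0
  uniform:
    K_s: [0.0, 100.0]
    A_T: [0.0, 100.0]
phospholock:
  uniform:
    A_T: [0.0, 100.0]
    alpha1: [0.0, 100.0]
    beta1: [0.0, 100.0]
    alpha2: [0.0, 100.0]
    beta2: [0.0, 100.0]
    alpha3: [0.0, 100.0]
    beta3: [0.0, 100.0]
    k1f: [0.0, 1.0]
    k2f: [0.0, 1.0]
    k3: [0.0, 0.1]
activator_phospho:
  uniform:
    A_T: [0.0, 100.0]
    alpha1: [0.0, 100.0]
    beta1: [0.0, 100.0]
    alpha2: [0.0, 100.0]
    beta2: [0.0, 100.0]
    alpha3: [0.0, 100.0]
    beta3: [0.0, 100.0]
    k1f: [0.0, 1.0]
    k2r: [0.0, 1.0]
    k4f: [0.0, 1.0]
  fixed:
    Kd: 1.0e-5
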