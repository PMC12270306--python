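# Matrix-production network parameters (units: µM, h).
# Provenance: kdegm, kdegpro and the elevated SlrR turnover are literature-
# standard values; every other value is this package's own calibration
# (docs/methods.md, "Calibration of the matrix network"): the network is
# bistable at g = 0.2 1/h with a deactivation threshold near 0.1 µM Spo0A~P,
# ON/OFF TapA branches separated by more than an order of magnitude, and a
# threshold that rises steeply with the Spo0A~P oscillation period.
# Transcription/translation are factored so only their product enters the
# deterministic model; the split (low transcription, high translation)
# sets the burst noise of the stochastic variant.
sinI: {v0: 0.001,  vmax: 0.021625, K: 0.08, ktran: 80.0, p: 0.79}
sinR: {v0: 0.0338, vmax: 0.0,    K: 1.0,  ktran: 80.0, p: 0.79}
slrR: {v0: 0.0005, vmax: 0.035,  K: 0.15, ktran: 80.0, p: 0.26}
tapA: {v0: 0.0005, vmax: 0.06,   K: 0.03, ktran: 20.0, p: 0.78}
kdegm: 8.3         # 1/h, mRNA degradation
kdegpro: 0.2       # 1/h, protein degradation (dilution g is added)
kdegpro_slrR: 0.8  # 1/h, free SlrR is unstable
kdegpro_sinI: 2.0  # 1/h, free SinI is unstable (fast antagonist turnover)
kdegpro_lr: 0.9    # 1/h, SlrR·SinR complex turnover
kon_rt: 10.0       # 1/(µM h), SinR dimer -> tetramer association
koff_rt: 10.0      # 1/h, tetramer dissociation
kon_ir: 500.0      # 1/(µM h), SinI·SinR association
koff_ir: 10.0      # 1/h, IR dissociation
kon_lr: 120.0      # 1/(µM h), SlrR·SinR association
koff_lr: 10.0      # 1/h, LR dissociation
size: {a: 3.5, b: -0.6931471805599453, c: 3.7}
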