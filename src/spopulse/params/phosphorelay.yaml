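# Phosphorelay model rate constants (units: µM, h).
# Provenance: every value is this package's own calibration (see
# docs/methods.md, "Calibration of the phosphorelay"), chosen to give
# (i) one deep Spo0A~P pulse per cell cycle with the trough around the end
# of the DNA replication window and the overshoot in the post-replication
# phase, (ii) pulse amplitude increasing as growth slows and saturating at
# very slow growth, and (iii) sub-threshold levels at fast growth.
genes:
  # vb/vmax: basal / Spo0A~P-induced initiation rate per gene copy per unit
  # size factor; K (µM), m: Hill constant and exponent; p: fractional
  # chromosomal position relative to oriC (0 = oriC, 1 = terminus).
  kinA:  {vb: 0.18,  vmax: 0.0,  K: 1.0, m: 1, p: 1.0}   # terminus-proximal
  spo0F: {vb: 0.05,  vmax: 0.0,  K: 1.0, m: 1, p: 0.0}   # oriC-proximal
  spo0B: {vb: 0.01,  vmax: 0.0,  K: 1.0, m: 1, p: 0.66}
  spo0A: {vb: 0.02,  vmax: 0.6,  K: 1.5, m: 1, p: 0.79}  # mild autoactivation
  rap:   {vb: 0.0115, vmax: 0.0, K: 1.0, m: 1, p: 0.1}
  spo0E: {vb: 0.0115, vmax: 0.04, K: 0.6, m: 2, p: 0.1}  # 0A~P-induced (negative feedback)
kdel: 12.0       # 1/h, production-rate relaxation (~5 min delay)
ka: 40.0         # 1/h, KinA autophosphorylation
K_inh: 0.35      # Spo0F:KinA ratio at half-maximal KinA inhibition
inh_exp: 4.0     # Hill exponent of the ratio inhibition
kp_kf: 50.0      # 1/(µM h), KinA~P -> Spo0F transfer
kp_fb: 50.0      # 1/(µM h), Spo0F~P -> Spo0B transfer
kp_ba: 100.0     # 1/(µM h), Spo0B~P -> Spo0A transfer
kph_f: 5.0       # 1/(µM h), Rap dephosphorylation of Spo0F~P
kph_a: 13.2      # 1/(µM h), Spo0E dephosphorylation of Spo0A~P
kdeg: 0.05       # 1/h, intrinsic degradation of relay proteins
kdeg_kin: 5.0    # 1/h, extra degradation of KinA forms (fast turnover lets
                 # the kinase track the kinA copy-number step within a cycle)
kdeg_f: 3.0      # 1/h, extra degradation of Spo0F forms
kdeg_ph: 0.6     # 1/h, extra degradation of the phosphatases Rap/Spo0E
size: {a: 3.5, b: -0.6931471805599453, c: 3.7}
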