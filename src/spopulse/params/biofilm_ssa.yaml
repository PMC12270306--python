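# Stochastic-model extras (units: molecules, h).
# Provenance: this package's own calibration (docs/methods.md): omega maps
# the deterministic matrix-ON branch onto the ~500-molecule TapA mode, and
# the promoter switching rates set the transcriptional noise that enables
# stochastic matrix activation/deactivation.
omega: 250.0      # molecules per µM
ku_sinI: 10.0     # 1/h, 0A~P unbinding from the sinI promoter
ku_slrR: 3.0      # 1/h, SinR-tetramer unbinding from the slrR promoter
ku_tapA: 10.0     # 1/h, SinR-tetramer unbinding from the tapA promoter
k_lock: 1.0       # 1/h, promoter locking (used only by the locked variant)
k_unlock: 2.0     # 1/h, promoter unlocking
refresh_dt: 0.005 # h, input refresh interval for time-varying signals
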