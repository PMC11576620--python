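# Default whole-protein classifier boundaries.
#
# ch_slope / ch_intercept define the literature-standard charge-hydropathy
# line <R> = 2.785 <H> - 1.151 separating ordered from disordered proteins
# in mean-net-charge vs mean-scaled-hydropathy space.
#
# cdf_boundary is a SYNTHETIC 7-point order/disorder boundary in CDF space
# (score threshold x, cumulative fraction y), a diagonal offset chosen so
# that fully ordered tracks fall well above it; replace with a
# predictor-specific calibrated table for real data.
ch_slope: 2.785
ch_intercept: -1.151
hydropathy_window: 5
cdf_boundary:
  - [0.15, 0.22]
  - [0.25, 0.32]
  - [0.35, 0.42]
  - [0.45, 0.52]
  - [0.55, 0.62]
  - [0.65, 0.72]
  - [0.75, 0.82]
# Kyte-Doolittle hydropathy scale (raw; rescaled to [0,1] internally).
hydropathy_scale:
  A: 1.8
  R: -4.5
  N: -3.5
  D: -3.5
  C: 2.5
  Q: -3.5
  E: -3.5
  G: -0.4
  H: -3.2
  I: 4.5
  L: 3.8
  K: -3.9
  M: 1.9
  F: 2.8
  P: -1.6
  S: -0.8
  T: -0.7
  W: -0.9
  Y: -1.3
  V: 4.2
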