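name: fig3b_508
description: >
  Target model for carotenoid (508 nm) excitation of the astaxanthin-binding
  LHC monomer.  S2 branches into hot S1 and S*; S2, hot S1 and S1 transfer
  excitation to the chlorophyll pool, which is quenched by the dark state
  S_q.  A parallel uS2/uS1 branch models astaxanthin unconnected to the
  chlorophylls.  Rates in ns^-1.  Loss entries are decay to the ground
  state; the printed dark-state rates (183, 133, 84 ns^-1) are carried as
  ground losses, so a compartment's total decay is loss plus its transfer
  edges (e.g. S1 total = 183 + 366 = 549 ns^-1 under this bookkeeping).
compartments: [S2, hotS1, S1, Sstar, Sq, Chl, uS2, uS1]
transfers:
  S2 -> hotS1: 6000.0
  S2 -> Sstar: 5000.0
  S2 -> Chl: 7000.0
  hotS1 -> S1: 2882.0
  hotS1 -> Chl: 3000.0
  S1 -> Chl: 366.0
  Chl -> Sq: 3.0
  uS2 -> uS1: 18000.0
losses:
  S2: 2000.0
  S1: 183.0
  Sstar: 133.0
  Sq: 84.0
  Chl: 0.5
  uS1: 189.0
input:
  S2: 0.5
  uS2: 0.5
irf:
  center_ps: 0.0
  fwhm_fs: 120.0
provenance:
  S2 -> Chl: printed
  hotS1 -> Chl: printed
  S1 -> Chl: printed
  S1 -> ground: printed
  Sstar -> ground: printed
  Sq -> ground: printed
  S2 -> hotS1: free
  S2 -> Sstar: free
  S2 -> ground: free
  hotS1 -> S1: free
  Chl -> Sq: free
  Chl -> ground: free
  uS2 -> uS1: free
  uS1 -> ground: free
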