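name: fig3d_690
description: >
  Target model for chlorophyll (690 nm) excitation.  Three Chl a pools
  (a1 lowest energy, preferentially pumped at 690 nm) equilibrate uphill
  and are quenched into the shared dark state S_q at rates spanning the
  printed 1.59-5.07 ns^-1 range; minor triplet channels form Chl T and
  Car T.  Rates in ns^-1; losses are decay to the ground state.
compartments: [Chl_a1, Chl_a2, Chl_a3, Sq, ChlT, CarT]
transfers:
  Chl_a1 -> Chl_a2: 450.0
  Chl_a2 -> Chl_a3: 150.0
  Chl_a1 -> Sq: 1.59
  Chl_a2 -> Sq: 3.0
  Chl_a3 -> Sq: 5.07
  Chl_a1 -> ChlT: 0.2
  ChlT -> CarT: 50.0
losses:
  Chl_a1: 0.5
  Chl_a2: 0.6
  Chl_a3: 0.7
  Sq: 84.0
  CarT: 0.05
input:
  Chl_a1: 0.7
  Chl_a2: 0.3
irf:
  center_ps: 0.0
  fwhm_fs: 120.0
provenance:
  Chl_a1 -> Sq: printed
  Chl_a3 -> Sq: printed
  Sq -> ground: printed
  Chl_a1 -> Chl_a2: free
  Chl_a2 -> Chl_a3: free
  Chl_a2 -> Sq: free
  Chl_a1 -> ChlT: fixed-small
  ChlT -> CarT: fixed-small
  Chl_a1 -> ground: free
  Chl_a2 -> ground: free
  Chl_a3 -> ground: free
  CarT -> ground: fixed-small
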