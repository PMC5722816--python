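# astakin

Global and target analysis of femtosecond transient-absorption (TA) data
from carotenoid-binding light-harvesting complexes (LHCs), built around the
case of monomeric LHCII binding only astaxanthin — a complex that is
constitutively quenched, so that the carotenoid's optically dark singlet
states (S1, hot S1, S\*, and the quencher state S_q) can be disentangled
from the chlorophyll dynamics by compartmental modelling.

The package is for spectroscopists who fit pump–probe matrices
ΔA(t, λ): it provides the IRF-convolved kinetic forward model, sequential
("global") fitting that yields evolution- and decay-associated difference
spectra (EADS/DADS), constrained multi-dataset target fitting that yields
species-associated spectra (SADS) and rate constants, a synthetic-data
generator shaped like the real instrument, and a small structural module
for carotenoid end-ring dihedral distributions.

## Model

Populations of a compartmental scheme follow

```
dc/dt = K c + j · g(t; μ, σ)
```

with K the rate matrix (column = source compartment, rates in ns⁻¹,
diagonal = −total decay), j the excitation vector and g a unit-area
Gaussian instrument response (σ ≈ 51 fs for a 120-fs-FWHM IRF).  The
solution is computed analytically through the eigendecomposition of K;
each eigenmode is the closed-form convolution

```
g(k, t) = ½ · exp(k²σ²/2 − k(t−μ)) · erfc((μ + kσ² − t)/(σ√2))
```

evaluated in overflow-safe (scaled-erfc) form.  The data model is
Ψ = C(θ) Sᵀ + noise; the spectra S are linear parameters and are
eliminated analytically at every step of the nonlinear optimisation over
the rates θ (variable projection), honouring zero-region constraints
(e.g. triplet SADS zero above/below 630 nm) and spectral links (one
spectrum shared by several compartments or datasets, e.g. the quencher
S_q across the two excitation experiments).

Global analysis is the special case of an unbranched chain
1 → 2 → … → n; its EADS convert exactly to the DADS of the equivalent
parallel model through the triangular amplitude matrix of the chain.

## Worked example

Simultaneous target analysis of synthetic 508-nm (carotenoid-pumped) and
690-nm (Chl-pumped) experiments generated from the shipped models:

```sh
python analysis/01_simulate_experiments.py
python analysis/02_global_analysis.py
python analysis/03_target_analysis.py
```

The global-analysis step prints, for the 508-nm carotenoid window,

```
 generating tau (ps)   recovered (ps)   err %
                0.05           0.0501     0.2
                0.17            0.154    -9.4
                 2.7              2.7    -0.1
                 7.8             7.81     0.2
                 250              245    -1.9
               2e+03         1.82e+03    -9.1
```

i.e. the two picosecond carotenoid decay constants (2.7 ps for S1,
7.8 ps for the S\*-like species) come back essentially exactly, while the
sub-IRF and near-flat tail components carry larger uncertainty, as they
should.  The target step then re-estimates five rate constants of the
compartmental models with the quencher linked across both experiments:

```
           rate  true (ns^-1)    fitted   stderr  err %
        S1->Chl           366     327.8       18  -10.4
     S1->ground           183     157.4       12  -14.0
  Sstar->ground           133     109.8      7.5  -17.4
     Sq->ground            84     77.54      4.5   -7.7
     Chl_a3->Sq          5.07     5.085    0.017    0.3
```

The energy-transfer and quenching rates (S1→Chl, Chl→S_q) are recovered
tightly; the dark-state ground losses scatter by 10–20% at this noise
level because the quencher sits in quasi-steady state — its 12-ps
lifetime only enters through a small rise lag.  `analysis/04_ring_dihedrals.py`
runs the structural module on a synthetic multi-MODEL ensemble and
reports circular means/variances of the end-ring torsions per binding
site and membrane side.

The command-line interface mirrors these steps
(`astakin simulate | fit-global | fit-target | schemes | geometry`).

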