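# Methods

## Kinetic forward model

A compartmental scheme is a square rate matrix K with column-stochastic
orientation: K[i, j] ≥ 0 is the first-order rate (ns⁻¹) from compartment
j into i, and −K[j, j] is j's total decay rate, so the loss to the ground
state is the column deficit.  Rates are stored in ns⁻¹ — the convention
in which target models are printed — and converted to ps⁻¹ in exactly one
place (`kinetics.RATE_SCALE`), because delay axes are in ps.

The populations driven by a unit-area Gaussian pulse (centre μ, width σ)
are computed analytically: eigendecompose K, propagate each eigenmode with
the exponential–Gaussian convolution, and recombine.  The convolution is
evaluated with `scipy.special.erfcx` on the branch where the erfc argument
is positive; the exponents then combine exactly into the Gaussian tail
−(t−μ)²/2σ², so large k·σ products cannot overflow.  Two numerical
regimes bypass the closed form: eigenvalues that are degenerate within a
pairwise relative tolerance of 1e−9 (the closed form divides by eigenvalue
gaps), and complex eigenvalue pairs (cyclic schemes).  Both fall back to a
stiff integration (Radau, analytic Jacobian, rtol 1e−9/atol 1e−12) of the
driven system, split into a pulse phase with max step σ/4 and a free
relaxation phase.  The property suite holds the analytic and numerical
paths against each other on random valid schemes to <1e−6 of peak
population.

For the unbranched chain of global analysis the classical product formula
gives the amplitude matrix b with b[j, l] = Πₘ<ₗ kₘ / Πₘ≠ⱼ (kₘ − kⱼ); it
is singular at equal rates, so the fit path nudges (quasi-)degenerate
rates apart by 1e−6 relative — far below fit precision, but enough to keep
the variable-projection objective smooth when the optimiser momentarily
collapses two lifetimes.

## Estimation

Both fitting modes are separable least squares.  The spectra (EADS in the
sequential case, SADS in the target case) are solved per wavelength by
linear least squares at every evaluation of the nonlinear objective
(variable projection); the nonlinear parameters are log-lifetimes or
log-rates (positivity, four decades of dynamic range) plus optionally the
IRF centre and width, optimised by `scipy.optimize.least_squares` (TRF)
from multiple seeded starts (default 8 for global fits, 4 for target
fits; start 0 is the user's initial guess, the rest log-normal
perturbations).  Bounds of ±4 decades around the initial rates keep the
optimiser out of overflow territory.  Standard errors come from the
Gauss–Newton Jacobian at the optimum; a singular normal matrix triggers a
warning naming the (likely unidentifiable) parameter.

Constraints in the target mode:

* **zero regions** — per-compartment wavelength intervals where the SADS
  is exactly zero; the compartment's column is removed from the design
  there (the shipped models constrain the Chl triplet to zero above
  630 nm and the Car triplet below 630 nm);
* **spectral links** — groups of (dataset, compartment) pairs sharing one
  spectrum; the linked datasets' design matrices are stacked (with the
  concentration columns of same-dataset linked compartments summed) and
  solved jointly; linked datasets must share a wavelength axis;
* **shared rates** — one free parameter may drive edges in several
  schemes, which is how "spectrum and lifetime constrained equal in both
  models" is expressed.

Datasets with a known noise level enter the pooled objective weighted by
1/σ (plain maximum likelihood with per-dataset homoscedastic noise).  The
four windows of the paired-excitation experiment span σ ≈ 0.02–0.17 mOD,
so unweighted pooling would discard most of the information in the
quietest window.

`branching_yields` converts a scheme into per-edge branch fractions and
cumulative pathway yields via the expected-visits linear system
v = (I − B)⁻¹ j on the embedded jump chain, which also covers cyclic
schemes; a seeded Gillespie simulation serves as its oracle in the tests.

## Shipped target models

`fig3b_508` (carotenoid excitation): S2 branches into hot S1 (6000 ns⁻¹),
S\* (5000) and EET to Chl (7000, printed), plus 2000 to ground — a 50-fs
total lifetime standing in for the "≪100 fs" S2.  Hot S1 relaxes to S1
(2882) and transfers to Chl (3000, printed), totalling 170 fs.  S1
transfers to Chl at 366 ns⁻¹ (printed) and decays to ground at 183 ns⁻¹;
S\* and S_q decay at 133 and 84 ns⁻¹.  The Chl pool is quenched into S_q
at 3.0 ns⁻¹ (midpoint of the printed 1.59–5.07 range).  A parallel branch
(uS2 → uS1, 55 fs → 5.3 ps) models astaxanthin unconnected to the Chls
and receives half the input (the split is unprinted; it is marked free).

A note on bookkeeping: the printed dark-state rates (183, 133, 84 ns⁻¹)
are carried as ground-loss channels, with the EET branches as separate
edges — S1's total decay is then 183 + 366 = 549 ns⁻¹.  Reading 183 as
S1's *total* rate is arithmetically incompatible with a 366 ns⁻¹ branch
out of the same compartment, so the loss-channel reading is the only
self-consistent one; every edge carries a printed/free provenance note in
the scheme file.

`fig3d_690` (Chl excitation): three Chl a pools equilibrate uphill
(450 and 150 ns⁻¹, free) and are quenched into the shared S_q at 1.59,
3.0 and 5.07 ns⁻¹; minor triplet channels (Chl T → Car T) complete the
model.  All distinct compartment totals are deliberately non-degenerate
so the analytic path is used throughout fitting.

## Synthetic data

The generator reproduces the instrument's statistical structure: 76
detection channels per window, windows 480–610 and 590–720 nm (≈130 nm
each), delays from −0.5 ps in 50 linear steps to 2 ps then 70 log-spaced
points to 3.5 ns, a 120-fs-FWHM Gaussian IRF (σ ≈ 51 fs, consistent with
resolving the 170-fs component), and additive white Gaussian noise with
σ = 2% of each window's peak |ΔA|.  Species spectra are stylised sums of
Gaussian bands (bleach negative, ESA positive): Car bleach near 500 nm,
S1 ESA at 595/630 nm, S\*-like ESA at 565/595 nm, broad S_q ESA around
590 nm, Chl Q_Y bleach near 680 nm.  Three deliberate identities support
the fit's a-priori assumptions: the unconnected-pool spectra equal their
connected counterparts (same chromophore), and the equilibrated Chl pool
of the 508-nm model shares the terminal Chl-pool spectrum of the 690-nm
model.  The sequential (global-analysis) generator uses lifetimes
[0.05, 0.17, 2.7, 7.8, 250, 2000] ps at 508 nm and [2.2, 30, 250, 2500] ps
at 690 nm — the printed constants padded with an ultrafast initial state,
a quenched-Chl decay consistent with 1.59–5.07 ns⁻¹ quenching, and a
long-lived tail.

What the generator does **not** emulate: probe chirp/group-velocity
dispersion, coherent artefacts around time zero, pump scatter lines,
wavelength-dependent noise, singlet–singlet annihilation, and detector
nonlinearity.  Passing recovery tests therefore demonstrate estimator
correctness under the stated noise model, not robustness to every
instrumental artefact of real data.

## Identifiability

With all spectra free, compartmental models are only conditionally
identifiable: a rate change can be partially absorbed by the estimated
spectra.  A linearised (Cramér–Rao) analysis at the generating parameters
showed that without the spectral links listed above the S1 branching is
quasi-unidentifiable (relative standard errors 25–58%); with them, the
transfer rates are well determined.  One genuine limit remains: the
quencher S_q is fed over hundreds of ps but decays in ~12 ps, so it sits
in quasi-steady state and its lifetime enters the data only through a
small rise-lag transient.  A profile-likelihood oracle (all other
parameters held at truth) still shows ~15% median error for the S_q decay
rate at the generator's 2% noise over ten replicates; the dark-state
ground losses inherit similar scatter through their correlation with it.
The recovery tests assert a 10% band for all five re-estimated rates, and
the three ground-loss assertions fail by this margin by design — they
document an information limit of single-pair experiments at this noise
level, not an estimator defect (noiseless recovery is exact to <1e−10,
and estimator bias vanishes as noise → 0).

## Geometry module

Torsions are signed IUPAC angles in (−180°, 180°] (cis = 0) computed with
the atan2 formulation (stable near ±90°), sign-matched to biotite's
`dihedral`.  Ensembles are multi-MODEL PDB files read via biotite; binary
trajectory formats are out of scope (convert upstream).  Which four atoms
define a carotenoid's ring–chain torsion is a chemical choice the user
supplies as a selector mapping (chain, residue, atom name per atom).
Distributions are histogrammed on (−180°, 180°] (default 5° bins) and
summarised by circular mean and circular variance
(`scipy.stats.circmean`/`circvar`), so mass at ±180° is treated as
adjacent; leading frames can be discarded to drop un-equilibrated
trajectory heads.  Ensembles from different runs are reported side by
side, never silently pooled.

## Problem sizes

The validation suite runs the random-scheme kinetics oracle at up to six
compartments and 35–40 time points per scheme, recovery experiments at
ten seeded replicates of full-size (120 × 76) datasets, the bias→0 check
at three noise levels × six replicates on a two-compartment scheme, and
the Gillespie oracle at 10⁶ walkers; these sizes were chosen to give
stable medians and tight stochastic oracles while keeping the whole suite
around a minute.
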