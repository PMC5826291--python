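# Methods

`fgpore` models biomimetic nuclear pore complexes: solid-state nanopores
whose inner wall is coated with intrinsically disordered FG-nucleoporin
domains (yeast Nsp1, residues 1–601, with its expression leader and a
C-terminal cysteine anchor; and the "SG" mutant in which the hydrophobic
residues F, I, L, V of the FG domain are replaced by serine).  The package
covers the full computational arc of such a study: a one-bead-per-residue
force field and Langevin simulator, density-field analysis, a
density-based ionic-conductance relation, umbrella-sampling free-energy
profiles with Arrhenius event rates, and single-molecule current-trace
analytics, with synthetic generators standing in for the instruments.

## Coarse-grained model

Each residue is one bead at its Cα position.  Units are kJ/mol, nm, Da and
ps throughout, so kBT = 2.479 kJ/mol at 298 K.

**Bonds.** Stiff harmonic springs, r0 = 0.38 nm, k = 8000 kJ/mol/nm².  The
stability bound for the integrator timestep is checked against this
stiffest constant (dt ≤ 0.5/√(k/m_min) ≈ 0.042 ps for glycine).

**Bending and torsion.** Tabulated potentials evaluated by cubic-spline
interpolation.  The published parameterisation of these terms (derived
from Ramachandran statistics of coil regions) is not reproduced in the
source material available to this package; the shipped defaults — a mild
harmonic-like bend about 1.85 rad (k = 4 kJ/mol/rad²) and zero torsion —
are *reconstructions* and can be replaced by dropping other tables into
`ForceField(bending=…, torsion=…)`.

**Hydrophobic attraction.** An Ashbaugh–Hatch-type λ-scaled Lennard-Jones
potential: every pair has a WCA repulsive core (σ = 0.6 nm), and the
attractive well is scaled by the combined hydrophobicity
λ_ij = √(λ_i λ_j).  The geometric mean is chosen so the attraction
vanishes identically when either bead is fully hydrophilic.  Per-residue λ
values are Fauchère–Pliska octanol partition energies min–max normalised
to [0, 1] (`fgpore/data/residues.tsv`) — again a reconstruction of a
"normalised experimental partition energy" scale.  The well-depth scale
ε0 was calibrated on a measurable: with ε0 = 2.0 kJ/mol a long single-chain
run of the Nsp1 head segment (residues 1–172) reproduces its known Stokes
radius of ≈3.2 nm (the model's stated accuracy for such predictions is
±20%); ε0 = 3 kJ/mol over-collapses the head to ≈2.4 nm.  The potential is
multiplied by a C¹ smoothstep that switches it to zero between 0.8·rc and
rc = 1.8 nm, so energies and analytic forces are continuous everywhere.

**Electrostatics.** D and E carry −1e, K and R +1e, histidine is neutral
at pH 7.4.  Pairs interact by a screened Coulomb law
q_i q_j e^{−κr}/(4πε0 ε(r) r) with Debye constant κ = 1.27 nm⁻¹
(150 mM 1:1 salt at 298 K; `debye_constant` computes κ from ionic strength
from first principles) and a sigmoidal distance-dependent dielectric
rising from ~10 at contact to 80 in bulk (midpoint 0.4 nm, width 0.15 nm —
the exact curve is config-exposed because only its qualitative form is
specified).  The same C¹ switch applies at the electrostatic cutoff
(default 2.4 nm; the desk-scale pore presets use 1.5–1.8 nm, which at
κ = 1.27 nm⁻¹ discards interactions already attenuated ~10-fold).

**Cargo models.** Rigid spheres: an inert control (radius 7.4 nm, neutral,
no binding sites, emulating a tetrameric fluorescent protein) and a
transport-receptor model (radius 8.5 nm, net charge −43e, 10 hydrophobic
binding sites placed deterministically by Riesz-energy minimisation on the
sphere).  Sites attract beads whose λ exceeds a threshold (default 0.5)
through a Gaussian well at contact; the site strength (default 8 kJ/mol)
is config-exposed.  Cargo dynamics is rigid-body translation only —
rotation is redundant for homogeneously distributed sites.

## Pore construction

Pores are cylinders of height 20 nm (the membrane thickness) with wall
beads of 3 nm diameter tiling the inner surface in offset rings.  Anchor
sites wrap a close-packed triangular lattice onto the cylinder: the column
count is fixed to round(πd/a), which preserves the target areal density
(one chain per (√3/2)a² ≈ 28 nm² at a = 5.7 nm) at the cost of a few
percent deviation in realized spacing (reported by `AnchorLattice`).
Chains grow from their anchors as self-avoiding persistent random walks
confined to the lumen (spilling axially out of the pore mouths is allowed,
as the real brushes do).  In the dynamics kernels the inert wall is
represented by an equivalent analytic confinement — a radial harmonic
contact at the lumen radius plus repulsive membrane faces — which is
physically identical for a purely repulsive immobile wall and keeps the
neighbour-list cutoff set by the residue beads, not the 3 nm wall beads.
The top/bottom membrane faces outside the pore mouth are repulsive planes
(explicit face beads are available via `build_wall(include_membrane=True)`
for visualisation).

## Simulation protocol

BAOAB-split Langevin dynamics, bit-reproducible for a given seed (single
thread; the thermostat noise stream is part of the seed contract).
Default protocol: steepest-descent minimisation to remove construction
overlaps, then dynamics with the long-range (hydrophobic-attraction and
electrostatic) prefactors ramped linearly from zero over the first 5–20%
of the run, then production.  The friction coefficient (default 0.5 ps⁻¹)
and timestep (0.01–0.02 ps) are reconstructions — the source protocol
delegates them to an external engine.  Equilibration discards follow the
convention of ignoring the first 10% of a production run by default.

Observables: mass-weighted radius of gyration, and the hydrodynamic
(Stokes) radius via the Kirkwood double-sum 1/R_S = ⟨Σ_{i≠j} 1/r_ij⟩/N²
(a post-hoc estimator; no hydrodynamic interactions act during dynamics).

## Density analysis

Frames are binned onto (0.5 nm)³ cells by particle-in-cell counting (no
smoothing kernel), time-averaged, and converted to mg/ml
(1 Da/nm³ = 1.66054 mg/ml).  The grid reduces azimuthally to (r, z) maps —
cells share one volume, so the plain mean over an annulus is the correct
volume weighting — and further to radial profiles: the pore window
|z| < 10 nm in twenty 1 nm slices, and the access windows
10 nm < |z| < 40 nm.  Mass is conserved at every reduction within binning
tolerance, and each reduction is tested against analytic fields.  The
"characteristic in-pore density" is defined here as the mean density
inside the pore cylinder (`mean_pore_density`); the averaging volume
behind published characteristic densities is not printed, so this
assumption is explicit.

## Conductance model

A bare cylindrical pore follows G(d) = σ_bare [4l/(πd²) + 1/d]⁻¹ (pore
resistance in series with access resistance; σ_bare = 2.2 nS/nm for
150 mM KCl).  Grafted protein suppresses the local conductivity linearly,
σ(r) = σ_bare max(0, 1 − ρ(r)/ρ_crit) with ρ_crit = 85 mg/ml, and radial
integration (trapezoid on the profile's own grid — exact for piecewise-
linear profiles) gives effective pore and access conductivities that enter
G(d) = [4l/(πd²σ_pore) + 1/(dσ_access)]⁻¹.  The access conductivity uses
the same radial integral over the access-window profile out to d/2; the
published formula for the access region is unspecified ("a related
expression"), so this symmetric construction is an assumption, and a
regression test checks that shrinking the access window threefold moves G
by a bounded amount (≤15% on the packaged synthetic fields; ≤13% was
reported on the original density data).  σ_bare is fitted from bare-pore
G(d) data and ρ_crit by 1-D least squares on coated-pore data given their
density profiles.  Smooth G(d) curves use 4-parameter logistic fits of
σ_pore(d) and σ_access(d), bounded to [0, σ_bare]; extrapolation beyond
the fitted diameter range is refused unless requested.

## Umbrella sampling and rates

Harmonic restraints (spring 10 kJ/mol/nm²) hold the cargo at axial
positions spaced 1.3 nm apart; at least two starting configurations per
window are pooled.  WHAM combines the biased histograms (bin width 0.1 nm,
convergence tolerance 1e-6 kJ/mol); bins visited fewer than 10 times are
reported as NaN rather than as noise, and disjoint window sets are
rejected.  The transport barrier is max − min of the profile after
fitting sixth-order polynomials to the z < 0 and z > 0 branches
independently (no extrapolation beyond the fitted span).  Event rates
follow Γ = Γ0 exp(−ΔE/kBT).  Γ0 nominally resembles the bare-pore event
frequency, but published computed rates are not exactly reproduced by that
identification, so Γ0 is an explicit per-particle constant and the
*ratio* of rates — in which Γ0 cancels — is the validated quantity:
barriers of 6 vs 12 kJ/mol give an ~11-fold rate contrast, matching the
order-of-magnitude selectivity between a transport receptor and an inert
cargo of similar size.

## Trace analytics

Translocation events are downward current spikes.  Detection uses a
moving baseline (block medians interpolated to the sampling grid), a
robust MAD noise scale, and a two-threshold scheme: an event opens on a
4σ excursion and spans the surrounding 1.5σ region; dips whose gap never
recrosses the exit threshold merge.  The 4σ entry default keeps the
Gaussian false-positive expectation below ~1 per minute of trace at
50 kHz while catching the weak tail of the blockade distribution.  Dwell
ensembles get a maximum-likelihood log-normal fit reported as linear-scale
mean ± sd; event frequencies carry Poisson errors; a Welch PSD utility
characterises 1/f noise.  Grafting estimators: chain count =
(G_bare − G_coated)/ΔG_single with the cylinder-geometry conversions to
area per chain, triangular spacing and in-pore mass density; and the
Sauerbrey conversion of QCM-D frequency shifts, with the
overtone-handling convention exposed as an enum because the published
arithmetic (constant 17.7e-9 kg·s/m² with Δm = −C·p·Δf) does not
reproduce the published 5.6 nm spacing — the standard convention
Δm = C|Δf|/p with C = 17.7 ng cm⁻² Hz⁻¹ and a square lattice does, and a
test records that fact rather than assuming it.

## Synthetic data

Generators return their ground truth so every analysis stage has a
recovery test.  Current traces: Poisson event times, log-normal dwells,
truncated-normal blockades shaped as trapezoids with 2-sample edges, white
noise plus spectrally shaped 1/f^α noise; the defaults emulate the
bare-pore transport-receptor panel (1.7 Hz, τ = 0.29 ± 0.16 ms,
ΔG = 0.22 ± 0.07 nS at 7 nA baseline, 100 mV, 50 kHz, 3 pA RMS white
noise).  Density fields: uniform (mutant-like), centre-peaked
(wildtype-like) and ring-shaped (collapsed-domain-like) axisymmetric
families on the analysis grid.  Test chains with controlled residue
composition support force-field property tests.  What the generators do
*not* emulate: amplifier filtering and capacitive transients, correlated
baseline drift, and any physical origin of the 1/f noise — recovery tests
therefore validate the estimators' statistics, not instrument artefacts.

## Desk-scale presets and known limitations

The study-condition systems (45–60 nm pores, ~100 chains of 600+ residues,
5×10⁷ steps) are cluster-scale.  The packaged desk-scale analogue used by
the test suite and the acceptance script is a 16 nm pore, 36 chains of the
N-terminal 90 residues, 14 000 steps of dt = 0.02 ps with a 1.5 nm
electrostatic cutoff — small enough to run in minutes, large enough that
the wildtype's cohesion measurably raises its in-pore density over the SG
mutant's (the qualitative analogue of the 70–100 vs ~50 mg/ml contrast;
run lengths here sample the collapsed state, not full brush relaxation).
Other limitations: implicit solvent with no hydrodynamic coupling between
beads; torsion potentials default to zero; the cargo's charge acts as a
screened point charge at its centre; cargo–wall interactions reduce to
the same analytic confinement as beads; and the bending/torsion/λ tables
are reconstructions as noted above.
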