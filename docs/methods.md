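# Methods

## The model

The system is a solvent-free coarse-grained membrane carrying 16-site
ENTH domains.

**Lipids.** Each lipid is one Gay–Berne ellipsoid with aspect ratio 3:1
(breadth σ0 = 0.8 nm, length 2.4 nm), a director **u** (head → tail),
the standard orientation-dependent contact distance and well depth
(exponents ν = 1, μ = 2), and an extra term

    U_a = ε_a (u1·r̂ − u2·r̂) h⁻⁶,

odd under flipping a single director, which breaks the symmetry along
the long axis: with ε_a < 0, tail–tail end contact is cohesive and
head–head contact is penalized, the amphiphilic bias that keeps two
leaflets tail-to-tail without solvent.  h is the shifted anisotropic
distance of the Gay–Berne form, so the asymmetry acts at contact in
every geometry.  Pairs are smoothly switched off (quintic smoothstep)
over the final 0.3 nm before the 2.8-nm cutoff.

**Fixture parameter set.** The in-plane interaction of the parent
lipid model was parameterized from atomistic data that are not public,
so the package carries its own calibrated set: ε0 = 2.2 kcal/mol, well
anisotropy κ′ = 5, ε_a = −0.45 kcal/mol, area per lipid 0.772 nm².  Two
diagnostics fix these values (`examples/calibrate_lipids.py`): a flat
bilayer at the fixture density must stay intact at 300 K with directors
aligned to the normal, and a membrane tube built at that density must be
tensionless — its mean radius must not drift.  The second criterion
matters most: with shallower wells the membrane's relaxed density is
lower, a built tube swells by ~10%, and the stretch tears any protein
lattice on it.  The area per lipid itself is back-computed from the
published system sizes (6510 lipids on a 16 nm × 50 nm periodic tube
gives 2π·L·d/N = 0.772 nm²); the same value reproduces the published
vesicle (20 998) and capped-tube (16 485) counts within 10%, which is
what the builder count checks assert.

**Proteins.** The ENTH domain is 16 sites connected by harmonic springs.
Sites 1–2 are the two halves of H0, site 5 the V50/V51 hydrophobic
patch, site 10 the R114 loop, site 7 (configurable) the PIP2 pocket.
Interaction channels (kcal/mol): H0–membrane 4 total (2 per H0 site),
R114–membrane 1.2, pocket–PIP2 2.4 per pair, inter-protein H0–H0 2,
patch–patch 2.  The H0- and R114-membrane depths are totals over the
membrane: a site at its preferred height sums Lennard-Jones wells over
~4.5 lipids (lattice sum at the fixture density, σ = 1.0 nm), so the
per-pair well is the channel total divided by that coordination number.
Treating the printed totals as per-pair wells instead produces ~15×
overbinding, drags H0 a full lipid length below the head shell and melts
the coat.  All remaining protein site pairs carry a weak 0.2 kcal/mol
LJ well (≈ kT/3) — the parent model used LJ for all protein cross
interactions, tuned weak enough that domains do not condense; purely
repulsive generic sites proved unable to sustain the documented lattice.
H0–H0 attraction acts between all four combinations of H0 sites: the
antiparallel dimer pairing uses the 1↔2 contacts, and the short
inter-dimer label distances at residues 13/14 (10–15 Å) imply the H0
C-terminal ends of adjacent dimers also touch.

**The 16-site fixture.** The published model does not include site
coordinates or the residue→site map, so the topology ships as an
idealized synthetic fixture: H0 along x at the membrane plane, a
globular body displaced away from the dimer interface, and spin-label
anchor points 0.7–1.0 nm off the H0 axis along side-chain directions.
The anchor directions are chosen so that an exact two-fold-symmetric
dimer and an exact translated tetramer satisfying every distance
restraint exist, with the designed physical contacts (patch–patch at
the LJ minimum, H0 end–end near contact) realized simultaneously.  A
loader accepts user-supplied 16-site coordinates instead.

## Construction and measurement

The dimer is fit by rigid-body least squares over (dx, dy, θ) with the
second copy the C2 image about the membrane normal; with a C2 axis the
intra-dimer anchor distance is twice the anchor's cylindrical radius,
which makes the fit well-conditioned.  The tetramer adds a pure
translation (axial + lateral) fit to the residue-13/14 restraints with a
softly weighted patch-contact term selecting among the two geometric
roots.  Tubule coats tile the dimer in axial columns whose rise and
tangential shift are taken from the built tetramer, so consecutive
dimers sit at their designed contacts; on periodic tubes the rise is
scaled to close the box (build the tube with length = n_rows × rise to
keep contacts exact).  The protein lattice does not bond across the
periodic boundary (the helical phase does not close), matching the
published setup in which the lattice does not interact with its own
images.  Restraint satisfaction is always verified by an independent
routine: Kabsch superposition of the reference sites onto the placed
(possibly deformed) sites, anchors mapped through that fit.

## Dynamics

NVT at 300 K, velocity Verlet with dt = 0.001 ps, single Nosé–Hoover
thermostat (τ = 0.1 ps) acting on translations and rotations.  Directors
integrate as constrained unit vectors (SHAKE/RATTLE with the exact
Lagrange multiplier); with the thermostat off the integrator conserves
energy to ~10⁻⁷ relative over 10⁴ steps, which is the NVE integrity
check.  Verlet neighbour lists (0.4-nm skin) rebuild on half-skin
displacement.  Units are nm / ps / amu / kcal mol⁻¹; EPR lengths are
reported in Å.  Particle masses are reduced (lipid 100 amu, site
150 amu, director inertia 40 amu nm²) to shorten relaxation times; CG
dynamics carries no physical time scale, and equilibrium averages are
mass-independent.

## EPR forward model and estimation

The basis lineshape is a three-line Lorentzian-derivative nitroxide
spectrum (hyperfine 15 G, half-width 2 G, 150-G scan) — representative
values, since the source spectra's intrinsic parameters are not
published; all recovery tests are generator↔estimator self-consistent.
Dipolar broadening is a Gaussian in field with σ_B = C/r³ and
C = 6.6 × 10³ G Å³, fixed once from the orientation-averaged nitroxide
point-dipole constant so that r = 13 Å broadens comparably to the
intrinsic linewidth; distance distributions mix kernels over a Gaussian
in r (clipped to the 5–25 Å sensitivity window).  Estimation removes a
linear baseline, normalizes both spectra to the same double integral
(this makes the estimate amplitude-invariant), and fits (fraction, r,
width) by bounded least squares with five starts across the window.

## Synthetic data

Generators are pure functions of their arguments plus one seed.  The
elastic-network trajectories are i.i.d. Gaussian draws with covariance
k_BT·H⁺ (all Hessian null modes — rigid-body and any mechanisms —
carry no displacement, so frames arrive aligned).  They emulate the
*statistics* a fluctuation-matching workflow needs, not protein
anharmonicity, solvent friction or time correlation; passing recovery
tests therefore validates the estimators' algebra, not their behaviour
on real trajectories.  Accessibility profiles are cosines in residue
number with the 3.6-residue period; calibration sets draw from
d = aΦ + b with Gaussian noise.

## Partitioning

ΔG_total(h) = ΔG_unfolded + h · (L−4) · ΔG_fold, with per-residue
water→POPC-interface values from the Wimley–White scale (charged R/K,
neutral H), end-group adjustments for NH3+/CONH2 termini, and a
per-residue helical folding bonus for the L−4 backbone hydrogen bonds
of a single helix; helicity scales the folding term uniformly (the
alternative — unfolding terminal residues — is not implemented).  The
folding bonus (−0.545 kcal/mol per H-bonded residue, within the
published 0.4–0.6 range) and the end-group terms (−0.60/−0.75 kcal/mol)
are calibrated once so the H0 sweep reproduces the −3.4/−4.3 kcal/mol
endpoints; they are plain config fields for other choices.

## Problem sizes

The headline coat simulations run at desk scale: a 16-nm tube of
~23-nm periodic length carrying 60 domains (3 columns × 10 dimer rows,
~3000 lipids), 2 × 10⁴ NVT steps per seed, 3 seeds; the capped tube
adds hemispherical caps (~5100 lipids, cap domains included in the
average).  The published systems are 3–10× larger and run 200× longer.
The reported order parameter is the mean over the trailing 40% of the
trace.

## Numerical choices

Deeply overlapping Gay–Berne pairs clamp the shifted distance at
h = 0.2 (builders reject overlapping initial states; the clamp only
guards transient excursions).  EDCG cost ties break toward the earlier
boundary; the essential subspace defaults to the smallest mode set
holding 90% of variance.  heteroENM damps updates with exponent 0.5 and
floors k at 10⁻³ kcal/(mol nm²).  The periodicity fit bounds the period
in [3, 5] residues and flags near-flat profiles unidentifiable.  Defect
threshold S < 0.8 is configurable; the order-parameter neighbourhood
excludes self.  Convergence of order traces is a Mann–Kendall trend
test on the trailing 25% at the 5% level.

## Known limitations

* The scaled-down coat equilibrates at global order ≈ 0.75–0.82
  (control without H0–H0 attraction: ≈ 0.55–0.67; vesicle-scattered
  monomers lower still), below the published 0.92/0.88.  The
  inequalities — coat above control in every seed, tube above vesicle —
  reproduce robustly; the absolute level does not at this scale.  The
  main suspects are the substituted lipid parameterization (the real
  in-plane potential is not public), the unknown generic protein LJ
  terms, and the 2–4× smaller lattice, whose periodic-boundary column
  ends fray and depress the global mean.  With stronger lattice
  channels the built coat holds arbitrarily high order, so the gap is a
  parameterization statement, not a construction artifact.
* CW distance estimation assumes the static-broadening regime; mobile
  interspin vectors at room temperature would partially average the
  dipolar interaction, and no correction is applied.
* The membrane has no electrostatics and no explicit solvent; PIP2
  differs from the host lipid only through the pocket channel.
* Insertion-depth profiles use an idealized shell fit (plane, cylinder
  or sphere); strongly deformed membranes need a local surface model.
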