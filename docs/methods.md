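# Methods

## The model

`torsionfep` studies why alchemical free-energy calculations of the
smallest imaginable side-chain mutation — alanine to glycine, i.e.
removing a single united-atom CH3 — can fail to converge, and how
standard remedies (longer sampling, softer cores, modified exclusions,
Hamiltonian replica exchange, one-step perturbation) repair it.  The
full problem (a solvated KXK tripeptide in an explicit-water force
field) is replaced by a reduced model chosen so that the *exact* answer
is computable by quadrature and every protocol can be run on one CPU in
seconds to minutes.

The system is a nine-bead fragment of a peptide backbone around the
central residue: previous carbonyl (C1=O1), amide (N–H), alpha carbon
(CA) carrying the side-chain bead CB, and the next carbonyl/amide
(C=O, N2).  Bond lengths and angles are rigid (standing in for
SHAKE-constrained dynamics); the only degrees of freedom are the two
backbone dihedrals phi2 (C1–N–CA–C) and psi2 (N–CA–C–N2).  Angles are
degrees in [-180, 180), IUPAC sign convention.

Nonbonded terms are GROMOS-flavoured united-atom Lennard-Jones pairs
(geometric combination of C12/C6) plus Coulomb electrostatics with a
reaction-field correction (relative dielectric 61, cutoff 1.4 nm, never
truncated — the molecule is smaller than the cutoff, the functional
form is simply exercised).  All 1,2 and 1,3 pairs are excluded.  The
torsional potential-energy terms k(1 + cos(3 phi)) have k = 0.5 kJ/mol,
i.e. barriers of 1 kJ/mol: the phi2/psi2 barriers that matter are
dominated by the *nonbonded* 1,4 interactions of CB with the previous
carbonyl carbon, the amide hydrogen, the carbonyl oxygen and the next
amide nitrogen.

CB is the only alchemically perturbed site: CH3 parameters and zero
charge at state A (lambda = 0, alanine-like), a dummy atom at state B
(lambda = 1, glycine-like).

## Softcore coupling

Perturbed pairs use a Beutler-style softcore.  For the Lennard-Jones
part,

    U(r, l) = (1-l)^n [C12_A/D_A^2 - C6_A/D_A] + l^n [C12_B/D_B^2 - C6_B/D_B]
    D_A = a_vdw l^2 (C12_A/C6_A) + r^6,   D_B = a_vdw (1-l)^2 (C12_B/C6_B) + r^6

with n = 1 by default.  `a_vdw` (the usual alpha_VdW) is dimensionless
here because the C12/C6 ratio supplies the nm^6; the electrostatic
softness `a_crf` carries nm^2 and softens the squared distance in both
the Coulomb and reaction-field terms the same two-branch way.  At the
endpoints both reduce exactly to the plain end-state pair energies, and
for 0 < lambda < 1 every term with a nonzero C6 is finite down to
r = 0.  Pairs identical in both end states bypass the softcore and
contribute nothing to dU/dlambda; dU/dlambda of perturbed pairs is
analytic and validated against central finite differences at 1e-6
relative (restricted to |U| <= 1e4 kJ/mol, beyond which the finite
difference itself drowns in float cancellation).

The one-step-perturbation reference state R replaces the CB pair terms
by the fixed softcore form C12_A/D^2 - C6_A/D with D = 1.51 (C12/C6) +
r^6 and no charge: a "half-present" side chain whose ensemble overlaps
both end states.

## Calibration of the default model

The default parameters (in `model_system.DEFAULT_CONFIG`) were tuned
once, against the quadrature oracle, to reproduce the statistical
structure that makes this mutation hard, and then frozen:

* at lambda = 0 the psi2 ~ +135 (beta-like) basin dominates; a
  psi2 ~ -45 (alpha-like) minority basin carries ~2% weight and the
  free-energy gates between them exceed 30 kJ/mol (>> 5 kT), so
  sampling is restricted;
* the minority weight swings to ~50% as lambda -> 1 while the gates
  collapse to ~3 kJ/mol, so the glycine-like state samples broadly
  (its marginal entropies are strictly larger);
* in between (lambda ~ 0.3) the gate is ~18 kJ/mol: crossing times are
  several times the "1x" run length but well inside the "10x" run
  length.  This window is what produces hysteresis at 1x and removes
  it at 10x.

The tuned values are the C12 of the carbonyl O (4.5e-6), amide N
(8.134e-6) and CB (4.797e-5 kJ/mol nm^12) and the N2 bond angle
(119 deg).  They are ordinary united-atom magnitudes; no further
adjustment was made after the acceptance tests were written.

## Sampling

Configurations are generated by Metropolis Monte Carlo in torsion
space: one torsion chosen uniformly per step, Gaussian proposal of
width 30 deg (acceptance 0.39 at lambda = 0, 0.64 at lambda = 1).  A
"jump" move (uniform resample of one torsion) exists with probability
`p_jump`, default **0**: jump moves teleport across the very barriers
whose crossing statistics are the object of study — at p_jump >= 1e-3
the hysteresis phenomenon disappears entirely.  Validation tests that
need fast mixing (e.g. chi-square against exact marginals) switch jumps
on explicitly.

Step-count convention: 1 ns of the original molecular-dynamics
protocol maps to 200 000 MC steps, recorded every 10th step; "10x"
means ten times the production length.  Equilibration is 5% of
production and discarded.  The sequential TI protocol chains legs: each
lambda starts from the final *equilibration* configuration of the
previous lambda, and the backward pass starts from the last production
snapshot of the forward lambda = 1 leg.  Per-leg RNG streams are
split from the master seed via `numpy.random.SeedSequence([master,
direction, leg, 7])`, so legs are independent but reproducible.

## Estimators

* **TI**: per-lambda means of dU/dlambda, integrated by the trapezoid
  rule; errors propagate through the trapezoid weights assuming
  per-lambda independence (legs are separate simulations).  On the
  default profile the 11-point trapezoid carries a +0.2 kJ/mol
  quadrature error; the refined 21-point schedule reduces it to +0.05,
  and the adaptive `refine_schedule` subdivides intervals adjacent to
  large second differences.
* **Block errors**: err^2(b) from block means at power-of-two block
  sizes, fit to A - C/b over the larger half of the sizes (the 1/b
  approach to the plateau is exact for AR(1)); the result is floored
  at the naive sigma/sqrt(N).  Validated against i.i.d. (within 20%)
  and AR(1) rho = 0.9 (within 25%) closed forms.
* **Hysteresis**: forward minus backward dG on the common A->B scale
  (both curves are integrated 0 -> 1, so no negation is needed);
  the integrated absolute hysteresis interpolates both curves linearly
  onto the union lambda grid.  Signed hysteresis is reported with the
  absolute value alongside.
* **Zwanzig / OSP**: exponential averages via log-sum-exp;
  ddG(A->B) = dG(R->B) - dG(R->A) from one reference trajectory with
  both end-state Hamiltonians re-evaluated on every stored frame.
* **Exclusion-bias reweighting**: sampling with the extra 1,4
  exclusions is unbiased by umbrella-style reweighting,
  <dU/dl>_NoExcl = <dU/dl_NoExcl w> / <w>, w = exp(-(U_NoExcl -
  U_Excl)/kT), evaluated from stored configurations.
* **Bootstrap errors** (Zwanzig, OSP, reweighting): circular block
  bootstrap, 1000 resamples, block length max(plateau, N/16) — the
  floor keeps slow modes comparable to the run length visible in the
  resampled error.  OSP errors bootstrap both end states jointly.
  Estimators warn (`OverlapWarning`) when the exponential-weight
  effective sample size falls below 2% of N; for the deliberately wide
  OSP reference this warning is expected and benign.
* **HREMD**: neighbour pairs alternate even/odd between attempts;
  lambda values are swapped (configurations stay), with probability
  min(1, exp(-[(U_i(x_j)+U_j(x_i)) - (U_i(x_i)+U_j(x_j))]/kT)).
  Exchange attempts are nearly free in Monte Carlo, so the default
  interval is 25 MC steps: the ladder-wide basin population (refreshed
  only via the barrier-free high-lambda rungs) is the slowest
  collective mode and must relax many times per run for the error
  estimate to be meaningful (at intervals of 50-400 steps the
  seed-to-seed spread of dG is 2-3x the nominal error).  Replicas are
  cold-started, so each equilibrates at its own lambda for a full
  production length before exchanges begin.  The dG error is
  therefore computed by block-averaging the per-window dG series, which
  captures the cross-lambda correlations that per-lambda block errors
  miss.

## The oracle

With two torsional degrees of freedom, Z(lambda) is a 2-D periodic
integral evaluated by the midpoint rule on a 1-degree grid (spectrally
accurate for smooth periodic integrands; the grid-halving change in dG
is < 1e-6 kJ/mol, and <dU/dl> agrees with the numerical derivative of
-kT ln Z to 1e-4 relative).  The oracle refuses more than three
torsions.  It is used only in tests and validation, never inside an
estimator.

## What a green test does and does not establish

The synthetic model reproduces the *statistical mechanism* of the
published experiment — orthogonal-barrier trapping, its signature in
forward/backward dihedral distributions, and the relative merits of
longer sampling, softer cores, replica exchange and one-step
perturbation — with an exactly solvable reference.  It does not
reproduce force-field-faithful energetics, explicit solvent, inertial
dynamics (mass effects are out of scope by construction), or the
published numerical dG values, which depend on the full force field
and water model.

Known limitations:

* Increasing alpha_vdw to 1.0 reduces mid-lambda barriers (as in the
  published system) but also moves minority-basin weight into the
  low-lambda region where gates are insurmountable at any protocol
  length, so the net benefit of softness is smaller here than in the
  original study — consistent with that study's own caveat that the
  softness remedy is "rather fortuitous".
* The 1x protocols are deliberately out of equilibrium; their per-leg
  block errors underestimate the true uncertainty whenever a basin is
  never visited.  That is the phenomenon under study, not a defect of
  the error estimator.
* Chi-square sampling checks thin the chains and/or enable jump moves
  because the test statistic assumes independent counts.
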