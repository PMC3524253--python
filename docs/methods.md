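# Methods

## The screening model

The package estimates how mutations change the barrier of one enzymatic
elementary step. The model system it is designed around is a serine-hydrolase
active site: a catalytic Ser–His–Asp triad attacks an amide/ester carbonyl,
and the step screened is formation of the tetrahedral intermediate (TI) from
the enzyme–substrate complex (ES). The reaction coordinate is the single
distance d between the nucleophile oxygen (Oγ of the catalytic serine) and
the substrate carbonyl carbon; d ≈ 3.5 Å in ES and ≈ 1.5 Å in the TI.

Several deliberate approximations define the scope:

- **Gas-phase energies.** No continuum solvation; the assumption is that
  solvation contributions largely cancel in *relative* barriers between
  variants of the same scaffold.
- **Adiabatic mapping instead of saddle search.** Penalty-potential or
  Newton–Raphson transition-state searches are unreliable and expensive at
  protein-model size; constraining d at a ladder of values and relaxing
  everything else brackets the barrier robustly. The profile maximum is a
  barrier *estimate*, upper-bounded by the discretization of d.
- **ES derived from the optimized TI.** The ES endpoint inherits the TI's
  relaxed environment (substrate swapped to its planar form at d = 3.5 Å,
  proton returned to Oγ). This biases the ES toward the TI basin and tends
  to *underestimate* absolute barriers, but is consistent across variants —
  again, relative ordering is the target.
- **Electronic energies only.** No zero-point or thermal corrections;
  frequencies are used solely to count imaginary modes.

## Truncated model construction

A screening model is cut from the full structure by an any-atom-to-any-atom
distance criterion around a center residue (all residues with any atom
within the radius of any center-residue atom). The inclusive any-atom rule
is a design choice: the radius is meant to capture the active-site
environment, and the alternative (Cα–Cα or centroid distances) drops
residues whose side chains reach into the site. Crystal waters are included
by default. A residue interrupting the selected backbone by exactly one is
re-included (gaps of two or more stay open). Introduced C-termini are capped
as aldehydes (-CHO): the backbone C and O are kept and one H is added at
1.09 Å in the backbone plane opposite the CA–C and C=O bonds — the direction
of the removed peptide bond, reconstructed from local geometry because the
excluded neighbor is no longer in the model. Introduced N-termini are
annotated neutral with no added atoms (a charge-bookkeeping convention, not
a geometry operation). The outermost residue of each chain in a truncated
model is treated as a native terminus and left alone: from the truncated
model by itself, a terminal cut is indistinguishable from the native end,
and callers who know better can cap manually.

The ES proton is placed 0.97 Å from Oγ pointing toward the electrophile
carbon. Both the 0.97 Å length and the direction are package conventions;
the placement only needs to be a reasonable pre-optimization guess because
the endpoint is relaxed afterwards.

## Engine contract and configurations

An engine configuration M(Cx, Gy) bundles the NDDO cutoff x (Å) — the
distance beyond which two-center NDDO interactions are replaced by point
charges in the localized-orbital (MOZYME-style) scheme — and the gradient
convergence criterion y (kcal/(mol·Å)). The default working configuration is
M(C15, G0.5); the coarser M(C12, G1.0) and M(C9, G5.0) exist for convergence
checks, since barriers converge toward a lower bound as the configuration is
tightened. Three energy channels are tracked explicitly: the
localized-orbital optimization energy, its 1SCF re-orthogonalized
re-evaluation, and the conventional delocalized single point. Profiles are
analysed on the conventional channel because localized-orbital energies
accumulate orthogonality error over long optimizations (worst in frames
needing many SCF cycles), and that drift can exceed the mutation effects
being screened.

Rendered input files are deterministic with a fixed keyword order
(method, MOZYME, CUTOFF, GNORM, CHARGE, 1SCF, extras), so job generation is
byte-reproducible and auditable by golden files. Per-coordinate optimization
flags (0 = frozen) carry all constraints; the interior-frame constraint
freezes both reaction-coordinate atoms outright, which fixes their distance
using the engine's native mechanism rather than a distance restraint.
The cutoff keyword name is treated as a dialect setting of the writer.

## Optimizer

The surrogate path uses a quasi-Newton minimizer (L-BFGS-B) over the free
coordinates only; frozen atoms are excluded from the variable set entirely,
so their coordinates are bit-identical before and after — the same guarantee
the per-coordinate flags give in an external engine. Termination is
max |gradient component| over free coordinates ≤ the configured criterion;
an iteration cap returns an unconverged result rather than raising, so a
screening batch never aborts on one stubborn frame. The minimizer is
deterministic, and tightening the criterion can only lower the final energy.

## Surrogate surface and the toy system

The surrogate potential is Σ ½k(d−d₀)² over a reference bond list plus a
quartic double well V(d) = A·(d−d₁)²(d−d₂)²/((d₂−d₁)/2)⁴ along one
designated atom pair: V vanishes at both wells and equals exactly A at the
midpoint. Gradients are analytic (validated against central differences).

The toy generator emulates the *shape* of the real problem at desk scale: a
short pseudo-backbone with a hydroxyl nucleophile on its center residue, a
four-atom substrate placed at d = 3.5 Å (ES) and rigidly advanced to 1.5 Å
(TI) with the proton displaced as if transferred, two distant waters, and a
matched surrogate with A = 10 kcal/mol, d₁ = 1.5 Å, d₂ = 3.5 Å. Bond
reference lengths are measured from the ES geometry, making ES an exact
stationary point; the bond topology is chosen so every component of the
model contains at most one constrained atom, which means interior frames can
relax their strain completely and the mapped profile reproduces V(d) at the
frozen distances. Both reaction-coordinate atoms carry three non-coplanar
bond anchors so the partial Hessian at the profile top has exactly one
negative direction. Default profiles use 10 divisions; the frame ladder then
crosses the analytic barrier top (2.5 Å) exactly, and recovery error is set
by the optimizer tolerance (~0.1%), improving from ~21% at 3 divisions and
~8% at 5 as the ladder refines.

What the toy does *not* emulate: a rugged many-minimum landscape (so it
cannot probe convergence-criterion sensitivity of real models), charged
residues and electrostatics, localized-orbital drift (the surrogate's two
channels agree by construction), and steric rearrangement on mutation.
Passing tests therefore demonstrate the machinery — interpolation,
constraints, job plumbing, extraction, vibrational analysis — not
semiempirical accuracy on real enzymes.

## Numerical choices

- Partial Hessians: central differences of analytic gradients, default step
  0.01 Å, symmetrized as (H+Hᵀ)/2; exact on surfaces quadratic in Cartesian
  coordinates, which makes the step choice auditable by step-doubling. On
  bond-length potentials (quadratic in distance, not Cartesians) the error
  is O(step²); tight-tolerance comparisons use step = 10⁻³ Å.
- Frequencies: eigendecomposition of M^(−1/2)·H·M^(−1/2);
  ω = sign(λ)√|λ| converted to cm⁻¹ with CODATA constants pinned in one
  table alongside standard atomic weights; negative eigenvalues are reported
  as negative wavenumber magnitudes with an explicit imaginary flag, and no
  noise threshold is applied — near-zero modes can carry either sign at the
  discretization floor, so imaginary-mode *counts* should be read on
  structures without exact zero modes (anchored subsets, as in the toy).
- Barrier extraction: ties at the maximum (and at the preceding minimum)
  break toward the lowest frame index; failed frames are skipped with the
  profile kept. The reference is the lowest point *before* the maximum, not
  frame 0 — variant profiles can dip below their initial ES energy when the
  interpolation opens a lower local minimum.
- Superposition RMSD: optimal proper rotation via SVD of the
  cross-covariance (reflections excluded); the residual is computed by
  applying the rotation explicitly, avoiding the cancellation error of
  closed-form residual norms. Default atom mapping pairs (residue, atom
  name) with hydrogens excluded — heavy-atom geometry is the standard basis
  for comparing transition-state models — with an opt-in flag for H.
- PDB dialect: fixed-column v3.3, coordinates at 3 decimals, insertion codes
  honored, altLoc other than blank/'A' rejected (de-duplicate upstream).
  Fragment files carry their formal charge in a REMARK line plus a JSON
  manifest (order, flags, charges); serials are renumbered 1-based on
  assembly because mutant fragments arrive from modeling tools with
  arbitrary numbering.

## Known limitations

- Protonation states are input annotations; no pKa prediction.
- No automatic substrate docking: planar-substrate coordinates for the ES
  endpoint are modelled upstream and supplied as input.
- The frame ladder fixes both reaction-coordinate atoms, so the estimated
  transition state inherits the (arbitrary) division of the coordinate; the
  partial-Hessian check validates saddle character, not its exact location.
- Whether surface freeze lists also apply to the endpoint frames is a
  per-run choice (for variant screening they should, to keep wild type and
  mutant in the same basin); the endpoint frames always drop the
  reaction-coordinate constraint itself.
- Residue counts of truncated models depend on the water set and radius
  convention; no attempt is made to reproduce a particular published
  selection without its residue list.
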