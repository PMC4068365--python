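# Methods

`archkit` analyses beads-on-a-string multidomain proteins: tandem arrays of
small prolate modules (such as the ~51–62-residue complement control protein
(CCP) modules of complement factor H) joined by 3–8-residue linkers.  This
note records the models implemented, the parameters that matter, the
numerical choices, and what the synthetic-data generators do and do not
emulate.

## Module frames and junction angles

Each module's orientation is an orthonormal right-handed triad. The z-axis is
the eigenvector of the smallest eigenvalue of the inertia tensor of the
module's heavy atoms (unit masses; the long axis of a prolate body),
sign-fixed so that z points from the Cα of the first boundary cysteine,
Cys(I), toward the Cα of the last, Cys(IV). The x-axis is the unit component
of the vector from the centroid to a chosen off-axis reference atom,
orthogonalized against z; y = z × x. Two guards apply: if the two smallest
inertia eigenvalues agree within 1% (relative) the long axis is ill-defined
and an error is raised; likewise if the reference atom lies within 1° of the
axis.

The orientation of module *j* relative to its predecessor *i* is the rotation
A = Mᵢᵀ Mⱼ (columns of M are x, y, z), decomposed as intrinsic z–y–z Euler
angles A = R_z(α)·R_y(β)·R_z(γ):

- **tilt** = β ∈ [0°, 180°] — deviation from collinear extension,
- **skew** = α,
- **twist** = α + γ.

The twist convention is chosen so that at tilt → 0 a pure rotation about the
shared long axis is pure twist. At tilt within 10⁻⁶ ° of 0 or 180° only the
combined axial angle is defined; the result is flagged degenerate, with the
axial rotation reported as twist and skew set to 0. Unit masses (rather than
atomic masses) are the default for shape axes; a mass-weighted option is
exposed. Backbone means N, Cα, C′, O throughout.

The synthetic chain builder inverts this map exactly: given (tilt, twist,
skew) it places the next module with frame Mⱼ = Mᵢ·R_z(skew)·R_y(tilt)·
R_z(twist − skew). Because the frame construction is covariant under rigid
transforms, measurement after construction is the identity to ~10⁻¹² °; the
package's central geometry-consistency property tests this over 1000 random
draws.

## Surface areas

SASA is Shrake–Rupley with a deterministic golden-spiral point set (default
960 points per atom, probe 1.4 Å, radii C 1.70 / N 1.55 / O 1.52 / S 1.80 Å,
heavy atoms only by default). Repeated runs are bit-identical. Against
closed forms (isolated sphere; two intersecting spheres' cap formula) the
default settings agree to ≲ 0.5%, and totals move < 0.5% between 960 and
4000 points.

Buried surface area between consecutive modules is SA(half_i) + SA(half_j) −
SA(both), with each half evaluated in isolation and extended-boundary spans:
the N-side module runs from one residue before its Cys(I) through three
residues after its Cys(IV); the C-side module from the third residue before
its Cys(I) through one residue after its Cys(IV). With a six-residue linker
these two extended spans tile the bi-module exactly around the linker
midpoint; if they would share residues (linker ≤ 5 residues) the rule is
inapplicable and an error is raised.

## Fragment concatenation and NOE-list merging

Two overlapping fragments (A ending in module X, B starting at X) are joined
by superposing B onto A over X's backbone (Kabsch, proper rotations only) and
taking A's atoms through Cys(IV) of X plus B's transformed atoms strictly
after it — so the shared module's coordinates come from the N-terminal
fragment (a deterministic, documented choice). The overlap backbone RMSD is
reported; above 3 Å a warning flags an incompatible overlap.

NOE lists are merged with a partition keyed to the *sequence* midpoint of the
shared module (the spatial N/C-half criterion would differ only for a handful
of boundary restraints): a restraint from A survives iff both atoms lie in
preceding modules/linkers or the N-half; from B iff both lie in the C-half or
later. Straddlers are dropped and counted. Because the two kept regions are
disjoint, the union is duplicate-free by construction.

## Scattering

Momentum transfer is s = 4π sin θ / λ in nm⁻¹; coordinates are Å and
converted only inside the scattering module. The forward model is the
orientationally averaged Debye sum I(s) = Σᵢⱼ fᵢfⱼ sinc(s·rᵢⱼ) with unit
point form factors, either over heavy atoms or one bead per residue (Cα).
There is no hydration shell or excluded-volume correction, so model curves
describe the bare coordinate envelope; model Rg sits at or slightly below
what a hydrated-particle analysis of experimental data would give.
Above ~600 scatterers pair distances are histogrammed at 0.005 nm before
summation (≤ 0.1% deviation from the direct sum).

Discrete point sets scatter with a constant self-term N; comparisons with
continuum closed forms subtract it. Pointwise relative agreement near a
form-factor zero is meaningless for any finite sample, so sphere-oracle
checks are asserted where the form factor exceeds 1% of its maximum (2%
tolerance there, with a deterministic ~5000-point grid fill).

**Guinier analysis** fits ln I against s² on an iteratively shrunken window
with s·Rg ≤ 1.3, including an s⁴ curvature-correction term whose omission
biases a sphere's Rg upward by ~2% at this window; with the correction the
closed-form sphere Rg = √(3/5)·R is recovered to < 0.1% on noise-free data.
I(0) is the fitted intercept; upward residuals at the lowest angles raise an
aggregation flag.

**p(r)** is computed two ways: directly from coordinates (pair-distance
histogram, 0.05 nm bins, unit area, peak positions reported) and by indirect
Fourier transform of a curve: I(s) ≈ 4π Σₖ p(rₖ) sinc(s rₖ) Δr solved by
non-negative weighted least squares with second-difference (Tikhonov)
smoothing and p(0) = p(Dmax) = 0. The regularization weight defaults to the
maximum-curvature corner of the L-curve over a 12-point logarithmic grid; a
reduced misfit χ > 3 warns that Dmax is too small. Rg and I(0) come from the
moments of p(r).

**Porod volume** is V_p = 2π² I(0)/Q with Q = ∫s² I ds; a constant
background and an A·s⁻⁴ tail are fitted on the top quarter of the s-range,
the tail integrated analytically beyond s_max, and a noisy plateau downgrades
to no extrapolation with a warning. **Molecular mass** follows from
comparing I(0)/c with a reference standard (default 66 kDa, serum albumin).
**Frame reduction** drops frames whose integrated intensity deviates > 3
robust σ (MAD-based) from the median — a radiation-damage screen — then
averages with error propagation, subtracts buffer, and scales by
concentration.

## Ensemble optimization (flexibility analysis)

A pool of conformers (default 10,000) is generated from rigid bodies —
modules, plus linkers internal to a rigid group — connected by flexible
linkers rebuilt as dummy-residue bead chains (3.8 Å virtual bonds, bond angle
uniform in [90°, 180°], dihedral uniform), with the following body
re-attached at the chain end in a uniformly random orientation. Conformers
with beads of non-adjacent bodies closer than 4 Å are rejected and resampled
(cap 100 attempts). Per conformer the Cα-bead Debye curve and Rg are stored;
everything is deterministic under the seed.

Selection is an elitist genetic algorithm over multisets of fixed size
(default 20; population 50, generations 100, mutation 0.1 with half of the
mutations duplicating an already-selected conformer so that multiplicity —
the ensemble weight — can accumulate, crossover 0.5, tournament parents).
The GA winner is polished by exhaustive single-slot coordinate descent
(vectorized over the pool) after an exhaustive scan of pure single-conformer
ensembles; best-χ is monotone throughout. χ is the error-weighted RMS misfit
after optimal scaling, normalized by N − 1.

Scattering is a low-information functional: conformers with near-identical
curves are interchangeable in the selection, so per-index weights are
identifiable only up to curve equivalence. Mixture-recovery checks therefore
attribute each selected conformer to the nearest planted component in curve
space; with that metric a 30/70 two-component mixture planted among 500
random decoys is recovered within ±10% at χ ≤ 1.1.

## Hybrid NOE + SAXS annealing

The refinement is Metropolis Monte Carlo over (i) pivot rotations at
flexible-linker atoms — 50% torsion-flavoured, about the bond into the pivot,
which preserves all 1-2/1-3 local geometry, 15% about a random axis — (ii)
rigid-group spins about the group's own end-to-end axis through its centroid
(25%), which explore the spin degeneracy the scattering term cannot see, and
(iii) small rigid translations (10%). An always-on harmonic restraint on
consecutive-atom distances (k = 10 Å⁻²) stands in for covalent connectivity,
and a soft-sphere penalty on inter-module Cα beads (4 Å cutoff, the two
junction-flanking residues exempt) prevents overlap; there is no physical
force field.

The energy is E = w_NOE·Σ max(0, d − d_upper)² + w_SAXS·χ² + E_geom, with
NOE distances and model curves ensemble-averaged over the N members
(d_eff = ⟨d⁻⁶⟩^(−1/6); intensities averaged before scaling) when N > 1.
w_NOE defaults to 1 Å⁻²; w_SAXS auto-balances so both experimental terms are
comparable at the start, both overridable. The schedule cools from 2000 to
600 in 50-unit steps with the experimental weights ramped up linearly
(multiplicatively), then 600 to 100 in 25-unit steps at full weight, 300
moves per temperature. Temperature maps linearly to the Metropolis scale
with kT at the hottest stage set to one tenth of the starting energy — a
setting at which a 60° tilt perturbation of a two-module junction is
recovered to within 10° in 10/10 seeds on contact-derived restraints plus a
noise-free curve (≈ 4 s per seed at ~750 atoms, 40 s-points). The best
ensemble encountered is returned with a per-temperature energy trace
(monotone by construction). With an empty restraint list the same machinery
is SAXS-only rigid-body fitting; with w_SAXS = 0 the result is provably
independent of the target curve.

Because synthetic NOEs are upper bounds only and the Debye term is blind to
module spin, N = 2 ensemble members converge to the same junction geometry
(tilt within ~10°) but not atom-by-atom; data as rich as a real NMR list
with a full force field would be needed to make members nearly identical.

## Synthetic data: what it emulates, and what it does not

`make_module` winds backbone quartets (N, Cα, C′, O) helically along a
prolate envelope (defaults: 60 residues, 38 Å long axis, 8 Å radius —
CCP-like), names the boundary residues CYS, and takes a mid-module Cα as the
off-axis reference; the point cloud's long axis is within 3° of the
generating axis. `build_chain` realizes prescribed junction angles exactly
and bridges modules with bowed dummy-glycine linkers whose bead spacing is
kept at ~3.8 Å by solving the bow amplitude to the contour length. The
junction chord defaults to (n_linker + 1)·1.0 Å — much shorter than the
contour — so that compact tilts (~118°) bring module surfaces into NOE range
(single-digit inter-module contacts, mirroring how strongly tilted real
junctions bury surface and show few inter-module NOEs) while near-collinear
junctions show fewer; the chord escalates automatically if prescribed angles
would collide whole modules. `simulate_curve` adds multiplicative Gaussian
noise σ(s) = rel_noise·I·(1 + s/s_max) (2% default; not Poisson counting).
`synth_noe` converts backbone heavy-atom contacts (< 5 Å, residue separation
≥ 2) into upper bounds at d + 0.5 Å. `jitter_ensemble` applies i.i.d.
Gaussian coordinate noise.

None of this has side chains, real secondary structure, hydration, or
chemically valid linker torsions; passing tests demonstrate the correctness
and internal consistency of the geometry, scattering and optimization
machinery, not the biological accuracy of any particular structure. Analyses
of deposited NMR ensembles (multi-model PDB + CYANA-style restraint lists)
use exactly the same code paths via the readers in `archkit.core`.

## Problem sizes used in the standard checks

Angle round trip: 1000 junctions of two 60-residue modules. Sphere closed
forms: ~5000-point deterministic fill of a 3-nm sphere. IFT: 120-point curve
on [0.05, 4] nm⁻¹, 201-point p(r) grid. GA: 502-conformer pool, 60 s-points.
Annealing: 10 seeds × the full two-stage schedule (~14,700 moves each) on a
≈750-atom two-module chain. These sizes keep the full check suite at a few
minutes on one CPU while leaving every tolerance comfortably resolved.
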