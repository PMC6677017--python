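# Methods

## The problem

Ordered solvent — water, sulfate/phosphate anions, small-molecule
heterogens (glycerol, PEG fragments, acetate, halides) and metal ions —
accounts for a large fraction of the atoms in deposited macromolecular
crystal structures, and misassigned solvent (a sulfate modelled as a water
cluster, a metal modelled as water) is a common, persistent class of model
error. `solventscope` classifies candidate solvent sites ("peaks") from a
structure model plus its 2Fo−Fc and Fo−Fc density maps into the four
classes above, or flags them as likely model errors.

## Features

At each peak 21 features are extracted.

**Density features (19).** CC1–CC14 are real-space correlation
coefficients (RSCC): Pearson correlations between observed map values and
an idealized probe model over the voxels within 2.0 Å of any probe atom.
Two probes are used — a single water O, and a rigid ideal sulfate (S–O
1.49 Å, tetrahedral) — each fitted by bounded real-space refinement
(translation ≤ 1.0 Å; rotation too for sulfate; Nelder–Mead direct search
with a deterministic start simplex, ≤ 200 evaluations, RSCC tolerance
1e-5). The fourteen RSCCs combine {water, sulfate} × {Fo−Fc, 2Fo−Fc} ×
{refined, carried pose} × {observed map, sign-inverted map}; the
sign-inverted ("pseudoinverse") map, defined here as ρ⁺ = −ρ, measures a
pose's overlap with negative and void density. CC13/CC14 average the
refined sulfate's RSCC over 12 fixed generic rotations (three angles —
36°, 72°, 144° — about four axes, none a symmetry of the tetrahedron), and
ED1/ED2 are the standard deviations of those rotation samples: near zero
for spherically symmetric density, larger for shaped density. ED3/ED4 are
flood-fill peak volumes — the 26-connected component above contour (3.0σ
on Fo−Fc, 1.0σ on 2Fo−Fc) containing the peak, capped at 5.0 Å to stop
fills escaping into macromolecular density — and ED5 is the interpolated
2Fo−Fc value at the peak.

**Contact features (2).** CF1 is the distance to the closest model atom,
computed with full space-group symmetry (all operators × 27 neighboring
cells, closed ball); validated solvent placed during triage can shrink it.
CF2 sums per-contact log-odds weights over atoms within 4.0 Å, where each
weight is the add-one-smoothed log ratio of that atom type's frequency
near sulfate versus near water (nine-type vocabulary: charged/H-bonding
nitrogens, backbone N/O, carboxylate/hydroxyl/amide O-N, carbon, other).
A chemically-motivated default table is used until one is estimated from
contact counts.

The probe model density is a sum of isotropic Gaussians with amplitude
equal to the electron count and width σ² = B/(8π²) + (d/3)² with a fixed
B = 20 Å² and d the resolution — a deliberate single-width simplification
(no per-element form factors, no anisotropy).

## Score space

The 19 density features are strongly resolution-dependent and mutually
correlated; the two contact features are neither. The ED path is

standardize → decorrelate → midpoint-scale → Johnson-S_U log-odds → rescale

with every resolution-dependent parameter represented by a
**resolution-to-parameter mapping spline (RPMS)**: a natural cubic
regression spline with six basis functions, knots at resolution quantiles,
clamped outside its fitted range. Decorrelation multiplies the
standardized 19-vector by the transpose of a 19×19 modal matrix whose 361
entries are each an RPMS; scaling centres the sulfate/water class-mean
midpoint at zero. The log-odds stage sums, over components, ln of the
ratio of sulfate to water Johnson-S_U densities (densities floored at
1e-12 so an extreme value contributes boundedly); the final rescale again
midpoint-centres and scales by a pooled sd. The census is structural: 19×2
standardize + 361 decorrelation + 19×2 scale + 19×8 S_U + 2 rescale = 591
ED-path parameters; the CC path uses 20 constants (2×2 standardize + 2×8
S_U) plus 2 rescale splines. The C2 statistic is the squared z-distance of
the (ED, CC) pair from the water population, mapped to a not-water
probability by the χ² CDF with 2 degrees of freedom — a pseudo-χ² choice
made here; at the water means C2 = 0 and p = 0.

## Classification and triage

Each class contributes normalized 1D histograms of its final ED and CC
scores (40 bins spanning [−6, 6], scores clamped); the 2D joint is their
outer product, which the upstream decorrelation justifies. The evidence
for class c at a score pair is L_c = ln[π_c J_c / Σ_{c′≠c} π_{c′} J_{c′}]
(per-bin floor 1e-9; a class absent from training gets zero mass so it
never outbids an observed class). Three priors are used — flat, the
Dirichlet-smoothed (α = 1) training class frequencies, and an adaptive
per-structure prior built by tallying decisive predictions (L ≥ 0.5),
smoothing with five training-prior pseudo-counts, and iterating to a fixed
point (≥ 20 peaks required, ≤ 10 rounds). The final class is the majority
of the three argmaxes (ties to the adaptive scheme); quality is *strong*
when unanimous with L ≥ 0.5, *weak* when L < 0 or the not-water
probability contradicts the call (thresholds 0.95/0.05), else *moderate*.

Triage then (i) flags **model errors** — ED > 1.0 ∧ CC < 0.0 ∧ ≥ 2
macromolecule contacts under 2.2 Å (the clash requirement keeps metals,
which share the score pattern, unflagged); (ii) builds a symmetry-aware
peak graph (edges < 2.4 Å, weight exp(−d²/2σ_c²)·score-similarity with
σ_c = 1.0 Å) whose connected components are clusters; the member most
strongly predicted sulfate/heterogen becomes the representative, members
within S–O bonding range (1.8 Å) join its model, members more strongly
attached to another cluster's representative are reassigned, remaining
members are examined as waters with pairs under 0.9 Å collapsed as split
peaks; (iii) updates CF1 against newly validated solvent for suspicious
peaks (CF1 > 3.2 Å with ED < 0 ∧ CC > 0, or p_water > 0.9 against a
nonwater call) and rescores them. The validated set only grows between
rounds, so the loop reaches a fixed point (≤ 10 rounds). Output waters are
single O (HOH), sulfates ideal SO4 at the peak; heterogens/metals are
carried over from the input model only — never built de novo. Emitted B
factors use the placeholder map B = max(10, 80/ED5). All thresholds above
are this package's calibration constants, exposed in `config.py`.

## Training

Training is staged — each stage's parameters are estimated, the table is
pushed through that stage, and the result feeds the next. Resolution
dependence is captured by overlapping moving windows over the
resolution-sorted rows (window = 20,000 rows or n/10, step half a window,
last window anchored); per-window estimates are smoothed into RPMSs.

Two choices depart from the most literal scheme and matter at desk scale:

* **Eigenbasis alignment.** Beyond greedy sign/order matching of adjacent
  windows, every window's eigenvectors are aligned to the global PCA basis
  by orthogonal Procrustes. Most of the 19 eigenvalues are nearly
  degenerate, so each window's eigenbasis is arbitrary up to rotation
  inside those subspaces; without the alignment the 361 splines chase that
  arbitrary rotation rather than the real covariance drift, and the
  evaluated matrix drifts off orthogonality.

* **Pooled S_U shapes.** The Johnson-S_U shape parameters (γ, δ) are
  fitted once per (component, class) on all rows (moment-matched start,
  L-BFGS-B with analytic gradients), while location and scale (ξ, λ)
  follow each window's moments analytically. Windows hold only a few
  hundred minority-class rows — far too few for stable tail/shape
  estimates — and mismatched tails between the two class densities turn
  the log-odds sum into noise; the scaled components are shape-stationary
  by construction, so pooling the shapes is the right bias/variance
  trade-off here.

Determinism: subsampling uses even strides, optimizers have fixed starts,
so retraining on the same table is bit-identical.

## Synthetic data

The **feature-table generator** emulates the statistical structure the
pipeline assumes, not the physics: class frequencies 96.2/1.7/1.6/0.5%
(minority floor 100 rows), resolutions 0.6–5.0 Å drawn from a Beta(2.2,
3.0) density peaking near 2 Å, smooth planted per-feature resolution
trends (linear+quadratic, amplitudes 1–2.5 sd), a two-factor correlation
structure (an RSCC factor and a volume factor, loadings ≈ 0.6 with mild
resolution drift), and exact Johnson-S_U marginals obtained by the sinh
transform of correlated normals. Class offsets ride the local sd, so
separability does not drift with resolution. The planted sulfate−water
separations follow the qualitative ordering expected of the real features
— largest on the volumes (ED4 4.4 sd, ED3 3.6) and tetrahedral-probe
RSCCs (CC4 3.2, CC14 2.2), near zero on ED1/ED2 — with magnitudes chosen
so the flat-prior Bayes error of the water/sulfate problem is in the
~1–2% regime that real deposited data support; heterogens sit halfway on
density features with a near-water contact environment, and metals pair
sulfate-like density (ED5 +4 sd) with shorter-than-water contacts.
Passing tests on these tables demonstrates that the pipeline recovers
planted structure, not that real maps are this clean.

The **scene generator** builds toy P1 crystals: a pseudo-peptide backbone
curve, planted waters and sulfates 2.4–12 Å from the chain and ≥ 3 Å
apart, Gaussian-atom maps at 0.5 Å spacing (2Fo−Fc = everything, Fo−Fc =
solvent only, emulating a solvent-omit difference map), plus band-limited
noise (smoothed white noise, amplitude 1% of a water peak). It omits
Fourier-truncation ripple, bulk solvent, anisotropy and disorder. A
scene-feature classifier for pipeline tests is trained on features
extracted from 12 scenes at four resolutions with a deliberately enriched
water:sulfate ratio (2:1) so both classes support distribution fits at
~200 rows.

## Problem sizes and verification

The reference synthetic training run uses n = 2×10⁵ rows (≈ 19 windows);
held-out evaluation uses fresh 5×10⁴-row draws; the retrain-determinism
check uses n = 3×10⁴; the flagship scene holds 30 waters + 2 sulfates in
a 40 Å cell. On these conditions the trained pipeline leaves the mean
absolute pairwise correlation of decorrelated features below 0.05 in
every window, holds the binned ED-score mean range under 25% of the mean
raw-feature scaled range, and reaches held-out water/sulfate F1 ≥ 0.95
under the flat prior; the structure pipeline recovers all planted waters
and both sulfates and is idempotent on its own output. All of these are
asserted by the test suite; no empirical claim is made beyond what the
tests and `scripts/acceptance.py` compute.

## Known limitations

* Maps are consumed, never computed: no structure factors, phases or bulk
  solvent; pseudoinverse maps are plain sign inversions.
* The probe density model is a single-width Gaussian per atom; no
  H atoms, anisotropy or occupancy refinement.
* Sulfate and phosphate are deliberately indistinguishable, and members
  within the heterogen or metal classes are not discriminated.
* Heterogen and metal models are never built de novo.
* The classifier trained on synthetic tables is calibrated to the
  generator's units; classifying real extracted features requires
  training on features extracted by the same path (as the scene
  classifier does).
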