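# Methods

This note documents the models implemented in `lungsim`, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical decisions a maintainer would want to know. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Airway-tree model

The conducting airways are represented as a rooted tree of cylindrical
segments, trachea = generation 1, with at most binary branching. The packaged
morphometry table (`data/airway_morphometry.csv`) specifies, for 26
generations, the number of branches, the number of terminal branches, and the
diameter distribution (mean, max, min, sd in mm). Its branch counts total
64,893 with 32,447 terminals; terminals appear from generation 9 onward, which
makes the tree strongly asymmetric.

The generator reproduces branch and terminal counts per generation exactly:
which branches of a generation terminate is a seeded random choice, and
non-terminal branches receive one or two children as the next generation's
count requires (for the packaged table this is always exactly two). Diameters
are drawn per generation from a normal(d_mean, d_std) clipped to
[d_min, d_max] and then recentred (shift + re-clip, three passes) so that
clipping does not bias the generation mean; without recentring the bias
exceeds two standard errors of the mean for the mid-tree generations, where n
is in the thousands.

**Spatial embedding.** Each branch owns an axis-aligned box; a two-child
branch splits its box in half along the longest axis, children end at their
half-box centres, and the branch runs from its parent's endpoint to its own
box centre. Subtrees therefore occupy contiguous, non-overlapping regions —
the property the defect-closure stage relies on. The embedding is schematic:
centerlines are not anatomical, and branch *lengths* are the geometric
endpoint distances of the embedding, since the morphometry table carries no
length data. Absolute impedance magnitudes consequently reflect this length
model; all downstream claims are therefore about directions, orderings and
correlations rather than absolute values. The default bounding box is
300 × 250 × 210 mm (left–right, in-plane, slice axis), matching a
128 × 128 × 14 image at 3.13 × 3.13 × 15 mm voxels.

**Volume scaling.** Trees are generated at total lung capacity and deflated to
functional residual capacity by multiplying diameters, lengths and coordinates
by 0.8, i.e. a lumen volume ratio of 0.512. All cohort simulations run on the
deflated tree.

## Oscillation mechanics

Airway impedance uses the rigid-tube Womersley solution (see README for the
formula), evaluated in SI units (Pa·s/m³) and converted once to cmH₂O·s/L
(÷ 98,066.5). Defaults: gas density 1.16 kg/m³ and viscosity 1.85·10⁻⁵ Pa·s
(humid air at body temperature).

Lung compliance is distributed evenly over the terminal airways: with N
terminals and total lung elastance E_L, each terminal unit has elastance
E_t = N·E_L, so the parallel combination returns E_L exactly. The default
E_L = 10 cmH₂O/L is a conventional normal-lung value and is configurable; the
respiratory-system layer adds R_central = R_cw = 0.5 cmH₂O·s/L and
E_cw = 10.6 cmH₂O/L. An upper-airway shunt can be enabled as a parallel
impedance Z_uaw(f), interpolated linearly in log-frequency (with edge
extrapolation, e.g. down to 0.2 Hz) from a user table; the packaged table
(`data/upper_airway_shunt_synthetic.csv`) holds literature-plausible
magnitudes generated from a resistance–inertance–compliance description of the
upper airway walls and is a synthetic, replaceable fixture. The shunt is off
by default.

Input impedance is the series/parallel reduction
Z_in(b) = Z_a(b) + (Σ_children 1/Z_in(c))⁻¹, implemented as a vectorised
generation-by-generation sweep (no recursion, so 26-generation depth is no
concern). The tests check this reduction against an independent full nodal
analysis (assembling the admittance matrix over all junctions and solving the
linear system) to 1e-9 relative on random trees.

**Numerical evaluation of the Bessel bracket.** The ratio
2J₁(z)/(zJ₀(z)) with z = α√−j is computed with exponentially scaled Bessel
functions (`scipy.special.jve`), whose scaling cancels in the ratio; this is
exact at every α and removes the overflow that unscaled J₀/J₁ hit near α ≈ 40.
Below α = 3·10⁻³ the bracket suffers catastrophic cancellation, so a series
form −8/z²·(1 − z²/6 − z⁴/1152) is used; the two branches agree to better than
1e-9 at the switch, and the series reproduces the Poiseuille limit
8μl/(πr⁴) exactly as f → 0.

**Derived metrics.** R_rs and X_rs at 0.2, 5 and 20 Hz; band differences
R_rs0.2−5 and R_rs5−20; elastance E_rs = 2πf·|X_rs(f)| at 0.2 and 5 Hz only,
where reactance is elastance-dominated. The magnitude is used so that
elastance is positive although low-frequency X_rs is negative. The default
frequency grid is {0.2, 0.5, 1, 2, 5, 8, 12, 16, 20, 24, 32} Hz.

**Narrowing and monotonicity.** Closure narrows selected branches to 10% of
their diameter (Poiseuille factor 10⁴), never to zero. On morphometry-
structured trees this closure never decreases R_rs at any grid frequency, and
R_rs5/−X_rs5 grow monotonically with the number of closed branches; both are
asserted in the tests. No *universal* monotonicity holds, however: on
arbitrary reactive networks, narrowing an inertive parallel pathway near the
resonant frequency can lower Re(Z_in) — the classic resistance–reactance
interdependence — and the suite deliberately does not claim otherwise.

## Imaging

Images are numpy volumes with voxel spacing and origin in mm (world =
origin + index·spacing), default grid 128 × 128 × 14 at 3.13 × 3.13 × 15 mm;
NIfTI I/O goes through nibabel.

**Cavity segmentation** is seeded region growing on the proton image: voxels
within the seed intensity range widened by `tolerance` × global range (default
0.15) and 26-connected to a seed. Seeds are proposed automatically from the
ventilation image (brightest smoothed voxel per lateral half — the gas signal
exists only inside the lungs), and can always be supplied explicitly.

**Ventilation clustering.** Plain Lloyd's K-means (k = 5, k-means++ seeding,
100-iteration cap, 1e-6 relative tolerance, deterministic under a seed) on the
1-D voxel intensity, relabelled by ascending cluster mean so cluster 1 is
signal void and cluster 5 hyperintense. The pipeline runs the clustering in a
*background-anchored* variant: the cluster-1 centre is pinned to the noise
floor estimated from outside-cavity voxels (median, with MAD-based spread),
and the remaining four centres — initialised at quantiles of the
above-noise-floor values — follow ordinary Lloyd updates. The anchor gives the
signal-void class a fixed physical reference: without it, a defect-free lung
donates its dimmest ~10% of ventilated voxels to cluster 1 and VDP is
overestimated by several points, while with it an image with no true defects
classifies essentially nothing as void. This emulates how the validated
clinical classification treats cluster 1 as background-level signal.

VDP is the cluster-1 share of the cavity in percent. Defect regions are
26-connected components of cluster 1; only regions whose bounding box strictly
exceeds 10 voxels in x or y (≈3 cm in-plane) drive airway closure, though all
cluster-1 voxels count toward VDP. Partial-volume voxels (cluster 2) are never
counted as defect.

## Coregistration

Paired fiducials (default 10 per subject, placed on the lung boundary by the
phantom generator, image side perturbed by a 1 mm localisation error) yield a
least-squares rigid transform via the orthogonal-Procrustes/Kabsch solution
with a reflection guard; the fiducial registration error (RMS residual) is
reported. Per-slice 2-D refinements are collapsed into this single 3-D rigid
transform plus slab bookkeeping: z positions map to 15 mm coronal slabs under
half-open intervals, so every point belongs to exactly one slab. Overlap is
scored with the Dice coefficient, including per-slab. Registration quality is
assessed on slabs holding at least 1% of the cavity volume; the extreme slabs
of an ellipsoidal lung contain only a handful of voxels and their Dice is
noise. A nonrigid refinement is deliberately out of scope.

## Closure semantics

A branch is "spatially related" to a defect when its *midpoint's* nearest
voxel lies inside the defect mask dilated by `margin_voxels` (default 2,
26-connected) — the midpoint rule keeps selection unambiguous on 15 mm slabs.
Narrowing is applied to the selected target-generation branches themselves
(default `narrow_scope="at_generation"`); since a 10⁴ resistance increase
blocks the distal subtree (distal admittance falls below 1% of open, tested),
this already realises "closed distal to generation N". The alternative reading
— narrowing the selected branches *and* all their descendants — is available
as `narrow_scope="at_and_distal"`.

## Synthetic data

**Phantom geometry.** A bright body ellipsoid containing two darker lung
ellipsoids (the cavity), dimensioned as fractions of the field of view so
smaller test grids scale coherently; the body additionally includes a ≥3-voxel
tissue shell around the lungs so the dark cavity is never connected to the
dark background. Proton intensities: body 800, cavity 100, background 30.
Ventilation intensity exists only inside the cavity: mean 600 modulated by a
smooth ±8% texture field, zero in defects, plus zero-mean Gaussian noise of
sd = mean/SNR everywhere (SNR default 20; the noise model is Gaussian, not
Rician — a deliberate simplification).

**Defects.** Signal-void blobs are accumulated until the defect fraction is
within 0.5 percentage points of the target. With a tree supplied, each blob is
the dilated voxel footprint of a randomly chosen subtree's terminal airways
(candidate roots from generation 9 downward, chosen so a blob never overshoots
the remaining deficit) — defects are therefore segmental/subsegmental and
spatially aligned with closable airways. Without a tree, random compact
ellipsoidal blobs with a shrinking-radius schedule are used.

**Cohort.** 25 subjects × 3 conditions. True VDP per condition is drawn from
truncated normals on [0, 60]%: baseline (4, 4), post-methacholine (11, 10),
post-salbutamol (4, 2) — the condition means and spreads of the emulated study
design. FEV₁ %predicted is drawn per condition with means/sds (84, 15),
(64, 15), (87, 15) and correlation −0.6 to the condition's VDP; airways
resistance %predicted is one per-subject baseline plethysmography value,
(126, 69), correlated +0.7 with baseline VDP. The couplings are generator
design choices (sign-matched to the emulated study, magnitudes not claimed as
measured values) and are config-exposed. One shared airway tree serves all
subjects, as in a generic-model study; each subject-condition gets its own
phantom, registration and closure plans at generations 9 and 14.

**What passing tests show.** The synthetic cohort demonstrates that the
*pipeline* — segmentation through closure to impedance — preserves and
propagates a known ventilation-defect signal with the expected signs and
orderings (R_rs5 up and X_rs5 down with VDP; low-frequency reactance slopes
dominating; proximal closure ≥ distal closure in R_rs5). It does not validate
the model against measured patient impedance: real images carry coil shading,
motion, Rician noise and anatomical variability that the phantoms do not, and
absolute impedance levels depend on the schematic length model above.

## Statistical layer

Correlation defaults to Pearson with an automatic switch to Spearman when a
Shapiro–Wilk screen (α = 0.05) rejects normality of either variable.
Correlation strengths are compared with the independent-samples Fisher z
formula applied to |r| (appropriate when a negative correlation is compared
with positive ones); a Steiger-type dependent variant is provided for the case
where both correlations share a variable and the inter-predictor correlation
is known. Slope homogeneity across frequencies uses ANCOVA
(y ~ group + x + group:x), with the interaction F computed from full-vs-pooled
residual sums of squares and verified against a brute-force RSS oracle.
Holm–Bonferroni (statsmodels step-down) controls each comparison family.
`analyze_cohort` pools the three conditions as independent observations
(n = subjects × conditions), replicating the repeated-measures pooling of the
emulated design; the report flags this explicitly in its notes.

## Problem sizes and runtime

The defaults are chosen so that everything runs comfortably on one CPU: the
full 64,893-branch tree builds in well under a second; an 11-frequency
impedance sweep takes ~0.3 s (a caching engine recomputes only narrowed
branches on repeated sweeps, bit-identical to the direct path); a full
25 × 3 cohort with imaging, registration, closure at two generations and
sweeps completes in about half a minute; the complete test suite runs in
roughly a minute.

## Known limitations

- Airway-wall compliance and intra-airway gas compression are neglected (the
  alveolar compartment dominates); tissue hysteresivity is not modelled.
- Branch lengths come from the spatial embedding, not measured morphometry;
  absolute R_rs/X_rs levels are embedding-dependent.
- Graded constriction outside defects is not modelled: airways are either open
  or narrowed to 10%.
- The rigid registration has no nonrigid refinement; phantom fiducials are
  exact up to an isotropic localisation error.
- The cohort treats repeated measures as independent when pooling; no
  mixed-effects modelling is provided.
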