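# Methods

`foxmorph` implements a geometric-morphometrics inference chain for asking
whether skull shape diverges between habitats and sexes within a species,
and whether that microevolutionary divergence aligns with the
macroevolutionary divergence of the surrounding clade. This note records
the models, the numerical choices, and what the synthetic test bed does and
does not establish.

## Shape variables

A specimen is k ordered 2D landmarks. Generalized Procrustes analysis
(GPA) removes location, scale and orientation: each configuration is
centred, scaled to unit centroid size (CS, the square root of summed
squared landmark distances from the centroid — full Procrustes scaling),
and rotated by the proper orthogonal least-squares fit onto the evolving
consensus; the consensus is the coordinate mean, renormalised during
iteration, and the loop stops when it moves by less than 1e-10 (max 100
iterations, first configuration as the initial consensus). Reflections
are never allowed: specimens are photographed in one standard view, and an
improper fit could silently flip an asymmetric configuration. After
convergence the reported consensus is the plain coordinate mean of the
aligned set, and the whole solution is rotated to a canonical orientation
(consensus major principal axis along x, signed by landmark 1) so results
do not depend on specimen order.

Partial-warp scores re-express Procrustes residuals in an orthonormal
2k−4 dimensional basis: eigenvectors of the thin-plate-spline bending-energy
matrix of the consensus (kernel U(r) = r² log r²) give k−3 principal warps,
each expanded into an x- and a y-displacement direction (2k−6 non-uniform
components); the two uniform (affine) components are the stretch and shear
displacements of the consensus orthogonalized against the similarity and
non-uniform subspaces (the complement method). One geometric subtlety:
with full Procrustes scaling the residuals retain an O(ρ²) component along
the consensus direction (ρ = Procrustes distance to the consensus), which
no 2k−4 basis can represent — the shape manifold is curved. Scores are
therefore computed on the orthogonal tangent-space projection of the
residuals; reconstruction from scores reproduces that projection to
machine precision, and the discarded component is quadratically small
(checked in the tests against the residual scatter). Statistical analyses
may use either partial-warp scores or aligned coordinates; the projection
is an isometry between them on the tangent space.

## Two-way MANOVA and canonical axes

Habitat (urban/rural) and sex (F/M) form a 2×2 factorial on the shape
scores. Effects are tested by Pillai's trace, V = tr(H(H+E)⁻¹), with
Type II sums of squares and cross-products: each main effect adjusted for
the other, the interaction adjusted for both, E from the full model. The
approximate F and its degrees of freedom follow the standard Pillai
formulas. Type II matches the convention of the R packages this mirrors
(car/candisc-style "each factor taking account of the other"), and the
implementation reproduces `car::Anova(type = 2)` to ten digits on a frozen
reference dataset. Designs with more than two levels per factor or an
empty cell are rejected rather than silently reinterpreted. E must be
nonsingular, which requires fewer shape variables than residual degrees of
freedom — satisfied by the study-scale design (p = 68, n = 111).

The canonical axis of a factor solves the generalized eigenproblem of that
factor's H against E from the same two-way model, so habitat scores are
adjusted for sex and vice versa. The axis is unit-norm in score space;
its sign is fixed by convention (urban and M poles positive). On
bootstrap resamples E is structurally singular — duplicated specimens pull
the design vectors into the data column space — so the trajectory helper
solves the eigenproblem on the range of E (the pseudo-inverse canonical
variate), which coincides with the exact solution whenever E is
invertible.

## Allometry

Shape is regressed coordinate-wise on log CS (the field's standard size
covariate; raw CS available behind a flag). The pooled
r² = SS_model/SS_total over all coordinates, a Goodall-style F pools the
same sums of squares, and the p-value permutes the size values (999
permutations by default, (count+1)/(reps+1) convention). Residual shapes
— consensus plus residual deviations — have exactly zero sample covariance
with the predictor and feed the species means used by the comparative
analyses.

## Dimorphism bootstrap

Dimorphism magnitude within a habitat is the Procrustes distance between
male and female mean shapes. The two habitats are compared with 900
bootstrap replicates resampling specimens with replacement within each
sex×habitat cell (cell sizes preserved; the superimposition is held fixed,
with per-replicate re-GPA available as a sensitivity flag). 95% intervals
for both distances and for their difference use the classical percentile
convention throughout the package: the ⌊0.025(B+1)⌋-th and ⌈0.975(B+1)⌉-th
order statistics of the bootstrap draws, which is marginally wider — and
measurably closer to nominal coverage — than interpolated quantiles.
Both significance readings are reported: CI overlap of the two distances,
and the difference CI excluding zero; the latter is treated as primary
because it is the coherent test of the difference. A caution the module
actively warns about: a mean-difference norm is biased upward by sampling
noise, increasingly so at small cell sizes, and the bootstrap inflates it
again, so a marginal distance CI can fail to bracket its own point
estimate; the difference CI is the quantity to interpret.

## Phylogenetic signal

Phylogenetic signal in species-mean shape is the distance-based
multivariate generalization of Blomberg's K:

K = (MSE0/MSE) / ((tr C − N/1ᵀC⁻¹1)/(N−1)),

where C is the Brownian-motion tip covariance (shared root-to-MRCA branch
lengths), MSE0 the summed squared deviation of tip data from the
phylogenetically weighted ancestral estimate, and MSE the same after
whitening by C⁻¹. It reduces exactly to univariate K for p = 1 (verified
against an independent GLS oracle and a frozen `phytools::phylosig`
reference), needs no inversion in trait space (p may exceed N), averages 1
under Brownian motion, and is invariant to trait-space rotation, common
trait scaling, and common branch-length scaling. Root edges left by
pruning are ignored in C (a shared root edge only shifts the unobservable
root state).

The no-signal null follows the star-phylogeny construction: i.i.d. tip
draws matching the observed trait covariance (distributionally equivalent
to rescaling branches to a star), evaluated against the real tree; p is
one-sided, (count+1)/(n_sim+1), 1000 simulations by default. Power is
defined as the rejection rate (null 95th percentile) of Brownian datasets
simulated on the real tree with the rate matrix estimated from the data by
GLS. This power definition is the package's own (other implementations do
not document theirs), so power values need not agree across software.

## Divergence trajectories

The microevolutionary divergence vector regresses each aligned coordinate
on the habitat canonical scores and normalizes the slope vector; the
macroevolutionary vector does the same with PC1 scores of the species-mean
shapes. Because the two datasets are superimposed separately, the clade
shape space is first rigidly rotated onto the population consensus
(ordinary Procrustes fit of consensus onto consensus) — without a common
orientation a cross-dataset angle is meaningless. The observed angle is
the arc cosine of the dot product, reported on [0, 180°] without folding.

Uncertainty: 900 bootstrap replicates resample the population (stratified
by habitat) and the species-mean rows independently, recompute axes and
vectors, and record the replicate angle. Canonical and principal axes
carry an arbitrary sign, which would make the replicate angle distribution
artificially bimodal, so each replicate vector is sign-aligned to the
observed vector of its own dataset; the unaligned interval is also
reported for comparison with tools that apply no alignment. The decision
rule keeps the classical two-group bootstrap reading — the observed angle
outside the replicate CI is taken as a difference between trajectories —
with the
documented caveat that this rule is not a calibrated test: when an axis
estimate is noise-dominated, replicate angles concentrate away from the
observed one and the rule can fire with no planted difference.

The RRPP comparison tests magnitude differences along a common trajectory:
responses from both datasets are stacked; the full model fits a per-group
intercept and per-group slope vector on the axis scores (standardized to
unit variance within group so slope norms are comparable); the statistics
are |‖b₁‖ − ‖b₂‖| and the angle between slope vectors; the reduced (null)
model shares one slope, and its residuals are permuted across rows, the
full model refit per permutation. The test is conditional on the axis
scores, as is standard for randomized-residual permutation with
covariates: magnitudes are displacement per standard deviation of score,
and score-scale sampling noise is outside the null.

## The synthetic test bed

The generator plants known structure so every estimator can be scored
against truth. Specimens are built in shape space as
base + a_h·v_hab + a_s·v_sex + a_h·a_s·v_int + slope·(log CS − mean) +
isotropic N(0, σ²) per coordinate (a_h, a_s = ±½), then randomly sized
(log-normal CS), rotated and translated so GPA has real work to do.
Effect vectors live in the tangent space of the base shape (orthogonal to
its similarity transforms), so planted displacements survive
superimposition; a requested dimorphism ratio r sets the interaction
vector to 2(r−1)/(r+1)·v_sex, making the urban/rural male–female distance
ratio exactly r by construction. Species means for the clade evolve by
Brownian motion (covariance C ⊗ σ²I) on a supplied or simulated pure-birth
tree, optionally plus a planted macro axis scaled per species. All
randomness flows from one seed through named child streams, so each stage
is independently reproducible.

Defaults mirror the study design this emulates: k = 36 landmarks; 111
specimens in cells urban (38 F, 37 M) and rural (19 F, 17 M); a 12-taxon
fox clade sampled by 163 specimens with uneven per-species counts
(30 … 7); a ~15 Myr ultrametric tree. Quantities the source does not
print were set once at realistic Procrustes scales: habitat effect 0.02,
sex effect 0.015 (shape units ≈ Procrustes distance), landmark noise
σ = 0.01 per coordinate, log CS mean 5.7 / sd 0.1 (centroid size ~300 in
image units), BM rate 9.3e-6 per coordinate per Myr (clade spread several
fold larger than the habitat effect), pose jitter ±30° (full-circle
rotations available for invariance tests).

What passing the synthetic suite shows: the estimators recover planted
directions, ratios and variances under the model's assumptions —
homologous landmarks, isotropic Gaussian digitizing noise, additive
effects, Brownian interspecific divergence. What it does not show:
robustness to correlated or landmark-specific digitizing error, missing or
sliding landmarks, allometric curvature, non-Brownian evolution, or
module-structured covariance — none of which the generator emulates.

## Calibration experiments and problem sizes

Two calibration quantities are recomputed from scratch by
`scripts/acceptance.py` and asserted in the test suite: the mean of K over
300 six-trait Brownian datasets on a 12-tip pure-birth tree (expected 1),
and the empirical coverage of the 95% bootstrap CI for the sex-mean
distance over 200 replicates of a fixed 12-landmark Gaussian model with 30
specimens per sex and 400 bootstraps (expected 95%). The coverage model
uses an effect:noise ratio of 100:1 so the distance estimator's bias is
negligible and the experiment isolates the bootstrap machinery; the
percentile method's residual finite-sample undercoverage at these group
sizes (measured near one percentage point, driven by plug-in variance
estimation) is a property of the method, not of the implementation, and is
why coverage is asserted as a band rather than a point. Remaining
simulation-based tests (type-I error of the MANOVA at 1000 null datasets,
KS uniformity of K and RRPP p-values at 150–200 runs, parameter-recovery
scenarios at n = 200 specimens) use sizes chosen to keep each check's
Monte-Carlo error well inside its assertion band.

## Known limitations

- 2D landmarks only; no semilandmarks, no 3D TPS, no relative-warp α
  weighting beyond uniform.
- The MANOVA requires the 2×2 design and errors out otherwise; no mixed
  models or repeated measures.
- The observed-angle-versus-bootstrap-CI rule is reported because it is
  the source convention, but it is not a calibrated hypothesis test; the
  RRPP comparison is the defensible inferential route.
- K's power estimate follows this package's stated definition; other
  software's internal power numbers need not match.
- Percentile bootstrap intervals undercover by roughly a point at n ≈ 30
  per group; at museum-collection cell sizes (17–38) marginal distance CIs
  should be read with the module's inflation warning in mind.
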