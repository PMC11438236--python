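# Methods

## Convex-hull geometry

Segment meshes (OBJ/PLY/STL, read through trimesh) are reduced to point
sets and hulled with Qhull (scipy).  Volume and centroid are then computed
by this package's own signed-tetrahedron summation: every hull triangle,
taken with the interior point-mean as apex, contributes a signed
tetrahedron volume `det(a, b, c)/6` and centroid `(a+b+c+0)/4`; sums are
origin-independent for a closed surface and exact for polytopes (no
voxelisation or sampling error).  Input winding is never trusted — faces
are re-wound to agree with Qhull's outward halfspace normals, and a hull
whose total signed volume is non-positive raises an orientation error.
Coplanar or collinear inputs are an error naming the deficient affine
rank, not a zero-volume result: a silent zero-volume "segment" would
corrupt every downstream mass sum.  All internal lengths are metres
(mm→m is an exact 1e-3 scaling); point-in-hull tests use a 1e-9 m
closed-boundary tolerance.

## Body models and CoM

A body is a list of named segments (controlled vocabulary: the 16
canonical segments, optional `sail`, optional `tail_sub_k` series), each
carrying hull volume, centroid, density (default 1000 kg/m³, the
measured whole-animal range being roughly 893–1080 kg/m³) and an
expansion factor.  Whole-body volume is the plain sum of hull volumes
(expansion factors excluded — that is the quantity the predictive
equation was calibrated on); effective mass is Σ V·EF·ρ.  CoM is the
mass-weighted centroid mean.  The two positional proxies project the CoM
onto the acetabulum→glenoid unit vector: %C(AG) = 100·dca/|AG| and
DCA/FL = dca/femur length.  Using one shared axis for both makes them
proportional, rigid-motion invariant, and exactly independent of any
uniform density rescaling (each segment mass scales by the same factor,
so the weights cancel; in floating point this holds to ~1e-12).

Expansion factors (MEF from mammal reference specimens, SEF from
sauropsids) are arithmetic means over specimens of per-segment skin/hull
volume ratios.  Inflation is modelled as uniform about each segment's
centroid, so centroids do not move; whether re-posed expanded models
should recompute centroids is genuinely open, and centroid-preserving
inflation is the simplest defensible choice — it makes an all-unity table
an exact identity, which the tests exploit.  Trunk deflation to 90/80/70%
multiplies the trunk's expansion factor, probing non-uniform segment
density.  Tailless or skull-less models simply mark the skull:tail ratio
unavailable rather than failing, and missing landmarks disable the CoM
proxies but never mass estimation.

## Scaling fits and PPE

All fits are OLS (statsmodels) on log10–log10 axes with t-based 95% CIs
(n−2 df); base-10 logs everywhere.  The raw-scale through-origin variant
(slope = Σxy/Σx², interpretable as a whole-body volume expansion factor)
is provided for comparison, with Q–Q diagnostics at Blom plotting
positions ((i−3/8)/(n+1/4)) and adjusted Fisher–Pearson skewness (defined
as 0 for an exact fit).  Percent prediction error uses the prediction as
denominator for the absolute form, 100·|obs−pred|/pred, and the
observation for the signed form, 100·(pred−obs)/obs, so underestimates
fall left of zero in density plots; both conventions are exposed because
the field uses both.  "Logged PPE" is the sign-preserving pseudo-log
sign(s)·log10(1+|s|), which maps zero to zero exactly.  Group precision
is the mean absolute PPE with a t interval (n−1 df); sample-size effects
are probed by subsampling *without* replacement (default 1000 iterations
down to n=33).  Allometry calls are the CI-versus-null trichotomy:
positive iff the whole CI is above the null slope, negative iff below,
isometry otherwise.

## Synthetic data

Primitives: boxes and 64-gon frusta are exact vertex polytopes (the
frustum's analytic volume is the truncated-pyramid closed form of the
polygonal solid, i.e. (πh/3)(R²+Rr+r²) scaled by (n/2π)·sin(2π/n)), so
hull volume matches the analytic value to ~1e-12 relative; ellipsoid
clouds are surface samples whose hull inscribes the ellipsoid and
under-covers (4/3)πabc by a deficit that is ~1.2% at 1000 points and
~0.25% at 5000, shrinking as n^(−2/3) — chosen deliberately because real
skeletal hulls likewise inscribe the fleshed body.  Bodies are laid out
cranio-caudally from boxes with clade-templated proportions
(crocodylian-like: tail-heavy; mammal-like: skull-heavy); the skull box
is sized to hit the requested skull:tail volume ratio exactly, and the
ground truth (volumes, centroids, CoM, %C(AG), DCA/FL) is recomputed
from the closed forms with plain sums, independently of the code paths
it validates.

Populations are generated under log10-linear laws defaulting to the
calibrated coefficients (volumetric 0.968/0.215; stylopodial
2.716/−4.078; per-clade robustness laws).  Noise placement matters: the
recorded specimen mass carries the log10-normal residual
(`sigma_log10_mass`, default 0.15 — the order of scatter typical of such
calibrations) and the predictors derive deterministically from latent
structural size, with a second residual on circumference given length
(`sigma_log10_robustness`, default 0.10, which reproduces robustness
r² ≈ 0.95 over the default size span).  This keeps every regression the
pipeline fits *classical* — residual on the response, independent of the
regressor — so the generating slopes are exactly the estimands and
simulated confidence intervals attain nominal coverage.  Putting the
noise on the predictors instead would be an errors-in-variables model
whose OLS slopes are attenuated (by ~10% for the stylopodial law at
σ = 0.15), which is not the model any of the analyses assume.  True
specimen size is log-uniform over 0.127–2735 kg by default, matching the
leverage structure of the extant calibration range; the recorded masses
spread slightly beyond it through the residuals.

Synthetic fossils invert the volumetric law exactly (so the hull route
recovers true mass) but draw circumferences from a steeper robustness
law (default slope 1.319 vs the extant reference 1.179) evaluated at
extant-implied lengths.  Above the two laws' crossing point the
stylopodial estimate therefore exceeds the volumetric one by a factor
that grows with size — the qualitative overestimation pattern — and
setting the fossil law equal to the reference collapses the mean ratio
to 1.  All randomness flows from one integer seed through
`numpy.random.SeedSequence.spawn`, so sub-streams are independent and
individually reproducible.

## Pipeline and reporting conventions

Specimen CSVs are validated row-wise with 1-based line numbers in error
messages; a record must carry a hull volume or a circumference pair, and
masses approximated from species-specific literature scaling are flagged
(`mass_provenance`) so calibrations can be rerun without them.  Fossil
comparison tables report the stylopodial/volumetric ratio at 1 decimal
(full precision kept internally) sorted descending.  CoM regressions are
reported per group × variant with a p < 0.05 two-sided slope-test gate
and no multiple-testing correction (none is conventional for this
family of descriptive fits); groups with n < 3 are skipped with a
warning.  The circumference unit is fixed to millimetres and config
validation rejects anything else, since the stylopodial equation's
intercept is unit-bound.

## Problem sizes in the checks

The test-suite and acceptance-script simulation sizes are chosen as the
smallest that make each check sharp: Monte-Carlo hull oracles use 10⁶
rejection samples on 20 seeded polytopes (3-SE bands), CI-coverage runs
use 300–500 replicates at the calibration design points (n = 33 and
n = 266), and the CoM study uses 8 bodies per clade template across a
decade of skull:tail ratios.

## Limitations

Hulls are minimum convex hulls of posed skeletons: no mesh repair,
non-convex volumes, lung cavities, inertia tensors or articulated
re-posing.  The synthetic bodies are box assemblies — they exercise the
arithmetic and the qualitative proportion–CoM relationship, not
anatomical realism, and passing tests on them says nothing about
segmentation or posing error in real CT data.  Phylogenetic GLS is out
of scope (it demonstrably moved these calibrations very little), as are
SMA/RMA fits and heteroscedasticity-robust errors.  Numeric MEF/SEF
values are user-supplied configuration, not package constants, since
they belong to their source datasets.
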