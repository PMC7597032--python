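# Methods

This note records the conventions, parameter choices and numerical
decisions behind `pedarch`, and what the synthetic-data tests do and do
not establish about real data.

## Foot anatomical frame

The ground segment is fitted by a total-least-squares plane (SVD of the
centred vertices; the normal is oriented toward the bone centroid
cloud).  The vertical axis is the ground normal.  The antero/posterior
axis is the on-ground segment from the projection of the calcaneus's
most plantar vertex to the projection of the most plantar vertex of the
second metatarsal *head*; the head is taken as the distal 30 % of M2's
extent along its principal axis, found with a provisional PCA axis and
refined once with the resulting frame's ap direction.  The medio-lateral
axis closes the right-handed triad (ap × ml = vert).  Realignment maps
ap → x, ml → y, vert → z with the calcaneus plantar projection at the
origin; foot length is the on-ground distance between the two defining
plantar points and normalises the relative bone heights.

Plantar-point selection carries a deterministic tie-break: vertices
within 10⁻³ mm of the minimal ground distance are resolved by the
largest projection onto the provisional medio-lateral axis.  Real meshes
essentially never tie; the synthetic ellipsoid meshes are deliberately
reflection-symmetric and tie exactly, and without a frame-invariant rule
the chosen vertex — hence the frame azimuth — would depend on the
arbitrary scanner pose.

## PCA bone frames and angles

Bone frames come from the eigendecomposition of the unique-vertex
covariance about the centroid (unweighted; an area-weighted variant is a
documented possible extension, but surface points are the input here).
Axes are ordered by descending variance; signs are anatomical: the
longitudinal axis points anteriorly (non-negative dot with ap), of the
remaining two the axis closer to vertical becomes dorsi-plantar (dorsal
positive), and the medio-lateral axis is flipped to make
longitudinal × ml = dp.  A first-to-second eigenvalue ratio below 1.05
flags the bone as having no dominant long axis (warning; axes still
returned in eigen order with a deterministic pre-sign fix:
largest-magnitude component positive).

Angle conventions (degrees, dorsal positive): I3 = asin(u_z) is the
signed elevation above the ground plane; IL = atan2(u_z, u_x),
IT = atan2(u_y, u_x), IF = atan2(u_z, u_y) are the planar projections
measured from the ap axis (IL, IT) or ml axis (IF).  A projection
shorter than 10⁻⁹ leaves that angle undefined (NaN), which propagates as
a missing value into the correlation stage (pairwise deletion), never as
a zero.  Relative angles are differences of projected absolute
inclinations (distal − proximal), so RL_MxPx = IL_Px − IL_Mx identically
and planar relative angles negate under argument swap; R3 is the
unsigned 3D angle.  Plantarflexion is negative dorsiflexion.

The "relative" bone heights are normalised by foot length.  Other
normalisations are conceivable; this one is scale-free across feet and
is recorded in the output metadata.

## Footprint masking and LOAD variables

The contact mask is `peak pressure > 10 kPa` (configurable).  The foot
axis is the principal axis of the contact mask, pointed anteriorly by
the CAL → M2 marker direction.  The medial and lateral tangents of the
footprint are the supporting bitangent edges of the contact convex hull
that run from the heel bulge to the forefoot bulge (the classic
footprint-angle construction); their intersection behind the heel is the
fan apex and the angle between them the whole-foot plantar angle γ.
Rays from the apex split γ medial-to-lateral into 30 / 51 / 19 %
sectors (first, central, fifth metatarsal).  Exactly parallel tangents
(γ = 0, e.g. a rectangular test footprint) degrade to partitioning the
strip width in the same proportions.  The forefoot band lies between the
metatarsal-head marker line (offset −25 mm along the axis, so the band
covers the heads) and the toe line through the hallux marker; the hallux
region is the toe-side contact medial of the first sector boundary.
This is a marker-based reconstruction of a masking geometry whose
commercial implementations are proprietary; it is a documented
approximation, not a re-implementation of any vendor's masks.

Per region and trial: PP is the maximum over frames and sensors; PTI
integrates the regional peak-pressure curve (per-frame maximum over the
region's sensors) times the frame interval — a per-sensor-integral
alternative is available as `pti_convention="per_sensor"`; PTI_N divides
by the whole-foot contact time in seconds.  Contact time counts frames
with any sensor above threshold.  LOAD metrics are computed per trial
and averaged over the five trials: the registered-and-averaged footprint
has no time axis, so PTI cannot be computed from it.  Registration
(contact-centroid plus principal-axis alignment, rotation resolved to
the nearest half-turn) is retained for the arch index and reporting.
The arch index splits the toe-free footprint into three equal-length
bands along the foot axis and takes the middle band's area share.

## Clinical scoring

NS-VPT sums four max-normalised contributions (MNSI history / 15, MNSI
physical / 10, VPT hallux / 40, VPT malleolus / 40).  Grouping uses the
two-of-three rule with strict inequalities: MNSI > 2 (physical
assessment score by default — the conventional 2-point cut-off —
switchable to the history score), MDNS > 7, VPT > 25 V; a LADA
diagnosis overrides.

## Correlation screen

1512 inter-variable, 3486 intra-skeletal and 66 intra-LOAD pairs are
evaluated per group (ALL, N, D) with the sample Pearson correlation,
pairwise-complete deletion and the exact two-sided t-test p-value on
n − 2 df.  The screen is a p < 0.05 filter without multiple-testing
correction — it is an exploratory screen, and that is the design being
reproduced; a Benjamini–Hochberg option exists but is off by default.
Strength classes: weak R² ≤ 0.30 < moderate ≤ 0.70 < strong.  Group
comparisons use the pooled-variance Student's t-test (Welch available).
Fewer than 3 complete pairs or zero variance flag the pair instead of
producing a number.

## Synthetic data

Bones are scalene ellipsoids: their principal axes, centroids and
ground-tangent heights are known in closed form, giving exact ground
truth for every one of the 84 variables.  The surface sampling folds a
quasi-uniform spherical point set into one octant and unfolds it through
all eight reflections, so the sample second-moment matrix is exactly
diagonal in the body frame and PCA recovers the planted axes to machine
precision.  The generated scene is pre-aligned so that the anatomical
frame the pipeline will reconstruct is exactly canonical; ground truth
is read off the planted poses there, and a random rigid scanner pose is
then applied to all meshes including the ground.  Default poses follow
adult forefoot anatomy: metatarsals declining 18–23° to their heads,
near-horizontal phalanges (means from the −11° hallux to +8° fifth
phalanx), arch bones raised.

Pressure trials are Gaussian blobs in space (compact support at 2.5 σ,
centres on the sensor lattice) with half-sine time envelopes whose peaks
fall on sampling instants, so planted peak pressures and contact times
are recovered exactly in the jitter-free case and the discrete PTI
matches the analytic 2AT/π to well under 2 %.  Stance lasts 680 ms with
heel-to-toe timing; amplitudes 220–420 kPa under the forefoot.  Trials
get rigid jitter (σ 2 mm translation, 1.5° rotation) and 5 % amplitude
variation by default.  The blob layout is chosen so each metatarsal
head's contact area falls inside its 30/51/19 % sector — the anatomical
premise of that subdivision.

Cohorts mirror the study structure (7 N / 8 D / 1 LADA by default).
Clinical records are drawn to satisfy the grouping rule by
construction; all 102 variables start as independent normals at
realistic scales, then each planted link overwrites its LOAD variable as
intercept + slope·angle + noise.  The noise variance is calibrated
against the *realized sample variance* of the drawn angle values via
R² = β²s²ₓ / (β²s²ₓ + σ²ε).  Calibrating against the population variance
instead leaves the full sampling variability of the bivariate-normal
correlation (sd(r̂²) ≈ 0.029 at R² = 0.77, n = 200), which is too wide
for a ±0.05 recovery band at 95 % coverage; sample calibration removes
the regressor's share of that variability while keeping the noise's, and
is what "planting a target R²" means here: the target describes the
generated cohort, not a hypothetical superpopulation.

## What passing tests show — and what they do not

The synthetic feet are convex, symmetric and noiseless, so geometry
recovery at 10⁻¹³ degrees demonstrates correctness of the frame and
angle algebra, not robustness to segmentation noise, partial scans or
deformed bones.  The pressure model has no soft-tissue spreading,
sensor noise or gait variability beyond rigid jitter; masking agreement
on it validates the sector geometry, not marker-placement error
handling.  Cohort planting validates the screen's statistics, not any
clinical effect.  Patient-level results depend on data that is not
publicly deposited and are out of scope.

## Sizes and numerics

Default problem sizes: 520 vertices per bone (8-fold symmetric), 64 × 32
sensor grid, 68 frames per trial, 5 trials, 16-patient cohorts; the
recovery studies use 50 feet, 100 cohort replicates at n = 200 and 5000
null pairs.  All generators are deterministic given their seed; seeds
change noise realizations, never structure.  Angle wrap-around uses
(−180, 180]; r is clipped to [−1, 1] before R²; BH adjustment passes
NaNs through.
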