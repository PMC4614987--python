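# Methods

`phragmovol` analyses the volumetric ontogeny of chambered cephalopod
conchs: how the volume of each phragmocone chamber changes through
growth, how trajectories differ between conspecific individuals and
between sexes, and how chamber volumes are measured from tomographic
reconstructions in the first place. This note records the models, the
conventions, and the choices made where the problem left the design
open.

## Data model

A specimen's growth record is a `ChamberSeries`: strictly increasing
1-based chamber indices with a per-chamber volume (mm³ for the
ammonites, ml for *Nautilus*, stored in the unit of the source table)
and optionally a per-chamber width in mm. Missing measurements are NaN
and are never imputed; a series may begin after chamber 1 when early
chambers could not be measured (the ammonite series start at chambers
25 and 27). The single conversion constant 1 ml = 1000 mm³ is applied
only on explicit request (`volumes_mm3()`).

The packaged tables reproduce the published raw data verbatim and are
pinned by SHA-256 checksums. Known oddities of the print are kept, not
repaired: specimen 53's width column is typographically identical to
specimen 8's; specimen 8's widths run to chamber 35 although its
metadata row records 30 chambers (and specimen 7 carries a width at
chamber 36 against a recorded count of 35) — `validate_against_specimen`
flags these; specimen 17's chamber 5–6 volumes (1.987 and 1.266 ml,
two orders of magnitude off trend) are flagged as probable segmentation
artefacts and can be masked with `exclude_artifacts=True`, default off
because the source does not state they were excluded from any
statistic. The published *Nautilus* volume table embeds the 10
specimen columns that appear in the available print (specimens 7, 8,
10, 11, 12, 15, 16, 17, 20, 23: two mature males, six mature females,
two juveniles); statistics that the original authors computed over all
21 mature specimens can therefore only be recomputed over this subset,
and the report says so wherever it matters.

## Growth model

Chamber volumes through ontogeny are modeled by the three-parameter
logistic

    V_i = K / (1 + exp(−r (i − m)))

with `K` the asymptotic chamber volume (volume units), `r` the growth
rate per chamber (dimensionless), and `m` the midpoint chamber. Fits
are multi-start nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective, bounds K, r > 0; seven starts spanning K
between 1.05× and 5× the observed maximum and two midpoint guesses,
with the rate seeded from the log-slope). Residuals are on the raw
volume scale by default — consistent with the magnitude of the
published RSS decomposition — with a log-scale option for series
spanning several orders of magnitude. On noiseless logistic input the
fit recovers (K, r, m) to better than 1e-6 relative error; a
non-convergent fit raises with per-start diagnostics rather than
returning a bad optimum.

### Breakpoints

Growth-stage transitions (end of the embryonic stage in nautilids, end
of the neanic stage in ammonoids) appear as a change of slope in
log-volume versus chamber number. The detector fits, for every
admissible hinge position, the continuous two-segment piecewise-linear
least-squares model on (chamber, log V) and takes the global RSS
minimum — an exhaustive search, so it is its own brute-force oracle.
Admissible hinges need at least 3 points on each side. The reported
`breakpoint` is the first chamber governed by the second slope; the
hinge chamber itself (last chamber of the first regime) is exposed as
`knot`. A breakpoint is *declared* (`found=True`) only when the
two-segment RSS is at most 0.8× the single-line RSS (configurable) and
the single line does not already fit perfectly. On the ammonite Nm.1
the best split lies at chambers 27/28 but the improvement ratio is
0.90 — a real but subtle transition, reported with `found=False`.

### Terminal countdown

The decline of chamber volumes before maturity has no agreed formal
definition, so the package fixes one: the onset is the centre chamber
of the maximal 3-point moving average of measured volumes (earliest
centre on ties), and a countdown is declared only if the last measured
volume lies below the onset volume; its length counts chambers from
onset through the last. This rule reproduces the published countdown
lengths (5 chambers for Nm.1, 7 for Nm.2) from the raw table, but it
is this package's operationalization, not a claim about how the
original assessment (possibly visual) was done. The largest anomalous
drop is simply the maximum of (V_{i−1} − V_i)/V_{i−1} over consecutive
measured pairs; both detectors are scale-invariant.

### Width–volume covariation

The covariation index is the Pearson correlation between Δlog(width)
and Δlog(volume) over consecutive chambers with both quantities
present (at least 5 such chambers required). Using log-increments
removes the shared ontogenetic trend that would otherwise force any
two growing quantities toward r ≈ 1; what remains is whether the conch
changes shape in step with chamber volume (ammonites, r ≈ 0.4–0.7) or
expands width at a constant pace regardless (*Nautilus*, r ≈ 0 or
negative). Constant width or volume increments make the index
undefined; `None` is returned rather than a silent 0.

## Group comparison (ARSS)

Two analysis-of-residual-sum-of-squares tests compare male and female
growth:

* **Linear**: ordinary least-squares lines per group; the slope
  difference is tested with the pooled residual mean square
  s² = (RSS_a + RSS_b)/(n_a + n_b − 4),
  t = (b_a − b_b) / √(s² (1/Sxx_a + 1/Sxx_b)), two-sided p. Per-group
  RSS and df (n − 2) are reported to mirror the published table
  layout. Noiseless groups with distinct slopes report t = ±∞ and
  p = 0 rather than overflowing.
* **Nonlinear**: the extra-sum-of-squares F test for logistic curves,
  F = ((RSS_pooled − (RSS_a + RSS_b))/p) / ((RSS_a + RSS_b)/(N − 2p))
  with p = 3 parameters, df1 = 3, df2 = N − 6. This df convention
  reproduces the published F (4.55) from the published RSS
  decomposition to within print rounding. Pooled fits share the
  per-specimen fitting engine.

Comparisons of chamber volumes start from chamber 6 by default, with
the embryonic chambers 1–5 compared separately, mirroring the
two-regime growth. p-values are two-sided; the published tiered labels
("s (P < 0.05)", "s (P < 0.1)", "ns (P > 0.5)") are preserved as
labels, not collapsed to a single α, and no multiple-testing
correction is applied. The F test assumes additive homoscedastic
Gaussian residuals; under multiplicative (lognormal) noise — which
real volume series resemble — it is anticonservative (simulated null
mean of F ≈ 2.3 instead of ≈ 1.0), so its p-values on raw-scale fits
of wide-ranging volumes should be read as descriptive. The
null-calibration test therefore simulates additive Gaussian noise (the
test's own model), while the power analysis uses the lognormal
generator.

Group dispersion is the sample standard deviation (n − 1 denominator)
of per-specimen total phragmocone volumes, per sex and combined.

## Volumetrics

* **Mesh volume** is the signed-tetrahedron (divergence-theorem) sum
  over triangles, orientation-normalized per closed component, so
  multi-component files yield the sum of the parts; non-watertight
  meshes are rejected naming the number of open edges. Rigid motions
  change the result by < 1e-9 relative; `trimesh`'s own volume serves
  as an independent cross-check in the tests, and STL I/O goes through
  `trimesh`.
* **Voxel volume** is exact by construction: label count × dz·dy·dx,
  with anisotropic (z, y, x) voxel dimensions in mm carried by the
  stack (TIFF stacks travel with a JSON sidecar recording dimensions
  and axis order, since TIFF alone does not carry them reliably).
* **Chamber labeling** uses 6-connectivity (thin septa separate
  chambers; 26-connectivity would bridge across voxel corners) and
  orders components ontogenetically by walking the component centroids
  along the spiral about the coiling axis, starting at the innermost
  centroid and accepting either coiling handedness.
* **Slice subsampling** emulates segmenting only every k-th
  tomographic section: retained slices are extruded into slabs of k
  original slices (zeroth order, deliberately — the emulated workflow
  does no interpolation). The estimate is unbiased over slab phases;
  per-chamber error at k = 4 stays below 5% once a chamber spans a
  dozen original slices.
* **Width** is the axis-aligned physical extent (index span + 1
  voxels) along the declared coiling axis — the simplest reproducible
  convention, since the source never defines its width measurement.
* **Buoyancy**: the neutral-buoyancy cameral-liquid fill fraction
  solves m_shell + m_soft + f·V_cam·ρ_liq = ρ_sw·(V_shell + V_soft +
  V_cam); out-of-range solutions (f < 0: sinks even empty; f > 1:
  cannot reach neutrality) are reported explicitly, never clamped, and
  the mass-balance residual at the returned f is below 1e-9 of the
  displaced mass. Shell-volume bounds from shell mass use the
  aragonite density range 2.54–2.62 g/cm³.

## Synthetic data

The series generator produces what the analysis stages must detect,
with known truth. Its defaults emulate a mature *Nautilus*: K = 35 ml,
r = 0.2, m = 30, 32 chambers (volumes ~0.001–25 ml), an embryonic
log-linear segment through chamber 5 with 6× the logistic log-slope
(matching the observed ~1.3/chamber embryonic log-slope), a one-chamber
terminal decline with factor 0.85 (most adult *Nautilus* show only the
last chamber reduced, by ~15%), and multiplicative lognormal noise with
σ = 0.15 on the log scale — noise is multiplicative because volumes are
positive and span four orders of magnitude. Chambers i ≤ b0 lie on the
embryonic segment anchored so chamber b0 takes exactly the logistic
value; the hinge of the underlying piecewise model therefore sits at
b0, and the breakpoint detector recovers `knot == b0` exactly on
noiseless output. Ammonite-like series are obtained by raising
`countdown_k` to 5–7. Cohorts derive per-specimen seeds from one seed
via `numpy` seed sequences; sexual dimorphism is a scale factor on K
(and optionally extra chambers for males).

What the generator does *not* emulate: measurement error correlated
across adjacent chambers, missing-value patterns, septal crowding, or
injury-driven growth interruptions. Tests passing on synthetic cohorts
show the machinery is correct under the stated model, not that real
conchs satisfy the model.

The 3D generator sweeps a circular or elliptical aperture of radius
f·d(θ) along the logarithmic spiral d(θ) = d0·W^(θ/2π) in the coiling
plane (planispiral only — translation is fixed at 0, as in the studied
taxa), partitioned by planar radial septa every Δθ (true septal
curvature is out of scope). Geometry that would self-intersect
(f ≥ (W−1)/(W+1)) is rejected. Chamber meshes are watertight by
construction (shared ring vertices, fan caps on the planar septal
half-planes). Ground-truth volumes integrate the radial first moment
π a b d of the cross-section over θ with composite Simpson at three
halving step sizes; the relative change of the last refinement is
reported (≈1e-11 at the defaults), and for this self-similar geometry
the integral also has a closed form used as an independent oracle in
the tests. Voxelization rasterizes each mesh by x-ray parity counting
on the voxel-centre grid (one ray per (z, y) row, crossings by
barycentric tests against each triangle's projection, ray coordinates
offset by irrational fractions of a voxel so edge/vertex hits have
measure zero); a voxel claimed by two meshes — possible only on the
shared septal plane — keeps the first label, so labels are disjoint.

## Numerical choices and degenerate inputs

Ties in the countdown moving-average maximum break to the earliest
chamber. The breakpoint search requires ≥ 6 measured points and, when
the single-line RSS is below 1e-10·n (a perfect line), declares no
breakpoint regardless of ratio. Logistic fits require ≥ 4 positive
volumes. `largest_drop` ignores pairs spanning a measurement gap.
Countdown chambers are excluded from logistic fit ranges in the
per-specimen reports, since the terminal decline is a departure from
the logistic trend. All detectors treat missing values by omission,
never interpolation.

## Problem sizes in the test suite

The statistical property tests use: 1000 replicates for the linear
ARSS type-I error (n = 12 + 9 per replicate), 200 replicates for the
nonlinear ARSS power analysis at the published group sizes (12 males,
9 females, 32 chambers), 500 replicates of 3 + 3 specimens × 26
chambers for the F null calibration, and 200 replicates for the
logistic K-bias check (σ = 0.15, n = 30). Voxel grids in the tests use
0.01–0.8 mm pitches on unit-scale solids and 6–8-chamber shells; these
sizes give stable verdicts for every property tested while keeping the
suite quick to run.

## Known limitations

* The report juxtaposes its dispersion and regression summaries with
  the published reference values, but the published per-group RSS of
  the diameter-versus-chamber-count comparison (46.5 / 14.6) is not
  reproduced by ordinary least squares on the specimen table (an
  independent OLS oracle gives 35.6 / 7.5); the exact regression
  variant behind those printed cells is unknown, and the package
  reports its own values rather than tuning toward the print.
* The published ~27% neutral-buoyancy fill fraction needs the original
  reconstructed mesh of specimen Nm.1, which is not available; only
  the mass-balance solver is provided.
* The published per-sex SDs of total phragmocone volume (15.4 / 13.4 /
  14.3) cover 12 males and 9 females, but the available raw-volume
  table prints only 2 mature males and 6 mature females, over which
  the same statistic gives 9.2 / 16.0 — reported alongside the
  reference values, not in place of them.
* Grey-level segmentation of real CT data is out of scope: inputs to
  the volumetrics layer are already-labeled masks or meshes.
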