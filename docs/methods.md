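# Methods

This note documents the models, conventions, defaults and known
limitations of `vasomech`, in the spirit of a methods appendix: everything
a user needs to interpret the numbers the package produces. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Units

Two mmHg conversions coexist deliberately. Circumferential stress in
pressure myography is reported in CGS units with the rounded literature
convention **1 mmHg = 133.4×10³ dyn/cm²**; the wire-myography Laplace
isobar uses SI (**1 mmHg = 133.322 Pa**). Wall tension in N/m is
numerically identical to mN/mm (the myograph's native unit), which is why
the isobar slope for diameters in µm is simply `P[Pa]·10⁻⁶/2`.

## Wire myography

Tension per unit segment length is `T = F/(2L)`: the ring hangs on two
wires, so two wall strips bear the transducer force. This two-wall
convention is standard wire-myograph practice; recordings may instead
supply tension directly.

The diameter–tension relationship is summarized by ordinary least squares
of `T` on `d`. `Y₀ = −intercept/slope` is the extrapolated zero-tension
diameter; `d₁₀₀` solves `slope·d + intercept = k·d` with `k` the
100 mmHg Laplace isobar slope. A non-positive fitted slope marks the
recording as non-physiologic: `Y₀` and `d₁₀₀` are returned as NaN rather
than raising, so QC can act downstream. `d₁₀₀` is solved on the *linear*
fit (not an exponential refit) because the group comparisons are made on
linear-regression slopes; the strategy is isolated in `estimate_d100` and
can be replaced.

Note on Laplace's law: wall tension is `T = P·r` (force per unit vessel
length). The variant "tension = P·r/thickness" sometimes quoted in
acquisition-software manuals is dimensionally a stress; this package uses
the tension form consistently.

Two caveats inherited from common acquisition software are handled
explicitly: the calibration-QC threshold ("discrepancy > 5" between unit
and software) is interpreted in mN and kept configurable, with the
boundary value itself retained (strict inequality).

**Accuracy of d₁₀₀ against a nonlinear vessel.** A real (exponential)
vessel's diameter–tension curve is convex; a straight line fitted over a
range that includes very low loads is a poor tangent near the 100 mmHg
isobar. Fitted over the stepwise-stretch working range that brackets the
isobar (about 43–120 mmHg equivalent loads), the linear estimate matches
the true equilibrium diameter to well under 1% for stiffness exponents
β ∈ [3, 8]; over the full 3–120 mmHg range the error grows to ~10%. The
test suite and acceptance script therefore evaluate `d₁₀₀` on
working-range pairs, which mirrors how stepwise stretching actually
samples the curve.

## Pressure myography

Per-pressure quantities: `WT = (Dₑ−Dᵢ)/2`, `wall:lumen = (Dₑ−Dᵢ)/(2Dᵢ)`,
incremental distensibility `ΔDᵢ/(Dᵢ·ΔP)·100` (%/mmHg). The denominator
diameter of each step is the lower-pressure diameter by default
(configurable to the step midpoint); the pressure grid is whatever the
file contains — the nominal protocol of 20 mmHg steps from 3 mmHg capped
at 120 mmHg makes the last step 17 mmHg, and nothing is enforced beyond
monotonicity and the presence of the 3 mmHg reference.

Strain is referenced to `D₀₀`, the inner diameter at 3 mmHg, taken
strictly from the 3 mmHg entry of each series. The exponential wall model
`σ = σ_orig·e^{βε}` is fitted **per animal** by least squares on
`ln σ = ln σ_orig + β·ε`. The log transform linearizes the model exactly
and stabilizes multiplicative error; on noiseless exponential data it
coincides with nonlinear least squares to machine precision (verified in
the tests against `scipy.optimize.curve_fit`). Group comparisons then act
on the per-animal β values, never on a pooled fit. `E_inc = β·σ` follows
by differentiation.

## Synthetic vessel generator

The generator closes the passive-mechanics model with an
**incompressible wall**: the wall cross-sectional area `A` is constant
across pressures, so `WT(Dᵢ) = (√(Dᵢ² + 4A/π) − Dᵢ)/2`. At each pressure
the inner diameter solves the force balance

&nbsp;&nbsp;`σ_orig·e^{β(Dᵢ−D₀₀)/D₀₀} = P·Dᵢ/(2·WT(Dᵢ))`

by bracketed Brent root finding on `(D₀₀, 10·D₀₀)` (tolerance 10⁻⁶ µm), a
generous physiologic range; an unbracketed root aborts generation with
the offending parameters. Noise is additive Gaussian on both diameter
channels — no instrument error model is published for these rigs, so the
default magnitudes (1 µm on diameters in the demo study; 0.05 mN/mm on
wire tension; 0.005 mm² on MRI areas; SNR 10 on fiber images) are chosen
once as plausible bench values and are parameters of the generators, not
estimates of any particular instrument.

**Anchoring σ_orig.** `σ_orig` is the stress at the unloaded (3 mmHg)
diameter, so it is not a free parameter: given `D₀₀` and `A` the 3 mmHg
force balance fixes it. When `sigma_orig=None` (the default) the
generator derives it from that balance, which places `D₀₀` exactly at the
3 mmHg equilibrium and makes the noiseless series an *exact* round trip
through the analysis formulas (β recovered to ≤0.1%). An explicit
`sigma_orig` is honoured as given; if it contradicts the 3 mmHg balance
the generated 3 mmHg diameter — the strain reference the analysis reads
from the data — shifts away from `D₀₀`, and the refitted β equals
`β·Dᵢ(3)/D₀₀` rather than β. Recovery tests therefore use the derived
(consistent) σ_orig.

Default geometry (`D₀₀` = 200 µm, `A` = 3×10⁴ µm², implying
WT ≈ 42 µm and σ_orig ≈ 1.0×10⁶ dyn/cm² at 3 mmHg) is typical of a mouse
mesenteric resistance artery.

## MRI kinetics and PWV

Curves are linearly interpolated onto a 1 ms grid and cut at 150 ms;
beyond that point differing cycle lengths prevent meaningful time
alignment, so nothing is computed there. NaN samples in the upper slice
are substituted with the time-matched lower-slice value *before*
interpolation; a coverage gap wider than a quarter heart period with no
secondary slice is an error rather than silent extrapolation. The
ascending slope is OLS over the first 20 ms; total strain uses the
trapezoidal rule on the resampled grid (refinement-stable to <0.5%,
checked in the tests). "Distensibility" here is deliberately the
area–time slope in mm²/ms — not the conventional pressure-normalized
distensibility — because no simultaneous pressure is acquired.

Foot-of-wave times for PWV are operator-supplied inputs; an
intersecting-tangent detector is included for convenience but flagged
experimental, since manual foot placement is the reference method here.
PWV = distance/transit-time, with mm/ms ≡ m/s requiring no conversion.

## Elastin rectilinearity

The chain: median filter (disk radius 2 px) → rolling-ball background
subtraction (radius 25–50 px; must be larger than the fiber width and
smaller than the image) → threshold (Otsu by default; Yen and fixed
values supported — a fixed mode is essential for reproducing
operator-chosen thresholds) → removal of connected components smaller
than `min_component_px` (default 64) → thinning to 1-px center lines
(Lee's method) → branch decomposition → `Σ chord / Σ length`.

**Junctions.** A skeleton pixel is a junction when its neighbors form ≥3
connected clusters around the 8-ring (crossing-number rule). Counting
clusters rather than raw neighbors keeps simple corners intact — an
L-bend has three mutually adjacent neighbors but only two branch
directions. Junction pixels are removed before tracing, so branches share
no pixels; neighbor-order ties during tracing are broken
orthogonal-first, then row-major. Closed branches (cycles) are flagged
and use the maximum pairwise pixel distance as their chord.

**Geodesic length.** Two estimators are provided.

- `"polyline"` (default): the traced path subsampled every 5 pixels
  (endpoints kept) and measured as an inscribed polygon. This is unbiased
  for smooth curves of any orientation and *exact* on straight
  axis-aligned and 45° segments (N pixels → N−1 steps), so a straight
  fiber scores exactly 1.0.
- `"chain"`: the classical step count (1 orthogonal, √2 diagonal). It is
  exact on axis/diagonal lines but overestimates smooth curves by up to
  ~8% depending on local orientation (≈ +5.5% averaged over a circle),
  which biases rectilinearity low — a digitized half circle measures
  ≈ 0.61 instead of 2/π ≈ 0.637. It is retained for compatibility with
  step-counting skeleton tools, not as the default.

With the default estimator the analytic oracles hold within 2%: half
circle → 2/π, sinusoid with amplitude λ/2π → 0.822 (quadrature), and the
measure is invariant to fiber thickness (3 px vs 9 px within 2%) and to
rotation.

Coordinates are 0-based with half-open ROIs `(row0, col0, row1, col1)`.

## Histology quantification

Hue classification uses HSV bands in degrees — red [0°,30°]∪[330°,360°],
green [70°,170°], orange-yellow [20°,60°] — with saturation and value
floors of 0.15 to exclude unstained/background pixels; all bands and
floors are configurable, as staining and white balance vary between
scanners. Trichrome fractions are percentages of the media mask (they
need not sum to 100). Picrosirius classes are quantified within the
adventitia, the layer where birefringent bundles are observed.

Lumen perimeter and layer boundaries are measured on marching-squares
contours subsampled into inscribed polygons (the same anti-staircase
device as the fiber-length estimator; a digitized circle of radius 100 px
measures 2πr within 1%). Media thickness = media area / midline length,
the midline being the mean of the inner (lumen) and outer contours —
robust to locally irregular sections, unlike per-ray thickness.

The **Kapur maximum-entropy threshold** maximizes the summed Shannon
entropies of the sub- and supra-threshold class histograms, computed with
vectorized cumulative sums; ties take the lowest threshold, and the test
suite proves equivalence with an exhaustive search on random histograms.
Integrated density sums intensities over strictly supra-threshold pixels.
Normalization divides by the control-group median, so the normalized
control median is exactly 1 by construction. SHG kurtosis and skewness
are the Pearson central-moment ratios `m₄/m₂²` (normal → 3) and
`m₃/m₂^1.5`; excess kurtosis is a flag away. The SHG "signal" threshold is
not standardized anywhere; the maximum-entropy threshold is reused by
default and is an explicit parameter. Nuclei are counted as
Otsu-thresholded components ≥ `min_area_px`, with an optional
distance-transform watershed to split touching nuclei.

## Statistics

Grubbs' test is two-sided (statistic `G = max|x−x̄|/s`) with critical
value `G_c = ((n−1)/√n)·√(t²/(n−2+t²))`, `t` the upper `α/(2n)` quantile
of Student's t with n−2 df, applied iteratively with a safety cap of
⌊n/5⌋ removals per sample to prevent runaway exclusion in small groups;
zero-variance samples exclude nothing and warn. Two numerical facts worth
knowing: (i) the one-at-a-time type-I exclusion rate on null normal
samples of n=10 is near-nominal (~5%, bounded in the acceptance run at
≤7%); (ii) in a total sample of five, a point exactly 6 inlier-SDs from
the inlier mean yields G = 1.702 < G_c(5) = 1.715 — the two-sided test
*cannot* flag it, a hard ceiling of the statistic (G ≤ (n−1)/√n = 1.789
at n=5), while the same outlier against five baseline values (n=6) gives
G = 1.92 > G_c(6) = 1.85 and is removed.

Šidák adjustment `p' = 1−(1−p)^k` is applied over the planned
comparisons (pairwise count for one-way ANOVA; factor-level count for
two-way curve comparisons). Slope comparisons default to a Student t test
on per-segment fitted slopes — matching the one-regression-per-vessel
design — with a pooled-ANCOVA interaction test available as an
alternative. Significance is declared at p < 0.05 throughout.

## Pipeline

Group labels never enter the per-animal computation stages; they join the
derived metrics only at the statistics step (blinding emulation). The
manifest records package/library versions, the seed, every parameter, and
each excluded datum with a reason string. All tabular output is RFC-4180
CSV written deterministically, so re-running a configuration reproduces
byte-identical files — this is asserted in the acceptance run.

The bundled demo study (`pipeline.simulate_demo`) simulates two groups
(control vs stiff) of 4 animals: wire slopes 0.010 vs 0.018 mN/mm/µm,
unloaded diameters 1000 vs 850 µm, β 4 vs 7, MRI pulse areas 1.0→1.25 vs
0.8→0.92 mm², PWV 3.5 vs 5.5 m/s, fiber amplitudes 12 vs 4 µm, with ~3–5%
inter-animal variation — effect sizes on the order of what distinguishes
a severely stiffened from a healthy murine arterial tree, large enough to
be detected at n=4.

## What the synthetic data does and does not show

The generators emulate the *formulas'* data-generating processes: an
ideal exponential incompressible-wall vessel, an exactly linear
diameter–tension ring, a piecewise-analytic area waveform, sinusoidal
fibers with stationary amplitude, two-hue stained sections, disk-shaped
nuclei. Passing tests therefore demonstrate correctness of the
implementations and their numerical conventions — not robustness to
everything real tissue does: non-exponential stress–strain tails, axial
coupling, wall compression, segmentation ambiguity at fiber crossings,
stain variability between batches, out-of-plane fibers in 2D sections, or
arrhythmic gating in MRI. Those require real data and are out of scope.

## Problem sizes

Default test/acceptance workloads are deliberately modest: 7-point
pressure series, 50-seed Monte-Carlo recoveries, 256² fiber images with
3 fibers, 10⁴ null samples for the Grubbs operating characteristic, 10⁶
samples for moment checks, and a 2×3–4 animal demo study. These sizes
give Monte-Carlo errors comfortably inside the asserted tolerances while
keeping a full verification run in the tens of seconds.

## Known limitations

- `d₁₀₀` from a linear fit is range-sensitive (see above); callers should
  fit over loads bracketing the target isobar.
- The rectilinearity toolbox is 2D; serial-section tracking and 3D
  skeletons are out of scope.
- Media/adventitia masks are inputs; no automatic layer segmentation.
- No stain deconvolution or cross-scanner color normalization.
- The intersecting-tangent foot detector is a convenience, not a
  validated replacement for manual foot placement.
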