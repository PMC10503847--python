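# Methods

## Thin-wall biaxial mechanics

The mechanics module treats the artery as an incompressible thin-walled
cylinder. Three assumptions matter:

1. **Membrane equilibrium.** Stresses are wall-averaged; no transmural
   stress gradient or residual-stress (opening angle) analysis is attempted.
   This matches how pressure-myograph data are conventionally reduced and is
   adequate for h/r ≈ 0.1–0.25 vessels.
2. **Incompressibility.** Wall volume is conserved, giving the deformed
   inner diameter d_i = sqrt(d_o² − (D_o² − D_i²)/λz) and the closure
   λθ·λz·λr = 1. Every computed state is checked against this identity
   (cross-section area × λz conserved to better than 1e-6 relative).
3. **Passive response.** Smooth-muscle tone is out of scope; the quantities
   computed describe the passive wall.

Units are fixed: pressures are carried in mmHg and converted to kPa
(1 mmHg = 0.133322 kPa) only inside stress evaluations; lengths are µm,
forces mN, stresses kPa, moduli MPa.

**Circumferential stretch** uses the mid-wall convention
λθ = (d_i + d_o)/(D_i + D_o); the inner-wall alternative is available via
`convention="inner"`. Mid-wall is the default because the wall-averaged
stresses are mid-wall quantities.

**In vivo stretch.** For each sweep the slope of axial force vs pressure is
estimated by ordinary least squares; the in vivo stretch is the zero crossing
of slope vs λz — linear interpolation between the bracketing sweeps for the
standard three-sweep protocol, a quadratic fit when four or more sweeps are
available. If no sign change exists, the λz with the smallest |slope| is
returned with `no_sign_change` set, so degenerate protocols are visible
rather than silently wrong.

**Tangent modulus.** dσθ/dλθ from a local least-squares line over a 5-point
window centred on the sample nearest the reference pressure (window
truncated at curve ends, width configurable). A local line was chosen over
spline differentiation because myograph sweeps have ~13 points and the
modulus is only requested at one operating point.

## Fiber tracing and straightness

Each collagen frame is band-pass filtered (difference of Gaussians,
`low_sigma=1`, `high_sigma=8` px, normalised to unit gain at the passband
centre so in-band fiber structure is preserved), segmented by Otsu's
threshold (fixed-threshold override available), and skeletonised by the
medial axis — the ridge of the Euclidean distance transform, with a seeded
tie-break so tracing is fully deterministic. The centerline network is split
at junction pixels, short dangling spurs (< 12 px with one free end) are
pruned, and fragments are re-linked across junctions when their end tangents
continue one another (bend < 50°, end-gap ≤ 3–3.5 px, tangents estimated
over 4 px to tolerate the curvature of wavy fibers). Paths shorter than 30 px
are discarded; each ridge pixel belongs to at most one fiber. Pixel chains
are smoothed by a 7-px moving average (ends reflected, so chord length is
preserved) before arc length is accumulated — this removes the 8-connected
digitisation bias that otherwise inflates arc length by several percent.

Straightness is P_s = chord/arc, clamped to (0, 1]. Per-slice histograms use
20 uniform bins on (0.5, 1.0] by default (the visually informative range);
values below 0.5 are counted in the lowest bin so counts always sum to the
number of fibers. The per-stack scalar is the mean of per-slice medians,
with empty slices flagged and excluded. Note this statistic weights slices
equally regardless of fiber count; with very unequal per-slice counts a
pooled median would differ.

## Orientation analysis

Orientation distributions come from the 2-D power spectrum: radially
symmetric Hann window (suppresses edge leakage), mean subtraction, FFT,
exclusion of the DC component and a 3-pixel low-frequency disk (removes
illumination gradients), then binning of each frequency component's power by
the orientation of the structure that produced it — the spectral angle
rotated by 90°, the classic transpose/sign pitfall, pinned by unit tests on
rendered gratings. Default 90 bins of 2° on (−90°, 90°], 0° = axial.

Q_C/Q_A splits the distribution at ±45° (configurable; the CLI reports a
30°/45°/60° sensitivity), with straddling bins contributing proportionally.
The adventitia–media interface is the first depth at which Q_C/Q_A > 1 for
3 consecutive frames; persistence 3 is a heuristic standing in for the
visual identification used with real stacks, and its failure mode (no
detection in shallow or purely axial stacks) returns "absent" rather than a
depth.

## Synthetic data

`synth` provides the ground truth the tests are built on.

**Vessel sweeps.** A neo-Hookean matrix plus two symmetric exponential
fiber families at ±α from the axial direction:

    W = c/2 (I1 − 3) + c1/(2 c2) [exp(c2 (I4 − 1)²) − 1],
    I4 = λθ² sin²α + λz² cos²α  (fibers resist extension only).

For each pressure the deformed diameter solves the membrane equilibrium
σθ(λθ, λz) = P·r_i/h by bracketed root finding (σr = 0 plane stress, so
σi = λi ∂W/∂λi on the reduced energy); the axial force is then read off the
σz relation. Defaults — D_i = 800 µm, D_o = 1000 µm, c = 25 kPa,
c1 = 15 kPa, c2 = 1.5, α = 60° — give a rat-carotid-like response: a
force-invariant stretch of ≈ 1.67, wall stresses of ≈ 130–160 kPa and a
tangent modulus of ≈ 1.1 MPa at 100 mmHg, with convex pressure stiffening.
They are fixture choices on the right physiological scale, not fits to any
animal. Observation noise is multiplicative Gaussian on diameter and force
observables only, so many noisy realisations can be drawn from one
equilibrium solve. The default pressure grid is 0.5, 10, 20, …, 120 mmHg —
the stepwise inflation protocol, with the unloaded point at 0.5 mmHg because
membrane equilibrium at exactly zero pressure is degenerate for strongly
stretched fiber models.

**Fiber images.** Fibers are sinusoids y = a·sin(2πt/w) rendered as
Gaussian-profile polylines at orientations drawn from a von Mises mixture on
the doubled angle (axial data have period 180°). Whole fibers are kept
inside the canvas — the placement margin accounts for each fiber's own
orientation — so the analytic straightness P_s* (chord over quadrature arc
length, computed once per amplitude/wavelength) applies exactly to every
rendered fiber. Depth stacks switch the mixture mean from 0° to 90° at a
programmed frame to emulate the adventitia→media orientation flip.

**What the generators do not emulate:** fiber bundling and diameter
variation, depth-dependent attenuation and scattering blur, speckle,
partial-volume effects between frames, curved or branching fibers, and any
coupling between load and image (each stack is rendered at one nominal
state). Passing tests therefore demonstrate that the estimators recover
known structure from idealised images with additive noise and realistic
crossing density — not that they match CT-FIRE or Directionality outputs on
real tissue.

## Numerical choices and degenerate inputs

- Equilibrium roots: Brent's method with xtol 1e-10 after an explicit
  bracket check; an unbracketable root raises a model-stiffness error naming
  the pressure step.
- Force-invariant stretch: 13-point scan of slope(λz) over [1.3, 2.2], then
  bisection to |slope| < 1e-6 mN/mmHg.
- Inadmissible load points (negative radicand in d_i) raise with the
  offending values; d_i = 0 is flagged degenerate but processed.
- Constant images yield a uniform orientation distribution with a
  `no_structure` flag instead of an error; empty foregrounds yield zero
  fibers, not an error.
- All RNG flows through `numpy.random.default_rng` with explicit seeds;
  repeated runs of the manifest pipeline are byte-identical.

## Group statistics

One-way ANOVA (scipy) across groups with Bonferroni-adjusted pairwise
t-tests, p_adj = min(1, p·n_pairs), significance at p < 0.05. Summary tables
report mean ± SEM for mechanical metrics and mean ± SD for imaging metrics,
following the field's reporting convention. Samples are treated as
independent; left/right vessels from one animal are not modelled as paired.

## Test sizing

The suite's image fixtures are 256×256 (single-frame oracles) and 128×128
(stack-level checks: 40-frame interface detection across 10 seeds, 6-frame
pipeline runs); sweeps use the 13-step grid throughout. These sizes keep the
full suite under a minute while leaving every protocol parameter (flip
depth, persistence, noise levels, seed counts) at its stated value.

## Known limitations

- The tangent modulus is sensitive to the window width on strongly convex
  curves; the 5-point default trades noise against curvature bias.
- Junction linking can occasionally join two different fibers that cross at
  a very shallow angle; with realistic crossing densities the per-image
  median P_s stays within ~0.02 of truth, but per-fiber identities are not
  guaranteed.
- The FFT orientation method measures a power-weighted angular density, not
  a per-fiber count; thick or bright fibers contribute more mass.
- Interface detection assumes the medial side becomes circumferential-
  dominant within the imaged depth; vessels imaged only through the
  adventitia correctly report no interface.
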