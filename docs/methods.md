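# Methods

This note documents the models, conventions and numerical choices behind
`nanospt`, and what its synthetic-data validation does and does not
establish.

## Coordinate and calibration conventions

All positions are in micrometres with the pixel-centre convention: integer
pixel `i` spans `[i, i+1)` in pixel units, so its centre is at
`(i + 0.5) * pixel_size` µm. Every module shares this convention, so
detections, tracks, ground truth and line profiles are directly comparable.
Time is in seconds; a movie's `frame_interval` is the reciprocal of the
acquisition frame rate (20, 5 or 2.5 fps are the usual settings for this
kind of imaging; 20 fps = 50 ms/frame is the default).

The default pixel size is 0.1 µm/px (a 160× objective on a 16 µm-pixel
EMCCD); it is a configurable parameter everywhere, never a constant.

## Simulation model

**Motion.** Per-axis increments of a Brownian particle are i.i.d.
N(0, 2·D·Δt); the 2-D ensemble MSD is 4·D·t. Confined motion uses the same
increments reflected specularly at the walls of a square of side L centred
on the start position. This choice (rather than a harmonic potential) gives
a closed-form long-lag plateau for testing: the stationary position is
uniform on the square, the variance of a difference of two independent
uniforms is L²/6 per axis, so the time-averaged MSD converges to **L²/3**.
Static particles never move. Blinking is an independent per-frame Bernoulli
draw with probability `on_fraction`.

**Rendering.** Each emitting particle deposits an expected
`photons_per_particle` photons per frame as a 2-D Gaussian of width
`psf_sigma` integrated over pixel areas (difference of error functions per
axis, evaluated on a ±5σ window). Pixel values are Poisson draws around
background + signal. The PSF default is σ = 0.17 µm, i.e. a 0.4 µm
full-width-at-half-maximum spot (FWHM = 2.355 σ), matching the particle
size the detection stage is tuned for. Rendering with `psf_sigma` below
0.25 px is rejected as unresolvable. `noise=False` returns the expected
photon image — the high-photon limit used by localization oracles.

**Randomness.** One root seed per run; every particle consumes an
independent sub-stream keyed by its index (`SeedSequence(seed,
spawn_key=(i,))`), and rendering noise uses a reserved key. Consequently
adding or removing a particle never perturbs the trajectories of the
others, and identical config + seed reproduces bit-identical stacks.

**Defaults the imaging literature does not pin.** Background 100
photons/px/frame and 5000 photons/particle/frame give a peak-pixel SNR of
roughly 14 — a bright, well-behaved single-fluorophore movie.
The scenario presets describe one imaged cell on a 12.8 × 12.8 µm field:

- `static_clustered` — 360 particles in 60 immobile foci (6 per focus,
  Gaussian scatter σ = 0.06 µm). 0.37 foci/µm² is the conservative end of
  published plasma-membrane nanodomain densities (~0.5–2 µm⁻²); below
  roughly 0.2 µm⁻² a random 8 µm line profile usually misses all structure
  and the clustering index measures line-placement luck instead of
  organization.
- `mobile_dispersed` — 150 particles (0.9 µm⁻²) diffusing at
  D = 0.05 µm²/s, the upper range reported for plant plasma-membrane
  receptors. The density is deliberately sparse enough that 0.4 µm-gated
  linking is unambiguous — consistent with the experimental observation
  that dense, fast populations defeat single-particle tracking.
- `confined_dispersed` — as mobile, but inside reflecting 0.4 µm squares.

## Detection

The LoG response is the scale-normalized, sign-inverted
Laplacian-of-Gaussian, `-σ² ∇²(G_σ * I)`, at σ = diameter/(2√2) — the scale
maximizing the response of a disc of that diameter. Candidate spots are
local maxima above `quality_threshold` after non-maximum suppression within
one spot radius (exact response ties, which arise only in noiseless
symmetric images, keep the lexicographically first candidate). Each
candidate is refined by fitting a 2-D quadratic to the 3×3 response
neighbourhood (finite-difference gradient and Hessian, Newton step); a
refinement displacing more than 1 px falls back to the integer maximum.
This deterministic scheme localizes noiseless emitters to ~0.01 px and
high-SNR noisy emitters to better than 0.1 px RMSE.

The quality threshold is an explicit analyst input, as it is in interactive
tracking software; `auto_quality_threshold` (Otsu split of the pooled
per-frame response maxima) is provided as a labelled heuristic for
exploration only. Detection runs on raw frames; background subtraction is
display preprocessing (see below).

## Linking

For each consecutive frame pair the rectangular assignment problem is
solved exactly (`scipy.optimize.linear_sum_assignment`) on the augmented
block matrix: real→real links cost squared distance (infeasible beyond the
gate), and every spot has a dummy "no-link" alternative costing gate².
Minimizing total cost therefore trades link quality against track birth and
death exactly as the classical frame-to-frame linear-assignment-problem
formulation of particle tracking prescribes. There is no gap closing and no
merge/split handling. Spots are canonicalized by (frame, x, y) before
assignment, so the result is independent of input row order. The solver is
deterministic; among exactly-equal-cost optima it does not guarantee a
lexicographic preference (a measure-zero event on real data).

The track **duration convention counts points, not intervals**:
`duration = n_points × Δt`, pinned by the convention that a 10-point track
at 20 fps was followed for 500 ms. The default minimum track length is 10
points.

## Mobility

`compute_msd` defaults to the time-averaged estimator over all overlapping
pairs — the standard, low-variance choice. The origin-referenced form
`(x_k − x_0)² + (y_k − y_0)²` (one pair per lag) is available via
`method="origin"` because per-particle displacement-from-start summaries
are sometimes written that way; the two agree in expectation for stationary
increments but differ sharply in variance, and the time-averaged form is
the default.

`fit_diffusion` regresses MSD on lag time over the first four points with a
**free intercept** and reports D = slope/4. The free intercept absorbs
static localization error (which offsets the MSD curve by ≈ 4σ_loc² without
changing its slope), so 20 nm of localization noise shifts the intercept,
not the estimate. Negative fitted slopes are reported as-is with a
`negative_D` flag; clamping them at zero would bias group medians upward.
The anomalous exponent α is the log–log slope over the same lags and is
NaN-flagged when any fitted MSD value is non-positive (e.g. perfectly
static tracks).

A note on sensitivity: whether confinement in an L = 0.4 µm domain is
visible in α depends on where the confinement time τ = L²/4D falls relative
to the 0.05–0.2 s fit window. At 20 fps, D = 0.1 µm²/s gives α ≈ 0.69
while D = 0.05 µm²/s gives α ≈ 0.81 (reflected-Brownian series solution,
confirmed by simulation); the confinement-signature tests therefore use
D = 0.1 µm²/s, and α should generally be read as a window-relative
descriptor, not an absolute motion class.

## Organization (nanodomain module)

Maximum projections are per-pixel maxima over the first n frames (20 by
default). Background subtraction estimates the background by grayscale
opening with a 30 px disc — the flat-element form of rolling-ball
subtraction — clips the residual at zero and applies a 3×3 mean smoothing
("smoothing" is otherwise unspecified; the 3×3 mean is the mildest standard
choice).

Line profiles are placed by rejection sampling: centre and orientation
uniform, accepted when the whole line lies inside the mask (or, without a
mask, inside a 10 px border margin); intensities are sampled at 1 px
spacing by bilinear interpolation, giving 81 samples for an 8 µm line at
0.1 µm/px. Three lines per cell is the default.

The spatial clustering index uses tails of k = max(1, round(0.05·n))
samples. **SCI is computed on the raw maximum projection**, not the
background-subtracted one: the index is a top/bottom intensity ratio, and
removing the background drives the denominator toward zero so that the
"index" degenerates into a measure of the local noise floor (simulated
dispersed cells then score as high as clustered ones). The background
offset in the denominator is what makes the ratio informative;
`subtract_for_sci=True` remains available and such measurements are
floored at one intensity quantum and flagged `floored` whenever the
bottom-tail mean falls below it. SCI is exactly invariant under positive
rescaling of the image whenever the floor is inactive, and the
`intensity_sci_correlation` audit (Spearman ρ between per-line mean
intensity and SCI) makes that insensitivity checkable on any results table.

Kymographs stack the bilinear line profile of every frame into a
position × time image; stable particles appear as vertical stripes, motion
as sloped stripes (slope v·Δt/pixel_size px/frame).

## Statistics

Two groups: two-tailed Mann–Whitney U — exact null distribution when the
pooled sample has ≤ 20 observations and no ties, otherwise the normal
approximation with tie and continuity corrections. Three or more groups:
tie-corrected Kruskal–Wallis with the chi-square approximation, then Dunn's
pairwise z on pooled mean ranks with the tie-corrected variance,
Bonferroni-adjusted over all pairs (the behaviour of mainstream commercial
statistics software; Šidák is available). The compact letter display uses
insert-and-absorb with deterministic group ordering. Both tests are
invariant under strictly monotone transforms of the data, and their type-I
error at α = 0.05 is verified by null simulation at n = 25–30 per group —
the scale of per-condition cell counts this workflow produces; note the
chi-square omnibus is mildly conservative at smaller n (measured size
0.045 at n = 15/group).

## What a green test establishes — and what it does not

The simulator emulates: diffraction-limited spots of a single size,
spatially uniform background, Poisson shot noise, uncorrelated blinking,
and motion that is exactly Brownian/confined/static. It does **not**
emulate photobleaching kinetics, EMCCD excess noise or read noise, uneven
illumination or cell-edge geometry, focal drift, heterogeneous spot sizes,
or motion switching within one trajectory. Parameter-recovery results
(median D within 10–20%, detection recall/precision ≥ 0.99, the
clustered-vs-mobile contrast) are therefore statements about the analysis
chain under its stated assumptions, not about any biological system; the
end-to-end scenario contrast reproduces the expected *direction* of
organization differences on simulation ground truth only.

## Degenerate inputs and tie-breaking (summary)

- Empty frames: no detections, tracks simply terminate (no error).
- All-static track: MSD ≡ 0, D = 0, α undefined (flagged).
- Bottom-tail mean below one quantum: SCI floored and flagged.
- Constant profiles or constant SCI: correlation reported as undefined,
  ρ = 0 with `defined=False`, never NaN.
- Exact LoG response ties: lexicographically first maximum kept.
- Equal-cost optimal assignments: deterministic (solver-defined) choice.
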