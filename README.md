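# nanospt

Single-particle tracking and membrane-nanodomain quantification for
VA-TIRFM (variable-angle total internal reflection fluorescence microscopy)
image time series — with a ground-truthed synthetic movie generator for
validating every stage.

## The problem

Plasma-membrane receptors are not uniformly mixed in the membrane: some sit
in laterally stable, sub-micron foci (nanodomains), others diffuse freely.
Evanescent-field microscopy of single fluorescent proteins makes this
directly observable, but turning movies into numbers requires a chain of
image-analysis steps, each with conventions that change the answer. This
package implements that chain as a tested, reusable library for cell
biologists quantifying receptor dynamics:

1. **Detection** — per-frame Laplacian-of-Gaussian (LoG) filtering at the
   blob-optimal scale for a 0.4 µm particle, local maxima refined to
   sub-pixel positions by a 3×3 quadratic fit of the filter response.
2. **Linking** — frame-to-frame linear assignment (squared-distance cost,
   exact Jonker–Volgenant solution) with a hard 0.4 µm gate and no gap
   closing; tracks shorter than 10 consecutive points are discarded.
3. **Mobility** — per-track time-averaged mean square displacement
   MSD(k·Δt) = ⟨(x(t+kΔt) − x(t))² + (y(t+kΔt) − y(t))²⟩; the diffusion
   coefficient is D = slope/4 of an ordinary least-squares line through the
   first four MSD points (free intercept, which absorbs localization error),
   plus the log–log slope α as a confinement descriptor (α ≈ 1 free,
   α < 1 confined).
4. **Organization** — maximum projections, rolling-background subtraction
   (30 px radius), randomized 8 µm line profiles (3 per cell), and the
   spatial clustering index SCI = mean(top 5% of samples) / mean(bottom 5%),
   a scale-invariant measure of lateral heterogeneity, with a built-in
   intensity–SCI correlation audit; kymographs for visual inspection.
5. **Statistics** — two-tailed Mann–Whitney U for two groups; tie-corrected
   Kruskal–Wallis with Dunn's Bonferroni-adjusted pairwise z-tests and a
   compact letter display for three or more.
6. **Simulation** — Brownian, confined (reflecting square domain) and static
   particle regimes, rendered as integrated Gaussian PSFs with Poisson shot
   noise; ground-truth trajectories let every stage above be validated by
   parameter recovery rather than by eye.

## Worked example

Simulate two contrasting populations of eight cells each — receptors held in
static clustered foci versus freely diffusing dispersed receptors — then run
the full pipeline and compare the groups:

```bash
nanospt all --outdir run1 --seed 1 --n-cells 8 --quality-threshold 50
```

or equivalently in Python:

```python
from nanospt import PipelineConfig, run_pipeline
run_pipeline(PipelineConfig(outdir="run1", seed=1, n_cells=8,
                            quality_threshold=50.0))
```

`run1/per_cell_summary.csv` then holds one row per cell and
`run1/stats.csv` the group comparison. With seed 1 the group medians are:

```
                      median_D  median_sci
group
mobile_dispersed  4.975959e-02    4.823190
static_clustered -3.834615e-07   11.969519

        test                               groups     metric  statistic        p
mann_whitney mobile_dispersed vs static_clustered   median_D       64.0 0.000155
mann_whitney mobile_dispersed vs static_clustered median_sci        0.0 0.000155
```

Read: mobile cells recover the simulated diffusion coefficient
(0.0498 vs the true 0.05 µm²/s), static cells sit at zero mobility
(−4·10⁻⁷ µm²/s — tiny negative fitted slopes are reported, not clamped), and
the clustered cells score a ~2.5× higher spatial clustering index
(12.0 vs 4.8); both contrasts are significant by the two-tailed
Mann–Whitney test (p ≈ 1.6·10⁻⁴ at n = 8 cells per group).

Each cell directory additionally contains the rendered movie
(`movie.tif`), the simulator's ground truth (`ground_truth.csv`), and the
per-stage tables (`spots.csv`, `tracks.csv`, `diffusion.csv`, `sci.csv`)
plus a kymograph image. Real movies enter the same pipeline through
`PipelineConfig(input_movies=(...,), pixel_size=..., fps=...)` or via the
per-stage CLI subcommands (`nanospt detect --help`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete simulate → detect → track → mobility → SCI → statistics
chain from scratch on seeded synthetic cells, prints the recovered group
medians and test results, and writes the results JSON.
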