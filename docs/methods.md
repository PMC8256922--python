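# Methods

This note records how each statistic in `ire1quant` is defined, the
defaults and why, what the synthetic data do and do not emulate, and the
numerical choices a maintainer should know about.

## Cell identification

Cells are detected on a single designated *detection image* — by default
the sum projection of the z-stack, which integrates the diffuse cellular
autofluorescence and gives the most stable cell outline. The image is
median-filtered with a disk footprint (default radius 2 px; borders by
edge replication) and thresholded globally by minimum cross-entropy.

**Li threshold.** For a candidate level *t*, pixels are split into
background (≤ *t*, total intensity S_b, count N_b) and foreground
(> *t*, S_f, N_f), and the (constant-shifted) Li–Lee cross-entropy

    η(t) = −S_b·log(S_b/N_b) − S_f·log(S_f/N_f)

is minimised **exactly** over every distinct grey level except the
maximum, using cumulative sums over the level histogram. We deliberately
do not use an iterative fixed-point scheme: the discrete minimiser is the
contract, and it is cheap (O(L log L) in the number of levels). Images
with fewer than two distinct values raise `DegenerateImageError`. Classes
with zero total intensity contribute 0 (the x·log x → 0 limit).

Foreground components (8-connectivity, holes filled) become candidate
cells. Features — area, equivalent circular diameter
d = 2·√(area/π), mean/max intensity — are measured on the **unsmoothed**
detection image; smoothing exists only to stabilise the threshold.

**Gates.** Candidates outside 1.9–6.3 µm equivalent diameter are flagged
`too_small`/`too_large`. The viability rule then computes M, the mean of
per-cell mean intensities over *all* diameter-passing candidates, in one
pass (bright cells included, no recomputation after exclusions), and
flags any cell with mean intensity > (1+ε)·M as `too_bright`, with
ε = 0.30 in standard mode and ε = 0.10 in stringent mode. "Average" here
means the mean of per-cell means, the symmetric reading for both modes.
Touching cells are not declumped; the simulator guarantees non-overlap,
and this is a known limitation on crowded real fields.

## Cluster calling

Clusters are detected on the **raw maximum projection** (no smoothing).

*Standard mode.* One global threshold per field,
T = 1.5 × (pixel-pooled mean intensity of all kept-cell pixels on the
max projection). The pooled-global reading (rather than per-cell) matches
the use of a single threshold per image; a per-cell variant is available
via `ClusterParams(per_cell_threshold=True)`. Components above T
(8-connected) are assigned to the cell containing their centroid,
clipped to that cell's mask, measured, and counted if their equivalent
diameter lies in 0.3–0.9 µm. A kept cell is cluster-positive iff it owns
≥ 1 counted focus.

*Stringent mode.* Candidates are gated to 0.3–1.2 µm. Per cell, the
coverage = (summed area of diameter-passing candidates)/(cell area) is
computed **before** any intensity gate; if coverage > 3.5% the cell is
*unfit*: zero counted clusters, called cluster-free, but it remains in
the denominator of the positive fraction. Otherwise a candidate is
counted iff its maximum intensity ≥ 2.5 × the mean intensity of its own
cell, where both numbers live on the max projection and the cell mean
includes the candidate pixels themselves (the plain reading of "mean
intensity of the respective cell"). Stringent mode pairs with the 10%
brightness exclusion at segmentation time.

The positive fraction of a field is (#positive)/(#kept cells), unfit
cells included in the denominator.

## Per-field statistics

Fields of view are the unit of replication. `summarize` reports the mean
and SEM (sd/√n, ddof = 1; a single field reports SEM 0) of per-field
fractions and pools cluster areas and integrated intensities across
fields. Conditions are compared with the classical pooled-variance
unpaired two-tailed t test on per-field fractions and with the
two-sample Kolmogorov–Smirnov test (asymptotic p) on pooled cluster
morphometrics. Integrated intensities are raw pixel sums in arbitrary
units; no normalisation is applied. The helical-wheel helper places
residue k at (k·100°) mod 360°, the standard α-helix periodicity of 3.6
residues per turn.

## Synthetic imaging model

The generator renders what the pipeline assumes, not optics:

- **Field**: 400×400 px at 0.13 µm/px (a 52-µm field at 63×/1.4 NA
  scale), 9 planes at 0.45 µm — the acquisition geometry of the imaging
  this pipeline targets. Bit depth is 16-bit unsigned.
- **Cells**: 30 per field by default, non-overlapping ellipses (axis
  ratio 0.8–1.0; budding-yeast cross-sections are near-circular and only
  area/diameter matter downstream), equivalent diameters uniform in
  2.5–5.5 µm — comfortably inside the 1.9–6.3 µm gate so that size
  gating is not the limiting step in recovery experiments. Placement is
  rejection sampling with a hard cap of 1000 attempts per cell
  (`PlacementError` beats silent overlap); a coarse capacity check
  rejects configurations that cannot fit.
- **Autofluorescence**: constant across planes within a cell, drawn per
  cell from N(100, 5) arbitrary units over a background of 20. The 5%
  cell-to-cell CV reflects a tightly controlled field; it also makes the
  brightness gate's behaviour analysable: with 10% dead cells at 2×
  brightness, the 30% rule's cutoff sits many dead-cell SDs below the
  dead mean for any plausible realised dead count.
- **Dead cells**: fraction 0.1, brightness ×2, never cluster-positive.
- **Clusters**: 60% of live cells positive by default; positive cells
  draw Poisson(1.5) spots (minimum 1). A spot of truth diameter d is a
  2-D Gaussian with σ = √((d/4)² + σ_PSF²), σ_PSF = 0.12 µm, amplitude
  4× the parent cell's autofluorescence, modulated over planes by a
  Gaussian z-envelope (σ ≈ 300 nm) peaking at 1 on a random in-focus
  plane — so the max projection recovers the full amplitude. Exact PSF
  shape is irrelevant to the gates under test.
- **Noise**: Poisson shot noise on the expected image plus Gaussian read
  noise (sd 2), then rounding to uint16. The noiseless intermediate is
  returned alongside for intensity assertions.

All randomness flows from one `numpy` `default_rng(seed)`; identical
(config, seed) pairs are bit-identical. Dataset seeds are base_seed + i.

What the simulator does **not** emulate — and what passing tests
therefore do not certify on real data: touching/budding cells (no
declumping exists), uneven illumination, spectral bleed-through,
out-of-focus haze, drift (the generator has none; `register_xy` is
opt-in and integer-valued, sufficient because all gates are
area/intensity based), and realistic PSF side lobes.

On these defaults the standard pipeline under-estimates the true
positive fraction by ~5 points (e.g. 0.545 measured vs 0.60 configured,
20 fields): occasional twin spots merge into a single component above
the 0.9 µm gate, and spots clipped at the cell border can fall below the
0.3 µm gate. This is a faithful property of the diameter-gated counting
rule, not a bug; the stringent mode is more conservative still, because
its 3.5% coverage rule declares small multi-spotted cells unfit.

## Gel densitometry

A lane rectangle collapses to a per-row sum; polarity is auto-detected
(profiles whose mean exceeds their midrange are inverted so bands are
peaks). The baseline is the rolling minimum (default window 25 px) of a
lightly box-smoothed copy of the profile (width 5 px): smoothing enters
only the baseline estimate and damps the downward bias a raw minimum
picks up from noise troughs; the subtraction itself acts on the raw
profile, negatives clipped to 0. A constant offset is removed exactly;
a linear drift leaves ≤ slope×window per point. The window should
exceed the band width plus the smoothing width so each window sees
band-free rows. Band windows (monomer, dimer) are user-supplied — on a
real blot they are identified from molecular-weight position, which no
peak-finder can certify — and integrated as plain sums; the readout is
100·dimer/(monomer+dimer), a two-band model that excludes smears and
aggregates from both integrals. The synthetic gel generator places
Gaussian bands of known integral, uniform across the lane width, with
i.i.d. Gaussian pixel noise; band SNR = peak band amplitude / noise sd.

## Membrane thickness maps

Thickness is computed per frame and per x–y bin as (mean z of
upper-leaflet phosphates in the bin) − (mean z of lower-leaflet
phosphates in the bin); per-bin leaflet means rather than
nearest-neighbour pairing is the direct reading of "average vertical
distance between the two phosphate layers". Frames in which a bin lacks
either leaflet contribute nothing to that bin; the map reports the mean
over contributing frames and SEM = sd/√n (ddof = 1, SEM 0 at n = 1).
Bin edges come from the box, with periodic x–y wrapping applied before
binning; bins never populated by both leaflets are NaN with n = 0,
never silently zero. The per-frame-then-average convention is what
makes the SEM over frames well-defined.

The synthetic bilayer places particles on a jittered lattice with
leaflets at ±z0 (default 2.0 nm, i.e. 4.0 nm thickness), an optional
Gaussian dimple (depth d, width w) split half-and-half between leaflets,
and i.i.d. Gaussian z-noise. Note that a binned map attenuates a dimple
of width w by the bin-average of the Gaussian: recovery fixtures use
bins no wider than ~2/3·w and centre the dimple on a bin centre, so the
residual attenuation is a few percent; with bins of width ~w centred on
a dimple corner the apparent depth can drop by >10% — a discretisation
property of any binned thickness map, not an estimator error.

## Problem sizes

Defaults throughout are sized so a full analysis is interactive: one
simulated field renders in ~0.5 s and analyses in ~0.1 s; recovery
experiments use 20 fields (~600 cells), discrimination experiments 10
fields per condition, thickness statistics 100 frames of a 36×36
lattice. These sizes give binomial/sampling errors well inside the
tolerances asserted in the tests.
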