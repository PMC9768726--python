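# Methods

This note documents the models, parameter choices and numerical decisions
behind `dropphase`, and what the synthetic benchmark does and does not
demonstrate about real microscopy data.

## Forward model of a droplet experiment

**Compositions.** A flow programme is an ordered list of inlet
volume-fraction tuples (each summing to 1, total aqueous flow constant) plus
per-inlet stock concentrations.  Droplet *j* receives ramp step
*j* mod *L*, so the full ramp is traversed whenever *n* ≥ *L*; assignment is
deterministic and all randomness enters through pixel noise and label flips.
Component concentrations are `fraction · stock`, so every concentration is
bounded by its stock and mixtures are convex combinations of the inlet
stocks.  Inlets held at a fixed fraction model constant-flow-rate modulator
injection (e.g. a 1 mM small-molecule stock diluted 10-fold on chip to
100 µM in every droplet).

**Phase boundaries.** Ground-truth labels come from parametric boundaries in
concentration space:

* `linear` — separated iff `w·c + b > 0` (protein/crowder scans);
* `reentrant_band` — separated iff a designated coordinate lies strictly
  between two affine bounds of the other coordinates (protein–RNA
  coacervates that dissolve again at high RNA);
* `threshold_3d` — a planar drive term on two coordinates must exceed a
  suppression term proportional to the third (an aliphatic-diol-like
  modulator that monotonically disfavours separation).

A `flip_rate` inverts the noiseless label with that probability, modelling
classification/label noise; the empirical flip frequency is tested against
the binomial oracle at n = 10⁴.

**Rendering.** Droplets are flat discs: inside the circle the pre-noise
fluorophore-space intensity is `gain_f · conc_f + background` — a focal-slice
image, appropriate for low-NA widefield imaging of trapped droplets.
Separated droplets receive 1–5 condensate puncta (discs of radius 2–4 px at
2× the droplet's own signal, the first always at the maximum radius so at
least one punctum exceeds 3 connected pixels even after mask erosion),
placed uniformly inside the circle but clear of the rim.  The real
count/size distribution of condensates inside microdroplets is not
documented; this puncta model is a stand-in that guarantees the
classification rule is exercised, not a claim about real data.  Observed
channels are the crosstalk matrix applied pixelwise to the fluorophore
stack, plus additive per-pixel Gaussian noise (camera read noise proxy;
Poisson shot noise is deliberately omitted because the classifier uses
robust statistics and the distribution shape is secondary).  Layouts are
rejection-sampled to be non-overlapping unless an overlap fraction is
requested as QC test material.

## Detection

Segmentation thresholds the detection channel (default: channel sum) at the
image median plus 6 scaled MADs after σ = 1 px Gaussian smoothing.  A
bimodal (Otsu) split is available but not the default: droplet brightness
spans several-fold along the composition ramp, and Otsu can place the cut
*between* dim and bright droplets, losing the dim ones.  Because the robust
floor sits just above background, each component is then re-thresholded at
the midpoint between its interior median and the background — the 50% edge
crossing — which removes the brightness-dependent radius bias the global
floor would otherwise cause.

Each connected component becomes a circle via an algebraic (Kåsa)
least-squares fit to its sub-pixel contour.  This is deterministic, robust
to single-pixel mask noise, and for border-truncated components (contour
points on the image frame are excluded from the fit) it extrapolates the
underlying circle from the visible arc.  Circularity is 4πA/P² with the
Crofton perimeter, clamped at 1 to absorb digitisation bias on smooth discs.

QC flags: `non_circular` below `min_circularity` (default 0.85),
`overlapping` when a centre pair is closer than 1.05 × the radius sum,
`touching_edge` within 2 px of the border, `low_contrast` below 1.2 × the
background median.  A droplet is kept iff it has no flags; `qc_filter`
recomputes flags from stored metrics and is therefore idempotent.  On clean
simulated scenes (≥ 10× contrast, non-overlapping, radii in range) detection
recall is 100% with zero false positives — verified against the generator
manifest.

## Volume normalisation and calibration

Per-droplet totals are sums over the fitted circle, background-subtracted
using the per-channel median of pixels outside all detected circles (robust
to droplet density), then divided by droplet volume.  Two volume models are
provided:

* `sphere` — V = (π/6)·d³ from the fitted diameter (1 nL = 10⁶ µm³; a
  110.6 µm droplet is ≈ 0.7 nL, the typical trapped-droplet volume);
* `cylinder` (default for normalisation) — V = π·r²·h with h = 50 µm, the
  depth of the trap wells.

The cylinder default is deliberate: trapped droplets are squashed into
~50 µm wells and the renderer is a focal-slice model, so the total is
proportional to the projected area.  Normalising by π·r²·h makes
intensity-per-volume independent of droplet radius, which is what makes
calibration and sample droplets of different sizes directly comparable (two
droplets of equal concentration and radii r and 2r give equal
intensity-per-volume).  For truly spherical, depth-integrated imaging switch
to `sphere`.

Crosstalk removal is linear spectral unmixing: column *f* of K holds the
per-channel response slopes of fluorophore *f*'s single-fluorophore dilution
series, column-normalised to a unit diagonal; per-droplet channel vectors
are multiplied by K⁻¹.  Negative fitted off-diagonals are clipped to zero
(warning below −0.01).  Concentrations follow from per-fluorophore ordinary
least-squares affine maps `ipv = gain·conc + offset` fitted to the unmixed
series responses (a through-origin variant is available); negative unmixed
or converted values are floored at zero and flagged rather than discarded so
droplet counts are preserved for the phase diagram.  Because both sample and
calibration images pass through identical steps, concentration estimates are
invariant to any global gain applied to both.

## Classification

A droplet is phase separated iff its protein channel contains at least
3 connected pixels (8-connectivity by default; 4 available) strictly above a
threshold computed from the droplet's own pixels after eroding the fitted
circle by 2 px (bright-rim suppression).  The default threshold is
median + 6 · 1.4826 · MAD: the median and MAD are essentially untouched by
the few percent of pixels belonging to condensates, and both are
scale-equivariant, so the label is invariant under positive rescaling of the
image.  `mean_sd` and `fixed` rules are provided for sensitivity analysis.
Droplets with fewer than 25 usable pixels are excluded as unclassifiable
(logged).  Droplets whose protein-concentration estimate is zero are still
classified — they populate the dilute region of the diagram.

With 2× puncta and noise at SNR 20 (see benchmark conditions below) the
decision margin is comfortable: a punctum sits at twice the droplet signal
while the threshold sits ≈ 6 noise-sd above it, and the false-positive rate
per droplet (≥ 3 connected pixels each beyond 6 sd) is negligible.

## Phase diagrams

Points are standardised per dimension and fed to an RBF-kernel SVM (C = 1;
bandwidth from the median heuristic on pairwise squared distances of the
standardised points, subsampled at 500) wrapped in sigmoid (Platt)
calibration on 5 internal cross-validation folds.  All stochastic steps take
explicit seeds.  Probability grids default to the [1st, 99th] percentile box
of the data, 200 points per axis in 2-D and 50 in 3-D.  The phase boundary
is the p = 0.5 isocontour via marching squares (2-D) or marching cubes
(3-D).  Differential maps are elementwise P_B − P_A after resampling B onto
A's axes when they differ (disjoint ranges are an error).  3-D diagrams are
sliced by nearest plane, optionally with linear interpolation.

Diagram stability is quantified by refitting the SVM on with-replacement
bootstrap resamples (a single-class resample is redrawn, at most 10 times)
and reporting the mean over resample pairs of (i) the fraction of grid cells
whose p ≥ 0.5 classification differs — the primary "disagreement" number —
and (ii) the mean absolute probability difference.  Disagreement is the most
direct reading of "difference in diagram generation between sampling
repeats"; both numbers are reported.

## Benchmark conditions

The default synthetic experiment fixes, once: 10 µM protein and 10 %w/v
crowder stocks barcoded at gain 300 counts per concentration unit;
background 100 counts; a 12×12 volume-fraction grid with each varied inlet
spanning 8–45%; linear boundary `c_prot + 0.8·c_crowd > 5.2`; droplet radii
40–55 px (1 µm/px) in 1024×1024 fields of ~35 droplets; crosstalk
[[1, 0.08], [0.05, 1]]; puncta contrast 2×; pixel noise sd 24 counts.  SNR
is defined as the barcode signal of the dimmest truly separated droplet
(1.6 µM × 300 = 480 counts) over the pixel noise sd — 20 with these
defaults.  Calibration uses 5-point dilution series (1–10 units) per
fluorophore rendered with the same optics.

The classification benchmark renders ≥ 2000 droplets per seed with zero
label noise, runs the full pipeline with default parameters, matches kept
droplets to the manifest by centre position (10 px gate) and reports
(FP + FN)/N over classified droplets, averaged over five seeds.  The
stability benchmark draws 1500 composition/label points from the same
generator with 2% label flips and runs 20 bootstrap refits on a 200×200
grid.  These problem sizes mirror the operating scale of a real experiment
(a few thousand droplets per scan, diagrams built from ≥ 1500 droplets)
while remaining desk-computable.

## What passing these tests does and does not show

The simulator exercises the full algorithmic chain with known ground truth,
but idealises the physics: flat-disc droplets with hard edges, additive
Gaussian noise only (no shot noise, flat-field error or vignetting), linear
fluorophore response (no quenching or inner-filter effects), stationary
droplets (no shrinkage, coalescence or ripening) and a puncta model chosen
to be detectable by construction.  Zero measured classification error on
this benchmark therefore validates the implementation against its own
forward model — it bounds algorithmic error, not experimental error on real
images, where condensate SNR varies by system.  Likewise the < 5%
concentration-recovery checks validate the calibration algebra, not
photophysics.

## Known limitations

* Circularity of a digitised disc depends on the perimeter estimator;
  values are clamped at 1 and the 0.85 default gate is a declared choice,
  not a reconstruction of any particular instrument's setting.
* The crosstalk estimator assumes channel *i* is fluorophore *i*'s primary
  channel (ordered configuration) and a square channel×fluorophore system.
* Probability calibration beyond Platt scaling (e.g. isotonic) and SVM
  hyperparameter search are out of scope; defaults are fixed for
  reproducibility.
* Brightfield-only detection is supported only through a single grey
  channel or the channel sum; there is no time-lapse tracking.
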