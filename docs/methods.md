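# Methods

This note documents the models and procedures implemented in `spbkit`,
the parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Phosphoproteomics pipeline

### Data model

A phosphorylation *event* is a (protein, site position, residue,
multiplicity) tuple; different multiplicities of the same site are
distinct events throughout.  A single TMT 10-plex covers both strains
(SPB-tethered and control) at the same five timepoints, so "quantified in
all timepoints" means all ten channels.  Reporter intensities of zero are
treated as missing — a zero reporter ion is not quantifiable and would
poison every downstream ratio — and missing data are never imputed;
events are excluded instead.

### Filtering

Events are removed if flagged contaminant or reverse (decoy), if the
phospho-localization probability is below 0.7 (boundary inclusive — at
exactly 0.7 the event is kept), or if any design channel is unquantified.
Filtering is idempotent and order-preserving; the filter report counts
removals per rule (rules are applied jointly, so one event can count
toward several rules).

### Normalization cascade

Order is fixed: median → T0 → protein.

* **Median.** Every channel column is divided by its median over the
  events quantified in that channel.  Channels are the unit of mixing
  error (pipetting/labeling bias multiplies a whole channel), and the
  median is taken per table: the flow-through proteome is a separate
  quantification with its own mixing errors, so protein tables get their
  own medians rather than borrowing the site-table's.  Even-count
  medians are the mean of the two central order statistics.
* **T0.** Within each strain, every channel is divided row-wise by that
  strain's T0 channel.  Rows with missing or zero T0 are dropped and
  counted.
* **Protein.** Each site trajectory is divided by its protein's
  median- and T0-normalized trajectory.  Events whose protein is absent
  or incomplete in the proteome table are excluded and counted.

The testable content of the mixing-error correction is an exact
invariance: multiplying all intensities of any channel (site and protein
tables alike) by an arbitrary positive constant changes no normalized
value by more than floating round-off (assertions use 1e-12).

### Rescue statistic

Per event, R = (max over all timepoints of tethered P) / (max over all
timepoints of control P).  The maximum is taken over *all* timepoints
including T0, where P = 1 by construction.  Consequence: if an event's
normalized phosphorylation only declines (its rise is below the median
event's rise, so protein- and median-relative P falls below 1), the
control maximum saturates at P(T0) = 1 and R has a floor of
max(P_tethered); programmed effects on such events are recovered
compressed.  This is a property of the ratio as defined, not of the
implementation; the median over a rescued group is unaffected as long as
most members rise faster than the median event.

R ≥ 1.2 (inclusive) classifies an event as "increased"; percentages are
reported within each HP class over classified events.  Because a ratio
of maxima of noisy series is upward-biased, a noise-only population puts
mass above 1.2 (≈14 % at 10 % CV over five timepoints) — the threshold
separates classes by enrichment, not as a per-event significance test.

### Group comparison and summaries

`rank_sum_test` wraps the two-sided Mann–Whitney U (scipy): exact null
when n_A + n_B ≤ 12 with no ties, otherwise normal approximation with
tie and continuity corrections; with ties the exact path is undefined
and the normal path is used.  U is the count of (a, b) pairs with
a > b, so swapping groups maps U → n_A·n_B − U with identical p.  An
exhaustive-enumeration oracle in the test suite checks the exact path
case-by-case and the normal path to within 0.01 at n = 10 + 10.

Median trajectories carry percentile-bootstrap 95 % CIs (events
resampled with replacement, default 10 000 resamples, seeded).  The
percentile bootstrap was chosen because it is distribution-free and
matches a median summary; its coverage is verified at ≈95 % (±3 %) by
simulation.  Fig-style localization breakdowns report per-category R
lists and medians on the raw scale (the median is invariant under the
log transform, so log-scale medians would coincide).

### Synthetic TMT generator

`phospho_synth` emulates the two-strain washout experiment: per event a
scaled-logistic rising base curve (phosphorylation increases after CDK
reactivation; amplitude 0.5–4, midpoint 15–40 min, steepness 5–15 min,
value exactly 1 at T0) shared between strains; per-protein abundance
with log-normal scale and a shared-between-strains drift
(`protein_drift_sd`); per-channel mixing factors drawn from
[1/(1+r), 1+r]; multiplicative log-normal noise of CV `noise_cv` on both
tables; decoy and contaminant rows drawn from the same intensity
marginal (so only the flags can remove them); and a configurable
fraction of events with localization probability below 0.7.  Timepoints
default to 0/15/30/45/60 min as a documented stand-in.  Rescued events —
a subset of the HP-sensitive class — have their tethered post-T0 values
multiplied by `rescue_effect`.

Two deliberate bookkeeping choices:

* Rescued events are sampled from events lying strictly above the upper
  central order statistic of the surviving events in every tethered
  post-T0 channel.  Median normalization is only meaningful when the
  perturbed fraction does not straddle the median; sampling this way
  keeps each channel's median element literally unchanged by the rescue
  multiplication, so in the noise-free limit the pipeline recovers
  R = rescue_effect exactly for fast-rising events and exactly 1 for all
  unrescued events.  Low-localization events are drawn before and
  disjointly from the rescued set for the same reason.
* `n_events` counts genuine events; decoys and contaminants are
  additional rows, so post-filter survivors equal
  `n_events − round(loc_prob_below_frac · n_events)`.

What the generator does **not** emulate: PSM-level effects, isotope
impurity, partial missingness (only complete-channel presence/absence),
batch structure across plexes, or biologically heterogeneous effect
sizes (all rescued events share one multiplier).  Passing recovery tests
therefore demonstrates correctness of the pipeline's arithmetic and
statistics under its stated model, not robustness to those unmodeled
features of real data.

## Imaging pipeline

### Synthetic fields

Cells are 2-D spherocylinders (uniform random orientation, length 7–12
µm, width 3.5 µm) placed by rejection sampling with a minimum gap;
time-lapse cells neither move nor grow.  Channels: cyclin = per-cell
cytoplasmic fill (log-normal across cells) blurred by the PSF, plus an
optional focus at the SPB; SPB marker = one focus per cell, rendered per
frame with probability `spb_detectable_frac_frames` (emulating a marker
close to background); edge plane = bright interior with a darker rim
(boundary at 35 % of interior over a 0.2 µm band), emulating the
off-focus plane used for segmentation.  Foci are isotropic Gaussians
with FWHM equal to the 0.35 µm spot diameter; camera noise is additive
Gaussian.  Default pixel size 0.065 µm/px (typical 100×/1.45 NA sCMOS
sampling); recovery benchmarks run at 0.07 µm/px, which keeps the spot
at 5 px FWHM while halving pixel counts — a desk-scale choice, stated
here as the package's own.  Ground truth records masks, sub-pixel SPB
positions, per-frame focus presence, and the per-cell colocalization
verdict under a literal transcription of the scoring rules.

Not emulated: 3-D PSF structure, photobleaching, stage drift, cell
growth/division, autofluorescence texture.

### Segmentation

The ten-step sequence is listed in `segmentation_tracking`.  Open
choices and their resolutions:

* "Adaptive threshold" = local-mean threshold (`uniform_filter` window,
  additive offset); window default 121 px ≈ 2× cell width at 0.065 µm/px,
  offset 30 ≈ 6× camera noise so background stays clean.
* Watershed input = negated Euclidean distance transform with markers at
  the *h-maxima of the EDT* (reconstruction of EDT − h under EDT, then
  regional maxima, 8-connected).  The EDT ridge of a rod is a long
  plateau whose discretized height fluctuates by a pixel or two;
  point-wise maxima fragment it, while the h-transform (default
  `marker_h` = 2 px) merges fluctuations and keeps one marker per cell,
  yet still separates touching cells whose neck dips by more than h
  (tip-to-tip rods dip by roughly the half-width, ≈25 px).
* Erosion and dilation use equal-radius disks so dilation restores the
  original size; dilation is label-aware (`expand_labels`) and clipped
  to the pre-erosion foreground.
* The second watershed pass re-derives markers on the restored mask; a
  changed label count is logged and the second result kept.
* Hole filling after labeling assigns filled pixels to the nearest
  label.  Area/intensity artifact thresholds (defaults 500 px, mean
  intensity 100) are empirical by nature and calibrated once on the
  simulator's default geometry.

Recovery on simulated well-separated fields: exact cell counts and mean
IoU ≈ 0.98 (the rim excluded by thresholding costs a few boundary
pixels).

### Tracking

A deliberately simple greedy maximum-overlap linker stands in for
dedicated lineage-tracking tools: a label at t+1 joins the track of the
label at t with maximal overlap when that overlap covers ≥ 50 % of its
own area (a conservative identity criterion for slow-moving yeast),
otherwise it starts a new track.  Division and lineage handling are out
of scope.

### Spot detection

DoG with σ_center = (d/2)/√2 (the scale at which a 2-D LoG/DoG response
peaks for a blob of radius d/2) bracketed by √κ with κ = √2; optional
3×3 median prefilter (implemented as a median-of-9 sorting network for
speed); local 8-connected maxima at or above the quality threshold;
quality = DoG response at the maximum; per-axis quadratic sub-pixel
refinement clipped to ±0.5 px; non-maximum suppression at one spot
radius, strongest first.  Quality thresholds are per-experiment
configuration with no asserted default (benchmarks use 4.0 on flat
background at SNR 8, 5.9 on textured cytoplasm at SNR 10, both
calibrated once on the simulator).  Measured at SNR 8: precision and
recall 1.0, localization RMSE ≈ 0.2 px.

### Colocalization scoring

Two spots intersect iff their center distance is at most the sum of
their radii (inclusive; radii are the configured diameter/2 shared by
both channels).  Still mode: a cell is positive iff one of its cyclin
foci intersects one of its SPB foci.  Time-lapse mode adds the
two-of-three rule for frames where the SPB marker is undetectable: a
track is also positive if some window of three consecutive track frames
contains a cyclin focus in at least two frames and no SPB focus detected
in that cell in any of the three.  "No SPB focus" is evaluated per cell,
not per field; the intersection rule takes precedence in the reported
`rule_fired`; tracks shorter than three frames are scored by
intersection only (logged).  On simulated 20-cell × 30-frame lapses with
the SPB marker rendered in 60 % of frames, per-cell verdicts agree with
generator truth ≈ 97–98 %.

### Intensities

Whole-cell intensity is the mean of the channel over the mask, minus an
autofluorescence background estimated as the median of per-cell means of
a no-reporter control population; values are not clipped at zero.
Expression-matched subsetting keeps cells whose background-subtracted
mean lies in a closed interval.

## Orchestration and reproducibility

Every pipeline run writes a provenance record (package and library
versions, SHA-256 of the canonicalized config, seed, per-stage row
counts satisfying rows-in = rows-out + rows-removed).  All randomness
flows through `numpy.random.default_rng(seed)`; reruns under a fixed
config and seed are byte-identical, which the test suite asserts by
hashing output bundles.  Benchmark problem sizes (2 000-event TMT sets,
20-field segmentation runs, ten 20-cell × 30-frame lapses, 200 bootstrap
replicates) are desk-scale choices that keep the full suite and the
reproduction script in the minutes range.

## Known limitations

* The R-statistic floor behavior for slow-rising events (above) means
  per-event effect sizes below the population's median kinetics are
  compressed; conclusions should rest on group medians and enrichments.
* The rank-sum exact path refuses ties rather than enumerating a
  tie-adjusted null.
* Segmentation assumes bright-interior/dark-rim off-focus images; it is
  not a general-purpose cell segmenter, and strongly overlapping (not
  merely touching) cells will not be separated.
* The linker has no division model; daughter cells start new tracks.
* Still-image scoring requires the SPB focus to be detected; there is no
  two-of-three fallback in a single frame.
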