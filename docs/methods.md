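# Methods

This note documents the models implemented in `cytoplate`, the defaults
that matter, and the choices made where the design was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic plate generator

The generator (`cytoplate.simulate`) emulates the staining designs that the
pipeline analyses, with an exact per-cell ledger so recovery can be tested
cell by cell.

**Nuclei.** Each nucleus is an isotropic Gaussian spot with σ = radius/2,
truncated at 3σ. The discrete pixel sum of the rendered patch is normalised
to the cell's true integrated signal, so the ledger is exact by
construction (no truncation residual). Radii are log-normal around
`nucleus_radius_px` (default 8 px, CV 0.15).

**Placement.** Centers are rejection-sampled with two constraints: at least
2.2× the mean radius between any pair, and disjoint truncated footprints
(centers ≥ 1.5·(r_i + r_j) + 1 px apart). The second constraint is what
makes "the integrated intensity of cell k" well defined at the pixel level:
without it, close pairs exchange up to ~1.4 % of a G1 cell's Hoechst signal
through overlapping tails, and per-cell ledger recovery to 1 % would be
impossible for any segmenter. Placement failure beyond the retry cap raises
an error naming the achievable density. Clustered/overlapping growth is
deliberately not simulated (it is the known failure mode of automated
contouring, not something this generator needs to reproduce).

**DNA content.** Phase is multinomial over (G0/G1, S, G2/M) (default
0.55/0.25/0.20). Integrated Hoechst signal is `g1_dna_intensity` (default
20 000 a.u.) × content × a mean-1 log-normal factor with CV `dna_cv`
(default 0.05); content is 1 for G0/G1, 2 for G2/M, uniform on (1, 2) for
S — the familiar 2N/4N histogram with an S bridge.

**Markers.** Each marker channel is a two-component log-normal mixture:
arithmetic means 2 000 (negative) and 20 000 a.u. (positive), common
log-sd 0.4. At these defaults the populations are ~5.8 log-sd apart, so
gate placement, not mixture overlap, dominates the error budget — this is
intended: the pipeline's correctness is what is under test, not a
deconvolution problem.

**Viability.** Dead cells (Bernoulli `dead_fraction`) carry PI signal and
zero calcein; live cells the reverse; dead cells keep their Hoechst signal
so they count toward the total, matching how totals are counted with
nuclear staining.

**Image formation.** Channels are rendered noiseless, mixed by the optional
bleed-through matrix (row i, col j = fraction of channel i added to j; unit
diagonal), then constant background (default 100 a.u.) and additive
Gaussian read noise (default sd 2 a.u.) are applied and the image clipped
at zero. Noise is Gaussian only; shot noise is not modelled — the generator
targets recovery testing, not photorealism. Images are written as one
16-bit TIFF per well per channel.

**Dose plates.** Expected cells per well follow a 4PL inhibition curve of
concentration; the dead fraction follows a rising logistic with a baseline
(default 5 %) at concentration zero. Realised counts get multiplicative
Gaussian jitter (CV 0.10). Per-well seeds are `master_seed XOR
CRC32(well_id)`, so wells are reproducible independently of iteration
order.

**Scenario library.** Packaged parameterisations encode ground-truth
outcomes used as end-to-end smoke tests — e.g. a G2/M-arrest pair (66 %
treated vs 22 % untreated), a triple-marker multiplex well (90/80/60 %
positive for γH2AX/pATM/pATR), and an ATR-inhibitor-plus-platinum
combination with S-phase collapse. They validate that the pipeline recovers
its own generator truth, not any biology.

## Segmentation and quantification

The commercial counterpart is undisclosed, so the module is a standard,
fully surfaced design: Gaussian smoothing (σ = 2 px) → global threshold →
hole filling → optional watershed split (seeded at smoothed-intensity
maxima ≥ 9 px apart) → area filter (min 40 px²) → tail capture → relabel.

Two numerical choices deserve note:

* **Threshold domain.** Otsu's criterion is computed on
  arcsinh-compressed intensities referenced to the background median, and
  clamped to a robust background floor (median + 6 robust sd via the MAD).
  Linear-domain Otsu sits too high for dim, large nuclei (spot peak
  brightness varies ~4–5× across DNA content and radius) and loses them;
  the median referencing makes the threshold exactly invariant to adding a
  constant offset; the floor clamp keeps Otsu from splitting inside the
  noise band of empty or sparse wells.
* **Tail capture.** A threshold that finds cores necessarily cuts the dim
  outer tail of each nucleus, biasing integrated intensities low by
  several percent. Each core is therefore extended by an intensity-guided
  watershed over all pixels above the background floor: the full signal
  support is integrated, and contested pixels between neighbours split at
  the intensity saddle.

`apply_mask` subtracts a per-channel background estimate (default: median
of out-of-mask pixels; `fixed` and `none` modes are provided since it is
not knowable whether instrument-reported integrated intensities are
background-corrected) from every in-mask pixel. Corrected sums may be ≤ 0
and are retained, not clipped. Centroids are weighted by the corrected
Hoechst signal, which makes them insensitive to how generously the mask
captured the tail. Coordinates are 0-based, row-major, single-plane.

## Gating

Gates are 1D thresholds on integrated intensity at the empirical q-quantile
(default 0.99) of the pooled CT (secondary-antibody-only) cells — a
reproducible, monotone stand-in for gates drawn by hand on dot plots.
Positivity is strictly above threshold; ties are negative, so a degenerate
CT distribution gates 0 % of itself positive. Every downstream % positive
therefore carries a nominal false-positive floor of 1 − q (1 % at the
default), which also sets the default tolerance of the channel-overlap
check (1 − q plus 2 points). Fold change is the ratio of % positive
(intensity fold change is available separately); a zero denominator is
reported as inf with an explicit warning. Quadrant analysis assigns every
cell to exactly one of the 2^m joint combinations of m ≤ 3 gates, so the
fractions partition by construction. Replicate comparison is a two-sided
pooled-variance Student's t-test with significance at p < 0.01; two
zero-variance groups with equal means give p = 1.

## Cell-cycle analysis

The DNA histogram (256 bins up to 1.25× the 99.9th percentile, Gaussian
kernel smoothing of 2 bins — all ratios of data quantiles, hence exactly
scale-invariant) is searched for a mode pair with position ratio in
[1.6, 2.4]; the pair maximising combined height defines the G1 and G2
peaks. This pair rule, rather than "G1 = dominant mode", is what keeps a
G2/M-arrested population from being misread. With no usable pair, G2 falls
back to exactly 2×G1 and the fit is flagged; a peak ratio outside
[1.8, 2.2] is also flagged.

Windows are peak × (1 ± 0.15) by default (no widths are standardised
anywhere; 0.15 covers ±3 sd of staining CV 0.05). Per-cell assignment is a
pure window lookup — closed windows, below-G1 = sub-G1, between-windows =
S, above-G2 = >4N — mirroring visible box gates and staying deterministic.

**S-bridge correction.** Window counting alone over-counts both peaks: with
S uniform on (1, 2)×G1 and 0.15 half-width windows, 45 % of S-phase cells
fall inside the G1/G2 windows (15 % under G1, 30 % under G2), an expected
S under-count of ~13 points at 30 % S. The reported `fractions` therefore
estimate the S density from the inter-window region (where only S cells
live), extrapolate it over the full G1–G2 span, and subtract the implied S
share from each peak window; for uniform-bridge data the correction is
exact in expectation. Raw window counts remain as `window_fractions`. This
is a flat-S (rectangular) correction, not Dean–Jett–Fox/Watson mixture
deconvolution, which stays out of scope. Sub-G1 and >4N are reported and
can be excluded via `three_phase_fractions()`.

## Viability and dose-response

Dead cells are PI-gate positives. Two live-cell modes mirror bench
practice: `calcein_gate` (live = calcein+ and PI−; double-positive cells
count dead by PI dominance and are tallied for QC) and
`hoechst_subtraction` (live = total − dead, exact by construction), the
fallback when cytoplasmic calcein contouring is unreliable. The PI gate in
the orchestrated pipeline is an Otsu split of the pooled per-cell PI
intensities (negatives scatter around zero after background correction,
positives carry real stain; there is no CT analogue for viability stains).
Wells under 100 cells are flagged.

Growth % = 100 × total cells / untreated mean total. The 4PL is fitted on
log10 concentration with top ≤ 110, bottom ≥ −10, Hill slope in [0.1, 10];
concentration zero anchors the normalisation but is excluded from the
log-scale fit. The reported IC50 is the concentration where the *fitted
curve* crosses 50 % absolute growth (not the curve midpoint, which differs
under partial inhibition); a curve that never crosses 50 % within the
tested range is reported as "> cmax". Non-monotone mean growth beyond
3× the residual sd is flagged.

Mechanism classification bins % dead into: [0, 30) primarily cytostatic,
[30, 50) cytostatic ≥ cytotoxic, [50, 70) cytostatic ≤ cytotoxic, [70, 100]
mainly cytotoxic. The source convention leaves equality at the edges
undefined; lower bounds are closed here, so 30/50/70 fall into the higher
bin. The classification point is the tested concentration nearest the
fitted IC50 on the log scale (configurable to a fixed concentration; which
convention instruments use is not standardised, so both are exposed and
neither asserted). With an unresolved IC50 the highest tested concentration
is used.

## Orchestration

`run_pipeline` validates the layout before touching any image, then runs
segment → quantify → gate (per marker, CT-anchored) → marker stats and fold
changes → optional cell-cycle, quadrant and dose-response stages. The
summary JSON echoes every open parameter (gate quantile, window half-width,
histogram bins, segmentation settings), and report bodies contain no
timestamps, so reruns are byte-identical. The CLI subcommands are thin
wrappers over these functions.

## What the synthetic tests do and do not show

Passing recovery tests shows the chain of estimators is correct on data
matching the generator's assumptions: well-separated log-normal mixtures,
non-overlapping nuclei, uniform background, Gaussian noise, exact
uniform-bridge S phase. Real plates violate most of these to some degree —
clumped and overlapping nuclei, spatially varying background and
vignetting, shot noise, skewed S distributions, debris and partial wells —
so the recovery tolerances measured here are best-case floors, not
guarantees for instrument data. The problem sizes used by the test suite
and the acceptance script (wells of 80–2 000 cells, histogram fits at
2 000–5 000 cells, one triplicate 7-concentration plate) were chosen as the
smallest sizes at which the statistical tolerances are meaningful.

## Known limitations

* 1D quantile gates; no 2D region gating or spectral compensation beyond
  the linear overlap check.
* No foci counting, no cytoplasm rendering/contouring, no 3D cultures.
* The S-bridge correction assumes a roughly flat bridge; strongly skewed
  S distributions bias it.
* Gaussian read noise only; no shot noise or PSF modelling.
* Watershed seeding at fixed minimum peak distance can over-split very
  large nuclei if the defaults are left untouched at other magnifications.
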