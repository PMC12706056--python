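# Methods

`polasym` quantifies pole-resolved intracellular asymmetry in rod-shaped
bacteria from labeled segmentation masks and co-registered fluorescence
channels. This note records the models, the numerical choices behind each
estimator, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Coordinate and orientation conventions

Coordinates are 0-based `(row, col)` pixel indices; arc length is in
pixels; intervals are half-open. Each cell's medial axis is oriented
deterministically: pole 1 is the endpoint with the smaller `(row, col)`
in lexicographic order. This is a geometric convention only — biological
old/new pole identity is assigned exclusively by the lineage layer
(mother-machine trenches: the closed end, minimal row, holds the old
pole). In snapshot data pole identity is unknowable, so signed
pole-resolved metrics use a *seeded random orientation per cell, shared
across channels of that cell*, which makes cross-channel sign
comparisons meaningful while populations remain symmetric by
construction. Consumers comparing measured constriction or nucleoid
positions against known ground truth must fold positions across the
cell midpoint (`min(|p - t|, |1 - p - t|)`) because the geometric
orientation of a near-symmetric cell is decided by sub-pixel jitter.

## Medial axis

The centerline is a weighted polynomial fit rather than a skeleton: the
cell region's pixel coordinates are projected onto its principal axes
(PCA of the pixel cloud); the transverse coordinate is fitted as a cubic
polynomial of the axial coordinate with least-squares residual weights
equal to the interior Euclidean distance transform (so the objective
weights are its square and deep-interior pixels dominate, insulating the
fit from boundary digitization). The fitted curve is extended until it
exits the mask and resampled at 1-px arc-length steps. Cells with
circularity `4*pi*A/P^2 >= 0.9` (configurable) are flagged as axis-less
rather than fitted. A cubic reproduces straight rods exactly and tracks
gently bent (sinusoidal) rods to well under 1 px; strongly S-shaped or
branched cells are out of scope.

## Width profiles and constriction detection

Half-widths are measured at each axis sample as the distance to the
nearest crossing of the 0.5-level mask contour along the local ±normal;
normals that miss the outline (at the hemispherical caps) give NaN
samples. Raw values are stored; detection then:

1. smooths each half-profile with a centered moving mean (window 5
   samples — the smallest window that suppresses single-pixel outline
   jitter);
2. normalizes by the cell's maximum width and inverts
   (`1 - w/max(w)`), so a relative indentation of depth *d* appears as a
   peak of height ≈ *d*. Dividing by the max rather than min–max scaling
   is deliberate: min–max would stretch pixel jitter on
   non-constricting cells across the full [0, 1] range and make the
   prominence threshold meaningless;
3. finds peaks with prominence ≥ 0.1 (relative-width units) and
   separation ≥ 15 samples, excluding the first/last 10% of arc length
   (caps always end in spurious width minima);
4. calls a constriction when each half has a peak, the two peaks agree
   within 15 samples, **and** the total width shows a matching prominent
   minimum. The third condition is the package's combination rule for
   the two half-profiles: a genuine division site indents both halves at
   the same place, so the total width dips about twice as deep, whereas
   bends and digitization artifacts produce shallow, one-sided dips that
   can pass the per-half threshold but not the combined one. On the
   default synthetic population this removes all false positives at no
   cost in recall.

The constriction position is the mean of the matched pair;
`rel_signed_position = s/L - 0.5` and `norm_offset` is its absolute
value — the division-asymmetry statistic.

## Pole regions, pole difference, SCF

Pole regions span 30% of the cell length from each pole (pixels binned
by the arc-length coordinate of their nearest axis point) and are
binary-eroded by 2 px against the full image frame to avoid boundary
effects. The normalized pole difference is (mean intensity in one pole
region − the other) / mean whole-cell intensity; it is exactly zero for
uniform cells and invariant to intensity rescaling. The signal
correlation factor (SCF) is the Pearson correlation of two channels over
a strip 4 px wide along the axis, trimmed 5 px from each pole;
undersized strips (< 10 px) or zero-variance channels are flagged NaN.

## Nucleoid segmentation and positioning

Otsu's threshold is computed over in-cell pixels only (background pixels
would dominate a whole-image threshold). The binary mask is refined with
a watershed of the inverted interior distance transform
(4-connectivity), seeded at distance-transform maxima, to split touching
nucleoids; each object is then cleaned by binary opening and closing
with a radius-1 disk and hole filling, and objects under 10 px are
dropped. Two positional conventions are implemented because they
genuinely differ for ≥ 3 objects: `distal_pair` (midpoint of the two
axially most extreme objects; the default) and `mean_relative` (mean of
relative positions, which puts two quarter-cell nucleoids exactly at
mid-cell). The pipeline reports both whenever they disagree by more
than 0.01·L. A resolvability caveat: two Gaussian nucleoids closer than
2σ produce a unimodal intensity profile, a convex thresholded blob and a
single distance-transform maximum — no watershed can split them. The
split tests therefore use separations ≥ 3.5σ, where the thresholded
mask is genuinely two-lobed.

## Sensor-area asymmetry and future daughters

The glycogen-sensor signal is segmented by the same in-cell Otsu policy.
Segmented area is assigned to pole halves by the axial coordinate
(s < L/2 vs. ≥ L/2 — a guaranteed partition; the 30% pole masks are
available behind a switch) and the difference is normalized by cell
area. Constricting cells are computationally divided at the constriction
into future daughters by the sign of `s(pixel) - s_constriction`, so the
two areas always sum exactly to the cell area.

## Lineages, polarity, growth

Microcolonies/trenches are found by DBSCAN on cell centroids (agarose
defaults ε = 45 px, minPts = 4; mother machine ε = 25 px, minPts = 10).
The implementation is in-package because the package fixes a
deterministic tie-break — clusters numbered by smallest core index,
border points joining the lowest-numbered qualifying cluster — that
off-the-shelf implementations do not guarantee; tests verify exact
agreement with a brute-force reachability oracle and agreement with
scikit-learn on core/noise sets. Frame-to-frame identity uses greedy
maximal mask-overlap matching, with a division recorded when one cell
maps to two next-frame cells (≥ 30% of each child's area); this is
sufficient for trench-confined synthetic data and is pluggable. At each
division the pole facing the division plane is each daughter's new pole;
the opposite pole inherits the parent's identity, so old-pole age
increments only in the daughter that kept it. Instantaneous growth rates
are sliding-window (default 5 frames) least-squares slopes of ln(length)
vs. time, exact on noise-free exponentials; windows never cross
divisions. Per-generation population bands are bootstrap 95% CIs
resampling lineages (1000 reps, seeded) — the CI construction is the
package's choice.

## FRAP

Global photobleaching is corrected by the ratio-to-t₀ factor
`mean_control(0)/mean_control(t)` from non-bleached control cells (an
additive variant exists behind a flag). Traces are normalized so the
first post-bleach frame is exactly 0 and the post-bleach maximum exactly
1, then fitted with a free-amplitude single exponential
`A·(1 − exp(−(t−t₀)/τ))` (initialization A = 1, τ = span/3; parameter
tolerance 1e-8; ≤ 500 evaluations, non-convergence flagged). The
half-time to maximal recovery is `τ·ln 2` by construction, and `1 − A`
estimates the immobile fraction; the plateau is deliberately not pinned
to 1. Normalizing by the noisy post-bleach maximum biases τ slightly
upward (≈ 1% at τ = 20 s with 2% noise over a 30-s window); the
parameter-recovery tests therefore check the median recovered τ.

## AFM

Force curves are approach curves: z is piezo extension (nm), force in nN,
slopes in nN/nm ≡ N/m, reported as raw stiffness without contact-
mechanics modeling. Contact is the first point exceeding the baseline
(first 50 samples) by 5σ for 10 consecutive samples — the rule is the
package's own, as instrument software rarely exports its contact point.
Surface stiffness fits the samples whose force lies in the terminal
80–100% of the maximum. Tomography fits a slope per consecutive 20-nm
indentation bin after contact (bins tile, do not overlap; bins with < 5
samples are dropped) and reports the deviation from the per-depth median
across axial positions, whose per-bin median is zero by construction.
Rupture is the first post-contact sample at least 0.5 nN (configurable)
below the running 3-sample maximum; intracellular stiffness is the
post-rupture slope, summarized per cell as the median over its
rupture-bearing curves (curves without rupture are excluded and
counted). Cell height is the difference between the off-cell (glass)
median contact z and the on-cell contact z, invariant to global z
offsets.

## Synthetic data: what it emulates, and what it does not

The generator is the package's ground-truth instrument, not a renderer
of realistic micrographs. Cells are capsules (hemispherical caps) with
optional sinusoidal bend and a smooth cosine constriction; channels are
structure-dependent profiles times a base level (1000 a.u.), convolved
with an isotropic Gaussian PSF (default 1 px) and corrupted by additive
Gaussian noise — Poisson shot noise, shading, cell-to-cell expression
variability and segmentation errors are deliberately absent, so passing
tests demonstrate estimator correctness under the stated image model,
not robustness to real segmentation artifacts. The default pixel scale
is 0.066 µm/px (typical 100× sCMOS); defaults sketch a transition-phase
population (lengths 55–85 px, widths 11–13 px, ~30% constricting at
relative positions 0.45–0.65 and depths 0.35–0.6, noise 2% of base).

The lineage model is the minimal additive-inheritance model consistent
with progressive old-pole accumulation: per generation
`a_g = f·a_{g−1} + s` (defaults f = 0.95, s = 30 px — condensates are
almost fully retained at the old pole, with steady de-novo synthesis),
nucleoid offset toward the new pole `c·a_g/area + N(0, σ_d)` with
coupling c = 1 and σ_d = 0.015 (≈ 1.5% of cell length of division-
positioning jitter, which puts the simulated offset–pole-area rank
correlation in the ~0.8–0.95 range reported for such couplings), and the
division plane displaced toward the new pole by the same offset. Mothers
divide on reaching twice the nominal birth length (sizer homeostasis),
which keeps cell size stationary across generations despite asymmetric
division. Trenches render at 10-min frames with the mother at the closed
(top) end and at most two descendants visible below.

FRAP traces follow
`baseline·e^{−kt}·[1 − depth·(1 − plateau·(1 − e^{−(t−t₀)/τ}))]` at the
experimental cadence (50-ms frames, 30 s); force curves are
piecewise-linear in indentation with optional instantaneous rupture
drops. Every artifact is a pure function of its seed.

## Problem sizes used in validation

Snapshot recovery uses 200-cell seeded populations (nucleoid-offset MAE
≤ 0.02·L; constriction recall ≥ 0.95 and position MAE ≤ 0.02·L at depth
≥ 0.3; bimodal ±0.4 pole depletion reproduced within 0.05 of direct
computation on noise-free renders). Lineage structure uses 35 lineages ×
8 generations measured through the full image pipeline. Oracle checks
run 100 random DBSCAN instances (≤ 100 points) and 50 Spearman vectors
with heavy ties. FRAP recovery uses 50 seeds per τ ∈ {5, 10, 20} s. The
whole suite completes in well under a minute on one CPU.

## Known limitations

- The medial axis assumes a single, roughly convex rod; filaments with
  multiple constrictions are reported only at the best-matching site.
- Width normals fail inside the cap region; metrics there rely on the
  10% cap exclusion rather than measurement.
- The tracker's greedy overlap matching assumes confined, slowly moving
  cells; it is not a general-purpose cell tracker.
- Sensor "area" is threshold-dependent; only Otsu-within-cell is
  implemented, matching the nucleoid policy.
- The FRAP model is a well-mixed single-pool exponential; no
  reaction–diffusion modeling is attempted.
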