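# Methods

This note documents the models, parameter choices, and numerical
decisions behind `crevalid`, and what the synthetic benchmarks do and do
not demonstrate about real data.

## 1. FISH quantification

### Nucleus segmentation (`nucleus_segmentation`)

The DAPI pipeline runs, in order: tiled contrast-limited histogram
equalization (512-px tiles, clip limit 0.01); adaptive low-pass Wiener
denoising (5×5); a contrast stretch saturating the top and bottom 1% of
intensities; an adaptive threshold keeping pixels strictly above 110% of
the mean in the surrounding 30-px window (rounded up to a 31-px odd
window, reflected borders); erosion-then-dilation cleanup; watershed
separation; reprocessing of objects over 5000 px; and a 5-px Euclidean
dilation of every accepted nucleus. Counting uses the dilated regions
because perinuclear mRNA (endoplasmic reticulum) sits just outside the
DAPI boundary.

Decisions worth knowing:

* **Global foreground gate.** A pure ratio threshold (pixel > 1.1 ×
  local mean) fires on roughly 40% of pure-background pixels whenever
  background dominates the histogram: after a bottom-1% contrast
  stretch the background mean is pinned near 2.3 of its own SDs, so
  "10% above the local mean" is only ~0.2 SD. On densely packed tissue
  the 30-px window almost always contains nuclei and the problem is
  masked; on sparse synthetic fields it floods the mask with speckle.
  The mask is therefore ANDed with a global Otsu foreground threshold
  (`global_gate`, on by default, computed on the same stretched image,
  hence scale-invariant). The adaptive criterion still carves the
  boundary inside bright regions.
* **"Erosion then dilation, 10 iterations"** is implemented as ten
  repetitions of a single-step 3×3 erosion followed by a single-step
  3×3 dilation. One such round is a morphological opening and opening
  is idempotent, so the loop converges after the first pass; the
  iteration count is kept for configurability and provenance. Holes are
  filled before the opening. Components under 5 px are then removed.
* **Watershed topography** is the negated Euclidean distance transform
  of the cleaned mask, seeded by distance-map maxima with prominence ≥ 2
  px (an H-maxima transform; `hminima` config). This splits touching
  nuclei whose fused mask has two distance basins.
* **Oversize reprocessing.** Connected objects > 5000 px are
  re-thresholded inside their bounding box with the ratio factor raised
  by 0.05 and re-watershedded, to recursion depth 2; objects that still
  exceed the cap are flagged `unresolved` rather than silently kept.
* **Label dilation** assigns contested pixels to the nearest core, with
  exact distance ties going to the smaller label id. This is computed
  with per-label distance transforms over padded bounding boxes updated
  in ascending label order under strict improvement — a construction
  that realizes the tie rule exactly, unlike a single global
  nearest-feature transform.
* Areas are measured on the dilated labels (the counting region), and
  positivity thresholds use each cell's own dilated area.

### Puncta detection (`puncta_detection`)

Each probe channel runs: white top-hat with a disc of radius 12 px
(configurable over 9–15); Wiener denoising (15×15); a 1% contrast
stretch rescaled to 0–255; the extended-maxima transform (8-connected,
h = 5 on the 0–255 scale); marker-controlled watershed; a one-step 3×3
erosion per object; rejection of objects under 5 px; unweighted
centroids.

The extended-maxima regions of a diffraction-limited (≈2-px-sigma)
Gaussian spot are only 1–3 px — the transform marks pixels within h of
each local peak — so they cannot themselves be the segmented objects
without the ≥5-px filter deleting every spot. They are used as
*markers*: the object extent is the bright foreground mask, split
between markers by watershed on the negated distance transform.
The foreground floor defaults to median + 5 robust SDs (1.4826 × MAD)
of the stretched image, so the spot footprint starts where intensity
clears the background noise band; a fixed floor can be configured. The
one-step erosion never deletes an object outright (its innermost pixel
is retained) — the ≥5-px filter is the only place objects die.

An h of 5 intensity units is read on the contrast-adjusted 0–255 image;
the alternative reading ("5 maxima") is not a parameter of the standard
transform.

### Counting, thresholding, summaries (`coexpression_stats`)

A punctum belongs to the dilated nucleus containing its (rounded)
centroid; puncta on background pixels form the outside pool, so total
counts are conserved. The background rate is outside-pool puncta divided
by outside-nuclei pixels (dilated regions count as nuclear — they are
the counting region). The positivity threshold for a cell of area A is
the smallest k with Poisson CDF(k; rate·A) ≥ 0.95, and a cell is
positive iff count > k (strict: a percentile is a value to exceed).
`scipy.stats.poisson.ppf` provides the quantile; the test suite checks
it against an independent brute-force CDF summation over λ ∈ {0.1 … 20}.
A fixed count override (e.g. "> 30 puncta/cell") can replace the
Poisson threshold per probe. R² is the squared Pearson correlation of
raw, untransformed per-cell counts. Ratios with empty denominators are
reported as NaN, never 0.

## 2. Insertion mapping and off-target screen (`insertion_locator`)

Anchored pairs have one mate on the cassette contig with aligned block
length ≥ 100 bp ("aligned block" reading; ungapped identity span is the
other possible reading of a minimum-match filter) and the other mate on
a genome contig; both-genome and both-cassette pairs are dropped, and
records without a usable mate are skipped with a logged count. Genome
mates are clustered per contig by single linkage with a 1000-bp window
(about two fragment sizes; the generator's default fragment is 500 bp),
each cluster becoming a locus at the median mate position. The
single-copy verdict passes iff exactly one locus exists, on the expected
contig, within tolerance of the expected junction.

The off-target screen is a pure function of per-line variant
observations at predicted sites: same allele in both lines →
`shared_strain_variant`; variant only in the line whose sgRNA predicted
the site → `candidate_offtarget`; no variant → `no_change`. A variant
present only in the *non*-targeted line is classified as strain
background too, which keeps the classification symmetric under
exchanging line labels together with their site lists. Discordant
alleles in both lines are flagged but classed as shared.

## 3. Opto-tagging (`optotag_classifier`)

A unit is tagged only if all three criteria hold: latency-test
p < 0.001, z-scored PSTH peak > 10 for both the 5-ms and 10-ms pulse
blocks, and Pearson r > 0.9 between the mean light-evoked and mean
session-wide waveform (on the channel with the largest session
peak-to-trough amplitude).

The latency test is a seeded window-resampling test, stated in full
because published latency tests vary: the statistic is the fraction of
pulses with ≥ 1 spike in [onset, onset + 10 ms); the null re-places the
same number of windows uniformly at random over the session, excluding a
20-ms pad around every real pulse; p = (1 + #{null ≥ observed}) /
(1 + resamples). With the default 1999 resamples the attainable floor is
1/2000 = 0.0005 < α; at 999 resamples the floor would be exactly 0.001
and the test could never reject. `classify_unit` accepts a `latency_fn`
hook for substituting another test; no equivalence to any published test
is claimed. The test suite checks the p-values are super-uniform under a
Poisson null.

The PSTH uses 1-ms bins over 0–10 ms post-onset; the baseline is the
pooled 0.5 s preceding each pulse, binned identically, with z = (peak −
baseline mean) / baseline SD. Zero baseline SD (e.g. a silent unit)
yields a flagged NaN, which can never satisfy a `>` criterion, so
degenerate units are never tagged.

## 4. Synthetic data (`synthetic_data`)

What the generators emulate, and the defaults (chosen once as
field-plausible study conditions; the source study does not report its
imaging noise or cell density):

* **FISH fields.** Elliptical nuclei with semi-axes uniform in 12–20 px,
  rendered flat-topped ((1−r²)^0.25 — chromatin fills the nucleus, the
  rim falls off smoothly) at peak ≈ 180 on an 8-bit-like scale over a
  background offset of 10, per-cell brightness 0.75–1.05. A
  configurable fraction of nuclei are placed as touching pairs at a
  given fractional area overlap (solved for circle pairs by bisection).
  Expressing cells draw counts from a negative binomial (mean 25,
  dispersion 5); puncta are ≈2-px-sigma Gaussian spots (amplitude 120 ±
  30%) placed ≥ 3 px apart inside the nucleus grown by 2.5 px — a
  margin inside the 5-px counting dilation, so pixel rounding can never
  push a planted punctum outside its cell's footprint and truth
  re-counts are exact. Background puncta fall uniformly outside all
  dilated footprints at 5·10⁻⁵ per px per probe (a few dozen per field,
  typical of a clean RNAscope negative control). A ±20% linear
  multiplicative illumination gradient and i.i.d. Gaussian noise
  (SD 4) are applied to every channel. The joint (target, off-target,
  cre) state is drawn per cell from an explicit 8-state joint
  probability table; `CoexpressionSpec.from_rates` builds one from
  planted specificity/consistency and marker-segregation rates.
* **Insertion reads.** Concordant genome pairs plus exactly
  `n_supporting_pairs` junction pairs whose genome mate falls within one
  fragment (500 bp default) of the planted junction, emitted as records
  and standard SAM (1-based, cassette as an extra contig). No sequencing
  error model.
* **Opto units.** Homogeneous Poisson baseline (5 Hz) over a session of
  a 60-s silent lead-in plus two 1-Hz pulse blocks (10 ms then 5 ms,
  120 pulses each); tagged units add one spike per pulse with the given
  reliability at the given latency ± 0.3 ms Gaussian jitter (inside the
  10-ms criterion window). Every spike of a unit reuses the unit's
  biphasic waveform template plus i.i.d. sample noise, so evoked and
  session waveforms agree for real units by construction — the waveform
  criterion guards against sorting artifacts, not against Poisson nulls.

Not emulated: 3-D stacks, optics/PSF realism, autofluorescence
structure, sequencing errors, bursting or adapting spike trains. Passing
benchmarks therefore demonstrates algorithmic correctness and
calibration under the stated conditions, not robustness to every
real-world artifact.

## 5. Benchmark problem sizes

The validation suite and `scripts/acceptance.py` use: 7 fields of 150
cells at 1024×1024 (≈1050 cells) for end-to-end recovery, compared
against the *realized* planted rates of the drawn sample; 3×70-cell
non-touching and 2×40-cell all-touching fields for segmentation
fidelity; 550 isolated spots at 10× background SD for puncta fidelity;
24- and 12-pair insertions on a 300-kb + 200-kb two-contig genome; a
48-site all-shared off-target table plus one planted line-specific
indel; and 1000 null units / 100 responsive units (reliability 0.8,
latency 5 ms, 120 pulses per duration) for tagging error rates. End-to-
end FISH recovery lands within ~2 percentage points of the realized
planted specificity/consistency (tolerance ±5); residual bias comes
from merged puncta in dense nuclei and boundary leakage of perinuclear
puncta, both of which shrink counts but rarely cross the positivity
threshold.
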