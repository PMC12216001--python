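# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `ionflow`, in the spirit of a package methods appendix. It
states no empirical numbers beyond those the test suite and
`scripts/acceptance.py` compute themselves.

## Data model and units

A run is an ordered list of scans; each scan carries centroid m/z and
intensity arrays (m/z strictly ascending, arrays equal length), an MS level,
and a retention time. Retention time is **minutes everywhere**; files that
store seconds are converted at the I/O boundary and nowhere else. Input is
assumed centroided — no centroiding is performed; profile data triggers a
warning and is processed on the points provided. A missing acquisition
timestamp falls back to the file's modification time and is flagged, so
acquisition-order-based normalization remains usable.

The mzML reader is a compact lxml stream parser keyed on controlled-
vocabulary accessions (scan start time with its unit, 32/64-bit float
encodings, zlib or no compression); mzXML goes through pyteomics. The mzML
writer emits plain, uncompressed 64-bit arrays, so synthetic files
round-trip bit-identically — a property the test suite asserts.

## Trace building

Traces are initialized from every m/z in the first MS1 scan and extended
scan by scan. Matching rules, chosen to be deterministic:

* a centroid within `mz_tol` (default 0.01 Da) of a trace's **running m/z**
  — the intensity-weighted mean of its matched points — may extend it;
* each centroid extends at most one trace: the nearest in m/z wins, exact
  ties go to the lower trace id; when several centroids claim one trace,
  the nearest centroid wins, ties to the lower m/z;
* losing or unmatched centroids immediately found new traces, so signal
  coverage is exact by construction (asserted as a property test);
* `gap_run` counts **consecutive** missed scans; after each scan, traces
  with `gap_run > gap_max` (default 30) are finalized and never extended.
  (Counting total rather than consecutive misses is a defensible alternative
  reading; consecutive was chosen because a matched scan plainly interrupts
  a "gap".)

## Segmentation

The trace is laid on its even scan-index grid with gaps as zeros; a
Gaussian kernel (σ in scan units, default 1.2, truncated at 4σ, reflect
padding) produces the smoothed array used **only** for edge detection.
Local maxima are retained when their prominence is at least
`prominence_ratio × max(smoothed)` (default 0.1); the leftmost minimum of
the smoothed array between two adjacent retained maxima is the shared
edge. The edge scan is assigned to the left segment so segments are
disjoint. Heights, areas (trapezoidal, over minutes) and weighted m/z are
computed from the raw intensities. Segments with fewer than `min_scans`
(default 5) matched scans are retained as sub-threshold "features" but not
counted as peaks. A trace with no sufficiently prominent smoothed maximum —
e.g. a fluctuating elevated baseline — produces no segments at all.

Segmentation on traces of modest length is verified against an exhaustive
brute-force implementation of the same rules (explicit kernel convolution,
prominence by outward walking).

## Quality metrics

* **Asymmetry factor**: the apex is the leftmost maximal scan; walking
  outward, the first scan strictly below 10 % of the height is the flank
  (the terminal scan if none qualifies; no interpolation between scans —
  nearest-scan semantics keep the metric exact on the sampled grid).
  Sentinel 99 when the left flank is the apex itself.
* **Gaussian similarity**: three-parameter Gaussian least squares
  (amplitude, center, width), initialized at (max, apex RT, half span),
  width bounded positive; score is the cosine between signal and fit,
  clipped to [−1, 1]. Non-convergence yields score 0 plus a flag, never an
  exception.
* **Noise score**: (p − 1)/(n − 2) over interior turning points, clamped at
  0 since monotone signals (p = 0) would otherwise go negative and a
  perfectly smooth peak is defined to score 0.

## Grouping

Sequential precedence — isotopes, then in-source fragments, then adducts —
with each peak holding at most one role; bases and their satellites link by
trace id. Scan-to-scan Pearson correlation is computed over commonly
detected scans and declared undefined below 5 shared scans, in which case
apex-RT agreement within 0.05 min substitutes (the isotope step reuses the
adduct tolerances, which the source material leaves implicit). Isotope
spacing is 1.003355 Da/z with charge read off the spacing, higher charges
tested first so z = 2 patterns are not mis-read as z = 1. Adduct mass
shifts are hard-coded to five decimals with the electron mass included;
conflicting pairings resolve by higher correlation, then smaller m/z error;
the group's base is its tallest member (protonated/deprotonated preferred
on ties). MS2 spectra attach to the peak containing their retention time
whose m/z matches the precursor, keeping the spectrum nearest the apex.
Spectral similarity itself is delegated: a plain cosine hook is provided
and any engine with the same signature can be plugged in.

## RT correction, alignment, normalization

Anchors are features m/z-unique against both sorted neighbours beyond
`mz_tol`, with noise score < 0.3, top-50 by height, split alternately by
height rank into training and testing halves (deterministic). Per sample,
anchors are matched by nearest m/z; a first-pass linear fit flags residuals
beyond 3 × 1.4826 × MAD as outliers; surviving pairs must increase
monotonically, and the map is piecewise-linear interpolation with terminal
segments extended linearly. Fewer than four usable pairs disables
correction (identity map, warning). Evaluation reports the median absolute
test-anchor shift before and after correction, in seconds.

Alignment is greedy from the tallest peak: each row collects at most one
unused peak per sample within 0.01 Da / 0.2 min, consensus m/z and RT are
intensity-weighted. Gap filling inserts the maximum raw MS1 intensity at
the row m/z within ± 0.05 min (zero when blank, always flagged). PQN
divides each sample by the median intensity quotient against the reference
(QC median spectrum when QCs exist, otherwise the global median) over
features positive in both; summed-intensity normalization is offered as the
documented alternative. QC drift correction fits a LOWESS curve (span 0.3
of the QC points, 2 robustifying iterations) to each feature's QC
intensities versus acquisition order, divides all samples by the curve and
rescales to the QC median; features missing in more than half the QCs, or
with a non-positive curve, are left untouched and reported. Corrected
intensities are clamped at zero.

## Synthetic benchmark: what it emulates and what it does not

The simulator fixes the study conditions: larger-peak height 10⁶ counts,
peak σ of 5 scan intervals (40 scans across ± 4σ, one scan per 0.5 s —
realistic UHPLC sampling and comfortably above the 10-scan floor), additive
Gaussian noise with standard deviation `noise_frac` × larger height
(so S/N = 1/noise_frac), and apex separation 4σ·Rs under the convention
Rs = Δt/(2(σ₁+σ₂)). Doubles whose smaller peak has S/N < 3 are excluded as
below the detection limit; on the 5 × 5 × 5 grid this removes 15
combinations, leaving 110; the benchmark set adds a zero-noise level (135
combinations). The single-peak grid mirrors the double grid, exclusion
included, so the two sets are the same size; the single is one Gaussian at
the nominal height, so its S/N is 1/noise_frac. Replicate seeds are
(base, combination, replicate) triples fed to a SeedSequence, making every
replicate bit-reproducible.

Signals are embedded on isolated m/z channels starting at 1500.05 Da
(outside any real acquisition range) with spacing well above twice the
matching tolerance; the default carrier is a synthetic blank, so the whole
benchmark is self-contained, and a user-supplied real run can be used
instead. Zero-clamped points are dropped, as in centroided data, which
exercises the gap handling of trace building.

Not emulated: m/z jitter across scans (channels are mass-exact), peak
tailing/fronting, intensity spikes, detector saturation, and chemical
background co-eluting with the inserted channels. Passing benchmark tests
therefore demonstrates the segmentation logic under controlled shape/noise
conditions, not performance on matrix-laden experimental data. On this
blank-carrier, well-sampled geometry the detector's accuracies run slightly
higher than one should expect on real-carrier data: single peaks are
nearly saturated and noiseless doubles fail only in the hardest corner
(Rs = 1.0 at height ratio 5). The σ × prominence heatmap consequently has a
fairly flat high plateau, and the sensitivity-robustness trade-off shows up
as directions (large σ merges doubles, small prominence splits noisy
singles) rather than as a sharp interior optimum.

## Problem sizes and runtime choices

Simulation-backed tests run at reduced replicate counts (tens per
combination) and the acceptance script defaults to 100 replicates per
combination — 22,000 optimization signals plus 27,000 benchmark signals —
chosen so the full study regenerates in well under a minute on one core
while keeping the binomial uncertainty of each stratum accuracy a few
tenths of a percentage point. Channel processing is blocked (2,000
channels per in-memory run) purely to bound memory; blocking does not
change results because channels are independent by construction.

## Degenerate inputs and tie-breaks

Empty runs yield empty trace lists; empty scans are legal. All-zero
signals make asymmetry and similarity undefined (errors), as does a
noise-score input shorter than 3 points. Plateaued apexes take the
leftmost maximal scan; plateaued inter-peak minima take the leftmost
minimal scan. Weighted means fall back to unweighted when all weights are
zero. PQN refuses samples sharing no positive features with the reference;
drift correction refuses fewer than five QCs.

## Known limitations

* mzXML support exists behind the same reader interface but only mzML is
  exercised end to end by the test suite.
* Isotope annotation flags patterns only via spacing and co-elution; it
  does not infer elemental composition, and halogen-specific intensity
  patterns are not modelled.
* The identity/fuzzy spectral search that would consume the preprocessed
  MS/MS spectra is intentionally out of scope; only the preprocessing
  filters and a cosine hook are provided.
* Gap-filling reuses the alignment m/z tolerance (0.01 Da); a separate
  tolerance may be preferable for very-high-resolution instruments.
* Single-threaded; files are processed sequentially in the workflow.
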