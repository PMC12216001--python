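# ionflow

Feature detection, grouping, alignment and normalization for centroided
untargeted LC-MS (metabolomics / lipidomics) data, plus a synthetic
chromatographic-peak benchmark that measures how accurately the detector
separates real peaks from noise and from co-eluting isomers.

It is aimed at mass-spectrometry data scientists who want a transparent,
fully scriptable processing core: mzML/mzXML in, an aligned feature ×
sample table with peak-quality metadata out, and a simulation harness to
quantify detector behaviour under controlled signal-to-noise, peak-height
ratio and chromatographic resolution.

## The method

**Mass traces.** MS1 centroids are clustered into traces (regions of
interest): a trace is an m/z value followed across consecutive scans within
a tolerance (default 0.01 Da), tolerating up to 30 consecutive missed
scans. Every single MS1 point is assigned to exactly one trace — no signal
is discarded before evaluation.

**Peak segmentation.** Each trace's intensity array *I* is smoothed with a
1-D Gaussian filter (σ = 1.2 scans) to give *I′*; local maxima of *I′*
whose prominence exceeds 0.1 × max(*I′*) are kept, and the local minimum of
*I′* between two adjacent maxima becomes the shared peak edge. Heights and
areas are always reported from the **raw** array *I* — smoothing is used
for edge finding only. Segments with ≥ 5 matched scans qualify as peaks;
shorter ones remain "features".

**Peak quality.** Per peak: asymmetry factor
(t_right − t_a)/(t_a − t_left) at the 10 %-height crossings (sentinel 99
when the apex is its own left flank), Gaussian similarity = cosine(S, S′)
against a least-squares Gaussian fit, and a noise score
max(0, (p − 1)/(n − 2)) counting interior turning points p.

**Grouping.** Co-eluting peaks are annotated sequentially as isotopes
(Δm/z = 1.003355/z), in-source fragments (fragment m/z present in the
parent's MS/MS and scan-to-scan Pearson r > 0.7), then adducts
([M+H]⁺, [M+Na]⁺, [2M+H]⁺, … and the negative-mode equivalents); each peak
carries at most one role.

**Alignment and normalization.** Standard-free retention-time correction
picks unique, low-noise, high-intensity anchor features from the reference
QC run, matches them by m/z in every sample, removes outliers (3 × MAD) and
interpolates a monotone piecewise-linear RT map; features are then aligned
greedily (0.01 Da / 0.2 min), gaps filled by forced extraction (± 0.05 min),
and intensities normalized by probabilistic quotient normalization and
QC-anchored LOWESS drift correction.

**Benchmark.** Synthetic single and double Gaussian peaks are generated over
a grid of noise level (0–10 % of the larger height), height ratio (1–5) and
resolution Rs (1.00–2.00), excluding doubles whose smaller peak has
S/N < 3, embedded on isolated m/z channels above 1500 Da, and pushed through
the full detection path. A single counts as correct iff exactly one peak is
reported in its channel; a double iff exactly two.

## Worked example

Simulate one double peak (4 % noise, height ratio 2, Rs = 1.5), embed it in
a blank run and detect:

```python
from ionflow import sim_benchmark as sb
from ionflow.feature_detection import detect_features
from ionflow.peak_quality import compute_quality

spec = sb.SimSpec(kind="double", noise_frac=0.04, height_ratio=2,
                  resolution=1.5, seed=(1, 0, 0))
rts, y, truth = sb.simulate_signal(spec)
run, truths = sb.insert_into_run([(rts, y, truth)], spacing=1.0)
result = detect_features(run)
print(f"traces={len(result.traces)}  features={len(result.features)}  "
      f"peaks={len(result.peaks)}")
for p in result.peaks:
    q = compute_quality(p)
    print(f"m/z {p.mz:.2f}  apex {p.apex_rt:.3f} min  height {p.height:,.0f}  "
          f"area {p.area:,.0f}  scans {p.n_scans}  AF {q.asymmetry_factor:.2f}  "
          f"gauss {q.gaussian_similarity:.3f}  noise {q.noise_score:.2f}")
```

prints

```
traces=1  features=2  peaks=2
m/z 1500.05  apex 0.167 min  height 1,000,326  area 105,467  scans 34  AF 0.92  gauss 0.997  noise 0.31
m/z 1500.05  apex 0.408 min  height 525,746  area 51,217  scans 29  AF 1.67  gauss 0.996  noise 0.41
true apexes: [0.167, 0.417]
```

One trace was cut into exactly two peaks; the apexes land on the planted
positions (0.167 / 0.417 min), the recovered height ratio is ≈ 2, both
shapes are near-Gaussian (similarity ≈ 0.997) and the noise scores reflect
the 4 % additive noise.

The same machinery is available from the shell:

```bash
ionflow untargeted -i my_project_folder          # full pipeline
ionflow simulate-benchmark --replicates 100      # accuracy benchmark
ionflow score truth.csv features.csv             # score external results
```

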