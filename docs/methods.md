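# Methods

`carscope` quantifies how chimeric antigen receptors (CARs) with different
costimulatory domains organize and move in the T-cell membrane, and how the
resulting T cells kill adherent targets. It implements four quantitative
pipelines — fluorescence correlation spectroscopy (FCS) with a
triplet-corrected two-component diffusion model, membrane cluster
segmentation, immune-synapse intensity quantification, and double-normalized
impedance killing kinetics — each paired with a synthetic-data generator so
every stage can be validated against known ground truth without any
external data.

## 1. FCS model

The fitted autocorrelation is

    G(τ) = 1 + G_triplet(τ) · G_diffusion(τ)

    G_triplet(τ)   = 1 + T_t · exp(−τ/τ_t) / (1 − T_t)
    G_diffusion(τ) = f1 / [(1 + τ/τ_d1) · √(1 + τ/(S² τ_d1))]
                   + f2 / (1 + τ/τ_d2)

with `T_t` the dark-state (triplet) fraction, `τ_t` its correlation time,
`f1, τ_d1` the amplitude and diffusion correlation time of a freely
diffusing 3D species (detached labeled ligand), `f2, τ_d2` those of the 2D
membrane-confined receptor, and `S` the axial/lateral ratio of the
ellipsoidal Gaussian detection volume. Amplitudes are free and
non-negative; `f1 + f2` equals the zero-lag diffusion amplitude (there is
no explicit 1/N prefactor), and reported component fractions are
`f_i/(f1+f2)`. Diffusion times convert to coefficients through
`τ_d = ω_r²/(4D)` with `ω_r` the lateral 1/e² focus radius.

### Calibration protocol

1. **Free dye** of known literature diffusion coefficient
   (Alexa Fluor 647, D = 325 µm²/s) determines the dye's τ_d and hence
   `ω_r = √(4 D τ_d)`.
2. **Free labeled ligand** (monomeric HER2 extracellular domain) fitted
   with S fixed gives the 3D time `τ_d1` used in all cell fits.
3. **Cell curves** are fitted with S and τ_d1 fixed; free parameters are
   `T_t, τ_t, f1, f2, τ_d2`.  The recovery studies additionally share the
   dark-state parameters from the calibration
   (`fit_cell(..., share_triplet=True)`): the same fluorophore is measured
   minutes apart on the same instrument, and freeing five parameters on a
   short-record curve re-opens the triplet/amplitude trade.

The classical two-stage fit (`calibrate_dye` + `calibrate_ligand`) is
implemented and tested. The *default* calibration used by the study
workflows (`calibrate_joint`) fits the dye and ligand curves globally with
shared `T_t, τ_t, S`: both measurements see the same fluorophore and the
same detection volume, and because the ligand diffuses ~5× more slowly, its
curve separates triplet from diffusion cleanly and pins the shared
photophysics. On short desk-scale records this removes an otherwise severe
triplet↔τ_d trade-off in the dye-only fit.

In the synthetic recovery studies, S and the dark-state parameters
(T_t, τ_t) are additionally **fixed at the simulated instrument's and
fluorophore's known values**. Both are near-unidentifiable at desk-scale
signal-to-noise: the axial tail of a 3D curve carries little information,
so a free S trades against the diffusion times along a likelihood ridge;
and a joint (T_t, τ_t, τ_d) fit of the dye curve has a nearly flat valley
in which τ errors of 20–30% cost a χ² change at the noise level (measured
— a truth-started and a 30%-off solution differed by an effective
Δχ² ≈ 1). Fixing constants that are known by construction — as bead
calibrations and dedicated photophysics measurements provide on a real
instrument — validates recovery of the quantities the protocol actually
propagates: the diffusion times and coefficients. The fully free fits
remain available (`calibration_study(joint=False)`, `calibrate_dye`,
`calibrate_joint` without the fixing arguments) and are exercised by unit
tests on noiseless curves.

Calibration fits use restricted lag windows (dye ≤ 1.5 ms, ligand ≤ 8 ms,
roughly 50 diffusion times): beyond that the one-component model is
indistinguishable from its baseline, while the finite periodic simulation
box contributes re-entry correlations — a particle leaving the box
re-enters on the far side and revisits the focus after the lateral
crossing time L²/2D ≈ 6 ms for the dye — that an infinite-medium model
does not describe.

### Fitting

Bounded trust-region least squares (lmfit/`least_squares`), weighted by
1/SEM² when the pooled curve carries per-lag standard errors. Start
values: `T_t = 0.1`, `τ_t = 5 µs`, `τ_d2 = 10 ms`, amplitudes split
half/half from the observed zero-lag amplitude; τ_d1 from the calibration
where fixed. Bounds: `T_t ∈ [0, 0.8]`, correlation times within the lag
range, `S ∈ [1, 25]`, and `τ_t ≤ 30 µs` — triplet correlation times of
organic fluorophores at moderate excitation are a few to a few tens of µs,
and the cap prevents the dark-state term from absorbing the free-ligand
shoulder (τ_d1 ≈ 170 µs), a degenerate solution on noisy curves. Fits
restart from a small deterministic grid of start values (three S values ×
three τ factors) and keep the lowest residual norm. Non-convergence is
reported in the fit metadata, never silently replaced.

Uncertainty on the membrane D is available two ways: the standard error of
the ensemble fit, and the spread of leave-one-run-out refits
(`jackknife_membrane_D`).

## 2. Correlation estimation and pooling

`compute_acf` implements the standard multi-tau correlator: 16 linear lags
per octave, trace rebinned by 2 per octave, upper half of the lag block
reused, lags capped at one tenth of the run duration. Symmetric
normalization (separate left/right segment means per lag) is used per run.

Pooling across runs is done two ways:

* `pool_curves` — per-lag mean and SEM of the per-run normalized curves
  (the conventional "average the curves" operation).
* `pool_curves_ensemble` (pipeline default) — averages the *raw*
  correlation moments across runs and normalizes by ensemble means. The
  per-run normalized estimator has a finite-record bias of order
  τ_corr/(N_eff·T) per run which averaging curves cannot remove; at
  desk-scale occupancies (N_eff ≲ 1) and 1–2 s records this bias visibly
  depresses the curve tail, while ensemble normalization shrinks it by
  roughly the run count. The attached per-lag SEM is the delete-one-run
  jackknife standard error of the pooled estimator itself, which remains
  calibrated where across-run covariance makes the naive SEM optimistic.

### Run QC

A run is flagged `bleaching` when its fractional intensity trend (OLS
slope of 10-ms-binned intensity × duration / mean) falls below a
threshold, and `outlier` when the RMS deviation of its curve from the
leave-one-out mean of the other runs exceeds `outlier_k` (default 3) times
the typical across-run spread computed *without* that run (so a wild run
cannot inflate the scale it is judged against). Each run receives exactly
one flag.

The synthetic study pipeline sets both thresholds so that honest
single-molecule records are never excluded (bleach 1000%, outliers at
20×). This is deliberate: at N_eff ~ 1–2, a single molecule entering or
leaving the focus produces intensity trends approaching 100% and curve
excursions many times the typical spread — these ARE the correlation
signal, and no threshold separates them from artifacts (of which the
generator has none). Trimming them truncates the amplitude distribution
asymmetrically and was measured to bias recovered diffusion times by
10–30% toward faster diffusion. The conventional screens (10% bleach,
3σ outliers) are the `qc_runs` defaults, appropriate for instrument data
where runs at one spot form a homogeneous population and excursions are
rare artifacts; they are exercised in the test suite on constructed
decays and injected aggregate spikes.

## 3. Brownian-dynamics trace simulator

Each species diffuses independently (Gaussian steps of variance 2DΔt per
axis; 2D species confined to z = 0) in a periodic box, observed through a
3D Gaussian detection profile `exp(−2(x²+y²)/ω_r² − 2z²/(Sω_r)²)`. Each
particle carries a bright/dark telegraph process with stationary dark
fraction T_t and relaxation time τ_t (rates T_t/τ_t and (1−T_t)/τ_t).
Expected counts per bin are brightness × detection weight × bright state ×
bin width, summed over particles; realized counts are Poisson. Particle
numbers are drawn per run from a Poisson law around the configured mean:
the observation region exchanges molecules with a vast reservoir (bulk
solution, the surrounding membrane), and this grand-canonical ensemble is
the one the standard FCS model describes. (A fixed particle number
instead shifts G(τ) down by ≈ Σ Rᵢ²/Nᵢ at all finite lags relative to
that model — a ~0.015 offset at the study occupancies which a baseline-1
fit converts into a ~20% diffusion-time error; the canonical variant
remains available via ``poisson_count=False``.) Identical seeds give
bit-identical traces.

Numerical scheme: the position-sampling interval targets
τ_d/`position_resolution` (default 20 samples per focus transit). Species
faster than that get sub-bin substeps with the detection weight averaged
within the bin; species much slower than the bin are updated every several
bins with the weight held constant in between (for a membrane receptor at
τ_d ≈ 20–30 ms and 2 µs bins this saves ~500× with distortions of order
(interval/τ_d)² ≪ 1%). The dark/bright state is point-sampled at bin
centres, exact for the correlation at all fitted lags because bins must
resolve τ_t. The box is 10 ω_r laterally; the study configurations use
6 ω_z axially (detection weight ≤ e⁻¹⁸ at the boundary) to keep particle
counts moderate at fixed concentration.

### Study conditions (desk scale)

Real measurements of this kind use nanomolar dye (thousands of molecules
in the detection volume) and minutes of acquisition; simulating that is
not feasible on a desktop, so the synthetic studies run in the
single-molecule regime with conditions chosen once as a realistic,
self-consistent instrument:

| quantity | value |
|---|---|
| focus radius ω_r | 0.2 µm |
| structural parameter S | 4 |
| triplet | T_t = 0.15, τ_t = 5 µs |
| brightness | 10⁵ counts/s per molecule at beam centre |
| dye | D = 325 µm²/s, N_eff ≈ 0.33, 60 × 2-s runs, 1 µs bins |
| ligand | D = 60 µm²/s (≈70 kDa globular protein), N_eff ≈ 0.33, 40 × 2-s runs, 2 µs bins |
| membrane receptor | D ∈ {0.31, 0.44, 0.53} µm²/s, N_eff ≈ 2, plus free ligand, 120–150 × 2-s runs, 2 µs bins |

The large membrane run counts are dictated by the statistics of slow 2D
diffusion: at τ_d2 ≈ 20–30 ms a 2-s record contains only ~10² independent
occupancy fluctuations, and the pooled-curve noise at the lags that
determine τ_d2 shrinks only as the square root of total record time.
150 runs put the diffusion-time estimator at ≈5% (1σ), comfortably inside
the 10–15% recovery tolerances; the published measurements achieve their
precision the same way, by pooling hundreds of 10-s runs across cells and
donors before the ensemble fit.

The membrane ground truths are the published diffusion coefficients of the
four CAR generations (.z 0.31, CD28.z 0.44, 41BB.z 0.44,
CD28.41BB.z 0.53 µm²/s); recovery within the acceptance tolerances
therefore demonstrates that the pipeline measures the quantity the
published protocol reports, under scaled-down but physically faithful
conditions. What passing does *not* show: robustness to photobleaching,
detector afterpulsing, membrane undulations, or instrument drift — none of
which the generator emulates (bleaching and rare-event screens are instead
verified on constructed anomalies).

## 4. Cluster imaging

Per-cell mean intensities are screened with a lognormal fit (Gaussian in
log space, exclusion beyond ±2.5 SD). Segmentation: Gaussian smoothing
(σ = 1.2 px), global threshold, watershed flooding of the inverted
smoothed image seeded at h-maxima (prominence ≥ 30% of the
threshold-to-background rise) — prominence-based markers do not fragment
broad cluster plateaus under counting noise, while genuinely distinct
clusters separated by a deep saddle are still split. Clusters below 4 px
are discarded. Threshold options: `otsu` (default), quantile `q:<f>`,
robust background `mad:<k>`, and `rise:<f>` — a fraction of the rise from
the background median to the bright-core level (99.5th percentile), which
tracks the half-maximum contour of PSF-blurred objects and is the choice
used in the synthetic recovery studies.

Metrics per cell: cluster count per 10 µm² of membrane, per-cluster areas
(px × pixel area) and integrated intensities, and mean intensities
inside/outside clusters normalized to the whole-mask mean (so a uniform
image gives exactly 1.0 for both; the normalization reference is a
documented choice).

The generator places non-overlapping discs (lognormal radii, median
0.2 µm, σ_log 0.25, ≥0.1 µm edge separation so that ground-truth counts
are resolvable at the simulated PSF), renders receptor density
(300/15 molecules/µm² inside/outside), convolves with a Gaussian PSF
(σ = 80 nm at 40 nm pixels), adds background and Poisson noise.

## 5. Synapse quantification and blot fractions

The synaptic ROI is the set of pixels inside a contact band — the
target-cell boundary dilated by 3 px, restricted to effector-adjacent
pixels — whose phospho-label intensity exceeds a threshold computed within
the band (Otsu by default, hence invariant to uniform rescaling of the
channel). Reported metrics: area (px × pixel area), mean and integrated
phospho intensity, with integrated = mean × pixel count exactly. The
operational ROI definition is a documented surrogate for a manual
delineation. Blot dimer/oligomer proportions are computed per lane from
background-corrected band intensities as oligomer/(dimer+oligomer);
densitometry itself happens upstream.

## 6. Impedance killing kinetics

Replicate impedance traces are averaged, divided by their value at
treatment start, then divided pointwise by the non-transduced (NT) control
(linear interpolation if grids differ) — the NT control maps to the
constant 1 exactly. A flag switches to normalize-then-average for
sensitivity checks. The simulator produces a logistic pre-treatment rise
to plateau (confluent monolayer), then dZ/dt = −k(t)·Z with k ramping
linearly from 0 to the condition's kill rate over 1 h after a
condition-specific lag; the NT condition has zero kill plus a slow drift;
noise is multiplicative lognormal. Analysis is single-frequency; column
selection from an impedance spectrum is I/O.

## 7. Reproducibility and problem sizes

All randomness flows from explicit integer seeds (`numpy` PCG64); study
seeds are derived from a single seed via `default_rng(seed).integers`.
The recovery studies use the run counts in the table above (~10 minutes
total on one CPU); these sizes were chosen so that the estimator spread
sits well inside the acceptance tolerances while the full suite stays
desktop-friendly. Degenerate inputs (all-zero traces, empty masks,
all-zero lanes, zero control impedance) raise errors rather than
propagating NaNs; ties and bound-hits in fits are reported through fit
metadata and calibration warnings.

## Known limitations

* The FCS generator omits photobleaching, detector afterpulsing and dead
  time, cross-correlation, and anomalous diffusion.
* Ensemble normalization assumes runs sample the same stationary process;
  it is not appropriate for runs with systematic intensity differences
  (different cells), where per-run normalization (`pool_curves`) should be
  used instead.
* The S-free calibration is honest but high-variance on desk-scale
  records; treat its S estimate as indicative only.
* Cluster-area recovery is PSF-limited: areas carry a systematic
  threshold-dependent bias of order 10–20% for objects a few PSF widths
  across.
* The synapse ROI rule is a surrogate for expert delineation; absolute
  areas depend on the band width and threshold choices.
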