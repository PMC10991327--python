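# Methods

This note documents the models, conventions and design choices behind
`cortexwaves`, in the order the pipeline applies them.

## Signal model and the synthetic generator

The generator (`synthdata`) renders a movie as

    movie(t, p) = E(p) · ( Σ_k a_k · ρ_k(p) · Re[ w_k(t) · e^{−iθ_k(p)} ] + ε(t, p) )

* `w_k` — a complex analytic waveform from a white-noise-driven second-order
  linear oscillator `x'' + 2ξω_n x' + ω_n² x = w(t)`, discretized by the
  bilinear transform at the sampling rate and lifted by the Hilbert
  transform. This family is chosen because its stationary autocorrelation
  is exactly the damped-oscillator form that `wavemetrics.fit_oscillator`
  fits, so the generator and the estimator share one model. A burn-in of
  ten envelope time constants precedes the retained record so the output is
  stationary; the real part is normalized to zero mean, unit variance.
* `ρ_k, θ_k` — amplitude and phase maps. A per-pixel time *delay* is
  implemented as a phase rotation of the analytic waveform, valid for
  narrowband signals and exactly the model complex PCA assumes; no
  integer-sample shifting is used.
* `a_k` — a scale factor setting wave k's realized energy fraction to its
  requested `variance_share`; the remainder `1 − Σ shares` is the white
  Gaussian noise variance (per pixel, per frame).
* `E(p)` — a strictly positive expression-efficiency map, modelling the
  spatially varying gain of fluorescent-protein expression. It multiplies
  the *detected* signal, noise included: optically, pixels that express
  more indicator report both signal and fluctuation at higher gain. A
  consequence used throughout testing is that per-pixel z-scoring removes
  `E` exactly, so decompositions are invariant to the efficiency map — the
  rationale for z-scoring before CPCA.
* `ε` — zero-mean Gaussian noise, i.i.d. over pixels and frames.

Everything derives deterministically from one integer seed via spawned
`SeedSequence` children: identical ground truth ⇒ bit-identical movie.

**Default fixture.** 40×40 grid, 3000 frames at 30 Hz; a standing wave at
35% energy share (f = 0.3 Hz, ξ = 0.05, i.e. Q = 10), a traveling wave
sweeping one full 2π phase cycle across the columns (25%, 1.2 Hz, ξ = 0.1),
a two-lobe anti-phase wave split across the rows (20%, 3.0 Hz, ξ = 0.1),
and 20% noise. The exact map geometries and frequencies of the original
validation simulation are not published; these are parametric stand-ins
chosen once. The amplitude profiles vary along the axis orthogonal to each
wave's phase variation and are mirror-symmetric, which makes the three
complex ground-truth maps mutually orthogonal — three genuinely distinct
spatial sources, the regime in which a principal-component method can
separate them. Sub-sampled grids (20×20 and below) of the same fixture are
used where a test only needs the structure, not the full resolution.

**What the generator does not emulate.** Indicator kinetics (GECI rise/decay
filtering), hemodynamic contamination, photobleaching, vasculature
artifacts, movement, and 1/f background. Passing recovery tests therefore
show that the decomposition chain is correct under the stated signal model,
not that real recordings satisfy that model.

**Synthetic gene maps.** `simulate_gene_maps` constructs each map as
`r·ẑ_ref + √(1−r²)·n̂` with `n̂` a smoothed random field orthogonalized
against the standardized reference, so the realized in-mask Pearson
correlation equals the target exactly up to rounding.

## Preprocessing

Pipeline order: flatten → bandpass → z-score (→ optional GSR).

* **Bandpass.** Chebyshev type II, 4th order, ≥ 40 dB stopband, applied
  forward-backward (zero phase; attenuation doubles). SciPy's critical
  frequencies for this family are *stopband* edges; they are placed at
  `low/2` and midway between `high` and Nyquist so the nominal 0.1–14.5 Hz
  band lies in the passband (0.3 Hz gain ≥ 0.999; 0.01 Hz ≤ −80 dB after
  two passes). The first/last 5 s may carry transients; they are flagged in
  metadata, not trimmed.
* **Z-score.** Population (1/N) variance convention, recorded in metadata;
  downstream correlations are invariant to the 1/N vs 1/(N−1) choice.
  Whether z-scoring precedes or follows filtering is not prescribed by the
  method description; filtering first avoids re-introducing variance
  differences and is the order used here.
* **GSR.** Per-pixel ordinary least squares on the spatial-mean trace with
  intercept (the standard definition), not plain subtraction; residuals are
  exactly uncorrelated with the global mean.

## Complex PCA conventions

* SVD of the analytic matrix without re-centering: columns are z-scored
  real signals and the Hilbert transform preserves zero mean.
* `loading_k = V_k`, `score_k = U_k·d_k`, so `M[t,p] = Σ_k t_k(t)·conj(l_k(p))`
  and the analytic covariance obeys `MᴴM = Σ_k d_k²·l_k l_kᴴ` exactly.
* **Variance accounting.** `variance_fraction = d_k²/Σ_j d_j²`, a
  normalization-invariant ratio; the raw singular values are stored so any
  absolute-variance convention can be produced.
* **Gauge.** Each component is defined only up to `e^{iα}`. The gauge is
  fixed by rotating so the ρ-weighted circular mean of θ is zero (standing
  waves then display θ ≈ 0). Because a further π flip would negate the
  resultant, this condition is complete whenever the resultant is nonzero;
  in the degenerate zero-resultant case the sign is set so the score's
  largest-magnitude excursion is real-positive. All reported quantities
  (ρ, phase differences, variance fractions, per-wave FC) are
  gauge-invariant; gauge fixing only standardizes display and
  reproducibility across linear-algebra backends.
* Default 10 retained components, configurable; the method cannot itself
  determine the "true" number of waves. Rank-deficient input returns fewer
  nonzero components with a warning, not an error.

## Wave metrics

* **Oscillator fit.** Nonlinear least squares of the damped-oscillator ACF
  over (A, f_n, ξ), with `f_d = f_n√(1−ξ²)` tied (not independently
  fitted); bounds ξ ∈ (1e−4, 0.999), f_n ∈ (1/L, Nyquist); multi-start
  over the top-5 spectral peaks of the measured ACF × three damping starts;
  the lowest-residual solution wins. The curve is normalized to 1 at lag 0
  but A is left free, so A ≈ 1 doubles as a fit sanity check. Default lag
  window 30 s. `ξ = 1/(2Q)` converters are provided.
* **PSNR quality.** Per part (real, imaginary, summed):
  `10·log10(x_max / var(x − median_{10×10}(x)))` with `x_max` the plain
  maximum of that part over the mask — deliberately literal, *not* the
  conventional squared-peak PSNR. The even 10×10 kernel has no center
  pixel; the window covers offsets −5…+4 in both axes, reflect-padded,
  mask-aware (out-of-mask pixels excluded per window). Degenerate inputs
  are returned flagged: zero residual variance caps the part at 100 dB; a
  non-positive maximum falls back to max|x|. The real/imag split makes the
  raw score gauge-sensitive; scores are computed on gauge-fixed loadings.
* **Circular variance.** `1 − |Σ_p ρ_p e^{iθ_p}| / Σ_p ρ_p`,
  amplitude-weighted because low-ρ pixels carry unreliable phase; an
  unweighted variant is available. 0 iff all in-mask phases agree; exactly
  1 for equal-mass antipodal lobes.
* **Spectra.** Hann-windowed periodogram normalized to unit integral; band
  power maps use half-open bands `(low, high]` over the rfft bins with DC
  excluded, so a full partition of (0, Nyquist] sums to 1 per pixel. The
  six default bands are logarithmically spaced over 0.1–14.5 Hz (the
  original band edges are not published).

## Functional connectivity

* `C_Φk` is the Pearson matrix of wave k's reconstructed pixel series.
  Since every such series lies in the 2-D span of Re(t_k), Im(t_k), the
  matrix is computed from the 2×2 score covariance — identical to
  correlating the full reconstruction, at O(n²) cost. For a proper
  analytic score (the discrete Hilbert transform guarantees equal-variance,
  orthogonal quadratures) the entries equal `cos(θ_j − θ_k)`: a π phase lag
  *is* a −1 correlation, the mechanism behind negative connections after
  GSR. Pixels with ρ = 0 reconstruct to the zero series and are flagged
  undefined rather than raised.
* **Superposition.** The weights of `Σ_t s_t·C_Φt` are not defined
  numerically in the source description; variance fractions are used, with
  unit-diagonal renormalization (default; the unrenormalized variant is a
  flag). With scalar weights the superposition of *correlation* matrices
  reproduces the raw FC only insofar as the amplitude maps are spatially
  uniform — the exact identity holds for covariances. On uniform-amplitude
  synthetic data the full-rank similarity exceeds 0.99 once the record is a
  few minutes long (pseudo-covariance terms decay with duration); with
  strongly structured amplitude maps it saturates near 0.97. The
  superposition-similarity curve rises steeply while true waves are added
  and is flat, up to sampling jitter, across the noise tail.
* **Hemispheric difference.** Homolateral minus contralateral mean |FC| per
  pixel (the figure-caption sign convention; the Methods prose phrase with
  the opposite order is not adopted). The midline is a mask column index
  supplied by configuration; no atlas logic. Note that under the
  absolute-value definition a pure anti-phase wave produces *equal* |FC|
  within and across hemispheres; positive difference maps require
  hemisphere-specific coupling, which is how the property is exercised in
  tests.
* **Seed selection.** k-means on FC rows; k maximizes the silhouette over
  2–25 (the manual choice it assists can be forced via `k_override`);
  silhouette is estimated on a 400-pixel subsample above that size; the
  seed of a cluster is the in-mask pixel nearest its centroid in FC-row
  space; deterministic given the seed argument. Constant FC degenerates to
  a warned trivial k = 2 split.
* **Group statistics.** Pearson r clipped at |r| = 1 − 1e−7, Fisher
  z-transformed; one-sample two-sided t (mean z = 0) within a group,
  Welch's unequal-variance t between groups; Benjamini–Hochberg across the
  upper-triangle edges; significance at q < 0.05. Zero-variance edges get
  ±∞ statistics with p ∈ {0, 1}, flagged.

## Wave matching

MSE between `C_Φ` matrices over the upper triangle (the full-matrix variant
differs by a constant factor and never changes an argmin). Assignment is
per-query-row argmin with ties to the lower reference index; it may be
non-injective (flagged), and a Hungarian one-to-one variant is provided.
Grids are assumed pre-aligned; no resampling.

`recovery_report` (generator-side validation) instead matches truth waves
to components one-to-one by maximizing the modulus of the complex loading
inner product — gauge-invariant — via the Hungarian algorithm, and reports
per-wave |corr| and variance-share error.

## Gene-map correlation

A wave's "spatial distribution" is its amplitude map ρ by default; the
signed map Re(ρe^{iθ}) is available behind a flag since either reading is
defensible. Pearson r per gene over in-mask pixels; categories on |r| with
*inclusive* boundaries: ≥ 0.3 correlated, ≥ 0.75 highly correlated.
Coexpression-module construction and enrichment analysis are out of scope;
the synthetic gene generator supplies test fixtures.

## Problem sizes and tolerances

Tests and the acceptance script run the full default fixture (40×40 × 3000
frames) once for recovery, and reduced grids (8×8–20×20, 60–240 s) where
only the structure matters — the identities they check are
scale-independent. Exact linear-algebra identities are asserted at 1e−8;
stochastic recovery checks use the generator's own study conditions (20%
noise, 3000 frames) with thresholds of 0.95 on loading correlations and
5 pp on shares. The null FDR experiment uses 200 Monte-Carlo repetitions of
20 independent-noise recordings × 45 edges.

## Known limitations

* Near-equal singular values make the component basis ill-conditioned; the
  decomposition is then reproducible (LAPACK is deterministic) but the
  individual components are not physically meaningful. Tie-breaking order
  is arbitrary and documented as such.
* The literal PSNR definition (un-squared peak, raw maximum) can go
  negative for low-amplitude parts and is gauge-sensitive pre-fixing; it is
  kept for fidelity, flagged in the degenerate cases.
* Scalar-weight FC superposition is an approximation wherever amplitude
  maps are non-uniform (see above).
* No atlas registration, movement screening, hemodynamic correction, or
  real-data I/O beyond NPY movies and masks.
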