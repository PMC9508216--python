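# Methods

This note documents the models, numerical choices and known limitations of
each stage, and what the synthetic generators do and do not emulate.

## Spindle detection

**Procedure.** Welch power spectra (resolution ≤ 0.25 Hz, per 30-s epoch,
averaged over artifact-free N2/N3 epochs) → individual spindle peak →
band-pass ±1.5 Hz around the peak → RMS in consecutive non-overlapping
200-ms windows → events where RMS > 1.5 × SD of the filtered signal for
0.5–3 s. Duration is the interval between threshold crossings of the RMS
step function; amplitude is the maximal absolute filtered voltage within the
event; density is events per included epoch.

**Peak finding.** The original workflow identified each subject's spindle
peak visually. Here the call is automated: the spectrum is box-smoothed over
0.5 Hz, a log–log linear background is fitted over 4–20 Hz excluding
9–16 Hz, and the most prominent in-band local maximum whose power is ≥ 10 %
above the background is taken. "No detectable peak" is a first-class outcome
(`SpindlePeak.peak_frequency_hz is None`); such subjects are excluded from
that band's analysis rather than scored zero, which matters mostly for the
slow band.

**Numerical choices.**

* Filter: 4th-order Butterworth, applied forward–backward (`sosfiltfilt`) so
  event timing is not phase-shifted. The effective order is therefore 8.
* RMS window boundaries are placed at `round(i·fs·0.2)` samples; at 256 Hz a
  window is 51 or 52 samples and the grid tiles each 30-s epoch exactly, so
  no window straddles an epoch boundary.
* The threshold SD is computed from the filtered signal restricted to
  included epochs, one threshold per subject across N2 and N3. A config
  switch (`threshold_on="rms"`) instead uses mean + 1.5 SD of the RMS
  series; which variant the original MATLAB tool used is not documented, so
  both readings are available and the filtered-signal reading is the
  default.
* Runs longer than 3 s are discarded entirely (not truncated); adjacent
  supra-threshold runs are not merged; an event belongs to the epoch
  containing its onset, and every epoch its span touches must be included.

**Quantization caveat.** Because durations are multiples of the 200-ms
window, a physical burst of 0.3 s can occupy two or three windows depending
on phase relative to the grid, and filter ringing at very high SNR can
extend a run by one window. The 0.5-s minimum therefore rejects sub-0.5-s
*RMS runs* exactly (unit-tested), while sub-0.5-s *physical bursts* are
rejected in the typical operating regime but not at arbitrarily high SNR.
The detector's density recovery is what the acceptance checks quantify.

## EEG simulator

Background is 1/f (power α = 1) noise at 10 µV RMS plus a 2 µV white floor —
a standard EEG surrogate that puts realistic low-frequency power under the
sigma band so peak detection is nontrivial. Spindles are Hann-windowed
sinusoids; defaults follow the healthy-adult cohort values the pipeline
targets: density 2.22/30 s (fast) and 1.50/30 s (slow), duration
0.82 ± 0.05 s, peak amplitude 27.56 µV, peak frequency 13.46 Hz (fast) /
10.84 Hz (slow) with 0.25 Hz between-event jitter. Event count is Poisson
with mean density × epochs; onsets are rejection-sampled with a 1-s
refractory gap so planted events never merge. Inter-subject variability of
amplitude and frequency is exposed as configuration rather than fixed,
since the cohort-level distributions of those parameters are not published.

Not emulated: sleep-stage microstructure (all epochs default to N2), slow
oscillations and their coupling to spindles, artifacts with realistic
morphology, multi-channel topography. Passing recovery tests therefore show
the detector implements its stated rule faithfully — not that it matches
human scorers on real polysomnography.

## Genotype simulator

Each individual carries two haplotypes; a haplotype allele is the indicator
`Z < Φ⁻¹(MAF)` of a latent Gaussian. HWE holds exactly per variant. LD is
induced by an equicorrelated latent factor within fixed-size blocks
(ld_rho is the latent correlation; genotype r² is somewhat lower). Related
pairs share one haplotype, giving expected π̂ ≈ 0.5; they occupy the last
rows as consecutive pairs. There is no mutation/recombination model, no
demography, no sex chromosomes — the generator exists to exercise QC and
scoring, not to be population-genetically realistic.

**Small-panel caveat.** The π̂ estimator is the off-diagonal of the genomic
relationship matrix on the pruned high-quality set; its sampling SD is
roughly `1/√m_eff`. Below ~500 effectively independent variants the
π̂ > 0.20 rule starts firing on noise, so simulated cohorts should use
≥ 1,000–2,000 variants (the presets do).

## QC cascade

Order: sample QC → variant QC → high-quality set → LD pruning → relatedness
→ PCA outliers; re-running the cascade on its own output is a fixed point.
Heterozygosity uses the normalized deviation (observed − expected)/expected
het computed on the high-quality set (whether the original analysis computed
it before or after variant QC is unstated; this choice is configurable).
Sex-mismatch checking is a logged no-op (no sex chromosomes simulated). The
HWE exact test sums probabilities of heterozygote counts no more probable
than observed, conditional on allele counts, via a multiplicative recurrence
(cross-checked against exact-rational enumeration to 10⁻¹²). Pruning slides
a 200-variant window by 50 (the window size is stated in the workflow being
reproduced; the step is the conventional quarter-window) and drops the
lower-MAF member of each violating pair (tie → later position). PCA
standardizes dosages by `2p̂` and `√(2p̂(1−p̂))`, removes > 6 SD outliers on
the first 20 components, and re-fits once so removed outliers do not define
the covariate axes; the first 10 PCs are exported as association covariates.

## Polygenic scoring

Odds ratios enter on the log scale (additivity requires it). Dosages are
oriented to the GWAS effect allele *before* mean imputation with twice the
cohort effect-allele frequency — this order makes scores bit-identical under
storage-orientation flips. Palindromic (A/T, C/G) variants are always
removed: simulated and array `.bim` files carry no strand information.
Threshold comparison is strict (p < t). Clumping (250 kb, r² 0.1, cohort
genotypes as the LD reference) is available but off by default: whether the
original scores were clumped is not stated, and the simulators' null
variants carry exactly zero effect, so thresholding alone is well defined
either way. The concordant/discordant split uses only sign agreement of the
two traits' effects; zero-effect variants join neither subset (concordance
is undefined at zero).

## Phenotype simulator and association

The phenotype model is `y = Xb + γ·s⊥ + ε`, where `s⊥` is the true score
residualized on the covariates and standardized, and
`γ² = t(Var(Xb) + σ²)/(1 − t)` so the population ΔR² of the score over the
covariate model equals the target `t` regardless of score–covariate
correlation. In the end-to-end pipeline the latent phenotype is mapped
linearly to a spindle-density scale (mean 2.22, SD 0.38, floored at 0.1/30 s;
the floor binds ~5.8 SD out) and, in EEG mode, each subject's density is
*measured* by running the full detector on a recording simulated at their
true density — measurement noise then attenuates ΔR² below the generative
target, as it would in practice.

ΔR² is the ordinary (unadjusted) R² difference; the reported p-value is the
two-sided t-test of the score coefficient in the full model. The identity
`ΔR² = r²_partial · (1 − R²_base)`, with `r_partial` from residual-on-
residual regression, holds to 10⁻¹⁰ and is used as an independent oracle in
tests. A score collinear with the base design yields ΔR² = 0, p = 1 rather
than an error. The best threshold maximizes ΔR² (ties by smaller p); all
thresholds are always reported, and no multiple-testing correction is
applied across the grid — the scan's min-p is anti-conservative, which the
permutation test in the suite documents.

The gene-based test residualizes phenotype and standardized region dosages
on the covariates, takes principal components of the residualized genotype
matrix retaining ≥ 99.9 % of variance, and F-tests their joint fit with
denominator degrees of freedom n − k_covariates − n_components. Conditional
on genotypes the statistic is exactly F-distributed under a Gaussian null,
and a single-variant region reduces exactly to the covariate-adjusted
single-SNP F-test.

## Pipeline, seeds and problem sizes

One global seed fans out to per-stage child seeds via
`numpy.random.SeedSequence`, so stages are independently reproducible and
reports at a fixed seed are byte-identical (reports contain no timestamps).
Distinct generators must receive distinct seeds; reusing one integer across
two `default_rng` streams yields identical draws.

Preset problem sizes are chosen to finish in seconds while keeping every
estimator in its statistically stable regime: `smoke` (120 × 600,
direct phenotypes), `cohort` (150 subjects × 2,000 variants, 10 EEG epochs
per subject, detector-measured phenotypes). Calibration-style checks in the
test suite use n = 5,000 individuals × 200 replicates (incremental-R²
recovery) and 2,000 null simulations (gene-test type-I error).

## Known limitations

* The detector's duration estimates are quantized to 200 ms and understate
  the planted burst duration by roughly one window at the default threshold
  (threshold crossings trim the Hann tails): planted 0.82 s bursts are
  measured at ~0.7 s.
* The noise-floor false-event rate depends on the in-band background; with
  the default 1/f profile and no spindles it is ~0.6/30 s, dropping steeply
  once real spindle energy raises the per-subject threshold.
* Summary-statistic nulls have exactly zero effect, so scores at successive
  thresholds differ only by zero-effect variants unless non-null p-values
  are spread across the grid (`nonnull_p_range`).
* PLINK I/O supports the SNP-major `.bed` layout only; EDF support is
  single-channel with 1-s records.
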