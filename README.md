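# spindlepgs

From NREM sleep EEG to stratified polygenic-score association — a tested,
reusable implementation of the analysis chain linking **fast sleep spindle
density** to **polygenic risk for schizophrenia**, exercised entirely on
synthetic cohorts with known ground truth.

The package is aimed at sleep/psychiatric-genetics researchers who want to
reproduce, stress-test or extend this kind of analysis without access to a
private cohort: every input (EEG, genotypes, GWAS summary statistics,
phenotypes) can be simulated with controlled truth, so each stage's output is
checkable against what was planted.

## What it computes

1. **Spindle detection** (`spindlepgs.spindle`) — the individually-adapted
   peak method: average the power spectrum over artifact-free N2/N3 30-s
   epochs, find the subject's own spindle peak in the fast (12–15 Hz) or slow
   (9–12 Hz) sigma band, band-pass filter ±1.5 Hz around it, compute the RMS
   of the filtered signal in consecutive 200-ms windows, and call a spindle
   wherever the RMS exceeds 1.5 SD of the filtered signal for 0.5–3 s.
   Density = events per included 30-s epoch. Subjects without a detectable
   slow peak are excluded from slow-spindle analysis, never zeroed.

2. **Genotype QC** (`spindlepgs.qc`) — sample missingness > 0.02 and
   |heterozygosity deviation| > 0.2; variant MAF < 0.01, Hardy–Weinberg exact
   p < 10⁻⁶, missingness > 0.02; a high-quality SNP set (HWE p > 0.02,
   MAF > 0.20, no missingness) feeding LD pruning (pairwise r² < 0.1 in
   200-SNP windows), π̂ > 0.20 relatedness exclusion, and 6-SD outlier removal
   on the first 20 principal components.

3. **Polygenic scores** (`spindlepgs.pgs`) — info-score ≥ 0.9 filtering,
   allele harmonization with palindromic-SNP removal, optional LD clumping,
   and scoring

   `PGS_i(t) = Σ_{j : p_j < t} dosage_ij · log(OR_j)`

   at the threshold grid PT ∈ {0.001, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1}.
   Cross-trait stratification splits variants into SCZ–IQ *concordant*
   (sign(log OR) = sign(β)) and *discordant* subsets, each scored with the
   SCZ effects and p-values.

4. **Association** (`spindlepgs.assoc`) — incremental R²
   (`ΔR² = R²_full − R²_base`) of each score over a base model of
   sex + age + 10 PCs, scanned over the grid; quintile summaries relative to
   the lowest score quintile; and a multi-SNP gene-region test by
   principal-components regression (an F-test on the components retaining
   ≥ 99.9 % of region genotype variance, after residualizing on covariates).

5. **Simulators** (`spindlepgs.synth`) — 1/f EEG with Hann-windowed sigma
   bursts at known density/frequency/amplitude/duration; HWE genotypes with
   block LD (Gaussian copula) and planted relatedness; paired GWAS tables
   with an exact effect-direction concordance fraction; phenotypes with a
   prescribed population incremental R².

## Worked example

```python
from spindlepgs.pipeline import preset, run_pipeline

report = run_pipeline(preset("cohort", seed=11))
best = report["association"]["all"]
print(report["stages"]["qc"])
print("best PT", best["best_threshold"],
      "incremental R2 %.3f" % best["best_incremental_r2"],
      "p %.3g" % best["best_p"])
```

prints (seed 11):

```
{'n_individuals_removed': 2, 'n_variants_removed': 1, 'n_individuals': 148,
 'n_variants': 1999, 'n_pruned_set': 678}
best PT 0.3 incremental R2 0.012 p 0.186
```

i.e. a 150-subject synthetic cohort in which each subject's spindle density
was *measured by the detector from simulated EEG*, QC removed both planted
related individuals, and the score–density association peaked at PT 0.3 with
ΔR² = 1.2 % — smaller than the 5.2 % generative truth because detector
measurement noise attenuates the association, exactly as it would in a real
cohort of this size.

The same stages are exposed on the command line:

```bash
spindlepgs simulate --preset smoke --seed 1 --out bundle/
spindlepgs spindle detect --signal bundle/eeg.csv --hypnogram bundle/hypnogram.tsv --band fast --out spindles/
spindlepgs qc run --bfile bundle/genotypes --out qc/clean
spindlepgs pipeline run --preset cohort --seed 11 --out run/
```

## Layout

```
src/spindlepgs/
  synth/        EEG, genotype, summary-stat and phenotype simulators
  spindle.py    adaptive spindle detection
  qc.py         genotype quality-control cascade
  pgs.py        harmonization, stratification, threshold scoring
  assoc.py      incremental R2, quintiles, gene-based test
  pipeline.py   end-to-end orchestration with YAML config
  io.py         CSV/EDF signals, PLINK bed/bim/fam, sumstats TSV
  cli.py        click command groups
docs/methods.md detailed model and design notes
```
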