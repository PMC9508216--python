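"""End-to-end orchestration: synthesize a cohort, derive spindle phenotypes,
run genotype QC, build stratified polygenic scores, scan the threshold grid.

The run is driven by a single serializable :class:`PipelineConfig` whose
defaults are the conventional analysis values (30-s epochs, +/-1.5 Hz
adaptive band, 200-ms RMS windows, 1.5 SD threshold, 0.5-3 s durations,
MAF 0.01 / HWE 1e-6 / missingness 0.02 variant filters, r^2 < 0.1 in
200-SNP pruning windows, pi-hat 0.20, 6 SD on 20 PCs, info 0.9, the
eight-threshold PT grid, +/-20 kb gene flanks). One global seed fans out to
per-stage child seeds through ``numpy.random.SeedSequence`` so each stage is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .assoc import incremental_r2, quintile_summary, threshold_scan
from .pgs import (
    PGSMatrix,
    ThresholdGrid,
    harmonize_alleles,
    info_filter,
    score_individuals,
    split_by_concordance,
)
from .qc import QCThresholds, run_qc
from .spindle import (
    detect_spindle_events,
    find_spindle_peak,
    nrem_power_spectrum,
    summarize_spindles,
)
from .synth import (
    PhenoModel,
    SimGenConfig,
    simulate_eeg,
    simulate_genotypes,
    simulate_phenotype,
    simulate_summary_stats,
)


@dataclass
class PipelineConfig:
    """Fully serializable configuration for one synthetic cohort run."""

    seed: int = 0
    genotypes: SimGenConfig = field(default_factory=SimGenConfig)
    # summary statistics
    concordant_fraction: float = 0.5
    null_fraction: float = 0.5
    effect_sd: float = 0.05
    info_threshold: float = 0.9
    # phenotype
    target_incremental_r2: float = 0.052
    covariate_effects: dict = field(
        default_factory=lambda: {"sex": 0.1, "age": 0.01}
    )
    noise_sd: float = 1.0
    phenotype_source: str = "direct"  # "direct" | "eeg"
    # EEG phenotype settings (used when phenotype_source == "eeg")
    eeg_epochs_per_subject: int = 10
    eeg_band: str = "fast"
    density_mean: float = 2.22
    density_sd: float = 0.38
    # spindle detector
    spindle_halfwidth_hz: float = 1.5
    spindle_rms_window_s: float = 0.2
    spindle_threshold_sd: float = 1.5
    spindle_min_dur_s: float = 0.5
    spindle_max_dur_s: float = 3.0
    # QC / PGS / association
    qc: QCThresholds = field(default_factory=QCThresholds)
    thresholds: tuple[float, ...] = ThresholdGrid().thresholds
    n_assoc_pcs: int = 10

    def validate(self) -> None:
        if self.genotypes.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.genotypes.n_variants <= 0:
            raise ValueError("n_variants must be positive")
        if self.phenotype_source not in ("direct", "eeg"):
            raise ValueError("phenotype_source must be 'direct' or 'eeg'")
        ThresholdGrid(tuple(self.thresholds))

    def to_yaml(self, path: str | Path) -> None:
        def _plain(obj):
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            return obj

        Path(path).write_text(yaml.safe_dump(_plain(asdict(self)), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "genotypes" in d and isinstance(d["genotypes"], dict):
            g = dict(d["genotypes"])
            if "maf_range" in g:
                g["maf_range"] = tuple(g["maf_range"])
            d["genotypes"] = SimGenConfig(**g)
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QCThresholds(**d["qc"])
        if "thresholds" in d:
            d["thresholds"] = tuple(d["thresholds"])
        return cls(**d)


def preset(name: str, seed: int = 0) -> PipelineConfig:
    """Ready-made configurations.

    ``cohort`` mimics the study design at reduced scale (array-cohort
    genotypes, EEG-derived spindle density); ``smoke`` is a fast end-to-end
    exercise with directly simulated phenotypes.
    """
    if name == "cohort":
        return PipelineConfig(
            seed=seed,
            genotypes=SimGenConfig(
                n_individuals=150, n_variants=2_000, ld_block_size=10,
                ld_rho=0.4, n_related_pairs=2, missing_rate=0.002, seed=seed,
            ),
            phenotype_source="eeg",
            eeg_epochs_per_subject=10,
        )
    if name == "smoke":
        return PipelineConfig(
            seed=seed,
            genotypes=SimGenConfig(
                n_individuals=120, n_variants=600, ld_block_size=5,
                ld_rho=0.3, seed=seed,
            ),
            phenotype_source="direct",
        )
    raise ValueError(f"unknown preset: {name}")


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _density_phenotype_from_eeg(
    target_density: np.ndarray, config: PipelineConfig, seeds: list[int]
) -> np.ndarray:
    """Per-subject: simulate a recording at the subject's true density, run
    the full adaptive detector, return the measured density."""
    measured = np.empty(target_density.size)
    duration = config.eeg_epochs_per_subject * 30.0
    for i, (d, s) in enumerate(zip(target_density, seeds)):
        rec, hyp, _ = simulate_eeg(
            duration, band=config.eeg_band, truth_density=float(d), seed=s
        )
        spectrum = nrem_power_spectrum(rec, hyp)
        peak = find_spindle_peak(spectrum, config.eeg_band)
        if not peak.present:
            measured[i] = np.nan
            continue
        events = detect_spindle_events(
            rec, hyp, peak,
            halfwidth_hz=config.spindle_halfwidth_hz,
            rms_window_s=config.spindle_rms_window_s,
            threshold_sd=config.spindle_threshold_sd,
            min_dur_s=config.spindle_min_dur_s,
            max_dur_s=config.spindle_max_dur_s,
        )
        measured[i] = summarize_spindles(events, hyp, peak).density
    return measured


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages in order and return the run report (a dict that is
    also written as ``report.json`` when ``out_dir`` is given)."""
    config.validate()
    seeds = _child_seeds(config.seed, 6)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report: dict = {"seed": config.seed, "stages": {}}

    # --- stage 1: genotypes -------------------------------------------------
    geno_cfg = replace(config.genotypes, seed=seeds[0])
    dataset = simulate_genotypes(geno_cfg)
    report["stages"]["genotypes"] = {
        "n_individuals": dataset.n_individuals,
        "n_variants": dataset.n_variants,
    }

    # --- stage 2: summary statistics ---------------------------------------
    scz, iq = simulate_summary_stats(
        dataset.variants,
        concordant_fraction=config.concordant_fraction,
        effect_sd=config.effect_sd,
        null_fraction=config.null_fraction,
        seed=seeds[1],
    )

    # --- stage 3: phenotype (true score -> spindle density) ----------------
    rng = np.random.default_rng(seeds[2])
    age = rng.normal(35.0, 10.0, size=dataset.n_individuals)
    sex = dataset.individuals["sex"].to_numpy(dtype=float)
    covar = pd.DataFrame({"sex": sex, "age": age})

    log_or = np.log(scz["OR"].to_numpy(dtype=float))
    dos = np.nan_to_num(dataset.dosages, nan=0.0)
    true_score = dos @ log_or
    model = PhenoModel(
        target_incremental_r2=config.target_incremental_r2,
        covariate_effects=config.covariate_effects,
        noise_sd=config.noise_sd,
    )
    latent = simulate_phenotype(true_score, covar, model, seed=seeds[3])
    sd = latent.std() if latent.std() > 0 else 1.0
    density_true = np.maximum(
        config.density_mean + config.density_sd * (latent - latent.mean()) / sd, 0.1
    )

    if config.phenotype_source == "eeg":
        subj_seeds = _child_seeds(seeds[4], dataset.n_individuals)
        phenotype = _density_phenotype_from_eeg(density_true, config, subj_seeds)
    else:
        phenotype = density_true
    pheno = pd.DataFrame(
        {"iid": dataset.individuals["iid"], "phenotype": phenotype}
    ).dropna()
    report["stages"]["phenotype"] = {
        "source": config.phenotype_source,
        "n_phenotyped": int(len(pheno)),
        "mean_density": float(np.nanmean(phenotype)),
    }

    # --- stage 4: genotype QC -----------------------------------------------
    clean, pcs, qc_report = run_qc(dataset, config.qc, seed=seeds[5])
    report["stages"]["qc"] = {
        "n_individuals_removed": len(qc_report.removed_individuals),
        "n_variants_removed": len(qc_report.removed_variants),
        "n_individuals": clean.n_individuals,
        "n_variants": clean.n_variants,
        "n_pruned_set": len(qc_report.pruned_snp_set),
    }

    # --- stage 5: polygenic scores ------------------------------------------
    scz_f = info_filter(scz, config.info_threshold)
    iq_f = info_filter(iq, config.info_threshold)
    h_scz = harmonize_alleles(scz_f, clean)
    h_iq = harmonize_alleles(iq_f, clean)
    shared = set(h_scz["SNP"]) & set(h_iq["SNP"])
    conc, disc = split_by_concordance(
        h_scz[h_scz["SNP"].isin(shared)].reset_index(drop=True),
        h_iq[h_iq["SNP"].isin(shared)].reset_index(drop=True),
    )
    grid = ThresholdGrid(tuple(config.thresholds))
    matrices = {
        "all": score_individuals(clean, h_scz, grid, "all", harmonized=True),
        "concordant": score_individuals(
            clean, conc, grid, "concordant", harmonized=True
        ),
        "discordant": score_individuals(
            clean, disc, grid, "discordant", harmonized=True
        ),
    }
    report["stages"]["pgs"] = {
        "n_info_filtered": int(len(scz) - len(scz_f)),
        "n_harmonized": int(len(h_scz)),
        "n_concordant": int(len(conc)),
        "n_discordant": int(len(disc)),
    }

    # --- stage 6: association ------------------------------------------------
    aligned = (
        pheno.set_index("iid")
        .join(pcs.set_index("iid"), how="inner")
        .join(covar.set_index(dataset.individuals["iid"]), how="inner")
    )
    pc_cols = [f"PC{k + 1}" for k in range(config.n_assoc_pcs)]
    pc_cols = [c for c in pc_cols if c in aligned.columns]
    covariates = aligned[["sex", "age"] + pc_cols]
    y = aligned["phenotype"].to_numpy()

    assoc_report: dict = {}
    for label, mat in matrices.items():
        scores = mat.scores.loc[aligned.index]
        sub = PGSMatrix(scores, mat.n_snps_per_threshold, label)
        results, best = threshold_scan(y, sub, covariates)
        assoc_report[label] = {
            "results": [
                {
                    "threshold": r.threshold,
                    "incremental_r2": r.incremental_r2,
                    "p": r.coefficient_p,
                    "n": r.n,
                    "n_snps": r.n_snps,
                }
                for r in results
            ],
            "best_threshold": best.threshold,
            "best_incremental_r2": best.incremental_r2,
            "best_p": best.coefficient_p,
        }
        q = quintile_summary(
            scores[best.threshold].to_numpy(), y
        )
        assoc_report[label]["quintile_changes"] = list(q.changes)
    report["association"] = assoc_report
    report["n_analyzed"] = int(len(aligned))

    if out is not None:
        io.write_plink(out / "genotypes", dataset)
        io.write_sumstats(out / "scz_sumstats.tsv", scz)
        io.write_sumstats(out / "iq_sumstats.tsv", iq)
        pheno.to_csv(out / "phenotype.tsv", sep="\t", index=False)
        aligned.reset_index()[["iid", "sex", "age"] + pc_cols].to_csv(
            out / "covariates.tsv", sep="\t", index=False
        )
        for label, mat in matrices.items():
            mat.scores.to_csv(out / f"pgs_{label}.tsv", sep="\t")
        io.write_json(out / "qc_report.json", qc_report.to_dict())
        io.write_json(out / "report.json", report)
    return report
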