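"""Core domain containers shared across the pipeline.

Conventions
-----------
* EEG amplitudes are microvolts; time is seconds from recording start.
* Hypnogram epochs are 30 s; stages use AASM labels ``W, N1, N2, N3, REM``.
* Genotypes are additive dosages in {0, 1, 2} with ``NaN`` for missing calls,
  counted on ``allele1`` (the effect/minor allele of the ``.bim`` convention).
* GWAS summary statistics live in a :class:`pandas.DataFrame` with columns
  ``SNP CHR BP A1 A2 OR|BETA SE P INFO`` (see :mod:`spindlepgs.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EPOCH_LENGTH_S = 30.0
NREM_STAGES = ("N2", "N3")
STAGES = ("W", "N1", "N2", "N3", "REM")


@dataclass
class EEGRecording:
    """Single-channel EEG trace."""

    samples: np.ndarray  # microvolts
    sampling_rate: float  # Hz
    channel: str = "C3-A2"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class Hypnogram:
    """Per-epoch sleep stages and artifact flags (30-s epochs)."""

    stages: list[str]
    artifact_flags: np.ndarray  # bool per epoch
    epoch_length_s: float = EPOCH_LENGTH_S

    def __post_init__(self) -> None:
        self.stages = list(self.stages)
        self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
        if len(self.stages) != self.artifact_flags.size:
            raise ValueError("stages and artifact_flags lengths differ")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown sleep stages: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    def included_epochs(self) -> np.ndarray:
        """Indices of artifact-free N2/N3 epochs (the analysis set)."""
        ok = np.array([s in NREM_STAGES for s in self.stages])
        return np.flatnonzero(ok & ~self.artifact_flags)


@dataclass(frozen=True)
class SpindlePeak:
    """Individual spectral spindle peak; ``peak_frequency_hz`` is ``None``
    when no peak passed the prominence criterion (a legal state — such
    subjects are excluded from that band's analysis, never zeroed)."""

    band: str  # "fast" | "slow"
    peak_frequency_hz: float | None
    prominence: float  # power ratio over the fitted 1/f background

    @property
    def present(self) -> bool:
        return self.peak_frequency_hz is not None


@dataclass(frozen=True)
class SpindleEvent:
    onset_s: float
    duration_s: float
    amplitude_uv: float
    epoch_index: int


@dataclass(frozen=True)
class SpindleSummary:
    density: float  # events per 30-s included epoch
    mean_duration_s: float | None
    mean_amplitude_uv: float | None
    peak_frequency_hz: float | None
    n_epochs_included: int
    n_events: int


@dataclass
class GenotypeDataset:
    """Individuals x variants dosage matrix with metadata.

    ``dosages[i, j]`` counts copies of ``variants.a1[j]`` carried by
    ``individuals.iid[i]``; missing calls are ``NaN``.
    """

    dosages: np.ndarray  # float, n x m, entries {0,1,2,NaN}
    individuals: pd.DataFrame  # columns: iid, sex
    variants: pd.DataFrame  # columns: snp, chrom, pos, a1, a2

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.individuals) != n or len(self.variants) != m:
            raise ValueError("dosage matrix does not match metadata lengths")
        if self.variants["snp"].duplicated().any():
            raise ValueError("variant IDs must be unique")
        if (self.variants["pos"] < 0).any():
            raise ValueError("positions must be non-negative")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset(self, *, individuals: np.ndarray | None = None,
               variants: np.ndarray | None = None) -> "GenotypeDataset":
        """Return a copy restricted to the given boolean/index selections."""
        dos = self.dosages
        ind = self.individuals
        var = self.variants
        if individuals is not None:
            dos = dos[individuals, :]
            ind = ind.iloc[np.arange(len(ind))[individuals]].reset_index(drop=True)
        if variants is not None:
            dos = dos[:, variants]
            var = var.iloc[np.arange(len(var))[variants]].reset_index(drop=True)
        return GenotypeDataset(dos.copy(), ind.copy(), var.copy())

    def allele_freq(self) -> np.ndarray:
        """Frequency of allele1 per variant over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class QCReport:
    """Accumulates the quality-control cascade's removals and artifacts.

    Each removed ID carries exactly the first reason that triggered it.
    """

    removed_individuals: list[tuple[str, str]] = field(default_factory=list)
    removed_variants: list[tuple[str, str]] = field(default_factory=list)
    pc_matrix: pd.DataFrame | None = None  # index iid, columns PC1..PC20
    pruned_snp_set: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def removed_individual_ids(self) -> set[str]:
        return {i for i, _ in self.removed_individuals}

    def removed_variant_ids(self) -> set[str]:
        return {v for v, _ in self.removed_variants}

    def to_dict(self) -> dict:
        return {
            "removed_individuals": [
                {"iid": i, "reason": r} for i, r in self.removed_individuals
            ],
            "removed_variants": [
                {"snp": v, "reason": r} for v, r in self.removed_variants
            ],
            "pruned_snp_set": list(self.pruned_snp_set),
            "notes": list(self.notes),
        }


@dataclass(frozen=True)
class AssociationResult:
    threshold: float
    incremental_r2: float
    coefficient_p: float
    n: int
    base_r2: float
    n_snps: int = 0


@dataclass(frozen=True)
class QuintileSummary:
    changes: tuple[float, ...]  # mean phenotype minus lowest-quintile mean
    boundaries: tuple[float, ...]  # PGS cut points between quintiles
    group_sizes: tuple[int, ...]
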