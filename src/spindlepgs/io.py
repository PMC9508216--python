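"""File formats: EEG signals (CSV/EDF), hypnograms, PLINK bed/bim/fam,
GWAS summary statistics, ground-truth sidecars.

Text formats are favoured throughout; the two binary formats the wider
toolchain expects (PLINK ``.bed``, EDF) are implemented directly — both are
simple fixed layouts (2-bit genotype codes, 16-bit EDF samples).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import EEGRecording, GenotypeDataset, Hypnogram

# ---------------------------------------------------------------------------
# EEG signal
# ---------------------------------------------------------------------------


def write_signal_csv(path: str | Path, rec: EEGRecording) -> None:
    """Two-column CSV: time_s, amplitude_uv."""
    t = np.arange(rec.samples.size) / rec.sampling_rate
    pd.DataFrame({"time_s": t, "amplitude_uv": rec.samples}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_signal_csv(path: str | Path, channel: str = "C3-A2") -> EEGRecording:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("signal CSV needs at least two samples")
    # total span is robust to the per-sample rounding of the written times
    fs = (t.size - 1) / (t[-1] - t[0])
    return EEGRecording(df["amplitude_uv"].to_numpy(), float(round(fs, 6)), channel)


def write_edf(path: str | Path, rec: EEGRecording) -> None:
    """Minimal single-channel EDF writer (1-s data records, int16 samples).

    The sampling rate must be an integer and the recording a whole number of
    seconds; both hold for the 256 Hz, 30-s-epoch recordings produced here.
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    x = rec.samples
    if x.size % fs != 0:
        raise ValueError("EDF writer requires a whole number of seconds")
    n_records = x.size // fs

    pmin, pmax = float(x.min()), float(x.max())
    if pmax <= pmin:  # constant signal: avoid zero gain
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    dig = np.round((x - pmin) * gain + dmin).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate X X X X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 + 256), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad("1", 4),
            # per-signal fields
            pad(f"EEG {rec.channel}", 16),
            pad("", 80),
            pad("uV", 8),
            pad(f"{pmin:.3f}"[:8], 8),
            pad(f"{pmax:.3f}"[:8], 8),
            pad(str(dmin), 8),
            pad(str(dmax), 8),
            pad("", 80),
            pad(str(fs), 8),
            pad("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(dig.tobytes())


def read_eeg(path: str | Path, channel: str = "C3-A2") -> EEGRecording:
    """Read an EEG trace from CSV (``.csv``) or EDF (``.edf``, via MNE)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_signal_csv(path, channel)
    if path.suffix.lower() == ".edf":
        import mne  # heavy import kept lazy

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data()[0] * 1e6  # MNE stores volts
        return EEGRecording(data, float(raw.info["sfreq"]), channel)
    raise ValueError(f"unsupported signal format: {path.suffix}")


# ---------------------------------------------------------------------------
# Hypnogram
# ---------------------------------------------------------------------------


def write_hypnogram(path: str | Path, hyp: Hypnogram) -> None:
    pd.DataFrame(
        {
            "epoch_index": np.arange(hyp.n_epochs),
            "stage": hyp.stages,
            "artifact": hyp.artifact_flags.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def read_hypnogram(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path, sep="\t")
    return Hypnogram(df["stage"].tolist(), df["artifact"].to_numpy().astype(bool))


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major

# 2-bit codes (PLINK 1): 00=hom allele1, 01=missing, 10=het, 11=hom allele2.
# Dosage counts allele1 copies: 00 -> 2, 10 -> 1, 11 -> 0, 01 -> NaN.
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(prefix: str | Path, ds: GenotypeDataset) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    fam = pd.DataFrame(
        {
            "fid": ds.individuals["iid"],
            "iid": ds.individuals["iid"],
            "pat": 0,
            "mat": 0,
            "sex": ds.individuals.get("sex", pd.Series([0] * ds.n_individuals)),
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    bim = pd.DataFrame(
        {
            "chrom": ds.variants["chrom"],
            "snp": ds.variants["snp"],
            "cm": 0,
            "pos": ds.variants["pos"],
            "a1": ds.variants["a1"],
            "a2": ds.variants["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    n = ds.n_individuals
    dos = ds.dosages
    codes = np.empty((ds.n_variants, n), dtype=np.uint8)
    codes[:] = 1  # missing
    codes[dos.T == 2] = 0
    codes[dos.T == 1] = 2
    codes[dos.T == 0] = 3
    # pack 4 individuals per byte, little-endian within the byte
    n_bytes = (n + 3) // 4
    padded = np.zeros((ds.n_variants, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> GenotypeDataset:
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"snp": str, "a1": str, "a2": str},
    )
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK .bed file")
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    body = raw[3:].reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T
    individuals = fam[["iid", "sex"]].copy()
    variants = bim[["snp", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeDataset(dosages, individuals, variants)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

SUMSTATS_COLUMNS_OR = ["SNP", "CHR", "BP", "A1", "A2", "OR", "SE", "P", "INFO"]
SUMSTATS_COLUMNS_BETA = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "INFO"]


def write_sumstats(path: str | Path, stats: pd.DataFrame) -> None:
    stats.to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str, "A2": str})
    if "OR" not in df.columns and "BETA" not in df.columns:
        raise ValueError("summary statistics need an OR or BETA column")
    return df


# ---------------------------------------------------------------------------
# JSON sidecars
# ---------------------------------------------------------------------------


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
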