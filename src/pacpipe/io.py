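"""File formats: recordings (TSV/EDF), cohort manifests, and configuration.

TSV (tab-separated, header row of 10-20 channel labels) is the canonical
text format for recordings and for every result table; EDF is supported for
input only, through MNE.  The pipeline configuration surfaces every analysis
parameter with the defaults used throughout: 30 segments of 2 s, a 3-SD
joint-probability rejection threshold, 200 surrogates with 0.1-1.9 s shifts,
alpha 0.05, and 200 flip-half permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .recording import COLLECTION_AGES_MONTHS, Recording

__all__ = [
    "PipelineConfig",
    "read_recording",
    "write_recording_tsv",
    "read_manifest",
    "write_manifest",
    "read_pac_maps",
]

NOMINAL_FS_HZ = 250.0


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis pipeline."""

    fs_hz: float = NOMINAL_FS_HZ
    segment_len_s: float = 2.0
    sd_threshold: float = 3.0
    n_segments: int = 30
    lf_centers: list[float] | None = None  # None -> 2..20 Hz in 2-Hz steps
    lf_bandwidth: float = 2.0
    hf_centers: list[float] | None = None  # None -> 40..100 Hz in 4-Hz steps
    hf_bandwidth: float = 20.0
    n_surrogates: int = 200
    shift_range_s: tuple[float, float] = (0.1, 1.9)
    alpha: float = 0.05
    n_permutations: int = 200
    null_mode: str = "pooled"
    cluster_percentile: float = 95.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.shift_range_s = tuple(float(v) for v in self.shift_range_s)
        if len(self.shift_range_s) != 2 or not (
            0 < self.shift_range_s[0] <= self.shift_range_s[1] < self.segment_len_s
        ):
            raise ValueError(
                f"shift range {self.shift_range_s} s must lie strictly inside "
                f"a {self.segment_len_s} s segment"
            )
        if self.null_mode not in ("pooled", "max"):
            raise ValueError("null_mode must be 'pooled' or 'max'")
        if self.n_segments < 1 or self.n_surrogates < 0 or self.n_permutations < 1:
            raise ValueError("counts must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["shift_range_s"] = list(self.shift_range_s)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def write_recording_tsv(rec: Recording, path: str | Path) -> None:
    """One column per channel, header row of channel labels, full precision."""
    df = pd.DataFrame(rec.data.T, columns=rec.ch_names)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _read_recording_tsv(path: Path, fs_hz: float) -> Recording:
    df = pd.read_csv(path, sep="\t")

    def _numeric(label: str) -> bool:
        try:
            float(label)
            return True
        except ValueError:
            return False

    if any(_numeric(str(c)) for c in df.columns):
        raise ValueError(f"{path}: TSV recording must have a header row of channel labels")
    return Recording(
        data=df.to_numpy().T,
        fs_hz=fs_hz,
        ch_names=[str(c) for c in df.columns],
        subject_id=path.stem,
    )


def _read_recording_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an optional extra
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        data=raw.get_data(),
        fs_hz=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        subject_id=path.stem,
    )


def read_recording(path: str | Path, fs_hz: float = NOMINAL_FS_HZ) -> Recording:
    """Read a recording from TSV (canonical) or EDF (input only).

    ``fs_hz`` applies to TSV input, which carries no rate; EDF carries its
    own.  A rate other than the 250 Hz this pipeline is parameterized for is
    accepted with a warning — no implicit resampling is performed.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt"):
        rec = _read_recording_tsv(path, fs_hz)
    elif suffix == ".edf":
        rec = _read_recording_edf(path)
    else:
        raise ValueError(f"unknown recording format {suffix!r} (expected .tsv or .edf)")
    if rec.fs_hz != NOMINAL_FS_HZ:
        warnings.warn(
            f"{path.name}: sampling rate {rec.fs_hz} Hz differs from the nominal "
            f"{NOMINAL_FS_HZ} Hz; no resampling is applied",
            stacklevel=2,
        )
    return rec


def read_pac_maps(path: str | Path, spec) -> list:
    """Re-read a pac_map.tsv result table into per-recording PacMap objects.

    ``spec`` is the :class:`~pacpipe.filterbank.FilterBankSpec` the maps were
    computed with (the TSV stores only analyzable cells).  Values round-trip
    exactly at the 10-significant-digit TSV precision.
    """
    from .metrics import PacMap

    df = pd.read_csv(path, sep="\t")
    maps = []
    for sid, sub in df.groupby("subject_id", sort=False):
        ch_names = list(dict.fromkeys(sub["channel"]))
        shape = (len(ch_names), len(spec.lf_centers), len(spec.hf_centers))
        arrays = {
            k: np.full(shape, np.nan)
            for k in ("mi_raw", "surr_mean", "surr_sd", "mi_norm", "phase_max_deg")
        }
        tie = np.zeros(shape, dtype=bool)
        for row in sub.itertuples():
            c = ch_names.index(row.channel)
            i, j = spec.lf_index(row.lf_hz), spec.hf_index(row.hf_hz)
            for k in arrays:
                arrays[k][c, i, j] = getattr(row, k)
            tie[c, i, j] = bool(row.tie_flag)
        age = sub["age_months"].iloc[0]
        maps.append(
            PacMap(
                subject_id=str(sid),
                age_months=None if pd.isna(age) else float(age),
                ch_names=ch_names,
                spec=spec,
                tie_flag=tie,
                **arrays,
            )
        )
    return maps


def write_manifest(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Cohort manifest: subject_id, age_months, path (tab-separated).

    Paths are resolved relative to the manifest's directory; missing files
    and duplicate (subject_id, path) rows are rejected, off-schedule ages
    warned about.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "age_months", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    df = df.copy()
    df["path"] = [
        str(p) if Path(p).is_absolute() else str(path.parent / p) for p in df["path"]
    ]
    if df.duplicated(subset=["subject_id", "path"]).any():
        raise ValueError("manifest has duplicate (subject_id, path) rows")
    unresolved = [p for p in df["path"] if not Path(p).exists()]
    if unresolved:
        raise FileNotFoundError(f"manifest paths not found: {unresolved}")
    if (df["age_months"] <= 0).any():
        raise ValueError("ages must be positive")
    off = sorted(set(df["age_months"]) - set(COLLECTION_AGES_MONTHS))
    if off:
        warnings.warn(
            f"ages {off} are not standard collection time points "
            f"{COLLECTION_AGES_MONTHS}", stacklevel=2,
        )
    return df
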