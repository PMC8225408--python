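"""Phase-amplitude distributions, modulation index, surrogates, and phase max.

The coupling statistic is the Kullback-Leibler modulation index: the
high-frequency amplitude is averaged within 18 bins of 20 degrees of
low-frequency phase, the binned means are normalized to a probability
distribution P, and

    MI = (log N - H(P)) / log N,        N = 18,

so MI is 0 for a uniform distribution and 1 when all amplitude concentrates
in a single bin.  Because MI is biased by power and noise, 200 surrogate MI
values are computed after circularly time-shifting the amplitude series
relative to the phase series (independent uniform shift of 0.1-1.9 s per
segment per surrogate), and the observed MI is expressed as a z-score
against that surrogate distribution (MI_norm).  Phase max is the center of
the phase bin holding the largest mean amplitude — the coupling's preferred
phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filterbank import FilterBankSpec, complex_bandpass, kernel_half_length
from .recording import SegmentedRecording

__all__ = [
    "N_BINS",
    "BIN_EDGES_DEG",
    "BIN_CENTERS_DEG",
    "PhaseAmpDistribution",
    "PacCell",
    "PacMap",
    "bin_amplitude_by_phase",
    "average_distributions",
    "modulation_index",
    "surrogate_mi",
    "normalize_mi",
    "phase_max",
    "compute_pac_map",
]

N_BINS = 18
BIN_WIDTH_DEG = 360.0 / N_BINS
BIN_EDGES_DEG = -180.0 + BIN_WIDTH_DEG * np.arange(N_BINS + 1)
BIN_CENTERS_DEG = BIN_EDGES_DEG[:-1] + BIN_WIDTH_DEG / 2

N_SURROGATES_DEFAULT = 200
SHIFT_RANGE_S_DEFAULT = (0.1, 1.9)


@dataclass
class PhaseAmpDistribution:
    """Mean high-frequency amplitude in each of 18 low-frequency phase bins.

    ``mean_amp`` is NaN for bins that received no samples (flagged missing
    and resolved when averaging across segments).
    """

    mean_amp: np.ndarray
    n_segments_averaged: int = 1

    def __post_init__(self) -> None:
        self.mean_amp = np.asarray(self.mean_amp, dtype=float)
        if self.mean_amp.shape != (N_BINS,):
            raise ValueError(f"mean_amp must have exactly {N_BINS} values")
        finite = self.mean_amp[np.isfinite(self.mean_amp)]
        if finite.size and (finite < 0).any():
            raise ValueError("mean amplitudes must be non-negative")

    @property
    def missing_bins(self) -> np.ndarray:
        return ~np.isfinite(self.mean_amp)


def phase_bin_indices(phase_deg: np.ndarray) -> np.ndarray:
    """Bin index (0..17) of each phase sample; phases wrapped to [-180, 180)."""
    wrapped = (np.asarray(phase_deg, dtype=float) + 180.0) % 360.0 - 180.0
    return np.clip(((wrapped + 180.0) // BIN_WIDTH_DEG).astype(int), 0, N_BINS - 1)


def bin_amplitude_by_phase(phase_deg: np.ndarray, amp: np.ndarray) -> PhaseAmpDistribution:
    """Mean amplitude per 20-degree phase bin for one segment."""
    phase_deg = np.asarray(phase_deg, dtype=float).ravel()
    amp = np.asarray(amp, dtype=float).ravel()
    if phase_deg.shape != amp.shape:
        raise ValueError("phase and amplitude series must have equal length")
    if phase_deg.size == 0:
        raise ValueError("cannot bin an empty series")
    idx = phase_bin_indices(phase_deg)
    sums = np.bincount(idx, weights=amp, minlength=N_BINS)
    counts = np.bincount(idx, minlength=N_BINS)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PhaseAmpDistribution(mean_amp=means, n_segments_averaged=1)


def average_distributions(dists: list[PhaseAmpDistribution]) -> PhaseAmpDistribution:
    """Per-bin mean over segments, ignoring bins missing in a segment.

    Raises if a bin is missing in every segment (it would leave the averaged
    distribution undefined there).
    """
    if not dists:
        raise ValueError("need at least one distribution")
    stacked = np.vstack([d.mean_amp for d in dists])
    all_missing = ~np.isfinite(stacked).any(axis=0)
    if all_missing.any():
        bins = BIN_CENTERS_DEG[all_missing]
        raise ValueError(f"phase bins centered at {bins} deg are empty in every segment")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stacked, axis=0)
    return PhaseAmpDistribution(mean_amp=mean, n_segments_averaged=len(dists))


def modulation_index(dist: PhaseAmpDistribution | np.ndarray) -> float:
    """Kullback-Leibler modulation index, normalized to [0, 1].

    ``MI = sum_b P(b) log(N P(b)) / log N`` with ``P`` the binned mean
    amplitudes normalized to unit sum and the convention ``0 log 0 = 0``.
    """
    amp = dist.mean_amp if isinstance(dist, PhaseAmpDistribution) else np.asarray(dist, float)
    if not np.isfinite(amp).all():
        raise ValueError("modulation index requires all phase bins to be present")
    total = amp.sum()
    if total <= 0:
        raise ValueError("total amplitude is zero; distribution undefined")
    p = amp / total
    nz = p > 0
    entropy = float(-(p[nz] * np.log(p[nz])).sum())
    return float((np.log(N_BINS) - entropy) / np.log(N_BINS))


def phase_max(dist: PhaseAmpDistribution) -> tuple[float, bool]:
    """Bin center (degrees) of the maximal mean amplitude.

    Ties are broken toward the smallest bin center; the second return value
    flags whether a tie occurred.
    """
    amp = dist.mean_amp
    if not np.isfinite(amp).all():
        raise ValueError("phase max requires all phase bins to be present")
    best = int(np.argmax(amp))  # argmax takes the first = smallest center
    tie = bool(np.sum(amp == amp[best]) > 1)
    return float(BIN_CENTERS_DEG[best]), tie


def normalize_mi(mi_raw: float, surrogates: np.ndarray) -> tuple[float, float, float]:
    """z-score the observed MI against the surrogate distribution.

    Returns ``(surr_mean, surr_sd, mi_norm)`` with the sample (n-1) SD.
    """
    surr = np.asarray(surrogates, dtype=float)
    if surr.size < 2:
        raise ValueError("need at least 2 surrogate values")
    mean = float(surr.mean())
    sd = float(surr.std(ddof=1))
    if sd == 0:
        raise ValueError("surrogate distribution has zero spread; z-score undefined")
    return mean, sd, float((mi_raw - mean) / sd)


def _shift_bounds(shift_range_s: tuple[float, float], fs_hz: float, n_samples: int
                  ) -> tuple[int, int]:
    lo = int(round(shift_range_s[0] * fs_hz))
    hi = int(round(shift_range_s[1] * fs_hz))
    if not 0 < lo <= hi < n_samples:
        raise ValueError(
            f"shift range {shift_range_s} s is invalid for segments of "
            f"{n_samples / fs_hz:.2f} s"
        )
    return lo, hi


def surrogate_mi(
    phase_deg: np.ndarray,
    amp: np.ndarray,
    fs_hz: float,
    n_surr: int = N_SURROGATES_DEFAULT,
    shift_range_s: tuple[float, float] = SHIFT_RANGE_S_DEFAULT,
    seed: int | np.random.Generator | None = None,
    edge_trim: int = 0,
) -> np.ndarray:
    """Surrogate modulation indices from circular amplitude time-shifts.

    ``phase_deg`` and ``amp`` are (n_segments, n_samples) stacks.  For each
    surrogate, every segment's amplitude series is circularly shifted (over
    the full segment) by an independent uniform draw from ``shift_range_s``;
    binning, cross-segment averaging, and MI then proceed exactly as for the
    real data.  The shift preserves each segment's amplitude marginal while
    destroying its alignment with phase.  ``edge_trim`` samples at each
    segment end are excluded from the binned statistic, mirroring the
    real-data computation (filter edge transients live there).
    """
    phase_deg = np.atleast_2d(phase_deg)
    amp = np.atleast_2d(amp)
    if phase_deg.shape != amp.shape:
        raise ValueError("phase and amplitude stacks must share a shape")
    n_seg, n = phase_deg.shape
    lo, hi = _shift_bounds(shift_range_s, fs_hz, n)
    if edge_trim < 0 or 2 * edge_trim >= n:
        raise ValueError("edge_trim must leave a nonempty central span")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shifts = rng.integers(lo, hi + 1, size=(n_surr, n_seg))

    core = slice(edge_trim, n - edge_trim)
    bin_idx = phase_bin_indices(phase_deg[:, core])  # the phase series is not shifted
    counts = np.stack([np.bincount(bin_idx[s], minlength=N_BINS) for s in range(n_seg)])
    if (counts == 0).any():
        return _surrogate_mi_slow(bin_idx, amp, shifts, core)

    onehot = [
        (bin_idx[s][np.newaxis, :] == np.arange(N_BINS)[:, np.newaxis]).astype(float)
        for s in range(n_seg)
    ]
    acc = np.zeros((n_surr, N_BINS))
    cols = np.arange(n)[core]
    for s in range(n_seg):
        gathered = amp[s][(cols[np.newaxis, :] - shifts[:, s, np.newaxis]) % n]
        acc += (gathered @ onehot[s].T) / counts[s]
    dist = acc / n_seg

    p = dist / dist.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = -plogp.sum(axis=1)
    return (np.log(N_BINS) - entropy) / np.log(N_BINS)


def _surrogate_mi_slow(bin_idx: np.ndarray, amp: np.ndarray, shifts: np.ndarray,
                       core: slice) -> np.ndarray:
    """Fallback handling empty bins segment by segment (rare: only when a
    segment covers less than one full low-frequency cycle)."""
    n_surr, n_seg = shifts.shape
    out = np.empty(n_surr)
    for k in range(n_surr):
        dists = []
        for s in range(n_seg):
            rolled = np.roll(amp[s], shifts[k, s])[core]
            sums = np.bincount(bin_idx[s], weights=rolled, minlength=N_BINS)
            counts = np.bincount(bin_idx[s], minlength=N_BINS)
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
            dists.append(PhaseAmpDistribution(mean_amp=means))
        out[k] = modulation_index(average_distributions(dists))
    return out


@dataclass
class PacCell:
    """PAC summary for one channel and one frequency pair."""

    channel: str
    lf_hz: float
    hf_hz: float
    mi_raw: float
    surr_mean: float
    surr_sd: float
    mi_norm: float
    phase_max_deg: float
    tie_flag: bool


@dataclass
class PacMap:
    """Per-recording grid of PAC metrics over channels x valid frequency pairs.

    Arrays have shape (n_channels, n_lf, n_hf) and are NaN at invalid pairs;
    :meth:`to_frame` lists one row per analyzable cell.
    """

    subject_id: str
    age_months: float | None
    ch_names: list[str]
    spec: FilterBankSpec
    mi_raw: np.ndarray
    surr_mean: np.ndarray
    surr_sd: np.ndarray
    mi_norm: np.ndarray
    phase_max_deg: np.ndarray
    tie_flag: np.ndarray

    def cell(self, channel: str, lf_hz: float, hf_hz: float) -> PacCell:
        c = self.ch_names.index(channel)
        i, j = self.spec.lf_index(lf_hz), self.spec.hf_index(hf_hz)
        if not self.spec.valid_pair_mask[i, j]:
            raise KeyError(f"pair ({lf_hz}, {hf_hz}) is not analyzable")
        return PacCell(
            channel=channel,
            lf_hz=lf_hz,
            hf_hz=hf_hz,
            mi_raw=float(self.mi_raw[c, i, j]),
            surr_mean=float(self.surr_mean[c, i, j]),
            surr_sd=float(self.surr_sd[c, i, j]),
            mi_norm=float(self.mi_norm[c, i, j]),
            phase_max_deg=float(self.phase_max_deg[c, i, j]),
            tie_flag=bool(self.tie_flag[c, i, j]),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c, ch in enumerate(self.ch_names):
            for i, lf in enumerate(self.spec.lf_centers):
                for j, hf in enumerate(self.spec.hf_centers):
                    if not self.spec.valid_pair_mask[i, j]:
                        continue
                    rows.append(
                        {
                            "subject_id": self.subject_id,
                            "age_months": self.age_months,
                            "channel": ch,
                            "lf_hz": lf,
                            "hf_hz": hf,
                            "mi_raw": self.mi_raw[c, i, j],
                            "surr_mean": self.surr_mean[c, i, j],
                            "surr_sd": self.surr_sd[c, i, j],
                            "mi_norm": self.mi_norm[c, i, j],
                            "phase_max_deg": self.phase_max_deg[c, i, j],
                            "tie_flag": bool(self.tie_flag[c, i, j]),
                        }
                    )
        return pd.DataFrame.from_records(rows)


def compute_pac_map(
    seg_rec: SegmentedRecording,
    spec: FilterBankSpec,
    n_surr: int = N_SURROGATES_DEFAULT,
    shift_range_s: tuple[float, float] = SHIFT_RANGE_S_DEFAULT,
    seed: int | None = None,
    edge_trim: int | None = None,
) -> PacMap:
    """Run the full per-recording PAC computation.

    For every channel and every valid frequency pair: extract phase and
    amplitude, bin amplitude by phase per segment, average across segments,
    compute MI_raw and phase max, then the surrogate distribution and
    MI_norm.  Deterministic for a fixed seed (one independent surrogate
    stream per channel x pair cell, in fixed order).

    ``edge_trim`` (samples per segment end) excludes the low-frequency
    filter's edge-transient span from the binned statistic; the default
    (None) uses the filter's half-kernel length.  Without it, segments whose
    boundary phase is not random (e.g., simulated carriers with an integer
    number of cycles per segment) acquire a spurious phase-amplitude
    association from the edge transients.
    """
    n_ch = seg_rec.n_channels
    if edge_trim is None:
        edge_trim = kernel_half_length(spec.lf_bandwidth, spec.fs_hz)
    n_in_seg = seg_rec.segments.shape[2]
    if 2 * edge_trim >= n_in_seg:
        raise ValueError(
            f"edge trim of {edge_trim} samples per end leaves no data in "
            f"{n_in_seg}-sample segments"
        )
    core = slice(edge_trim, n_in_seg - edge_trim)
    n_lf, n_hf = len(spec.lf_centers), len(spec.hf_centers)
    shape = (n_ch, n_lf, n_hf)
    nanfull = lambda: np.full(shape, np.nan)
    mi_raw_a, surr_mean_a, surr_sd_a = nanfull(), nanfull(), nanfull()
    mi_norm_a, phase_max_a = nanfull(), nanfull()
    tie_a = np.zeros(shape, dtype=bool)

    cell_seeds = iter(np.random.SeedSequence(seed).spawn(n_ch * n_lf * n_hf))
    for c in range(n_ch):
        x = seg_rec.segments[:, c, :]
        lf_cache = {
            i: complex_bandpass(x, lf, spec.lf_bandwidth, spec.fs_hz)
            for i, lf in enumerate(spec.lf_centers)
            if spec.valid_pair_mask[i].any()
        }
        hf_cache = {
            j: complex_bandpass(x, hf, spec.hf_bandwidth, spec.fs_hz)
            for j, hf in enumerate(spec.hf_centers)
            if spec.valid_pair_mask[:, j].any()
        }
        for i in range(n_lf):
            for j in range(n_hf):
                sseq = next(cell_seeds)
                if not spec.valid_pair_mask[i, j]:
                    continue
                phase = (np.rad2deg(np.angle(lf_cache[i])) + 180.0) % 360.0 - 180.0
                amp = np.abs(hf_cache[j])
                dists = [
                    bin_amplitude_by_phase(phase[s, core], amp[s, core])
                    for s in range(seg_rec.n_segments)
                ]
                dist = average_distributions(dists)
                mi = modulation_index(dist)
                pmax, tie = phase_max(dist)
                if n_surr > 0:
                    surr = surrogate_mi(
                        phase,
                        amp,
                        seg_rec.fs_hz,
                        n_surr=n_surr,
                        shift_range_s=shift_range_s,
                        seed=np.random.default_rng(sseq),
                        edge_trim=edge_trim,
                    )
                    s_mean, s_sd, z = normalize_mi(mi, surr)
                else:
                    s_mean = s_sd = z = np.nan
                mi_raw_a[c, i, j] = mi
                surr_mean_a[c, i, j] = s_mean
                surr_sd_a[c, i, j] = s_sd
                mi_norm_a[c, i, j] = z
                phase_max_a[c, i, j] = pmax
                tie_a[c, i, j] = tie
    return PacMap(
        subject_id=seg_rec.subject_id,
        age_months=seg_rec.age_months,
        ch_names=list(seg_rec.ch_names),
        spec=spec,
        mi_raw=mi_raw_a,
        surr_mean=surr_mean_a,
        surr_sd=surr_sd_a,
        mi_norm=mi_norm_a,
        phase_max_deg=phase_max_a,
        tie_flag=tie_a,
    )
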