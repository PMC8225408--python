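"""Segmentation, joint-probability artifact rejection, and segment selection.

Continuous recordings are cut into non-overlapping 2-s windows, improbable
(segment, electrode) combinations are rejected with a 3-SD rule along two
dimensions (an electrode's activity relative to its own activity in all other
segments, and relative to the other electrodes within the same segment), and
exactly 30 windows are then drawn at random for the coupling analysis.
Recordings that cannot supply 30 clean windows are excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .recording import Recording, SegmentedRecording

__all__ = [
    "InsufficientDataError",
    "segment_recording",
    "joint_probability_reject",
    "select_segments",
]

#: Default number of segments retained per recording (60 s of data at 2 s each).
N_SEGMENTS_DEFAULT = 30


class InsufficientDataError(RuntimeError):
    """Raised when a recording cannot supply the required number of segments."""


def segment_recording(rec: Recording, segment_len_s: float = 2.0) -> SegmentedRecording:
    """Cut a recording into consecutive non-overlapping windows.

    A trailing partial window is discarded (the bandpass filters require full
    windows).  Raises ``ValueError`` for recordings shorter than one window.
    """
    n_per_seg = int(round(segment_len_s * rec.fs_hz))
    n_segments = rec.n_samples // n_per_seg
    if n_segments < 1:
        raise ValueError(
            f"recording of {rec.duration_s:.2f} s is shorter than one "
            f"{segment_len_s} s window"
        )
    usable = rec.data[:, : n_segments * n_per_seg]
    segs = usable.reshape(rec.n_channels, n_segments, n_per_seg).transpose(1, 0, 2)
    return SegmentedRecording(
        segments=segs.copy(),
        fs_hz=rec.fs_hz,
        ch_names=list(rec.ch_names),
        segment_len_s=segment_len_s,
        subject_id=rec.subject_id,
        age_months=rec.age_months,
    )


def _kde_score(samples: np.ndarray, reference: np.ndarray, max_ref: int = 2000,
               max_eval: int = 500, trim: float = 0.02) -> float:
    """Improbability of ``samples`` under a Gaussian KDE of ``reference``:
    the trimmed mean of the per-sample negative log-likelihood.

    Symmetric 2% trimming keeps single extreme samples from dominating the
    segment score, which would otherwise skew the score distribution and
    inflate the 3-SD rejection tail on clean data.  Deterministic strided
    subsampling of the reference keeps the estimate tractable.
    """
    ref = reference[:: max(1, len(reference) // max_ref)]
    ev = samples[:: max(1, len(samples) // max_eval)]
    if ref.std() == 0:  # degenerate flat reference
        return 0.0
    kde = gaussian_kde(ref)
    ll = -np.log(np.clip(kde(ev), 1e-300, None))
    k = int(len(ll) * trim)
    if k:
        ll = np.sort(ll)[k:-k]
    return float(np.mean(ll))


def _zscore(scores: np.ndarray, axis: int) -> np.ndarray:
    mu = scores.mean(axis=axis, keepdims=True)
    sd = scores.std(axis=axis, ddof=1, keepdims=True)
    sd = np.where(sd == 0, np.inf, sd)
    return (scores - mu) / sd


def joint_probability_reject(
    seg: SegmentedRecording, sd_threshold: float = 3.0
) -> tuple[SegmentedRecording, pd.DataFrame]:
    """Reject segments whose per-electrode activity is improbable.

    For each (segment, electrode) an improbability score — the negative mean
    log-likelihood of the electrode's samples under a kernel density estimate
    of a reference distribution — is computed along two dimensions:

    * *across*: reference = that electrode's samples pooled over all segments;
      scores z-scored across segments for each electrode.
    * *within*: reference = all electrodes' samples within the same segment;
      scores z-scored across electrodes for each segment (skipped when the
      recording has fewer than 3 electrodes).

    A segment is removed when any electrode's |z| exceeds ``sd_threshold`` in
    either dimension.  Returns the surviving segments and a per-(segment,
    electrode) rejection log.
    """
    if seg.n_segments < 2:
        raise ValueError("joint-probability rejection needs at least 2 segments")
    n_seg, n_ch, _ = seg.segments.shape

    across = np.zeros((n_seg, n_ch))
    for c in range(n_ch):
        pooled = seg.segments[:, c, :].ravel()
        for s in range(n_seg):
            across[s, c] = _kde_score(seg.segments[s, c, :], pooled)
    z_across = _zscore(across, axis=0)

    if n_ch >= 3:
        within = np.zeros((n_seg, n_ch))
        for s in range(n_seg):
            pooled = seg.segments[s].ravel()
            for c in range(n_ch):
                within[s, c] = _kde_score(seg.segments[s, c, :], pooled)
        z_within = _zscore(within, axis=1)
    else:
        z_within = np.zeros((n_seg, n_ch))

    exceed = (np.abs(z_across) > sd_threshold) | (np.abs(z_within) > sd_threshold)
    rejected_segments = exceed.any(axis=1)

    records = []
    for s in range(n_seg):
        for c in range(n_ch):
            records.append(
                {
                    "subject_id": seg.subject_id,
                    "segment_index": int(seg.segment_indices[s]),
                    "channel": seg.ch_names[c],
                    "z_across": z_across[s, c],
                    "z_within": z_within[s, c],
                    "max_z": max(abs(z_across[s, c]), abs(z_within[s, c])),
                    "rejected": bool(rejected_segments[s]),
                }
            )
    log = pd.DataFrame.from_records(records)

    keep = ~rejected_segments
    surviving = SegmentedRecording(
        segments=seg.segments[keep],
        fs_hz=seg.fs_hz,
        ch_names=list(seg.ch_names),
        segment_len_s=seg.segment_len_s,
        subject_id=seg.subject_id,
        age_months=seg.age_months,
        segment_indices=seg.segment_indices[keep],
    )
    return surviving, log


def select_segments(
    seg: SegmentedRecording,
    n: int = N_SEGMENTS_DEFAULT,
    seed: int | np.random.Generator | None = None,
) -> SegmentedRecording:
    """Randomly select exactly ``n`` segments (without replacement, original
    order preserved); raises ``InsufficientDataError`` when fewer are
    available, marking the recording as not analyzable."""
    if seg.n_segments < n:
        raise InsufficientDataError(
            f"{seg.subject_id}: only {seg.n_segments} segments available, "
            f"{n} required — recording not analyzed"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = np.sort(rng.choice(seg.n_segments, size=n, replace=False))
    return SegmentedRecording(
        segments=seg.segments[chosen],
        fs_hz=seg.fs_hz,
        ch_names=list(seg.ch_names),
        segment_len_s=seg.segment_len_s,
        subject_id=seg.subject_id,
        age_months=seg.age_months,
        segment_indices=seg.segment_indices[chosen],
    )
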