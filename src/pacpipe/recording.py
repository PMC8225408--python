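"""Core in-memory containers for multichannel EEG recordings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Standard 10-20 regional channel groupings used throughout the analysis.
ANTERIOR_CHANNELS = ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz")
POSTERIOR_CHANNELS = ("P3", "P4", "P7", "P8", "Pz", "O1", "O2")

#: Ages (months) at which cohort recordings are collected.
COLLECTION_AGES_MONTHS = (3, 6, 9, 12, 18, 24, 36)


@dataclass
class Recording:
    """One subject's multichannel EEG plus metadata.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Scalp potential time series, arbitrary units.
    fs_hz : float
        Sampling rate in Hz (250 Hz nominal for this pipeline).
    ch_names : list of str
        10-20 channel labels, one per row of ``data``.
    subject_id : str
        Identifier carried through to all result tables.
    age_months : float or None
        Age at recording, in months.
    """

    data: np.ndarray
    fs_hz: float
    ch_names: list[str]
    subject_id: str = "sub-00"
    age_months: float | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.ch_names)} channel labels"
            )
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class SegmentedRecording:
    """A recording cut into equal-length analysis windows.

    ``segments`` has shape (n_segments, n_channels, n_samples_per_segment);
    channel order is identical across segments.
    """

    segments: np.ndarray
    fs_hz: float
    ch_names: list[str]
    segment_len_s: float = 2.0
    subject_id: str = "sub-00"
    age_months: float | None = None
    segment_indices: np.ndarray = field(default=None)  # original window indices

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float)
        if self.segments.ndim != 3:
            raise ValueError("segments must be (n_segments, n_channels, n_samples)")
        expected = int(round(self.segment_len_s * self.fs_hz))
        if self.segments.shape[2] != expected:
            raise ValueError(
                f"segments have {self.segments.shape[2]} samples, "
                f"expected {expected} for {self.segment_len_s} s at {self.fs_hz} Hz"
            )
        if self.segments.shape[1] != len(self.ch_names):
            raise ValueError("channel label count does not match segment channel axis")
        if self.segment_indices is None:
            self.segment_indices = np.arange(self.segments.shape[0])
        else:
            self.segment_indices = np.asarray(self.segment_indices, dtype=int)

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def n_channels(self) -> int:
        return self.segments.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None
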