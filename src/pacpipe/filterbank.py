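"""Zero-phase complex filter bank for phase and amplitude extraction.

Each band is realized as a pair of finite-impulse-response kernels — a cosine
carrier and a sine carrier under a common Blackman window — applied by
symmetric convolution with reflection padding.  The cosine kernel is even
(zero phase); the sine kernel is odd (a pure 90-degree shift); together they
yield a complex band-limited signal whose argument is the instantaneous phase
(0 degrees at the waveform peak, increasing with time) and whose modulus is
the instantaneous amplitude.  Window length is set by the band's width
(~1.65/bandwidth seconds), and frequency pairs whose magnitude responses
overlap are excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import SegmentedRecording

__all__ = [
    "FilterBankSpec",
    "build_filterbank",
    "complex_bandpass",
    "valid_pair",
    "filter_support",
    "extract_phase_amp",
]

#: Fraction of peak magnitude response defining a filter's support
#: (~-26 dB); pairs with overlapping supports are not analyzed.
SUPPORT_THRESHOLD = 0.05

#: Kernel duration in seconds is this constant divided by the bandwidth in Hz.
KERNEL_DURATION_FACTOR = 1.65


def design_kernel(center_hz: float, bandwidth_hz: float, fs_hz: float) -> np.ndarray:
    """Complex FIR kernel: Blackman-windowed ``exp(2j pi f t)`` carrier,
    odd-length, normalized to unit amplitude gain for an in-band cosine."""
    if bandwidth_hz <= 0 or center_hz <= 0:
        raise ValueError("center and bandwidth must be positive")
    if center_hz + bandwidth_hz / 2 >= fs_hz / 2:
        raise ValueError(
            f"band {center_hz}+/-{bandwidth_hz / 2} Hz exceeds Nyquist {fs_hz / 2} Hz"
        )
    n_taps = int(round(KERNEL_DURATION_FACTOR / bandwidth_hz * fs_hz))
    if n_taps % 2 == 0:
        n_taps += 1
    t = (np.arange(n_taps) - n_taps // 2) / fs_hz
    window = np.blackman(n_taps)
    kernel = window * np.exp(2j * np.pi * center_hz * t)
    # unit cosine at center frequency -> unit-modulus complex output
    return kernel * (2.0 / window.sum())


def kernel_half_length(bandwidth_hz: float, fs_hz: float) -> int:
    """Half-length (samples) of the kernel for a band of the given width;
    the span at each segment end where the output carries edge transients."""
    n_taps = int(round(KERNEL_DURATION_FACTOR / bandwidth_hz * fs_hz))
    if n_taps % 2 == 0:
        n_taps += 1
    return n_taps // 2


def magnitude_response(kernel: np.ndarray, fs_hz: float, freqs: np.ndarray) -> np.ndarray:
    """Magnitude response of a (centered) kernel on an arbitrary frequency grid."""
    t = (np.arange(len(kernel)) - len(kernel) // 2) / fs_hz
    return np.abs(np.exp(-2j * np.pi * np.outer(freqs, t)) @ kernel)


def filter_support(
    center_hz: float,
    bandwidth_hz: float,
    fs_hz: float,
    threshold: float = SUPPORT_THRESHOLD,
    grid_hz: float = 0.05,
) -> tuple[float, float]:
    """Frequency interval where the magnitude response is at least
    ``threshold`` of its peak, evaluated on a fine grid up to Nyquist."""
    kernel = design_kernel(center_hz, bandwidth_hz, fs_hz)
    freqs = np.arange(0.0, fs_hz / 2 + grid_hz, grid_hz)
    resp = magnitude_response(kernel, fs_hz, freqs)
    above = freqs[resp >= threshold * resp.max()]
    return float(above.min()), float(above.max())


@dataclass
class FilterBankSpec:
    """Low/high-frequency band grid and the mask of analyzable pairs.

    Defaults follow the comodulogram grid used for the developmental EEG
    analysis: low-frequency centers 2-20 Hz in 2-Hz steps (2-Hz bandwidth),
    high-frequency centers 40-100 Hz in 4-Hz steps (20-Hz bandwidth).
    """

    fs_hz: float = 250.0
    lf_centers: np.ndarray = field(default_factory=lambda: np.arange(2.0, 20.0 + 1e-9, 2.0))
    lf_bandwidth: float = 2.0
    hf_centers: np.ndarray = field(default_factory=lambda: np.arange(40.0, 100.0 + 1e-9, 4.0))
    hf_bandwidth: float = 20.0
    support_threshold: float = SUPPORT_THRESHOLD
    valid_pair_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.lf_centers = np.asarray(self.lf_centers, dtype=float)
        self.hf_centers = np.asarray(self.hf_centers, dtype=float)
        if self.valid_pair_mask is None:
            lf_sup = [
                filter_support(c, self.lf_bandwidth, self.fs_hz, self.support_threshold)
                for c in self.lf_centers
            ]
            hf_sup = [
                filter_support(c, self.hf_bandwidth, self.fs_hz, self.support_threshold)
                for c in self.hf_centers
            ]
            mask = np.zeros((len(self.lf_centers), len(self.hf_centers)), dtype=bool)
            for i, (lo_l, hi_l) in enumerate(lf_sup):
                for j, (lo_h, hi_h) in enumerate(hf_sup):
                    mask[i, j] = hi_l < lo_h or hi_h < lo_l
            self.valid_pair_mask = mask
        else:
            self.valid_pair_mask = np.asarray(self.valid_pair_mask, dtype=bool)
            if self.valid_pair_mask.shape != (len(self.lf_centers), len(self.hf_centers)):
                raise ValueError("valid_pair_mask shape does not match center grids")

    @property
    def n_pairs(self) -> int:
        return self.valid_pair_mask.size

    def lf_index(self, lf_hz: float) -> int:
        idx = np.flatnonzero(np.isclose(self.lf_centers, lf_hz))
        if len(idx) == 0:
            raise KeyError(f"{lf_hz} Hz is not a low-frequency center of this bank")
        return int(idx[0])

    def hf_index(self, hf_hz: float) -> int:
        idx = np.flatnonzero(np.isclose(self.hf_centers, hf_hz))
        if len(idx) == 0:
            raise KeyError(f"{hf_hz} Hz is not a high-frequency center of this bank")
        return int(idx[0])

    def mask_frame(self):
        """valid_pair_mask as a pandas DataFrame (rows LF, columns HF)."""
        import pandas as pd

        return pd.DataFrame(
            self.valid_pair_mask.astype(int),
            index=self.lf_centers,
            columns=self.hf_centers,
        )


def build_filterbank(
    fs_hz: float = 250.0,
    lf_centers=None,
    lf_bandwidth: float = 2.0,
    hf_centers=None,
    hf_bandwidth: float = 20.0,
    support_threshold: float = SUPPORT_THRESHOLD,
) -> FilterBankSpec:
    """Construct a :class:`FilterBankSpec`, validating the Nyquist margin."""
    kwargs = {}
    if lf_centers is not None:
        kwargs["lf_centers"] = np.atleast_1d(np.asarray(lf_centers, dtype=float))
    if hf_centers is not None:
        kwargs["hf_centers"] = np.atleast_1d(np.asarray(hf_centers, dtype=float))
    spec = FilterBankSpec(
        fs_hz=fs_hz,
        lf_bandwidth=lf_bandwidth,
        hf_bandwidth=hf_bandwidth,
        support_threshold=support_threshold,
        **kwargs,
    )
    top = spec.hf_centers.max() + hf_bandwidth / 2
    if fs_hz / 2 <= top:
        raise ValueError(
            f"Nyquist {fs_hz / 2} Hz does not clear the highest band edge {top} Hz"
        )
    return spec


def valid_pair(lf_hz: float, hf_hz: float, spec: FilterBankSpec) -> bool:
    """True iff the two filters' magnitude-response supports are disjoint."""
    return bool(spec.valid_pair_mask[spec.lf_index(lf_hz), spec.hf_index(hf_hz)])


def complex_bandpass(
    segment: np.ndarray, center_hz: float, bandwidth_hz: float, fs_hz: float
) -> np.ndarray:
    """Filter real segment(s) into a complex band-limited signal.

    Accepts a 1-D segment or a stack with time on the last axis; output has
    the same shape.  Reflection padding at the edges, symmetric (zero-delay)
    convolution: for a pure in-band sinusoid the output argument tracks the
    input phase with no distortion.
    """
    kernel = design_kernel(center_hz, bandwidth_hz, fs_hz)
    half = len(kernel) // 2
    x = np.asarray(segment, dtype=float)
    if x.shape[-1] < len(kernel):
        raise ValueError(
            f"segment of {x.shape[-1]} samples is shorter than the "
            f"{len(kernel)}-tap kernel for {center_hz}+/-{bandwidth_hz / 2} Hz"
        )
    padded = np.concatenate(
        [x[..., 1 : half + 1][..., ::-1], x, x[..., -half - 1 : -1][..., ::-1]], axis=-1
    )
    flat = padded.reshape(-1, padded.shape[-1])
    out = np.empty((flat.shape[0], x.shape[-1]), dtype=complex)
    for i, row in enumerate(flat):
        out[i] = np.convolve(row, kernel, mode="valid")
    return out.reshape(*x.shape[:-1], x.shape[-1]) if x.ndim > 1 else out[0]


def extract_phase_amp(
    seg_rec: SegmentedRecording,
    channel: str,
    pair: tuple[float, float],
    spec: FilterBankSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment low-frequency phase (degrees in [-180, 180)) and
    high-frequency amplitude for one channel and one valid frequency pair.

    Returns two arrays of shape (n_segments, n_samples_per_segment).
    """
    lf_hz, hf_hz = pair
    if not valid_pair(lf_hz, hf_hz, spec):
        raise ValueError(
            f"pair ({lf_hz}, {hf_hz}) Hz has overlapping filter responses and "
            "is not analyzable"
        )
    ci = seg_rec.channel_index(channel)
    x = seg_rec.segments[:, ci, :]
    lf = complex_bandpass(x, lf_hz, spec.lf_bandwidth, spec.fs_hz)
    hf = complex_bandpass(x, hf_hz, spec.hf_bandwidth, spec.fs_hz)
    phase_deg = (np.rad2deg(np.angle(lf)) + 180.0) % 360.0 - 180.0
    return phase_deg, np.abs(hf)
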