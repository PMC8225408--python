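"""Synthetic coupled-oscillation signals, pink noise, and multi-subject cohorts.

The generators emulate the statistical structure the downstream analysis
assumes: a low-frequency (alpha-beta range) oscillation whose phase modulates
the amplitude of a gamma-band oscillation, riding on 1/f background noise.
Cohorts carry a regional phase preference (anterior vs posterior channels) and
a coupling depth that increases linearly with age, so every stage of the
pipeline — segment QC, filtering, modulation index, cluster inference, age
trends — can be validated end to end without any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import (
    ANTERIOR_CHANNELS,
    COLLECTION_AGES_MONTHS,
    POSTERIOR_CHANNELS,
    Recording,
)

__all__ = [
    "SimSignalParams",
    "CohortSpec",
    "pink_noise",
    "simulate_coupled_signal",
    "simulate_cohort",
]


def pink_noise(
    n_samples: int,
    fs_hz: float = 250.0,
    scale: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Generate pink (1/f) noise by spectral synthesis.

    Gaussian white Fourier coefficients are shaped by ``f ** -0.5`` (so power
    goes as 1/f), inverse-transformed, and standardized to sample SD
    ``scale``.  Reproducible for a fixed seed; ``scale`` is a pure
    multiplier of the same realization.

    Parameters
    ----------
    n_samples : int
        Length of the series; 0 returns an empty array.
    fs_hz : float
        Sampling rate (sets the frequency axis of the 1/f shaping).
    scale : float
        Sample standard deviation of the output.
    seed : int, Generator, or None
        Randomness source.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be non-negative")
    if n_samples == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    coeffs = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** -0.5  # amplitude ~ f^-1/2 => PSD ~ 1/f
    x = np.fft.irfft(coeffs * shaping, n=n_samples)
    sd = x.std()
    if sd > 0:
        x = x / sd
    return scale * x


@dataclass
class SimSignalParams:
    """Parameters of a single phase-amplitude-coupled test signal.

    The signal is

        x(t) = cos(phi_lf(t)) + a_hf * (1 + m cos(phi_lf(t) - pref)) * cos(2 pi f_hf t) + noise

    with phi_lf(t) = 2 pi f_lf t, so the high-frequency envelope peaks exactly
    where the low-frequency phase equals ``phase_pref_deg`` (phase 0 deg at the
    LF waveform peak, increasing with time, wrapped to [-180, 180)).
    """

    lf_hz: float = 8.0
    hf_hz: float = 64.0
    phase_pref_deg: float = 0.0
    coupling_depth: float = 0.8
    duration_s: float = 60.0
    fs_hz: float = 250.0
    amp_ratio: float = 0.5  # HF carrier amplitude relative to the unit LF amplitude
    noise_scale: float = 1.0  # pink-noise SD relative to the unit LF amplitude
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.lf_hz < self.hf_hz < self.fs_hz / 2):
            raise ValueError(
                f"need 0 < lf ({self.lf_hz}) < hf ({self.hf_hz}) < Nyquist ({self.fs_hz / 2})"
            )
        if not 0 <= self.coupling_depth <= 1:
            raise ValueError("coupling_depth must be in [0, 1]")
        n = self.duration_s * self.fs_hz
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fs_hz must be a positive integer sample count")
        if not -180 <= self.phase_pref_deg < 180:
            self.phase_pref_deg = ((self.phase_pref_deg + 180) % 360) - 180
        if self.noise_scale < 0 or self.amp_ratio < 0:
            raise ValueError("noise_scale and amp_ratio must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_hz))


def simulate_coupled_signal(
    params: SimSignalParams,
    ch_name: str = "Cz",
    subject_id: str = "sim-00",
    age_months: float | None = None,
) -> Recording:
    """Build a single-channel recording with known phase-amplitude coupling.

    The analytic HF envelope is ``a_hf * (1 + m cos(phi - pref))``, maximal at
    LF phase equal to ``phase_pref_deg``; with ``coupling_depth`` 0 the
    envelope is constant and the true modulation index is 0.
    """
    p = params
    t = np.arange(p.n_samples) / p.fs_hz
    lf_phase = 2 * np.pi * p.lf_hz * t
    pref = np.deg2rad(p.phase_pref_deg)
    envelope = p.amp_ratio * (1.0 + p.coupling_depth * np.cos(lf_phase - pref))
    x = np.cos(lf_phase) + envelope * np.cos(2 * np.pi * p.hf_hz * t)
    if p.noise_scale > 0:
        x = x + pink_noise(p.n_samples, p.fs_hz, p.noise_scale, p.seed)
    return Recording(
        data=x[np.newaxis, :],
        fs_hz=p.fs_hz,
        ch_names=[ch_name],
        subject_id=subject_id,
        age_months=age_months,
    )


@dataclass
class CohortSpec:
    """A synthetic cross-sectional cohort with regional phase preference and
    an age-dependent coupling depth.

    Anterior channels couple at ``anterior_pref_deg`` and posterior channels
    at ``posterior_pref_deg``; coupling depth for a subject of age ``a``
    months is ``base_depth + depth_slope_per_month * (a - 3)`` (3 months being
    the youngest collection time point), validated to stay within [0, 1].
    Ages are assigned round-robin over the seven collection time points
    unless given explicitly.
    """

    n_subjects: int = 14
    ages_months: list[float] | None = None
    anterior_pref_deg: float = -110.0
    posterior_pref_deg: float = 70.0
    base_depth: float = 0.2
    depth_slope_per_month: float = 0.6 / 33.0  # depth 0.2 at 3 mo -> 0.8 at 36 mo
    channel_labels: list[str] = field(
        default_factory=lambda: list(ANTERIOR_CHANNELS) + list(POSTERIOR_CHANNELS)
    )
    lf_hz: float = 8.0
    hf_hz: float = 64.0
    duration_s: float = 70.0
    fs_hz: float = 250.0
    amp_ratio: float = 0.5
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.ages_months is None:
            self.ages_months = [
                COLLECTION_AGES_MONTHS[i % len(COLLECTION_AGES_MONTHS)]
                for i in range(self.n_subjects)
            ]
        if len(self.ages_months) != self.n_subjects:
            raise ValueError("ages_months length must equal n_subjects")
        bad = [a for a in self.ages_months if a not in COLLECTION_AGES_MONTHS]
        if bad:
            raise ValueError(f"ages must be drawn from {COLLECTION_AGES_MONTHS}; got {bad}")
        for a in self.ages_months:
            d = self.depth_at_age(a)
            if not 0 <= d <= 1:
                raise ValueError(f"coupling depth {d:.3f} at age {a} months is outside [0, 1]")
        known = set(ANTERIOR_CHANNELS) | set(POSTERIOR_CHANNELS)
        unknown = [c for c in self.channel_labels if c not in known]
        if unknown:
            raise ValueError(
                f"channels {unknown} belong to neither the anterior nor the posterior set"
            )

    def depth_at_age(self, age_months: float) -> float:
        return self.base_depth + self.depth_slope_per_month * (age_months - 3.0)

    def pref_for_channel(self, label: str) -> float:
        return (
            self.anterior_pref_deg
            if label in ANTERIOR_CHANNELS
            else self.posterior_pref_deg
        )


def simulate_cohort(spec: CohortSpec) -> list[Recording]:
    """Generate one multichannel recording per subject.

    Each channel carries an independently seeded coupled signal at the
    regional phase preference with the subject's age-dependent coupling
    depth; deterministic for a fixed ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)
    recordings: list[Recording] = []
    for i, (age, sseq) in enumerate(zip(spec.ages_months, subject_seeds)):
        depth = spec.depth_at_age(age)
        ch_seeds = sseq.spawn(len(spec.channel_labels))
        rows = []
        for label, cseq in zip(spec.channel_labels, ch_seeds):
            params = SimSignalParams(
                lf_hz=spec.lf_hz,
                hf_hz=spec.hf_hz,
                phase_pref_deg=spec.pref_for_channel(label),
                coupling_depth=depth,
                duration_s=spec.duration_s,
                fs_hz=spec.fs_hz,
                amp_ratio=spec.amp_ratio,
                noise_scale=spec.noise_scale,
            )
            t = np.arange(params.n_samples) / params.fs_hz
            lf_phase = 2 * np.pi * params.lf_hz * t
            env = params.amp_ratio * (
                1.0 + depth * np.cos(lf_phase - np.deg2rad(params.phase_pref_deg))
            )
            x = np.cos(lf_phase) + env * np.cos(2 * np.pi * params.hf_hz * t)
            if spec.noise_scale > 0:
                x = x + pink_noise(
                    params.n_samples,
                    spec.fs_hz,
                    spec.noise_scale,
                    np.random.default_rng(cseq),
                )
            rows.append(x)
        recordings.append(
            Recording(
                data=np.vstack(rows),
                fs_hz=spec.fs_hz,
                ch_names=list(spec.channel_labels),
                subject_id=f"sim-{i:03d}",
                age_months=float(age),
            )
        )
    return recordings
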