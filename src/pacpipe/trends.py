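"""Age associations of PAC metrics and regional circular summaries.

After PAC+ selection, each recording is summarized by (a) its mean MI_norm
over PAC+ cells, correlated with age (Pearson), and (b) the proportion of
its PAC+ cells whose phase max falls in each of the 18 phase bins,
correlated with age bin by bin with Bonferroni correction for 18 tests.
Regional variants restrict to the anterior or posterior 10-20 channel sets,
and preferred phases are aggregated with the circular mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import BIN_CENTERS_DEG, N_BINS, phase_bin_indices
from .recording import ANTERIOR_CHANNELS, POSTERIOR_CHANNELS
from .metrics import PacMap

__all__ = [
    "RegionSpec",
    "ANTERIOR_REGION",
    "POSTERIOR_REGION",
    "PhaseTrend",
    "mean_minorm_in_mask",
    "pearson_age_correlation",
    "phase_max_proportions",
    "phase_trend",
    "circular_mean_phase",
]


@dataclass(frozen=True)
class RegionSpec:
    """A named scalp region given by its 10-20 channel labels."""

    name: str
    channels: tuple[str, ...]


ANTERIOR_REGION = RegionSpec("anterior", ANTERIOR_CHANNELS)
POSTERIOR_REGION = RegionSpec("posterior", POSTERIOR_CHANNELS)


def _region_channel_indices(pac_map: PacMap, region: RegionSpec | None) -> np.ndarray:
    if region is None:
        return np.arange(len(pac_map.ch_names))
    idx = [i for i, ch in enumerate(pac_map.ch_names) if ch in region.channels]
    if not idx:
        raise ValueError(f"no channels of region {region.name!r} present in the recording")
    return np.asarray(idx)


def mean_minorm_in_mask(pac_map: PacMap, mask: np.ndarray) -> float:
    """Arithmetic mean of MI_norm over the masked (PAC+) cells."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pac_map.mi_norm.shape:
        raise ValueError("mask shape does not match the PAC map grid")
    if not mask.any():
        raise ValueError("mask selects no cells; mean MI_norm undefined")
    return float(pac_map.mi_norm[mask].mean())


def pearson_age_correlation(values: np.ndarray, ages_months: np.ndarray
                            ) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of per-recording scalars with age."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages_months, dtype=float)
    if len(values) != len(ages) or len(values) < 3:
        raise ValueError("need at least 3 aligned (value, age) pairs")
    if np.ptp(values) == 0 or np.ptp(ages) == 0:
        raise ValueError("correlation undefined for constant values or ages")
    r, p = stats.pearsonr(values, ages)
    return float(r), float(p)


def phase_max_proportions(
    pac_map: PacMap, mask: np.ndarray, region: RegionSpec | None = None
) -> np.ndarray:
    """Fraction of masked cells with phase max in each of the 18 bins.

    Restricted to the region's channels when one is given; the 18-vector
    sums to 1.  Raises when the region holds no masked cells for this
    recording (the proportion vector would be undefined).
    """
    mask = np.asarray(mask, dtype=bool)
    ch_idx = _region_channel_indices(pac_map, region)
    sub = mask[ch_idx]
    values = pac_map.phase_max_deg[ch_idx][sub]
    values = values[np.isfinite(values)]
    if values.size == 0:
        where = "" if region is None else f" in region {region.name!r}"
        raise ValueError(f"no PAC+ cells{where} for recording {pac_map.subject_id}")
    counts = np.bincount(phase_bin_indices(values), minlength=N_BINS)
    return counts / counts.sum()


@dataclass
class PhaseTrend:
    """Per-bin Pearson correlation of phase-max proportions with age."""

    bin_centers_deg: np.ndarray
    r_per_bin: np.ndarray
    p_per_bin: np.ndarray
    significant: np.ndarray  # Bonferroni-corrected over the 18 bins
    untestable: np.ndarray  # bins with constant proportions across recordings
    n_recordings: int
    alpha: float = 0.05

    def to_frame(self, region_name: str = "all") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": region_name,
                "bin_center_deg": self.bin_centers_deg,
                "r": self.r_per_bin,
                "p": self.p_per_bin,
                "significant": self.significant,
                "untestable": self.untestable,
            }
        )


def phase_trend(
    proportions: np.ndarray, ages_months: np.ndarray, alpha: float = 0.05
) -> PhaseTrend:
    """Correlate each bin's phase-max proportion with age across recordings.

    ``proportions`` is (n_recordings, 18).  Significance uses the Bonferroni
    threshold ``alpha / 18``; bins whose proportions are constant across
    recordings are flagged untestable instead.
    """
    props = np.atleast_2d(np.asarray(proportions, dtype=float))
    ages = np.asarray(ages_months, dtype=float)
    if props.shape[0] != len(ages) or props.shape[0] < 3:
        raise ValueError("need at least 3 recordings with aligned ages")
    if props.shape[1] != N_BINS:
        raise ValueError(f"proportions must have {N_BINS} bins")
    r = np.full(N_BINS, np.nan)
    p = np.full(N_BINS, np.nan)
    untestable = np.zeros(N_BINS, dtype=bool)
    for b in range(N_BINS):
        if np.ptp(props[:, b]) == 0:
            untestable[b] = True
            continue
        r[b], p[b] = stats.pearsonr(props[:, b], ages)
    significant = np.where(np.isfinite(p), p < alpha / N_BINS, False)
    return PhaseTrend(
        bin_centers_deg=BIN_CENTERS_DEG.copy(),
        r_per_bin=r,
        p_per_bin=p,
        significant=significant,
        untestable=untestable,
        n_recordings=props.shape[0],
        alpha=alpha,
    )


def circular_mean_phase(phases_deg: np.ndarray) -> tuple[float, float]:
    """Circular mean of phase angles in degrees.

    Returns ``(mean_deg, resultant_length)`` with the mean wrapped to
    [-180, 180).  Raises for an (anti)balanced configuration whose mean
    resultant vector vanishes (mean direction undefined).
    """
    phases = np.deg2rad(np.asarray(phases_deg, dtype=float).ravel())
    if phases.size == 0:
        raise ValueError("need at least one phase value")
    vec = np.exp(1j * phases).mean()
    resultant = float(np.abs(vec))
    if resultant < 1e-9:
        raise ValueError("antipodally balanced phases: circular mean undefined")
    mean_deg = (np.rad2deg(np.angle(vec)) + 180.0) % 360.0 - 180.0
    return float(mean_deg), resultant
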