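"""Cluster-based permutation identification of significant PAC (PAC+).

Resting EEG has no task/baseline contrast, so the surrogate mean modulation
index serves as the comparison condition: it keeps the signal's power and
noise characteristics while carrying no true coupling.  Per channel and
frequency pair, MI_raw is compared against the surrogate mean across
recordings with a paired t-test; supra-threshold cells are grouped into
4-connected clusters within each channel's comodulogram; cluster mass is the
sum of (t - t_crit) over the cluster; and a null distribution of cluster
masses is built by re-running the procedure after swapping MI_raw with the
surrogate mean in a random half of the recordings ("flip-half"), repeated
200 times.  Observed clusters at or above the null's 95th percentile are
retained as PAC+.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .filterbank import FilterBankSpec
from .metrics import PacMap

__all__ = [
    "GroupDataset",
    "TMap",
    "ClusterResult",
    "t_map",
    "threshold_mask",
    "label_clusters",
    "cluster_masses",
    "flip_half",
    "permutation_null",
    "pac_positive_mask",
    "cluster_analysis",
]

#: 4-connectivity structure: neighbors differ by one LF step or one HF step.
FOUR_CONNECTIVITY = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class GroupDataset:
    """PAC maps of all usable recordings, aligned with their ages."""

    pac_maps: list[PacMap]
    ages_months: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if not self.pac_maps:
            raise ValueError("group dataset needs at least one PAC map")
        first = self.pac_maps[0]
        for m in self.pac_maps[1:]:
            if m.ch_names != first.ch_names:
                raise ValueError("all PAC maps must share the same channel set")
            if not np.array_equal(m.spec.valid_pair_mask, first.spec.valid_pair_mask):
                raise ValueError("all PAC maps must share the same valid-pair grid")
        if self.ages_months is None:
            self.ages_months = np.array(
                [np.nan if m.age_months is None else m.age_months for m in self.pac_maps]
            )
        self.ages_months = np.asarray(self.ages_months, dtype=float)
        if len(self.ages_months) != len(self.pac_maps):
            raise ValueError("ages and PAC maps must be aligned")

    @property
    def n_recordings(self) -> int:
        return len(self.pac_maps)

    @property
    def spec(self) -> FilterBankSpec:
        return self.pac_maps[0].spec

    @property
    def ch_names(self) -> list[str]:
        return self.pac_maps[0].ch_names

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """(mi_raw, surr_mean) stacks of shape (n_rec, n_ch, n_lf, n_hf)."""
        return (
            np.stack([m.mi_raw for m in self.pac_maps]),
            np.stack([m.surr_mean for m in self.pac_maps]),
        )


@dataclass
class TMap:
    """Paired-t statistics per (channel, lf, hf) cell."""

    t: np.ndarray
    p: np.ndarray
    valid: np.ndarray  # analyzable cells with nonzero difference variance
    df: int


def t_map(group: GroupDataset) -> TMap:
    """Paired two-sided t-test of MI_raw vs the surrogate mean at every cell.

    Cells with zero variance of the paired differences are flagged invalid
    and excluded from downstream masks rather than assigned infinite t.
    """
    if group.n_recordings < 3:
        raise ValueError("need at least 3 recordings for the t-map")
    mi, surr = group.stacked()
    diffs = mi - surr
    pair_valid = np.isfinite(diffs).all(axis=0)
    n = group.n_recordings
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    nonzero = sd > 0
    valid = pair_valid & nonzero
    t = np.zeros(mean.shape)
    p = np.ones(mean.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        t[valid] = mean[valid] / (sd[valid] / np.sqrt(n))
    p[valid] = 2 * stats.t.sf(np.abs(t[valid]), df=n - 1)
    return TMap(t=t, p=p, valid=valid, df=n - 1)


def threshold_mask(tmap: TMap, alpha: float = 0.05) -> np.ndarray:
    """Cells where the paired test rejects at ``alpha`` (strict p < alpha)."""
    return (tmap.p < alpha) & tmap.valid


def label_clusters(sig_mask: np.ndarray) -> np.ndarray:
    """4-connected components of the significance mask, per channel.

    ``sig_mask`` has shape (n_ch, n_lf, n_hf).  Labels are positive integers,
    globally unique across channels (clusters never span channels); 0 marks
    background.  Cells excluded by the valid-pair mask are False in
    ``sig_mask`` and therefore never connect cells through themselves.
    """
    sig_mask = np.asarray(sig_mask, dtype=bool)
    labels = np.zeros(sig_mask.shape, dtype=int)
    offset = 0
    for c in range(sig_mask.shape[0]):
        lab, n = ndimage.label(sig_mask[c], structure=FOUR_CONNECTIVITY)
        lab[lab > 0] += offset
        labels[c] = lab
        offset += n
    return labels


def cluster_masses(t: np.ndarray, labels: np.ndarray, t_crit: float) -> dict[int, float]:
    """Cluster-level statistic: sum of (t - t_crit) over each cluster's cells.

    Positive by construction for supra-threshold positive-t cells.
    """
    masses: dict[int, float] = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        masses[int(lab)] = float((t[labels == lab] - t_crit).sum())
    return masses


def critical_t(df: int, alpha: float = 0.05) -> float:
    """Two-sided critical t value at ``alpha`` for ``df`` degrees of freedom."""
    return float(stats.t.ppf(1 - alpha / 2, df))


def flip_half(
    group: GroupDataset,
    seed: int | np.random.Generator | None = None,
    indices: np.ndarray | None = None,
) -> GroupDataset:
    """Swap MI_raw with the surrogate mean in a random half of recordings.

    Exactly floor(N/2) recordings (chosen uniformly, or given explicitly via
    ``indices``) have the two fields exchanged at every cell; applying the
    same selection twice restores the original dataset.
    """
    n = group.n_recordings
    if indices is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        indices = rng.choice(n, size=n // 2, replace=False)
    chosen = set(int(i) for i in np.asarray(indices).ravel())
    flipped_maps = []
    for i, m in enumerate(group.pac_maps):
        if i in chosen:
            m = PacMap(
                subject_id=m.subject_id,
                age_months=m.age_months,
                ch_names=m.ch_names,
                spec=m.spec,
                mi_raw=m.surr_mean,
                surr_mean=m.mi_raw,
                surr_sd=m.surr_sd,
                mi_norm=m.mi_norm,
                phase_max_deg=m.phase_max_deg,
                tie_flag=m.tie_flag,
            )
        flipped_maps.append(m)
    return GroupDataset(pac_maps=flipped_maps, ages_months=group.ages_months)


def permutation_null(
    group: GroupDataset,
    alpha: float = 0.05,
    n_perm: int = 200,
    seed: int | None = None,
    null_mode: str = "pooled",
) -> np.ndarray:
    """Null distribution of cluster masses from flip-half permutations.

    Each permutation: flip half the recordings, recompute the t-map,
    threshold, label, and collect cluster masses.  ``null_mode="pooled"``
    (default) pools every cluster mass from every permutation;
    ``null_mode="max"`` keeps only each permutation's maximum (standard
    family-wise control).  A permutation with no supra-threshold cluster
    contributes a single 0.
    """
    if null_mode not in ("pooled", "max"):
        raise ValueError("null_mode must be 'pooled' or 'max'")
    rng = np.random.default_rng(seed)
    t_crit = critical_t(group.n_recordings - 1, alpha)
    null: list[float] = []
    for _ in range(n_perm):
        perm = flip_half(group, seed=rng)
        tm = t_map(perm)
        mask = threshold_mask(tm, alpha)
        masses = cluster_masses(tm.t, label_clusters(mask), t_crit)
        values = list(masses.values())
        if not values:
            null.append(0.0)
        elif null_mode == "max":
            null.append(max(values))
        else:
            null.extend(values)
    return np.asarray(null)


@dataclass
class ClusterResult:
    """Observed t-map, clusters, permutation null, and the PAC+ mask."""

    t_map: TMap
    sig_mask: np.ndarray
    labels: np.ndarray
    masses: dict[int, float]
    null_distribution: np.ndarray
    null_mode: str
    pac_plus_mask: np.ndarray
    n_permutations: int
    alpha: float
    threshold_mass: float
    valid_pair_mask: np.ndarray = None

    def cluster_table(self, group: GroupDataset) -> pd.DataFrame:
        rows = []
        for lab, mass in sorted(self.masses.items()):
            cells = self.labels == lab
            ch = group.ch_names[int(np.argwhere(cells)[0][0])]
            pct = float(np.mean(self.null_distribution < mass) * 100)
            rows.append(
                {
                    "channel": ch,
                    "cluster_id": lab,
                    "n_cells": int(cells.sum()),
                    "mass": mass,
                    "null_percentile": pct,
                    "significant": bool(mass >= self.threshold_mass),
                }
            )
        return pd.DataFrame.from_records(
            rows,
            columns=[
                "channel", "cluster_id", "n_cells", "mass",
                "null_percentile", "significant",
            ],
        )

    def cell_table(self, group: GroupDataset) -> pd.DataFrame:
        spec = group.spec
        rows = []
        for c, ch in enumerate(group.ch_names):
            for i, lf in enumerate(spec.lf_centers):
                for j, hf in enumerate(spec.hf_centers):
                    if not spec.valid_pair_mask[i, j]:
                        continue
                    rows.append(
                        {
                            "channel": ch,
                            "lf_hz": lf,
                            "hf_hz": hf,
                            "t": self.t_map.t[c, i, j],
                            "cluster_id": int(self.labels[c, i, j]),
                            "pac_plus": bool(self.pac_plus_mask[c, i, j]),
                        }
                    )
        return pd.DataFrame.from_records(rows)

    @property
    def pac_plus_fraction(self) -> float:
        """Fraction of analyzable (channel x valid pair) cells marked PAC+."""
        if self.valid_pair_mask is None:
            return float(self.pac_plus_mask.mean())
        n_valid = self.pac_plus_mask.shape[0] * int(self.valid_pair_mask.sum())
        return float(self.pac_plus_mask.sum() / n_valid) if n_valid else 0.0


def pac_positive_mask(
    labels: np.ndarray,
    masses: dict[int, float],
    null_distribution: np.ndarray,
    percentile: float = 95.0,
) -> tuple[np.ndarray, float]:
    """Keep observed clusters whose mass reaches the null's 95th percentile.

    Returns the cell mask and the mass threshold used.  Raises if there are
    observed clusters but the null distribution is empty.
    """
    if masses and len(null_distribution) == 0:
        raise ValueError("cannot assess observed clusters against an empty null")
    thr = float(np.percentile(null_distribution, percentile)) if len(null_distribution) else np.inf
    mask = np.zeros(labels.shape, dtype=bool)
    for lab, mass in masses.items():
        if mass >= thr:
            mask[labels == lab] = True
    return mask, thr


def cluster_analysis(
    group: GroupDataset,
    alpha: float = 0.05,
    n_perm: int = 200,
    seed: int | None = None,
    null_mode: str = "pooled",
    percentile: float = 95.0,
) -> ClusterResult:
    """Full observed-clusters + permutation-null + PAC+ selection pipeline."""
    tm = t_map(group)
    mask = threshold_mask(tm, alpha)
    labels = label_clusters(mask)
    t_crit = critical_t(group.n_recordings - 1, alpha)
    masses = cluster_masses(tm.t, labels, t_crit)
    null = permutation_null(group, alpha=alpha, n_perm=n_perm, seed=seed, null_mode=null_mode)
    pac_plus, thr = pac_positive_mask(labels, masses, null, percentile)
    return ClusterResult(
        t_map=tm,
        sig_mask=mask,
        labels=labels,
        masses=masses,
        null_distribution=null,
        null_mode=null_mode,
        pac_plus_mask=pac_plus,
        n_permutations=n_perm,
        alpha=alpha,
        threshold_mass=thr,
        valid_pair_mask=group.spec.valid_pair_mask,
    )
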