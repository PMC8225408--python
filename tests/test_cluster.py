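"""Cluster inference: t-maps, 4-connectivity labeling, flip-half permutations."""

import numpy as np
import pytest
from scipy import stats

import pacpipe as pp
from pacpipe.cluster import (
    GroupDataset,
    cluster_masses,
    critical_t,
    flip_half,
    label_clusters,
    pac_positive_mask,
    permutation_null,
    t_map,
    threshold_mask,
)
from pacpipe.filterbank import FilterBankSpec
from pacpipe.metrics import PacMap


def make_group(mi_raw, surr_mean, n_ch=1, n_lf=3, n_hf=4):
    """Synthetic GroupDataset from per-recording scalar or array values."""
    spec = FilterBankSpec(
        lf_centers=np.array([4.0, 8.0, 12.0]),
        hf_centers=np.array([52.0, 64.0, 76.0, 88.0]),
        valid_pair_mask=np.ones((n_lf, n_hf), dtype=bool),
    )
    maps = []
    for k, (mi, surr) in enumerate(zip(mi_raw, surr_mean)):
        mi = np.broadcast_to(np.asarray(mi, dtype=float), (n_ch, n_lf, n_hf)).copy()
        surr = np.broadcast_to(np.asarray(surr, dtype=float), (n_ch, n_lf, n_hf)).copy()
        maps.append(
            PacMap(
                subject_id=f"s{k}",
                age_months=3.0,
                ch_names=["Cz", "Fz", "Pz"][:n_ch],
                spec=spec,
                mi_raw=mi,
                surr_mean=surr,
                surr_sd=np.ones_like(mi),
                mi_norm=mi - surr,
                phase_max_deg=np.full_like(mi, 90.0),
                tie_flag=np.zeros_like(mi, dtype=bool),
            )
        )
    return GroupDataset(pac_maps=maps)


def flood_fill_labels(mask):
    """Brute-force 4-connected labeling oracle for one channel's grid."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and labels[i, j] == 0:
                nxt += 1
                stack = [(i, j)]
                while stack:
                    a, b = stack.pop()
                    if not (0 <= a < mask.shape[0] and 0 <= b < mask.shape[1]):
                        continue
                    if not mask[a, b] or labels[a, b]:
                        continue
                    labels[a, b] = nxt
                    stack.extend([(a + 1, b), (a - 1, b), (a, b + 1), (a, b - 1)])
    return labels


def labelings_equivalent(a, b):
    """True iff two labelings agree up to a permutation of label ids."""
    if (a > 0).sum() != (b > 0).sum() or not np.array_equal(a > 0, b > 0):
        return False
    pairs = {(x, y) for x, y in zip(a[a > 0].ravel(), b[b > 0].ravel())}
    return len({x for x, _ in pairs}) == len(pairs) == len({y for _, y in pairs})


class TestTMap:
    def test_null_identity_gives_zero_t(self):
        g = make_group([0.2, 0.3, 0.4], [0.2, 0.3, 0.4])
        tm = t_map(g)
        assert not tm.valid.any()  # zero-variance differences flagged out
        assert np.all(tm.p == 1.0)

    def test_hand_computed_paired_t(self):
        g = make_group([0.2, 0.3, 0.4], [0.1, 0.1, 0.1])
        tm = t_map(g)
        assert tm.t[0, 0, 0] == pytest.approx(3.464, rel=1e-3)
        assert tm.df == 2

    def test_sign_flip_negates_t(self):
        g = make_group([0.2, 0.3, 0.4], [0.1, 0.1, 0.1])
        g_neg = make_group([0.1, 0.1, 0.1], [0.2, 0.3, 0.4])
        assert t_map(g_neg).t[0, 0, 0] == pytest.approx(-t_map(g).t[0, 0, 0])
        assert t_map(g_neg).p[0, 0, 0] == pytest.approx(t_map(g).p[0, 0, 0])

    def test_threshold_boundary_strict(self):
        g = make_group([0.2, 0.3, 0.4], [0.1, 0.1, 0.1])
        tm = t_map(g)
        p = tm.p[0, 0, 0]
        assert threshold_mask(tm, alpha=p + 1e-6).all()
        assert not threshold_mask(tm, alpha=p).any()  # strict <


class TestLabeling:
    def test_example_two_clusters(self):
        mask = np.zeros((1, 3, 4), dtype=bool)
        mask[0, 0, 0] = mask[0, 0, 1] = True  # adjacent along HF
        mask[0, 2, 3] = True
        labels = label_clusters(mask)
        sizes = sorted(np.bincount(labels.ravel())[1:])
        assert sizes == [1, 2]

    def test_diagonals_not_connected(self):
        mask = np.zeros((1, 3, 3), dtype=bool)
        mask[0, 0, 0] = mask[0, 1, 1] = True
        labels = label_clusters(mask)
        assert labels.max() == 2

    def test_channels_labeled_independently(self):
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[:, 0, 0] = True
        labels = label_clusters(mask)
        assert labels[0, 0, 0] != labels[1, 0, 0]

    def test_matches_flood_fill_on_random_masks(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            mask = rng.random((10, 16)) < rng.uniform(0.1, 0.7)
            ours = label_clusters(mask[np.newaxis])[0]
            oracle = flood_fill_labels(mask)
            assert labelings_equivalent(ours, oracle)


class TestClusterMasses:
    def test_additivity(self):
        t = np.zeros((1, 3, 4))
        t[0, 0, 0], t[0, 0, 1] = 3.0, 4.0
        labels = np.zeros((1, 3, 4), dtype=int)
        labels[0, 0, 0] = labels[0, 0, 1] = 1
        masses = cluster_masses(t, labels, t_crit=2.0)
        assert masses == {1: pytest.approx(3.0)}

    def test_critical_t_quantile(self):
        assert critical_t(df=19, alpha=0.05) == pytest.approx(2.093, abs=1e-3)
        assert critical_t(df=19) == pytest.approx(stats.t.ppf(0.975, 19))


class TestFlipHalf:
    def test_involution(self):
        g = make_group(np.linspace(0.2, 0.4, 7), np.full(7, 0.1))
        idx = np.array([0, 2, 5])
        flipped = flip_half(g, indices=idx)
        restored = flip_half(flipped, indices=idx)
        orig_mi, _ = g.stacked()
        back_mi, _ = restored.stacked()
        assert np.array_equal(orig_mi, back_mi)

    def test_flipped_fields_swapped(self):
        g = make_group([0.2, 0.3], [0.05, 0.07])
        flipped = flip_half(g, indices=[1])
        assert np.array_equal(flipped.pac_maps[1].mi_raw, g.pac_maps[1].surr_mean)
        assert np.array_equal(flipped.pac_maps[0].mi_raw, g.pac_maps[0].mi_raw)

    def test_floor_half_flipped(self):
        g = make_group(np.linspace(0.2, 0.4, 7), np.full(7, 0.1))
        flipped = flip_half(g, seed=0)
        orig_mi, _ = g.stacked()
        new_mi, _ = flipped.stacked()
        n_changed = sum(
            not np.array_equal(orig_mi[i], new_mi[i]) for i in range(7)
        )
        assert n_changed == 3


class TestPermutationNull:
    def test_degenerate_null_all_zeros(self):
        g = make_group([0.2, 0.3, 0.4], [0.2, 0.3, 0.4])
        null = permutation_null(g, n_perm=20, seed=0)
        assert null.shape == (20,)
        assert np.all(null == 0.0)

    def test_pooled_collects_at_least_n_perm(self):
        rng = np.random.default_rng(0)
        g = make_group(
            [rng.uniform(0.1, 0.3, (1, 3, 4)) for _ in range(8)],
            [rng.uniform(0.1, 0.3, (1, 3, 4)) for _ in range(8)],
        )
        null = permutation_null(g, n_perm=50, seed=1, null_mode="pooled")
        null_max = permutation_null(g, n_perm=50, seed=1, null_mode="max")
        assert len(null) >= 50
        assert len(null_max) == 50

    def test_reproducible(self):
        rng = np.random.default_rng(3)
        g = make_group(
            [rng.uniform(0.1, 0.3, (1, 3, 4)) for _ in range(6)],
            [rng.uniform(0.1, 0.3, (1, 3, 4)) for _ in range(6)],
        )
        a = permutation_null(g, n_perm=30, seed=9)
        b = permutation_null(g, n_perm=30, seed=9)
        assert np.array_equal(a, b)


class TestPacPositiveMask:
    def test_all_below_percentile_empty_mask(self):
        labels = np.zeros((1, 3, 4), dtype=int)
        labels[0, 0, 0] = 1
        mask, thr = pac_positive_mask(labels, {1: 0.5}, np.linspace(1, 10, 100))
        assert not mask.any() and thr > 0.5

    def test_strong_cluster_retained(self):
        labels = np.zeros((1, 3, 4), dtype=int)
        labels[0, 0, :2] = 1
        mask, _ = pac_positive_mask(labels, {1: 50.0}, np.linspace(0, 10, 200))
        assert mask.sum() == 2

    def test_empty_null_with_observed_clusters_errors(self):
        labels = np.zeros((1, 3, 4), dtype=int)
        labels[0, 0, 0] = 1
        with pytest.raises(ValueError):
            pac_positive_mask(labels, {1: 1.0}, np.array([]))

    def test_monotonicity_in_t(self):
        # raising a PAC+ cell's t never removes it from the mask (null fixed)
        rng = np.random.default_rng(4)
        t = rng.normal(0, 1, (1, 3, 4))
        t[0, 1, 1] = 3.5
        sig = np.abs(t) > 2.5
        labels = label_clusters(sig)
        null = np.linspace(0, 2, 100)
        mask1, _ = pac_positive_mask(labels, cluster_masses(t, labels, 2.5), null)
        t2 = t.copy()
        t2[0, 1, 1] += 2.0
        sig2 = np.abs(t2) > 2.5
        labels2 = label_clusters(sig2)
        mask2, _ = pac_positive_mask(labels2, cluster_masses(t2, labels2, 2.5), null)
        assert mask2[0, 1, 1] >= mask1[0, 1, 1]
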