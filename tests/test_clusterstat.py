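"""Cluster statistics: t-maps, labeling vs flood-fill oracle, permutation
p-values vs exhaustive enumeration, and waveform time-course clusters."""

import numpy as np
import pytest
from scipy import stats

from prestim import clusterstat
from prestim.clusterstat import (BandRule, TFCluster, TMap, form_clusters,
                                 permutation_pvalues, select_band_clusters,
                                 timecourse_clusters, tmap_one_sample)
from prestim.plsmap import simpls


def tmap_from_t(t, df=19):
    t = np.asarray(t, dtype=float)
    return TMap(t=t, p=2 * stats.t.sf(np.abs(t), df), df=df)


class TestTMap:
    def test_identical_nonzero_maps_flagged_infinite(self):
        maps = np.tile(np.array([[1.0, -2.0], [0.0, 3.0]]), (5, 1, 1))
        tm = tmap_one_sample(maps)
        assert np.isinf(tm.t[0, 0]) and tm.t[0, 0] > 0
        assert np.isinf(tm.t[0, 1]) and tm.t[0, 1] < 0
        assert tm.t[1, 0] == 0.0 and tm.p[1, 0] == 1.0
        assert tm.degenerate.all()

    def test_antisymmetry(self, rng):
        maps = rng.normal(0, 1, (8, 6, 6))
        t1 = tmap_one_sample(maps).t
        t2 = tmap_one_sample(-maps).t
        assert np.allclose(t1, -t2)

    def test_null_calibration_monte_carlo(self, rng):
        maps = rng.normal(0, 1, (20, 10000))
        tm = tmap_one_sample(maps)
        frac = np.mean(tm.p < 0.05)
        assert 0.04 <= frac <= 0.06

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError):
            tmap_one_sample(rng.normal(0, 1, (2, 4)))


def _flood_fill_components(mask):
    """Brute-force 4-connectivity labeling oracle."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        stack, comp = [start], set()
        seen[start] = True
        while stack:
            i, j = stack.pop()
            comp.add((i, j))
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if (0 <= ni < mask.shape[0] and 0 <= nj < mask.shape[1]
                        and mask[ni, nj] and not seen[ni, nj]):
                    seen[ni, nj] = True
                    stack.append((ni, nj))
        comps.append(frozenset(comp))
    return set(comps)


class TestFormClusters:
    def test_no_significant_points_empty_list(self):
        tm = tmap_from_t(np.zeros((5, 5)))
        assert form_clusters(tm) == []

    def test_min_size_strictly_greater_than_20(self):
        t = np.zeros((4, 30))
        t[0, :21] = 5.0          # 21-point component survives
        t[2, :20] = 5.0          # 20-point component does not
        cl = form_clusters(tmap_from_t(t), min_size=20)
        assert len(cl) == 1 and cl[0].size == 21

    def test_components_match_flood_fill_oracle(self, rng):
        for _ in range(10):
            t = np.where(rng.random((15, 15)) < 0.35, 4.0, 0.0)
            cl = form_clusters(tmap_from_t(t), min_size=0)
            got = {frozenset(zip(*c.indices)) for c in cl}
            assert got == _flood_fill_components(t > 0)

    def test_signs_never_mix_and_partition_property(self, rng):
        t = rng.normal(0, 3, (20, 20))
        tm = tmap_from_t(t)
        cl = form_clusters(tm, min_size=0)
        seen = np.zeros(t.shape, bool)
        for c in cl:
            members_t = tm.t[c.indices]
            assert np.all(np.sign(members_t) == c.sign)
            assert np.all(tm.p[c.indices] < 0.05)
            assert not seen[c.indices].any()       # disjoint
            seen[c.indices] = True
            assert np.isclose(c.sum_t, members_t.sum())
        assert np.array_equal(seen, tm.p < 0.05)   # covers all significant


def _cluster_at(rows, cols, t_val, shape):
    idx = (np.asarray(rows), np.asarray(cols))
    return TFCluster(indices=idx, sum_t=t_val * len(rows), sign=int(np.sign(t_val)),
                     grid_shape=shape)


class TestSelectBandClusters:
    freqs = np.arange(2.0, 101.0, 2.0)       # 50 bins
    times = np.arange(-500.0, 1000.0, 20.0)  # 75 bins

    def _gamma_pre(self, n, t_val=4.0):
        rows = np.full(n, 40)                # 82 Hz
        cols = np.arange(n) + 5              # prestimulus times
        return _cluster_at(rows, cols, t_val, (50, 75))

    def test_largest_gamma_cluster_selected(self):
        c30, c50 = self._gamma_pre(15), self._gamma_pre(20)
        out = select_band_clusters([c30, c50], self.freqs, self.times)
        assert out["Pre-GBO"] == [c50]

    def test_no_gamma_cluster_is_empty_not_error(self):
        out = select_band_clusters([], self.freqs, self.times)
        assert out["Pre-GBO"] == []

    def test_equal_size_tie_broken_by_sum_t(self):
        a, b = self._gamma_pre(15, t_val=3.0), self._gamma_pre(15, t_val=-6.0)
        out = select_band_clusters([a, b], self.freqs, self.times)
        assert out["Pre-GBO"] == [b]


class TestPermutationPValues:
    def _subjects(self, rng, n_sub=4, n_trials=8, signal=3.0):
        feats, rates, energies = [], [], []
        for _ in range(n_sub):
            e = np.repeat([0, 1], n_trials // 2)
            x = rng.normal(0, 1, (n_trials, 1))
            y = signal * x[:, 0] + rng.normal(0, 0.3, n_trials)
            zx = (x - x.mean()) / x.std(ddof=1)
            zy = (y - y.mean()) / y.std(ddof=1)
            feats.append(zx)
            rates.append(zy)
            energies.append(e)
        return feats, rates, energies

    def _observed_cluster(self, feats, rates):
        coefs = np.array([simpls(X, y, 1)[0][0] for X, y in zip(feats, rates)])
        tm = tmap_one_sample(coefs[:, None])
        return TFCluster(indices=(np.array([0]),), sum_t=float(tm.t[0]),
                         sign=int(np.sign(tm.t[0])), grid_shape=(1,))

    def test_strong_signal_gives_minimum_p(self, rng):
        feats, rates, energies = self._subjects(rng, n_sub=6, signal=50.0)
        c = self._observed_cluster(feats, rates)
        permutation_pvalues(feats, rates, energies, [c], (1,),
                            n_perm=100, n_components=1, seed=0)
        assert c.p_perm == pytest.approx(1 / 101)

    def test_monte_carlo_agrees_with_exhaustive_enumeration(self, rng):
        # 3 subjects x 4 trials, single stratum: the joint permutation space
        # (4!)^3 = 13824 is enumerated exactly and compared with the
        # Monte-Carlo tail within its binomial interval
        from itertools import permutations

        feats, rates, energies = [], [], []
        g = np.random.default_rng(5)
        for _ in range(3):
            x = g.normal(0, 1, (4, 1))
            y = 1.0 * x[:, 0] + g.normal(0, 1.0, 4)
            feats.append((x - x.mean()) / x.std(ddof=1))
            rates.append((y - y.mean()) / y.std(ddof=1))
            energies.append(np.zeros(4, int))
        c = self._observed_cluster(feats, rates)

        perms = list(permutations(range(4)))
        coef_table = np.array([[simpls(X, y[list(p)], 1)[0][0] for p in perms]
                               for X, y in zip(feats, rates)])   # (3, 24)
        A = coef_table[0][:, None, None]
        B = coef_table[1][None, :, None]
        Cc = coef_table[2][None, None, :]
        mean = (A + B + Cc) / 3
        var = ((A - mean) ** 2 + (B - mean) ** 2 + (Cc - mean) ** 2) / 2
        t_all = mean / np.sqrt(var / 3)
        p_exact = np.mean(np.abs(t_all) >= abs(c.sum_t))

        M = 800
        permutation_pvalues(feats, rates, energies, [c], (1,),
                            n_perm=M, n_components=1, seed=7)
        se = np.sqrt(p_exact * (1 - p_exact) / M)
        assert abs(c.p_perm - p_exact) <= 3 * se + 2 / M

    def test_seeded_runs_reproducible(self, rng):
        feats, rates, energies = self._subjects(rng)
        c1 = self._observed_cluster(feats, rates)
        c2 = self._observed_cluster(feats, rates)
        permutation_pvalues(feats, rates, energies, [c1], (1,),
                            n_perm=200, n_components=1, seed=11)
        permutation_pvalues(feats, rates, energies, [c2], (1,),
                            n_perm=200, n_components=1, seed=11)
        assert c1.p_perm == c2.p_perm

    def test_invalid_inputs(self, rng):
        feats, rates, energies = self._subjects(rng)
        c = self._observed_cluster(feats, rates)
        with pytest.raises(ValueError):
            permutation_pvalues(feats, rates, energies, [c], (1,), n_perm=0)
        empty = TFCluster(indices=(np.array([], int),), sum_t=0.0, sign=1,
                          grid_shape=(1,))
        with pytest.raises(ValueError, match="empty"):
            permutation_pvalues(feats, rates, energies, [empty], (1,),
                                n_perm=10)


class TestTimecourseClusters:
    times = np.arange(0.0, 600.0, 4.0)

    def _cells(self, rng, effect=0.0, window=(150, 250), n_sub=12):
        # (sub, energy, split, time) smooth waveform cells
        from scipy.ndimage import gaussian_filter1d

        n_t = self.times.size
        base = np.sin(2 * np.pi * self.times / 600.0) * 5
        y = np.empty((n_sub, 4, 2, n_t))
        for s in range(n_sub):
            for a in range(4):
                for b in range(2):
                    noise = gaussian_filter1d(rng.standard_normal(n_t), 5)
                    bump = (effect * b * np.exp(
                        -0.5 * ((self.times - np.mean(window)) / 25.0) ** 2))
                    y[s, a, b] = base + (a + 1) + bump + noise
        return y

    def test_planted_window_detected(self, rng):
        found = 0
        for _ in range(25):
            y = self._cells(rng, effect=1.5)
            cl = timecourse_clusters(y, self.times, n_perm=200, seed=1)
            sig = [c for c in cl if c.p_perm is not None and c.p_perm < 0.05]
            found += any(c.start_ms <= 250 and c.end_ms >= 150 for c in sig)
        assert found >= 22     # >=90 % detection

    def test_null_familywise_rate_nominal(self, rng):
        hits = 0
        n = 60
        for _ in range(n):
            y = self._cells(rng, effect=0.0)
            cl = timecourse_clusters(y, self.times, n_perm=200, seed=2)
            hits += any(c.p_perm is not None and c.p_perm < 0.05 for c in cl)
        # one-sided binomial bound around 0.05 for the mask-fixed scheme on
        # temporally smooth data
        assert hits / n <= stats.binom.ppf(0.995, n, 0.05) / n + 0.05

    def test_interval_output_in_ms(self, rng):
        y = self._cells(rng, effect=2.0)
        cl = timecourse_clusters(y, self.times, n_perm=50, seed=3)
        assert cl and all(c.end_ms > c.start_ms for c in cl)
        assert all(c.start_ms in self.times and c.end_ms in self.times
                   for c in cl)

    def test_requires_two_split_levels(self, rng):
        with pytest.raises(ValueError):
            timecourse_clusters(rng.normal(0, 1, (5, 4, 3, 50)),
                                np.arange(50.0))
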