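"""Temperature binning, per-bin metrics, KS letter display, ordination."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ks_2samp

from mdrsmap.context import (
    bin_temperature,
    compare_distributions,
    enumerate_bins,
    instantaneous_metrics,
    interaction_profile_ordination,
    per_bin_keystones,
    per_bin_metrics,
    percent_change,
)
from tests.test_metrics import make_tensor


class TestBinTemperature:
    @pytest.mark.parametrize(
        "temp,expected", [(17.2, 17), (16.5, 17), (16.49, 16), (13.0, 13), (25.7, 26)]
    )
    def test_round_half_up(self, temp, expected):
        assert bin_temperature([temp])[0] == expected

    def test_fourteen_bins_over_observed_gradient(self, rng):
        temps = rng.uniform(12.51, 26.49, 500)  # observed gradient 13..26 C
        labels = bin_temperature(temps)
        assert len(enumerate_bins(labels)) == 14
        assert labels.min() == 13 and labels.max() == 26

    def test_assignment_total_and_deterministic(self, rng):
        temps = rng.uniform(10, 30, 200)
        labels = bin_temperature(temps)
        assert len(labels) == 200
        counts = sum((labels == b).sum() for b in np.unique(labels))
        assert counts == 200


class TestPerBinMetrics:
    def _toy(self):
        # 4 valid time points, 2 taxa; hand-set coefficients, all pairs strong
        vals = np.zeros((4, 2, 2))
        vals[:, 0, 1] = [1.0, 3.0, 2.0, 2.0]   # effect of t1 on t0
        vals[:, 1, 0] = [-1.0, -1.0, 4.0, 0.0]  # effect of t0 on t1
        tensor = make_tensor(vals)
        cls = pd.DataFrame(
            {
                "target": ["t0", "t1"],
                "source": ["t1", "t0"],
                "occurrence": [1.0, 1.0],
                "mean_strength": [2.0, 0.5],
                "nonzero_mean_strength": [2.0, 0.5],
                "strong": [True, True],
                "sign": ["positive", "positive"],
            }
        )
        return tensor, cls

    def test_hand_computed_means_and_ses(self):
        tensor, cls = self._toy()
        summary = per_bin_metrics(tensor, cls, bin_labels=[15, 15, 20, 20])
        # taxon t1 as source: instantaneous interactiveness = hypot(v, |v|) = sqrt(2)|v|
        inter_t1 = np.sqrt(2) * np.array([1.0, 3.0, 2.0, 2.0])
        m15 = summary.interactiveness_mean.loc["t1", 15]
        assert m15 == pytest.approx(inter_t1[:2].mean())
        assert summary.interactiveness_se.loc["t1", 15] == pytest.approx(
            inter_t1[:2].std(ddof=1) / np.sqrt(2)
        )
        # facilitation of t0 as source: signs -1, -1, +4, 0 -> 0, 0, 100, NaN
        assert summary.facilitation_mean.loc["t0", 15] == pytest.approx(0.0)
        assert summary.facilitation_mean.loc["t0", 20] == pytest.approx(100.0)

    def test_single_point_bin_has_zero_se(self):
        tensor, cls = self._toy()
        summary = per_bin_metrics(tensor, cls, bin_labels=[15, 16, 17, 18])
        assert (summary.n_points == 1).all()
        assert np.allclose(summary.interactiveness_se.to_numpy(), 0.0)

    def test_constant_coefficients_constant_across_bins(self):
        vals = np.zeros((6, 2, 2))
        vals[:, 0, 1] = 2.0
        tensor = make_tensor(vals)
        cls = pd.DataFrame(
            {
                "target": ["t0"], "source": ["t1"], "occurrence": [1.0],
                "mean_strength": [2.0], "nonzero_mean_strength": [2.0],
                "strong": [True], "sign": ["positive"],
            }
        )
        summary = per_bin_metrics(tensor, cls, bin_labels=[13, 13, 14, 14, 15, 15])
        row = summary.interactiveness_mean.loc["t1"]
        assert np.allclose(row, row.iloc[0])
        assert np.allclose(summary.interactiveness_se.loc["t1"], 0.0)

    def test_time_counts_conserved(self):
        tensor, cls = self._toy()
        labels = [15, 15, 16, 17]
        summary = per_bin_metrics(tensor, cls, labels)
        assert summary.n_points.sum() == len(labels)


class TestPerBinKeystones:
    def test_membership_size(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(10, 20, 20)) * 0.1
        tensor = make_tensor(vals)
        from mdrsmap.metrics import classify_pairs

        cls = classify_pairs(tensor, thresholds=(0.001, 0.01))
        summary = per_bin_metrics(tensor, cls, bin_labels=[14] * 5 + [20] * 5)
        turn = per_bin_keystones(summary, fraction=0.10)
        assert (turn.membership.sum(axis=0) == 2).all()  # floor(0.1*20)

    def test_crossover_switches_membership(self):
        # taxon A (t1 as source) dominates the cold bin, taxon B (t0) the warm
        vals = np.zeros((4, 3, 3))
        vals[:2, 0, 1] = 5.0   # t1 strong in cold times
        vals[2:, 1, 0] = 5.0   # t0 strong in warm times
        vals[:, 2, 0] = 0.1    # keep t0 weakly active throughout
        vals[:, 2, 1] = 0.1
        tensor = make_tensor(vals)
        from mdrsmap.metrics import classify_pairs

        cls = classify_pairs(tensor, thresholds=(0.01, 0.01))
        summary = per_bin_metrics(tensor, cls, bin_labels=[14, 14, 22, 22])
        turn = per_bin_keystones(summary, fraction=0.34)  # 1 keystone per bin
        # brute-force: ranking per bin by mean interactiveness
        for b in (14, 22):
            expected = summary.interactiveness_mean[b].fillna(0).idxmax()
            assert turn.membership[b].sum() == 1
            assert turn.membership.index[turn.membership[b]][0] == expected
        assert turn.membership[14].idxmax() != turn.membership[22].idxmax()

    def test_global_keystones_lost_flags(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(6, 10, 10)) * 0.1
        tensor = make_tensor(vals)
        from mdrsmap.metrics import classify_pairs

        cls = classify_pairs(tensor, thresholds=(0.001, 0.01))
        summary = per_bin_metrics(tensor, cls, bin_labels=[13, 13, 13, 19, 19, 19])
        turn = per_bin_keystones(summary, fraction=0.10, global_keystones=["t0"])
        assert list(turn.lost.index) == ["t0"]
        assert turn.lost.shape[1] == 2


class TestPercentChange:
    def test_field_study_medians(self):
        assert round(percent_change(0.33, 0.22)) == 33

    def test_identity(self):
        assert percent_change(5.0, 5.0) == 0.0

    def test_increase_is_negative(self):
        assert percent_change(60.5, 72.0) == pytest.approx(-19.0, abs=0.05)

    def test_zero_reference(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


class TestCompareDistributions:
    def test_identical_samples_share_letter(self, rng):
        x = rng.normal(size=30)
        res = compare_distributions({13: x, 14: x.copy()})
        assert res.letters[13] == res.letters[14]
        row = res.pairs.iloc[0]
        assert row["statistic"] == pytest.approx(0.0)

    def test_separated_distributions_differ(self, rng):
        res = compare_distributions(
            {1: rng.normal(0, 1, 50), 2: rng.normal(5, 1, 50)}
        )
        assert set(res.letters[1]).isdisjoint(set(res.letters[2]))

    def test_letters_match_significance_relation(self, rng):
        # outer pair differs, middle overlaps both
        samples = {
            1: rng.normal(0.0, 1.0, 60),
            2: rng.normal(1.1, 1.0, 60),
            3: rng.normal(2.2, 1.0, 60),
        }
        res = compare_distributions(samples)
        sig = {
            frozenset((a, b)): s
            for a, b, s in res.pairs[["a", "b", "significant"]].itertuples(index=False)
        }
        for a, b in itertools.combinations(samples, 2):
            share = bool(set(res.letters[a]) & set(res.letters[b]))
            assert share == (not sig[frozenset((a, b))]), (a, b, res.letters)

    def test_letters_symmetric_under_relabeling(self, rng):
        base = {1: rng.normal(0, 1, 40), 2: rng.normal(4, 1, 40), 3: rng.normal(0.2, 1, 40)}
        res1 = compare_distributions(base)
        relabeled = {10 + k: v for k, v in base.items()}
        res2 = compare_distributions(relabeled)
        for a, b in itertools.combinations(base, 2):
            share1 = bool(set(res1.letters[a]) & set(res1.letters[b]))
            share2 = bool(set(res2.letters[10 + a]) & set(res2.letters[10 + b]))
            assert share1 == share2

    def test_degenerate_sample_own_letter(self, rng):
        res = compare_distributions({1: np.ones(10), 2: rng.normal(0, 1, 30), 3: rng.normal(0, 1, 30)})
        assert res.letters[1] not in (res.letters[2], res.letters[3])
        assert res.pairs.set_index(["a", "b"]).loc[(1, 2), "pvalue"] != res.pairs.set_index(["a", "b"]).loc[(1, 2), "pvalue"]  # NaN

    def test_too_few_bins(self):
        with pytest.raises(ValueError):
            compare_distributions({1: np.arange(10)})

    def test_ks_values_match_scipy(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        res = compare_distributions({1: a, 2: b})
        ref = ks_2samp(a, b)
        row = res.pairs.iloc[0]
        assert row["statistic"] == pytest.approx(ref.statistic)
        assert row["pvalue"] == pytest.approx(ref.pvalue)


class TestOrdination:
    def _tensor_from_profiles(self, profiles):
        """Build a tensor whose taxon-0 outgoing coefficients at time t equal
        profiles[t] (over the other taxa)."""
        T = len(profiles)
        S = len(profiles[0]) + 1
        vals = np.zeros((T, S, S))
        for t, prof in enumerate(profiles):
            for k, v in enumerate(prof):
                vals[t, k + 1, 0] = v
        return make_tensor(vals)

    def test_identical_profiles_zero_dissimilarity(self):
        tensor = self._tensor_from_profiles([[1.0, 2.0]] * 6)
        res = interaction_profile_ordination(tensor, ["t0"], seed=0)
        # all profiles identical -> all embedded at (near) one point
        d = pdist(res.coords[["dim1", "dim2"]].to_numpy())
        assert np.allclose(d, 0.0, atol=1e-6) or not res.included

    def test_bray_curtis_hand_values(self):
        # 4 hand-set non-negative profiles; check split-transform BC matrix
        profiles = [[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [2.0, 0.0]]
        split = [np.concatenate([np.clip(p, 0, None), np.clip(-np.asarray(p), 0, None)]) for p in map(np.asarray, profiles)]
        expected = squareform(pdist(np.array(split), "braycurtis"))
        assert expected[0, 1] == pytest.approx(1.0)  # disjoint support
        assert expected[0, 3] == pytest.approx(1 / 3)  # (|1-2|)/(1+2)
        tensor = self._tensor_from_profiles(profiles)
        res = interaction_profile_ordination(tensor, ["t0"], seed=1, stress_cutoff=1.0)
        assert len(res.coords) == 4

    def test_negative_entries_split_blocks_disjoint(self):
        # +v and -v profiles have disjoint split support -> BC = 1
        profiles = [[1.0, 2.0], [-1.0, -2.0]]
        arrs = [np.concatenate([np.clip(np.asarray(p), 0, None), np.clip(-np.asarray(p), 0, None)]) for p in profiles]
        assert pdist(np.array(arrs), "braycurtis")[0] == pytest.approx(1.0)

    def test_embeddable_geometry_low_stress(self, rng):
        # profiles arranged so Bray-Curtis distances are well embeddable in 2d
        base = rng.uniform(0.5, 1.5, size=(12, 6))
        tensor = self._tensor_from_profiles(base)
        res = interaction_profile_ordination(tensor, ["t0"], seed=2, stress_cutoff=1.0)
        assert res.stress < 0.2

    def test_stress_cutoff_excludes_coordinates(self):
        profiles = np.random.default_rng(3).uniform(0, 1, size=(10, 5))
        tensor = self._tensor_from_profiles(profiles)
        res = interaction_profile_ordination(tensor, ["t0"], stress_cutoff=-1.0, seed=0)
        assert not res.included
        assert res.coords["dim1"].isna().all()
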