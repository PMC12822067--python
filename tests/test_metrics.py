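"""Strong-interaction thresholds, pair classification and taxon metrics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdrsmap.metrics import (
    classify_pairs,
    distribution_stats,
    select_keystones,
    strong_thresholds,
    taxon_metrics,
)
from mdrsmap.tensor import InteractionTensor


def make_tensor(values, has_temperature=False):
    """Wrap a (T, S, S) coefficient array (valid at all but the last step)."""
    values = np.asarray(values, dtype=float)
    T, S = values.shape[:2]
    full = np.full((T + 1, S, S), np.nan)
    full[:T] = values
    ids = [f"t{i}" for i in range(S)]
    return InteractionTensor(
        values=full,
        intercepts=np.zeros((T + 1, S)),
        taxon_ids=ids,
        times=pd.RangeIndex(T + 1),
        t0=0,
        has_temperature=has_temperature,
        diagnostics=pd.DataFrame({"failed": [False] * S}, index=ids),
    )


class TestStrongThresholds:
    def test_median_of_uniform_grid(self):
        # one off-diagonal pair carries |values| 0.001..0.010; median is the
        # midpoint of the two central order statistics
        T = 10
        vals = np.zeros((T, 2, 2))
        vals[:, 0, 1] = np.linspace(0.001, 0.010, T)
        s, o = strong_thresholds(make_tensor(vals))
        assert s == pytest.approx((0.005 + 0.006) / 2)

    def test_all_pairs_always_occur(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(8, 3, 3))
        _, o = strong_thresholds(make_tensor(vals))
        assert o == 1.0

    def test_overrides_returned_verbatim(self):
        vals = np.random.default_rng(1).normal(size=(6, 2, 2))
        assert strong_thresholds(make_tensor(vals), 0.005, 0.057) == (0.005, 0.057)

    def test_no_nonzero_errors(self):
        with pytest.raises(ValueError):
            strong_thresholds(make_tensor(np.zeros((5, 2, 2))))


class TestClassifyPairs:
    def test_rule_applications(self):
        T = 100
        vals = np.zeros((T, 3, 3))
        # pair (0,1): nonzero 10% of the time, mean over those +0.1 -> strong positive
        vals[:10, 0, 1] = 0.1
        # pair (0,2): nonzero 4% of the time with huge values -> fails occurrence
        vals[:4, 0, 2] = 5.0
        # pair (1,2): always zero -> neutral, occurrence 0
        cls = classify_pairs(make_tensor(vals), thresholds=(0.005, 0.057)).set_index(
            ["target", "source"]
        )
        assert cls.loc[("t0", "t1"), "sign"] == "positive"
        assert cls.loc[("t0", "t1"), "occurrence"] == pytest.approx(0.10)
        assert cls.loc[("t0", "t2"), "sign"] == "neutral"
        assert cls.loc[("t1", "t2"), "sign"] == "neutral"
        assert cls.loc[("t1", "t2"), "occurrence"] == 0.0

    def test_sign_fractions_sum_to_one(self, null_result):
        cls = null_result["classification"]
        fracs = cls["sign"].value_counts(normalize=True)
        assert fracs.sum() == pytest.approx(1.0)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(50, 4, 4)) * (rng.random((50, 4, 4)) < 0.5)
        tensor = make_tensor(vals)
        base = classify_pairs(tensor, thresholds=(0.01, 0.1))
        for thr in [(0.02, 0.1), (0.01, 0.3), (0.05, 0.5)]:
            tighter = classify_pairs(tensor, thresholds=thr)
            n_base = taxon_metrics(base, tensor.taxon_ids)["n_partners"]
            n_tight = taxon_metrics(tighter, tensor.taxon_ids)["n_partners"]
            assert (n_tight <= n_base).all()


class TestTaxonMetrics:
    def _classification(self, strengths, source="s"):
        rows = [
            {
                "target": f"t{i}",
                "source": source,
                "occurrence": 1.0,
                "mean_strength": v,
                "nonzero_mean_strength": v,
                "strong": True,
                "sign": "positive" if v > 0 else "negative",
            }
            for i, v in enumerate(strengths)
        ]
        return pd.DataFrame(rows)

    def test_hand_arithmetic(self):
        m = taxon_metrics(self._classification([3.0, -4.0]), ["s"])
        assert m.loc["s", "sum_strength"] == pytest.approx(-1.0)
        assert m.loc["s", "sum_abs_strength"] == pytest.approx(7.0)
        assert m.loc["s", "interactiveness"] == pytest.approx(np.sqrt(50), abs=1e-4)
        assert m.loc["s", "interactiveness"] == pytest.approx(7.0711, abs=1e-4)

    def test_facilitation_percentage(self):
        m = taxon_metrics(self._classification([2.0, -1.0, 1.0]), ["s"])
        assert m.loc["s", "facilitation_pct"] == pytest.approx(75.0)

    def test_no_strong_pairs(self):
        cls = self._classification([])
        m = taxon_metrics(cls, ["s"])
        assert m.loc["s", "interactiveness"] == 0.0
        assert np.isnan(m.loc["s", "facilitation_pct"])

    @given(st.lists(st.floats(-5, 5).filter(lambda v: abs(v) > 1e-6), min_size=1, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_invariants(self, strengths):
        m = taxon_metrics(self._classification(strengths), ["s"]).loc["s"]
        assert m["sum_abs_strength"] >= abs(m["sum_strength"]) - 1e-12
        assert m["interactiveness"] >= max(abs(m["sum_strength"]), m["sum_abs_strength"]) - 1e-12
        assert -1e-9 <= m["facilitation_pct"] <= 100 + 1e-9
        if all(v > 0 for v in strengths):
            assert m["facilitation_pct"] == pytest.approx(100.0)
        if all(v < 0 for v in strengths):
            assert m["facilitation_pct"] == pytest.approx(0.0)


class TestSelectKeystones:
    def _metrics(self, inter, sabs=None):
        n = len(inter)
        return pd.DataFrame(
            {
                "interactiveness": inter,
                "sum_abs_strength": sabs if sabs is not None else inter,
            },
            index=[f"x{i:03d}" for i in range(n)],
        )

    def test_field_study_count(self, rng):
        m = self._metrics(rng.random(162))
        flagged = select_keystones(m, 0.10)
        assert flagged["keystone"].sum() == 16

    def test_minimum_one(self, rng):
        flagged = select_keystones(self._metrics(rng.random(10)), 0.10)
        assert flagged["keystone"].sum() == 1
        assert flagged.loc[flagged["keystone"]].index[0] == flagged["interactiveness"].idxmax()

    def test_tie_break_by_sum_abs(self):
        m = self._metrics([1.0, 0.5, 0.5, 0.1] + [0.01] * 16, sabs=[1.0, 0.2, 0.9, 0.1] + [0.0] * 16)
        flagged = select_keystones(m, 0.10)  # top 2 of 20
        chosen = set(flagged.index[flagged["keystone"]])
        assert chosen == {"x000", "x002"}  # x002 beats x001 at the cutoff

    def test_floor_rule(self, rng):
        for n, k in [(20, 2), (25, 2), (30, 3), (162, 16)]:
            flagged = select_keystones(self._metrics(rng.random(n)), 0.10)
            assert flagged["keystone"].sum() == k


class TestDistributionStats:
    def test_symmetric_zero_skew(self):
        vals = np.tile([-1.0, 0.0, 1.0], 10)
        stats = distribution_stats(vals)
        assert stats.skewness == pytest.approx(0.0, abs=1e-12)

    def test_normal_sample_kurtosis_near_three(self):
        x = np.random.default_rng(123).normal(size=10000)
        stats = distribution_stats(x)
        assert stats.kurtosis == pytest.approx(3.0, abs=0.1)
        assert stats.jb_pvalue > 0.01

    def test_jb_matches_hand_formula(self):
        x = np.array([1.0, 2, 3, 4, 100, 2, 3, 1, 2, 5])
        n = len(x)
        m = x - x.mean()
        m2, m3, m4 = (m**2).mean(), (m**3).mean(), (m**4).mean()
        g1, g2 = m3 / m2**1.5, m4 / m2**2
        jb = n / 6 * (g1**2 + (g2 - 3) ** 2 / 4)
        stats = distribution_stats(x)
        assert stats.jb_stat == pytest.approx(jb, rel=1e-10)
        assert stats.skewness == pytest.approx(g1)
        assert stats.kurtosis == pytest.approx(g2)

    @pytest.mark.parametrize("bad", [np.ones(20), np.arange(5)])
    def test_degenerate_inputs(self, bad):
        with pytest.raises(ValueError):
            distribution_stats(bad)
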