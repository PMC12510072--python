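"""Segment comparison statistics, surrogate control, residual-band
monitoring and diary concordance."""
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from szproject.evaluate import (
    monitor_residuals,
    omnibus_and_posthoc,
    reporting_concordance,
    segment_residuals,
    surrogate_control,
)
from szproject.forecast import DatasetSplit, ModelOrder
from szproject.types import EventSeries


def brute_force_kruskal(groups):
    """Independent oracle: KW H from first principles — rank everything
    (mean ranks for ties), H = (12/(N(N+1))) * sum n_i (Rbar_i - Rbar)^2,
    divided by the tie-correction factor."""
    values = np.concatenate(groups)
    n = len(values)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    sv = values[order]
    while i < n:
        j = i
        while j + 1 < n and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    h = 0.0
    pos = 0
    for g in groups:
        r = ranks[pos : pos + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        pos += len(g)
    h *= 12.0 / (n * (n + 1))
    # tie correction
    _, counts = np.unique(values, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


def _records(residuals, dates):
    dates = pd.DatetimeIndex(dates)
    return pd.DataFrame(
        {
            "origin_date": dates - pd.Timedelta(days=14),
            "target_date": dates,
            "point": 0.0,
            "ci_low": -1.0,
            "ci_high": 1.0,
            "observed": residuals,
            "residual": residuals,
        }
    )


class TestSegmentResiduals:
    def _split(self):
        return DatasetSplit(
            train_validation=("2020-01-01", "2020-02-01"),
            test_segments={
                "a": ("2020-02-01", "2020-03-01"),
                "b": ("2020-03-01", "2020-04-01"),
            },
        )

    def test_single_covering_segment(self):
        dates = pd.date_range("2020-01-01", periods=40, freq="D")
        rec = _records(np.ones(40), dates)
        split = DatasetSplit(("2020-01-01", "2020-03-01"), {"all": ("2020-01-01", "2020-03-01")})
        groups = segment_residuals(rec, split, include_train=False)
        assert list(groups) == ["all"] and len(groups["all"]) == 40

    def test_partition_arithmetic(self):
        dates = pd.date_range("2020-01-01", periods=120, freq="D")
        rec = _records(np.arange(120.0), dates)
        groups = segment_residuals(rec, self._split())
        assert sum(len(g) for g in groups.values()) <= 120
        # no record in two groups
        all_dates = np.concatenate([g.index.view("int64") for g in groups.values()])
        assert len(all_dates) == len(set(all_dates))

    def test_empty_segment_excluded_with_warning(self):
        dates = pd.date_range("2020-01-01", periods=30, freq="D")
        rec = _records(np.ones(30), dates)
        with pytest.warns(UserWarning, match="no projection records"):
            groups = segment_residuals(rec, self._split())
        assert "a" not in groups and "b" not in groups


class TestOmnibusAndPosthoc:
    def test_identical_groups_h_zero(self):
        rep = omnibus_and_posthoc({"a": [2, 2, 2], "b": [2, 2, 2]})
        assert rep.kw_H == 0.0
        assert rep.posthoc.loc["a", "b"] == 1.0

    def test_hand_ranked_three_groups(self):
        groups = {"g1": [1, 2, 3], "g2": [4, 5, 6], "g3": [7, 8, 9]}
        rep = omnibus_and_posthoc(groups)
        oracle = brute_force_kruskal([np.array(v, float) for v in groups.values()])
        assert rep.kw_H == pytest.approx(oracle, abs=1e-12)
        assert rep.kw_df == 2

    def test_df_is_groups_minus_one(self):
        rng = np.random.default_rng(0)
        groups = {f"g{i}": rng.normal(size=10) for i in range(5)}
        rep = omnibus_and_posthoc(groups)
        assert rep.kw_df == 4

    def test_oracle_equivalence_exhaustive_small(self):
        """KW statistic matches the brute-force ranking oracle on every
        group-size configuration of total size <= 10 (with ties)."""
        rng = np.random.default_rng(1)
        configs = [
            (2, 2), (2, 3), (3, 3), (2, 2, 2), (2, 3, 4), (3, 3, 3), (2, 2, 3, 3), (2, 2, 2, 2, 2),
        ]
        for sizes in configs:
            vals = rng.integers(0, 5, size=sum(sizes)).astype(float)  # force ties
            groups, pos = [], 0
            for s in sizes:
                groups.append(vals[pos : pos + s])
                pos += s
            if np.ptp(vals) == 0:
                continue
            rep = omnibus_and_posthoc({f"g{i}": g for i, g in enumerate(groups)})
            assert rep.kw_H == pytest.approx(brute_force_kruskal(groups), abs=1e-10)

    def test_bonferroni_monotone_and_capped(self):
        rng = np.random.default_rng(2)
        groups = {f"g{i}": rng.normal(i * 0.5, 1, 20) for i in range(4)}
        rep = omnibus_and_posthoc(groups)
        from scipy import stats

        n_pairs = 6
        for a, b in combinations(groups, 2):
            raw = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue
            assert rep.posthoc.loc[a, b] == pytest.approx(min(1.0, raw * n_pairs))
        assert ((rep.posthoc.to_numpy() >= 0) & (rep.posthoc.to_numpy() <= 1)).all()
        assert np.allclose(rep.posthoc.to_numpy(), rep.posthoc.to_numpy().T)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            omnibus_and_posthoc({"only": [1, 2, 3]})


class TestSurrogate:
    def test_shuffle_preserves_values_and_is_deterministic(self):
        rng = np.random.default_rng(3)
        n = 260
        idx = pd.date_range("2020-01-01", periods=n, freq="D")
        s = pd.Series(np.abs(np.cumsum(rng.normal(0, 0.1, n))) + 1, index=idx)
        split = DatasetSplit(
            (idx[0], idx[130]), {"t1": (idx[130], idx[195]), "t2": (idx[195], idx[-1])}
        )
        rep1 = surrogate_control(s, None, ModelOrder(1, 0, 0), split, seed=7, train_len=100)
        rep2 = surrogate_control(s, None, ModelOrder(1, 0, 0), split, seed=7, train_len=100)
        assert rep1.kw_H == rep2.kw_H
        assert rep1.segment_mse == rep2.segment_mse

    def test_shuffled_ar1_loses_predictability(self):
        """On shuffled AR(1) data the fitted AR(1) should do no better than
        the series variance (autocorrelation destroyed)."""
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(40 + seed)
            n = 400
            x = np.zeros(n)
            for t in range(1, n):
                x[t] = 0.8 * x[t - 1] + rng.normal()
            idx = pd.date_range("2020-01-01", periods=n, freq="D")
            s = pd.Series(x, index=idx)
            shuffled = pd.Series(rng.permutation(x), index=idx)
            from szproject.forecast import fit_model, mse, rolling_projection

            rec = rolling_projection(shuffled, None, ModelOrder(1, 0, 0), 14, train_len=200)
            ratio = mse(rec) / shuffled.var()
            wins += 0.9 <= ratio <= 1.15
        assert wins >= 3


class TestMonitor:
    def _ref(self, rng):
        return rng.normal(0, 1, 100)

    def test_all_within_band_no_changepoints(self):
        rng = np.random.default_rng(5)
        dates = pd.date_range("2021-01-01", periods=60, freq="D")
        rec = _records(rng.normal(0, 0.5, 60), dates)
        st = monitor_residuals(rec, self._ref(rng), k_sd=3.0, persistence_days=14)
        assert not st.flags.any() and st.changepoints == []

    def test_step_excursion_two_changepoints(self):
        """A 30-day +5 SD excursion yields exactly an onset and a return."""
        rng = np.random.default_rng(6)
        ref = self._ref(rng)
        resid = np.zeros(120)
        resid[40:70] = 5.0  # 5 SD shift for 30 days
        dates = pd.date_range("2021-01-01", periods=120, freq="D")
        st = monitor_residuals(_records(resid, dates), ref, k_sd=3.0, persistence_days=14)
        assert len(st.changepoints) == 2
        assert st.changepoints[0] == dates[40]
        assert st.changepoints[1] == dates[70]

    def test_huge_band_never_flags(self):
        rng = np.random.default_rng(7)
        dates = pd.date_range("2021-01-01", periods=50, freq="D")
        rec = _records(rng.normal(0, 10, 50), dates)
        st = monitor_residuals(rec, self._ref(rng), k_sd=1e6)
        assert not st.flags.any()

    def test_short_flicker_ignored(self):
        rng = np.random.default_rng(8)
        resid = np.zeros(100)
        resid[50:53] = 9.0  # 3-day blip < persistence
        dates = pd.date_range("2021-01-01", periods=100, freq="D")
        st = monitor_residuals(_records(resid, dates), self._ref(rng), persistence_days=14)
        assert st.flags.sum() == 3 and st.changepoints == []

    def test_band_width_is_six_sd(self):
        rng = np.random.default_rng(9)
        ref = self._ref(rng)
        dates = pd.date_range("2021-01-01", periods=40, freq="D")
        st = monitor_residuals(_records(np.zeros(40), dates), ref)
        assert st.band[1] - st.band[0] == pytest.approx(6 * st.ref_sd)

    def test_reference_requirements(self):
        dates = pd.date_range("2021-01-01", periods=40, freq="D")
        rec = _records(np.zeros(40), dates)
        with pytest.raises(ValueError):
            monitor_residuals(rec, np.zeros(10))  # too few
        with pytest.raises(ValueError):
            monitor_residuals(rec, np.zeros(50))  # zero spread


class TestConcordance:
    def _events(self, n, seed=0):
        rng = np.random.default_rng(seed)
        ts = pd.Timestamp("2020-01-01") + pd.to_timedelta(
            np.sort(rng.uniform(0, 1000, n)), unit="D"
        )
        return EventSeries(pd.DatetimeIndex(ts))

    def test_paper_scale_fraction(self):
        det = self._events(3122)
        rep = EventSeries(det.timestamps[:1169])
        assert reporting_concordance(det, rep) == 37.44

    def test_zero_reported(self):
        det = self._events(50)
        assert reporting_concordance(det, EventSeries(pd.DatetimeIndex([]))) == 0.0

    def test_small_fraction_rounding(self):
        det = self._events(14)
        rep = EventSeries(det.timestamps[:4])
        assert reporting_concordance(det, rep) == 28.57

    def test_zero_detected_rejected(self):
        with pytest.raises(ValueError):
            reporting_concordance(EventSeries(pd.DatetimeIndex([])), EventSeries(pd.DatetimeIndex([])))

    def test_non_subset_rejected(self):
        det = self._events(10, seed=1)
        rep = self._events(5, seed=2)
        with pytest.raises(ValueError):
            reporting_concordance(det, rep)
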