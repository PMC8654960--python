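"""Window enumeration, normalization, preprocessing, splits, and I/O."""

import numpy as np
import pytest

import vitalembed as ve
from vitalembed.cohort import DRUG_CHANNELS

from conftest import make_record

VARS = ("SAO2", "ETCO2", "NIBPM", "PHENYL", "EPINE")


def _record_of_length(T, fill=95.0):
    sig = np.full((T, len(VARS)), fill)
    sig[:, -2:] = 0.0
    # make the anchor minute identifiable: signals[i] = i in channel 0
    sig[:, 0] = np.arange(T)
    return make_record(sig, VARS)


class TestEnumerateWindows:
    @pytest.mark.parametrize("T,expected", [(64, 0), (65, 1), (100, 36)])
    def test_window_counts(self, T, expected):
        rec = _record_of_length(T)
        assert len(ve.enumerate_windows(rec, stride=1)) == expected

    def test_count_formula_across_lengths(self):
        # every admissible 1-based anchor t satisfies 60 <= t <= T-5
        for T in range(1, 201):
            rec = _record_of_length(max(T, 1))
            wins = ve.enumerate_windows(rec, stride=1)
            oracle = [t for t in range(1, T + 1) if t >= 60 and t + 5 <= T]
            assert len(wins) == len(oracle) == max(0, T - 64)
            assert [w.anchor_t for w in wins] == oracle

    def test_first_window_anchor_and_content(self):
        rec = _record_of_length(65)
        (w,) = ve.enumerate_windows(rec)
        assert w.anchor_t == 60
        # history ends at the anchor minute, future starts right after
        assert w.history[0, -1] == rec.signals[59, 0]
        assert w.future[0, 0] == rec.signals[60, 0]
        assert w.history.shape == (len(VARS), 60)
        assert w.future.shape == (len(VARS), 5)

    def test_stride_subsamples_stride_one(self):
        rec = _record_of_length(150)
        all_w = ve.enumerate_windows(rec, stride=1)
        for s in (2, 3, 7):
            sub = ve.enumerate_windows(rec, stride=s)
            assert [w.anchor_t for w in sub] == [w.anchor_t for w in all_w][::s]

    def test_window_set_matches_per_record_enumeration(self):
        rec = _record_of_length(120)
        ws = ve.build_window_set([rec], stride=1)
        wins = ve.enumerate_windows(rec, stride=1)
        assert ws.n == len(wins)
        np.testing.assert_array_equal(ws.history[3], wins[3].history)
        np.testing.assert_array_equal(ws.future[-1], wins[-1].future)


class TestNormalization:
    def test_constant_variable_gets_unit_sd(self):
        sig = np.full((70, len(VARS)), 2.0)
        sig[:, -2:] = 0.0
        stats = ve.fit_normalization([make_record(sig, VARS)],
                                     variables=("SAO2",))
        m, s = stats.for_variable("SAO2")
        assert (m, s) == (2.0, 1.0)

    def test_population_sd_convention(self):
        sig = np.full((2, len(VARS)), np.nan)
        sig[0, 0], sig[1, 0] = 0.0, 2.0
        sig[:, 1:3] = 40.0
        sig[:, -2:] = 0.0
        stats = ve.fit_normalization([make_record(sig, VARS)],
                                     variables=("SAO2",))
        m, s = stats.for_variable("SAO2")
        assert m == 1.0 and s == 1.0  # population sd of {0, 2}, not sample

    def test_never_observed_variable_raises_with_name(self):
        sig = np.full((10, len(VARS)), np.nan)
        sig[:, 0] = 95.0
        sig[:, -2:] = 0.0
        with pytest.raises(ValueError, match="ETCO2"):
            ve.fit_normalization([make_record(sig, VARS)],
                                 variables=("SAO2", "ETCO2"))

    def test_all_missing_static_raises(self):
        sig = np.full((10, len(VARS)), 95.0)
        sig[:, -2:] = 0.0
        rec = make_record(sig, VARS, height=np.nan)
        with pytest.raises(ValueError, match="height"):
            ve.fit_normalization([rec], variables=("SAO2",))


class TestPreprocess:
    def _stats(self, mean=95.0):
        sig = np.full((70, len(VARS)), mean)
        sig[:, 1] = 40.0
        sig[:, 2] = 80.0
        sig[:, -2:] = 0.0
        return ve.fit_normalization(
            [make_record(sig, VARS)], variables=VARS[:3]
        )

    def test_missing_entries_get_train_mean(self):
        stats = self._stats(95.0)
        sig = np.full((70, len(VARS)), 97.0)
        sig[:, -2:] = 0.0
        sig[10, 0] = np.nan
        rec = make_record(sig, VARS)
        out = ve.preprocess(rec, stats, standardize=False)
        assert out.signals[10, 0] == 95.0
        assert out.signals[11, 0] == 97.0

    def test_standardize_centers_on_train_mean(self):
        stats = self._stats(95.0)
        sig = np.full((70, len(VARS)), 95.0)
        sig[:, 1] = 40.0
        sig[:, 2] = 80.0
        sig[:, -2:] = 0.0
        out = ve.preprocess(make_record(sig, VARS), stats, standardize=True)
        assert np.allclose(out.signals[:, 0], 0.0)

    def test_idempotent_on_fully_observed(self):
        stats = self._stats()
        sig = np.full((70, len(VARS)), 96.0)
        sig[:, -2:] = 0.0
        rec = make_record(sig, VARS)
        once = ve.preprocess(rec, stats, standardize=False)
        twice = ve.preprocess(once, stats, standardize=False)
        np.testing.assert_array_equal(once.signals, twice.signals)
        np.testing.assert_array_equal(rec.signals, once.signals)

    def test_drug_channels_imputed_to_zero_never_scaled(self):
        stats = self._stats()
        sig = np.full((70, len(VARS)), 96.0)
        sig[:, -2:] = np.nan
        out = ve.preprocess(make_record(sig, VARS), stats, standardize=True)
        for drug in DRUG_CHANNELS:
            j = out.var_index(drug)
            assert np.all(out.signals[:, j] == 0.0)

    def test_mask_preserved(self):
        stats = self._stats()
        sig = np.full((70, len(VARS)), 96.0)
        sig[5, 0] = np.nan
        sig[:, -2:] = 0.0
        rec = make_record(sig, VARS)
        out = ve.preprocess(rec, stats)
        np.testing.assert_array_equal(out.mask, rec.mask)


class TestSplit:
    def _records(self, n):
        sig = np.full((70, len(VARS)), 95.0)
        sig[:, -2:] = 0.0
        return [make_record(sig, VARS, stay_id=f"s{i}") for i in range(n)]

    def test_largest_remainder_counts(self):
        split = ve.split_by_stay(self._records(10), (0.8, 0.1, 0.1), seed=0)
        assert (len(split.train), len(split.val), len(split.test)) == (8, 1, 1)

    def test_deterministic_partition(self):
        recs = self._records(20)
        a = ve.split_by_stay(recs, (0.7, 0.15, 0.15), seed=3)
        b = ve.split_by_stay(recs, (0.7, 0.15, 0.15), seed=3)
        assert (a.train, a.val, a.test) == (b.train, b.val, b.test)

    def test_partition_is_disjoint_and_complete(self):
        recs = self._records(17)
        split = ve.split_by_stay(recs, (0.6, 0.2, 0.2), seed=1)
        parts = [set(split.train), set(split.val), set(split.test)]
        assert sum(len(p) for p in parts) == 17
        assert set.union(*parts) == {r.stay_id for r in recs}

    def test_too_few_stays_raises(self):
        with pytest.raises(ValueError):
            ve.split_by_stay(self._records(2), (0.5, 0.25, 0.25), seed=0)


class TestCohortIO:
    def test_csv_round_trip(self, tmp_path, tiny_cohort):
        _, records, _ = tiny_cohort
        prefix = tmp_path / "coh"
        ve.write_cohort(records, prefix, fmt="csv")
        back = ve.read_cohort(prefix, fmt="csv")
        assert len(back) == len(records)
        by_id = {r.stay_id: r for r in back}
        for rec in records:
            other = by_id[rec.stay_id]
            assert other.variables == rec.variables
            np.testing.assert_allclose(
                other.signals, np.where(rec.mask, rec.signals, np.nan),
                equal_nan=True, rtol=0, atol=1e-9,
            )
            np.testing.assert_array_equal(other.mask, rec.mask)
            np.testing.assert_allclose(
                other.static.to_array(), rec.static.to_array(), atol=1e-9
            )
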