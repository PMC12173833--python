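import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tedyn.io_formats import TECopyRecord
from tedyn.synthetic_data import BurstSpec, read_tree_from_string, simulate_te_copies
from tedyn.te_landscape import (
    build_landscape,
    detect_burst_peaks,
    dominant_families,
    insertion_time,
    kimura_correct,
    kimura_forward,
    landscape_summary,
    substitution_rate,
)


def _rec(family="fam", te_class="LTR", div=0.0, length=500, start=1):
    return TECopyRecord(
        scaffold="s", start=start, end=start + length - 1, strand="+",
        family_name=family, te_class=te_class, perc_div=div,
    )


class TestKimura:
    def test_zero_is_fixed_point(self):
        assert kimura_correct(0.0) == 0.0

    def test_worked_value(self):
        assert kimura_correct(10.0) == pytest.approx(10.7326, abs=5e-5)

    def test_near_saturation_finite(self):
        K = kimura_correct(74.9)
        assert np.isfinite(K)
        assert K == pytest.approx(496.505, abs=0.01)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            kimura_correct(75.0)

    @given(st.floats(min_value=0.0, max_value=74.0))
    @settings(max_examples=200, deadline=None)
    def test_correction_dominates_identity_and_inverts(self, d):
        k = kimura_correct(d)
        assert k >= d or k == pytest.approx(d, rel=1e-12)
        assert kimura_forward(k) == pytest.approx(d, abs=1e-9)

    @given(
        st.floats(min_value=0.0, max_value=74.0),
        st.floats(min_value=1e-6, max_value=74.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing(self, d, step):
        d2 = min(d + step, 74.5)
        assert kimura_correct(d2) > kimura_correct(d) or d2 == d


class TestInsertionTime:
    def test_zero(self):
        assert insertion_time(0.0, 0.005) == 0.0

    def test_worked_value(self):
        assert insertion_time(10.7326, 0.0049) == pytest.approx(10.952, abs=5e-4)

    def test_doubling_rate_halves_age(self):
        assert insertion_time(8.0, 0.002) == 2 * insertion_time(8.0, 0.004)

    def test_rate_must_be_positive(self):
        with pytest.raises(ValueError):
            insertion_time(1.0, 0.0)


class TestSubstitutionRate:
    def test_calibration_arithmetic(self):
        tree = read_tree_from_string("(deep:2.3765,other:1.0475);")
        assert substitution_rate(tree, "deep", 485.0) == pytest.approx(0.0049, abs=5e-6)
        assert substitution_rate(tree, "other", 485.0) == pytest.approx(0.00216, abs=5e-6)

    def test_missing_tip(self):
        tree = read_tree_from_string("(a:1,b:1);")
        with pytest.raises(KeyError):
            substitution_rate(tree, "zzz", 485.0)

    def test_zero_path_warns(self):
        tree = read_tree_from_string("(a:0.0,b:1);")
        with pytest.warns(UserWarning):
            assert substitution_rate(tree, "a", 485.0) == 0.0


class TestBuildLandscape:
    def test_fresh_copy_in_first_bin(self):
        ls = build_landscape([_rec(div=0.0, length=500)], r=0.005, bin_width=1.0)
        assert ls.total_profile[0] == 500
        assert ls.total_mass == 500

    def test_sharp_burst_occupies_single_bin(self):
        text, ledger = simulate_te_copies(
            [BurstSpec("f", "LTR", 200, age_mean=20.0, age_sd=0.0, rate_r=0.0049)],
            seed=0,
        )
        recs = [
            _rec(div=d, length=int(l), start=1 + 1000 * i)
            for i, (d, l) in enumerate(zip(ledger["perc_div"], ledger["copy_length"]))
        ]
        ls = build_landscape(recs, r=0.0049, bin_width=1.0)
        nonzero = np.nonzero(ls.total_profile)[0]
        assert len(nonzero) == 1
        assert ls.bin_edges[nonzero[0]] <= 20.0 < ls.bin_edges[nonzero[0] + 1]

    def test_mass_conservation_per_family(self):
        recs = [
            _rec("A", div=1.0, length=100),
            _rec("A", div=30.0, length=300),
            _rec("B", div=10.0, length=700),
        ]
        ls = build_landscape(recs, r=0.005)
        assert ls.matrix.loc["A"].sum() == 400
        assert ls.matrix.loc["B"].sum() == 700
        assert ls.total_mass == 1100

    def test_empty_records_warn(self):
        with pytest.warns(UserWarning):
            ls = build_landscape([], r=0.005)
        assert ls.total_mass == 0


class TestLandscapeSummary:
    def test_all_mass_in_window(self):
        recs = [_rec(div=kimura_forward(200 * 0.005 * 12.0), length=100)] * 3
        ls = build_landscape(recs, r=0.005)
        summary = landscape_summary(ls, [(10, 30)])
        assert summary.window_fractions[(10, 30)] == 1.0

    def test_uniform_ages_give_window_share(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(0, 50, size=4000)
        divs = kimura_forward(200 * 0.005 * ages)
        recs = [_rec(div=d, length=100) for d in divs]
        ls = build_landscape(recs, r=0.005)
        frac = landscape_summary(ls, [(0, 5)]).window_fractions[(0, 5)]
        assert frac == pytest.approx(0.10, abs=0.02)

    def test_partition_sums_to_one(self):
        rng = np.random.default_rng(1)
        divs = kimura_forward(200 * 0.005 * rng.uniform(0, 40, 500))
        recs = [_rec(div=d, length=100) for d in divs]
        ls = build_landscape(recs, r=0.005)
        fr = landscape_summary(ls, [(0, 10), (10.000001, 40)]).window_fractions
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_landscape_errors(self):
        with pytest.warns(UserWarning):
            ls = build_landscape([], r=0.005)
        with pytest.raises(ValueError):
            landscape_summary(ls, [(0, 5)])


class TestPeaks:
    def _burst_landscape(self, means, seed=0):
        specs = [
            BurstSpec(f"f{i}", "LTR", 2000, age_mean=m, age_sd=1.0, rate_r=0.0049)
            for i, m in enumerate(means)
        ]
        _, ledger = simulate_te_copies(specs, seed=seed)
        recs = [
            _rec(family=f, div=d, length=int(l))
            for f, d, l in zip(ledger["family"], ledger["perc_div"], ledger["copy_length"])
        ]
        return build_landscape(recs, r=0.0049, bin_width=1.0)

    def test_single_burst_peak_contains_truth(self):
        peaks = detect_burst_peaks(self._burst_landscape([20.0]))
        assert len(peaks) == 1
        lo, hi = peaks[0]
        assert lo <= 20.0 <= hi

    def test_two_bursts_two_peaks(self):
        peaks = detect_burst_peaks(self._burst_landscape([5.0, 25.0]))
        assert len(peaks) == 2
        covered = [lo <= m <= hi for m in (5.0, 25.0) for lo, hi in peaks]
        assert sum(covered) >= 2

    def test_flat_landscape_no_peaks(self):
        with pytest.warns(UserWarning):
            ls = build_landscape([], r=0.005)
        assert detect_burst_peaks(ls) == []


class TestDominantFamilies:
    def _records(self, shares):
        return [
            _rec(family=f"f{i}", te_class="LTR", div=1.0, length=int(s * 10000))
            for i, s in enumerate(shares)
        ]

    def test_minimal_prefix_over_half(self):
        out = dominant_families(self._records([0.43, 0.20, 0.15, 0.12, 0.10]))
        assert list(out["family"]) == ["f0", "f1"]
        assert out["cumulative_share"].iloc[-1] == pytest.approx(0.63, abs=1e-9)

    def test_single_family(self):
        out = dominant_families(self._records([1.0]))
        assert len(out) == 1
        assert out["share"].iloc[0] == 1.0

    def test_boundary_tie_includes_both(self):
        out = dominant_families(self._records([0.4, 0.3, 0.3]))
        # 0.4 + 0.3 crosses 0.5; the second 0.3 ties the last kept family
        assert len(out) == 3

    def test_unknown_only_errors(self):
        recs = [_rec(family="un", te_class="Unknown", div=1.0)]
        with pytest.raises(ValueError):
            dominant_families(recs)

    def test_unknown_excluded_from_denominator(self):
        recs = self._records([0.6, 0.4]) + [
            _rec(family="un", te_class="Unknown", div=1.0, length=100000)
        ]
        out = dominant_families(recs)
        assert list(out["family"]) == ["f0"]
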