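"""Chromosome-quotient core: modal depth, DQ rules, windowing, classification."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cqpipe import (
    CQConfig,
    DepthTrack,
    LocusStatus,
    ModalDepth,
    ModalDepthError,
    ScaffoldIndex,
    SexDepthPair,
    UndefinedMeanError,
    classify_scaffold,
    compute_window_ratios,
    estimate_modal_depth,
    normalize_and_flag,
    verify_hemizygosity,
)
from cqpipe.core import NormalizedLoci, modal_window_ratio

CFG = CQConfig()
SMALL = CQConfig(min_scaffold_len=10)


def make_track(depths, scaffold="s1"):
    depths = np.asarray(depths)
    return DepthTrack(scaffold, np.arange(1, len(depths) + 1), depths)


def make_pair(male, female, scaffold="s1"):
    male, female = np.asarray(male), np.asarray(female)
    return SexDepthPair(
        scaffold, np.arange(1, len(male) + 1), male, female
    )


def normalized(pair, male_mode=65, female_mode=60, config=SMALL):
    return normalize_and_flag(
        pair,
        ModalDepth("male", male_mode),
        ModalDepth("female", female_mode),
        config,
    )


class TestEstimateModalDepth:
    def test_constant_depth_is_its_own_mode(self):
        mode = estimate_modal_depth({"s1": make_track([10] * 20)}, SMALL)
        assert mode.value == 10

    def test_argmax_of_histogram_excluding_zeros(self):
        # hand-built histogram: 58 x600, 30 x100, 116 x50, 0 x200 -> mode 58
        depths = [58] * 600 + [30] * 100 + [116] * 50 + [0] * 200
        mode = estimate_modal_depth({"s1": make_track(depths)}, SMALL)
        assert mode.value == 58
        assert 0 not in mode.histogram
        assert mode.histogram[58] == 600 and mode.histogram[116] == 50

    def test_tie_breaks_toward_smaller_depth(self):
        depths = [40] * 100 + [50] * 100
        mode = estimate_modal_depth({"s1": make_track(depths)}, SMALL)
        assert mode.value == 40

    def test_short_scaffolds_excluded_via_index(self):
        tracks = {
            "long": make_track([20] * 50, "long"),
            "short": make_track([90] * 200, "short"),
        }
        index = ScaffoldIndex({"long": 1000, "short": 5})
        mode = estimate_modal_depth(
            tracks, CQConfig(min_scaffold_len=100), index
        )
        assert mode.value == 20

    def test_no_qualifying_loci_is_estimation_error(self):
        with pytest.raises(ModalDepthError, match="min_scaffold_len"):
            estimate_modal_depth({"s1": make_track([0, 0, 0])}, SMALL)
        with pytest.raises(ModalDepthError):
            estimate_modal_depth({}, SMALL)


class TestNormalizeAndFlag:
    """The three DQ rules, enumerated over (male, female) raw depth pairs.

    With modes (65, 60) and max normalized depth 3: male 0 disqualifies,
    normalized depth > 3 in either sex disqualifies, female 0 is retained
    with ratio exactly 0.
    """

    @pytest.mark.parametrize(
        "m, f, status",
        [
            (0, 12, LocusStatus.DQ_MALE_ZERO),
            (0, 0, LocusStatus.DQ_MALE_ZERO),
            (0, 500, LocusStatus.DQ_MALE_ZERO),  # male-zero wins over high depth
            (65, 60, LocusStatus.OK),
            (65, 0, LocusStatus.OK),  # candidate male-specific locus
            (1, 1, LocusStatus.OK),
            (195, 180, LocusStatus.OK),  # exactly 3.0x in both sexes: not > 3
            (196, 60, LocusStatus.DQ_HIGH_DEPTH),  # male_norm > 3
            (260, 60, LocusStatus.DQ_HIGH_DEPTH),  # 260/65 = 4.0
            (65, 181, LocusStatus.DQ_HIGH_DEPTH),  # female_norm > 3
            (300, 300, LocusStatus.DQ_HIGH_DEPTH),
        ],
    )
    def test_dq_rules_enumerated(self, m, f, status):
        loci = normalized(make_pair([m], [f]))
        assert LocusStatus(loci.status[0]) == status

    def test_identity_normalization(self):
        loci = normalized(make_pair([65], [60]))
        locus = loci[0]
        assert locus.male_norm == 1.0 and locus.female_norm == 1.0
        assert locus.ratio == 1.0 and locus.status == LocusStatus.OK

    def test_female_zero_retained_with_ratio_exactly_zero(self):
        loci = normalized(make_pair([65], [0]))
        assert loci[0].status == LocusStatus.OK
        assert loci[0].ratio == 0.0

    def test_ratio_is_nan_at_disqualified_loci(self):
        loci = normalized(make_pair([0, 260], [12, 60]))
        assert np.isnan(loci.ratio).all()

    @given(
        m=st.lists(st.integers(0, 400), min_size=1, max_size=60),
        f=st.lists(st.integers(0, 400), min_size=1, max_size=60),
    )
    def test_ok_loci_never_violate_dq_invariants(self, m, f):
        n = min(len(m), len(f))
        loci = normalized(make_pair(m[:n], f[:n]))
        ok = loci.ok
        assert not np.any(loci.male_raw[ok] == 0)
        assert np.all(loci.male_norm[ok] <= SMALL.max_norm_depth)
        assert np.all(loci.female_norm[ok] <= SMALL.max_norm_depth)
        assert np.all(loci.ratio[ok] >= 0)


def brute_force_windows(loci, scaffold_length, config):
    """Direct per-window enumeration oracle for the windowed mean ratio."""
    out = []
    w = config.window_size
    for start in range(1, scaffold_length + 1, w):
        end = min(start + w - 1, scaffold_length)
        ratios = [
            loci[i].ratio
            for i in range(len(loci))
            if start <= loci[i].position <= end
            and loci[i].status == LocusStatus.OK
        ]
        if ratios:
            out.append((start, end, sum(ratios) / len(ratios), len(ratios)))
    return out


class TestComputeWindowRatios:
    def test_five_uniform_loci_make_one_window(self):
        loci = normalized(make_pair([65] * 5, [60] * 5))
        table = compute_window_ratios(loci, 5, SMALL)
        assert len(table) == 1
        (w,) = list(table)
        assert (w.start, w.end, w.n_loci) == (1, 5, 5)
        assert w.mean_ratio == pytest.approx(1.0)

    def test_mean_taken_over_ok_loci_only(self):
        # ratios (2, 2, DQ, 2, 2): the male-zero locus is excluded
        loci = normalized(make_pair([65, 65, 0, 65, 65], [120, 120, 9, 120, 120]))
        table = compute_window_ratios(loci, 5, SMALL)
        (w,) = list(table)
        assert w.n_loci == 4
        assert w.mean_ratio == pytest.approx((120 / 60) / 1.0)

    def test_all_dq_window_omitted(self):
        loci = normalized(make_pair([0] * 5, [60] * 5))
        assert len(compute_window_ratios(loci, 5, SMALL)) == 0

    def test_final_partial_window_kept(self):
        loci = normalized(make_pair([65] * 7, [60] * 7))
        table = compute_window_ratios(loci, 7, SMALL)
        last = list(table)[-1]
        assert (last.start, last.end, last.n_loci) == (6, 7, 2)
        assert last.mean_ratio == pytest.approx(1.0)

    @given(
        depths=st.lists(
            st.tuples(st.integers(0, 250), st.integers(0, 250)),
            min_size=1,
            max_size=200,
        ),
        gap=st.integers(1, 3),
        window=st.integers(1, 9),
    )
    def test_matches_brute_force_oracle(self, depths, gap, window):
        """Vectorized windowing equals per-window enumeration exactly."""
        m, f = zip(*depths)
        positions = np.arange(1, len(depths) * gap + 1, gap)
        pair = SexDepthPair("s1", positions, np.array(m), np.array(f))
        cfg = CQConfig(window_size=window, min_scaffold_len=10)
        loci = normalized(pair, config=cfg)
        length = int(positions[-1])
        got = [
            (w.start, w.end, w.mean_ratio, w.n_loci)
            for w in compute_window_ratios(loci, length, cfg)
        ]
        expected = brute_force_windows(loci, length, cfg)
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            assert g[0] == e[0] and g[1] == e[1] and g[3] == e[3]
            assert g[2] == pytest.approx(e[2])
        assert len(got) <= math.ceil(length / window)
        assert all(w.n_loci >= 1 for w in compute_window_ratios(loci, length, cfg))


class TestModalWindowRatio:
    def test_boundary_value_falls_in_upper_bin(self):
        # 1.0 sits on a bin edge; it belongs to [1.0, 1.1)
        assert modal_window_ratio(np.array([1.0, 1.0, 0.95]), CFG) == pytest.approx(1.05)

    def test_tie_breaks_toward_lower_bin(self):
        assert modal_window_ratio(np.array([0.55, 1.25]), CFG) == pytest.approx(0.55)

    def test_values_beyond_top_edge_clip_into_last_bin(self):
        assert modal_window_ratio(np.array([50.0, 60.0]), CFG) == pytest.approx(3.95)


def window_table(mean_ratios, scaffold="s1", w=5):
    from cqpipe.core import WindowTable

    n = len(mean_ratios)
    start = np.arange(n) * w + 1
    return WindowTable(
        scaffold, start, start + w - 1,
        np.asarray(mean_ratios, dtype=float),
        np.full(n, w),
    )


class TestClassifyScaffold:
    def test_ratios_near_one_is_autosome(self):
        res = classify_scaffold(window_table([1.0] * 1000), None, 2_000_000, CFG)
        assert res.label == "AUTOSOME"
        assert res.modal_ratio == pytest.approx(1.05)

    def test_ratio_peak_near_two_is_x_linked(self, rng):
        ratios = rng.normal(2.0, 0.15, size=5000)
        res = classify_scaffold(window_table(ratios), None, 20_000_000, CFG)
        assert res.label == "X_LINKED"

    def test_high_frequency_near_zero_is_y_linked(self):
        ratios = [0.02] * 90 + [1.0] * 10
        res = classify_scaffold(window_table(ratios), None, 1_100_000, CFG)
        assert res.label == "Y_LINKED"
        assert res.frac_low_ratio == pytest.approx(0.9)

    def test_short_scaffold_unassigned_regardless_of_windows(self):
        res = classify_scaffold(window_table([1.0] * 50), None, 500_000, CFG)
        assert res.label == "UNASSIGNED_SHORT"

    def test_no_windows_is_ambiguous_with_nan_diagnostics(self):
        res = classify_scaffold(window_table([]), None, 2_000_000, CFG)
        assert res.label == "AMBIGUOUS" and res.n_windows == 0
        assert math.isnan(res.modal_ratio) and math.isnan(res.mean_male_norm)

    def test_intermediate_modal_ratio_is_ambiguous(self):
        res = classify_scaffold(window_table([1.5] * 100), None, 2_000_000, CFG)
        assert res.label == "AMBIGUOUS"

    def test_y_precedence_over_band_membership(self):
        # majority of windows at 0 but a minor mode near 1: still Y
        ratios = [0.02] * 70 + [1.0] * 30
        res = classify_scaffold(window_table(ratios), None, 1_100_000, CFG)
        assert res.label == "Y_LINKED"


class TestVerifyHemizygosity:
    @staticmethod
    def loci_with_male_norm(values):
        values = np.asarray(values, dtype=float)
        n = len(values)
        return NormalizedLoci(
            "sY", np.arange(1, n + 1), (values * 65).astype(np.int64),
            np.zeros(n, np.int64), values, np.zeros(n), np.zeros(n),
            np.zeros(n, np.int8),
        )

    def test_half_coverage_flags_hemizygous(self):
        mean, flag = verify_hemizygosity(self.loci_with_male_norm([0.5] * 10), CFG)
        assert mean == pytest.approx(0.5) and flag

    def test_full_coverage_does_not_flag(self):
        mean, flag = verify_hemizygosity(self.loci_with_male_norm([1.0] * 10), CFG)
        assert mean == pytest.approx(1.0) and not flag

    def test_poisson_half_coverage_converges_to_half(self, rng):
        # law of large numbers: Poisson(32)/65 over 1e5 loci -> mean ~ 0.492
        values = rng.poisson(32, size=100_000) / 65
        mean, flag = verify_hemizygosity(self.loci_with_male_norm(values), CFG)
        assert 0.45 <= mean <= 0.55 and flag

    def test_zero_retained_loci_is_undefined_mean(self):
        loci = self.loci_with_male_norm([0.5])
        loci.status[:] = LocusStatus.DQ_MALE_ZERO
        with pytest.raises(UndefinedMeanError):
            verify_hemizygosity(loci, CFG)


class TestScaleInvariance:
    def test_scaling_one_sex_by_integer_constant_preserves_ratios(self, rng):
        """Multiplying all male depths by k scales the male mode by k and
        leaves every window ratio unchanged (below the DQ cutoff)."""
        m = rng.poisson(65, size=400) + 1  # avoid male zeros
        f = rng.poisson(60, size=400)
        k = 3
        cfg = CQConfig(min_scaffold_len=10)
        base = normalized(make_pair(m, f), 65, 60, cfg)
        scaled = normalized(make_pair(m * k, f), 65 * k, 60, cfg)
        assert np.array_equal(base.status, scaled.status)
        w1 = compute_window_ratios(base, 400, cfg)
        w2 = compute_window_ratios(scaled, 400, cfg)
        assert np.array_equal(w1.start, w2.start)
        np.testing.assert_allclose(w1.mean_ratio, w2.mean_ratio, rtol=1e-12)
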