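"""Binned frequencies, coding potential, overlap, regression and h(x)."""

import numpy as np
import pytest

from orfdom import (
    BIN_MEDIANS,
    BinnedDistribution,
    KaKsRecord,
    OrfProfile,
    bin_scores,
    coding_potential,
    fit_potential_regression,
    negative_selection_frequency,
    overlap_score,
    predict_potential,
    stratify_distributions,
)
from orfdom.distributions import bin_index

from oracles import ols_closed_form, tally_bins


def make_dist(freqs, total=1000, kind="dominance"):
    counts = np.rint(np.asarray(freqs) * total).astype(int)
    return BinnedDistribution(score_kind=kind, counts=counts, total=int(counts.sum()))


def make_profile(tid, dominance, label="coding"):
    return OrfProfile(
        transcript_id=tid, transcript_length=1000, porf_length=100,
        secorf_lengths=[], dominance=dominance, coverage=0.3, label=label,
    )


class TestBinning:
    def test_degenerate_all_ones(self):
        d = bin_scores([1.0, 1.0])
        assert d.counts[9] == 2 and d.freqs[9] == 1.0 and d.freqs[:9].sum() == 0

    def test_ncym_score_falls_in_the_055_bin(self):
        assert BIN_MEDIANS[bin_index(0.568)] == 0.55

    @pytest.mark.parametrize(
        "score, median",
        [(0.05, 0.05), (0.1, 0.15), (0.3, 0.35), (0.5, 0.55), (1.0, 0.95)],
    )
    def test_edge_scores_go_to_the_higher_bin(self, score, median):
        assert BIN_MEDIANS[bin_index(score)] == median

    @pytest.mark.parametrize("score", [0.0, -0.1, 1.2])
    def test_scores_outside_unit_interval_are_rejected(self, score):
        with pytest.raises(ValueError):
            bin_index(score)

    def test_counts_match_direct_tally_on_uniform_draws(self, rng):
        scores = 1.0 - rng.random(1000)  # uniform over (0, 1]
        d = bin_scores(scores)
        assert np.array_equal(d.counts, tally_bins(scores))
        assert d.total == 1000

    def test_frequencies_sum_to_one(self, rng):
        scores = 1.0 - rng.random(500)
        d = bin_scores(scores)
        assert d.freqs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_input_gives_undefined_frequencies(self):
        d = bin_scores([])
        assert d.total == 0 and np.isnan(d.freqs).all()


class TestCodingPotential:
    def test_worked_example_at_015(self):
        """f(0.15)=0.060, g(0.15)=0.268 gives F(0.15)=0.183."""
        f = make_dist([0.0, 0.060, 0.1, 0.1, 0.1, 0.44, 0.1, 0.05, 0.03, 0.02])
        g = make_dist([0.5, 0.268, 0.1, 0.05, 0.03, 0.022, 0.01, 0.01, 0.005, 0.005])
        F = coding_potential(f, g)
        assert F.values[1] == pytest.approx(0.060 / 0.328, abs=5e-4)
        assert round(F.values[1], 3) == 0.183

    def test_pure_coding_bin_and_symmetry(self):
        f = make_dist([0.2, 0.1, 0.7, 0, 0, 0, 0, 0, 0, 0])
        g = make_dist([0.0, 0.1, 0.0, 0, 0, 0, 0, 0, 0, 0.9])
        F = coding_potential(f, g)
        assert F.values[0] == 1.0  # g = 0 with f > 0
        assert F.values[1] == pytest.approx(0.5)  # f = g
        assert np.isnan(F.values[3])  # both empty -> undefined

    def test_values_lie_in_unit_interval(self, rng):
        f = bin_scores(1.0 - rng.random(400))
        g = bin_scores(1.0 - rng.random(400))
        vals = coding_potential(f, g).values
        assert np.all((vals[np.isfinite(vals)] >= 0) & (vals[np.isfinite(vals)] <= 1))

    def test_mismatched_score_kinds_error(self):
        f = make_dist([0.1] * 10, kind="dominance")
        g = make_dist([0.1] * 10, kind="coverage")
        with pytest.raises(ValueError, match="score kinds differ"):
            coding_potential(f, g)


class TestOverlap:
    def test_identical_distributions_overlap_fully(self):
        f = make_dist([0.1] * 10)
        assert overlap_score(f, f).O == pytest.approx(1.0)

    def test_disjoint_supports_do_not_overlap(self):
        f = make_dist([0.5, 0.5] + [0] * 8)
        g = make_dist([0] * 8 + [0.5, 0.5])
        assert overlap_score(f, g).O == 0.0

    def test_half_overlap_hand_case(self):
        f = make_dist([0.5, 0.5] + [0] * 8)
        g = make_dist([0, 0.5, 0.5] + [0] * 7)
        assert overlap_score(f, g).O == pytest.approx(0.5)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            f = bin_scores(1.0 - rng.random(200))
            g = bin_scores(1.0 - rng.random(50))
            o_fg = overlap_score(f, g).O
            assert o_fg == pytest.approx(overlap_score(g, f, min_noncoding=0).O)
            assert 0 <= o_fg <= 1

    def test_too_few_noncoding_transcripts_error(self):
        f = make_dist([0.1] * 10)
        g = BinnedDistribution("dominance", np.array([2] + [0] * 9), 2)
        with pytest.raises(ValueError, match="at least 3"):
            overlap_score(f, g)
        with pytest.raises(ValueError, match="non-empty"):
            overlap_score(f, BinnedDistribution("dominance", np.zeros(10, int), 0))


class TestRegression:
    @staticmethod
    def table(values):
        from orfdom import CodingPotentialTable

        return CodingPotentialTable(values=np.asarray(values, dtype=float))

    def test_exact_linear_recovery(self):
        y = 0.9 * BIN_MEDIANS + 0.05
        fit = fit_potential_regression(self.table(y))
        assert fit.slope == pytest.approx(0.9, abs=1e-9)
        assert fit.intercept == pytest.approx(0.05, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.bins_used == [0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65]

    def test_flat_potential_recovers_constant(self):
        fit = fit_potential_regression(self.table([0.4] * 10))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.4)
        assert 0 <= fit.r_squared <= 1

    def test_noisy_fit_matches_closed_form_oracle(self, rng):
        y = 1.3 * BIN_MEDIANS + 0.02 + rng.normal(0, 0.01, size=10)
        fit = fit_potential_regression(self.table(y))
        mask = BIN_MEDIANS <= 0.65 + 1e-9
        slope, intercept = ols_closed_form(BIN_MEDIANS[mask], y[mask])
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)
        assert abs(fit.slope - 1.3) < 0.1

    def test_underpopulated_bins_are_eliminated(self):
        y = 1.0 * BIN_MEDIANS
        counts = [2, 10, 10, 10, 10, 10, 10, 10, 10, 10]
        fit = fit_potential_regression(self.table(y), bin_counts=counts)
        assert 0.05 not in fit.bins_used

    def test_too_few_usable_bins_error(self):
        vals = [0.1, 0.2, np.nan, np.nan, np.nan, np.nan, np.nan] + [0.9] * 3
        with pytest.raises(ValueError, match="at least 3"):
            fit_potential_regression(self.table(vals))

    def test_prediction_reproduces_printed_human_fits(self):
        """Published human fits evaluated at the NCYM dominance 0.568."""
        from orfdom import RegressionFit, round_half_up

        refseq = RegressionFit(slope=1.313, intercept=0.0189, r_squared=0.990)
        ensembl = RegressionFit(slope=1.301, intercept=0.0072, r_squared=0.984)
        assert round_half_up(predict_potential(refseq, 0.568)) == 0.765
        assert round_half_up(predict_potential(ensembl, 0.568)) == 0.746
        assert predict_potential(refseq, 0.0) == pytest.approx(0.0189)

    def test_prediction_is_clamped_and_warns_above_x_max(self):
        from orfdom import RegressionFit

        fit = RegressionFit(slope=1.313, intercept=0.0189, r_squared=0.99)
        with pytest.warns(UserWarning, match="exceeds the fitted range"):
            assert predict_potential(fit, 0.95) <= 1.0
        assert predict_potential(RegressionFit(-1, 0.0, 1.0), 0.5) == 0.0


class TestNegativeSelection:
    def test_all_under_and_all_over_threshold(self):
        profiles = [make_profile(f"t{i}", 0.05 + 0.1 * i) for i in range(10)]
        under = [KaKsRecord(f"t{i}", ka=0.1, ks=1.0) for i in range(10)]
        over = [KaKsRecord(f"t{i}", ka=0.8, ks=1.0) for i in range(10)]
        assert np.all(negative_selection_frequency(under, profiles).h == 1.0)
        assert np.all(negative_selection_frequency(over, profiles).h == 0.0)

    def test_outlier_and_zero_ks_records_are_excluded(self):
        profiles = [make_profile("a", 0.55), make_profile("b", 0.55)]
        records = [
            KaKsRecord("a", ka=0.1, ks=0.5),   # ratio 0.2: selected
            KaKsRecord("b", ka=1.5, ks=0.5),   # Ka > 1: outlier
            KaKsRecord("a", ka=0.1, ks=1.2),   # Ks > 1: outlier
            KaKsRecord("b", ka=0.1, ks=0.0),   # undefined ratio
        ]
        tab = negative_selection_frequency(records, profiles)
        assert tab.n_total[5] == 1 and tab.h[5] == 1.0
        assert np.isnan(tab.h[0])

    def test_matches_direct_tally_and_order_invariance(self, rng):
        n = 200
        doms = 1.0 - rng.random(n)
        ratios = rng.random(n) * 1.0
        profiles = [make_profile(f"t{i}", doms[i]) for i in range(n)]
        records = [KaKsRecord(f"t{i}", ka=ratios[i], ks=1.0) for i in range(n)]
        tab = negative_selection_frequency(records, profiles)
        expect_tot = tally_bins(doms)
        expect_sel = tally_bins(doms[ratios < 0.5]) if (ratios < 0.5).any() else 0
        assert np.array_equal(tab.n_total, expect_tot)
        assert np.array_equal(tab.n_selected, expect_sel)
        shuffled = list(records)
        rng.shuffle(shuffled)
        tab2 = negative_selection_frequency(shuffled, profiles)
        assert np.array_equal(tab.n_selected, tab2.n_selected)
        assert np.array_equal(tab.n_total, tab2.n_total)


class TestStratify:
    def test_single_group_equals_plain_binning(self):
        profiles = [make_profile(f"t{i}", 0.05 + 0.09 * i) for i in range(10)]
        strata = stratify_distributions(profiles, {p.transcript_id: "all" for p in profiles})
        direct = bin_scores([p.dominance for p in profiles])
        assert np.array_equal(strata["all"].counts, direct.counts)

    def test_group_totals_partition_the_whole(self, rng):
        n = 90
        profiles = [make_profile(f"t{i}", 1.0 - rng.random()) for i in range(n)]
        keys = rng.integers(0, 3, size=n)
        groups = {f"t{i}": int(keys[i]) for i in range(n)}
        strata = stratify_distributions(profiles, groups)
        assert sum(d.total for d in strata.values()) == n
        for key in set(keys):
            members = [profiles[i].dominance for i in range(n) if keys[i] == key]
            assert np.array_equal(strata[int(key)].counts, tally_bins(members))

    def test_unknown_ids_are_reported(self):
        profiles = [make_profile("known", 0.5)]
        with pytest.raises(KeyError, match="ghost"):
            stratify_distributions(profiles, {"known": 1, "ghost": 2})
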