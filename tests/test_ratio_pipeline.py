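"""Treatment/control ratio pipeline: cleaning, per-case metrics, fixtures."""

import math

import numpy as np
import pandas as pd
import pytest

from pulsestab import (
    CleaningConfig,
    FixtureConfig,
    RatioCase,
    case_metrics,
    cases_to_frame,
    clean_dataset,
    frame_to_cases,
    generate_fixture_dataset,
    group_growth_rate,
    lrr_to_ratio,
    rgr,
    summarise_groups,
)
from pulsestab.ratio_pipeline import analyse_cases, latent_recovery


class TestLrrToRatio:
    @pytest.mark.parametrize(
        "lrr, expected", [(0.0, 1.0), (math.log(2.0), 2.0), (-math.log(2.0), 0.5)]
    )
    def test_exponentiation(self, lrr, expected):
        assert lrr_to_ratio(lrr) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            lrr_to_ratio(math.nan)


class TestRgr:
    @pytest.mark.parametrize(
        "w_i, w_t, dt, expected",
        [
            (1.0, 2.0, 1.0, math.log(2.0)),  # doubling in a day
            (3.0, 3.0, 5.0, 0.0),
            (2.0, 1.0, 2.0, -math.log(2.0) / 2.0),
        ],
    )
    def test_formula(self, w_i, w_t, dt, expected):
        assert rgr(w_i, w_t, dt) == pytest.approx(expected)

    @pytest.mark.parametrize("args", [(0.0, 1.0, 1.0), (1.0, -1.0, 1.0), (1.0, 2.0, 0.0)])
    def test_domain_errors(self, args):
        with pytest.raises(ValueError):
            rgr(*args)


class TestGroupGrowthRate:
    def test_mean_and_permutation_invariance(self):
        assert group_growth_rate([0.6, 0.8], min_estimates=2) == pytest.approx(0.7)
        assert group_growth_rate([0.8, 0.6], min_estimates=2) == pytest.approx(0.7)

    def test_single_estimate_warns(self):
        with pytest.warns(UserWarning):
            assert group_growth_rate([0.3]) == pytest.approx(0.3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            group_growth_rate([])


class TestCaseMetrics:
    def test_hand_computed_example(self):
        """Ratio series 1.0 (pre), 0.2, 0.6 with the disturbance just
        after t=0: resistance 0.2, recovery 0.6, resilience
        -((0.4-0.8)/0.6)/1 = 2/3 on the displacement |ratio - 1|."""
        case = RatioCase(
            case_id="hand",
            group="g",
            times=[0.0, 1.0, 2.0],
            lrr=np.log([1.0, 0.2, 0.6]),
            growth_rate=1.0,
            t_dist=0.5,
        )
        rep = case_metrics(case)
        assert rep.realised_resistance == pytest.approx(0.2)
        assert rep.realised_recovery == pytest.approx(0.6)
        assert rep.realised_resilience == pytest.approx(2.0 / 3.0)

    def test_undisturbed_case_flags_resilience(self):
        case = RatioCase(
            case_id="flat",
            group="g",
            times=[0.0, 1.0, 2.0],
            lrr=[0.0, 0.0, 0.0],
            growth_rate=0.5,
        )
        rep = case_metrics(case)
        assert rep.realised_resistance == pytest.approx(1.0)
        assert rep.realised_recovery == pytest.approx(1.0)
        assert math.isnan(rep.realised_resilience)

    def test_missing_growth_rate_gives_realised_only(self):
        case = RatioCase(
            case_id="norate",
            group="g",
            times=[0.0, 1.0, 2.0],
            lrr=np.log([0.2, 0.5, 0.9]),
        )
        rep = case_metrics(case, r_fast=1.0, dt_fast=0.1, tau_ref=1.0)
        assert not math.isnan(rep.realised_recovery)
        assert math.isnan(rep.intrinsic_recovery)
        assert math.isnan(rep.intrinsic_resilience)


class TestFixtureGenerator:
    def test_deterministic_in_seed(self):
        a = generate_fixture_dataset(seed=5)
        b = generate_fixture_dataset(seed=5)
        c = generate_fixture_dataset(seed=6)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert x.case_id == y.case_id
            np.testing.assert_array_equal(x.times, y.times)
            np.testing.assert_array_equal(x.lrr, y.lrr)
        assert any(
            not np.array_equal(x.lrr, y.lrr) for x, y in zip(a, c)
        )

    def test_group_rates_span_empirical_range(self):
        cases = generate_fixture_dataset(seed=0)
        rates = {c.growth_rate for c in cases if not c.case_id.startswith("sparse")}
        assert min(rates) == pytest.approx(0.08)
        assert max(rates) == pytest.approx(1.38)

    def test_noise_free_recovery_matches_latent_curve(self):
        cfg = FixtureConfig(noise_sd=0.0)
        for case in generate_fixture_dataset(cfg, seed=1):
            if case.case_id.startswith(("sparse", "outlier")):
                continue
            rep = case_metrics(case)
            expected = latent_recovery(
                case.growth_rate * case.times[-1], cfg.drop_fraction
            )
            assert rep.realised_recovery == pytest.approx(expected, rel=1e-9)


class TestCleaning:
    def test_removes_exactly_the_injected_violations(self):
        """The under-sampled group fails the 10-observation rule and the
        three extreme-resistance cases exceed 50x the median; nothing else
        is touched."""
        cases = generate_fixture_dataset(seed=2)
        kept, log = clean_dataset(cases)
        excluded = {e["case_id"] for e in log}
        assert excluded == {
            c.case_id
            for c in cases
            if c.case_id.startswith(("sparse", "outlier"))
        }
        rules = sorted(e["rule"] for e in log)
        assert rules.count("group_size") == 3
        assert rules.count("resistance_outlier") == 3
        assert len(kept) == len(cases) - 6

    def test_idempotent(self):
        cases = generate_fixture_dataset(seed=3)
        once, _ = clean_dataset(cases)
        twice, log2 = clean_dataset(once)
        assert [c.case_id for c in twice] == [c.case_id for c in once]
        assert log2 == []

    def test_identity_when_no_rule_triggers(self):
        cfg = FixtureConfig(n_sparse_cases=0, n_outliers=0)
        cases = generate_fixture_dataset(cfg, seed=4)
        kept, log = clean_dataset(cases)
        assert len(kept) == len(cases)
        assert all(a is b for a, b in zip(kept, cases))
        assert log == []

    def test_exclusion_list_drops_named_group(self):
        cases = generate_fixture_dataset(seed=1)
        cleaning = CleaningConfig(excluded_groups=("grasses",))
        kept, log = clean_dataset(cases, cleaning)
        assert not any(c.group == "grasses" for c in kept)
        assert any(e["rule"] == "excluded_group" for e in log)

    def test_count_mode_cases(self):
        cases = generate_fixture_dataset(seed=1)
        cleaning = CleaningConfig(min_observations=4, count_mode="cases")
        kept, log = clean_dataset(cases, cleaning)
        # sparse group has only 3 cases -> still excluded when counting cases
        assert not any(c.group == "mosses" for c in kept)


class TestGroupInvariance:
    def test_intrinsic_metrics_equal_across_groups_on_noise_free_data(self):
        """All groups share one latent recovery curve in tau, so after
        growth-rate correction their recovery/resistance/resilience
        coincide, while realised resilience still tracks r."""
        cfg = FixtureConfig(noise_sd=0.0, n_sparse_cases=0, n_outliers=0)
        cases = generate_fixture_dataset(cfg, seed=7)
        reports, log = analyse_cases(cases)
        assert log == []
        for col in ("intrinsic_recovery", "intrinsic_resistance"):
            vals = reports[col].dropna()
            assert len(vals) == len(reports)
            spread = (vals.max() - vals.min()) / vals.mean()
            assert spread < 0.01, col
        by_rate = reports.groupby("growth_rate")["realised_resilience"].mean()
        assert by_rate.is_monotonic_increasing

    def test_intrinsic_resilience_equal_across_groups(self):
        """The first post-disturbance observation pair sits at the same
        tau coordinates for every case, so the growth-rate-corrected
        resilience coincides across groups on noise-free data."""
        cfg = FixtureConfig(noise_sd=0.0, n_sparse_cases=0, n_outliers=0)
        reports, _ = analyse_cases(generate_fixture_dataset(cfg, seed=8))
        by_rate = reports.groupby("growth_rate")["intrinsic_resilience"].mean()
        spread = (by_rate.max() - by_rate.min()) / by_rate.mean()
        assert spread < 0.01


class TestSummaries:
    def test_median_and_mean(self):
        reports = pd.DataFrame(
            {
                "case_id": ["a", "b", "c"],
                "group": ["g", "g", "g"],
                "growth_rate": [0.5] * 3,
                "realised_temporal_stability": [1.0] * 3,
                "realised_resistance": [0.5] * 3,
                "realised_recovery": [0.5, 1.0, 1.5],
                "realised_resilience": [0.1] * 3,
                "intrinsic_temporal_stability": [math.nan] * 3,
                "intrinsic_resistance": [math.nan] * 3,
                "intrinsic_recovery": [math.nan] * 3,
                "intrinsic_resilience": [math.nan] * 3,
            }
        )
        summary = summarise_groups(reports)
        row = summary[summary["metric"] == "realised_recovery"].iloc[0]
        assert row["median"] == pytest.approx(1.0)
        assert row["mean"] == pytest.approx(1.0)
        assert row["n_cases"] == 3
        miss = summary[summary["metric"] == "intrinsic_recovery"].iloc[0]
        assert miss["n_missing"] == 3

    def test_summaries_track_generator_distribution(self):
        cfg = FixtureConfig(noise_sd=0.0, n_sparse_cases=0, n_outliers=0)
        reports, _ = analyse_cases(generate_fixture_dataset(cfg, seed=9))
        summary = summarise_groups(reports)
        rec = summary[summary["metric"] == "intrinsic_recovery"]
        expected = latent_recovery(cfg.tau_end, cfg.drop_fraction)
        assert np.allclose(rec["median"], expected, rtol=1e-6)


class TestTabularRoundTrip:
    def test_frames_reproduce_cases(self):
        cases = generate_fixture_dataset(seed=11)
        long, groups = cases_to_frame(cases)
        back = frame_to_cases(long, groups)
        orig = {c.case_id: c for c in cases}
        assert set(orig) == {c.case_id for c in back}
        for c in back:
            np.testing.assert_allclose(c.times, orig[c.case_id].times)
            np.testing.assert_allclose(c.lrr, orig[c.case_id].lrr)
            assert c.growth_rate == pytest.approx(orig[c.case_id].growth_rate)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="case_id"):
            frame_to_cases(pd.DataFrame({"time": [1.0], "lrr": [0.0]}))
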