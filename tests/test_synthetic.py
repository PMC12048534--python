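import numpy as np
import pandas as pd
import pytest

from actisym.ingest import epochize
from actisym.nonwear import NonwearConfig, detect_short_nonwear, wear_mask
from actisym.synthetic import (
    CohortConfig,
    inject_nonwear,
    simulate_cohort,
    simulate_participant,
)


def small_config(**kw):
    defaults = dict(n_participants=2, days_per_cycle=5, n_cycles=1, seed=0)
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw", [{"n_cycles": 4}, {"coupling_fatigue_activity": 1.5},
               {"prom_missing_rate": -0.1}, {"sample_rate": 0},
               {"phenotypes": "unknown"}],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_config(**kw)

    def test_surgery_outside_span_rejected(self):
        with pytest.raises(ValueError, match="surgery_day"):
            simulate_participant(small_config(surgery_day=99), 0, include_raw=False)

    def test_nonpositive_cohort_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(small_config(n_participants=0))


class TestDeterminism:
    def test_identical_seed_identical_outputs(self):
        cfg = small_config(nonwear_events=[(200, 60)])
        rec1, proms1, ehp1, truth1 = simulate_participant(cfg, 0)
        rec2, proms2, ehp2, truth2 = simulate_participant(cfg, 0)
        np.testing.assert_array_equal(rec1.ax, rec2.ax)
        np.testing.assert_array_equal(rec1.temperature, rec2.temperature)
        pd.testing.assert_frame_equal(proms1, proms2)
        pd.testing.assert_frame_equal(ehp1, ehp2)
        pd.testing.assert_frame_equal(truth1.daily, truth2.daily)

    def test_seed_sweep_distinct_missingness(self):
        masks = []
        for seed in range(5):
            _, proms, _, _ = simulate_participant(
                small_config(seed=seed, days_per_cycle=28), 0, include_raw=False
            )
            masks.append(tuple(pd.to_datetime(proms["assoc_date"]).dt.day))
        assert len(set(masks)) > 1


class TestScaleBounds:
    def test_item_ranges(self):
        cfg = small_config(n_participants=4, days_per_cycle=28)
        bundle = simulate_cohort(cfg, include_raw=False)
        p = bundle.proms
        assert p["pain_avg"].between(1, 10).all()
        assert p["pain_worst"].between(1, 10).all()
        for k in range(1, 10):
            assert p[f"bfi_q{k}"].between(0, 10).all()
        items = [c for c in bundle.ehp30.columns if c.startswith("item_")]
        assert bundle.ehp30[items].stack().between(0, 4).all()


class TestNoVarianceLimit:
    def test_constant_phenotype_zero_noise(self):
        cfg = small_config(phenotypes="constant-severe", noise_scale=0.0,
                           coupling_fatigue_activity=0.0, prom_missing_rate=0.0)
        _, proms, _, truth = simulate_participant(cfg, 0, include_raw=False)
        lat = truth.daily
        assert lat["fatigue"].std() == pytest.approx(0.0, abs=1e-12)
        assert lat["activity"].std() == pytest.approx(0.0, abs=1e-12)
        assert proms["pain_avg"].nunique() == 1


class TestInjectNonwear:
    def test_empty_list_identity(self):
        rec, *_ = simulate_participant(small_config(days_per_cycle=1), 0)
        out = inject_nonwear(rec, [])
        assert out is rec

    def test_temperature_decay(self):
        rec, *_ = simulate_participant(small_config(days_per_cycle=1), 0)
        out = inject_nonwear(rec, [(600, 120)], ambient=21.0)
        ep = epochize(out)
        t = ep.minute["t_smooth"].to_numpy()
        assert t[715] < 24.0  # near interval end, relaxed to ambient
        assert t[500] > 28.0  # untouched before

    def test_overlap_merged_with_warning(self):
        rec, *_ = simulate_participant(small_config(days_per_cycle=1), 0)
        with pytest.warns(UserWarning, match="merged"):
            inject_nonwear(rec, [(100, 60), (130, 60)])

    def test_stillness_below_detector_floor(self):
        rec, *_ = simulate_participant(small_config(days_per_cycle=1), 0)
        out = inject_nonwear(rec, [(600, 120)])
        ep = epochize(out)
        rocam = ep.minute["rocam"].to_numpy()[605:715]
        assert np.nanmean(rocam) < NonwearConfig().rocam_thresh

    def test_ten_minute_event_undetectable(self):
        # present in truth labels but below the 15-min floor of the short pass
        cfg = small_config(days_per_cycle=2, nonwear_events=[(600, 10)])
        rec, *_, truth = simulate_participant(cfg, 0)
        assert truth.wear_intervals == [(0.0, 600 * 60.0), (610 * 60.0, 2 * 86400.0)]
        ep = epochize(rec)
        mask = wear_mask(ep)
        assert mask.pass2_intervals == []
        assert mask.wear_fraction() == 1.0


class TestCohortBundle:
    def test_single_participant_manifest(self):
        bundle = simulate_cohort(small_config(n_participants=1), include_raw=False)
        assert len(bundle.manifest) == 1  # one participant x one cycle
        assert set(bundle.manifest.columns) >= {
            "participant", "cycle", "start_date", "end_date", "surgery_date", "wrist"}

    def test_post_surgical_activity_dips_then_recovers(self):
        cfg = small_config(n_participants=1, days_per_cycle=28, n_cycles=2,
                           phenotypes="post-surgical", noise_scale=0.3)
        _, _, _, truth = simulate_participant(cfg, 0, include_raw=False)
        lat = truth.daily
        sday = 28
        pre = lat.loc[lat["day"] < sday, "activity"].mean()
        post10 = lat.loc[(lat["day"] > sday) & (lat["day"] <= sday + 10), "activity"].mean()
        late = lat.loc[lat["day"] >= sday + 20, "activity"].mean()
        assert post10 < pre
        assert late > post10

    def test_coupling_recovery_band(self):
        # realized within-person activity-fatigue correlation tracks the dial
        from actisym.stats import rmcorr
        for c in (-0.5, 0.0, 0.3):
            rs = []
            for seed in range(8):
                cfg = CohortConfig(n_participants=30, days_per_cycle=28, n_cycles=1,
                                   seed=seed, coupling_fatigue_activity=c,
                                   prom_missing_rate=0.0)
                bundle = simulate_cohort(cfg, include_raw=False)
                xs, ys, ss = [], [], []
                for pid, tr in bundle.truths.items():
                    xs.append(tr.daily["activity"].to_numpy())
                    ys.append(tr.daily["fatigue"].to_numpy())
                    ss.extend([pid] * len(tr.daily))
                res = rmcorr(np.concatenate(xs), np.concatenate(ys), np.array(ss))
                rs.append(res.r)
            assert abs(np.mean(rs) - c) < 0.1
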