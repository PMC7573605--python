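import numpy as np
import pandas as pd
import pytest

from hemovalid import SimConfig, make_fixture, simulate_experiment, split_series
from hemovalid.synthetic_cohort import ConfigError, DeviceErrorModel


class TestConfigValidation:
    @pytest.mark.parametrize("field, value", [
        ("n_animals", 0),
        ("dropout_prob", 1.5),
        ("co_missing_prob", -0.1),
        ("spike_prob", 2.0),
        ("map_floor", 0.0),
    ])
    def test_invalid_scalar_rejected_before_sampling(self, field, value):
        cfg = SimConfig(**{field: value})
        with pytest.raises(ConfigError):
            simulate_experiment(cfg)

    def test_invalid_device_model_rejected(self):
        dev = DeviceErrorModel(ar1_rho=1.0)
        with pytest.raises(ConfigError):
            simulate_experiment(SimConfig(device=dev))

    def test_config_round_trips_through_dict(self):
        cfg = SimConfig(seed=42, dropout_prob=0.25)
        again = SimConfig.from_dict(cfg.to_dict())
        assert again.seed == 42
        assert again.dropout_prob == 0.25
        assert [p.name for p in again.phases] == [p.name for p in cfg.phases]


class TestDeterminism:
    def test_same_seed_same_dataset(self):
        cfg = SimConfig(n_animals=3, seed=11)
        a = simulate_experiment(cfg)
        b = simulate_experiment(SimConfig(n_animals=3, seed=11))
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_different_seed_different_dataset(self):
        a = simulate_experiment(SimConfig(n_animals=3, seed=1))
        b = simulate_experiment(SimConfig(n_animals=3, seed=2))
        assert not a.df["reference_value"].equals(b.df["reference_value"])


class TestDegenerateErrorModel:
    def test_device_equals_reference_exactly(self, degenerate_cohort):
        df = degenerate_cohort.df
        assert (df["device_value"] == df["reference_value"]).all()


class TestProtocolShape:
    def test_phase_cadences_and_bleed_duration(self, default_cohort):
        for s in split_series(default_cohort):
            d = s.df
            t_pre = d.loc[d.phase == "pre_bleeding", "time_min"].to_numpy()
            t_bleed = d.loc[d.phase == "bleeding", "time_min"].to_numpy()
            t_post = d.loc[d.phase == "post_bleeding", "time_min"].to_numpy()
            assert np.allclose(np.diff(t_pre), 5.0)
            if s.variable != "CO":  # CO thinning breaks equal spacing
                assert np.allclose(np.diff(t_bleed), 5.0)
                assert np.allclose(np.diff(t_post), 20.0)
            if len(t_bleed):
                dur = t_bleed[-1] - t_pre[-1]
                assert 20.0 <= dur <= 60.0

    def test_bleeding_map_respects_floor(self, default_cohort):
        df = default_cohort.df
        sb = df[(df.phase == "bleeding") & (df.variable == "SBP")]
        db = df[(df.phase == "bleeding") & (df.variable == "DBP")]
        merged = sb.merge(db, on=["animal_id", "time_min"], suffixes=("_s", "_d"))
        map_ = (merged["reference_value_s"] + 2 * merged["reference_value_d"]) / 3
        assert (map_ >= 30.0).all()

    def test_dropout_truncates_all_series_of_an_animal(self):
        cfg = SimConfig(n_animals=30, dropout_prob=1.0, seed=3)
        ds = simulate_experiment(cfg)
        last = ds.df.groupby(["animal_id", "variable"])["time_min"].max().unstack()
        # all non-CO series of one animal end at the same (truncated) time
        sub = last[["SBP", "DBP", "HR"]]
        assert (sub.nunique(axis=1) == 1).all()
        # with certain dropout, most animals end well before the full 7 h
        bleed_end = (ds.df[ds.df.phase == "bleeding"]
                     .groupby("animal_id")["time_min"].max())
        followup = last["SBP"] - bleed_end
        assert (followup < 400.0).sum() >= len(followup) * 0.5

    def test_co_thinning_reduces_co_counts(self, default_cohort):
        df = default_cohort.df
        late = df[df.phase != "pre_bleeding"]
        n_co = (late.variable == "CO").sum()
        n_sbp = (late.variable == "SBP").sum()
        assert n_co < n_sbp
        pre = df[df.phase == "pre_bleeding"]
        assert (pre.variable == "CO").sum() == (pre.variable == "SBP").sum()


class TestParameterFidelity:
    def test_phase_levels_converge_to_configured_targets(self):
        """Generated phase mean/SD approach the configured values as the
        cohort grows (strict for baseline; bleeding BP means sit at or above
        target because the MAP floor binds)."""
        cfg = SimConfig(n_animals=120, dropout_prob=0.0, co_missing_prob=0.0,
                        spike_prob=0.0, seed=99)
        df = simulate_experiment(cfg).df
        pre = cfg.phases[0]
        for var in ("SBP", "DBP", "HR", "CO"):
            vals = df[(df.phase == "pre_bleeding") & (df.variable == var)][
                "reference_value"]
            se_mean = pre.level_sd[var] / np.sqrt(cfg.n_animals)
            assert abs(vals.mean() - pre.level_mean[var]) < 3 * se_mean
            assert abs(vals.std() - pre.level_sd[var]) < 0.2 * pre.level_sd[var]
        # HR and CO are unconstrained by the MAP floor in every phase
        for phase_spec, label in zip(cfg.phases[1:], ("bleeding", "post_bleeding")):
            for var in ("HR", "CO"):
                vals = df[(df.phase == label) & (df.variable == var)][
                    "reference_value"]
                tol = 3 * phase_spec.level_sd[var] / np.sqrt(cfg.n_animals) \
                    + 0.05 * phase_spec.level_mean[var]
                assert abs(vals.mean() - phase_spec.level_mean[var]) < tol


class TestFixtures:
    def test_unknown_name_lists_valid_names(self):
        with pytest.raises(ValueError, match="perfect"):
            make_fixture("bogus")

    @pytest.mark.parametrize("name", ["perfect", "biased", "noisy", "spiky"])
    def test_fixtures_are_small_and_deterministic(self, name):
        a = make_fixture(name)
        b = make_fixture(name)
        assert len(a) < 200
        assert a == b

    def test_perfect_fixture_identity(self, perfect_fixture):
        df = perfect_fixture.df
        assert (df.device_value == df.reference_value).all()

    def test_biased_fixture_offsets_bp_only(self, biased_fixture):
        df = biased_fixture.df
        bp = df.variable.isin(("SBP", "DBP"))
        assert np.allclose(df.loc[bp, "device_value"]
                           - df.loc[bp, "reference_value"], 4.0)
        assert (df.loc[~bp, "device_value"] == df.loc[~bp, "reference_value"]).all()

    def test_noisy_fixture_records_noise_sd(self, noisy_fixture):
        sd = noisy_fixture.metadata["noise_sd"]
        df = noisy_fixture.df
        for var, s in sd.items():
            diff = df[df.variable == var]
            resid = diff.device_value - diff.reference_value
            assert 0.5 * s < resid.std() < 1.6 * s

    def test_spiky_fixture_records_spikes(self, spiky_fixture, perfect_fixture):
        keys = spiky_fixture.metadata["spike_keys"]
        assert len(keys) == 6
        clean = perfect_fixture.df.set_index(["animal_id", "variable", "time_min"])
        spiked = spiky_fixture.df.set_index(["animal_id", "variable", "time_min"])
        for key in keys:
            assert spiked.loc[key, "reference_value"] == pytest.approx(
                1.5 * clean.loc[key, "reference_value"])
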