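"""Experiment orchestration: configurations, pruning, AIS sweep plumbing."""

import numpy as np
import pandas as pd
import pytest

from gbcsim import an_surrogate as ans
from gbcsim import experiments as X
from gbcsim import metrics as mt
from gbcsim import morphology as mor
from gbcsim import synthetic as syn
from gbcsim.morphology import Tag


class TestConfigMasks:
    def test_masks(self):
        assert X._config_mask("all", 5).sum() == 5
        m = X._config_mask("largest_only", 5)
        assert m.sum() == 1 and m[0]
        m = X._config_mask("all_but_largest", 5)
        assert m.sum() == 4 and not m[0]
        m = X._config_mask("remove_two_largest", 5)
        assert m.sum() == 3 and not m[0] and not m[1]

    def test_unknown_config(self):
        with pytest.raises(ValueError):
            X._config_mask("strongest_two", 5)


@pytest.fixture(scope="module")
def mixed_setup(toy_model_half_active):
    profile = syn.make_endbulb_profile("mixed", n_inputs=6, seed=7)
    spec = ans.StimulusSpec(kind="SAM", f_mod_hz=200.0, level_db_spl=30.0,
                            duration_ms=300.0)
    return toy_model_half_active, profile, spec


class TestSoundResponse:
    def test_deterministic_per_seed(self, mixed_setup):
        model, profile, spec = mixed_setup
        a = X.simulate_sound_response(model, profile, spec, n_trials=2, seed=3)
        b = X.simulate_sound_response(model, profile, spec, n_trials=2, seed=3)
        for ta, tb in zip(a.post_trains, b.post_trains):
            assert np.array_equal(ta, tb)

    def test_suprathreshold_input_outdrives_small_input(self, mixed_setup):
        model, profile, spec = mixed_setup
        big = np.zeros(6, bool)
        big[0] = True
        small = np.zeros(6, bool)
        small[-1] = True
        ra = X.simulate_sound_response(model, profile, spec, n_trials=3, seed=1,
                                       active_inputs=big)
        rb = X.simulate_sound_response(model, profile, spec, n_trials=3, seed=1,
                                       active_inputs=small)
        eff_big = mt.efficacy(ra.pre_trains[0], ra.post_trains)
        eff_small = mt.efficacy(rb.pre_trains[-1], rb.post_trains)
        assert eff_big > eff_small
        assert eff_small < 0.05  # a 35-80 um^2 endbulb alone rarely drives spikes

    def test_input_configuration_table(self, mixed_setup):
        model, profile, spec = mixed_setup
        df = X.run_input_configuration_experiment(
            model, profile, configs=("all", "largest_only"), f_mods=(200.0,),
            n_trials=3, duration_ms=300.0, seed=2,
        )
        assert isinstance(df, pd.DataFrame)
        assert set(df["config"]) == {"all", "largest_only"}
        assert {"vs", "rate_hz", "entrainment", "vs_anf"} <= set(df.columns)
        # all-inputs drives a higher rate than the largest alone
        r_all = df.loc[df.config == "all", "rate_hz"].iloc[0]
        r_one = df.loc[df.config == "largest_only", "rate_hz"].iloc[0]
        assert r_all > r_one


class TestPruning:
    def test_pruning_increases_rin_and_lowers_threshold(self, toy_cell):
        shafts = [
            s.id for s in toy_cell.sections
            if s.tag is Tag.DISTAL_DENDRITE
            and toy_cell.section(s.parent_id).tag is Tag.HUB
        ]
        out = X.run_pruning_experiment(toy_cell, set(shafts[:3]))
        assert out["pruned"]["Rin_MOhm"] > out["intact"]["Rin_MOhm"]
        assert out["pruned"]["threshold_nA"] < out["intact"]["threshold_nA"]
        assert out["pruned"]["area_um2"] < out["intact"]["area_um2"]


class TestPruningSynapticMetrics:
    def test_efficacy_and_vs_reported_per_condition(self, toy_cell):
        # tiny 2-input profile keeps the lone-input runs affordable
        profile = syn.EndbulbProfile(mode="mixed", asas=np.array([210.0, 60.0]))
        shafts = [
            s.id for s in toy_cell.sections
            if s.tag is Tag.DISTAL_DENDRITE
            and toy_cell.section(s.parent_id).tag is Tag.HUB
        ]
        spec = ans.StimulusSpec(kind="SAM", f_mod_hz=200.0, level_db_spl=30.0,
                                duration_ms=250.0)
        out = X.run_pruning_experiment(
            toy_cell, set(shafts[:3]), profile=profile, stim_spec=spec,
            n_trials=2, seed=4,
        )
        assert len(out["intact"]["efficacy_per_input"]) == 2
        assert len(out["delta"]["efficacy_per_input"]) == 2
        assert "vs" in out["pruned"]
        # the suprathreshold input keeps finite efficacy in both conditions
        assert out["intact"]["efficacy_per_input"][0] > 0
        # pruning cannot reduce the largest input's efficacy
        assert out["delta"]["efficacy_per_input"][0] >= -0.05


class TestAISSweep:
    def test_threshold_monotone_decreasing(self):
        df = X.run_ais_sweep(lengths_um=(14.2, 21.4))
        thr = df.sort_values("ais_length_um")["threshold_nA"].to_numpy()
        assert thr[0] > thr[-1]  # longer AIS -> lower threshold
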