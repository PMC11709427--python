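import numpy as np
import pytest

from wormpheno.synthetic_data import (EffectSpec, ExperimentDesign,
                                      StimulusSchedule, WormParams,
                                      feature_names,
                                      generate_feature_experiment,
                                      generate_screen_experiment,
                                      generate_skeleton_tracks,
                                      make_screen_compound_specs)


@pytest.fixture(scope="session")
def small_experiment():
    """3 days x 3 wells/group/day, two groups, one planted effect."""
    design = ExperimentDesign(n_features_per_period=8, seed=42)
    effects = {"mut_DMSO": EffectSpec(effect_sizes={"ft0001": 3.0,
                                                    "ft0004@bluelight": -2.5})}
    return generate_feature_experiment(design, effects)


@pytest.fixture(scope="session")
def null_experiment():
    """No planted effects, day batch structure present."""
    design = ExperimentDesign(n_features_per_period=30, seed=7)
    return generate_feature_experiment(design, EffectSpec(day_sd=1.0))


@pytest.fixture(scope="session")
def screen_experiment():
    """12-compound screen: 2 full, 2 partial, 1 toxic, 7 inert."""
    design = ExperimentDesign(groups=("N2_DMSO", "mut_DMSO"),
                              n_features_per_period=60, seed=11)
    names = feature_names(60, core_first=True)
    disease = EffectSpec(effect_sizes={
        "curvature_mean": -3.0, "speed_mean": -3.0, "fraction_paused": 3.0,
        **{f"ft{j:04d}": 2.5 for j in range(3, 15)}})
    specs = make_screen_compound_specs(
        12, n_full=2, n_partial=2, n_toxic=1, n_side_effect_features=20,
        available_features=[f"{n}@{p}" for n in names[20:]
                            for p in design.periods], seed=1)
    tables, meta, truth = generate_screen_experiment(design, disease, specs,
                                                     names=names)
    return tables, meta, truth


@pytest.fixture(scope="session")
def short_schedule():
    return StimulusSchedule(period_durations=(30.0, 60.0, 30.0),
                            pulse_starts=(10.0, 40.0), pulse_duration=10.0)


@pytest.fixture(scope="session")
def fainter_track(short_schedule):
    params = WormParams(faint_prob=1.0, faint_duration_s=10.0)
    ts = generate_skeleton_tracks(short_schedule, params, n_tracks=1, seed=3)
    return ts.tracks[0]
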