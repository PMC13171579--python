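import numpy as np
import pandas as pd
import pytest

from dbslfp.design import PAIRS, make_design
from dbslfp.errors import ConfigurationError, ValidationError
from dbslfp.preprocess import RecordingSession
from dbslfp.synth import (
    EffectSpec,
    SCENARIOS,
    build_ground_truth,
    inject_edge_artifacts,
    plant_effects,
    read_fixture,
    simulate_power_table,
    synthesize_session,
    write_fixture,
)


@pytest.fixture(scope="module")
def tiny_design():
    return make_design(
        {"subjects": 1, "datasets_per_subject": 1, "trials_per_condition": 2,
         "channels_per_roi": 2, "rois": ("lOFC", "rOFC")}
    )


# ---------------------------------------------------------------------------
# plant_effects / ground truth
# ---------------------------------------------------------------------------


def test_unknown_scenario_lists_valid_names(tiny_design):
    with pytest.raises(ConfigurationError) as err:
        plant_effects(tiny_design, "bogus")
    for name in SCENARIOS:
        assert name in str(err.value)


def test_null_scenario_all_additive_with_zero_interactions(tiny_design):
    effects, truth = plant_effects(tiny_design, "null")
    assert (effects.delta_p_true == 0).all()
    assert (effects.interaction_true == 0).all()
    assert (truth["class_true"] == "additive").all()


def test_all_super_scenario_every_cell_super_additive(tiny_design):
    effects, truth = plant_effects(
        tiny_design, "all_super",
        unilateral_amps={"rSCC": 0.2, "lSCC": 0.2, "rVCVS": 0.2, "lVCVS": 0.2},
        interaction_magnitude=0.2,
    )
    assert (truth["class_true"] == "super-additive").all()
    # sign of each interaction matches the expected additive effect
    assert (np.sign(truth["interaction_true"]) == np.sign(truth["expected_sum"])).all()


def test_all_sub_scenario_signs_oppose_expected(tiny_design):
    _, truth = plant_effects(tiny_design, "all_sub")
    assert (truth["class_true"] == "sub-additive").all()
    assert (np.sign(truth["interaction_true"]) == -np.sign(truth["expected_sum"])).all()


def test_sign_rule_on_handpicked_cell():
    """delta_A=0.3, delta_B=0.2, interaction=-0.25 classifies sub-additive."""
    idx = pd.MultiIndex.from_product([["lOFC"], ["theta"]], names=["roi", "band"])
    one = lambda v: pd.Series([v], index=idx)
    delta = {"rSCC": 0.3, "lSCC": 0.2, "rVCVS": 0.1, "lVCVS": 0.1}
    inter = {"SCC_bilateral": -0.25, "VCVS_bilateral": 0.0, "multi_target": 0.0}
    dp, it = {}, {}
    for pair, (a, b, ab) in PAIRS.items():
        for c in (a, b):
            if c in delta:
                dp[c] = one(delta[c])
        it[pair] = one(inter[pair])
        dp[ab] = dp[a] + dp[b] + it[pair]
    effects = EffectSpec(
        delta_p_true=pd.concat(dp, names=["condition"]),
        interaction_true=pd.concat(it, names=["pair"]),
        base_power=one(1.0),
    )
    truth = build_ground_truth(effects).set_index("pair")
    assert truth.loc["SCC_bilateral", "class_true"] == "sub-additive"
    assert truth.loc["VCVS_bilateral", "class_true"] == "additive"


@pytest.mark.parametrize("scenario", SCENARIOS)
def test_planted_additive_identity_exact(tiny_design, scenario):
    """delta(AB) - delta(A) - delta(B) equals the planted interaction exactly."""
    effects, _ = plant_effects(tiny_design, scenario)
    for pair, (a, b, ab) in PAIRS.items():
        lhs = (
            effects.delta_p_true.loc[ab]
            - effects.delta_p_true.loc[a]
            - effects.delta_p_true.loc[b]
        )
        assert np.allclose(
            lhs.values, effects.interaction_true.loc[pair].values, rtol=0, atol=1e-15
        )


def test_effect_spec_rejects_broken_identity(tiny_design):
    effects, _ = plant_effects(tiny_design, "mixed")
    broken = effects.delta_p_true.copy()
    broken.loc[("bSCC", "lOFC", "theta")] += 0.1
    with pytest.raises(ValidationError, match="additive identity"):
        EffectSpec(
            delta_p_true=broken,
            interaction_true=effects.interaction_true,
            base_power=effects.base_power,
        )


def test_mixed_scenario_contains_all_three_classes_in_every_band(tiny_design):
    d = make_design({"subjects": 1, "trials_per_condition": 1, "channels_per_roi": 2})
    _, truth = plant_effects(d, "mixed")
    counts = truth.groupby(["band", "class_true"]).size().unstack(fill_value=0)
    assert (counts > 0).all().all(), "every class must appear in every band"
    # additive dominates, super-additive rarest (per-pair 33/11/4 split)
    tall = truth["class_true"].value_counts()
    assert tall["additive"] > tall["sub-additive"] > tall["super-additive"]


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------


def test_synthesis_is_bit_reproducible(tiny_design):
    effects, _ = plant_effects(tiny_design, "mixed")
    s1 = synthesize_session(tiny_design, effects, "S01", "d0", seed=3)
    s2 = synthesize_session(tiny_design, effects, "S01", "d0", seed=3)
    assert np.array_equal(s1.signals, s2.signals)
    assert s1.events.equals(s2.events)
    s3 = synthesize_session(tiny_design, effects, "S01", "d0", seed=4)
    assert not np.array_equal(s1.signals, s3.signals)


def test_session_layout(tiny_design):
    effects, _ = plant_effects(tiny_design, "null")
    ses = synthesize_session(tiny_design, effects, "S01", "d0", seed=0)
    assert len(ses.events) == tiny_design.epochs_per_dataset
    assert ses.signals.shape[0] == len(tiny_design.rois) * tiny_design.channels_per_roi
    assert set(ses.events["condition"]) == set(tiny_design.conditions)
    # every epoch fits inside the recording with its pre/post second
    assert (ses.events["onset_s"] >= 1.0).all()
    assert (ses.events["onset_s"] + 2.0 <= ses.duration_s).all()


def test_planted_power_change_below_minus_one_errors(tiny_design):
    effects, _ = plant_effects(
        tiny_design, "all_sub",
        unilateral_amps={"rSCC": -0.7, "lSCC": -0.7, "rVCVS": 0.1, "lVCVS": 0.1},
        interaction_magnitude=0.1,
    )
    assert (effects.delta_p_true <= -1).any()
    with pytest.raises(ValidationError, match="power cannot be negative"):
        synthesize_session(tiny_design, effects, "S01", "d0", seed=0)


# ---------------------------------------------------------------------------
# edge artifacts
# ---------------------------------------------------------------------------


def _fake_session(n_epochs: int, fs: float = 200.0) -> RecordingSession:
    period = 3.5
    n = int((0.5 + n_epochs * period) * fs)
    rng = np.random.default_rng(0)
    events = pd.DataFrame(
        {
            "onset_s": 0.5 + np.arange(n_epochs) * period + 1.0,
            "condition": ["rSCC"] * n_epochs,
            "trial": [f"t{i:03d}" for i in range(n_epochs)],
        }
    )
    channels = pd.DataFrame(
        [{"name": "lOFC1", "roi": "lOFC", "hemisphere": "left", "lead": "lOFC", "contact": 1}]
    )
    return RecordingSession(
        signals=rng.standard_normal((1, n)),
        sampling_rate=fs,
        channels=channels,
        events=events,
        subject="S01",
        dataset="d0",
        meta={"pre_s": 1.0, "stim_s": 1.0, "post_s": 1.0},
    )


def test_artifact_count_matches_rounded_fraction():
    ses = _fake_session(1000)
    _, labels = inject_edge_artifacts(ses, fraction=0.097, seed=0)
    assert len(labels) == 97


def test_zero_fraction_leaves_session_unchanged():
    ses = _fake_session(10)
    out, labels = inject_edge_artifacts(ses, fraction=0.0, seed=0)
    assert len(labels) == 0
    assert np.array_equal(out.signals, ses.signals)


def test_full_fraction_labels_every_epoch():
    ses = _fake_session(10)
    _, labels = inject_edge_artifacts(ses, fraction=1.0, seed=0)
    assert sorted(labels) == list(range(10))


def test_labels_match_modified_epochs_one_to_one():
    ses = _fake_session(40)
    out, labels = inject_edge_artifacts(ses, fraction=0.25, amplitude=10.0, seed=2)
    fs = ses.sampling_rate
    changed = []
    for i, ev in ses.events.iterrows():
        i0 = int((ev.onset_s - 0.1) * fs)
        if not np.allclose(out.signals[0, i0:i0 + 20], ses.signals[0, i0:i0 + 20]):
            changed.append(i)
    assert changed == sorted(labels)


def test_fraction_out_of_range_errors():
    with pytest.raises(ValidationError):
        inject_edge_artifacts(_fake_session(5), fraction=1.5)


# ---------------------------------------------------------------------------
# model-level generator
# ---------------------------------------------------------------------------


def test_simulate_power_table_shape_and_identity(tiny_design):
    effects, _ = plant_effects(tiny_design, "mixed")
    tab = simulate_power_table(tiny_design, effects, seed=0)
    # epochs x bipolar channels x bands
    assert len(tab) == 14 * 2 * 4
    assert np.allclose(tab["p_post"], tab["p_pre"] * (1 + tab["delta_p"]))
    assert (tab["p_pre"] > 0).all()
    assert simulate_power_table(tiny_design, effects, seed=0).equals(tab)


def test_simulate_power_table_recovers_planted_mean(tiny_design):
    effects, _ = plant_effects(tiny_design, "mixed", sd_trial=0, sd_channel=0, sd_residual=0)
    tab = simulate_power_table(tiny_design, effects, seed=0)
    got = tab.set_index(["condition", "roi", "band"])["delta_p"]
    for key, val in effects.delta_p_true.items():
        assert got.loc[key].max() == pytest.approx(val, abs=1e-12)


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------


def test_fixture_round_trip(tmp_path, tiny_design):
    effects, truth = plant_effects(tiny_design, "mixed")
    ses = synthesize_session(tiny_design, effects, "S01", "d0", seed=5)
    gt5 = truth[["pair", "roi", "band", "interaction_true", "class_true"]]
    write_fixture(ses, {"ground_truth": gt5}, tmp_path / "fx")
    sessions, tables = read_fixture(tmp_path / "fx")
    back = sessions[("S01", "d0")]
    assert np.allclose(back.signals, ses.signals, atol=1e-6)
    assert back.sampling_rate == ses.sampling_rate
    assert back.channels.equals(ses.channels)
    assert list(tables["ground_truth"].columns) == list(gt5.columns)
    assert len(tables["ground_truth"]) == len(gt5)


def test_fixture_sidecar_lists_twelve_rois(tmp_path):
    d = make_design({"subjects": 1, "datasets_per_subject": 1,
                     "trials_per_condition": 1, "channels_per_roi": 2})
    effects, _ = plant_effects(d, "null")
    ses = synthesize_session(d, effects, "S01", "d0", seed=0)
    import json

    write_fixture(ses, {}, tmp_path / "fx")
    meta = json.loads((tmp_path / "fx" / "meta.json").read_text())
    assert len(meta["rois"]) == 12


def test_empty_session_errors_instead_of_writing(tmp_path):
    ses = _fake_session(3)
    empty = RecordingSession(
        signals=np.empty((0, 100)),
        sampling_rate=200.0,
        channels=ses.channels.iloc[:0],
        events=ses.events,
        subject="S01",
        dataset="d0",
    )
    with pytest.raises(ValidationError, match="empty"):
        write_fixture(empty, {}, tmp_path / "fx")
    assert not (tmp_path / "fx" / "signals.h5").exists()
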