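"""Time grid, sequence encoding, and network forward-pass contracts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynrisk.deep_survival import (
    Standardizer,
    SurvivalNetConfig,
    TimeGrid,
    attention_context,
    cause_forward,
    cif_at,
    encode_cohort,
    full_forward,
    init_params,
    shared_forward,
    train,
)
from dynrisk.synthetic_cohort import CohortDataset

GRID = TimeGrid(horizon=10.0, n_bins=20)


class TestTimeGrid:
    def test_bin_index_edges(self):
        assert GRID.bin_index(0.25) == 0
        assert GRID.bin_index(0.5) == 1  # half-open bins [l, u)
        assert GRID.bin_index(9.99) == 19
        assert GRID.bin_index(10.0) == 19  # horizon folds into the last bin
        with pytest.raises(ValueError):
            GRID.bin_index(0.0)
        with pytest.raises(ValueError):
            GRID.bin_index(10.5)

    def test_cif_full_sum_is_one_minus_terminal(self):
        probs = np.full(21, 1 / 21)
        assert cif_at(probs, 10.0, GRID) == pytest.approx(20 / 21)

    def test_cif_uniform_hand_value(self):
        # uniform over 21 slots, t at the end of bin 10 of 20
        probs = np.full(21, 1 / 21)
        assert cif_at(probs, 5.0, GRID) == pytest.approx(10 / 21)

    @given(st.lists(st.floats(0.01, 1.0), min_size=21, max_size=21), st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_cif_monotone(self, raw, data):
        probs = np.array(raw) / np.sum(raw)
        t1 = data.draw(st.floats(0.01, 10.0))
        t2 = data.draw(st.floats(0.01, 10.0))
        t1, t2 = min(t1, t2), max(t1, t2)
        assert cif_at(probs, t1, GRID) <= cif_at(probs, t2, GRID) + 1e-12


def _mini_cohort(exam_specs):
    """Build a cohort from {pid: [(time, sbp, dbp, tc, hdl, observed_mask), ...]}."""
    statics = pd.DataFrame(
        {
            "id": list(exam_specs),
            "sex": "female",
            "race": "other",
            "age_at_prediction": 55.0,
            "smoker": False,
            "diabetes": False,
            "htn_treatment": False,
            "prior_ascvd": False,
        }
    )
    rows = []
    for pid, exams in exam_specs.items():
        for t, vals, mask in exams:
            row = {"id": pid, "exam_time_years": t}
            for f, v, m in zip(("sbp", "dbp", "tc", "hdl"), vals, mask):
                row[f] = v if m else np.nan
                row[f"{f}_observed"] = m
            rows.append(row)
    outcomes = pd.DataFrame(
        {"id": list(exam_specs), "time_years": 5.0, "event": 0}
    )
    return CohortDataset(statics=statics, exams=pd.DataFrame(rows), outcomes=outcomes)


STD = Standardizer(
    means={"sbp": 120.0, "dbp": 75.0, "tc": 200.0, "hdl": 50.0, "age": 55.0},
    sds={"sbp": 10.0, "dbp": 10.0, "tc": 40.0, "hdl": 15.0, "age": 7.0},
    medians={"sbp": 120.0, "dbp": 75.0, "tc": 200.0, "hdl": 50.0, "age": 55.0},
)


class TestEncoding:
    def test_single_exam_sequence(self):
        c = _mini_cohort({0: [(0.0, (130, 80, 210, 45), (True,) * 4)]})
        b = encode_cohort(c, STD)
        assert b.valid[0].sum() == 1
        assert b.x[0, 0, 8] == 0.0  # delta-time channel at the first exam
        assert b.next_mask.sum() == 0

    def test_forward_fill_with_mask(self):
        c = _mini_cohort(
            {
                0: [
                    (-4.0, (130, 80, 210, 45), (True,) * 4),
                    (0.0, (140, 80, 210, 45), (False, True, True, True)),
                ]
            }
        )
        b = encode_cohort(c, STD)
        # missing SBP at exam 2 carries exam 1's standardized value, mask 0
        assert b.x[0, 1, 0] == pytest.approx(b.x[0, 0, 0])
        assert b.x[0, 1, 4] == 0.0  # sbp mask channel
        assert b.x[0, 0, 4] == 1.0

    def test_median_fill_before_first_observation(self):
        c = _mini_cohort({0: [(0.0, (np.nan, 80, 210, 45), (False, True, True, True))]})
        b = encode_cohort(c, STD)
        assert b.x[0, 0, 0] == pytest.approx(0.0)  # standardized median

    def test_delta_time_channel_hand_values(self):
        c = _mini_cohort(
            {
                0: [
                    (-8.0, (120, 75, 200, 50), (True,) * 4),
                    (-4.0, (120, 75, 200, 50), (True,) * 4),
                    (0.0, (120, 75, 200, 50), (True,) * 4),
                ]
            }
        )
        b = encode_cohort(c, STD)
        assert b.x[0, :3, 8] == pytest.approx([0.0, 4.0, 4.0])

    def test_empty_series_errors(self):
        c = _mini_cohort({0: [(0.0, (120, 75, 200, 50), (True,) * 4)]})
        c.exams = c.exams.iloc[:0]
        with pytest.raises(ValueError):
            encode_cohort(c, STD)

    def test_unknown_exclude_errors(self):
        c = _mini_cohort({0: [(0.0, (120, 75, 200, 50), (True,) * 4)]})
        with pytest.raises(ValueError):
            encode_cohort(c, STD, exclude={"bmi"})

    def test_exclude_drops_channels(self):
        c = _mini_cohort({0: [(0.0, (120, 75, 200, 50), (True,) * 4)]})
        full = encode_cohort(c, STD)
        no_sbp = encode_cohort(c, STD, exclude={"sbp"})
        assert no_sbp.x.shape[2] == full.x.shape[2] - 2  # value + mask channels
        assert no_sbp.last_cov.shape[1] == full.last_cov.shape[1] - 1
        no_age = encode_cohort(c, STD, exclude={"age"})
        assert no_age.x.shape[2] == full.x.shape[2] - 1
        assert no_age.last_cov.shape[1] == full.last_cov.shape[1] - 1


def _params(rng, d_in=15, d_last=10, mode="dynamic", rnn_hidden=8, fc=(8,), n_out=21):
    return init_params(
        rng, d_in=d_in, d_last=d_last, n_cont=4, rnn_hidden=rnn_hidden,
        rnn_layers=1, fc_hidden=fc, n_out=n_out, mode=mode,
    )


class TestNetwork:
    def test_attention_length_one_forces_unit_weight(self, rng):
        p = _params(rng)
        h = rng.normal(size=(3, 1, 8))
        _, w = attention_context(p, h, np.ones((3, 1), dtype=bool))
        assert np.allclose(w, 1.0)

    def test_attention_masked_steps_have_zero_weight(self, rng):
        p = _params(rng)
        h = rng.normal(size=(2, 4, 8))
        valid = np.array([[True, True, False, False], [True, True, True, True]])
        _, w = attention_context(p, h, valid)
        assert np.allclose(w[0, 2:], 0.0)
        assert np.allclose(w.sum(axis=1), 1.0)
        assert (w >= 0).all()

    def test_attention_identical_states_split_evenly(self, rng):
        p = _params(rng)
        h = np.tile(rng.normal(size=(1, 1, 8)), (1, 2, 1))
        _, w = attention_context(p, h, np.ones((1, 2), dtype=bool))
        assert np.allclose(w, 0.5)

    def test_attention_all_invalid_errors(self, rng):
        p = _params(rng)
        with pytest.raises(ValueError):
            attention_context(p, rng.normal(size=(1, 2, 8)), np.zeros((1, 2), dtype=bool))

    def test_cause_forward_normalizes(self, rng):
        p = _params(rng)
        out = cause_forward(p, rng.normal(size=(50, 18)), (8,))
        assert np.allclose(np.asarray(out).sum(axis=1), 1.0)
        assert (np.asarray(out) >= 0).all()

    def test_cause_forward_zero_weights_uniform(self, rng):
        p = _params(rng)
        p["Wout"] = np.zeros_like(p["Wout"])
        p["bout"] = np.zeros_like(p["bout"])
        out = np.asarray(cause_forward(p, rng.normal(size=(5, 18)), (8,)))
        assert np.allclose(out, 1 / 21)

    def test_step_ahead_prediction_count(self, rng):
        # a length-L sequence yields exactly L-1 scored step-ahead predictions
        c = _mini_cohort(
            {
                0: [
                    (-6.0, (120, 75, 200, 50), (True,) * 4),
                    (-3.0, (125, 76, 205, 49), (True,) * 4),
                    (0.0, (130, 77, 210, 48), (True,) * 4),
                ]
            }
        )
        b = encode_cohort(c, STD)
        assert b.next_mask.any(axis=2).sum() == 2

    def test_masking_invariance_padding(self, rng):
        # appending padded steps never changes any output
        p = _params(rng)
        cfg = SurvivalNetConfig(rnn_hidden=8, fc_hidden=(8,), mode="dynamic")
        c = _mini_cohort(
            {
                0: [(-5.0, (120, 75, 200, 50), (True,) * 4), (0.0, (125, 76, 205, 49), (True,) * 4)],
            }
        )
        b2 = encode_cohort(c, STD, max_len=2)
        b4 = encode_cohort(c, STD, max_len=4)
        probs2, _, _ = full_forward(p, b2, cfg)
        probs4, _, _ = full_forward(p, b4, cfg)
        assert np.allclose(np.asarray(probs2), np.asarray(probs4), atol=1e-12)

    def test_forward_deterministic(self, rng):
        p = _params(rng)
        cfg = SurvivalNetConfig(rnn_hidden=8, fc_hidden=(8,), mode="dynamic")
        c = _mini_cohort({0: [(0.0, (120, 75, 200, 50), (True,) * 4)]})
        b = encode_cohort(c, STD)
        a1 = np.asarray(full_forward(p, b, cfg)[0])
        a2 = np.asarray(full_forward(p, b, cfg)[0])
        assert np.array_equal(a1, a2)


class TestCrossSectionalMode:
    def test_invariant_to_earlier_exams(self, rng):
        p = _params(rng, mode="cross_sectional")
        cfg = SurvivalNetConfig(rnn_hidden=8, fc_hidden=(8,), mode="cross_sectional")
        hist_a = {0: [(-5.0, (150, 95, 280, 30), (True,) * 4), (0.0, (120, 75, 200, 50), (True,) * 4)]}
        hist_b = {0: [(-5.0, (100, 60, 150, 70), (True,) * 4), (0.0, (120, 75, 200, 50), (True,) * 4)]}
        pa = np.asarray(full_forward(p, encode_cohort(_mini_cohort(hist_a), STD), cfg)[0])
        pb = np.asarray(full_forward(p, encode_cohort(_mini_cohort(hist_b), STD), cfg)[0])
        assert np.allclose(pa, pb, atol=1e-12)

    def test_beta_forced_to_zero(self):
        cfg = SurvivalNetConfig(mode="cross_sectional", beta=0.5)
        assert cfg.beta == 0.0


class TestTraining:
    def test_loss_decreases(self, tiny_dynamic_model):
        h = tiny_dynamic_model.history
        assert min(h.train_loss) < h.train_loss[0]
        assert h.best_epoch >= 0

    def test_training_deterministic(self, small_splits):
        cfg = SurvivalNetConfig(rnn_hidden=8, fc_hidden=(8,), max_epochs=3, seed=5)
        m1 = train(cfg, small_splits["train"], small_splits["tune"])
        m2 = train(cfg, small_splits["train"], small_splits["tune"])
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_predictions_valid_and_repeatable(self, tiny_dynamic_model, small_splits):
        r1 = tiny_dynamic_model.predict_risk(small_splits["test"])
        r2 = tiny_dynamic_model.predict_risk(small_splits["test"])
        assert np.array_equal(r1, r2)
        assert ((r1 >= 0) & (r1 <= 1)).all()

    def test_identical_histories_identical_risks(self, tiny_dynamic_model):
        c = _mini_cohort(
            {
                0: [(0.0, (130, 80, 210, 45), (True,) * 4)],
                1: [(0.0, (130, 80, 210, 45), (True,) * 4)],
            }
        )
        r = tiny_dynamic_model.predict_risk(c)
        assert r[0] == pytest.approx(r[1], abs=1e-12)

    def test_overlapping_train_tune_rejected(self, small_splits):
        cfg = SurvivalNetConfig(max_epochs=1)
        with pytest.raises(ValueError):
            train(cfg, small_splits["train"], small_splits["train"])

    def test_permuted_labels_give_chance_auroc(self):
        # destroying the outcome signal leaves test AUROC near 0.5
        from dynrisk import default_simulation_config, simulate_cohort, split_dataset
        from dynrisk.evaluation import auroc, binary_labels_at_horizon

        dev = simulate_cohort(default_simulation_config(n_participants=2000, seed=17))
        dev.outcomes[["time_years", "event"]] = (
            dev.outcomes[["time_years", "event"]].sample(frac=1, random_state=17).to_numpy()
        )
        splits = split_dataset(dev, (3, 1, 0.01), seed=17)
        parts = {
            s: dev.subset(splits.loc[splits["split"] == s, "id"]) for s in ("train", "tune")
        }
        test = simulate_cohort(default_simulation_config(n_participants=3000, seed=18))
        test.outcomes[["time_years", "event"]] = (
            test.outcomes[["time_years", "event"]].sample(frac=1, random_state=18).to_numpy()
        )
        net = SurvivalNetConfig(rnn_hidden=16, fc_hidden=(16,), max_epochs=10, seed=17)
        model = train(net, parts["train"], parts["tune"])
        risks = model.predict_risk(test)
        labels = binary_labels_at_horizon(test.outcomes)
        inc = labels["included"].to_numpy()
        a = auroc(risks[inc], labels.loc[inc, "label"])
        assert abs(a - 0.5) < 0.05


class TestCheckpoint:
    def test_round_trip(self, tiny_dynamic_model, small_splits, tmp_path):
        from dynrisk.deep_survival import SurvivalModel

        path = tmp_path / "model.ckpt.npz"
        tiny_dynamic_model.save(path)
        loaded = SurvivalModel.load(path)
        r1 = tiny_dynamic_model.predict_risk(small_splits["test"])
        r2 = loaded.predict_risk(small_splits["test"])
        assert np.allclose(r1, r2)

    def test_config_mismatch_refused(self, tiny_dynamic_model, tmp_path):
        from dynrisk.deep_survival import SurvivalModel

        path = tmp_path / "model.ckpt.npz"
        tiny_dynamic_model.save(path)
        other = dataclasses.replace(tiny_dynamic_model.config, rnn_hidden=64)
        with pytest.raises(ValueError):
            SurvivalModel.load(path, expect_config=other)
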