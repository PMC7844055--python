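"""Evolving output layer: populations, fit, prediction and serialization."""

import dataclasses

import numpy as np
import pytest

import bisnn
from bisnn import espannet as en
from bisnn import span_core as sp
from bisnn.signals import SpikeRaster, SpikeTrain


def _population(n_members=3, weights=None, th_n=0.5):
    cfg = sp.SPANConfig()
    members = [
        sp.SPANNeuron(weights=np.ones(2), config=cfg, afferents=np.array([0, 1]))
        for _ in range(n_members)
    ]
    pop = en.SPANPopulation(label="x", members=members, th_n=th_n)
    pop.readout_weights = (
        np.asarray(weights, float) if weights is not None else np.ones(n_members)
    )
    return pop


class TestReadout:
    def test_no_spikes_means_zero_current(self):
        pop = _population(2)
        grid = np.arange(0.0, 100.0, 10.0)
        out = en.readout_current(pop, [np.array([]), np.array([])], grid, 50.0)
        assert not out.any()

    def test_single_member_equals_its_convolution(self):
        pop = _population(1)
        grid = np.arange(0.0, 500.0, 10.0)
        out = en.readout_current(pop, [np.array([100.0])], grid, 50.0)
        np.testing.assert_allclose(out, sp.convolve_train([100.0], 50.0, grid))

    def test_weighted_average_of_identical_trains(self):
        pop = _population(3, weights=[1.0, 1.0, 0.0])
        grid = np.arange(0.0, 500.0, 10.0)
        train = np.array([100.0, 200.0])
        out = en.readout_current(pop, [train, train, train], grid, 50.0)
        np.testing.assert_allclose(
            out, (2 / 3) * sp.convolve_train(train, 50.0, grid)
        )

    def test_empty_population_current_is_an_error(self):
        pop = en.SPANPopulation(label="x")
        with pytest.raises(ValueError):
            en.readout_current(pop, [], np.arange(3.0), 50.0)

    def test_state_threshold_is_inclusive(self):
        pop = _population(1, th_n=0.5)
        states = en.readout_state(pop, np.array([0.49, 0.5, 0.51, 0.0]))
        np.testing.assert_array_equal(states, [0, 1, 1, 0])

    def test_current_is_linear_in_member_weights(self):
        grid = np.arange(0.0, 500.0, 10.0)
        trains = [np.array([50.0]), np.array([150.0, 300.0])]
        pop = _population(2, weights=[0.4, 0.7])
        base = en.readout_current(pop, trains, grid, 50.0)
        pop.readout_weights = pop.readout_weights * 3.0
        np.testing.assert_allclose(
            en.readout_current(pop, trains, grid, 50.0), 3.0 * base, atol=1e-12
        )


class TestSpawn:
    def _clusters(self):
        return {"r0": np.array([0, 1]), "r1": np.array([2]), "r2": np.array([3, 4])}

    def test_empty_population_spawns_exactly_one(self, rng):
        pop = en.SPANPopulation(label="x")
        grid = np.arange(0.0, 500.0, 10.0)
        aff = [np.array([100.0])] * 5
        new = en.spawn_span(
            pop, aff, np.array([150.0]), self._clusters(), sp.SPANConfig(max_epochs=3),
            grid, rng,
        )
        assert new is not None
        assert pop.n_members == 1
        assert pop.cluster_cursor == 1

    def test_round_robin_walks_through_clusters(self, rng):
        pop = en.SPANPopulation(label="x")
        grid = np.arange(0.0, 500.0, 10.0)
        aff = [np.array([100.0])] * 5
        cfg = sp.SPANConfig(max_epochs=1)  # never converges -> always spawns
        order = ["r2", "r0", "r1"]
        for _ in range(3):
            en.spawn_span(pop, aff, np.array([150.0]), self._clusters(), cfg, grid,
                          rng, cluster_order=order)
        wired = [tuple(m.afferents) for m in pop.members]
        assert wired == [(3, 4), (0, 1), (2,)]

    def test_trained_member_reproducing_desired_blocks_spawn(self, rng):
        pop = en.SPANPopulation(label="x")
        grid = np.arange(0.0, 500.0, 10.0)
        cfg = sp.SPANConfig(tau_s=50.0, th_m=0.5, max_epochs=1, match_tolerance=20.0)
        aff = [np.array([100.0])]
        clusters = {"r0": np.array([0])}
        member = sp.SPANNeuron(weights=np.array([1.0]), config=cfg,
                               afferents=np.array([0]), trained=True)
        pop.members.append(member)
        pop.readout_weights = np.ones(1)
        desired = en._member_output_ms(member, aff, grid, cfg)
        assert desired.size > 0
        out = en.spawn_span(pop, aff, desired, clusters, cfg, grid, rng)
        assert out is None
        assert pop.n_members == 1


class TestValidation:
    def test_single_member_always_retained(self):
        cfg = sp.SPANConfig(tau_s=50.0, th_m=0.5, match_tolerance=20.0)
        member = sp.SPANNeuron(weights=np.array([1.0]), config=cfg,
                               afferents=np.array([0]))
        pop = en.SPANPopulation(label="x", members=[member],
                                readout_weights=np.ones(1))
        grid = np.arange(0.0, 500.0, 10.0)
        aff = [[np.array([100.0])]]
        desired = [en._member_output_ms(member, aff[0], grid, cfg)]
        en.validate_population(pop, aff, desired, [grid], cfg, kappa=0.8)
        assert member.accuracy == 1.0
        assert pop.readout_weights[0] == 1.0

    def test_zero_accuracy_member_is_silenced_not_dropped(self):
        cfg = sp.SPANConfig(tau_s=50.0, th_m=0.5, match_tolerance=20.0)
        good = sp.SPANNeuron(weights=np.array([1.0]), config=cfg,
                             afferents=np.array([0]))
        bad = sp.SPANNeuron(weights=np.array([0.0]), config=cfg,
                            afferents=np.array([0]))
        pop = en.SPANPopulation(label="x", members=[good, bad],
                                readout_weights=np.ones(2))
        grid = np.arange(0.0, 500.0, 10.0)
        aff = [[np.array([100.0])]]
        desired = [en._member_output_ms(good, aff[0], grid, cfg)]
        assert desired[0].size > 0  # bad (zero-weight) member can't emit this
        en.validate_population(pop, aff, desired, [grid], cfg, kappa=0.5)
        assert pop.n_members == 2
        assert pop.readout_weights[1] == 0.0
        assert pop.readout_weights[0] == 1.0

    def test_silenced_members_never_change_the_readout(self):
        grid = np.arange(0.0, 500.0, 10.0)
        trains = [np.array([100.0]), np.array([250.0])]
        with_silenced = _population(2, weights=[0.8, 0.0])
        cur = en.readout_current(with_silenced, trains, grid, 50.0)
        states = en.readout_state(with_silenced, cur)
        # drop the silenced member entirely; scale for the 1/m normalisation
        alone = _population(1, weights=[0.8])
        cur_alone = en.readout_current(alone, trains[:1], grid, 50.0) / 2.0
        np.testing.assert_allclose(cur, cur_alone, atol=1e-12)
        np.testing.assert_array_equal(states, en.readout_state(alone, cur_alone))


class TestFit:
    def test_zero_trials_yields_empty_populations(self, small_session):
        s = small_session
        model = bisnn.fit(s.inputs, s.targets, s.montage, [], seed=1)
        assert all(p.n_members == 0 for p in model.populations)
        assert model.target_labels == list(s.targets.channel_labels)

    def test_single_trial_spawns_one_member_per_target(self, small_session):
        s = small_session
        model = bisnn.fit(
            s.inputs, s.targets, s.montage, s.trial_windows[:1], seed=1
        )
        assert all(p.n_members == 1 for p in model.populations)

    def test_mismatched_signals_rejected(self, small_session):
        s = small_session
        bad = bisnn.ContinuousSignal(
            s.targets.values[:-10], s.targets.sample_rate,
            list(s.targets.channel_labels),
        )
        with pytest.raises(ValueError):
            bisnn.fit(s.inputs, bad, s.montage, s.trial_windows)

    def test_incremental_fit_matches_single_pass(self, small_session):
        s = small_session
        one = bisnn.fit(s.inputs, s.targets, s.montage, s.trial_windows, seed=3)
        part = bisnn.fit(s.inputs, s.targets, s.montage, s.trial_windows[:2], seed=3)
        bisnn.extend(part, s.targets, s.trial_windows[2:])
        for p1, p2 in zip(one.populations, part.populations):
            assert p1.n_members == p2.n_members
            for m1, m2 in zip(p1.members, p2.members):
                np.testing.assert_array_equal(m1.afferents, m2.afferents)
                np.testing.assert_array_equal(m1.weights, m2.weights)

    def test_extend_requires_in_memory_model(self, small_session, tmp_path):
        s = small_session
        model = bisnn.fit(s.inputs, s.targets, s.montage, s.trial_windows[:1], seed=3)
        path = tmp_path / "m.json"
        model.to_json(path)
        reloaded = en.DecoderModel.from_json(path)
        with pytest.raises(ValueError):
            bisnn.extend(reloaded, s.targets, s.trial_windows[1:])


class TestPredict:
    def test_streaming_equals_batch_bitwise(self, small_model, small_test_session):
        inputs = small_test_session.inputs
        a = bisnn.predict_stream(small_model, inputs, mode="streaming")
        b = bisnn.predict_stream(small_model, inputs, mode="batch")
        np.testing.assert_array_equal(a.readout_states, b.readout_states)
        np.testing.assert_array_equal(a.decoded.values, b.decoded.values)
        for label in a.member_rasters:
            for ta, tb in zip(a.member_rasters[label].trains,
                              b.member_rasters[label].trains):
                np.testing.assert_array_equal(ta.times, tb.times)

    def test_all_zero_input_is_flat_at_initial_values(self, small_model,
                                                      small_test_session):
        sig = small_test_session.inputs
        flat = bisnn.ContinuousSignal(
            np.zeros_like(sig.values), sig.sample_rate, list(sig.channel_labels)
        )
        res = bisnn.predict_stream(small_model, flat, mode="batch")
        assert all(t.n == 0 for r in res.member_rasters.values() for t in r.trains)
        for j, label in enumerate(res.decoded.channel_labels):
            init = small_model.thresholds_target[label].initial
            np.testing.assert_allclose(res.decoded.values[:, j], init)

    def test_unknown_channels_rejected(self, small_model, small_test_session):
        sig = small_test_session.inputs
        renamed = bisnn.ContinuousSignal(
            sig.values, sig.sample_rate,
            [f"zz_{c}" for c in sig.channel_labels],
        )
        with pytest.raises(ValueError, match="unknown"):
            bisnn.predict_stream(small_model, renamed)

    def test_streaming_logs_wall_times(self, small_model, small_test_session):
        res = bisnn.predict_stream(
            small_model, small_test_session.inputs, mode="streaming"
        )
        assert res.tick_wall_times.size == small_test_session.inputs.n_samples
        assert (res.tick_wall_times >= 0).all()


class TestSerialization:
    def test_round_trip_preserves_predictions(self, small_model,
                                              small_test_session, tmp_path):
        path = tmp_path / "model.json"
        small_model.to_json(path)
        reloaded = en.DecoderModel.from_json(path)
        a = bisnn.predict_stream(small_model, small_test_session.inputs, "batch")
        b = bisnn.predict_stream(reloaded, small_test_session.inputs, "batch")
        np.testing.assert_array_equal(a.readout_states, b.readout_states)
        np.testing.assert_array_equal(a.decoded.values, b.decoded.values)

    def test_json_is_stable_across_dumps(self, small_model, tmp_path):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        small_model.to_json(p1)
        small_model.to_json(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestPredictLabels:
    def _result(self, states, sr=100.0):
        n = states.shape[0]
        labels = [f"p{i}" for i in range(states.shape[1])]
        rasters = {
            lab: SpikeRaster([SpikeTrain([], (n - 1) / sr)], [f"{lab}_m0"])
            for lab in labels
        }
        return en.PredictionResult(
            member_rasters=rasters,
            readout_trains={lab: SpikeTrain([], (n - 1) / sr) for lab in labels},
            readout_states=states,
            population_labels=labels,
            decoded=None,
            reservoir_raster=SpikeRaster([], []),
            tick_wall_times=np.zeros(0),
            sample_rate=sr,
        )

    def test_single_active_population_wins_window(self):
        states = np.zeros((100, 2), dtype=int)
        states[10:30, 1] = 1
        res = self._result(states)
        df = en.predict_labels(res, window_s=1.0)
        assert df["label"].iloc[0] == "p1"

    def test_silence_gives_no_event(self):
        res = self._result(np.zeros((50, 2), dtype=int))
        df = en.predict_labels(res, window_s=0.5)
        assert (df["label"] == en.NO_EVENT).all()

    def test_exact_tie_gives_no_event(self):
        states = np.zeros((40, 2), dtype=int)
        states[:10, 0] = 1
        states[:10, 1] = 1
        res = self._result(states)
        df = en.predict_labels(res, window_s=0.4)
        assert df["label"].iloc[0] == en.NO_EVENT
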