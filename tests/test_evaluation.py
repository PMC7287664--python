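"""Metrics, initial-contact detection, event extraction and reports."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import accelgait as ag
from accelgait.evaluation import GaitEvents, _concat_events
from accelgait.simulate import EVENT_NAMES


def brute_rmse(y, y_hat):
    return (sum((a - b) ** 2 for a, b in zip(y, y_hat)) / len(y)) ** 0.5


series = st.lists(st.floats(-100, 100), min_size=2, max_size=40)


class TestContinuousMetrics:
    def test_rmse_examples(self):
        assert ag.rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert ag.rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(12.5))

    def test_rmse_translation_invariance(self):
        rng = np.random.default_rng(0)
        y, y_hat = rng.normal(size=50), rng.normal(size=50)
        assert ag.rmse(y + 7.5, y_hat + 7.5) == pytest.approx(ag.rmse(y, y_hat))

    @given(series, series)
    def test_metrics_match_brute_force(self, y, y_hat):
        n = min(len(y), len(y_hat))
        y, y_hat = y[:n], y_hat[:n]
        assert ag.rmse(y, y_hat) == pytest.approx(brute_rmse(y, y_hat),
                                                  abs=1e-9)
        rng = max(y) - min(y)
        if rng > 1e-6:
            assert ag.nrmse(y, y_hat) == pytest.approx(
                100 * brute_rmse(y, y_hat) / rng, abs=1e-6)
        ss_tot = sum((v - sum(y) / n) ** 2 for v in y)
        if ss_tot > 1e-6:
            ss_res = sum((a - b) ** 2 for a, b in zip(y, y_hat))
            assert ag.r2(y, y_hat) == pytest.approx(1 - ss_res / ss_tot,
                                                    abs=1e-6)

    def test_nrmse_examples_and_scale_invariance(self):
        y = np.linspace(0, 40, 100)
        y_hat = y + 2.0
        assert ag.nrmse(y, y_hat) == pytest.approx(5.0)
        assert ag.nrmse(y, y) == 0.0
        assert ag.nrmse(3 * y, 3 * y_hat) == pytest.approx(ag.nrmse(y, y_hat))

    def test_r2_examples(self):
        y = np.array([0.0, 1.0, 2.0])
        assert ag.r2(y, y) == 1.0
        assert ag.r2(y, np.full(3, y.mean())) == 0.0
        assert ag.r2(y, [0.0, 1.0, 4.0]) == pytest.approx(-1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ag.rmse([], [])
        with pytest.raises(ValueError):
            ag.rmse([1, 2], [1])
        with pytest.raises(ValueError):
            ag.nrmse([2.0, 2.0], [1.0, 3.0])     # zero range
        with pytest.raises(ValueError):
            ag.r2([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


class TestInitialContacts:
    def test_matches_simulator_ground_truth(self, noiseless_trial):
        ics = ag.detect_initial_contacts(noiseless_trial.heel_height, 100.0)
        true = noiseless_trial.true_ic_indices
        # every detected IC within 1 sample of a true one, none missed inside
        dist = np.abs(ics[:, None] - true[None, :]).min(axis=1)
        assert dist.max() <= 1
        assert len(ics) >= len(true) - 2        # edges may be undetectable

    def test_robust_to_measurement_noise(self, noisy_trial):
        heel = noisy_trial.heel_height + np.random.default_rng(0).normal(
            0, 1.0, noisy_trial.n_samples)
        ics = ag.detect_initial_contacts(heel, 100.0)
        dist = np.abs(ics[:, None]
                      - noisy_trial.true_ic_indices[None, :]).min(axis=1)
        assert np.median(dist) <= 2

    def test_two_strides_two_contacts(self):
        t = np.arange(0, 1.45, 0.01)            # ~2 periods of a 0.7 s stride
        heel = 50 + 30 * np.cos(2 * np.pi * t / 0.7)
        ics = ag.detect_initial_contacts(heel, 100.0)
        assert len(ics) == 2                    # interior minima at 0.35, 1.05

    def test_flat_and_monotone_rejected(self):
        with pytest.raises(ValueError):
            ag.detect_initial_contacts(np.full(500, 30.0), 100.0)
        with pytest.raises(ValueError):
            ag.detect_initial_contacts(np.linspace(0, 100, 500), 100.0)


class TestExtractEvents:
    def test_noiseless_events_within_half_degree(self, noiseless_trial):
        tr = noiseless_trial
        ics = ag.detect_initial_contacts(tr.heel_height, tr.sample_rate)
        ev = ag.extract_events(tr.angles, ics)
        for name in EVENT_NAMES:
            assert np.abs(getattr(ev, name)
                          - tr.true_events[name]).max() < 0.5

    def test_sinusoid_closed_form(self):
        # Hip = 6.15 + 27.6 sin(.) -> peak flexion 33.75, extension 21.45.
        t = np.arange(0, 3.0, 0.001)
        hip = 6.15 + 27.6 * np.sin(2 * np.pi * t / 0.7)
        angles = np.column_stack([hip, np.full_like(t, 20.0), hip / 3.0])
        ics = np.arange(0, len(t), 700)
        ev = ag.extract_events(angles, ics)
        assert ev.hip_peak_flexion.mean() == pytest.approx(33.75, abs=0.01)
        assert ev.hip_peak_extension.mean() == pytest.approx(21.45, abs=0.01)

    def test_one_value_per_event_per_stride(self, noiseless_trial):
        ics = noiseless_trial.true_ic_indices
        ev = ag.extract_events(noiseless_trial.angles, ics)
        assert ev.n_strides == len(ics) - 1
        for name in EVENT_NAMES:
            assert len(getattr(ev, name)) == ev.n_strides

    def test_fewer_than_two_contacts_rejected(self, noiseless_trial):
        with pytest.raises(ValueError):
            ag.extract_events(noiseless_trial.angles, [100])


class TestEventErrors:
    def _events(self, trial):
        return ag.extract_events(trial.angles, trial.true_ic_indices)

    def test_identity_gives_zero_mae(self, noiseless_trial):
        ev = self._events(noiseless_trial)
        table = ag.event_errors(ev, ev)
        assert np.allclose(table["mae"], 0.0)
        assert np.allclose(table["mean_difference"], 0.0)

    def test_constant_offset(self, noiseless_trial):
        ref = self._events(noiseless_trial)
        shifted = GaitEvents(
            ic_index=ref.ic_index,
            **{n: getattr(ref, n) + 2.0 for n in EVENT_NAMES})
        table = ag.event_errors(ref, shifted)
        assert np.allclose(table["mae"], 2.0)
        assert np.allclose(table["mean_difference"], 2.0)

    def test_mae_bounds_mean_difference(self, noiseless_trial):
        rng = np.random.default_rng(5)
        ref = self._events(noiseless_trial)
        noisy = GaitEvents(
            ic_index=ref.ic_index,
            **{n: getattr(ref, n) + rng.normal(0, 2, ref.n_strides)
               for n in EVENT_NAMES})
        table = ag.event_errors(ref, noisy)
        assert np.all(table["mae"] + 1e-12
                      >= np.abs(table["mean_difference"]))

    def test_unmatchable_strides_rejected(self, noiseless_trial):
        ref = self._events(noiseless_trial)
        far = GaitEvents(
            ic_index=ref.ic_index + 10_000,
            **{n: getattr(ref, n) for n in EVENT_NAMES})
        with pytest.raises(ValueError, match="matched"):
            ag.event_errors(ref, far)


class _LookupEstimator:
    """Oracle stand-in: returns stored targets (plus optional offset)."""

    def __init__(self, datasets, offset=0.0):
        self.fingerprint = {}
        self._table = {}
        self.offset = offset
        for ds in datasets:
            for row, target in zip(ds.X, ds.y):
                self._table[row.tobytes()] = target
        self.spec = ag.CnnSpec()

    def predict_windows(self, X):
        out = np.stack([self._table[row.tobytes()] for row in X])
        return out.astype(float) + self.offset


@pytest.fixture(scope="module")
def two_participant_trials(population):
    import dataclasses

    trials = []
    for profile in population[:2]:
        p = dataclasses.replace(profile, noise_sd=0.0)
        trials.append(ag.filter_trial(
            ag.simulate_trial(p, 10.0, duration=8.0), ag.FilterSpec()))
    return trials


class TestEvaluate:
    def test_oracle_estimator_scores_perfectly(self, two_participant_trials):
        datasets = [ag.make_windows(t) for t in two_participant_trials]
        report = ag.evaluate(_LookupEstimator(datasets),
                             two_participant_trials)
        assert len(report.per_participant) == 2
        for joint in ("hip", "knee", "ankle"):
            assert np.allclose(report.per_participant[f"rmse_{joint}"], 0.0)
            assert np.allclose(report.per_participant[f"r2_{joint}"], 1.0)
        assert np.allclose(report.events_summary["mae"], 0.0)

    def test_internal_consistency_nrmse_rmse(self, two_participant_trials):
        datasets = [ag.make_windows(t) for t in two_participant_trials]
        est = _LookupEstimator(datasets, offset=1.5)
        report = ag.evaluate(est, two_participant_trials)
        for trial, ds in zip(two_participant_trials, datasets):
            pid = trial.participant_id
            for j, joint in enumerate(("hip", "knee", "ankle")):
                y = ds.y[:, j].astype(float)
                rng = y.max() - y.min()
                lhs = (report.per_participant.loc[pid, f"nrmse_{joint}"]
                       * rng / 100.0)
                assert lhs == pytest.approx(
                    report.per_participant.loc[pid, f"rmse_{joint}"], abs=1e-9)

    def test_summary_is_mean_of_participant_rows(self, two_participant_trials):
        datasets = [ag.make_windows(t) for t in two_participant_trials]
        report = ag.evaluate(_LookupEstimator(datasets, offset=0.7),
                             two_participant_trials)
        np.testing.assert_allclose(report.summary["mean"],
                                   report.per_participant.mean(axis=0))

    def test_fingerprint_mismatch_rejected(self, two_participant_trials):
        datasets = [ag.make_windows(t) for t in two_participant_trials]
        est = _LookupEstimator(datasets)
        est.fingerprint = {"filter_order": 2}
        with pytest.raises(ValueError, match="fingerprint"):
            ag.evaluate(est, two_participant_trials)

    def test_report_text_and_json(self, tmp_path, two_participant_trials):
        datasets = [ag.make_windows(t) for t in two_participant_trials]
        report = ag.evaluate(_LookupEstimator(datasets, offset=0.5),
                             two_participant_trials)
        text = report.to_text()
        assert "RMSE" in text and "hip" in text
        out = tmp_path / "report.json"
        report.to_json(out)
        import json

        loaded = json.loads(out.read_text())
        assert set(loaded["per_participant"]) == {
            t.participant_id for t in two_participant_trials}
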