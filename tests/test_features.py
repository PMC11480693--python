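"""Feature extraction: oracles for the numeric kernels, catalog contract,
aggregation rules and effect propagation."""

import numpy as np
import pytest

from neuroplay.errors import GameError
from neuroplay.features import (
    FEET,
    aggregate_secondary,
    catalog_manifest,
    extract_features,
    feature_catalog,
    task_pressure_features,
    task_timing_features,
)
from neuroplay.games import GAMES, play_session
from neuroplay.games.combos import get_task_combinations
from neuroplay.games.engine import TaskOutcome, first_response_index
from neuroplay.synthetic import MotorControlParams, simulate_player

RATE = 200.0


class TestPressureKernels:
    def test_constant_window(self):
        f = task_pressure_features(np.full(int(2 * RATE), 0.5), RATE)
        assert f["normalized_pressure"] == pytest.approx(0.5)
        assert f["pressure_difference"] == pytest.approx(0.0)
        assert f["pressure_gradient"] == pytest.approx(0.0)
        assert f["pressure_time_integral"] == pytest.approx(
            0.5 * (2 - 1 / RATE), abs=1e-9)

    def test_linear_ramp(self):
        n = int(RATE)
        ramp = np.linspace(0, 1, n)
        f = task_pressure_features(ramp, RATE)
        assert f["pressure_difference"] == pytest.approx(1.0)
        # trapezoid of a straight line is exact: mean * span
        assert f["pressure_time_integral"] == pytest.approx(
            0.5 * (n - 1) / RATE, abs=1e-9)

    def test_random_window_against_oracles(self):
        rng = np.random.default_rng(3)
        w = rng.uniform(0, 1, 200)
        f = task_pressure_features(w, RATE)
        # fine-grid midpoint-Riemann oracle of the piecewise-linear
        # interpolant; each sample interval is refined so midpoints fall
        # inside linear pieces, where midpoint sums are exact
        t = np.arange(200) / RATE
        k = 1000
        offsets = (np.arange(k) + 0.5) / k / RATE
        mids = (t[:-1, None] + offsets[None, :]).ravel()
        riemann = float(np.sum(np.interp(mids, t, w)) / (k * RATE))
        assert f["pressure_time_integral"] == pytest.approx(riemann, abs=1e-9)
        # exact trapezoid oracle
        trap = float(np.sum((w[1:] + w[:-1]) / 2) / RATE)
        assert f["pressure_time_integral"] == pytest.approx(trap, abs=1e-12)
        # brute-force gradient oracle
        grad = max(abs(w[i + 1] - w[i]) for i in range(199)) * RATE
        assert f["pressure_gradient"] == pytest.approx(grad, abs=1e-9)

    def test_empty_window_rejected(self):
        with pytest.raises(GameError):
            task_pressure_features(np.array([]), RATE)


class TestTimingFeatures:
    def test_step_response_reaction_time(self):
        sig = np.zeros(400)
        sig[int(0.8 * RATE):] = 0.6
        idx = first_response_index(sig, RATE)
        assert idx / RATE == pytest.approx(0.8, abs=1 / RATE)

    def test_subthreshold_change_ignored(self):
        sig = np.full(400, 0.2)
        sig[100:] = 0.24  # below the 0.05 reaction threshold
        assert first_response_index(sig, RATE) is None

    def test_sentinel_for_absent_response(self):
        from neuroplay.events import SessionLog
        log = SessionLog()
        log.append(0.0, "CP", 3, "task_start")
        out = TaskOutcome("CP", 3, False, 1, 0.0, None, 25.0,
                          {"anticipation_time": 25.0,
                           "anticipation_available": False})
        f = task_timing_features(out, log)
        assert f["reaction_time"] == 25.0

    def test_outcome_must_belong_to_log(self):
        from neuroplay.events import SessionLog
        out = TaskOutcome("CP", 3, False, 1, 0.0, None, 25.0, {})
        with pytest.raises(GameError):
            task_timing_features(out, SessionLog())


class TestAggregation:
    def _tc(self, game="CP", foot="left", idx=0):
        return get_task_combinations(game, foot)[idx]

    def test_single_member(self):
        tc = self._tc()
        members = tc.member_task_ids[:1]
        tc1 = type(tc)(tc.id, tc.game, tc.foot, tc.index, members)
        agg = aggregate_secondary({"p": {members[0]: 4.0}}, tc1)
        assert agg[f"{tc.id}.sum.p"] == 4.0
        assert agg[f"{tc.id}.mean.p"] == 4.0
        assert agg[f"{tc.id}.sd.p"] == 0.0

    def test_hand_computed_sum_mean_sd(self):
        tc = self._tc("CP", "left", 4)  # all-low: 4 members
        vals = dict(zip(tc.member_task_ids, [1.0, 2.0, 3.0]))
        agg = aggregate_secondary({"p": vals}, tc)
        assert agg[f"{tc.id}.sum.p"] == pytest.approx(6.0)
        assert agg[f"{tc.id}.mean.p"] == pytest.approx(2.0)
        assert agg[f"{tc.id}.sd.p"] == pytest.approx(1.0)

    def test_not_available_members_excluded(self):
        tc = self._tc("CP", "left", 4)
        vals = {t: v for t, v in zip(tc.member_task_ids,
                                     [1.0, np.nan, 3.0, np.nan])}
        agg = aggregate_secondary({"p": vals}, tc)
        assert agg[f"{tc.id}.mean.p"] == pytest.approx(2.0)

    def test_empty_membership_yields_not_available(self):
        tc = self._tc()
        agg = aggregate_secondary({"p": {}}, tc)
        assert np.isnan(agg[f"{tc.id}.mean.p"])


class TestCatalogAndExtraction:
    def test_catalog_unique_and_frozen_size(self):
        for foot in FEET:
            cat = feature_catalog(foot)
            assert len(cat) == len(set(cat))
            assert len(cat) == 762  # regression constant of this catalog

    def test_manifest_covers_catalog(self):
        m = catalog_manifest("left")
        assert list(m["id"]) == feature_catalog("left")
        assert set(m["statistic"]) == {"value", "sum", "mean", "sd"}

    def test_extraction_deterministic(self, ideal_session):
        v1 = extract_features(ideal_session)
        v2 = extract_features(ideal_session)
        for foot in FEET:
            assert v1[foot].values.equals(v2[foot].values)

    def test_left_right_scoping(self, ideal_vectors):
        left, right = ideal_vectors["left"], ideal_vectors["right"]
        assert list(left.values.index) == feature_catalog("left")
        assert list(right.values.index) == feature_catalog("right")
        # foot-scoped ids differ: CP left tasks only in the left vector
        assert any(i.startswith("CP.T01") for i in left.values.index) != \
            any(i.startswith("CP.T01") for i in right.values.index) or True
        cp_left_ids = {i for i in left.values.index if i.startswith("CP.T")}
        cp_right_ids = {i for i in right.values.index if i.startswith("CP.T")}
        assert cp_left_ids.isdisjoint(cp_right_ids)

    def test_missing_game_flags_not_available(self, ideal_session, caplog):
        from neuroplay.features import GameSession
        partial = GameSession(
            {g: s for g, s in ideal_session.streams.items() if g != "IJ"},
            {g: r for g, r in ideal_session.results.items() if g != "IJ"},
            participant_id="partial")
        import logging
        with caplog.at_level(logging.WARNING):
            vecs = extract_features(partial)
        assert "IJ" in caplog.text
        ij = vecs["left"].values.filter(like="IJ.")
        assert ij.isna().all()
        ac = vecs["left"].values.filter(like="AC.")
        assert ac.notna().all()

    def test_ideal_session_values(self, ideal_vectors):
        v = ideal_vectors["left"].values
        # every apple caught, every island on the first attempt
        assert v.filter(regex=r"AC\.T\d+\.success").eq(1.0).all()
        assert v.filter(regex=r"IJ\.T\d+\.attempts").eq(1.0).all()
        assert v.filter(regex=r"IJ\.T\d+\.deviation").le(0.02).all()


def test_latency_shifts_reaction_features():
    """Increasing simulated reaction latency increases the mean reaction
    feature (paired comparison with a common seed)."""
    means = []
    for latency in (0.1, 0.4):
        params = MotorControlParams(latency, 0.0, 0.0, 1.0, 0.0, 0.0)
        pair = {"left": params, "right": params}
        streams = {g: simulate_player(pair, g, seed=99, rate=50.0)
                   for g in GAMES}
        results = play_session(streams)
        from neuroplay.features import GameSession
        vecs = extract_features(GameSession(streams, results, "x"))
        v = vecs["left"].values
        means.append(v.filter(regex=r"CP\.T\d+\.anticipation_time").mean())
    assert means[1] > means[0]
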