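"""Tests for the event-driven polysome traffic simulator."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from ribocollide import (
    CollisionGeometry,
    DrugModel,
    InitiationSpec,
    ParameterError,
    PolysomeSnapshot,
    QCParams,
    RibosomeState,
    SimulationParams,
    TranscriptSpec,
    make_preset,
    queue_decomposition,
    simulate,
    steady_state_ird,
)

QC_OFF = QCParams(sensor_present=False)


def _params(**kw):
    defaults = dict(t_max=100.0, seed=0, qc=QC_OFF, initiation=InitiationSpec(0.0, False))
    defaults.update(kw)
    return SimulationParams(**defaults)


class TestSingleRibosome:
    def test_transit_time_matches_sum_of_exponentials(self):
        # a lone ribosome crosses L-1 codons at rate k: mean transit (L-1)/k
        L, k = 50, 5.6
        transcript = TranscriptSpec(L, k, {}, termination_rate=1e9)
        times = []
        for seed in range(200):
            _, log = simulate(transcript, _params(seed=seed, initial_positions=(1,)))
            term = log.of_kind("termination")
            assert len(term) == 1
            assert not log.of_kind("collision")
            times.append(term[0].time)
        expected = (L - 1) / k
        se = np.sqrt(L - 1) / k / np.sqrt(len(times))
        assert abs(np.mean(times) - expected) < 3 * se

    def test_determinism_bit_identical_logs(self):
        pre = make_preset("eRF1AAQ_stall", seed=5)
        _, log1 = simulate(pre.transcript, pre.params)
        _, log2 = simulate(pre.transcript, pre.params)
        assert log1 == log2
        _, log3 = simulate(pre.transcript, replace(pre.params, seed=6))
        assert log3 != log1


class TestStallQueueing:
    def test_trapped_termination_complex_builds_compact_queue(self):
        # termination rate 0: ribosomes queue 5' of the stop with gaps of
        # exactly the collided footprint
        pre = make_preset("eRF1AAQ_stall", seed=3)
        params = replace(pre.params, qc=QC_OFF)
        trajectory, log = simulate(pre.transcript, params)
        final = trajectory[-1]
        positions = final.positions()
        assert positions[0] == pre.transcript.length_codons
        gaps = [a - b for a, b in zip(positions, positions[1:])]
        assert all(g == 10 for g in gaps[:5])
        assert len(queue_decomposition(final, params.geometry)) < len(positions)
        assert log.of_kind("collision")

    def test_collision_events_recorded_at_footprint_gap(self):
        pre = make_preset("eRF1AAQ_stall", seed=9)
        params = replace(pre.params, qc=QC_OFF)
        trajectory, log = simulate(pre.transcript, params)
        # every collision record coincides with a gap of exactly footprint:
        # the colliding ribosome sits escape-1 codons behind some other one
        positions_at = {}
        for snap in trajectory:
            positions_at[snap.time] = snap.positions()
        for ev in log.of_kind("collision"):
            assert 1 <= ev.position <= pre.transcript.length_codons - 10

    def test_exclusion_safety_everywhere(self):
        pre = make_preset("eRF1AAQ_stall", seed=11)
        trajectory, _ = simulate(pre.transcript, replace(pre.params, qc=QC_OFF))
        fp = pre.params.geometry.footprint_codons
        for snap in trajectory:
            ps = snap.positions()
            assert all(a - b >= fp for a, b in zip(ps, ps[1:]))

    def test_conservation_of_ribosomes(self):
        pre = make_preset("genome_average", seed=2)
        trajectory, log = simulate(pre.transcript, pre.params)
        n_init = len(log.of_kind("initiation"))
        n_term = len(log.of_kind("termination"))
        n_res = len(log.of_kind("resolution"))
        assert n_init == len(trajectory[-1].ribosomes) + n_term + n_res


class TestCollisionFlux:
    def test_queue_growth_matches_birth_process_oracle(self):
        """With a permanently stalled lead and slow Poisson initiation the
        queue size follows a delayed birth process: arrival i joins after
        its initiation time plus the travel time to its queue slot."""
        alpha, v, t_max, stall_at, L = 0.02, 5.6, 400.0, 200, 260
        transcript = TranscriptSpec(L, v, {stall_at: 0.0}, termination_rate=0.0)
        sizes = []
        for seed in range(100):
            trajectory, _ = simulate(
                transcript,
                _params(
                    t_max=t_max,
                    seed=seed,
                    initiation=InitiationSpec(alpha, True),
                    initial_positions=(stall_at,),
                ),
            )
            # queue size = collided run containing the stalled lead
            runs = queue_decomposition(trajectory[-1], CollisionGeometry())
            sizes.append((runs[0] if runs else 1) - 1)

        # independent oracle: Poisson-ish arrivals (initiation dead time of
        # footprint codons) + gamma travel to slot stall_at - 10*i
        rng = np.random.default_rng(12345)
        oracle = []
        for _ in range(400):
            t, joined = 0.0, 0
            for i in range(1, 60):
                if i > 1:
                    t += rng.gamma(10, 1 / v)
                t += rng.exponential(1 / alpha)
                slot = stall_at - 10 * i
                if slot < 2 or t > t_max:
                    break
                join_time = t + rng.gamma(slot - 1, 1 / v)
                if join_time <= t_max:
                    joined += 1
            oracle.append(joined)
        se = np.std(sizes) / np.sqrt(len(sizes)) + np.std(oracle) / np.sqrt(len(oracle))
        assert abs(np.mean(sizes) - np.mean(oracle)) < 3 * se
        # growth is initiation-limited: never beyond the Poisson arrivals
        assert np.mean(sizes) <= alpha * t_max


class TestDrugRegimes:
    def test_global_arrest_freezes_everyone(self):
        pre = make_preset("emetine_high", seed=4)
        trajectory, log = simulate(pre.transcript, pre.params)
        onset = pre.params.drug.onset_time
        assert all(e.time >= onset for e in log.of_kind("arrest"))
        # (the snapshot at exactly the onset instant shows the pre-arrest state)
        frozen = [s for s in trajectory if s.time > onset]
        assert all(r.arrested for snap in frozen for r in snap.ribosomes)
        # no elongation after the arrest sweep
        assert not [e for e in log.of_kind("elongation") if e.time > onset]

    def test_stochastic_arrest_is_irreversible_and_partial(self):
        pre = make_preset("emetine_low", seed=4)
        trajectory, log = simulate(pre.transcript, pre.params)
        arrests = log.of_kind("arrest")
        assert arrests and all(e.time >= pre.params.drug.onset_time for e in arrests)
        arrested_ids = {e.ribosome_id for e in arrests}
        # an arrested ribosome never elongates again
        for e in log.of_kind("elongation"):
            first_arrest = min(a.time for a in arrests if a.ribosome_id == e.ribosome_id) if e.ribosome_id in arrested_ids else np.inf
            assert e.time <= first_arrest
        # low dose arrests only a subset of ribosomes
        all_ids = {e.ribosome_id for e in log.of_kind("initiation")}
        assert arrested_ids < all_ids


class TestQueueDecomposition:
    @pytest.mark.parametrize(
        "positions, expected",
        [
            ((300, 290, 280, 100), [3, 1]),
            ((300,), [1]),
            ((300, 250, 200), [1, 1, 1]),
            ((), []),
            ((50, 40, 30, 20, 10), [5]),
        ],
    )
    def test_examples(self, geometry, positions, expected):
        snap = PolysomeSnapshot(
            0.0, tuple(RibosomeState(id=i + 1, p_site=p) for i, p in enumerate(positions))
        )
        assert queue_decomposition(snap, geometry) == expected

    @given(st.lists(st.integers(min_value=10, max_value=40), min_size=0, max_size=12))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_sizes_sum_to_ribosome_count(self, gaps):
        geometry = CollisionGeometry()
        positions = [30]
        for g in gaps:
            positions.append(positions[-1] + g)
        positions = positions[::-1]
        snap = PolysomeSnapshot(
            0.0, tuple(RibosomeState(id=i + 1, p_site=p) for i, p in enumerate(positions))
        )
        sizes = queue_decomposition(snap, geometry)
        assert sum(sizes) == len(positions)
        assert all(s >= 1 for s in sizes)


class TestSteadyStateSpacing:
    def test_free_flow_spacing_matches_renewal_prediction(self):
        # consecutive initiations are separated by the footprint clearance
        # time (10 codons) plus 1/alpha, so spacing = v/alpha + footprint;
        # the genome-average preset is calibrated to 66 codons
        pre = make_preset("genome_average", seed=7)
        trajectory, _ = simulate(pre.transcript, pre.params)
        ird = steady_state_ird(trajectory, window=300.0)
        assert ird == pytest.approx(66.0, rel=0.10)

    def test_no_initiation_reports_nan(self):
        transcript = TranscriptSpec(100, 5.6, {}, 5.6)
        trajectory, _ = simulate(transcript, _params(initial_positions=(1,)))
        assert np.isnan(steady_state_ird(trajectory, window=50.0))

    def test_fully_queued_stall_spacing_equals_footprint(self, geometry):
        transcript = TranscriptSpec(100, 5.6, {}, termination_rate=0.0)
        trajectory, _ = simulate(
            transcript,
            _params(t_max=200.0, seed=1, initial_positions=(100, 90, 80, 70)),
        )
        assert steady_state_ird(trajectory, window=10.0) == 10.0


class TestCollidedResumeSwitch:
    def test_trailing_resumes_by_default_but_not_when_locked(self):
        # lead pauses at codon 30, trailing collides, then the lead moves on
        transcript = TranscriptSpec(100, 5.6, {30: 0.05}, 1e9)
        base = _params(t_max=300.0, seed=8, initial_positions=(25, 5))
        _, log_free = simulate(transcript, base)
        _, log_locked = simulate(transcript, replace(base, allow_collided_resume=False))
        assert log_free.of_kind("collision") and log_locked.of_kind("collision")
        assert len(log_free.of_kind("termination")) == 2
        # the locked trailing ribosome never terminates
        locked_terms = {e.ribosome_id for e in log_locked.of_kind("termination")}
        collided_ids = {e.ribosome_id for e in log_locked.of_kind("collision")}
        assert collided_ids.isdisjoint(locked_terms)


class TestValidation:
    def test_footprint_longer_than_transcript_rejected(self, geometry):
        with pytest.raises(ParameterError):
            simulate(TranscriptSpec(5, 5.6, {}, 5.6), _params())

    def test_negative_rates_rejected(self):
        with pytest.raises(ParameterError):
            TranscriptSpec(100, -1.0, {}, 5.6)
        with pytest.raises(ParameterError):
            TranscriptSpec(100, 5.6, {5: -0.1}, 5.6)
        with pytest.raises(ParameterError):
            TranscriptSpec(100, 5.6, {200: 1.0}, 5.6)

    def test_missing_seed_rejected(self):
        with pytest.raises(ParameterError):
            SimulationParams(t_max=10.0, seed=None)

    def test_overlapping_initial_positions_rejected(self):
        with pytest.raises(ParameterError):
            simulate(TranscriptSpec(100, 5.6, {}, 5.6), _params(initial_positions=(20, 15)))
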