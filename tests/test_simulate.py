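"""Synthetic gait simulator: events, spectra, phase tracks, coverage."""

import numpy as np
import pytest

from locomode.io import EVENT_HEEL_STRIKE, EVENT_TOE_OFF
from locomode.labels import ENABL3S_SCHEMA, MYLEG_SCHEMA, LocomotionMode, SchemaError
from locomode.simulate import (
    DEFAULT_PHASE_CONVENTION,
    Scenario,
    default_params,
    generate,
    make_dataset,
    phase_track,
)

W = LocomotionMode.WALKING
S = LocomotionMode.SITTING
ST = LocomotionMode.STANDING
SA = LocomotionMode.STAIR_ASCENT


class TestGenerate:
    def test_walking_five_seconds_event_counts(self):
        """1.0 Hz gait cycles over 5 s give ~5 heel strikes and toe-offs."""
        stream = generate(Scenario(segments=((W, 5.0),), seed=0), schema=ENABL3S_SCHEMA)
        assert stream.n_samples == 2500
        hs = stream.event_indices(EVENT_HEEL_STRIKE)
        to = stream.event_indices(EVENT_TOE_OFF)
        assert 4 <= len(hs) <= 6
        assert 4 <= len(to) <= 6
        # heel strikes at cycle starts: 1 s apart at the default walking rate
        assert np.allclose(np.diff(hs), 500, atol=1)

    def test_static_mode_has_no_events_and_near_constant_channels(self):
        stream = generate(Scenario(segments=((S, 2.0),), seed=1), schema=ENABL3S_SCHEMA)
        assert len(stream.event_indices(EVENT_HEEL_STRIKE)) == 0
        assert len(stream.event_indices(EVENT_TOE_OFF)) == 0
        assert np.all(stream.channels.std(axis=0) < 0.2)

    def test_same_seed_reproduces_stream(self):
        scenario = Scenario(segments=((W, 3.0), (ST, 2.0)), seed=9)
        a = generate(scenario, schema=ENABL3S_SCHEMA)
        b = generate(scenario, schema=ENABL3S_SCHEMA)
        np.testing.assert_array_equal(a.channels, b.channels)
        assert list(a.mode) == list(b.mode)
        assert list(a.event) == list(b.event)

    def test_disallowed_transition_rejected(self):
        scenario = Scenario(segments=((W, 2.0), (S, 2.0)), seed=0)  # W-S not allowed
        with pytest.raises(SchemaError):
            generate(scenario, schema=ENABL3S_SCHEMA)

    def test_mode_track_follows_segment_boundaries_exactly(self):
        stream = generate(Scenario(segments=((W, 2.0), (ST, 1.0)), seed=2),
                          schema=ENABL3S_SCHEMA)
        assert set(stream.mode[:1000]) == {"W"}
        assert set(stream.mode[1000:]) == {"ST"}

    def test_one_imu_gives_six_channels(self):
        stream = generate(Scenario(segments=((W, 2.0),), n_imus=1, seed=0),
                          schema=ENABL3S_SCHEMA)
        assert stream.n_features == 6


class TestSpectralContent:
    @pytest.mark.parametrize(
        "mode", [m for m in LocomotionMode if not m.is_static], ids=lambda m: m.code
    )
    def test_dominant_power_below_3p5_hz(self, mode):
        """>= 90% of non-DC signal power in the human-movement band."""
        stream = generate(Scenario(segments=((mode, 20.0),), seed=4),
                          schema=ENABL3S_SCHEMA)
        x = stream.channels - stream.channels.mean(axis=0)
        spec = np.abs(np.fft.rfft(x, axis=0)) ** 2
        freqs = np.fft.rfftfreq(stream.n_samples, d=1 / stream.sample_rate)
        low = spec[freqs < 3.5].sum(axis=0)
        frac = low / spec.sum(axis=0)
        assert np.all(frac >= 0.90), frac.min()


class TestPhaseTrack:
    def test_walking_stride_arithmetic(self):
        """One 1.0 s stride, toe-off at 0.6 s: W1-W4 split the stance in
        0.15 s steps, W5-W7 split the swing in ~0.133 s steps."""
        stream = generate(Scenario(segments=((W, 3.0),), seed=5), schema=ENABL3S_SCHEMA)
        hs = stream.event_indices(EVENT_HEEL_STRIKE)
        a, b = hs[0], hs[1]
        to = stream.event_indices(EVENT_TOE_OFF)
        t_off = to[(to > a) & (to < b)][0]
        track = phase_track(stream)
        assert t_off - a == pytest.approx(0.6 * (b - a), abs=2)
        # stance: 4 equal parts
        for k in range(4):
            lo = a + int(np.ceil(k * (t_off - a) / 4))
            assert track[lo] == k + 1
        # swing: 3 equal parts numbered 5..7
        for k in range(3):
            lo = t_off + int(np.ceil(k * (b - t_off) / 3))
            assert track[lo] == 5 + k
        assert track[b - 1] == 7

    def test_stair_ascent_has_five_phases(self):
        stream = generate(Scenario(segments=((SA, 10.0),), seed=6), schema=ENABL3S_SCHEMA)
        track = phase_track(stream)
        assert set(track[track > 0]) == {1, 2, 3, 4, 5}

    def test_static_mode_track_empty(self):
        stream = generate(Scenario(segments=((ST, 3.0),), seed=7), schema=ENABL3S_SCHEMA)
        assert np.all(phase_track(stream) == 0)

    def test_samples_outside_complete_strides_unphased_without_extrapolation(self):
        stream = generate(Scenario(segments=((W, 3.0),), seed=8), schema=ENABL3S_SCHEMA)
        hs = stream.event_indices(EVENT_HEEL_STRIKE)
        track = phase_track(stream, extrapolate_tail=False)
        assert np.all(track[: hs[0]] == 0)
        assert np.all(track[hs[-1]:] == 0)

    def test_tail_extrapolation_continues_last_stride(self):
        """The default track phases the bout's final partial stride using
        the previous stride's duration as the expected cycle."""
        stream = generate(Scenario(segments=((W, 3.0),), seed=8), schema=ENABL3S_SCHEMA)
        hs = stream.event_indices(EVENT_HEEL_STRIKE)
        track = phase_track(stream)
        tail = track[hs[-1]:]
        assert tail[0] == 1  # a fresh stride starts at the heel strike
        assert np.all(np.diff(tail[tail > 0]) >= 0)  # monotone within the stride
        assert np.any(tail > 0)
        assert np.all(track[: hs[0]] == 0)


class TestMakeDataset:
    def test_covers_every_transition_with_min_count(self):
        streams, manifest = make_dataset(
            ENABL3S_SCHEMA, minutes=0.5, seed=0, min_transition_count=2
        )
        assert all(c >= 2 for c in manifest["transition_counts"].values())
        assert set(manifest["transition_counts"]) == {
            str(t) for t in ENABL3S_SCHEMA.transitions
        }

    def test_total_duration_reaches_request(self):
        streams, manifest = make_dataset(ENABL3S_SCHEMA, minutes=1.0, seed=1)
        assert manifest["total_seconds"] >= 60.0
        assert sum(s.duration_s for s in streams) == pytest.approx(
            manifest["total_seconds"]
        )

    def test_seeded_reproducibility(self):
        a, ma = make_dataset(ENABL3S_SCHEMA, minutes=0.3, seed=3)
        b, mb = make_dataset(ENABL3S_SCHEMA, minutes=0.3, seed=3)
        assert ma == mb
        np.testing.assert_array_equal(a[0].channels, b[0].channels)

    def test_myleg_schema_supported(self):
        streams, manifest = make_dataset(MYLEG_SCHEMA, minutes=0.3, seed=2, n_imus=1)
        assert streams[0].n_features == 6
        assert set(manifest["transition_counts"]) == {
            str(t) for t in MYLEG_SCHEMA.transitions
        }


class TestDefaultParams:
    def test_modes_have_distinct_signatures(self):
        params = default_params(ENABL3S_SCHEMA)
        offsets = {m.code: tuple(p.gravity_offset[:3].round(3)) for m, p in params.items()}
        assert len(set(offsets.values())) == 7
        assert params[S].cycle_freq == 0 and params[ST].cycle_freq == 0
        for m, p in params.items():
            if not m.is_static:
                assert 3 * p.cycle_freq <= 3.5

    def test_noise_scale_is_a_difficulty_knob(self):
        easy = default_params(ENABL3S_SCHEMA, noise_scale=1.0)
        hard = default_params(ENABL3S_SCHEMA, noise_scale=3.0)
        np.testing.assert_allclose(hard[W].noise_sd, 3.0 * easy[W].noise_sd)
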