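"""Seeded synthetic IMU locomotion simulator.

Generates labeled streams with the statistical structure the classification
pipeline assumes about real lower-limb IMU recordings:

* Each non-static locomotion mode is a quasi-periodic signal: per-channel
  sums of the first three harmonics of the mode's gait-cycle frequency, on
  top of a constant gravity-projection offset, plus Gaussian sensor noise.
  Cycle frequencies stay at or below 1.1 Hz so the dominant signal energy
  sits below 3.5 Hz, where most human-movement information lives.
* Gait events anchor the cycle: a heel strike at every cycle start and a
  toe-off at 60% of the cycle (stance/swing boundary).  Both events inject
  short Gaussian-windowed oscillatory bursts into the channels, mimicking
  foot-impact transients; these make the *position within the gait cycle*
  visible to a spectrogram classifier, as it is in real accelerometry.
* Static modes (sitting, standing) are near-constant channels distinguished
  by their gravity offsets (thigh orientation differs between sitting and
  standing), with no events.
* Mode changes are linear parameter cross-fades over ``transition_blend_s``
  centered at each segment boundary, so transition windows carry
  transition-specific signal structure rather than discontinuities.

Everything is reproducible from a seed.  The per-mode defaults are chosen so
modes are separable but overlap under noise; ``noise_scale`` is the
difficulty knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import EVENT_HEEL_STRIKE, EVENT_NONE, EVENT_TOE_OFF, ImuStream
from .labels import LabelSchema, LocomotionMode, SchemaError

GRAVITY = 9.81  # m/s^2

#: Fraction of the gait cycle at which toe-off occurs (stance/swing split);
#: the standard gait-literature value.
TOE_OFF_FRACTION = 0.6


@dataclass(frozen=True)
class PhaseConvention:
    """How heel-strike/toe-off events map to numbered gait phases.

    Each stride (heel strike to next heel strike) splits into stance (heel
    strike to toe-off) and swing (toe-off to next heel strike).  Stance is
    divided into ``stance_phases[mode]`` equal-duration sub-phases and swing
    into the remaining ones, numbered in temporal order.  The default gives
    walking 4 stance + 3 swing = 7 phases and every ramp/stair mode
    3 stance + 2 swing = 5.
    """

    stance_phases: Mapping[LocomotionMode, int] = field(
        default_factory=lambda: {
            LocomotionMode.WALKING: 4,
            LocomotionMode.RAMP_ASCENT: 3,
            LocomotionMode.RAMP_DESCENT: 3,
            LocomotionMode.STAIR_ASCENT: 3,
            LocomotionMode.STAIR_DESCENT: 3,
        }
    )
    swing_phases: Mapping[LocomotionMode, int] = field(
        default_factory=lambda: {
            LocomotionMode.WALKING: 3,
            LocomotionMode.RAMP_ASCENT: 2,
            LocomotionMode.RAMP_DESCENT: 2,
            LocomotionMode.STAIR_ASCENT: 2,
            LocomotionMode.STAIR_DESCENT: 2,
        }
    )

    def counts(self, mode: LocomotionMode) -> tuple[int, int]:
        if mode.is_static:
            return (0, 0)
        return self.stance_phases[mode], self.swing_phases[mode]


DEFAULT_PHASE_CONVENTION = PhaseConvention()


@dataclass(frozen=True)
class ModeSignalParams:
    """Signal model of one locomotion mode.

    ``harmonic_amps`` has shape (n_channels, 3): amplitude of harmonics 1-3
    of ``cycle_freq`` per channel.  ``harmonic_phases`` (same shape) holds
    fixed phase offsets decorrelating the channels.  ``gravity_offset`` is
    the per-channel constant (gravity projection on accelerometer axes, zero
    on gyroscopes).  ``impact_amps`` scales the heel-strike/toe-off bursts
    per channel.  All amplitude-like entries share the channel order of
    :class:`~locomode.io.ImuStream`.
    """

    mode: LocomotionMode
    cycle_freq: float  # Hz; 0 for static modes
    harmonic_amps: np.ndarray
    harmonic_phases: np.ndarray
    gravity_offset: np.ndarray
    noise_sd: np.ndarray
    impact_amps: np.ndarray
    impact_freq_hs: float = 26.0  # Hz, heel-strike burst carrier
    impact_freq_to: float = 16.0  # Hz, toe-off burst carrier
    impact_width_s: float = 0.022  # Gaussian envelope sigma

    def __post_init__(self) -> None:
        if self.cycle_freq < 0:
            raise ValueError("cycle_freq must be >= 0")
        if self.cycle_freq > 0 and 3.0 * self.cycle_freq > 3.5:
            raise ValueError(
                "3 x cycle_freq must stay at or below 3.5 Hz so the dominant "
                f"energy is in the human-movement band; got {self.cycle_freq} Hz"
            )
        if self.mode.is_static and self.cycle_freq != 0:
            raise ValueError(f"static mode {self.mode.code} must have cycle_freq 0")


@dataclass(frozen=True)
class Scenario:
    """An ordered plan of locomotion segments to synthesize."""

    segments: tuple[tuple[LocomotionMode, float], ...]
    sample_rate: float = 500.0
    transition_blend_s: float = 0.5
    n_imus: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("scenario needs at least one segment")
        for mode, dur in self.segments:
            if dur <= 0:
                raise ValueError(f"segment duration must be > 0, got {dur}")
        for (a, _), (b, _) in zip(self.segments, self.segments[1:]):
            if a == b:
                raise ValueError("consecutive segments must differ (merge them)")
        if self.n_imus not in (1, 2):
            raise ValueError("n_imus must be 1 or 2")


# Per-mode signal templates.  Harmonic profiles (relative amplitude of
# harmonics 1-3) and gravity orientations differ per mode; the second IMU
# (lower leg) is an attenuated, phase-lagged copy of the first.
_HARMONIC_PROFILES: dict[LocomotionMode, tuple[float, float, float]] = {
    LocomotionMode.WALKING: (1.00, 0.50, 0.25),
    LocomotionMode.RAMP_ASCENT: (0.85, 0.65, 0.20),
    LocomotionMode.RAMP_DESCENT: (1.10, 0.35, 0.30),
    LocomotionMode.STAIR_ASCENT: (0.70, 0.60, 0.40),
    LocomotionMode.STAIR_DESCENT: (0.95, 0.30, 0.50),
}

_CYCLE_FREQS: dict[LocomotionMode, float] = {
    LocomotionMode.WALKING: 1.0,
    LocomotionMode.RAMP_ASCENT: 0.8,
    LocomotionMode.RAMP_DESCENT: 0.9,
    LocomotionMode.STAIR_ASCENT: 0.8,
    LocomotionMode.STAIR_DESCENT: 0.9,
}

# Unit gravity direction on the thigh accelerometer (x: along segment,
# z: perpendicular); sitting tilts the thigh near-horizontal.
_GRAVITY_DIR: dict[LocomotionMode, tuple[float, float, float]] = {
    LocomotionMode.SITTING: (0.92, 0.10, 0.38),
    LocomotionMode.STANDING: (0.08, 0.06, 0.99),
    LocomotionMode.WALKING: (0.15, 0.08, 0.98),
    LocomotionMode.RAMP_ASCENT: (0.30, 0.09, 0.95),
    LocomotionMode.RAMP_DESCENT: (-0.12, 0.07, 0.99),
    LocomotionMode.STAIR_ASCENT: (0.45, 0.10, 0.89),
    LocomotionMode.STAIR_DESCENT: (-0.25, 0.08, 0.96),
}

# Per-channel gains within one IMU: acc x/y/z then gyr x/y/z.
_CHANNEL_GAINS = np.array([1.0, 0.7, 0.5, 1.2, 0.8, 0.4])
_SECOND_IMU_GAIN = 0.75
_SECOND_IMU_LAG = 0.12  # cycle fraction
#: Sensor noise, as a fraction of each channel's oscillation gain.
_NOISE_FRACTION = 0.08
_STATIC_NOISE_SD = 0.05
# Heel-strike burst amplitude relative to the channel's oscillation gain.
# Foot-impact transients in real leg accelerometry are sharp spikes whose
# peak exceeds the smooth gait oscillation; 1.4 is the largest amplitude
# that keeps >= 90% of every channel's non-DC power below 3.5 Hz.
_IMPACT_GAIN = 1.4


def _channel_arrays(n_channels: int, profile: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    gains = np.concatenate([_CHANNEL_GAINS, _SECOND_IMU_GAIN * _CHANNEL_GAINS])[:n_channels]
    amps = np.outer(gains, profile)
    # fixed per-channel/harmonic phase offsets; second IMU lags the first
    ch = np.arange(n_channels)[:, None]
    h = np.arange(1, 4)[None, :]
    phases = 0.7 * ch * h + 2 * np.pi * _SECOND_IMU_LAG * (ch >= 6) * h
    return amps, phases


def default_params(
    schema: LabelSchema, n_channels: int = 12, noise_scale: float = 1.0
) -> dict[LocomotionMode, ModeSignalParams]:
    """Default per-mode signal parameters (the simulator's study conditions).

    ``noise_scale`` multiplies every noise standard deviation and is the
    difficulty knob: 1.0 is the default separability, larger values blur the
    modes together.
    """
    if n_channels not in (6, 12):
        raise ValueError("n_channels must be 6 or 12")
    params: dict[LocomotionMode, ModeSignalParams] = {}
    gains = np.concatenate([_CHANNEL_GAINS, _SECOND_IMU_GAIN * _CHANNEL_GAINS])[:n_channels]
    for mode in schema.modes:
        grav = np.zeros(n_channels)
        gdir = np.array(_GRAVITY_DIR[mode])
        grav[0:3] = GRAVITY * gdir
        if n_channels == 12:
            # lower-leg segment: same orientation family, slightly rotated
            grav[6:9] = GRAVITY * np.array([gdir[0] * 0.6 + 0.1, gdir[1], gdir[2]])
            grav[6:9] *= 1.0 / max(np.linalg.norm(grav[6:9]) / GRAVITY, 1e-9)
        if mode.is_static:
            amps = np.zeros((n_channels, 3))
            phases = np.zeros((n_channels, 3))
            noise = np.full(n_channels, _STATIC_NOISE_SD) * noise_scale
            cycle = 0.0
            impact = np.zeros(n_channels)
        else:
            amps, phases = _channel_arrays(n_channels, _HARMONIC_PROFILES[mode])
            noise = _NOISE_FRACTION * gains * noise_scale
            cycle = _CYCLE_FREQS[mode]
            impact = _IMPACT_GAIN * gains
        params[mode] = ModeSignalParams(
            mode=mode,
            cycle_freq=cycle,
            harmonic_amps=amps,
            harmonic_phases=phases,
            gravity_offset=grav,
            noise_sd=noise,
            impact_amps=impact,
        )
    return params


def _mode_signal(p: ModeSignalParams, t: np.ndarray) -> np.ndarray:
    """Deterministic (noise-free, burst-free) signal of one mode at times t."""
    n_channels = p.harmonic_amps.shape[0]
    out = np.tile(p.gravity_offset[None, :], (len(t), 1))
    if p.cycle_freq > 0:
        h = np.arange(1, 4)
        # angle: (n, 3) per harmonic; accumulate per channel
        ang = 2 * np.pi * p.cycle_freq * t[:, None] * h[None, :]
        for c in range(n_channels):
            out[:, c] += np.sum(
                p.harmonic_amps[c] * np.cos(ang + p.harmonic_phases[c]), axis=1
            )
    return out


def _burst(t: np.ndarray, center: float, freq: float, width: float) -> np.ndarray:
    env = np.exp(-0.5 * ((t - center) / width) ** 2)
    return env * np.cos(2 * np.pi * freq * (t - center))


def generate(
    scenario: Scenario,
    params: Mapping[LocomotionMode, ModeSignalParams] | None = None,
    schema: LabelSchema | None = None,
) -> ImuStream:
    """Synthesize one labeled stream from a scenario.

    When ``schema`` is given, every consecutive segment pair must be an
    allowed transition of the schema (:class:`~locomode.labels.SchemaError`
    otherwise).  Channels are the cross-faded per-mode signals plus event
    bursts and noise; the mode track follows the segment plan exactly; heel
    strikes sit at each cycle start and toe-offs at 60% of each cycle of
    non-static segments.
    """
    if schema is not None:
        for (a, _), (b, _) in zip(scenario.segments, scenario.segments[1:]):
            if not schema.allows_transition(a, b):
                raise SchemaError(
                    f"transition {a.code}-{b.code} is not allowed by schema {schema.name!r}"
                )
    n_channels = 6 * scenario.n_imus
    if params is None:
        params = default_params(
            schema if schema is not None else _schema_of(scenario), n_channels
        )
    first = next(iter(params.values()))
    if first.harmonic_amps.shape[0] != n_channels:
        raise ValueError(
            f"params are for {first.harmonic_amps.shape[0]} channels, "
            f"scenario needs {n_channels}"
        )

    fs = scenario.sample_rate
    seg_samples = [int(round(d * fs)) for _, d in scenario.segments]
    n = sum(seg_samples)
    t = np.arange(n) / fs
    rng = np.random.default_rng(scenario.seed)

    # per-sample mode labels
    mode_track = np.empty(n, dtype=object)
    bounds = np.cumsum([0] + seg_samples)
    for (mode, _), lo, hi in zip(scenario.segments, bounds[:-1], bounds[1:]):
        mode_track[lo:hi] = mode.code

    # cross-fade weights per segment, linear ramps over the blend interval
    half_blend = scenario.transition_blend_s / 2.0
    channels = np.zeros((n, n_channels))
    events = np.full(n, EVENT_NONE, dtype=object)

    for i, (mode, _) in enumerate(scenario.segments):
        t_lo, t_hi = bounds[i] / fs, bounds[i + 1] / fs
        # support of this segment's weight (segment plus blend margins)
        s_lo = max(0.0, t_lo - half_blend)
        s_hi = min(n / fs, t_hi + half_blend)
        lo_idx = int(np.ceil(s_lo * fs))
        hi_idx = min(n, int(np.ceil(s_hi * fs)))
        tt = t[lo_idx:hi_idx]
        w = np.ones_like(tt)
        if i > 0:
            w = np.minimum(w, np.clip((tt - (t_lo - half_blend)) / (2 * half_blend + 1e-12), 0, 1))
        if i < len(scenario.segments) - 1:
            w = np.minimum(w, np.clip(((t_hi + half_blend) - tt) / (2 * half_blend + 1e-12), 0, 1))
        p = params[mode]
        sig = _mode_signal(p, tt)

        if p.cycle_freq > 0:
            # events belong to samples inside the segment proper
            k_lo = int(np.ceil(t_lo * p.cycle_freq))
            k_hi = int(np.floor(t_hi * p.cycle_freq))
            for k in range(k_lo, k_hi + 1):
                for frac, freq, kind, amp_scale in (
                    (0.0, p.impact_freq_hs, EVENT_HEEL_STRIKE, 1.0),
                    (TOE_OFF_FRACTION, p.impact_freq_to, EVENT_TOE_OFF, 0.6),
                ):
                    tc = (k + frac) / p.cycle_freq
                    if not (t_lo <= tc < t_hi):
                        continue
                    idx = int(round(tc * fs))
                    if 0 <= idx < n and bounds[i] <= idx < bounds[i + 1]:
                        events[idx] = kind
                    burst = _burst(tt, tc, freq, p.impact_width_s)
                    sig += amp_scale * burst[:, None] * p.impact_amps[None, :]

        channels[lo_idx:hi_idx] += w[:, None] * sig

    # sensor noise: use the active mode's noise level per sample
    noise_sd = np.empty((n, n_channels))
    for (mode, _), lo, hi in zip(scenario.segments, bounds[:-1], bounds[1:]):
        noise_sd[lo:hi] = params[mode].noise_sd[None, :]
    channels += rng.normal(size=(n, n_channels)) * noise_sd

    return ImuStream(
        sample_rate=fs, channels=channels, mode=mode_track, event=events
    )


def _schema_of(scenario: Scenario) -> LabelSchema:
    # permissive throwaway schema covering the scenario's own mode set
    from .labels import ENABL3S_SCHEMA

    return ENABL3S_SCHEMA


def _fill_stride(
    track: np.ndarray,
    a: int,
    t_off: int,
    b: int,
    n_stance: int,
    n_swing: int,
    end: int,
) -> None:
    """Write phase indices for one stride [a, b) into the track (clipped
    at ``end``); stance [a, t_off) and swing [t_off, b) split equally."""
    stance_edges = np.linspace(a, t_off, n_stance + 1)
    swing_edges = np.linspace(t_off, b, n_swing + 1)
    hi = min(b, end)
    idx = np.arange(a, hi)
    phase = np.empty(hi - a, dtype=np.int64)
    stance_mask = idx < t_off
    phase[stance_mask] = 1 + np.clip(
        np.searchsorted(stance_edges, idx[stance_mask], side="right") - 1,
        0, n_stance - 1,
    )
    phase[~stance_mask] = 1 + n_stance + np.clip(
        np.searchsorted(swing_edges, idx[~stance_mask], side="right") - 1,
        0, n_swing - 1,
    )
    track[a:hi] = phase


def phase_track(
    stream: ImuStream,
    convention: PhaseConvention = DEFAULT_PHASE_CONVENTION,
    extrapolate_tail: bool = True,
) -> np.ndarray:
    """Per-sample gait-phase indices built from the stream's event markers.

    Returns an int array of shape (n_samples,): the 1-based phase index
    within the sample's locomotion mode, or 0 where no phase applies
    (static modes, samples before the first heel strike of a bout).  Each
    complete stride — a heel strike, the toe-off after it, and the next
    heel strike — is split into equal-duration stance sub-phases and
    equal-duration swing sub-phases per the convention.

    With ``extrapolate_tail`` (default), the partial stride after a bout's
    last heel strike is phased too, taking the previous stride's duration
    as the expected cycle — the same forward estimate an online phase
    tracker would make; without it only complete strides are phased.

    Raises ``ValueError`` if events within a stride do not alternate
    (several toe-offs between two heel strikes).
    """
    n = stream.n_samples
    track = np.zeros(n, dtype=np.int64)
    hs = stream.event_indices(EVENT_HEEL_STRIKE)
    to = stream.event_indices(EVENT_TOE_OFF)
    last_duration: dict[int, int] = {}  # last heel strike -> stride length
    for a, b in zip(hs, hs[1:]):
        mode_code = stream.mode[a]
        if "-" in str(mode_code):
            continue
        mode = LocomotionMode.from_code(str(mode_code))
        if mode.is_static:
            continue
        # the stride is valid only if uninterrupted by a mode change
        if not np.all(stream.mode[a:b] == mode_code):
            continue
        inside = to[(to > a) & (to < b)]
        if len(inside) != 1:
            if len(inside) > 1:
                raise ValueError(
                    f"events do not alternate: {len(inside)} toe-offs in stride "
                    f"[{a}, {b})"
                )
            continue  # incomplete stride: no toe-off recorded
        n_stance, n_swing = convention.counts(mode)
        _fill_stride(track, a, int(inside[0]), b, n_stance, n_swing, n)
        last_duration[int(b)] = b - a
    if extrapolate_tail:
        for a, cycle in [(k, v) for k, v in last_duration.items()]:
            # a is a bout's last heel strike only if no complete stride
            # starts there
            if track[a] != 0 or a >= n:
                continue
            mode_code = stream.mode[a]
            if "-" in str(mode_code):
                continue
            mode = LocomotionMode.from_code(str(mode_code))
            if mode.is_static:
                continue
            b_est = a + cycle
            # stay within the uninterrupted same-mode run
            run_end = a
            while run_end < n and stream.mode[run_end] == mode_code:
                run_end += 1
            inside = to[(to > a) & (to < min(b_est, run_end))]
            t_off = int(inside[0]) if len(inside) else a + int(
                TOE_OFF_FRACTION * cycle
            )
            n_stance, n_swing = convention.counts(mode)
            _fill_stride(track, a, t_off, b_est, n_stance, n_swing,
                         min(run_end, n))
    return track


def _transition_walk(
    schema: LabelSchema, rng: np.random.Generator, length: int
) -> list[LocomotionMode]:
    """Random walk on the schema's transition graph favoring rare edges."""
    usage: dict[tuple[str, str], int] = {}
    out_edges: dict[LocomotionMode, list[LocomotionMode]] = {}
    for tr in schema.transitions:
        out_edges.setdefault(tr.from_mode, []).append(tr.to_mode)
    start = rng.choice([m for m in schema.modes if m in out_edges])
    chain = [start]
    while len(chain) < length:
        cur = chain[-1]
        nxt_opts = out_edges.get(cur)
        if not nxt_opts:
            break
        counts = [usage.get((cur.code, m.code), 0) for m in nxt_opts]
        least = min(counts)
        pick = rng.choice([m for m, c in zip(nxt_opts, counts) if c == least])
        usage[(cur.code, pick.code)] = usage.get((cur.code, pick.code), 0) + 1
        chain.append(pick)
    return chain


def make_dataset(
    schema: LabelSchema,
    *,
    minutes: float = 5.0,
    n_imus: int = 2,
    sample_rate: float = 500.0,
    seed: int = 0,
    segment_s: float = 4.0,
    segments_per_scenario: int = 8,
    noise_scale: float = 1.0,
    min_transition_count: int = 1,
) -> tuple[list[ImuStream], dict]:
    """Generate a seeded collection of scenarios covering the whole schema.

    Scenarios chain segments along the schema's transition graph so every
    allowed transition appears at least ``min_transition_count`` times (the
    walk favors the least-used edge); additional scenarios are appended
    until the total duration reaches ``minutes``.  Returns the streams plus
    a manifest recording seeds and parameters.
    """
    rng = np.random.default_rng(seed)
    params = default_params(schema, 6 * n_imus, noise_scale=noise_scale)
    streams: list[ImuStream] = []
    scenarios: list[Scenario] = []
    total_s = 0.0
    covered: dict[str, int] = {str(t): 0 for t in schema.transitions}
    i = 0
    # Ramp/stair bouts run longer than the hub modes: the transition graph
    # funnels through walking/standing, so sustained ramp/stair segments
    # are needed to collect comparable numbers of strides per mode.
    duration_boost = {
        m: 1.75 if (not m.is_static and m != LocomotionMode.WALKING) else 1.0
        for m in schema.modes
    }
    while total_s < minutes * 60.0 or any(
        c < min_transition_count for c in covered.values()
    ):
        chain = _transition_walk(schema, rng, segments_per_scenario)
        durations = segment_s * rng.uniform(0.85, 1.15, size=len(chain))
        durations *= np.array([duration_boost[m] for m in chain])
        scenario = Scenario(
            segments=tuple(zip(chain, durations)),
            sample_rate=sample_rate,
            n_imus=n_imus,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        stream = generate(scenario, params, schema=schema)
        streams.append(stream)
        scenarios.append(scenario)
        for a, b in zip(chain, chain[1:]):
            key = f"{a.code}-{b.code}"
            if key in covered:
                covered[key] += 1
        total_s += stream.duration_s
        i += 1
        if i > 10000:
            raise RuntimeError("could not cover all transitions; check the schema graph")
    manifest = {
        "schema": schema.name,
        "seed": seed,
        "n_imus": n_imus,
        "sample_rate": sample_rate,
        "noise_scale": noise_scale,
        "total_seconds": total_s,
        "transition_counts": covered,
        "scenarios": [
            {
                "seed": s.seed,
                "segments": [[m.code, float(d)] for m, d in s.segments],
            }
            for s in scenarios
        ],
    }
    return streams, manifest
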