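"""Mel-spectrogram frequency encoding of IMU sequences.

Each channel of a 1.3 s sequence becomes a 10 x 50 image: a short-time
Fourier transform with a Hann window of 20 samples and a hop of 13, squared
to power, projected onto 10 triangular mel bands, converted to dB and
min-max normalized into [0, 1].  The mel warping
``m(f) = 2595 * log10(1 + f / 700)`` expands the low frequencies where the
human-movement energy lives (below 3.5 Hz).

Framing convention: frames are non-centered (no reflection padding), giving
``1 + floor((650 - 20) / 13) = 49`` frames from a 650-sample channel; the
fixed 10 x 50 network input contract is then enforced by ``fit-to-width``
(the final frame is repeated, or excess frames cropped).  1000 Hz sequences
are anti-alias filtered and decimated to 500 Hz first so every network sees
the same input geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .windowing import SequenceWindow

#: Sampling rate every sequence is brought to before encoding.
CANONICAL_RATE = 500.0


class SpectrogramConfigError(ValueError):
    """Spectrogram parameters incompatible with the signal geometry."""


@dataclass(frozen=True)
class SpectrogramParams:
    """STFT and mel-projection parameters.

    Defaults give the 10 x 50 image contract for a 650-sample channel at
    500 Hz.  ``db_floor`` guards the dB conversion against log of zero.
    """

    fft_window_len: int = 20
    hop: int = 13
    n_mel_bins: int = 10
    target_frames: int = 50
    db_floor: float = 1e-10

    def __post_init__(self) -> None:
        if not (self.fft_window_len > self.hop > 0):
            raise SpectrogramConfigError(
                "need fft_window_len > hop > 0, got "
                f"({self.fft_window_len}, {self.hop})"
            )
        if self.n_mel_bins < 1 or self.target_frames < 1:
            raise SpectrogramConfigError("n_mel_bins and target_frames must be >= 1")

    @property
    def n_freq_bins(self) -> int:
        return self.fft_window_len // 2 + 1

    def n_frames(self, n_samples: int) -> int:
        """Frame count of the non-centered framing before fit-to-width."""
        if n_samples < self.fft_window_len:
            raise SpectrogramConfigError(
                f"signal of {n_samples} samples is shorter than the "
                f"{self.fft_window_len}-sample analysis window"
            )
        return 1 + (n_samples - self.fft_window_len) // self.hop


def mel_scale(f):
    """Mel value of frequency ``f`` in Hz: ``2595 * log10(1 + f / 700)``.

    The constant 2595 calibrates the scale so that 1000 Hz maps to
    1000 mel; 700 Hz is the corner between the linear and logarithmic
    regimes.  Accepts scalars or arrays; strictly increasing; rejects
    negative frequencies.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be nonnegative")
    out = 2595.0 * np.log10(1.0 + f / 700.0)
    return float(out) if out.ndim == 0 else out


def mel_to_hz(m):
    """Inverse of :func:`mel_scale`."""
    m = np.asarray(m, dtype=float)
    out = 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    return float(out) if out.ndim == 0 else out


def _hann(n: int) -> np.ndarray:
    # periodic Hann, the analysis-window convention of spectrogram practice
    return np.hanning(n + 1)[:-1]


def stft_power(x: np.ndarray, params: SpectrogramParams = SpectrogramParams()) -> np.ndarray:
    """Power spectrogram ``|STFT|^2`` of one or many channels.

    ``x`` is (n_samples,) or (n_signals, n_samples).  Returns
    (..., n_freq_bins, target_frames): Hann-windowed non-centered frames,
    squared magnitude, then fit-to-width (repeat the last frame or crop) to
    the fixed frame count.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, :]
    n = x.shape[-1]
    n_frames = params.n_frames(n)
    frames = np.lib.stride_tricks.sliding_window_view(x, params.fft_window_len, axis=-1)
    frames = frames[:, :: params.hop, :][:, :n_frames, :]
    spec = np.fft.rfft(frames * _hann(params.fft_window_len), axis=-1)
    power = np.abs(spec) ** 2  # (n_signals, n_frames, n_freq_bins)
    power = np.swapaxes(power, -1, -2)
    power = _fit_to_width(power, params.target_frames)
    return power[0] if squeeze else power


def _fit_to_width(spec: np.ndarray, width: int) -> np.ndarray:
    """Pad (repeating the final frame) or crop the frame axis to ``width``."""
    have = spec.shape[-1]
    if have == width:
        return spec
    if have > width:
        return spec[..., :width]
    pad = np.repeat(spec[..., -1:], width - have, axis=-1)
    return np.concatenate([spec, pad], axis=-1)


def mel_filterbank(
    params: SpectrogramParams, sample_rate: float = CANONICAL_RATE
) -> np.ndarray:
    """Triangular mel filterbank, (n_mel_bins, n_freq_bins).

    Band centers are equally spaced on the mel axis between 0 and Nyquist.
    Every band must receive at least one FFT bin; otherwise the partition is
    too fine for the FFT resolution and a configuration error tells the
    user to reduce ``n_mel_bins``.
    """
    nyquist = sample_rate / 2.0
    fft_freqs = np.linspace(0.0, nyquist, params.n_freq_bins)
    mel_pts = np.linspace(mel_scale(0.0), mel_scale(nyquist), params.n_mel_bins + 2)
    hz_pts = mel_to_hz(mel_pts)
    fb = np.zeros((params.n_mel_bins, params.n_freq_bins))
    for b in range(params.n_mel_bins):
        lo, ctr, hi = hz_pts[b], hz_pts[b + 1], hz_pts[b + 2]
        rising = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        falling = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[b] = np.clip(np.minimum(rising, falling), 0.0, None)
    empty = np.flatnonzero(fb.sum(axis=1) == 0)
    if empty.size:
        raise SpectrogramConfigError(
            f"mel bands {empty.tolist()} receive no FFT bin at "
            f"{sample_rate} Hz with a {params.fft_window_len}-point window; "
            "reduce n_mel_bins"
        )
    return fb


def mel_project(
    power_spec: np.ndarray,
    params: SpectrogramParams = SpectrogramParams(),
    sample_rate: float = CANONICAL_RATE,
) -> np.ndarray:
    """Project a power spectrogram onto the triangular mel bands."""
    fb = mel_filterbank(params, sample_rate)
    return np.einsum("mf,...ft->...mt", fb, np.asarray(power_spec, dtype=float))


def db_normalize(
    mel_spec: np.ndarray, params: SpectrogramParams = SpectrogramParams()
) -> np.ndarray:
    """Convert to dB and min-max normalize each image into [0, 1].

    Normalization is per image (the trailing two axes), so the encoding is
    invariant to the overall amplitude of the signal.  A zero-dynamic-range
    image (e.g. from an all-zero signal) maps to all 0.5 by convention.
    """
    x = np.asarray(mel_spec, dtype=float)
    if np.any(x < 0):
        raise ValueError("mel spectrogram must be nonnegative")
    db = 10.0 * np.log10(np.maximum(x, params.db_floor))
    lo = db.min(axis=(-2, -1), keepdims=True)
    hi = db.max(axis=(-2, -1), keepdims=True)
    rng = hi - lo
    flat = rng <= 0
    rng = np.where(flat, 1.0, rng)
    out = (db - lo) / rng
    return np.where(flat, 0.5, out)


def _decimate_to_canonical(samples: np.ndarray, sample_rate: float) -> np.ndarray:
    """Anti-alias filter and decimate a (n, channels) block to 500 Hz."""
    factor = sample_rate / CANONICAL_RATE
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"sample rate {sample_rate} Hz is not an integer multiple of "
            f"{CANONICAL_RATE} Hz"
        )
    factor = int(round(factor))
    if factor == 1:
        return samples
    return sps.decimate(samples, factor, axis=0, ftype="fir", zero_phase=True)


def encode_channels(
    samples: np.ndarray,
    sample_rate: float,
    params: SpectrogramParams = SpectrogramParams(),
) -> np.ndarray:
    """Encode a (n_samples, n_channels) block into (n_channels, 10, 50)."""
    samples = _decimate_to_canonical(np.asarray(samples, dtype=float), sample_rate)
    power = stft_power(samples.T, params)  # (n_channels, freq, frames)
    mel = mel_project(power, params, CANONICAL_RATE)
    return db_normalize(mel, params)


def encode_sequence(
    window: SequenceWindow, params: SpectrogramParams = SpectrogramParams()
) -> np.ndarray:
    """Encode one sequence into its (n_channels, 10, 50) image stack.

    Channel order follows the stream layout (IMU 1 accelerometer x/y/z,
    gyroscope x/y/z, then IMU 2 likewise).  Sequences sampled above 500 Hz
    are decimated first.
    """
    if window.samples.shape[1] not in (6, 12):
        raise ValueError(
            f"expected 6 or 12 channels, got {window.samples.shape[1]}"
        )
    return encode_channels(window.samples, window.sample_rate, params)


def encode_batch(
    windows: list[SequenceWindow], params: SpectrogramParams = SpectrogramParams()
) -> np.ndarray:
    """Encode many same-shape sequences at once -> (n, channels, 10, 50)."""
    if not windows:
        return np.zeros((0, 0, params.n_mel_bins, params.target_frames))
    block = np.stack([w.samples for w in windows])  # (n, samples, ch)
    rate = windows[0].sample_rate
    if any(w.sample_rate != rate for w in windows):
        raise ValueError("all windows in a batch must share one sample rate")
    n, n_samp, n_ch = block.shape
    flat = block.transpose(0, 2, 1).reshape(n * n_ch, n_samp)
    flat = _decimate_to_canonical(flat.T, rate).T
    power = stft_power(flat, params)
    mel = mel_project(power, params, CANONICAL_RATE)
    img = db_normalize(mel, params)
    return img.reshape(n, n_ch, params.n_mel_bins, params.target_frames)
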