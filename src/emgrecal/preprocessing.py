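"""Raw-EMG conditioning: mV scaling, filtering, kinematic-rate downsampling.

The pipeline mirrors standard surface-EMG practice: scale ADC counts to
millivolts, band-pass 60-500 Hz to remove motion artifacts, notch out
power-line interference at 60 and 120 Hz, then reduce the 1,000 Hz EMG
stream to the kinematic frame rate (~72 Hz average) by applying an
anti-alias low-pass and keeping the sample nearest each kinematic
timestamp, so every kinematic label has exactly one EMG column.

All filters are applied forward-backward (zero phase) so filtering never
shifts samples relative to the annotation timeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io_interface import EMGSeries

__all__ = [
    "FilterSpec",
    "ProcessedSeries",
    "InvalidFilterDesign",
    "scale_to_millivolts",
    "apply_filters",
    "downsample_to_kinematic",
    "preprocess_session",
    "filter_response_db",
]

log = logging.getLogger("emgrecal.preprocessing")


class InvalidFilterDesign(ValueError):
    """Band edges incompatible with the sampling rate."""


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass + notch design for 1 kHz surface EMG.

    Defaults: 4th-order Butterworth band-pass 60-500 Hz and two
    second-order IIR notches (Q=30) at 60 and 120 Hz, zero-phase.
    """

    bandpass_lo: float = 60.0
    bandpass_hi: float = 500.0
    notch_freqs: tuple[float, ...] = (60.0, 120.0)
    notch_q: float = 30.0
    filter_order: int = 4
    zero_phase: bool = True

    def validate(self, rate: float) -> None:
        nyq = rate / 2.0
        if not (0 < self.bandpass_lo < self.bandpass_hi <= nyq):
            raise InvalidFilterDesign(
                f"invalid filter design: band {self.bandpass_lo}-{self.bandpass_hi} Hz "
                f"vs Nyquist {nyq} Hz"
            )
        for f in self.notch_freqs:
            if not 0 < f < nyq:
                raise InvalidFilterDesign(f"invalid filter design: notch {f} Hz vs Nyquist {nyq}")

    def design(self, rate: float) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
        """Return (band-pass sos, [(b, a) per notch]) for sampling rate ``rate``."""
        self.validate(rate)
        hi = min(self.bandpass_hi, 0.999 * rate / 2.0)
        sos = signal.butter(
            self.filter_order, [self.bandpass_lo, hi], btype="bandpass", fs=rate, output="sos"
        )
        notches = [signal.iirnotch(f, self.notch_q, fs=rate) for f in self.notch_freqs]
        return sos, notches


@dataclass
class ProcessedSeries:
    """Kinematic-rate, millivolt EMG: one column per retained kinematic frame."""

    timestamps: np.ndarray            # retained kinematic timestamps, ms
    samples: np.ndarray               # (8, M) mV
    session_id: str = ""
    filter_spec: FilterSpec | None = None
    dropped_frames: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.samples.shape[1]


def scale_to_millivolts(emg: EMGSeries, adc_gain: float) -> EMGSeries:
    """Convert raw ADC counts to millivolts with ``adc_gain`` volts/count.

    Already-millivolt input is returned unchanged with a warning.
    """
    if emg.units == "millivolts":
        warnings.warn("EMG already in millivolts; scale_to_millivolts is a no-op")
        return emg
    if not adc_gain > 0:
        raise ValueError("adc_gain must be positive")
    return EMGSeries(
        timestamps=emg.timestamps.copy(),
        samples=emg.samples * (adc_gain * 1e3),
        units="millivolts",
        nominal_rate=emg.nominal_rate,
    )


def _zero_phase(filt, x: np.ndarray, zero_phase: bool, sos: bool) -> np.ndarray:
    # even (reflect) padding avoids transients at recording edges
    if sos:
        if zero_phase:
            return signal.sosfiltfilt(filt, x, axis=-1, padtype="even")
        return signal.sosfilt(filt, x, axis=-1)
    b, a = filt
    if zero_phase:
        return signal.filtfilt(b, a, x, axis=-1, padtype="even")
    return signal.lfilter(b, a, x, axis=-1)


def apply_filters(emg: EMGSeries, spec: FilterSpec | None = None) -> EMGSeries:
    """Band-pass + notch filtering; shape-preserving and linear."""
    spec = spec or FilterSpec()
    sos, notches = spec.design(emg.nominal_rate)
    y = _zero_phase(sos, emg.samples, spec.zero_phase, sos=True)
    for ba in notches:
        y = _zero_phase(ba, y, spec.zero_phase, sos=False)
    return EMGSeries(
        timestamps=emg.timestamps.copy(),
        samples=y,
        units=emg.units,
        nominal_rate=emg.nominal_rate,
    )


def filter_response_db(
    spec: FilterSpec, rate: float, freqs: np.ndarray | list[float]
) -> np.ndarray:
    """Single-pass magnitude response (dB) of the designed cascade at ``freqs``."""
    sos, notches = spec.design(rate)
    freqs = np.asarray(freqs, dtype=float)
    _, h = signal.sosfreqz(sos, worN=2 * np.pi * freqs / rate)
    mag = np.abs(h)
    for b, a in notches:
        _, hn = signal.freqz(b, a, worN=2 * np.pi * freqs / rate)
        mag = mag * np.abs(hn)
    return 20.0 * np.log10(np.maximum(mag, 1e-12))


def downsample_to_kinematic(
    emg: EMGSeries,
    kin_times: np.ndarray,
    antialias_hz: float | None = 30.0,
    antialias_order: int = 4,
    session_id: str = "",
    filter_spec: FilterSpec | None = None,
) -> ProcessedSeries:
    """Reduce EMG to the kinematic rate by nearest-timestamp extraction.

    A zero-phase Butterworth low-pass at ``antialias_hz`` is applied
    first (pass ``None`` to disable); then, for each kinematic
    timestamp, the EMG sample whose timestamp is nearest is kept.
    Kinematic frames outside the EMG time range are dropped with a
    warning and counted in ``dropped_frames``.
    """
    kin_times = np.asarray(kin_times, dtype=float)
    x = emg.samples
    if antialias_hz is not None:
        sos = signal.butter(antialias_order, antialias_hz, btype="low", fs=emg.nominal_rate, output="sos")
        x = signal.sosfiltfilt(sos, x, axis=-1, padtype="even")

    t = emg.timestamps
    in_range = (kin_times >= t[0]) & (kin_times <= t[-1])
    dropped = int(np.size(kin_times) - np.count_nonzero(in_range))
    if dropped:
        warnings.warn(f"out-of-range frame: dropped {dropped} kinematic frames outside EMG range")
    kept = kin_times[in_range]

    # nearest EMG timestamp per kinematic frame
    right = np.searchsorted(t, kept)
    right = np.clip(right, 1, t.size - 1)
    left = right - 1
    choose_right = (t[right] - kept) < (kept - t[left])
    idx = np.where(choose_right, right, left)

    return ProcessedSeries(
        timestamps=kept,
        samples=x[:, idx],
        session_id=session_id,
        filter_spec=filter_spec,
        dropped_frames=dropped,
    )


def preprocess_session(
    session,
    adc_gain: float | None = None,
    spec: FilterSpec | None = None,
    antialias_hz: float | None = 30.0,
) -> ProcessedSeries:
    """Full chain on one session: mV scaling, filters, kinematic downsampling.

    ``adc_gain`` (V/count) is taken from ``session.meta['adc_gain_v_per_count']``
    when not given; sessions already in millivolts skip the scaling step.
    """
    spec = spec or FilterSpec()
    emg = session.emg
    if emg.units == "counts":
        gain = adc_gain if adc_gain is not None else session.meta.get("adc_gain_v_per_count")
        if gain is None:
            raise ValueError("adc_gain required for count-valued EMG")
        emg = scale_to_millivolts(emg, float(gain))
    filtered = apply_filters(emg, spec)
    out = downsample_to_kinematic(
        filtered,
        session.kinematic_times,
        antialias_hz=antialias_hz,
        session_id=session.session_id,
        filter_spec=spec,
    )
    return out
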