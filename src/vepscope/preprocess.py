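"""Sweep containers, baseline/SNR computation, gated averaging, filtering.

Repeated-presentation evoked-potential recordings are stored as a
rectangular sweep matrix (one row per stimulus presentation, microvolts)
plus acquisition metadata.  Averaging is gated on a per-sweep
signal-to-noise ratio: the RMS of the baseline-subtracted trace in the
response window divided by the RMS in the pre-stimulus window.  Under
this convention a sweep containing only stationary noise scores SNR ~ 1,
which makes an exclusion threshold of 1 meaningful.

Time convention: t = 0 at stimulus onset everywhere; records store the
onset position within the sweep (``onset_s``) so absolute sample indices
can always be recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import signal as _signal

__all__ = [
    "SweepSet",
    "AveragedWaveform",
    "baseline",
    "sweep_snr",
    "average_sweeps",
    "butterworth_filter",
]


@dataclass
class SweepSet:
    """Raw repeated-presentation traces with acquisition metadata.

    Attributes
    ----------
    traces
        Array of shape ``(n_sweeps, n_samples)``, voltages in uV.
    sample_rate_hz
        Sampling rate in Hz.
    onset_s
        Stimulus-onset time within the record, seconds from the first
        sample; must lie strictly inside the record.
    meta
        Free-form metadata (animal id, genotype label, stimulus fields,
        seed if synthetic, ...).
    """

    traces: np.ndarray
    sample_rate_hz: float
    onset_s: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError(f"traces must be 2-D (n_sweeps, n_samples), got ndim={self.traces.ndim}")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        if not 0.0 < self.onset_s < self.duration_s:
            raise ValueError(
                f"onset_s={self.onset_s} must lie strictly inside the record (0, {self.duration_s})"
            )

    @property
    def n_sweeps(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.traces.shape[1] / self.sample_rate_hz

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return np.arange(self.n_samples) / self.sample_rate_hz - self.onset_s


@dataclass
class AveragedWaveform:
    """Mean of the SNR-included sweeps of a :class:`SweepSet`.

    ``n_included == 0`` marks an empty average (all sweeps excluded);
    downstream detection refuses such waveforms.
    """

    trace: np.ndarray
    sample_rate_hz: float
    onset_s: float
    n_included: int
    n_excluded: int
    baseline_uv: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)
        if self.trace.ndim != 1:
            raise ValueError("trace must be 1-D")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")

    @property
    def valid(self) -> bool:
        return self.n_included >= 1

    @property
    def n_samples(self) -> int:
        return self.trace.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return np.arange(self.n_samples) / self.sample_rate_hz - self.onset_s


def _window_indices(
    n_samples: int, sample_rate_hz: float, start_s: float, stop_s: float
) -> tuple[int, int]:
    """Half-open sample-index range [i0, i1) for the time window [start, stop)."""
    i0 = int(round(start_s * sample_rate_hz))
    i1 = int(round(stop_s * sample_rate_hz))
    if i0 < 0 or i1 > n_samples or i1 <= i0:
        raise ValueError(
            f"window [{start_s}, {stop_s}) s lies outside the record "
            f"(n_samples={n_samples}, fs={sample_rate_hz} Hz)"
        )
    return i0, i1


def baseline(
    trace: np.ndarray,
    sample_rate_hz: float,
    onset_s: float,
    baseline_window_s: float = 0.1,
) -> float:
    """Pre-stimulus baseline: mean over ``[onset - window, onset)``."""
    trace = np.asarray(trace, dtype=float)
    i0, i1 = _window_indices(
        trace.shape[0], sample_rate_hz, onset_s - baseline_window_s, onset_s
    )
    return float(np.mean(trace[i0:i1]))


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def sweep_snr(
    trace: np.ndarray,
    sample_rate_hz: float,
    onset_s: float,
    response_window_s: float = 0.4,
    baseline_window_s: float = 0.1,
) -> float:
    """Per-sweep signal-to-noise ratio.

    RMS of the baseline-subtracted trace over ``[onset, onset +
    response_window]`` divided by the RMS over the pre-stimulus window
    ``[onset - baseline_window, onset)``.  A noiseless record (zero
    pre-stimulus RMS) returns ``inf`` rather than raising.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[0]
    b0, b1 = _window_indices(n, sample_rate_hz, onset_s - baseline_window_s, onset_s)
    r0, r1 = _window_indices(n, sample_rate_hz, onset_s, onset_s + response_window_s)
    base = float(np.mean(trace[b0:b1]))
    pre_rms = _rms(trace[b0:b1] - base)
    post_rms = _rms(trace[r0:r1] - base)
    if pre_rms == 0.0:
        return float("inf")
    return post_rms / pre_rms


def average_sweeps(
    sweeps: SweepSet,
    snr_threshold: float = 1.0,
    response_window_s: float = 0.4,
    baseline_window_s: float = 0.1,
) -> AveragedWaveform:
    """Average the sweeps whose SNR meets the threshold.

    Sweeps with ``sweep_snr >= snr_threshold`` are included.  If every
    sweep is excluded the result is an explicit empty average
    (``n_included == 0``, zero trace) rather than an error; component
    detection refuses such averages.
    """
    if sweeps.n_sweeps < 1:
        raise ValueError("SweepSet contains no sweeps")
    snrs = np.array(
        [
            sweep_snr(
                t,
                sweeps.sample_rate_hz,
                sweeps.onset_s,
                response_window_s=response_window_s,
                baseline_window_s=baseline_window_s,
            )
            for t in sweeps.traces
        ]
    )
    include = snrs >= snr_threshold
    n_inc = int(np.count_nonzero(include))
    if n_inc == 0:
        trace = np.zeros(sweeps.n_samples)
        base = 0.0
    else:
        trace = sweeps.traces[include].mean(axis=0)
        base = baseline(trace, sweeps.sample_rate_hz, sweeps.onset_s, baseline_window_s)
    return AveragedWaveform(
        trace=trace,
        sample_rate_hz=sweeps.sample_rate_hz,
        onset_s=sweeps.onset_s,
        n_included=n_inc,
        n_excluded=sweeps.n_sweeps - n_inc,
        baseline_uv=base,
        meta=dict(sweeps.meta),
    )


def butterworth_filter(
    trace: np.ndarray,
    sample_rate_hz: float,
    kind: str = "lowpass",
    order: int = 4,
    cutoffs_hz: float | tuple[float, float] = 200.0,
) -> np.ndarray:
    """Zero-phase Butterworth filter (forward-backward, SOS form).

    ``kind`` is ``"lowpass"`` or ``"bandpass"``; ``cutoffs_hz`` is a
    scalar for lowpass or a ``(low, high)`` pair for bandpass.  Cutoffs
    must lie below the Nyquist frequency.  DC gain is 1 for lowpass and
    the output has the same length as the input.  Zero-phase application
    squares the single-pass magnitude response but does not shift peaks,
    so filtering does not bias latency estimates.
    """
    trace = np.asarray(trace, dtype=float)
    if order < 1:
        raise ValueError("order must be >= 1")
    nyquist = sample_rate_hz / 2.0
    cut = np.atleast_1d(np.asarray(cutoffs_hz, dtype=float))
    if np.any(cut <= 0) or np.any(cut >= nyquist):
        raise ValueError(f"cutoffs {cutoffs_hz} Hz must lie in (0, Nyquist={nyquist} Hz)")
    if kind == "lowpass":
        if cut.size != 1:
            raise ValueError("lowpass takes a single cutoff")
        wn: float | tuple[float, float] = float(cut[0])
        btype = "lowpass"
    elif kind == "bandpass":
        if cut.size != 2 or not cut[0] < cut[1]:
            raise ValueError("bandpass takes an increasing (low, high) pair")
        wn = (float(cut[0]), float(cut[1]))
        btype = "bandpass"
    else:
        raise ValueError(f"unknown filter kind {kind!r}")
    sos = _signal.butter(order, wn, btype=btype, fs=sample_rate_hz, output="sos")
    return _signal.sosfiltfilt(sos, trace)
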