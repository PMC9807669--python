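"""P1/N1/P2 detection in averaged VEPs and a-/b-wave features in ERGs.

VEP component metrics follow the standard conventions for this
preparation: latency is the time from stimulus onset to the P1 peak, and
the response amplitude is the absolute voltage difference between the P1
and N1 peaks (both measured from the pre-stimulus baseline).

Detection strategy: the averaged trace is low-passed (zero-phase
Butterworth, 200 Hz by default) so that local extrema reflect waveform
lobes rather than single noise samples; candidate extrema must exceed
``k_sigma`` times the pre-stimulus noise SD of the same filtered trace;
peak times are then refined on the unfiltered trace within a small
window.  A blanking period after onset skips the stimulus artifact.
The earliest qualifying extremum wins; plateaus resolve to their first
sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .preprocess import AveragedWaveform, butterworth_filter

__all__ = [
    "DetectionStatus",
    "VEPComponents",
    "ComponentResult",
    "ERGFeatures",
    "detect_components",
    "detect_erg_features",
]


class DetectionStatus(str, Enum):
    OK = "ok"
    NO_RESPONSE = "no_response"
    EMPTY_AVERAGE = "empty_average"


@dataclass(frozen=True)
class VEPComponents:
    """P1/N1/P2 peak times (s, relative to onset) and voltages (uV,
    baseline-subtracted).  P2 is optional; its absence does not
    invalidate P1/N1."""

    p1_time_s: float
    p1_uv: float
    n1_time_s: float
    n1_uv: float
    p2_time_s: float | None = None
    p2_uv: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p1_time_s < self.n1_time_s:
            raise ValueError("component ordering violated: need 0 < P1 < N1 time")
        if self.p2_time_s is not None and self.p2_time_s <= self.n1_time_s:
            raise ValueError("component ordering violated: need N1 < P2 time")
        if not (self.p1_uv > 0 > self.n1_uv):
            raise ValueError("sign pattern violated: need P1 > 0 > N1 (baseline-subtracted)")

    @property
    def latency_s(self) -> float:
        """Stimulus onset to P1 peak."""
        return self.p1_time_s

    @property
    def p1n1_amplitude_uv(self) -> float:
        """Absolute voltage difference between P1 and N1 peaks."""
        return abs(self.p1_uv - self.n1_uv)


@dataclass(frozen=True)
class ComponentResult:
    status: DetectionStatus
    components: VEPComponents | None = None

    @property
    def ok(self) -> bool:
        return self.status is DetectionStatus.OK


@dataclass(frozen=True)
class ERGFeatures:
    """a-wave trough, b-wave peak, oscillatory-potential RMS.

    ``response_present`` is False when no qualifying a-then-b pattern is
    found; feature fields are then NaN.
    """

    a_time_s: float
    a_uv: float
    b_time_s: float
    b_uv: float
    op_rms_uv: float
    response_present: bool

    def __post_init__(self) -> None:
        if self.response_present:
            if not self.a_time_s < self.b_time_s:
                raise ValueError("a-wave must precede b-wave")
            if not (self.a_uv < 0 < self.b_uv):
                raise ValueError("a-wave must be negative and b-wave positive")


def _local_extrema(x: np.ndarray, mode: str) -> np.ndarray:
    """Indices of local maxima (or minima), plateaus at their first sample."""
    y = x if mode == "max" else -x
    dy = np.diff(y)
    nz = np.flatnonzero(dy != 0)
    if nz.size < 2:
        return np.empty(0, dtype=int)
    s = np.sign(dy[nz])
    # rise immediately followed (across any plateau) by a fall; the
    # extremum is the first sample after the rise
    k = np.flatnonzero((s[:-1] > 0) & (s[1:] < 0))
    return nz[k] + 1


def _filtered_and_noise(
    avg: AveragedWaveform,
    lowpass_hz: float,
    lowpass_order: int,
    baseline_window_s: float,
) -> tuple[np.ndarray, float, int]:
    fs = avg.sample_rate_hz
    filt = butterworth_filter(avg.trace, fs, "lowpass", lowpass_order, lowpass_hz)
    onset_idx = int(round(avg.onset_s * fs))
    b0 = max(0, onset_idx - int(round(baseline_window_s * fs)))
    pre = filt[b0:onset_idx]
    filt = filt - float(np.mean(pre))
    noise_sd = float(np.std(filt[b0:onset_idx]))
    return filt, noise_sd, onset_idx


def _refine(trace: np.ndarray, idx: int, lo: int, hi: int, mode: str) -> int:
    """Refine a filtered-trace extremum on the raw trace within [lo, hi)."""
    lo = max(lo, 0)
    hi = min(hi, trace.size)
    seg = trace[lo:hi]
    off = int(np.argmax(seg)) if mode == "max" else int(np.argmin(seg))
    return lo + off


def detect_components(
    avg: AveragedWaveform,
    search_window_s: float = 0.4,
    k_sigma: float = 3.0,
    blank_s: float = 0.010,
    lowpass_hz: float = 200.0,
    lowpass_order: int = 4,
    refine_s: float = 0.002,
    baseline_window_s: float = 0.1,
    min_relative_amplitude: float = 0.5,
) -> ComponentResult:
    """Detect P1, N1 and (optionally) P2 in an averaged VEP.

    Searches ``[onset + blank_s, onset + search_window_s]``.  P1 is the
    earliest local maximum of the low-passed, baseline-subtracted trace
    exceeding ``+k_sigma * noise_sd``; N1 the earliest subsequent local
    minimum below ``-k_sigma * noise_sd``; P2 the earliest subsequent
    local maximum above the positive threshold (optional).  Candidates
    must additionally reach ``min_relative_amplitude`` times the largest
    same-polarity excursion in the search window, so that small noise
    bumps cannot pre-empt the dominant deflection under the
    earliest-extremum rule.  Peak times are refined on the unfiltered
    trace within ``+-refine_s``.  Returns a :class:`ComponentResult`
    whose status is ``EMPTY_AVERAGE`` for an all-excluded average and
    ``NO_RESPONSE`` when P1 or N1 is not found.
    """
    if not avg.valid:
        return ComponentResult(DetectionStatus.EMPTY_AVERAGE)
    fs = avg.sample_rate_hz
    filt, noise_sd, onset_idx = _filtered_and_noise(
        avg, lowpass_hz, lowpass_order, baseline_window_s
    )
    raw = avg.trace - avg.baseline_uv
    w0 = onset_idx + int(round(blank_s * fs))
    w1 = min(onset_idx + int(round(search_window_s * fs)), filt.size)
    if w1 - w0 < 3:
        return ComponentResult(DetectionStatus.NO_RESPONSE)
    seg = filt[w0:w1]
    thr = k_sigma * noise_sd
    rel_pos = min_relative_amplitude * float(seg.max())
    rel_neg = min_relative_amplitude * float(seg.min())
    r = max(1, int(round(refine_s * fs)))

    maxima = _local_extrema(seg, "max")
    p1_cands = maxima[(seg[maxima] > thr) & (seg[maxima] >= rel_pos)]
    if p1_cands.size == 0:
        return ComponentResult(DetectionStatus.NO_RESPONSE)
    p1_f = w0 + int(p1_cands[0])
    p1 = _refine(raw, p1_f, p1_f - r, p1_f + r + 1, "max")

    minima = _local_extrema(seg, "min")
    n1_cands = minima[
        (minima > (p1_f - w0)) & (seg[minima] < -thr) & (seg[minima] <= rel_neg)
    ]
    if n1_cands.size == 0:
        return ComponentResult(DetectionStatus.NO_RESPONSE)
    n1_f = w0 + int(n1_cands[0])
    n1 = _refine(raw, n1_f, max(n1_f - r, p1 + 1), n1_f + r + 1, "min")

    p2: int | None = None
    p2_cands = maxima[(maxima > (n1_f - w0)) & (seg[maxima] > thr) & (seg[maxima] >= rel_pos)]
    if p2_cands.size > 0:
        p2_f = w0 + int(p2_cands[0])
        p2 = _refine(raw, p2_f, max(p2_f - r, n1 + 1), p2_f + r + 1, "max")

    if raw[p1] <= 0 or raw[n1] >= 0:
        return ComponentResult(DetectionStatus.NO_RESPONSE)
    comps = VEPComponents(
        p1_time_s=(p1 - onset_idx) / fs,
        p1_uv=float(raw[p1]),
        n1_time_s=(n1 - onset_idx) / fs,
        n1_uv=float(raw[n1]),
        p2_time_s=None if p2 is None else (p2 - onset_idx) / fs,
        p2_uv=None if p2 is None else float(raw[p2]),
    )
    return ComponentResult(DetectionStatus.OK, comps)


def detect_erg_features(
    avg: AveragedWaveform,
    a_window_s: float = 0.05,
    b_window_s: float = 0.4,
    op_band_hz: tuple[float, float] = (75.0, 300.0),
    k_sigma: float = 3.0,
    lowpass_hz: float = 200.0,
    lowpass_order: int = 4,
    baseline_window_s: float = 0.1,
) -> ERGFeatures:
    """Detect a-wave, b-wave and oscillatory potentials in an ERG average.

    The a-wave is the global minimum of the cleaned (200 Hz low-passed,
    baseline-subtracted) trace in ``[onset, onset + a_window_s]``,
    required to fall below ``-k_sigma * noise_sd``; the b-wave is the
    global maximum after the a-wave (within ``b_window_s`` of onset)
    required to exceed the positive threshold.  ``op_rms_uv`` is the RMS
    of the trace band-passed to ``op_band_hz`` over the a-to-b interval.
    Absence of a qualifying pattern is encoded in ``response_present``,
    never raised.
    """
    nan = float("nan")
    absent = ERGFeatures(nan, nan, nan, nan, nan, response_present=False)
    if not avg.valid:
        return absent
    fs = avg.sample_rate_hz
    filt, noise_sd, onset_idx = _filtered_and_noise(
        avg, lowpass_hz, lowpass_order, baseline_window_s
    )
    thr = k_sigma * noise_sd
    a0 = onset_idx
    a1 = min(onset_idx + int(round(a_window_s * fs)), filt.size)
    if a1 - a0 < 2:
        return absent
    a_idx = a0 + int(np.argmin(filt[a0:a1]))
    if not filt[a_idx] < -thr:
        return absent
    b1 = min(onset_idx + int(round(b_window_s * fs)), filt.size)
    if b1 - a_idx < 2:
        return absent
    b_idx = a_idx + 1 + int(np.argmax(filt[a_idx + 1 : b1]))
    if not filt[b_idx] > thr:
        return absent
    banded = butterworth_filter(avg.trace, fs, "bandpass", 2, op_band_hz)
    op_rms = float(np.sqrt(np.mean(np.square(banded[a_idx : b_idx + 1]))))
    return ERGFeatures(
        a_time_s=(a_idx - onset_idx) / fs,
        a_uv=float(filt[a_idx]),
        b_time_s=(b_idx - onset_idx) / fs,
        b_uv=float(filt[b_idx]),
        op_rms_uv=op_rms,
        response_present=True,
    )
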