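"""Tonic and phasic EDA feature extraction.

Tonic features summarise the slowly varying skin conductance level over a
64-s window: mean (SCL), minimum, maximum and population standard
deviation, all in µS.  Phasic features describe skin conductance responses
(SCRs): each event has an amplitude measured trough to peak, a duration
from onset until the signal first recovers to 50% of the peak amplitude,
and an area AUC = 1/2 x amplitude x duration.

The detector is a deliberately simple trough-to-peak scan: an event onset
is a local minimum, its peak the next local maximum, and the event counts
when the rise meets ``min_amplitude``.  A new event may begin only after
the previous event's peak (no deconvolution of compound SCRs).  The same
detector is applied to original and reconstructed signals, so compression
impact is measured with a fixed, fully specified reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidInputError
from .wavelet import SAMPLE_RATE_HZ, EdaWindow

__all__ = [
    "ScrEvent",
    "FeatureSet",
    "tonic_features",
    "detect_scrs",
    "phasic_sums",
    "extract_features",
    "write_features_csv",
]

#: Default minimum trough-to-peak rise (µS) for an SCR; the sensor's
#: conductance resolution.
DEFAULT_MIN_AMPLITUDE = 0.01


@dataclass(frozen=True)
class ScrEvent:
    """One skin conductance response."""

    onset_idx: int
    peak_idx: int
    amplitude: float  # µS, trough to peak
    duration: float   # s, onset to 50%-of-peak recovery
    auc: float        # µS*s, 1/2 * amplitude * duration

    def __post_init__(self) -> None:
        if self.onset_idx >= self.peak_idx:
            raise InvalidInputError("onset must precede peak")
        if self.amplitude <= 0 or self.duration <= 0:
            raise InvalidInputError("amplitude and duration must be positive")
        if abs(self.auc - 0.5 * self.amplitude * self.duration) > 1e-12:
            raise InvalidInputError("auc must equal amplitude*duration/2")


@dataclass(frozen=True)
class FeatureSet:
    """Tonic + phasic feature summary of one window."""

    scl: float
    sc_min: float
    sc_max: float
    sc_std: float
    sum_amp: float
    sum_dur: float
    sum_auc: float
    n_scrs: int

    def __post_init__(self) -> None:
        if not self.sc_min <= self.scl <= self.sc_max:
            raise InvalidInputError("mean must lie between min and max")
        if min(self.sum_amp, self.sum_dur, self.sum_auc) < 0:
            raise InvalidInputError("phasic sums must be non-negative")


def _samples(x: EdaWindow | Sequence[float]) -> np.ndarray:
    s = x.samples if isinstance(x, EdaWindow) else np.asarray(x, dtype=np.float64)
    if s.ndim != 1 or s.size < 2:
        raise InvalidInputError("expected a 1-D signal of length >= 2")
    return s


def tonic_features(x: EdaWindow | Sequence[float]) -> tuple[float, float, float, float]:
    """(SCL, SC_Min, SC_Max, EDA_Std) — mean, min, max, population std."""
    s = _samples(x)
    return float(s.mean()), float(s.min()), float(s.max()), float(s.std(ddof=0))


def detect_scrs(
    x: EdaWindow | Sequence[float],
    min_amplitude: float = DEFAULT_MIN_AMPLITUDE,
    fs: float = SAMPLE_RATE_HZ,
) -> list[ScrEvent]:
    """Trough-to-peak SCR detection.

    Scans for a local minimum (onset) followed by a local maximum (peak);
    the rise must be at least ``min_amplitude`` µS.  Duration runs from the
    onset until the signal first falls to peak - amplitude/2, truncated at
    the window end.  Returns an empty list for flat or monotone-decreasing
    input.
    """
    if min_amplitude <= 0:
        raise InvalidInputError("min_amplitude must be positive")
    s = _samples(x)
    n = s.size
    events: list[ScrEvent] = []
    i = 0
    while i < n - 1:
        # descend to the next local minimum
        while i < n - 1 and s[i + 1] < s[i]:
            i += 1
        onset = i
        # climb to the following local maximum (plateaus belong to the rise)
        j = onset
        while j < n - 1 and s[j + 1] >= s[j]:
            j += 1
        peak = j
        if peak > onset:
            # anchor the onset at the end of any flat run: last sample of
            # the rise interval that still sits at the trough level
            trough = s[onset:peak].min()
            onset = onset + int(np.flatnonzero(s[onset:peak] == trough)[-1])
        amplitude = float(s[peak] - s[onset])
        if peak > onset and amplitude >= min_amplitude:
            half_level = s[peak] - 0.5 * amplitude
            t = peak
            while t < n - 1 and s[t + 1] > half_level:
                t += 1
            if t < n - 1:
                t += 1  # first sample at or below the 50% level
            duration = (t - onset) / fs
            events.append(
                ScrEvent(
                    onset_idx=onset,
                    peak_idx=peak,
                    amplitude=amplitude,
                    duration=duration,
                    auc=0.5 * amplitude * duration,
                )
            )
        i = peak if peak > i else i + 1
    return events


def phasic_sums(events: Iterable[ScrEvent]) -> tuple[float, float, float]:
    """(Sum_Amp, Sum_Dur, Sum_AUC) over the given events; zeros if empty."""
    amp = dur = auc = 0.0
    for ev in events:
        amp += ev.amplitude
        dur += ev.duration
        auc += ev.auc
    return amp, dur, auc


def extract_features(
    x: EdaWindow | Sequence[float],
    min_amplitude: float = DEFAULT_MIN_AMPLITUDE,
    fs: float = SAMPLE_RATE_HZ,
) -> FeatureSet:
    """Full tonic + phasic summary of one window."""
    scl, sc_min, sc_max, sc_std = tonic_features(x)
    events = detect_scrs(x, min_amplitude=min_amplitude, fs=fs)
    sum_amp, sum_dur, sum_auc = phasic_sums(events)
    return FeatureSet(
        scl=scl, sc_min=sc_min, sc_max=sc_max, sc_std=sc_std,
        sum_amp=sum_amp, sum_dur=sum_dur, sum_auc=sum_auc, n_scrs=len(events),
    )


def write_features_csv(
    feature_sets: Iterable[tuple[str, FeatureSet]], path: str | Path
) -> None:
    """One row per window: window id plus every FeatureSet field."""
    import csv

    fields = ["window_id", "scl", "sc_min", "sc_max", "sc_std",
              "sum_amp", "sum_dur", "sum_auc", "n_scrs"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(fields)
        for window_id, fs_ in feature_sets:
            writer.writerow([window_id, fs_.scl, fs_.sc_min, fs_.sc_max,
                             fs_.sc_std, fs_.sum_amp, fs_.sum_dur,
                             fs_.sum_auc, fs_.n_scrs])
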