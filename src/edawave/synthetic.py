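"""Seeded synthetic EDA generator and dataset-preparation filter.

Real wrist EDA recorded in a stress-induction session combines a slowly
drifting tonic conductance level (validated sensor range roughly
0.25-6.67 µS), superimposed phasic SCR pulses, and small measurement
noise.  The generator emulates exactly that structure:

* tonic level — a bounded Gaussian random walk (reflected at the bounds);
* phasic activity — Poisson-arrival pulses with lognormal amplitudes and a
  difference-of-exponentials shape (fast rise, slow decay), the canonical
  SCR morphology;
* additive white Gaussian noise;
* the result clipped to the sensor-plausible range [0, 10] µS.

Ground-truth pulse times/amplitudes are returned alongside the signal so
detector recall can be scored.  Every draw comes from one seeded
generator: identical seeds give identical sessions.

The Chebyshev type-II low-pass used to clean sessions before compression
(0.6 Hz passband edge at 3 dB, 0.9 Hz stopband at 74 dB, causal
minimum-order design at 2 Hz) lives here too: it belongs to dataset
preparation, not to the codec.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError, InvalidInputError
from .wavelet import SAMPLE_RATE_HZ, WINDOW_SAMPLES, EdaWindow

__all__ = [
    "SynthConfig",
    "generate_session",
    "preprocess_filter",
    "window_session",
    "write_session_csv",
    "read_session_csv",
    "write_truth_json",
]

#: Sensor-plausible conductance range (µS) that all output is clipped to.
CLIP_RANGE = (0.0, 10.0)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic EDA session.

    Defaults describe a quiet lab session: a tonic level near 2 µS with a
    gentle drift, about two SCRs per minute with amplitudes mostly in
    0.1-0.5 µS (lognormal, median ~0.22 µS), a 0.7 s rise / 4 s decay
    pulse shape, and 0.01 µS white noise (the sensor resolution).
    """

    duration: float = 640.0          # s
    fs: float = SAMPLE_RATE_HZ       # Hz, fixed at 2
    baseline_start: float = 2.0      # µS
    baseline_drift_sd: float = 0.01  # µS per sample step
    scr_rate: float = 2.0            # events/min
    amp_log_mean: float = -1.5       # log-µS (median ~0.22 µS)
    amp_log_sd: float = 0.45         # log-µS
    rise_tau: float = 0.7            # s
    decay_tau: float = 4.0           # s
    noise_sd: float = 0.01           # µS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise ConfigurationError("duration and fs must be positive")
        if self.baseline_start < CLIP_RANGE[0] or self.baseline_start > CLIP_RANGE[1]:
            raise ConfigurationError("baseline_start outside the sensor range")
        if min(self.rise_tau, self.decay_tau) <= 0:
            raise ConfigurationError("time constants must be positive")
        if self.rise_tau >= self.decay_tau:
            raise ConfigurationError("SCR rise must be faster than its decay")
        if self.scr_rate < 0 or self.baseline_drift_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError("rates and noise levels must be non-negative")


def _reflect(walk: np.ndarray, lo: float, hi: float) -> np.ndarray:
    # fold an unbounded walk into [lo, hi] by repeated reflection
    span = hi - lo
    y = np.mod(walk - lo, 2.0 * span)
    return lo + np.where(y > span, 2.0 * span - y, y)


def _scr_kernel(rise_tau: float, decay_tau: float, fs: float) -> np.ndarray:
    # difference of exponentials, unit peak amplitude
    t = np.arange(0.0, 6.0 * decay_tau, 1.0 / fs)
    k = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    return k / k.max()


def generate_session(cfg: SynthConfig) -> tuple[np.ndarray, list[dict]]:
    """Synthesize one session; returns (samples µS, ground-truth events).

    Each truth entry is ``{"time_s", "sample_idx", "amplitude_uS"}`` for
    one injected SCR pulse.  Output is deterministic for a fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs))
    if n < 1:
        raise ConfigurationError("duration too short for one sample")

    steps = rng.normal(0.0, cfg.baseline_drift_sd, size=n) if cfg.baseline_drift_sd else np.zeros(n)
    tonic = _reflect(cfg.baseline_start + np.cumsum(steps),
                     max(CLIP_RANGE[0] + 0.1, 0.1), CLIP_RANGE[1] - 2.0)

    phasic = np.zeros(n)
    truth: list[dict] = []
    n_events = rng.poisson(cfg.scr_rate / 60.0 * cfg.duration) if cfg.scr_rate else 0
    if n_events:
        kernel = _scr_kernel(cfg.rise_tau, cfg.decay_tau, cfg.fs)
        onsets = np.sort(rng.uniform(0.0, cfg.duration, size=n_events))
        amps = rng.lognormal(cfg.amp_log_mean, cfg.amp_log_sd, size=n_events)
        for t0, amp in zip(onsets, amps):
            i0 = int(round(t0 * cfg.fs))
            if i0 >= n:
                continue
            seg = kernel[: n - i0]
            phasic[i0 : i0 + seg.size] += amp * seg
            truth.append({"time_s": float(i0 / cfg.fs),
                          "sample_idx": i0,
                          "amplitude_uS": float(amp)})

    noise = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd else np.zeros(n)
    samples = np.clip(tonic + phasic + noise, *CLIP_RANGE)
    return samples, truth


def preprocess_filter(samples: Sequence[float], fs: float = SAMPLE_RATE_HZ) -> np.ndarray:
    """Causal Chebyshev type-II low-pass used before compression.

    Minimum-order design meeting 0.6 Hz passband (3 dB) and 0.9 Hz
    stopband (74 dB) at fs = 2 Hz, applied forward with a DC-matched
    initial state so constant input passes unchanged (DC gain 1).
    """
    if abs(fs - SAMPLE_RATE_HZ) > 1e-9:
        raise ConfigurationError("the preprocessing filter is specified for fs = 2 Hz")
    x = np.asarray(samples, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise InvalidInputError("expected a non-empty 1-D signal")
    order, wn = sps.cheb2ord(wp=0.6, ws=0.9, gpass=3.0, gstop=74.0, fs=fs)
    b, a = sps.cheby2(order, 74.0, wn, btype="low", fs=fs)
    dc = np.sum(b) / np.sum(a)
    if abs(dc - 1.0) > 1e-3:
        raise ConfigurationError(f"designed filter DC gain {dc:g} off unity")
    zi = sps.lfilter_zi(b, a) * x[0]
    y, _ = sps.lfilter(b, a, x, zi=zi)
    return y


def window_session(samples: Sequence[float]) -> list[EdaWindow]:
    """Split a session into non-overlapping 128-sample (64 s) windows.

    The trailing remainder is dropped; a too-short session yields an empty
    list with a warning.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.ndim != 1:
        raise InvalidInputError("expected a 1-D signal")
    n_windows = x.size // WINDOW_SAMPLES
    if n_windows == 0:
        warnings.warn(
            f"session of {x.size} samples is shorter than one "
            f"{WINDOW_SAMPLES}-sample window", stacklevel=2)
        return []
    return [
        EdaWindow(
            samples=x[i * WINDOW_SAMPLES : (i + 1) * WINDOW_SAMPLES],
            t0=i * WINDOW_SAMPLES / SAMPLE_RATE_HZ,
        )
        for i in range(n_windows)
    ]


# -- session file I/O ---------------------------------------------------------

CSV_COLUMNS = ("time_s", "conductance_uS")


def write_session_csv(samples: Sequence[float], path: str | Path,
                      fs: float = SAMPLE_RATE_HZ) -> None:
    x = np.asarray(samples, dtype=np.float64)
    pd.DataFrame({CSV_COLUMNS[0]: np.arange(x.size) / fs,
                  CSV_COLUMNS[1]: x}).to_csv(path, index=False)


def read_session_csv(path: str | Path, fs: float = SAMPLE_RATE_HZ) -> np.ndarray:
    """Read a session CSV, validating the 2 Hz uniform time base (±1 ms)."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise InvalidInputError(f"malformed session CSV {path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"session CSV missing columns {missing}")
    if len(df) == 0:
        raise InvalidInputError("session CSV holds no samples")
    t = df[CSV_COLUMNS[0]].to_numpy(dtype=np.float64)
    expected = np.arange(t.size) / fs + t[0]
    if np.max(np.abs(t - expected)) > 1e-3:
        raise InvalidInputError(
            f"time base is not uniform {fs} Hz within 1 ms")
    x = df[CSV_COLUMNS[1]].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("non-finite conductance value in CSV")
    return x


def write_truth_json(truth: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
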