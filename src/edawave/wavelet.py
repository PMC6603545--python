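"""Multilevel db3 wavelet analysis and synthesis of 64-s EDA windows.

Skin conductance is sampled at 2 Hz and processed in 128-sample (64 s)
windows.  Each window is decomposed four times with the 6-tap Daubechies-3
filter pair under whole-sample symmetric boundary extension, producing the
flat 145-coefficient vector

    W4 = [A4 (12) | D4 (12) | D3 (20) | D2 (35) | D1 (66)]

whose level boundaries are fixed by the length chain 128 -> 66 -> 35 -> 20
-> 12.  The decomposition here is pure floating point; fixed-point effects
live in :mod:`edawave.codec`.

Synthesis uses PyWavelets' ``waverec`` (mode ``symmetric``), which is the
exact inverse of this analysis convention: a round trip through
:func:`ml_dwt` and :func:`inverse_ml_dwt` reproduces the window to within
floating-point rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt

from .errors import InvalidInputError

__all__ = [
    "WINDOW_SAMPLES",
    "SAMPLE_RATE_HZ",
    "LEVEL_LENGTHS",
    "FLAT_LENGTH",
    "LEVEL_SLICES",
    "EdaWindow",
    "FilterBank",
    "WaveletCoeffs",
    "pad_symmetric",
    "dwt_step",
    "ml_dwt",
    "inverse_ml_dwt",
]

#: Samples per analysis window (64 s at 2 Hz).
WINDOW_SAMPLES = 128
#: Fixed sampling rate of the sensor front end (Hz).
SAMPLE_RATE_HZ = 2.0

#: Coefficient-vector lengths in flat order (A4, D4, D3, D2, D1).
LEVEL_LENGTHS = {"A4": 12, "D4": 12, "D3": 20, "D2": 35, "D1": 66}
#: Total length of the flat transform vector.
FLAT_LENGTH = 145

#: Half-open index ranges of each level inside the flat vector.
LEVEL_SLICES = {
    "A4": slice(0, 12),
    "D4": slice(12, 24),
    "D3": slice(24, 44),
    "D2": slice(44, 79),
    "D1": slice(79, 145),
}

# Numerical slack allowed below zero for reconstructed conductance values.
_NEG_TOL = 1e-6


@dataclass(frozen=True)
class EdaWindow:
    """One 128-sample, 64-s skin-conductance window in µS."""

    samples: np.ndarray
    fs: float = SAMPLE_RATE_HZ
    t0: float | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size != WINDOW_SAMPLES:
            raise InvalidInputError(
                f"an EDA window must hold exactly {WINDOW_SAMPLES} samples, "
                f"got shape {samples.shape}"
            )
        if not np.all(np.isfinite(samples)):
            raise InvalidInputError("EDA window contains non-finite values")
        if samples.min() < -_NEG_TOL:
            raise InvalidInputError(
                f"conductance must be non-negative, min={samples.min():g} µS"
            )
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return WINDOW_SAMPLES / self.fs


@dataclass(frozen=True)
class FilterBank:
    """6-tap scaling/wavelet analysis filter pair (db3 by default).

    ``h0`` is the low-pass (scaling) filter and ``h1`` the band-pass
    (wavelet) filter, both normalised to unit L2 norm so that
    ``sum(h0) = sqrt(2)`` and ``sum(h1) = 0``.
    """

    h0: np.ndarray
    h1: np.ndarray

    def __post_init__(self) -> None:
        h0 = np.asarray(self.h0, dtype=np.float64)
        h1 = np.asarray(self.h1, dtype=np.float64)
        for name, h in (("h0", h0), ("h1", h1)):
            if h.shape != (6,):
                raise InvalidInputError(f"{name} must have exactly 6 taps")
            if abs(h @ h - 1.0) > 1e-10:
                raise InvalidInputError(f"{name} must have unit L2 norm")
        if abs(h0.sum() - np.sqrt(2.0)) > 1e-10:
            raise InvalidInputError("h0 taps must sum to sqrt(2)")
        if abs(h1.sum()) > 1e-10:
            raise InvalidInputError("h1 taps must sum to 0")
        object.__setattr__(self, "h0", h0)
        object.__setattr__(self, "h1", h1)

    @classmethod
    def db3(cls) -> "FilterBank":
        """Daubechies-3 filter pair, oriented for the stride-2 correlation
        of :func:`dwt_step` (equivalently, convolution with PyWavelets'
        decomposition filters)."""
        w = pywt.Wavelet("db3")
        return cls(h0=np.asarray(w.rec_lo), h1=np.asarray(w.rec_hi))


_DB3 = None


def _default_fb() -> FilterBank:
    global _DB3
    if _DB3 is None:
        _DB3 = FilterBank.db3()
    return _DB3


@dataclass(frozen=True)
class WaveletCoeffs:
    """Four-level transform of one window: A4, D4, D3, D2, D1.

    The flat view ``W4`` concatenates the levels in that order; its slice
    boundaries are ``W4[0:12]=A4, W4[12:24]=D4, W4[24:44]=D3, W4[44:79]=D2,
    W4[79:145]=D1``.
    """

    A4: np.ndarray
    D4: np.ndarray
    D3: np.ndarray
    D2: np.ndarray
    D1: np.ndarray

    def __post_init__(self) -> None:
        for name, n in LEVEL_LENGTHS.items():
            v = np.asarray(getattr(self, name), dtype=np.float64)
            if v.shape != (n,):
                raise InvalidInputError(
                    f"{name} must have length {n}, got {v.shape}"
                )
            object.__setattr__(self, name, v)

    @property
    def flat(self) -> np.ndarray:
        """The 145-element flat vector [A4, D4, D3, D2, D1]."""
        return np.concatenate([self.A4, self.D4, self.D3, self.D2, self.D1])

    @classmethod
    def from_flat(cls, w4: Sequence[float]) -> "WaveletCoeffs":
        w4 = np.asarray(w4, dtype=np.float64)
        if w4.shape != (FLAT_LENGTH,):
            raise InvalidInputError(
                f"flat coefficient vector must have length {FLAT_LENGTH}"
            )
        return cls(*(w4[LEVEL_SLICES[k]] for k in LEVEL_LENGTHS))

    def levels(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in LEVEL_LENGTHS}


def pad_symmetric(a: Sequence[float], width: int = 4) -> np.ndarray:
    """Whole-sample symmetric extension of ``a`` by ``width`` on each side.

    ``[x0..x(N-1)] -> [x(w-1)..x0 | x0..x(N-1) | x(N-1)..x(N-w)]``; the
    border sample is repeated (mirror about the sample itself).
    """
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 1:
        raise InvalidInputError("pad_symmetric expects a 1-D vector")
    if width < 1 or a.size < width:
        raise InvalidInputError(
            f"input of length {a.size} cannot be mirrored by width {width}"
        )
    return np.concatenate([a[:width][::-1], a, a[-width:][::-1]])


def dwt_step(a: Sequence[float], fb: FilterBank | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One analysis step: symmetric extension + stride-2 correlation.

    The approximation output is ``A[n] = sum_k h0[k] * a_pad[2n + k]`` and
    the detail output uses ``h1``.  For input length ``N`` both outputs
    have length ``floor((N + 5) / 2)`` — the convention that yields the
    fixed level lengths (66, 35, 20, 12) from a 128-sample window.  Odd
    ``N`` takes one additional mirrored sample on the right so the final
    stride-2 window is complete.
    """
    fb = fb or _default_fb()
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 1 or a.size < 6:
        raise InvalidInputError("dwt_step requires a 1-D input of length >= 6")
    ap = pad_symmetric(a, 4)
    if a.size % 2 == 1:
        # continue the right-hand mirror by one sample (x[N-5])
        ap = np.append(ap, a[-5])
    n_out = (ap.size - 6) // 2 + 1
    windows = np.lib.stride_tricks.sliding_window_view(ap, 6)[::2][:n_out]
    return windows @ fb.h0, windows @ fb.h1


def ml_dwt(x: EdaWindow | Sequence[float], fb: FilterBank | None = None) -> WaveletCoeffs:
    """Four-level decomposition of a 128-sample window into W4."""
    samples = x.samples if isinstance(x, EdaWindow) else np.asarray(x, dtype=np.float64)
    if samples.shape != (WINDOW_SAMPLES,):
        raise InvalidInputError(
            f"ml_dwt expects a {WINDOW_SAMPLES}-sample window"
        )
    approx = samples
    details: list[np.ndarray] = []
    for _ in range(4):
        approx, d = dwt_step(approx, fb)
        details.append(d)
    d1, d2, d3, d4 = details
    return WaveletCoeffs(A4=approx, D4=d4, D3=d3, D2=d2, D1=d1)


def inverse_ml_dwt(w: WaveletCoeffs, fb: FilterBank | None = None) -> np.ndarray:
    """Reconstruct the 128-sample window from W4 by the inverse DWT.

    Exact inverse of :func:`ml_dwt` when no coefficients were altered;
    with coefficients zeroed or quantized it returns the corresponding
    least-distorted synthesis.  ``fb`` is accepted for symmetry of the API
    but synthesis always uses the db3 pair matching :func:`ml_dwt`.
    """
    if not isinstance(w, WaveletCoeffs):
        w = WaveletCoeffs.from_flat(np.asarray(w, dtype=np.float64))
    coeffs = [w.A4, w.D4, w.D3, w.D2, w.D1]
    x = pywt.waverec(coeffs, "db3", mode="symmetric")
    return np.asarray(x[:WINDOW_SAMPLES], dtype=np.float64)
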