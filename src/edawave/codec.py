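"""Fixed-point quantization, top-K selection and bit-exact block coding.

The on-sensor codec stores a 64-s window as a small block built from the
145-element wavelet vector W4:

1. the window is expressed in 0.01 µS units (x100) before the transform,
   and each float coefficient is truncated toward zero to an integer
   (mirroring the firmware's Q15.16 -> Q15.0 cast);
2. A4 coefficients are unsigned 12-bit (clamped to [0, 4095]); detail
   coefficients are signed 8-bit (clamped to [-128, 127]);
3. the K largest-magnitude coefficients are retained.  A4 (flat indices
   0-11) is always kept whole when K >= 12, encoded in natural order so no
   addresses are needed; detail positions are absolute flat indices
   (12-144) stored in 8 bits.

Block layout for K >= 12 (all 16-bit little-endian words):

* twelve A-words: bits 15..4 = A4[i], bits 3..0 = an address nibble.  The
  8-bit address of retained detail j (j < min(K-12, 6)) is split
  low-nibble -> word 2j, high-nibble -> word 2j+1; unused nibbles are 0
  (a sentinel — real detail addresses are >= 12);
* ceil(min(K-12, 6)/2) detail-value words, two signed bytes per word with
  the even-position value in the low byte; an odd count leaves the high
  byte 0;
* one extended word per detail beyond the sixth: value in bits 15..8,
  address in bits 7..0.

For K < 12 only the K largest-magnitude A4 entries are kept; each A-word
carries the entry's A4 position (0-11) in its nibble so the decoder can
restore it, and dropped A4 slots decode to zero.

The retained count K travels in the container record header, not the
payload; compression-ratio accounting counts payload bits only.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import BinaryIO, Iterable, Sequence

import numpy as np

from .errors import CorruptBlockError, InvalidInputError
from .wavelet import (
    FLAT_LENGTH,
    WINDOW_SAMPLES,
    EdaWindow,
    FilterBank,
    WaveletCoeffs,
    inverse_ml_dwt,
    ml_dwt,
)

__all__ = [
    "QUANT_SCALE",
    "A4_MAX",
    "DETAIL_MIN",
    "DETAIL_MAX",
    "QuantizedCoeffs",
    "SortedIndexList",
    "CompressedBlock",
    "quantize",
    "select_top_k",
    "bits_for_k",
    "bitwidth_for_max",
    "encode_block",
    "decode_block",
    "compress_window",
    "decompress_window",
    "write_container",
    "read_container",
]

#: Conversion factor from µS to the fixed-point unit (0.01 µS).
QUANT_SCALE = 100.0
#: Unsigned 12-bit ceiling for A4 entries.
A4_MAX = 4095
#: Signed 8-bit range for detail entries.
DETAIL_MIN, DETAIL_MAX = -128, 127

_N_A4 = 12
CONTAINER_MAGIC = b"EDW1"


@dataclass(frozen=True)
class QuantizedCoeffs:
    """145 signed integers in 0.01 µS units, plus a saturation flag."""

    values: np.ndarray
    saturated: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int64)
        if v.shape != (FLAT_LENGTH,):
            raise InvalidInputError(
                f"quantized vector must have length {FLAT_LENGTH}"
            )
        if v.min() < -(2**15) or v.max() >= 2**15:
            raise InvalidInputError("quantized values must fit in signed 16 bits")
        if v[:_N_A4].min() < 0:
            raise InvalidInputError("A4 entries must be non-negative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class SortedIndexList:
    """Positions of the K retained coefficients in the flat W4 vector.

    Ordering: for K >= 12 all of A4 (0-11, natural order) first, then
    detail indices by non-increasing magnitude with ties broken by lowest
    index; for K < 12 the K largest-magnitude A4 positions, same ordering.
    """

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(idx) != len(set(idx)):
            raise InvalidInputError("duplicate indices in sorted index list")
        if idx and (min(idx) < 0 or max(idx) >= FLAT_LENGTH):
            raise InvalidInputError("indices must lie in [0, 144]")
        if len(idx) >= _N_A4 and set(range(_N_A4)) - set(idx):
            raise InvalidInputError("K >= 12 requires all A4 indices present")
        object.__setattr__(self, "indices", idx)

    @property
    def k(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class CompressedBlock:
    """The packed block: payload bytes plus the retained count K."""

    k: int
    payload: bytes

    def __post_init__(self) -> None:
        expected = bits_for_k(self.k)
        if len(self.payload) * 8 != expected:
            raise InvalidInputError(
                f"payload for k={self.k} must be {expected // 8} bytes, "
                f"got {len(self.payload)}"
            )

    @property
    def bit_count(self) -> int:
        return len(self.payload) * 8


def quantize(w: WaveletCoeffs | Sequence[float]) -> QuantizedCoeffs:
    """Cast float coefficients (0.01 µS units) to the stored integer ranges.

    Truncates toward zero, then clamps A4 to unsigned 12 bits and details
    to signed 8 bits; any clamping sets the ``saturated`` flag.
    """
    flat = w.flat if isinstance(w, WaveletCoeffs) else np.asarray(w, dtype=np.float64)
    if flat.shape != (FLAT_LENGTH,):
        raise InvalidInputError(f"expected {FLAT_LENGTH} coefficients")
    if not np.all(np.isfinite(flat)):
        raise InvalidInputError("non-finite wavelet coefficient")
    v = np.trunc(flat).astype(np.int64)
    clipped = v.copy()
    clipped[:_N_A4] = np.clip(v[:_N_A4], 0, A4_MAX)
    clipped[_N_A4:] = np.clip(v[_N_A4:], DETAIL_MIN, DETAIL_MAX)
    return QuantizedCoeffs(values=clipped, saturated=bool(np.any(clipped != v)))


def _rank_by_magnitude(values: np.ndarray, positions: np.ndarray) -> list[int]:
    # strict-greater scan semantics: larger |value| first, ties -> lowest index
    mags = np.abs(values[positions])
    order = np.lexsort((positions, -mags))
    return [int(positions[i]) for i in order]


def select_top_k(q: QuantizedCoeffs, k: int) -> SortedIndexList:
    """Indices of the k largest-magnitude coefficients.

    For k >= 12 the twelve A4 positions are force-included (in natural
    order) and the remaining k-12 slots go to the largest-magnitude detail
    coefficients; for k < 12 only A4 entries compete.  Equal magnitudes
    resolve to the lowest index, matching a strict-greater maximum scan.
    """
    if not isinstance(q, QuantizedCoeffs):
        raise InvalidInputError("select_top_k expects QuantizedCoeffs")
    if not 1 <= k <= FLAT_LENGTH:
        raise InvalidInputError(f"k must be in [1, {FLAT_LENGTH}], got {k}")
    v = q.values
    if k < _N_A4:
        ranked = _rank_by_magnitude(v, np.arange(_N_A4))
        return SortedIndexList(tuple(ranked[:k]))
    detail_rank = _rank_by_magnitude(v, np.arange(_N_A4, FLAT_LENGTH))
    return SortedIndexList(tuple(range(_N_A4)) + tuple(detail_rank[: k - _N_A4]))


def bits_for_k(k: int) -> int:
    """Payload size in bits of a block retaining k coefficients.

    k < 12: 16 bits per retained A4 entry.  k >= 12: 192 bits of A-words,
    one 16-bit value word per pair of the first min(k-12, 6) details, and
    one 16-bit extended word per detail beyond the sixth.  Always a
    multiple of 16 (the target is a 16-bit architecture).
    """
    if not isinstance(k, (int, np.integer)) or not 1 <= k <= FLAT_LENGTH:
        raise InvalidInputError(f"k must be an integer in [1, {FLAT_LENGTH}]")
    if k < _N_A4:
        return 16 * k
    packed = min(k - _N_A4, 6)
    return 192 + 16 * ((packed + 1) // 2) + 16 * max(0, k - 18)


def bitwidth_for_max(max_abs: float, signed: bool = False) -> tuple[float, int]:
    """(log2 of the maximum magnitude, minimum field width in bits).

    The width is ``ceil(log2(max))`` magnitude bits plus one sign bit when
    ``signed`` — the rule used to size the block's coefficient fields from
    a corpus of observed maxima.
    """
    if max_abs <= 0:
        raise InvalidInputError("maximum magnitude must be positive")
    log2max = float(np.log2(max_abs))
    return log2max, int(np.ceil(log2max)) + (1 if signed else 0)


def _split_addr(addr: int) -> tuple[int, int]:
    return addr & 0x0F, (addr >> 4) & 0x0F


def encode_block(q: QuantizedCoeffs, lsi: SortedIndexList) -> CompressedBlock:
    """Pack the retained coefficients into the bit-exact block layout."""
    if not isinstance(q, QuantizedCoeffs) or not isinstance(lsi, SortedIndexList):
        raise InvalidInputError("encode_block expects QuantizedCoeffs and SortedIndexList")
    k = lsi.k
    if k < 1:
        raise InvalidInputError("cannot encode an empty selection")
    v = q.values
    words: list[int] = []
    if k < _N_A4:
        for idx in lsi.indices:
            if idx >= _N_A4:
                raise InvalidInputError("k < 12 blocks may only retain A4 entries")
            words.append((int(v[idx]) << 4) | idx)
    else:
        details = [i for i in lsi.indices if i >= _N_A4]
        nibbles = [0] * _N_A4
        for j, idx in enumerate(details[:6]):
            lo, hi = _split_addr(idx)
            nibbles[2 * j] = lo
            nibbles[2 * j + 1] = hi
        for i in range(_N_A4):
            words.append((int(v[i]) << 4) | nibbles[i])
        packed = details[:6]
        for j in range(0, len(packed), 2):
            lo = int(v[packed[j]]) & 0xFF
            hi = (int(v[packed[j + 1]]) & 0xFF) if j + 1 < len(packed) else 0
            words.append((hi << 8) | lo)
        for idx in details[6:]:
            words.append(((int(v[idx]) & 0xFF) << 8) | idx)
    payload = struct.pack(f"<{len(words)}H", *words)
    return CompressedBlock(k=k, payload=payload)


def _sign8(byte: int) -> int:
    return byte - 256 if byte >= 128 else byte


def decode_block(b: CompressedBlock) -> QuantizedCoeffs:
    """Exact inverse of :func:`encode_block`; unset positions are zero."""
    if not isinstance(b, CompressedBlock):
        raise InvalidInputError("decode_block expects a CompressedBlock")
    k = b.k
    n_words = len(b.payload) // 2
    words = struct.unpack(f"<{n_words}H", b.payload)
    out = np.zeros(FLAT_LENGTH, dtype=np.int64)
    if k < _N_A4:
        seen: set[int] = set()
        for w in words:
            idx = w & 0x0F
            if idx >= _N_A4:
                raise CorruptBlockError(f"A4 position nibble {idx} out of range")
            if idx in seen:
                raise CorruptBlockError(f"duplicate A4 position {idx}")
            seen.add(idx)
            out[idx] = w >> 4
        return QuantizedCoeffs(values=out)
    a_words, rest = words[:_N_A4], words[_N_A4:]
    nibbles = [w & 0x0F for w in a_words]
    for i, w in enumerate(a_words):
        out[i] = w >> 4
    n_packed = min(k - _N_A4, 6)
    addrs = []
    for j in range(n_packed):
        addr = nibbles[2 * j] | (nibbles[2 * j + 1] << 4)
        if addr < _N_A4 or addr >= FLAT_LENGTH:
            raise CorruptBlockError(f"detail address {addr} out of range")
        if addr in addrs:
            raise CorruptBlockError(f"duplicate detail address {addr}")
        addrs.append(addr)
    n_value_words = (n_packed + 1) // 2
    if len(rest) != n_value_words + max(0, k - 18):
        raise CorruptBlockError("payload truncated")
    for j, addr in enumerate(addrs):
        w = rest[j // 2]
        byte = w & 0xFF if j % 2 == 0 else (w >> 8) & 0xFF
        out[addr] = _sign8(byte)
    for w in rest[n_value_words:]:
        addr = w & 0xFF
        if addr < _N_A4 or addr >= FLAT_LENGTH:
            raise CorruptBlockError(f"extended detail address {addr} out of range")
        if addr in addrs:
            raise CorruptBlockError(f"duplicate detail address {addr}")
        addrs.append(addr)
        out[addr] = _sign8((w >> 8) & 0xFF)
    return QuantizedCoeffs(values=out)


def compress_window(
    x: EdaWindow | Sequence[float], k: int, fb: FilterBank | None = None
) -> CompressedBlock:
    """µS window -> packed block: scale x100, ML-DWT, quantize, top-K, encode."""
    samples = x.samples if isinstance(x, EdaWindow) else np.asarray(x, dtype=np.float64)
    w = ml_dwt(samples * QUANT_SCALE, fb)
    q = quantize(w)
    return encode_block(q, select_top_k(q, k))


def decompress_window(b: CompressedBlock, fb: FilterBank | None = None) -> EdaWindow:
    """Packed block -> reconstructed µS window (inverse DWT, rescale /100)."""
    q = decode_block(b)
    w = WaveletCoeffs.from_flat(q.values.astype(np.float64))
    x = inverse_ml_dwt(w, fb) / QUANT_SCALE
    return EdaWindow(samples=np.clip(x, 0.0, None))


# -- container file -----------------------------------------------------------
#
# Little-endian; magic "EDW1"; then per block: uint32 t0 (seconds), uint8 k,
# payload bytes (length implied by k via bits_for_k).


def write_container(fh: BinaryIO, blocks: Iterable[tuple[int, CompressedBlock]]) -> int:
    """Write ``(t0_seconds, block)`` records; returns total payload bytes."""
    fh.write(CONTAINER_MAGIC)
    total = 0
    for t0, block in blocks:
        if not 0 <= int(t0) < 2**32:
            raise InvalidInputError("t0 must fit an unsigned 32-bit second count")
        fh.write(struct.pack("<IB", int(t0), block.k))
        fh.write(block.payload)
        total += len(block.payload)
    return total


def read_container(fh: BinaryIO) -> list[tuple[int, CompressedBlock]]:
    magic = fh.read(4)
    if magic != CONTAINER_MAGIC:
        raise CorruptBlockError(f"bad container magic {magic!r}")
    out: list[tuple[int, CompressedBlock]] = []
    while True:
        head = fh.read(5)
        if not head:
            break
        if len(head) != 5:
            raise CorruptBlockError("truncated record header")
        t0, k = struct.unpack("<IB", head)
        if not 1 <= k <= FLAT_LENGTH:
            raise CorruptBlockError(f"record k={k} out of range")
        n_bytes = bits_for_k(k) // 8
        payload = fh.read(n_bytes)
        if len(payload) != n_bytes:
            raise CorruptBlockError("truncated record payload")
        out.append((t0, CompressedBlock(k=k, payload=payload)))
    return out
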