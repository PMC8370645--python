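"""Spectral and temporal transforms shared by all privacy mechanisms.

The Fourier transform convention is the non-unitary one: the forward transform
is ``F_j = sum_t x_t exp(-2*pi*i*j*t/n)`` and the inverse carries the ``1/n``
factor, so Parseval's identity reads ``sum_j |F_j|^2 = n * sum_t |x_t|^2``.
This is the convention in which the Fourier-perturbation noise scale
``lambda = sqrt(n*k) * Delta_2 / epsilon`` is calibrated, and it matches
``numpy.fft`` defaults.

Noisy spectra lose conjugate symmetry, so the inverse transform returns the
real part of the complex inverse; for symmetric (noise-free) spectra this is
exact to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralVector",
    "ChunkPartition",
    "dft",
    "idft",
    "truncate_pad",
    "difference_transform",
    "cumulative_reconstruct",
    "chunk_partition",
    "chunk_split",
    "chunk_join",
]


def _as_signal(x, name: str = "x") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size < 1:
        raise ValueError(f"{name} must have length >= 1")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class SpectralVector:
    """A full-length complex spectrum of a real signal."""

    coefficients: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coefficients, dtype=complex)
        object.__setattr__(self, "coefficients", coeffs)
        if coeffs.ndim != 1 or coeffs.size != self.source_length:
            raise ValueError(
                f"coefficient length {coeffs.size} != source_length {self.source_length}"
            )
        if not np.all(np.isfinite(coeffs)):
            raise ValueError("spectral coefficients must be finite")


@dataclass(frozen=True)
class ChunkPartition:
    """Disjoint, contiguous half-open index intervals covering ``[0, n)``.

    All chunks have length ``chunk_size`` except possibly the last; signals
    are never padded to a multiple of the chunk size.
    """

    chunk_size: int
    boundaries: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        prev_end = 0
        for i, (start, end) in enumerate(self.boundaries):
            if start != prev_end or end <= start:
                raise ValueError("chunk boundaries must be contiguous and non-empty")
            if end - start > self.chunk_size:
                raise ValueError("chunk exceeds chunk_size")
            if end - start < self.chunk_size and i != len(self.boundaries) - 1:
                raise ValueError("only the final chunk may be shorter than chunk_size")
            prev_end = end

    @property
    def n(self) -> int:
        return self.boundaries[-1][1] if self.boundaries else 0

    def __len__(self) -> int:
        return len(self.boundaries)


def dft(x) -> SpectralVector:
    """Non-unitary forward discrete Fourier transform of a real signal."""
    arr = _as_signal(x)
    return SpectralVector(np.fft.fft(arr), arr.size)


def idft(spectrum: SpectralVector) -> np.ndarray:
    """Inverse DFT with ``1/n`` normalization; returns the real part."""
    return np.fft.ifft(spectrum.coefficients).real


def truncate_pad(spectrum: SpectralVector, k: int) -> SpectralVector:
    """Keep the first ``k`` coefficients (the ``k`` lowest frequencies), zero the rest."""
    n = spectrum.source_length
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= {n}, got {k}")
    out = np.zeros(n, dtype=complex)
    out[:k] = spectrum.coefficients[:k]
    return SpectralVector(out, n)


def difference_transform(x) -> np.ndarray:
    """Consecutive differences with the first element preserved.

    ``d[0] = x[0]``, ``d[t] = x[t] - x[t-1]``; exact inverse is
    :func:`cumulative_reconstruct`.
    """
    arr = _as_signal(x)
    out = np.empty_like(arr)
    out[0] = arr[0]
    out[1:] = np.diff(arr)
    return out


def cumulative_reconstruct(d) -> np.ndarray:
    """Prefix sums; exact inverse of :func:`difference_transform`."""
    arr = _as_signal(d, "d")
    return np.cumsum(arr)


def chunk_partition(n: int, chunk_size: int) -> ChunkPartition:
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    starts = range(0, n, chunk_size)
    bounds = tuple((s, min(s + chunk_size, n)) for s in starts)
    return ChunkPartition(chunk_size, bounds)


def chunk_split(x, chunk_size: int):
    """Split a signal into consecutive non-overlapping chunks.

    Returns ``(chunks, partition)`` with ``ceil(n / chunk_size)`` chunks whose
    concatenation reproduces the input.
    """
    arr = _as_signal(x)
    part = chunk_partition(arr.size, chunk_size)
    chunks = [arr[s:e] for s, e in part.boundaries]
    return chunks, part


def chunk_join(chunks) -> np.ndarray:
    if not chunks:
        raise ValueError("no chunks to join")
    return np.concatenate([np.asarray(c, dtype=float) for c in chunks])
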