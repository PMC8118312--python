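"""Incomplete periodic discrete-wavelet low-pass basis for daily activity series.

The smoother used throughout this package is an *incomplete* discrete wavelet
transform: of the full orthonormal periodized DWT of a length-``n`` daily
series, only the level-``level`` scaling (approximation) coefficients are
retained and all detail coefficients are discarded.  Writing the retained
synthesis vectors as the columns of a matrix ``Y`` (``n`` rows, ``K = n/2**level``
columns), the smoother is the orthogonal projection

    x_sm = Y @ Y.T @ x

which acts as a low-pass filter on the 24-hour count curve: rapid swings
between inactivity and activity bursts are removed while the circadian
envelope is preserved.  Because the DWT is periodized, the basis functions
are periodic with a period of one day, so the smoother treats midnight as an
ordinary instant — appropriate for circadian data.

The default configuration (``n=288`` five-minute epochs, Daubechies filter of
length 10, depth 4) yields 18 basis functions; a single level-1 function of
the d10 filter covers 10 epochs = 50 minutes of clock time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "WaveletBasis",
    "build_basis",
    "smooth",
    "coefficients",
    "filter_length_minutes",
]

# Naming convention of the classic R 'wavelets' package: the digit is the
# filter length in taps.  PyWavelets indexes Daubechies by vanishing moments
# (db5 has 10 taps), least-asymmetric by sym*, Coiflets by coif*.
_FILTER_ALIASES = {
    "d2": "haar",
    "d4": "db2",
    "d6": "db3",
    "d8": "db4",
    "d10": "db5",
    "d12": "db6",
    "d14": "db7",
    "d16": "db8",
    "d18": "db9",
    "d20": "db10",
    "la8": "sym4",
    "la10": "sym5",
    "la12": "sym6",
    "la16": "sym8",
    "la20": "sym10",
    "c6": "coif1",
    "c12": "coif2",
    "c18": "coif3",
    "c24": "coif4",
}

DEFAULT_N = 288
DEFAULT_FILTER = "d10"
DEFAULT_LEVEL = 4


def _resolve_wavelet(filter_name: str) -> pywt.Wavelet:
    name = _FILTER_ALIASES.get(filter_name.lower(), filter_name.lower())
    try:
        wavelet = pywt.Wavelet(name)
    except ValueError as exc:
        known = ", ".join(sorted(_FILTER_ALIASES))
        raise ValueError(
            f"unknown wavelet filter {filter_name!r}; use one of the "
            f"short names ({known}) or any orthogonal PyWavelets name"
        ) from exc
    if not wavelet.orthogonal:
        raise ValueError(
            f"filter {filter_name!r} is not orthogonal; the incomplete "
            "transform requires an orthonormal DWT"
        )
    return wavelet


@dataclass(frozen=True)
class WaveletBasis:
    """The retained low-pass synthesis matrix of a periodized DWT.

    Attributes
    ----------
    matrix
        ``(n, k)`` array whose orthonormal columns span the level-``level``
        scaling subspace.
    filter_name
        Filter identifier as requested (e.g. ``"d10"``).
    level
        Decomposition depth.
    n
        Series length (288 for a 5-minute daily grid).
    boundary
        Always ``"periodic"``: the basis functions have period one day.
    """

    matrix: np.ndarray
    filter_name: str = DEFAULT_FILTER
    level: int = DEFAULT_LEVEL
    n: int = DEFAULT_N
    boundary: str = "periodic"
    filter_taps: int = field(default=10)

    @property
    def k(self) -> int:
        """Number of retained basis functions (columns)."""
        return self.matrix.shape[1]

    def smooth(self, x: np.ndarray) -> np.ndarray:
        return smooth(x, self)

    def coefficients(self, x: np.ndarray) -> np.ndarray:
        return coefficients(x, self)

    @property
    def projector(self) -> np.ndarray:
        """The n-by-n projection matrix ``Y @ Y.T``."""
        return self.matrix @ self.matrix.T

    def to_csv(self, path) -> None:
        """Write the basis matrix as plain delimited text (one row per epoch)."""
        np.savetxt(path, self.matrix, delimiter=",")


def build_basis(
    n: int = DEFAULT_N,
    filter_name: str = DEFAULT_FILTER,
    level: int = DEFAULT_LEVEL,
) -> WaveletBasis:
    """Construct the incomplete periodic wavelet basis.

    The columns are the synthesis vectors of the level-``level`` scaling
    coefficients of the periodized orthonormal DWT, obtained by inverse
    transforming unit coefficient vectors.  For ``(288, "d10", 4)`` this is
    the 288x18 low-pass matrix.

    Parameters
    ----------
    n
        Series length; must be divisible by ``2**level``.
    filter_name
        Wavelet filter; default the 10-tap Daubechies ("d10").
    level
        Decomposition depth; ``k = n / 2**level`` functions are retained.

    Raises
    ------
    ValueError
        If ``n`` is not divisible by ``2**level``, the filter is unknown or
        not orthogonal, or the filter is longer than the series.
    """
    if level < 1:
        raise ValueError(f"level must be >= 1, got {level}")
    if n % (1 << level) != 0:
        raise ValueError(f"series length {n} is not divisible by 2**{level}")
    wavelet = _resolve_wavelet(filter_name)
    if wavelet.dec_len > n:
        raise ValueError(
            f"filter length {wavelet.dec_len} exceeds series length {n}"
        )
    k = n >> level
    template = pywt.wavedec(np.zeros(n), wavelet, mode="periodization", level=level)
    cols = np.empty((n, k))
    for j in range(k):
        coeffs = [np.zeros_like(c) for c in template]
        coeffs[0][j] = 1.0
        cols[:, j] = pywt.waverec(coeffs, wavelet, mode="periodization")
    return WaveletBasis(
        matrix=cols,
        filter_name=filter_name,
        level=level,
        n=n,
        filter_taps=wavelet.dec_len,
    )


def _check_length(x: np.ndarray, basis: WaveletBasis) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != basis.n:
        raise ValueError(
            f"series length {x.shape[-1]} does not match basis length {basis.n}"
        )
    return x


def smooth(x: np.ndarray, basis: WaveletBasis) -> np.ndarray:
    """Orthogonal projection of ``x`` onto the low-pass subspace (``Y Y^T x``)."""
    x = _check_length(x, basis)
    return (x @ basis.matrix) @ basis.matrix.T


def coefficients(x: np.ndarray, basis: WaveletBasis) -> np.ndarray:
    """Basis coordinates ``Y^T x``; ``smooth(x) = matrix @ coefficients(x)``."""
    x = _check_length(x, basis)
    return x @ basis.matrix


def filter_length_minutes(basis: WaveletBasis, epoch_minutes: float = 5.0) -> float:
    """Clock-time span of one level-1 wavelet function (taps x epoch length)."""
    return basis.filter_taps * epoch_minutes
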