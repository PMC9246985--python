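"""Offset-domain <-> fixed-size time-domain conversions for network I/O.

A CEST profile of N offsets (50 <= N <= 128 for training data) is turned into
the network input in four steps:

1. ``dip_transform``: max(I/I0) - I/I0, so dips become positive peaks and the
   profile resembles a simple NMR spectrum.
2. ``real_ft``: real (forward-normalized) Fourier transform; only the
   floor(N/2) + 1 non-redundant complex coefficients of the Hermitian
   spectrum are kept.
3. ``zero_fill``: append zeros up to exactly 65 complex points (the value
   forced by the 128-offset maximum), together with the uniform time axis
   t_k = k / SW, where SW is the offset span in Hz at the given field.
4. ``pack_input``: two real vectors of length 2 x 65 = 130 - real parts in
   slots 0-64 and imaginary parts in slots 65-129, and the time axis
   replicated into the same layout.

``upsample_to_offsets`` inverts the chain: an inverse real FT of the 65
complex points to exactly 128 real points, which is band-limited (sinc)
interpolation of the original profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import CESTProfile
from .scenarios import ValidationError

__all__ = [
    "PACKED_SIZE",
    "N_UPSAMPLED",
    "PackedTimeDomain",
    "dip_transform",
    "real_ft",
    "inverse_real_ft",
    "zero_fill",
    "pack_input",
    "unpack_input",
    "upsample_to_offsets",
    "trig_interpolate",
    "upsampled_grid",
    "pack_profile",
]

PACKED_SIZE = 65  # complex points after zero-fill (from the 128-offset maximum)
N_UPSAMPLED = 128  # offsets in the upsampled in-phase profile


@dataclass
class PackedTimeDomain:
    """Fixed-size time-domain representation: 65 complex points + time axis."""

    coefficients: np.ndarray  # complex, length 65
    times: np.ndarray  # seconds, length 65, t_0 = 0
    n_original: int  # offsets before zero-fill

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=complex)
        self.times = np.asarray(self.times, dtype=float)
        if self.coefficients.size != PACKED_SIZE or self.times.size != PACKED_SIZE:
            raise ValidationError("PackedTimeDomain must hold exactly 65 points")
        if np.any(np.diff(self.times) <= 0) or self.times[0] != 0.0:
            raise ValidationError("time axis must be strictly increasing from 0")


def dip_transform(intensities: np.ndarray) -> np.ndarray:
    """max(I/I0) - I/I0: dips become positive peaks, minimum exactly 0."""
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValidationError("empty profile")
    return np.max(x) - x


def real_ft(dip: np.ndarray) -> np.ndarray:
    """Forward-normalized real FT keeping the floor(N/2)+1 non-redundant points.

    For real input of length N the discrete Fourier transform is
    Hermitian-symmetric: N/2 - 1 points are redundant for even N and
    (N - 1)/2 for odd N, leaving floor(N/2) + 1 unique complex coefficients.
    """
    x = np.asarray(dip, dtype=float)
    if x.size < 2:
        raise ValidationError("real_ft needs at least 2 points")
    return np.fft.rfft(x, norm="forward")


def inverse_real_ft(coeffs: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`real_ft` for an original length ``n``."""
    return np.fft.irfft(np.asarray(coeffs, dtype=complex), n=n, norm="forward")


def zero_fill(
    td: np.ndarray, sweep_width_hz: float, n_original: int | None = None
) -> PackedTimeDomain:
    """Zero-fill a truncated time-domain vector to exactly 65 complex points.

    ``sweep_width_hz`` is the offset span in Hz; the time axis is
    t_k = k / SW.  ``n_original`` is the offset count before the real FT
    (defaults to the even length 2 * (len(td) - 1)).
    """
    td = np.asarray(td, dtype=complex)
    if td.size > PACKED_SIZE:
        raise ValidationError(
            f"time-domain input has {td.size} points > {PACKED_SIZE}; "
            "profiles are capped at 128 offsets"
        )
    if sweep_width_hz <= 0:
        raise ValidationError("sweep width must be positive")
    out = np.zeros(PACKED_SIZE, dtype=complex)
    out[: td.size] = td
    times = np.arange(PACKED_SIZE) / sweep_width_hz
    if n_original is None:
        n_original = 2 * (td.size - 1)
    return PackedTimeDomain(out, times, int(n_original))


def pack_input(ptd: PackedTimeDomain) -> tuple[np.ndarray, np.ndarray]:
    """Two 130-vectors: [Re(c_0) | Im(c_0)] and the aligned time points."""
    vec = np.concatenate([ptd.coefficients.real, ptd.coefficients.imag])
    tvec = np.concatenate([ptd.times, ptd.times])
    return vec, tvec


def unpack_input(vec: np.ndarray, tvec: np.ndarray, n_original: int) -> PackedTimeDomain:
    """Inverse of :func:`pack_input`."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != 2 * PACKED_SIZE:
        raise ValidationError("packed vector must have length 130")
    coeffs = vec[:PACKED_SIZE] + 1j * vec[PACKED_SIZE:]
    return PackedTimeDomain(coeffs, np.asarray(tvec)[:PACKED_SIZE], n_original)


def upsample_to_offsets(td65: np.ndarray, n_original: int | None = None) -> np.ndarray:
    """Inverse real FT of 65 complex points to exactly 128 real offsets.

    With forward-normalized coefficients this is band-limited (sinc)
    interpolation onto 128 points spanning the original offset range; an
    input originally sampled at 128 points round-trips exactly.  For even
    original lengths below 128 the (real) Nyquist coefficient is halved, the
    standard spectral-interpolation convention that keeps the interpolant
    real and exact on band-limited profiles.
    """
    c = np.asarray(td65, dtype=complex).copy()
    if c.size != PACKED_SIZE:
        raise ValidationError("expected exactly 65 complex points")
    if n_original is not None and n_original % 2 == 0 and n_original < 2 * (PACKED_SIZE - 1):
        c[n_original // 2] *= 0.5
    return np.fft.irfft(c, n=N_UPSAMPLED, norm="forward")


def trig_interpolate(values: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Evaluate the band-limited interpolant of uniform samples at fractional indices.

    ``values`` are N uniform samples (period N in index units); ``positions``
    are fractional sample indices.  Used to compare an upsampled profile with
    the original grid, which is generally incommensurate with 128 points.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    c = np.fft.rfft(x, norm="forward")
    if n % 2 == 0:
        c[-1] *= 0.5
    k = np.arange(c.size)
    phases = np.exp(2j * np.pi * np.outer(np.asarray(positions, dtype=float), k) / n)
    weights = np.where(k == 0, 1.0, 2.0)
    return (phases * weights * c).real.sum(axis=1)


def upsampled_grid(offset_min: float, span: float, n_original: int) -> np.ndarray:
    """Offset positions (ppm) of the 128-point upsampled profile.

    The N original offsets are uniform samples with step span/(N-1) and DFT
    period N*step; the inverse FT therefore lands on 128 uniform samples of
    that period starting at the first offset.
    """
    step = span / (n_original - 1)
    return offset_min + np.arange(N_UPSAMPLED) * (n_original * step) / N_UPSAMPLED


def pack_profile(profile: CESTProfile, larmor_mhz: float) -> PackedTimeDomain:
    """Full chain dip_transform -> real_ft -> zero_fill for one profile."""
    dip = dip_transform(profile.intensities)
    td = real_ft(dip)
    sw_hz = profile.span * larmor_mhz
    return zero_fill(td, sw_hz, n_original=profile.n_offsets)
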