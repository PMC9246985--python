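"""CEST profile container and plain-text I/O.

Profiles are stored as whitespace- or comma-separated columns
``offset  intensity  [error]`` with ``#``-prefixed header lines carrying
acquisition metadata, e.g.::

    # b0_T: 18.8
    # b1_Hz: 30.0
    # t_ex_s: 0.4
    # phase: ap
    # units: ppm

Offsets may be given in Hz (``units: Hz``), in which case a ``b0_T`` header is
required to convert them to ppm.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .scenarios import ValidationError, larmor_MHz

__all__ = ["CESTProfile", "read_profile", "write_profile"]


@dataclass
class CESTProfile:
    """A vector of (offset, I/I0) pairs tagged anti-phase or in-phase."""

    offsets: np.ndarray  # ppm
    intensities: np.ndarray  # I/I0
    phase: str = "ap"  # "ap" | "ip"
    provenance: str = "simulated"  # "simulated" | "experimental"
    noise: float = 0.0  # gaussian sigma as a fraction of max intensity
    meta: dict = field(default_factory=dict)  # b0, b1, t_ex, ...

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.offsets.shape != self.intensities.shape:
            raise ValidationError("offsets and intensities must have equal length")
        if self.phase not in ("ap", "ip"):
            raise ValidationError(f"unknown phase tag {self.phase!r}")

    @property
    def n_offsets(self) -> int:
        return self.offsets.size

    @property
    def offset_min(self) -> float:
        return float(self.offsets.min())

    @property
    def span(self) -> float:
        return float(self.offsets.max() - self.offsets.min())


_META_KEYS = {"b0": "b0_T", "b1": "b1_Hz", "t_ex": "t_ex_s", "d1": "d1_s"}


def write_profile(profile: CESTProfile, path: str | Path) -> None:
    """Write a profile as commented plain text (offsets in ppm)."""
    lines = []
    for key, label in _META_KEYS.items():
        if key in profile.meta:
            lines.append(f"# {label}: {profile.meta[key]:.6g}")
    lines.append(f"# phase: {profile.phase}")
    lines.append(f"# provenance: {profile.provenance}")
    lines.append(f"# noise: {profile.noise:.6g}")
    lines.append("# units: ppm")
    for off, inten in zip(profile.offsets, profile.intensities):
        lines.append(f"{off:.10f} {inten:.12e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path) -> CESTProfile:
    """Read a plain-text profile; Hz offsets are converted to ppm via b0."""
    meta: dict = {}
    phase = "ap"
    provenance = "experimental"
    noise = 0.0
    units = "ppm"
    offsets, intensities = [], []
    label_to_key = {v: k for k, v in _META_KEYS.items()}
    text = Path(path).read_text()
    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key, val = key.strip(), val.strip()
                if key in label_to_key:
                    meta[label_to_key[key]] = float(val)
                elif key == "phase":
                    phase = val
                elif key == "provenance":
                    provenance = val
                elif key == "noise":
                    noise = float(val)
                elif key == "units":
                    units = val
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ValidationError(f"{path}:{lineno}: expected 'offset intensity', got {line!r}")
        try:
            offsets.append(float(parts[0]))
            intensities.append(float(parts[1]))
        except ValueError as err:
            raise ValidationError(f"{path}:{lineno}: malformed row {line!r}") from err
    offs = np.array(offsets)
    if units.lower() == "hz":
        if "b0" not in meta:
            raise ValidationError(f"{path}: offsets in Hz require a 'b0_T' header")
        offs = offs / larmor_MHz(meta["b0"])
    return CESTProfile(offs, np.array(intensities), phase=phase,
                       provenance=provenance, noise=noise, meta=meta)
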