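"""The :class:`Spectrum` container: one wavenumber-indexed intensity trace.

A spectrum carries its acquisition provenance (``sample_id``, ``map_id``) and a
set of monotone processing-state flags.  Stage functions never mutate their
input; they return a new ``Spectrum`` with the corresponding flag set, so a
flag, once set, is never unset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError, GridMismatchError


@dataclass
class Spectrum:
    """One intensity trace on an ascending wavenumber grid (cm^-1)."""

    wavenumber: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    map_id: int = 0
    despiked: bool = False
    smoothed: bool = False
    baseline_corrected: bool = False
    snv_normalized: bool = False
    n_averaged: int = 1

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.ndim != 1 or self.intensity.ndim != 1:
            raise FormatError("wavenumber and intensity must be 1-D")
        if self.wavenumber.size != self.intensity.size:
            raise FormatError(
                f"grid length {self.wavenumber.size} != intensity length "
                f"{self.intensity.size} for trace ({self.sample_id}, {self.map_id})"
            )
        if self.wavenumber.size and np.any(np.diff(self.wavenumber) <= 0):
            raise FormatError(
                f"wavenumber grid not strictly ascending for trace "
                f"({self.sample_id}, {self.map_id})"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise FormatError(
                f"non-finite intensity in trace ({self.sample_id}, {self.map_id})"
            )

    def __len__(self) -> int:
        return self.wavenumber.size

    def with_intensity(self, intensity: np.ndarray, **flags) -> "Spectrum":
        """New spectrum with replaced intensities and updated state flags."""
        out = replace(self, intensity=np.asarray(intensity, dtype=float))
        for name, value in flags.items():
            setattr(out, name, value)
        return out

    @property
    def state(self) -> tuple[bool, bool, bool, bool]:
        return (
            self.despiked,
            self.smoothed,
            self.baseline_corrected,
            self.snv_normalized,
        )


def check_common_grid(spectra) -> np.ndarray:
    """Return the shared grid; raise :class:`GridMismatchError` naming the
    first trace that deviates from it."""
    spectra = list(spectra)
    if not spectra:
        raise FormatError("no spectra given")
    grid = spectra[0].wavenumber
    for s in spectra[1:]:
        if s.wavenumber.size != grid.size or not np.allclose(
            s.wavenumber, grid, rtol=0, atol=1e-9
        ):
            raise GridMismatchError(
                f"trace ({s.sample_id}, {s.map_id}) is not on the common grid "
                f"of trace ({spectra[0].sample_id}, {spectra[0].map_id})"
            )
    return grid
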