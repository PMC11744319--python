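"""Spectral data model and algebra.

Spectra (irradiance, reflectance, transmittance, sensitivity) are sampled on a
uniform wavelength grid; the session default is 300-750 nm at 1 nm, the span of
stomatopod spectral sensitivity.  All pipeline arithmetic (filter stacking,
illuminant filtering, quantum-catch integration) happens pointwise on a shared
grid, so every spectrum is resampled on load: linear interpolation inside the
measured range, zero outside it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

SPECTRUM_KINDS = ("irradiance", "reflectance", "transmittance", "sensitivity")

#: kinds whose values are physically bounded to [0, 1]
_BOUNDED_KINDS = ("reflectance", "transmittance")

#: plausible wavelength range for input files (nm)
_WL_MIN, _WL_MAX = 200.0, 900.0


class SpectrumError(ValueError):
    """Malformed spectral data or incompatible grids."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid ``start, start+step, ..., stop`` (nm, inclusive)."""

    start: float = 300.0
    stop: float = 750.0
    step: float = 1.0

    def __post_init__(self):
        if not self.start < self.stop:
            raise SpectrumError(f"grid start ({self.start}) must be < stop ({self.stop})")
        if self.step <= 0:
            raise SpectrumError(f"grid step must be positive, got {self.step}")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1


#: session default grid
DEFAULT_GRID = WavelengthGrid(300.0, 750.0, 1.0)


@dataclass(frozen=True)
class Spectrum:
    """A sampled function of wavelength on a :class:`WavelengthGrid`.

    Parameters
    ----------
    grid
        Sampling grid.
    values
        Non-negative values, one per grid point.  Reflectance and
        transmittance are additionally clipped into [0, 1] (with a warning)
        since values outside that range can only be measurement noise.
    kind
        One of ``irradiance``, ``reflectance``, ``transmittance``,
        ``sensitivity``.
    units
        Free-text unit label; irradiance is treated throughout as a photon
        number distribution (quantal units), as quantum-catch integration
        requires.
    provenance
        Optional free-text record of the source (file path, original range).
    """

    grid: WavelengthGrid
    values: np.ndarray
    kind: str
    units: str = ""
    provenance: str = ""

    def __post_init__(self):
        if self.kind not in SPECTRUM_KINDS:
            raise SpectrumError(f"unknown spectrum kind {self.kind!r}; expected one of {SPECTRUM_KINDS}")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or len(vals) != len(self.grid):
            raise SpectrumError(
                f"values length {vals.shape} does not match grid length {len(self.grid)}"
            )
        if np.any(~np.isfinite(vals)):
            raise SpectrumError("spectrum contains non-finite values")
        if np.any(vals < 0):
            if self.kind in _BOUNDED_KINDS or np.min(vals) > -1e-9:
                logger.warning("clipping %d negative %s values to 0", int(np.sum(vals < 0)), self.kind)
                vals = np.clip(vals, 0.0, None)
            else:
                raise SpectrumError(f"{self.kind} spectrum has negative values (min {vals.min():g})")
        if self.kind in _BOUNDED_KINDS and np.any(vals > 1.0):
            logger.warning("clipping %d %s values > 1 to 1", int(np.sum(vals > 1.0)), self.kind)
            vals = np.clip(vals, None, 1.0)
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "Spectrum":
        return replace(self, values=np.asarray(values, dtype=float), kind=kind or self.kind)

    def __mul__(self, other):
        if isinstance(other, Spectrum):
            _require_common_grid(self, other)
            kind = self.kind if other.kind == "transmittance" else other.kind
            return self.with_values(self.values * other.values, kind=kind)
        return self.with_values(self.values * float(other))

    __rmul__ = __mul__


def _require_common_grid(*spectra: Spectrum) -> None:
    g0 = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != g0:
            raise SpectrumError(
                f"grid mismatch ({s.grid} vs {g0}); resample spectra onto a common grid first"
            )


@dataclass(frozen=True)
class FilterSpec:
    """A physical filter: per-layer transmittance plus a layer count.

    Stacked identical layers obey Beer-Lambert attenuation, so the effective
    transmittance is the single-layer curve raised to ``layers`` — this is how
    the double-layered tent filters are represented.
    """

    name: str
    transmittance: Spectrum
    layers: int = 1

    def __post_init__(self):
        if self.transmittance.kind != "transmittance":
            raise SpectrumError(f"filter {self.name!r} needs a transmittance spectrum")
        if self.layers < 1:
            raise SpectrumError(f"filter {self.name!r}: layers must be >= 1")

    def effective(self) -> Spectrum:
        """Effective transmittance of the full stack."""
        return self.transmittance.with_values(self.transmittance.values ** self.layers)


def resample(s: Spectrum, grid: WavelengthGrid) -> Spectrum:
    """Resample onto ``grid``: linear interpolation inside the source range,
    zero-fill outside it; kind preserved."""
    if len(s.grid) < 2:
        raise SpectrumError("cannot interpolate a single-point spectrum")
    if s.grid == grid:
        return s
    vals = np.interp(grid.wavelengths, s.wavelengths, s.values, left=0.0, right=0.0)
    return Spectrum(grid, vals, s.kind, s.units, s.provenance)


def combine_filters(filters: list[FilterSpec], grid: WavelengthGrid | None = None) -> Spectrum:
    """Pointwise product of effective filter transmittances.

    An empty list yields the identity (unit) filter.  If ``grid`` is given the
    result (and inputs) are resampled onto it; otherwise all filters must
    already share a grid.
    """
    if not filters:
        g = grid or DEFAULT_GRID
        return Spectrum(g, np.ones(len(g)), "transmittance", units="dimensionless")
    effs = [f.effective() for f in filters]
    if grid is not None:
        effs = [resample(e, grid) for e in effs]
    _require_common_grid(*effs)
    vals = np.ones(len(effs[0].grid))
    for e in effs:
        vals *= e.values
    return Spectrum(effs[0].grid, vals, "transmittance", units="dimensionless",
                    provenance="*".join(f.name for f in filters))


def apply_illuminant_filter(illuminant: Spectrum, filt: Spectrum | FilterSpec) -> Spectrum:
    """Irradiance transmitted through a filter (pointwise product)."""
    if isinstance(filt, FilterSpec):
        filt = filt.effective()
    if illuminant.kind != "irradiance":
        raise SpectrumError(f"expected an irradiance spectrum, got kind={illuminant.kind!r}")
    if filt.kind != "transmittance":
        raise SpectrumError(f"expected a transmittance spectrum, got kind={filt.kind!r}")
    _require_common_grid(illuminant, filt)
    return illuminant.with_values(illuminant.values * filt.values)


# ---------------------------------------------------------------------------
# File I/O: two-column CSV, `wavelength_nm,value`, optional one header line.


def read_spectrum(path, kind: str, grid: WavelengthGrid | None = None) -> Spectrum:
    """Read a two-column (wavelength nm, value) CSV and resample onto ``grid``
    (session default if omitted)."""
    grid = grid or DEFAULT_GRID
    wl, vals = [], []
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise SpectrumError(f"{path}: empty spectrum file")
    start = 0
    first = lines[0].split(",")
    try:
        float(first[0])
    except ValueError:
        start = 1  # tolerate one header line
    if start == len(lines):
        raise SpectrumError(f"{path}: no data rows")
    for i, ln in enumerate(lines[start:], start=start + 1):
        parts = ln.split(",")
        if len(parts) < 2:
            raise SpectrumError(f"{path}: line {i}: expected two comma-separated columns")
        try:
            w, v = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise SpectrumError(f"{path}: line {i}: non-numeric row {ln!r}") from exc
        if not (_WL_MIN <= w <= _WL_MAX):
            raise SpectrumError(f"{path}: line {i}: wavelength {w} nm outside {_WL_MIN}-{_WL_MAX} nm")
        wl.append(w)
        vals.append(v)
    wl = np.asarray(wl)
    if np.any(np.diff(wl) <= 0):
        raise SpectrumError(f"{path}: wavelengths must be strictly increasing")
    if len(wl) == 1:
        raise SpectrumError(f"{path}: single-point spectrum cannot be interpolated")
    # interpolate directly from the native (possibly non-uniform) samples
    out = np.interp(grid.wavelengths, wl, np.asarray(vals, dtype=float), left=0.0, right=0.0)
    return Spectrum(grid, out, kind, provenance=f"{path} [{wl[0]:g}-{wl[-1]:g} nm]")


def write_spectrum(s: Spectrum, path) -> None:
    """Write `wavelength_nm,value` CSV at 6 significant digits."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("wavelength_nm,value\n")
        for w, v in zip(s.wavelengths, s.values):
            fh.write(f"{w:g},{v:.6g}\n")
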