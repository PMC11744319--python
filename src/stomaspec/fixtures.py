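"""Synthetic spectral fixtures emulating the grey-card experiment's optics.

The study's measured spectra (shallow-water daylight, LEE colour filters,
neutral-density filters, cable-tie stimuli) are not published as tables, so
this module generates smooth stand-ins with the stated passbands:

* stimulus colour filters — blue 360-550 nm, green 500-560 nm, red >610 nm;
* illumination tent filters — blue 360-590 nm, green 450-600 nm, red >590 nm;
* neutral-density filters of optical density 0.15 / 0.3 / 0.6 / 0.9
  (transmittance 10**-OD), optionally with the documented long-wavelength
  leak above ~680 nm where the real ND gels stop attenuating;
* a smooth, strictly positive daylight irradiance peaking in the blue-green.

Band edges use logistic shoulders, >= 0.9 transmittance deep in the passband
and <= 0.01 beyond three softness widths outside it.  Double-layer tents are
expressed through FilterSpec(layers=2), i.e. the single-layer curve squared.
"""

from __future__ import annotations

import math

import numpy as np

from .spectral import DEFAULT_GRID, FilterSpec, Spectrum, WavelengthGrid

#: stated passbands (nm) of the stimulus colour filters
STIMULUS_BANDS = {"blue": (360.0, 550.0), "green": (500.0, 560.0), "red": (610.0, math.inf)}

#: stated passbands (nm) of the illumination tent filters
TENT_BANDS = {"blue": (360.0, 590.0), "green": (450.0, 600.0), "red": (590.0, math.inf)}

#: optical densities of the grey (ND) stimuli and tents
ND_LEVELS = (0.15, 0.3, 0.6, 0.9)

#: the six distractor OD combinations used in testing
DISTRACTOR_COMBINATIONS = (
    (0.15, 0.3), (0.15, 0.6), (0.15, 0.9), (0.3, 0.6), (0.3, 0.9), (0.6, 0.9),
)

#: white plastic base reflectance of the cable-tie stimuli
WHITE_BASE = 0.9

#: peak single-layer transmittance of the synthetic gels
PEAK_TRANSMITTANCE = 0.95

#: logistic steepness so that T <= 0.01 three softness widths outside the band
_EDGE_GAIN = 1.6


def make_illuminant_daylight(grid: WavelengthGrid | None = None,
                             peak_nm: float = 490.0, width: float = 0.22) -> Spectrum:
    """Smooth shallow-water daylight stand-in: log-normal hump, unit peak.

    Strictly positive on the whole grid (the log-normal never reaches zero),
    peaking in the blue-green as downwelling light does at a few metres depth.
    Deterministic — no randomness enters the spectral fixtures.
    """
    grid = grid or DEFAULT_GRID
    wl = grid.wavelengths
    vals = np.exp(-0.5 * (np.log(wl / peak_nm) / width) ** 2)
    return Spectrum(grid, vals / vals.max(), "irradiance",
                    units="photons (relative)", provenance="synthetic daylight")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def make_bandpass_filter(low_nm: float, high_nm: float, softness_nm: float = 8.0,
                         grid: WavelengthGrid | None = None, name: str = "bandpass",
                         layers: int = 1) -> FilterSpec:
    """Band-pass (or long-pass, ``high_nm=inf``) gel with logistic edges."""
    if softness_nm <= 0:
        raise ValueError(f"edge softness must be positive, got {softness_nm}")
    if not low_nm < high_nm:
        raise ValueError(f"low edge {low_nm} must be below high edge {high_nm}")
    grid = grid or DEFAULT_GRID
    wl = grid.wavelengths
    t = _logistic(_EDGE_GAIN * (wl - low_nm) / softness_nm)
    if math.isfinite(high_nm):
        t = t * _logistic(_EDGE_GAIN * (high_nm - wl) / softness_nm)
    spec = Spectrum(grid, PEAK_TRANSMITTANCE * t, "transmittance",
                    provenance=f"synthetic band {low_nm:g}-{high_nm:g} nm")
    return FilterSpec(name, spec, layers=layers)


def make_nd_filter(od: float, red_leak: bool = False,
                   grid: WavelengthGrid | None = None,
                   leak_onset_nm: float = 680.0, leak_ceiling: float = 0.8,
                   name: str | None = None) -> FilterSpec:
    """Neutral-density gel: flat transmittance 10**(-OD).

    With ``red_leak`` the transmittance rises smoothly above ``leak_onset_nm``
    toward ``leak_ceiling``, emulating the real gels' failure to attenuate
    long wavelengths (the reason the red-group ND tent tests were abandoned).
    """
    if od < 0:
        raise ValueError(f"optical density must be >= 0, got {od}")
    grid = grid or DEFAULT_GRID
    wl = grid.wavelengths
    base = 10.0 ** (-od)
    vals = np.full(len(grid), base)
    if red_leak and od > 0:
        rise = _logistic((wl - (leak_onset_nm + 20.0)) / 12.0)
        vals = base + (max(leak_ceiling, base) - base) * rise
    spec = Spectrum(grid, vals, "transmittance",
                    provenance=f"synthetic ND OD={od:g}{' leak' if red_leak else ''}")
    return FilterSpec(name or f"ND{od:g}", spec)


def make_reflectance(kind, grid: WavelengthGrid | None = None,
                     red_leak: bool = False) -> Spectrum:
    """Stimulus reflectance: a colour name or a grey optical density.

    Colour stimuli are the white cable-tie base (flat 0.9) seen through the
    corresponding stimulus colour filter; greys are the base attenuated by an
    ND filter, 0.9 * 10**(-OD), optionally with the long-wavelength leak.
    """
    grid = grid or DEFAULT_GRID
    if isinstance(kind, str):
        if kind not in STIMULUS_BANDS:
            raise ValueError(f"unknown stimulus kind {kind!r}; "
                             f"expected a colour in {sorted(STIMULUS_BANDS)} or a grey OD")
        low, high = STIMULUS_BANDS[kind]
        filt = make_bandpass_filter(low, high, grid=grid, name=f"{kind}-stimulus")
        vals = WHITE_BASE * filt.effective().values
        return Spectrum(grid, vals, "reflectance", provenance=f"synthetic {kind} stimulus")
    od = float(kind)
    filt = make_nd_filter(od, red_leak=red_leak, grid=grid)
    vals = WHITE_BASE * filt.effective().values
    return Spectrum(grid, vals, "reflectance", provenance=f"synthetic grey OD={od:g}")


def make_tent_filter(colour: str, layers: int = 1,
                     grid: WavelengthGrid | None = None) -> FilterSpec:
    """Illumination tent gel for one colour group (``layers=2`` = dim double tent)."""
    if colour not in TENT_BANDS:
        raise ValueError(f"unknown tent colour {colour!r}")
    low, high = TENT_BANDS[colour]
    return make_bandpass_filter(low, high, grid=grid, name=f"{colour}-tent", layers=layers)


def spectral_library(grid: WavelengthGrid | None = None, red_leak: bool = False) -> dict:
    """The full fixture set keyed for the pipeline.

    Returns a dict with ``illuminants`` (natural + each tent single/double +
    ND tents), ``reflectances`` (three colours + four greys) and ``filters``.
    """
    from .spectral import apply_illuminant_filter

    grid = grid or DEFAULT_GRID
    daylight = make_illuminant_daylight(grid)
    filters: dict[str, FilterSpec] = {}
    illuminants: dict[str, Spectrum] = {"natural": daylight}
    for colour in TENT_BANDS:
        for layers, tag in ((1, "tent"), (2, "tent2")):
            f = make_tent_filter(colour, layers=layers, grid=grid)
            filters[f"{colour}-{tag}"] = f
            illuminants[f"{colour}-{tag}"] = apply_illuminant_filter(daylight, f)
    for od in ND_LEVELS[1:]:  # ND tents used 0.3/0.6/0.9
        f = make_nd_filter(od, red_leak=red_leak, grid=grid, name=f"ND{od:g}-tent")
        filters[f"nd{od:g}-tent"] = f
        illuminants[f"nd{od:g}-tent"] = apply_illuminant_filter(daylight, f)
    reflectances = {c: make_reflectance(c, grid) for c in STIMULUS_BANDS}
    reflectances.update({f"grey{od:g}": make_reflectance(od, grid, red_leak=red_leak)
                         for od in ND_LEVELS})
    return {"grid": grid, "illuminants": illuminants,
            "reflectances": reflectances, "filters": filters}
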