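"""The 12-channel midband receptor set.

Stomatopod colour vision uses midband rows 1-4, each row stacking a UV R8 cell
over a distal (R1, R4, R5) and a proximal (R2, R3, R6, R7) tier of the main
rhabdom.  Each of the 12 resulting photoreceptor classes has its own spectral
sensitivity; within a row the distal tier peaks at a shorter wavelength than
the proximal one, and the (distal, proximal) pair of each row forms a putative
dichromatic opponent channel.

Sensitivities come either from user-supplied curves (two-column CSV) or from a
single-parameter A1 visual-pigment absorbance template (Govardovskii et al.
2000, alpha band only).  The packaged default lambda-max table is a documented
placeholder — the species' measured sensitivities are not published in tabular
form — and spans ~400-700 nm across rows 1-4 with row 3 long-wavelength only,
mirroring the qualitative layout reported for gonodactyloid stomatopods.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .spectral import DEFAULT_GRID, Spectrum, WavelengthGrid, read_spectrum

TIERS = ("R8", "distal", "proximal")
ROWS = (1, 2, 3, 4)

#: placeholder peak sensitivities (nm); overridable via config — not measured values
DEFAULT_LAMBDA_MAX = {
    (1, "R8"): 315.0, (1, "distal"): 420.0, (1, "proximal"): 450.0,
    (2, "R8"): 330.0, (2, "distal"): 460.0, (2, "proximal"): 520.0,
    (3, "R8"): 345.0, (3, "distal"): 570.0, (3, "proximal"): 690.0,
    (4, "R8"): 380.0, (4, "distal"): 535.0, (4, "proximal"): 575.0,
}


class RetinaConfigError(ValueError):
    """Inconsistent or incomplete retina configuration."""


def pigment_template(lambda_max: float, grid: WavelengthGrid | None = None) -> Spectrum:
    """A1 visual-pigment absorbance template (alpha band), peak-normalized.

    Uses the Govardovskii (2000) rhodopsin alpha-band form

        S(x) = 1 / (exp[A(a - x)] + exp[B(b - x)] + exp[C(c - x)] + D),

    with x = lambda_max / lambda.  The beta (UV) band is omitted: it adds
    short-wave mass irrelevant to the 400-750 nm opponency analyses.
    """
    grid = grid or DEFAULT_GRID
    if not (300.0 <= lambda_max <= 750.0):
        raise RetinaConfigError(f"lambda_max {lambda_max} nm outside the 300-750 nm template domain")
    if not (grid.start <= lambda_max <= grid.stop):
        raise RetinaConfigError(f"lambda_max {lambda_max} nm outside grid {grid.start}-{grid.stop} nm")
    vals = template_values(lambda_max, grid.wavelengths)
    return Spectrum(grid, vals / vals.max(), "sensitivity", units="dimensionless",
                    provenance=f"A1 template lmax={lambda_max:g}nm")


def template_values(lambda_max: float, wavelengths) -> np.ndarray:
    """Un-normalized alpha-band template evaluated at arbitrary wavelengths."""
    x = lambda_max / np.asarray(wavelengths, dtype=float)
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    b, c = 0.922, 1.104
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    with np.errstate(over="ignore"):
        s = 1.0 / (np.exp(A * (a - x)) + np.exp(B * (b - x)) + np.exp(C * (c - x)) + D)
    return s


@dataclass(frozen=True)
class ChannelSpec:
    """One photoreceptor class: its midband row, tier and peak-1 sensitivity."""

    row: int
    tier: str
    label: str
    sensitivity: Spectrum
    lambda_max: float | None = None

    def __post_init__(self):
        if self.row not in ROWS:
            raise RetinaConfigError(f"channel {self.label!r}: row must be 1-4, got {self.row}")
        if self.tier not in TIERS:
            raise RetinaConfigError(f"channel {self.label!r}: tier must be one of {TIERS}")
        if self.sensitivity.kind != "sensitivity":
            raise RetinaConfigError(f"channel {self.label!r}: spectrum kind must be 'sensitivity'")
        if not np.isclose(self.sensitivity.values.max(), 1.0):
            raise RetinaConfigError(f"channel {self.label!r}: sensitivity must be peak-normalized to 1")


def default_label(row: int, tier: str) -> str:
    """Field-convention label: R8 row n -> 'R8-n'; tiers -> 'R{row}{D|P}' (e.g. R2P)."""
    if tier == "R8":
        return f"R8-{row}"
    return f"R{row}{'D' if tier == 'distal' else 'P'}"


@dataclass(frozen=True)
class RetinaModel:
    """The 12-channel receptor set with per-row opponent (distal, proximal) pairs."""

    channels: tuple[ChannelSpec, ...]
    grid: WavelengthGrid

    def __post_init__(self):
        seen = {}
        for ch in self.channels:
            key = (ch.row, ch.tier)
            if key in seen:
                raise RetinaConfigError(f"duplicate channel for row {ch.row} tier {ch.tier}")
            seen[key] = ch
        missing = [(r, t) for r in ROWS for t in TIERS if (r, t) not in seen]
        if missing:
            raise RetinaConfigError(f"missing channels: {missing}")
        labels = [ch.label for ch in self.channels]
        if len(set(labels)) != len(labels):
            raise RetinaConfigError("channel labels must be unique")
        for r in ROWS:
            d, p = seen[(r, "distal")], seen[(r, "proximal")]
            if d.lambda_max is not None and p.lambda_max is not None and d.lambda_max >= p.lambda_max:
                raise RetinaConfigError(
                    f"row {r}: distal lambda_max ({d.lambda_max}) must be < proximal ({p.lambda_max})"
                )

    def channel(self, label_or_key) -> ChannelSpec:
        if isinstance(label_or_key, tuple):
            row, tier = label_or_key
            return next(ch for ch in self.channels if ch.row == row and ch.tier == tier)
        for ch in self.channels:
            if ch.label == label_or_key:
                return ch
        raise KeyError(f"no channel {label_or_key!r}")

    @property
    def opponent_pairs(self) -> dict[int, tuple[ChannelSpec, ChannelSpec]]:
        """Row -> (distal, proximal) opponent channel pair (R8 excluded)."""
        return {r: (self.channel((r, "distal")), self.channel((r, "proximal"))) for r in ROWS}

    @property
    def labels(self) -> list[str]:
        return [ch.label for ch in self.channels]


def build_retina(config: dict | str | Path | None = None,
                 grid: WavelengthGrid | None = None,
                 base_dir: Path | None = None) -> RetinaModel:
    """Build a :class:`RetinaModel` from a config mapping or YAML file.

    ``config`` lists 12 channels, each with ``row``, ``tier`` and either
    ``lambda_max_nm`` (template sensitivity) or ``sensitivity_file`` (CSV,
    re-normalized to peak 1).  ``None`` loads the packaged placeholder table.
    """
    grid = grid or DEFAULT_GRID
    if config is None:
        config = {"channels": [
            {"row": r, "tier": t, "lambda_max_nm": DEFAULT_LAMBDA_MAX[(r, t)]}
            for r in ROWS for t in TIERS
        ]}
    if isinstance(config, (str, Path)):
        path = Path(config)
        base_dir = base_dir or path.parent
        with open(path, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    entries = config.get("channels")
    if not entries:
        raise RetinaConfigError("retina config must list 'channels'")
    channels = []
    for e in entries:
        row, tier = int(e["row"]), str(e["tier"])
        label = e.get("label") or default_label(row, tier)
        if "lambda_max_nm" in e and e["lambda_max_nm"] is not None:
            lmax = float(e["lambda_max_nm"])
            sens = pigment_template(lmax, grid)
        elif "sensitivity_file" in e:
            fpath = Path(e["sensitivity_file"])
            if base_dir is not None and not fpath.is_absolute():
                fpath = base_dir / fpath
            sens = read_spectrum(fpath, "sensitivity", grid)
            peak = sens.values.max()
            if peak <= 0:
                raise RetinaConfigError(f"channel {label!r}: sensitivity file is all zero")
            sens = sens.with_values(sens.values / peak)
            lmax = float(grid.wavelengths[int(np.argmax(sens.values))])
        else:
            raise RetinaConfigError(f"channel {label!r}: needs lambda_max_nm or sensitivity_file")
        channels.append(ChannelSpec(row, tier, label, sens, lmax))
    return RetinaModel(tuple(channels), grid)


def default_retina(grid: WavelengthGrid | None = None) -> RetinaModel:
    """The packaged placeholder retina on the session (or given) grid."""
    return build_retina(None, grid)
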