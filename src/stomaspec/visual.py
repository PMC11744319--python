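"""Quantum catches and the two competing colour-processing models.

The photon signal a receptor absorbs from a stimulus is the quantum catch

    Q = integral over lambda of  S(lambda) R(lambda) I(lambda) dlambda,

with S the receptor sensitivity, R the stimulus reflectance and I the
illuminant photon distribution (trapezoid rule on the session grid).

Two readouts of the 12-channel catch vector are implemented:

* the multi-dichromatic opponent model — each midband row n yields an
  activity profile A_n = ln(Q_distal) - ln(Q_proximal), and two stimuli X, Y
  are separated in row n by the contrast difference CD_n = A_n(X) - A_n(Y);
* the binning (barcode) comparator — colour is the activation pattern of all
  channels rescaled to unit maximum, dominated by the strongest channel.

Both readouts are invariant to rescaling the illuminant, which is the formal
content of the grey-card logic: intensity alone carries no chromatic signal.
Spectrally flat (grey) reflectances of any two optical densities are metamers
under both models: CD = 0 in every row and identical binning patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import trapezoid

from .retina import ROWS, RetinaModel
from .spectral import Spectrum, _require_common_grid

#: catches below this fraction of the normalization reference are treated as
#: numerically zero for the log-opponency (narrowband tents drive some
#: channels to zero catch; ln would produce -inf)
LOG_FLOOR = 1e-12

#: default normalized-catch threshold for a channel to count as activated
ACTIVATION_THRESHOLD = 0.05

#: |CD| above this is annotated "high" in contrast reports
HIGH_CD = 0.5


def quantum_catch(sensitivity: Spectrum, reflectance: Spectrum, illuminant: Spectrum) -> float:
    """Trapezoid-rule quantum catch of one receptor viewing one stimulus."""
    _require_common_grid(sensitivity, reflectance, illuminant)
    integrand = sensitivity.values * reflectance.values * illuminant.values
    return float(trapezoid(integrand, sensitivity.wavelengths))


@dataclass(frozen=True)
class CatchTable:
    """Quantum catches of every channel for one (stimulus, illuminant) pair."""

    entries: dict  # channel label -> catch
    stimulus: str
    illuminant: str
    normalization: tuple | str = "raw"  # (channel, stimulus, illuminant) or "raw"

    @property
    def is_normalized(self) -> bool:
        return self.normalization != "raw"

    def __getitem__(self, label: str) -> float:
        return self.entries[label]


def catch_table(retina: RetinaModel, reflectance: Spectrum, illuminant: Spectrum,
                stimulus: str = "", illuminant_id: str = "") -> CatchTable:
    """Raw quantum catches of all 12 channels for one stimulus/illuminant."""
    entries = {
        ch.label: quantum_catch(ch.sensitivity, reflectance, illuminant)
        for ch in retina.channels
    }
    return CatchTable(entries, stimulus, illuminant_id)


def normalize_catches(tables: list[CatchTable],
                      reference: tuple[str, str, str]) -> list[CatchTable]:
    """Divide every catch in every table by one reference entry.

    ``reference`` is (channel label, stimulus id, illuminant id) — the
    published convention uses the highest catch, R2P viewing the ND 0.15 grey
    under natural light.  The reference entry becomes exactly 1.
    """
    ch_label, stim, illum = reference
    ref_val = None
    for t in tables:
        if t.stimulus == stim and t.illuminant == illum and ch_label in t.entries:
            ref_val = t.entries[ch_label]
    if ref_val is None:
        raise KeyError(f"reference entry {reference} not found among the given tables")
    if ref_val <= 0:
        raise ValueError(f"reference entry {reference} has non-positive catch {ref_val}")
    out = []
    for t in tables:
        entries = {k: v / ref_val for k, v in t.entries.items()}
        out.append(replace(t, entries=entries, normalization=tuple(reference)))
    return out


@dataclass(frozen=True)
class ActivityProfile:
    """Per-row opponent signals A_n for one stimulus under one illuminant.

    Rows where either opponent catch is at the numerical log-floor are
    undefined (``None``): the channel is simply not reporting.
    """

    values: dict  # row -> float | None
    stimulus: str
    illuminant: str

    def defined_rows(self) -> list[int]:
        return [r for r in ROWS if self.values.get(r) is not None]


def activity_profile(retina: RetinaModel, catches: CatchTable,
                     form: str = "log") -> ActivityProfile:
    """Per-row opponent activity from a catch table.

    ``form='log'`` (default) is A_n = ln(Q_distal) - ln(Q_proximal);
    ``form='normalized'`` is the bounded alternative
    (Q_distal - Q_proximal)/(Q_distal + Q_proximal).
    """
    if form not in ("log", "normalized"):
        raise ValueError(f"unknown opponency form {form!r}")
    scale = max(catches.entries.values(), default=0.0)
    floor = LOG_FLOOR * (1.0 if catches.is_normalized else scale if scale > 0 else 1.0)
    values: dict[int, float | None] = {}
    for row, (dist, prox) in retina.opponent_pairs.items():
        qd, qp = catches[dist.label], catches[prox.label]
        if qd <= floor or qp <= floor:
            values[row] = None
        elif form == "log":
            values[row] = math.log(qd) - math.log(qp)
        else:
            values[row] = (qd - qp) / (qd + qp)
    return ActivityProfile(values, catches.stimulus, catches.illuminant)


@dataclass(frozen=True)
class ContrastTable:
    """Per-row contrast differences CD_n between two stimuli under one illuminant."""

    cd: dict  # row -> float | None
    stimulus_pair: tuple[str, str]
    illuminant: str
    active_rows: frozenset = field(default_factory=frozenset)

    @property
    def abs_cd(self) -> dict:
        return {r: (None if v is None else abs(v)) for r, v in self.cd.items()}

    def max_abs_cd(self, rows=None) -> float | None:
        """Largest |CD| over ``rows`` (default: rows defined on both profiles)."""
        pool = self.cd.keys() if rows is None else rows
        vals = [abs(self.cd[r]) for r in pool if self.cd.get(r) is not None]
        return max(vals) if vals else None

    def high_cd_rows(self, threshold: float = HIGH_CD) -> list[int]:
        return [r for r, v in self.cd.items() if v is not None and abs(v) > threshold]


def contrast_difference(profile_x: ActivityProfile, profile_y: ActivityProfile,
                        active_rows=None) -> ContrastTable:
    """CD_n = A_n(X) - A_n(Y); undefined rows propagate as undefined."""
    if profile_x.illuminant != profile_y.illuminant:
        raise ValueError(
            f"profiles computed under different illuminants "
            f"({profile_x.illuminant!r} vs {profile_y.illuminant!r}); "
            "stimuli are compared under a single illumination"
        )
    cd: dict[int, float | None] = {}
    for r in ROWS:
        ax, ay = profile_x.values.get(r), profile_y.values.get(r)
        cd[r] = None if ax is None or ay is None else ax - ay
    if active_rows is None:
        active_rows = frozenset(r for r in ROWS if cd[r] is not None)
    return ContrastTable(cd, (profile_x.stimulus, profile_y.stimulus),
                         profile_x.illuminant, frozenset(active_rows))


def row_activation(catches: CatchTable, threshold: float = ACTIVATION_THRESHOLD,
                   retina: RetinaModel | None = None) -> set[int]:
    """Rows whose both opponent channels exceed ``threshold`` normalized catch.

    Under a narrowband tent some rows receive essentially no light in their
    sampling window; their opponent signal exists numerically but carries no
    usable information, mirroring the hatched (non-activated) rows of the
    published contrast figures.
    """
    if not catches.is_normalized:
        raise ValueError("row_activation requires a normalized catch table "
                         "(see normalize_catches)")
    active = set()
    for row in ROWS:
        if retina is not None:
            dist, prox = retina.opponent_pairs[row]
            labels = [dist.label, prox.label]
        else:
            labels = [f"R{row}D", f"R{row}P"]  # default label convention
        if any(lab not in catches.entries for lab in labels):
            raise KeyError(f"catch table lacks opponent channels for row {row}")
        if all(catches[lab] > threshold for lab in labels):
            active.add(row)
    return active


# ---------------------------------------------------------------------------
# Binning / barcode comparator


@dataclass(frozen=True)
class BinningPattern:
    """Channel-ordered catch vector rescaled to unit maximum."""

    labels: tuple
    values: np.ndarray
    dominant: str | None  # None for the all-zero (undefined) pattern
    tie: bool = False

    @property
    def defined(self) -> bool:
        return self.dominant is not None


def binning_pattern(catches: CatchTable, retina: RetinaModel | None = None,
                    include_r8: bool = True) -> BinningPattern:
    """Activation pattern across channels, strongest channel = 1.

    The dominant channel is the argmax; exact ties are broken by channel
    order and flagged.  An all-zero catch vector has no defined pattern.
    """
    labels = [lab for lab in catches.entries
              if include_r8 or not lab.startswith("R8")]
    if retina is not None:
        order = [lab for lab in retina.labels if lab in labels]
        labels = order
    vec = np.array([catches[lab] for lab in labels], dtype=float)
    top = vec.max(initial=0.0)
    if top <= 0:
        return BinningPattern(tuple(labels), vec, None)
    scaled = vec / top
    winners = np.flatnonzero(scaled == scaled.max())
    return BinningPattern(tuple(labels), scaled, labels[int(winners[0])],
                          tie=len(winners) > 1)


def binning_discriminable(p1: BinningPattern, p2: BinningPattern,
                          tolerance: float = 0.1) -> tuple[bool, float]:
    """Chebyshev distance between patterns; discriminable iff it exceeds ``tolerance``."""
    if p1.labels != p2.labels:
        raise ValueError("patterns cover different channel sets")
    if not (p1.defined and p2.defined):
        raise ValueError("cannot compare an undefined (all-zero) pattern")
    dist = float(np.max(np.abs(p1.values - p2.values)))
    return dist > tolerance, dist


# ---------------------------------------------------------------------------
# Convenience: full contrast computation for a stimulus pair


def contrast_between(retina: RetinaModel, refl_x: Spectrum, refl_y: Spectrum,
                     illuminant: Spectrum, *, stimulus_x: str = "X", stimulus_y: str = "Y",
                     illuminant_id: str = "illum", reference: tuple | None = None,
                     activation_threshold: float = ACTIVATION_THRESHOLD,
                     form: str = "log") -> ContrastTable:
    """Catches -> profiles -> CD for two stimuli under one illuminant.

    If ``reference`` (channel, stimulus, illuminant-id) with a reference
    catch table is not supplied, tables are normalized to the larger of the
    two stimuli's own maxima, which only affects the activation gate — the
    log-form CD itself is normalization-invariant.
    """
    tx = catch_table(retina, refl_x, illuminant, stimulus_x, illuminant_id)
    ty = catch_table(retina, refl_y, illuminant, stimulus_y, illuminant_id)
    if reference is None:
        allv = {**{(tx.stimulus, k): v for k, v in tx.entries.items()},
                **{(ty.stimulus, k): v for k, v in ty.entries.items()}}
        (stim, ch), _ = max(allv.items(), key=lambda kv: kv[1])
        reference = (ch, stim, illuminant_id)
    tx_n, ty_n = normalize_catches([tx, ty], reference)
    act = (row_activation(tx_n, activation_threshold, retina)
           & row_activation(ty_n, activation_threshold, retina))
    px = activity_profile(retina, tx_n, form=form)
    py = activity_profile(retina, ty_n, form=form)
    return contrast_difference(px, py, active_rows=act & set(px.defined_rows()) & set(py.defined_rows()))
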