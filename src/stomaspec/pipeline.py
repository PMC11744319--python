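"""End-to-end orchestration: config, validation, and the full run.

A run is reproducible from config + seed alone: fixture generation, catch and
contrast tables, experiment simulation and the statistical report are all
derived from one seeded generator and written as CSV/JSON with a manifest
recording the config hash and library versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .experiment import (ChooserParams, ExperimentDesign, ExperimentContext, StagePlan,
                         simulate_experiment)
from .fixtures import ND_LEVELS, spectral_library
from .retina import RetinaModel, build_retina, default_retina
from .spectral import WavelengthGrid, write_spectrum
from .stats import summarize_experiment
from .visual import HIGH_CD, contrast_between

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one run."""

    grid: dict = field(default_factory=lambda: {"start": 300.0, "stop": 750.0, "step": 1.0})
    retina_config: str | None = None
    fixtures: dict = field(default_factory=lambda: {"red_leak": False, "nd_levels": list(ND_LEVELS)})
    design: dict = field(default_factory=dict)
    chooser: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "run"
    fit_model: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def wavelength_grid(self) -> WavelengthGrid:
        g = self.grid or {}
        return WavelengthGrid(g.get("start", 300.0), g.get("stop", 750.0), g.get("step", 1.0))

    def stage_plan(self) -> StagePlan:
        keys = StagePlan.__dataclass_fields__
        return StagePlan(**{k: v for k, v in (self.design or {}).items() if k in keys})

    def experiment_design(self) -> ExperimentDesign:
        d = dict(self.design or {})
        kwargs = {}
        if "groups" in d:
            kwargs["groups"] = tuple(d["groups"])
        for k in ("n_per_group", "training_illumination", "activation_threshold"):
            if k in d:
                kwargs[k] = d[k]
        if "coloured_illuminations" in d:
            kwargs["coloured_illuminations"] = d["coloured_illuminations"]
        kwargs["plan"] = self.stage_plan()
        kwargs["red_leak"] = bool((self.fixtures or {}).get("red_leak", False))
        return ExperimentDesign(**kwargs)

    def chooser_params(self) -> ChooserParams:
        keys = ChooserParams.__dataclass_fields__
        return ChooserParams(**{k: v for k, v in (self.chooser or {}).items() if k in keys})


@dataclass(frozen=True)
class Finding:
    level: str  # "error" | "warning"
    message: str


def validate_config(config: RunConfig) -> list[Finding]:
    """Schema and cross-field checks; findings are returned, never raised."""
    findings: list[Finding] = []
    try:
        config.wavelength_grid()
    except Exception as exc:
        findings.append(Finding("error", f"grid: {exc}"))
    if config.retina_config is not None and not Path(config.retina_config).exists():
        findings.append(Finding("error", f"retina config file not found: {config.retina_config}"))
    fx = config.fixtures or {}
    for od in fx.get("nd_levels", ND_LEVELS):
        if od not in ND_LEVELS:
            findings.append(Finding("warning",
                                    f"non-standard optical density {od} (protocol set is {ND_LEVELS})"))
        if od < 0:
            findings.append(Finding("error", f"optical density must be >= 0, got {od}"))
    for name, band in (fx.get("bands") or {}).items():
        lo, hi = band
        if not lo < hi:
            findings.append(Finding("error", f"band {name!r}: low edge {lo} >= high edge {hi}"))
    d = config.design or {}
    if "groups" in d and not d["groups"]:
        findings.append(Finding("error", "design.groups is empty"))
    thr = d.get("activation_threshold")
    if thr is not None and not 0 <= thr <= 1:
        findings.append(Finding("error", f"activation_threshold must lie in [0,1], got {thr}"))
    ch = config.chooser or {}
    try:
        ChooserParams(**{k: v for k, v in ch.items() if k in ChooserParams.__dataclass_fields__})
    except ValueError as exc:
        findings.append(Finding("error", f"chooser: {exc}"))
    return findings


def write_fixture_library(out_dir: Path, grid: WavelengthGrid, red_leak: bool = False) -> dict:
    """Write the spectral library as CSVs under spectra/{illuminants,filters,reflectances}."""
    lib = spectral_library(grid, red_leak=red_leak)
    base = Path(out_dir) / "spectra"
    for sub, items in (("illuminants", lib["illuminants"]),
                       ("reflectances", lib["reflectances"])):
        (base / sub).mkdir(parents=True, exist_ok=True)
        for name, spec in items.items():
            write_spectrum(spec, base / sub / f"{name}.csv")
    (base / "filters").mkdir(parents=True, exist_ok=True)
    for name, filt in lib["filters"].items():
        write_spectrum(filt.effective(), base / "filters" / f"{name}.csv")
    return lib


def contrast_report(retina: RetinaModel, lib: dict, activation_threshold: float) -> pd.DataFrame:
    """Tidy per-row CD table: each colour vs each grey under natural + own tents."""
    rows = []
    ill, refl = lib["illuminants"], lib["reflectances"]
    greys = [k for k in refl if k.startswith("grey")]
    for colour in ("blue", "green", "red"):
        for illum in ("natural", f"{colour}-tent", f"{colour}-tent2"):
            for g in greys:
                ct = contrast_between(retina, refl[colour], refl[g], ill[illum],
                                      stimulus_x=colour, stimulus_y=g, illuminant_id=illum,
                                      activation_threshold=activation_threshold)
                for r in sorted(ct.cd):
                    v = ct.cd[r]
                    rows.append({"illuminant": illum, "stimulus": colour, "distractor": g,
                                 "row": r, "cd": v, "abs_cd": None if v is None else abs(v),
                                 "active": r in ct.active_rows,
                                 "high_cd": v is not None and abs(v) > HIGH_CD})
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> Path:
    """Fixtures -> catches/contrasts -> simulation -> analysis; returns the run directory."""
    findings = validate_config(config)
    errors = [f for f in findings if f.level == "error"]
    for f in findings:
        (logger.error if f.level == "error" else logger.warning)("%s", f.message)
    if errors:
        raise ValueError("configuration invalid: " + "; ".join(f.message for f in errors))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = config.wavelength_grid()
    retina = (build_retina(config.retina_config, grid) if config.retina_config
              else default_retina(grid))
    red_leak = bool((config.fixtures or {}).get("red_leak", False))

    lib = write_fixture_library(out, grid, red_leak=red_leak)
    design = config.experiment_design()
    ctx = ExperimentContext(design, retina, grid)

    contrast = contrast_report(retina, lib, design.activation_threshold)
    contrast.insert(0, "normalization", "R2P/grey0.15/natural")
    contrast.to_csv(out / "contrast_tables.csv", index=False)

    dataset, fates = simulate_experiment(design, config.chooser_params(),
                                         seed=config.seed, context=ctx)
    dataset.to_csv(out / "trials.csv")
    fates.to_csv(out / "fates.csv", index=False)

    report = summarize_experiment(dataset, fates, fit_model=config.fit_model)
    report.group_summaries.to_csv(out / "group_summaries.csv", index=False)
    report.inclusion_ledger.to_csv(out / "inclusion_ledger.csv", index=False)
    with open(out / "model_fits.json", "w", encoding="utf-8") as fh:
        fh.write(json.dumps(report.model_fits, indent=2, default=str))

    manifest = {
        "stomaspec_version": __version__,
        "numpy": np.__version__, "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "normalization_reference": "R2P viewing grey0.15 under natural light",
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return out
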