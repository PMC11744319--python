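"""Simulation of the three-stage grey-card choice experiment.

Each simulated animal is assigned a colour group (blue, green, red) and runs
through priming (learn to grab the cable tie), training (pick the colour
target out of two grey distractors under natural light) and testing (one
natural-light and two coloured-illumination trials per day, a reinforcement
trial after every six testing trials).  Stage progression follows the
protocol's thresholds via :func:`stomaspec.stats.inclusion_filter`.

The chooser links behaviour to the opponent model: during training the animal
stores the target's per-row activity profile under natural light (the learned
signature); at test each presented stimulus is scored by the negative of the
largest per-row deviation |A_row(stimulus) - A_row(signature)| over rows that
are activated under the current illumination, and a choice is drawn from a
Luce/softmax rule with sensitivity beta, mixed with a lapse rate and a
no-choice rate.  Rows carry no intensity information (flat greys are exact
metamers of each other), so a null chooser (beta = 0) picks uniformly — the
1/3 chance level of the paradigm.

beta defaults to 2*ln(6) ~ 3.58, the value at which a single row separating
target from distractor by |CD| = 0.5 yields a 75% success probability; this
is a modelling calibration, not a measured constant.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as bstats
from .fixtures import DISTRACTOR_COMBINATIONS, spectral_library
from .retina import RetinaModel, default_retina
from .spectral import DEFAULT_GRID, WavelengthGrid
from .visual import (ACTIVATION_THRESHOLD, CatchTable, activity_profile, catch_table,
                     row_activation)

POSITIONS = ("left", "middle", "right")

#: softmax sensitivity at which one row of |CD| = 0.5 gives 75% success
BETA_CALIBRATED = 2.0 * math.log(6.0)


@dataclass(frozen=True)
class ChooserParams:
    """Stochastic choice mechanism parameters (modelling constructs)."""

    beta: float = BETA_CALIBRATED
    lapse: float = 0.02
    no_choice: float = 0.05

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if not (0 <= self.lapse <= 1 and 0 <= self.no_choice <= 1):
            raise ValueError("lapse and no_choice must be probabilities")
        if self.lapse + self.no_choice > 1:
            raise ValueError("lapse + no_choice must not exceed 1")


@dataclass(frozen=True)
class StagePlan:
    """Days per stage (three trials per day)."""

    priming_days: int = 3
    training_days: int = 5
    testing_days: int = 12
    trials_per_day: int = 3
    reinforce_every: int = 6
    training_assessment_after: int = 9  # trials before progression is evaluated


@dataclass(frozen=True)
class ExperimentDesign:
    """Full design of one simulated study."""

    groups: tuple = ("blue", "green", "red")
    n_per_group: int = 12
    plan: StagePlan = field(default_factory=StagePlan)
    coloured_illuminations: dict | None = None  # group -> illuminant id
    training_illumination: str = "natural"
    activation_threshold: float = ACTIVATION_THRESHOLD
    red_leak: bool = False

    def coloured_for(self, group: str) -> str:
        if self.coloured_illuminations and group in self.coloured_illuminations:
            return self.coloured_illuminations[group]
        return f"{group}-tent"


@dataclass(frozen=True)
class TargetSignature:
    """The learned per-row activity profile of the target (training illuminant)."""

    colour: str
    illuminant: str
    values: dict  # row -> float | None


@dataclass
class ChoiceDataset:
    """Trial-level records of one simulated (or loaded) experiment."""

    records: pd.DataFrame
    provenance: str = ""

    CSV_COLUMNS = ("individual", "group", "stage", "day", "trial", "illumination",
                   "combination", "target_pos", "choice_pos", "correct", "reinforcement")

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False, columns=list(self.CSV_COLUMNS))

    @classmethod
    def from_csv(cls, path) -> "ChoiceDataset":
        df = pd.read_csv(path)
        if "correct" in df:
            df["correct"] = df["correct"].map(
                lambda v: v if pd.isna(v) else bool(v) if isinstance(v, (bool, np.bool_))
                else str(v).lower() in ("true", "1", "1.0"))
        return cls(df, provenance=str(path))


# ---------------------------------------------------------------------------
# Scheduling with the protocol's pseudo-randomization constraints


def _draw_no_triple(rng, options, history) -> object:
    """Uniform draw avoiding a third consecutive repeat of the same value."""
    if len(options) < 2:
        raise ValueError("need at least two options to satisfy the no-triple-repeat rule")
    banned = history[-1] if len(history) >= 2 and history[-1] == history[-2] else None
    pool = [o for o in options if o != banned]
    return pool[rng.integers(len(pool))]


def schedule_trials(n_individuals: int, plan: StagePlan | None = None,
                    seed: int = 0, coloured: str = "tent") -> dict:
    """Pseudo-randomized testing-stage templates per individual.

    Guarantees: the target never sits at the same position on more than two
    consecutive trials; the same distractor combination never occurs three
    times running; day 1 is natural light only and every later day holds one
    natural-light and two coloured-illumination trials in random order; one
    reinforcement trial follows every six testing trials (so every seventh
    record carries the reinforcement flag).
    """
    plan = plan or StagePlan()
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n_individuals):
        templates, pos_hist, comb_hist = [], [], []
        n_tested = 0
        for day in range(1, plan.testing_days + 1):
            conditions = (["natural"] * plan.trials_per_day if day == 1
                          else ["natural"] + [coloured] * (plan.trials_per_day - 1))
            rng.shuffle(conditions)
            for cond in conditions:
                pos = _draw_no_triple(rng, POSITIONS, pos_hist)
                comb = _draw_no_triple(rng, DISTRACTOR_COMBINATIONS, comb_hist)
                pos_hist.append(pos)
                comb_hist.append(comb)
                templates.append({"day": day, "illumination": cond, "target_pos": pos,
                                  "combination": comb, "reinforcement": False})
                n_tested += 1
                if n_tested % plan.reinforce_every == 0:
                    rpos = _draw_no_triple(rng, POSITIONS, pos_hist)
                    rcomb = _draw_no_triple(rng, DISTRACTOR_COMBINATIONS, comb_hist)
                    pos_hist.append(rpos)
                    comb_hist.append(rcomb)
                    templates.append({"day": day, "illumination": "natural",
                                      "target_pos": rpos, "combination": rcomb,
                                      "reinforcement": True})
        out[f"ind{i:03d}"] = templates
    return out


# ---------------------------------------------------------------------------
# The chooser


def choice_probabilities(scores, chooser: ChooserParams) -> tuple[np.ndarray, float]:
    """Position probabilities and no-choice probability from similarity scores.

    Luce/softmax over finite scores (a stimulus with no usable chromatic
    signal scores -inf and is never preferred), mixed with the lapse rate;
    all-(-inf) or beta = 0 degrade to the uniform chooser.
    """
    s = np.asarray(scores, dtype=float)
    finite = np.isfinite(s)
    if chooser.beta == 0 or not finite.any():
        base = np.full(len(s), 1.0 / len(s))
    else:
        w = np.zeros(len(s))
        z = chooser.beta * (s[finite] - s[finite].max())
        w[finite] = np.exp(z)
        base = w / w.sum()
    # lapse mass is uniform, the remainder follows the softmax
    p = (1.0 - chooser.no_choice - chooser.lapse) * base + chooser.lapse / len(s)
    return p, chooser.no_choice


def simulate_choice(scores, chooser: ChooserParams, rng) -> int | None:
    """Draw one choice: a position index, or None for a no-choice trial."""
    p, p_none = choice_probabilities(scores, chooser)
    u = rng.random()
    if u < p_none:
        return None
    u -= p_none
    cum = np.cumsum(p)
    return int(np.searchsorted(cum, u, side="right").clip(0, len(p) - 1))


# ---------------------------------------------------------------------------
# Precomputed spectral context (keeps per-trial work trivial)


class ExperimentContext:
    """Catch tables, activation sets and signatures for all fixture stimuli.

    All spectral integrals are evaluated once; trials then only index into
    score tables, so simulating 10^5+ choices is cheap.
    """

    def __init__(self, design: ExperimentDesign, retina: RetinaModel | None = None,
                 grid: WavelengthGrid | None = None):
        self.design = design
        self.grid = grid or DEFAULT_GRID
        self.retina = retina or default_retina(self.grid)
        self.library = spectral_library(self.grid, red_leak=design.red_leak)
        ill, refl = self.library["illuminants"], self.library["reflectances"]
        ref_raw = catch_table(self.retina, refl["grey0.15"], ill["natural"],
                              "grey0.15", "natural")
        self.reference_value = ref_raw["R2P"]
        if self.reference_value <= 0:
            raise ValueError("normalization reference catch is not positive")
        self.reference = ("R2P", "grey0.15", "natural")
        # normalized catch tables, profiles and activation per (stimulus, illuminant)
        self._profiles, self._active = {}, {}
        for iname, I in ill.items():
            for rname, R in refl.items():
                raw = catch_table(self.retina, R, I, rname, iname)
                norm = CatchTable({k: v / self.reference_value for k, v in raw.entries.items()},
                                  rname, iname, normalization=self.reference)
                self._profiles[(rname, iname)] = activity_profile(self.retina, norm)
                self._active[(rname, iname)] = row_activation(
                    norm, design.activation_threshold, self.retina)
        self.signatures = {
            colour: TargetSignature(colour, design.training_illumination,
                                    self._profiles[(colour, design.training_illumination)].values)
            for colour in design.groups}

    def similarity(self, stimulus: str, illuminant: str, signature: TargetSignature) -> float:
        """Negative max per-row deviation from the learned signature (active rows)."""
        prof = self._profiles[(stimulus, illuminant)]
        rows = [r for r in self._active[(stimulus, illuminant)]
                if prof.values.get(r) is not None and signature.values.get(r) is not None]
        if not rows:
            return -math.inf
        return -max(abs(prof.values[r] - signature.values[r]) for r in rows)

    def trial_scores(self, group: str, illuminant: str, stimuli) -> np.ndarray:
        sig = self.signatures[group]
        return np.array([self.similarity(s, illuminant, sig) for s in stimuli])


def grey_name(od: float) -> str:
    return f"grey{od:g}"


# ---------------------------------------------------------------------------
# Whole-experiment simulation


def _individual_rng(seed: int, individual: str):
    """Independent, reproducible substream per individual (stable id hashing)."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(individual.encode())])


def simulate_experiment(design: ExperimentDesign | None = None,
                        chooser: ChooserParams | None = None,
                        seed: int = 0,
                        retina: RetinaModel | None = None,
                        grid: WavelengthGrid | None = None,
                        context: ExperimentContext | None = None
                        ) -> tuple[ChoiceDataset, pd.DataFrame]:
    """Run priming -> training -> testing for every individual.

    Returns the trial records and a per-individual fate table with values
    ``removed_priming``, ``removed_training``, ``excluded`` (failed the
    natural-light reliability gate) or ``included``.
    """
    design = design or ExperimentDesign()
    chooser = chooser or ChooserParams()
    ctx = context or ExperimentContext(design, retina, grid)
    records, fates = [], []

    for group in design.groups:
        coloured = design.coloured_for(group)
        for k in range(design.n_per_group):
            ind = f"{group}-{k:03d}"
            rng = _individual_rng(seed, ind)
            rec, fate = _run_individual(ind, group, coloured, design, chooser, ctx, rng)
            records.extend(rec)
            fates.append({"individual": ind, "group": group, "fate": fate})

    df = pd.DataFrame(records, columns=list(ChoiceDataset.CSV_COLUMNS))
    return ChoiceDataset(df, provenance=f"simulated seed={seed}"), pd.DataFrame(fates)


def _run_individual(ind, group, coloured, design, chooser, ctx, rng):
    plan = design.plan
    records = []
    trial_no = 0

    # --- priming: single target, participation only
    part_hist = []
    promoted = False
    for day in range(1, plan.priming_days + 1):
        for _ in range(plan.trials_per_day):
            trial_no += 1
            participated = rng.random() >= chooser.no_choice
            pos = POSITIONS[rng.integers(3)]
            part_hist.append(participated)
            records.append(dict(individual=ind, group=group, stage="priming", day=day,
                                trial=trial_no, illumination=design.training_illumination,
                                combination=None, target_pos=pos,
                                choice_pos=pos if participated else None,
                                correct=None, reinforcement=False))
            decision = bstats.inclusion_filter(part_hist, "priming")
            if decision == bstats.PROMOTE:
                promoted = True
                break
            if decision == bstats.REMOVE:
                return records, "removed_priming"
        if promoted:
            break
    if not promoted:
        return records, "removed_priming"

    # --- training: target + two greys under natural light
    train_hist, pos_hist, comb_hist = [], [], []
    promoted = False
    for day in range(1, plan.training_days + 1):
        for _ in range(plan.trials_per_day):
            trial_no += 1
            comb = _draw_no_triple(rng, DISTRACTOR_COMBINATIONS, comb_hist)
            comb_hist.append(comb)
            rec, correct = _choice_trial(ind, group, "training", day, trial_no,
                                         design.training_illumination, comb, False,
                                         design, chooser, ctx, rng, pos_hist)
            records.append(rec)
            if correct is not None:
                train_hist.append(correct)
            if len(train_hist) >= plan.training_assessment_after:
                decision = bstats.inclusion_filter(train_hist, "training")
                if decision == bstats.PROMOTE:
                    promoted = True
                    break
                if decision == bstats.REMOVE:
                    return records, "removed_training"
        if promoted:
            break
    if not promoted:
        return records, "removed_training"

    # --- testing
    natural_hist = []
    pos_hist, comb_hist = [], []
    n_tested = 0
    for day in range(1, plan.testing_days + 1):
        conditions = (["natural"] * plan.trials_per_day if day == 1
                      else ["natural"] + [coloured] * (plan.trials_per_day - 1))
        rng.shuffle(conditions)
        for cond in conditions:
            trial_no += 1
            comb = _draw_no_triple(rng, DISTRACTOR_COMBINATIONS, comb_hist)
            comb_hist.append(comb)
            rec, correct = _choice_trial(ind, group, "testing", day, trial_no,
                                         cond, comb, False, design, chooser, ctx,
                                         rng, pos_hist)
            records.append(rec)
            if cond == "natural" and correct is not None:
                natural_hist.append(correct)
            n_tested += 1
            if n_tested % plan.reinforce_every == 0:
                trial_no += 1
                comb = _draw_no_triple(rng, DISTRACTOR_COMBINATIONS, comb_hist)
                comb_hist.append(comb)
                rec, _ = _choice_trial(ind, group, "testing", day, trial_no,
                                       design.training_illumination, comb, True,
                                       design, chooser, ctx, rng, pos_hist)
                records.append(rec)
    fate = ("included" if bstats.inclusion_filter(natural_hist, "testing") == bstats.INCLUDE
            else "excluded")
    return records, fate


def _choice_trial(ind, group, stage, day, trial_no, illumination, comb, reinforcement,
                  design, chooser, ctx, rng, pos_hist):
    target_pos = _draw_no_triple(rng, POSITIONS, pos_hist)
    pos_hist.append(target_pos)
    names = [grey_name(comb[0]), grey_name(comb[1])]
    t_idx = POSITIONS.index(target_pos)
    stimuli = names[:t_idx] + [group] + names[t_idx:]
    illum_key = illumination if illumination in ctx.library["illuminants"] else "natural"
    scores = ctx.trial_scores(group, illum_key, stimuli)
    choice = simulate_choice(scores, chooser, rng)
    correct = None if choice is None else (choice == t_idx)
    rec = dict(individual=ind, group=group, stage=stage, day=day, trial=trial_no,
               illumination=illumination, combination=f"{comb[0]:g}/{comb[1]:g}",
               target_pos=target_pos,
               choice_pos=None if choice is None else POSITIONS[choice],
               correct=correct, reinforcement=reinforcement)
    return rec, correct
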