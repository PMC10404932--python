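"""Forward simulation of the pilot heading-discrimination experiment.

Emulates the pilot design: 5 participants, ~4000 trials in total across
vestibular-only, visual-only and combined conditions, visual coherences
0.4 and 0.7, cue-conflict trials with the visual and vestibular headings
displaced 1.5 degrees to either side of the assigned heading, continuous
confidence ratings on a guess(0) -> certain(1) scale, and feedback only as
percent correct per 30-trial block.  Every trial is drawn from the full
generative model (reliability-weighted drift -> anticorrelated race ->
log-odds confidence), so all downstream analyses and fits can be exercised
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .confidence import ConfidenceLink, assign_confidence, build_logodds_map
from .evidence import Modality, TemporalProfile, TrialCondition, drift_schedule, make_profile
from .race import RaceParams, simulate_race

__all__ = [
    "ExperimentDesign",
    "SubjectParams",
    "TRIAL_COLUMNS",
    "default_design",
    "default_subject_params",
    "generate_dataset",
    "block_feedback",
    "write_trials",
    "read_trials",
]

#: Canonical column order of a trial table.
TRIAL_COLUMNS = [
    "subject_id", "block", "trial", "modality", "coherence", "heading_deg",
    "delta_deg", "choice", "rt_s", "conf", "correct", "censored",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial design of one session of the heading task."""

    n_subjects: int = 5
    headings_deg: tuple = (-12.0, -6.0, -3.0, -1.5, 0.0, 1.5, 3.0, 6.0, 12.0)
    modalities: tuple = (Modality.VES, Modality.VIS, Modality.COMB)
    coherences: tuple = (0.4, 0.7)
    deltas_deg: tuple = (-3.0, 0.0, 3.0)
    trials_per_cell: int = 10
    block_size: int = 30

    def __post_init__(self) -> None:
        hs = sorted(self.headings_deg)
        if any(-h not in self.headings_deg for h in hs):
            raise ValueError("headings must be symmetric about 0")
        if self.block_size <= 0 or self.trials_per_cell <= 0 or self.n_subjects <= 0:
            raise ValueError("counts must be positive")
        object.__setattr__(
            self, "modalities", tuple(Modality.coerce(m) for m in self.modalities)
        )

    def conditions(self) -> list[TrialCondition]:
        """Enumerate the condition cells; conflicts apply to combined cells only."""
        cells: list[TrialCondition] = []
        for m in self.modalities:
            if m is Modality.VES:
                cells += [TrialCondition(m, h, 0.0, 0.0) for h in self.headings_deg]
            elif m is Modality.VIS:
                cells += [
                    TrialCondition(m, h, c, 0.0)
                    for c in self.coherences for h in self.headings_deg
                ]
            else:
                cells += [
                    TrialCondition(m, h, c, d)
                    for c in self.coherences for d in self.deltas_deg
                    for h in self.headings_deg
                ]
        return cells

    @property
    def n_trials_per_subject(self) -> int:
        return len(self.conditions()) * self.trials_per_cell

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["modalities"] = [m.value for m in self.modalities]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentDesign":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("headings_deg", "modalities", "coherences", "deltas_deg"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class SubjectParams:
    """Generative parameters for one simulated participant.

    Defaults reproduce the intended regime of the pilot: vestibular
    threshold ~3 deg, visual thresholds straddling it across the two
    coherences, mean RTs near 1-1.4 s.
    """

    k_vis: float = 120.0
    k_ves: float = 42.0
    B: float = 2.0
    rho: float = -0.7
    t_nd: float = 0.3
    link_offset: float = 0.0
    link_scale: float = 1.0

    def race_params(self, t_max: float | None = None) -> RaceParams:
        return RaceParams(B=self.B, rho=self.rho, t_nd=self.t_nd, t_max=t_max)

    def link(self) -> ConfidenceLink:
        return ConfidenceLink(offset=self.link_offset, scale=self.link_scale)


def default_design() -> ExperimentDesign:
    """The pilot-style design: 5 subjects x 81 cells x 10 trials = 4050 trials."""
    return ExperimentDesign()


def default_subject_params(
    n_subjects: int = 5, seed: int = 20230 , spread: float = 0.15
) -> list[SubjectParams]:
    """Mildly heterogeneous participants around the calibrated defaults.

    Gains and bound are jittered by a +-``spread`` uniform factor, the
    non-decision time by +-50 ms; deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    base = SubjectParams()
    out = []
    for _ in range(n_subjects):
        f = lambda: 1.0 + rng.uniform(-spread, spread)
        out.append(
            SubjectParams(
                k_vis=base.k_vis * f(),
                k_ves=base.k_ves * f(),
                B=base.B * (1.0 + rng.uniform(-0.1, 0.1)),
                rho=base.rho,
                t_nd=base.t_nd + rng.uniform(-0.05, 0.05),
                link_offset=base.link_offset,
                link_scale=base.link_scale,
            )
        )
    return out


def subject_params_to_yaml(params: Sequence[SubjectParams], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([asdict(p) for p in params], fh)


def subject_params_from_yaml(path) -> list[SubjectParams]:
    with open(path) as fh:
        return [SubjectParams(**d) for d in yaml.safe_load(fh)]


def generate_dataset(
    design: ExperimentDesign,
    subject_params: Sequence[SubjectParams],
    seed: int,
    profile: TemporalProfile | None = None,
    map_n_sims: int = 50_000,
    map_bins: int = 40,
) -> pd.DataFrame:
    """Simulate a complete trial table under the generative model.

    For every subject x condition cell x trial: build the drift schedule,
    run the race, and assign confidence through that subject's log-odds map
    (one map per modality x coherence, built from the design's nonzero
    headings).  Trial order is randomized within subjects and cut into
    blocks of ``design.block_size``.  Deterministic for a given seed.
    """
    if len(subject_params) != design.n_subjects:
        raise ValueError(
            f"need {design.n_subjects} SubjectParams, got {len(subject_params)}"
        )
    profile = profile or make_profile()
    cells = design.conditions()
    master = np.random.SeedSequence(seed)
    frames = []
    for si, sp in enumerate(subject_params):
        params = sp.race_params()
        link = sp.link()
        # observer's learned confidence maps, one per modality x coherence
        maps = {}
        map_keys = sorted({(c.modality, c.coherence) for c in cells})
        for mi, (mod, coh) in enumerate(map_keys):
            conds = [
                TrialCondition(mod, h, coh, 0.0)
                for h in design.headings_deg if h != 0.0
            ]
            map_seed = int(
                np.random.SeedSequence(
                    entropy=master.entropy, spawn_key=(si, 1000 + mi)
                ).generate_state(1)[0] % (2**31)
            )
            maps[(mod, coh)] = build_logodds_map(
                conds, params, profile, sp.k_vis, sp.k_ves,
                n_sims=map_n_sims, n_t_bins=map_bins, n_x_bins=map_bins,
                seed=map_seed,
            )
        rows = []
        for ci, cond in enumerate(cells):
            sched = drift_schedule(cond, profile, sp.k_vis, sp.k_ves)
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=master.entropy, spawn_key=(si, ci))
            )
            out = simulate_race(sched, params, design.trials_per_cell, rng)
            out = assign_confidence(out, maps[(cond.modality, cond.coherence)], link)
            h = cond.heading_deg
            if h == 0.0:
                correct = (rng.random(len(out)) < 0.5).astype(int)
            else:
                correct = ((out.choice == 1) == (h > 0)).astype(int)
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": si,
                        "modality": cond.modality.value,
                        "coherence": cond.coherence,
                        "heading_deg": h,
                        "delta_deg": cond.delta_deg,
                        "choice": out.choice.astype(int),
                        "rt_s": out.rt,
                        "conf": out.conf,
                        "correct": correct,
                        "censored": out.censored.astype(int),
                    }
                )
            )
        sub = pd.concat(rows, ignore_index=True)
        order_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=master.entropy, spawn_key=(si, 999_999))
        )
        sub = sub.iloc[order_rng.permutation(len(sub))].reset_index(drop=True)
        sub["block"] = np.arange(len(sub)) // design.block_size
        sub["trial"] = np.arange(len(sub)) % design.block_size
        frames.append(sub[TRIAL_COLUMNS])
    return pd.concat(frames, ignore_index=True)


def block_feedback(trials: pd.DataFrame) -> pd.DataFrame:
    """Percent correct per subject x block — the only feedback shown in the task."""
    g = trials.groupby(["subject_id", "block"])["correct"].agg(["mean", "size"])
    g = g.rename(columns={"mean": "pct_correct", "size": "n"}).reset_index()
    g["pct_correct"] = 100.0 * g["pct_correct"]
    return g


def write_trials(trials: pd.DataFrame, path) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df[TRIAL_COLUMNS]
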