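"""Anticorrelated race: two bounded accumulators for left vs right heading.

Momentary evidence at each step is bivariate normal with mean
``[mu dt, -mu dt]`` and covariance ``dt [[1, rho], [rho, 1]]`` with
``rho < -0.5``: the two accumulators receive partially anticorrelated
evidence for the two choice alternatives.  The first accumulator to reach
the bound ``B`` determines the choice and the decision time; reaction time
adds a non-decision latency.  The state of the *losing* accumulator at that
moment is recorded because, together with decision time, it carries the
information used downstream to compute confidence.

The simulation is an Euler–Maruyama walk on the schedule's grid, jitted
with numba.  A single seeded bit generator is consumed sequentially across
trials, so results are exactly reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .evidence import DriftSchedule

__all__ = [
    "RaceParams",
    "RaceOutcome",
    "RaceOutcomes",
    "RaceSummary",
    "simulate_race",
    "race_summary",
]


@dataclass(frozen=True)
class RaceParams:
    """Parameters of the accumulation process.

    B : bound height (evidence units); sets the speed–accuracy trade-off.
    rho : correlation of the momentary evidence increments, in [-1, -0.5).
    t_nd : non-decision time (s) added to decision time to give RT.
    t_nd_jitter : half-width of a uniform jitter on t_nd (s); 0 = fixed.
    t_max : censoring deadline (s); None = twice the schedule duration.
    """

    B: float = 2.0
    rho: float = -0.7
    t_nd: float = 0.3
    t_nd_jitter: float = 0.0
    t_max: float | None = None

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError("bound B must be positive")
        if not -1.0 <= self.rho < -0.5:
            raise ValueError("rho must lie in [-1, -0.5)")
        if self.t_nd < 0 or self.t_nd_jitter < 0:
            raise ValueError("non-decision time must be non-negative")
        if self.t_max is not None and self.t_max <= self.t_nd:
            raise ValueError("t_max must exceed t_nd")

    @classmethod
    def from_yaml(cls, path) -> "RaceParams":
        """Load from YAML; keys ``B``, ``rho``, ``t_nd_s``, ``t_max_s``."""
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(
            B=cfg.get("B", 2.0),
            rho=cfg.get("rho", -0.7),
            t_nd=cfg.get("t_nd_s", 0.3),
            t_max=cfg.get("t_max_s"),
        )


@dataclass(frozen=True)
class RaceOutcome:
    """One trial's result: choice, timing, and losing-accumulator state."""

    choice: int  # 1 = right, 0 = left
    dt_decision: float
    rt: float
    x_lose: float
    censored: bool
    logodds: float = np.nan
    conf: float = np.nan


@njit(cache=True)
def _race_kernel(rng, mu_dt, sdt, c21, c22, B, n_steps_max, n_trials,
                 choice, step, x_lose, censored):  # pragma: no cover - jitted
    n_sched = mu_dt.shape[0]
    for tr in range(n_trials):
        x1 = 0.0
        x2 = 0.0
        done = False
        for i in range(n_steps_max):
            m = mu_dt[i] if i < n_sched else 0.0
            z1 = rng.standard_normal()
            z2 = rng.standard_normal()
            x1 += m + sdt * z1
            x2 += -m + sdt * (c21 * z1 + c22 * z2)
            hit1 = x1 >= B
            hit2 = x2 >= B
            if hit1 or hit2:
                if hit1 and hit2:
                    # same-step double crossing: larger overshoot wins,
                    # exact tie broken by a fair coin
                    if x1 - B > x2 - B:
                        win1 = True
                    elif x2 - B > x1 - B:
                        win1 = False
                    else:
                        win1 = rng.random() < 0.5
                else:
                    win1 = hit1
                choice[tr] = 1 if win1 else 0
                step[tr] = i + 1
                x_lose[tr] = x2 if win1 else x1
                censored[tr] = False
                done = True
                break
        if not done:
            if x1 > x2:
                ch = 1
            elif x2 > x1:
                ch = 0
            else:
                ch = 1 if rng.random() < 0.5 else 0
            choice[tr] = ch
            step[tr] = n_steps_max
            x_lose[tr] = x2 if ch == 1 else x1
            censored[tr] = True


class RaceOutcomes:
    """Column-oriented sequence of :class:`RaceOutcome`.

    Behaves like a list of per-trial outcomes (``len``, indexing) while
    storing each field as a numpy array for fast downstream analysis.
    ``logodds`` and ``conf`` are NaN until confidence is assigned.
    """

    __slots__ = ("choice", "dt_decision", "rt", "x_lose", "censored",
                 "logodds", "conf")

    def __init__(self, choice, dt_decision, rt, x_lose, censored,
                 logodds=None, conf=None):
        n = len(choice)
        self.choice = np.asarray(choice, dtype=np.int8)
        self.dt_decision = np.asarray(dt_decision, dtype=np.float64)
        self.rt = np.asarray(rt, dtype=np.float64)
        self.x_lose = np.asarray(x_lose, dtype=np.float64)
        self.censored = np.asarray(censored, dtype=bool)
        self.logodds = np.full(n, np.nan) if logodds is None else np.asarray(logodds, float)
        self.conf = np.full(n, np.nan) if conf is None else np.asarray(conf, float)

    def __len__(self) -> int:
        return len(self.choice)

    def __getitem__(self, idx):
        if isinstance(idx, (int, np.integer)):
            i = int(idx)
            return RaceOutcome(
                choice=int(self.choice[i]),
                dt_decision=float(self.dt_decision[i]),
                rt=float(self.rt[i]),
                x_lose=float(self.x_lose[i]),
                censored=bool(self.censored[i]),
                logodds=float(self.logodds[i]),
                conf=float(self.conf[i]),
            )
        return RaceOutcomes(
            self.choice[idx], self.dt_decision[idx], self.rt[idx],
            self.x_lose[idx], self.censored[idx],
            self.logodds[idx], self.conf[idx],
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def with_confidence(self, logodds, conf) -> "RaceOutcomes":
        return RaceOutcomes(self.choice, self.dt_decision, self.rt,
                            self.x_lose, self.censored, logodds, conf)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(len(self)),
                "choice": self.choice.astype(int),
                "rt_s": self.rt,
                "dt_decision_s": self.dt_decision,
                "x_lose": self.x_lose,
                "censored": self.censored.astype(int),
                "logodds": self.logodds,
                "conf": self.conf,
            }
        )


def simulate_race(
    schedule: DriftSchedule,
    params: RaceParams,
    n_trials: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> RaceOutcomes:
    """Simulate ``n_trials`` of the anticorrelated race for one condition.

    Both accumulators start at 0; increments over each step ``dt`` follow
    the schedule's drift (0 after the stimulus ends) while diffusion
    continues until the deadline.  Trials that reach the deadline without a
    bound crossing are censored: the choice is read from the sign of the
    accumulator difference (exact ties by a fair coin) and ``dt_decision``
    is the deadline.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    dt = schedule.dt
    t_max = params.t_max if params.t_max is not None else 2.0 * schedule.duration
    n_steps_max = int(round(t_max / dt))
    if n_steps_max < len(schedule.t):
        raise ValueError("t_max shorter than the drift schedule")

    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)

    choice = np.empty(n_trials, dtype=np.int8)
    step = np.empty(n_trials, dtype=np.int64)
    x_lose = np.empty(n_trials, dtype=np.float64)
    censored = np.empty(n_trials, dtype=np.bool_)

    c21 = params.rho
    c22 = np.sqrt(max(0.0, 1.0 - params.rho**2))
    _race_kernel(
        rng, np.ascontiguousarray(schedule.mu * dt), np.sqrt(dt),
        c21, c22, params.B, n_steps_max, n_trials,
        choice, step, x_lose, censored,
    )
    dt_decision = step * dt
    t_nd = np.full(n_trials, params.t_nd)
    if params.t_nd_jitter > 0:
        t_nd = t_nd + rng.uniform(-params.t_nd_jitter, params.t_nd_jitter, n_trials)
    return RaceOutcomes(choice, dt_decision, dt_decision + t_nd, x_lose, censored)


@dataclass(frozen=True)
class RaceSummary:
    p_right: float
    mean_rt: float
    median_rt: float
    censor_rate: float
    n: int
    n_rt: int  # trials entering the RT summaries (censored excluded)


def race_summary(outcomes: RaceOutcomes) -> RaceSummary:
    """Empirical summary of a batch of race outcomes.

    Censored trials count toward the choice proportion but are excluded
    from the RT means/medians (their count is reported via ``n_rt``).
    """
    n = len(outcomes)
    if n == 0:
        raise ValueError("empty outcome list")
    ok = ~outcomes.censored
    rt = outcomes.rt[ok]
    return RaceSummary(
        p_right=float(np.mean(outcomes.choice == 1)),
        mean_rt=float(np.mean(rt)) if len(rt) else np.nan,
        median_rt=float(np.median(rt)) if len(rt) else np.nan,
        censor_rate=float(np.mean(outcomes.censored)),
        n=n,
        n_rt=int(ok.sum()),
    )
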