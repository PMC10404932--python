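"""Confidence as the log odds of being correct, read from the losing race.

At decision time the winning accumulator is pinned at the bound, so the
informative quantities are the losing accumulator's state and the elapsed
decision time.  The observer is assumed to know (or to have learned) the
mapping from that pair to the probability of having chosen correctly; we
estimate the mapping by Monte-Carlo simulation of the generative model over
the experiment's nonzero headings, binning trials on a
(decision time x losing state) grid and converting the per-bin fraction
correct to log odds.  A saturating link then turns log odds into a rating
on the experiment's guess(0) -> certain(1) scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import expit

from .evidence import Modality, TemporalProfile, TrialCondition, drift_schedule
from .race import RaceOutcomes, RaceParams, simulate_race

__all__ = [
    "LogOddsMap",
    "ConfidenceLink",
    "build_logodds_map",
    "map_from_samples",
    "assign_confidence",
]


@dataclass
class LogOddsMap:
    """Gridded estimate of log P(correct)/P(error) over (decision time, losing state).

    Bins that received no simulated trials are invalid (``logodds`` NaN) and
    are never interpolated silently: lookups fall back to the nearest valid
    bin.  Laplace (add-one) smoothing keeps all valid-bin log odds finite.
    """

    t_edges: np.ndarray
    x_edges: np.ndarray
    logodds: np.ndarray  # shape (n_t_bins, n_x_bins), NaN where invalid
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nt, nx = len(self.t_edges) - 1, len(self.x_edges) - 1
        if self.logodds.shape != (nt, nx) or self.counts.shape != (nt, nx):
            raise ValueError("grid shape inconsistent with bin edges")
        self._tree = None
        self._valid_idx = None

    @property
    def valid(self) -> np.ndarray:
        return self.counts > 0

    def _build_tree(self) -> None:
        tc = 0.5 * (self.t_edges[:-1] + self.t_edges[1:])
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        ti, xi = np.nonzero(self.valid)
        if len(ti) == 0:
            raise ValueError("log-odds map has no valid bins")
        # normalize axes so time and state contribute comparably
        ts = np.ptp(self.t_edges) or 1.0
        xs = np.ptp(self.x_edges) or 1.0
        self._tree = cKDTree(np.column_stack([tc[ti] / ts, xc[xi] / xs]))
        self._valid_idx = (ti, xi)
        self._scales = (ts, xs)

    def lookup(self, dt_decision, x_lose) -> tuple[np.ndarray, np.ndarray]:
        """Log odds at each (decision time, losing state) pair.

        Returns ``(L, out_of_grid)`` where ``out_of_grid`` flags queries
        that fell outside the grid or in an invalid bin and were resolved
        to the nearest valid bin.
        """
        t = np.atleast_1d(np.asarray(dt_decision, float))
        x = np.atleast_1d(np.asarray(x_lose, float))
        ti = np.searchsorted(self.t_edges, t, side="right") - 1
        xi = np.searchsorted(self.x_edges, x, side="right") - 1
        nt, nx = self.logodds.shape
        inside = (ti >= 0) & (ti < nt) & (xi >= 0) & (xi < nx)
        # queries exactly on the upper edge belong to the last bin
        ti_c = np.clip(ti, 0, nt - 1)
        xi_c = np.clip(xi, 0, nx - 1)
        ok = inside & self.valid[ti_c, xi_c]
        L = np.full(t.shape, np.nan)
        L[ok] = self.logodds[ti_c[ok], xi_c[ok]]
        fallback = ~ok
        if fallback.any():
            if self._tree is None:
                self._build_tree()
            ts, xs = self._scales
            _, nn = self._tree.query(np.column_stack([t[fallback] / ts, x[fallback] / xs]))
            vi, vj = self._valid_idx
            L[fallback] = self.logodds[vi[nn], vj[nn]]
        return L, fallback

    # -- serialization ------------------------------------------------------

    def to_csv(self, path) -> None:
        """Long-format CSV (t_bin, x_bin, logodds, count) + JSON sidecar."""
        nt, nx = self.logodds.shape
        ti, xi = np.meshgrid(np.arange(nt), np.arange(nx), indexing="ij")
        pd.DataFrame(
            {
                "t_bin": ti.ravel(),
                "x_bin": xi.ravel(),
                "logodds": self.logodds.ravel(),
                "count": self.counts.ravel().astype(int),
            }
        ).to_csv(path, index=False)
        sidecar = {
            "t_edges": self.t_edges.tolist(),
            "x_edges": self.x_edges.tolist(),
            "meta": _jsonable(self.meta),
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh)

    @classmethod
    def from_csv(cls, path) -> "LogOddsMap":
        df = pd.read_csv(path)
        with open(str(path) + ".json") as fh:
            sidecar = json.load(fh)
        t_edges = np.asarray(sidecar["t_edges"])
        x_edges = np.asarray(sidecar["x_edges"])
        nt, nx = len(t_edges) - 1, len(x_edges) - 1
        logodds = np.full((nt, nx), np.nan)
        counts = np.zeros((nt, nx))
        logodds[df["t_bin"], df["x_bin"]] = df["logodds"]
        counts[df["t_bin"], df["x_bin"]] = df["count"]
        return cls(t_edges, x_edges, logodds, counts, meta=sidecar.get("meta", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Modality):
        return obj.value
    return obj


def map_from_samples(
    dt_decision: np.ndarray,
    x_lose: np.ndarray,
    correct: np.ndarray,
    t_max: float,
    bound: float,
    n_t_bins: int = 40,
    n_x_bins: int = 40,
    meta: dict | None = None,
) -> LogOddsMap:
    """Bin labeled simulation samples into a log-odds-correct map.

    Time bins span [0, t_max]; losing-state bins span from the 0.1th
    percentile of the samples up to the bound.  Samples outside the state
    range are clipped into the boundary bins.  Per-bin probability correct
    uses add-one smoothing: (n_correct + 1) / (n + 2).
    """
    dt_decision = np.asarray(dt_decision, float)
    x_lose = np.asarray(x_lose, float)
    correct = np.asarray(correct, bool)
    t_edges = np.linspace(0.0, t_max, n_t_bins + 1)
    x_lo = float(np.percentile(x_lose, 0.1))
    if x_lo >= bound:
        x_lo = bound - 1.0
    x_edges = np.linspace(x_lo, bound, n_x_bins + 1)

    ti = np.clip(np.searchsorted(t_edges, dt_decision, side="right") - 1, 0, n_t_bins - 1)
    xi = np.clip(np.searchsorted(x_edges, x_lose, side="right") - 1, 0, n_x_bins - 1)
    flat = ti * n_x_bins + xi
    counts = np.bincount(flat, minlength=n_t_bins * n_x_bins).astype(float)
    ncorr = np.bincount(flat, weights=correct.astype(float), minlength=n_t_bins * n_x_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (ncorr + 1.0) / (counts + 2.0)
        lo = np.log(p / (1.0 - p))
    lo[counts == 0] = np.nan
    counts = counts.reshape(n_t_bins, n_x_bins)
    lo = lo.reshape(n_t_bins, n_x_bins)
    med = np.median(counts[counts > 0]) if (counts > 0).any() else 0
    if med < 20:
        warnings.warn(
            f"median occupied-bin count {med:.0f} < 20; consider more simulations "
            "or a coarser grid",
            stacklevel=2,
        )
    return LogOddsMap(t_edges, x_edges, lo, counts, meta=meta or {})


def build_logodds_map(
    design: Iterable[TrialCondition],
    params: RaceParams,
    profile: TemporalProfile,
    k_vis: float,
    k_ves: float,
    n_sims: int = 200_000,
    n_t_bins: int = 40,
    n_x_bins: int = 40,
    seed: int = 0,
) -> LogOddsMap:
    """Monte-Carlo estimate of the log-odds-correct map for a set of conditions.

    For every distinct (modality, coherence, conflict) cell in ``design``,
    ``n_sims`` trials are simulated with headings drawn uniformly over the
    design's signed *nonzero* headings (zero headings carry no correct
    answer and are excluded).  All cells are pooled into one map; pass a
    subset of conditions to build per-modality or per-coherence maps.
    """
    design = list(design)
    headings = sorted({c.heading_deg for c in design if c.heading_deg != 0.0})
    if not design or not headings:
        raise ValueError("design must contain at least one nonzero heading")
    groups = sorted({(c.modality, c.coherence, c.delta_deg) for c in design})
    t_max = params.t_max if params.t_max is not None else 2.0 * profile.duration

    per = max(1, n_sims // len(headings))
    ss = np.random.SeedSequence(seed)
    dts, xls, cors = [], [], []
    for gi, (mod, coh, delta) in enumerate(groups):
        for hi, h in enumerate(headings):
            cond = TrialCondition(modality=mod, heading_deg=h, coherence=coh,
                                  delta_deg=delta if mod is Modality.COMB else 0.0)
            sched = drift_schedule(cond, profile, k_vis, k_ves)
            rng = np.random.default_rng(np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=(gi, hi)))
            out = simulate_race(sched, params, per, rng)
            dts.append(out.dt_decision)
            xls.append(out.x_lose)
            cors.append((out.choice == 1) == (h > 0))
    meta = {
        "headings": headings,
        "groups": [(m.value, c, d) for m, c, d in groups],
        "n_sims_per_group": per * len(headings),
        "B": params.B,
        "rho": params.rho,
        "seed": seed,
    }
    return map_from_samples(
        np.concatenate(dts), np.concatenate(xls), np.concatenate(cors),
        t_max=t_max, bound=params.B, n_t_bins=n_t_bins, n_x_bins=n_x_bins,
        meta=meta,
    )


@dataclass(frozen=True)
class ConfidenceLink:
    """Saturating map from log odds correct to a rating in [0, 1].

    ``rating = clip(2 * sigmoid(scale * (L - offset)) - 1, 0, 1)``: with the
    default offset 0 and scale 1, log odds 0 (a coin flip) maps to 0
    ("complete guess") and large log odds saturate at 1 ("100% certain").
    """

    offset: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def rating(self, logodds) -> np.ndarray:
        L = np.asarray(logodds, float)
        return np.clip(2.0 * expit(self.scale * (L - self.offset)) - 1.0, 0.0, 1.0)

    __call__ = rating


def assign_confidence(
    outcomes: RaceOutcomes,
    lomap: LogOddsMap,
    link: ConfidenceLink = ConfidenceLink(),
) -> RaceOutcomes:
    """Attach log odds and confidence ratings to race outcomes.

    Each trial's log odds is looked up at its (decision time, losing state);
    censored trials query the deadline time bin.  Out-of-grid or empty-bin
    queries resolve to the nearest valid bin.
    """
    if len(outcomes) == 0:
        raise ValueError("empty outcome list")
    if not lomap.valid.any():
        raise ValueError("log-odds map has no valid bins")
    L, _ = lomap.lookup(outcomes.dt_decision, outcomes.x_lose)
    return outcomes.with_confidence(L, link.rating(L))
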