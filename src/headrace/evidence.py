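"""Stimulus dynamics and reliability-weighted momentary evidence.

The heading stimulus is a brief forward translation whose velocity follows a
Gaussian bell.  The visual cue (optic flow) is informative in proportion to
instantaneous *velocity* and to motion coherence, while the vestibular cue
(inertial motion sensed by the otoliths) is informative in proportion to
instantaneous *acceleration*.  Momentary evidence about heading is the
reliability-weighted combination of the two cues at each time step, which
yields a time-varying drift rate for the downstream accumulation process.

Units convention: the diffusion variance of momentary evidence is fixed at
1 per second, so all stimulus sensitivity is carried by the gains ``k_vis``
and ``k_ves`` and the drift ``mu`` is in evidence units per second.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "TemporalProfile",
    "TrialCondition",
    "StaticMLE",
    "DriftSchedule",
    "make_profile",
    "profile_from_yaml",
    "mle_combined_sigma",
    "mle_weights",
    "static_mle",
    "drift_schedule",
]


class Modality(str, enum.Enum):
    """Stimulus modality: vestibular only, visual only, or combined."""

    VES = "ves"
    VIS = "vis"
    COMB = "comb"

    @classmethod
    def coerce(cls, value: "Modality | str") -> "Modality":
        if isinstance(value, Modality):
            return value
        return cls(str(value).lower())


# ---------------------------------------------------------------------------
# Temporal stimulus profile
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TemporalProfile:
    """Discretized stimulus velocity and acceleration traces.

    Attributes
    ----------
    t : ndarray
        Time grid in seconds, uniform step ``dt``.
    v : ndarray
        Normalized velocity trace, peak magnitude 1.
    a : ndarray
        Normalized acceleration trace (signed, biphasic), peak magnitude 1.
        Proportional to the discrete time-derivative of ``v``.
    duration : float
        Stimulus duration in seconds.
    """

    t: np.ndarray
    v: np.ndarray
    a: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.v) == len(self.a)):
            raise ValueError("t, v, a must have equal length")
        steps = np.diff(self.t)
        if len(steps) and not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("time grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "v": self.v, "a": self.a})

    def to_csv(self, path, which: str = "v") -> None:
        """Write a two-column CSV ``(t, value)`` of the velocity or acceleration."""
        if which not in ("v", "a"):
            raise ValueError("which must be 'v' or 'a'")
        pd.DataFrame({"t": self.t, which: getattr(self, which)}).to_csv(path, index=False)


def make_profile(
    duration: float = 2.0, dt: float = 0.001, sigma_frac: float = 1.0 / 6.0
) -> TemporalProfile:
    """Build a Gaussian-bell velocity profile and its normalized derivative.

    Parameters
    ----------
    duration : float
        Stimulus duration in seconds.
    dt : float
        Time step in seconds.
    sigma_frac : float
        Standard deviation of the Gaussian bell as a fraction of ``duration``.

    Returns
    -------
    TemporalProfile
        Velocity peaks (value 1) at ``duration / 2``; acceleration is the
        discrete derivative of velocity rescaled to peak magnitude 1.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if dt >= duration:
        raise ValueError("dt must be smaller than duration")
    if not (0 < sigma_frac < 0.5):
        raise ValueError("sigma_frac must lie in (0, 0.5)")

    n_exact = duration / dt
    n = int(round(n_exact))
    if not math.isclose(n_exact, n, rel_tol=1e-9):
        n = int(math.floor(n_exact))
        warnings.warn(
            f"dt={dt} does not divide duration={duration} evenly; "
            f"grid truncated to {n} steps",
            stacklevel=2,
        )
    t = np.arange(n) * dt
    sigma = sigma_frac * duration
    v = np.exp(-0.5 * ((t - duration / 2.0) / sigma) ** 2)
    v = v / np.max(np.abs(v))
    a = np.gradient(v, dt)
    a = a / np.max(np.abs(a))
    return TemporalProfile(t=t, v=v, a=a, duration=float(duration))


def profile_from_yaml(path) -> tuple[TemporalProfile, float, float]:
    """Load stimulus/sensitivity settings from a YAML file.

    Recognized keys: ``duration_s``, ``dt_s``, ``sigma_frac``, ``k_vis``,
    ``k_ves`` (all optional, defaulting to the package defaults). Returns
    ``(profile, k_vis, k_ves)``.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    prof = make_profile(
        duration=cfg.get("duration_s", 2.0),
        dt=cfg.get("dt_s", 0.001),
        sigma_frac=cfg.get("sigma_frac", 1.0 / 6.0),
    )
    return prof, float(cfg.get("k_vis", 120.0)), float(cfg.get("k_ves", 42.0))


# ---------------------------------------------------------------------------
# Trial conditions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialCondition:
    """One stimulus condition of the heading-discrimination task.

    ``heading_deg`` is the assigned heading (positive = rightward).  On
    cue-conflict trials (``delta_deg`` nonzero, combined modality only) the
    visual heading is displaced to ``heading - delta/2`` and the vestibular
    heading to ``heading + delta/2``.
    """

    modality: Modality
    heading_deg: float
    coherence: float = 0.0
    delta_deg: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "modality", Modality.coerce(self.modality))
        if self.delta_deg != 0.0 and self.modality is not Modality.COMB:
            raise ValueError("cue conflict (delta_deg != 0) requires the combined modality")
        if not -90.0 < self.heading_deg < 90.0:
            raise ValueError("heading_deg must lie in (-90, 90)")
        if self.modality is not Modality.VES and not 0.0 <= self.coherence <= 1.0:
            raise ValueError("coherence must lie in [0, 1]")

    @property
    def heading_vis_deg(self) -> float:
        return self.heading_deg - self.delta_deg / 2.0

    @property
    def heading_ves_deg(self) -> float:
        return self.heading_deg + self.delta_deg / 2.0

    def mirrored(self) -> "TrialCondition":
        """The left/right reflection of this condition."""
        return TrialCondition(
            modality=self.modality,
            heading_deg=-self.heading_deg,
            coherence=self.coherence,
            delta_deg=-self.delta_deg,
        )


# ---------------------------------------------------------------------------
# Static maximum-likelihood cue combination
# ---------------------------------------------------------------------------


def mle_combined_sigma(sigma_a: float, sigma_b: float) -> float:
    """Standard deviation of the optimal (inverse-variance weighted) combined estimate.

    ``sigma_c = sqrt(sigma_a^2 sigma_b^2 / (sigma_a^2 + sigma_b^2))``, which is
    never larger than the smaller of the two unimodal standard deviations.
    """
    if sigma_a <= 0 or sigma_b <= 0:
        raise ValueError("sigmas must be positive")
    va, vb = sigma_a**2, sigma_b**2
    return math.sqrt(va * vb / (va + vb))


def mle_weights(sigma_a: float, sigma_b: float) -> tuple[float, float]:
    """Inverse-variance cue weights ``(w_a, w_b)``; they sum to 1."""
    if sigma_a <= 0 or sigma_b <= 0:
        raise ValueError("sigmas must be positive")
    va, vb = sigma_a**2, sigma_b**2
    w_a = vb / (va + vb)
    return w_a, 1.0 - w_a


@dataclass(frozen=True)
class StaticMLE:
    """Static optimal-combination prediction from two unimodal sigmas."""

    sigma_a: float
    sigma_b: float
    sigma_c: float
    w_a: float
    w_b: float


def static_mle(sigma_a: float, sigma_b: float) -> StaticMLE:
    w_a, w_b = mle_weights(sigma_a, sigma_b)
    return StaticMLE(
        sigma_a=sigma_a,
        sigma_b=sigma_b,
        sigma_c=mle_combined_sigma(sigma_a, sigma_b),
        w_a=w_a,
        w_b=w_b,
    )


# ---------------------------------------------------------------------------
# Dynamic drift schedules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DriftSchedule:
    """Per-time-step signed drift of combined momentary evidence.

    ``mu`` is in evidence units per second under the unit-diffusion
    convention (diffusion variance 1 per second at every step).  ``s_vis``
    and ``s_ves`` are the unimodal sensitivity envelopes from which ``mu``
    was built; in unimodal conditions the absent cue's envelope is zero.
    """

    t: np.ndarray
    mu: np.ndarray
    s_vis: np.ndarray
    s_ves: np.ndarray
    condition: TrialCondition | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.mu) == len(self.s_vis) == len(self.s_ves)):
            raise ValueError("t, mu, s_vis, s_ves must have equal length")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(len(self.t) * self.dt)

    def integrated_snr2(self) -> float:
        """Integral of squared drift over the stimulus, a d'-like quantity."""
        return float(np.sum(self.mu**2) * self.dt)

    def to_csv(self, path) -> None:
        pd.DataFrame({"t": self.t, "mu": self.mu}).to_csv(path, index=False)


def drift_schedule(
    cond: TrialCondition,
    prof: TemporalProfile,
    k_vis: float,
    k_ves: float,
    signed_acceleration: bool = False,
) -> DriftSchedule:
    """Build the reliability-weighted drift schedule for one condition.

    Sensitivity envelopes are ``s_vis(t) = k_vis * coherence * |v(t)|`` and
    ``s_ves(t) = k_ves * |a(t)|``.  The unimodal drift is
    ``mu_m(t) = s_m(t) * sin(h_m)``; the combined drift weights the two cue
    headings by their instantaneous squared sensitivities:

        mu_comb(t) = sqrt(s_vis^2 + s_ves^2)
                     * [w_vis(t) sin(h_vis) + w_ves(t) sin(h_ves)],
        w_m(t) = s_m(t)^2 / (s_vis(t)^2 + s_ves(t)^2).

    Both weights are taken as 0 (drift 0) at steps where both envelopes
    vanish.  With ``signed_acceleration=True`` the vestibular evidence keeps
    the biphasic sign of ``a(t)`` instead of its magnitude, so the
    deceleration phase pushes the accumulators back; the default treats
    reliability-weighted evidence as sign-corrected.
    """
    if k_vis < 0 or k_ves < 0:
        raise ValueError("sensitivities must be non-negative")
    if len(prof.t) == 0:
        raise ValueError("empty temporal profile")

    h_vis = math.radians(cond.heading_vis_deg)
    h_ves = math.radians(cond.heading_ves_deg)
    a_env = prof.a if signed_acceleration else np.abs(prof.a)
    s_ves = k_ves * np.abs(prof.a)
    s_vis = k_vis * cond.coherence * np.abs(prof.v)

    if cond.modality is Modality.VES:
        s_vis = np.zeros_like(prof.t)
        mu = k_ves * a_env * math.sin(h_ves)
    elif cond.modality is Modality.VIS:
        s_ves = np.zeros_like(prof.t)
        mu = s_vis * math.sin(h_vis)
    else:
        s2 = s_vis**2 + s_ves**2
        num = s_vis**2 * math.sin(h_vis) + (k_ves * a_env) * s_ves * math.sin(h_ves)
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = np.where(s2 > 0, num / np.sqrt(np.where(s2 > 0, s2, 1.0)), 0.0)
    return DriftSchedule(
        t=prof.t, mu=np.ascontiguousarray(mu, dtype=np.float64),
        s_vis=s_vis, s_ves=s_ves, condition=cond,
    )
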