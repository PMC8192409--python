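"""Two-parameter critical-speed model and its algebraic variants.

The speed--duration relationship of exhaustive constant-speed running is
described by two parameters: the critical speed ``CS`` (m/s), the asymptote
separating the heavy from the severe exercise-intensity domain, and
``d'`` (m), the finite distance that can be covered above CS before
exhaustion.  Four rearrangements of the same hyperbola are in common use:

    t(s) = d' / (s - CS)            time to exhaustion vs. speed
    d(s) = s * d' / (s - CS)        distance vs. speed
    s(t) = d' / t + CS              speed vs. time
    d(t) = d' + CS * t              distance vs. time (the linear form)

They are mathematically equivalent; they differ only in which variable is
placed on the vertical axis, which matters for regression (see
:mod:`critspeed.fitting` and :mod:`critspeed.selector`).

Canonical internal units are m/s, s and m.  Incremental-test speeds are
conventionally reported in km/h and converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CSParameters",
    "TrialObservation",
    "SubjectTrials",
    "IncrementalTestResult",
    "predict_time",
    "predict_distance_from_speed",
    "predict_speed",
    "predict_distance_from_time",
    "peak_speed",
    "kmh_to_mps",
    "mps_to_kmh",
]

#: exact factor between km/h and m/s
KMH_PER_MPS = 3.6


def kmh_to_mps(speed_kmh):
    """Convert a speed from km/h to m/s (exact factor 1000/3600)."""
    return np.asarray(speed_kmh, dtype=float) / KMH_PER_MPS if np.ndim(speed_kmh) else float(speed_kmh) / KMH_PER_MPS


def mps_to_kmh(speed_mps):
    """Convert a speed from m/s to km/h."""
    return np.asarray(speed_mps, dtype=float) * KMH_PER_MPS if np.ndim(speed_mps) else float(speed_mps) * KMH_PER_MPS


@dataclass(frozen=True)
class CSParameters:
    """The two model parameters.

    Parameters
    ----------
    cs
        Critical speed in m/s.
    d_prime
        Distance that can be run above CS, in m.

    Fits are allowed to return physically meaningless values (e.g. a
    negative d' on pathological data); :attr:`is_physical` flags whether
    both parameters are positive.
    """

    cs: float
    d_prime: float

    @property
    def is_physical(self) -> bool:
        return self.cs > 0 and self.d_prime > 0


@dataclass(frozen=True)
class TrialObservation:
    """One exhaustive constant-speed run.

    Speed is the experimentally fixed intensity and carries no error;
    time to exhaustion is the measured quantity.  Distance is therefore a
    derived variable (speed x time) and is never stored independently --
    any error in distance is induced by the error in time.
    """

    speed: float  # m/s, fixed by the protocol
    time_to_exhaustion: float  # s, measured

    def __post_init__(self) -> None:
        if not self.speed > 0:
            raise ValueError(f"trial speed must be positive, got {self.speed}")
        if not self.time_to_exhaustion > 0:
            raise ValueError(
                f"time to exhaustion must be positive, got {self.time_to_exhaustion}"
            )

    @property
    def distance(self) -> float:
        """Distance covered, m (always recomputed as speed x time)."""
        return self.speed * self.time_to_exhaustion


@dataclass(frozen=True)
class SubjectTrials:
    """The per-subject data set of a critical-speed test.

    At least two trials at distinct speeds are required for a
    two-parameter fit; the typical protocol uses four, at fixed
    percentages of the subject's incremental-test peak speed.
    """

    subject_id: str
    trials: tuple[TrialObservation, ...]
    peak_speed: float | None = None  # m/s, optional

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        if len(self.trials) < 2:
            raise ValueError(
                f"subject {self.subject_id!r}: need >= 2 trials, got {len(self.trials)}"
            )
        speeds = [tr.speed for tr in self.trials]
        if len(set(speeds)) != len(speeds):
            raise ValueError(
                f"subject {self.subject_id!r}: trial speeds must be distinct "
                "(repeated speeds make the design singular)"
            )

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def speeds(self) -> np.ndarray:
        """Trial speeds, m/s."""
        return np.array([tr.speed for tr in self.trials], dtype=float)

    @property
    def times(self) -> np.ndarray:
        """Measured times to exhaustion, s."""
        return np.array([tr.time_to_exhaustion for tr in self.trials], dtype=float)

    @property
    def distances(self) -> np.ndarray:
        """Derived distances, m."""
        return self.speeds * self.times


@dataclass(frozen=True)
class IncrementalTestResult:
    """Outcome of a maximal incremental (ramp) treadmill test.

    ``s_vo2max`` is the speed of the last fully completed increment,
    ``alpha`` the fraction of the following, uncompleted increment that
    was sustained, and ``delta_s`` the speed increment between stages.
    Units are km/h, as conventionally reported for treadmill protocols.
    """

    s_vo2max: float  # km/h
    alpha: float  # in [0, 1]
    delta_s: float = 1.0  # km/h

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not self.delta_s > 0:
            raise ValueError(f"delta_s must be positive, got {self.delta_s}")
        if not self.s_vo2max > 0:
            raise ValueError(f"s_vo2max must be positive, got {self.s_vo2max}")


def _check_above_cs(params: CSParameters, s) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if np.any(s <= params.cs):
        raise ValueError(
            f"speed must exceed CS = {params.cs} m/s (time to exhaustion is "
            "unbounded at or below CS); got speed <= CS"
        )
    return s


def _maybe_scalar(x: np.ndarray, scalar: bool):
    return float(x) if scalar else x


def predict_time(params: CSParameters, s):
    """Time to exhaustion t(s) = d' / (s - CS) at speed ``s`` (m/s).

    Strictly decreasing on (CS, inf) with a vertical asymptote at CS.
    Raises ``ValueError`` for s <= CS.
    """
    scalar = np.ndim(s) == 0
    s = _check_above_cs(params, s)
    return _maybe_scalar(params.d_prime / (s - params.cs), scalar)


def predict_distance_from_speed(params: CSParameters, s):
    """Distance d(s) = s * d' / (s - CS) covered at speed ``s``.

    Strictly decreasing on (CS, inf), tending to d' as s -> inf.
    """
    scalar = np.ndim(s) == 0
    s = _check_above_cs(params, s)
    return _maybe_scalar(s * params.d_prime / (s - params.cs), scalar)


def predict_speed(params: CSParameters, t):
    """Highest sustainable speed s(t) = d'/t + CS for duration ``t`` (s).

    The inverse of :func:`predict_time`; approaches CS as t -> inf.
    """
    scalar = np.ndim(t) == 0
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("duration must be positive")
    return _maybe_scalar(params.d_prime / t + params.cs, scalar)


def predict_distance_from_time(params: CSParameters, t):
    """Distance d(t) = d' + CS * t coverable in time ``t`` (s).

    The linear form: slope CS, intercept d'.
    """
    scalar = np.ndim(t) == 0
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("duration must be positive")
    return _maybe_scalar(params.d_prime + params.cs * t, scalar)


def peak_speed(inc: IncrementalTestResult) -> float:
    """Peak speed of an incremental test, in the units of its inputs.

    PS = s_vo2max + alpha * delta_s: the last completed stage speed plus
    the completed fraction of the next stage times the increment.
    """
    return inc.s_vo2max + inc.alpha * inc.delta_s
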