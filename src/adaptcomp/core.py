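"""State-space models of visuomotor adaptation with implicit and explicit learners.

The central object is a pair of first-order learners, an implicit state ``x_i``
and an explicit (strategic) state ``x_e``, each updated trial-by-trial through
learning and forgetting::

    x(n+1) = a * x(n) + b * e(n)

where ``a`` is a retention factor and ``b`` an error sensitivity.  The reach
angle is ``y = x_i + x_e``.  A rotation ``r`` imposed on cursor feedback
creates two candidate teaching signals:

* target error   ``e_target = r - (x_i + x_e)`` -- reduced by both systems;
* sensory prediction error ``e_SPE = r - x_i`` -- anchored to the aim
  direction, reduced by implicit adaptation alone.

When the implicit learner is driven by target error, the explicit strategy
eats into its driving signal and the two systems *compete*; when driven by
SPE the implicit asymptote is *independent* of strategy.  All closed-form
steady states of these architectures live here, alongside the trial-level
simulators used throughout the estimation and analysis layers.

Angles are degrees everywhere; states start at zero at schedule start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FEEDBACK_MODES",
    "PROBE_TYPES",
    "UnstableParameterError",
    "LearnerParams",
    "PerturbationSchedule",
    "LearningTrace",
    "SteadyState",
    "simulate_competition",
    "simulate_independence",
    "simulate_dual_error",
    "steady_state_competition",
    "steady_state_independence",
    "coupled_steady_state",
    "implicit_gain",
    "implicit_from_total",
    "error_clamp_steady_state",
    "dual_error_steady_state",
]

FEEDBACK_MODES = frozenset({"rotated", "veridical", "none", "clamped"})
PROBE_TYPES = frozenset({"none", "exclusion", "no_feedback"})


class UnstableParameterError(ValueError):
    """Raised when learner parameters place the coupled system outside its
    stable regime (nonpositive steady-state denominator, or a divergent
    error-clamp response at full retention)."""


def _check_retention(a: float, name: str) -> None:
    if not (0.0 < a <= 1.0):
        raise ValueError(f"{name} must lie in (0, 1], got {a}")


def _check_sensitivity(b: float, name: str) -> None:
    if not (0.0 <= b < 1.0):
        raise ValueError(f"{name} must lie in [0, 1), got {b}")


def coupling_denominator(a_i: float, b_i: float, a_e: float, b_e: float) -> float:
    """Denominator of the coupled steady state,
    ``(1-a_i+b_i)(1-a_e+b_e) - b_i*b_e``.  Positive for a stable system."""
    return (1.0 - a_i + b_i) * (1.0 - a_e + b_e) - b_i * b_e


@dataclass(frozen=True)
class LearnerParams:
    """Retention and error-sensitivity parameters of the two learners.

    Parameters
    ----------
    a_i, b_i:
        Implicit retention (per update, in (0, 1]) and error sensitivity
        (in [0, 1)).
    a_e, b_e:
        Explicit retention and error sensitivity.  The defaults
        ``a_e=1, b_e=0`` describe an inert explicit system, i.e. a purely
        implicit learner.
    exposure_overrides:
        Optional ordered ``(b_i, b_e)`` pairs, one per exposure block.  When
        a schedule tags trials with an exposure index, the sensitivities of
        that exposure replace the base ones (retention is never overridden,
        mirroring how savings is modelled as a sensitivity change).
    """

    a_i: float
    b_i: float
    a_e: float = 1.0
    b_e: float = 0.0
    exposure_overrides: Optional[tuple[tuple[float, float], ...]] = None

    def __post_init__(self) -> None:
        _check_retention(self.a_i, "a_i")
        _check_retention(self.a_e, "a_e")
        _check_sensitivity(self.b_i, "b_i")
        _check_sensitivity(self.b_e, "b_e")
        if self.exposure_overrides is not None:
            object.__setattr__(
                self,
                "exposure_overrides",
                tuple((float(bi), float(be)) for bi, be in self.exposure_overrides),
            )
            for bi, be in self.exposure_overrides:
                _check_sensitivity(bi, "exposure b_i")
                _check_sensitivity(be, "exposure b_e")
        # note: the coupled denominator expands to (1-a_i)(1-a_e)
        # + (1-a_i) b_e + b_i (1-a_e) and so is never negative for valid
        # retentions; it vanishes only for pure integrators (a_i = a_e = 1),
        # which simulate fine but have no unique coupled steady state --
        # that degeneracy is policed in coupled_steady_state instead.

    def sensitivities(self, exposure: int = 0) -> tuple[float, float]:
        """(b_i, b_e) in effect during ``exposure`` (0-based block index)."""
        if self.exposure_overrides is None:
            return self.b_i, self.b_e
        if not (0 <= exposure < len(self.exposure_overrides)):
            raise ValueError(
                f"exposure {exposure} outside declared overrides "
                f"(n={len(self.exposure_overrides)})"
            )
        return self.exposure_overrides[exposure]


def _as_array(values, n: int, default, dtype) -> np.ndarray:
    if values is None:
        return np.full(n, default, dtype=dtype)
    arr = np.asarray(values, dtype=dtype)
    if arr.shape != (n,):
        raise ValueError(f"per-trial field has shape {arr.shape}, expected ({n},)")
    return arr.copy()


@dataclass
class PerturbationSchedule:
    """Per-trial rotation, feedback mode and probe structure of an experiment.

    ``rotation`` is the imposed cursor rotation in degrees.  ``feedback_mode``
    is one of rotated / veridical / none / clamped; ``clamp_error`` must be
    finite exactly on clamped trials.  ``probe`` marks exclusion ("no aiming")
    and no-feedback probe trials, on which the learners receive no error and
    purely retain.  ``exposure`` and ``block`` tag trials for parameter
    overrides and block-level analyses; ``target_id`` supports per-target
    bookkeeping.  Indices inside the schedule are 0-based; the canonical
    on-disk table is 1-based.
    """

    rotation: np.ndarray
    feedback_mode: np.ndarray = None  # type: ignore[assignment]
    clamp_error: np.ndarray = None  # type: ignore[assignment]
    probe: np.ndarray = None  # type: ignore[assignment]
    dual_target_active: np.ndarray = None  # type: ignore[assignment]
    target_id: np.ndarray = None  # type: ignore[assignment]
    exposure: np.ndarray = None  # type: ignore[assignment]
    block: np.ndarray = None  # type: ignore[assignment]
    trials_per_epoch: int = 4
    n_targets: int = 1

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        n = self.rotation.size
        if n == 0:
            raise ValueError("schedule must contain at least one trial")
        if not np.all(np.isfinite(self.rotation)):
            raise ValueError("rotation must be finite on every trial")
        if self.trials_per_epoch < 1:
            raise ValueError("trials_per_epoch must be >= 1")
        self.feedback_mode = _as_array(self.feedback_mode, n, "rotated", object)
        self.probe = _as_array(self.probe, n, "none", object)
        self.clamp_error = _as_array(self.clamp_error, n, np.nan, float)
        self.dual_target_active = _as_array(self.dual_target_active, n, False, bool)
        self.target_id = _as_array(self.target_id, n, 0, int)
        self.exposure = _as_array(self.exposure, n, 0, int)
        self.block = _as_array(self.block, n, 0, int)
        bad = set(np.unique(self.feedback_mode)) - FEEDBACK_MODES
        if bad:
            raise ValueError(f"unknown feedback modes: {sorted(bad)}")
        bad = set(np.unique(self.probe)) - PROBE_TYPES
        if bad:
            raise ValueError(f"unknown probe types: {sorted(bad)}")
        clamped = self.feedback_mode == "clamped"
        if not np.all(np.isfinite(self.clamp_error[clamped])):
            raise ValueError("clamp_error must be finite on all clamped trials")
        if np.any(np.isfinite(self.clamp_error[~clamped])):
            raise ValueError("clamp_error only allowed on clamped trials")

    @property
    def n_trials(self) -> int:
        return int(self.rotation.size)

    @property
    def epoch(self) -> np.ndarray:
        """1-based epoch index per trial (``ceil(trial / trials_per_epoch)``)."""
        return np.arange(self.n_trials) // self.trials_per_epoch + 1

    @classmethod
    def constant(cls, r: float, n_trials: int, **kwargs) -> "PerturbationSchedule":
        """A flat rotation of ``r`` degrees for ``n_trials`` trials."""
        return cls(rotation=np.full(n_trials, float(r)), **kwargs)


@dataclass
class LearningTrace:
    """Latent states, errors and reach angles of one simulated run.

    ``y = x_i + x_e`` exactly -- motor noise is added only when a synthetic
    cohort is observed, never to the latent dynamics.  Errors are NaN on
    trials where feedback was withheld (probes, no-feedback trials).
    """

    x_i: np.ndarray
    x_e: np.ndarray
    y: np.ndarray
    e_target: np.ndarray
    e_spe: np.ndarray
    aim: Optional[np.ndarray] = None
    x_i1: Optional[np.ndarray] = None
    x_i2: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return int(self.x_i.size)


@dataclass(frozen=True)
class SteadyState:
    """Closed-form asymptotes of the coupled system and the implicit gain."""

    x_i_ss: float
    x_e_ss: float
    x_T_ss: float
    p_i: float
    p_e: Optional[float] = None


def _prepare_aim(aim, n: int) -> np.ndarray:
    aim = np.asarray(aim, dtype=float)
    if aim.shape != (n,):
        raise ValueError(f"aim sequence length {aim.shape} does not match schedule ({n} trials)")
    return aim


def _trial_error(
    schedule: PerturbationSchedule, n: int, x_i: float, x_e: float, noise: float = 0.0
):
    """(e_target, e_spe, update_error_available) on trial ``n``.

    Probe trials and no-feedback trials provide no teaching signal at all;
    clamped feedback pins both error channels to the imposed clamp.
    ``noise`` is the executed-movement deviation on this trial: it shifts the
    cursor and therefore both visually experienced errors.
    """
    mode = schedule.feedback_mode[n]
    if schedule.probe[n] != "none" or mode == "none":
        return np.nan, np.nan, False
    if mode == "clamped":
        e = schedule.clamp_error[n]
        return e, e, True
    r = schedule.rotation[n]
    return r - x_i - x_e - noise, r - x_i - noise, True


def _simulate(
    params: LearnerParams,
    schedule: PerturbationSchedule,
    implicit_error: str,
    explicit_mode: str,
    aim: Optional[Sequence[float]],
    execution_noise: Optional[np.ndarray] = None,
) -> LearningTrace:
    n_trials = schedule.n_trials
    if explicit_mode not in ("state_space", "prescribed"):
        raise ValueError(f"unknown explicit_mode {explicit_mode!r}")
    if explicit_mode == "prescribed":
        aim_arr = _prepare_aim(aim, n_trials)
    elif aim is not None:
        raise ValueError("aim sequence only valid with explicit_mode='prescribed'")
    noise = _as_array(execution_noise, n_trials, 0.0, float)
    x_i = np.zeros(n_trials)
    x_e = np.zeros(n_trials)
    e_t = np.full(n_trials, np.nan)
    e_s = np.full(n_trials, np.nan)
    xi, xe = 0.0, 0.0
    for n in range(n_trials):
        if explicit_mode == "prescribed":
            xe = aim_arr[n]
        x_i[n], x_e[n] = xi, xe
        et, es, have_feedback = _trial_error(schedule, n, xi, xe, noise[n])
        e_t[n], e_s[n] = et, es
        b_i, b_e = params.sensitivities(int(schedule.exposure[n]))
        e_impl = (et if implicit_error == "target" else es) if have_feedback else 0.0
        xi = params.a_i * xi + b_i * e_impl
        if explicit_mode == "state_space":
            xe = params.a_e * xe + b_e * (et if have_feedback else 0.0)
    return LearningTrace(
        x_i=x_i,
        x_e=x_e,
        y=x_i + x_e,
        e_target=e_t,
        e_spe=e_s,
        aim=None if explicit_mode == "state_space" else x_e.copy(),
    )


def simulate_competition(
    params: LearnerParams,
    schedule: PerturbationSchedule,
    explicit_mode: str = "state_space",
    aim: Optional[Sequence[float]] = None,
    execution_noise: Optional[np.ndarray] = None,
) -> LearningTrace:
    """Simulate the competition architecture: both learners driven by target error.

    With ``explicit_mode='prescribed'`` the explicit state is pinned to the
    given ``aim`` sequence (instructed-aiming experiments); otherwise it
    evolves as its own state-space learner.  ``execution_noise`` is an
    optional per-trial motor deviation of the executed reach: it shifts the
    experienced errors (the learners respond to it) but not the latent
    states recorded in the trace.
    """
    return _simulate(params, schedule, "target", explicit_mode, aim, execution_noise)


def simulate_independence(
    params: LearnerParams,
    schedule: PerturbationSchedule,
    explicit_mode: str = "state_space",
    aim: Optional[Sequence[float]] = None,
    execution_noise: Optional[np.ndarray] = None,
) -> LearningTrace:
    """Simulate the independence (SPE-driven) architecture.

    The implicit state updates from ``e_SPE = r - x_i`` and is therefore
    unaffected by strategy; the explicit learner (if state-space) still
    responds to target error.
    """
    return _simulate(params, schedule, "spe", explicit_mode, aim, execution_noise)


def simulate_dual_error(
    params: LearnerParams,
    schedule: PerturbationSchedule,
    aim: Sequence[float],
    module2_params: Optional[tuple[float, float]] = None,
    execution_noise: Optional[np.ndarray] = None,
) -> LearningTrace:
    """Simulate the dual-target-error architecture.

    Two implicit sub-modules adapt in parallel: module 1 to the primary
    target error ``e1 = r - x_i - x_e`` and module 2 to the aim-anchored
    error ``e2 = r - x_i``, but only on trials where the aiming landmark is
    present (``schedule.dual_target_active``); elsewhere module 2 purely
    retains.  Both modules share ``(a_i, b_i)`` unless ``module2_params``
    supplies a distinct pair.  The explicit state is the prescribed ``aim``.
    """
    n_trials = schedule.n_trials
    aim_arr = _prepare_aim(aim, n_trials)
    a2, b2_base = module2_params if module2_params is not None else (params.a_i, params.b_i)
    _check_retention(a2, "module-2 a_i")
    _check_sensitivity(b2_base, "module-2 b_i")
    noise = _as_array(execution_noise, n_trials, 0.0, float)
    x_i1 = np.zeros(n_trials)
    x_i2 = np.zeros(n_trials)
    x_e = np.zeros(n_trials)
    e_t = np.full(n_trials, np.nan)
    e_s = np.full(n_trials, np.nan)
    x1, x2 = 0.0, 0.0
    for n in range(n_trials):
        xe = aim_arr[n]
        xi = x1 + x2
        x_i1[n], x_i2[n], x_e[n] = x1, x2, xe
        e1, e2, have_feedback = _trial_error(schedule, n, xi, xe, noise[n])
        e_t[n], e_s[n] = e1, e2
        b_i, _ = params.sensitivities(int(schedule.exposure[n]))
        b2 = b2_base if module2_params is not None else b_i
        x1 = params.a_i * x1 + b_i * (e1 if have_feedback else 0.0)
        active = have_feedback and bool(schedule.dual_target_active[n])
        x2 = a2 * x2 + b2 * (e2 if active else 0.0)
    x_i = x_i1 + x_i2
    return LearningTrace(
        x_i=x_i,
        x_e=x_e,
        y=x_i + x_e,
        e_target=e_t,
        e_spe=e_s,
        aim=x_e.copy(),
        x_i1=x_i1,
        x_i2=x_i2,
    )


# ---------------------------------------------------------------------------
# Closed-form steady states


def steady_state_competition(a_i: float, b_i: float, r: float, x_e_ss: float) -> float:
    """Implicit asymptote under target-error learning with a fixed explicit
    strategy: ``b_i / (1 - a_i + b_i) * (r - x_e_ss)``."""
    _check_retention(a_i, "a_i")
    _check_sensitivity(b_i, "b_i")
    return b_i / (1.0 - a_i + b_i) * (r - x_e_ss)


def steady_state_independence(a_i: float, b_i: float, r: float) -> float:
    """Implicit asymptote under SPE learning: ``b_i / (1 - a_i + b_i) * r``.
    Depends on the rotation alone, never on strategy."""
    _check_retention(a_i, "a_i")
    _check_sensitivity(b_i, "b_i")
    return b_i / (1.0 - a_i + b_i) * r


def implicit_gain(a_i: float, b_i: float) -> float:
    """The implicit learning gain ``p_i = b_i / (1 - a_i + b_i)``, in [0, 1]."""
    _check_retention(a_i, "a_i")
    _check_sensitivity(b_i, "b_i")
    if b_i == 0.0 and a_i == 1.0:
        return 1.0  # limit of b/(b) as the state becomes a pure integrator
    return b_i / (1.0 - a_i + b_i)


def implicit_from_total(p_i: float, r: float, x_T_ss: float) -> float:
    """Implicit asymptote expressed against *total* learning:
    ``p_i / (1 - p_i) * (r - x_T_ss)``.

    Algebraically identical to the competition form after substituting
    ``x_T = x_i + x_e``; useful when only total adaptation is observed.
    """
    if not (0.0 <= p_i < 1.0):
        raise ValueError(f"p_i must lie in [0, 1) for the total-learning form, got {p_i}")
    return p_i / (1.0 - p_i) * (r - x_T_ss)


def coupled_steady_state(params: LearnerParams, r: float, exposure: int = 0) -> SteadyState:
    """Joint asymptote of two coupled target-error learners.

    ``x_i_ss = b_i (1 - a_e) r / D`` and ``x_e_ss = b_e (1 - a_i) r / D``
    with ``D = (1 - a_i + b_i)(1 - a_e + b_e) - b_i b_e``.  Raises
    :class:`UnstableParameterError` when ``D <= 0`` (both learners pure
    integrators: the asymptote split is then degenerate).
    """
    b_i, b_e = params.sensitivities(exposure)
    d = coupling_denominator(params.a_i, b_i, params.a_e, b_e)
    if d <= 0.0:
        raise UnstableParameterError(f"nonpositive steady-state denominator {d:g}")
    x_i = b_i * (1.0 - params.a_e) * r / d
    x_e = b_e * (1.0 - params.a_i) * r / d
    return SteadyState(
        x_i_ss=x_i,
        x_e_ss=x_e,
        x_T_ss=x_i + x_e,
        p_i=implicit_gain(params.a_i, b_i),
    )


def error_clamp_steady_state(a_i: float, b_i: float, r: float) -> float:
    """Implicit asymptote under an invariant error clamp of size ``r``:
    ``b_i / (1 - a_i) * r``.

    The clamp severs the feedback loop, so the state integrates the fixed
    error until forgetting balances it -- the asymptote can exceed the
    rotation many-fold.  ``a_i = 1`` diverges and raises.
    """
    _check_retention(a_i, "a_i")
    _check_sensitivity(b_i, "b_i")
    if b_i == 0.0:
        return 0.0
    if a_i >= 1.0:
        raise UnstableParameterError("error-clamp steady state diverges at a_i = 1")
    return b_i / (1.0 - a_i) * r


def dual_error_steady_state(a_i: float, b_i: float, r: float, aim: float) -> float:
    """Implicit asymptote of the dual-error model with constant aim ``A``:
    ``b_i (2r - A) / (1 - a_i + 2 b_i)``.

    With both modules active the two errors sum to ``2r - A - 2 x_i`` at
    steady state; opposing errors cancel exactly when ``A = 2r``.
    """
    _check_retention(a_i, "a_i")
    _check_sensitivity(b_i, "b_i")
    return b_i * (2.0 * r - aim) / (1.0 - a_i + 2.0 * b_i)
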