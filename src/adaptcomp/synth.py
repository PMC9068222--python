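"""Synthetic cohorts emulating visuomotor-rotation experiment designs.

Generates perturbation schedules (abrupt, stepwise, gradual ramp, A-B
interference, error clamp, washout savings) and noisy per-subject trial
tables with the statistical structure the analyses assume: a shared implicit
learner, inter-subject variability concentrated on the explicit side (the
dominant source of individual differences in strategy use), additive
Gaussian motor noise on the observed reach, and exclusion ("no aiming")
probes that reveal the implicit state without updating it.

The latent dynamics are noiseless; noise enters only at observation.  Every
dataset retains its generating truth so estimators can be validated by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core import (
    LearnerParams,
    LearningTrace,
    PerturbationSchedule,
    simulate_competition,
    simulate_dual_error,
    simulate_independence,
)

__all__ = [
    "CohortSpec",
    "CohortDataset",
    "make_schedule",
    "generate_cohort",
    "recovery_report",
]

DEFAULT_MOTOR_NOISE_SD = 3.0  # degrees, typical reach endpoint variability


# ---------------------------------------------------------------------------
# Schedules


def _segment(n, r, **kw):
    base = {
        "rotation": np.full(n, float(r)),
        "feedback_mode": np.full(n, "rotated", dtype=object),
        "probe": np.full(n, "none", dtype=object),
        "clamp_error": np.full(n, np.nan),
        "dual_target_active": np.zeros(n, dtype=bool),
        "block": np.zeros(n, dtype=int),
        "exposure": np.zeros(n, dtype=int),
    }
    base.update({k: np.asarray(v) for k, v in kw.items()})
    return base


def _concat(segments, trials_per_epoch, n_targets):
    keys = segments[0].keys()
    data = {k: np.concatenate([s[k] for s in segments]) for k in keys}
    n = data["rotation"].size
    target_id = np.arange(n) % n_targets
    return PerturbationSchedule(
        rotation=data["rotation"],
        feedback_mode=data["feedback_mode"],
        clamp_error=data["clamp_error"],
        probe=data["probe"],
        dual_target_active=data["dual_target_active"],
        target_id=target_id,
        exposure=data["exposure"],
        block=data["block"],
        trials_per_epoch=trials_per_epoch,
        n_targets=n_targets,
    )


def _with_probes(seg: dict, positions, n_probe: int) -> dict:
    """Insert exclusion probe markers (no feedback, no update) at positions."""
    for pos in positions:
        for k in range(n_probe):
            idx = min(pos + k, seg["rotation"].size - 1)
            seg["probe"][idx] = "exclusion"
            seg["feedback_mode"][idx] = "none"
    return seg


def make_schedule(kind: str, **config) -> PerturbationSchedule:
    """Build a trial-accurate perturbation schedule.

    Kinds
    -----
    ``abrupt``
        Baseline epochs of null trials, then a constant rotation, then an
        optional terminal no-feedback decay period (``decay_epochs``) and
        terminal exclusion probes.
    ``stepwise``
        The rotation climbs through ``steps`` (default 15/30/45/60 degrees),
        each held for ``trials_per_block`` trials with two exclusion-probe
        sets per block (at ~75% and at the block end).
    ``gradual_ramp``
        Linear ramp to ``rotation`` over ``ramp_trials`` then hold.
    ``ab_interference``
        Baseline, exposure A at ``+rotation``, short no-feedback break,
        exposure B at ``-rotation``.
    ``error_clamp``
        Baseline then invariant clamped error of ``clamp_error`` degrees.
    ``washout_savings``
        Baseline, exposure 1, veridical washout, exposure 2 (same sign);
        exposures are tagged 0 and 1 for sensitivity overrides.
    """
    tpe = int(config.get("trials_per_epoch", 4))
    n_targets = int(config.get("n_targets", tpe))
    baseline_epochs = int(config.get("baseline_epochs", 10))
    nb = baseline_epochs * tpe

    if kind == "abrupt":
        r = float(config.get("rotation", 30.0))
        rot_epochs = int(config.get("rotation_epochs", 60))
        decay_epochs = int(config.get("decay_epochs", 0))
        probe_epochs = int(config.get("probe_epochs", 0))
        segs = [
            _segment(nb, 0.0, feedback_mode=np.full(nb, "veridical", dtype=object)),
            _segment(rot_epochs * tpe, r, block=np.ones(rot_epochs * tpe, dtype=int)),
        ]
        if probe_epochs:
            n = probe_epochs * tpe
            segs.append(
                _segment(
                    n, r,
                    feedback_mode=np.full(n, "none", dtype=object),
                    probe=np.full(n, "exclusion", dtype=object),
                    block=np.ones(n, dtype=int),
                )
            )
        if decay_epochs:
            n = decay_epochs * tpe
            segs.append(
                _segment(
                    n, r,
                    feedback_mode=np.full(n, "none", dtype=object),
                    probe=np.full(n, "no_feedback", dtype=object),
                    block=np.full(n, 2, dtype=int),
                )
            )
        return _concat(segs, tpe, n_targets)

    if kind == "stepwise":
        steps = list(config.get("steps", (15.0, 30.0, 45.0, 60.0)))
        if not steps or any(s <= 0 for s in steps):
            raise ValueError("stepwise steps must be positive")
        tpb = int(config.get("trials_per_block", 66))
        segs = [_segment(nb, 0.0, feedback_mode=np.full(nb, "veridical", dtype=object))]
        for j, r in enumerate(steps, start=1):
            seg = _segment(tpb, r, block=np.full(tpb, j, dtype=int))
            _with_probes(
                seg,
                positions=(int(0.75 * tpb) - n_targets, tpb - n_targets),
                n_probe=n_targets,
            )
            segs.append(seg)
        return _concat(segs, tpe, n_targets)

    if kind == "gradual_ramp":
        r = float(config.get("rotation", 30.0))
        ramp = int(config.get("ramp_trials", 120))
        hold = int(config.get("hold_trials", 120))
        if ramp < 1 or hold < 0 or r == 0:
            raise ValueError("ramp configuration must be positive")
        rotation = np.concatenate(
            [np.zeros(nb), np.linspace(r / ramp, r, ramp), np.full(hold, r)]
        )
        fb = np.full(rotation.size, "rotated", dtype=object)
        fb[:nb] = "veridical"
        block = np.zeros(rotation.size, dtype=int)
        block[nb:] = 1
        seg = _segment(rotation.size, 0.0, rotation=rotation, feedback_mode=fb, block=block)
        return _concat([seg], tpe, n_targets)

    if kind == "ab_interference":
        r = float(config.get("rotation", 30.0))
        exp_epochs = int(config.get("exposure_epochs", 60))
        n = exp_epochs * tpe
        nbrk = int(config.get("break_trials", tpe))
        segs = [
            _segment(nb, 0.0, feedback_mode=np.full(nb, "veridical", dtype=object)),
            _segment(n, r, block=np.ones(n, dtype=int)),
            _segment(
                nbrk, 0.0,
                feedback_mode=np.full(nbrk, "none", dtype=object),
                probe=np.full(nbrk, "no_feedback", dtype=object),
                block=np.ones(nbrk, dtype=int),
            ),
            _segment(n, -r, block=np.full(n, 2, dtype=int), exposure=np.ones(n, dtype=int)),
        ]
        return _concat(segs, tpe, n_targets)

    if kind == "error_clamp":
        e = float(config.get("clamp_error", 5.0))
        n = int(config.get("clamp_trials", 240))
        segs = [
            _segment(nb, 0.0, feedback_mode=np.full(nb, "veridical", dtype=object)),
            _segment(
                n, 0.0,
                feedback_mode=np.full(n, "clamped", dtype=object),
                clamp_error=np.full(n, e),
                block=np.ones(n, dtype=int),
            ),
        ]
        return _concat(segs, tpe, n_targets)

    if kind == "washout_savings":
        r = float(config.get("rotation", 30.0))
        exp_epochs = int(config.get("exposure_epochs", 60))
        washout_epochs = int(config.get("washout_epochs", 70))
        n, nw = exp_epochs * tpe, washout_epochs * tpe
        segs = [
            _segment(nb, 0.0, feedback_mode=np.full(nb, "veridical", dtype=object)),
            _segment(n, r, block=np.ones(n, dtype=int)),
            _segment(
                nw, 0.0,
                feedback_mode=np.full(nw, "veridical", dtype=object),
                block=np.full(nw, 2, dtype=int),
            ),
            _segment(n, r, block=np.full(n, 3, dtype=int), exposure=np.ones(n, dtype=int)),
        ]
        return _concat(segs, tpe, n_targets)

    raise ValueError(f"unknown schedule kind {kind!r}")


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``param_distributions`` maps parameter names (``a_i``, ``b_i``, ``a_e``,
    ``b_e``, ``p_e``) to ``(mean, sd, (lo, hi))`` truncated-normal draws; any
    parameter not listed is fixed at its value in ``params``.  By default
    only the explicit side varies between subjects (``b_e`` for state-space
    models, ``p_e`` or ``b_i`` for the explicit-responds rival, where the
    implicit side carries the variability).
    """

    n_subjects: int
    schedule: PerturbationSchedule
    params: LearnerParams
    model: str = "competition"
    param_distributions: Optional[Mapping[str, tuple]] = None
    motor_noise_sd: float = DEFAULT_MOTOR_NOISE_SD
    noise_in_dynamics: bool = True
    p_e: float = 0.5
    aim: Optional[np.ndarray] = None
    probe_generalization: Optional[object] = None  # GeneralizationCurve
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.motor_noise_sd < 0:
            raise ValueError("motor_noise_sd must be >= 0")
        if self.model not in ("competition", "independence", "dual_error", "explicit_responds"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "dual_error" and self.aim is None:
            raise ValueError("dual_error cohorts need an aim sequence")


@dataclass
class CohortDataset:
    """Observed trial tables plus the hidden generating truth."""

    table: pd.DataFrame
    truth: dict[str, dict]
    schedule: PerturbationSchedule
    spec: CohortSpec


def _draw_param(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    raise ValueError(f"could not draw a value in [{lo}, {hi}] around {mean} +/- {sd}")


def _subject_params(spec: CohortSpec, rng: np.random.Generator) -> tuple[LearnerParams, float]:
    dists = dict(spec.param_distributions or {})
    if not dists:
        if spec.model == "explicit_responds":
            # variability rides on the implicit side; strategy responds
            dists = {"b_i": (spec.params.b_i, 0.25 * spec.params.b_i, (0.01, 0.95))}
        elif spec.params.b_e > 0:
            dists = {"b_e": (spec.params.b_e, 0.25 * spec.params.b_e, (0.0, 0.95))}
    values = {
        "a_i": spec.params.a_i,
        "b_i": spec.params.b_i,
        "a_e": spec.params.a_e,
        "b_e": spec.params.b_e,
        "p_e": spec.p_e,
    }
    for _ in range(1000):
        trial = dict(values)
        for name, (mean, sd, bounds) in dists.items():
            if name not in trial:
                raise ValueError(f"unknown parameter {name!r} in distributions")
            trial[name] = _draw_param(rng, mean, sd, *bounds)
        try:
            params = LearnerParams(
                a_i=trial["a_i"],
                b_i=trial["b_i"],
                a_e=trial["a_e"],
                b_e=trial["b_e"],
                exposure_overrides=spec.params.exposure_overrides,
            )
            return params, float(trial["p_e"])
        except ValueError:
            continue
    raise ValueError("rejection sampling failed to produce valid learner parameters")


def _simulate_subject(
    spec: CohortSpec, params: LearnerParams, p_e: float, noise: Optional[np.ndarray]
) -> LearningTrace:
    if spec.model == "competition":
        return simulate_competition(params, spec.schedule, execution_noise=noise)
    if spec.model == "independence":
        return simulate_independence(params, spec.schedule, execution_noise=noise)
    if spec.model == "dual_error":
        return simulate_dual_error(params, spec.schedule, spec.aim, execution_noise=noise)
    # explicit_responds: SPE-driven implicit state; the strategy tracks the
    # residual error algebraically, x_e(n) = p_e (r(n) - x_i(n))
    trace = simulate_independence(params, spec.schedule, explicit_mode="prescribed",
                                  aim=np.zeros(spec.schedule.n_trials),
                                  execution_noise=noise)
    x_e = p_e * (spec.schedule.rotation - trace.x_i)
    return LearningTrace(
        x_i=trace.x_i,
        x_e=x_e,
        y=trace.x_i + x_e,
        e_target=trace.e_target,
        e_spe=trace.e_spe,
    )


def generate_cohort(spec: CohortSpec) -> CohortDataset:
    """Simulate a cohort and observe it through motor noise.

    The observed reach equals ``x_i + x_e + eps`` on ordinary trials and
    ``x_i + eps`` on exclusion probes (strategy withheld), with
    ``eps ~ N(0, motor_noise_sd)`` i.i.d.  By default (``noise_in_dynamics``)
    the same ``eps`` is the executed motor deviation, so it also shifts the
    errors the learners experience on feedback trials -- the physically
    realistic coupling between movement variability and the teaching signal.
    With ``noise_in_dynamics=False`` the latent dynamics are noiseless and
    ``eps`` is pure observation noise.  Identical specs (including seed)
    give identical datasets.
    """
    rng = np.random.default_rng(spec.seed)
    sched = spec.schedule
    n = sched.n_trials
    exclusion = sched.probe == "exclusion"
    target_deg = sched.target_id * (360.0 / max(sched.n_targets, 1))
    epoch = sched.epoch
    frames = []
    truth: dict[str, dict] = {}
    width = max(2, len(str(spec.n_subjects)))
    for s in range(spec.n_subjects):
        params, p_e = _subject_params(spec, rng)
        noise = (
            rng.normal(0.0, spec.motor_noise_sd, size=n)
            if spec.motor_noise_sd
            else np.zeros(n)
        )
        trace = _simulate_subject(
            spec, params, p_e, noise if spec.noise_in_dynamics else None
        )
        probe_implicit = trace.x_i
        if spec.probe_generalization is not None:
            # probe at the training target samples an aim-centred adapted
            # response: the measured implicit value is attenuated by g(x_e)
            probe_implicit = trace.x_i * np.asarray(
                spec.probe_generalization(trace.x_e), dtype=float
            )
        observed = np.where(exclusion, probe_implicit, trace.y) + noise
        sid = f"S{s + 1:0{width}d}"
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "trial": np.arange(1, n + 1),
                    "epoch": epoch,
                    "target_deg": target_deg,
                    "rotation_deg": sched.rotation,
                    "feedback_mode": sched.feedback_mode,
                    "probe_type": sched.probe,
                    "reach_angle_deg": observed,
                    "clamp_error_deg": sched.clamp_error,
                    "block": sched.block,
                    "exposure": sched.exposure,
                }
            )
        )
        truth[sid] = {"params": params, "p_e": p_e, "trace": trace}
    return CohortDataset(
        table=pd.concat(frames, ignore_index=True),
        truth=truth,
        schedule=sched,
        spec=spec,
    )


def recovery_report(truth: pd.DataFrame, estimates: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter bias, RMSE and (optionally) CI coverage of estimates.

    Both frames are indexed by subject with one column per parameter;
    ``estimates`` may additionally carry ``<name>_ci_low`` / ``<name>_ci_high``
    columns, in which case coverage of the truth is reported.  Subject ids
    must match exactly.
    """
    if not truth.index.equals(estimates.index):
        if set(truth.index) != set(estimates.index):
            raise ValueError("truth and estimate subject ids do not match")
        estimates = estimates.loc[truth.index]
    rows = []
    for name in truth.columns:
        if name not in estimates.columns:
            continue
        err = estimates[name].to_numpy(float) - truth[name].to_numpy(float)
        row = {
            "parameter": name,
            "bias": float(np.mean(err)),
            "rmse": float(np.sqrt(np.mean(err**2))),
            "coverage": np.nan,
        }
        lo, hi = f"{name}_ci_low", f"{name}_ci_high"
        if lo in estimates.columns and hi in estimates.columns:
            inside = (truth[name] >= estimates[lo]) & (truth[name] <= estimates[hi])
            row["coverage"] = float(np.mean(inside))
        rows.append(row)
    if not rows:
        raise ValueError("no common parameters between truth and estimates")
    return pd.DataFrame(rows).set_index("parameter")
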