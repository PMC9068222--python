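"""Parameter estimation and rate metrics for adaptation data.

Covers every estimator the analysis layer relies on:

* retention from no-feedback decay (geometric fit);
* epoch <-> trial retention conversion;
* trial-wise empirical error sensitivity with MAD outlier filtering;
* tied bounded-least-squares fits of the state-space architectures;
* subject-level bootstrap with percentile intervals;
* baseline-constrained exponential learning-rate fits and the savings /
  anterograde-interference metrics built on them;
* Gaussian-likelihood AIC and per-subject model comparison;
* ordinary least squares with t-based confidence intervals.

Nonconvex fits (state space, exponential) use bounded least squares with
seeded multi-start; all resampling flows from an explicit seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import (
    LearnerParams,
    PerturbationSchedule,
    simulate_competition,
    simulate_dual_error,
    simulate_independence,
)

__all__ = [
    "FitResult",
    "ExponentialFit",
    "Observation",
    "SensitivityResult",
    "BootstrapResult",
    "LinearFit",
    "fit_retention",
    "convert_retention",
    "empirical_error_sensitivity",
    "fit_state_space",
    "bootstrap",
    "fit_exponential",
    "savings_metrics",
    "interference_metrics",
    "SavingsMetrics",
    "aic",
    "model_compare",
    "linfit_ci",
]


# ---------------------------------------------------------------------------
# Retention


def fit_retention(decay_sequence: Sequence[float], y_ss: float) -> float:
    """Retention factor from a no-feedback decay, ``y(n) = a^n * y_ss``.

    ``decay_sequence[k]`` is the reach on the k-th error-free step after the
    asymptote (n = k+1).  Returns the least-squares ``a`` in (0, 1].
    A sequence whose mean sign disagrees with ``y_ss`` triggers a warning but
    the fit proceeds.
    """
    y = np.asarray(decay_sequence, dtype=float)
    if y.size == 0:
        raise ValueError("decay sequence is empty")
    if y_ss == 0:
        raise ValueError("y_ss must be nonzero")
    if np.sign(np.mean(y)) * np.sign(y_ss) < 0:
        warnings.warn("decay sequence sign disagrees with y_ss; fitting anyway")
    n = np.arange(1, y.size + 1)

    def sse(a: float) -> float:
        return float(np.sum((y - a**n * y_ss) ** 2))

    res = optimize.minimize_scalar(sse, bounds=(1e-9, 1.0), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)


def convert_retention(a: float, k: int, direction: str = "per_step_root") -> float:
    """Convert a retention factor across time scales.

    ``per_step_root`` maps a k-step (epoch/cycle) factor to its per-step
    value ``a**(1/k)``; ``compound`` maps a per-step factor to the k-step
    value ``a**k``.
    """
    if not (0.0 < a <= 1.0):
        raise ValueError(f"retention must lie in (0, 1], got {a}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if direction == "per_step_root":
        return float(a ** (1.0 / k))
    if direction == "compound":
        return float(a**k)
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# Empirical error sensitivity


@dataclass
class SensitivityResult:
    """Per-visit error-sensitivity estimates and their steady-state summary."""

    table: pd.DataFrame  # columns: target, trial, epoch, b, outlier
    summary: float
    n_zero_error: int
    n_used: int


def empirical_error_sensitivity(
    visits: pd.DataFrame,
    retention: float,
    filter: str = "mad",
    window_epochs: int = 10,
    mad_thresh: float = 3.0,
    terminal_window: int | tuple[int, int] = 5,
    trials_per_epoch: int = 1,
) -> SensitivityResult:
    """Trial-wise error sensitivity from its empirical definition.

    For consecutive visits to the same target on trials ``n1 < n2``::

        b(n1) = (y(n2) - a^(n2-n1) * y(n1)) / e(n1)

    ``visits`` must have columns ``target``, ``trial``, ``y``, ``e`` (reach
    and experienced error, degrees).  Pairs with ``e(n1) == 0`` are dropped
    and counted.  With ``filter='mad'``, estimates deviating from the median
    of a centred ``window_epochs``-epoch window by more than ``mad_thresh``
    raw median absolute deviations are flagged as outliers (edge windows
    truncate).  The summary is the mean of retained estimates inside
    ``terminal_window`` -- either the last k epochs (int) or an inclusive
    ``(first, last)`` epoch range.
    """
    required = {"target", "trial", "y", "e"}
    if not required.issubset(visits.columns):
        raise ValueError(f"visits needs columns {sorted(required)}")
    if not (0.0 < retention <= 1.0):
        raise ValueError("retention must lie in (0, 1]")
    rows = []
    n_zero = 0
    for target, grp in visits.groupby("target", sort=False):
        grp = grp.sort_values("trial")
        if len(grp) < 2:
            continue
        t = grp["trial"].to_numpy(float)
        y = grp["y"].to_numpy(float)
        e = grp["e"].to_numpy(float)
        gap = np.diff(t)
        e1 = e[:-1]
        zero = e1 == 0.0
        n_zero += int(zero.sum())
        b = np.where(zero, np.nan, (y[1:] - retention**gap * y[:-1]) / np.where(zero, 1.0, e1))
        keep = ~zero
        rows.append(
            pd.DataFrame({"target": target, "trial": t[:-1][keep], "b": b[keep]})
        )
    if not rows:
        raise ValueError("need at least 2 visits to some target")
    table = pd.concat(rows, ignore_index=True).sort_values("trial").reset_index(drop=True)
    table["epoch"] = ((table["trial"] - 1) // trials_per_epoch + 1).astype(int)
    table["outlier"] = False
    if filter == "mad":
        half = window_epochs // 2
        epochs = table["epoch"].to_numpy()
        b_all = table["b"].to_numpy()
        flags = np.zeros(len(table), dtype=bool)
        for i in range(len(table)):
            sel = np.abs(epochs - epochs[i]) <= half
            window = b_all[sel]
            med = np.median(window)
            mad = np.median(np.abs(window - med))
            if mad > 0 and abs(b_all[i] - med) > mad_thresh * mad:
                flags[i] = True
        table["outlier"] = flags
    elif filter != "none":
        raise ValueError(f"unknown filter {filter!r}")
    kept = table.loc[~table["outlier"]]
    max_epoch = int(table["epoch"].max())
    if isinstance(terminal_window, tuple):
        lo, hi = terminal_window
    else:
        lo, hi = max_epoch - int(terminal_window) + 1, max_epoch
    terminal = kept.loc[(kept["epoch"] >= lo) & (kept["epoch"] <= hi), "b"]
    summary = float(terminal.mean()) if len(terminal) else float("nan")
    return SensitivityResult(
        table=table, summary=summary, n_zero_error=n_zero, n_used=int(len(terminal))
    )


# ---------------------------------------------------------------------------
# Tied state-space fits


@dataclass
class Observation:
    """One observed reach series with its schedule and observation map.

    ``observed_state`` declares, per trial, which latent combination the
    reach angle reports: ``"total"`` (x_i + x_e) on ordinary / high-PT
    trials, ``"implicit"`` (x_i alone) on exclusion / low-PT trials.  NaNs in
    ``observed`` mark unmeasured trials.  ``aim`` is required for the
    dual-error model.
    """

    schedule: PerturbationSchedule
    observed: np.ndarray
    observed_state: np.ndarray | str = "total"
    aim: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        n = self.schedule.n_trials
        if self.observed.shape != (n,):
            raise ValueError("observed series length must match schedule")
        if isinstance(self.observed_state, str):
            self.observed_state = np.full(n, self.observed_state, dtype=object)
        else:
            self.observed_state = np.asarray(self.observed_state, dtype=object)
            if self.observed_state.shape != (n,):
                raise ValueError("observation map length must match schedule")
        bad = set(np.unique(self.observed_state)) - {"total", "implicit"}
        if bad:
            raise ValueError(f"unknown observation states: {sorted(bad)}")


@dataclass
class FitResult:
    """Outcome of a tied least-squares fit."""

    estimates: dict[str, float]
    rss: float
    n_obs: int
    k_params: int
    aic: float
    tie_map: dict
    flags: list[str] = field(default_factory=list)
    bootstrap: Optional["BootstrapResult"] = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"parameter": k, "estimate": v, "rss": self.rss, "aic": self.aic}
            for k, v in self.estimates.items()
        ]
        return pd.DataFrame(rows)


_PARAM_BOUNDS = {"a_i": (0.5, 1.0), "a_e": (0.5, 1.0), "b_i": (0.0, 0.999), "b_e": (0.0, 0.999)}
_SIMULATORS = {
    "competition": simulate_competition,
    "independence": simulate_independence,
}


def _build_design(tie_map: Mapping, n_exposures: int, n_obs: int):
    """Flatten the tie declaration into a free-parameter vector layout."""
    layout = []  # (name, slot_count, kind)
    fixed = {}
    for name in ("a_i", "a_e", "b_i", "b_e"):
        spec = tie_map.get(name, "shared")
        if isinstance(spec, (int, float)):
            fixed[name] = float(spec)
        elif spec == "shared":
            layout.append((name, 1, "shared"))
        elif spec == "per_exposure":
            layout.append((name, n_exposures, "per_exposure"))
        elif spec == "per_observation":
            layout.append((name, n_obs, "per_observation"))
        else:
            raise ValueError(f"unknown tie for {name!r}: {spec!r}")
    unknown = set(tie_map) - {"a_i", "a_e", "b_i", "b_e"}
    if unknown:
        raise ValueError(f"tie_map references unknown parameters: {sorted(unknown)}")
    return layout, fixed


def _unpack(theta, layout, fixed, n_exposures, obs_index):
    """Parameter values for one observation as (a_i, a_e, b_i_per_exp, b_e_per_exp)."""
    values = dict(fixed)
    pos = 0
    for name, count, kind in layout:
        block = theta[pos : pos + count]
        pos += count
        if kind == "shared":
            values[name] = block[0]
        elif kind == "per_exposure":
            values[name] = np.asarray(block)
        else:
            values[name] = block[obs_index]
    out = {}
    for name in ("a_i", "a_e", "b_i", "b_e"):
        v = values[name]
        out[name] = v
    return out


def _params_for(values: dict, n_exposures: int) -> LearnerParams:
    b_i, b_e = values["b_i"], values["b_e"]
    bi_arr = np.broadcast_to(np.asarray(b_i, float), (n_exposures,))
    be_arr = np.broadcast_to(np.asarray(b_e, float), (n_exposures,))
    overrides = tuple(zip(bi_arr.tolist(), be_arr.tolist()))
    return LearnerParams(
        a_i=float(values["a_i"]),
        b_i=float(bi_arr[0]),
        a_e=float(values["a_e"]),
        b_e=float(be_arr[0]),
        exposure_overrides=overrides,
    )


def fit_state_space(
    observations: Sequence[Observation],
    model: str = "competition",
    tie_map: Optional[Mapping] = None,
    n_starts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Bounded least-squares fit of a learner architecture to observed reaches.

    ``tie_map`` maps each of ``a_i, a_e, b_i, b_e`` to ``"shared"`` (one
    value across everything, the default), ``"per_exposure"``,
    ``"per_observation"``, or a fixed numeric value.  The cost is the summed
    squared difference between predicted and observed reach angles over all
    measured trials of all observations, with the prediction taken from the
    latent state each trial reports (total vs implicit).  Restarts are drawn
    uniformly within bounds from a seeded generator and the best optimum is
    kept.
    """
    if len(observations) == 0:
        raise ValueError("no observations to fit")
    if model not in ("competition", "independence", "dual_error"):
        raise ValueError(f"unknown model {model!r}")
    tie_map = dict(tie_map or {})
    if model == "dual_error":
        tie_map.setdefault("a_e", 1.0)
        tie_map.setdefault("b_e", 0.0)
        for obs in observations:
            if obs.aim is None:
                raise ValueError("dual_error fits require an aim sequence per observation")
    n_exposures = max(int(obs.schedule.exposure.max()) + 1 for obs in observations)
    layout, fixed = _build_design(tie_map, n_exposures, len(observations))
    masks = [np.isfinite(obs.observed) for obs in observations]
    n_obs_total = int(sum(m.sum() for m in masks))
    if n_obs_total == 0:
        raise ValueError("all trials unobservable; fit is unidentifiable")
    flags = []
    any_implicit = any(
        np.any(obs.observed_state[m] == "implicit") for obs, m in zip(observations, masks)
    )
    free_explicit = any(name in ("a_e", "b_e") for name, _, _ in layout)
    if model == "competition" and free_explicit and not any_implicit:
        flags.append("no_implicit_observations")

    def residuals(theta: np.ndarray) -> np.ndarray:
        res = []
        for k, (obs, m) in enumerate(zip(observations, masks)):
            values = _unpack(theta, layout, fixed, n_exposures, k)
            try:
                params = _params_for(values, n_exposures)
            except ValueError:
                return np.full(n_obs_total, 1e6)
            if model == "dual_error":
                trace = simulate_dual_error(params, obs.schedule, obs.aim)
            else:
                trace = _SIMULATORS[model](params, obs.schedule)
            pred = np.where(obs.observed_state == "implicit", trace.x_i, trace.y)
            res.append(pred[m] - obs.observed[m])
        return np.concatenate(res)

    lower, upper, names = [], [], []
    for name, count, kind in layout:
        lo, hi = _PARAM_BOUNDS[name]
        lower += [lo] * count
        upper += [hi] * count
        if count == 1:
            names.append(name)
        else:
            names += [f"{name}[{j}]" for j in range(count)]
    lower, upper = np.array(lower), np.array(upper)
    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        x0 = rng.uniform(lower, upper) if start else 0.5 * (lower + upper)
        sol = optimize.least_squares(residuals, x0, bounds=(lower, upper), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
    rss = float(np.sum(best.fun**2))
    k_params = int(lower.size)
    estimates = dict(zip(names, best.x.tolist()))
    for name, value in fixed.items():
        estimates.setdefault(name, value)
    return FitResult(
        estimates=estimates,
        rss=rss,
        n_obs=n_obs_total,
        k_params=k_params,
        aic=aic(rss, n_obs_total, k_params) if rss > 0 else float("nan"),
        tie_map=tie_map,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Bootstrap


@dataclass
class BootstrapResult:
    samples: np.ndarray
    mean: float | np.ndarray
    sd: float | np.ndarray
    ci_low: float | np.ndarray
    ci_high: float | np.ndarray


def bootstrap(
    cohort_values,
    statistic: Callable,
    n_boot: int = 10_000,
    seed: int = 0,
    ci: tuple[float, float] = (2.5, 97.5),
) -> BootstrapResult:
    """Subject-level resampling with replacement; percentile CI.

    ``cohort_values`` is an array (first axis = subjects) or DataFrame (rows
    = subjects); ``statistic`` maps a resampled cohort to a scalar or vector.
    Identical seeds give identical intervals.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    is_frame = isinstance(cohort_values, pd.DataFrame)
    n = len(cohort_values)
    if n == 0:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    samples = []
    arr = cohort_values if is_frame else np.asarray(cohort_values)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resampled = arr.iloc[idx] if is_frame else arr[idx]
        samples.append(statistic(resampled))
    samples = np.asarray(samples, dtype=float)
    lo, hi = np.percentile(samples, ci, axis=0)
    return BootstrapResult(
        samples=samples,
        mean=samples.mean(axis=0),
        sd=samples.std(axis=0, ddof=1) if n_boot > 1 else samples.std(axis=0),
        ci_low=lo,
        ci_high=hi,
    )


# ---------------------------------------------------------------------------
# Exponential rates, savings, interference


@dataclass
class ExponentialFit:
    """Baseline-constrained exponential ``y(n) = asy + (start - asy) e^(-rate n)``.

    ``start`` is pinned to the measured pre-onset baseline (n = 0);
    ``curve[k]`` corresponds to n = k+1.  ``x_intercept`` is the real-valued
    n at which the fitted curve crosses zero, or None when start and
    asymptote share a sign.
    """

    rate: float
    asymptote: float
    start: float
    x_intercept: Optional[float]
    rss: float

    def predict(self, n) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        return self.asymptote + (self.start - self.asymptote) * np.exp(-self.rate * n)


def fit_exponential(curve: Sequence[float], baseline: float) -> ExponentialFit:
    """Two-parameter exponential fit with the start pinned to ``baseline``."""
    y = np.asarray(curve, dtype=float)
    if y.size < 3:
        raise ValueError("curve must have at least 3 samples")
    if not np.all(np.isfinite(y)) or not math.isfinite(baseline):
        raise ValueError("curve and baseline must be finite")
    n = np.arange(1, y.size + 1, dtype=float)
    if np.allclose(y, baseline):
        return ExponentialFit(rate=0.0, asymptote=float(baseline), start=float(baseline),
                              x_intercept=None, rss=0.0)

    def resid(theta):
        rate, asy = theta
        return asy + (baseline - asy) * np.exp(-rate * n) - y

    best = None
    spans = max(abs(float(y[-1] - baseline)), 1.0)
    for rate0 in (0.01, 0.05, 0.2, 0.7):
        x0 = np.array([rate0, float(y[-1])])
        sol = optimize.least_squares(
            resid, x0, bounds=([0.0, -50.0 * spans - 100.0], [10.0, 50.0 * spans + 100.0])
        )
        if best is None or sol.cost < best.cost:
            best = sol
    rate, asy = best.x
    x_int = None
    if rate > 0 and asy != 0 and baseline * asy < 0:
        # solve asy + (start - asy) e^{-rate n} = 0
        x_int = float(np.log((asy - baseline) / asy) / rate)
    return ExponentialFit(
        rate=float(rate),
        asymptote=float(asy),
        start=float(baseline),
        x_intercept=x_int,
        rss=float(np.sum(best.fun**2)),
    )


@dataclass
class SavingsMetrics:
    rate_1: float
    rate_2: float
    rate_ratio: float
    angle_change_1: float
    angle_change_2: float
    angle_contrast: float
    fits: tuple[ExponentialFit, ExponentialFit]


def savings_metrics(
    exposure1_curve: Sequence[float],
    exposure2_curve: Sequence[float],
    baseline1: float,
    baseline2: float,
    early_window: int = 5,
    onset1: Optional[int] = None,
    onset2: Optional[int] = None,
) -> SavingsMetrics:
    """Savings between two perturbation exposures.

    Each curve contains epoch-level reach angles spanning the onset: samples
    before ``onset`` (default ``early_window``) are pre-perturbation.  Two
    indicators are returned: the ratio of baseline-constrained exponential
    rates (exposure 2 over exposure 1), and the change in the early angle
    difference (mean of ``early_window`` samples after onset minus before),
    contrasted across exposures.
    """
    m = []
    fits = []
    for curve, baseline, onset in (
        (exposure1_curve, baseline1, onset1),
        (exposure2_curve, baseline2, onset2),
    ):
        y = np.asarray(curve, dtype=float)
        k = early_window if onset is None else int(onset)
        if k < early_window or k + early_window > y.size:
            raise ValueError("early window exceeds curve bounds")
        pre = float(np.mean(y[k - early_window : k]))
        post = float(np.mean(y[k : k + early_window]))
        m.append(post - pre)
        fits.append(fit_exponential(y[k:], baseline))
    f1, f2 = fits
    return SavingsMetrics(
        rate_1=f1.rate,
        rate_2=f2.rate,
        rate_ratio=f2.rate / f1.rate if f1.rate > 0 else float("inf"),
        angle_change_1=m[0],
        angle_change_2=m[1],
        angle_contrast=m[1] - m[0],
        fits=(f1, f2),
    )


def interference_metrics(
    exposureA_curve: Sequence[float],
    exposureB_curve: Sequence[float],
    mode: str = "full",
) -> dict:
    """Anterograde interference: rate of B-period learning relative to A.

    ``exposureB_curve`` is recorded under the opposite-sign perturbation and
    is sign-flipped internally so both exposures climb toward a positive
    asymptote.  Each exponential is constrained to start from the first
    sample of its own curve.  A ratio below 1 signals interference.  With
    ``mode='post_zero_crossing'`` the B curve is refit from its fitted
    x-intercept onward (start pinned to 0), removing the influence of the
    initial opposite-sign error; a B curve that never crosses zero raises.
    """
    if mode not in ("full", "post_zero_crossing"):
        raise ValueError(f"unknown mode {mode!r}")
    a = np.asarray(exposureA_curve, dtype=float)
    b = -np.asarray(exposureB_curve, dtype=float)
    fit_a = fit_exponential(a[1:], baseline=float(a[0]))
    fit_b = fit_exponential(b[1:], baseline=float(b[0]))
    if mode == "post_zero_crossing":
        if fit_b.x_intercept is None:
            raise ValueError("exposure B never crosses zero; post-crossing rate undefined")
        k = int(np.ceil(fit_b.x_intercept))  # x_intercept in n-units, curve[1:] is n=1..
        tail = b[1:][k:]
        if tail.size < 3:
            raise ValueError("too few samples after the zero crossing")
        fit_b = fit_exponential(tail, baseline=0.0)
    ratio = fit_b.rate / fit_a.rate if fit_a.rate > 0 else float("inf")
    return {"rate_A": fit_a.rate, "rate_B": fit_b.rate, "rate_ratio": ratio,
            "fit_A": fit_a, "fit_B": fit_b}


# ---------------------------------------------------------------------------
# Model comparison


def aic(rss: float, n_obs: int, k_params: int) -> float:
    """Gaussian-likelihood AIC, ``n ln(rss/n) + 2k``.  ``rss`` must be > 0."""
    if rss <= 0:
        raise ValueError("AIC undefined for rss <= 0 (degenerate fit)")
    if n_obs < 1 or k_params < 1:
        raise ValueError("need n_obs >= 1 and k_params >= 1")
    return float(n_obs * math.log(rss / n_obs) + 2 * k_params)


def model_compare(fits_per_subject: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Per-subject AIC comparison across models.

    ``fits_per_subject`` maps model name -> AIC per subject (aligned).
    Returns one row per subject with each model's AIC, its difference from
    the per-subject minimum (``delta_<model>``) and the winning model; the
    frame's ``attrs["winner_counts"]`` holds the tally.
    """
    models = list(fits_per_subject)
    if not models:
        raise ValueError("no models to compare")
    mat = np.column_stack([np.asarray(fits_per_subject[m], dtype=float) for m in models])
    winners = [models[i] for i in np.argmin(mat, axis=1)]
    out = pd.DataFrame(mat, columns=models)
    best = mat.min(axis=1)
    for j, m in enumerate(models):
        out[f"delta_{m}"] = mat[:, j] - best
    out["winner"] = winners
    out.attrs["winner_counts"] = pd.Series(winners).value_counts().to_dict()
    return out


# ---------------------------------------------------------------------------
# Linear regression with CIs


@dataclass
class LinearFit:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    rho: float
    p_value: float
    n: int


def linfit_ci(x, y, alpha: float = 0.05) -> LinearFit:
    """Ordinary least squares with t-based confidence intervals and Pearson rho."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be the same length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    dof = x.size - 2
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, dof)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci=(float(res.slope - tcrit * res.stderr), float(res.slope + tcrit * res.stderr)),
        intercept_ci=(
            float(res.intercept - tcrit * res.intercept_stderr),
            float(res.intercept + tcrit * res.intercept_stderr),
        ),
        rho=float(res.rvalue),
        p_value=float(res.pvalue),
        n=int(x.size),
    )
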