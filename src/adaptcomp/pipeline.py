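"""End-to-end analysis stages on trial tables.

Each stage consumes the canonical trial table (synthetic or user-supplied)
and reproduces one of the study-level analyses: probe-based decomposition of
adaptation into implicit and explicit parts, tied group-level model
predictions with bootstrap uncertainty, individual implicit-explicit
regressions against the theory line, pairwise correlation signatures,
held-out block tests with per-subject AIC winners, and the savings /
interference stage built on exponential rate fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import rivals
from .estimation import (
    LinearFit,
    aic,
    bootstrap,
    interference_metrics,
    linfit_ci,
    model_compare,
    savings_metrics,
)
from .core import implicit_gain
from .synth import CohortDataset

__all__ = [
    "DecompositionResult",
    "decompose",
    "explicit_gain",
    "group_model_predictions",
    "individual_regression",
    "pairwise_correlations",
    "holdout_block_test",
    "savings_and_interference_stage",
]


@dataclass
class DecompositionResult:
    """Per subject x block decomposition of adaptation.

    ``table`` columns: subject_id, block, rotation, implicit (mean exclusion
    probe), total (terminal-window mean), explicit = total - implicit, and
    driving_force = rotation - explicit.
    """

    table: pd.DataFrame

    def block(self, block: int) -> pd.DataFrame:
        return self.table.loc[self.table["block"] == block]

    @property
    def blocks(self) -> list[int]:
        return sorted(self.table["block"].unique().tolist())


def _cohort_frame(cohort) -> pd.DataFrame:
    return cohort.table if isinstance(cohort, CohortDataset) else cohort


def decompose(
    cohort,
    total_window: int = 20,
    probe_selector: str = "exclusion",
    blocks: Optional[Iterable[int]] = None,
) -> DecompositionResult:
    """Split adaptation into implicit and explicit parts per subject and block.

    Implicit learning is the mean reach across the block's exclusion probes
    (both probe sets pooled); total adaptation is the mean over the last
    ``total_window`` feedback trials of the block; explicit strategy is their
    difference.  Blocks without probes raise.
    """
    df = _cohort_frame(cohort)
    if "block" not in df.columns:
        raise ValueError("trial table has no block column")
    rows = []
    wanted = set(blocks) if blocks is not None else None
    for (sid, block), grp in df.groupby(["subject_id", "block"], sort=True):
        if block == 0 or (wanted is not None and block not in wanted):
            continue
        probes = grp.loc[grp["probe_type"] == probe_selector, "reach_angle_deg"]
        if probes.empty:
            raise ValueError(f"block {block} has no {probe_selector!r} probes")
        normal = grp.loc[(grp["probe_type"] == "none") & (grp["feedback_mode"] != "none")]
        if normal.empty:
            raise ValueError(f"block {block} has no feedback trials")
        total = float(normal["reach_angle_deg"].tail(total_window).mean())
        implicit = float(probes.mean())
        r = float(normal["rotation_deg"].iloc[-1])
        rows.append(
            {
                "subject_id": sid,
                "block": int(block),
                "rotation": r,
                "implicit": implicit,
                "total": total,
                "explicit": total - implicit,
                "driving_force": r - (total - implicit),
            }
        )
    if not rows:
        raise ValueError("no analyzable blocks found")
    return DecompositionResult(table=pd.DataFrame(rows))


def explicit_gain(
    strategy_by_condition: Sequence[float],
    rotation_by_condition: Sequence[float],
) -> np.ndarray:
    """Explicit gain between consecutive conditions, percent:
    ``100 * delta(strategy) / delta(rotation)``."""
    s = np.asarray(strategy_by_condition, dtype=float)
    r = np.asarray(rotation_by_condition, dtype=float)
    if s.size != r.size or s.size < 2:
        raise ValueError("need >= 2 aligned conditions")
    dr = np.diff(r)
    if np.any(dr == 0):
        raise ValueError("consecutive conditions with zero rotation change")
    return 100.0 * np.diff(s) / dr


def _fit_gain(implicit_mean, driving_mean):
    d = np.asarray(driving_mean, dtype=float)
    xi = np.asarray(implicit_mean, dtype=float)
    denom = float(d @ d)
    if denom == 0:
        raise ValueError("zero driving force; gain unidentifiable")
    return float(d @ xi) / denom


def group_model_predictions(
    decomposition: DecompositionResult,
    models: Sequence[str] = ("competition", "independence"),
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Fit one implicit gain jointly across conditions and predict each one.

    The competition model predicts ``p * (r - x_e)`` per condition from the
    condition-mean strategies; the independence model predicts ``p * r``.
    Subject-level bootstrap (stratified by ``group`` if the decomposition
    carries one) yields a standard deviation per predicted condition.
    """
    tbl = decomposition.table
    conditions = decomposition.blocks
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions to identify a tied gain")

    def condition_means(frame: pd.DataFrame) -> pd.DataFrame:
        return frame.groupby("block")[["rotation", "implicit", "explicit"]].mean()

    def predict(frame: pd.DataFrame, model: str) -> np.ndarray:
        m = condition_means(frame)
        driving = m["rotation"] - m["explicit"] if model == "competition" else m["rotation"]
        p = _fit_gain(m["implicit"], driving)
        return (p * driving).to_numpy()

    out = {}
    strat = "group" in tbl.columns
    subjects = tbl["subject_id"].unique()
    rng_seed = seed
    for model in models:
        point = predict(tbl, model)

        def stat(resampled_subjects, _model=model):
            frame = pd.concat(
                [tbl.loc[tbl["subject_id"] == s] for s in resampled_subjects],
                ignore_index=True,
            )
            return predict(frame, _model)

        if strat:
            # resample subjects within each group, preserving group sizes
            groups = tbl.drop_duplicates("subject_id").groupby("group")["subject_id"]
            rng = np.random.default_rng(rng_seed)
            samples = []
            for _ in range(n_boot):
                chosen = np.concatenate(
                    [np.asarray(ids)[rng.integers(0, len(ids), len(ids))]
                     for _, ids in groups]
                )
                samples.append(stat(chosen))
            samples = np.asarray(samples)
            sd = samples.std(axis=0, ddof=1)
        else:
            boot = bootstrap(np.asarray(subjects, dtype=object), stat, n_boot=n_boot, seed=rng_seed)
            sd = np.asarray(boot.sd)
        m = condition_means(tbl)
        out[model] = pd.DataFrame(
            {
                "block": conditions,
                "rotation": m["rotation"].to_numpy(),
                "observed_implicit": m["implicit"].to_numpy(),
                "predicted_implicit": point,
                "boot_sd": sd,
            }
        )
    return out


@dataclass
class RegressionComparison:
    regression: LinearFit
    theory_slope: float
    theory_intercept: float
    slope_discrepancy: float
    intercept_discrepancy: float


def individual_regression(
    decomposition: DecompositionResult,
    a_i: float,
    b_i: float,
    block: Optional[int] = None,
) -> RegressionComparison:
    """Regress implicit on explicit across subjects and compare to theory.

    The competition equation predicts the between-subject line
    ``x_i = p_i (r - x_e)`` with ``p_i`` taken from *independently* estimated
    implicit parameters, i.e. slope ``-p_i`` and intercept ``p_i * r``.
    """
    tbl = decomposition.table if block is None else decomposition.block(block)
    if tbl["subject_id"].nunique() < 3:
        raise ValueError("need >= 3 subjects")
    fit = linfit_ci(tbl["explicit"], tbl["implicit"])
    p = implicit_gain(a_i, b_i)
    r = float(tbl["rotation"].mean())
    slope_t, int_t = -p, p * r
    return RegressionComparison(
        regression=fit,
        theory_slope=slope_t,
        theory_intercept=int_t,
        slope_discrepancy=abs(fit.slope - slope_t) / abs(slope_t) if slope_t else np.inf,
        intercept_discrepancy=abs(fit.intercept - int_t) / abs(int_t) if int_t else np.inf,
    )


def pairwise_correlations(
    decomposition: DecompositionResult, block: Optional[int] = None
) -> pd.DataFrame:
    """Pearson correlations and OLS slopes among implicit, explicit, total."""
    tbl = decomposition.table if block is None else decomposition.block(block)
    pairs = [("implicit", "explicit"), ("explicit", "total"), ("implicit", "total")]
    rows = []
    for ycol, xcol in pairs:
        x = tbl[xcol].to_numpy(float)
        y = tbl[ycol].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"degenerate (zero-variance) data for {ycol} vs {xcol}")
        fit = linfit_ci(x, y)
        rows.append({"pair": f"{ycol}_vs_{xcol}", "rho": fit.rho, "slope": fit.slope,
                     "p_value": fit.p_value})
    return pd.DataFrame(rows)


@dataclass
class HoldoutResult:
    comparison: pd.DataFrame  # per-subject AIC table with winners
    rmse: dict[str, float]
    block_slopes: pd.DataFrame
    gains: dict[str, float]

    @property
    def winner_counts(self) -> dict[str, int]:
        return self.comparison.attrs["winner_counts"]


def _predict_from_total(model_curve, p: float, r: float, total: np.ndarray) -> np.ndarray:
    """Probe-measured implicit predicted from measured total adaptation.

    Competition uses its total-learning form ``x_i = p (r - x_T) / (1 - p)``;
    the SPE+generalization rival uses its own true implicit ``p r`` to infer
    the strategy from total, ``x_i_measured = p r g(x_T - p r)``.  Driving
    both predictions by total keeps the comparison symmetric and avoids
    feeding either model the probe measurement it is trying to predict.
    """
    total = np.asarray(total, dtype=float)
    if model_curve is None:
        return p * (r - total) / (1.0 - p)
    return p * r * np.asarray(model_curve(total - p * r), dtype=float)


def holdout_block_test(
    decomposition: DecompositionResult,
    fit_block: Optional[int] = None,
    models: Optional[Mapping[str, Optional[rivals.GeneralizationCurve]]] = None,
) -> HoldoutResult:
    """Fit each model's gain on one block (group level), score the others.

    For every model the single implicit gain is fitted across subjects on
    ``fit_block`` by least squares over the total-driven prediction of the
    probe-measured implicit value, then each subject's held-out blocks are
    predicted from their own measured totals.  Per-subject RSS over those
    blocks feeds a per-subject AIC (k = 1, identical across models) and the
    winner tally.  Also reports the implicit-vs-explicit slope per block,
    which the competition account predicts to be constant at ``-p_i``
    across rotation sizes.
    """
    from scipy.optimize import minimize_scalar

    tbl = decomposition.table
    blocks = decomposition.blocks
    if len(blocks) < 2:
        raise ValueError("need >= 2 blocks")
    fit_block = blocks[-1] if fit_block is None else fit_block
    predict_blocks = [b for b in blocks if b != fit_block]
    if models is None:
        models = {
            "competition": None,
            "spe_gaussian": rivals.GeneralizationCurve(),
        }
    wide = tbl.pivot(index="subject_id", columns="block")
    subjects = wide.index
    aics: dict[str, list[float]] = {}
    rss_tot = {m: 0.0 for m in models}
    n_tot = {m: 0 for m in models}
    gains: dict[str, float] = {}
    xi_f = wide[("implicit", fit_block)].to_numpy(float)
    to_f = wide[("total", fit_block)].to_numpy(float)
    r_f = float(wide[("rotation", fit_block)].iloc[0])
    for name, curve in models.items():
        sse = lambda p: float(
            np.sum((xi_f - _predict_from_total(curve, p, r_f, to_f)) ** 2)
        )
        p = float(minimize_scalar(sse, bounds=(1e-3, 0.95), method="bounded").x)
        gains[name] = p
        resid2 = np.zeros(len(subjects))
        for b in predict_blocks:
            xi_b = wide[("implicit", b)].to_numpy(float)
            to_b = wide[("total", b)].to_numpy(float)
            r_b = float(wide[("rotation", b)].iloc[0])
            resid2 += (xi_b - _predict_from_total(curve, p, r_b, to_b)) ** 2
        rss_tot[name] = float(resid2.sum())
        n_tot[name] = len(predict_blocks) * len(subjects)
        aics[name] = [
            aic(max(r2, 1e-12), len(predict_blocks), 1) for r2 in resid2
        ]
    comparison = model_compare(aics)
    comparison.index = subjects
    slope_rows = []
    for b in blocks:
        sub = decomposition.block(b)
        fit = linfit_ci(sub["explicit"], sub["implicit"])
        slope_rows.append(
            {"block": b, "slope": fit.slope, "slope_ci_low": fit.slope_ci[0],
             "slope_ci_high": fit.slope_ci[1], "rotation": sub["rotation"].mean()}
        )
    return HoldoutResult(
        comparison=comparison,
        rmse={m: float(np.sqrt(rss_tot[m] / n_tot[m])) for m in models},
        block_slopes=pd.DataFrame(slope_rows),
        gains=gains,
    )


def _epoch_curve(grp: pd.DataFrame) -> np.ndarray:
    """Epoch-mean reach over feedback trials, in epoch order."""
    ok = grp.loc[grp["probe_type"] == "none"]
    return ok.groupby("epoch")["reach_angle_deg"].mean().to_numpy()


def savings_and_interference_stage(
    cohort,
    kind: str = "savings",
    early_window: int = 5,
    mode: str = "full",
) -> pd.DataFrame:
    """Per-subject savings or interference metrics from a two-exposure cohort.

    For ``kind='savings'`` the table must carry blocks 0 (baseline),
    1 (exposure 1), 2 (washout) and 3 (exposure 2); each exposure curve is
    the epoch-mean reach with its preceding ``early_window`` epochs as the
    pre-onset segment, and exponential baselines taken from those pre-onset
    means.  For ``kind='interference'`` blocks 1 and 2 hold the A and B
    exposures and the rate ratio B/A is returned (``mode`` as in
    :func:`adaptcomp.estimation.interference_metrics`).
    """
    df = _cohort_frame(cohort)
    if "exposure" not in df.columns or "block" not in df.columns:
        raise ValueError("cohort table lacks exposure/block markers")
    rows = []
    for sid, grp in df.groupby("subject_id", sort=True):
        if kind == "savings":
            pre1 = _epoch_curve(grp.loc[grp["block"] == 0])[-early_window:]
            exp1 = _epoch_curve(grp.loc[grp["block"] == 1])
            pre2 = _epoch_curve(grp.loc[grp["block"] == 2])[-early_window:]
            exp2 = _epoch_curve(grp.loc[grp["block"] == 3])
            m = savings_metrics(
                np.concatenate([pre1, exp1]),
                np.concatenate([pre2, exp2]),
                baseline1=float(np.mean(pre1)),
                baseline2=float(np.mean(pre2)),
                early_window=early_window,
            )
            rows.append(
                {"subject_id": sid, "rate_1": m.rate_1, "rate_2": m.rate_2,
                 "rate_ratio": m.rate_ratio, "angle_change_1": m.angle_change_1,
                 "angle_change_2": m.angle_change_2, "angle_contrast": m.angle_contrast}
            )
        elif kind == "interference":
            a = _epoch_curve(grp.loc[grp["block"] == 1])
            b = _epoch_curve(grp.loc[grp["block"] == 2])
            m = interference_metrics(a, b, mode=mode)
            rows.append(
                {"subject_id": sid, "rate_A": m["rate_A"], "rate_B": m["rate_B"],
                 "rate_ratio": m["rate_ratio"]}
            )
        else:
            raise ValueError(f"unknown kind {kind!r}")
    return pd.DataFrame(rows)
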