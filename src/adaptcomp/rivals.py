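"""Rival explanations of the implicit-explicit relationship.

Two alternatives to target-error competition are implemented:

1. *SPE learning with aim-centred generalization*: the implicit system is
   independent of strategy (asymptote ``p_i * r``), but the probe at the
   training target samples an adapted response centred on the aim location,
   so the **measured** implicit value is attenuated by a generalization
   curve: ``x_i_measured = p_i * r * g(x_e)``.

2. *Explicit-responds competition*: implicit learning varies on its own and
   the explicit system mops up the residual error,
   ``x_e_ss = p_e (r - x_i_ss)``.

Each model makes a falsifiable sign prediction for the pairwise slopes among
implicit, explicit and total adaptation, which is what separates them from
the competition account in cohort data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "MCDOUGLE_SIGMA_DEG",
    "GeneralizationCurve",
    "measured_implicit",
    "correct_explicit",
    "fit_and_predict_generalization",
    "sensitivity_scan",
    "explicit_responds",
    "correlation_sign_predictions",
    "GeneralizationFit",
]

#: Width (standard deviation, degrees) of the Gaussian generalization curve
#: reported by McDougle and colleagues; the default reference width.
MCDOUGLE_SIGMA_DEG = 37.76

# linear fallback slope chosen so the linear curve matches the Gaussian
# default at a 22.5 degree aim offset
_DEFAULT_LINEAR_SLOPE = (1.0 - float(np.exp(-22.5**2 / (2 * MCDOUGLE_SIGMA_DEG**2)))) / 22.5


@dataclass(frozen=True)
class GeneralizationCurve:
    """Aim-centred generalization ``g(delta)`` with ``g(0) = 1``.

    ``form='gaussian'`` uses ``exp(-delta^2 / (2 sigma^2))`` with
    ``width = sigma`` in degrees; ``form='linear'`` uses
    ``max(0, 1 - width * |delta|)`` with ``width`` a slope per degree.
    """

    form: str = "gaussian"
    width: float = MCDOUGLE_SIGMA_DEG

    def __post_init__(self) -> None:
        if self.form not in ("gaussian", "linear"):
            raise ValueError(f"unknown generalization form {self.form!r}")
        if self.width <= 0:
            raise ValueError("curve width must be positive")

    @classmethod
    def linear_default(cls) -> "GeneralizationCurve":
        return cls(form="linear", width=_DEFAULT_LINEAR_SLOPE)

    def scaled(self, pct: float) -> "GeneralizationCurve":
        """Curve with its width changed by ``pct`` percent (Gaussian: sigma
        scales; linear: slope scales inversely so the footprint widens)."""
        factor = 1.0 + pct / 100.0
        if factor <= 0:
            raise ValueError("width scale must keep the curve positive")
        w = self.width * factor if self.form == "gaussian" else self.width / factor
        return GeneralizationCurve(form=self.form, width=w)

    def __call__(self, delta) -> np.ndarray | float:
        delta = np.abs(np.asarray(delta, dtype=float))
        if self.form == "gaussian":
            out = np.exp(-(delta**2) / (2.0 * self.width**2))
        else:
            out = np.maximum(0.0, 1.0 - self.width * delta)
        return out if out.ndim else float(out)


def measured_implicit(
    p_i: float, r: float, x_e, curve: Optional[GeneralizationCurve]
) -> np.ndarray | float:
    """Probe-measured implicit learning under the SPE+generalization model:
    ``p_i * r * g(x_e)``.  ``curve=None`` means no generalization (g == 1)."""
    g = 1.0 if curve is None else curve(x_e)
    return p_i * r * g


def correct_explicit(
    x_T: float,
    measured: float,
    curve: Optional[GeneralizationCurve],
    p_i: float,
    r: float,
) -> tuple[float, float]:
    """Invert the probe attenuation to recover the actual strategy.

    Under SPE learning the true implicit asymptote is ``p_i * r`` and the
    apparent explicit value ``x_T - measured`` overstates the real strategy.
    Solves ``measured = p_i * r * g(x_e)`` for ``x_e`` on ``[0, x_T]`` and
    returns ``(x_e, true_implicit)``.
    """
    true_implicit = p_i * r
    if measured > true_implicit + 1e-12:
        raise ValueError(
            f"measured implicit {measured:g} exceeds p_i*r = {true_implicit:g}; "
            "inconsistent with g <= 1"
        )
    if curve is None:
        return x_T - measured, true_implicit

    def f(x_e: float) -> float:
        return true_implicit * float(curve(x_e)) - measured

    lo, hi = f(0.0), f(x_T)
    if lo < -1e-12 or hi > 1e-12:
        raise ValueError("no strategy in [0, x_T] is consistent with the curve")
    if abs(lo) <= 1e-12:
        return 0.0, true_implicit
    if abs(hi) <= 1e-12:
        return float(x_T), true_implicit
    root = brentq(f, 0.0, x_T, xtol=1e-12)
    return float(root), true_implicit


@dataclass
class GeneralizationFit:
    """Gain fitted on one block plus held-out prediction errors elsewhere."""

    model: str
    p_i: float
    rmse: dict
    predictions: pd.DataFrame
    rss: float = 0.0
    n_obs: int = 0


def _block_xy(block: Mapping) -> tuple[np.ndarray, np.ndarray, float]:
    implicit = np.asarray(block["implicit"], dtype=float)
    explicit = np.asarray(block["explicit"], dtype=float)
    if implicit.size != explicit.size:
        raise ValueError("implicit and explicit arrays must be the same length")
    if implicit.size == 0:
        raise ValueError("empty block")
    return implicit, explicit, float(block["rotation"])


def _design(explicit: np.ndarray, r: float, curve: Optional[GeneralizationCurve]) -> np.ndarray:
    """Regressor d such that predicted implicit = p_i * d."""
    if curve is None:
        return r - explicit  # competition: x_i = p_i (r - x_e)
    return r * np.asarray(curve(explicit), dtype=float)  # SPE: x_i = p_i r g(x_e)


def fit_and_predict_generalization(
    block_data: Mapping[str, Mapping],
    fit_block: str,
    predict_blocks: Iterable[str],
    curve: Optional[GeneralizationCurve],
) -> GeneralizationFit:
    """Fit ``p_i`` on one block and score held-out blocks.

    ``block_data`` maps block name -> ``{"implicit": array, "explicit": array,
    "rotation": degrees}`` with subjects aligned across blocks.  The gain is
    the least-squares solution on the fit block (the model is linear in
    ``p_i``); held-out RMSE is reported per predicted block.
    ``curve=None`` fits the competition model.
    """
    if not block_data:
        raise ValueError("empty block data")
    predict_blocks = list(predict_blocks)
    xi, xe, r = _block_xy(block_data[fit_block])
    if xi.size < 2 and len(predict_blocks) == 0:
        raise ValueError("degenerate single-subject block with nothing to predict")
    d = _design(xe, r, curve)
    denom = float(d @ d)
    if denom == 0.0:
        raise ValueError("fit block has no usable driving signal")
    p_i = float(d @ xi) / denom
    rows = []
    rmse = {}
    rss = 0.0
    n_obs = 0
    for name in predict_blocks:
        xi_b, xe_b, r_b = _block_xy(block_data[name])
        pred = p_i * _design(xe_b, r_b, curve)
        resid = xi_b - pred
        rmse[name] = float(np.sqrt(np.mean(resid**2)))
        rss += float(resid @ resid)
        n_obs += resid.size
        rows.append(
            pd.DataFrame(
                {"block": name, "implicit": xi_b, "explicit": xe_b, "predicted": pred}
            )
        )
    predictions = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    return GeneralizationFit(
        model="competition" if curve is None else f"spe_{curve.form}",
        p_i=p_i,
        rmse=rmse,
        predictions=predictions,
        rss=rss,
        n_obs=n_obs,
    )


def sensitivity_scan(
    block_data: Mapping[str, Mapping],
    fit_block: str,
    predict_blocks: Iterable[str],
    width_scales_pct: Iterable[float] = (-50, -25, 0, 25, 50, 75, 100),
    base_curve: Optional[GeneralizationCurve] = None,
) -> pd.DataFrame:
    """Repeat the fit/predict exercise over rescaled generalization widths.

    Each row holds the held-out RMSE of the SPE+generalization model at one
    width scale, next to the width-independent competition RMSE, so model
    superiority can be read off across the whole plausible width range.
    """
    width_scales_pct = list(width_scales_pct)
    if not width_scales_pct:
        raise ValueError("empty width list")
    base_curve = base_curve or GeneralizationCurve()
    predict_blocks = list(predict_blocks)
    comp = fit_and_predict_generalization(block_data, fit_block, predict_blocks, None)
    comp_rmse = float(np.sqrt(comp.rss / comp.n_obs)) if comp.n_obs else np.nan
    rows = []
    for pct in width_scales_pct:
        fit = fit_and_predict_generalization(
            block_data, fit_block, predict_blocks, base_curve.scaled(pct)
        )
        rows.append(
            {
                "width_scale_pct": pct,
                "sigma": base_curve.scaled(pct).width,
                "p_i": fit.p_i,
                "rmse": float(np.sqrt(fit.rss / fit.n_obs)) if fit.n_obs else np.nan,
                "competition_rmse": comp_rmse,
            }
        )
    return pd.DataFrame(rows)


def explicit_responds(p_e: float, r: float, x_i) -> np.ndarray | float:
    """Explicit asymptote when strategy responds to leftover error:
    ``x_e_ss = p_e (r - x_i_ss)``.  Requires ``0 <= p_e < 1`` for stability."""
    if not (0.0 <= p_e < 1.0):
        raise ValueError(f"p_e must lie in [0, 1) for a stable system, got {p_e}")
    x_i = np.asarray(x_i, dtype=float)
    out = p_e * (r - x_i)
    return out if out.ndim else float(out)


def correlation_sign_predictions(model: str, gain: float) -> dict[str, float]:
    """Pairwise slope predictions among implicit, explicit and total learning.

    Keys are ``"<dependent>_vs_<independent>"`` regression slopes implied by
    the model algebra when the free variable (strategy for competition,
    implicit learning for explicit-responds) carries the between-subject
    variability.
    """
    if not (0.0 <= gain < 1.0):
        raise ValueError(f"gain must lie in [0, 1), got {gain}")
    if model == "competition":
        # x_i = p (r - x_e); x_T = p r + (1 - p) x_e
        return {
            "xe_vs_xT": 1.0 / (1.0 - gain),
            "xi_vs_xT": -gain / (1.0 - gain),
            "xi_vs_xe": -gain,
        }
    if model == "explicit_responds":
        # x_e = p (r - x_i); x_T = p r + (1 - p) x_i
        return {
            "xe_vs_xT": -gain / (1.0 - gain),
            "xi_vs_xT": 1.0 / (1.0 - gain),
            "xi_vs_xe": -1.0 / gain if gain > 0 else -np.inf,
        }
    raise ValueError(f"unknown model {model!r}")
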