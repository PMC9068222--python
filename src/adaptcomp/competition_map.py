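"""The competition map: how steady-state implicit learning responds to joint
changes in implicit and explicit error sensitivity.

The map evaluates the coupled steady state over a grid of percent changes
``(delta_b_i, delta_b_e)`` relative to a reference parameter set, with both
retention factors held fixed.  Because the implicit asymptote is
``x_i_ss = b_i (1 - a_e) r / D`` with ``D`` bilinear in ``(b_i, b_e)``, every
iso-change contour is exactly affine in sensitivity space -- which is why a
"perceived invariance" region (|change| below a tolerance, Region C) is
bounded by two straight lines.

Regions:

* ``A`` -- matching decrease: implicit sensitivity and implicit adaptation
  both fall.
* ``B`` -- mismatching decrease: adaptation falls although sensitivity rose
  (explicit competition hides the gain).
* ``C`` -- perceived invariance: |change| below tolerance (closed region;
  boundary ties break into C).
* ``D`` -- matching increase.
* ``E`` -- mismatching increase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LearnerParams, coupling_denominator

__all__ = ["CompetitionMapGrid", "build_map", "classify_region", "region_c_bounds"]


def _implicit_ss(a_i, b_i, a_e, b_e, r):
    d = coupling_denominator(a_i, b_i, a_e, b_e)
    return np.where(d > 0.0, b_i * (1.0 - a_e) * r / np.where(d > 0.0, d, 1.0), np.nan)


@dataclass
class CompetitionMapGrid:
    """Grid of percent changes in steady-state implicit adaptation.

    ``values[i, j]`` is the percent change at ``delta_be_axis[i]`` (rows) and
    ``delta_bi_axis[j]`` (columns); ``regions`` holds the matching label per
    cell and ``valid`` is False where the tested sensitivities leave the
    stable regime.
    """

    delta_bi_axis: np.ndarray
    delta_be_axis: np.ndarray
    values: np.ndarray
    regions: np.ndarray
    valid: np.ndarray
    reference: LearnerParams
    r: float
    tol: float = 5.0

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per cell with value and region label."""
        bi, be = np.meshgrid(self.delta_bi_axis, self.delta_be_axis)
        return pd.DataFrame(
            {
                "delta_bi_pct": bi.ravel(),
                "delta_be_pct": be.ravel(),
                "implicit_change_pct": self.values.ravel(),
                "region": self.regions.ravel(),
                "valid": self.valid.ravel(),
            }
        )


def _classify(values: np.ndarray, delta_bi: np.ndarray, tol: float) -> np.ndarray:
    regions = np.full(values.shape, "C", dtype=object)
    dec = values < -tol
    inc = values > tol
    regions[dec & (delta_bi < 0)] = "A"
    regions[dec & (delta_bi >= 0)] = "B"
    regions[inc & (delta_bi > 0)] = "D"
    regions[inc & (delta_bi <= 0)] = "E"
    regions[~np.isfinite(values)] = "invalid"
    return regions


def build_map(
    reference: LearnerParams,
    grid_ranges: tuple[np.ndarray, np.ndarray] | None = None,
    r: float = 30.0,
    tol: float = 5.0,
) -> CompetitionMapGrid:
    """Evaluate the coupled steady state over a grid of sensitivity changes.

    ``grid_ranges`` is a pair of percent-change axes ``(delta_bi, delta_be)``;
    the default spans -100%..+200% in 1% steps.  Each cell holds
    ``100 * (x_i_ss(test) / x_i_ss(ref) - 1)`` with retention factors fixed at
    the reference values.  Cells whose test sensitivities are unstable are
    flagged invalid rather than raising.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if grid_ranges is None:
        axis = np.arange(-100.0, 200.0 + 0.5, 1.0)
        grid_ranges = (axis, axis.copy())
    dbi, dbe = (np.asarray(g, dtype=float) for g in grid_ranges)
    ref_ss = _implicit_ss(reference.a_i, reference.b_i, reference.a_e, reference.b_e, r)
    if not np.isfinite(ref_ss) or ref_ss == 0.0:
        raise ValueError("reference parameters give a zero or unstable implicit steady state")
    bi = reference.b_i * (1.0 + dbi[None, :] / 100.0)
    be = reference.b_e * (1.0 + dbe[:, None] / 100.0)
    in_range = (bi >= 0) & (bi < 1) & (be >= 0) & (be < 1)
    d = coupling_denominator(reference.a_i, bi, reference.a_e, be)
    valid = in_range & (d > 0.0)
    with np.errstate(invalid="ignore"):
        ss = np.where(valid, _implicit_ss(reference.a_i, bi, reference.a_e, be, r), np.nan)
    values = 100.0 * (ss / ref_ss - 1.0)
    # the reference cell is exact zero by construction, not merely rounded
    zero_bi = np.isclose(dbi, 0.0)
    zero_be = np.isclose(dbe, 0.0)
    if zero_bi.any() and zero_be.any():
        values[np.ix_(zero_be, zero_bi)] = 0.0
    regions = _classify(values, np.broadcast_to(dbi[None, :], values.shape), tol)
    return CompetitionMapGrid(
        delta_bi_axis=dbi,
        delta_be_axis=dbe,
        values=values,
        regions=regions,
        valid=valid,
        reference=reference,
        r=r,
        tol=tol,
    )


def classify_region(
    delta_bi: float,
    delta_be: float,
    reference: LearnerParams,
    r: float = 30.0,
    tol: float = 5.0,
) -> str:
    """Region label for a single ``(delta_b_i, delta_b_e)`` percent-change cell."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    bi = reference.b_i * (1.0 + delta_bi / 100.0)
    be = reference.b_e * (1.0 + delta_be / 100.0)
    if not (0 <= bi < 1 and 0 <= be < 1):
        raise ValueError("sensitivity change leaves the valid parameter range")
    d = coupling_denominator(reference.a_i, bi, reference.a_e, be)
    if d <= 0.0:
        raise ValueError("sensitivity change leaves the stable regime")
    ref_ss = _implicit_ss(reference.a_i, reference.b_i, reference.a_e, reference.b_e, r)
    if delta_bi == 0.0 and delta_be == 0.0:
        value = 0.0
    else:
        value = 100.0 * (
            _implicit_ss(reference.a_i, bi, reference.a_e, be, r) / ref_ss - 1.0
        )
    return str(_classify(np.array([[value]]), np.array([[delta_bi]]), tol)[0, 0])


def region_c_bounds(
    reference: LearnerParams,
    r: float = 30.0,
    tol: float = 5.0,
) -> dict[str, tuple[float, float]]:
    """Closed-form affine boundaries of Region C in absolute ``(b_i, b_e)`` space.

    Setting ``x_i_ss(test) = (1 +/- tol/100) x_i_ss(ref)`` and solving for
    ``b_e`` as a function of ``b_i`` gives, for each target ratio ``c`` of
    ``b_i / D``::

        b_e = [ b_i (1/c - (1 - a_e)) - (1 - a_i)(1 - a_e) ] / (1 - a_i)

    which is affine in ``b_i``.  Returns ``{"upper": (slope, intercept),
    "lower": (slope, intercept)}`` where "upper" is the +tol% contour.
    Every point on a returned line evaluates to exactly +/-tol% through the
    coupled steady state.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    a_i, a_e = reference.a_i, reference.a_e
    if a_i >= 1.0:
        raise ValueError("Region C bounds require a_i < 1")
    d_ref = coupling_denominator(a_i, reference.b_i, a_e, reference.b_e)
    h_ref = reference.b_i / d_ref  # x_i_ss = h * (1 - a_e) * r
    out = {}
    for name, scale in (("upper", 1.0 + tol / 100.0), ("lower", 1.0 - tol / 100.0)):
        c = scale * h_ref
        slope = (1.0 / c - (1.0 - a_e)) / (1.0 - a_i)
        intercept = -(1.0 - a_e)
        out[name] = (slope, intercept)
    return out
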