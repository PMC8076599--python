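"""Absolute quantification of amino acids from linear calibration curves.

Standards are run as grouped series by comparative response factor (high,
medium, low), six points per amino acid, and fitted as ordinary least squares
peak height vs amount (nmol). A fit is accepted when its adjusted R-squared
reaches 0.94. Sample heights are back-calculated to nmol in the vial, divided
by the number of pooled oocytes to give pmol/oocyte, and converted to a
cytosolic concentration through the water-accessible oocyte volume of 365 nL:

    content [pmol/oocyte] = concentration [uM] x 0.365 [nL -> pmol/uM]
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .library import OOCYTE_VOLUME_NL

__all__ = ["CalibrationCurve", "OocyteContent", "fit_calibration",
           "quantify_sample", "content_from_concentration",
           "concentration_from_content", "ADJ_R2_FLOOR"]

ADJ_R2_FLOOR = 0.94
_UM_TO_PMOL = OOCYTE_VOLUME_NL / 1000.0  # 0.365


@dataclass(frozen=True)
class CalibrationCurve:
    metabolite: str
    rf_group: str
    points: tuple[tuple[float, float], ...]   # (amount nmol, height)
    slope: float
    intercept: float
    adjusted_r2: float
    accepted: bool
    has_duplicate_amounts: bool = False


@dataclass(frozen=True)
class OocyteContent:
    metabolite: str
    concentration_um: float
    content_pmol_per_oocyte: float
    n_oocytes: int
    volume_nl: float = OOCYTE_VOLUME_NL
    clipped: bool = False


def fit_calibration(points, metabolite: str = "",
                    rf_group: str = "") -> CalibrationCurve:
    """Ordinary least squares ``height = slope * amount + intercept``.

    ``points`` is an iterable of (amount_nmol, height) with at least three
    points. Duplicate amounts are tolerated (flagged); zero variance in the
    amounts is a hard failure. Curves with adjusted R-squared below 0.94 are
    kept but flagged ``accepted=False`` with a warning.
    """
    pts = tuple((float(a), float(h)) for a, h in points)
    if len(pts) < 3:
        raise ValueError(f"need >= 3 calibration points, got {len(pts)}")
    amounts = np.array([a for a, _ in pts])
    heights = np.array([h for _, h in pts])
    if np.ptp(amounts) == 0:
        raise ValueError("calibration amounts have zero variance")
    dup = len(set(amounts.tolist())) < len(amounts)
    X = sm.add_constant(amounts)
    fit = sm.OLS(heights, X).fit()
    adj = float(fit.rsquared_adj)
    accepted = adj >= ADJ_R2_FLOOR
    if not accepted:
        warnings.warn(f"calibration for {metabolite or 'metabolite'}: "
                      f"adjusted R^2 {adj:.3f} < {ADJ_R2_FLOOR}", stacklevel=2)
    return CalibrationCurve(
        metabolite=metabolite, rf_group=rf_group, points=pts,
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        adjusted_r2=min(max(adj, 0.0), 1.0), accepted=accepted,
        has_duplicate_amounts=dup)


def quantify_sample(height: float, curve: CalibrationCurve,
                    n_oocytes: int) -> OocyteContent:
    """Back-calculate one pooled-sample height to per-oocyte content.

    nmol in the vial = (height - intercept) / slope; pmol/oocyte =
    nmol * 1000 / n_oocytes; concentration uM = content / 0.365. Negative
    back-calculated amounts are clipped to zero and flagged.
    """
    if curve.slope <= 0:
        raise ValueError(f"{curve.metabolite}: non-positive calibration slope")
    if height < 0:
        raise ValueError("height must be non-negative")
    amount_nmol = (height - curve.intercept) / curve.slope
    clipped = amount_nmol < 0
    amount_nmol = max(amount_nmol, 0.0)
    content = amount_nmol * 1000.0 / n_oocytes
    return OocyteContent(
        metabolite=curve.metabolite,
        concentration_um=concentration_from_content(content),
        content_pmol_per_oocyte=content,
        n_oocytes=int(n_oocytes), clipped=clipped)


def content_from_concentration(concentration_um: float) -> float:
    """Per-oocyte content (pmol) at a cytosolic concentration (uM), through
    the 365 nL water-accessible volume."""
    if concentration_um < 0:
        raise ValueError("concentration must be non-negative")
    return concentration_um * _UM_TO_PMOL


def concentration_from_content(content_pmol: float) -> float:
    """Inverse of :func:`content_from_concentration`."""
    return content_pmol / _UM_TO_PMOL
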