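"""Log-linear fluorescence calibration and concentration estimation.

The incubation experiment relates dry-weight-normalized fluorescence F to
genipin concentration C through ``F = beta0 + beta1 * ln(C)``.  The fit is an
ordinary-least-squares regression on the positive-concentration samples
(ln 0 is undefined; zero-concentration controls are summarized as detection
background).  Inverting the line gives a tissue-concentration estimate
``C = exp((F - beta0) / beta1)``; readings at or below background are flagged
as below detection rather than mapped to a vanishing concentration.

The per-percent sensitivity ``beta1 * ln(1.01)`` expresses the slope as the
fluorescence rise caused by a +1% concentration increase.

An absorption-based calibration table can be passed through the same
machinery unchanged; only the response column differs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class CalibrationFit:
    """Fitted log-linear calibration line."""

    beta0: float            # a.u./mg at 1 mM (ln 1 = 0)
    beta1: float            # a.u./mg per ln(mM)
    r2_adj: float
    n_used: int             # positive-concentration samples in the fit
    #: mean normalized reading of the 0 mM controls; -inf when the table has
    #: no controls (no detection floor).
    background_mean: float
    n_background: int = 0
    beta1_p: float = float("nan")

    def predict(self, concentration: float) -> float:
        if concentration <= 0:
            raise ValueError("prediction requires a positive concentration")
        return self.beta0 + self.beta1 * math.log(concentration)


@dataclass
class ConcentrationEstimate:
    """Estimated tissue concentration for one fluorescence reading."""

    concentration: float          # mM; 0.0 when below detection
    fluorescence: float           # a.u./mg input reading
    below_detection: bool = False


def normalize_reading(raw: float, dry_weight: float) -> float:
    """Dry-weight normalization: raw reading [a.u.] / dry weight [mg]."""
    if dry_weight <= 0:
        raise ValueError(f"dry_weight must be positive, got {dry_weight!r}")
    return raw / dry_weight


def fit_calibration(
    concentration: Sequence[float],
    fluorescence: Sequence[float],
) -> CalibrationFit:
    """OLS of normalized fluorescence on ln(concentration).

    Only rows with concentration > 0 enter the regression; at least three
    distinct positive levels are required.  Zero-concentration rows are
    summarized as ``background_mean``.
    """
    c = np.asarray(concentration, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if c.size != f.size:
        raise ValueError("concentration and fluorescence must have equal length")
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    pos = c > 0
    if np.unique(c[pos]).size < 3:
        raise ValueError("need at least 3 distinct positive concentration levels")
    x = np.log(c[pos])
    y = f[pos]
    design = sm.add_constant(x)
    res = sm.OLS(y, design).fit()
    zero = ~pos
    return CalibrationFit(
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        r2_adj=float(res.rsquared_adj),
        n_used=int(pos.sum()),
        background_mean=float(f[zero].mean()) if zero.any() else float("-inf"),
        n_background=int(zero.sum()),
        beta1_p=float(res.pvalues[1]),
    )


def fit_calibration_table(table: pd.DataFrame) -> CalibrationFit:
    """Fit from a calibration table with columns ``concentration_mM``,
    ``dry_weight_mg`` and ``fluorescence_au`` (raw plate-reader values)."""
    norm = table["fluorescence_au"] / table["dry_weight_mg"]
    if np.any(table["dry_weight_mg"] <= 0):
        raise ValueError("dry weights must be positive")
    return fit_calibration(table["concentration_mM"].to_numpy(), norm.to_numpy())


def slope_per_percent(fit: CalibrationFit) -> float:
    """Fluorescence rise [a.u./mg] caused by a +1% concentration increase."""
    return fit.beta1 * math.log(1.01)


def estimate_concentration(
    fluorescence: float, fit: CalibrationFit
) -> ConcentrationEstimate:
    """Invert the calibration line: ``C = exp((F - beta0) / beta1)``.

    Readings at or below the detection background are flagged instead of
    being mapped to a vanishing or spuriously small concentration.
    """
    if fit.beta1 <= 0:
        raise ValueError("calibration slope must be positive to invert")
    if fluorescence <= fit.background_mean:
        return ConcentrationEstimate(0.0, fluorescence, below_detection=True)
    c = math.exp((fluorescence - fit.beta0) / fit.beta1)
    return ConcentrationEstimate(c, fluorescence, below_detection=False)


def concentration_table(
    samples: pd.DataFrame,
    fit: CalibrationFit,
    response: str = "fluorescence",
) -> pd.DataFrame:
    """Per-biopsy concentration estimates from a spectral sample table.

    Returns columns ``sample_id, group, distance_mm, concentration_mM, flag``
    with flag ``below_detection`` or ``ok``.
    """
    col = {"fluorescence": "fluorescence_au", "absorption": "absorption_au"}[response]
    rows = []
    for _, row in samples.iterrows():
        norm = normalize_reading(row[col], row["dry_weight_mg"])
        est = estimate_concentration(norm, fit)
        rows.append(
            {
                "sample_id": row["specimen_id"],
                "group": row["group"],
                "distance_mm": row["distance_mm"],
                "concentration_mM": est.concentration,
                "flag": "below_detection" if est.below_detection else "ok",
            }
        )
    return pd.DataFrame(rows)
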