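"""Spatial modelling of crosslink-induced fluorescence and absorption.

Two OLS designs mirror the study's spectral analysis:

* an injection-site model with cell-means coding (one dummy per group, no
  intercept) so coefficients are directly the group means at distance 0, with
  pairwise contrasts from the coefficient covariance; and
* a distance model over the two treated groups with the injection site as
  baseline: an intercept (healthy-treated injection-site mean), a
  degenerated-treated offset, and one interaction dummy per (distance, group)
  cell.  On balanced noise-free data every coefficient equals the
  corresponding cell-mean difference.

Percent drops express the interaction coefficients relative to the group's
own injection-site baseline.  The fluorescence and absorption pipelines share
this code path; the response is a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import GROUPS

#: The two genipin-treated arms (the distance model applies only to them).
TREATED_GROUPS = ("GP", "ColGP")

#: Distances with dummies in the default distance model [mm].  The strict
#: two-distance variant (9, 15) is available by passing distances=(9, 15).
DEFAULT_DESIGN_DISTANCES: tuple[float, ...] = (3.0, 9.0, 15.0)


def normalized_response(df: pd.DataFrame, response: str) -> pd.Series:
    """Dry-weight-normalized readout column (a.u./mg) for ``response``."""
    col = {"fluorescence": "fluorescence_au", "absorption": "absorption_au"}.get(response)
    if col is None:
        raise ValueError(f"response must be 'fluorescence' or 'absorption', got {response!r}")
    if np.any(df["dry_weight_mg"] <= 0):
        raise ValueError("dry weights must be positive")
    return df[col] / df["dry_weight_mg"]


@dataclass
class InjectionSiteFit:
    """Group means, standard errors and pairwise contrasts at distance 0."""

    response: str
    means: dict[str, float]
    se: dict[str, float]
    n: dict[str, int]
    _results: object = field(repr=False, default=None)
    _order: tuple[str, ...] = field(repr=False, default=GROUPS)

    def contrast(self, a: str, b: str) -> tuple[float, float, float]:
        """(difference a-b, t, two-sided p) between two group means."""
        vec = np.zeros(len(self._order))
        vec[self._order.index(a)] = 1.0
        vec[self._order.index(b)] = -1.0
        t_res = self._results.t_test(vec)
        return (
            float(np.ravel(t_res.effect)[0]),
            float(np.ravel(t_res.tvalue)[0]),
            float(np.ravel(t_res.pvalue)[0]),
        )


def fit_injection_site_model(
    samples: pd.DataFrame, response: str = "fluorescence"
) -> InjectionSiteFit:
    """OLS on group dummies (cell-means coding) at the injection site.

    ``samples`` may contain all distances; only rows at distance 0 are used.
    Every group must be represented.
    """
    at0 = samples[samples["distance_mm"] == 0]
    present = set(at0["group"])
    missing = [g for g in GROUPS if g not in present]
    if missing:
        raise ValueError(f"missing group(s) at the injection site: {missing}")
    y = normalized_response(at0, response).to_numpy()
    design = np.column_stack(
        [(at0["group"] == g).to_numpy(float) for g in GROUPS]
    )
    res = sm.OLS(y, design).fit()
    means = {g: float(res.params[i]) for i, g in enumerate(GROUPS)}
    se = {g: float(res.bse[i]) for i, g in enumerate(GROUPS)}
    n = {g: int((at0["group"] == g).sum()) for g in GROUPS}
    return InjectionSiteFit(response, means, se, n, _results=res, _order=GROUPS)


@dataclass
class SpatialFit:
    """Coefficients of the distance model for one response.

    ``terms`` maps a term name -- ``intercept``, ``degenerated_offset`` or
    ``drop_{distance}mm_{group}`` -- to (estimate, se, p).  Coefficients whose
    design cell is empty are reported as NaN, never extrapolated.
    """

    response: str
    distances: tuple[float, ...]
    terms: dict[str, tuple[float, float, float]]
    n_obs: int

    @staticmethod
    def term_name(distance: float, group: str) -> str:
        return f"drop_{distance:g}mm_{group}"

    def coefficient(self, distance: float, group: str) -> tuple[float, float, float]:
        return self.terms[self.term_name(distance, group)]

    def baseline(self, group: str) -> float:
        """Fitted injection-site mean of ``group``."""
        b0 = self.terms["intercept"][0]
        if group == "GP":
            return b0
        if group == "ColGP":
            return b0 + self.terms["degenerated_offset"][0]
        raise ValueError(f"distance model covers treated groups only, got {group!r}")


def fit_spatial_model(
    samples: pd.DataFrame,
    response: str = "fluorescence",
    distances: Sequence[float] = DEFAULT_DESIGN_DISTANCES,
) -> SpatialFit:
    """Least-squares fit of the distance x treatment-group dummy design.

    Uses only treated-group rows at the injection site or at a design
    distance.  The injection site of the healthy-treated group is the
    baseline (intercept).
    """
    distances = tuple(float(d) for d in distances)
    df = samples[samples["group"].isin(TREATED_GROUPS)]
    df = df[df["distance_mm"].isin((0.0,) + distances)]
    if df.empty:
        raise ValueError("no treated-group samples at the design distances")
    for g in TREATED_GROUPS:
        if not ((df["group"] == g) & (df["distance_mm"] == 0)).any():
            raise ValueError(f"injection-site cell for group {g!r} is empty")
    y = normalized_response(df, response).to_numpy()
    d_colgp = (df["group"] == "ColGP").to_numpy(float)

    names = ["intercept", "degenerated_offset"]
    cols = [np.ones(len(df)), d_colgp]
    for d in distances:
        at_d = (df["distance_mm"] == d).to_numpy(float)
        names.append(SpatialFit.term_name(d, "GP"))
        cols.append(at_d * (1.0 - d_colgp))
        names.append(SpatialFit.term_name(d, "ColGP"))
        cols.append(at_d * d_colgp)
    design = np.column_stack(cols)

    populated = design.any(axis=0)
    res = sm.OLS(y, design[:, populated]).fit()
    terms: dict[str, tuple[float, float, float]] = {}
    j = 0
    for i, name in enumerate(names):
        if populated[i]:
            terms[name] = (float(res.params[j]), float(res.bse[j]), float(res.pvalues[j]))
            j += 1
        else:
            terms[name] = (float("nan"), float("nan"), float("nan"))
    return SpatialFit(response, distances, terms, n_obs=len(df))


def percent_drop(fit: SpatialFit, group: str, distance: float) -> float:
    """Percent change at ``distance`` relative to the group's injection-site
    baseline: 100 * beta_{distance,group} / baseline(group)."""
    base = fit.baseline(group)
    if base == 0:
        raise ValueError(f"injection-site baseline of group {group!r} is zero")
    if distance == 0:
        return 0.0
    beta = fit.coefficient(distance, group)[0]
    return 100.0 * beta / base


def drop_table(fit: SpatialFit) -> pd.DataFrame:
    """Tidy percent-drop table: one row per (group, distance) with the drop
    and the coefficient's two-sided p-value."""
    rows = []
    for g in TREATED_GROUPS:
        for d in fit.distances:
            _, _, p = fit.coefficient(d, g)
            rows.append(
                {
                    "response": fit.response,
                    "group": g,
                    "distance_mm": d,
                    "percent_drop": percent_drop(fit, g, d),
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def coefficient_table(fit: SpatialFit) -> pd.DataFrame:
    rows = [
        {"response": fit.response, "term": name, "estimate": est, "se": se, "p": p}
        for name, (est, se, p) in fit.terms.items()
    ]
    return pd.DataFrame(rows)


def test_nonzero(samples: Sequence[float]) -> tuple[float, float]:
    """One-sample two-sided t-test of the mean against zero."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError(f"need n >= 2, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: t-test undefined")
    res = stats.ttest_1samp(x, 0.0)
    return float(res.statistic), float(res.pvalue)
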