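"""Nonparametric group comparison and reporting helpers.

The study's inference chain for mechanical variables: a Shapiro-Wilk
normality gate, a Kruskal-Wallis omnibus test across the four groups, Dunn's
rank-based pairwise comparisons (two-sided, unadjusted by default, Holm
adjustment available), median percent differences for effect reporting, and
the a priori two-sample t-test sample-size computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.power import TTestIndPower

from .core import as_grouped

Groups = Mapping[str, Sequence[float]]


def normality_test(sample: Sequence[float]) -> float:
    """Two-sided p-value for the null of normality (Shapiro-Wilk)."""
    x = as_grouped(sample)
    if x.size < 3:
        raise ValueError(f"normality test needs n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("normality test is undefined for a constant sample")
    return float(stats.shapiro(x).pvalue)


def kruskal_wallis(groups: Groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected mid-ranks) and chi-square p-value.

    When every value across all groups is identical the statistic degenerates;
    (H, p) = (0, 1) is returned.
    """
    arrays = {g: as_grouped(v) for g, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    if any(a.size < 1 for a in arrays.values()):
        raise ValueError("every group must contain at least one value")
    pooled = np.concatenate(list(arrays.values()))
    if pooled.size < 3:
        raise ValueError("Kruskal-Wallis needs a total of at least 3 values")
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays.values())
    return float(h), float(p)


def _pooled_midranks(arrays: dict[str, np.ndarray]) -> tuple[dict[str, np.ndarray], float]:
    """Mid-ranks per group over the pooled family, plus the tie term T."""
    labels = list(arrays)
    pooled = np.concatenate([arrays[g] for g in labels])
    ranks = stats.rankdata(pooled)
    big_n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (big_n - 1)) if big_n > 1 else 0.0
    out, i = {}, 0
    for g in labels:
        n = arrays[g].size
        out[g] = ranks[i:i + n]
        i += n
    return out, tie_term


def dunn_test(
    groups: Groups,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    adjustment: str = "none",
) -> dict[tuple[str, str], tuple[float, float]]:
    """Dunn's multiple median comparison over a family of groups.

    Ranking is pooled over *all* groups in ``groups``; for each requested pair
    (i, j),

        z = (meanrank_i - meanrank_j)
            / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)),

    with tie correction T = sum(t^3 - t) / (12 (N - 1)).  p-values are
    two-sided normal, optionally Holm-adjusted across the requested pairs.
    """
    if adjustment not in ("none", "holm"):
        raise ValueError(f"adjustment must be 'none' or 'holm', got {adjustment!r}")
    arrays = {g: as_grouped(v) for g, v in groups.items()}
    for g, a in arrays.items():
        if a.size == 0:
            raise ValueError(f"group {g!r} is empty")
    if pairs is None:
        labels = list(arrays)
        pairs = [(labels[i], labels[j]) for i in range(len(labels))
                 for j in range(i + 1, len(labels))]
    for a, b in pairs:
        if a not in arrays or b not in arrays:
            raise ValueError(f"pair ({a!r}, {b!r}) not in the group family")
    ranks, tie_term = _pooled_midranks(arrays)
    big_n = sum(a.size for a in arrays.values())
    var_base = big_n * (big_n + 1) / 12.0 - tie_term
    results = {}
    for a, b in pairs:
        n_a, n_b = arrays[a].size, arrays[b].size
        se = math.sqrt(var_base * (1.0 / n_a + 1.0 / n_b))
        if se == 0:
            z = 0.0
        else:
            z = (float(ranks[a].mean()) - float(ranks[b].mean())) / se
        p = 2.0 * stats.norm.sf(abs(z))
        results[(a, b)] = (z, min(1.0, p))
    if adjustment == "holm":
        keys = sorted(results, key=lambda k: results[k][1])
        m = len(keys)
        running = 0.0
        for rank, key in enumerate(keys):
            z, p = results[key]
            adj = min(1.0, (m - rank) * p)
            running = max(running, adj)
            results[key] = (z, running)
    return results


def dunn_pairwise(
    groups: Groups, pair: tuple[str, str], adjustment: str = "none"
) -> tuple[float, float]:
    """Dunn z and p for one pair, ranked over the full family in ``groups``."""
    return dunn_test(groups, pairs=[pair], adjustment=adjustment)[pair]


def median_percent_difference(m_treated: float, m_control: float) -> float:
    """Signed percent difference 100 * (treated - control) / control.

    The denominator keeps its sign, so a shrinking negative quantity (e.g.
    stress relaxation moving toward zero) yields a negative percent.
    """
    if m_control == 0:
        raise ValueError("control median must be nonzero")
    return 100.0 * (m_treated - m_control) / m_control


def round_percent(value: float) -> int:
    """Round to the nearest integer percent, halves away from zero."""
    return int(math.floor(abs(value) + 0.5) * (1 if value >= 0 else -1))


def required_sample_size(
    mid_fraction: float,
    coefficient_of_variation: float,
    alpha: float = 0.05,
    power: float = 0.8,
) -> int:
    """Per-group n for a two-sample t-test to detect a fractional difference.

    The standardized effect is d = ``mid_fraction / coefficient_of_variation``
    (minimally important difference over the outcome's relative spread); the
    smallest integer n meeting the noncentral-t power requirement is returned,
    floored at 2 (the minimum allowing a variance estimate).
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if coefficient_of_variation <= 0:
        raise ValueError("coefficient_of_variation must be positive")
    if mid_fraction == 0:
        raise ValueError("zero effect size: required n is unbounded")
    d = abs(mid_fraction) / coefficient_of_variation
    if d > 50:
        return 2
    n = TTestIndPower().solve_power(effect_size=d, alpha=alpha, power=power, ratio=1.0)
    return max(2, int(math.ceil(n)))


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

#: Pairwise comparisons reported by the study: treatment effects within
#: condition, degeneration effect, and treated-degenerated vs healthy control.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("GP", "C"),
    ("ColGP", "Col"),
    ("Col", "C"),
    ("ColGP", "C"),
)


@dataclass
class ComparisonResult:
    """Omnibus and pairwise comparison of one property across groups."""

    omnibus_h: float
    omnibus_p: float
    pairwise: dict[tuple[str, str], tuple[float, float]]
    median_diff_percent: dict[tuple[str, str], float]


def compare_property(
    groups: Groups,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    adjustment: str = "none",
) -> ComparisonResult:
    h, p = kruskal_wallis(groups)
    pairwise = dunn_test(groups, pairs=list(pairs), adjustment=adjustment)
    diffs = {
        (a, b): median_percent_difference(
            float(np.median(as_grouped(groups[a]))),
            float(np.median(as_grouped(groups[b]))),
        )
        for a, b in pairs
    }
    return ComparisonResult(h, p, pairwise, diffs)


def group_summary(
    properties: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    adjustment: str = "none",
) -> pd.DataFrame:
    """Summary table in the shape of the study's results table.

    ``properties`` must hold one row per specimen with a ``group`` column and
    one column per property.  The output has one row per (property, pair)
    with group medians, ranges, the rounded percent difference and the Dunn p.
    """
    prop_cols = [c for c in properties.columns if c not in ("specimen_id", "group")]
    rows = []
    for prop in prop_cols:
        groups = {
            g: sub[prop].to_numpy()
            for g, sub in properties.groupby("group", sort=False)
        }
        res = compare_property(groups, pairs=pairs, adjustment=adjustment)
        for (a, b) in pairs:
            z, p = res.pairwise[(a, b)]
            rows.append(
                {
                    "property": prop,
                    "group": a,
                    "reference": b,
                    "median": float(np.median(groups[a])),
                    "min": float(np.min(groups[a])),
                    "max": float(np.max(groups[a])),
                    "reference_median": float(np.median(groups[b])),
                    "reference_min": float(np.min(groups[b])),
                    "reference_max": float(np.max(groups[b])),
                    "percent_difference": round_percent(res.median_diff_percent[(a, b)]),
                    "dunn_z": z,
                    "p_value": p,
                    "omnibus_H": res.omnibus_h,
                    "omnibus_p": res.omnibus_p,
                }
            )
    return pd.DataFrame(rows)
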