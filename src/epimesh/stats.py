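"""Nonparametric comparison of metric distributions between conditions.

Groups are compared with the two-sided Mann-Whitney U test: exact null
enumeration for small untied samples (n1 + n2 <= 16, no ties), otherwise the
normal approximation with tie and continuity corrections. Sampling units are
individual triangles (area, gamma_k, phi_k) or unique edges (length), not
images. Raw p-values are reported; an optional Benjamini-Hochberg adjustment
is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .metrics import MeshSummary

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))
EXACT_MAX_N = 16


def significance_stars(p: float) -> str:
    """Star convention: * p<=0.05, ** p<=0.01, *** p<=0.001, **** p<=0.0001."""
    for thr, stars in STAR_THRESHOLDS:
        if p <= thr:
            return stars
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    group_x: str
    group_y: str
    n_x: int
    n_y: int
    u_statistic: float
    p_value: float
    stars: str
    method: str

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "group_x": self.group_x,
            "group_y": self.group_y,
            "n_x": self.n_x,
            "n_y": self.n_y,
            "U": self.u_statistic,
            "p": self.p_value,
            "stars": self.stars,
            "method": self.method,
        }


def mann_whitney(
    x, y, metric: str = "", group_x: str = "x", group_y: str = "y"
) -> GroupComparison:
    """Two-sided Mann-Whitney U test of two independent samples.

    ``U`` is the statistic of the first sample (number of (x_i, y_j) pairs
    with x_i > y_j, ties counting half), in [0, n1*n2].
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if x.size + y.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = _sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    p = float(min(res.pvalue, 1.0))
    return GroupComparison(
        metric=metric,
        group_x=group_x,
        group_y=group_y,
        n_x=int(x.size),
        n_y=int(y.size),
        u_statistic=float(res.statistic),
        p_value=p,
        stars=significance_stars(p),
        method="exact" if method == "exact" else "normal approximation (tie + continuity corrected)",
    )


def compare_conditions(
    summaries: dict[str, MeshSummary],
    metrics: tuple[str, ...] = ("area", "edge_length", "gamma", "phi"),
    reference: str | None = None,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Test every non-reference condition against the reference per metric.

    ``reference`` defaults to the first condition in the mapping (e.g. wild
    type). With ``bh_correction`` an adjusted-p column is added; star
    assignment always uses the raw p-values.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 conditions to compare")
    names = list(summaries)
    reference = reference if reference is not None else names[0]
    if reference not in summaries:
        raise KeyError(f"reference condition {reference!r} not in summaries")
    comparisons: list[GroupComparison] = []
    for name in names:
        if name == reference:
            continue
        for metric in metrics:
            comparisons.append(
                mann_whitney(
                    summaries[reference].values(metric),
                    summaries[name].values(metric),
                    metric=metric,
                    group_x=reference,
                    group_y=name,
                )
            )
    table = pd.DataFrame([c.to_dict() for c in comparisons])
    if bh_correction and len(table):
        table["p_adjusted"] = _benjamini_hochberg(table["p"].to_numpy())
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
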