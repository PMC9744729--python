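"""Per-index group comparisons with significance tiers.

Each of the 41 pulse indices is compared between groups — Welch's t-test
(default) or the pooled-variance t-test for two groups, one-way ANOVA for
four — and assigned a tier: ``significant`` (p < 0.05), ``marginal``
(0.05 <= p < 0.1) or ``none``. The marginal tier feeds index selection in
the bar-scoring classifier.

No multiple-testing correction is applied by default, matching per-index
reporting conventions in pulse-waveform studies; a Benjamini-Hochberg
helper is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .exceptions import ValidationError

SIGNIFICANT_P = 0.05
MARGINAL_P = 0.10


@dataclass
class IndexComparison:
    index_name: str
    group_means: dict
    group_sds: dict
    p_value: float
    tier: str


def assign_tier(p_value: float) -> str:
    if np.isnan(p_value):
        return "none"
    if p_value < SIGNIFICANT_P:
        return "significant"
    if p_value < MARGINAL_P:
        return "marginal"
    return "none"


def _group_arrays(
    features: pd.DataFrame, labels: np.ndarray
) -> tuple[list, list[pd.DataFrame]]:
    labels = np.asarray(labels)
    if labels.shape[0] != features.shape[0]:
        raise ValidationError("labels must align with feature rows")
    levels = list(pd.unique(labels))
    groups = [features.loc[labels == lv] for lv in levels]
    return levels, groups


def _degenerate_p(samples: list[np.ndarray]) -> float | None:
    """p-value when every group is internally constant, else None."""
    if all(s.std(ddof=1) == 0 if s.size > 1 else True for s in samples):
        means = [s.mean() for s in samples]
        return 1.0 if np.allclose(means, means[0]) else 0.0
    return None


def compare_two_groups(
    features: pd.DataFrame,
    labels: np.ndarray,
    *,
    equal_var: bool = False,
) -> list[IndexComparison]:
    """Two-sample t-test per index (Welch by default).

    ``equal_var=True`` selects the pooled-variance test, whose squared
    statistic equals the two-group one-way ANOVA F on the same data.
    """
    levels, groups = _group_arrays(features, labels)
    if len(levels) != 2:
        raise ValidationError(f"expected exactly two groups, got {len(levels)}")
    if any(g.shape[0] < 2 for g in groups):
        raise ValidationError("each group needs at least two members")
    out = []
    for col in features.columns:
        samples = [g[col].to_numpy(dtype=float) for g in groups]
        p = _degenerate_p(samples)
        if p is None:
            p = float(_st.ttest_ind(samples[0], samples[1], equal_var=equal_var).pvalue)
        out.append(
            IndexComparison(
                index_name=str(col),
                group_means={lv: float(s.mean()) for lv, s in zip(levels, samples)},
                group_sds={lv: float(s.std(ddof=1)) for lv, s in zip(levels, samples)},
                p_value=p,
                tier=assign_tier(p),
            )
        )
    return out


def compare_four_groups(
    features: pd.DataFrame, labels: np.ndarray
) -> list[IndexComparison]:
    """One-way ANOVA per index across a 4-level (or k-level) grouping."""
    levels, groups = _group_arrays(features, labels)
    if any(g.shape[0] < 1 for g in groups):
        raise ValidationError("every group must be nonempty")
    out = []
    for col in features.columns:
        samples = [g[col].to_numpy(dtype=float) for g in groups]
        p = _degenerate_p(samples)
        if p is None:
            p = float(_st.f_oneway(*samples).pvalue)
        out.append(
            IndexComparison(
                index_name=str(col),
                group_means={lv: float(s.mean()) for lv, s in zip(levels, samples)},
                group_sds={
                    lv: float(s.std(ddof=1)) if s.size > 1 else 0.0
                    for lv, s in zip(levels, samples)
                },
                p_value=p,
                tier=assign_tier(p),
            )
        )
    return out


def benjamini_hochberg(comparisons: list[IndexComparison]) -> pd.Series:
    """BH-adjusted q-values for a comparison list (reporting aid, off the
    default path)."""
    p = np.array([c.p_value for c in comparisons])
    order = np.argsort(p)
    m = p.size
    q = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return pd.Series(q, index=[c.index_name for c in comparisons])


def comparisons_to_frame(comparisons: list[IndexComparison]) -> pd.DataFrame:
    """Flatten comparisons into the tabular report format."""
    rows = []
    for c in comparisons:
        row = {"index": c.index_name, "p_value": c.p_value, "tier": c.tier}
        for lv, m in c.group_means.items():
            row[f"mean_{lv}"] = m
        for lv, s in c.group_sds.items():
            row[f"sd_{lv}"] = s
        rows.append(row)
    return pd.DataFrame(rows)
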