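"""Nonparametric group comparison of entropy profiles, scale by scale.

For each temporal scale the entropy values of all subjects are pooled
and ranked jointly (midranks for ties); the per-group mean ranks, a
Kruskal-Wallis or Wilcoxon-Mann-Whitney p-value, and (for two groups)
the area under the ROC curve are reported.  AUC is computed through
its rank identity AUC = U / (n1 * n2) = P(X > Y) + 0.5 * P(X = Y).

Per-scale p-values are reported without multiplicity correction by
default (a Bonferroni option is provided).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .symbolic import EntropyProfile

__all__ = [
    "GroupComparison",
    "MannWhitneyResult",
    "mean_ranks",
    "kruskal_wallis",
    "mann_whitney",
    "auc",
    "compare_at_scale",
    "compare_profiles",
]

#: Exact Mann-Whitney enumeration is used up to this n1*n2 (ties permitting).
EXACT_MW_LIMIT = 400
#: Default significance threshold for the rank tests.
ALPHA = 0.05


def _as_groups(values_by_group: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    groups = {
        str(name): np.asarray(vals, dtype=float)
        for name, vals in values_by_group.items()
    }
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if vals.size == 0:
            raise ValueError(f"group {name!r} is empty")
    return groups


def mean_ranks(values_by_group: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Per-group mean of joint midranks over the pooled sample."""
    groups = _as_groups(values_by_group)
    pooled = np.concatenate(list(groups.values()))
    ranks = stats.rankdata(pooled)
    out: dict[str, float] = {}
    start = 0
    for name, vals in groups.items():
        out[name] = float(ranks[start : start + vals.size].mean())
        start += vals.size
    return out


def kruskal_wallis(
    values_by_group: Mapping[str, Sequence[float]],
) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value (k-1 df)."""
    groups = _as_groups(values_by_group)
    for name, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {name!r} needs >= 2 observations")
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0.0:  # all values identical: no evidence at all
        return 0.0, 1.0
    h, p = stats.kruskal(*groups.values())
    return float(h), float(p)


@dataclass
class MannWhitneyResult:
    """Both U conventions plus the two-sided p-value."""

    u1: float  # pairs where the first sample wins (+ half-ties)
    u2: float  # complementary statistic, n1*n2 - u1
    p_value: float
    method: str  # "exact" or "asymptotic"


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Exact enumeration of the null distribution when n1*n2 <= 400 and
    the pooled sample is tie-free; otherwise the normal approximation
    with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= EXACT_MW_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    return MannWhitneyResult(
        u1=u1, u2=float(a.size * b.size - u1), p_value=float(res.pvalue),
        method=method,
    )


def auc(group_pos: Sequence[float], group_neg: Sequence[float]) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney U) identity."""
    pos = np.asarray(group_pos, dtype=float)
    neg = np.asarray(group_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be nonempty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u_pos = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u_pos / (pos.size * neg.size))


@dataclass
class GroupComparison:
    """Per-scale comparison summary across subject groups."""

    scale: int
    group_names: tuple[str, ...]
    mean_ranks: dict[str, float]
    p_value: float
    auc: float | None  # two-group case only
    n_per_group: dict[str, int]
    test: str  # "mann-whitney" or "kruskal-wallis"


def compare_at_scale(
    values_by_group: Mapping[str, Sequence[float]], scale: int
) -> GroupComparison:
    """Compare groups of entropy values measured at one scale.

    Two groups: Mann-Whitney p and AUC of the first group versus the
    second.  Three or more: Kruskal-Wallis p, no AUC.
    """
    groups = _as_groups(values_by_group)
    names = tuple(groups)
    ranks = mean_ranks(groups)
    if len(groups) == 2:
        a, b = groups[names[0]], groups[names[1]]
        mw = mann_whitney(a, b)
        return GroupComparison(
            scale=int(scale),
            group_names=names,
            mean_ranks=ranks,
            p_value=mw.p_value,
            auc=auc(a, b),
            n_per_group={n: int(groups[n].size) for n in names},
            test="mann-whitney",
        )
    _, p = kruskal_wallis(groups)
    return GroupComparison(
        scale=int(scale),
        group_names=names,
        mean_ranks=ranks,
        p_value=p,
        auc=None,
        n_per_group={n: int(groups[n].size) for n in names},
        test="kruskal-wallis",
    )


def compare_profiles(
    profiles_by_group: Mapping[str, Sequence[EntropyProfile]],
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-scale comparison table for groups of entropy profiles.

    Undefined (NaN) scale values are dropped per subject; a scale is
    skipped when any group has no defined value there.  With
    ``bonferroni=True`` the p-values are multiplied by the number of
    scales tested (capped at 1).
    """
    if len(profiles_by_group) < 2:
        raise ValueError("need at least two groups of profiles")
    all_scales = sorted(
        set(
            int(s)
            for profs in profiles_by_group.values()
            for p in profs
            for s in p.scales
        )
    )
    rows = []
    for scale in all_scales:
        values_by_group = {}
        ok = True
        for name, profs in profiles_by_group.items():
            vals = []
            for prof in profs:
                try:
                    v = prof.value_at(scale)
                except KeyError:
                    continue
                if np.isfinite(v):
                    vals.append(v)
            if not vals:
                ok = False
                break
            values_by_group[name] = vals
        if not ok:
            continue
        cmp = compare_at_scale(values_by_group, scale)
        row: dict[str, object] = {"scale": scale}
        for name in cmp.group_names:
            row[f"mean_rank_{name}"] = cmp.mean_ranks[name]
            row[f"n_{name}"] = cmp.n_per_group[name]
        row["p_value"] = cmp.p_value
        row["auc"] = cmp.auc
        row["test"] = cmp.test
        rows.append(row)
    if not rows:
        raise ValueError("no scale had defined values in every group")
    df = pd.DataFrame(rows)
    if bonferroni:
        df["p_value"] = np.minimum(df["p_value"] * len(df), 1.0)
    return df
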