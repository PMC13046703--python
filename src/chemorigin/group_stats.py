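"""Regional screening of single components: one-way ANOVA, Tukey HSD, letters.

For every chemical component the screening question is whether its mean
concentration differs among origin groups.  The answer is reported the way
agricultural-chemistry tables conventionally print it: an F test over all
groups, a significance category (ns / * / ** / ***), and a compact letter
display (CLD) summarising all pairwise Tukey HSD comparisons — groups that
share a letter are not significantly different.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .registry import ComponentRegistry
from .synthesis import ChemTable

__all__ = [
    "AnovaResult",
    "one_way_anova",
    "tukey_hsd",
    "compact_letter_display",
    "significance_category",
    "anova_table",
]


def significance_category(p: float) -> str:
    """Map a p-value to the conventional table label.

    Right-closed bins: ns if p > 0.05, '*' if 0.01 < p ≤ 0.05,
    '**' if 0.001 < p ≤ 0.01, '***' if p ≤ 0.001.
    """
    if not (0.0 <= p <= 1.0) or math.isnan(p):
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    if p > 0.05:
        return "ns"
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    return "***"


@dataclass(frozen=True)
class AnovaResult:
    component: str
    F: float
    df_between: int
    df_within: int
    p: float
    category: str
    group_order: tuple[str, ...]
    group_means: dict[str, float]
    group_letters: dict[str, str]
    degenerate: bool = False


def _grouped_column(table: ChemTable, component: str, group_by: str):
    x = table.column(component)
    labels = table.labels(group_by)
    order = list(dict.fromkeys(labels))  # first-appearance order
    groups = [x[labels == g] for g in order]
    if len(order) < 2:
        raise ValueError("need at least two groups")
    for g, vals in zip(order, groups):
        if vals.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    return order, groups


def _anova_decomposition(groups: list[np.ndarray]) -> tuple[float, int, int, float, bool]:
    """Classical fixed-effects F = MSB / MSW from the sum-of-squares identity."""
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = all_x.size - len(groups)
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, dfb, dfw, 1.0, False
        return math.inf, dfb, dfw, 0.0, True  # unequal means, zero within-variance
    F = (ssb / dfb) / (ssw / dfw)
    return float(F), dfb, dfw, float(stats.f.sf(F, dfb, dfw)), False


@lru_cache(maxsize=None)
def _q_crit(alpha: float, k: int, dfw: int) -> float:
    """Upper-α studentized-range quantile; cached — one table shares (k, dfw)."""
    return float(stats.studentized_range.ppf(1.0 - alpha, k, dfw))


def tukey_hsd(table: ChemTable, component: str, group_by: str = "region",
              alpha: float = 0.05) -> tuple[np.ndarray, list[str]]:
    """All-pairs Tukey HSD on one component.

    Returns ``(significant, order)``: a symmetric boolean matrix over groups in
    first-appearance ``order`` using the studentized-range criterion with
    Tukey–Kramer standard errors for unbalanced groups.
    """
    order, groups = _grouped_column(table, component, group_by)
    means = np.array([g.mean() for g in groups])
    if all(np.ptp(g) == 0.0 for g in groups):
        # zero within-group variance: pairs differ exactly when their means do
        sig = means[:, None] != means[None, :]
    else:
        k = len(order)
        dfw = sum(g.size for g in groups) - k
        msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / dfw
        inv_n = np.array([1.0 / g.size for g in groups])
        # Tukey–Kramer SE of each pairwise mean difference
        se = np.sqrt(msw / 2.0 * (inv_n[:, None] + inv_n[None, :]))
        q = np.abs(means[:, None] - means[None, :]) / np.where(se > 0, se, np.inf)
        sig = q > _q_crit(alpha, k, dfw)
    sig = sig.astype(bool)
    np.fill_diagonal(sig, False)
    return sig, order


def compact_letter_display(significant: np.ndarray, group_order: list[str]) -> dict[str, str]:
    """Insert-and-absorb letter assignment.

    Two groups share at least one letter iff they are NOT significantly
    different.  Letters are assigned 'a', 'b', … ordered by the earliest
    group (in ``group_order``) each letter covers; ties broken by the full
    sorted membership, so the output is deterministic.
    """
    sig = np.asarray(significant)
    k = len(group_order)
    if sig.shape != (k, k):
        raise ValueError("matrix shape does not match the group list")
    if not np.array_equal(sig, sig.T):
        raise ValueError("significance matrix must be symmetric")

    sets: list[frozenset[int]] = [frozenset(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            nxt: list[frozenset[int]] = []
            for s in sets:
                if i in s and j in s:
                    nxt.extend((s - {i}, s - {j}))
                else:
                    nxt.append(s)
            # absorb: drop any set contained in another
            nxt = sorted(set(nxt), key=lambda s: (min(s), sorted(s)))
            sets = [s for s in nxt if not any(s < t for t in nxt)]

    sets = sorted(sets, key=lambda s: (min(s), sorted(s)))
    letters = ["" for _ in range(k)]
    for idx, s in enumerate(sets):
        letter = _letter(idx)
        for g in sorted(s):
            letters[g] += letter
    if any(not l for l in letters):
        raise RuntimeError("letter assignment left a group uncovered")
    return {group_order[i]: letters[i] for i in range(k)}


def _letter(idx: int) -> str:
    out = ""
    idx += 1
    while idx:
        idx, rem = divmod(idx - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def one_way_anova(table: ChemTable, component: str, group_by: str = "region",
                  alpha: float = 0.05) -> AnovaResult:
    """One-way fixed-effects ANOVA for one component, with post hoc letters."""
    order, groups = _grouped_column(table, component, group_by)
    F, dfb, dfw, p, degenerate = _anova_decomposition(groups)
    sig, _ = tukey_hsd(table, component, group_by, alpha=alpha)
    letters = compact_letter_display(sig, order)
    return AnovaResult(
        component=component, F=F, df_between=dfb, df_within=dfw, p=p,
        category=significance_category(p), group_order=tuple(order),
        group_means={g: float(v.mean()) for g, v in zip(order, groups)},
        group_letters=letters, degenerate=degenerate,
    )


def anova_table(table: ChemTable, group_by: str = "region",
                registry: ComponentRegistry | None = None,
                components: list[str] | None = None) -> pd.DataFrame:
    """Per-component screening table mirroring the published layout.

    One row per component: units, per-group "mean ± sd letters", F, p and the
    significance category.  No multiplicity correction is applied across
    components, matching the published analysis.
    """
    components = components or list(table.component_names)
    units = registry.units if registry is not None else {}
    labels = table.labels(group_by)
    order = list(dict.fromkeys(labels))
    rows = []
    for comp in components:
        res = one_way_anova(table, comp, group_by)
        x = table.column(comp)
        row: dict[str, object] = {"component": comp, "units": units.get(comp, "")}
        for g in order:
            vals = x[labels == g]
            row[g] = f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f}{res.group_letters[g]}"
        row["F"] = res.F
        row["p"] = res.p
        row["category"] = res.category
        rows.append(row)
    return pd.DataFrame(rows)
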