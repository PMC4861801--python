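"""Group comparison: one-way ANOVA with Tukey HSD post hoc.

Marker values and assay concentrations are compared across treatment
groups by one-way ANOVA; when the omnibus test finds a difference,
Tukey's honestly-significant-difference test localizes it pairwise at a
familywise significance level (alpha = 0.05 by default). Unbalanced
designs use the Tukey-Kramer standard error. A compact letter display
summarizes the pairwise table in the style of grouped bar annotations:
treatments sharing a letter are not significantly different.

Each marker or assay is tested separately; no correction is applied
across the four markers (a documented limitation, matching the practice
of reporting each ratio independently).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

__all__ = [
    "AnovaResult",
    "one_way_anova",
    "tukey_hsd",
    "letters_display",
    "compare_groups",
]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_within: float


def _validate_groups(g: Mapping[str, Sequence[float]], min_size: int = 2) -> dict:
    if len(g) < 2:
        raise ValueError(f"need >= 2 groups, got {len(g)}")
    out = {}
    for label, obs in g.items():
        arr = np.asarray(obs, dtype=float)
        if arr.ndim != 1 or arr.size < min_size:
            raise ValueError(
                f"group {label!r} needs >= {min_size} observations, got {arr.size}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {label!r} contains non-finite values")
        out[label] = arr
    return out


def one_way_anova(g: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Standard between/within mean-square F test.

    F is invariant to adding a constant to every observation and to
    multiplying all observations by a nonzero constant. Identical group
    means give F = 0, p = 1; zero variance both between and within groups
    is degenerate and raises.
    """
    groups = _validate_groups(g)
    all_obs = np.concatenate(list(groups.values()))
    grand = all_obs.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in groups.values())
    ss_within = sum(np.sum((a - a.mean()) ** 2) for a in groups.values())
    df_between = len(groups) - 1
    df_within = all_obs.size - len(groups)
    if ss_within == 0.0 and ss_between == 0.0:
        raise ValueError("degenerate data: zero variance between and within groups")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        return AnovaResult(np.inf, df_between, df_within, 0.0, 0.0)
    F = ms_between / ms_within
    p = float(f_dist.sf(F, df_between, df_within))
    return AnovaResult(float(F), df_between, df_within, p, float(ms_within))


def tukey_hsd(g: Mapping[str, Sequence[float]], alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey HSD table.

    For each unordered pair the q statistic is
    ``|mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))`` (the
    Tukey-Kramer form, exact for balanced groups) and the adjusted p-value
    comes from the studentized-range distribution with (k, df_within).

    Returns a frame with columns group_a, group_b, mean_diff, q_statistic,
    p_adjusted, significant — one row per unordered pair, labels sorted.
    """
    groups = _validate_groups(g)
    anova = one_way_anova(groups)
    k = len(groups)
    rows = []
    for a, b in combinations(sorted(groups), 2):
        xa, xb = groups[a], groups[b]
        diff = float(xa.mean() - xb.mean())
        se = np.sqrt(anova.ms_within / 2.0 * (1.0 / xa.size + 1.0 / xb.size))
        if se == 0.0:
            q = np.inf if diff != 0 else 0.0
        else:
            q = abs(diff) / se
        p = float(np.clip(studentized_range.sf(q, k, anova.df_within), 0.0, 1.0))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_diff": diff,
                "q_statistic": float(q),
                "p_adjusted": p,
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)


def letters_display(table: pd.DataFrame) -> dict[str, str]:
    """Compact letter display from a complete Tukey table.

    Implements the insert-and-absorb algorithm: start with one letter
    covering every treatment; for each significant pair, split any letter
    column containing both members; absorb columns that became subsets of
    another. Treatments sharing a letter are not significantly different.
    Deterministic given the sorted label order.
    """
    needed = {"group_a", "group_b", "significant"}
    if not needed.issubset(table.columns):
        raise ValueError(f"Tukey table must have columns {sorted(needed)}")
    treatments = sorted(set(table["group_a"]) | set(table["group_b"]))
    n_pairs = len(treatments) * (len(treatments) - 1) // 2
    if len(table) != n_pairs:
        raise ValueError(
            f"incomplete pairwise table: {len(table)} rows for "
            f"{len(treatments)} treatments (need {n_pairs})"
        )
    columns: list[set[str]] = [set(treatments)]
    sig_pairs = sorted(
        (min(r.group_a, r.group_b), max(r.group_a, r.group_b))
        for r in table.itertuples(index=False)
        if r.significant
    )
    for a, b in sig_pairs:
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: dedupe, then drop any column that is a proper subset
        unique: list[set[str]] = []
        for col in new_columns:
            if col not in unique:
                unique.append(col)
        columns = [c for c in unique if not any(c < o for o in unique)]
    columns.sort(key=lambda col: (min(col), sorted(col)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {t: "" for t in treatments}
    for i, col in enumerate(columns):
        letter = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for t in sorted(col):
            out[t] += letter
    return out


def compare_groups(
    frame: pd.DataFrame,
    value_col: str,
    group_col: str = "treatment",
    alpha: float = 0.05,
) -> dict:
    """ANOVA + Tukey + letters for one tidy measurement column."""
    groups = {
        str(label): sub[value_col].to_numpy(float)
        for label, sub in frame.groupby(group_col)
    }
    anova = one_way_anova(groups)
    tukey = tukey_hsd(groups, alpha=alpha)
    return {"anova": anova, "tukey": tukey, "letters": letters_display(tukey)}
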