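"""Between-group comparison of network measures with Welch's t test.

Groups (healthy controls, minimally conscious state, unresponsive
wakefulness syndrome, and their union DOC) are compared per measure and
per node — or per network average — with the unpaired two-sample t test
that does not assume equal variances:

    t  = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b)

with Welch–Satterthwaite degrees of freedom and a two-sided p-value.
Nodal families are Bonferroni-corrected over the 10 networks (the
reporting convention p < alpha/10); average measures form a family of
one.  A summary-statistics entry point recomputes printed t values from
published means and standard deviations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateSeriesError, InvalidArgumentError

__all__ = [
    "welch_t",
    "welch_t_from_summary",
    "compare_groups",
    "DEFAULT_PAIRS",
]

#: Group contrasts reported for the consciousness cohorts; "DOC" is the
#: pooled MCS + UWS patient population.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("HC", "MCS"),
    ("HC", "UWS"),
    ("HC", "DOC"),
    ("MCS", "UWS"),
)


def welch_t_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's t, degrees of freedom and two-sided p from summary statistics.

    ``sd`` values are sample standard deviations (ddof = 1).  Raises
    :class:`DegenerateSeriesError` when both variances are zero.
    """
    if n1 < 2 or n2 < 2:
        raise InvalidArgumentError("each sample must have n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise InvalidArgumentError("standard deviations must be nonnegative")
    va, vb = sd1**2 / n1, sd2**2 / n2
    if va + vb == 0:
        raise DegenerateSeriesError("both samples have zero variance")
    t = (m1 - m2) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n1 - 1) + vb**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch's t, degrees of freedom and two-sided p from raw samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("each sample must have n >= 2")
    return welch_t_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


def _resolve_groups(table: pd.DataFrame, name: str) -> pd.DataFrame:
    if name == "DOC":
        return table[table["group"].isin(["MCS", "UWS"])]
    return table[table["group"] == name]


def compare_groups(
    table: pd.DataFrame,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
    alpha: float = 0.05,
    family: int = 10,
) -> pd.DataFrame:
    """Welch tests for every (measure, node-or-average, group pair).

    Parameters
    ----------
    table:
        Tidy per-subject metrics with columns ``subject, group, node,
        measure, value`` (node ``"average"`` holds network means).
    pairs:
        Group contrasts; ``"DOC"`` pools MCS and UWS subjects.
    alpha, family:
        Nodal tests are flagged significant at ``alpha / family``
        (Bonferroni over the networks); ``"average"`` rows at ``alpha``.

    Returns a table with columns ``measure, node, pair, group_a, group_b,
    mean_a, mean_b, t, df, p, significant``.
    """
    required = {"subject", "group", "node", "measure", "value"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidArgumentError(f"metrics table lacks columns {sorted(missing)}")
    known = set(table["group"].unique()) | {"DOC"}
    rows = []
    for ga, gb in pairs:
        if ga not in known or gb not in known:
            raise InvalidArgumentError(f"unknown group pair ({ga}, {gb})")
        ta, tb = _resolve_groups(table, ga), _resolve_groups(table, gb)
        if ta.empty or tb.empty:
            raise InvalidArgumentError(f"empty group in pair ({ga}, {gb})")
        for (measure, node), sub_a in ta.groupby(["measure", "node"], sort=True):
            sub_b = tb[(tb["measure"] == measure) & (tb["node"] == node)]
            a, b = sub_a["value"].to_numpy(), sub_b["value"].to_numpy()
            try:
                t, df, p = welch_t(a, b)
            except DegenerateSeriesError:
                t, df, p = 0.0, float(a.size + b.size - 2), 1.0
            threshold = alpha if node == "average" else alpha / family
            rows.append(
                {
                    "measure": measure,
                    "node": node,
                    "pair": f"{ga}-{gb}",
                    "group_a": ga,
                    "group_b": gb,
                    "mean_a": float(a.mean()),
                    "mean_b": float(b.mean()),
                    "t": t,
                    "df": df,
                    "p": p,
                    "significant": bool(p < threshold),
                }
            )
    return pd.DataFrame(rows)
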