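"""Top-author vs general-opposition theme comparison with per-theme χ² tests.

Each comparison row holds a theme's message count and percentage in the
top-author group and in the remaining opposition, plus a Pearson χ² test (no
continuity correction, 1 df, two-sided) on the 2×2 table::

    [[x_top,   n_top - x_top],
     [x_other, n_other - x_other]]

Percentages use the group message totals as denominators, supplied explicitly
(multi-label tagging means per-theme percentages may sum past 100%).
Displayed percentages round half-up to one decimal.  P-values are unadjusted;
an optional Bonferroni column is available but off by default.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import chi2_contingency

from .errors import DegenerateTableError, PartitionError, UndefinedDenominatorError
from .themes import TaggedPost, theme_counts

__all__ = [
    "ComparisonRow",
    "ComparisonTable",
    "theme_proportions",
    "chi2_two_proportion",
    "build_comparison_table",
    "table_from_counts",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 7.3511 -> 7.4 at one decimal)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def theme_proportions(
    tagged: Iterable[TaggedPost] | Mapping[str, int],
    group_denominator: int,
) -> dict[str, tuple[int, float]]:
    """Per-theme (count, percent) with an explicit group denominator.

    Accepts tagged posts or precomputed counts.  Multi-label posts count once
    per theme they carry; the percent is ``100 * count / denominator``
    (unrounded — round on display).
    """
    if group_denominator <= 0:
        raise UndefinedDenominatorError("group denominator must be positive")
    counts = (
        dict(tagged) if isinstance(tagged, Mapping) else theme_counts(tagged)
    )
    return {
        theme: (count, 100.0 * count / group_denominator)
        for theme, count in counts.items()
    }


def chi2_two_proportion(
    x1: int, n1: int, x2: int, n2: int
) -> tuple[float, float]:
    """Pearson χ² (no continuity correction) comparing two proportions.

    Tests x1/n1 against x2/n2 on the implied 2×2 table; returns
    ``(chi2_stat, two_sided_p)``.  A zero margin (both counts zero, or both
    complements zero) makes the test undefined.
    """
    if n1 <= 0 or n2 <= 0:
        raise UndefinedDenominatorError("group sizes must be positive")
    if x1 < 0 or x2 < 0 or x1 > n1 or x2 > n2:
        raise ValueError("counts must satisfy 0 <= x <= n")
    table = [[x1, n1 - x1], [x2, n2 - x2]]
    if x1 + x2 == 0 or (n1 - x1) + (n2 - x2) == 0:
        raise DegenerateTableError(f"zero margin in table {table}")
    result = chi2_contingency(table, correction=False)
    return float(result.statistic), float(result.pvalue)


@dataclass(frozen=True)
class ComparisonRow:
    """One theme's counts, percentages and test in the two-group comparison."""

    theme_name: str
    count_top: int
    pct_top: float
    count_other: int
    pct_other: float
    chi2_stat: float
    p_value: float
    p_bonferroni: Optional[float] = None

    def formatted_p(self) -> str:
        if self.p_value < 0.001:
            return "<0.001"
        return f"{round_half_up(self.p_value, 2):.2f}"


@dataclass(frozen=True)
class ComparisonTable:
    """Rows sorted by top-author percentage descending, fixed denominators."""

    rows: tuple[ComparisonRow, ...]
    denominator_top: int
    denominator_other: int

    def to_rows(self) -> list[dict]:
        return [
            {
                "theme": r.theme_name,
                "pct_top": f"{round_half_up(r.pct_top, 1):.1f}",
                "count_top": r.count_top,
                "pct_other": f"{round_half_up(r.pct_other, 1):.1f}",
                "count_other": r.count_other,
                "p_value": r.formatted_p(),
                **(
                    {"p_bonferroni": f"{min(1.0, r.p_bonferroni):.3g}"}
                    if r.p_bonferroni is not None
                    else {}
                ),
            }
            for r in self.rows
        ]

    def to_csv(self, path=None) -> Optional[str]:
        rows = self.to_rows()
        fieldnames = list(rows[0]) if rows else [
            "theme", "pct_top", "count_top", "pct_other", "count_other", "p_value"
        ]
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=fieldnames, lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)
        text = buf.getvalue()
        if path is None:
            return text
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        return None

    def to_markdown(self) -> str:
        header = (
            f"| Theme | Top authors % (n), N={self.denominator_top} "
            f"| Other opposition % (n), N={self.denominator_other} | P value |"
        )
        lines = [header, "|---|---|---|---|"]
        for r in self.rows:
            lines.append(
                f"| {r.theme_name} "
                f"| {round_half_up(r.pct_top, 1):.1f} ({r.count_top}) "
                f"| {round_half_up(r.pct_other, 1):.1f} ({r.count_other}) "
                f"| {r.formatted_p()} |"
            )
        return "\n".join(lines)


def table_from_counts(
    counts_top: Mapping[str, int],
    counts_other: Mapping[str, int],
    denominator_top: int,
    denominator_other: int,
    themes: Optional[Sequence[str]] = None,
    bonferroni: bool = False,
) -> ComparisonTable:
    """Build the comparison table from per-theme counts and group totals."""
    if themes is None:
        themes = sorted(set(counts_top) | set(counts_other))
    props_top = theme_proportions(
        {t: counts_top.get(t, 0) for t in themes}, denominator_top
    )
    props_other = theme_proportions(
        {t: counts_other.get(t, 0) for t in themes}, denominator_other
    )
    m = len(themes)
    rows = []
    for theme in themes:
        x1, pct1 = props_top[theme]
        x2, pct2 = props_other[theme]
        try:
            stat, p = chi2_two_proportion(x1, denominator_top, x2, denominator_other)
        except DegenerateTableError:
            stat, p = 0.0, 1.0  # both groups empty (or full) for this theme
        rows.append(
            ComparisonRow(
                theme_name=theme,
                count_top=x1,
                pct_top=pct1,
                count_other=x2,
                pct_other=pct2,
                chi2_stat=stat,
                p_value=p,
                p_bonferroni=min(1.0, p * m) if bonferroni else None,
            )
        )
    rows.sort(key=lambda r: (-r.pct_top, r.theme_name))
    return ComparisonTable(
        rows=tuple(rows),
        denominator_top=denominator_top,
        denominator_other=denominator_other,
    )


def build_comparison_table(
    top: Sequence[TaggedPost],
    other: Sequence[TaggedPost],
    themes: Sequence[str],
    bonferroni: bool = False,
) -> ComparisonTable:
    """Comparison table from two disjoint tagged groups.

    Denominators are the group message totals (posts with zero themes stay in
    the denominator).  Overlapping groups are a partition error.
    """
    ids_top = {tp.post.post_id for tp in top}
    ids_other = {tp.post.post_id for tp in other}
    overlap = ids_top & ids_other
    if overlap:
        raise PartitionError(f"groups overlap on {len(overlap)} post(s)")
    if not top or not other:
        raise UndefinedDenominatorError("both groups must be nonempty")
    return table_from_counts(
        theme_counts(top),
        theme_counts(other),
        denominator_top=len(top),
        denominator_other=len(other),
        themes=themes,
        bonferroni=bonferroni,
    )
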