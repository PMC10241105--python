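"""Classification of miRNA differential-expression trajectories across an
ordered comparison plan.

Each miRNA is book-kept at the *first* comparison in which it is called
differentially expressed (the convention used for time-course summaries:
a miRNA that stays deregulated later is not re-listed). Downstream
comparisons then decide whether the change is

* **persistent** — the same direction is called in every provided
  *cumulative* comparison, i.e. every comparison whose later time point
  lies strictly after the first-DE window and whose baseline is at or
  before the first window's baseline (vacuously true when no such
  comparison exists, e.g. a hit in the last window);
* **transient** — at least one such cumulative comparison exists and all
  of them are ns (the "dip that recovers" pattern);
* **non-monotone** — some later comparison calls the opposite direction;
  excluded from persistence bookkeeping.

A miRNA can also be neither (mixed ns and same-direction later calls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .diffexpr import ComparisonSpec
from .io_formats import ValidationError

__all__ = ["TemporalPattern", "classify_patterns", "pattern_summary", "patterns_to_frame"]


@dataclass(frozen=True)
class TemporalPattern:
    mirna: str
    first_comparison: str | None
    direction: str | None  # up/down at the first comparison; None if never DE
    persistent: bool
    transient: bool
    non_monotone: bool
    supporting: tuple[tuple[str, str], ...]  # (comparison id, direction) where DE

    def __post_init__(self) -> None:
        if self.persistent and self.transient:
            raise ValidationError("persistent and transient are mutually exclusive")
        if self.first_comparison is None and self.direction is not None:
            raise ValidationError("direction undefined without a first comparison")


def _ordered_plan(
    adjacent_order: list[ComparisonSpec],
    long_range: list[ComparisonSpec],
    include_long_range: bool,
) -> tuple[list[ComparisonSpec], list[str]]:
    """Scan order for first-DE bookkeeping.

    The time-point order is inferred from the adjacent chain; comparisons are
    sorted by the later time point, adjacent windows before long-range ones
    ending at the same point (i.e. earlier time point descending).
    """
    if not adjacent_order:
        raise ValidationError("adjacent_order must name at least one comparison")
    tp_order = [adjacent_order[0].earlier] + [c.later for c in adjacent_order]
    for c in adjacent_order:
        c.validate_order(tp_order)
    plan = list(adjacent_order) + (list(long_range) if include_long_range else [])
    for c in plan:
        c.validate_order(tp_order)
    plan.sort(key=lambda c: (tp_order.index(c.later), -tp_order.index(c.earlier)))
    return plan, tp_order


def _direction_map(results: dict[str, pd.DataFrame], cmp_id: str) -> dict[str, str]:
    if cmp_id not in results:
        raise ValidationError(f"missing differential result table for comparison {cmp_id!r}")
    df = results[cmp_id]
    return dict(zip(df["feature"], df["direction"]))


def classify_patterns(
    results: dict[str, pd.DataFrame],
    adjacent_order: list[ComparisonSpec],
    long_range: list[ComparisonSpec] | None = None,
    include_long_range: bool = True,
) -> list[TemporalPattern]:
    """Classify every miRNA appearing in any result table.

    ``results`` maps comparison id ("P04-P01") to a ``call_differential``
    table. Output order is by miRNA id, independent of input row order.
    """
    long_range = long_range or []
    plan, tp_order = _ordered_plan(adjacent_order, long_range, include_long_range)
    dir_maps = {c.id: _direction_map(results, c.id) for c in plan}

    mirnas = sorted(set().union(*(m.keys() for m in dir_maps.values())))
    patterns: list[TemporalPattern] = []
    for mirna in mirnas:
        calls = [(c, dir_maps[c.id].get(mirna, "ns")) for c in plan]
        supporting = tuple((c.id, d) for c, d in calls if d in ("up", "down"))

        first = next(((c, d) for c, d in calls if d in ("up", "down")), None)
        if first is None:
            patterns.append(
                TemporalPattern(mirna, None, None, False, False, False, supporting)
            )
            continue
        first_cmp, direction = first
        later_calls = [
            d
            for c, d in calls
            if tp_order.index(c.later) > tp_order.index(first_cmp.later)
            and tp_order.index(c.earlier) <= tp_order.index(first_cmp.earlier)
        ]
        non_monotone = any(d in ("up", "down") and d != direction for d in later_calls)
        persistent = (not non_monotone) and all(d == direction for d in later_calls)
        transient = (
            (not non_monotone)
            and len(later_calls) > 0
            and all(d == "ns" for d in later_calls)
        )
        patterns.append(
            TemporalPattern(
                mirna, first_cmp.id, direction, persistent, transient, non_monotone,
                supporting,
            )
        )
    return patterns


def pattern_summary(
    patterns: list[TemporalPattern], comparison_ids: list[str] | None = None
) -> pd.DataFrame:
    """Per-comparison counts: n_up / n_down among DE calls, and n_new —
    miRNAs whose first DE call lands in that comparison."""
    if comparison_ids is None:
        comparison_ids = sorted({cid for p in patterns for cid, _ in p.supporting})
    rows = []
    for cid in comparison_ids:
        n_up = sum(1 for p in patterns if (cid, "up") in p.supporting)
        n_down = sum(1 for p in patterns if (cid, "down") in p.supporting)
        n_new = sum(1 for p in patterns if p.first_comparison == cid)
        rows.append({"comparison": cid, "n_up": n_up, "n_down": n_down, "n_new": n_new})
    return pd.DataFrame(rows, columns=["comparison", "n_up", "n_down", "n_new"])


def patterns_to_frame(patterns: list[TemporalPattern]) -> pd.DataFrame:
    """Flat TSV-ready view of a pattern list."""
    rows = []
    for p in patterns:
        rows.append(
            {
                "mirna": p.mirna,
                "first_comparison": p.first_comparison or "",
                "direction": p.direction or "",
                "persistent": p.persistent,
                "transient": p.transient,
                "non_monotone": p.non_monotone,
                "supporting": ";".join(f"{c}:{d}" for c, d in p.supporting),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna", "first_comparison", "direction",
            "persistent", "transient", "non_monotone", "supporting",
        ],
    )
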