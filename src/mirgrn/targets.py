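"""Anti-correlation verification of predicted miRNA targets.

A predicted target of an *upregulated* miRNA counts as "verified" when the
gene itself is called *down* in the matched mRNA comparison, and vice versa
— the standard repression argument: a rising repressor should depress its
true targets. Verified sets then pass a minimum-size gate before gene-set
enrichment (sets that are too small produce unstable enrichment and are
flagged ineligible, never deleted).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .io_formats import (
    DifferentialGeneTable,
    PredictedTargetTable,
    ValidationError,
    normalize_mirna_id,
)

__all__ = [
    "VerifiedTargetSet",
    "verify_targets",
    "filter_min_targets",
    "verified_to_frames",
    "frames_to_verified",
]

DEFAULT_MIN_TARGETS = 40

_OPPOSITE = {"up": "down", "down": "up"}


@dataclass(frozen=True)
class VerifiedTargetSet:
    mirna: str
    direction: str  # miRNA direction (up/down) in `comparison`
    comparison: str
    verified: frozenset[str]
    no_prediction: bool = False
    eligible: bool | None = None  # set by filter_min_targets

    @property
    def n_verified(self) -> int:
        return len(self.verified)


def verify_targets(
    predicted: PredictedTargetTable,
    mrna: DifferentialGeneTable,
    mirna_calls: pd.DataFrame,
    comparison: str,
    mirnas: list[str] | None = None,
) -> list[VerifiedTargetSet]:
    """Intersect each DE miRNA's predicted targets with oppositely-regulated
    mRNAs of ``comparison``.

    ``mirna_calls`` is a ``call_differential`` table for the same comparison.
    By default every miRNA called up/down there is integrated; passing an
    explicit ``mirnas`` list that contains a non-DE miRNA is an error, since
    verification is defined only for DE miRNAs.
    """
    if comparison not in mrna.comparisons():
        raise ValidationError(f"comparison {comparison!r} absent from mRNA table")
    directions = dict(zip(mirna_calls["feature"], mirna_calls["direction"]))
    if mirnas is None:
        mirnas = [m for m, d in directions.items() if d in _OPPOSITE]
    opposite_genes = {
        d: mrna.genes_with_direction(comparison, _OPPOSITE[d]) for d in _OPPOSITE
    }

    out: list[VerifiedTargetSet] = []
    for mirna in mirnas:
        mirna = normalize_mirna_id(mirna)
        direction = directions.get(mirna, "ns")
        if direction not in _OPPOSITE:
            raise ValidationError(
                f"miRNA {mirna!r} is not differentially expressed in {comparison!r}; "
                "only DE miRNAs are integrated"
            )
        pred = predicted.predicted_for(mirna)
        if pred is None:
            out.append(
                VerifiedTargetSet(mirna, direction, comparison, frozenset(), True)
            )
            continue
        out.append(
            VerifiedTargetSet(
                mirna, direction, comparison, frozenset(pred & opposite_genes[direction])
            )
        )
    return sorted(out, key=lambda v: v.mirna)


def filter_min_targets(
    sets: list[VerifiedTargetSet], min_targets: int = DEFAULT_MIN_TARGETS
) -> list[VerifiedTargetSet]:
    """Flag each set eligible iff it holds at least ``min_targets`` verified
    genes. Nothing is removed."""
    if min_targets < 1:
        raise ValidationError("min_targets must be >= 1")
    return [replace(v, eligible=v.n_verified >= min_targets) for v in sets]


def verified_to_frames(sets: list[VerifiedTargetSet]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(long edge table, per-miRNA summary) TSV-ready views."""
    edges = [
        {"mirna": v.mirna, "comparison": v.comparison, "gene": g}
        for v in sets
        for g in sorted(v.verified)
    ]
    summary = [
        {
            "mirna": v.mirna,
            "comparison": v.comparison,
            "direction": v.direction,
            "n_verified": v.n_verified,
            "no_prediction": v.no_prediction,
            "eligible": v.eligible if v.eligible is not None else "",
        }
        for v in sets
    ]
    return (
        pd.DataFrame(edges, columns=["mirna", "comparison", "gene"]),
        pd.DataFrame(
            summary,
            columns=["mirna", "comparison", "direction", "n_verified", "no_prediction", "eligible"],
        ),
    )


def frames_to_verified(
    edges: pd.DataFrame, summary: pd.DataFrame
) -> list[VerifiedTargetSet]:
    """Inverse of :func:`verified_to_frames` (used by file-based callers)."""

    def _to_bool(x):
        if isinstance(x, str):
            if x == "":
                return None
            return x.strip().lower() == "true"
        if pd.isna(x):
            return None
        return bool(x)

    by_key: dict[tuple[str, str], set[str]] = {}
    for row in edges.itertuples():
        by_key.setdefault((row.mirna, row.comparison), set()).add(row.gene)
    out = []
    for row in summary.itertuples():
        key = (row.mirna, row.comparison)
        out.append(
            VerifiedTargetSet(
                mirna=row.mirna,
                direction=row.direction,
                comparison=row.comparison,
                verified=frozenset(by_key.get(key, set())),
                no_prediction=bool(_to_bool(row.no_prediction)),
                eligible=_to_bool(row.eligible),
            )
        )
    return out
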