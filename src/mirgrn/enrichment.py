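"""Over-representation analysis of verified target sets.

One-sided hypergeometric (Fisher exact) tail probabilities, with an optional
EASE variant — the conservative modification used by DAVID-style annotation
tools, which decrements the observed overlap by one before taking the tail
(a set supported by a single gene can then never score).

The default background ("universe") is the set of genes measured in the
differential mRNA input intersected with collection-annotated genes: genes
that could never have been observed or annotated cannot carry evidence for
or against a term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg
from .io_formats import GeneSetCollection, ValidationError, normalize_gene_id
from .targets import VerifiedTargetSet

__all__ = [
    "EnrichmentRecord",
    "hypergeometric_p",
    "ease_p",
    "enrich_mirna",
    "records_to_frame",
    "records_from_frame",
]

DEFAULT_ALPHA = 0.05


def _check_margins(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"inconsistent margins: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValidationError(f"overlap k={k} outside [0, min(K={K}, n={n})]")


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    k = observed overlap, K = annotated genes in the universe, n = query
    size, N = universe size. Exact survival function (log-space internals),
    stable for N up to at least 1e5.
    """
    _check_margins(k, K, n, N)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ease_p(k: int, K: int, n: int, N: int) -> float:
    """EASE score: the hypergeometric tail after decrementing the overlap."""
    _check_margins(k, K, n, N)
    return hypergeometric_p(max(k - 1, 0), K, n, N)


@dataclass(frozen=True)
class EnrichmentRecord:
    mirna: str
    set_id: str
    set_name: str
    category: str
    overlap: frozenset[str]
    K: int
    n: int
    N: int
    pvalue: float
    fdr: float  # BH across the collection; informational, not the call
    significant: bool

    @property
    def k(self) -> int:
        return len(self.overlap)


def enrich_mirna(
    vts: VerifiedTargetSet,
    collection: GeneSetCollection,
    universe: frozenset[str] | set[str],
    alpha: float = DEFAULT_ALPHA,
    mode: str = "fisher",
) -> list[EnrichmentRecord]:
    """Test one eligible verified target set against every gene set.

    Query genes outside the universe are dropped (their count is recorded on
    the module logger); gene sets with no member in the universe are
    skipped. Records are sorted by p ascending, ties by set id. The
    significance flag is the raw p <= alpha (a BH column is carried for
    transparency but does not drive the flag).
    """
    if vts.eligible is not True:
        raise ValidationError(
            f"verified set for {vts.mirna!r} is not eligible for enrichment; "
            "run filter_min_targets first"
        )
    if not universe:
        raise ValidationError("empty universe")
    if mode not in ("fisher", "ease"):
        raise ValidationError(f"unknown enrichment mode {mode!r}")
    universe = frozenset(normalize_gene_id(g) for g in universe)
    query = vts.verified & universe
    dropped = len(vts.verified) - len(query)
    if dropped:
        import logging

        logging.getLogger(__name__).info(
            "%s: %d verified gene(s) outside the universe dropped", vts.mirna, dropped
        )
    N = len(universe)
    n = len(query)
    pfun = hypergeometric_p if mode == "fisher" else ease_p

    raw: list[tuple] = []
    for gs in collection:
        members = gs.members & universe
        if not members:
            continue
        overlap = frozenset(query & members)
        p = pfun(len(overlap), len(members), n, N)
        raw.append((gs, overlap, len(members), p))
    if not raw:
        return []
    fdrs = benjamini_hochberg([r[3] for r in raw])
    records = [
        EnrichmentRecord(
            mirna=vts.mirna,
            set_id=gs.set_id,
            set_name=gs.name,
            category=gs.category,
            overlap=overlap,
            K=K,
            n=n,
            N=N,
            pvalue=p,
            fdr=float(f),
            significant=p <= alpha,
        )
        for (gs, overlap, K, p), f in zip(raw, fdrs)
    ]
    return sorted(records, key=lambda r: (r.pvalue, r.set_id))


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    rows = [
        {
            "mirna": r.mirna,
            "set_id": r.set_id,
            "set_name": r.set_name,
            "category": r.category,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "pvalue": r.pvalue,
            "fdr": r.fdr,
            "significant": r.significant,
            "overlap_genes": ",".join(sorted(r.overlap)),
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "mirna", "set_id", "set_name", "category", "k", "K", "n", "N",
            "pvalue", "fdr", "significant", "overlap_genes",
        ],
    )


def records_from_frame(df: pd.DataFrame) -> list[EnrichmentRecord]:
    """Inverse of :func:`records_to_frame` (used by file-based callers)."""

    def _to_bool(x):
        return x.strip().lower() == "true" if isinstance(x, str) else bool(x)

    out = []
    for row in df.itertuples():
        genes = str(row.overlap_genes) if not pd.isna(row.overlap_genes) else ""
        overlap = frozenset(g for g in genes.split(",") if g)
        out.append(
            EnrichmentRecord(
                mirna=row.mirna,
                set_id=row.set_id,
                set_name=row.set_name,
                category=row.category,
                overlap=overlap,
                K=int(row.K),
                n=int(row.n),
                N=int(row.N),
                pvalue=float(row.pvalue),
                fdr=float(row.fdr),
                significant=_to_bool(row.significant),
            )
        )
    return out
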