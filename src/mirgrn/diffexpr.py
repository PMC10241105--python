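"""Negative-binomial differential expression for pairwise time-point
comparisons.

This is a deliberately transparent small-RNA-seq testing chain:

* **median-of-ratios normalization** — per-sample size factors computed as
  the median ratio of counts to a geometric-mean pseudo-reference, using
  only features with positive counts in every sample;
* **method-of-moments dispersion** — per-feature NB overdispersion
  (variance = mu + phi * mu^2) pooled over within-group residuals of the
  normalized counts, mildly shrunk toward the across-feature mean;
* **plug-in NB Wald test** — two-group test on the log ratio of normalized
  group means, with a delta-method standard error using the plug-in
  dispersion;
* **Benjamini–Hochberg** step-up FDR over the features that survive the
  low-count filter;
* the field-standard call rule: a feature is "up" when its linear fold
  change (later/earlier) passes the threshold (default 1.8) at the FDR
  level (default 0.01), "down" when the reciprocal does.

Low-count filtering uses raw counts: a feature is kept only if its mean raw
count reaches ``min_mean`` (default 300) at at least one time point —
features below the threshold at *all* time points are excluded before
testing and before FDR correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix, SampleMetadata, ValidationError

__all__ = [
    "ComparisonSpec",
    "size_factors",
    "estimate_dispersions",
    "low_count_filter",
    "nb_wald_test",
    "benjamini_hochberg",
    "assign_direction",
    "call_differential",
]

DEFAULT_FC_THRESHOLD = 1.8
DEFAULT_FDR_ALPHA = 0.01
DEFAULT_MIN_MEAN = 300.0
DEFAULT_EPSILON = 0.5
DISPERSION_FLOOR = 1e-8


@dataclass(frozen=True)
class ComparisonSpec:
    """A later-vs-earlier time point contrast (fold change = later/earlier)."""

    later: str
    earlier: str

    def __post_init__(self) -> None:
        if self.later == self.earlier:
            raise ValidationError("comparison must contrast two distinct time points")

    @property
    def id(self) -> str:
        return f"{self.later}-{self.earlier}"

    def validate_order(self, time_points_order: list[str]) -> None:
        if self.later not in time_points_order or self.earlier not in time_points_order:
            raise ValidationError(f"comparison {self.id}: unknown time point")
        if time_points_order.index(self.later) <= time_points_order.index(self.earlier):
            raise ValidationError(
                f"comparison {self.id}: {self.later!r} does not come after {self.earlier!r}"
            )


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean reference.

    Only features with strictly positive counts in every sample contribute
    to the median. Raises when no such feature exists (advising total-count
    normalization as fallback — not applied silently).
    """
    df = counts.counts
    positive = (df > 0).all(axis=1)
    if not positive.any():
        raise ValidationError(
            "no feature has positive counts in every sample; median-of-ratios "
            "undefined — consider total-count (pseudo-reference) normalization"
        )
    logs = np.log(df.loc[positive].to_numpy(dtype=float))
    log_ref = logs.mean(axis=1, keepdims=True)  # geometric mean per feature
    factors = np.exp(np.median(logs - log_ref, axis=0))
    return pd.Series(factors, index=df.columns, name="size_factor")


def low_count_filter(
    counts: CountMatrix, metadata: SampleMetadata, min_mean: float = DEFAULT_MIN_MEAN
) -> frozenset[str]:
    """Features whose mean raw count reaches ``min_mean`` at >= 1 time point.

    A feature is excluded only when it is below the threshold at *all* time
    points.
    """
    df = counts.counts
    keep = pd.Series(False, index=df.index)
    for tp in metadata.time_points_order:
        samples = [s for s in metadata.samples_for(tp) if s in df.columns]
        if samples:
            keep |= df[samples].mean(axis=1) >= min_mean
    return frozenset(df.index[keep])


def estimate_dispersions(
    counts: CountMatrix,
    metadata: SampleMetadata,
    floor: float = DISPERSION_FLOOR,
    shrink_weight: float = 0.2,
    sf: pd.Series | None = None,
) -> pd.Series:
    """Per-feature NB dispersion by pooled within-group method of moments.

    For each group g with normalized mean m_g and variance v_g, the moment
    estimate solves v = m + phi m^2; per-group estimates are pooled with
    weights (n_g - 1) and then shrunk toward the across-feature mean of the
    positive raw estimates with weight ``shrink_weight``. Features whose
    within-group variance does not exceed the mean get the floor outright.
    """
    if not (0.0 <= shrink_weight < 1.0):
        raise ValidationError("shrink_weight must be in [0, 1)")
    groups = []
    for tp in metadata.time_points_order:
        samples = [s for s in metadata.samples_for(tp) if s in counts.counts.columns]
        if 0 < len(samples) < 2:
            raise ValidationError(f"time point {tp!r} has fewer than 2 samples")
        if samples:
            groups.append(samples)
    if not groups:
        raise ValidationError("metadata matches no sample in the count matrix")

    if sf is None:
        sf = size_factors(counts)
    y = counts.counts.div(sf, axis=1)

    num = np.zeros(len(y.index))
    den = np.zeros(len(y.index))
    for samples in groups:
        vals = y[samples].to_numpy(dtype=float)
        if vals.shape[1] < 2:
            continue
        m = vals.mean(axis=1)
        v = vals.var(axis=1, ddof=1)
        ok = m > 0
        w = vals.shape[1] - 1
        num[ok] += w * (v[ok] - m[ok]) / (m[ok] * m[ok])
        den[ok] += w
    with np.errstate(invalid="ignore"):
        raw = pd.Series(np.where(den > 0, num / np.maximum(den, 1), np.nan), index=y.index)

    positive = raw[raw > 0]
    trend = float(positive.mean()) if len(positive) else floor
    phi = raw.copy()
    phi[raw.isna() | (raw <= 0)] = floor
    mask = raw > 0
    phi[mask] = (1.0 - shrink_weight) * raw[mask] + shrink_weight * trend
    phi = phi.clip(lower=floor)
    phi.name = "dispersion"
    return phi


def nb_wald_test(
    counts: CountMatrix,
    metadata: SampleMetadata,
    cmp: ComparisonSpec,
    dispersions: pd.Series,
    epsilon: float = DEFAULT_EPSILON,
    sf: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald test on the log ratio of normalized group means.

    Returns a DataFrame indexed by feature with columns ``mean_<earlier>``,
    ``mean_<later>``, ``fc``, ``log2fc``, ``pvalue`` and ``degenerate``.
    The fold change adds the pseudo-count ``epsilon`` to both group means
    (guards the ratio at zeros); the Wald statistic uses the delta-method
    variance Var(log ybar_g) ~ (1/mu_g + phi) / n_g.
    """
    cmp.validate_order(metadata.time_points_order)
    df = counts.counts
    g_earlier = [s for s in metadata.samples_for(cmp.earlier) if s in df.columns]
    g_later = [s for s in metadata.samples_for(cmp.later) if s in df.columns]
    if not g_earlier or not g_later:
        raise ValidationError(f"comparison {cmp.id}: group without samples")

    if sf is None:
        sf = size_factors(counts)
    y = df.div(sf, axis=1)
    mu_e = y[g_earlier].mean(axis=1)
    mu_l = y[g_later].mean(axis=1)
    n_e, n_l = len(g_earlier), len(g_later)
    phi = dispersions.reindex(df.index).fillna(DISPERSION_FLOOR)

    fc = (mu_l + epsilon) / (mu_e + epsilon)
    log2fc = np.log2(fc)
    se2 = (1.0 / (mu_l + epsilon) + phi) / n_l + (1.0 / (mu_e + epsilon) + phi) / n_e
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.log(fc) / np.sqrt(se2)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))

    degenerate = (df[g_earlier].sum(axis=1) == 0) & (df[g_later].sum(axis=1) == 0)
    fc = fc.where(~degenerate, 1.0)
    log2fc = log2fc.where(~degenerate, 0.0)
    pvalue = pd.Series(pvalue, index=df.index).where(~degenerate, 1.0)
    # exact null (identical means) must give p = 1, not 1 - tiny rounding
    pvalue = pvalue.clip(upper=1.0)

    out = pd.DataFrame(
        {
            f"mean_{cmp.earlier}": mu_e,
            f"mean_{cmp.later}": mu_l,
            "fc": fc,
            "log2fc": log2fc,
            "pvalue": pvalue,
            "degenerate": degenerate,
        }
    )
    return out


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("benjamini_hochberg requires a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adj, 1.0)
    return out


def assign_direction(
    fc: float,
    fdr: float,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    fdr_alpha: float = DEFAULT_FDR_ALPHA,
) -> str:
    """Call rule: up iff FC >= threshold and FDR <= alpha; down iff
    1/FC >= threshold and FDR <= alpha; otherwise ns."""
    if not np.isfinite(fc) or not np.isfinite(fdr):
        return "ns"
    if fdr <= fdr_alpha:
        if fc >= fc_threshold:
            return "up"
        if fc > 0 and 1.0 / fc >= fc_threshold:
            return "down"
    return "ns"


def call_differential(
    counts: CountMatrix,
    metadata: SampleMetadata,
    cmp: ComparisonSpec,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    fdr_alpha: float = DEFAULT_FDR_ALPHA,
    min_mean: float = DEFAULT_MIN_MEAN,
    epsilon: float = DEFAULT_EPSILON,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Full differential call for one comparison.

    The low-count filter (raw counts, all time points) runs first; BH is
    applied over retained features only, and only retained features can be
    called up/down. Rows are sorted by FDR ascending, then |log2FC|
    descending, ties broken by feature id; filtered-out features trail with
    FDR = NaN and direction ns.

    Returns a DataFrame with columns feature, mean_<earlier>, mean_<later>,
    fc, log2fc, pvalue, fdr, direction, retained, degenerate.
    """
    if dispersions is None:
        dispersions = estimate_dispersions(counts, metadata)
    res = nb_wald_test(counts, metadata, cmp, dispersions, epsilon=epsilon)
    retained = low_count_filter(counts, metadata, min_mean=min_mean)
    res["retained"] = res.index.isin(retained)

    res["fdr"] = np.nan
    kept = res.index[res["retained"]]
    if len(kept):
        res.loc[kept, "fdr"] = benjamini_hochberg(res.loc[kept, "pvalue"].to_numpy())

    res["direction"] = [
        assign_direction(row.fc, row.fdr, fc_threshold, fdr_alpha) if row.retained else "ns"
        for row in res.itertuples()
    ]

    res.index.name = "feature"
    res = res.reset_index()
    res["_abs_lfc"] = res["log2fc"].abs()
    res = res.sort_values(
        by=["fdr", "_abs_lfc", "feature"],
        ascending=[True, False, True],
        na_position="last",
        kind="mergesort",
    ).drop(columns="_abs_lfc")
    return res.reset_index(drop=True)


def write_differential_results(res: pd.DataFrame, path) -> None:
    """Serialize a call_differential table as TSV (version comment + header)."""
    from ._version import __version__

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# mirgrn {__version__}\n")
        res.to_csv(fh, sep="\t", index=False, float_format="%.6g")
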