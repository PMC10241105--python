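"""ddCt relative quantification for qPCR miRNA panels.

Cq values (quantification cycles) are inputs; this module implements the
classical comparative-Ct chain with multi-reference normalization:

    dCt(sample, target)  = Cq_target - mean(Cq over reference assays)
    ddCt(group, target)  = mean dCt(group) - mean dCt(control group)
    fold change          = base^(-ddCt)          (base 2 by default)

Group differences are tested on the dCt values with a two-tailed two-sample
t-test (equal variance by default — plain Student's test — with a Welch
option). Spike-in assays are quality controls only: their across-sample Cq
spread can be validated, but they never enter normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._version import __version__
from .io_formats import ValidationError

__all__ = [
    "QpcrPlate",
    "read_qpcr_plate",
    "write_qpcr_plate",
    "delta_ct",
    "relative_expression",
    "ttest_delta_ct",
    "check_spike_ins",
]

_PLATE_COLUMNS = ["sample", "assay", "cq", "designation", "group"]
_DESIGNATIONS = {"target", "reference", "spike_in"}


@dataclass(frozen=True)
class QpcrPlate:
    """Long-format plate: one row per (sample, assay) with a Cq value.

    An undetermined Cq (no amplification) is stored as NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in _PLATE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"qPCR plate missing column(s): {missing}")
        df = df[_PLATE_COLUMNS]
        bad = ~df["designation"].isin(_DESIGNATIONS)
        if bad.any():
            raise ValidationError(
                f"unknown assay designation {df.loc[bad, 'designation'].iloc[0]!r}"
            )
        df["cq"] = pd.to_numeric(df["cq"], errors="coerce").astype(float)
        if (df["cq"].dropna() < 0).any():
            raise ValidationError("negative Cq value")
        if df.duplicated(subset=["sample", "assay"]).any():
            pair = df.loc[df.duplicated(subset=["sample", "assay"]), ["sample", "assay"]]
            raise ValidationError(f"duplicate (sample, assay) row: {pair.iloc[0].tolist()}")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    def assays(self, designation: str) -> list[str]:
        df = self.data
        return sorted(df.loc[df["designation"] == designation, "assay"].unique())

    def groups(self) -> list[str]:
        return list(pd.unique(self.data["group"]))


def read_qpcr_plate(path) -> QpcrPlate:
    """TSV columns: sample, assay, cq, designation, group. 'NA' or empty Cq
    marks an undetermined reaction."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty plate file") from None
    return QpcrPlate(df)


def write_qpcr_plate(plate: QpcrPlate, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# mirgrn {__version__}\n")
        plate.data.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def delta_ct(plate: QpcrPlate, reference_ids: list[str]) -> pd.DataFrame:
    """dCt per (sample, target assay) against the mean of the references.

    Every reference must have a finite Cq in every sample (a failed
    housekeeping reaction invalidates the whole sample, so it is an error
    naming the sample and assay); an undetermined *target* Cq yields a row
    flagged ``missing`` with NaN dCt.
    """
    if not reference_ids:
        raise ValidationError("at least one reference assay is required")
    df = plate.data
    refs = df[df["assay"].isin(reference_ids)]
    found = set(refs["assay"])
    absent = [r for r in reference_ids if r not in found]
    if absent:
        raise ValidationError(f"reference assay(s) not on plate: {absent}")
    bad = refs[refs["cq"].isna()]
    if len(bad):
        row = bad.iloc[0]
        raise ValidationError(
            f"undetermined reference Cq: sample {row['sample']!r}, assay {row['assay']!r}"
        )
    ref_mean = refs.groupby("sample")["cq"].mean()

    targets = df[df["designation"] == "target"]
    out = targets[["sample", "group", "assay", "cq"]].copy()
    out["ref_mean"] = out["sample"].map(ref_mean)
    if out["ref_mean"].isna().any():
        s = out.loc[out["ref_mean"].isna(), "sample"].iloc[0]
        raise ValidationError(f"sample {s!r} has no reference measurements")
    out["delta_ct"] = out["cq"] - out["ref_mean"]
    out["missing"] = out["cq"].isna()
    return out[["sample", "group", "assay", "delta_ct", "missing"]].reset_index(drop=True)


def relative_expression(
    dct: pd.DataFrame, control_group: str, base: float = 2.0
) -> pd.DataFrame:
    """ddCt fold changes per (assay, group) relative to ``control_group``.

    fold = base^(-ddCt) with ddCt = mean dCt(group) - mean dCt(control);
    the control group's own fold change is exactly 1 by construction.
    Returns assay, group, n, mean_dct, sd_dct, ddct, fold_change.
    """
    if control_group not in set(dct["group"]):
        raise ValidationError(f"control group {control_group!r} not present")
    d = dct[~dct["missing"]]
    rows = []
    for assay in sorted(d["assay"].unique()):
        sub = d[d["assay"] == assay]
        ctrl = sub.loc[sub["group"] == control_group, "delta_ct"]
        if ctrl.empty:
            raise ValidationError(f"assay {assay!r}: control group has no usable dCt")
        ctrl_mean = float(ctrl.mean())
        for group in pd.unique(sub["group"]):
            vals = sub.loc[sub["group"] == group, "delta_ct"]
            if vals.empty:
                raise ValidationError(f"assay {assay!r}: group {group!r} empty")
            ddct = 0.0 if group == control_group else float(vals.mean()) - ctrl_mean
            rows.append(
                {
                    "assay": assay,
                    "group": group,
                    "n": int(len(vals)),
                    "mean_dct": float(vals.mean()),
                    "sd_dct": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                    "ddct": ddct,
                    "fold_change": float(base ** (-ddct)),
                }
            )
    return pd.DataFrame(
        rows, columns=["assay", "group", "n", "mean_dct", "sd_dct", "ddct", "fold_change"]
    )


def ttest_delta_ct(a, b, equal_var: bool = True) -> float:
    """Two-sided two-sample t-test p-value on dCt values.

    Student's (pooled-variance) test by default; ``equal_var=False`` gives
    Welch. Both groups need >= 2 finite values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("t-test needs >= 2 finite dCt values per group")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(p):  # zero variance in both groups, identical means
        return 1.0
    return float(p)


def check_spike_ins(plate: QpcrPlate, max_sd: float = 1.0) -> pd.DataFrame:
    """Quality flag per spike-in assay: across-sample Cq SD vs ``max_sd``."""
    df = plate.data
    spikes = df[df["designation"] == "spike_in"]
    rows = []
    for assay in sorted(spikes["assay"].unique()):
        cq = spikes.loc[spikes["assay"] == assay, "cq"].dropna()
        sd = float(cq.std(ddof=1)) if len(cq) > 1 else np.nan
        rows.append({"assay": assay, "n": int(len(cq)), "sd": sd,
                     "ok": bool(np.isnan(sd) or sd <= max_sd)})
    return pd.DataFrame(rows, columns=["assay", "n", "sd", "ok"])
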