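"""Readers, writers and validated in-memory containers for every table the
pipeline touches.

All tabular formats are plain TSV (UTF-8, tab separated, ``.`` decimal, no
quoting); gene sets use the standard GMT exchange format.  Writers emit a
single leading comment line recording the tool version; readers skip any
line starting with ``#``, so a read -> write -> read round trip is the
identity for every container defined here.

Identifier matching convention: gene symbols are compared after stripping
whitespace and uppercasing (predicted-target tables and transcriptome tables
frequently disagree on capitalisation of mouse symbols); miRNA identifiers
are stripped but case-preserved, since miRNA nomenclature is case-significant
(``miR-150-5p`` vs ``MIR150``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

from ._version import __version__

__all__ = [
    "ValidationError",
    "CountMatrix",
    "SampleMetadata",
    "PredictedTargetTable",
    "GeneSet",
    "GeneSetCollection",
    "DifferentialGeneTable",
    "normalize_gene_id",
    "normalize_mirna_id",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_gmt",
    "write_gmt",
    "read_predicted_targets",
    "write_predicted_targets",
    "read_differential_genes",
    "write_differential_genes",
]

_HEADER_COMMENT = f"# mirgrn {__version__}\n"

VALID_CATEGORIES = ("GO_BP", "GO_CC", "KEGG")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant.

    Validation is all-or-nothing: a failure never yields a partially
    constructed container.
    """


def normalize_gene_id(gene: str) -> str:
    """Canonical form of a gene symbol: stripped and uppercased."""
    return str(gene).strip().upper()


def normalize_mirna_id(mirna: str) -> str:
    """Canonical form of a miRNA id: stripped, case preserved."""
    return str(mirna).strip()


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer feature x sample table.

    ``counts`` is a pandas DataFrame indexed by feature id with sample ids
    as columns, dtype int64.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[1] < 1:
            raise ValidationError("count matrix has no samples")
        dup_f = df.index[df.index.duplicated()].unique().tolist()
        if dup_f:
            raise ValidationError(f"duplicate feature id(s): {dup_f}")
        dup_s = df.columns[df.columns.duplicated()].unique().tolist()
        if dup_s:
            raise ValidationError(f"duplicate sample id(s): {dup_s}")
        for col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() | (vals < 0) | (vals % 1 != 0)
            if bad.any():
                row = df.index[bad.argmax()]
                raise ValidationError(
                    f"negative or non-integer count at feature {row!r}, sample {col!r}"
                )
        object.__setattr__(self, "counts", df.astype("int64"))

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class SampleMetadata:
    """Maps each sample to its time point, with an explicit time-point order."""

    time_point: dict[str, str]
    time_points_order: list[str]

    def __post_init__(self) -> None:
        order = list(self.time_points_order)
        if len(set(order)) != len(order):
            raise ValidationError("time_points_order contains duplicates")
        unknown = {tp for tp in self.time_point.values() if tp not in order}
        if unknown:
            raise ValidationError(
                f"sample time point(s) {sorted(unknown)} missing from time_points_order"
            )
        object.__setattr__(self, "time_points_order", order)

    def samples_for(self, time_point: str) -> list[str]:
        return [s for s, tp in self.time_point.items() if tp == time_point]

    def time_index(self, time_point: str) -> int:
        return self.time_points_order.index(time_point)


_NO_PREDICTION = object()


@dataclass(frozen=True)
class PredictedTargetTable:
    """miRNA -> predicted target gene sets (e.g. a miRWalk export).

    A miRNA absent from the table is distinct from one with an empty set:
    :meth:`predicted_for` returns ``None`` for "no prediction available".
    """

    targets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for mirna, genes in self.targets.items():
            m = normalize_mirna_id(mirna)
            gs = frozenset(normalize_gene_id(g) for g in genes)
            if any(not g for g in gs):
                raise ValidationError(f"empty gene id in predictions for {m!r}")
            clean[m] = gs
        object.__setattr__(self, "targets", clean)

    def predicted_for(self, mirna: str) -> frozenset[str] | None:
        """Predicted gene set, or None when no prediction is available."""
        return self.targets.get(normalize_mirna_id(mirna))

    def __contains__(self, mirna: str) -> bool:
        return normalize_mirna_id(mirna) in self.targets


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    category: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.category not in VALID_CATEGORIES:
            raise ValidationError(
                f"gene set {self.set_id!r}: category {self.category!r} not in {VALID_CATEGORIES}"
            )
        if not self.members:
            raise ValidationError(f"gene set {self.set_id!r} is empty")
        object.__setattr__(
            self, "members", frozenset(normalize_gene_id(g) for g in self.members)
        )


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of gene sets with unique ids."""

    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        dups = sorted({i for i in ids if ids.count(i) > 1})
        if dups:
            raise ValidationError(f"duplicate gene set id(s): {dups}")
        object.__setattr__(self, "sets", tuple(self.sets))

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def by_id(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)

    def annotated_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.members
        return frozenset(out)

    @staticmethod
    def merge(*collections: "GeneSetCollection") -> "GeneSetCollection":
        sets: list[GeneSet] = []
        for c in collections:
            sets.extend(c.sets)
        return GeneSetCollection(tuple(sets))


_DIFF_COLUMNS = ["gene", "comparison", "direction", "fold_change", "fdr"]


@dataclass(frozen=True)
class DifferentialGeneTable:
    """Differential mRNA calls: one row per (gene, comparison).

    Columns: gene, comparison, direction (up/down), fold_change (>= 0,
    linear, later/earlier), fdr in [0, 1].
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in _DIFF_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"differential gene table missing column(s): {missing}")
        df = df[_DIFF_COLUMNS]
        df["gene"] = df["gene"].map(normalize_gene_id)
        dup = df.duplicated(subset=["gene", "comparison"])
        if dup.any():
            pair = df.loc[dup, ["gene", "comparison"]].iloc[0].tolist()
            raise ValidationError(f"duplicate (gene, comparison) row: {pair}")
        bad_dir = ~df["direction"].isin(["up", "down"])
        if bad_dir.any():
            raise ValidationError(
                f"invalid direction {df.loc[bad_dir, 'direction'].iloc[0]!r} (must be up/down)"
            )
        if (df["fold_change"] < 0).any():
            raise ValidationError("negative fold change in differential gene table")
        if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
            raise ValidationError("FDR outside [0, 1] in differential gene table")
        object.__setattr__(self, "table", df.reset_index(drop=True))

    def genes_with_direction(self, comparison: str, direction: str) -> frozenset[str]:
        df = self.table
        mask = (df["comparison"] == comparison) & (df["direction"] == direction)
        return frozenset(df.loc[mask, "gene"])

    def comparisons(self) -> list[str]:
        return sorted(self.table["comparison"].unique())

    def measured_genes(self) -> frozenset[str]:
        return frozenset(self.table["gene"])


# ---------------------------------------------------------------------------
# TSV / GMT I/O
# ---------------------------------------------------------------------------


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no samples (file empty)") from None


def read_count_matrix(path) -> CountMatrix:
    """Read a feature x sample TSV: header row of sample ids, first column
    feature ids."""
    # pandas mangles duplicate header names (S1, S1.1), so check the raw header
    with open(path, encoding="utf-8") as fh:
        header = next((ln for ln in fh if ln.strip() and not ln.startswith("#")), None)
    if header is not None:
        cols = header.rstrip("\n").split("\t")[1:]
        dups = sorted({c for c in cols if cols.count(c) > 1})
        if dups:
            raise ValidationError(f"duplicate sample id(s): {dups}")
    df = _read_tsv(path, index_col=0)
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no samples")
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    return CountMatrix(df)


def write_count_matrix(cm: CountMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER_COMMENT)
        cm.counts.to_csv(fh, sep="\t", index_label="feature")


def read_sample_metadata(path) -> SampleMetadata:
    """TSV with columns sample, time_point, order (order = integer position
    of the time point in the time course)."""
    df = _read_tsv(path)
    for col in ("sample", "time_point", "order"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValidationError(f"{path}: duplicate sample {dup!r}")
    order_map = (
        df[["time_point", "order"]]
        .drop_duplicates()
        .assign(order=lambda d: d["order"].astype(int))
        .sort_values("order")
    )
    return SampleMetadata(
        time_point=dict(zip(df["sample"], df["time_point"])),
        time_points_order=list(order_map["time_point"]),
    )


def write_sample_metadata(md: SampleMetadata, path) -> None:
    rows = [
        {"sample": s, "time_point": tp, "order": md.time_index(tp)}
        for s, tp in md.time_point.items()
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER_COMMENT)
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_gmt(path, category: str = "GO_BP") -> GeneSetCollection:
    """Read a GMT file: ``set_id TAB description TAB gene1 TAB gene2 ...``.

    Duplicate genes within a line are deduplicated; blank lines are skipped;
    a line with fewer than three fields (i.e. no genes) is an error.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            genes = [g for g in fields[2:] if g.strip()]
            if len(fields) < 3 or not genes:
                raise ValidationError(f"{path}:{lineno}: GMT line has no genes")
            sets.append(
                GeneSet(
                    set_id=fields[0].strip(),
                    name=fields[1].strip(),
                    category=category,
                    members=frozenset(genes),
                )
            )
    return GeneSetCollection(tuple(sets))


def write_gmt(collection: GeneSetCollection, path) -> None:
    # GMT has no comment convention in some tools, so no version line here;
    # read_gmt skips '#' lines anyway, but plain GMT maximises interoperability.
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.members)]) + "\n")


def read_predicted_targets(path, header: bool = True) -> PredictedTargetTable:
    """Read a two-column (miRNA, gene) TSV into a per-miRNA target mapping."""
    targets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [
            (i, ln.rstrip("\n"))
            for i, ln in enumerate(fh, start=1)
            if ln.strip() and not ln.startswith("#")
        ]
    if header and lines:
        lines = lines[1:]
    for lineno, line in lines:
        fields = line.split("\t")
        if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
            raise ValidationError(f"{path}:{lineno}: malformed predicted-target row")
        m = normalize_mirna_id(fields[0])
        targets.setdefault(m, set()).add(normalize_gene_id(fields[1]))
    return PredictedTargetTable({m: frozenset(g) for m, g in targets.items()})


def write_predicted_targets(table: PredictedTargetTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER_COMMENT)
        fh.write("mirna\tgene\n")
        for mirna in sorted(table.targets):
            for gene in sorted(table.targets[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


def read_differential_genes(path) -> DifferentialGeneTable:
    df = _read_tsv(path)
    df["fold_change"] = df["fold_change"].astype(float)
    df["fdr"] = df["fdr"].astype(float)
    return DifferentialGeneTable(df)


def write_differential_genes(table: DifferentialGeneTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER_COMMENT)
        df = table.table.sort_values(["comparison", "gene"]).reset_index(drop=True)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
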